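"""Surrogate nominal parameter set.

No experimentally fitted nominal vector is shipped with the model; the
values below are order-of-magnitude mass-action defaults on the minute time
scale (concentrations in a.u., pool totals of order one) chosen so that the
model's qualitative behavior matches the study system: downstream outputs
are zero at the unstimulated steady state, Erkp shows a graded dose
response over the 5.5-150 ug/mL ligand range, orthogonal inhibitor
suppresses signaling under the AQL scenario, and the MAPK cascade runs
closer to saturation than the IKK/NF-kB branch (so NF-kB tracks upstream
signal reductions more faithfully than Erkp does).  Alternative vectors are
loaded from config files; see :meth:`bcrsignal.model.ParameterSet.load`.
"""

from .model import POOL_TOTALS, ParameterSet

NOMINAL_VALUES: dict[str, float] = {
    # --- BCR dynamics (group 1)
    "r_association": 1.0,        # per (a.u. ligand) per min
    "r_disassociation": 0.1,     # per min
    "r_recycling": 0.05,
    "r_internalization": 0.2,
    "r_degradation": 0.02,
    "r_bcrp1_phos1": 1.0,
    "r_bcrp1_phos2": 1.0,
    "r_bcrp1_dephos": 0.2,
    "r_bcrp1_dephos_bg": 0.05,
    "r_bcrp2_phos": 1.0,
    "r_bcrp2_dephos": 0.2,
    "r_bcrp2_dephos_bg": 0.05,
    "r_clathrin_loc": 0.3,
    "r_clathrin_deloc": 0.3,
    # --- Syk activation (group 2)
    "r_syk_bcr_binding1": 1.0,
    "r_syk_bcr_binding2": 1.0,
    "r_syk_bcr_unbinding": 0.1,
    "r_syk342_via_lyn": 1.0,
    "r_syk342_auto": 0.3,
    "r_syk342_dephos": 0.3,
    "r_syk342_dephos_bg": 0.1,
    "r_syk317_phos1": 0.05,
    "r_syk317_phos2": 0.05,
    "r_syk317_dephos": 0.05,
    "r_oi_association": 0.05,    # per (a.u. OI) per min: gradual, partial inhibition at 1 uM
    # --- Lyn and regulatory enzymes (group 3)
    "r_lyn_dephos": 0.5,
    "r_lyn_phos": 1.0,
    "r_lynstar_phos": 0.2,
    "r_lynstar_auto": 1.0,
    "r_lyn_deauto_cd45": 0.2,
    "r_lyn_deauto_shp1": 0.5,
    "r_lyn_deauto_bg": 0.05,
    "r_shp1_act": 0.5,
    "r_shp1_inact": 0.5,
    "r_csk_act": 1.0,
    "r_csk_dis": 0.5,
    "r_cbp_phos": 0.5,
    "r_cbp_dephos": 0.5,
    # --- medial scaffold (group 4)
    "r_blnk_phos": 2.0,
    "r_blnk_dephos": 0.3,
    "r_blnk_dephos_bg": 0.1,
    "r_btk_blnk_binding": 1.0,
    "r_btk_blnk_unbinding": 0.1,
    "r_btk_phos_syk": 1.0,
    "r_btk_phos_lyn": 0.5,
    "r_btk_dephos": 0.2,
    "r_plc_blnk_binding": 1.0,
    "r_plc_blnk_unbinding": 0.1,
    # --- PLC2g / DAG (group 5)
    "r_plc_phos_syk": 2.0,
    "r_plc_phos_btk": 1.0,
    "r_plc_dephos": 0.2,
    "r_dag_production": 2.0,
    "r_dag_decay": 0.5,
    # --- PKC and MAPK cascade (group 6): activation strong relative to
    # deactivation, so the cascade saturates and compresses upstream changes
    "r_pkc_act": 0.5,
    "r_pkc_deact": 0.5,
    "r_sos_blnk_binding": 1.0,
    "r_sos_blnk_unbinding": 0.1,
    "r_ras_act": 0.8,
    "r_ras_deact": 0.2,
    "r_raf_act": 0.8,
    "r_raf_deact": 0.2,
    "r_mek_phos": 0.8,
    "r_mek_dephos": 0.2,
    "r_erk_phos": 1.5,
    "r_erk_dephos": 0.2,
    # --- IKK / IkB / NF-kB (group 7): kept in the linear response regime
    "r_ikk_act": 1.0,
    "r_ikk_deact": 0.5,
    "r_ikb_phos": 1.0,
    "r_ikbp_deg": 1.0,
    "r_ikb_syn": 0.5,
    "r_ikb_nfkb_assoc": 5.0,
    # --- constant input and unit conversions
    "CD45_level": 1.0,      # a.u.; constant in this model version
    "ligand_scale": 0.01,   # a.u. per ug/mL (150 ug/mL -> 1.5 a.u., near saturation)
    "oi_scale": 1.0,        # a.u. per uM
}
NOMINAL_VALUES.update({t: 1.0 for t in POOL_TOTALS})

#: the 12 kinetic rates retained by the sensitivity screen in the study regime
SENSITIVE_PARAMETERS = (
    "rw0_kf",
    "rw7_kr", "rw9_kf",
    "rw15_kf", "rw16_kf", "rw16_kr",
    "r12s_kf", "r13_kf", "r13_kr",
    "r18_kf", "r19_kf",
    "r38_kf",
)


def nominal_parameters() -> ParameterSet:
    """The surrogate nominal :class:`~bcrsignal.model.ParameterSet`."""
    return ParameterSet(dict(NOMINAL_VALUES), provenance=("surrogate nominal",))
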