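"""Independent oracles for the test suite.

``reference_rhs`` is a straight hand transcription of the model equations,
written variable by variable (no reaction ledger, no stoichiometry matrix),
so that agreement with the ledger-assembled right-hand side is a meaningful
cross-check.  ``sobol_double_loop`` is a brute-force nested Monte-Carlo
estimate of first-order Sobol indices, independent of the pick-freeze
estimator it is used to validate.
"""

import numpy as np

from bcrsignal.model import STATE_INDEX


def reference_rhs(y, p, ligand=0.0, oi=0.0, scenario="WT"):
    """Hand-coded transcription of all 32 balance equations (a.u./min)."""
    s = {name: y[i] for name, i in STATE_INDEX.items()}
    g = p.get
    CD45 = g("CD45_level")

    # conservation-implied free pools, clamped at zero
    free = lambda total, used: max(total - used, 0.0)
    Syk = free(g("Syk_total"), s["Sykb"] + s["Syk342"] + s["Syk317"] + s["Syk_inh"])
    Lyn = free(g("Lyn_total"), s["Lyndp"] + s["LynStar"])
    SHP1 = free(g("SHP1_total"), s["SHP1Star"])
    Csk = free(g("Csk_total"), s["CskStar"])
    Cbp = free(g("Cbp_total"), s["Cbpp"])
    Clathrin = free(g("Clathrin_total"), s["Clathrin_local"])
    BLNK = free(g("BLNK_total"), s["BLNKp"])
    BTK = free(g("BTK_total"), s["BTKb"] + s["BTKp"])
    PLC = free(g("PLC2g_total"), s["PLC2gb"] + s["PLC2gp"])
    PIP2 = free(g("PIP2_total"), s["DAG"])
    PKC = free(g("PKC_total"), s["PKCStar"])
    SOS = free(g("SOS_total"), s["SOSb"])
    Ras = free(g("Ras_total"), s["RasStar"])
    Raf = free(g("Raf_total"), s["RafStar"])
    MEK = free(g("MEK_total"), s["MEKp"])
    Erk = free(g("Erk_total"), s["Erkp1"] + s["Erkp2"])
    IKK = free(g("IKK_total"), s["IKKStar"])
    complex_ = free(g("NFkB_total"), s["NFkB"])  # NF-kB:IkB complex

    oi_on = 1.0 if scenario == "AQL" else 0.0
    d = {}

    # --- BCR activation
    d["BCRfree"] = (g("r_recycling") * s["BCRi"]
                    - g("r_internalization") * s["Clathrin_local"] * s["BCRfree"]
                    + g("r_disassociation") * s["BCRb"]
                    - g("r_association") * ligand * s["BCRfree"])
    itam1_phos = (g("r_bcrp1_phos1") * s["LynStar"]
                  + g("r_bcrp1_phos2") * s["Syk342"]) * s["BCRb"]
    itam1_dephos = (g("r_bcrp1_dephos") * s["SHP1Star"]
                    + g("r_bcrp1_dephos_bg")) * s["BCRp1"]
    itam2_dephos = (g("r_bcrp2_dephos") * s["SHP1Star"]
                    + g("r_bcrp2_dephos_bg")) * s["BCRp2"]
    d["BCRb"] = (g("r_association") * ligand * s["BCRfree"]
                 - g("r_disassociation") * s["BCRb"] + itam1_dephos - itam1_phos)
    d["BCRp1"] = (itam1_phos - itam1_dephos + itam2_dephos
                  - (g("r_bcrp2_phos") * s["Syk342"]
                     + g("r_syk_bcr_binding1") * Syk) * s["BCRp1"])
    d["BCRp2"] = (g("r_bcrp2_phos") * s["Syk342"] * s["BCRp1"] - itam2_dephos
                  + g("r_syk_bcr_unbinding") * s["Sykb"]
                  - g("r_syk_bcr_binding2") * Syk * s["BCRp2"])
    d["BCRi"] = (g("r_internalization") * s["Clathrin_local"] * s["BCRfree"]
                 - g("r_recycling") * s["BCRi"] - g("r_degradation") * s["BCRi"])
    d["Clathrin_local"] = (g("r_clathrin_loc") * s["Syk342"] * Clathrin
                           - g("r_clathrin_deloc") * s["Clathrin_local"])

    # --- Syk activation
    y342_phos = (g("r_syk342_via_lyn") * s["LynStar"]
                 + g("r_syk342_auto") * s["Syk342"]) * s["Sykb"]
    y342_dephos = (g("r_syk342_dephos") * s["SHP1Star"]
                   + g("r_syk342_dephos_bg")) * s["Syk342"]
    d["Sykb"] = ((g("r_syk_bcr_binding1") * s["BCRp1"]
                  + g("r_syk_bcr_binding2") * s["BCRp2"]) * Syk
                 - g("r_syk_bcr_unbinding") * s["Sykb"]
                 + y342_dephos - y342_phos
                 + g("r_syk317_dephos") * s["Syk317"]
                 - g("r_syk317_phos1") * s["LynStar"] * s["Sykb"]
                 - oi_on * g("r_oi_association") * oi * s["Sykb"])
    d["Syk342"] = (y342_phos - y342_dephos
                   + g("r_syk317_dephos") * s["Syk317"]
                   - g("r_syk317_phos2") * s["LynStar"] * s["Syk342"]
                   - oi_on * g("r_oi_association") * oi * s["Syk342"])
    d["Syk317"] = ((g("r_syk317_phos1") * s["Sykb"]
                    + g("r_syk317_phos2") * s["Syk342"]) * s["LynStar"]
                   - 2.0 * g("r_syk317_dephos") * s["Syk317"]
                   - oi_on * g("r_oi_association") * oi * s["Syk317"])
    d["Syk_inh"] = oi_on * g("r_oi_association") * oi * (
        s["Sykb"] + s["Syk342"] + s["Syk317"] + Syk)

    # --- Lyn activation
    lyn_auto = (g("r_lynstar_phos") + g("r_lynstar_auto") * s["LynStar"]) * s["Lyndp"]
    lyn_deauto = (g("r_lyn_deauto_cd45") * CD45
                  + g("r_lyn_deauto_shp1") * s["SHP1Star"]
                  + g("r_lyn_deauto_bg")) * s["LynStar"]
    d["Lyndp"] = (g("r_lyn_dephos") * CD45 * Lyn
                  - g("r_lyn_phos") * s["CskStar"] * s["Lyndp"]
                  + lyn_deauto - lyn_auto)
    d["LynStar"] = lyn_auto - lyn_deauto

    # --- regulatory enzymes
    d["SHP1Star"] = (g("r_shp1_act") * s["Lyndp"] * SHP1
                     - g("r_shp1_inact") * s["SHP1Star"])
    d["CskStar"] = g("r_csk_act") * s["Cbpp"] * Csk - g("r_csk_dis") * s["CskStar"]
    d["Cbpp"] = (g("r_cbp_phos") * s["Lyndp"] * Cbp
                 - g("r_cbp_dephos") * CD45 * s["Cbpp"])

    # --- medial scaffold
    d["BLNKp"] = (g("r_blnk_phos") * s["Syk342"] * BLNK
                  - (g("r_blnk_dephos") * s["SHP1Star"]
                     + g("r_blnk_dephos_bg")) * s["BLNKp"])
    btk_phos = (g("r_btk_phos_syk") * s["Syk342"]
                + g("r_btk_phos_lyn") * s["LynStar"]) * s["BTKb"]
    d["BTKb"] = (g("r_btk_blnk_binding") * BTK * s["BLNKp"]
                 - g("r_btk_blnk_unbinding") * s["BTKb"]
                 - btk_phos + g("r_btk_dephos") * s["BTKp"])
    d["BTKp"] = btk_phos - g("r_btk_dephos") * s["BTKp"]
    plc_phos = (g("r_plc_phos_syk") * s["Syk342"]
                + g("r_plc_phos_btk") * s["BTKp"]) * s["PLC2gb"]
    d["PLC2gb"] = (g("r_plc_blnk_binding") * PLC * s["BLNKp"]
                   - g("r_plc_blnk_unbinding") * s["PLC2gb"]
                   - plc_phos + g("r_plc_dephos") * s["PLC2gp"])
    d["PLC2gp"] = plc_phos - g("r_plc_dephos") * s["PLC2gp"]

    # --- DAG / PKC / IKK / IkB / NF-kB
    d["DAG"] = (g("r_dag_production") * s["PLC2gp"] * PIP2
                - g("r_dag_decay") * s["DAG"])
    d["PKCStar"] = (g("r_pkc_act") * s["DAG"] * PKC
                    - g("r_pkc_deact") * s["PKCStar"])
    d["IKKStar"] = (g("r_ikk_act") * s["PKCStar"] * IKK
                    - g("r_ikk_deact") * s["IKKStar"])
    d["IkB"] = (g("r_ikb_syn") * s["NFkB"]
                - g("r_ikb_phos") * s["IKKStar"] * s["IkB"]
                - g("r_ikb_nfkb_assoc") * s["IkB"] * s["NFkB"])
    d["IkBp"] = (g("r_ikb_phos") * s["IKKStar"] * (complex_ + s["IkB"])
                 - g("r_ikbp_deg") * s["IkBp"])
    d["NFkB"] = (g("r_ikb_phos") * s["IKKStar"] * complex_
                 - g("r_ikb_nfkb_assoc") * s["IkB"] * s["NFkB"])

    # --- MAPK cascade
    d["SOSb"] = (g("r_sos_blnk_binding") * SOS * s["BLNKp"]
                 - g("r_sos_blnk_unbinding") * s["SOSb"])
    d["RasStar"] = (g("r_ras_act") * s["SOSb"] * Ras
                    - g("r_ras_deact") * s["RasStar"])
    d["RafStar"] = (g("r_raf_act") * s["RasStar"] * Raf
                    - g("r_raf_deact") * s["RafStar"])
    d["MEKp"] = (g("r_mek_phos") * s["RafStar"] * MEK
                 - g("r_mek_dephos") * s["MEKp"])
    d["Erkp1"] = (g("r_erk_phos") * s["MEKp"] * Erk
                  - g("r_erk_phos") * s["MEKp"] * s["Erkp1"]
                  + g("r_erk_dephos") * s["Erkp2"]
                  - g("r_erk_dephos") * s["Erkp1"])
    d["Erkp2"] = (g("r_erk_phos") * s["MEKp"] * s["Erkp1"]
                  - g("r_erk_dephos") * s["Erkp2"])

    out = np.zeros(len(STATE_INDEX))
    for name, i in STATE_INDEX.items():
        out[i] = d[name]
    return out


def sobol_double_loop(f, names, log_ranges, n_outer, n_inner, seed=0):
    """Brute-force first-order Sobol indices Var(E[Y|p_k])/Var(Y).

    For each parameter, the conditioning value runs over ``n_outer``
    stratum midpoints of its range; at each, the conditional mean is taken
    over one shared joint sample of size ``n_inner``.  Sharing the inner
    sample makes the common part of the inner-loop noise cancel in the
    outer variance, so the oracle converges at the stated budget.
    """
    rng = np.random.default_rng(seed)
    names = list(names)
    lo = np.array([log_ranges[n][0] for n in names])
    hi = np.array([log_ranges[n][1] for n in names])
    d = len(names)
    inner = rng.uniform(lo, hi, size=(n_inner, d))

    def evaluate(logs):
        return f({n: 10.0 ** v for n, v in zip(names, logs)})

    cond_means = np.empty((d, n_outer))
    for k in range(d):
        grid = lo[k] + (hi[k] - lo[k]) * (np.arange(n_outer) + 0.5) / n_outer
        for j, pk in enumerate(grid):
            logs = inner.copy()
            logs[:, k] = pk
            cond_means[k, j] = np.mean([evaluate(row) for row in logs])
    # total variance from a fresh independent joint sample
    fresh = rng.uniform(lo, hi, size=(n_outer * n_inner, d))
    var_y = np.var([evaluate(row) for row in fresh])
    if var_y == 0:
        return np.zeros(d)
    return np.var(cond_means, axis=1) / var_y
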