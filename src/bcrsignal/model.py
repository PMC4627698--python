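"""Mass-action reaction network for B-cell-receptor (BCR) signaling.

The model tracks 32 state variables: 20 early-signaling states (receptor
engagement and internalization, the four modified forms of the kinase Syk,
Lyn activation, the SHP1/Csk/Cbp regulatory loop, and the medial
BLNK/BTK/PLC2gamma scaffold) and 12 downstream states (DAG, the PKC/IKK/IkB/
NF-kB branch and the SOS/Ras/Raf/MEK/Erk MAPK cascade).  All kinetics are
mass action; free (unmodified) protein pools are eliminated by conservation
laws, so e.g. free Syk is ``Syk_total - Sykb - Syk342 - Syk317 - Syk_inh``.

Two scenarios are supported.  ``"WT"`` is wild-type Syk.  ``"AQL"`` is the
analog-sensitive Syk mutant, which additionally binds an orthogonal
inhibitor (OI): four irreversible association reactions, one per form of
Syk, move kinase into the inactive ``Syk_inh`` state.

Concentrations are in arbitrary units (a.u.); time is in minutes.  Ligand
and OI doses carry physical units (ug/mL, uM) only at the simulation
surface, where they are converted by the ``ligand_scale`` / ``oi_scale``
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError, IntegrityError, ValidationError

# --------------------------------------------------------------------------- states

EARLY_STATES = (
    "BCRfree", "BCRb", "BCRp1", "BCRp2", "BCRi", "Clathrin_local",
    "Sykb", "Syk342", "Syk317", "Syk_inh",
    "Lyndp", "LynStar", "SHP1Star", "CskStar", "Cbpp",
    "BLNKp", "BTKb", "BTKp", "PLC2gb", "PLC2gp",
)
DOWNSTREAM_STATES = (
    "DAG", "PKCStar", "SOSb", "RasStar", "RafStar", "MEKp",
    "Erkp1", "Erkp2", "IKKStar", "IkB", "IkBp", "NFkB",
)
STATE_NAMES: tuple[str, ...] = EARLY_STATES + DOWNSTREAM_STATES
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)  # 32

# Free pools implied by conservation: name -> (total parameter, explicit members).
# ``NFkB_IkB_complex`` is the NF-kB:IkB complex; all NF-kB not free is complexed.
IMPLIED_SPECIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "Syk_free": ("Syk_total", ("Sykb", "Syk342", "Syk317", "Syk_inh")),
    "Lyn_free": ("Lyn_total", ("Lyndp", "LynStar")),
    "SHP1_free": ("SHP1_total", ("SHP1Star",)),
    "Csk_free": ("Csk_total", ("CskStar",)),
    "Cbp_free": ("Cbp_total", ("Cbpp",)),
    "Clathrin_free": ("Clathrin_total", ("Clathrin_local",)),
    "BLNK_free": ("BLNK_total", ("BLNKp",)),
    "BTK_free": ("BTK_total", ("BTKb", "BTKp")),
    "PLC2g_free": ("PLC2g_total", ("PLC2gb", "PLC2gp")),
    "PIP2_free": ("PIP2_total", ("DAG",)),
    "PKC_free": ("PKC_total", ("PKCStar",)),
    "SOS_free": ("SOS_total", ("SOSb",)),
    "Ras_free": ("Ras_total", ("RasStar",)),
    "Raf_free": ("Raf_total", ("RafStar",)),
    "MEK_free": ("MEK_total", ("MEKp",)),
    "Erk_free": ("Erk_total", ("Erkp1", "Erkp2")),
    "IKK_free": ("IKK_total", ("IKKStar",)),
    "NFkB_IkB_complex": ("NFkB_total", ("NFkB",)),
}
IMPLIED_NAMES = tuple(IMPLIED_SPECIES)

# External inputs available as rate-law factors.
INPUT_NAMES = ("ONE", "LIGAND", "OI", "CD45")

# --------------------------------------------------------------------------- parameters

#: kinetic rate constant -> parameter group (natural reaction-subsystem divisions)
RATE_GROUPS: dict[str, int] = {
    # group 1 - BCR dynamics
    "r_association": 1, "r_disassociation": 1,
    "r_recycling": 1, "r_internalization": 1, "r_degradation": 1,
    "r_bcrp1_phos1": 1, "r_bcrp1_phos2": 1,
    "r_bcrp1_dephos": 1, "r_bcrp1_dephos_bg": 1,
    "r_bcrp2_phos": 1, "r_bcrp2_dephos": 1, "r_bcrp2_dephos_bg": 1,
    "r_clathrin_loc": 1, "r_clathrin_deloc": 1,
    # group 2 - Syk activation
    "r_syk_bcr_binding1": 2, "r_syk_bcr_binding2": 2, "r_syk_bcr_unbinding": 2,
    "r_syk342_via_lyn": 2, "r_syk342_auto": 2,
    "r_syk342_dephos": 2, "r_syk342_dephos_bg": 2,
    "r_syk317_phos1": 2, "r_syk317_phos2": 2, "r_syk317_dephos": 2,
    "r_oi_association": 2,
    # group 3 - Lyn and regulatory enzymes (SHP1/Csk/Cbp, driven by constant CD45)
    "r_lyn_dephos": 3, "r_lyn_phos": 3,
    "r_lynstar_phos": 3, "r_lynstar_auto": 3,
    "r_lyn_deauto_cd45": 3, "r_lyn_deauto_shp1": 3, "r_lyn_deauto_bg": 3,
    "r_shp1_act": 3, "r_shp1_inact": 3,
    "r_csk_act": 3, "r_csk_dis": 3,
    "r_cbp_phos": 3, "r_cbp_dephos": 3,
    # group 4 - medial scaffolding (BLNK phosphorylation, BTK/PLC2g binding)
    "r_blnk_phos": 4, "r_blnk_dephos": 4, "r_blnk_dephos_bg": 4,
    "r_btk_blnk_binding": 4, "r_btk_blnk_unbinding": 4,
    "r_btk_phos_syk": 4, "r_btk_phos_lyn": 4, "r_btk_dephos": 4,
    "r_plc_blnk_binding": 4, "r_plc_blnk_unbinding": 4,
    # group 5 - PLC2g activation and DAG turnover
    "r_plc_phos_syk": 5, "r_plc_phos_btk": 5, "r_plc_dephos": 5,
    "r_dag_production": 5, "r_dag_decay": 5,
    # group 6 - PKC and the MAPK cascade to Erk
    "r_pkc_act": 6, "r_pkc_deact": 6,
    "r_sos_blnk_binding": 6, "r_sos_blnk_unbinding": 6,
    "r_ras_act": 6, "r_ras_deact": 6,
    "r_raf_act": 6, "r_raf_deact": 6,
    "r_mek_phos": 6, "r_mek_dephos": 6,
    "r_erk_phos": 6, "r_erk_dephos": 6,
    # group 7 - IKK / IkB / NF-kB
    "r_ikk_act": 7, "r_ikk_deact": 7,
    "r_ikb_phos": 7, "r_ikbp_deg": 7,
    "r_ikb_syn": 7, "r_ikb_nfkb_assoc": 7,
}

#: short literature-style aliases for rate constants
ALIASES: dict[str, str] = {
    "rw0_kf": "r_association",
    "rw0_kr": "r_disassociation",
    "rw7_kr": "r_syk342_dephos_bg",
    "rw9_kf": "r_syk317_phos2",
    "rw15_kf": "r_blnk_phos",
    "rw16_kf": "r_plc_blnk_binding",
    "rw16_kr": "r_plc_blnk_unbinding",
    "r12s_kf": "r_plc_phos_syk",
    "r13_kf": "r_dag_production",
    "r13_kr": "r_dag_decay",
    "r18_kf": "r_erk_phos",
    "r19_kf": "r_sos_blnk_binding",
    "r38_kf": "r_ikb_phos",
}

POOL_TOTALS = (
    "BCR_total", "Syk_total", "Lyn_total", "SHP1_total", "Csk_total",
    "Cbp_total", "Clathrin_total", "BLNK_total", "BTK_total", "PLC2g_total",
    "PIP2_total", "PKC_total", "SOS_total", "Ras_total", "Raf_total",
    "MEK_total", "Erk_total", "IKK_total", "IkB_total", "NFkB_total",
)

#: nonnegative scalars that are not kinetic rates
SCALARS = ("CD45_level", "ligand_scale", "oi_scale")

ALL_PARAMETERS = tuple(RATE_GROUPS) + POOL_TOTALS + SCALARS

SCENARIOS = ("WT", "AQL")


@dataclass(frozen=True)
class ParameterSet:
    """Named positive kinetic rates, pool totals and scenario-free scalars.

    ``values`` maps every symbol in :data:`ALL_PARAMETERS` to a float.  Rates
    and totals must be strictly positive; ``CD45_level`` and the unit scales
    must be nonnegative.  Table-style aliases (``rw0_kf`` etc.) resolve
    through :data:`ALIASES`.
    """

    values: dict[str, float]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        missing = [k for k in ALL_PARAMETERS if k not in self.values]
        if missing:
            raise ConfigurationError(f"missing parameters: {missing}")
        unknown = [k for k in self.values if k not in ALL_PARAMETERS]
        if unknown:
            raise ConfigurationError(f"unknown parameters: {unknown}")
        for k in tuple(RATE_GROUPS) + POOL_TOTALS:
            v = self.values[k]
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"parameter {k!r} must be strictly positive, got {v}")
        for k in SCALARS:
            v = self.values[k]
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"parameter {k!r} must be nonnegative, got {v}")

    @staticmethod
    def resolve(name: str) -> str:
        return ALIASES.get(name, name)

    def get(self, name: str) -> float:
        key = self.resolve(name)
        if key not in self.values:
            raise ConfigurationError(f"unknown parameter symbol {name!r}")
        return self.values[key]

    def __getitem__(self, name: str) -> float:
        return self.get(name)

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) in self.values

    def updated(self, changes: dict[str, float], note: str | None = None) -> "ParameterSet":
        """Return a copy with ``changes`` applied (alias-aware)."""
        vals = dict(self.values)
        for k, v in changes.items():
            key = self.resolve(k)
            if key not in vals:
                raise ConfigurationError(f"unknown parameter symbol {k!r}")
            vals[key] = float(v)
        prov = self.provenance + ((note,) if note else ())
        return ParameterSet(vals, prov)

    def scaled(self, name: str, factor: float, note: str | None = None) -> "ParameterSet":
        if factor <= 0:
            raise ValidationError(f"scale factor must be positive, got {factor}")
        note = note or f"{name} x {factor:g}"
        return self.updated({name: self.get(name) * factor}, note=note)

    @staticmethod
    def group_of(name: str) -> int:
        key = ParameterSet.resolve(name)
        if key not in RATE_GROUPS:
            raise ConfigurationError(f"{name!r} is not a grouped kinetic rate")
        return RATE_GROUPS[key]

    def log_ranges(self, names, decades: float) -> dict[str, tuple[float, float]]:
        """Symmetric log10 ranges of +-``decades`` around the current values."""
        out = {}
        for n in names:
            c = np.log10(self.get(n))
            out[n] = (c - decades, c + decades)
        return out

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {"values": dict(self.values), "provenance": list(self.provenance)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        if set(d) <= {"values", "provenance"} and "values" in d:
            return cls({k: float(v) for k, v in d["values"].items()},
                       tuple(d.get("provenance", ())))
        # flat key -> value mapping
        return cls({k: float(v) for k, v in d.items()})

    def save(self, path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        else:
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


# --------------------------------------------------------------------------- reactions

@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: flux = rate * product(factor concentrations).

    ``reactants``/``products`` are consumed/produced species (explicit states
    or implied free pools); ``modifiers`` are catalysts or constant inputs
    that enter the rate law without being consumed.  ``factors`` lists the
    concentration factors of the mass-action flux (at most two).
    """

    name: str
    rate: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...] = ()
    factors: tuple[str, ...] = ()

    @property
    def stoich(self) -> dict[str, float]:
        s: dict[str, float] = {}
        for r in self.reactants:
            s[r] = s.get(r, 0.0) - 1.0
        for p in self.products:
            s[p] = s.get(p, 0.0) + 1.0
        return s


def _reactions_for(scenario: str) -> tuple[Reaction, ...]:
    R = Reaction
    rxns = [
        # --- BCR engagement, phosphorylation, trafficking
        R("ligand_association", "r_association", ("BCRfree",), ("BCRb",),
          ("LIGAND",), ("LIGAND", "BCRfree")),
        R("ligand_disassociation", "r_disassociation", ("BCRb",), ("BCRfree",),
          (), ("BCRb",)),
        R("BCR_recycling", "r_recycling", ("BCRi",), ("BCRfree",), (), ("BCRi",)),
        R("BCR_internalization", "r_internalization", ("BCRfree",), ("BCRi",),
          ("Clathrin_local",), ("Clathrin_local", "BCRfree")),
        R("BCR_degradation", "r_degradation", ("BCRi",), (), (), ("BCRi",)),
        R("ITAM1_phos_by_LynStar", "r_bcrp1_phos1", ("BCRb",), ("BCRp1",),
          ("LynStar",), ("LynStar", "BCRb")),
        R("ITAM1_phos_by_Syk342", "r_bcrp1_phos2", ("BCRb",), ("BCRp1",),
          ("Syk342",), ("Syk342", "BCRb")),
        R("ITAM1_dephos_by_SHP1", "r_bcrp1_dephos", ("BCRp1",), ("BCRb",),
          ("SHP1Star",), ("SHP1Star", "BCRp1")),
        R("ITAM1_dephos_background", "r_bcrp1_dephos_bg", ("BCRp1",), ("BCRb",),
          (), ("BCRp1",)),
        R("ITAM2_phos_by_Syk342", "r_bcrp2_phos", ("BCRp1",), ("BCRp2",),
          ("Syk342",), ("Syk342", "BCRp1")),
        R("ITAM2_dephos_by_SHP1", "r_bcrp2_dephos", ("BCRp2",), ("BCRp1",),
          ("SHP1Star",), ("SHP1Star", "BCRp2")),
        R("ITAM2_dephos_background", "r_bcrp2_dephos_bg", ("BCRp2",), ("BCRp1",),
          (), ("BCRp2",)),
        R("clathrin_localization", "r_clathrin_loc", ("Clathrin_free",), ("Clathrin_local",),
          ("Syk342",), ("Syk342", "Clathrin_free")),
        R("clathrin_delocalization", "r_clathrin_deloc", ("Clathrin_local",), ("Clathrin_free",),
          (), ("Clathrin_local",)),
        # --- Syk binding and phosphorylation (bound receptor is carried by Syk states)
        R("Syk_BCR_binding1", "r_syk_bcr_binding1", ("BCRp1", "Syk_free"), ("Sykb",),
          (), ("Syk_free", "BCRp1")),
        R("Syk_BCR_binding2", "r_syk_bcr_binding2", ("BCRp2", "Syk_free"), ("Sykb",),
          (), ("Syk_free", "BCRp2")),
        R("Syk_BCR_unbinding", "r_syk_bcr_unbinding", ("Sykb",), ("BCRp2", "Syk_free"),
          (), ("Sykb",)),
        R("Syk342_phos_via_LynStar", "r_syk342_via_lyn", ("Sykb",), ("Syk342",),
          ("LynStar",), ("LynStar", "Sykb")),
        R("Syk342_autophosphorylation", "r_syk342_auto", ("Sykb",), ("Syk342",),
          ("Syk342",), ("Syk342", "Sykb")),
        R("Syk342_dephos_by_SHP1", "r_syk342_dephos", ("Syk342",), ("Sykb",),
          ("SHP1Star",), ("SHP1Star", "Syk342")),
        R("Syk342_dephos_background", "r_syk342_dephos_bg", ("Syk342",), ("Sykb",),
          (), ("Syk342",)),
        R("Syk317_phos_on_Sykb", "r_syk317_phos1", ("Sykb",), ("Syk317",),
          ("LynStar",), ("LynStar", "Sykb")),
        R("Syk317_phos_on_Syk342", "r_syk317_phos2", ("Syk342",), ("Syk317",),
          ("LynStar",), ("LynStar", "Syk342")),
        # Y317 dephosphorylation returns equally to the two active bound forms,
        # matching the factor-2 loss in the Syk317 balance.
        R("Syk317_dephos_to_Sykb", "r_syk317_dephos", ("Syk317",), ("Sykb",),
          (), ("Syk317",)),
        R("Syk317_dephos_to_Syk342", "r_syk317_dephos", ("Syk317",), ("Syk342",),
          (), ("Syk317",)),
        # --- Lyn activation (CD45 constant input)
        R("Lyn_dephos_by_CD45", "r_lyn_dephos", ("Lyn_free",), ("Lyndp",),
          ("CD45",), ("CD45", "Lyn_free")),
        R("Lyn_phos_by_CskStar", "r_lyn_phos", ("Lyndp",), ("Lyn_free",),
          ("CskStar",), ("CskStar", "Lyndp")),
        R("LynStar_basal_phos", "r_lynstar_phos", ("Lyndp",), ("LynStar",),
          (), ("Lyndp",)),
        R("LynStar_autophos", "r_lynstar_auto", ("Lyndp",), ("LynStar",),
          ("LynStar",), ("LynStar", "Lyndp")),
        R("Lyn_deauto_by_CD45", "r_lyn_deauto_cd45", ("LynStar",), ("Lyndp",),
          ("CD45",), ("CD45", "LynStar")),
        R("Lyn_deauto_by_SHP1", "r_lyn_deauto_shp1", ("LynStar",), ("Lyndp",),
          ("SHP1Star",), ("SHP1Star", "LynStar")),
        R("Lyn_deauto_background", "r_lyn_deauto_bg", ("LynStar",), ("Lyndp",),
          (), ("LynStar",)),
        # --- regulatory enzymes
        R("SHP1_activation", "r_shp1_act", ("SHP1_free",), ("SHP1Star",),
          ("Lyndp",), ("Lyndp", "SHP1_free")),
        R("SHP1_inactivation", "r_shp1_inact", ("SHP1Star",), ("SHP1_free",),
          (), ("SHP1Star",)),
        R("Csk_activation", "r_csk_act", ("Csk_free",), ("CskStar",),
          ("Cbpp",), ("Cbpp", "Csk_free")),
        R("Csk_disassociation", "r_csk_dis", ("CskStar",), ("Csk_free",),
          (), ("CskStar",)),
        R("Cbp_phosphorylation", "r_cbp_phos", ("Cbp_free",), ("Cbpp",),
          ("Lyndp",), ("Lyndp", "Cbp_free")),
        R("Cbp_dephos_by_CD45", "r_cbp_dephos", ("Cbpp",), ("Cbp_free",),
          ("CD45",), ("CD45", "Cbpp")),
        # --- medial scaffold: BLNK (catalytic scaffold), BTK, PLC2g
        R("BLNK_phos_by_Syk342", "r_blnk_phos", ("BLNK_free",), ("BLNKp",),
          ("Syk342",), ("Syk342", "BLNK_free")),
        R("BLNK_dephos_by_SHP1", "r_blnk_dephos", ("BLNKp",), ("BLNK_free",),
          ("SHP1Star",), ("SHP1Star", "BLNKp")),
        R("BLNK_dephos_background", "r_blnk_dephos_bg", ("BLNKp",), ("BLNK_free",),
          (), ("BLNKp",)),
        # BLNKp is a catalytic scaffold: binding reads its level without depleting it.
        R("BTK_BLNK_binding", "r_btk_blnk_binding", ("BTK_free",), ("BTKb",),
          ("BLNKp",), ("BLNKp", "BTK_free")),
        R("BTK_BLNK_unbinding", "r_btk_blnk_unbinding", ("BTKb",), ("BTK_free",),
          (), ("BTKb",)),
        R("BTK_phos_by_Syk342", "r_btk_phos_syk", ("BTKb",), ("BTKp",),
          ("Syk342",), ("Syk342", "BTKb")),
        R("BTK_phos_by_LynStar", "r_btk_phos_lyn", ("BTKb",), ("BTKp",),
          ("LynStar",), ("LynStar", "BTKb")),
        R("BTK_dephosphorylation", "r_btk_dephos", ("BTKp",), ("BTKb",),
          (), ("BTKp",)),
        R("PLC2g_BLNK_binding", "r_plc_blnk_binding", ("PLC2g_free",), ("PLC2gb",),
          ("BLNKp",), ("BLNKp", "PLC2g_free")),
        R("PLC2g_BLNK_unbinding", "r_plc_blnk_unbinding", ("PLC2gb",), ("PLC2g_free",),
          (), ("PLC2gb",)),
        R("PLC2g_phos_by_Syk342", "r_plc_phos_syk", ("PLC2gb",), ("PLC2gp",),
          ("Syk342",), ("Syk342", "PLC2gb")),
        R("PLC2g_phos_by_BTKp", "r_plc_phos_btk", ("PLC2gb",), ("PLC2gp",),
          ("BTKp",), ("BTKp", "PLC2gb")),
        R("PLC2g_dephosphorylation", "r_plc_dephos", ("PLC2gp",), ("PLC2gb",),
          (), ("PLC2gp",)),
        # --- DAG and the PKC / IKK / IkB / NF-kB branch
        R("DAG_production", "r_dag_production", ("PIP2_free",), ("DAG",),
          ("PLC2gp",), ("PLC2gp", "PIP2_free")),
        R("DAG_decay", "r_dag_decay", ("DAG",), ("PIP2_free",), (), ("DAG",)),
        R("PKC_activation_by_DAG", "r_pkc_act", ("PKC_free",), ("PKCStar",),
          ("DAG",), ("DAG", "PKC_free")),
        R("PKC_deactivation", "r_pkc_deact", ("PKCStar",), ("PKC_free",),
          (), ("PKCStar",)),
        R("IKK_activation_by_PKC", "r_ikk_act", ("IKK_free",), ("IKKStar",),
          ("PKCStar",), ("PKCStar", "IKK_free")),
        R("IKK_deactivation", "r_ikk_deact", ("IKKStar",), ("IKK_free",),
          (), ("IKKStar",)),
        R("IkB_phos_in_complex", "r_ikb_phos", ("NFkB_IkB_complex",), ("IkBp", "NFkB"),
          ("IKKStar",), ("IKKStar", "NFkB_IkB_complex")),
        R("IkB_phos_free", "r_ikb_phos", ("IkB",), ("IkBp",),
          ("IKKStar",), ("IKKStar", "IkB")),
        R("IkBp_degradation", "r_ikbp_deg", ("IkBp",), (), (), ("IkBp",)),
        # NF-kB-driven IkB resynthesis: the negative feedback closing the loop.
        R("IkB_synthesis", "r_ikb_syn", (), ("IkB",), ("NFkB",), ("NFkB",)),
        R("IkB_NFkB_association", "r_ikb_nfkb_assoc", ("IkB", "NFkB"), ("NFkB_IkB_complex",),
          (), ("IkB", "NFkB")),
        # --- MAPK cascade: SOS on the BLNKp scaffold, Ras, Raf, MEK, two-step Erk
        R("SOS_BLNK_binding", "r_sos_blnk_binding", ("SOS_free",), ("SOSb",),
          ("BLNKp",), ("BLNKp", "SOS_free")),
        R("SOS_BLNK_unbinding", "r_sos_blnk_unbinding", ("SOSb",), ("SOS_free",),
          (), ("SOSb",)),
        R("Ras_activation_by_SOS", "r_ras_act", ("Ras_free",), ("RasStar",),
          ("SOSb",), ("SOSb", "Ras_free")),
        R("Ras_deactivation", "r_ras_deact", ("RasStar",), ("Ras_free",),
          (), ("RasStar",)),
        R("Raf_activation_by_Ras", "r_raf_act", ("Raf_free",), ("RafStar",),
          ("RasStar",), ("RasStar", "Raf_free")),
        R("Raf_deactivation", "r_raf_deact", ("RafStar",), ("Raf_free",),
          (), ("RafStar",)),
        R("MEK_phos_by_Raf", "r_mek_phos", ("MEK_free",), ("MEKp",),
          ("RafStar",), ("RafStar", "MEK_free")),
        R("MEK_dephosphorylation", "r_mek_dephos", ("MEKp",), ("MEK_free",),
          (), ("MEKp",)),
        R("Erk_phos1_by_MEK", "r_erk_phos", ("Erk_free",), ("Erkp1",),
          ("MEKp",), ("MEKp", "Erk_free")),
        R("Erk_phos2_by_MEK", "r_erk_phos", ("Erkp1",), ("Erkp2",),
          ("MEKp",), ("MEKp", "Erkp1")),
        R("Erk_dephos2", "r_erk_dephos", ("Erkp2",), ("Erkp1",), (), ("Erkp2",)),
        R("Erk_dephos1", "r_erk_dephos", ("Erkp1",), ("Erk_free",), (), ("Erkp1",)),
    ]
    if scenario == "AQL":
        # Irreversible orthogonal-inhibitor association with each Syk form.
        for form in ("Sykb", "Syk342", "Syk317", "Syk_free"):
            rxns.append(R(f"OI_binds_{form}", "r_oi_association",
                          (form,), ("Syk_inh",), ("OI",), ("OI", form)))
    return tuple(rxns)


# --------------------------------------------------------------------------- pools

#: conserved pools for bookkeeping.  ``sources``/``sinks`` name the reactions
#: that are allowed to change the pool total.
POOLS: dict[str, dict] = {
    "Syk": {"members": ("Sykb", "Syk342", "Syk317", "Syk_inh", "Syk_free"),
            "total": "Syk_total", "sources": (), "sinks": ()},
    # The receptor occupied by bound Syk is carried by the Syk states; OI
    # sequestration of a bound Syk form removes that receptor from view.
    "BCR": {"members": ("BCRfree", "BCRb", "BCRp1", "BCRp2", "BCRi",
                        "Sykb", "Syk342", "Syk317"),
            "total": "BCR_total", "sources": (),
            "sinks": ("BCR_degradation", "OI_binds_Sykb",
                      "OI_binds_Syk342", "OI_binds_Syk317")},
    "Lyn": {"members": ("Lyndp", "LynStar", "Lyn_free"),
            "total": "Lyn_total", "sources": (), "sinks": ()},
    "SHP1": {"members": ("SHP1Star", "SHP1_free"),
             "total": "SHP1_total", "sources": (), "sinks": ()},
    "Csk": {"members": ("CskStar", "Csk_free"),
            "total": "Csk_total", "sources": (), "sinks": ()},
    "Cbp": {"members": ("Cbpp", "Cbp_free"),
            "total": "Cbp_total", "sources": (), "sinks": ()},
    "Clathrin": {"members": ("Clathrin_local", "Clathrin_free"),
                 "total": "Clathrin_total", "sources": (), "sinks": ()},
    "BLNK": {"members": ("BLNKp", "BLNK_free"),
             "total": "BLNK_total", "sources": (), "sinks": ()},
    "BTK": {"members": ("BTKb", "BTKp", "BTK_free"),
            "total": "BTK_total", "sources": (), "sinks": ()},
    "PLC2g": {"members": ("PLC2gb", "PLC2gp", "PLC2g_free"),
              "total": "PLC2g_total", "sources": (), "sinks": ()},
    "PIP2": {"members": ("DAG", "PIP2_free"),
             "total": "PIP2_total", "sources": (), "sinks": ()},
    "PKC": {"members": ("PKCStar", "PKC_free"),
            "total": "PKC_total", "sources": (), "sinks": ()},
    "SOS": {"members": ("SOSb", "SOS_free"),
            "total": "SOS_total", "sources": (), "sinks": ()},
    "Ras": {"members": ("RasStar", "Ras_free"),
            "total": "Ras_total", "sources": (), "sinks": ()},
    "Raf": {"members": ("RafStar", "Raf_free"),
            "total": "Raf_total", "sources": (), "sinks": ()},
    "MEK": {"members": ("MEKp", "MEK_free"),
            "total": "MEK_total", "sources": (), "sinks": ()},
    "Erk": {"members": ("Erkp1", "Erkp2", "Erk_free"),
            "total": "Erk_total", "sources": (), "sinks": ()},
    "IKK": {"members": ("IKKStar", "IKK_free"),
            "total": "IKK_total", "sources": (), "sinks": ()},
    "NFkB": {"members": ("NFkB", "NFkB_IkB_complex"),
             "total": "NFkB_total", "sources": (), "sinks": ()},
    # IkB is synthesised (NF-kB feedback) and degraded (after phosphorylation).
    "IkB": {"members": ("IkB", "IkBp", "NFkB_IkB_complex"),
            "total": None, "sources": ("IkB_synthesis",),
            "sinks": ("IkBp_degradation",)},
}


# --------------------------------------------------------------------------- ledger

class _Structure:
    """Index arrays compiled from a ledger for fast RHS evaluation."""

    def __init__(self, reactions: tuple[Reaction, ...]):
        n_imp = len(IMPLIED_NAMES)
        imp_index = {n: N_STATES + j for j, n in enumerate(IMPLIED_NAMES)}
        base = N_STATES + n_imp
        input_index = {"ONE": base, "LIGAND": base + 1, "OI": base + 2, "CD45": base + 3}
        self.ext_len = base + 4

        def idx(name: str) -> int:
            if name in STATE_INDEX:
                return STATE_INDEX[name]
            if name in imp_index:
                return imp_index[name]
            if name in input_index:
                return input_index[name]
            raise ConfigurationError(f"unknown species or input {name!r}")

        nr = len(reactions)
        self.i1 = np.empty(nr, dtype=np.intp)
        self.i2 = np.empty(nr, dtype=np.intp)
        self.S = np.zeros((N_STATES, nr))
        self.rate_names = [r.rate for r in reactions]
        for j, rxn in enumerate(reactions):
            if not 1 <= len(rxn.factors) <= 2:
                raise ConfigurationError(
                    f"reaction {rxn.name!r} must have one or two rate-law factors")
            self.i1[j] = idx(rxn.factors[0])
            self.i2[j] = idx(rxn.factors[1]) if len(rxn.factors) == 2 else input_index["ONE"]
            for sp, coef in rxn.stoich.items():
                if sp in STATE_INDEX:
                    self.S[STATE_INDEX[sp], j] += coef
        # membership matrix for implied free pools: free = total - M @ y
        self.M = np.zeros((n_imp, N_STATES))
        self.total_names = []
        for j, (name, (total, members)) in enumerate(IMPLIED_SPECIES.items()):
            self.total_names.append(total)
            for m in members:
                self.M[j, STATE_INDEX[m]] = 1.0
        self.one_idx = input_index["ONE"]
        self.ligand_idx = input_index["LIGAND"]
        self.oi_idx = input_index["OI"]
        self.cd45_idx = input_index["CD45"]


@dataclass(frozen=True)
class ReactionLedger:
    """Ordered reaction list defining the model for one scenario."""

    scenario: str
    reactions: tuple[Reaction, ...]

    @property
    def n_states(self) -> int:
        return N_STATES

    @property
    def state_names(self) -> tuple[str, ...]:
        return STATE_NAMES

    def structure(self) -> _Structure:
        st = getattr(self, "_structure_cache", None)
        if st is None:
            st = _Structure(self.reactions)
            object.__setattr__(self, "_structure_cache", st)
        return st

    def rate_symbols(self) -> set[str]:
        return {r.rate for r in self.reactions}

    def pool_net(self, pool: str, reaction: Reaction) -> float:
        """Net stoichiometry of ``reaction`` over the members of ``pool``."""
        members = set(POOLS[pool]["members"])
        return sum(c for sp, c in reaction.stoich.items() if sp in members)

    def to_frame(self):
        """Export the ledger as a tidy table (for documentation and diffing)."""
        import pandas as pd

        rows = [{
            "reaction": r.name,
            "rate": r.rate,
            "reactants": "+".join(r.reactants),
            "products": "+".join(r.products),
            "modifiers": "+".join(r.modifiers),
        } for r in self.reactions]
        return pd.DataFrame(rows)


def assemble_model(params: ParameterSet, scenario: str = "WT") -> ReactionLedger:
    """Build the reaction ledger for a scenario and validate it against ``params``.

    Raises :class:`ConfigurationError` if a rate symbol used by the ledger is
    absent from ``params`` and :class:`ValidationError` if any used rate is
    nonpositive.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    ledger = ReactionLedger(scenario, _reactions_for(scenario))
    for sym in sorted(ledger.rate_symbols()):
        if sym not in params:
            raise ConfigurationError(f"missing rate symbol {sym!r}")
        if params.get(sym) <= 0:
            raise ValidationError(f"rate {sym!r} must be positive")
    return ledger


# --------------------------------------------------------------------------- RHS

class CompiledModel:
    """Ledger + parameter values compiled into a fast ODE right-hand side.

    Free-pool concentrations implied by conservation are clamped at zero to
    guard against transient integrator undershoot.
    """

    def __init__(self, ledger: ReactionLedger, params: ParameterSet):
        st = ledger.structure()
        self.ledger = ledger
        self.params = params
        self._st = st
        self.k = np.array([params.get(n) for n in st.rate_names])
        self.totals = np.array([params.get(n) for n in st.total_names])
        self._ext = np.zeros(st.ext_len)
        self._ext[st.one_idx] = 1.0
        self._ext[st.cd45_idx] = params.get("CD45_level")
        self.set_inputs(0.0, 0.0)

    def set_inputs(self, ligand: float, oi: float) -> None:
        """Set constant external inputs in model units (a.u.)."""
        self._ext[self._st.ligand_idx] = ligand
        self._ext[self._st.oi_idx] = oi

    def implied(self, y: np.ndarray) -> np.ndarray:
        """Conservation-implied free concentrations, clamped at zero."""
        free = self.totals - self._st.M @ y
        return np.clip(free, 0.0, None)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        st = self._st
        ext = self._ext
        ext[:N_STATES] = y
        ext[N_STATES:N_STATES + st.M.shape[0]] = self.implied(y)
        flux = self.k * ext[st.i1] * ext[st.i2]
        return st.S @ flux

    def fluxes(self, y: np.ndarray, ligand: float = 0.0, oi: float = 0.0) -> np.ndarray:
        self.set_inputs(ligand, oi)
        st = self._st
        ext = self._ext
        ext[:N_STATES] = y
        ext[N_STATES:N_STATES + st.M.shape[0]] = self.implied(y)
        return self.k * ext[st.i1] * ext[st.i2]


def rhs(state: np.ndarray, params: ParameterSet, ligand: float = 0.0,
        oi: float = 0.0, ledger: ReactionLedger | None = None,
        conservation_tol: float = 1e-9) -> np.ndarray:
    """Time derivative of the 32-state vector (a.u./min).

    ``ligand`` and ``oi`` are in model units (a.u.); dose conversion happens
    at the simulation layer.  Raises :class:`DomainError` for negative state
    components and :class:`IntegrityError` when a conservation-implied free
    concentration is negative beyond ``conservation_tol``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise DomainError(f"state must have shape ({N_STATES},), got {state.shape}")
    if np.any(state < 0):
        bad = STATE_NAMES[int(np.argmin(state))]
        raise DomainError(f"negative state component {bad!r}")
    if ligand < 0 or oi < 0:
        raise DomainError("ligand and oi must be nonnegative")
    if ledger is None:
        ledger = assemble_model(params, "WT")
    cm = CompiledModel(ledger, params)
    raw_free = cm.totals - cm._st.M @ state
    if np.any(raw_free < -conservation_tol):
        j = int(np.argmin(raw_free))
        raise IntegrityError(
            f"conservation residual negative for {IMPLIED_NAMES[j]!r}: {raw_free[j]:.3e}")
    cm.set_inputs(ligand, oi)
    return cm.rhs(0.0, state)


def conserved_totals(state: np.ndarray, params: ParameterSet) -> dict[str, float]:
    """Current totals of every bookkept pool.

    Pools with an implied free form count it via the (clamped) conservation
    expression; the BCR pool is a plain sum of explicit states.  Pools with a
    nonempty ``sources``/``sinks`` entry in :data:`POOLS` (BCR, IkB) are not
    expected to stay constant.
    """
    state = np.asarray(state, dtype=float)
    out: dict[str, float] = {}
    for pool, info in POOLS.items():
        total = 0.0
        for m in info["members"]:
            if m in STATE_INDEX:
                total += state[STATE_INDEX[m]]
            else:
                tot_sym, members = IMPLIED_SPECIES[m]
                free = params.get(tot_sym) - sum(state[STATE_INDEX[x]] for x in members)
                total += max(free, 0.0)
        out[pool] = float(total)
    return out
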