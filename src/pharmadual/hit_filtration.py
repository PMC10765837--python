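"""Post-screening lead-likeness and ADME filtration cascade.

Screened hits pass through, in order: duplicate removal, Oprea lead-like
filter (MW < 450, logP <= 4.5, HBA <= 8, HBD <= 5), mutagenicity structural
alerts, Veber polar-surface-area rule (TPSA < 140 A^2), aqueous-solubility
gate (logS >= -5), PAINS substructure removal, and a pharmacokinetic gate
(high predicted gastrointestinal absorption, no predicted blood-brain-barrier
permeation, not a P-glycoprotein substrate). GI absorption and BBB
permeation are classified by membership in the two published WLOGP-vs-TPSA
ellipses of the BOILED-Egg method; the P-gp call is an external annotation
(it comes from a machine-learned predictor outside this package's scope).

Every stage records exactly which compounds it removed and why, so the
cascade is auditable end to end.

Descriptors: MW, Wildman-Crippen logP (used for both the lead-like logP and
the BOILED-Egg WLOGP axis), TPSA, H-bond donor/acceptor and rotatable-bond
counts are computed with RDKit; logS uses the ESOL linear estimator
(intercept + terms in logP, MW, rotatable bonds and aromatic proportion),
a documented stand-in configurable per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

__all__ = [
    "PropertyRecord",
    "StageResult",
    "CascadeReport",
    "MUTAGENIC_ALERTS",
    "BoiledEggEllipse",
    "WHITE_ELLIPSE",
    "YOLK_ELLIPSE",
    "compute_properties",
    "esol_logs",
    "prefilter",
    "dedupe",
    "oprea_filter",
    "mutagenic_filter",
    "veber_filter",
    "logs_filter",
    "pains_filter",
    "admet_gate",
    "run_cascade",
    "DEFAULT_STAGES",
]

# Curated mutagenicity structural alerts (editable). A subset of the classic
# toxicophore families; the cascade contract, not the exact alert census, is
# the reproducible object.
MUTAGENIC_ALERTS = {
    "nitroaromatic": "[c][N+](=O)[O-]",
    "aromatic_amine": "[c][NX3;H2]",
    "epoxide": "C1OC1",
    "aziridine": "C1NC1",
    "aliphatic_halide": "[CX4][Cl,Br,I]",
    "azo": "[#6]N=N[#6]",
    "n_oxide": "[#7+;!$([#7+][O-]=*)][O-]",
    "polycyclic_planar": "c1ccc2cc3ccccc3cc2c1",
}


@dataclass(frozen=True)
class BoiledEggEllipse:
    """Rotated ellipse in (TPSA, WLOGP) space; angle in degrees."""

    center_tpsa: float
    center_wlogp: float
    width: float   # full axis along the rotated TPSA direction
    height: float  # full axis along the rotated WLOGP direction
    angle_deg: float

    def contains(self, tpsa: float, wlogp: float) -> bool:
        th = math.radians(self.angle_deg)
        dx, dy = tpsa - self.center_tpsa, wlogp - self.center_wlogp
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        return (u / (self.width / 2)) ** 2 + (v / (self.height / 2)) ** 2 <= 1.0


# Published BOILED-Egg ellipse coefficients: the white region predicts high
# gastrointestinal absorption, the yolk predicts blood-brain-barrier
# permeation. Overridable via the cascade config.
WHITE_ELLIPSE = BoiledEggEllipse(71.051, 2.292, 142.081, 8.740, -1.031325)
YOLK_ELLIPSE = BoiledEggEllipse(38.117, 3.177, 82.061, 5.557, -0.171887)


@dataclass(frozen=True)
class PropertyRecord:
    """Computed (or supplied) physicochemical profile of one compound."""

    compound_id: str
    mw: float
    logp: float
    hba: int
    hbd: int
    rotb: int
    tpsa: float
    logs: float
    wlogp: float
    canonical_smiles: str = ""
    mutagenic_alerts: tuple[str, ...] = ()
    pains_alerts: tuple[str, ...] = ()
    annotations: dict = field(default_factory=dict)  # gi_absorption / bbb / pgp_substrate
    quarantined: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.quarantined:
            if self.mw <= 0:
                raise ValueError(f"{self.compound_id!r}: MW must be > 0")
            if min(self.hba, self.hbd, self.rotb) < 0:
                raise ValueError(f"{self.compound_id!r}: counts must be >= 0")


@dataclass(frozen=True)
class StageResult:
    name: str
    n_in: int
    n_out: int
    removed: tuple[str, ...]
    reasons: dict  # id -> reason string


@dataclass(frozen=True)
class CascadeReport:
    stages: tuple[StageResult, ...]
    survivors: tuple[PropertyRecord, ...]

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            [{"stage": s.name, "in": s.n_in, "out": s.n_out, "removed": len(s.removed)} for s in self.stages]
        )


_pains_catalog = None


def _get_pains_catalog() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        for fam in (
            FilterCatalogParams.FilterCatalogs.PAINS_A,
            FilterCatalogParams.FilterCatalogs.PAINS_B,
            FilterCatalogParams.FilterCatalogs.PAINS_C,
        ):
            params.AddCatalog(fam)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


def esol_logs(logp: float, mw: float, rotb: int, aromatic_proportion: float) -> float:
    """ESOL aqueous solubility estimate (log mol/L).

    logS = 0.16 - 0.63*logP - 0.0062*MW + 0.066*RotB - 0.74*AP,
    with AP the fraction of heavy atoms that are aromatic.
    """
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * aromatic_proportion


def compute_properties(mol, compound_id: str | None = None, annotations: dict | None = None) -> PropertyRecord:
    """Compute a :class:`PropertyRecord` from a molecule.

    Accepts an RDKit ``Mol``, a :class:`~pharmadual.feature_perception.Molecule3D`,
    or a SMILES string. A molecule that fails descriptor computation is
    returned quarantined rather than dropped.
    """
    if isinstance(mol, str):
        cid = compound_id or mol
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            return PropertyRecord(
                compound_id=cid, mw=0, logp=0, hba=0, hbd=0, rotb=0, tpsa=0,
                logs=0, wlogp=0, quarantined=True, flags=("parse_failure",),
            )
    elif hasattr(mol, "mol"):  # Molecule3D
        compound_id = compound_id or mol.id
        mol = mol.mol
    cid = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed")
    try:
        heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        arom_prop = sum(a.GetIsAromatic() for a in heavy) / len(heavy) if heavy else 0.0
        logp = Crippen.MolLogP(mol)
        rotb = Lipinski.NumRotatableBonds(mol)
        mw = Descriptors.MolWt(mol)
        muta = tuple(
            name
            for name, smarts in MUTAGENIC_ALERTS.items()
            if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))
        )
        pains_matches = _get_pains_catalog().GetMatches(mol)
        pains = tuple(sorted(m.GetDescription() for m in pains_matches))
        return PropertyRecord(
            compound_id=cid,
            mw=mw,
            logp=logp,
            hba=Lipinski.NumHAcceptors(mol),
            hbd=Lipinski.NumHDonors(mol),
            rotb=rotb,
            tpsa=Descriptors.TPSA(mol),
            logs=esol_logs(logp, mw, rotb, arom_prop),
            wlogp=logp,
            canonical_smiles=Chem.MolToSmiles(mol),
            mutagenic_alerts=muta,
            pains_alerts=pains,
            annotations=dict(annotations or {}),
        )
    except Exception as exc:  # quarantine, never silently drop
        return PropertyRecord(
            compound_id=cid, mw=0, logp=0, hba=0, hbd=0, rotb=0, tpsa=0,
            logs=0, wlogp=0, quarantined=True, flags=(f"property_failure:{exc}",),
        )


def _apply(records, keep_fn, reason_fn):
    survivors, removed, reasons = [], [], {}
    for r in records:
        if r.quarantined:
            removed.append(r.compound_id)
            reasons[r.compound_id] = "quarantined"
        elif keep_fn(r):
            survivors.append(r)
        else:
            removed.append(r.compound_id)
            reasons[r.compound_id] = reason_fn(r)
    return survivors, removed, reasons


def prefilter(records, mw_range=(350.0, 500.0), rotb_range=(0, 10)):
    """Screening-library prefilter: inclusive MW and rotatable-bond windows."""
    lo, hi = mw_range
    rlo, rhi = rotb_range
    return _apply(
        records,
        lambda r: lo <= r.mw <= hi and rlo <= r.rotb <= rhi,
        lambda r: f"MW={r.mw:.1f} or RotB={r.rotb} outside prefilter windows",
    )[0]


def dedupe(records):
    """Keep the first occurrence of each canonical structure.

    The duplicate key is the canonical isomeric SMILES, so stereoisomers are
    distinct structures and both survive. Records without a structure key
    are kept (nothing to compare).
    """
    seen: set[str] = set()
    survivors = []
    for r in records:
        key = r.canonical_smiles
        if key and key in seen:
            continue
        if key:
            seen.add(key)
        survivors.append(r)
    return survivors


def oprea_filter(records):
    """Lead-likeness: MW < 450 (strict), logP <= 4.5, HBA <= 8, HBD <= 5."""
    return _apply(
        records,
        lambda r: r.mw < 450 and r.logp <= 4.5 and r.hba <= 8 and r.hbd <= 5,
        lambda r: "fails lead-like bounds "
        f"(MW={r.mw:.1f}, logP={r.logp:.2f}, HBA={r.hba}, HBD={r.hbd})",
    )[0]


def mutagenic_filter(records, alerts=None):
    """Remove compounds matching any mutagenicity structural alert.

    ``alerts``: alert-name -> SMARTS map; ``None`` uses the flags already on
    the records (populated from :data:`MUTAGENIC_ALERTS` at property time).
    """
    if alerts is None:
        return _apply(
            records,
            lambda r: not r.mutagenic_alerts,
            lambda r: f"mutagenic alerts: {','.join(r.mutagenic_alerts)}",
        )[0]
    compiled = {name: Chem.MolFromSmarts(s) for name, s in alerts.items()}

    def clean(r):
        mol = Chem.MolFromSmiles(r.canonical_smiles) if r.canonical_smiles else None
        if mol is None:
            return True
        return not any(mol.HasSubstructMatch(p) for p in compiled.values())

    return _apply(records, clean, lambda r: "mutagenic alert (custom set)")[0]


def veber_filter(records, tpsa_max: float = 140.0):
    """Permeability rule: TPSA strictly below 140 A^2 (rotatable bonds are
    already gated by the prefilter and not re-checked here)."""
    return _apply(
        records,
        lambda r: r.tpsa < tpsa_max,
        lambda r: f"TPSA={r.tpsa:.1f} >= {tpsa_max}",
    )[0]


def logs_filter(records, logs_min: float = -5.0):
    """Solubility gate: keep iff logS >= -5 (inclusive boundary)."""
    return _apply(
        records,
        lambda r: r.logs >= logs_min,
        lambda r: f"logS={r.logs:.2f} < {logs_min}",
    )[0]


def pains_filter(records, enabled: bool = True):
    """Remove pan-assay interference compounds (catalog flags on the record)."""
    if not enabled:
        return list(records)
    return _apply(
        records,
        lambda r: not r.pains_alerts,
        lambda r: f"PAINS: {','.join(r.pains_alerts)}",
    )[0]


def classify_boiled_egg(record, white=WHITE_ELLIPSE, yolk=YOLK_ELLIPSE) -> tuple[str, str]:
    """(GI absorption, BBB permeation) classification from (TPSA, WLOGP)."""
    gi = "high" if white.contains(record.tpsa, record.wlogp) else "low"
    bbb = "yes" if yolk.contains(record.tpsa, record.wlogp) else "no"
    return gi, bbb


def admet_gate(records, white=WHITE_ELLIPSE, yolk=YOLK_ELLIPSE, missing_pgp: str = "keep"):
    """Pharmacokinetic gate: GI absorption high, BBB no, P-gp substrate no.

    GI/BBB come from the BOILED-Egg ellipses unless the record carries
    explicit ``gi_absorption`` / ``bbb`` annotations. The P-gp call is read
    from the ``pgp_substrate`` annotation; a missing annotation is handled
    per ``missing_pgp`` ("keep" keeps-and-flags, "remove" removes).
    """
    if missing_pgp not in ("keep", "remove"):
        raise ValueError("missing_pgp must be 'keep' or 'remove'")

    def keep(r):
        gi, bbb = classify_boiled_egg(r, white, yolk)
        gi = r.annotations.get("gi_absorption", gi)
        bbb = r.annotations.get("bbb", bbb)
        pgp = r.annotations.get("pgp_substrate")
        if gi != "high" or bbb != "no":
            return False
        if pgp is None:
            return missing_pgp == "keep"
        return pgp in ("no", False)

    return _apply(
        records,
        keep,
        lambda r: "pharmacokinetic gate (GI/BBB/P-gp)",
    )[0]


DEFAULT_STAGES = ("dedupe", "oprea", "mutagenic", "veber", "logs", "pains", "admet")

_STAGE_FNS = {
    "prefilter": prefilter,
    "dedupe": dedupe,
    "oprea": oprea_filter,
    "mutagenic": mutagenic_filter,
    "veber": veber_filter,
    "logs": logs_filter,
    "pains": pains_filter,
    "admet": admet_gate,
}


def run_cascade(records, stages=DEFAULT_STAGES, stage_kwargs: dict | None = None) -> CascadeReport:
    """Apply the filtration cascade in order with a full removal audit."""
    stage_kwargs = stage_kwargs or {}
    current = list(records)
    results = []
    for name in stages:
        fn = _STAGE_FNS.get(name)
        if fn is None:
            raise ValueError(f"unknown cascade stage {name!r}")
        n_in = len(current)
        nxt = fn(current, **stage_kwargs.get(name, {}))
        gone = {r.compound_id for r in current} - {r.compound_id for r in nxt}
        results.append(
            StageResult(
                name=name,
                n_in=n_in,
                n_out=len(nxt),
                removed=tuple(sorted(gone)),
                reasons={cid: name for cid in sorted(gone)},
            )
        )
        current = nxt
    return CascadeReport(stages=tuple(results), survivors=tuple(current))
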