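"""Offline synthetic fixtures with analytically known ground truth.

Because the original screening corpora (vendor databases, published
active/decoy benchmark sets) are not redistributable, every input the
pipeline needs is generated here by construction:

* *matchers* — molecules assembled from rigid chemical fragments (benzene /
  pyridine rings for aromatic features, acetone / DMSO carbonyl-sulfoxide
  oxygens for acceptors) whose perceived pharmacophoric points land exactly
  on — or at a controlled Gaussian jitter around — a query model's feature
  centers, so whether the molecule should match is known analytically;
* *decoys* — fragment assemblies property-matched to the actives but with
  at most one aromatic ring, which makes matching a two-aromatic-essential
  query impossible by construction regardless of geometry;
* *benchmarks* — labeled active/decoy libraries with small conformer
  ensembles (one planted matching conformer per active, scrambled
  non-matching geometries otherwise) and a derivable confusion matrix;
* *filter panels* — property records that each violate a chosen subset of
  the filtration-cascade rules exactly.

Fragments are placed as disconnected rigid units (a formal mixture), which
keeps the feature geometry analytic; no conformer search or distance-
geometry embedding is involved. Scrambled geometries put fragment anchors
>= 16 A apart, provably beyond the query's pairwise-distance pruning reach.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_perception import ConformerEnsemble, Molecule3D, mol_from_smiles, write_sdf
from .hit_filtration import PropertyRecord
from .pharmacophore_core import PharmacophoreModel
from .screening_validation import ConfusionMatrix, LabeledLibrary

__all__ = [
    "FRAGMENTS",
    "PlantedBenchmark",
    "make_matcher",
    "make_decoy_set",
    "make_benchmark",
    "make_filter_panel",
    "write_fixtures",
]


def _hexagon(radius: float, z: float = 0.0) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)], axis=1)


@dataclass(frozen=True)
class _Fragment:
    """Rigid fragment template: SMILES + local coordinates + anchor.

    The anchor is the point (in local coordinates) that will be placed on a
    feature center: the ring centroid for aromatic fragments, the acceptor
    atom for acceptor fragments.
    """

    name: str
    smiles: str
    coords: np.ndarray  # (n_heavy, 3), local frame with anchor at origin
    ftype: str | None   # feature the anchor realizes (None for inert fragments)


def _build_fragments() -> dict:
    frags = {}
    hexa = _hexagon(1.39)
    frags["benzene"] = _Fragment("benzene", "c1ccccc1", hexa, "aromatic")
    # pyridine c1ccncc1: atom 3 is N at a ring vertex; anchor = centroid
    frags["pyridine"] = _Fragment("pyridine", "c1ccncc1", hexa, "aromatic")
    # acetone CC(C)=O: atoms C,C,C,O — anchor is the carbonyl O at origin
    acetone = np.array(
        [[1.97, 1.30, 0.0], [1.22, 0.0, 0.0], [1.97, -1.30, 0.0], [0.0, 0.0, 0.0]]
    )
    frags["acetone"] = _Fragment("acetone", "CC(C)=O", acetone, "acceptor")
    # DMSO CS(C)=O: atoms C,S,C,O — anchor is the sulfoxide O at origin
    dmso = np.array(
        [[2.3, 1.4, 0.3], [1.49, 0.0, 0.0], [2.3, -1.4, 0.3], [0.0, 0.0, 0.0]]
    )
    frags["dmso"] = _Fragment("dmso", "CS(C)=O", dmso, "acceptor")
    # saturated stand-ins for property matching (no pharmacophoric anchor)
    frags["cyclohexane"] = _Fragment("cyclohexane", "C1CCCCC1", _hexagon(1.5), None)
    return frags


FRAGMENTS = _build_fragments()

#: fragments usable for each feature type when assembling a matcher
_FTYPE_CHOICES = {"aromatic": ("benzene", "pyridine"), "acceptor": ("acetone", "dmso")}

#: anchor separation (A) used for scrambled non-matching geometries; beyond
#: the pruning reach of any query with pairwise distances <= ~11 A and
#: radius sums <= ~3 A.
_SCRAMBLE_SPACING = 20.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _assemble(frag_names, anchor_positions, rng, mol_id: str) -> Molecule3D:
    """Place rigid fragments with randomized orientations at anchor positions."""
    smiles = ".".join(FRAGMENTS[n].smiles for n in frag_names)
    coords = []
    for name, anchor in zip(frag_names, anchor_positions):
        rot = _random_rotation(rng)
        coords.append(FRAGMENTS[name].coords @ rot.T + np.asarray(anchor))
    return mol_from_smiles(smiles, mol_id, np.vstack(coords))


def _scrambled_anchors(k: int, rng: np.random.Generator) -> np.ndarray:
    base = np.arange(k)[:, None] * np.array([_SCRAMBLE_SPACING, 0.0, 0.0])
    return base + rng.uniform(-2.0, 2.0, size=(k, 3))


def _compose_matcher(model: PharmacophoreModel, rng) -> list[str]:
    return [
        FRAGMENTS[rng.choice(_FTYPE_CHOICES[f.ftype])].name for f in model.features
    ]


def make_matcher(
    model: PharmacophoreModel,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    mol_id: str = "matcher",
    max_retries: int = 20,
) -> tuple[Molecule3D, bool]:
    """Assemble a molecule whose features sit at jittered query feature centers.

    One fragment per query feature is placed with its anchor at
    ``center + sigma * z`` (``z`` standard normal). Returns the molecule and
    the planted truth ``should_match``: every essential feature's jittered
    anchor within its tolerance radius and at least ``min_match`` anchors
    within radius overall (at ``jitter_sigma=0`` this is always true). Since
    anchor placement cannot fail geometrically for disconnected rigid
    fragments, retries are only consumed by degenerate random draws.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        frag_names = _compose_matcher(model, rng)
        offsets = jitter_sigma * rng.normal(size=(len(model.features), 3))
        anchors = model.centers() + offsets
        within = [
            float(np.linalg.norm(off)) <= f.radius
            for off, f in zip(offsets, model.features)
        ]
        should_match = all(
            w for w, f in zip(within, model.features) if f.essential
        ) and sum(within) >= model.min_match
        mol = _assemble(frag_names, anchors, rng, mol_id)
        return mol, should_match
    raise RuntimeError("could not assemble matcher")  # pragma: no cover


def make_decoy_set(
    actives_compositions,
    n: int,
    seed: int = 0,
    id_prefix: str = "decoy",
) -> tuple[list[Molecule3D], pd.DataFrame]:
    """Decoys property-matched to active compositions but unable to match.

    Each decoy copies a randomly chosen active's fragment multiset with
    every aromatic fragment beyond none replaced by cyclohexane, so decoys
    contain no aromatic ring and cannot satisfy a query with two essential
    aromatic features, independent of geometry. Fragments are placed on a
    widely spaced scrambled lattice. Returns the molecules plus a
    per-fragment composition audit of actives vs decoys.
    """
    rng = np.random.default_rng(seed)
    comps = [list(c) for c in actives_compositions]
    mols = []
    decoy_comps = []
    for i in range(n):
        comp = list(comps[rng.integers(len(comps))]) if comps else []
        comp = ["cyclohexane" if FRAGMENTS[f].ftype == "aromatic" else f for f in comp]
        decoy_comps.append(comp)
        anchors = _scrambled_anchors(len(comp), rng)
        mols.append(_assemble(comp, anchors, rng, f"{id_prefix}{i}"))

    def frac(comp_list, name):
        tot = sum(len(c) for c in comp_list) or 1
        return sum(c.count(name) for c in comp_list) / tot

    audit = pd.DataFrame(
        [
            {
                "fragment": name,
                "actives_fraction": frac(comps, name),
                "decoys_fraction": frac(decoy_comps, name),
            }
            for name in FRAGMENTS
        ]
    )
    return mols, audit


@dataclass(frozen=True)
class PlantedBenchmark:
    """Labeled library + conformer ensembles with construction ground truth."""

    library: LabeledLibrary
    ensembles: tuple[ConformerEnsemble, ...]
    should_match: dict  # id -> bool (planted truth)
    params: dict

    def expected_confusion(self) -> ConfusionMatrix:
        """Confusion matrix implied by the planted truth."""
        tp = sum(1 for i in self.library.actives if self.should_match[i])
        fp = sum(1 for i in self.library.decoys if self.should_match[i])
        return ConfusionMatrix(
            TP=tp,
            FP=fp,
            FN=self.library.n_actives - tp,
            TN=self.library.n_decoys - fp,
        )


def make_benchmark(
    model: PharmacophoreModel,
    n_actives: int = 39,
    n_decoys: int = 1198,
    k_conformers: int = 3,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> PlantedBenchmark:
    """Planted active/decoy benchmark emulating the dual-kinase test-set design.

    Defaults mirror the study's test set: 39 actives vs 1198 decoys (a
    >1:30 active:inactive ratio). Each active carries one planted matching
    conformer (rigidly moved, so screening must be invariant to pose) among
    ``k_conformers``; remaining conformers and all decoy conformers are
    scrambled non-matching geometries.
    """
    rng = np.random.default_rng(seed)
    ensembles = []
    truth = {}
    active_comps = []
    for i in range(n_actives):
        cid = f"active{i}"
        mol, should = make_matcher(
            model, jitter_sigma, seed=int(rng.integers(2**31)), mol_id=cid
        )
        active_comps.append(_composition_of(mol))
        confs = []
        planted_slot = int(rng.integers(k_conformers))
        for ci in range(k_conformers):
            if ci == planted_slot:
                rot, t = _random_rotation(rng), rng.uniform(-10, 10, size=3)
                confs.append(mol.transformed(rot, t))
            else:
                confs.append(_scramble_copy(mol, rng))
        ensembles.append(ConformerEnsemble(cid, tuple(confs)))
        truth[cid] = bool(should)
    decoys, _audit = make_decoy_set(
        active_comps, n_decoys, seed=int(rng.integers(2**31))
    )
    for d in decoys:
        confs = tuple(_scramble_copy(d, rng) for _ in range(k_conformers))
        ensembles.append(ConformerEnsemble(d.id, confs))
        truth[d.id] = False
    labels = {f"active{i}": "active" for i in range(n_actives)}
    labels.update({d.id: "decoy" for d in decoys})
    return PlantedBenchmark(
        library=LabeledLibrary(labels),
        ensembles=tuple(ensembles),
        should_match=truth,
        params={
            "n_actives": n_actives,
            "n_decoys": n_decoys,
            "k_conformers": k_conformers,
            "jitter_sigma": jitter_sigma,
            "seed": seed,
        },
    )


def _composition_of(mol3d: Molecule3D) -> list[str]:
    from rdkit import Chem

    by_smiles = {}
    for f in FRAGMENTS.values():
        by_smiles[Chem.CanonSmiles(f.smiles)] = f.name
    return [
        by_smiles[Chem.MolToSmiles(frag)]
        for frag in Chem.GetMolFrags(mol3d.mol, asMols=True)
    ]


def _scramble_copy(mol3d: Molecule3D, rng) -> Molecule3D:
    """Non-matching conformer: fragments redistributed on the spaced lattice."""
    from rdkit import Chem

    frag_idx = Chem.GetMolFrags(mol3d.mol)
    anchors = _scrambled_anchors(len(frag_idx), rng)
    coords = mol3d.coords.copy()
    for fi, atom_ids in enumerate(frag_idx):
        ids = list(atom_ids)
        rot = _random_rotation(rng)
        local = coords[ids] - coords[ids].mean(axis=0)
        coords[ids] = local @ rot.T + anchors[fi]
    new = Chem.Mol(mol3d.mol)
    conf = new.GetConformer()
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, [float(x) for x in p])
    return Molecule3D(id=mol3d.id, mol=new)


# ---------------------------------------------------------------------------
# Filter panels

_CLEAN_BASE = dict(
    mw=380.0, logp=2.0, hba=3, hbd=1, rotb=4, tpsa=120.0, logs=-3.0, wlogp=1.0
)

#: violation name -> (record overrides, cascade stage expected to remove it)
_VIOLATIONS = {
    "prefilter_mw": ({"mw": 330.0}, "prefilter"),
    "prefilter_rotb": ({"rotb": 11}, "prefilter"),
    "oprea_mw": ({"mw": 455.0}, "oprea"),
    "oprea_mw_boundary": ({"mw": 450.0}, "oprea"),   # MW < 450 is strict
    "oprea_logp": ({"logp": 5.0}, "oprea"),
    "oprea_hba": ({"hba": 9}, "oprea"),
    "oprea_hbd": ({"hbd": 6}, "oprea"),
    "mutagenic": ({"mutagenic_alerts": ("nitroaromatic",)}, "mutagenic"),
    "veber": ({"tpsa": 150.0}, "veber"),
    "veber_boundary": ({"tpsa": 140.0}, "veber"),    # TPSA < 140 is strict
    "logs": ({"logs": -5.5}, "logs"),
    "pains": ({"pains_alerts": ("rhod_sat_A(33)",)}, "pains"),
    "admet_gi": ({"tpsa": 135.0, "wlogp": -3.0}, "admet"),
    "admet_bbb": ({"tpsa": 60.0, "wlogp": 1.5}, "admet"),
    "admet_pgp": ({"annotations": {"pgp_substrate": "yes"}}, "admet"),
}

#: boundary cases that the documented inclusive conventions keep
_INCLUSIVE_KEPT = {
    "prefilter_mw_low_edge": {"mw": 350.0},
    "prefilter_mw_high_edge": {"mw": 500.0},
    "oprea_logp_edge": {"logp": 4.5},
    "logs_edge": {"logs": -5.0},
}


def make_filter_panel(panel_spec, seed: int = 0) -> tuple[list[PropertyRecord], dict]:
    """Build property records with exactly planted filter violations.

    ``panel_spec`` is a list of entries, each ``None``/``"clean"``, a
    violation name from :data:`_VIOLATIONS`, an inclusive-boundary name from
    :data:`_INCLUSIVE_KEPT`, ``"duplicate"`` (structure key copied from the
    previous entry), or a list of violation names. Returns the records and a
    truth map ``id -> {"violations": [...], "removed_at": stage | None}``.
    """
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    stage_order = ("prefilter", "dedupe", "oprea", "mutagenic", "veber", "logs", "pains", "admet")
    prev_key = None
    for i, entry in enumerate(panel_spec):
        cid = f"panel{i:03d}"
        fields = dict(_CLEAN_BASE)
        fields["mw"] = float(fields["mw"] + rng.uniform(-15, 15))
        key = f"KEY:{cid}"
        names: list[str] = []
        stages: list[str] = []
        if entry in (None, "clean"):
            pass
        elif entry == "duplicate":
            if prev_key is None:
                raise ValueError("'duplicate' cannot be the first panel entry")
            key = prev_key
            names, stages = ["duplicate"], ["dedupe"]
        else:
            items = [entry] if isinstance(entry, str) else list(entry)
            for name in items:
                if name in _VIOLATIONS:
                    overrides, stage = _VIOLATIONS[name]
                    fields.update(overrides)
                    names.append(name)
                    stages.append(stage)
                elif name in _INCLUSIVE_KEPT:
                    fields.update(_INCLUSIVE_KEPT[name])
                    names.append(name)
                else:
                    raise ValueError(f"unknown panel violation {name!r}")
        rec = PropertyRecord(compound_id=cid, canonical_smiles=key, **fields)
        removed_at = min(stages, key=stage_order.index) if stages else None
        records.append(rec)
        truth[cid] = {"violations": names, "removed_at": removed_at}
        prev_key = key if entry != "duplicate" else prev_key
    return records, truth


# ---------------------------------------------------------------------------
# Fixture persistence


def write_fixtures(benchmark: PlantedBenchmark, out_dir) -> dict:
    """Write a benchmark to disk: SDF library, labels CSV, truth JSON.

    Output is deterministic for a given benchmark; returns file paths keyed
    by role plus a content checksum of the truth file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sdf = out / "library.sdf"
    write_sdf(benchmark.ensembles, sdf)
    labels = out / "labels.csv"
    pd.DataFrame(
        sorted(benchmark.library.labels.items()), columns=["id", "label"]
    ).to_csv(labels, index=False)
    truth = out / "planted_truth.json"
    doc = {
        "params": benchmark.params,
        "should_match": dict(sorted(benchmark.should_match.items())),
    }
    truth.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    checksum = hashlib.sha256(truth.read_bytes()).hexdigest()
    return {"sdf": str(sdf), "labels": str(labels), "truth": str(truth), "sha256": checksum}


def read_fixtures(in_dir) -> tuple[LabeledLibrary, list, dict]:
    """Round-trip loader for :func:`write_fixtures` output."""
    from .feature_perception import read_sdf

    inp = Path(in_dir)
    ensembles = read_sdf(inp / "library.sdf")
    labels_df = pd.read_csv(inp / "labels.csv")
    lib = LabeledLibrary(dict(zip(labels_df["id"].astype(str), labels_df["label"])))
    doc = json.loads((inp / "planted_truth.json").read_text())
    return lib, ensembles, doc
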