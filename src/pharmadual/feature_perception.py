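"""Perception of pharmacophoric points from 3D conformers.

Hydrogen-bond acceptors are perceived as single qualifying N/O atoms via an
explicit, editable SMARTS pattern list; aromatic features as the unweighted
centroid of each smallest aromatic ring. Donors (N-H, O-H) are available for
completeness; hydrophobic perception is disabled by default because the
packaged query model does not use it.

Molecules are carried as thin wrappers over RDKit ``Mol`` objects with a
single 3D conformer each; a compound's alternative geometries form a
:class:`ConformerEnsemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem

__all__ = [
    "Molecule3D",
    "ConformerEnsemble",
    "PerceivedFeature",
    "FeatureSet",
    "PerceptionRules",
    "DEFAULT_ACCEPTOR_SMARTS",
    "DEFAULT_DONOR_SMARTS",
    "perceive_features",
    "ring_centroid",
    "acceptor_atoms",
    "read_sdf",
    "write_sdf",
    "mol_from_smiles",
]

# Acceptor patterns: each match's first atom is the acceptor point. The set
# covers pyridine/azole-type aromatic N, nitrile N, non-amide amines,
# carbonyl and sulfoxide O, hydroxyl and ether O; it excludes pyrrole-type
# aromatic N-H and amide N (donor-only treatment).
DEFAULT_ACCEPTOR_SMARTS = (
    "[n;X2;H0]",                                    # pyridine/azole-type aromatic N
    "[N;X1]",                                       # nitrile N
    "[N;X3;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N;a])]",  # amine N (amide excluded)
    "[O;X1;$([OX1]=[C,S,N,P])]",                    # carbonyl / sulfoxide / N-oxide O
    "[O;X2;H1]",                                    # hydroxyl O
    "[O;X2;H0;!a]",                                 # ether / ester O
)

DEFAULT_DONOR_SMARTS = (
    "[N;!H0]",
    "[O;!H0]",
)


@dataclass(frozen=True)
class PerceptionRules:
    """Substructure-pattern rules controlling feature perception."""

    acceptor_smarts: tuple[str, ...] = DEFAULT_ACCEPTOR_SMARTS
    donor_smarts: tuple[str, ...] = DEFAULT_DONOR_SMARTS
    perceive_aromatic: bool = True
    perceive_donors: bool = False
    perceive_hydrophobic: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PerceptionRules":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("acceptor_smarts", "donor_smarts"):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        for key in ("perceive_aromatic", "perceive_donors", "perceive_hydrophobic"):
            if key in doc:
                kwargs[key] = bool(doc[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        doc = {
            "acceptor_smarts": list(self.acceptor_smarts),
            "donor_smarts": list(self.donor_smarts),
            "perceive_aromatic": self.perceive_aromatic,
            "perceive_donors": self.perceive_donors,
            "perceive_hydrophobic": self.perceive_hydrophobic,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


@dataclass(frozen=True)
class Molecule3D:
    """A sanitized RDKit molecule with exactly one 3D conformer."""

    id: str
    mol: Chem.Mol

    def __post_init__(self):
        if self.mol.GetNumConformers() != 1:
            raise ValueError(
                f"{self.id!r}: Molecule3D requires exactly 1 conformer, "
                f"got {self.mol.GetNumConformers()}"
            )

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates, Angstrom, shape (n_atoms, 3)."""
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def heavy_coords(self) -> np.ndarray:
        pos = self.coords
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return pos[idx]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coordinates mapped through x -> R x + t."""
        new = Chem.Mol(self.mol)
        conf = new.GetConformer()
        pts = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        for i, p in enumerate(pts):
            conf.SetAtomPosition(i, [float(p[0]), float(p[1]), float(p[2])])
        return Molecule3D(id=self.id, mol=new)


@dataclass(frozen=True)
class ConformerEnsemble:
    """Alternative rigid geometries of one compound (shared topology)."""

    compound_id: str
    conformers: tuple[Molecule3D, ...]

    def __post_init__(self):
        object.__setattr__(self, "conformers", tuple(self.conformers))
        if not self.conformers:
            raise ValueError(f"{self.compound_id!r}: ensemble needs >= 1 conformer")
        n = self.conformers[0].mol.GetNumAtoms()
        if any(c.mol.GetNumAtoms() != n for c in self.conformers):
            raise ValueError(f"{self.compound_id!r}: conformer atom counts differ")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class PerceivedFeature:
    """One perceived ligand feature point."""

    ftype: str
    position: np.ndarray
    source_atoms: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "source_atoms", tuple(self.source_atoms))
        if self.ftype == "aromatic" and len(self.source_atoms) < 5:
            raise ValueError("aromatic feature must carry the ring atoms (>= 5)")
        if self.ftype == "acceptor" and len(self.source_atoms) != 1:
            raise ValueError("acceptor feature must carry exactly 1 source atom")


@dataclass(frozen=True)
class FeatureSet:
    """All perceived features of one conformer, in deterministic order."""

    molecule: Molecule3D
    features: tuple[PerceivedFeature, ...]

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.features)


def _require_sanitized(mol: Chem.Mol) -> None:
    if Chem.SanitizeMol(Chem.Mol(mol), catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
        raise ValueError("molecule failed sanitization; sanitize before perception")
    try:
        mol.GetRingInfo().NumRings()
    except RuntimeError as exc:  # pragma: no cover - ring info always present post-sanitize
        raise ValueError("molecule lacks ring information") from exc


def acceptor_atoms(mol: Chem.Mol, rules: PerceptionRules = PerceptionRules()) -> list[int]:
    """Indices of hydrogen-bond-acceptor atoms, deduplicated and sorted."""
    _require_sanitized(mol)
    hits: set[int] = set()
    for smarts in rules.acceptor_smarts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid acceptor SMARTS {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return sorted(hits)


def _donor_atoms(mol: Chem.Mol, rules: PerceptionRules) -> list[int]:
    hits: set[int] = set()
    for smarts in rules.donor_smarts:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return sorted(hits)


def ring_centroid(mol3d: Molecule3D, ring_atoms) -> np.ndarray:
    """Unweighted centroid of a ring's atom coordinates.

    ``ring_atoms`` must be exactly the atom set of one ring of the molecule
    (smallest set of smallest rings); anything else is an error.
    """
    ring = frozenset(int(i) for i in ring_atoms)
    rings = [frozenset(r) for r in mol3d.mol.GetRingInfo().AtomRings()]
    if ring not in rings:
        raise ValueError(f"atoms {sorted(ring)} do not form a ring of the molecule")
    return mol3d.coords[sorted(ring)].mean(axis=0)


def perceive_features(
    mol3d: Molecule3D, rules: PerceptionRules = PerceptionRules()
) -> FeatureSet:
    """Perceive pharmacophoric points of one conformer.

    Acceptors sit on the matched atom; aromatic features at the unweighted
    centroid of each smallest aromatic ring (one per ring, including each
    ring of a fused system). Features are ordered by first source-atom
    index, then type name, which makes the output deterministic.
    """
    mol = mol3d.mol
    _require_sanitized(mol)
    feats: list[PerceivedFeature] = []
    coords = mol3d.coords
    for idx in acceptor_atoms(mol, rules):
        feats.append(PerceivedFeature("acceptor", coords[idx], (idx,)))
    if rules.perceive_donors:
        for idx in _donor_atoms(mol, rules):
            feats.append(PerceivedFeature("donor", coords[idx], (idx,)))
    if rules.perceive_aromatic:
        for ring in mol.GetRingInfo().AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                pos = coords[list(ring)].mean(axis=0)
                feats.append(PerceivedFeature("aromatic", pos, tuple(sorted(ring))))
    feats.sort(key=lambda f: (f.source_atoms[0], f.ftype))
    return FeatureSet(molecule=mol3d, features=tuple(feats))


# ---------------------------------------------------------------------------
# I/O


def mol_from_smiles(smiles: str, mol_id: str, coords=None) -> Molecule3D:
    """Build a :class:`Molecule3D` from SMILES plus explicit heavy-atom coordinates.

    ``coords`` must supply one (x, y, z) per atom in RDKit atom order; when
    omitted, a flat all-zero conformer is attached (topology-only use).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r} for {mol_id!r}")
    n = mol.GetNumAtoms()
    conf = Chem.Conformer(n)
    pts = np.zeros((n, 3)) if coords is None else np.asarray(coords, dtype=float).reshape(n, 3)
    for i in range(n):
        conf.SetAtomPosition(i, [float(x) for x in pts[i]])
    mol.AddConformer(conf, assignId=True)
    return Molecule3D(id=mol_id, mol=mol)


def read_sdf(path, group_conformers: bool = True):
    """Read an SDF file into :class:`ConformerEnsemble` objects.

    Consecutive records sharing the same title (or ``_Name`` property) are
    treated as conformers of one compound. With ``group_conformers=False``
    a flat list of :class:`Molecule3D` is returned instead.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    mols: list[Molecule3D] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: record {i} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        mols.append(Molecule3D(id=name, mol=mol))
    if not group_conformers:
        return mols
    ensembles: list[ConformerEnsemble] = []
    current: list[Molecule3D] = []
    for m in mols:
        if current and m.id != current[0].id:
            ensembles.append(ConformerEnsemble(current[0].id, tuple(current)))
            current = []
        current.append(m)
    if current:
        ensembles.append(ConformerEnsemble(current[0].id, tuple(current)))
    return ensembles


def write_sdf(mols, path, feature_annotations: bool = False,
              rules: PerceptionRules = PerceptionRules()) -> None:
    """Write molecules (or ensembles) to SDF, optionally annotating features."""
    flat: list[Molecule3D] = []
    for m in mols:
        if isinstance(m, ConformerEnsemble):
            flat.extend(m.conformers)
        else:
            flat.append(m)
    writer = Chem.SDWriter(str(path))
    try:
        for m in flat:
            out = Chem.Mol(m.mol)
            out.SetProp("_Name", m.id)
            if feature_annotations:
                fs = perceive_features(m, rules)
                ann = ";".join(
                    f"{f.ftype}@{f.position[0]:.3f},{f.position[1]:.3f},{f.position[2]:.3f}"
                    for f in fs.features
                )
                out.SetProp("pharmacophore_features", ann)
            writer.write(out)
    finally:
        writer.close()
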