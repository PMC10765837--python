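"""Matching 3D conformers against a pharmacophore query.

The decision pipeline per conformer is:

1. enumerate type-consistent injective feature correspondences that cover
   every essential query feature, reach the model's minimum-match count and
   survive pairwise distance pruning;
2. rigidly align the mapped ligand feature points onto the query centers
   (Kabsch least-squares superposition, proper rotation only);
3. accept if every mapped point falls inside its query feature sphere and
   no ligand heavy atom enters an excluded volume after alignment.

Among accepted correspondences, a larger mapping beats a lower RMSD; the
RMSD is reported as the alignment-quality score. A compound is a hit if any
conformer of its ensemble is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_perception import (
    ConformerEnsemble,
    FeatureSet,
    Molecule3D,
    PerceptionRules,
    perceive_features,
)
from .pharmacophore_core import PharmacophoreModel

__all__ = [
    "Correspondence",
    "RigidTransform",
    "MatchResult",
    "enumerate_correspondences",
    "kabsch_align",
    "check_containment",
    "check_excluded_volumes",
    "match_conformer",
    "screen_library",
]

#: singular-value ratio below which an alignment is flagged degenerate
_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class Correspondence:
    """Injective map from query feature labels to perceived feature indices."""

    pairs: tuple[tuple[str, int], ...]
    covers_essentials: bool

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.pairs)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(idx for _, idx in self.pairs)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float).reshape(-1, 3) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one conformer against one model."""

    compound_id: str
    conformer_index: int
    correspondence: Correspondence
    transform: RigidTransform
    rmsd: float
    ev_clash: bool
    accepted: bool


def enumerate_correspondences(
    fs: FeatureSet, model: PharmacophoreModel
) -> list[Correspondence]:
    """All acceptable-by-necessary-conditions feature correspondences.

    A correspondence is emitted iff it is injective, type-consistent, maps
    every essential query feature, has size >= ``model.min_match`` and passes
    pairwise distance pruning: for every mapped pair (i, j),
    ``|d_ligand(i,j) - d_query(i,j)| <= r_i + r_j``. The radius-sum bound is a
    necessary condition for both points to sit inside their spheres after any
    rigid alignment, so pruning is sound. Enumeration order is deterministic:
    query features in model order, candidate ligand features by index.
    """
    qfeats = model.features
    lig_pos = fs.positions()
    n_lig = len(fs.features)
    lig_type = [f.ftype for f in fs.features]
    # precompute ligand pairwise distances
    if n_lig:
        lig_d = np.linalg.norm(lig_pos[:, None, :] - lig_pos[None, :, :], axis=-1)
    else:
        lig_d = np.zeros((0, 0))
    q_centers = model.centers()
    q_d = np.linalg.norm(q_centers[:, None, :] - q_centers[None, :, :], axis=-1)

    out: list[Correspondence] = []
    n_q = len(qfeats)

    def recurse(k: int, assigned: list[tuple[str, int]], used: set[int], q_idx: list[int]):
        if k == n_q:
            if len(assigned) >= model.min_match:
                out.append(
                    Correspondence(pairs=tuple(assigned), covers_essentials=True)
                )
            return
        # feasibility: even mapping every remaining feature can't reach min_match
        if len(assigned) + (n_q - k) < model.min_match:
            return
        qf = qfeats[k]
        for j in range(n_lig):
            if j in used or lig_type[j] != qf.ftype:
                continue
            ok = True
            for (qi, li) in zip(q_idx, (idx for _, idx in assigned)):
                tol = qfeats[qi].radius + qf.radius
                if abs(lig_d[li, j] - q_d[qi, k]) > tol:
                    ok = False
                    break
            if ok:
                assigned.append((qf.label, j))
                q_idx.append(k)
                used.add(j)
                recurse(k + 1, assigned, used, q_idx)
                used.discard(j)
                q_idx.pop()
                assigned.pop()
        if not qf.essential:
            recurse(k + 1, assigned, used, q_idx)

    recurse(0, [], set(), [])
    return out


def kabsch_align(query_pts: np.ndarray, ligand_pts: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ligand points onto query points.

    Returns the proper rotation + translation minimizing the RMSD of the
    transformed ligand points to the query points, and that minimal RMSD.
    Collinear or two-point sets are allowed: the SVD solution is still
    RMSD-optimal, the rotation about the degenerate axis is fixed by the
    deterministic SVD convention, and the transform is flagged degenerate.
    """
    q = np.asarray(query_pts, dtype=float).reshape(-1, 3)
    p = np.asarray(ligand_pts, dtype=float).reshape(-1, 3)
    if q.shape != p.shape or q.shape[0] < 1:
        raise ValueError("point sets must be same-shape and non-empty")
    qc, pc = q.mean(axis=0), p.mean(axis=0)
    q0, p0 = q - qc, p - pc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    degenerate = q.shape[0] < 3 or (s[0] > 0 and s[1] / s[0] < _DEGENERACY_TOL) or s[0] == 0
    trans = qc - rot @ pc
    tf = RigidTransform(rotation=rot, translation=trans, degenerate=bool(degenerate))
    aligned = tf.apply(p)
    rmsd = float(np.sqrt(((aligned - q) ** 2).sum() / q.shape[0]))
    return tf, rmsd


def check_containment(aligned_pts: np.ndarray, model: PharmacophoreModel, labels) -> list[bool]:
    """Per mapped feature: aligned ligand point inside its query sphere (<= radius)."""
    pts = np.asarray(aligned_pts, dtype=float).reshape(-1, 3)
    out = []
    for p, lab in zip(pts, labels):
        f = model.feature(lab)
        out.append(bool(np.linalg.norm(p - f.center) <= f.radius))
    return out


def check_excluded_volumes(mol_aligned: Molecule3D, model: PharmacophoreModel) -> bool:
    """True (clash) iff any heavy atom lies strictly inside an excluded volume."""
    if not model.excluded_volumes:
        return False
    coords = mol_aligned.heavy_coords
    for ev in model.excluded_volumes:
        if np.any(np.linalg.norm(coords - ev.center, axis=1) < ev.radius):
            return True
    return False


def match_conformer(
    mol3d: Molecule3D,
    model: PharmacophoreModel,
    rules: PerceptionRules = PerceptionRules(),
    conformer_index: int = 0,
) -> MatchResult | None:
    """Best accepted match of one conformer, or ``None`` if it is rejected.

    Among accepted correspondences the winner has the largest size, then the
    lowest RMSD, then the lexicographically smallest mapped label sequence.
    """
    fs = perceive_features(mol3d, rules)
    best: tuple | None = None
    for corr in enumerate_correspondences(fs, model):
        q_pts = np.array([model.feature(lab).center for lab in corr.labels])
        l_pts = fs.positions()[list(corr.indices)]
        tf, rmsd = kabsch_align(q_pts, l_pts)
        aligned = tf.apply(l_pts)
        if not all(check_containment(aligned, model, corr.labels)):
            continue
        clash = check_excluded_volumes(mol3d.transformed(tf.rotation, tf.translation), model)
        if clash:
            continue
        key = (-corr.size, rmsd, corr.labels)
        if best is None or key < best[0]:
            best = (key, corr, tf, rmsd)
    if best is None:
        return None
    _, corr, tf, rmsd = best
    return MatchResult(
        compound_id=mol3d.id,
        conformer_index=conformer_index,
        correspondence=corr,
        transform=tf,
        rmsd=rmsd,
        ev_clash=False,
        accepted=True,
    )


def screen_library(
    ensembles,
    model: PharmacophoreModel,
    rules: PerceptionRules = PerceptionRules(),
) -> pd.DataFrame:
    """Screen conformer ensembles; a compound is a hit if any conformer matches.

    Returns a table with one row per hit compound: ``compound_id``,
    ``conformer_index`` (the best conformer), ``size`` (matched features),
    ``rmsd`` and ``features`` (mapped query labels). Rows are in input order.
    Duplicate compound ids are an error.
    """
    seen: set[str] = set()
    rows = []
    for ens in ensembles:
        if isinstance(ens, Molecule3D):
            ens = ConformerEnsemble(ens.id, (ens,))
        if ens.compound_id in seen:
            raise ValueError(f"duplicate compound id {ens.compound_id!r}")
        seen.add(ens.compound_id)
        best: MatchResult | None = None
        for ci, conf in enumerate(ens.conformers):
            res = match_conformer(conf, model, rules, conformer_index=ci)
            if res is None:
                continue
            if best is None or (-res.correspondence.size, res.rmsd) < (
                -best.correspondence.size,
                best.rmsd,
            ):
                best = res
        if best is not None:
            rows.append(
                {
                    "compound_id": ens.compound_id,
                    "conformer_index": best.conformer_index,
                    "size": best.correspondence.size,
                    "rmsd": best.rmsd,
                    "features": "+".join(best.correspondence.labels),
                }
            )
    return pd.DataFrame(rows, columns=["compound_id", "conformer_index", "size", "rmsd", "features"])
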