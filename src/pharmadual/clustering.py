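"""Structural clustering of screening hits.

Hits are grouped by agglomerative clustering on a Tanimoto similarity
matrix of hashed circular (Morgan) fingerprints. Merging proceeds from the
most similar pair of clusters downward and stops when the largest
inter-cluster similarity falls below the threshold (default 60% — note the
threshold is on similarity, not on distance 1-s). Complete linkage is the
default because it guarantees every cross-cluster compound pair in the
final partition is below the threshold; single and average linkage are
available. One representative per cluster is drawn uniformly at random with
a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "SimilarityMatrix",
    "Clustering",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "agglomerate",
    "cluster_report",
]

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1], unit diagonal."""

    ids: tuple[str, ...]
    s: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        n = len(self.ids)
        if s.shape != (n, n):
            raise ValueError(f"matrix shape {s.shape} does not match {n} ids")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("diagonal must be 1")
        if s.min() < -1e-9 or s.max() > 1 + 1e-9:
            raise ValueError("entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Clustering:
    """Partition of compound ids with per-cluster representatives."""

    clusters: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]
    threshold: float
    final_max_similarity: float

    def __post_init__(self):
        flat = [i for c in self.clusters for i in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must be disjoint")
        for rep, cl in zip(self.representatives, self.clusters):
            if rep not in cl:
                raise ValueError(f"representative {rep!r} not in its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def fingerprint(mol) -> DataStructs.ExplicitBitVect:
    """Hashed circular substructure fingerprint (Morgan radius 2, 2048 bits)."""
    if hasattr(mol, "mol"):
        mol = mol.mol
    elif isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("invalid SMILES")
    return _fpgen.GetFingerprint(mol)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |A n B| / |A u B| of two bit vectors."""
    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


def similarity_matrix(mols, ids=None) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity of a molecule list."""
    mols = list(mols)
    if ids is None:
        ids = [getattr(m, "id", f"mol{i}") for i, m in enumerate(mols)]
    fps = [fingerprint(m) for m in mols]
    n = len(fps)
    s = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            s[i, i + 1 :] = sims
            s[i + 1 :, i] = sims
    return SimilarityMatrix(ids=tuple(ids), s=s)


_LINKAGES = {
    "complete": min,
    "single": max,
    "average": None,  # handled separately
}


def _linkage_sim(s: np.ndarray, a: tuple[int, ...], b: tuple[int, ...], linkage: str) -> float:
    block = s[np.ix_(a, b)]
    if linkage == "complete":
        return float(block.min())
    if linkage == "single":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    raise ValueError(f"unknown linkage {linkage!r}")


def agglomerate(
    sim: SimilarityMatrix,
    threshold: float = 0.60,
    seed: int = 0,
    linkage: str = "complete",
) -> Clustering:
    """Agglomerative clustering with a similarity stop criterion.

    Repeatedly merges the pair of clusters with the highest inter-cluster
    similarity (under ``linkage``) while that similarity is >= ``threshold``;
    stops when the maximum falls below it. Ties between equal-similarity
    merge candidates are broken by the lexicographically smallest pair of
    cluster member-index minima, making the partition deterministic; the
    seed only affects which member represents each cluster.
    """
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = sim.n
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    while len(clusters) > 1:
        best = None  # (sim, min_a, min_b, ia, ib)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                val = _linkage_sim(sim.s, clusters[ia], clusters[ib], linkage)
                key = (-val, min(clusters[ia]), min(clusters[ib]))
                if best is None or key < best[0]:
                    best = (key, ia, ib, val)
        _, ia, ib, val = best
        if val < threshold:
            break
        merged = tuple(sorted(clusters[ia] + clusters[ib]))
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
    # residual maximum inter-cluster similarity (1.0 sentinel when single cluster)
    if len(clusters) > 1:
        final_max = max(
            _linkage_sim(sim.s, a, b, linkage)
            for i, a in enumerate(clusters)
            for b in clusters[i + 1 :]
        )
    else:
        final_max = 0.0
    clusters.sort(key=lambda c: c[0])
    rng = np.random.default_rng(seed)
    id_clusters = tuple(tuple(sim.ids[i] for i in c) for c in clusters)
    reps = tuple(c[rng.integers(len(c))] for c in id_clusters)
    return Clustering(
        clusters=id_clusters,
        representatives=reps,
        threshold=threshold,
        final_max_similarity=final_max,
    )


def cluster_report(clustering: Clustering, mols=None) -> pd.DataFrame:
    """Cluster table sorted by size (descending; ties in member-id order).

    When ``mols`` (id -> molecule or SMILES) is given, representatives are
    rendered as canonical SMILES.
    """
    smiles = {}
    if mols is not None:
        lookup = {getattr(m, "id", None) or k: m for k, m in (
            mols.items() if isinstance(mols, dict) else ((None, m) for m in mols)
        )}
        for rep in clustering.representatives:
            m = lookup.get(rep)
            if m is None:
                continue
            rd = m.mol if hasattr(m, "mol") else (Chem.MolFromSmiles(m) if isinstance(m, str) else m)
            if rd is not None:
                smiles[rep] = Chem.MolToSmiles(rd)
    rows = [
        {
            "cluster": None,
            "representative": rep,
            "representative_smiles": smiles.get(rep, ""),
            "size": len(cl),
            "members": ";".join(cl),
            "_min_id": min(cl),
        }
        for rep, cl in zip(clustering.representatives, clustering.clusters)
    ]
    df = pd.DataFrame(rows).sort_values(
        ["size", "_min_id"], ascending=[False, True], kind="stable"
    ).drop(columns="_min_id").reset_index(drop=True)
    df["cluster"] = np.arange(1, len(df) + 1)
    return df
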