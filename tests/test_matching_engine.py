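"""Correspondence search, Kabsch alignment and screening semantics."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmadual.feature_perception import (
    ConformerEnsemble,
    FeatureSet,
    Molecule3D,
    PerceivedFeature,
    mol_from_smiles,
    perceive_features,
)
from pharmadual.matching_engine import (
    Correspondence,
    check_containment,
    check_excluded_volumes,
    enumerate_correspondences,
    kabsch_align,
    match_conformer,
    screen_library,
)
from pharmadual.pharmacophore_core import (
    ExcludedVolume,
    PharmacophoreModel,
    PharmFeature,
    build_model11,
)
from pharmadual.synthetic_data import make_benchmark, make_matcher


def fake_featureset(positions, ftypes):
    """FeatureSet with given geometry, detached from real perception."""
    positions = np.asarray(positions, dtype=float)
    carrier = mol_from_smiles("C" * max(len(positions), 1), "fake")
    feats = tuple(
        PerceivedFeature(
            ft,
            p,
            (i,) if ft != "aromatic" else (0, 1, 2, 3, 4),
        )
        for i, (p, ft) in enumerate(zip(positions, ftypes))
    )
    return FeatureSet(molecule=carrier, features=feats)


def brute_force_correspondences(fs, model):
    """Independent enumeration: all injections filtered by the same predicate."""
    out = []
    q = model.features
    n_lig = len(fs.features)
    lig = fs.positions()
    for r in range(model.min_match, len(q) + 1):
        for q_subset in itertools.combinations(range(len(q)), r):
            if not all(
                i in q_subset for i, f in enumerate(q) if f.essential
            ):
                continue
            for lig_perm in itertools.permutations(range(n_lig), r):
                if any(
                    fs.features[lj].ftype != q[qi].ftype
                    for qi, lj in zip(q_subset, lig_perm)
                ):
                    continue
                ok = True
                for (qi, li), (qj, lj) in itertools.combinations(
                    zip(q_subset, lig_perm), 2
                ):
                    dq = np.linalg.norm(q[qi].center - q[qj].center)
                    dl = np.linalg.norm(lig[li] - lig[lj])
                    if abs(dl - dq) > q[qi].radius + q[qj].radius:
                        ok = False
                        break
                if ok:
                    out.append(tuple((q[qi].label, lj) for qi, lj in zip(q_subset, lig_perm)))
    return sorted(out)


class TestEnumerateCorrespondences:
    def test_identity_mapping_found_for_exact_features(self, model11):
        fs = fake_featureset(model11.centers(), [f.ftype for f in model11.features])
        corrs = enumerate_correspondences(fs, model11)
        identity = tuple((lab, i) for i, lab in enumerate(model11.labels))
        assert identity in [c.pairs for c in corrs]
        assert all(c.size >= 4 and c.covers_essentials for c in corrs)

    def test_missing_essential_acceptor_gives_nothing(self, model11):
        # drop the feature serving F1; F2/F3 acceptors remain but are > 2 A away
        centers = model11.centers()[1:]
        fs = fake_featureset(centers, [f.ftype for f in model11.features[1:]])
        # F1 is essential and no remaining acceptor is geometrically
        # compatible with mapping it, so nothing survives
        assert enumerate_correspondences(fs, model11) == []

    def test_agrees_with_brute_force_on_toy_query(self, rng):
        toy = PharmacophoreModel(
            "toy",
            (
                PharmFeature("A", "acceptor", (0, 0, 0), 1.0, essential=True),
                PharmFeature("B", "aromatic", (4, 0, 0), 1.4),
                PharmFeature("C", "acceptor", (0, 3, 0), 1.0),
            ),
            min_match=2,
        )
        for _ in range(20):
            n = int(rng.integers(3, 7))
            pos = rng.uniform(-2, 6, size=(n, 3))
            types = [
                ["acceptor", "aromatic"][int(t)] for t in rng.integers(0, 2, size=n)
            ]
            fs = fake_featureset(pos, types)
            got = sorted(c.pairs for c in enumerate_correspondences(fs, toy))
            assert got == brute_force_correspondences(fs, toy)


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        tf, rmsd = kabsch_align(pts, pts)
        assert rmsd == pytest.approx(0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0, atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        pts = rng.uniform(-3, 3, size=(5, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + [2, -1, 4]
        tf, rmsd = kabsch_align(pts, moved)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(tf.apply(moved), pts, atol=1e-9)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)

    def test_matches_numerical_minimizer_on_perturbed_points(self, rng):
        """RMSD agrees with an independent optimizer over rigid motions."""
        from scipy.optimize import minimize

        q = rng.uniform(-3, 3, size=(4, 3))
        p = q + rng.normal(scale=0.3, size=(4, 3))
        _, rmsd = kabsch_align(q, p)

        def objective(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            moved = p @ rot.T + x[3:]
            return np.sqrt(((moved - q) ** 2).sum() / len(q))

        best = min(
            minimize(objective, x0, method="Nelder-Mead").fun
            for x0 in rng.normal(scale=1.0, size=(8, 6))
        )
        assert rmsd == pytest.approx(best, abs=1e-3)
        assert rmsd <= best + 1e-6

    def test_no_random_transform_beats_kabsch(self, rng):
        q = rng.uniform(-3, 3, size=(5, 3))
        p = q + rng.normal(scale=0.5, size=(5, 3))
        _, rmsd = kabsch_align(q, p)
        for _ in range(100):
            rot = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-5, 5, size=3)
            moved = p @ rot.T + t
            trial = np.sqrt(((moved - q) ** 2).sum() / len(q))
            assert trial >= rmsd - 1e-9

    def test_two_point_alignment_flagged_degenerate(self):
        q = np.array([[0, 0, 0], [2, 0, 0]], dtype=float)
        p = np.array([[1, 1, 0], [1, 3, 0]], dtype=float)
        tf, rmsd = kabsch_align(q, p)
        assert tf.degenerate
        assert rmsd == pytest.approx(0, abs=1e-9)

    def test_reflection_never_returned(self, rng):
        # mirror-image configurations must be fit with a proper rotation
        q = rng.uniform(-3, 3, size=(4, 3))
        p = q * np.array([-1, 1, 1])
        tf, _ = kabsch_align(q, p)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)


class TestContainmentAndVolumes:
    def test_boundary_conventions(self, model11):
        f = model11.features[0]
        at_center = f.center.reshape(1, 3)
        on_surface = (f.center + [f.radius, 0, 0]).reshape(1, 3)
        outside = (f.center + [f.radius + 0.001, 0, 0]).reshape(1, 3)
        assert check_containment(at_center, model11, ["F1"]) == [True]
        assert check_containment(on_surface, model11, ["F1"]) == [True]
        assert check_containment(outside, model11, ["F1"]) == [False]

    def test_randomized_offsets_match_direct_comparison(self, model11, rng):
        for _ in range(50):
            lab = model11.labels[int(rng.integers(5))]
            f = model11.feature(lab)
            off = rng.normal(scale=1.0, size=3)
            expected = np.linalg.norm(off) <= f.radius
            assert check_containment((f.center + off).reshape(1, 3), model11, [lab]) == [expected]

    def test_excluded_volume_strict_interior(self, model11):
        from dataclasses import replace

        mol = mol_from_smiles("C", "probe", [[0.0, 0.0, 0.0]])
        m_ev = replace(
            model11,
            excluded_volumes=(ExcludedVolume(center=(0, 0, 0), radius=1.2),),
        )
        assert check_excluded_volumes(mol, model11) is False  # no EVs
        assert check_excluded_volumes(mol, m_ev) is True      # at center
        on_surface = mol_from_smiles("C", "probe", [[1.2, 0.0, 0.0]])
        assert check_excluded_volumes(on_surface, m_ev) is False


class TestMatchConformer:
    def test_planted_matcher_accepted_with_near_zero_rmsd(self, model11):
        mol, should = make_matcher(model11, 0.0, seed=5)
        assert should
        res = match_conformer(mol, model11)
        assert res is not None and res.accepted
        assert res.correspondence.size == 5
        assert res.rmsd < 0.1

    def test_missing_essential_ring_rejected(self, model11):
        from rdkit import Chem

        mol, _ = make_matcher(model11, 0.0, seed=5)
        # delete one aromatic ring (the fragment serving F4 or F5)
        frags = Chem.GetMolFrags(mol.mol, asMols=True)
        kept = [f for f in frags if not any(a.GetIsAromatic() for a in f.GetAtoms())]
        arom = [f for f in frags if any(a.GetIsAromatic() for a in f.GetAtoms())]
        pruned = kept + arom[:1]  # only one aromatic ring left
        combined = pruned[0]
        for f in pruned[1:]:
            combined = Chem.CombineMols(combined, f)
        Chem.SanitizeMol(combined)
        res = match_conformer(Molecule3D("pruned", combined), model11)
        assert res is None

    def test_rigid_motion_invariance(self, model11, rng):
        mol, _ = make_matcher(model11, 0.4, seed=11)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        res0 = match_conformer(mol, model11)
        res1 = match_conformer(mol.transformed(rot, t), model11)
        assert (res0 is None) == (res1 is None)
        if res0 is not None:
            assert res0.correspondence.pairs == res1.correspondence.pairs
            assert res0.rmsd == pytest.approx(res1.rmsd, abs=1e-6)

    def test_larger_radii_never_lose_a_hit(self, rng):
        from pharmadual.pharmacophore_core import build_model11 as bm

        small, big = bm(1.0, 1.4), bm(1.5, 2.1)
        for seed in range(10):
            mol, _ = make_matcher(small, 0.8, seed=seed)
            if match_conformer(mol, small) is not None:
                assert match_conformer(mol, big) is not None


class TestScreenLibrary:
    def test_any_conformer_rule(self, model11):
        bench = make_benchmark(model11, n_actives=3, n_decoys=5, k_conformers=4, seed=9)
        hits = screen_library(bench.ensembles, model11)
        assert set(hits["compound_id"]) == {f"active{i}" for i in range(3)}

    def test_empty_library(self, model11):
        hits = screen_library([], model11)
        assert len(hits) == 0
        assert list(hits.columns) == ["compound_id", "conformer_index", "size", "rmsd", "features"]

    def test_duplicate_ids_rejected(self, model11):
        mol, _ = make_matcher(model11, 0.0, seed=1, mol_id="dup")
        ens = ConformerEnsemble("dup", (mol,))
        with pytest.raises(ValueError, match="duplicate"):
            screen_library([ens, ens], model11)
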