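"""Geometry reconstruction, model invariants and model-file round trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pharmadual.pharmacophore_core import (
    MODEL11_DISTANCES,
    MODEL11_LABELS,
    DistanceMatrix,
    EmbeddingError,
    MalformedModelError,
    PharmacophoreModel,
    PharmFeature,
    ProteinStructure,
    SchemaVersionError,
    UnknownFeatureTypeError,
    add_excluded_volumes,
    build_model11,
    distance_matrix,
    embed_coordinates,
    read_model,
    read_pdb,
    write_model,
)


def _pairwise(pts):
    pts = np.asarray(pts)
    return np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)


class TestEmbedding:
    def test_regular_tetrahedron_exact(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=("a", "b", "c", "d"), d=d)
        pts = embed_coordinates(dm)
        assert np.allclose(_pairwise(pts), d, atol=1e-9)

    def test_published_matrix_reproduces_printed_distances(self):
        dm = DistanceMatrix(labels=MODEL11_LABELS, d=MODEL11_DISTANCES)
        pts = embed_coordinates(dm)
        rec = _pairwise(pts)
        assert abs(rec[0, 1] - 10.07) < 0.05  # F1-F2
        assert abs(rec[1, 2] - 1.84) < 0.05   # F2-F3
        assert np.abs(rec - MODEL11_DISTANCES).max() < 0.05

    def test_random_configuration_round_trip(self, rng):
        pts_in = rng.uniform(-5, 5, size=(5, 3))
        dm = distance_matrix(pts_in, "abcde")
        pts_out = embed_coordinates(dm, tol=1e-6)
        assert np.abs(_pairwise(pts_out) - dm.d).max() < 1e-9

    def test_embedding_centered_and_deterministic(self):
        dm = DistanceMatrix(labels=MODEL11_LABELS, d=MODEL11_DISTANCES)
        a, b = embed_coordinates(dm), embed_coordinates(dm)
        assert np.array_equal(a, b)
        assert np.allclose(a.mean(axis=0), 0, atol=1e-9)

    def test_non_embeddable_matrix_raises(self):
        # 4D simplex: five points all 1.0 apart cannot exist in 3D
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(labels="abcde", d=d)
        with pytest.raises(EmbeddingError):
            embed_coordinates(dm, tol=0.05)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_property(self, seed):
        """Any exact 3D distance matrix is recovered within tolerance."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 8))
        pts = r.uniform(-8, 8, size=(n, 3))
        if np.min(_pairwise(pts)[~np.eye(n, dtype=bool)]) < 1e-3:
            return  # skip near-coincident draws
        dm = distance_matrix(pts, [f"p{i}" for i in range(n)])
        out = embed_coordinates(dm, tol=1e-6)
        assert np.abs(_pairwise(out) - dm.d).max() < 0.05

    def test_rigid_motion_leaves_distances_unchanged(self, rng):
        pts = rng.uniform(-5, 5, size=(5, 3))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + np.array([3.0, -2.0, 7.0])
        d0 = distance_matrix(pts, "abcde").d
        d1 = distance_matrix(moved, "abcde").d
        assert np.abs(d0 - d1).max() < 1e-9


class TestDistanceMatrix:
    def test_three_four_five(self):
        dm = distance_matrix([(0, 0, 0), (3, 4, 0)], ["a", "b"])
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([(1, 1, 1), (1, 1, 1)], ["a", "b"])

    def test_triangle_inequality_enforced(self):
        d = np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="triangle"):
            DistanceMatrix(labels="abc", d=d)


class TestModel11:
    def test_structure(self, model11):
        assert model11.name == "model11"
        assert len(model11.features) == 5
        assert model11.essential_labels == ("F1", "F4", "F5")
        assert model11.min_match == 4
        types = [f.ftype for f in model11.features]
        assert types == ["acceptor"] * 3 + ["aromatic"] * 2
        assert model11.excluded_volumes == ()

    def test_own_distance_matrix_matches_published(self, model11):
        assert np.abs(model11.distance_matrix().d - MODEL11_DISTANCES).max() < 0.05

    def test_deterministic_across_calls(self, model11):
        again = build_model11()
        assert np.array_equal(model11.centers(), again.centers())

    def test_invariant_violations_rejected(self):
        f = PharmFeature("F1", "acceptor", (0, 0, 0), 1.0, essential=True)
        g = PharmFeature("F2", "aromatic", (3, 0, 0), 1.4, essential=True)
        with pytest.raises(ValueError):
            PharmacophoreModel("bad", (f, g), min_match=1)  # essentials > min_match
        with pytest.raises(ValueError):
            PharmacophoreModel("bad", (f, f), min_match=1)  # duplicate labels
        with pytest.raises(ValueError):
            PharmFeature("F1", "metal", (0, 0, 0), 1.0)
        with pytest.raises(ValueError):
            PharmFeature("F1", "acceptor", (0, 0, 0), -1.0)


class TestExcludedVolumes:
    def _receptor(self):
        return ProteinStructure(
            name="toy",
            elements=("C", "N", "O"),
            coords=np.array([[4.0, 0, 0], [30.0, 0, 0], [5.0, 1, 0]]),
        )

    def test_atoms_within_shell_become_evs(self, model11):
        site = [np.zeros(3)]
        m2 = add_excluded_volumes(model11, self._receptor(), site, shell=6.0)
        assert 1 <= len(m2.excluded_volumes) <= 3
        centers = np.array([ev.center for ev in m2.excluded_volumes])
        assert any(np.allclose(c, [4.0, 0, 0]) for c in centers)
        assert all(ev.origin == "receptor-derived" for ev in m2.excluded_volumes)
        assert m2.features == model11.features

    def test_shell_zero_adds_nothing(self, model11):
        with pytest.warns(UserWarning):
            m2 = add_excluded_volumes(model11, self._receptor(), [np.zeros(3)], shell=0.0)
        assert m2.excluded_volumes == ()

    def test_atom_on_feature_center_still_creates_ev(self, model11):
        rec = ProteinStructure("toy", ("C",), model11.features[0].center.reshape(1, 3))
        m2 = add_excluded_volumes(model11, rec, [model11.features[0].center], shell=6.0)
        assert len(m2.excluded_volumes) == 1  # clash handling is the matcher's job

    def test_empty_receptor_rejected(self, model11):
        empty = ProteinStructure("e", (), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            add_excluded_volumes(model11, empty, [np.zeros(3)])


class TestPdbReading:
    def test_atom_records_and_residue_text(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A  12      11.104   6.134  -6.504  1.00  0.00           N\n"
            "ATOM      2  H   ALA A  12      11.500   6.500  -6.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A 101A      1.000   2.000   3.000  1.00  0.00           O\n"
            "REMARK ignored\n"
        )
        prot = read_pdb(pdb)
        assert prot.n_atoms == 2  # hydrogen dropped
        assert prot.elements == ("N", "O")
        assert prot.residue_ids == ("12", "101A")
        assert np.allclose(prot.coords[0], [11.104, 6.134, -6.504])


class TestModelIO:
    def test_round_trip(self, model11, tmp_path):
        path = tmp_path / "m.json"
        write_model(model11, path)
        back = read_model(path)
        assert back.name == model11.name
        assert back.min_match == model11.min_match
        for a, b in zip(back.features, model11.features):
            assert a.label == b.label and a.ftype == b.ftype
            assert a.essential == b.essential and a.radius == b.radius
            assert np.allclose(a.center, b.center)

    def test_unknown_ftype_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({
            "schema_version": 1,
            "features": [{"label": "F1", "ftype": "metal", "center": [0, 0, 0]}],
        }))
        with pytest.raises(UnknownFeatureTypeError):
            read_model(path)

    def test_malformed_and_version_errors_distinct(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(MalformedModelError):
            read_model(bad)
        wrong = tmp_path / "wrong.json"
        wrong.write_text(json.dumps({"schema_version": 99, "features": []}))
        with pytest.raises(SchemaVersionError):
            read_model(wrong)

    def test_minimal_model_gets_defaults(self, tmp_path):
        path = tmp_path / "mini.json"
        path.write_text(json.dumps({
            "features": [{"label": "A", "ftype": "aromatic", "center": [1, 2, 3]}],
        }))
        m = read_model(path)
        assert m.features[0].radius == 1.4  # aromatic default
        assert m.features[0].essential is False
        assert m.min_match == 1
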