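"""Pharmacophore model data structures and geometry.

A pharmacophore model is an abstract 3D arrangement of chemical features
(hydrogen-bond acceptors/donors, aromatic ring centers, hydrophobic points)
required for binding, each represented as a sphere (center + tolerance
radius), optionally surrounded by excluded-volume spheres marking
receptor-occupied space.

The reference model shipped here ("model11") is a five-feature dual-kinase
hinge-binder query — three acceptors and two aromatic features — whose
geometry is reconstructed from its published inter-feature distance matrix
by classical multidimensional scaling, since only distances (not
coordinates) are reported for it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FEATURE_TYPES",
    "PharmFeature",
    "ExcludedVolume",
    "PharmacophoreModel",
    "DistanceMatrix",
    "ProteinStructure",
    "ModelFormatError",
    "MalformedModelError",
    "UnknownFeatureTypeError",
    "SchemaVersionError",
    "EmbeddingError",
    "MODEL11_LABELS",
    "MODEL11_DISTANCES",
    "embed_coordinates",
    "distance_matrix",
    "build_model11",
    "add_excluded_volumes",
    "read_pdb",
    "read_model",
    "write_model",
]

FEATURE_TYPES = frozenset({"acceptor", "donor", "aromatic", "hydrophobic"})

#: Default tolerance radii (Angstrom) when a model does not specify them.
DEFAULT_RADII = {"acceptor": 1.0, "donor": 1.0, "aromatic": 1.4, "hydrophobic": 1.4}

SCHEMA_VERSION = 1

# Inter-feature distances (Angstrom) of the selected five-feature model:
# three H-bond acceptors (F1-F3) and two aromatic centers (F4, F5).
MODEL11_LABELS = ("F1", "F2", "F3", "F4", "F5")
MODEL11_DISTANCES = np.array(
    [
        [0.00, 10.07, 8.67, 1.61, 5.20],
        [10.07, 0.00, 1.84, 8.55, 4.90],
        [8.67, 1.84, 0.00, 7.10, 3.68],
        [1.61, 8.55, 7.10, 0.00, 3.74],
        [5.20, 4.90, 3.68, 3.74, 0.00],
    ]
)
MODEL11_TYPES = ("acceptor", "acceptor", "acceptor", "aromatic", "aromatic")
MODEL11_ESSENTIAL = ("F1", "F4", "F5")
MODEL11_MIN_MATCH = 4


class ModelFormatError(ValueError):
    """Base class for model serialization problems."""


class MalformedModelError(ModelFormatError):
    """File is not a syntactically valid model document."""


class UnknownFeatureTypeError(ModelFormatError):
    """A feature declares a type outside the closed feature-type set."""


class SchemaVersionError(ModelFormatError):
    """Document schema version is not supported."""


class EmbeddingError(ValueError):
    """Distance matrix could not be embedded in 3D within tolerance."""


@dataclass(frozen=True)
class PharmFeature:
    """One pharmacophoric feature sphere.

    Parameters
    ----------
    label : str
        Short identifier, unique within a model (e.g. ``"F1"``).
    ftype : str
        One of :data:`FEATURE_TYPES`.
    center : ndarray of shape (3,)
        Feature center, Angstrom.
    radius : float
        Tolerance sphere radius, Angstrom; must be positive.
    essential : bool
        Essential features must be matched in every accepted hit; partial
        features only contribute toward the minimum-match count.
    """

    label: str
    ftype: str
    center: np.ndarray
    radius: float
    essential: bool = False

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise UnknownFeatureTypeError(
                f"unknown feature type {self.ftype!r}; expected one of {sorted(FEATURE_TYPES)}"
            )
        if not self.radius > 0:
            raise ValueError(f"feature {self.label!r}: radius must be > 0, got {self.radius}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"feature {self.label!r}: non-finite center")


@dataclass(frozen=True)
class ExcludedVolume:
    """Sphere marking receptor-occupied space; ligand heavy atoms may not enter."""

    center: np.ndarray
    radius: float
    origin: str = "manual"  # "receptor-derived" or "manual"

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"excluded volume radius must be > 0, got {self.radius}")
        if self.origin not in ("receptor-derived", "manual"):
            raise ValueError(f"unknown excluded-volume origin {self.origin!r}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))


@dataclass(frozen=True)
class PharmacophoreModel:
    """A named set of feature spheres plus matching rules.

    ``min_match`` is the minimum number of simultaneously matched features
    an acceptable hit must map (essential features are always required and
    count toward this minimum).
    """

    name: str
    features: tuple[PharmFeature, ...]
    min_match: int
    excluded_volumes: tuple[ExcludedVolume, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "excluded_volumes", tuple(self.excluded_volumes))
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate feature labels in model {self.name!r}")
        if not 0 < self.min_match <= len(self.features):
            raise ValueError(
                f"min_match={self.min_match} outside 1..{len(self.features)}"
            )
        n_essential = sum(f.essential for f in self.features)
        if n_essential > self.min_match:
            raise ValueError(
                f"{n_essential} essential features exceed min_match={self.min_match}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.features)

    @property
    def essential_labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.features if f.essential)

    def feature(self, label: str) -> PharmFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])

    def distance_matrix(self) -> "DistanceMatrix":
        return distance_matrix([f.center for f in self.features], self.labels)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise inter-feature distances, Angstrom."""

    labels: tuple[str, ...]
    d: np.ndarray

    #: slack allowed on the triangle inequality, to absorb printed rounding
    TRIANGLE_SLACK = 0.1

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        off = d[~np.eye(n, dtype=bool)]
        if n > 1 and not np.all(off > 0):
            raise ValueError("all off-diagonal distances must be > 0")
        # triangle inequality with slack for rounded published entries
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if d[i, j] > d[i, k] + d[k, j] + self.TRIANGLE_SLACK:
                        raise ValueError(
                            f"triangle inequality violated for "
                            f"({self.labels[i]},{self.labels[j]},{self.labels[k]})"
                        )

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ProteinStructure:
    """Minimal receptor representation: heavy atoms from ATOM/HETATM records.

    Residue numbering is preserved verbatim as text (insertion codes kept).
    """

    name: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    residue_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 3))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def read_pdb(path, name: str | None = None, heavy_only: bool = True) -> ProteinStructure:
    """Read ATOM/HETATM records of a PDB file into a :class:`ProteinStructure`.

    Only the coordinate records are consulted; residue numbers are kept as
    the raw column text (1-based author numbering, insertion codes intact).
    """
    elements, coords, resids = [], [], []
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            element = line[76:78].strip() or line[12:16].strip()[:1]
            if heavy_only and element.upper() == "H":
                continue
            coords.append(
                (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            )
            elements.append(element)
            resids.append(line[22:27].strip())
    if not elements:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return ProteinStructure(
        name=name or str(path),
        elements=tuple(elements),
        coords=np.array(coords),
        residue_ids=tuple(resids),
    )


def embed_coordinates(dm: DistanceMatrix, tol: float = 0.05) -> np.ndarray:
    """Recover 3D coordinates from a distance matrix by classical MDS.

    The Gram matrix is formed by double-centering the squared distances,
    eigendecomposed, negative eigenvalues clamped to zero, and the top three
    components retained. The configuration is centered at the origin; the
    sign of each principal axis is fixed so that the first feature with a
    non-negligible coordinate on that axis has a positive one, which makes
    the embedding deterministic.

    Parameters
    ----------
    dm : DistanceMatrix
    tol : float
        Maximum allowed residual |d_in - d_out| on any pair, Angstrom.
        The default 0.05 absorbs two-decimal rounding of published tables.

    Returns
    -------
    ndarray of shape (n, 3)

    Raises
    ------
    EmbeddingError
        If the recomputed distances deviate from ``dm`` by more than ``tol``
        (matrix not 3D-embeddable within rounding).
    """
    d = dm.d
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    k = min(3, n)
    pts = evecs[:, :k] * np.sqrt(evals[:k])
    if k < 3:
        pts = np.hstack([pts, np.zeros((n, 3 - k))])
    # deterministic axis orientation
    for axis in range(3):
        col = pts[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if nz.size and col[nz[0]] < 0:
            pts[:, axis] = -col
    pts -= pts.mean(axis=0)
    rec = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    err = float(np.abs(rec - d).max())
    if err > tol:
        raise EmbeddingError(
            f"distance matrix not 3D-embeddable within {tol} A (residual {err:.4f} A)"
        )
    return pts


def distance_matrix(points, labels) -> DistanceMatrix:
    """Euclidean distance matrix of a point configuration.

    Inverse of :func:`embed_coordinates` up to rigid motion. Raises if the
    result would violate :class:`DistanceMatrix` invariants (e.g. duplicate
    points give a zero off-diagonal distance).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] != len(tuple(labels)):
        raise ValueError("labels and points length mismatch")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return DistanceMatrix(labels=tuple(labels), d=d)


def build_model11(
    acceptor_radius: float = DEFAULT_RADII["acceptor"],
    aromatic_radius: float = DEFAULT_RADII["aromatic"],
) -> PharmacophoreModel:
    """Construct the packaged five-feature dual ROCK1/ASK1 query model.

    Features F1-F3 are hydrogen-bond acceptors (catalytic-lysine and hinge
    interactions), F4-F5 aromatic ring centers near the catalytic domain.
    F1, F4 and F5 are essential; F2 and F3 are partial, with a minimum
    requirement of four matched features in total. Coordinates are the
    classical-MDS embedding of the published inter-feature distance matrix.
    The model ships without excluded volumes; use :func:`add_excluded_volumes`
    with a receptor structure to add them.
    """
    dm = DistanceMatrix(labels=MODEL11_LABELS, d=MODEL11_DISTANCES)
    pts = embed_coordinates(dm)
    radii = {"acceptor": acceptor_radius, "aromatic": aromatic_radius}
    features = tuple(
        PharmFeature(
            label=lab,
            ftype=ftype,
            center=pts[i],
            radius=radii[ftype],
            essential=lab in MODEL11_ESSENTIAL,
        )
        for i, (lab, ftype) in enumerate(zip(MODEL11_LABELS, MODEL11_TYPES))
    )
    return PharmacophoreModel(name="model11", features=features, min_match=MODEL11_MIN_MATCH)


def add_excluded_volumes(
    model: PharmacophoreModel,
    receptor: ProteinStructure,
    ligand_site,
    shell: float = 8.0,
    ev_radius: float = 1.2,
) -> PharmacophoreModel:
    """Add one excluded volume per receptor heavy atom near the binding site.

    Every receptor atom within ``shell`` Angstrom of any site point becomes
    an excluded-volume sphere of radius ``ev_radius`` centered on the atom.
    Existing features and excluded volumes are unchanged; a new model is
    returned.
    """
    if receptor.n_atoms == 0:
        raise ValueError("receptor has no atoms")
    site = np.asarray(ligand_site, dtype=float).reshape(-1, 3)
    if site.shape[0] == 0:
        raise ValueError("ligand_site is empty")
    dists = np.linalg.norm(receptor.coords[:, None, :] - site[None, :, :], axis=-1)
    within = np.nonzero(dists.min(axis=1) <= shell)[0]
    if within.size == 0:
        warnings.warn(
            f"no receptor atoms within {shell} A of the site; model unchanged",
            stacklevel=2,
        )
        return model
    evs = tuple(
        ExcludedVolume(center=receptor.coords[i], radius=ev_radius, origin="receptor-derived")
        for i in within
    )
    return replace(model, excluded_volumes=model.excluded_volumes + evs)


# ---------------------------------------------------------------------------
# JSON serialization


def _feature_to_dict(f: PharmFeature) -> dict:
    return {
        "label": f.label,
        "ftype": f.ftype,
        "center": [float(x) for x in f.center],
        "radius": float(f.radius),
        "essential": bool(f.essential),
    }


def write_model(model: PharmacophoreModel, path) -> None:
    """Write a model to the versioned JSON format (lossless round trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "min_match": model.min_match,
        "features": [_feature_to_dict(f) for f in model.features],
        "excluded_volumes": [
            {"center": [float(x) for x in ev.center], "radius": float(ev.radius), "origin": ev.origin}
            for ev in model.excluded_volumes
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_model(path) -> PharmacophoreModel:
    """Read a model from the JSON format written by :func:`write_model`.

    Missing optional fields get defaults (radius by feature type,
    ``essential`` false, no excluded volumes).
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MalformedModelError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "features" not in doc:
        raise MalformedModelError(f"{path}: missing 'features'")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    features = []
    for fd in doc["features"]:
        try:
            ftype = fd["ftype"]
            label = fd["label"]
            center = fd["center"]
        except (KeyError, TypeError) as exc:
            raise MalformedModelError(f"{path}: bad feature entry {fd!r}") from exc
        if ftype not in FEATURE_TYPES:
            raise UnknownFeatureTypeError(f"{path}: unknown ftype {ftype!r} in {label!r}")
        features.append(
            PharmFeature(
                label=label,
                ftype=ftype,
                center=center,
                radius=float(fd.get("radius", DEFAULT_RADII[ftype])),
                essential=bool(fd.get("essential", False)),
            )
        )
    evs = tuple(
        ExcludedVolume(center=ed["center"], radius=float(ed["radius"]), origin=ed.get("origin", "manual"))
        for ed in doc.get("excluded_volumes", [])
    )
    return PharmacophoreModel(
        name=doc.get("name", "model"),
        features=tuple(features),
        min_match=int(doc.get("min_match", len(features))),
        excluded_volumes=evs,
    )
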