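"""Reference face space: a polar grid of faces on a random 2D slice.

Faces are points in a D-dimensional reference space whose origin is the
norm (average) face.  Identity is carried by direction from the norm and
distinctiveness by eccentricity.  A stimulus set is a polar grid of 12
faces on a randomly oriented plane through the origin: 3 eccentricity
levels (30%, 100% and 170% of a mean eccentricity ``r``) crossed with 4
directions at 60 degree separation spanning a half circle.  Each face is
shown at two mirror-symmetric viewpoints (left, right) which share the
same face-space coordinate, giving 24 stimulus conditions.

The grid's Euclidean distance matrix is the reference against which
perceptual and simulated-cortical dissimilarity structures are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ECC_SCALES",
    "DIRECTIONS_DEG",
    "VIEWPOINTS",
    "SliceBasis",
    "FaceSpaceGrid",
    "RDM",
    "sample_slice",
    "build_polar_grid",
    "euclidean_rdm",
]

#: Eccentricity levels as fractions of the mean eccentricity (sub-caricature,
#: typical, caricature).
ECC_SCALES = (0.3, 1.0, 1.7)

#: Polar-grid directions in degrees; 4 directions at 60 degree separation
#: spanning a half circle, with 0 deg aligned with the first basis vector.
DIRECTIONS_DEG = (0.0, 60.0, 120.0, 180.0)

VIEWPOINTS = ("left", "right")

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class SliceBasis:
    """An orthonormal 2-frame defining a plane through the origin.

    Attributes
    ----------
    dimension
        Ambient dimensionality D of the reference space.
    basis
        Array of shape (2, D); rows are unit-length, mutually orthogonal
        direction vectors spanning the plane.
    """

    dimension: int
    basis: np.ndarray

    def __post_init__(self) -> None:
        basis = np.asarray(self.basis, dtype=float)
        if basis.shape != (2, self.dimension):
            raise ValueError(
                f"basis must have shape (2, {self.dimension}), got {basis.shape}"
            )
        norms = np.linalg.norm(basis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("basis vectors must be unit length")
        if abs(float(basis[0] @ basis[1])) > 1e-8:
            raise ValueError("basis vectors must be orthogonal")
        object.__setattr__(self, "basis", basis)

    def embed(self, coords_2d: np.ndarray) -> np.ndarray:
        """Map 2D plane coordinates into the D-dimensional space."""
        coords_2d = np.atleast_2d(np.asarray(coords_2d, dtype=float))
        return coords_2d @ self.basis


def sample_slice(dimension: int, rng: np.random.Generator) -> SliceBasis:
    """Draw a uniformly random (rotation-invariant) orthonormal 2-frame.

    Two independent standard-normal D-vectors are orthonormalized by QR
    decomposition; sign-fixing the diagonal of R makes the map from the
    Gaussian draw to the frame unique.  The spherical symmetry of the
    Gaussian makes the resulting plane orientation uniform.

    Parameters
    ----------
    dimension
        Ambient dimensionality D (>= 2).
    rng
        Seeded random generator; the draw is deterministic given its state.
    """
    if dimension < 2:
        raise ValueError(f"dimension must be >= 2, got {dimension}")
    raw = rng.standard_normal((dimension, 2))
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # make decomposition unique
    return SliceBasis(dimension=dimension, basis=q.T)


@dataclass
class FaceSpaceGrid:
    """The 12-face polar grid and its 24 (identity x viewpoint) conditions.

    Faces are ordered eccentricity-major (the 4 sub-caricatures first, then
    typicals, then caricatures), identity indices 1-12.  Conditions are
    ordered identity-major then viewpoint: (id01, left), (id01, right),
    (id02, left), ...
    """

    mean_eccentricity: float
    basis: SliceBasis
    identities: np.ndarray = field(repr=False)  # (12,) int, 1-based
    ecc_levels: np.ndarray = field(repr=False)  # (12,) float
    angles_deg: np.ndarray = field(repr=False)  # (12,) float
    coords_2d: np.ndarray = field(repr=False)  # (12, 2)

    @property
    def n_faces(self) -> int:
        return len(self.identities)

    @property
    def n_conditions(self) -> int:
        return 2 * self.n_faces

    @property
    def embedded_coords(self) -> np.ndarray:
        """(12, D) face coordinates in the ambient space."""
        return self.basis.embed(self.coords_2d)

    @property
    def face_labels(self) -> list[str]:
        return [f"id{i:02d}" for i in self.identities]

    @property
    def condition_labels(self) -> list[str]:
        return [
            f"id{i:02d}-{vp}" for i in self.identities for vp in VIEWPOINTS
        ]

    @property
    def condition_coords_2d(self) -> np.ndarray:
        """(24, 2) coordinates; both viewpoints of an identity coincide."""
        return np.repeat(self.coords_2d, 2, axis=0)

    @property
    def condition_ecc_levels(self) -> np.ndarray:
        return np.repeat(self.ecc_levels, 2)

    @property
    def condition_viewpoints(self) -> np.ndarray:
        return np.tile(np.array(VIEWPOINTS), self.n_faces)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the 24 conditions, embedded coordinates included."""
        emb = np.repeat(self.embedded_coords, 2, axis=0)
        data = {
            "identity": np.repeat(self.identities, 2),
            "viewpoint": self.condition_viewpoints,
            "ecc_level": np.repeat(self.ecc_levels, 2),
            "angle_deg": np.repeat(self.angles_deg, 2),
            "x": np.repeat(self.coords_2d[:, 0], 2),
            "y": np.repeat(self.coords_2d[:, 1], 2),
        }
        frame = pd.DataFrame(data)
        for k in range(self.basis.dimension):
            frame[f"dim{k:02d}"] = emb[:, k]
        return frame

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_polar_grid(
    mean_eccentricity: float, basis: SliceBasis
) -> FaceSpaceGrid:
    """Place the 12-face polar grid on the plane spanned by ``basis``.

    Parameters
    ----------
    mean_eccentricity
        Reference scale r (> 0); eccentricity levels are 0.3 r, 1.0 r and
        1.7 r.
    basis
        Slice orientation from :func:`sample_slice`.
    """
    if mean_eccentricity <= 0:
        raise ValueError("mean_eccentricity must be positive")
    eccs, angles = [], []
    for scale in ECC_SCALES:
        for angle in DIRECTIONS_DEG:
            eccs.append(scale * mean_eccentricity)
            angles.append(angle)
    eccs = np.array(eccs)
    angles = np.array(angles)
    theta = np.deg2rad(angles)
    coords = np.column_stack([eccs * np.cos(theta), eccs * np.sin(theta)])
    return FaceSpaceGrid(
        mean_eccentricity=float(mean_eccentricity),
        basis=basis,
        identities=np.arange(1, 13),
        ecc_levels=eccs,
        angles_deg=angles,
        coords_2d=coords,
    )


@dataclass
class RDM:
    """A labeled symmetric dissimilarity matrix.

    ``metric`` tags the provenance of the entries: ``euclidean`` (model or
    reference distances), ``crossvalidated`` (crossnobis estimates, which
    may be negative), ``percent-choice`` (pair-of-pairs judgments) or
    ``correlation`` (1 - Pearson r between feature vectors).
    """

    labels: list[str]
    matrix: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, atol=1e-8, rtol=0):
            raise ValueError("dissimilarity matrix must be symmetric")
        self.matrix = m

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    @property
    def vector(self) -> np.ndarray:
        """Off-diagonal entries in condensed (pair) order."""
        i, j = np.triu_indices(self.n_conditions, k=1)
        return self.matrix[i, j]

    @classmethod
    def from_vector(
        cls, vector: np.ndarray, labels: list[str], metric: str = "euclidean"
    ) -> "RDM":
        return cls(labels=list(labels), matrix=squareform(vector), metric=metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def save(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = f"metric={self.metric}"
        frame.to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "RDM":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        metric = "euclidean"
        if frame.index.name and frame.index.name.startswith("metric="):
            metric = frame.index.name.split("=", 1)[1]
        matrix = frame.to_numpy(dtype=float)
        if not np.allclose(matrix, matrix.T, atol=1e-8, rtol=0):
            raise ValueError(f"RDM file {path} is not symmetric")
        return cls(labels=list(frame.columns), matrix=matrix, metric=metric)


def euclidean_rdm(
    coords: np.ndarray, labels: list[str] | None = None
) -> RDM:
    """Pairwise Euclidean distance matrix for a set of points.

    ``coords`` has one row per condition; all rows must share a dimension.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need >= 2 points of equal dimension")
    if labels is None:
        labels = [f"c{i:02d}" for i in range(coords.shape[0])]
    if len(labels) != coords.shape[0]:
        raise ValueError("label count does not match point count")
    return RDM(
        labels=list(labels),
        matrix=squareform(pdist(coords)),
        metric="euclidean",
    )
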