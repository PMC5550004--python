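"""Image-input predictors: the Gabor-filter model and a pixelwise control.

The Gabor-filter model receives gray-scale stimulus images rather than
face-space coordinates.  Images are filtered by 5 banks of Gabor filters
that vary in spatial scale; within a bank, filters tile a square grid of
center positions (spacing proportional to the wavelength, so coarser for
lower spatial frequencies) and cover 8 orientations, each as a quadrature
pair of phases.  Phase is collapsed into non-negative contrast energy
(root-sum-of-squares over the pair).  Energies are weighted per bank (5
free parameters) and passed through two measurement-level population
averaging stages: a hemifield-specific pool (filters left/right of the
vertical midline shrink toward their side's mean, strength ``p_hemi``)
followed by a global pool (strength ``p_global``).  The model's
dissimilarity prediction is the Euclidean distance matrix between pooled
feature vectors.

Mirror-symmetric views of a face drive mirror-symmetric Gabor features:
activity patterns differ, but feature means match, so pooling renders
symmetric views similar without any intrinsic view-invariant computation.
Filter center grids here are exactly symmetric about the image midline
and orientations are closed under left-right reflection, so with full
global pooling the mirror-pair distance vanishes identically.

The pixelwise-correlation predictor is a parameter-free control: one
minus the Pearson correlation between raw intensity vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .face_space import RDM, euclidean_rdm
from .encoding_models import population_average

__all__ = [
    "GaborModelParams",
    "GaborFilterBank",
    "build_filter_bank",
    "contrast_energy",
    "gabor_feature_vector",
    "gabor_rdm",
    "pixelwise_correlation_rdm",
]

#: Octave-spaced wavelengths in pixels for a 96-pixel image; scaled
#: proportionally for other sizes.
DEFAULT_WAVELENGTHS_96 = (32.0, 16.0, 8.0, 4.0, 2.0)

#: Gaussian envelope standard deviation as a fraction of the wavelength.
SIGMA_PER_WAVELENGTH = 0.5


@dataclass(frozen=True)
class GaborModelParams:
    """Fitted parameters of the Gabor model: 5 bank weights + 2 pools."""

    bank_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    p_hemi: float = 0.0
    p_global: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.bank_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("bank weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("at least one bank weight must be positive")
        for name in ("p_hemi", "p_global"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class _BankGeometry:
    wavelength: float
    sigma: float
    spacing: float
    centers: np.ndarray  # (m, 2) float (x, y), mirror-symmetric about midline
    n_grid: int


class GaborFilterBank:
    """Filter geometry for one image resolution.

    Every filter is evaluated explicitly over the full image support and
    is made DC-free (mean subtracted) and unit-norm; the two phases of a
    quadrature pair differ only by a 90 degree carrier phase shift.
    """

    def __init__(
        self,
        image_size: int,
        wavelengths: tuple[float, ...],
        n_orientations: int = 8,
    ) -> None:
        if image_size < 32:
            raise ValueError("image_size must be >= 32")
        self.image_size = int(image_size)
        self.n_orientations = int(n_orientations)
        self.orientations = np.pi * np.arange(n_orientations) / n_orientations
        self.phases = (0.0, -np.pi / 2.0)  # quadrature pair (cos, sin)
        self.banks: list[_BankGeometry] = []
        mid = (image_size - 1) / 2.0  # continuous midline of the pixel grid
        for wav in wavelengths:
            if wav < 2.0:
                raise ValueError(
                    f"wavelength {wav:.2f} px is below the 2-px sampling "
                    "limit; pass explicit wavelengths for this image size"
                )
            spacing = float(wav)
            half = int(image_size // (2.0 * spacing))
            if half < 1:
                raise ValueError(
                    f"image too small for the coarsest bank "
                    f"(wavelength {wav:.2f} px)"
                )
            # Offsets spacing/2, 3*spacing/2, ... about the midline: the
            # center set is exactly closed under left-right reflection and
            # never touches the midline itself.
            offsets = spacing * (np.arange(half) + 0.5)
            axis = np.sort(np.concatenate([mid - offsets, mid + offsets]))
            xs, ys = np.meshgrid(axis, axis)
            centers = np.column_stack([xs.ravel(), ys.ravel()])
            self.banks.append(
                _BankGeometry(
                    wavelength=float(wav),
                    sigma=SIGMA_PER_WAVELENGTH * float(wav),
                    spacing=spacing,
                    centers=centers,
                    n_grid=2 * half,
                )
            )
        # Feature bookkeeping (one feature = one position x orientation,
        # phases collapsed by contrast energy), bank-major order.
        bank_idx, cx = [], []
        for b, geo in enumerate(self.banks):
            m = geo.centers.shape[0]
            bank_idx.append(np.full(m * n_orientations, b))
            cx.append(np.repeat(geo.centers[:, 0], n_orientations))
        self.feature_bank = np.concatenate(bank_idx)
        self.feature_center_x = np.concatenate(cx)

    @property
    def n_banks(self) -> int:
        return len(self.banks)

    @property
    def n_features(self) -> int:
        """Number of contrast-energy features (positions x orientations)."""
        return len(self.feature_bank)

    @property
    def n_filters(self) -> int:
        """Number of raw filters (positions x orientations x 2 phases)."""
        return 2 * self.n_features

    @property
    def left_mask(self) -> np.ndarray:
        """Features whose center lies left of (or on) the vertical midline."""
        return self.feature_center_x <= (self.image_size - 1) / 2.0

    def _pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        ax = np.arange(self.image_size, dtype=float)
        px, py = np.meshgrid(ax, ax)
        return px.ravel(), py.ravel()

    def filter_image(
        self, bank: int, center_index: int, orientation_index: int, phase_index: int
    ) -> np.ndarray:
        """Materialize one DC-free, unit-norm filter as a 2D image."""
        geo = self.banks[bank]
        cx, cy = geo.centers[center_index]
        theta = self.orientations[orientation_index]
        phase = self.phases[phase_index]
        px, py = self._pixel_grid()
        f = self._evaluate(px - cx, py - cy, geo, theta, phase)
        f -= f.mean()
        f /= np.linalg.norm(f)
        return f.reshape(self.image_size, self.image_size)

    @staticmethod
    def _evaluate(dx, dy, geo: _BankGeometry, theta: float, phase: float):
        envelope = np.exp(-(dx**2 + dy**2) / (2.0 * geo.sigma**2))
        carrier = np.cos(
            2.0 * np.pi * (dx * np.cos(theta) + dy * np.sin(theta))
            / geo.wavelength
            + phase
        )
        return envelope * carrier

    def energy_matrix(self, images: np.ndarray) -> np.ndarray:
        """Contrast energies for a stack of images.

        Parameters
        ----------
        images
            Array (n_images, size, size) or a single (size, size) image.

        Returns
        -------
        Array (n_images, n_features) of non-negative contrast energies in
        bank-major, then position, then orientation order.
        """
        images = np.asarray(images, dtype=float)
        single = images.ndim == 2
        if single:
            images = images[None]
        if images.shape[1:] != (self.image_size, self.image_size):
            raise ValueError(
                f"images must be {self.image_size}x{self.image_size}, "
                f"got {images.shape[1:]}"
            )
        flat = images.reshape(images.shape[0], -1).T  # (npx, K)
        px, py = self._pixel_grid()
        blocks = []
        for geo in self.banks:
            # Transcendentals are evaluated in float32 for speed (the
            # isotropic envelope once per bank, one cos/sin pair per
            # orientation); DC removal and normalization run in float64 so
            # the zero-mean/unit-norm filter properties hold to full
            # precision.
            dx = (px[None, :] - geo.centers[:, 0][:, None]).astype(np.float32)
            dy = (py[None, :] - geo.centers[:, 1][:, None]).astype(np.float32)
            env = np.exp(-(dx**2 + dy**2) / np.float32(2.0 * geo.sigma**2))
            freq = np.float32(2.0 * np.pi / geo.wavelength)
            m = geo.centers.shape[0]
            bank_energy = np.empty((flat.shape[1], m, self.n_orientations))
            for oi, theta in enumerate(self.orientations):
                arg = freq * (
                    np.float32(np.cos(theta)) * dx
                    + np.float32(np.sin(theta)) * dy
                )
                quad = []
                # phases (0, -pi/2): cos(arg) and sin(arg)
                for f in (env * np.cos(arg), env * np.sin(arg)):
                    f = f.astype(np.float64)
                    f -= f.mean(axis=1, keepdims=True)
                    f /= np.linalg.norm(f, axis=1, keepdims=True)
                    quad.append(f @ flat)  # (m, K)
                bank_energy[:, :, oi] = contrast_energy(quad[0], quad[1]).T
            blocks.append(bank_energy.reshape(flat.shape[1], -1))
        out = np.concatenate(blocks, axis=1)
        return out[0] if single else out


def build_filter_bank(
    image_size: int,
    n_banks: int = 5,
    n_orientations: int = 8,
    wavelengths: tuple[float, ...] | None = None,
) -> GaborFilterBank:
    """Construct the multi-scale Gabor filter bank for one image size.

    Default wavelengths are octave-spaced (32, 16, 8, 4, 2 px at a 96-px
    image) and scale proportionally with ``image_size``; grid spacing
    equals the wavelength and the envelope sigma is half the wavelength.
    """
    if wavelengths is None:
        scale = image_size / 96.0
        wavelengths = tuple(w * scale for w in DEFAULT_WAVELENGTHS_96[:n_banks])
    elif len(wavelengths) != n_banks:
        raise ValueError("number of wavelengths must equal n_banks")
    return GaborFilterBank(image_size, tuple(wavelengths), n_orientations)


def contrast_energy(resp_phase0: np.ndarray, resp_phase90: np.ndarray) -> np.ndarray:
    """Phase-invariant energy: sqrt(a^2 + b^2) over a quadrature pair."""
    a = np.asarray(resp_phase0, dtype=float)
    b = np.asarray(resp_phase90, dtype=float)
    return np.sqrt(a**2 + b**2)


def pool_features(
    energies: np.ndarray, bank: GaborFilterBank, params: GaborModelParams
) -> np.ndarray:
    """Weight energies by bank and apply the two pooling stages.

    ``energies`` is (n_features,) or (n_images, n_features) from
    :meth:`GaborFilterBank.energy_matrix`.  Weighting precedes pooling;
    hemifield pooling shrinks each side's features toward that side's
    mean by ``p_hemi``; global pooling then shrinks all features toward
    the all-filter mean by ``p_global`` (mean-preserving at each stage).
    """
    e = np.atleast_2d(np.asarray(energies, dtype=float))
    weights = np.asarray(params.bank_weights, dtype=float)
    if len(weights) != bank.n_banks:
        raise ValueError("need one weight per bank")
    out = e * weights[bank.feature_bank][None, :]
    left = bank.left_mask
    for mask in (left, ~left):
        # population_average averages over axis 0 (units): transpose so the
        # feature axis is the unit axis.
        out[:, mask] = population_average(out[:, mask].T, params.p_hemi).T
    out = population_average(out.T, params.p_global).T
    return out[0] if np.asarray(energies).ndim == 1 else out


def gabor_feature_vector(
    image: np.ndarray, bank: GaborFilterBank, params: GaborModelParams
) -> np.ndarray:
    """Weighted, pooled contrast-energy feature vector for one image."""
    return pool_features(bank.energy_matrix(image), bank, params)


def gabor_rdm(
    images: np.ndarray,
    bank: GaborFilterBank,
    params: GaborModelParams,
    labels: list[str] | None = None,
    energies: np.ndarray | None = None,
) -> RDM:
    """Euclidean distance matrix between pooled feature vectors.

    ``energies`` may be passed to reuse a precomputed
    :meth:`GaborFilterBank.energy_matrix` result (pooling and weighting
    are cheap relative to filtering, so parameter fits reuse energies).
    """
    if energies is None:
        energies = bank.energy_matrix(images)
    features = pool_features(energies, bank, params)
    if labels is None:
        labels = [f"img{i:02d}" for i in range(features.shape[0])]
    return euclidean_rdm(features, labels=labels)


def pixelwise_correlation_rdm(
    images: np.ndarray, labels: list[str] | None = None
) -> RDM:
    """Correlation-distance matrix (1 - Pearson r) between intensity vectors."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("need >= 2 images of equal resolution")
    flat = images.reshape(images.shape[0], -1)
    if np.any(flat.std(axis=1) == 0):
        raise ValueError("constant image: correlation distance undefined")
    corr = np.corrcoef(flat)
    matrix = 1.0 - corr
    np.fill_diagonal(matrix, 0.0)
    matrix = (matrix + matrix.T) / 2.0
    if labels is None:
        labels = [f"img{i:02d}" for i in range(images.shape[0])]
    return RDM(labels=list(labels), matrix=matrix, metric="correlation")
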