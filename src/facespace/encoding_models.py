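"""Coordinate-input neural population encoding models.

Two model families map face-space coordinates to simulated neuronal
population responses:

* **Sigmoidal ramp tuning** — each unit responds monotonically along a
  random preferred direction from the norm,
  ``y = 1 / (1 + exp((-x + o) / s))`` where ``x`` is the signed position
  of the stimulus along the unit's preferred direction, ``o`` shifts the
  midpoint away from the norm, and ``s`` controls saturation (large s is
  near-linear over the stimulus range; s near 0 is step-like).
* **Exemplar tuning** — each unit prefers a location in the plane with an
  isotropic Gaussian fall-off of full width at half maximum ``w``.
  Preferred locations are drawn from an isotropic Gaussian centered on
  the norm whose radial spread is set by ``d``: the Z = 2.32 point of the
  radial-distance distribution lies at ``d`` times the eccentricity of
  the caricatures.  An inverted variant reflects each radial distance at
  that Z = 2.32 point (negative distances truncated to zero), so most
  units prefer distinctive rather than typical faces.

Both families share a measurement-level population-averaging stage that
models how an fMRI voxel locally mixes many neurons: every unit's
response is translated toward the population mean by strength
``p`` in [0, 1] (p = 0 leaves responses untouched, p = 1 makes every unit
return the population mean).  Averaging preserves the population-mean
activation profile exactly while shrinking between-unit differences, so
it warps predicted distance matrices without changing predicted
regional-mean activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .face_space import RDM, FaceSpaceGrid, euclidean_rdm

__all__ = [
    "Z_INVERSION",
    "RampParams",
    "ExemplarParams",
    "ramp_response",
    "population_average",
    "sample_ramp_population",
    "sample_exemplar_centers",
    "exemplar_response",
    "RampModel",
    "ExemplarModel",
    "model_rdm",
    "model_activation_profile",
]

#: Standard-normal Z value at which the exemplar-center radial distribution
#: is anchored (and, for the inverted variant, reflected).
Z_INVERSION = 2.32

#: Cumulative probability at Z_INVERSION (~0.98983); the radial quantile at
#: this probability is placed at d times the caricature eccentricity.
P_INVERSION = float(norm.cdf(Z_INVERSION))


@dataclass(frozen=True)
class RampParams:
    """Sigmoidal-ramp model parameters (face-space units unless noted)."""

    o: float = 0.0  # horizontal offset of the sigmoid midpoint
    s: float = 1.0  # saturation; must be > 0
    p: float = 0.0  # population-averaging strength in [0, 1]
    n_units: int = 1000

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("saturation s must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("averaging strength p must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass(frozen=True)
class ExemplarParams:
    """Exemplar model parameters.

    ``w`` is the FWHM of the Gaussian tuning function in face-space units;
    ``d`` scales the radial spread of tuning centers relative to the
    caricature eccentricity; ``inverted`` selects the inverted-Gaussian
    center distribution.
    """

    w: float = 1.0
    d: float = 1.0
    p: float = 0.0
    inverted: bool = False
    n_units: int = 1000

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("tuning width w must be > 0")
        if self.d <= 0:
            raise ValueError("center spread d must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("averaging strength p must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


def ramp_response(x: np.ndarray, o: float, s: float) -> np.ndarray:
    """Sigmoid response at signed position ``x`` along a preferred direction.

    ``1 / (1 + exp((-x + o) / s))``; monotonically increasing in x, 0.5 at
    x = o, asymptotes 0 and 1.
    """
    if s <= 0:
        raise ValueError("saturation s must be > 0")
    return expit((np.asarray(x, dtype=float) - o) / s)


def population_average(responses: np.ndarray, p: float) -> np.ndarray:
    """Translate each unit's response toward the population mean.

    ``y_final = (y_raw - y_mean) * (1 - p) + y_mean`` where ``y_mean`` is
    the per-stimulus mean over units (axis 0).  The per-stimulus mean is
    preserved exactly; the spread across units is scaled by (1 - p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("averaging strength p must be in [0, 1]")
    responses = np.asarray(responses, dtype=float)
    mean = responses.mean(axis=0, keepdims=True)
    return (responses - mean) * (1.0 - p) + mean


def sample_ramp_population(
    n_units: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly distributed unit preferred-direction vectors, shape (n, 2)."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_units)
    return np.column_stack([np.cos(theta), np.sin(theta)])


def _radial_sigma(d: float, caricature_ecc: float) -> float:
    # Radial distance of an isotropic 2D Gaussian is Rayleigh(sigma); place
    # its P_INVERSION quantile at d * caricature_ecc.
    return d * caricature_ecc / np.sqrt(-2.0 * np.log1p(-P_INVERSION))


def sample_exemplar_centers(
    params: ExemplarParams,
    caricature_ecc: float,
    rng: np.random.Generator,
    interpretation: str = "radial",
) -> np.ndarray:
    """Draw exemplar tuning centers, shape (n_units, 2).

    Centers come from an isotropic 2D Gaussian on the norm.  With the
    default ``radial`` interpretation the per-axis scale is chosen so the
    Z = 2.32 quantile of the *radial* distance distribution (a Rayleigh)
    lies at ``d * caricature_ecc``; with ``marginal`` the 1D per-axis
    Gaussian has its Z = 2.32 point there instead.  For the inverted
    variant each radial distance t is mapped to (T - t), T being the
    Z = 2.32 point, and negatives (about 1% of units) are truncated to 0.
    """
    if caricature_ecc <= 0:
        raise ValueError("caricature_ecc must be > 0")
    if interpretation == "radial":
        sigma = _radial_sigma(params.d, caricature_ecc)
    elif interpretation == "marginal":
        sigma = params.d * caricature_ecc / Z_INVERSION
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    theta = rng.uniform(0.0, 2.0 * np.pi, size=params.n_units)
    # Radial distances: Rayleigh(sigma) in both variants (the inverted
    # variant reflects them afterwards).
    radii = sigma * np.sqrt(-2.0 * np.log(rng.uniform(size=params.n_units)))
    if params.inverted:
        pivot = sigma * np.sqrt(-2.0 * np.log1p(-P_INVERSION))
        radii = np.maximum(pivot - radii, 0.0)
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


def exemplar_response(
    coords: np.ndarray, centers: np.ndarray, w: float
) -> np.ndarray:
    """Isotropic Gaussian tuning, peak 1 at the center, FWHM ``w``.

    ``exp(-||x - c||^2 * 4 ln 2 / w^2)`` for every (center, stimulus)
    combination; returns shape (n_centers, n_stimuli).
    """
    if w <= 0:
        raise ValueError("tuning width w must be > 0")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sq = ((centers[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq * 4.0 * np.log(2.0) / w**2)


class RampModel:
    """Population of sigmoidal-ramp units on the 2D face-space slice."""

    def __init__(
        self,
        params: RampParams,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.params = params
        rng = np.random.default_rng(rng)
        self.directions = sample_ramp_population(params.n_units, rng)

    def unit_responses(self, grid: FaceSpaceGrid) -> np.ndarray:
        """(n_units, 24) responses after population averaging.

        Both viewpoints of an identity share a coordinate, so they evoke
        identical responses.
        """
        x = self.directions @ grid.condition_coords_2d.T
        raw = ramp_response(x, self.params.o, self.params.s)
        return population_average(raw, self.params.p)


class ExemplarModel:
    """Population of Gaussian exemplar units on the 2D face-space slice.

    Tuning centers are sampled once at unit scale and re-scaled lazily to
    the grid's caricature eccentricity, so the same model instance gives
    consistent predictions across grids that differ only in scale.
    """

    def __init__(
        self,
        params: ExemplarParams,
        rng: np.random.Generator | int | None = None,
        interpretation: str = "radial",
    ) -> None:
        self.params = params
        self.interpretation = interpretation
        rng = np.random.default_rng(rng)
        # Unit-scale draw (caricature_ecc = 1); centers scale linearly with
        # caricature eccentricity, including the inverted-variant reflection.
        self._unit_centers = sample_exemplar_centers(
            params, 1.0, rng, interpretation=interpretation
        )

    def centers(self, caricature_ecc: float) -> np.ndarray:
        return self._unit_centers * caricature_ecc

    def unit_responses(self, grid: FaceSpaceGrid) -> np.ndarray:
        caricature_ecc = max(ECC for ECC in grid.ecc_levels)
        raw = exemplar_response(
            grid.condition_coords_2d, self.centers(caricature_ecc), self.params.w
        )
        return population_average(raw, self.params.p)


def model_rdm(model, grid: FaceSpaceGrid) -> RDM:
    """Euclidean distance matrix between post-averaging population vectors.

    ``model`` is anything with a ``unit_responses(grid) -> (n_units, n_cond)``
    method.
    """
    responses = model.unit_responses(grid)
    rdm = euclidean_rdm(responses.T, labels=grid.condition_labels)
    return rdm


def model_activation_profile(model, grid: FaceSpaceGrid) -> np.ndarray:
    """Per-condition population-mean response (length 24).

    Unchanged by population averaging for any p, since averaging is
    mean-preserving.
    """
    return model.unit_responses(grid).mean(axis=0)
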