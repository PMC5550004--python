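"""Cross-validated discriminant (crossnobis) distances from run-wise data.

Pattern discriminability between two conditions is estimated in the
spirit of a linear discriminant: the weights are the condition contrast
multiplied by the inverse of the noise covariance of the residual time
courses.  The discriminant is estimated on every leave-one-run-out split
of the runs, the weights are scaled to unit length, and projected onto
the contrast estimate from the held-out run; the per-fold projections
are averaged.  Because training and test data are independent, the
statistic is centered on zero when the conditions do not truly differ
(estimates may be negative), which licenses conventional T tests for
above-chance discriminability.  When instead the same data are used for
estimation and evaluation with a full covariance estimator and no
unit-length normalization, the statistic reduces to the squared
Mahalanobis distance.

The noise covariance is estimated from residual time courses with
optimal shrinkage toward a diagonal target (Schafer-Strimmer), which is
well-conditioned even when voxels outnumber time points; a ``full``
sample-covariance estimator is available when time points suffice.

A mean-removal variant strips region-mean-related effects before
contrasts are formed: each condition pattern is set to zero spatial
mean (removing additive offsets), and for each pair the linear
contribution of the pair-mean pattern is projected out of each pattern
(removing multiplicative scaling of a common pattern).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .face_space import RDM

__all__ = [
    "DegeneratePairError",
    "RunDataset",
    "NoiseCovariance",
    "estimate_covariance",
    "cv_distance",
    "cv_rdm",
    "squared_mahalanobis",
]


class DegeneratePairError(ValueError):
    """Raised when discriminant weights are undefined (zero contrast)."""


@dataclass
class RunDataset:
    """Run-wise pattern estimates and residuals for one participant/region.

    Attributes
    ----------
    patterns
        Array (n_runs, n_conditions, n_voxels) of per-run condition
        pattern estimates.
    residuals
        Array (n_runs, n_timepoints, n_voxels) of residual time courses
        used for noise-covariance estimation.
    condition_labels
        One label per condition, shared by all runs.
    """

    patterns: np.ndarray
    residuals: np.ndarray
    condition_labels: list[str]

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.patterns.ndim != 3 or self.residuals.ndim != 3:
            raise ValueError("patterns and residuals must be 3D arrays")
        if self.patterns.shape[0] != self.residuals.shape[0]:
            raise ValueError("patterns and residuals disagree on run count")
        if self.patterns.shape[2] != self.residuals.shape[2]:
            raise ValueError("patterns and residuals disagree on voxel count")
        if self.patterns.shape[1] != len(self.condition_labels):
            raise ValueError("condition label count mismatch")

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]

    def save(self, directory: str | Path) -> None:
        """Write one pattern and one residual text file per run + manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for r in range(self.n_runs):
            np.savetxt(directory / f"run{r:02d}_patterns.tsv",
                       self.patterns[r], delimiter="\t")
            np.savetxt(directory / f"run{r:02d}_residuals.tsv",
                       self.residuals[r], delimiter="\t")
        manifest = {
            "n_runs": self.n_runs,
            "n_conditions": self.n_conditions,
            "n_voxels": self.n_voxels,
            "n_timepoints": int(self.residuals.shape[1]),
            "condition_labels": self.condition_labels,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "RunDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        patterns = np.stack([
            np.loadtxt(directory / f"run{r:02d}_patterns.tsv", delimiter="\t")
            for r in range(manifest["n_runs"])
        ])
        residuals = np.stack([
            np.loadtxt(directory / f"run{r:02d}_residuals.tsv", delimiter="\t")
            for r in range(manifest["n_runs"])
        ])
        return cls(patterns=patterns, residuals=residuals,
                   condition_labels=list(manifest["condition_labels"]))


@dataclass
class NoiseCovariance:
    """Symmetric positive-definite voxel covariance with estimator tag."""

    matrix: np.ndarray
    estimator: str = "shrinkage"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.matrix = (m + m.T) / 2.0

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def _shrinkage_covariance(residuals: np.ndarray) -> np.ndarray:
    # Schafer-Strimmer optimal shrinkage of off-diagonals toward zero
    # (equivalently, shrinkage toward the diagonal of the sample covariance).
    t, v = residuals.shape
    x = residuals - residuals.mean(axis=0, keepdims=True)
    s = x.T @ x / (t - 1)
    # var of each s_ij across time points: with w_kij = x_ki x_kj,
    # Var(s_ij) = t/(t-1)^3 * sum_k (w_kij - mean_k w_kij)^2
    x2 = x**2
    var_s = (x2.T @ x2 - (x.T @ x) ** 2 / t) * t / (t - 1) ** 3
    off = ~np.eye(v, dtype=bool)
    denom = np.sum(s[off] ** 2)
    lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
    target = np.diag(np.diag(s))
    sigma = lam * target + (1.0 - lam) * s
    # keep strictly positive definite even for degenerate voxels
    jitter = 1e-10 * max(np.trace(sigma) / v, 1.0)
    return sigma + jitter * np.eye(v)


def estimate_covariance(
    residuals: np.ndarray, estimator: str = "shrinkage"
) -> NoiseCovariance:
    """Estimate the voxel noise covariance from residual time courses.

    ``shrinkage`` (default) is guaranteed invertible regardless of the
    time-point/voxel ratio; ``full`` is the plain sample covariance and
    raises if it is singular.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("need a (timepoints, voxels) array with >= 2 rows")
    if estimator == "shrinkage":
        return NoiseCovariance(_shrinkage_covariance(residuals), "shrinkage")
    if estimator == "full":
        x = residuals - residuals.mean(axis=0, keepdims=True)
        s = x.T @ x / (residuals.shape[0] - 1)
        eigvals = np.linalg.eigvalsh(s)
        if eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0):
            raise np.linalg.LinAlgError(
                "full sample covariance is singular; use the shrinkage estimator"
            )
        return NoiseCovariance(s, "full")
    raise ValueError(f"unknown estimator {estimator!r}")


def _fold_inverses(
    data: RunDataset, cov: NoiseCovariance | None, estimator: str
) -> list[np.ndarray]:
    inverses = []
    for test_run in range(data.n_runs):
        if cov is not None:
            inverses.append(cov.inverse)
            continue
        train = [r for r in range(data.n_runs) if r != test_run]
        stacked = data.residuals[train].reshape(-1, data.n_voxels)
        inverses.append(estimate_covariance(stacked, estimator).inverse)
    return inverses


def _mean_removal(patterns: np.ndarray) -> np.ndarray:
    # Step 1: zero spatial mean per condition pattern.
    return patterns - patterns.mean(axis=-1, keepdims=True)


def _pair_contrasts(
    patterns: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray, mean_removal: bool
) -> np.ndarray:
    """Contrast vectors (n_pairs, V) for one split's patterns (C, V)."""
    if mean_removal:
        patterns = _mean_removal(patterns)
    a = patterns[idx_i]
    b = patterns[idx_j]
    c = a - b
    if mean_removal:
        # Step 2: project the pair-mean pattern out of each pattern; on the
        # contrast this amounts to removing the pair-mean direction.
        m = (a + b) / 2.0
        mm = np.einsum("ij,ij->i", m, m)
        cm = np.einsum("ij,ij->i", c, m)
        scale = np.where(mm > 0, cm / np.where(mm > 0, mm, 1.0), 0.0)
        c = c - scale[:, None] * m
    return c


def _cv_estimates(
    data: RunDataset,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
    cov: NoiseCovariance | None,
    estimator: str,
    mean_removal: bool,
    on_degenerate: str,
) -> np.ndarray:
    """Mean over leave-one-run-out folds of the projected distances."""
    inverses = _fold_inverses(data, cov, estimator)
    n_pairs = len(idx_i)
    estimates = np.zeros(n_pairs)
    for test_run in range(data.n_runs):
        train = [r for r in range(data.n_runs) if r != test_run]
        train_mean = data.patterns[train].mean(axis=0)
        c_train = _pair_contrasts(train_mean, idx_i, idx_j, mean_removal)
        c_test = _pair_contrasts(data.patterns[test_run], idx_i, idx_j,
                                 mean_removal)
        w = c_train @ inverses[test_run]
        norms = np.linalg.norm(w, axis=1)
        zero = norms <= 1e-300
        if np.any(zero):
            if on_degenerate == "raise":
                raise DegeneratePairError(
                    "zero training contrast: discriminant weights undefined"
                )
            norms = np.where(zero, 1.0, norms)
            w[zero] = 0.0
        w /= norms[:, None]
        estimates += np.einsum("ij,ij->i", w, c_test)
    return estimates / data.n_runs


def cv_distance(
    data: RunDataset,
    pair: tuple[int, int],
    cov: NoiseCovariance | None = None,
    estimator: str = "shrinkage",
    mean_removal: bool = False,
) -> float:
    """Cross-validated discriminant distance for one condition pair.

    ``cov`` fixes the noise covariance for all folds (useful for
    controlled simulations); when None it is estimated per training
    split from the concatenated training-run residuals.  Raises
    :class:`DegeneratePairError` if a training contrast vanishes.
    """
    if data.n_runs < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    i, j = pair
    est = _cv_estimates(
        data, np.array([i]), np.array([j]), cov, estimator, mean_removal,
        on_degenerate="raise",
    )
    return float(est[0])


def cv_rdm(
    data: RunDataset,
    cov: NoiseCovariance | None = None,
    estimator: str = "shrinkage",
    mean_removal: bool = False,
) -> RDM:
    """Cross-validated distance matrix over all condition pairs.

    Pairs whose training contrast vanishes identically (which the
    mean-removal variant produces by design for additively or
    multiplicatively related patterns) contribute zero rather than
    raising, so degenerate structure maps to zero distance.
    """
    if data.n_runs < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    idx_i, idx_j = np.triu_indices(data.n_conditions, k=1)
    est = _cv_estimates(
        data, idx_i, idx_j, cov, estimator, mean_removal, on_degenerate="zero"
    )
    matrix = np.zeros((data.n_conditions, data.n_conditions))
    matrix[idx_i, idx_j] = est
    matrix += matrix.T
    return RDM(labels=list(data.condition_labels), matrix=matrix,
               metric="crossvalidated")


def squared_mahalanobis(
    data: RunDataset,
    pair: tuple[int, int],
    estimator: str = "full",
) -> float:
    """Same-data, non-normalized discriminant statistic c' S^-1 c.

    Uses the run-mean patterns and the covariance of all concatenated
    residuals; with the full estimator this equals the squared
    Mahalanobis distance between the two condition patterns.
    """
    i, j = pair
    mean_patterns = data.patterns.mean(axis=0)
    c = mean_patterns[i] - mean_patterns[j]
    cov = estimate_covariance(
        data.residuals.reshape(-1, data.n_voxels), estimator
    )
    return float(c @ cov.inverse @ c)
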