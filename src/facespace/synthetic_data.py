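"""Synthetic study data: participants, images, runs, judgments, sequences.

Every generator is a pure function of its seed.  A synthetic participant
owns a private slice orientation through the reference space (so all
participants share the same reference distance matrix while their
stimuli are physically distinct), a 12-face polar grid, and 24 gray-scale
stimulus images (12 identities x 2 viewpoints, the right viewpoint being
the exact horizontal mirror of the left).

Images are a stand-in for rendered 3D face stimuli: each identity's
image is a deterministic smooth function of its face-space coordinate (a
band-limited random field whose basis weights are linear in the
embedded coordinates, on a participant-specific texture), normalized so
all 24 images share mean intensity and root-mean-square contrast.  Pixel
content therefore varies smoothly with face-space position, which is the
property the downstream image models rely on; the images are synthetic
and carry no facial features.

Run-wise fMRI-like data are generated from a ground-truth encoding model
by mixing unit responses into voxels with non-negative random weights
(voxels locally average neuronal activity), adding run-specific Gaussian
noise with mild spatial correlation, and drawing matching residual time
courses for covariance estimation.

Perceptual data follow the pair-of-pairs task: every pairing of the 66
face pairs (2145 trials per repeat) is judged by a logistic choice on
the true distance difference, aggregated into a percent-choice
dissimilarity matrix.

Trial sequences are first-order counterbalanced De Bruijn cycles over
the 12 faces (Eulerian circuit over the complete transition multigraph
with one extra repetition per face, 156 trials), with viewpoints
randomized under rejection sampling so no ordered 24-condition
transition occurs more than once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .face_space import RDM, FaceSpaceGrid, SliceBasis, build_polar_grid, sample_slice
from .encoding_models import (
    ExemplarModel,
    ExemplarParams,
    RampModel,
    RampParams,
)
from .crossnobis import RunDataset

__all__ = [
    "SyntheticParticipant",
    "TrialSequence",
    "JudgmentDataset",
    "generate_participant",
    "generate_face_images",
    "simulate_runs",
    "simulate_pair_of_pairs",
    "generate_trial_sequence",
    "randomize_viewpoints",
    "make_model",
]

#: Target mean intensity and RMS contrast shared by all stimulus images.
IMAGE_MEAN = 0.5
IMAGE_RMS = 0.15


def make_model(spec: dict, rng: np.random.Generator | int | None = None):
    """Instantiate a ground-truth encoding model from a plain spec dict.

    ``spec`` carries a ``family`` key (``ramp`` or ``exemplar``) plus the
    family's parameters, e.g. ``{"family": "ramp", "o": 0, "s": 1, "p": 0.9}``.
    """
    spec = dict(spec)
    family = spec.pop("family")
    if family == "ramp":
        return RampModel(RampParams(**spec), rng)
    if family == "exemplar":
        return ExemplarModel(ExemplarParams(**spec), rng)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class SyntheticParticipant:
    """One simulated participant: private stimuli plus ground truth."""

    seed: int
    basis: SliceBasis
    grid: FaceSpaceGrid
    images: np.ndarray = field(repr=False)  # (24, H, W)
    ground_truth: dict | None = None

    @property
    def reference_rdm(self) -> RDM:
        from .face_space import euclidean_rdm

        return euclidean_rdm(
            np.repeat(self.grid.embedded_coords, 2, axis=0),
            labels=self.grid.condition_labels,
        )


def generate_face_images(
    grid: FaceSpaceGrid,
    basis: SliceBasis,
    seed: int,
    resolution: int = 96,
) -> np.ndarray:
    """Deterministic smooth images for the 24 conditions, (24, H, W).

    A participant-specific base field plus D coordinate-weighted smooth
    fields give the left-viewpoint image of each identity; the right
    viewpoint is its exact horizontal mirror.  All images are normalized
    to a common mean and RMS contrast.

    The coordinate-dependent fields are band-limited at a finer spatial
    scale than the base field: a face far from the norm mixes in more of
    this finer structure, so local contrast energy grows with
    eccentricity even though every image has identical pixel mean and
    RMS contrast — mirroring how distinctiveness manifests in
    contrast-equated face photographs.
    """
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    rng = np.random.default_rng(seed)
    d = basis.dimension

    def smooth_field(sigma: float) -> np.ndarray:
        f = gaussian_filter(
            rng.standard_normal((resolution, resolution)), sigma,
            mode="wrap",
        )
        return f / f.std()

    base = smooth_field(resolution / 6.0)
    fields = np.stack(
        [smooth_field(resolution / 24.0) for _ in range(d)]
    )  # (D, H, W)
    embedded = grid.embedded_coords  # (12, D)
    images = np.empty((grid.n_conditions, resolution, resolution))
    for k in range(grid.n_faces):
        raw = base + np.tensordot(embedded[k], fields, axes=1)
        left = (raw - raw.mean()) / raw.std() * IMAGE_RMS + IMAGE_MEAN
        images[2 * k] = left
        images[2 * k + 1] = left[:, ::-1]
    return images


def generate_participant(
    seed: int,
    dimension: int = 50,
    mean_eccentricity: float = 1.0,
    ground_truth: dict | None = None,
    resolution: int = 96,
) -> SyntheticParticipant:
    """Deterministically build one participant from a seed.

    The grid's reference distance matrix is identical across participants
    (it only depends on the polar layout), while the slice orientation
    and images are participant-specific.
    """
    rng = np.random.default_rng(seed)
    basis = sample_slice(dimension, rng)
    grid = build_polar_grid(mean_eccentricity, basis)
    image_seed = int(rng.integers(0, 2**31 - 1))
    images = generate_face_images(grid, basis, image_seed, resolution)
    return SyntheticParticipant(
        seed=seed, basis=basis, grid=grid, images=images,
        ground_truth=ground_truth,
    )


def _ar1_covariance(n_voxels: int, rho: float) -> np.ndarray:
    idx = np.arange(n_voxels)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_runs(
    participant: SyntheticParticipant,
    model,
    n_runs: int = 16,
    n_voxels: int = 100,
    noise: float = 1.0,
    n_pool: int = 10,
    n_timepoints: int = 120,
    ar_rho: float = 0.3,
    seed: int | None = None,
) -> RunDataset:
    """Simulate run-wise voxel patterns from a ground-truth model.

    Each voxel takes a non-negative weighted average of a random subset
    of ``n_pool`` model units (uniform [0, 1] weights), implementing the
    premise that voxels locally average the activity of random subsets
    of neurons.  The pool size controls how strongly the measurement
    itself over-represents the population-mean dimension: large pools
    make every voxel nearly the population mean, which erases the
    generating model's unit-level structure; the small default keeps the
    generating parameters identifiable by the fitting machinery while
    still mixing units non-negatively.

    Per-run noise and residual time courses share a covariance with
    AR(1) spatial correlation ``ar_rho``; the noise standard deviation
    is ``noise`` times the standard deviation of the condition-demeaned
    true voxel patterns, so ``noise = 1`` means per-voxel noise as large
    as the pattern signal.
    """
    rng = np.random.default_rng(seed)
    units = model.unit_responses(participant.grid)  # (n_units, 24)
    n_units = units.shape[0]
    n_pool = min(n_pool, n_units)
    weights = np.zeros((n_voxels, n_units))
    for v in range(n_voxels):
        idx = rng.choice(n_units, size=n_pool, replace=False)
        weights[v, idx] = rng.uniform(0.0, 1.0, size=n_pool)
    weights /= n_pool
    true_patterns = (weights @ units).T  # (24, V)
    signal_sd = (true_patterns - true_patterns.mean(axis=0)).std()
    if signal_sd == 0:
        signal_sd = 1.0
    sigma_sd = noise * signal_sd
    chol = np.linalg.cholesky(_ar1_covariance(n_voxels, ar_rho)) * sigma_sd
    n_cond = true_patterns.shape[0]
    patterns = np.empty((n_runs, n_cond, n_voxels))
    residuals = np.empty((n_runs, n_timepoints, n_voxels))
    for r in range(n_runs):
        patterns[r] = (
            true_patterns
            + rng.standard_normal((n_cond, n_voxels)) @ chol.T
        )
        residuals[r] = rng.standard_normal((n_timepoints, n_voxels)) @ chol.T
    return RunDataset(
        patterns=patterns,
        residuals=residuals,
        condition_labels=participant.grid.condition_labels,
    )


@dataclass
class JudgmentDataset:
    """Pair-of-pairs choices aggregated into a percent-choice RDM."""

    rdm: RDM
    n_repeats: int
    tau: float
    choice_counts: np.ndarray = field(repr=False)  # (n_pairs,)
    trials_per_pair: int = 0

    @property
    def n_trials(self) -> int:
        n_pairs = len(self.choice_counts)
        return self.n_repeats * n_pairs * (n_pairs - 1) // 2


def simulate_pair_of_pairs(
    true_distances: RDM,
    n_repeats: int = 1,
    tau: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> JudgmentDataset:
    """Simulate the pair-of-pairs 2AFC task over all pairings of pairs.

    Each repeat enumerates every unordered pairing of the face pairs
    (2145 pairings of the 66 pairs of 12 faces); the probability of
    choosing the first pair as more dissimilar is
    ``logistic((d1 - d2) / tau)``; ``tau = 0`` gives the deterministic
    argmax (ties split at chance).  Entries of the returned matrix are
    the percentage of trials on which the pair was chosen as relatively
    more dissimilar.
    """
    if tau < 0:
        raise ValueError("decision noise tau must be >= 0")
    rng = np.random.default_rng(rng)
    d = true_distances.vector
    n_pairs = len(d)
    i, j = np.triu_indices(n_pairs, k=1)
    counts = np.zeros(n_pairs)
    diff = d[i] - d[j]
    for _ in range(n_repeats):
        if tau == 0:
            # deterministic argmax; exactly tied pairs split at chance so
            # tied distances map to identical percent-choice values
            choice = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
        else:
            prob = expit(diff / tau)
            choice = (rng.uniform(size=len(i)) < prob).astype(float)
        counts += np.bincount(i, weights=choice, minlength=n_pairs)
        counts += np.bincount(j, weights=1.0 - choice, minlength=n_pairs)
    trials_per_pair = n_repeats * (n_pairs - 1)
    percent = 100.0 * counts / trials_per_pair
    rdm = RDM.from_vector(percent, true_distances.labels,
                          metric="percent-choice")
    return JudgmentDataset(rdm=rdm, n_repeats=n_repeats, tau=tau,
                           choice_counts=counts,
                           trials_per_pair=trials_per_pair)


@dataclass
class TrialSequence:
    """A cyclic condition sequence with its ordered-transition counts."""

    conditions: np.ndarray  # (n_trials,) int condition indices
    n_conditions: int

    @property
    def n_trials(self) -> int:
        return len(self.conditions)

    @property
    def transfer_matrix(self) -> np.ndarray:
        """Counts of ordered transitions over the cyclic sequence."""
        counts = np.zeros((self.n_conditions, self.n_conditions), dtype=int)
        nxt = np.roll(self.conditions, -1)
        np.add.at(counts, (self.conditions, nxt), 1)
        return counts


def generate_trial_sequence(
    n_conditions: int = 12,
    extra_diagonal: int = 1,
    seed: int | None = None,
) -> TrialSequence:
    """First-order counterbalanced cyclic sequence (De Bruijn order 2).

    Built as an Eulerian circuit (Hierholzer) over the complete
    transition multigraph in which every ordered pair of distinct
    conditions is one edge and every condition carries
    ``1 + extra_diagonal`` self-transitions; the seed shuffles edge
    order.  The resulting transfer matrix has every off-diagonal entry
    exactly 1 and every diagonal entry exactly ``1 + extra_diagonal``;
    trial count is ``n**2 + n * extra_diagonal``.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    if extra_diagonal < 0:
        raise ValueError("extra_diagonal must be >= 0")
    rng = np.random.default_rng(seed)
    adjacency: list[list[int]] = []
    for u in range(n_conditions):
        targets = [v for v in range(n_conditions) if v != u]
        targets += [u] * (1 + extra_diagonal)
        rng.shuffle(targets)
        adjacency.append(targets)
    # Hierholzer: in-degree == out-degree at every node and the graph is
    # strongly connected, so an Eulerian circuit always exists.
    stack = [0]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(adjacency[v].pop())
        else:
            circuit.append(stack.pop())
    sequence = np.array(circuit[::-1][:-1], dtype=int)
    return TrialSequence(conditions=sequence, n_conditions=n_conditions)


def randomize_viewpoints(
    sequence: TrialSequence,
    seed: int | None = None,
    max_tries: int = 1000,
) -> TrialSequence:
    """Assign a viewpoint to every trial under a homogeneity constraint.

    Viewpoints are drawn uniformly and the assignment is rejected until
    the 24-condition transfer matrix has no off-diagonal entry above 1
    (each ordered stimulus-to-stimulus transfer appears once or not at
    all).  Condition indices are ``2 * face + viewpoint``, matching the
    identity-major-then-viewpoint condition order used throughout.
    """
    rng = np.random.default_rng(seed)
    n24 = 2 * sequence.n_conditions
    for attempt in range(1, max_tries + 1):
        viewpoints = rng.integers(0, 2, size=sequence.n_trials)
        candidate = TrialSequence(
            conditions=2 * sequence.conditions + viewpoints,
            n_conditions=n24,
        )
        transfer = candidate.transfer_matrix
        off = transfer[~np.eye(n24, dtype=bool)]
        if off.max() <= 1:
            import logging

            logging.getLogger(__name__).info(
                "viewpoint randomization accepted after %d tries", attempt
            )
            return candidate
    raise RuntimeError(
        f"no homogeneous viewpoint assignment found in {max_tries} tries"
    )
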