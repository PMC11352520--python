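"""Synthetic dynamic networks with planted overlapping communities.

The simulator provides ground truth for every downstream stage: a membership
matrix ``C*`` (regions x communities, non-negative, column max 1), smooth
positive temporal intensity profiles ``z*(t)``, per-subject connectivity
tensors generated from the low-rank forward model
``F_t = sum_p z_p(t) c_p c_p^T`` plus symmetric Gaussian noise, and ROI BOLD
series in which regions sharing a community co-fluctuate.

Regions are grouped into contiguous blocks, one per community.  The first
member of each block is an "anchor" with strength exactly 1.0 (so the column
maximum constraint holds by construction); remaining members draw strengths
uniformly from [0.4, 0.7].  Overlap nodes are the anchors (then, if needed,
later block members), carrying 1.0 in their home community and 0.8 in the
next community cyclically — both comfortably separable from the background
by a mean-plus-one-SD membership threshold on networks that are sparse
relative to their size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError

__all__ = ["SyntheticTruth", "make_truth", "simulate_group_tensors", "simulate_bold"]

#: membership strength above which a planted assignment counts as "belonging"
OVERLAP_STRENGTH_THRESHOLD = 0.5

_SECONDARY_STRENGTH = 0.8
_BACKGROUND_RANGE = (0.4, 0.7)
_TEMPORAL_FLOOR = 0.1


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for a dynamic overlapping community structure.

    Attributes
    ----------
    membership : ndarray, shape (n_regions, n_communities)
        Non-negative strengths; every column has maximum exactly 1.
    temporal_weights : ndarray, shape (T, n_communities)
        Non-negative community intensities per time point.
    overlap_nodes : tuple of int
        Region indices planted in at least two communities.
    noise_sd : float
        Default noise scale carried to the BOLD simulator.
    seed : int
        Seed the truth was generated from.
    """

    membership: np.ndarray
    temporal_weights: np.ndarray
    overlap_nodes: tuple[int, ...]
    noise_sd: float
    seed: int

    @property
    def n_regions(self) -> int:
        return self.membership.shape[0]

    @property
    def n_communities(self) -> int:
        return self.membership.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.temporal_weights.shape[0]

    def __post_init__(self) -> None:
        C = np.asarray(self.membership, dtype=float)
        Z = np.asarray(self.temporal_weights, dtype=float)
        if C.ndim != 2 or Z.ndim != 2 or Z.shape[1] != C.shape[1]:
            raise ParameterError("membership and temporal_weights shapes disagree")
        if (C < 0).any() or (Z < 0).any():
            raise ParameterError("planted strengths must be non-negative")
        if not np.allclose(C.max(axis=0), 1.0):
            raise ParameterError("every membership column must have maximum 1")
        object.__setattr__(self, "membership", C)
        object.__setattr__(self, "temporal_weights", Z)
        object.__setattr__(self, "overlap_nodes", tuple(int(i) for i in self.overlap_nodes))


def make_truth(
    n_regions: int,
    n_communities: int,
    overlap_fraction: float,
    T: int,
    seed: int,
    noise_sd: float = 0.1,
) -> SyntheticTruth:
    """Plant a block-structured overlapping community ground truth.

    ``ceil(overlap_fraction * n_regions)`` regions are assigned to two
    communities (home strength 1.0, secondary strength 0.8).  Temporal
    intensities are phase-shifted positive sinusoids floored at 0.1 so each
    community has a distinct, strictly positive activity profile — the
    per-time variation that makes the diagonal weights identifiable.
    """
    if n_communities < 1 or n_regions < 2 * n_communities:
        raise ParameterError(
            f"need n_regions >= 2*n_communities, got {n_regions} and {n_communities}"
        )
    if not 0.0 <= overlap_fraction <= 0.5:
        raise ParameterError(f"overlap_fraction must lie in [0, 0.5], got {overlap_fraction}")
    if T < 2:
        raise ParameterError(f"need at least 2 time points, got {T}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    k = n_communities
    blocks = np.array_split(np.arange(n_regions), k)

    C = np.zeros((n_regions, k))
    for p, block in enumerate(blocks):
        strengths = rng.uniform(*_BACKGROUND_RANGE, size=block.size)
        strengths[0] = 1.0  # anchor pins the column maximum
        C[block, p] = strengths

    n_overlap = math.ceil(overlap_fraction * n_regions)
    # overlap nodes taken round-robin across blocks: anchors first, then
    # second members, ... so no block is drained before another starts
    candidates = [
        (int(block[depth]), p)
        for depth in range(max(len(b) for b in blocks))
        for p, block in enumerate(blocks)
        if depth < len(block)
    ]
    overlap_nodes: list[int] = []
    for node, home in candidates[:n_overlap]:
        second = (home + 1) % k
        C[node, home] = 1.0
        C[node, second] = _SECONDARY_STRENGTH
        overlap_nodes.append(node)

    t = np.arange(T)
    phases = 2.0 * np.pi * np.arange(k) / k
    Z = np.maximum(_TEMPORAL_FLOOR, 1.0 + np.sin(2.0 * np.pi * t[:, None] / T + phases[None, :]))

    return SyntheticTruth(
        membership=C,
        temporal_weights=Z,
        overlap_nodes=tuple(sorted(overlap_nodes)),
        noise_sd=noise_sd,
        seed=int(seed),
    )


def noiseless_slices(truth: SyntheticTruth, zero_diagonal: bool = True) -> np.ndarray:
    """Exact forward-model connectivity, shape (N, N, T).

    Slice t is ``sum_p z_p(t) c_p c_p^T``; the diagonal (self-connectivity)
    is zeroed by convention.
    """
    C = truth.membership
    Z = truth.temporal_weights
    # (T,N,k) batched: (C * z_t) @ C.T per slice
    CZ = C[None, :, :] * Z[:, None, :]
    slices = CZ @ C.T  # (T, N, N)
    slices = 0.5 * (slices + slices.transpose(0, 2, 1))  # exact symmetry
    if zero_diagonal:
        idx = np.arange(C.shape[0])
        slices[:, idx, idx] = 0.0
    return np.moveaxis(slices, 0, -1)


def simulate_group_tensors(
    truth: SyntheticTruth,
    n_subjects: int,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Per-subject dynamic connectivity tensors, shape (S, N, N, T).

    Each subject's slice at time t is the noiseless forward model plus
    symmetric zero-mean Gaussian noise of scale ``noise_sd`` (upper triangle
    drawn, mirrored); diagonals are zero.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    base = noiseless_slices(truth)  # (N, N, T)
    N, _, T = base.shape
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(N, k=1)

    W = np.empty((n_subjects, N, N, T))
    for s in range(n_subjects):
        W[s] = base
        if noise_sd > 0:
            for t in range(T):
                noise = rng.normal(0.0, noise_sd, size=iu[0].size)
                W[s, iu[0], iu[1], t] += noise
                W[s, iu[1], iu[0], t] += noise
    return W


def simulate_bold(
    truth: SyntheticTruth,
    n_subjects: int,
    T_scan: int,
    seed: int,
):
    """Simulate per-region BOLD series mixing community latent signals.

    Each community p carries a smooth latent signal (Gaussian-filtered white
    noise, unit variance); region j observes ``sum_p C[j,p] * s_p(t)`` plus
    independent Gaussian noise of scale ``truth.noise_sd``, so regions sharing
    communities co-fluctuate.  Returns a list of
    :class:`~dynoc.jackknife.RoiTimeSeries`, one per subject.
    """
    from .jackknife import RoiTimeSeries  # local import avoids a cycle

    if T_scan < 10:
        raise ParameterError(f"T_scan must be >= 10, got {T_scan}")
    if n_subjects < 1:
        raise ParameterError("need at least one subject")

    C = truth.membership
    N, k = C.shape
    labels = [f"R{j + 1:03d}" for j in range(N)]
    rng = np.random.default_rng(seed)

    out = []
    for s in range(n_subjects):
        latent = rng.normal(size=(T_scan, k))
        latent = gaussian_filter1d(latent, sigma=2.0, axis=0, mode="wrap")
        latent = (latent - latent.mean(axis=0)) / latent.std(axis=0)
        values = latent @ C.T
        values += rng.normal(0.0, max(truth.noise_sd, 1e-3), size=(T_scan, N))
        out.append(
            RoiTimeSeries(values=values, region_labels=labels, subject_id=f"sim{s:03d}")
        )
    return out
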