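"""Evaluation metrics for dynamic overlapping community structure.

Three surfaces, plus membership thresholding and a permutation test:

* structural stability — repeated randomly initialized detections are
  hardened to partitions (per-node argmax), their co-assignment frequencies
  averaged into a consensus matrix, and the cophenetic correlation between
  consensus distances and the average-linkage tree built from them reports
  how hierarchically consistent the community structure is across runs
  (1 = perfectly stable);
* node functional diversity — the Shannon entropy of a region's normalized
  community weights at each time point, 0 for a single-community region and
  ln k when it belongs to all k communities equally;
* community activity level — each community's temporal intensity scaled by
  the mean membership strength of its thresholded member regions
  (strictly above mean + 1 population SD of the community's column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .factorization import CommunityModel, fit

__all__ = [
    "StabilityResult",
    "DiversityProfile",
    "ActivityProfile",
    "consensus_and_ccc",
    "stability_curve",
    "node_diversity",
    "community_members",
    "overlapping_nodes",
    "activity_level",
    "compare_groups",
]


@dataclass
class StabilityResult:
    """Consensus co-assignment matrix and cophenetic correlation for one k."""

    k: int
    n_runs: int
    consensus: np.ndarray
    ccc: float


@dataclass
class DiversityProfile:
    """Per-time, per-node Shannon entropies (nats); H has shape (T, N)."""

    H: np.ndarray
    k: int


@dataclass
class ActivityProfile:
    """Thresholded member sets, activity series (T, k) and per-community means."""

    members: list[np.ndarray]
    series: np.ndarray
    summary: np.ndarray


def _harden(C: np.ndarray) -> np.ndarray:
    """Partition an overlapping membership by per-node argmax (ties: lowest)."""
    return np.argmax(C, axis=1)


def consensus_and_ccc(runs: list[CommunityModel], k: int) -> StabilityResult:
    """Cross-run consensus matrix and its cophenetic correlation.

    Each run is hardened to a partition; the consensus matrix averages the
    co-assignment indicators over runs.  Average-linkage hierarchical
    clustering is applied to the distance matrix ``1 - consensus`` and the
    cophenetic correlation between the condensed consensus distances and the
    tree's cophenetic distances is returned.  Identical runs give exactly 1.
    """
    if len(runs) < 2:
        raise ParameterError("stability needs at least 2 runs")
    if any(m.k != k for m in runs):
        raise ParameterError("all runs must share the same k")
    N = runs[0].C.shape[0]
    if any(m.C.shape[0] != N for m in runs):
        raise ParameterError("all runs must share the same number of regions")

    consensus = np.zeros((N, N))
    for m in runs:
        labels = _harden(m.C)
        consensus += (labels[:, None] == labels[None, :]).astype(float)
    consensus /= len(runs)
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    if condensed.std() == 0:
        # single-block consensus: the tree reproduces the constant distances
        coph_d = cophenet(tree)
        ccc = 1.0 if np.allclose(coph_d, condensed) else 0.0
    else:
        ccc, _ = cophenet(tree, condensed)
        ccc = float(ccc)
    return StabilityResult(k=k, n_runs=len(runs), consensus=consensus, ccc=ccc)


def stability_curve(
    F,
    k_grid,
    n_runs: int = 100,
    beta: float = 0.1,
    seed: int = 0,
    tol: float = 1e-5,
    max_sweeps: int = 200,
) -> pd.DataFrame:
    """Cross-run stability for every k in the grid.

    For each k, ``n_runs`` single-restart detections with distinct seeds are
    hardened and fed to :func:`consensus_and_ccc`.  The resulting ccc-vs-k
    curve guides the choice of k (look for the change in slope).  Single
    restarts use a lighter convergence setting than a final fit — each run
    only needs a representative hardened partition, not a polished optimum.
    """
    if n_runs < 2:
        raise ParameterError("n_runs must be at least 2")
    root = np.random.SeedSequence(seed)
    rows = []
    for k in k_grid:
        streams = root.spawn(int(n_runs))
        runs = [
            fit(
                F,
                k=int(k),
                beta=beta,
                n_init=1,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                tol=tol,
                max_sweeps=max_sweeps,
            )
            for ss in streams
        ]
        res = consensus_and_ccc(runs, int(k))
        rows.append({"k": int(k), "ccc": res.ccc, "n_runs": int(n_runs)})
    return pd.DataFrame(rows)


def node_diversity(model: CommunityModel) -> DiversityProfile:
    """Shannon entropy of each node's community weights at each time point.

    At time i the weighted membership is ``D_i = C diag(sqrt(z_i))``; each
    node's k weights are normalized to a probability vector whose entropy
    (natural log, 0*ln 0 = 0) is returned.  All-zero rows yield entropy 0.
    """
    C = model.C
    Z = model.Z
    T, k = Z.shape
    H = np.zeros((T, model.n_regions))
    for i in range(T):
        D = C * np.sqrt(Z[i])[None, :]
        rowsum = D.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(rowsum > 0, D / np.where(rowsum > 0, rowsum, 1.0), 0.0)
            logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
        H[i] = -(P * logP).sum(axis=1)
    return DiversityProfile(H=H, k=k)


def community_members(C: np.ndarray, p: int) -> np.ndarray:
    """Regions strictly above mean + 1 population SD of community p's column.

    The rule keeps regions whose association with the community stands
    clearly above the column's background; it is invariant to rescaling the
    column.  A constant column has no region above its own mean + SD, so the
    member set is empty (with a warning).
    """
    C = np.asarray(C, dtype=float)
    if not 0 <= p < C.shape[1]:
        raise ParameterError(f"community index {p} out of range [0, {C.shape[1]})")
    col = C[:, p]
    thr = col.mean() + col.std()  # population SD
    members = np.where(col > thr)[0]
    if members.size == 0:
        warnings.warn(
            f"community {p}: no region exceeds mean + 1 SD (constant column?)",
            RuntimeWarning,
            stacklevel=2,
        )
    return members


def overlapping_nodes(C: np.ndarray) -> dict[int, list[int]]:
    """Regions that are thresholded members of at least two communities.

    Returns ``{region_index: [community, ...]}`` sorted by region index.
    """
    C = np.asarray(C, dtype=float)
    membership: dict[int, list[int]] = {}
    for p in range(C.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for j in community_members(C, p):
                membership.setdefault(int(j), []).append(p)
    return {j: ps for j, ps in sorted(membership.items()) if len(ps) >= 2}


def activity_level(model: CommunityModel) -> ActivityProfile:
    """Activity of each community over time and on average.

    For community p with thresholded members N_p, the activity at time t is
    ``z_p(t) * mean_{j in N_p} C[j, p]`` — the temporal intensity modulated
    by how strongly the member regions load on the community.  The summary
    is the mean over time.  Communities with no thresholded members get a
    zero series (with a warning from the membership rule).
    """
    C = model.C
    Z = model.Z
    T, k = Z.shape
    members = [community_members(C, p) for p in range(k)]
    series = np.zeros((T, k))
    for p in range(k):
        if members[p].size:
            series[:, p] = Z[:, p] * C[members[p], p].mean()
    return ActivityProfile(members=members, series=series, summary=series.mean(axis=0))


def compare_groups(
    values_a,
    values_b,
    n_perm: int = 10000,
    seed: int = 0,
):
    """Two-sided label-permutation test on the difference of means.

    Returns ``(difference, p_value)`` with difference = mean(a) - mean(b).
    The p-value counts permuted absolute differences at least as large as
    the observed one, with the +1 correction for the identity permutation.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if n_perm < 100:
        raise ParameterError("n_perm must be at least 100")

    diff = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p = 1", RuntimeWarning, stacklevel=2)
        return diff, 1.0

    rng = np.random.default_rng(seed)
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n_a].mean() - perm[n_a:].mean()
        if abs(d) >= abs(diff) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return diff, float(p)
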