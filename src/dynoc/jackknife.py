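"""Jackknife-correlation dynamic functional connectivity.

The jackknife correlation (JC) assigns connectivity to a single time point t
as MINUS the Pearson correlation of the two signals computed over all time
points except t.  Dropping a point that supports the correlation lowers the
retained correlation, so after the sign flip and per-edge standardization a
larger value means time point t contributed more to the edge.  The per-edge
standardization (z-score across time, population SD) removes each edge's
static correlation level, leaving only its temporal modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ParameterError, StructuralError

__all__ = [
    "RoiTimeSeries",
    "DynamicConnectivity",
    "jackknife_series",
    "normalize_edge",
    "dynamic_connectivity",
]

# relative tolerance below which a leave-one-out variance counts as zero
_VAR_RTOL = 1e-12


@dataclass
class RoiTimeSeries:
    """One subject's T x N BOLD matrix with region labels.

    Validation is strict: at least 4 time points (a leave-one-out Pearson
    needs three retained samples), no NaN/Inf anywhere, and non-zero variance
    in every column.
    """

    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise StructuralError("time series must be a 2-D (time x regions) matrix")
        if v.shape[0] < 4:
            raise StructuralError(
                f"need at least 4 time points, got {v.shape[0]}"
            )
        bad = ~np.isfinite(v)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise StructuralError(
                f"non-finite value at row {r}, column {c}"
                + (f" (subject {self.subject_id})" if self.subject_id else "")
            )
        flat = np.where(v.std(axis=0) == 0)[0]
        if flat.size:
            raise NumericalError(
                f"zero-variance region column(s) {flat.tolist()}"
                + (f" (subject {self.subject_id})" if self.subject_id else "")
            )
        if not self.region_labels:
            self.region_labels = [f"R{j + 1:03d}" for j in range(v.shape[1])]
        if len(self.region_labels) != v.shape[1]:
            raise StructuralError(
                f"{len(self.region_labels)} labels for {v.shape[1]} regions"
            )
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class DynamicConnectivity:
    """An N x N x T edge tensor; every slice symmetric with zero diagonal."""

    tensor: np.ndarray
    normalized: bool
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.ndim != 3 or t.shape[0] != t.shape[1]:
            raise StructuralError("connectivity tensor must have shape (N, N, T)")
        if not self.region_labels:
            self.region_labels = [f"R{j + 1:03d}" for j in range(t.shape[0])]
        self.tensor = t

    @property
    def n_regions(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.tensor.shape[2]


def _loo_moments(x: np.ndarray):
    """Leave-one-out first/second moments of a centred signal, vectorized."""
    T = x.size
    s = x.sum()
    ss = (x * x).sum()
    n = T - 1
    sx = s - x            # per-t sums over retained points
    sxx = ss - x * x
    var = sxx - sx * sx / n
    return sx, var


def jackknife_series(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw jackknife correlation of two signals.

    Element t is minus the Pearson correlation of ``x`` and ``y`` over all
    time points except t.  A leave-one-out subsample with zero variance in
    either signal yields 0 for that element (with a warning); if every
    element is degenerate a :class:`NumericalError` is raised.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError(f"signal lengths differ: {x.size} vs {y.size}")
    if x.size < 4:
        raise ParameterError(f"need at least 4 time points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("signals must be finite")

    # centring is Pearson-invariant and avoids cancellation for large offsets
    xc = x - x.mean()
    yc = y - y.mean()
    T = x.size
    n = T - 1

    sx, vx = _loo_moments(xc)
    sy, vy = _loo_moments(yc)
    sxy = (xc * yc).sum() - xc * yc
    cov = sxy - sx * sy / n

    scale = max(float(np.max(np.abs(vx))), float(np.max(np.abs(vy))), 1.0)
    ok = (vx > _VAR_RTOL * scale) & (vy > _VAR_RTOL * scale)
    if not ok.any():
        raise NumericalError("every leave-one-out subsample is degenerate")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} degenerate leave-one-out subsample(s) set to 0",
            RuntimeWarning,
            stacklevel=2,
        )

    jc = np.zeros(T)
    denom = np.sqrt(vx[ok] * vy[ok])
    jc[ok] = -np.clip(cov[ok] / denom, -1.0, 1.0)
    return jc


def normalize_edge(raw: np.ndarray) -> np.ndarray:
    """Z-score a per-edge series across time (population SD).

    A zero-variance series maps to the all-zero vector: a constant edge
    carries no temporal information.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    if not np.isfinite(raw).all():
        raise ParameterError("input must be finite")
    sd = raw.std()  # population (divide-by-T) convention
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def dynamic_connectivity(ts: RoiTimeSeries, normalize: bool = True) -> DynamicConnectivity:
    """Jackknife-correlation tensor for all region pairs of one subject.

    Applies :func:`jackknife_series` to every unordered pair (computed in a
    vectorized all-pairs form), fills both triangles, zeroes the diagonal,
    and z-scores each edge across time when ``normalize`` is set.
    """
    X = ts.values - ts.values.mean(axis=0)  # (T, N), centred per region
    T, N = X.shape
    n = T - 1

    S = X.sum(axis=0)             # (N,)
    G = X.T @ X                   # (N, N) gram of centred signals

    tensor = np.empty((N, N, T))
    var_t = np.empty((T, N))      # leave-one-out variance per (t, region)
    for t in range(T):
        xt = X[t]
        s_loo = S - xt
        g_loo = G - np.outer(xt, xt)
        cov = g_loo - np.outer(s_loo, s_loo) / n
        var_t[t] = np.diag(cov)
        denom = np.sqrt(np.outer(var_t[t], var_t[t]))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        tensor[:, :, t] = -np.clip(r, -1.0, 1.0)

    scale = max(float(var_t.max()), 1.0)
    degen = var_t <= _VAR_RTOL * scale  # (T, N)
    if degen.any():
        # a degenerate region at time t zeroes row/column for that slice
        always = degen.all(axis=0)
        if always.any():
            j = int(np.argmax(always))
            raise NumericalError(
                f"region {ts.region_labels[j]} degenerate at every time point"
            )
        n_el = 0
        for t in np.where(degen.any(axis=1))[0]:
            bad = np.where(degen[t])[0]
            tensor[bad, :, t] = 0.0
            tensor[:, bad, t] = 0.0
            n_el += bad.size
        warnings.warn(
            f"{n_el} degenerate (region, time) leave-one-out subsample(s) set to 0",
            RuntimeWarning,
            stacklevel=2,
        )

    idx = np.arange(N)
    tensor[idx, idx, :] = 0.0

    if normalize:
        mean = tensor.mean(axis=2, keepdims=True)
        sd = tensor.std(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            tensor = np.where(sd > 0, (tensor - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        tensor[idx, idx, :] = 0.0

    # exact symmetry despite floating-point round-off
    tensor = 0.5 * (tensor + tensor.transpose(1, 0, 2))
    return DynamicConnectivity(
        tensor=tensor, normalized=normalize, region_labels=list(ts.region_labels)
    )
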