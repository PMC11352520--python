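"""Overlapping community detection by constrained tri-factorization.

The model approximates every time slice of a non-negative group dynamic
network as ``F_t ~ C Z_t C^T`` with a single membership matrix C (N x k,
non-negative, every column's maximum pinned to 1) shared across time and a
diagonal non-negative intensity matrix Z_t per time point.  The objective is

    sum_t || F_t - C Z_t C^T ||_F^2  +  beta * ||C||_1 ,

minimized by block-coordinate descent: a Lee-Seung-style multiplicative rule
for the diagonal intensities (monotone for non-negative data) and a projected
gradient step with Armijo backtracking for C, followed by clipping negatives
and renormalizing each column to maximum 1.  Renormalizing column p by its
maximum m_p multiplies every z_p(t) by m_p^2, which leaves the product
C Z_t C^T — and hence the Frobenius term — unchanged; without that
compensation the renormalization step would destroy monotone descent.

Because all factors are non-negative, membership strengths read directly as
community affiliation intensities and a region may load on several columns
at once — the overlapping structure the method exists to expose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError
from .group import GroupDynamicNetwork

__all__ = [
    "CommunityModel",
    "objective",
    "reconstruct",
    "update_Z",
    "update_C",
    "fit",
    "preprocess_nonnegative",
    "select_parameters",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12          # multiplicative-rule denominator guard
_ARMIJO_SIGMA = 1e-4  # sufficient-decrease constant
_MAX_HALVINGS = 30

#: default cross-validation grids: k = 2..20, beta = 0, 0.1, ..., 1.0
DEFAULT_K_GRID = tuple(range(2, 21))
DEFAULT_BETA_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class CommunityModel:
    """Fitted overlapping community structure.

    Attributes
    ----------
    C : ndarray, shape (N, k)
        Non-negative membership; every column's maximum is 1 (a column that
        dies to all zeros during optimization is left as zeros).
    Z : ndarray, shape (T, k)
        Diagonal entries of the per-time intensity matrices, non-negative.
    beta : float
        L1 sparsity weight on C.
    objective_trace : ndarray
        Objective value after initialization and after every full
        (Z-then-C) sweep; non-increasing within 1e-9.
    """

    C: np.ndarray
    Z: np.ndarray
    k: int
    beta: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0
    converged: bool = False
    restart_index: int = 0
    restart_objectives: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.Z.shape[0]


def _as_time_major(F) -> np.ndarray:
    """Accept a GroupDynamicNetwork or an (N, N, T) array; return (T, N, N)."""
    if isinstance(F, GroupDynamicNetwork):
        F = F.F
    F = np.asarray(F, dtype=float)
    if F.ndim == 2:
        F = F[:, :, None]
    if F.ndim != 3 or F.shape[0] != F.shape[1]:
        raise StructuralError("connectivity input must have shape (N, N, T)")
    return np.moveaxis(F, 2, 0)


def _frobenius_term(Ft: np.ndarray, C: np.ndarray, Z: np.ndarray) -> float:
    CZ = C[None, :, :] * Z[:, None, :]       # (T, N, k)
    R = CZ @ C.T                              # (T, N, N)
    d = Ft - R
    return float(np.einsum("tnm,tnm->", d, d))


def _objective(Ft: np.ndarray, C: np.ndarray, Z: np.ndarray, beta: float) -> float:
    return _frobenius_term(Ft, C, Z) + beta * float(np.abs(C).sum())


def objective(F, model: CommunityModel) -> float:
    """Evaluate ``sum_t ||F_t - C Z_t C^T||_F^2 + beta ||C||_1``."""
    Ft = _as_time_major(F)
    if Ft.shape[1] != model.C.shape[0] or Ft.shape[0] != model.Z.shape[0]:
        raise StructuralError(
            f"tensor shape {Ft.shape} inconsistent with model "
            f"(N={model.C.shape[0]}, T={model.Z.shape[0]})"
        )
    return _objective(Ft, model.C, model.Z, model.beta)


def reconstruct(model: CommunityModel, i: int) -> np.ndarray:
    """Model connectivity at time i: ``sum_p z_p(i) c_p c_p^T`` (symmetric PSD)."""
    T = model.Z.shape[0]
    if not 0 <= i < T:
        raise ParameterError(f"time index {i} out of range [0, {T})")
    CZ = model.C * model.Z[i]
    return CZ @ model.C.T


def update_Z(F_i: np.ndarray, C: np.ndarray, z: np.ndarray) -> np.ndarray:
    """One multiplicative update of a slice's diagonal intensities.

    ``z_p <- z_p * (c_p^T F_i c_p) / (c_p^T C Z C^T c_p + eps)`` — the
    natural Lee-Seung rule for this diagonal tri-factorization, obtained from
    the gradient split of ``||F_i - C Z C^T||_F^2`` in z.  For non-negative
    F_i the slice residual never increases; z = 0 is a fixed point.
    """
    F_i = np.asarray(F_i, dtype=float)
    C = np.asarray(C, dtype=float)
    z = np.asarray(z, dtype=float)
    num = np.einsum("np,nm,mp->p", C, F_i, C)
    G = C.T @ C
    den = (G * G) @ z
    return z * np.maximum(num, 0.0) / (den + _EPS)


def _update_Z_all(Ft: np.ndarray, C: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Vectorized multiplicative update of every time point's intensities."""
    num = np.einsum("np,tnm,mp->tp", C, Ft, C, optimize=True)
    G = C.T @ C
    den = Z @ (G * G).T
    return Z * np.maximum(num, 0.0) / (den + _EPS)


def _renormalize(C: np.ndarray, Z: np.ndarray):
    """Rescale each column of C to max 1, compensating Z to keep C Z C^T."""
    m = C.max(axis=0)
    scale = np.where(m > 0, m, 1.0)  # dead columns left untouched
    return C / scale, Z * scale**2


def _gradient_C(Ft: np.ndarray, C: np.ndarray, Z: np.ndarray, beta: float) -> np.ndarray:
    CZ = C[None, :, :] * Z[:, None, :]
    R = CZ @ C.T
    resid = R - Ft
    # d/dC sum_t ||F_t - C Z_t C^T||^2 = 4 sum_t (C Z_t C^T - F_t) C Z_t
    grad = 4.0 * np.einsum("tnm,tmk->nk", resid, CZ, optimize=True)
    return grad + beta  # C >= 0, so d(beta * sum C)/dC = beta


def update_C(
    F,
    C: np.ndarray,
    Z: np.ndarray,
    beta: float,
    step0: float = 1.0,
):
    """One projected-gradient step on C with Armijo backtracking.

    Returns ``(C_new, Z_new, step)``: the clipped, column-renormalized
    membership, the intensity matrix rescaled to preserve the reconstruction,
    and the accepted step size (reusable as the next sweep's warm start).
    The step is accepted only when the full objective — evaluated after
    clipping AND renormalization — satisfies the sufficient-decrease
    condition; if no step of up to 30 halvings qualifies, C and Z are
    returned unchanged.
    """
    Ft = _as_time_major(F)
    C = np.asarray(C, dtype=float)
    Z = np.asarray(Z, dtype=float)
    f0 = _objective(Ft, C, Z, beta)
    grad = _gradient_C(Ft, C, Z, beta)

    step = float(step0)
    for _ in range(_MAX_HALVINGS):
        cand = np.maximum(C - step * grad, 0.0)
        # Armijo on the projected step direction
        decrease = float((grad * (C - cand)).sum())
        C_new, Z_new = _renormalize(cand, Z)
        f_new = _objective(Ft, C_new, Z_new, beta)
        if f_new <= f0 - _ARMIJO_SIGMA * decrease and f_new <= f0:
            return C_new, Z_new, step
        step *= 0.5
    return C, Z, step


def preprocess_nonnegative(F):
    """Clip negative entries to zero, logging the clipped fraction.

    The non-negative factors can only represent the non-negative part of the
    network, so standardized connectivity is clipped before fitting.  Returns
    the same type as the input (GroupDynamicNetwork or ndarray).
    """
    if isinstance(F, GroupDynamicNetwork):
        clipped = preprocess_nonnegative(F.F)
        return GroupDynamicNetwork(
            F=clipped, provenance=F.provenance, region_labels=list(F.region_labels)
        )
    F = np.asarray(F, dtype=float)
    frac = float((F < 0).mean())
    logger.info("preprocess_nonnegative: clipped %.1f%% of entries", 100 * frac)
    return np.maximum(F, 0.0)


def _init_restart(rng: np.random.Generator, N: int, T: int, k: int):
    C = rng.uniform(0.0, 1.0, size=(N, k))
    C, _ = _renormalize(C, np.zeros((1, k)))
    Z = rng.uniform(0.0, 1.0, size=(T, k))
    return C, Z


def _fit_single(
    Ft: np.ndarray,
    k: int,
    beta: float,
    rng: np.random.Generator,
    tol: float,
    max_sweeps: int,
):
    T, N, _ = Ft.shape
    C, Z = _init_restart(rng, N, T, k)
    trace = [_objective(Ft, C, Z, beta)]
    step = 1.0
    converged = False
    for _ in range(max_sweeps):
        Z = _update_Z_all(Ft, C, Z)
        # try growing the warm-started step so it can recover after halvings
        C, Z, step = update_C(np.moveaxis(Ft, 0, -1), C, Z, beta, step0=min(2.0 * step, 1.0))
        f = _objective(Ft, C, Z, beta)
        prev = trace[-1]
        trace.append(f)
        if abs(prev - f) <= tol * max(1.0, abs(prev)):
            converged = True
            break
    return C, Z, np.asarray(trace), converged


def fit(
    F,
    k: int,
    beta: float = 0.1,
    n_init: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> CommunityModel:
    """Detect k overlapping communities shared across all time points.

    Runs ``n_init`` random restarts (uniform non-negative C with columns
    normalized to max 1; uniform non-negative diagonal intensities), each
    alternating the multiplicative intensity update over all time points with
    a projected-gradient membership step until the relative objective change
    falls below ``tol`` or ``max_sweeps`` sweeps, and returns the restart
    with the smallest final objective.  Fully reproducible from ``seed``:
    one master seed spawns an independent stream per restart.
    """
    Ft = _as_time_major(F)
    T, N, _ = Ft.shape
    if not 1 <= k <= N:
        raise ParameterError(f"k must lie in [1, {N}], got {k}")
    if beta < 0:
        raise ParameterError("beta must be non-negative")
    if n_init < 1:
        raise ParameterError("need at least one restart")
    if Ft.min() < 0:
        raise ParameterError(
            "tensor has negative entries; apply preprocess_nonnegative first"
        )

    streams = np.random.SeedSequence(seed).spawn(n_init)
    best = None
    finals = np.empty(n_init)
    for r, ss in enumerate(streams):
        C, Z, trace, converged = _fit_single(
            Ft, k, beta, np.random.default_rng(ss), tol, max_sweeps
        )
        finals[r] = trace[-1]
        logger.debug("restart %d: objective %.6g (%d sweeps)", r, trace[-1], len(trace) - 1)
        if best is None or trace[-1] < best[2][-1]:
            best = (C, Z, trace, converged, r)

    C, Z, trace, converged, r = best
    return CommunityModel(
        C=C,
        Z=Z,
        k=k,
        beta=beta,
        objective_trace=trace,
        seed=int(seed),
        converged=converged,
        restart_index=r,
        restart_objectives=finals,
    )


def _heldout_error(
    Ft_train: np.ndarray,
    Ft_test: np.ndarray,
    k: int,
    beta: float,
    seed_seq: np.random.SeedSequence,
    n_init: int,
    tol: float,
    max_sweeps: int,
) -> float:
    """Fit on one fold, freeze C, re-estimate intensities on the other fold."""
    model = fit(
        np.moveaxis(Ft_train, 0, -1),
        k=k,
        beta=beta,
        n_init=n_init,
        seed=int(seed_seq.generate_state(1)[0] % (2**31)),
        tol=tol,
        max_sweeps=max_sweeps,
    )
    C = model.C
    Z = np.ones((Ft_test.shape[0], k))
    prev = math.inf
    for _ in range(500):
        Z = _update_Z_all(Ft_test, C, Z)
        err = _frobenius_term(Ft_test, C, Z)
        if abs(prev - err) <= 1e-9 * max(1.0, prev):
            break
        prev = err
    return _frobenius_term(Ft_test, C, Z)


def select_parameters(
    F,
    k_grid=None,
    beta_grid=None,
    seed: int = 0,
    n_init: int = 20,
    tol: float = 1e-6,
    max_sweeps: int = 500,
):
    """Grid search over (k, beta) with 2-fold cross-validation over time.

    Time points are split into interleaved (even/odd) folds.  For each cell
    the model is fitted on one fold, C is frozen, the held-out intensities
    are re-estimated by multiplicative updates alone, and the held-out
    Frobenius error is recorded; both directions are averaged.  Default grids
    are k = 2..20 and beta = 0, 0.1, ..., 1.0.

    Returns ``(table, (k_best, beta_best))`` where ``table`` is a DataFrame
    with columns k, beta, cv_error and the argmin is taken over the mean
    held-out error (lowest k then beta on ties).
    """
    Ft = _as_time_major(F)
    T = Ft.shape[0]
    if T < 2:
        raise ParameterError("2-fold time split needs at least 2 time points")
    k_grid = list(k_grid) if k_grid is not None else list(DEFAULT_K_GRID)
    beta_grid = (
        [float(b) for b in beta_grid] if beta_grid is not None else list(DEFAULT_BETA_GRID)
    )
    if not k_grid or not beta_grid:
        raise ParameterError("parameter grids must be non-empty")

    fold_a = np.arange(0, T, 2)
    fold_b = np.arange(1, T, 2)
    root = np.random.SeedSequence(seed)

    rows = []
    for k, beta in product(k_grid, beta_grid):
        cell_seed = root.spawn(1)[0]
        sub_a, sub_b = cell_seed.spawn(2)
        err = 0.5 * (
            _heldout_error(Ft[fold_a], Ft[fold_b], k, beta, sub_a, n_init, tol, max_sweeps)
            + _heldout_error(Ft[fold_b], Ft[fold_a], k, beta, sub_b, n_init, tol, max_sweeps)
        )
        rows.append({"k": k, "beta": beta, "cv_error": err})
        logger.info("cv k=%d beta=%.2f heldout=%.6g", k, beta, err)

    table = pd.DataFrame(rows)
    best = table.loc[table["cv_error"].idxmin()]
    return table, (int(best["k"]), float(best["beta"]))
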