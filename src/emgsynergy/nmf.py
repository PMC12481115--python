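"""Nonnegative matrix factorization of EMG envelopes and model-order selection.

The preprocessed matrix M (muscles x time) is modeled as M = W C + e with
nonnegative muscle weighting components W (muscles x n) and temporal pattern
components C (n x time). The solver is the classical multiplicative-update
algorithm for the squared Frobenius objective; because it only finds local
minima, each extraction is repeated from many random initializations and the
restart with the highest VAF is kept.

VAF (variance accounted for) is 100 x the squared *uncentered* Pearson
correlation between the flattened data and its reconstruction:

    VAF = 100 * ( <M, WC> / (||M||_F ||WC||_F) )^2

The model order n is the smallest candidate whose best-of-restarts VAF
exceeds the threshold (default 90 on the 0-100 scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, OrderError, ShapeError, UndefinedVAFError
from .preprocess import EMGMatrix

_EPS = 1e-12  # floor inside multiplicative updates; guards zero rows

DEFAULT_MAX_ITER = 1000
DEFAULT_TOL = 1e-6
DEFAULT_RESTARTS = 50
DEFAULT_VAF_THRESHOLD = 90.0


@dataclass
class SynergyDecomposition:
    """Result of order-selected NMF on one subject's EMG matrix."""

    W: np.ndarray                 # muscles x n, columns unit-norm
    C: np.ndarray                 # n x time
    n: int
    vaf_curve: np.ndarray         # percent, entry k-1 for order k (NaN if not run)
    vaf_selected: float
    residual_norm: float
    restarts: int
    seed: int
    threshold: float = DEFAULT_VAF_THRESHOLD
    threshold_reached: bool = True
    muscle_labels: list[str] | None = None
    n_trials: int | None = None


def _as_matrix(M) -> np.ndarray:
    values = M.values if isinstance(M, EMGMatrix) else np.asarray(M, dtype=float)
    if values.ndim != 2:
        raise ShapeError("M must be 2-D (muscles x time)")
    if not np.all(np.isfinite(values)):
        raise DataError("M contains NaN or infinite entries")
    if np.any(values < 0):
        raise DataError("M must be nonnegative")
    return values


def _sub_seed(seed: int, restart: int) -> np.random.Generator:
    # counter scheme: every (seed, restart) pair maps to an independent stream
    return np.random.default_rng([int(seed), int(restart)])


def nmf_fit(
    M,
    n: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update NMF run from a random initialization.

    Returns ``(W, C, final_error)`` with the Frobenius reconstruction error;
    the error is non-increasing across iterations and iteration stops when
    its relative decrease falls below ``tol``.
    """
    V = _as_matrix(M)
    m, t = V.shape
    if not (1 <= n <= m):
        raise OrderError(f"order n={n} outside 1..{m}")
    if rng is None:
        rng = np.random.default_rng(seed)
    # uniform on (0, 1]
    W = 1.0 - rng.random((m, n))
    C = 1.0 - rng.random((n, t))

    err_prev = np.inf
    err = np.linalg.norm(V - W @ C)
    for _ in range(max_iter):
        C *= (W.T @ V) / (W.T @ W @ C + _EPS)
        W *= (V @ C.T) / (W @ (C @ C.T) + _EPS)
        err_prev, err = err, np.linalg.norm(V - W @ C)
        if err_prev - err < tol * max(err_prev, _EPS):
            break
    return W, C, err


def vaf(M, W: np.ndarray, C: np.ndarray) -> float:
    """Variance accounted for: 100 x squared uncentered correlation."""
    V = _as_matrix(M)
    R = np.asarray(W) @ np.asarray(C)
    if R.shape != V.shape:
        raise ShapeError(f"reconstruction shape {R.shape} != data {V.shape}")
    norm_v = np.linalg.norm(V)
    norm_r = np.linalg.norm(R)
    if norm_v == 0 or norm_r == 0:
        raise UndefinedVAFError("VAF undefined for all-zero data or reconstruction")
    r = float(np.sum(V * R)) / (norm_v * norm_r)
    return 100.0 * r * r


def normalize_columns(W: np.ndarray, C: np.ndarray | None = None):
    """Scale each column of W to unit Euclidean norm, absorbing the inverse
    factor into the matching row of C (zero columns are left untouched)."""
    W = np.array(W, dtype=float)
    scales = np.linalg.norm(W, axis=0)
    scales[scales == 0] = 1.0
    W /= scales
    if C is None:
        return W
    C = np.array(C, dtype=float) * scales[:, None]
    return W, C


def nmf_best_of(
    M,
    n: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Repeat the extraction ``restarts`` times and keep the highest-VAF run.

    Restart r uses the deterministic sub-stream (seed, r), so the result is
    bitwise reproducible for a given master seed. Returns ``(W, C, vaf)``
    with W column-normalized.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best = None
    for r in range(1, restarts + 1):
        W, C, _ = nmf_fit(M, n, max_iter=max_iter, tol=tol,
                          rng=_sub_seed(seed, r))
        v = vaf(M, W, C)
        if best is None or v > best[2]:
            best = (W, C, v)
    W, C = normalize_columns(best[0], best[1])
    return W, C, best[2]


def select_order(
    M,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    scan: str = "full",
) -> SynergyDecomposition:
    """Pick the smallest order whose VAF strictly exceeds the threshold.

    ``scan="full"`` evaluates every candidate order 1..m so the whole VAF
    curve is reported; ``scan="stop"`` stops scanning once the threshold is
    crossed (remaining curve entries are NaN) — useful for large batch runs.
    """
    if scan not in ("full", "stop"):
        raise ValueError("scan must be 'full' or 'stop'")
    V = _as_matrix(M)
    m = V.shape[0]
    curve = np.full(m, np.nan)
    fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    selected = None
    for n in range(1, m + 1):
        W, C, v = nmf_best_of(M, n, restarts=restarts, seed=seed,
                              max_iter=max_iter, tol=tol)
        curve[n - 1] = v
        fits[n] = (W, C)
        if selected is None and v > vaf_threshold:
            selected = n
            if scan == "stop":
                break

    reached = selected is not None
    if not reached:
        warnings.warn(
            f"VAF threshold {vaf_threshold} not reached by order {m}; "
            "returning the full-order model", stacklevel=2)
        selected = m
    W, C = fits[selected]
    labels = M.muscle_labels if isinstance(M, EMGMatrix) else None
    n_trials = M.n_trials if isinstance(M, EMGMatrix) else None
    return SynergyDecomposition(
        W=W, C=C, n=selected, vaf_curve=curve,
        vaf_selected=float(curve[selected - 1]),
        residual_norm=float(np.linalg.norm(V - W @ C)),
        restarts=restarts, seed=seed, threshold=vaf_threshold,
        threshold_reached=reached, muscle_labels=labels, n_trials=n_trials,
    )


def average_temporal(C: np.ndarray, n_trials: int, n_points: int = 200) -> np.ndarray:
    """Average the temporal patterns over the concatenated trial blocks.

    ``C`` is n x (n_points * n_trials); returns n x n_points, the per-synergy
    mean time course of the averaged trial.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != n_points * n_trials:
        raise ShapeError(
            f"C has {C.shape[1] if C.ndim == 2 else '?'} columns, "
            f"expected {n_points} x {n_trials}"
        )
    return C.reshape(C.shape[0], n_trials, n_points).mean(axis=1)
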