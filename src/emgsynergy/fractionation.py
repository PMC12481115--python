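"""Synergy sparseness and fractionation/merging detection.

Sparseness of a nonnegative synergy vector w of length n is the normalized
L1/L2 ratio

    phi = (sqrt(n) - ||w||_1 / ||w||_2) / (sqrt(n) - 1),

which is 1 for a one-hot vector (one active muscle) and 0 for a uniform
vector (all muscles equally active), and is invariant to positive scaling.

Fractionation asks whether a synergy centroid of one group (the "parent")
can be written as a nonnegative combination of two or more centroids of the
other group:

    w_parent ~ sum_k m_k w_k,   m_k >= 0  (nonnegative least squares),

with the candidate accepted when at least two coefficients reach 0.2 and the
reconstruction's scalar product with the parent reaches 0.75. Merging is the
mirror-image question with the group roles swapped. Every basis subset of
size >= 2 is fit; the passing subset with the highest reconstruction SP
(ties broken toward fewer contributors) is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import (
    DimensionError,
    InsufficientBasisError,
    UndefinedSparsenessError,
)
from .nmf import SynergyDecomposition
from . import stats as group_stats

DEFAULT_COEF_THRESHOLD = 0.2
DEFAULT_SP_THRESHOLD = 0.75


def sparseness(w: np.ndarray, n: int | None = None) -> float:
    """Normalized L1/L2 sparseness phi of a nonnegative vector."""
    w = np.asarray(w, dtype=float).ravel()
    if n is None:
        n = w.size
    if n < 2 or w.size != n:
        raise DimensionError(f"need a vector of length n >= 2, got {w.size}/{n}")
    if np.any(w < 0):
        raise ValueError("sparseness is defined for nonnegative vectors")
    l2 = np.linalg.norm(w)
    if l2 == 0:
        raise UndefinedSparsenessError("sparseness undefined for the zero vector")
    root_n = np.sqrt(n)
    return float((root_n - np.abs(w).sum() / l2) / (root_n - 1.0))


@dataclass
class SparsenessReport:
    group: str
    per_synergy: pd.DataFrame        # columns: subject, synergy, phi
    per_subject_mean: pd.Series      # index: subject


def group_sparseness(
    decompositions: list[SynergyDecomposition],
    subject_ids: list[str] | None = None,
    group: str = "",
) -> SparsenessReport:
    """Per-synergy phi and per-subject mean phi for one group."""
    if subject_ids is None:
        subject_ids = [f"S{i + 1}" for i in range(len(decompositions))]
    rows = []
    for sid, dec in zip(subject_ids, decompositions):
        W = np.asarray(dec.W, dtype=float)
        for j in range(W.shape[1]):
            rows.append({"subject": sid, "synergy": j + 1,
                         "phi": sparseness(W[:, j])})
    df = pd.DataFrame(rows)
    means = df.groupby("subject", sort=False)["phi"].mean()
    return SparsenessReport(group=group, per_synergy=df, per_subject_mean=means)


def nnls_combination(target: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares coefficients m minimizing
    ||target - basis.T m||_2 with m >= 0. ``basis`` rows are the vectors."""
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if basis.shape[0] == 0:
        raise InsufficientBasisError("empty basis")
    coef, _ = nnls(basis.T, np.asarray(target, dtype=float).ravel())
    return coef


@dataclass
class CombinationResult:
    """One parent/merged centroid explained by a nonnegative combination."""

    target_id: int
    basis_ids: tuple[int, ...]
    coefficients: np.ndarray
    reconstruction_sp: float
    passed: bool
    diagnostics: pd.DataFrame = field(repr=False, default=None)  # type: ignore


# Fractionation and merging share the same algebra; the two public names
# keep the direction of explanation explicit in reports.
FractionationResult = CombinationResult
MergingResult = CombinationResult


def _reconstruction_sp(target: np.ndarray, basis: np.ndarray,
                       coef: np.ndarray) -> float:
    recon = coef @ basis
    norm = np.linalg.norm(recon)
    if norm == 0:
        return 0.0
    return float(recon @ target / (norm * np.linalg.norm(target)))


def _detect_combinations(
    targets: np.ndarray,
    basis: np.ndarray,
    coef_threshold: float,
    sp_threshold: float,
    target_ids=None,
    basis_ids=None,
) -> list[CombinationResult]:
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    nb = basis.shape[0]
    if nb < 2:
        raise InsufficientBasisError(
            f"need >= 2 basis centroids, got {nb}")
    target_ids = (np.arange(1, targets.shape[0] + 1)
                  if target_ids is None else np.asarray(target_ids))
    basis_ids = (np.arange(1, nb + 1)
                 if basis_ids is None else np.asarray(basis_ids))

    results = []
    for i, target in enumerate(targets):
        diag_rows = []
        best = None  # (passed, sp, -size, subset, coef)
        for size in range(2, nb + 1):
            for subset in itertools.combinations(range(nb), size):
                sub = basis[list(subset)]
                coef = nnls_combination(target, sub)
                sp = _reconstruction_sp(target, sub, coef)
                surviving = int(np.sum(coef >= coef_threshold))
                # pass rule: every contributing coefficient must clear the
                # threshold (subsets with weaker members are enumerated
                # separately), at least two contributors, SP at threshold
                passed = bool(np.all(coef >= coef_threshold)) and sp >= sp_threshold
                diag_rows.append({
                    "target": int(target_ids[i]),
                    "basis": tuple(int(basis_ids[k]) for k in subset),
                    "coefficients": tuple(np.round(coef, 6)),
                    "sp": sp,
                    "n_surviving": surviving,
                    "passed": passed,
                })
                key = (passed, sp, -size)
                if best is None or key > best[0]:
                    best = (key, subset, coef, sp, passed)
        _, subset, coef, sp, passed = best
        results.append(CombinationResult(
            target_id=int(target_ids[i]),
            basis_ids=tuple(int(basis_ids[k]) for k in subset),
            coefficients=coef,
            reconstruction_sp=sp,
            passed=passed,
            diagnostics=pd.DataFrame(diag_rows),
        ))
    return results


def detect_fractionation(
    parents: np.ndarray,
    fragments: np.ndarray,
    coef_threshold: float = DEFAULT_COEF_THRESHOLD,
    sp_threshold: float = DEFAULT_SP_THRESHOLD,
    parent_ids=None,
    fragment_ids=None,
) -> list[FractionationResult]:
    """Explain each younger-group centroid as >= 2 older-group centroids."""
    return _detect_combinations(parents, fragments, coef_threshold,
                                sp_threshold, parent_ids, fragment_ids)


def detect_merging(
    merged_candidates: np.ndarray,
    sources: np.ndarray,
    coef_threshold: float = DEFAULT_COEF_THRESHOLD,
    sp_threshold: float = DEFAULT_SP_THRESHOLD,
    merged_ids=None,
    source_ids=None,
) -> list[MergingResult]:
    """Explain each candidate merged centroid as >= 2 source centroids."""
    return _detect_combinations(merged_candidates, sources, coef_threshold,
                                sp_threshold, merged_ids, source_ids)


def direction_gate(
    sparseness_A: "SparsenessReport | np.ndarray",
    sparseness_B: "SparsenessReport | np.ndarray",
    alpha: float = 0.05,
) -> dict:
    """Decide which analysis the sparseness comparison licenses.

    If the older group (B) is significantly sparser, its synergies look like
    split versions of the younger group's: run the fractionation analysis.
    If significantly less sparse, run the merging analysis. Otherwise both
    analyses are exploratory. Advisory only — both can always be forced.
    """
    phi_a = (sparseness_A.per_subject_mean.to_numpy()
             if isinstance(sparseness_A, SparsenessReport)
             else np.asarray(sparseness_A, dtype=float))
    phi_b = (sparseness_B.per_subject_mean.to_numpy()
             if isinstance(sparseness_B, SparsenessReport)
             else np.asarray(sparseness_B, dtype=float))
    mw = group_stats.mann_whitney(phi_a, phi_b)
    if mw.p_value < alpha:
        directive = ("fractionation" if np.median(phi_b) > np.median(phi_a)
                     else "merging")
    else:
        directive = "both"
    return {"directive": directive, "u_statistic": mw.u_statistic,
            "p_value": mw.p_value, "alpha": alpha}
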