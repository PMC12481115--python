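"""End-to-end two-group analysis: envelopes -> synergies -> clusters ->
sparseness -> fractionation/merging.

Thin orchestration over the stage modules, mainly for the CLI, the
simulation studies and the recovery tests. Works on an in-memory dataset of
the form produced by :func:`emgsynergy.simulate.make_dataset` (or assembled
from files by the preprocessing manifest reader).
"""

from __future__ import annotations

import numpy as np

from . import cluster as cl
from . import fractionation as fr
from . import stats as gs
from .nmf import select_order
from .preprocess import assemble_subject


def subject_seed_int(seed: int, index: int) -> int:
    """Deterministic per-subject integer sub-seed (< 2**31)."""
    return int(np.random.SeedSequence([int(seed), int(index)])
               .generate_state(1)[0] & 0x7FFFFFFF)


def decompose_subjects(
    subjects: dict[str, dict],
    vaf_threshold: float = 90.0,
    restarts: int = 5,
    max_iter: int = 500,
    scan: str = "stop",
    seed: int = 0,
):
    """Assemble and order-select every subject; returns per-group dicts of
    SynergyDecomposition keyed by subject id."""
    groups: dict[str, dict] = {}
    for i, (sid, entry) in enumerate(sorted(subjects.items())):
        em = assemble_subject(entry["trials"], n_keep=len(entry["trials"]))
        dec = select_order(em, vaf_threshold=vaf_threshold, restarts=restarts,
                           max_iter=max_iter, scan=scan,
                           seed=subject_seed_int(seed, i))
        groups.setdefault(entry["group"], {})[sid] = dec
    return groups


def analyze_two_groups(
    subjects: dict[str, dict],
    vaf_threshold: float = 90.0,
    restarts: int = 5,
    max_iter: int = 500,
    scan: str = "stop",
    gap_B: int = 100,
    h_range: tuple[int, int] = (2, 20),
    sp_threshold: float = 0.75,
    subject_fraction: float = 1.0 / 3.0,
    coef_threshold: float = 0.2,
    seed: int = 0,
) -> dict:
    """Run the whole comparison between groups "A" and "B".

    Returns a dict with per-group decompositions, cluster solutions,
    subject-invariant centroids, the between-group match, sparseness
    reports, the direction gate, and the fractionation (and, when the gate
    says so, merging) results.
    """
    groups = decompose_subjects(subjects, vaf_threshold, restarts, max_iter,
                                scan, seed)
    out: dict = {"decompositions": groups}

    solutions, invariant = {}, {}
    for gi, gname in enumerate(sorted(groups)):
        decs = groups[gname]
        pooled = cl.pool_group(list(decs.values()), list(decs.keys()))
        sol = cl.cluster_group(pooled, h_range=h_range, B=gap_B,
                               seed=subject_seed_int(seed, 1000 + gi))
        solutions[gname] = sol
        ids, cents = cl.subject_invariant(sol, group_size=len(decs),
                                          fraction=subject_fraction)
        invariant[gname] = {"cluster_ids": ids, "centroids": cents}
    out["clusters"] = solutions
    out["invariant"] = invariant

    if set(groups) >= {"A", "B"}:
        out["match"] = cl.match_groups(
            invariant["A"]["centroids"], invariant["B"]["centroids"],
            sp_threshold=sp_threshold,
            ids_A=invariant["A"]["cluster_ids"],
            ids_B=invariant["B"]["cluster_ids"])

        rep_a = fr.group_sparseness(list(groups["A"].values()),
                                    list(groups["A"].keys()), group="A")
        rep_b = fr.group_sparseness(list(groups["B"].values()),
                                    list(groups["B"].keys()), group="B")
        out["sparseness"] = {"A": rep_a, "B": rep_b}
        out["gate"] = fr.direction_gate(rep_a, rep_b)
        out["sparseness_comparison"] = gs.summarize(
            "mean_phi", rep_a.per_subject_mean.to_numpy(),
            rep_b.per_subject_mean.to_numpy())

        if out["gate"]["directive"] in ("fractionation", "both"):
            if invariant["B"]["centroids"].shape[0] >= 2:
                out["fractionation"] = fr.detect_fractionation(
                    invariant["A"]["centroids"], invariant["B"]["centroids"],
                    coef_threshold=coef_threshold, sp_threshold=sp_threshold,
                    parent_ids=invariant["A"]["cluster_ids"],
                    fragment_ids=invariant["B"]["cluster_ids"])
        if out["gate"]["directive"] in ("merging", "both"):
            if invariant["A"]["centroids"].shape[0] >= 2:
                out["merging"] = fr.detect_merging(
                    invariant["B"]["centroids"], invariant["A"]["centroids"],
                    coef_threshold=coef_threshold, sp_threshold=sp_threshold,
                    merged_ids=invariant["B"]["cluster_ids"],
                    source_ids=invariant["A"]["cluster_ids"])
    return out
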