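"""Synthetic two-group EMG datasets with known modular ground truth.

The generator runs the synergy model forwards: nonnegative unit templates
(muscle weighting vectors) are combined with smooth nonnegative activation
profiles (Gaussian bursts with staggered centers, emulating the
proximal-to-distal sequencing of a throw) to produce per-trial envelope
matrices M = W C + e, with truncated-Gaussian (clip-at-zero) envelope noise.

Two groups are built so that their ground-truth synergy sets differ by
*fractionation*: selected templates of the younger group A are each split
into two fragments with disjoint dominant muscle supports (plus a small
shared leakage) such that a nonnegative combination of the fragments
reconstructs the parent almost exactly. Group B inherits the unsplit
templates unchanged. Fragments are sparser than their parent by
construction, so group B's mean sparseness exceeds group A's whenever any
split is planted.

Defaults mirror the study conditions: 13 vs 8 subjects, 16 muscles, 5 trials
per subject, 200 time points per trial, 6 group-A templates of which 2 are
fractionated (8 group-B templates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FeasibilityError, ParameterError, SplitError
from .fractionation import sparseness
from .preprocess import DEFAULT_MUSCLES

DEFAULT_SUBJECTS_A = 13
DEFAULT_SUBJECTS_B = 8
DEFAULT_K_A = 6
DEFAULT_N_FRACTIONATE = 2
DEFAULT_NOISE_SD = 0.05
DEFAULT_TRIALS = 5
DEFAULT_N_POINTS = 200
DEFAULT_N_MUSCLES = 16
DEFAULT_SPARSITY_TARGET = 0.5
DEFAULT_MIN_ANGLE = 65.0  # degrees between any two templates


@dataclass
class GaussianBump:
    """One synergy's activation burst on the normalized movement cycle."""

    center: float      # fraction of cycle, 0..1
    width: float       # fraction of cycle (standard deviation)
    amplitude: float = 1.0

    def evaluate(self, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
        x = np.linspace(0.0, 1.0, n_points)
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass
class GroundTruth:
    templates_A: np.ndarray                 # k_A x muscles, unit rows
    templates_B: np.ndarray                 # k_B x muscles, unit rows
    #: (parent index in A, (fragment i, fragment j) in B, (c_i, c_j))
    fractionation_map: list[tuple[int, tuple[int, int], tuple[float, float]]]
    profiles_A: list[GaussianBump]
    profiles_B: list[GaussianBump]
    noise_sd: float
    subjects_per_group: tuple[int, int]
    trials_per_subject: int
    seed: int
    muscle_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MUSCLES))


def _phi_of_power(u: np.ndarray, p: float) -> float:
    return sparseness(u ** p)


def make_templates(
    k: int,
    n_muscles: int = DEFAULT_N_MUSCLES,
    sparsity_target: float = DEFAULT_SPARSITY_TARGET,
    min_pairwise_angle: float = DEFAULT_MIN_ANGLE,
    seed: int = 0,
    max_attempts: int = 5000,
) -> np.ndarray:
    """Nonnegative unit synergy templates with controlled sparseness and
    pairwise separation.

    Each candidate has a dominant muscle support (supports are sampled to
    reuse muscles as little as possible, mimicking the largely distinct
    muscle groups of real synergies) plus a low random background; the
    background is raised to a power chosen by bisection so the vector's
    sparseness phi lands on the target (+/- 0.05). Candidates too close to
    an accepted template (scalar product above cos of the minimum angle)
    are rejected.
    """
    if k > n_muscles:
        raise FeasibilityError(f"cannot place {k} templates in {n_muscles} dims")
    rng = np.random.default_rng(seed)
    max_sp = float(np.cos(np.deg2rad(min_pairwise_angle)))
    # support size giving phi ~= target for a flat support:
    # phi = (sqrt(n) - sqrt(s)) / (sqrt(n) - 1)
    s = int(np.clip(round(
        (np.sqrt(n_muscles) - sparsity_target * (np.sqrt(n_muscles) - 1)) ** 2),
        1, n_muscles))
    use_count = np.zeros(n_muscles)
    accepted: list[np.ndarray] = []
    for _ in range(max_attempts):
        if len(accepted) == k:
            break
        if sparsity_target >= 0.98:
            v = np.zeros(n_muscles)
            v[rng.integers(n_muscles)] = 1.0
        else:
            # favor muscles not yet claimed by earlier templates
            w = 1.0 / (1.0 + 4.0 * use_count)
            support = rng.choice(n_muscles, size=s, replace=False,
                                 p=w / w.sum())
            u = np.full(n_muscles, 1e-3)
            u[support] = rng.uniform(0.6, 1.0, size=s)
            off = np.setdiff1d(np.arange(n_muscles), support)
            u[off] = rng.uniform(0.02, 0.3, size=off.size)
            lo, hi = 0.02, 400.0
            if _phi_of_power(u, hi) < sparsity_target or \
               _phi_of_power(u, lo) > sparsity_target:
                continue
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if _phi_of_power(u, mid) < sparsity_target:
                    lo = mid
                else:
                    hi = mid
            v = u ** (0.5 * (lo + hi))
            if abs(sparseness(v) - sparsity_target) > 0.05:
                continue
        v = v / np.linalg.norm(v)
        if all(float(v @ w_) <= max_sp for w_ in accepted):
            accepted.append(v)
            use_count[v > 0.1 * v.max()] += 1
    if len(accepted) < k:
        raise FeasibilityError(
            f"placed only {len(accepted)}/{k} templates within "
            f"{max_attempts} attempts (target phi {sparsity_target}, "
            f"min angle {min_pairwise_angle} deg)")
    return np.array(accepted)


def _balanced_partition(weights_sq: np.ndarray, active: np.ndarray):
    """Greedy split of active components into two groups of similar energy."""
    order = active[np.argsort(-weights_sq[active])]
    g1, g2, e1, e2 = [], [], 0.0, 0.0
    for idx in order:
        if e1 <= e2:
            g1.append(idx)
            e1 += weights_sq[idx]
        else:
            g2.append(idx)
            e2 += weights_sq[idx]
    return np.array(g1), np.array(g2)


def make_group_B_by_fractionation(
    templates_A: np.ndarray,
    which: list[int],
    coeffs: list[tuple[float, float]] | None = None,
    leakage: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, tuple[int, int], tuple[float, float]]]]:
    """Split selected group-A templates into pairs of fragments for group B.

    Each selected parent's active muscles are partitioned into two energy-
    balanced disjoint dominant supports; each fragment is the parent
    restricted to its support plus ``leakage`` x parent on the other support,
    renormalized. The recorded mixing coefficients reconstruct the parent
    with SP >= 0.9 (checked; SplitError otherwise). Unselected templates are
    copied to group B unchanged.
    """
    templates_A = np.asarray(templates_A, dtype=float)
    k_A, m = templates_A.shape
    for idx in which:
        if not 0 <= idx < k_A:
            raise SplitError(f"parent index {idx} out of range")
    if coeffs is not None and any(c < 0.3 for pair in coeffs for c in pair):
        raise SplitError("mixing coefficients must be >= 0.3")

    templates_B: list[np.ndarray] = [templates_A[i].copy()
                                     for i in range(k_A) if i not in which]
    frac_map = []
    for slot, parent_idx in enumerate(which):
        parent = templates_A[parent_idx]
        active = np.flatnonzero(parent > 0.1 * parent.max())
        if active.size < 2:
            raise SplitError(
                f"parent {parent_idx} has a single dominant muscle; "
                "cannot partition its support")
        g1, g2 = _balanced_partition(parent ** 2, active)
        frags, cs = [], []
        for own, other in ((g1, g2), (g2, g1)):
            f = np.zeros(m)
            f[own] = parent[own]
            f[other] = leakage * parent[other]
            norm = np.linalg.norm(f)
            frags.append(f / norm)
            cs.append(norm)
        if coeffs is not None:
            cs = list(coeffs[slot])
        recon = cs[0] * frags[0] + cs[1] * frags[1]
        sp = float(recon @ parent / np.linalg.norm(recon))
        if sp < 0.9:
            raise SplitError(
                f"fragments of parent {parent_idx} reconstruct it with "
                f"SP {sp:.3f} < 0.9")
        if min(cs) < 0.3:
            raise SplitError(
                f"parent {parent_idx} split is too unbalanced "
                f"(coefficient {min(cs):.3f} < 0.3)")
        i1 = len(templates_B)
        templates_B.extend(frags)
        frac_map.append((parent_idx, (i1, i1 + 1), (float(cs[0]), float(cs[1]))))
    return np.array(templates_B), frac_map


def staggered_profiles(k: int, seed: int = 0,
                       width_range: tuple[float, float] = (0.03, 0.03),
                       amplitude: float = 1.0) -> list[GaussianBump]:
    """Gaussian bursts with centers spread over the cycle (sequenced
    recruitment from early to late movement phases).

    Bursts are brief relative to their staggering — as in a ballistic
    throw — so each synergy carries distinct temporal variance and the
    ground-truth order is identifiable from the VAF curve.
    """
    rng = np.random.default_rng(seed)
    centers = np.linspace(0.15, 0.85, k)
    widths = rng.uniform(*width_range, size=k)
    return [GaussianBump(center=float(c), width=float(w), amplitude=amplitude)
            for c, w in zip(centers, widths)]


def simulate_subject(
    templates: np.ndarray,
    profiles: list[GaussianBump],
    trials: int = DEFAULT_TRIALS,
    noise_sd: float = DEFAULT_NOISE_SD,
    subject_variability: float = 0.05,
    timing_jitter_sd: float = 0.02,
    amplitude_jitter_sd: float = 0.1,
    n_points: int = DEFAULT_N_POINTS,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate one subject's envelope trials (each n_points x muscles).

    The subject's weights are the group templates plus Gaussian jitter
    (clipped at zero, renormalized); each trial jitters the burst timing and
    amplitude, then adds clip-at-zero Gaussian envelope noise.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    templates = np.asarray(templates, dtype=float)
    k, m = templates.shape
    if len(profiles) != k:
        raise ParameterError(f"{len(profiles)} profiles for {k} templates")
    rng = np.random.default_rng(seed)
    W_s = np.clip(templates + rng.normal(0.0, subject_variability, (k, m)), 0.0, None)
    norms = np.linalg.norm(W_s, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    W_s /= norms

    out = []
    for _ in range(trials):
        C = np.empty((k, n_points))
        for i, bump in enumerate(profiles):
            jittered = GaussianBump(
                center=float(np.clip(bump.center + rng.normal(0, timing_jitter_sd),
                                     0.0, 1.0)),
                width=bump.width,
                amplitude=bump.amplitude * max(
                    0.1, 1.0 + rng.normal(0, amplitude_jitter_sd)),
            )
            C[i] = jittered.evaluate(n_points)
        trial = C.T @ W_s
        if noise_sd > 0:
            trial = trial + rng.normal(0.0, noise_sd, trial.shape)
        out.append(np.clip(trial, 0.0, None))
    return out


def make_dataset(
    subjects_A: int = DEFAULT_SUBJECTS_A,
    subjects_B: int = DEFAULT_SUBJECTS_B,
    k_A: int = DEFAULT_K_A,
    n_fractionate: int = DEFAULT_N_FRACTIONATE,
    noise_sd: float = DEFAULT_NOISE_SD,
    trials: int = DEFAULT_TRIALS,
    n_muscles: int = DEFAULT_N_MUSCLES,
    sparsity_target: float = DEFAULT_SPARSITY_TARGET,
    min_pairwise_angle: float = DEFAULT_MIN_ANGLE,
    subject_variability: float = 0.05,
    seed: int = 0,
) -> dict:
    """Build the full two-group dataset: ground truth plus per-subject trials.

    Returns ``{"truth": GroundTruth, "subjects": {id: {"group", "trials"}}}``.
    Fractionated parents are the last ``n_fractionate`` templates of group A.
    """
    templates_A = make_templates(k_A, n_muscles, sparsity_target,
                                 min_pairwise_angle, seed=seed)
    which = list(range(k_A - n_fractionate, k_A))
    templates_B, frac_map = make_group_B_by_fractionation(
        templates_A, which, seed=seed)

    profiles_A = staggered_profiles(k_A, seed=seed)
    # B has its own staggering over the full cycle: fractionation comes with
    # differentiated timing, so every fragment gets a distinct burst slot.
    profiles_B = staggered_profiles(templates_B.shape[0], seed=seed)

    truth = GroundTruth(
        templates_A=templates_A, templates_B=templates_B,
        fractionation_map=frac_map, profiles_A=profiles_A,
        profiles_B=profiles_B, noise_sd=noise_sd,
        subjects_per_group=(subjects_A, subjects_B),
        trials_per_subject=trials, seed=seed,
        muscle_labels=(list(DEFAULT_MUSCLES[:n_muscles])
                       if n_muscles <= len(DEFAULT_MUSCLES)
                       else [f"ch{j + 1}" for j in range(n_muscles)]),
    )
    subjects: dict[str, dict] = {}
    for g_idx, (group, n_subj, templates, profiles) in enumerate([
        ("A", subjects_A, templates_A, profiles_A),
        ("B", subjects_B, templates_B, profiles_B),
    ]):
        for s in range(n_subj):
            sid = f"{group}{s + 1:02d}"
            subjects[sid] = {
                "group": group,
                "trials": simulate_subject(
                    templates, profiles, trials=trials, noise_sd=noise_sd,
                    subject_variability=subject_variability,
                    seed=_subject_seed(seed, g_idx, s)),
            }
    return {"truth": truth, "subjects": subjects}


def _subject_seed(seed: int, group_idx: int, subject_idx: int):
    return [int(seed), int(group_idx), int(subject_idx)]


def pseudo_raw_trial(
    envelope_trial: np.ndarray,
    sample_rate: float = 2000.0,
    duration: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Turn an envelope trial into a carrier-modulated pseudo-raw signal.

    Upsamples each channel's envelope to ``duration * sample_rate`` samples
    and multiplies it by white noise, producing a zero-mean broadband signal
    whose rectified low-passed amplitude tracks the input envelope. Exists to
    exercise the full filtering chain end-to-end; it makes no physiological
    claim.
    """
    env = np.asarray(envelope_trial, dtype=float)
    n_out = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    xi = np.linspace(0.0, 1.0, n_out)
    xp = np.linspace(0.0, 1.0, env.shape[0])
    up = np.column_stack([np.interp(xi, xp, env[:, j])
                          for j in range(env.shape[1])])
    return up * rng.standard_normal(up.shape)


def write_dataset(dataset: dict, out_dir: str | Path) -> Path:
    """Write trials as CSV, a manifest JSON and the ground-truth JSON.

    The layout is exactly what the preprocessing manifest reader consumes;
    trial files round-trip losslessly to printed precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth = dataset["truth"]
    labels = truth.muscle_labels
    manifest = {"sample_rate": 2000.0, "envelope_stage": True, "subjects": []}
    for sid, entry in dataset["subjects"].items():
        files = []
        for t, trial in enumerate(entry["trials"]):
            fname = f"{sid}_trial{t + 1:02d}.csv"
            header = ",".join(labels)
            np.savetxt(out_dir / fname, trial, delimiter=",",
                       header=header, comments="", fmt="%.8g")
            files.append(fname)
        manifest["subjects"].append({"id": sid, "group": entry["group"],
                                     "trials": files})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "templates_A": truth.templates_A.tolist(),
                "templates_B": truth.templates_B.tolist(),
                "fractionation_map": [
                    {"parent": p, "fragments": list(fr), "coefficients": list(c)}
                    for p, fr, c in truth.fractionation_map
                ],
                "profiles_A": [vars(b) for b in truth.profiles_A],
                "profiles_B": [vars(b) for b in truth.profiles_B],
                "noise_sd": truth.noise_sd,
                "subjects_per_group": list(truth.subjects_per_group),
                "trials_per_subject": truth.trials_per_subject,
                "seed": truth.seed,
                "muscle_labels": labels,
            },
            fh, indent=1,
        )
    return out_dir
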