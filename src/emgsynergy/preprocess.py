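"""EMG reading and envelope preprocessing.

Turns raw per-trial surface-EMG recordings into the nonnegative,
time-normalized, concatenated muscle-by-time matrices that the synergy
decomposition consumes. The chain per trial is:

1. demean each channel,
2. high-pass filter (40 Hz, 4th-order Butterworth, zero-phase) to remove
   motion artifact,
3. full-wave rectify,
4. low-pass filter (15 Hz, 4th-order Butterworth, zero-phase) to obtain
   the envelope, clipped at zero,
5. linearly time-interpolate the movement window to 200 points.

Per subject, the first five valid trials are concatenated along time; each
muscle row is normalized to its maximum over the concatenated matrix and then
scaled to unit variance so every muscle contributes equally to the
factorization.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .exceptions import (
    BoundsError,
    ConstantChannelError,
    FormatError,
    InsufficientTrialsError,
    LabelError,
    ParseError,
    SignalTooShortError,
)

#: Canonical 16-muscle upper-limb montage (shoulder girdle to forearm).
DEFAULT_MUSCLES = [
    "IF", "SSP", "LT", "MT", "UT", "DA", "DM", "DP",
    "SA", "PC", "BCl", "TLo", "BR", "FCU", "ECR", "LD",
]

DEFAULT_SAMPLE_RATE = 2000.0  # Hz
DEFAULT_N_POINTS = 200
DEFAULT_N_TRIALS = 5


@dataclass
class RawTrial:
    """One trial of multi-channel EMG, time samples x muscles."""

    samples: np.ndarray
    sample_rate: float
    muscle_labels: list[str]
    #: (start_index, release_index) inclusive, in samples.
    window: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("trial samples must be a 2-D array (time x muscles)")
        n_t, n_m = self.samples.shape
        if len(self.muscle_labels) != n_m:
            raise LabelError(
                f"{len(self.muscle_labels)} labels for {n_m} channels"
            )
        if len(set(self.muscle_labels)) != n_m:
            raise LabelError("muscle labels must be unique")
        if self.window is None:
            self.window = (0, n_t - 1)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[1]


@dataclass
class EMGMatrix:
    """Preprocessed nonnegative muscle-by-time matrix ready for NMF.

    ``values`` is muscles x time with time = n_points * n_trials.
    ``scale_max`` and ``scale_sd`` retain the per-muscle normalization
    factors so envelopes can be mapped back to original units.
    """

    values: np.ndarray
    muscle_labels: list[str]
    n_trials: int
    scale_max: np.ndarray
    scale_sd: np.ndarray

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_trial(
    path: str | Path,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    label_row: bool | None = None,
) -> RawTrial:
    """Read one delimited-text trial (rows = samples, columns = muscles).

    The delimiter (comma or tab) is auto-detected from the first line.
    ``label_row=None`` auto-detects a header by checking whether the first
    row parses as numbers; pass True/False to force.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        delim = _detect_delimiter(_peek_line(fh))
        text_rows = [row for row in csv.reader(fh, delimiter=delim) if row]
    if not text_rows:
        raise FormatError(f"{path}: empty file")

    header: list[str] | None = None
    if label_row is None:
        label_row = not all(_looks_numeric(tok) for tok in text_rows[0])
    if label_row:
        header = [tok.strip() for tok in text_rows[0]]
        text_rows = text_rows[1:]
        if not text_rows:
            raise FormatError(f"{path}: header but no data rows")

    width = len(text_rows[0])
    data = np.empty((len(text_rows), width), dtype=float)
    for i, row in enumerate(text_rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {i + 1} has {len(row)} values, expected {width}"
            )
        for j, tok in enumerate(row):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {i + 1}, "
                    f"column {j + 1}"
                ) from None

    if header is None:
        labels = (DEFAULT_MUSCLES[:width] if width <= len(DEFAULT_MUSCLES)
                  else [f"ch{j + 1}" for j in range(width)])
    else:
        labels = header
    return RawTrial(samples=data, sample_rate=sample_rate, muscle_labels=labels)


def _peek_line(fh) -> str:
    pos = fh.tell()
    line = fh.readline()
    fh.seek(pos)
    return line


def _butter_filtfilt(x: np.ndarray, cutoff: float, fs: float, order: int,
                     btype: str) -> np.ndarray:
    b, a = signal.butter(order, cutoff, btype=btype, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise SignalTooShortError(
            f"trial has {x.shape[0]} samples; zero-phase filtering needs "
            f"more than {padlen}"
        )
    return signal.filtfilt(b, a, x, axis=0, padlen=padlen)


def envelope(
    trial: RawTrial,
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 15.0,
    order: int = 4,
) -> RawTrial:
    """Demean, high-pass, rectify, low-pass: the linear-envelope chain.

    Filtering is zero-phase (forward-backward), so the effective attenuation
    is that of a squared Butterworth magnitude response; output is clipped
    at zero to keep the envelope nonnegative for NMF.
    """
    if trial.sample_rate <= 2 * hp_cutoff:
        raise ValueError(
            f"sample rate {trial.sample_rate} Hz too low for a "
            f"{hp_cutoff} Hz high-pass filter"
        )
    x = trial.samples - trial.samples.mean(axis=0, keepdims=True)
    x = _butter_filtfilt(x, hp_cutoff, trial.sample_rate, order, "high")
    x = np.abs(x)
    x = _butter_filtfilt(x, lp_cutoff, trial.sample_rate, order, "low")
    np.clip(x, 0.0, None, out=x)
    return RawTrial(samples=x, sample_rate=trial.sample_rate,
                    muscle_labels=list(trial.muscle_labels),
                    window=trial.window)


def time_normalize(trial: RawTrial, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Linearly resample the movement window onto ``n_points`` equally
    spaced points, inclusive of both window ends.

    Returns an ``n_points x muscles`` array.
    """
    start, release = trial.window
    n_t = trial.n_samples
    if not (0 <= start < n_t and 0 <= release < n_t):
        raise BoundsError(
            f"window ({start}, {release}) outside 0..{n_t - 1}"
        )
    if release - start < 1:
        raise BoundsError("window must contain at least 2 samples")
    xi = np.linspace(start, release, n_points)
    xp = np.arange(n_t, dtype=float)
    out = np.empty((n_points, trial.n_muscles))
    for j in range(trial.n_muscles):
        out[:, j] = np.interp(xi, xp, trial.samples[:, j])
    return out


def assemble_subject(
    trials: list[np.ndarray],
    muscle_labels: list[str] | None = None,
    n_keep: int = DEFAULT_N_TRIALS,
) -> EMGMatrix:
    """Concatenate the first ``n_keep`` time-normalized trials and scale.

    Each muscle row of the concatenated matrix is divided by its maximum
    (stored in ``scale_max``) and then by its standard deviation (stored in
    ``scale_sd``) so every muscle has unit variance. Both scalings are
    positive, so the matrix stays nonnegative.
    """
    if len(trials) < n_keep:
        raise InsufficientTrialsError(
            f"{len(trials)} trials available, {n_keep} required"
        )
    kept = [np.asarray(t, dtype=float) for t in trials[:n_keep]]
    n_points, n_m = kept[0].shape
    for t in kept:
        if t.shape != (n_points, n_m):
            raise FormatError("all trials must share the same shape")
    if muscle_labels is None:
        muscle_labels = (DEFAULT_MUSCLES[:n_m] if n_m <= len(DEFAULT_MUSCLES)
                         else [f"ch{j + 1}" for j in range(n_m)])
    if len(muscle_labels) != n_m:
        raise LabelError("label count does not match channel count")

    values = np.concatenate(kept, axis=0).T  # muscles x time
    scale_max = values.max(axis=1)
    flat = np.flatnonzero(scale_max <= 0)
    if flat.size:
        raise ConstantChannelError(
            f"muscle(s) {[muscle_labels[i] for i in flat]} have no activity"
        )
    values = values / scale_max[:, None]
    scale_sd = values.std(axis=1)
    const = np.flatnonzero(scale_sd < 1e-15)
    if const.size:
        raise ConstantChannelError(
            f"muscle(s) {[muscle_labels[i] for i in const]} are constant"
        )
    values = values / scale_sd[:, None]
    return EMGMatrix(values=values, muscle_labels=list(muscle_labels),
                     n_trials=n_keep, scale_max=scale_max, scale_sd=scale_sd)


def preprocess_trials(
    raw_trials: list[RawTrial],
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 15.0,
    order: int = 4,
    n_points: int = DEFAULT_N_POINTS,
    n_keep: int = DEFAULT_N_TRIALS,
    already_enveloped: bool = False,
) -> EMGMatrix:
    """Full per-subject chain: envelope -> time-normalize -> assemble.

    ``already_enveloped=True`` skips filtering for data that is already an
    envelope (e.g. simulated at the envelope stage).
    """
    processed = []
    labels = raw_trials[0].muscle_labels
    for tr in raw_trials:
        if tr.muscle_labels != labels:
            raise LabelError("trials disagree on muscle labels")
        env = tr if already_enveloped else envelope(tr, hp_cutoff, lp_cutoff, order)
        processed.append(time_normalize(env, n_points))
    return assemble_subject(processed, muscle_labels=labels, n_keep=n_keep)


# --- manifest-driven I/O ----------------------------------------------------

def load_manifest(path: str | Path) -> dict:
    """Load a dataset manifest: subject ids -> trial files, group, rate."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    if "subjects" not in manifest:
        raise FormatError(f"{path}: manifest missing 'subjects'")
    return manifest


def run_manifest(
    manifest_path: str | Path,
    out_dir: str | Path,
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 15.0,
    order: int = 4,
    n_points: int = DEFAULT_N_POINTS,
    n_keep: int = DEFAULT_N_TRIALS,
) -> dict[str, EMGMatrix]:
    """Preprocess every subject listed in a manifest and write TSV + JSON."""
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    already = bool(manifest.get("envelope_stage", False))
    result: dict[str, EMGMatrix] = {}
    for subj in manifest["subjects"]:
        sid = subj["id"]
        rate = float(subj.get("sample_rate", manifest.get("sample_rate",
                                                          DEFAULT_SAMPLE_RATE)))
        raw = [read_trial(base / f, sample_rate=rate) for f in subj["trials"]]
        for tr, win in zip(raw, subj.get("windows", [])):
            tr.window = tuple(win)
        em = preprocess_trials(raw, hp_cutoff, lp_cutoff, order,
                               n_points, n_keep, already_enveloped=already)
        write_emg_matrix(em, out_dir / sid)
        result[sid] = em
    return result


def write_emg_matrix(em: EMGMatrix, prefix: str | Path) -> None:
    """Write an EMGMatrix as <prefix>.tsv plus <prefix>.json sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}.tsv", em.values, delimiter="\t")
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {
                "muscle_labels": em.muscle_labels,
                "n_trials": em.n_trials,
                "scale_max": em.scale_max.tolist(),
                "scale_sd": em.scale_sd.tolist(),
            },
            fh, indent=1,
        )


def read_emg_matrix(prefix: str | Path) -> EMGMatrix:
    prefix = Path(prefix)
    values = np.loadtxt(f"{prefix}.tsv", delimiter="\t", ndmin=2)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    return EMGMatrix(values=values, muscle_labels=meta["muscle_labels"],
                     n_trials=meta["n_trials"],
                     scale_max=np.asarray(meta["scale_max"]),
                     scale_sd=np.asarray(meta["scale_sd"]))
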