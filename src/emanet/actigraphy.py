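"""Wrist-actigraphy processing: ENMO, nonwear scoring, pre-beep summaries.

Raw triaxial acceleration (milligravity, regularly sampled) is reduced to a
per-beep physical-activity value in three steps:

1. ``compute_enmo`` — Euclidean norm minus one gravity (ENMO), the standard
   gravity-corrected magnitude metric, averaged into short epochs.
2. ``score_nonwear`` — a sliding-window score counting how many axes are
   simultaneously still (low standard deviation *and* low range), the usual
   signature of a device lying on a table rather than being worn.
3. ``summarize_prebeep`` — mean ENMO over the hour preceding each prompt
   ("beep"), with windows dominated by nonwear returned as missing.

All timestamps in this module are seconds relative to the start of the
recording; callers working in wall-clock time convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawAccelSignal",
    "EnmoSeries",
    "NonwearScores",
    "BeepActivity",
    "compute_enmo",
    "score_nonwear",
    "summarize_prebeep",
]

#: 1 g expressed in milligravity; ENMO subtracts this from the vector norm.
ONE_G_MG = 1000.0


@dataclass
class RawAccelSignal:
    """Regularly sampled triaxial acceleration in milligravity.

    ``timestamps`` are seconds from recording start, uniform at
    ``1 / sampling_rate``.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("axes and timestamps must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count over rate)."""
        return self.n_samples / self.sampling_rate

    def axes(self) -> np.ndarray:
        """Return an (n, 3) array of the three axes."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class EnmoSeries:
    """Epoch-averaged ENMO in milligravity."""

    epoch_start: np.ndarray
    enmo: np.ndarray
    epoch_length: float

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.enmo = np.asarray(self.enmo, dtype=float)
        if len(self.epoch_start) != len(self.enmo):
            raise ValueError("epoch_start and enmo must align")


@dataclass
class NonwearScores:
    """Per-window nonwear score: number of still axes, 0-3."""

    window_start: np.ndarray
    score: np.ndarray
    window_length: float  # seconds

    def __post_init__(self) -> None:
        self.window_start = np.asarray(self.window_start, dtype=float)
        self.score = np.asarray(self.score, dtype=int)
        if len(self.window_start) != len(self.score):
            raise ValueError("window_start and score must align")
        if self.score.size and (self.score.min() < 0 or self.score.max() > 3):
            raise ValueError("scores must lie in {0, 1, 2, 3}")


@dataclass
class BeepActivity:
    """Mean ENMO (mg) over the hour before one beep; NaN when excluded."""

    subject_id: str
    timestamp: object  # seconds or a wall-clock label carried through
    mean_enmo: float

    @property
    def missing(self) -> bool:
        return not math.isfinite(self.mean_enmo)


def compute_enmo(
    signal: RawAccelSignal,
    epoch_length: float = 5.0,
    truncate: bool = True,
) -> EnmoSeries:
    """Per-sample ENMO averaged into non-overlapping epochs.

    ENMO of a sample is ``sqrt(x^2 + y^2 + z^2) - 1000`` mg; negative values
    (possible when the device reads less than 1 g, e.g. free fall or
    calibration error) are truncated to zero by convention unless
    ``truncate`` is disabled.
    """
    if signal.n_samples == 0:
        raise ValueError("empty signal")
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    a = signal.axes()
    if not np.all(np.isfinite(a)):
        raise ValueError("signal contains non-finite samples")
    enmo = np.linalg.norm(a, axis=1) - ONE_G_MG
    if truncate:
        enmo = np.maximum(enmo, 0.0)

    t0 = signal.timestamps[0]
    idx = np.floor((signal.timestamps - t0) / epoch_length).astype(np.int64)
    n_epochs = int(idx[-1]) + 1
    sums = np.bincount(idx, weights=enmo, minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    # Epochs with no samples cannot occur for a uniform grid, but guard anyway.
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = t0 + epoch_length * np.arange(n_epochs)
    return EnmoSeries(starts, means, epoch_length)


def score_nonwear(
    signal: RawAccelSignal,
    window_minutes: float = 60.0,
    std_threshold_mg: float = 13.0,
    range_threshold_mg: float = 50.0,
    step_minutes: float = 15.0,
) -> NonwearScores:
    """Sliding-window nonwear score.

    An axis is flagged in a window when its sample standard deviation is
    below ``std_threshold_mg`` *and* its value range (max - min) is below
    ``range_threshold_mg``; the window score is the number of flagged axes.
    Windows advance in ``step_minutes`` steps and only full windows are
    scored.
    """
    win = window_minutes * 60.0
    step = step_minutes * 60.0
    if win >= signal.duration:
        raise ValueError("window must be shorter than the signal")
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(win * signal.sampling_rate)
    if n_win < 2:
        raise ValueError("window holds fewer than 2 samples")

    a = signal.axes()
    t0 = signal.timestamps[0]
    starts = []
    scores = []
    pos = 0.0
    while pos + win <= signal.duration + 1e-9:
        i0 = int(round(pos * signal.sampling_rate))
        seg = a[i0 : i0 + n_win]
        sd = seg.std(axis=0, ddof=1)
        rng = seg.max(axis=0) - seg.min(axis=0)
        flagged = (sd < std_threshold_mg) & (rng < range_threshold_mg)
        starts.append(t0 + pos)
        scores.append(int(flagged.sum()))
        pos += step
    return NonwearScores(np.array(starts), np.array(scores), win)


def _excluded_intervals(nonwear: NonwearScores, score_cutoff: int) -> list[tuple[float, float]]:
    """Merged half-open intervals covered by windows scoring above cutoff."""
    bad = nonwear.score > score_cutoff
    intervals: list[tuple[float, float]] = []
    for s in nonwear.window_start[bad]:
        e = s + nonwear.window_length
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))
    return intervals


def summarize_prebeep(
    enmo: EnmoSeries,
    nonwear: NonwearScores | None,
    beeps,
    score_cutoff: int = 1,
    window_seconds: float = 3600.0,
    min_coverage: float = 0.5,
    subject_id: str = "",
    beep_labels=None,
) -> list[BeepActivity]:
    """Mean ENMO over ``[beep - window, beep)`` per beep.

    Epochs overlapping any nonwear window scoring above ``score_cutoff`` are
    excluded. If the remaining wear epochs cover less than ``min_coverage``
    of the window — or the window holds no data at all — the value is
    missing (NaN). Missing is a value here, never an error.

    ``beeps`` are seconds on the recording clock; ``beep_labels`` optionally
    carries the original wall-clock timestamps into the output.
    """
    beeps = np.asarray(beeps, dtype=float)
    if beep_labels is None:
        beep_labels = list(beeps)
    if np.any(np.diff(beeps) < 0):
        raise ValueError("beeps must be sorted")

    bad = _excluded_intervals(nonwear, score_cutoff) if nonwear is not None else []
    starts = enmo.epoch_start
    ep = enmo.epoch_length

    wear = np.ones(len(starts), dtype=bool)
    for s, e in bad:
        # exclude epochs overlapping [s, e)
        wear &= ~((starts < e) & (starts + ep > s))

    out: list[BeepActivity] = []
    n_needed = window_seconds / ep
    for t, label in zip(beeps, beep_labels):
        in_win = (starts >= t - window_seconds) & (starts < t)
        if not in_win.any():
            out.append(BeepActivity(subject_id, label, float("nan")))
            continue
        ok = in_win & wear & np.isfinite(enmo.enmo)
        if ok.sum() / n_needed < min_coverage:
            out.append(BeepActivity(subject_id, label, float("nan")))
        else:
            out.append(BeepActivity(subject_id, label, float(enmo.enmo[ok].mean())))
    return out
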