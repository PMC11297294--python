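"""Oculomotor event detection: fixations (I-DT) and blinks.

A fixation is the period when the eyes cease scanning and hold the foveal
field in one place; it is detected here with the dispersion-threshold (I-DT)
criterion: a maximal run of consecutive confident samples is a fixation iff
its time span is at least ``min_duration_ms`` and its dispersion — defined as
(max x - min x) + (max y - min y) — does not exceed ``dispersion_threshold``.
Windows are grown greedily left to right and never overlap; a sample that
could either extend the current fixation or begin the next extends the
current one.

Blinks are read off the pupil-detection confidence signal: during a blink the
eye cameras lose the pupil and confidence collapses, so a blink is a maximal
run of samples below ``confidence_threshold``, with nearby runs merged and
physiologically implausible durations removed (over-long runs are tracking
signal loss, not blinks, and are reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FIXATION_COLUMNS = [
    "onset_ms", "offset_ms", "duration_ms",
    "centroid_x", "centroid_y", "dispersion", "n_samples",
]
BLINK_COLUMNS = ["onset_ms", "offset_ms", "duration_ms", "last_good_x", "last_good_y"]

#: defaults permitting the ~135 ms mean fixation durations typical of
#: natural-task mobile eye-tracking; all are config-exposed, never hard-coded
DEFAULT_DISPERSION_THRESHOLD = 0.03
DEFAULT_MIN_FIXATION_MS = 80.0
DEFAULT_MIN_CONFIDENCE = 0.6

DEFAULT_BLINK_CONFIDENCE = 0.5
DEFAULT_BLINK_MIN_MS = 50.0
DEFAULT_BLINK_MAX_MS = 500.0
DEFAULT_BLINK_MERGE_GAP_MS = 20.0


def _check_sorted(t: np.ndarray) -> None:
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("gaze samples must be sorted by time")


def _empty_fixations() -> pd.DataFrame:
    return pd.DataFrame(columns=FIXATION_COLUMNS).astype(
        {c: float for c in FIXATION_COLUMNS[:-1]} | {"n_samples": int}
    )


def detect_fixations(
    samples: pd.DataFrame,
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD,
    min_duration_ms: float = DEFAULT_MIN_FIXATION_MS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> pd.DataFrame:
    """Dispersion-threshold (I-DT) fixation detection.

    Parameters
    ----------
    samples
        Time-sorted gaze stream with columns ``t_ms, x, y, confidence``.
    dispersion_threshold
        Maximum (x-range + y-range) of a fixation window, normalized units.
    min_duration_ms
        Minimum span (last minus first timestamp) of a fixation window.
    min_confidence
        Samples below this confidence terminate a window; fixations are
        detected within maximal runs of confident samples only.

    Returns
    -------
    DataFrame with one row per fixation: onset/offset/duration, centroid
    (arithmetic mean of member samples), dispersion and member count.
    """
    if dispersion_threshold <= 0 or min_duration_ms <= 0:
        raise ValueError("thresholds must be positive")
    if len(samples) == 0:
        return _empty_fixations()
    t = samples["t_ms"].to_numpy(float)
    _check_sorted(t)
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    good = samples["confidence"].to_numpy(float) >= min_confidence

    rows: list[tuple] = []
    # maximal runs of confident samples
    n = len(t)
    run_start = None
    boundaries = []
    for i in range(n + 1):
        if i < n and good[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            boundaries.append((run_start, i))  # [start, stop)
            run_start = None
    for start, stop in boundaries:
        rows.extend(
            _idt_run(t[start:stop], x[start:stop], y[start:stop],
                     dispersion_threshold, min_duration_ms)
        )
    if not rows:
        return _empty_fixations()
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def _idt_run(t, x, y, thr, min_dur):
    """Greedy left-to-right I-DT over one confident run."""
    out = []
    n = len(t)
    i = 0
    j = 0  # candidate window end, monotone over the scan
    while i < n:
        if j < i:
            j = i
        # minimal window end covering min_dur
        while j < n and t[j] - t[i] < min_dur:
            j += 1
        if j >= n:
            break
        if _dispersion(x, y, i, j) <= thr:
            # expand while dispersion stays within the threshold
            while j + 1 < n and _dispersion(x, y, i, j + 1) <= thr:
                j += 1
            out.append(_make_fixation(t, x, y, i, j))
            i = j + 1
            j = i
        else:
            i += 1
    return out


def _dispersion(x, y, i, j):
    xs = x[i:j + 1]
    ys = y[i:j + 1]
    return (xs.max() - xs.min()) + (ys.max() - ys.min())


def _make_fixation(t, x, y, i, j):
    xs = x[i:j + 1]
    ys = y[i:j + 1]
    return (
        t[i], t[j], t[j] - t[i],
        float(xs.mean()), float(ys.mean()),
        float((xs.max() - xs.min()) + (ys.max() - ys.min())),
        j - i + 1,
    )


# --------------------------------------------------------------------------- #
# Blinks


@dataclass
class BlinkQCReport:
    """Run-length accounting for the blink detector."""

    n_raw_runs: int = 0
    n_merged_runs: int = 0
    n_blinks: int = 0
    n_too_short: int = 0
    n_signal_loss: int = 0           # runs longer than max_duration_ms
    signal_loss_ms: float = 0.0


def detect_blinks(
    samples: pd.DataFrame,
    confidence_threshold: float = DEFAULT_BLINK_CONFIDENCE,
    min_duration_ms: float = DEFAULT_BLINK_MIN_MS,
    max_duration_ms: float = DEFAULT_BLINK_MAX_MS,
    merge_gap_ms: float = DEFAULT_BLINK_MERGE_GAP_MS,
) -> tuple[pd.DataFrame, BlinkQCReport]:
    """Detect blinks as low-confidence runs in a time-sorted gaze stream.

    A run spans from its first low-confidence sample to the next confident
    sample (or one nominal sample period past the last sample at end of
    stream).  Runs separated by gaps shorter than ``merge_gap_ms`` merge into
    one event.  Events shorter than ``min_duration_ms`` are discarded; events
    longer than ``max_duration_ms`` are counted as signal loss, not blinks.
    ``last_good_x/y`` hold the gaze at the last confident sample before onset
    (NaN if the stream starts inside a run) for downstream ROI attribution.
    """
    qc = BlinkQCReport()
    empty = pd.DataFrame(columns=BLINK_COLUMNS).astype(float)
    if len(samples) == 0:
        return empty, qc
    t = samples["t_ms"].to_numpy(float)
    _check_sorted(t)
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    low = samples["confidence"].to_numpy(float) < confidence_threshold
    n = len(t)
    period = float(np.median(np.diff(t))) if n > 1 else 0.0

    # maximal low-confidence runs: (onset, end, index before onset)
    runs = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            end = t[j + 1] if j + 1 < n else t[j] + period
            runs.append([t[i], end, i - 1])
            i = j + 1
        else:
            i += 1
    qc.n_raw_runs = len(runs)

    merged: list[list] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    qc.n_merged_runs = len(merged)

    rows = []
    for onset, end, prev_idx in merged:
        dur = end - onset
        if dur < min_duration_ms:
            qc.n_too_short += 1
            continue
        if dur > max_duration_ms:
            qc.n_signal_loss += 1
            qc.signal_loss_ms += dur
            continue
        if prev_idx >= 0:
            gx, gy = x[prev_idx], y[prev_idx]
        else:
            gx, gy = np.nan, np.nan
        rows.append((onset, end, dur, gx, gy))
    qc.n_blinks = len(rows)
    if not rows:
        return empty, qc
    return pd.DataFrame(rows, columns=BLINK_COLUMNS), qc


def event_rate(n_events: int, exposure_ms: float) -> float:
    """Events per minute over an exposure of ``exposure_ms`` milliseconds."""
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    return n_events / exposure_ms * 60_000.0
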