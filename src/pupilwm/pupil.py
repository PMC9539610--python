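"""Pupil-trace preprocessing: blink reconstruction, baseline correction,
baseline-outlier exclusion and window binning.

Traces are sampled at a uniform rate over roughly [-1500, 2800) ms relative
to memory-display onset.  Blinks appear as runs of zero (or NaN) samples —
the eye-tracker convention of reporting pupil size 0 while the eye is
closed — and are repaired by widening each run by a safety margin and
bridging it with a cubic polynomial through flanking valid samples.
Baseline correction subtracts the mean pupil size in an early window
(default the first 100 ms of the memory display) from the whole trace;
trials whose baseline deviates more than 2 SD from the participant's mean
baseline are excluded from the pupil analysis (behavioral data untouched).
For the statistical analysis, traces are binned into half-open windows
aligned to onset (default 10 ms) over the retention interval [0, 2500).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "TrialPupil",
    "reconstruct_blinks",
    "baseline_correct",
    "exclude_baseline_outliers",
    "downsample",
    "preprocess_traces",
    "windowed_frame",
]


@dataclass
class TrialPupil:
    """One trial's pupil time series plus preprocessing state."""

    participant: object
    trial: int
    times: np.ndarray            # ms relative to memory-display onset
    samples: np.ndarray          # pupil size, arbitrary units
    baseline: float | None = None
    excluded: bool = False
    window_starts: np.ndarray | None = field(default=None, repr=False)
    windowed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.times.shape != self.samples.shape:
            raise ValueError("times and samples must have the same shape")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def sample_period_ms(self) -> float:
        return float(self.times[1] - self.times[0])


def _invalid_mask(samples: np.ndarray) -> np.ndarray:
    return (samples == 0.0) | ~np.isfinite(samples)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def reconstruct_blinks(trace: TrialPupil, min_blink_ms: float = 20.0,
                       margin_ms: float = 50.0) -> TrialPupil:
    """Repair blink artifacts in place of zero/missing sample runs.

    Runs of invalid samples lasting at least ``min_blink_ms`` are widened
    by ``margin_ms`` on both sides (the pupil signal is distorted just
    before and after lid closure) and replaced by a cubic interpolation
    through four flanking valid samples; shorter dropouts are bridged
    linearly without a margin.  Runs touching a trace edge are filled with
    the nearest valid value.  A trace with no valid samples is returned
    marked ``excluded``.
    """
    samples = trace.samples.copy()
    invalid = _invalid_mask(samples)
    if invalid.all():
        return TrialPupil(trace.participant, trace.trial, trace.times,
                          samples, trace.baseline, excluded=True)
    if not invalid.any():
        return trace
    period = trace.sample_period_ms
    min_n = max(1, int(round(min_blink_ms / period)))
    margin_n = max(1, int(round(margin_ms / period)))
    n = samples.size

    widened = np.zeros(n, dtype=bool)
    for start, stop in _runs(invalid):
        if stop - start >= min_n:
            widened[max(0, start - margin_n):min(n, stop + margin_n)] = True
        else:
            widened[start:stop] = True
    # also treat any sample that was invalid to begin with as missing
    widened |= invalid

    valid_idx = np.flatnonzero(~widened)
    if valid_idx.size < 2:
        filled = np.full(n, samples[valid_idx[0]] if valid_idx.size else np.nan)
        return TrialPupil(trace.participant, trace.trial, trace.times, filled,
                          trace.baseline, excluded=valid_idx.size == 0)
    for start, stop in _runs(widened):
        if start == 0:
            samples[:stop] = samples[valid_idx[valid_idx >= stop][0]]
            continue
        if stop == n:
            samples[start:] = samples[valid_idx[valid_idx < start][-1]]
            continue
        left = valid_idx[valid_idx < start]
        right = valid_idx[valid_idx >= stop]
        # four anchors: two on each side, spaced by the margin where possible
        anchors = []
        if left.size >= 2:
            far = left[left <= left[-1] - margin_n]
            anchors.append(far[-1] if far.size else left[0])
        anchors.append(left[-1])
        anchors.append(right[0])
        if right.size >= 2:
            far = right[right >= right[0] + margin_n]
            anchors.append(far[0] if far.size else right[-1])
        anchors = sorted(set(int(a) for a in anchors))
        gap = np.arange(start, stop)
        if len(anchors) >= 3:
            spline = CubicSpline(trace.times[anchors], samples[anchors])
            samples[gap] = spline(trace.times[gap])
        else:
            samples[gap] = np.interp(trace.times[gap],
                                     trace.times[anchors], samples[anchors])
    return TrialPupil(trace.participant, trace.trial, trace.times, samples,
                      trace.baseline, excluded=trace.excluded)


def baseline_correct(trace: TrialPupil,
                     window: tuple = (0.0, 100.0)) -> TrialPupil:
    """Subtract the mean pupil size in ``[t0, t1)`` from the whole trace.

    The subtracted value is stored as the trial's baseline.  The default
    window is the first 100 ms of the memory display; the first 100 ms of
    the pre-cue (e.g. ``(-1500, -1400)``) is a common control choice.
    """
    t0, t1 = window
    mask = (trace.times >= t0) & (trace.times < t1)
    if not mask.any():
        raise ValueError(f"baseline window [{t0}, {t1}) contains no samples")
    baseline = float(np.mean(trace.samples[mask]))
    return TrialPupil(trace.participant, trace.trial, trace.times,
                      trace.samples - baseline, baseline=baseline,
                      excluded=trace.excluded)


def exclude_baseline_outliers(traces, z_threshold: float = 2.0):
    """Flag trials whose baseline deviates > ``z_threshold`` SD (two-sided).

    Z-scores are computed per participant over that participant's trial
    baselines (SD with n-1 denominator).  Flagging never alters sample
    values and never touches behavioral data; a participant with zero
    baseline SD gets no exclusions.  Returns a new list of traces with
    ``excluded`` set, preserving order.
    """
    by_pp: dict = {}
    for tr in traces:
        if tr.baseline is None:
            raise ValueError("baseline_correct must run before exclusion")
        by_pp.setdefault(tr.participant, []).append(tr)
    out = []
    for tr in traces:
        group = by_pp[tr.participant]
        if len(group) < 2:
            raise ValueError(
                f"participant {tr.participant} has fewer than 2 trials")
        baselines = np.array([t.baseline for t in group])
        sd = baselines.std(ddof=1)
        flag = tr.excluded
        if sd > 0:
            z = (tr.baseline - baselines.mean()) / sd
            flag = flag or abs(z) > z_threshold
        out.append(TrialPupil(tr.participant, tr.trial, tr.times, tr.samples,
                              tr.baseline, excluded=flag,
                              window_starts=tr.window_starts,
                              windowed=tr.windowed))
    return out


def downsample(trace: TrialPupil, bin_ms: float = 10.0,
               span: tuple = (0.0, 2500.0)) -> TrialPupil:
    """Bin the trace into half-open ``[t, t + bin_ms)`` windows over ``span``.

    Bins are aligned to 0 at memory-display onset; each bin value is the
    mean of the samples falling in it.  ``bin_ms`` must be a multiple of
    the sample period.
    """
    period = trace.sample_period_ms
    ratio = bin_ms / period
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"bin_ms={bin_ms} is not a multiple of the {period} ms sample period")
    t0, t1 = span
    starts = np.arange(t0, t1, bin_ms)
    values = np.empty(starts.size)
    for i, s in enumerate(starts):
        mask = (trace.times >= s) & (trace.times < s + bin_ms)
        values[i] = np.mean(trace.samples[mask]) if mask.any() else np.nan
    return TrialPupil(trace.participant, trace.trial, trace.times,
                      trace.samples, trace.baseline, trace.excluded,
                      window_starts=starts, windowed=values)


def preprocess_traces(traces, min_blink_ms: float = 20.0,
                      margin_ms: float = 50.0,
                      baseline_window: tuple = (0.0, 100.0),
                      z_threshold: float = 2.0, bin_ms: float = 10.0,
                      span: tuple = (0.0, 2500.0)):
    """Run the full preprocessing chain over a collection of traces."""
    out = [baseline_correct(reconstruct_blinks(t, min_blink_ms, margin_ms),
                            baseline_window) for t in traces]
    out = exclude_baseline_outliers(out, z_threshold)
    return [downsample(t, bin_ms, span) for t in out]


def windowed_frame(traces, trials: pd.DataFrame | None = None,
                   drop_excluded: bool = True) -> pd.DataFrame:
    """Long-format table (participant, trial, window_start_ms, pupil).

    If a trial table is given, memory_load and color_type are merged in.
    Excluded trials are dropped by default — the pupil-side exclusion that
    leaves behavioral analyses untouched.
    """
    frames = []
    for tr in traces:
        if tr.windowed is None:
            raise ValueError("downsample must run before windowed_frame")
        if drop_excluded and tr.excluded:
            continue
        frames.append(pd.DataFrame({
            "participant": tr.participant, "trial": tr.trial,
            "window_start_ms": tr.window_starts, "pupil": tr.windowed}))
    if not frames:
        raise ValueError("no traces to assemble (all excluded?)")
    df = pd.concat(frames, ignore_index=True)
    if trials is not None:
        df = df.merge(
            trials[["participant", "trial", "memory_load", "color_type"]],
            on=["participant", "trial"], how="left", validate="many_to_one")
    return df
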