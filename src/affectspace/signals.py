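"""Per-trial autonomic feature extraction from raw signal recordings.

Three features are computed, one per modality:

* pupil — invalid samples (outside the 2-10 mm physiological range, or
  masked) are linearly interpolated when the gap lasts at most 150 ms;
  a subtractive baseline correction uses the window from one second before
  to one second after stimulus onset, and the feature is the mean corrected
  diameter over the 0-6 s stimulus window (mm);
* SCR — trough-to-peak amplitude: the largest rise from a local trough to a
  later local peak inside the 1-6 s post-onset window, zero when no rise
  reaches the minimum-amplitude criterion (uS);
* HR — change score, mean post-onset heart rate minus mean pre-onset heart
  rate, so that deceleration is negative (bpm).

Trials whose preconditions fail (no valid baseline, window outside the
recording) are flagged missing, never silently zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecording",
    "PreprocessParams",
    "AlignmentError",
    "EmptySignalError",
    "interpolate_invalid",
    "baseline_correct_pupil",
    "score_scr_trough_to_peak",
    "hr_difference_score",
    "extract_trial_features",
]


class EmptySignalError(ValueError):
    """Every sample of a recording is invalid."""


class AlignmentError(ValueError):
    """Event manifests disagree across modalities."""


@dataclass
class SignalRecording:
    """A time-stamped univariate series with event markers for one trial.

    ``events`` holds (trial_id, onset_time_s) pairs; ``meta`` carries
    participant/stimulus identifiers used to assemble the trial table.
    """

    modality: str
    sampling_rate: float
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    events: list[tuple[str, float]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        span = (self.times[0], self.times[-1])
        for tid, onset in self.events:
            if not span[0] <= onset <= span[1]:
                raise ValueError(f"event {tid!r} onset {onset} outside recording span {span}")


@dataclass
class PreprocessParams:
    """Windows and thresholds of the preprocessing pipeline (seconds, mm, uS)."""

    pupil_valid_range: tuple[float, float] = (2.0, 10.0)
    max_interp_gap_s: float = 0.150
    baseline_window_s: tuple[float, float] = (-1.0, 1.0)
    stimulus_window_s: tuple[float, float] = (0.0, 6.0)
    scr_window_s: tuple[float, float] = (1.0, 6.0)
    scr_min_amplitude_us: float = 0.01
    #: optional moving-average smoother width (samples); 0 disables it
    scr_smooth_samples: int = 0
    hr_pre_window_s: tuple[float, float] = (-4.0, 0.0)
    hr_post_window_s: tuple[float, float] = (0.0, 6.0)
    #: use a conventional pre-onset-only pupil baseline instead of the
    #: onset-straddling default
    baseline_pre_only: bool = False

    def __post_init__(self):
        for name in ("baseline_window_s", "stimulus_window_s", "scr_window_s",
                     "hr_pre_window_s", "hr_post_window_s"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must have positive length")

    def pupil_baseline(self) -> tuple[float, float]:
        if self.baseline_pre_only:
            return (self.baseline_window_s[0], 0.0)
        return self.baseline_window_s


def _invalid_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of consecutive True entries."""
    runs = []
    n = bad.size
    i = 0
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_invalid(
    series: SignalRecording,
    valid_range: tuple[float, float] | None = None,
    max_gap_s: float | None = None,
    params: PreprocessParams | None = None,
) -> tuple[SignalRecording, dict]:
    """Linearly interpolate short runs of invalid samples.

    A sample is invalid if masked or outside ``valid_range``.  Runs lasting
    at most ``max_gap_s`` are replaced by linear interpolation between the
    nearest valid neighbours; longer runs (and runs touching the recording
    edge) remain flagged invalid and are excluded from downstream means.
    Valid samples are never altered and the output length equals the input
    length.

    Returns the cleaned recording and a report dict with
    ``n_interpolated``/``n_still_invalid``.
    """
    p = params or PreprocessParams()
    lo, hi = valid_range if valid_range is not None else p.pupil_valid_range
    max_gap = max_gap_s if max_gap_s is not None else p.max_interp_gap_s

    values = series.values.copy()
    bad = ~series.valid | (values < lo) | (values > hi)
    if bad.all():
        raise EmptySignalError(f"all samples invalid in {series.modality} recording")
    new_valid = ~bad
    n_interp = 0
    dt = 1.0 / series.sampling_rate
    for start, stop in _invalid_runs(bad):
        duration = (stop - start) * dt
        if duration > max_gap or start == 0 or stop == values.size:
            continue  # stays invalid
        t0, t1 = series.times[start - 1], series.times[stop]
        v0, v1 = values[start - 1], values[stop]
        tt = series.times[start:stop]
        values[start:stop] = v0 + (v1 - v0) * (tt - t0) / (t1 - t0)
        new_valid[start:stop] = True
        n_interp += stop - start
    cleaned = replace(series, values=values, valid=new_valid)
    report = {"n_interpolated": int(n_interp), "n_still_invalid": int((~new_valid).sum())}
    return cleaned, report


#: slack for floating-point jitter on regular sample grids (seconds)
_GRID_EPS = 1e-6


def window_mask(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Half-open window [lo, hi) with tolerance for sample-grid jitter."""
    return (times >= lo - _GRID_EPS) & (times < hi - _GRID_EPS)


def _window_mean(rec: SignalRecording, onset: float, window: tuple[float, float]) -> float:
    # half-open [lo, hi) so adjacent windows (e.g. HR pre/post) never share a sample
    sel = window_mask(rec.times, onset + window[0], onset + window[1]) & rec.valid
    if not sel.any():
        return np.nan
    return float(rec.values[sel].mean())


def baseline_correct_pupil(
    series: SignalRecording,
    onset: float,
    params: PreprocessParams | None = None,
) -> tuple[SignalRecording, float]:
    """Subtractive baseline correction around stimulus onset.

    Subtracts the mean of the valid samples in the baseline window from every
    sample and returns the corrected recording together with the mean
    corrected diameter over the stimulus window.  The feature is NaN (trial
    flagged missing) when the baseline window contains no valid sample.
    Adding any constant to the raw series leaves the corrected series
    unchanged.
    """
    p = params or PreprocessParams()
    base = _window_mean(series, onset, p.pupil_baseline())
    if np.isnan(base):
        return series, np.nan
    corrected = replace(series, values=series.values - base)
    feature = _window_mean(corrected, onset, p.stimulus_window_s)
    return corrected, feature


def score_scr_trough_to_peak(
    series: SignalRecording,
    onset: float,
    params: PreprocessParams | None = None,
) -> float:
    """Trough-to-peak phasic SCR amplitude inside the scoring window.

    Equals the maximum drawup — the largest (later value minus running
    minimum) over valid in-window samples, which coincides with the best
    trough/peak pair.  Amplitudes below the minimum-amplitude criterion score
    zero; the result is never negative.  NaN if the window lies outside the
    recording.
    """
    p = params or PreprocessParams()
    lo, hi = onset + p.scr_window_s[0], onset + p.scr_window_s[1]
    if lo < series.times[0] or hi > series.times[-1] + 1e-9:
        return np.nan
    values = series.values
    if p.scr_smooth_samples > 1:
        k = int(p.scr_smooth_samples)
        kernel = np.ones(k) / k
        values = np.convolve(values, kernel, mode="same")
    sel = window_mask(series.times, lo, hi) & series.valid
    if not sel.any():
        return np.nan
    v = values[sel]
    running_min = np.minimum.accumulate(v)
    amplitude = float(np.max(v - running_min))
    return amplitude if amplitude >= p.scr_min_amplitude_us else 0.0


def hr_difference_score(pre, post):
    """Heart-rate change score: post minus pre, deceleration negative.

    Accepts scalars or arrays (vectorized elementwise difference).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    out = post - pre
    return float(out) if out.ndim == 0 else out


def _hr_feature(rec: SignalRecording, onset: float, p: PreprocessParams) -> float:
    pre = _window_mean(rec, onset, p.hr_pre_window_s)
    post = _window_mean(rec, onset, p.hr_post_window_s)
    if np.isnan(pre) or np.isnan(post):
        return np.nan
    return hr_difference_score(pre, post)


def extract_trial_features(
    recordings: list[SignalRecording],
    params: PreprocessParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-trial feature table from a set of recordings.

    One row per trial id with ``pupil``/``scr``/``hr`` features and
    participant/stimulus metadata; cells whose preconditions fail are NaN
    with a reason in the quality report.  Trial ids must agree across
    modalities, otherwise an alignment error lists the unmatched ids.
    """
    p = params or PreprocessParams()
    by_trial: dict[str, dict[str, tuple[SignalRecording, float]]] = {}
    for rec in recordings:
        for trial_id, onset in rec.events:
            by_trial.setdefault(trial_id, {})[rec.modality] = (rec, onset)

    modalities = ("pupil", "scr", "hr")
    incomplete = {
        tid: sorted(set(modalities) - set(mods))
        for tid, mods in by_trial.items()
        if set(mods) != set(modalities)
    }
    if incomplete:
        raise AlignmentError(f"trials missing modalities: {incomplete}")

    rows = []
    quality = {"pupil_interpolated": 0, "pupil_still_invalid": 0, "missing_cells": {}}
    for trial_id, mods in by_trial.items():
        rec_p, onset_p = mods["pupil"]
        try:
            cleaned, rep = interpolate_invalid(rec_p, params=p)
            quality["pupil_interpolated"] += rep["n_interpolated"]
            quality["pupil_still_invalid"] += rep["n_still_invalid"]
            _, pupil = baseline_correct_pupil(cleaned, onset_p, p)
        except EmptySignalError:
            pupil = np.nan
        rec_s, onset_s = mods["scr"]
        scr = score_scr_trough_to_peak(rec_s, onset_s, p)
        rec_h, onset_h = mods["hr"]
        hr = _hr_feature(rec_h, onset_h, p)
        missing = [m for m, v in (("pupil", pupil), ("scr", scr), ("hr", hr)) if np.isnan(v)]
        if missing:
            quality["missing_cells"][trial_id] = missing
        rows.append(
            {
                "trial_id": trial_id,
                "participant": rec_p.meta.get("participant"),
                "stimulus": rec_p.meta.get("stimulus"),
                "pupil": pupil,
                "scr": scr,
                "hr": hr,
            }
        )
    table = pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)
    return table, quality
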