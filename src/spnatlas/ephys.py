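"""Spike-waveform and action-potential feature extraction.

Cell-attached analysis: isolated negative-peak spikes are detected in a
10 s window, each +/-5 ms waveform is normalized to zero baseline (first
3.75 ms) and -1 peak, the per-cell average is taken and the half-peak
width is read off as the time between the linearly interpolated
intersections with the -0.5 line.

Whole-cell analysis: the AP threshold is the voltage at the last sample
before the membrane-potential derivative first reaches 12 V/s (0.6 mV per
50 us); peak, amplitude (= peak - threshold), half width (at
threshold + amplitude/2, linear interpolation, reported in us) and fAHP
(threshold minus the trough within 4 ms past the peak, positive when the
trough is below threshold) follow from it. Passive input resistance is
the ordinary-least-squares slope of steady-state voltage deflection
against injected current (mV/pA x 1000 = MOhm), and the F-I curve counts
APs per 1 s current step (0-1000 pA in 50 pA increments) using the same
derivative criterion with a 2 ms refractory separation.

All millisecond/microsecond constants are converted to samples at the
recording's own sampling rate; traces need not be at 20 kHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "APFeatureSet",
    "detect_spikes_cell_attached",
    "normalize_and_average",
    "half_peak_width",
    "ap_threshold",
    "ap_features",
    "spontaneous_rate",
    "input_resistance",
    "fi_curve",
    "compare_groups",
]

DVDT_THRESHOLD_V_PER_S = 12.0
BASELINE_MS = 3.75
WINDOW_MS = 5.0
FAHP_WINDOW_MS = 4.0
REFRACTORY_MS = 2.0


@dataclass
class APFeatureSet:
    """Whole-cell AP features; half_width in microseconds, voltages in mV."""

    threshold: float
    peak: float
    amplitude: float
    half_width: float
    fahp: float


# ---------------------------------------------------------------------------
# cell-attached
# ---------------------------------------------------------------------------

def detect_spikes_cell_attached(
    trace: np.ndarray,
    sampling_rate: float,
    analysis_start_s: float = 0.0,
    duration_s: float = 10.0,
    amplitude_criterion: float | None = None,
    window_ms: float = WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect isolated negative-peak spikes and extract +/-window_ms windows.

    The default amplitude criterion is ``median - 5 * MAD`` of the analysis
    segment (configurable). Candidate peaks with a second candidate within
    the +/-window are rejected as non-single; peaks whose window extends
    past the trace are dropped with a log entry.

    Returns ``(peak_times_s, windows)`` with windows of
    ``2 * window_samples + 1`` samples centered on each peak.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(analysis_start_s * sampling_rate))
    i1 = i0 + int(round(duration_s * sampling_rate))
    if i0 < 0 or i1 > len(trace):
        raise ValueError("analysis window extends past the trace")
    seg = trace[i0:i1]
    med = np.median(seg)
    if amplitude_criterion is None:
        # normal-consistent MAD: a robust noise-SD estimate insensitive to spikes
        sigma = stats.median_abs_deviation(seg, scale="normal")
        amplitude_criterion = med - 5.0 * sigma
    # prominence at the detection depth keeps one candidate per spike: noise
    # minima riding on a spike trough are local minima below the amplitude
    # criterion but have only noise-scale prominence
    depth = max(med - amplitude_criterion, 0.0)
    peaks, _ = signal.find_peaks(-seg, height=-amplitude_criterion, prominence=depth)
    w = int(round(window_ms / 1000.0 * sampling_rate))
    # isolation: no other candidate peak within +/- window
    isolated = [
        p for k, p in enumerate(peaks)
        if (k == 0 or p - peaks[k - 1] > w) and (k == len(peaks) - 1 or peaks[k + 1] - p > w)
    ]
    times, windows = [], []
    for p in isolated:
        a, b = i0 + p - w, i0 + p + w + 1
        if a < 0 or b > len(trace):
            logger.info("spike at %.4f s dropped: window exceeds trace",
                        (i0 + p) / sampling_rate)
            continue
        times.append((i0 + p) / sampling_rate)
        windows.append(trace[a:b])
    return np.asarray(times), (
        np.vstack(windows) if windows else np.empty((0, 2 * w + 1))
    )


def normalize_and_average(
    waveforms: np.ndarray, sampling_rate: float, baseline_ms: float = BASELINE_MS
) -> np.ndarray:
    """Normalize each waveform to 0 baseline / -1 peak and average.

    The baseline is the mean over the first ``baseline_ms`` of the window;
    after subtraction each waveform is divided by the magnitude of its
    (negative) peak so the minimum is exactly -1. Waveforms with zero peak
    after baseline subtraction are excluded with a log entry.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if waveforms.shape[0] == 0:
        raise ValueError("no waveforms to average")
    nb = int(round(baseline_ms / 1000.0 * sampling_rate))
    if nb < 1 or nb >= waveforms.shape[1]:
        raise ValueError("baseline window empty or longer than the waveform")
    out = []
    for w in waveforms:
        w = w - w[:nb].mean()
        peak = w.min()
        if peak >= 0:
            logger.info("waveform excluded: non-negative peak after baseline")
            continue
        out.append(w / abs(peak))
    if not out:
        raise ValueError("every waveform was excluded during normalization")
    return np.mean(out, axis=0)


def _cross_down(w: np.ndarray, level: float, start: int = 1) -> float:
    """First index (interpolated) where w crosses below ``level``."""
    for i in range(start, len(w)):
        if w[i - 1] > level >= w[i]:
            if w[i - 1] == w[i]:
                return float(i)
            return (i - 1) + (w[i - 1] - level) / (w[i - 1] - w[i])
    raise ValueError("no downward crossing found")


def _cross_up(w: np.ndarray, level: float, start: int) -> float:
    for i in range(start, len(w)):
        if w[i - 1] <= level < w[i]:
            if w[i - 1] == w[i]:
                return float(i)
            return (i - 1) + (level - w[i - 1]) / (w[i] - w[i - 1])
    raise ValueError("no upward crossing found")


def half_peak_width(avg_waveform: np.ndarray, sampling_rate: float) -> float:
    """Width (ms) of the averaged normalized spike at the -0.5 line.

    Locates the first downward and the subsequent upward crossing of -0.5
    by linear interpolation between adjacent samples.
    """
    w = np.asarray(avg_waveform, dtype=float)
    if w.min() > -0.5:
        raise ValueError("malformed waveform: never crosses the -0.5 line")
    t_down = _cross_down(w, -0.5)
    t_up = _cross_up(w, -0.5, start=int(np.ceil(t_down)) + 1)
    return (t_up - t_down) * 1000.0 / sampling_rate


# ---------------------------------------------------------------------------
# whole-cell
# ---------------------------------------------------------------------------

def _dvdt_crit_mv_per_sample(sampling_rate: float,
                             dvdt_v_per_s: float = DVDT_THRESHOLD_V_PER_S) -> float:
    return dvdt_v_per_s * 1000.0 / sampling_rate  # 0.6 mV/sample at 20 kHz


def ap_threshold(
    sweep: np.ndarray, sampling_rate: float,
    dvdt_v_per_s: float = DVDT_THRESHOLD_V_PER_S,
) -> tuple[float, int]:
    """AP threshold: voltage at the last sample before dV/dt reaches 12 V/s.

    Returns ``(threshold_mV, index)`` where ``index`` is the position of
    that sample. Raises "no AP found" when the derivative never reaches
    the criterion.
    """
    v = np.asarray(sweep, dtype=float)
    crit = _dvdt_crit_mv_per_sample(sampling_rate, dvdt_v_per_s)
    d = np.diff(v)
    hits = np.flatnonzero(d >= crit)
    if hits.size == 0:
        raise ValueError("no AP found: dV/dt never reaches the threshold")
    j = int(hits[0])
    return float(v[j]), j


def ap_features(
    sweep: np.ndarray, sampling_rate: float,
    threshold: float | None = None, threshold_index: int | None = None,
) -> APFeatureSet:
    """Peak, amplitude, half width (us) and fAHP of the first AP in a sweep.

    fAHP is reported as ``threshold - trough`` over the 4 ms after the
    peak (positive when the trough lies below threshold).
    """
    v = np.asarray(sweep, dtype=float)
    if threshold is None or threshold_index is None:
        threshold, threshold_index = ap_threshold(v, sampling_rate)
    after = v[threshold_index:]
    peak_rel = int(np.argmax(after))
    peak_idx = threshold_index + peak_rel
    if peak_idx >= len(v) - 1:
        raise ValueError("AP peak at sweep end; cannot measure repolarization")
    peak = float(v[peak_idx])
    amplitude = peak - threshold
    level = threshold + amplitude / 2.0
    t_up = _cross_up(v, level, start=threshold_index + 1)
    down_start = int(np.ceil(t_up)) + 1
    t_down = _cross_down(v, level, start=max(down_start, peak_idx))
    half_width_us = (t_down - t_up) * 1e6 / sampling_rate
    n4 = int(round(FAHP_WINDOW_MS / 1000.0 * sampling_rate))
    post = v[peak_idx + 1: peak_idx + 1 + n4]
    if post.size == 0:
        raise ValueError("no samples after the AP peak for the fAHP window")
    fahp = threshold - float(post.min())
    return APFeatureSet(
        threshold=float(threshold), peak=peak, amplitude=float(amplitude),
        half_width=float(half_width_us), fahp=float(fahp),
    )


def _count_aps(v: np.ndarray, sampling_rate: float,
               refractory_ms: float = REFRACTORY_MS) -> int:
    crit = _dvdt_crit_mv_per_sample(sampling_rate)
    hits = np.flatnonzero(np.diff(np.asarray(v, dtype=float)) >= crit)
    if hits.size == 0:
        return 0
    gap = int(round(refractory_ms / 1000.0 * sampling_rate))
    count, last = 1, hits[0]
    for h in hits[1:]:
        if h - last > gap:
            count += 1
        last = h
    return count


def spontaneous_rate(
    trace: np.ndarray, sampling_rate: float,
    window_start_s: float = 0.0, window_len_s: float = 10.0,
    method: str = "dvdt",
) -> float:
    """Firing rate (Hz) over a window: spike count / window length.

    ``method='dvdt'`` counts threshold-crossing APs (whole-cell traces);
    ``method='negative_peak'`` counts isolated negative-going spikes
    (cell-attached traces).
    """
    i0 = int(round(window_start_s * sampling_rate))
    i1 = i0 + int(round(window_len_s * sampling_rate))
    if i0 < 0 or i1 > len(trace):
        raise ValueError("rate window extends past the trace")
    seg = np.asarray(trace[i0:i1], dtype=float)
    if method == "dvdt":
        n = _count_aps(seg, sampling_rate)
    elif method == "negative_peak":
        times, _ = detect_spikes_cell_attached(
            seg, sampling_rate, 0.0, window_len_s
        )
        n = len(times)
    else:
        raise ValueError(f"unknown method {method!r}")
    return n / window_len_s


def input_resistance(deflections: list[tuple[float, float]]) -> float:
    """Input resistance (MOhm) from (current pA, steady-state dV mV) points.

    Ordinary-least-squares slope in mV/pA, converted by x1000 to MOhm.
    Requires at least three step points (conventionally including 0 pA).
    """
    if len(deflections) < 3:
        raise ValueError("need at least three (current, deflection) points")
    i_pa = np.array([d[0] for d in deflections], dtype=float)
    dv = np.array([d[1] for d in deflections], dtype=float)
    slope = np.polyfit(i_pa, dv, 1)[0]  # mV / pA
    return float(slope * 1000.0)


def fi_curve(
    sweeps: list[tuple[float, np.ndarray]], sampling_rate: float,
    refractory_ms: float = REFRACTORY_MS,
) -> pd.DataFrame:
    """Spike count per current step from whole-cell sweeps.

    ``sweeps`` is a list of ``(current_pA, voltage_trace)``; counts use the
    dV/dt crossing rule with a refractory separation. Steps not supplied
    are simply absent from the table (not recorded as zero).
    """
    rows = [
        {"current_pa": float(i), "n_spikes": _count_aps(v, sampling_rate, refractory_ms)}
        for i, v in sweeps
    ]
    return pd.DataFrame(rows)


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two feature samples.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise; two identical constant
    groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
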