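"""Ripple event detection and event-rate utilities.

Detection thresholds the ripple-band (default 80-120 Hz) Hilbert envelope:
candidate intervals where the envelope exceeds ``envelope_threshold``
standard deviations above the mean amplitude of the filtered trace
(the SD is that of the band-passed voltage), adjacent candidates separated
by less than ``join_gap`` merged, and candidates retained only when at
least ``min_duration`` long with a peak exceeding ``max_threshold`` SDs.  The
strict preset (2 SD extent / 3 SD peak / 25 ms / 15 ms join) targets
classical ripples; the relaxed preset (1 SD / 2 SD / 10 ms) exposes the
continuum of smaller, shorter events.  Envelope statistics are computed per
channel over the whole session excluding artifact-masked samples, and any
event overlapping a masked sample is discarded.

An independent 1/f-referenced detector (``modal_narrowband_episodes``)
finds transient narrowband episodes without fixed amplitude thresholds, for
cross-validation of the threshold detector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import theilslopes

from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import RippleEvent, TimeSeriesRecording, TrialTable
from .spectral import band_filter_hilbert, morlet_tfr


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)

logger = logging.getLogger(__name__)

__all__ = ["DetectionParams", "STRICT", "RELAXED", "detect_ripples",
           "ripple_raster_rate", "modal_narrowband_episodes",
           "detection_parameter_sweep"]


@dataclass(frozen=True)
class DetectionParams:
    """Envelope-threshold detection parameters (SD units, ms)."""

    band: tuple[float, float] = (80.0, 120.0)
    envelope_threshold: float = 2.0
    max_threshold: float = 3.0
    min_duration_ms: float = 25.0
    join_gap_ms: float = 15.0

    def __post_init__(self) -> None:
        if self.max_threshold < self.envelope_threshold:
            raise ValueError("max_threshold must be >= envelope_threshold")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be positive")


STRICT = DetectionParams()
RELAXED = DetectionParams(envelope_threshold=1.0, max_threshold=2.0,
                          min_duration_ms=10.0)


def _runs(above: np.ndarray) -> np.ndarray:
    """(start, end) half-open runs of True."""
    d = np.diff(above.astype(np.int8), prepend=0, append=0)
    return np.column_stack([np.flatnonzero(d == 1), np.flatnonzero(d == -1)])


def detect_ripples(ts: TimeSeriesRecording, params: DetectionParams = STRICT,
                   mask: np.ndarray | None = None,
                   channels: list[int] | None = None) -> list[RippleEvent]:
    """Detect ripple events on each channel of a preprocessed recording.

    ``mask`` is a per-channel (or shared 1-D) boolean array, True where
    samples are artifactual: masked samples are excluded from the envelope
    mean/SD and events overlapping them are dropped.
    """
    fs = ts.fs
    min_dur = int(round(params.min_duration_ms / 1000.0 * fs))
    join = params.join_gap_ms / 1000.0 * fs
    events: list[RippleEvent] = []
    for ch in channels if channels is not None else range(ts.n_channels):
        filt = _bandpass(ts.data[ch], params.band, fs)
        env = np.abs(hilbert(filt))
        ch_mask = None
        if mask is not None:
            ch_mask = mask if mask.ndim == 1 else mask[ch]
            if ch_mask.all():
                warnings.warn(f"channel {ch} fully masked; no events")
                continue
            mu, sd = env[~ch_mask].mean(), filt[~ch_mask].std()
        else:
            mu, sd = env.mean(), filt.std()
        if sd == 0:
            continue
        z = (env - mu) / sd
        runs = _runs(z > params.envelope_threshold)
        if runs.size == 0:
            continue
        # merge runs separated by strictly less than the join gap
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < join:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            if e - s < min_dur:
                continue
            seg = z[s:e]
            peak_rel = int(np.argmax(seg))
            if seg[peak_rel] <= params.max_threshold:
                continue
            if ch_mask is not None and ch_mask[s:e].any():
                continue
            events.append(RippleEvent(channel=ch, start=int(s), end=int(e),
                                      peak_sample=int(s + peak_rel),
                                      peak_z=float(seg[peak_rel]), fs=fs,
                                      band=params.band))
    return events


def ripple_raster_rate(events: list[RippleEvent], trials: TrialTable, fs: float,
                       kernel_sd_s: float = 0.1, lag_range_s: float = 3.0
                       ) -> dict:
    """Trial-aligned event raster and smoothed rate time series.

    Event peak times are aligned to each trial's alignment sample; the rate
    trace is the across-trial mean event density (events/s) on a lag grid,
    smoothed with a Gaussian kernel.  Also returns the session-mean rate:
    events within trials divided by total in-trial time.
    """
    if trials.n_trials == 0:
        raise ValueError("empty trial table")
    peaks = np.array([e.peak_sample for e in events], dtype=np.int64)
    raster: list[np.ndarray] = []
    in_trial = 0
    for s, e, a in zip(trials.start, trials.end, trials.align):
        sel = peaks[(peaks >= s) & (peaks < e)]
        in_trial += sel.size
        raster.append((sel - a) / fs)
    total_time = float(np.sum(trials.end - trials.start)) / fs
    mean_rate = in_trial / total_time if total_time > 0 else 0.0

    dt = 0.01
    lags = np.arange(-lag_range_s, lag_range_s + dt / 2, dt)
    counts = np.zeros_like(lags)
    for r in raster:
        if r.size:
            idx = np.round((r - lags[0]) / dt).astype(int)
            idx = idx[(idx >= 0) & (idx < lags.size)]
            np.add.at(counts, idx, 1.0)
    rate = counts / (trials.n_trials * dt)
    if kernel_sd_s > 0:
        half = int(np.ceil(5 * kernel_sd_s / dt))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) * dt / kernel_sd_s) ** 2)
        k /= k.sum()
        rate = np.convolve(rate, k, mode="same")
    return {"raster": raster, "lags": lags, "rate": rate,
            "session_mean_rate": mean_rate}


# ---------------------------------------------------------------------------
# 1/f-referenced narrowband episode detector

def modal_narrowband_episodes(ts: TimeSeriesRecording, trials: TrialTable,
                              freq_range: tuple[float, float] = (70.0, 200.0),
                              n_freqs: int = 40, channel: int = 0,
                              smooth_ms: float = 10.0) -> pd.DataFrame:
    """Detect narrowband oscillation episodes against a per-trial 1/f fit.

    Per trial: the trial-mean wavelet log-power spectrum is fit with a
    robust (Theil-Sen) line in log-log coordinates over ``freq_range``;
    contiguous frequency ranges exceeding the fit define candidate
    narrowband bands.  Each band is band-pass filtered, the instantaneous
    frequency estimated by frequency sliding (median-smoothed derivative of
    unwrapped Hilbert phase), and samples whose band power falls below the
    1/f fit level are removed; the surviving contiguous sample runs are the
    episodes.

    Returns one row per episode: trial, band_lo, band_hi, start, end
    (session samples), duration_ms, center_freq (median instantaneous
    frequency).
    """
    fs = ts.fs
    lo, hi = freq_range
    freqs = np.linspace(lo, hi, n_freqs)
    min_len = int(2 * fs / lo)
    rows = []
    for ti, (s, e) in enumerate(zip(trials.start, trials.end)):
        if e - s < min_len:
            warnings.warn(f"trial {ti} shorter than 2 cycles of {lo} Hz; skipped")
            continue
        seg = TimeSeriesRecording(ts.data[channel:channel + 1, s:e], fs)
        buf_s = min(0.25, (e - s) / fs / 4)
        tfr = morlet_tfr(seg, freqs=freqs, zscore=False, buffer_s=buf_s)
        buf = tfr.buffer_samples
        spec = tfr.power[0].mean(axis=1)  # mean log power per frequency
        lx = np.log10(freqs)
        slope, intercept, *_ = theilslopes(spec, lx)
        fit = intercept + slope * lx
        above = spec > fit
        for b0, b1 in _runs(above):
            f_lo, f_hi = freqs[b0], freqs[min(b1, n_freqs - 1)]
            if f_hi - f_lo < 2.0:
                f_lo, f_hi = max(f_lo - 2.0, 1.0), f_hi + 2.0
            _, phase = band_filter_hilbert(seg.data[0], (f_lo, f_hi), fs)
            inst = np.gradient(np.unwrap(phase)) * fs / (2 * np.pi)
            k = max(int(round(smooth_ms / 1000 * fs)), 1)
            inst = uniform_filter1d(inst, size=k)[buf:phase.size - buf]
            # sample-level wavelet band power against the 1/f fit level
            band_sel = (freqs >= f_lo) & (freqs <= f_hi)
            p_t = tfr.power[0][band_sel].mean(axis=0)
            keep = p_t > fit[band_sel].mean()
            for r0, r1 in _runs(keep):
                if r1 - r0 < 2:
                    continue
                cf = float(np.median(inst[r0:r1]))
                rows.append({"trial": ti, "band_lo": f_lo, "band_hi": f_hi,
                             "start": int(s + buf + r0), "end": int(s + buf + r1),
                             "duration_ms": (r1 - r0) / fs * 1000.0,
                             "center_freq": cf})
    return pd.DataFrame(rows, columns=["trial", "band_lo", "band_hi", "start",
                                       "end", "duration_ms", "center_freq"])


def detection_parameter_sweep(ts_a: TimeSeriesRecording, ts_b: TimeSeriesRecording,
                              trials: TrialTable,
                              durations_ms: tuple[float, ...] = (10, 20, 30, 40),
                              max_amps_sd: tuple[float, ...] = (2.0, 3.0, 4.0),
                              base: DetectionParams = RELAXED,
                              channel_a: int = 0, channel_b: int = 0,
                              max_lag_ms: float = 200.0, bin_ms: float = 1.0,
                              window_ms: float = 50.0) -> pd.DataFrame:
    """Synchronization metric over a grid of detection parameters.

    For each (duration, max amplitude) pair, ripples are detected on both
    recordings with identical parameters and the shift-predictor-normalized
    synchronization metric is computed between the two event trains.
    """
    from .eventstats import (event_cross_correlogram, shift_predictor,
                             synchronization_metric)

    rows = []
    for dur in durations_ms:
        for amp in max_amps_sd:
            params = replace(base, min_duration_ms=dur, max_threshold=amp,
                             envelope_threshold=min(base.envelope_threshold, amp))
            ev_a = detect_ripples(ts_a, params, channels=[channel_a])
            ev_b = detect_ripples(ts_b, params, channels=[channel_b])
            true_ccg = event_cross_correlogram(ev_a, ev_b, trials, ts_a.fs,
                                               max_lag_ms, bin_ms)
            pred = shift_predictor(ev_a, ev_b, trials, ts_a.fs, max_lag_ms, bin_ms)
            try:
                sync = synchronization_metric(true_ccg, pred, window_ms)
            except ValueError:
                sync = np.nan
            rows.append({"min_duration_ms": dur, "max_threshold_sd": amp,
                         "n_events_a": len(ev_a), "n_events_b": len(ev_b),
                         "sync_metric": sync})
    return pd.DataFrame(rows)
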