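"""Recording cleanup: line-noise regression, detrending, trial and sample
artifact rejection, and common average referencing.

The transient-artifact detector flags any sample whose first-difference
(gradient) or >250 Hz high-frequency amplitude exceeds a z-score of 5 and
dilates each flag by 100 ms on both sides; ripple events overlapping a
flagged sample are excluded downstream.  Outlier trials are rejected with a
quartile rule: a trial is dropped when its voltage statistic exceeds
``Q3 + w * (Q3 - Q1)`` with ``w = 2.3``.

The per-trial voltage statistic is the mean *absolute* voltage per channel,
aggregated across channels by the maximum.  Raw signed means cancel around
zero and cannot index artifact severity; this interpretation is explicit
and configurable via ``stat`` / ``aggregate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import TimeSeriesRecording, TrialTable

__all__ = ["ArtifactMask", "remove_line_noise", "detrend_slow",
           "reject_outlier_trials", "mask_transient_artifacts",
           "common_average_reference"]

DILATE_S = 0.1  # flags extend 100 ms on each side of a seed sample


@dataclass
class ArtifactMask:
    """Per-channel boolean artifact masks (True = artifactual sample)."""

    mask: np.ndarray                      # (n_channels, n_samples) bool
    reasons: dict = field(default_factory=dict)  # tag -> bool array

    @property
    def any_channel(self) -> np.ndarray:
        """Union across channels — samples bad anywhere."""
        return self.mask.any(axis=0)

    def flagged_fraction(self) -> float:
        return float(self.mask.mean())

    def to_frame(self, fs: float) -> pd.DataFrame:
        """BED-like table of flagged runs: channel, start, end, reason."""
        rows = []
        for tag, m in self.reasons.items():
            for c in range(m.shape[0]):
                d = np.diff(m[c].astype(np.int8), prepend=0, append=0)
                for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
                    rows.append({"channel": c, "start_sample": int(s),
                                 "end_sample": int(e), "reason": tag})
        return pd.DataFrame(rows, columns=["channel", "start_sample",
                                           "end_sample", "reason"])


# ---------------------------------------------------------------------------

def remove_line_noise(ts: TimeSeriesRecording,
                      freqs: tuple[float, ...] = (60.0, 120.0),
                      window_s: float = 10.0,
                      overlap: float = 0.5) -> TimeSeriesRecording:
    """Regress out sinusoidal line components over sliding windows.

    Within each window a sine and cosine at each target frequency are fit
    by least squares and subtracted; windows overlap 50% and are blended
    with Hann weights so the subtraction tracks slow drifts in line
    amplitude without seams.
    """
    if max(freqs) >= ts.fs / 2:
        raise ValueError("line frequency at or above Nyquist")
    out = ts.copy()
    n = ts.n_samples
    win = min(int(round(window_s * ts.fs)), n)
    step = max(int(round(win * (1 - overlap))), 1)
    t = np.arange(n) / ts.fs
    fitted = np.zeros_like(out.data)
    weight = np.zeros(n)
    taper = np.hanning(win) + 1e-12
    for s in range(0, n, step):
        e = min(s + win, n)
        seg_t = t[s:e]
        cols = []
        for f in freqs:
            cols.append(np.cos(2 * np.pi * f * seg_t))
            cols.append(np.sin(2 * np.pi * f * seg_t))
        design = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(design, out.data[:, s:e].T, rcond=None)
        w = taper[: e - s]
        fitted[:, s:e] += (design @ coef).T * w
        weight[s:e] += w
        if e == n:
            break
    out.data -= fitted / weight
    return out


def detrend_slow(ts: TimeSeriesRecording, cutoff: float = 2.0) -> TimeSeriesRecording:
    """Remove slow fluctuations (<= cutoff Hz) by subtracting a zero-phase
    low-pass of the signal (local detrending without an explicit window)."""
    out = ts.copy()
    sos = butter(4, cutoff, btype="lowpass", fs=ts.fs, output="sos")
    out.data -= sosfiltfilt(sos, out.data, axis=-1)
    return out


def reject_outlier_trials(ts: TimeSeriesRecording, trials: TrialTable,
                          w: float = 2.3, stat: str = "mean_abs",
                          aggregate: str = "max") -> np.ndarray:
    """Indices of trials surviving the quartile outlier rule.

    Computes a per-trial voltage statistic (default: mean absolute voltage
    per channel, aggregated by the cross-channel maximum), then excludes
    trials exceeding ``Q3 + w * (Q3 - Q1)``.  With zero dispersion the
    threshold collapses to ``Q3`` and only strictly larger trials are
    excluded, so an all-equal set is kept in full.
    """
    if trials.n_trials < 4:
        raise ValueError("quartile rejection needs at least 4 trials")
    stats = np.empty(trials.n_trials)
    for i, (s, e) in enumerate(zip(trials.start, trials.end)):
        seg = ts.data[:, s:e]
        per_ch = np.abs(seg).mean(axis=1) if stat == "mean_abs" else seg.mean(axis=1)
        stats[i] = per_ch.max() if aggregate == "max" else per_ch.mean()
    q1, q3 = np.quantile(stats, [0.25, 0.75])
    threshold = q3 + w * (q3 - q1)
    return np.flatnonzero(stats <= threshold)


def mask_transient_artifacts(ts: TimeSeriesRecording, z_threshold: float = 5.0,
                             highpass: float = 250.0) -> ArtifactMask:
    """Flag sharp transients (IEDs, movement) by gradient / HF amplitude.

    Per channel, the first difference and the Hilbert amplitude of the
    >250 Hz high-passed signal are z-scored; samples where either exceeds
    ``z_threshold`` are flagged and dilated by 100 ms on each side (clipped
    at the edges).
    """
    if ts.fs < 2.4 * highpass:
        raise ValueError("sampling rate too low for the high-pass criterion")
    n_dilate = int(round(DILATE_S * ts.fs))
    structure = np.ones(2 * n_dilate + 1, dtype=bool)

    grad = np.diff(ts.data, axis=1, prepend=ts.data[:, :1])
    gz = (grad - grad.mean(axis=1, keepdims=True)) / grad.std(axis=1, keepdims=True)
    sos = butter(4, highpass, btype="highpass", fs=ts.fs, output="sos")
    hf = np.abs(hilbert(sosfiltfilt(sos, ts.data, axis=-1), axis=-1))
    hz = (hf - hf.mean(axis=1, keepdims=True)) / hf.std(axis=1, keepdims=True)

    masks = {}
    for tag, z in (("gradient", np.abs(gz)), ("hf_amplitude", hz)):
        seed = z > z_threshold
        masks[tag] = np.stack([
            binary_dilation(seed[c], structure=structure)
            for c in range(ts.n_channels)])
    combined = masks["gradient"] | masks["hf_amplitude"]
    return ArtifactMask(mask=combined, reasons=masks)


def common_average_reference(ts: TimeSeriesRecording) -> TimeSeriesRecording:
    """Subtract the per-sample mean across channels from every channel."""
    if ts.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = ts.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out
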