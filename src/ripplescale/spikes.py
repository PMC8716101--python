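"""Spike-derived continuous measures and waveform quality.

The instantaneous spike rate is the delta train convolved with a
unit-integral Gaussian kernel (sigma = 25 ms by default), optionally
z-scored against the session mean and SD.  Waveform signal-to-noise is
``(Vpeak - Vtrough) / (Noise * C)`` where Vpeak/Vtrough are the extrema of
the mean waveform, Noise is the SD of the concatenated waveform residuals
(each waveform minus the mean) and C = 5.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import SpikeTrain

__all__ = ["smoothed_spike_rate", "waveform_snr"]


def smoothed_spike_rate(train: SpikeTrain, n_samples: int, fs: float,
                        sigma_ms: float = 25.0, zscore: bool = False
                        ) -> np.ndarray:
    """Gaussian-smoothed instantaneous spike rate in Hz.

    The kernel is truncated at +/-5 sigma and boundaries are handled by
    reflection so that the rate integrates to the spike count.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    if train.indices.size and (train.indices.min() < 0
                               or train.indices.max() >= n_samples):
        raise ValueError("spike index outside the session")
    delta = np.zeros(n_samples)
    np.add.at(delta, train.indices, fs)  # delta train in Hz units
    sigma = sigma_ms / 1000.0 * fs
    rate = gaussian_filter1d(delta, sigma=sigma, mode="reflect", truncate=5.0)
    if zscore:
        mu, sd = rate.mean(), rate.std()
        if sd == 0:
            raise ValueError("zero-variance rate cannot be z-scored")
        rate = (rate - mu) / sd
    return rate


def waveform_snr(waveforms: np.ndarray, c: float = 5.0) -> float:
    """Signal-to-noise ratio of a unit's spike waveforms.

    ``waveforms`` is (n_spikes, n_samples).  Raises on identical waveforms
    (zero residual noise) rather than returning infinity.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    if waveforms.ndim != 2 or waveforms.shape[0] < 2:
        raise ValueError("need at least two waveforms")
    mean_wf = waveforms.mean(axis=0)
    residuals = (waveforms - mean_wf).ravel()
    noise = residuals.std()
    if noise == 0:
        raise ValueError("identical waveforms: SNR undefined (zero noise)")
    return float((mean_wf.max() - mean_wf.min()) / (noise * c))
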