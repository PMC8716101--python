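"""Phase-locking machinery: pairwise phase consistency (PPC), Rayleigh
tests, spike-field PPC spectra with shuffle z-scoring, condition contrasts,
cross-channel ripple-phase alignment and spike-triggered averages.

PPC is the mean pairwise cosine of phase differences,

    gamma_hat = 2 / (N (N-1)) * sum_{j<k} cos(theta_j - theta_k),

an estimator whose population value equals the squared phase-locking value
and which carries no sample-size bias.  It is computed via unit vectors as
``(|sum v|^2 - N) / (N (N-1))``, identical to the double loop to machine
precision.  The average pairwise circular distance (APCD) descriptive
statistic, ``mean_{j<k} (|theta_j - theta_k| mod pi)``, is reported
alongside for moderate N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import RippleEvent, SpikeTrain, TimeSeriesRecording, TrialTable

logger = logging.getLogger(__name__)

__all__ = ["PPCResult", "ppc", "ppc_value", "rayleigh_test", "wavelet_phases",
           "default_ppc_freqs", "spike_field_ppc_spectrum",
           "zscore_ppc_by_trial_shuffle", "compare_ppc_conditions",
           "ripple_alignment_ppc", "spike_triggered_average",
           "ppc_spectrum_frame"]


def ppc_spectrum_frame(freqs, ppc_matrix, units, z_matrix=None):
    """Long-format table of PPC spectra: unit, frequency_hz, ppc[, z]."""
    import pandas as pd

    rows = {
        "unit": np.repeat(units, len(freqs)),
        "frequency_hz": np.tile(freqs, len(units)),
        "ppc": np.asarray(ppc_matrix).ravel(),
    }
    if z_matrix is not None:
        rows["z"] = np.asarray(z_matrix).ravel()
    return pd.DataFrame(rows)

APCD_MAX_N = 5000  # pairwise distance matrix computed only below this size


@dataclass
class PPCResult:
    ppc: float
    n: int
    apcd: float | None
    preferred_phase: float
    z: float | None = None


def ppc_value(phases: np.ndarray) -> float:
    """PPC of a 1-D phase sample via the unit-vector identity."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC requires at least two phases")
    resultant = np.abs(np.exp(1j * phases).sum())
    return float((resultant ** 2 - n) / (n * (n - 1)))


def ppc(phases: np.ndarray) -> PPCResult:
    """Full PPC result: estimate, APCD and preferred phase."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC requires at least two phases")
    vec = np.exp(1j * phases).sum()
    gamma = float((np.abs(vec) ** 2 - n) / (n * (n - 1)))
    apcd = None
    if n <= APCD_MAX_N:
        diff = np.abs(phases[:, None] - phases[None, :])
        iu = np.triu_indices(n, k=1)
        apcd = float(np.mod(diff[iu], np.pi).mean())
    return PPCResult(ppc=gamma, n=n, apcd=apcd,
                     preferred_phase=float(np.angle(vec)))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: (mean resultant length, p).

    Uses Zar's finite-n approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with ``R = n*Rbar``.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("Rayleigh test requires at least two phases")
    rbar = float(np.abs(np.exp(1j * phases).mean()))
    big_r = n * rbar
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - big_r ** 2)) - (1 + 2 * n))
    return rbar, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# spike-field PPC spectra

def rayleigh_across_groups(phase_sets: list[np.ndarray]) -> tuple[float, float]:
    """Second-level phase consistency: Rayleigh on per-group preferred phases.

    Each group's (e.g. participant's) phase sample is reduced to the angle
    of its complex mean; the Rayleigh test then asks whether those
    preferred phases agree across groups.
    """
    if len(phase_sets) < 2:
        raise ValueError("need at least two groups")
    prefs = np.array([np.angle(np.exp(1j * np.asarray(p, dtype=float)).mean())
                      for p in phase_sets])
    return rayleigh_test(prefs)


def default_ppc_freqs() -> np.ndarray:
    """60 log-spaced frequencies between 2 and 400 Hz."""
    return np.geomspace(2.0, 400.0, 60)


def wavelet_phases(ts: TimeSeriesRecording, freqs: np.ndarray,
                   channels: list[int] | None = None, n_cycles: float = 6.0
                   ) -> dict[int, np.ndarray]:
    """Morlet phase per channel: maps channel -> (n_freqs, n_samples)."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= ts.fs / 2:
        raise ValueError("frequency at or above Nyquist")
    if channels is None:
        channels = list(range(ts.n_channels))
    out = {}
    for ch in channels:
        w = tfr_array_morlet(ts.data[ch][None, None, :], sfreq=ts.fs,
                             freqs=freqs, n_cycles=n_cycles, output="complex",
                             zero_mean=True, verbose="error")[0, 0]
        out[ch] = np.angle(w).astype(np.float32)
    return out


def _per_trial_ppc(phase_arr: np.ndarray, spike_idx: np.ndarray,
                   trials: TrialTable, min_spikes: int = 2) -> np.ndarray | None:
    """Trial-mean PPC spectrum for one unit; None when no trial qualifies."""
    n_freqs = phase_arr.shape[0]
    acc = np.zeros(n_freqs)
    n_tr = 0
    for s, e in zip(trials.start, trials.end):
        sel = spike_idx[(spike_idx >= s) & (spike_idx < e)]
        if sel.size < min_spikes:
            continue
        ph = phase_arr[:, sel].astype(float)
        vec = np.exp(1j * ph).sum(axis=1)
        n = sel.size
        acc += (np.abs(vec) ** 2 - n) / (n * (n - 1))
        n_tr += 1
    if n_tr == 0:
        return None
    return acc / n_tr


def spike_field_ppc_spectrum(trains: list[SpikeTrain],
                             lfp: TimeSeriesRecording, trials: TrialTable,
                             freqs: np.ndarray | None = None,
                             phases: dict[int, np.ndarray] | None = None
                             ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-unit spike-LFP PPC spectra, computed per trial then averaged.

    Each unit's spikes take the wavelet phase of its own channel.  Trials
    with fewer than two spikes are skipped; units with no qualifying trial
    are excluded (logged).  Returns ``(freqs, ppc_matrix, unit_ids)`` with
    ``ppc_matrix`` of shape (n_units_kept, n_freqs).
    """
    if freqs is None:
        freqs = default_ppc_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if phases is None:
        phases = wavelet_phases(lfp, freqs, sorted({t.channel for t in trains}))
    rows, kept = [], []
    for train in trains:
        spec = _per_trial_ppc(phases[train.channel], train.indices, trials)
        if spec is None:
            logger.info("unit %s excluded: no trial with >= 2 spikes", train.unit)
            continue
        rows.append(spec)
        kept.append(train.unit)
    return freqs, np.asarray(rows), kept


def zscore_ppc_by_trial_shuffle(trains: list[SpikeTrain],
                                lfp: TimeSeriesRecording, trials: TrialTable,
                                freqs: np.ndarray | None = None,
                                n_shuffle: int = 100,
                                rng: np.random.Generator | int | None = 0,
                                phases: dict[int, np.ndarray] | None = None
                                ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Z-score observed PPC spectra against a trial-label shuffle null.

    The null pairs each trial's spike pattern (spike times relative to
    trial onset) with the LFP phases of a randomly chosen other trial;
    ``n_shuffle`` reassignments give the null mean and SD per frequency.
    """
    if trials.n_trials < 2:
        raise ValueError("trial shuffling requires >= 2 trials")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if freqs is None:
        freqs = default_ppc_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if phases is None:
        phases = wavelet_phases(lfp, freqs, sorted({t.channel for t in trains}))
    obs_freqs, obs, kept = spike_field_ppc_spectrum(trains, lfp, trials, freqs,
                                                    phases)
    kept_trains = [t for t in trains if t.unit in set(kept)]
    lengths = trials.end - trials.start
    zmat = np.empty_like(obs)
    for ui, train in enumerate(kept_trains):
        rel = [train.indices[(train.indices >= s) & (train.indices < e)] - s
               for s, e in zip(trials.start, trials.end)]
        null = np.empty((n_shuffle, freqs.size))
        for k in range(n_shuffle):
            perm = rng.permutation(trials.n_trials)
            acc = np.zeros(freqs.size)
            n_tr = 0
            for ti, tj in enumerate(perm):
                r = rel[ti] % lengths[tj]
                if r.size < 2:
                    continue
                ph = phases[train.channel][:, trials.start[tj] + r].astype(float)
                vec = np.exp(1j * ph).sum(axis=1)
                n = r.size
                acc += (np.abs(vec) ** 2 - n) / (n * (n - 1))
                n_tr += 1
            null[k] = acc / n_tr if n_tr else np.nan
        mu, sd = np.nanmean(null, axis=0), np.nanstd(null, axis=0)
        if np.any(sd == 0):
            raise ValueError("degenerate shuffle null (zero SD)")
        zmat[ui] = (obs[ui] - mu) / sd
    return obs_freqs, zmat, kept


def compare_ppc_conditions(trains: list[SpikeTrain], trials: TrialTable,
                           cond_a: np.ndarray, cond_b: np.ndarray,
                           phases: dict[int, np.ndarray], freqs: np.ndarray,
                           min_spikes: int = 10, n_subsample: int = 200,
                           rng: np.random.Generator | int | None = 0
                           ) -> tuple[np.ndarray, list[str]]:
    """Per-unit PPC difference between two spike conditions.

    ``cond_a``/``cond_b`` are boolean masks over session samples defining
    which spikes belong to each condition (e.g. inside vs outside detected
    ripples, or correct vs incorrect trials).  Spikes are pooled across
    trials; the larger condition is subsampled to the smaller count
    (``n_subsample`` draws, averaged) so spike-count bias cancels.  Raw
    (not z-scored) PPC is used since the contrast is within unit.  Returns
    the (units x freqs) difference matrix (A minus B) and kept unit ids.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    in_trial = np.zeros(cond_a.size, dtype=bool)
    for s, e in zip(trials.start, trials.end):
        in_trial[s:e] = True
    diffs, kept = [], []
    for train in trains:
        idx = train.indices[in_trial[train.indices]]
        idx_a = idx[cond_a[idx]]
        idx_b = idx[cond_b[idx]]
        if idx_a.size < min_spikes or idx_b.size < min_spikes:
            continue
        ph = phases[train.channel]

        def pooled(idx_small: np.ndarray, idx_large: np.ndarray) -> tuple:
            m = idx_small.size
            small = _pooled_ppc(ph, idx_small)
            if idx_large.size == m:
                return small, _pooled_ppc(ph, idx_large)
            acc = np.zeros(ph.shape[0])
            for _ in range(n_subsample):
                sub = rng.choice(idx_large, size=m, replace=False)
                acc += _pooled_ppc(ph, sub)
            return small, acc / n_subsample

        if idx_a.size <= idx_b.size:
            ppc_a, ppc_b = pooled(idx_a, idx_b)
        else:
            ppc_b, ppc_a = pooled(idx_b, idx_a)
        diffs.append(ppc_a - ppc_b)
        kept.append(train.unit)
    return np.asarray(diffs), kept


def _pooled_ppc(phase_arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    ph = phase_arr[:, idx].astype(float)
    vec = np.exp(1j * ph).sum(axis=1)
    n = idx.size
    return (np.abs(vec) ** 2 - n) / (n * (n - 1))


# ---------------------------------------------------------------------------
# cross-channel ripple-phase alignment

def ripple_alignment_ppc(events: list[RippleEvent],
                         mea_phases: np.ndarray,
                         channel_mask: np.ndarray | None = None
                         ) -> np.ndarray:
    """Maximum across-channel PPC within each macro-scale ripple.

    ``mea_phases`` is the (n_channels, n_samples) ripple-band phase of the
    micro array.  At every sample of an event the across-channel phase set
    (one observation per channel) yields one PPC value; the event statistic
    is the maximum over its samples.  ``channel_mask`` (n_channels,
    n_samples) optionally restricts each sample's observation set to
    channels with a concurrently detected micro-scale ripple; samples with
    fewer than two eligible channels are skipped.
    """
    n_ch = mea_phases.shape[0]
    if n_ch < 2:
        raise ValueError("alignment PPC requires >= 2 channels")
    vec = np.exp(1j * mea_phases.astype(float))
    out = np.full(len(events), np.nan)
    for i, e in enumerate(events):
        v = vec[:, e.start:e.end]
        if channel_mask is not None:
            m = channel_mask[:, e.start:e.end]
            counts = m.sum(axis=0)
            ok = counts >= 2
            if not ok.any():
                continue
            s = (v * m).sum(axis=0)[ok]
            n = counts[ok]
        else:
            s = v.sum(axis=0)
            n = np.full(s.size, n_ch)
        vals = (np.abs(s) ** 2 - n) / (n * (n - 1))
        out[i] = vals.max()
    return out


# ---------------------------------------------------------------------------
# spike-triggered average

def spike_triggered_average(trains: list[SpikeTrain], ts: TimeSeriesRecording,
                            window_s: float = 0.25,
                            band: tuple[float, float] | None = None,
                            events: list[RippleEvent] | None = None,
                            inside: bool = True, channel: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean signal segment centered on spikes: ``(lags_s, sta, n_spikes)``.

    With ``band`` the signal is zero-phase band-passed first (e.g. 2-10 Hz
    for slow-deflection locking).  With ``events`` only spikes inside
    (``inside=True``) or outside detected events are used.
    """
    half = int(round(window_s * ts.fs))
    if 2 * half + 1 > ts.n_samples:
        raise ValueError("window longer than the session")
    if band is not None:
        from scipy.signal import butter, sosfiltfilt
        sos = butter(2, band, btype="bandpass", fs=ts.fs, output="sos")
        data = sosfiltfilt(sos, ts.data, axis=-1)
    else:
        data = ts.data
    in_event = None
    if events is not None:
        in_event = np.zeros(ts.n_samples, dtype=bool)
        for e in events:
            in_event[e.start:e.end] = True
    acc = np.zeros(2 * half + 1)
    count = 0
    for train in trains:
        ch = channel if channel is not None else train.channel
        idx = train.indices
        idx = idx[(idx >= half) & (idx < ts.n_samples - half)]
        if in_event is not None:
            keep = in_event[idx] if inside else ~in_event[idx]
            idx = idx[keep]
        for t0 in idx:
            acc += data[ch, t0 - half:t0 + half + 1]
        count += idx.size
    if count == 0:
        raise ValueError("no qualifying spikes for the STA")
    lags = np.arange(-half, half + 1) / ts.fs
    return lags, acc / count, count
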