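"""Synthetic multi-scale session generator with known ground truth.

The generator emulates the statistical structure of a simultaneous
macro-scale iEEG / micro-scale MEA recording during a cued-retrieval task:

* a 1/f voltage background with 60 and 120 Hz line components,
* transient ripple-band (default 80-120 Hz) bursts with a right-skewed
  spectrum of amplitudes and durations, at a higher rate on correct trials,
* a configurable fraction of bursts shared (same time, frequency and phase)
  across all MEA channels, the rest channel-private,
* iEEG channels formed as a weighted mean of the MEA ensemble plus
  independent 1/f noise,
* unit spike trains with Poisson baseline firing plus ripple-locked spikes
  whose ripple-band phases are von Mises concentrated at the trough
  (``phase = pi`` under the ``x = A cos(phi)`` convention),
* rare stereotyped sharp transients emulating interictal discharges (IEDs).

Event amplitudes are expressed as envelope z-scores: SD units of the
band-passed background trace above the mean envelope, exactly the
normalization the detector applies, so thresholds stated in SDs are
meaningful by construction.  Each burst holds its peak amplitude for the drawn duration
and is ramped on/off with short raised-cosine flanks outside that interval;
ground-truth start/end delimit the full-amplitude plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    GroundTruth,
    SpikeTrain,
    SyntheticSession,
    TimeSeriesRecording,
    TrialTable,
)

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "gen_background", "inject_ripples", "gen_locked_spikes",
           "build_session"]

#: half-cosine on/off ramp appended outside the plateau of each burst (ms)
RAMP_MS = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic session.

    All rates are in Hz, durations in seconds unless suffixed otherwise.
    Identical config + seed yields a bit-identical session.
    """

    sampling_rate: float = 1000.0
    n_mea_channels: int = 96
    n_ieeg_channels: int = 4
    session_duration: float | None = None   # derived from trials when None
    trial_count: int = 30
    trial_duration: float = 4.0
    inter_trial_gap: float = 1.0
    p_correct: float = 0.5
    noise_exponent: float = 1.5
    background_sd: float = 1.0
    line_noise_amp: float = 0.2             # 60/120 Hz sinusoid amplitude
    ripple_rate_correct: float = 0.4
    ripple_rate_incorrect: float = 0.2
    ripple_freq_range: tuple[float, float] = (80.0, 120.0)
    # log-normal amplitude (envelope z units): median 2.5 SD, sigma_log 0.4
    ripple_amp_median: float = 2.5
    ripple_amp_sigma_log: float = 0.4
    # gamma duration (ms): shape 3, mean 40 ms, floored at 15 ms
    ripple_dur_shape: float = 3.0
    ripple_dur_mean_ms: float = 40.0
    ripple_dur_min_ms: float = 15.0
    cross_channel_alignment: float = 0.5
    ieeg_mix: float = 0.6                   # weight of the MEA mean in iEEG
    n_units: int = 20
    spike_baseline_rate: float = 2.5
    spikes_per_ripple: float = 3.0          # mean locked spikes per event at median amplitude
    locking_kappa: float = 2.0
    spike_lock_phase: float = np.pi         # trough
    ied_rate: float = 0.0
    ied_amp_sd: float = 10.0                # IED peak in broadband-SD units
    waveform_peak: float = 40.0
    waveform_trough: float = -60.0
    waveform_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.ripple_freq_range
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("ripple_freq_range must lie within (0, Nyquist)")
        for name in ("ripple_rate_correct", "ripple_rate_incorrect",
                     "spike_baseline_rate", "ied_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cross_channel_alignment <= 1.0:
            raise ValueError("cross_channel_alignment must lie in [0, 1]")
        if self.locking_kappa < 0:
            raise ValueError("locking_kappa must be non-negative")
        if self.session_duration is not None and self.session_duration <= 0:
            raise ValueError("session_duration must be positive")

    # -- derived geometry -------------------------------------------------
    def trial_table(self, rng: np.random.Generator) -> TrialTable:
        fs = self.sampling_rate
        pad = int(round(2.0 * fs))
        tlen = int(round(self.trial_duration * fs))
        gap = int(round(self.inter_trial_gap * fs))
        start = pad + np.arange(self.trial_count) * (tlen + gap)
        end = start + tlen
        # vocalization 1 s before trial end: the epoch spans 3 s before to
        # 1 s after the alignment point for the default 4 s trial
        align = end - int(round(min(1.0, self.trial_duration / 4) * fs))
        labels = np.where(rng.random(self.trial_count) < self.p_correct,
                          "correct", "incorrect").astype(object)
        return TrialTable(start, end, align, labels)

    @property
    def n_samples(self) -> int:
        if self.session_duration is not None:
            return int(round(self.session_duration * self.sampling_rate))
        fs = self.sampling_rate
        pad = int(round(2.0 * fs))
        tlen = int(round(self.trial_duration * fs))
        gap = int(round(self.inter_trial_gap * fs))
        return 2 * pad + self.trial_count * (tlen + gap)


# ---------------------------------------------------------------------------
# background

def _one_over_f(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, flattened below 2 Hz, unit-normalized."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 2.0) ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def gen_background(config: SimConfig, n_channels: int | None = None,
                   scale: str = "lfp",
                   rng: np.random.Generator | None = None) -> TimeSeriesRecording:
    """Generate the 1/f + line-noise voltage background.

    Channels are mutually independent.  The power spectral density falls as
    ``f ** -noise_exponent`` above 2 Hz; sinusoids at 60 and 120 Hz with
    per-channel random phase model line noise.
    """
    if config.n_samples <= 0:
        raise ValueError("session duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_channels is None:
        n_channels = config.n_mea_channels
    fs = config.sampling_rate
    n = config.n_samples
    data = _one_over_f(rng, n_channels, n, fs, config.noise_exponent,
                       config.background_sd)
    if config.line_noise_amp > 0:
        t = np.arange(n) / fs
        for f_line, amp_scale in ((60.0, 1.0), (120.0, 0.5)):
            if f_line < fs / 2:
                phi = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
                data += (config.line_noise_amp * amp_scale
                         * np.sin(2 * np.pi * f_line * t[None, :] + phi))
    return TimeSeriesRecording(data, fs, scale=scale)


# ---------------------------------------------------------------------------
# ripple injection

def _draw_event(rng: np.random.Generator, config: SimConfig) -> tuple[float, float, float]:
    """Draw (center frequency Hz, amplitude SD, duration ms) for one event."""
    lo, hi = config.ripple_freq_range
    freq = rng.uniform(lo, hi)
    amp = np.exp(rng.normal(np.log(config.ripple_amp_median),
                            config.ripple_amp_sigma_log))
    scale = config.ripple_dur_mean_ms / config.ripple_dur_shape
    dur = max(rng.gamma(config.ripple_dur_shape, scale), config.ripple_dur_min_ms)
    return freq, amp, dur


def _burst_waveform(freq: float, dur_samples: int, ramp_samples: int,
                    fs: float, phase0: float) -> np.ndarray:
    """Constant-amplitude sinusoid with half-cosine on/off ramps.

    The returned array spans ``dur_samples + 2 * ramp_samples``; the plateau
    occupies the central ``dur_samples``.  Phase is referenced to the
    plateau start: ``x[k] = w[k] * cos(2 pi f (k - ramp)/fs + phase0)``.
    """
    total = dur_samples + 2 * ramp_samples
    k = np.arange(total)
    env = np.ones(total)
    if ramp_samples > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_samples) / ramp_samples))
        env[:ramp_samples] = up
        env[-ramp_samples:] = up[::-1]
    return env * np.cos(2 * np.pi * freq * (k - ramp_samples) / fs + phase0)


def _sample_event_times(rng: np.random.Generator, trials: TrialTable | None,
                        n_samples: int, fs: float, rate_by_label: dict) -> np.ndarray:
    """Poisson event times (plateau-center samples) within trial epochs."""
    if rate_by_label and trials is None:
        raise ValueError("trials required for label-dependent rates")
    times = []
    if trials is None:
        return np.empty(0, dtype=np.int64)
    for s, e, lab in zip(trials.start, trials.end, trials.label):
        rate = rate_by_label.get(str(lab), 0.0)
        if rate <= 0:
            continue
        count = rng.poisson(rate * (e - s) / fs)
        times.extend(rng.integers(s, e, size=count))
    return np.sort(np.asarray(times, dtype=np.int64))


def _envelope_stats(data: np.ndarray, fs: float,
                    band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per channel: (mean ripple-band envelope, SD of the band-passed trace).

    These are the normalization statistics the detector uses, so an event of
    amplitude A lands at an envelope z-score of about A by construction.
    """
    from scipy.signal import butter, hilbert, sosfiltfilt
    sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
    amp = np.empty(data.shape[0])
    sd = np.empty(data.shape[0])
    for c in range(data.shape[0]):
        filt = sosfiltfilt(sos, data[c])
        amp[c] = np.abs(hilbert(filt)).mean()
        sd[c] = filt.std()
    return amp, sd


def inject_ripples(ts: TimeSeriesRecording, config: SimConfig,
                   rng: np.random.Generator,
                   trials: TrialTable | None = None
                   ) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Add ripple bursts to a background recording and record ground truth.

    A fraction ``cross_channel_alignment`` of the per-channel event rate is
    carried by session-wide shared events (identical plateau interval,
    frequency and phase on every channel); the remainder is channel-private.
    Events whose footprint would leave the session, or overlap an existing
    event on the same channel, are resampled a bounded number of times and
    dropped (with a log message) if still infeasible.
    """
    out = ts.copy()
    fs = ts.fs
    n = ts.n_samples
    ramp = int(round(RAMP_MS / 1000.0 * fs))
    if trials is None:
        # homogeneous rate over the full session: treat as one long trial
        trials = TrialTable(np.array([0]), np.array([n]), np.array([n - 1]),
                            np.array(["correct"], dtype=object))
    rates = {"correct": config.ripple_rate_correct,
             "incorrect": config.ripple_rate_incorrect, "pass": 0.0}
    align = config.cross_channel_alignment
    mu_env, sd_env = _envelope_stats(ts.data, fs, config.ripple_freq_range)

    # zero-phase band-pass power gain of the ripple-band measurement filter:
    # injected amplitude is compensated so that "amplitude" means the
    # in-band envelope amplitude the event exhibits after filtering
    from scipy.signal import butter, sosfreqz
    sos = butter(2, config.ripple_freq_range, btype="bandpass", fs=fs,
                 output="sos")

    def _band_gain(freq: float) -> float:
        _, h = sosfreqz(sos, worN=[freq], fs=fs)
        return float(np.abs(h[0]) ** 2)  # forward-backward application

    occupied: list[list[tuple[int, int]]] = [[] for _ in range(ts.n_channels)]
    rows: list[dict] = []
    margin = int(round(0.02 * fs))  # 20 ms clearance between events

    def _free(ch: int, s: int, e: int) -> bool:
        return all(e + margin <= a or b + margin <= s for a, b in occupied[ch])

    def _place(channels: list[int], center: int, shared_id: int) -> None:
        freq, amp, dur_ms = _draw_event(rng, config)
        dur = max(int(round(dur_ms / 1000.0 * fs)), 2)
        for _ in range(20):
            s = center - dur // 2
            e = s + dur
            if (s - ramp >= 0 and e + ramp <= n
                    and all(_free(ch, s - ramp, e + ramp) for ch in channels)):
                break
            center = int(rng.integers(ramp + dur, n - ramp - dur))
        else:
            logger.info("dropped infeasible ripple event (center=%d)", center)
            return
        phase0 = rng.uniform(0, 2 * np.pi)
        wave = _burst_waveform(freq, dur, ramp, fs, phase0)
        gain = _band_gain(freq)
        for ch in channels:
            peak_v = (mu_env[ch] + amp * sd_env[ch]) / gain
            out.data[ch, s - ramp:e + ramp] += peak_v * wave
            occupied[ch].append((s - ramp, e + ramp))
            rows.append({"channel": ch, "start": s, "end": e,
                         "peak_sample": (s + e) // 2, "freq": freq,
                         "amplitude": amp, "phase0": phase0,
                         "shared_id": shared_id})

    shared_rates = {k: v * align for k, v in rates.items()}
    private_rates = {k: v * (1 - align) for k, v in rates.items()}
    all_channels = list(range(ts.n_channels))
    next_shared = 0
    for center in _sample_event_times(rng, trials, n, fs, shared_rates):
        _place(all_channels, int(center), next_shared)
        next_shared += 1
    for ch in all_channels:
        for center in _sample_event_times(rng, trials, n, fs, private_rates):
            _place([ch], int(center), -1)

    cols = ["channel", "start", "end", "peak_sample", "freq", "amplitude",
            "phase0", "shared_id"]
    events = pd.DataFrame(rows, columns=cols).sort_values(
        ["channel", "start"]).reset_index(drop=True)
    truth = GroundTruth(events=events, spike_lock_phase=config.spike_lock_phase)
    return out, truth


# ---------------------------------------------------------------------------
# spikes

def _waveform_template(config: SimConfig) -> np.ndarray:
    k = np.arange(32)
    peak = config.waveform_peak * np.exp(-0.5 * ((k - 9) / 2.0) ** 2)
    trough = config.waveform_trough * np.exp(-0.5 * ((k - 14) / 3.0) ** 2)
    return peak + trough


def gen_locked_spikes(truth: GroundTruth, config: SimConfig,
                      rng: np.random.Generator,
                      n_samples: int | None = None) -> list[SpikeTrain]:
    """Generate per-unit spike trains: Poisson baseline + ripple-locked bursts.

    Units are assigned round-robin to MEA channels.  Within each ripple
    event on the unit's channel, extra spikes are added whose ripple-band
    phases are von Mises distributed around ``spike_lock_phase`` (the
    trough); their expected number scales linearly with event amplitude so
    that larger ripples carry more spikes.  With ``locking_kappa = 0`` the
    in-event phases are uniform.
    """
    if config.locking_kappa < 0:
        raise ValueError("locking_kappa must be non-negative")
    fs = config.sampling_rate
    if n_samples is None:
        n_samples = config.n_samples
    trains: list[SpikeTrain] = []
    template = _waveform_template(config)
    counts: dict[str, int] = {}
    for u in range(config.n_units):
        ch = u % config.n_mea_channels
        n_base = rng.poisson(config.spike_baseline_rate * n_samples / fs)
        idx = list(rng.integers(0, n_samples, size=n_base))
        ev = truth.channel_events(ch)
        for _, row in ev.iterrows():
            n_cycles = max(int(np.floor((row.end - row.start) / fs * row.freq)), 1)
            lam = config.spikes_per_ripple * row.amplitude / config.ripple_amp_median
            n_lock = rng.poisson(lam)
            if n_lock == 0:
                continue
            if config.locking_kappa > 0:
                theta = rng.vonmises(config.spike_lock_phase,
                                     config.locking_kappa, size=n_lock)
            else:
                theta = rng.uniform(-np.pi, np.pi, size=n_lock)
            cycle = rng.integers(0, n_cycles, size=n_lock)
            # plateau phase: phi(t) = 2 pi f (t - start)/fs + phase0
            offs = (np.mod(theta - row.phase0, 2 * np.pi) / (2 * np.pi) + cycle) \
                / row.freq * fs
            t = row.start + np.round(offs).astype(np.int64)
            idx.extend(t[(t >= 0) & (t < n_samples)])
        idx = np.unique(np.asarray(idx, dtype=np.int64))
        unit = f"unit{u:03d}"
        counts[unit] = idx.size
        wf = template[None, :] + rng.normal(
            0.0, config.waveform_noise_sd, size=(idx.size, 32))
        trains.append(SpikeTrain(unit=unit, indices=idx, channel=ch, waveforms=wf))
    truth.spike_counts = counts
    return trains


# ---------------------------------------------------------------------------
# IEDs

def _ied_template(fs: float) -> np.ndarray:
    """Stereotyped biphasic sharp transient, ~50 ms wide, unit peak."""
    t = np.arange(int(round(0.08 * fs))) / fs - 0.04
    w = np.exp(-0.5 * (t / 0.006) ** 2) - 0.6 * np.exp(-0.5 * ((t - 0.015) / 0.012) ** 2)
    return w / np.abs(w).max()


def _insert_ieds(ieeg: TimeSeriesRecording, lfp: TimeSeriesRecording,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    fs = config.sampling_rate
    n = ieeg.n_samples
    count = rng.poisson(config.ied_rate * n / fs)
    if count == 0:
        return np.empty(0, dtype=np.int64)
    tmpl = _ied_template(fs)
    half = tmpl.size // 2
    times = np.sort(rng.integers(half, n - tmpl.size + half, size=count))
    for rec in (ieeg, lfp):
        sds = rec.data.std(axis=1)
        for t0 in times:
            sl = slice(t0 - half, t0 - half + tmpl.size)
            rec.data[:, sl] += config.ied_amp_sd * sds[:, None] * tmpl[None, :]
    return times.astype(np.int64)


# ---------------------------------------------------------------------------
# full session

def build_session(config: SimConfig) -> SyntheticSession:
    """Simulate one full multi-scale session.

    Independent RNG streams (spawned from the master seed) drive trials,
    MEA background, ripple placement, iEEG noise, spiking and IEDs, so each
    component is individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    r_trial, r_bg, r_rip, r_ieeg, r_spk, r_ied = [
        np.random.default_rng(s) for s in ss.spawn(6)]

    trials = config.trial_table(r_trial)
    mea_bg = gen_background(config, config.n_mea_channels, "lfp", r_bg)
    lfp, truth = inject_ripples(mea_bg, config, r_rip, trials)

    ieeg_noise = gen_background(config, config.n_ieeg_channels, "ieeg", r_ieeg)
    w = config.ieeg_mix
    mea_mean = lfp.data.mean(axis=0)
    ieeg = TimeSeriesRecording(
        w * mea_mean[None, :] + (1 - w) * ieeg_noise.data,
        config.sampling_rate, scale="ieeg")

    spikes = gen_locked_spikes(truth, config, r_spk)
    truth.ied_times = _insert_ieds(ieeg, lfp, config, r_ied)
    return SyntheticSession(ieeg=ieeg, lfp=lfp, spikes=spikes, trials=trials,
                            truth=truth, config=config)


def with_params(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
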