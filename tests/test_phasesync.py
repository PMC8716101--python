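"""PPC estimator, Rayleigh test, spike-field spectra and alignment PPC."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import i0, i1

import ripplescale as rs
from ripplescale import phasesync, simgen
from ripplescale.containers import RippleEvent, SpikeTrain
from ripplescale.spectral import band_filter_hilbert

from conftest import make_trials
from oracles import ppc_double_loop

FS = 1000.0


class TestPPC:
    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 201)
            ph = rng.uniform(-np.pi, np.pi, size=n)
            assert abs(rs.ppc_value(ph) - ppc_double_loop(ph)) < 1e-12

    def test_analytic_cases(self):
        assert rs.ppc_value(np.full(17, 0.31)) == pytest.approx(1.0, abs=1e-12)
        assert rs.ppc_value(np.array([0.0, np.pi])) == pytest.approx(-1.0, abs=1e-12)
        four = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert rs.ppc_value(four) == pytest.approx(-1 / 3, abs=1e-12)

    def test_range_and_rotation_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(3, 100)
            ph = rng.uniform(-np.pi, np.pi, size=n)
            v = rs.ppc_value(ph)
            assert -1 / (n - 1) - 1e-12 <= v <= 1 + 1e-12
            c = rng.uniform(0, 2 * np.pi)
            assert rs.ppc_value(ph + c) == pytest.approx(v, abs=1e-10)

    def test_apcd_and_preferred_phase(self):
        ph = np.array([0.1, 0.1, 0.1])
        res = rs.ppc(ph)
        assert res.apcd == pytest.approx(0.0, abs=1e-12)
        assert res.preferred_phase == pytest.approx(0.1, abs=1e-12)
        # antipodal pair: angular distance pi, mod pi = 0
        assert rs.ppc(np.array([0.0, np.pi])).apcd == pytest.approx(0.0, abs=1e-12)

    def test_vonmises_population_identity_smoke(self):
        rng = np.random.default_rng(2)
        kappa = 2.0
        vals = [rs.ppc_value(rng.vonmises(0, kappa, size=40)) for _ in range(600)]
        expected = (i1(kappa) / i0(kappa)) ** 2
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-3

    def test_too_few(self):
        with pytest.raises(ValueError):
            rs.ppc_value(np.array([0.5]))


class TestRayleigh:
    def test_identical_phases(self):
        _, p = rs.rayleigh_test(np.full(100, 1.0))
        assert p < 1e-10

    def test_against_pingouin(self):
        from pingouin import circ_rayleigh
        rng = np.random.default_rng(3)
        for n in (10, 50, 200):
            ph = rng.vonmises(0, 0.5, size=n)
            rbar, p = rs.rayleigh_test(ph)
            z_pg, p_pg = circ_rayleigh(ph)
            assert p == pytest.approx(p_pg, rel=1e-6, abs=1e-12)

    def test_power_at_kappa_two(self):
        rng = np.random.default_rng(4)
        rejections = sum(
            rs.rayleigh_test(rng.vonmises(0, 2.0, size=50))[1] < 1e-3
            for _ in range(200))
        assert rejections / 200 > 0.95

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        ps = [rs.rayleigh_test(rng.uniform(-np.pi, np.pi, size=30))[1]
              for _ in range(600)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def pinned_session():
    """Strongly locked session (kappa = 5, full alignment)."""
    cfg = rs.SimConfig(n_mea_channels=2, n_ieeg_channels=1, n_units=8,
                       trial_count=30, locking_kappa=5.0,
                       cross_channel_alignment=1.0, seed=21)
    s = rs.build_session(cfg)
    phases = phasesync.wavelet_phases(s.lfp, phasesync.default_ppc_freqs(),
                                      sorted({t.channel for t in s.spikes}))
    return s, phases


class TestSpikeFieldSpectrum:
    def test_peak_at_locked_frequency(self, pinned_session):
        s, phases = pinned_session
        freqs, mat, kept = phasesync.spike_field_ppc_spectrum(
            s.spikes, s.lfp, s.trials, phases=phases)
        assert mat.shape[0] == len(kept)
        # restrict to high frequencies: slow-deflection locking from burst
        # clustering legitimately dominates below ~30 Hz.  The 6-cycle
        # wavelet bandwidth and within-burst spike clustering smear (and
        # slightly skew) the peak, so the assertion is band-level.
        hi = freqs > 30
        peak = freqs[hi][np.argmax(mat.mean(axis=0)[hi])]
        assert 79.0 <= peak <= 121.0

    def test_kappa_monotonicity(self):
        vals = {}
        for kappa in (2.0, 6.0):
            cfg = rs.SimConfig(n_mea_channels=2, n_units=4, trial_count=15,
                               locking_kappa=kappa,
                               ripple_freq_range=(99.0, 101.0), seed=22)
            s = rs.build_session(cfg)
            freqs, mat, _ = phasesync.spike_field_ppc_spectrum(
                s.spikes, s.lfp, s.trials)
            idx = np.argmin(np.abs(freqs - 100))
            vals[kappa] = mat.mean(axis=0)[idx]
        assert vals[6.0] > vals[2.0]

    def test_shuffle_zscore_deterministic(self, pinned_session):
        s, phases = pinned_session
        trains = s.spikes[:2]
        out1 = phasesync.zscore_ppc_by_trial_shuffle(
            trains, s.lfp, s.trials, n_shuffle=10, rng=5, phases=phases)
        out2 = phasesync.zscore_ppc_by_trial_shuffle(
            trains, s.lfp, s.trials, n_shuffle=10, rng=5, phases=phases)
        assert np.array_equal(out1[1], out2[1])

    def test_locked_zscore_exceeds_null(self, pinned_session):
        s, phases = pinned_session
        freqs, z, _ = phasesync.zscore_ppc_by_trial_shuffle(
            s.spikes, s.lfp, s.trials, n_shuffle=60, rng=6, phases=phases)
        band = (freqs >= 80) & (freqs <= 120)
        out = (freqs >= 150) & (freqs <= 400)
        assert z[:, band].mean() > 0.5
        assert z[:, band].mean() > z[:, out].mean()


class TestCompareConditions:
    def test_identical_conditions_zero(self, pinned_session):
        s, phases = pinned_session
        freqs = phasesync.default_ppc_freqs()
        all_mask = np.ones(s.lfp.n_samples, dtype=bool)
        diff, kept = phasesync.compare_ppc_conditions(
            s.spikes, s.trials, all_mask, all_mask, phases, freqs)
        assert kept
        assert np.abs(diff.mean(axis=0)).max() < 1e-12

    def test_in_vs_out_ripple_positive_in_band(self, pinned_session):
        s, phases = pinned_session
        freqs = phasesync.default_ppc_freqs()
        in_ev = np.zeros(s.lfp.n_samples, dtype=bool)
        for _, r in s.truth.events.iterrows():
            in_ev[int(r.start):int(r.end)] = True
        diff, kept = phasesync.compare_ppc_conditions(
            s.spikes, s.trials, in_ev, ~in_ev, phases, freqs, rng=7)
        assert len(kept) >= 3
        band = (freqs >= 80) & (freqs <= 120)
        assert diff.mean(axis=0)[band].mean() > 0.02


class TestAlignmentPPC:
    def test_identical_channels_unity(self):
        ph = np.tile(np.linspace(-np.pi, np.pi, 500), (6, 1))
        events = [RippleEvent(0, 100, 160, 130, 4.0, FS)]
        out = phasesync.ripple_alignment_ppc(events, ph)
        assert out[0] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null_matches_simulation(self):
        rng = np.random.default_rng(8)
        n_ch, dur = 12, 40
        events = [RippleEvent(0, i * 100, i * 100 + dur, i * 100 + 20, 4.0, FS)
                  for i in range(200)]
        ph = rng.uniform(-np.pi, np.pi, size=(n_ch, 20100)).astype(np.float32)
        got = phasesync.ripple_alignment_ppc(events, ph)
        # direct max-of-null simulation at same N and duration
        sim = []
        for _ in range(200):
            p = rng.uniform(-np.pi, np.pi, size=(n_ch, dur))
            v = np.abs(np.exp(1j * p).sum(axis=0)) ** 2
            sim.append((((v - n_ch) / (n_ch * (n_ch - 1)))).max())
        ks = stats.ks_2samp(got, sim)
        assert ks.pvalue > 0.01

    def test_channel_restriction(self):
        rng = np.random.default_rng(9)
        ph = rng.uniform(-np.pi, np.pi, size=(4, 1000)).astype(np.float32)
        ph[:2, :] = 0.0  # two perfectly aligned channels
        events = [RippleEvent(0, 100, 150, 120, 4.0, FS)]
        mask = np.zeros((4, 1000), dtype=bool)
        mask[:2] = True
        out = phasesync.ripple_alignment_ppc(events, ph, channel_mask=mask)
        assert out[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_channel_error(self):
        with pytest.raises(ValueError):
            phasesync.ripple_alignment_ppc([], np.zeros((1, 100)))


class TestSTA:
    def test_trough_locked_spikes(self):
        t = np.arange(40000) / FS
        x = np.sin(2 * np.pi * 5 * t)
        ts = rs.TimeSeriesRecording(x[None, :], FS)
        # spikes at the troughs of the 5 Hz wave
        trough_idx = np.flatnonzero(
            (x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])) + 1
        trains = [SpikeTrain("u", trough_idx, channel=0)]
        # window shorter than half the 5 Hz period: only the lag-0 trough fits
        lags, sta, n = phasesync.spike_triggered_average(trains, ts, 0.09)
        assert n == len(trough_idx) - np.sum(
            (trough_idx < 90) | (trough_idx >= 40000 - 90))
        assert abs(lags[np.argmin(sta)]) < 0.01

    def test_amplitude_shrinks_with_n(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100000)
        ts = rs.TimeSeriesRecording(x[None, :], FS)
        amps = []
        for n in (50, 5000):
            idx = np.sort(rng.choice(np.arange(500, 99500), n, replace=False))
            _, sta, _ = phasesync.spike_triggered_average(
                [SpikeTrain("u", idx, channel=0)], ts, 0.1)
            amps.append(np.abs(sta).mean())
        assert amps[1] < amps[0] / 3

    def test_event_restriction_exact_count(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(20000)
        ts = rs.TimeSeriesRecording(x[None, :], FS)
        idx = np.sort(rng.choice(np.arange(500, 19500), 200, replace=False))
        events = [RippleEvent(0, 5000, 10000, 7000, 4.0, FS)]
        inside = ((idx >= 5000) & (idx < 10000)).sum()
        _, _, n_in = phasesync.spike_triggered_average(
            [SpikeTrain("u", idx, channel=0)], ts, 0.1, events=events)
        assert n_in == inside
        _, _, n_out = phasesync.spike_triggered_average(
            [SpikeTrain("u", idx, channel=0)], ts, 0.1, events=events,
            inside=False)
        assert n_out == 200 - inside

    def test_no_spikes_error(self):
        ts = rs.TimeSeriesRecording(np.zeros((1, 1000)), FS)
        with pytest.raises(ValueError):
            phasesync.spike_triggered_average(
                [SpikeTrain("u", [], channel=0)], ts, 0.1)


class TestRayleighAcrossGroups:
    def test_consistent_groups_significant(self):
        rng = np.random.default_rng(30)
        sets = [rng.vonmises(np.pi, 3.0, size=80) for _ in range(12)]
        _, p = phasesync.rayleigh_across_groups(sets)
        assert p < 1e-3

    def test_divergent_groups_nonsignificant(self):
        rng = np.random.default_rng(31)
        # each group tightly locked, but at its own random phase
        sets = [rng.vonmises(rng.uniform(-np.pi, np.pi), 5.0, size=80)
                for _ in range(8)]
        _, p = phasesync.rayleigh_across_groups(sets)
        assert p > 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            phasesync.rayleigh_across_groups([np.zeros(10)])
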