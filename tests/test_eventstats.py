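"""Correlograms, chance normalizations, dip test, cluster permutation,
correlation nulls and meta-analysis."""

import numpy as np
import pytest
from scipy import stats

from ripplescale import eventstats
from ripplescale.containers import SpikeTrain
from ripplescale.dip import dip_from_samples, dip_statistic

from conftest import make_events, make_trials
from oracles import dip_lp

FS = 1000.0


class TestCorrelogram:
    def test_autocorrelogram_excludes_self_pairs(self):
        trials = make_trials(3, 2000)
        ev = make_events([100, 700, 2500, 4100])
        ccg = eventstats.event_cross_correlogram(ev, ev, trials, FS)
        zero_bin = ccg.counts[np.argmin(np.abs(ccg.lags_ms))]
        assert zero_bin == 0

    def test_fixed_shift_mode(self):
        trials = make_trials(5, 2000)
        base = [150 + i * 2000 + j * 300 for i in range(5) for j in range(4)]
        a = make_events(base)
        b = make_events([t + 20 for t in base])
        ccg = eventstats.event_cross_correlogram(a, b, trials, FS)
        assert ccg.lags_ms[np.argmax(ccg.counts)] == pytest.approx(20.0)
        assert ccg.n_pairs >= 20

    def test_independent_uniform_flat(self):
        rng = np.random.default_rng(0)
        trials = make_trials(40, 2000)
        a = make_events(np.sort(np.concatenate(
            [rng.integers(s, e, 8) for s, e in zip(trials.start, trials.end)])))
        b = make_events(np.sort(np.concatenate(
            [rng.integers(s, e, 8) for s, e in zip(trials.start, trials.end)])))
        ccg = eventstats.event_cross_correlogram(a, b, trials, FS,
                                                 max_lag_ms=100, bin_ms=20)
        expected = ccg.counts.sum() / ccg.counts.size
        chi2 = ((ccg.counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=ccg.counts.size - 1)
        assert p > 0.01

    def test_empty_warns(self):
        trials = make_trials(2, 1000)
        with pytest.warns(UserWarning):
            ccg = eventstats.event_cross_correlogram([], make_events([100]),
                                                     trials, FS)
        assert ccg.counts.sum() == 0


class TestShiftPredictor:
    def test_stimulus_locked_matches_truth(self):
        # events at a fixed latency in every trial: trial-independent
        trials = make_trials(30, 2000)
        a = make_events(trials.start + 500)
        b = make_events(trials.start + 520)
        ccg = eventstats.event_cross_correlogram(a, b, trials, FS)
        pred = eventstats.shift_predictor(a, b, trials, FS)
        ratio = eventstats.synchronization_metric(ccg, pred)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_trial_coupled_peak_absent_from_predictor(self):
        rng = np.random.default_rng(1)
        trials = make_trials(30, 2000)
        times = np.array([rng.integers(s + 100, e - 100)
                          for s, e in zip(trials.start, trials.end)])
        a = make_events(times)
        b = make_events(times + 5)
        ccg = eventstats.event_cross_correlogram(a, b, trials, FS)
        pred = eventstats.shift_predictor(a, b, trials, FS)
        i5 = np.argmin(np.abs(ccg.lags_ms - 5))
        assert ccg.counts[i5] >= 25
        assert pred.counts[i5] < 5
        assert eventstats.synchronization_metric(ccg, pred) > 2

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(2)
        trials = make_trials(10, 1500)
        a = make_events(np.sort(rng.integers(0, 15000, 40)))
        b = make_events(np.sort(rng.integers(0, 15000, 40)))
        p1 = eventstats.shift_predictor(a, b, trials, FS)
        # permuting the trial order permutes the same pairings
        perm = rng.permutation(10)
        from ripplescale.containers import TrialTable
        t2 = TrialTable(trials.start[perm], trials.end[perm],
                        trials.align[perm], trials.label[perm])
        p2 = eventstats.shift_predictor(a, b, t2, FS)
        assert np.allclose(p1.counts, p2.counts)

    def test_two_trials_minimum(self):
        with pytest.raises(ValueError):
            eventstats.shift_predictor([], [], make_trials(1, 1000), FS)


class TestSyncMetric:
    def test_equal_correlograms_unity(self):
        lags = np.arange(-100, 101, dtype=float)
        c = eventstats.Correlogram(lags, np.random.default_rng(3).poisson(
            5, lags.size).astype(float), 100)
        assert eventstats.synchronization_metric(c, c) == 1.0

    def test_linearity_and_rescale_invariance(self):
        lags = np.arange(-100, 101, dtype=float)
        counts = np.ones(lags.size)
        base = eventstats.Correlogram(lags, counts, 0)
        doubled = eventstats.Correlogram(lags, 2 * counts, 0)
        assert eventstats.synchronization_metric(doubled, base) == 2.0
        scaled_both = eventstats.synchronization_metric(
            eventstats.Correlogram(lags, 7 * counts, 0),
            eventstats.Correlogram(lags, 7 * counts, 0))
        assert scaled_both == 1.0

    def test_zero_predictor_error(self):
        lags = np.arange(-100, 101, dtype=float)
        c = eventstats.Correlogram(lags, np.ones(lags.size), 0)
        z = eventstats.Correlogram(lags, np.zeros(lags.size), 0)
        with pytest.raises(ValueError):
            eventstats.synchronization_metric(c, z)


class TestCoincidence:
    def test_deterministic_with_seed(self):
        rng = np.random.default_rng(4)
        trials = make_trials(10, 1000)
        a = make_events(np.sort(rng.integers(0, 10000, 30)))
        b = make_events(np.sort(rng.integers(0, 10000, 30)))
        v1 = eventstats.circular_shift_coincidence(a, b, trials, FS,
                                                   n_shift=20, rng=9)
        v2 = eventstats.circular_shift_coincidence(a, b, trials, FS,
                                                   n_shift=20, rng=9)
        assert v1 == v2

    def test_no_events_error(self):
        with pytest.raises(ValueError):
            eventstats.circular_shift_coincidence([], [], make_trials(3, 1000),
                                                  FS)


class TestBurstMetric:
    def test_homogeneous_poisson_near_unity(self):
        rng = np.random.default_rng(5)
        n = 200000
        trains = [SpikeTrain(f"u{i}", np.sort(
            rng.choice(n, 2000, replace=False))) for i in range(3)]
        events = make_events(np.arange(2000, 190000, 2000), dur=50)
        v = eventstats.population_burst_metric(trains, events, n, FS,
                                               n_draws=10, rng=6)
        assert v == pytest.approx(1.0, abs=0.15)

    def test_zero_in_event_spikes(self):
        rng = np.random.default_rng(6)
        n = 50000
        idx = np.sort(rng.choice(np.arange(25000, n), 500, replace=False))
        trains = [SpikeTrain("u", idx)]
        events = make_events(np.arange(1000, 20000, 1000), dur=50)
        v = eventstats.population_burst_metric(trains, events, n, FS, rng=7)
        assert v == 0.0

    def test_no_events_error(self):
        with pytest.raises(ValueError):
            eventstats.population_burst_metric([], [], 1000, FS)


class TestDip:
    def test_matches_lp_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = rng.integers(2, 12)
            x = np.sort(rng.normal(size=m))
            if np.any(np.diff(x) <= 0):
                continue
            w = rng.integers(1, 6, size=m).astype(float)
            assert dip_statistic(x, w) == pytest.approx(dip_lp(x, w), abs=1e-7)

    def test_known_values(self):
        assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(0.25, abs=1e-8)
        n = 10
        assert dip_statistic(np.arange(float(n))) == pytest.approx(
            1 / (2 * n), abs=1e-8)
        assert dip_statistic(np.array([0.0, 0.5, 1.0])) == pytest.approx(
            1 / 6, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.normal(size=30))
        d1 = dip_from_samples(x)
        d2 = dip_from_samples(3.7 * x - 11.0)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_bimodal_exceeds_unimodal_z(self):
        rng = np.random.default_rng(9)
        n = 2000
        uni = rng.normal(size=n)
        bi = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)])
        cache = {}
        z_uni = eventstats.dip_bimodality_z(uni, n_null=150, rng=10,
                                            null_cache=cache)
        z_bi = eventstats.dip_bimodality_z(bi, n_null=150, rng=11,
                                           null_cache=cache)
        assert z_bi > 5
        assert z_uni < z_bi

    def test_errors(self):
        with pytest.raises(ValueError):
            eventstats.dip_bimodality_z(np.ones(100))
        with pytest.raises(ValueError):
            eventstats.dip_bimodality_z(np.arange(5))


class TestClusterPermutation:
    def test_all_zero_no_clusters(self):
        out = eventstats.cluster_permutation_across_frequencies(
            np.zeros((6, 60)), n_perm=100)
        assert out["clusters"] == []

    def test_injected_effect_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(40):
            vals = rng.standard_normal((6, 60))
            vals[:, 20:30] += 2.0  # effect size d = 2
            out = eventstats.cluster_permutation_across_frequencies(
                vals, n_perm=500, rng=rng)
            hits += any(c["significant"] and not (c["end"] <= 20 or c["start"] >= 30)
                        for c in out["clusters"])
        assert hits / 40 >= 0.95

    def test_exhaustive_flip_determinism(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal((5, 30))
        a = eventstats.cluster_permutation_across_frequencies(vals, rng=1)
        b = eventstats.cluster_permutation_across_frequencies(vals, rng=2)
        # 2^5 = 32 <= n_perm: exhaustive enumeration, rng-independent
        assert np.array_equal(a["null_max"], b["null_max"])

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            eventstats.cluster_permutation_across_frequencies(np.zeros((2, 10)))


class TestWindowedCorrelation:
    def test_identical_series(self):
        x = np.random.default_rng(14).standard_normal(50000)
        assert eventstats.windowed_amplitude_spike_correlation(
            x, x.copy(), FS) == pytest.approx(1.0, abs=1e-9)

    def test_independent_series(self):
        rng = np.random.default_rng(15)
        r = eventstats.windowed_amplitude_spike_correlation(
            rng.standard_normal(100000), rng.standard_normal(100000), FS)
        assert abs(r) < 0.1

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(16)
        n_win, win = 1000, 100
        z = rng.standard_normal(n_win)
        a = np.repeat(z, win) + 0 * rng.standard_normal(n_win * win)
        rho = 0.6
        b = np.repeat(rho * z + np.sqrt(1 - rho ** 2)
                      * rng.standard_normal(n_win), win)
        r = eventstats.windowed_amplitude_spike_correlation(a, b, FS)
        assert r == pytest.approx(0.6, abs=0.06)

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            eventstats.windowed_amplitude_spike_correlation(
                np.ones(150), np.ones(150), FS)


class TestCircularShiftNull:
    def test_zero_shift_excluded(self):
        trials = make_trials(4, 5000)
        rng = np.random.default_rng(17)
        idx = np.sort(rng.choice(20000, 50, replace=False))
        train = SpikeTrain("u", idx)

        def stat(trains):
            # 1.0 when any permutation reproduces the original train exactly
            return float(np.array_equal(trains[0].indices, idx))

        out = eventstats.circular_shift_correlation_null(
            stat, [train], trials, n_perm=200, rng=18)
        assert out["r_true"] == 1.0
        assert out["null"].max() == 0.0

    def test_true_effect_detected(self, locked_session):
        from ripplescale import ripples, spikes as spk
        from ripplescale.spectral import band_filter_hilbert
        s = locked_session
        amp, _ = band_filter_hilbert(s.lfp.data[0], (80, 120), FS)
        n = s.lfp.n_samples

        def stat(trains):
            rate = np.sum([spk.smoothed_spike_rate(t, n, FS)
                           for t in trains], axis=0)
            return eventstats.windowed_amplitude_spike_correlation(
                amp, rate, FS)

        out = eventstats.circular_shift_correlation_null(
            stat, s.spikes, s.trials, n_perm=60, rng=19)
        assert out["r_true"] > out["null_mean"]
        assert out["p"] < 0.05


class TestFisherAndMeta:
    def test_fisher_z_values(self):
        assert eventstats.fisher_z(0.0) == 0.0
        assert eventstats.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert eventstats.fisher_z(-0.3) == -eventstats.fisher_z(0.3)
        with pytest.raises(ValueError):
            eventstats.fisher_z(1.0)

    def test_r_equivalent_variance(self):
        rec = eventstats.r_equivalent(0.5, np.array([0.0, 0.1, -0.1, 0.05]),
                                      n=103, participant="p")
        assert rec.variance == pytest.approx(1 / 100)

    def test_reml_matches_metafor_oracle(self):
        # frozen oracle: R metafor rma(method="REML") on this exact input
        y = np.array([0.3294789972, 0.7202631565, 0.5165469893, -0.0701209601,
                      0.4022922402, -0.1654404917, 0.6899024659, 0.2775893505,
                      0.2467222775, 0.0442482033, 0.7352378421, 0.2264047444])
        v = np.array([0.1593120887, 0.0989981192, 0.1745476256, 0.1455262452,
                      0.0369519226, 0.1956120233, 0.1570051464, 0.1614915749,
                      0.0430604539, 0.1010694688, 0.0867436444, 0.1868176980])
        recs = [eventstats.EffectRecord(f"s{i}", y[i], v[i], 50)
                for i in range(12)]
        m = eventstats.random_effects_meta(recs)
        assert m["pooled"] == pytest.approx(0.3542932184, abs=1e-6)
        assert m["tau2"] == pytest.approx(0.0, abs=1e-6)
        assert m["se"] == pytest.approx(0.0899067116, abs=1e-6)
        # heterogeneous variant of the same data
        y2 = y + np.tile([0.5, -0.5], 6)
        m2 = eventstats.random_effects_meta(
            [eventstats.EffectRecord(f"s{i}", y2[i], v[i], 50)
             for i in range(12)])
        assert m2["pooled"] == pytest.approx(0.3576025149, abs=1e-6)
        assert m2["tau2"] == pytest.approx(0.3903845888, abs=1e-5)
        assert m2["se"] == pytest.approx(0.2069265061, abs=1e-6)

    def test_identical_effects(self):
        recs = [eventstats.EffectRecord(f"s{i}", 0.42, 0.1, 50)
                for i in range(5)]
        m = eventstats.random_effects_meta(recs)
        assert m["pooled"] == pytest.approx(0.42, abs=1e-10)
        assert m["tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_two_identical_studies(self):
        recs = [eventstats.EffectRecord("a", 0.2, 0.05, 30),
                eventstats.EffectRecord("b", 0.2, 0.05, 30)]
        assert eventstats.random_effects_meta(recs)["pooled"] == pytest.approx(0.2)

    def test_errors(self):
        with pytest.raises(ValueError):
            eventstats.EffectRecord("a", 0.1, -1.0, 10)
        with pytest.raises(ValueError):
            eventstats.random_effects_meta(
                [eventstats.EffectRecord("a", 0.1, 0.1, 10)])
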