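"""Event-level statistics: cross-correlograms with shift predictors,
synchronization / coincidence / burst ratios, dip-test bimodality,
cluster-based permutation across frequencies, windowed correlations with
circular-shift nulls, Fisher z and random-effects meta-analysis.

Chance normalization conventions
--------------------------------
* The *shift predictor* is the cross-correlogram of event times from
  mismatched trials: it captures stimulus-locked but trial-independent
  coincidence.  The synchronization metric is the ratio of true to
  predictor correlogram mass in a +/-50 ms window; 1 means chance.
* Circular-shift nulls rotate event or spike times uniformly within each
  trial, preserving within-trial structure while destroying cross-signal
  alignment; permutation p-values use the (b + 1) / (n + 1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import RippleEvent, SpikeTrain, TrialTable
from .dip import dip_statistic

__all__ = ["Correlogram", "EffectRecord", "event_cross_correlogram",
           "shift_predictor", "synchronization_metric",
           "circular_shift_coincidence", "population_burst_metric",
           "dip_bimodality_z", "cluster_permutation_across_frequencies",
           "windowed_amplitude_spike_correlation",
           "circular_shift_correlation_null", "fisher_z", "r_equivalent",
           "random_effects_meta"]


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    counts: np.ndarray
    n_pairs: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.counts.shape != self.lags_ms.shape:
            raise ValueError("lag grid and counts must match")

    def window_sum(self, window_ms: float) -> float:
        sel = np.abs(self.lags_ms) <= window_ms
        return float(self.counts[sel].sum())

    def window_mean(self, window_ms: float) -> float:
        sel = np.abs(self.lags_ms) <= window_ms
        return float(self.counts[sel].mean())


@dataclass
class EffectRecord:
    """Per-participant correlation-scale effect for meta-analysis."""
    participant: str
    effect: float          # r-equivalent (shuffle-z-scored correlation)
    variance: float        # sampling variance, default 1/(n-3)
    n: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("sampling variance must be positive")


def _lag_grid(max_lag_ms: float, bin_ms: float) -> np.ndarray:
    n = int(round(max_lag_ms / bin_ms))
    return np.arange(-n, n + 1, dtype=float) * float(bin_ms)


def _hist_lags(diffs_ms: np.ndarray, max_lag_ms: float, bin_ms: float
               ) -> np.ndarray:
    lags = _lag_grid(max_lag_ms, bin_ms)
    edges = np.concatenate([lags - bin_ms / 2, [lags[-1] + bin_ms / 2]])
    counts, _ = np.histogram(diffs_ms, bins=edges)
    return counts.astype(float)


def _peaks_by_trial(events: list[RippleEvent] | np.ndarray, trials: TrialTable,
                    fs: float) -> list[np.ndarray]:
    """Event peak times in ms relative to each trial start."""
    if isinstance(events, np.ndarray):
        peaks = events
    else:
        peaks = np.array([e.peak_sample for e in events], dtype=float)
    out = []
    for s, e in zip(trials.start, trials.end):
        sel = peaks[(peaks >= s) & (peaks < e)]
        out.append((sel - s) / fs * 1000.0)
    return out


def event_cross_correlogram(events_a, events_b, trials: TrialTable, fs: float,
                            max_lag_ms: float = 200.0, bin_ms: float = 1.0,
                            exclude_self: bool | None = None) -> Correlogram:
    """Histogram of within-trial peak-time differences (B relative to A).

    Correlograms are pooled across trials.  When A and B are the same
    event train (auto-correlogram) self-pairs are excluded.
    """
    same = events_a is events_b
    if exclude_self is None:
        exclude_self = same
    a_tr = _peaks_by_trial(events_a, trials, fs)
    b_tr = a_tr if same else _peaks_by_trial(events_b, trials, fs)
    lags = _lag_grid(max_lag_ms, bin_ms)
    counts = np.zeros_like(lags)
    n_pairs = 0
    if not any(len(a) for a in a_tr) or not any(len(b) for b in b_tr):
        warnings.warn("empty event set: zero correlogram")
        return Correlogram(lags, counts, 0)
    for a, b in zip(a_tr, b_tr):
        if not a.size or not b.size:
            continue
        d = b[None, :] - a[:, None]
        if exclude_self and same:
            d = d[~np.eye(a.size, dtype=bool)]
        d = d.ravel()
        d = d[np.abs(d) <= max_lag_ms + bin_ms / 2]
        counts += _hist_lags(d, max_lag_ms, bin_ms)
        n_pairs += d.size
    return Correlogram(lags, counts, n_pairs)


def shift_predictor(events_a, events_b, trials: TrialTable, fs: float,
                    max_lag_ms: float = 200.0, bin_ms: float = 1.0
                    ) -> Correlogram:
    """Chance correlogram from trial-mismatched pairings.

    For each trial, its A events (times relative to trial onset) are
    cross-correlated with the B events of every *other* trial; the n-1
    correlograms are averaged per trial and then across trials.
    """
    if trials.n_trials < 2:
        raise ValueError("shift predictor requires >= 2 trials")
    a_tr = _peaks_by_trial(events_a, trials, fs)
    b_tr = _peaks_by_trial(events_b, trials, fs)
    lags = _lag_grid(max_lag_ms, bin_ms)
    total = np.zeros_like(lags)
    n = trials.n_trials
    for i in range(n):
        if not a_tr[i].size:
            continue
        acc = np.zeros_like(lags)
        for j in range(n):
            if j == i or not b_tr[j].size:
                continue
            d = (b_tr[j][None, :] - a_tr[i][:, None]).ravel()
            acc += _hist_lags(d, max_lag_ms, bin_ms)
        total += acc / (n - 1)
    return Correlogram(lags, total, int(total.sum()), "shift_predictor")


def synchronization_metric(true_ccg: Correlogram, predictor: Correlogram,
                           window_ms: float = 50.0) -> float:
    """Ratio of true to chance correlogram mass in a +/-window; 1 = chance."""
    if not np.array_equal(true_ccg.lags_ms, predictor.lags_ms):
        raise ValueError("correlograms must share the lag grid")
    denom = predictor.window_sum(window_ms)
    if denom == 0:
        raise ValueError("zero predictor mass in the window")
    return true_ccg.window_sum(window_ms) / denom


def circular_shift_coincidence(lfp_events, ieeg_events, trials: TrialTable,
                               fs: float, window_ms: float = 50.0,
                               n_shift: int = 200, max_lag_ms: float = 200.0,
                               bin_ms: float = 1.0,
                               rng: np.random.Generator | int | None = 0
                               ) -> float:
    """Cross-scale coincidence ratio against a circular-shift null.

    Chance correlograms are built by uniformly circularly shifting the
    micro-scale (LFP) event times within each trial; the statistic is the
    ratio of windowed average correlogram mass, 1 = chance.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    true_ccg = event_cross_correlogram(lfp_events, ieeg_events, trials, fs,
                                       max_lag_ms, bin_ms)
    if true_ccg.n_pairs == 0:
        raise ValueError("no event pairs for coincidence metric")
    lfp_tr = _peaks_by_trial(lfp_events, trials, fs)
    ieeg_tr = _peaks_by_trial(ieeg_events, trials, fs)
    lens_ms = (trials.end - trials.start) / fs * 1000.0
    lags = _lag_grid(max_lag_ms, bin_ms)
    chance = np.zeros_like(lags)
    for _ in range(n_shift):
        acc = np.zeros_like(lags)
        for a, b, L in zip(lfp_tr, ieeg_tr, lens_ms):
            if not a.size or not b.size:
                continue
            shifted = np.mod(a + rng.uniform(0, L), L)
            d = (b[None, :] - shifted[:, None]).ravel()
            acc += _hist_lags(d, max_lag_ms, bin_ms)
        chance += acc
    chance /= n_shift
    sel = np.abs(lags) <= window_ms
    denom = chance[sel].mean()
    if denom == 0:
        raise ValueError("empty chance correlogram")
    return float(true_ccg.counts[sel].mean() / denom)


def population_burst_metric(trains: list[SpikeTrain], events: list[RippleEvent],
                            n_samples: int, fs: float, window_ms: float = 25.0,
                            max_lag_ms: float = 100.0, bin_ms: float = 1.0,
                            n_draws: int = 5,
                            rng: np.random.Generator | int | None = 0) -> float:
    """In-ripple population-spiking autocorrelogram mass vs matched windows.

    The spike trains are summed into a population train; its
    autocorrelogram is accumulated over event windows and over random
    duration-matched windows drawn between events; the metric is the ratio
    of the +/-window averages (0 when no in-event spikes, ~1 for
    event-independent spiking).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not events:
        raise ValueError("no events")
    pop = np.sort(np.concatenate([t.indices for t in trains]))
    ev = sorted(events, key=lambda e: e.start)
    in_event = np.zeros(n_samples, dtype=bool)
    for e in ev:
        in_event[e.start:e.end] = True

    def autocorr_in(start: int, end: int) -> np.ndarray:
        sel = pop[(pop >= start) & (pop < end)]
        if sel.size < 2:
            return np.zeros(_lag_grid(max_lag_ms, bin_ms).size)
        d = (sel[None, :] - sel[:, None]).astype(float)
        d = d[~np.eye(sel.size, dtype=bool)] / fs * 1000.0
        return _hist_lags(d, max_lag_ms, bin_ms)

    lags = _lag_grid(max_lag_ms, bin_ms)
    true_acc = np.zeros_like(lags)
    for e in ev:
        true_acc += autocorr_in(e.start, e.end)

    # duration-matched control windows between events
    gaps = []
    prev = 0
    for e in ev:
        if e.start - prev > 0:
            gaps.append((prev, e.start))
        prev = max(prev, e.end)
    if prev < n_samples:
        gaps.append((prev, n_samples))
    chance_acc = np.zeros_like(lags)
    for e in ev:
        dur = e.end - e.start
        ok = [(s, t) for s, t in gaps if t - s >= dur]
        if not ok:
            raise ValueError("no between-event room for a matched window")
        draw = np.zeros_like(lags)
        for _ in range(n_draws):
            s, t = ok[rng.integers(len(ok))]
            w0 = int(rng.integers(s, t - dur + 1))
            draw += autocorr_in(w0, w0 + dur)
        chance_acc += draw / n_draws

    sel = np.abs(lags) <= window_ms
    denom = chance_acc[sel].mean()
    if denom == 0:
        # no chance spikes at all: fall back to overall rate expectation
        raise ValueError("empty chance autocorrelogram")
    return float(true_acc[sel].mean() / denom)


# ---------------------------------------------------------------------------
# bimodality

def dip_bimodality_z(samples: np.ndarray, bins: int = 200,
                     n_null: int = 10000,
                     rng: np.random.Generator | int | None = 0,
                     null_cache: dict | None = None) -> float:
    """Z-scored dip statistic of the binned sample distribution.

    The dip is computed on a ``bins``-bin probability density over the
    sample range; the null is the dip of equally many samples from a
    uniform density, binned identically.  ``null_cache`` (an externally
    held dict) lets repeated calls with the same (n, bins, n_null) reuse
    the null moments.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(samples) == 0:
        raise ValueError("zero-range sample")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts, edges = np.histogram(samples, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    d_true = dip_statistic(centers[keep], counts[keep].astype(float))

    key = (samples.size, bins, n_null)
    if null_cache is not None and key in null_cache:
        mu, sd = null_cache[key]
    else:
        n = samples.size
        grid = np.arange(bins, dtype=float)
        null = np.empty(n_null)
        for i in range(n_null):
            c = np.bincount(rng.integers(0, bins, size=n), minlength=bins)
            k = c > 0
            null[i] = dip_statistic(grid[k], c[k].astype(float))
        mu, sd = null.mean(), null.std()
        if null_cache is not None:
            null_cache[key] = (mu, sd)
    if sd == 0:
        raise ValueError("degenerate dip null")
    return float((d_true - mu) / sd)


# ---------------------------------------------------------------------------
# cluster permutation

def cluster_permutation_across_frequencies(values: np.ndarray,
                                           n_perm: int = 1000,
                                           alpha: float = 0.05,
                                           cluster_alpha: float = 0.05,
                                           rng: np.random.Generator | int | None = 0,
                                           tail: int = 0) -> dict:
    """Sign-flip cluster permutation of participant x frequency values.

    Per frequency a one-sample t statistic against zero is computed;
    adjacent frequencies significant at ``alpha`` form clusters whose
    statistic is the sum of t values.  The null retains the maximum
    |cluster statistic| from each sign-flip permutation (enumerated
    exhaustively when ``2^k <= n_perm``); cluster p-values are exceedance
    fractions with the (b+1)/(n+1) convention.  The two-condition paired
    design reduces to this by passing A - B differences.
    """
    from scipy import stats

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need >= 3 participants (rows)")
    k, n_freq = values.shape
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_crit = stats.t.ppf(1 - alpha / 2, df=k - 1)

    def tstat(v: np.ndarray) -> np.ndarray:
        mu = v.mean(axis=0)
        se = v.std(axis=0, ddof=1) / np.sqrt(k)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mu / se, 0.0)
        return t

    def clusters_of(t: np.ndarray) -> list[tuple[int, int, float]]:
        sig = np.abs(t) > t_crit
        if tail > 0:
            sig &= t > 0
        elif tail < 0:
            sig &= t < 0
        out = []
        i = 0
        while i < n_freq:
            if sig[i]:
                j = i
                while j < n_freq and sig[j] and np.sign(t[j]) == np.sign(t[i]):
                    j += 1
                out.append((i, j, float(t[i:j].sum())))
                i = j
            else:
                i += 1
        return out

    t_obs = tstat(values)
    obs_clusters = clusters_of(t_obs)

    exhaustive = 2 ** k <= n_perm
    if exhaustive:
        flips = np.array(list(np.ndindex(*([2] * k)))) * 2 - 1
    else:
        flips = rng.integers(0, 2, size=(n_perm, k)) * 2 - 1
    null_max = np.zeros(len(flips))
    for i, f in enumerate(flips):
        cl = clusters_of(tstat(values * f[:, None]))
        null_max[i] = max((abs(c[2]) for c in cl), default=0.0)

    results = []
    for (i0, i1, cstat) in obs_clusters:
        # Exhaustive enumeration: the 2^k orbit is heavily discrete (flips
        # come in +/- pairs with identical max statistics), so the usual
        # >=-counting p can only attain multiples of 1/2^(k-1) and is far
        # from nominal levels at small k.  The mid-p convention (half
        # weight on ties, which include the identity flip) is the standard
        # correction for such discreteness and is never zero.  Sampled
        # permutations use the (b+1)/(n+1) convention.
        if exhaustive:
            gt = int(np.sum(null_max > abs(cstat)))
            eq = int(np.sum(null_max == abs(cstat)))
            p = (gt + 0.5 * max(eq, 1)) / len(flips)
        else:
            b = int(np.sum(null_max >= abs(cstat)))
            p = (b + 1) / (len(flips) + 1)
        results.append({"start": i0, "end": i1, "stat": cstat, "p": p,
                        "significant": p < cluster_alpha})
    return {"t": t_obs, "clusters": results, "null_max": null_max}


# ---------------------------------------------------------------------------
# windowed correlation and circular-shift nulls

def windowed_amplitude_spike_correlation(amplitude: np.ndarray,
                                         rate: np.ndarray, fs: float,
                                         window_ms: float = 100.0,
                                         sample_mask: np.ndarray | None = None
                                         ) -> float:
    """Pearson r between window means of z-scored amplitude and spike rate.

    Both series are z-scored over the retained samples, averaged in
    non-overlapping windows (default 100 ms) and correlated.
    """
    from scipy.stats import pearsonr

    if amplitude.shape != rate.shape:
        raise ValueError("series must be aligned")
    win = int(round(window_ms / 1000.0 * fs))
    n_win = amplitude.size // win
    if n_win < 3:
        raise ValueError("need >= 3 windows")

    def windowed(x: np.ndarray) -> np.ndarray:
        z = (x - x.mean()) / x.std()
        return z[: n_win * win].reshape(n_win, win).mean(axis=1)

    a, r = windowed(amplitude), windowed(rate)
    if sample_mask is not None:
        keep = sample_mask[: n_win * win].reshape(n_win, win).all(axis=1)
        a, r = a[keep], r[keep]
    return float(pearsonr(a, r)[0])


def circular_shift_correlation_null(statistic, trains: list[SpikeTrain],
                                    trials: TrialTable, n_perm: int = 1000,
                                    rng: np.random.Generator | int | None = 0
                                    ) -> dict:
    """Generic circular-shift permutation null for spike-based correlations.

    ``statistic`` is a callable mapping a list of spike trains to a scalar
    (e.g. the correlation of per-event amplitude with in-event spike rate).
    Each permutation applies an independent uniform circular shift (never
    zero) to the spike indices within every trial of every train and
    recomputes the statistic.  Returns the true value, null mean and the
    exceedance p-value with the (b+1)/(n+1) convention.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: p-values are coarse")
    r_true = float(statistic(trains))
    null = np.empty(n_perm)
    for p in range(n_perm):
        shifted_trains = []
        for train in trains:
            idx = train.indices.copy()
            for s, e in zip(trials.start, trials.end):
                sel = (idx >= s) & (idx < e)
                if not sel.any():
                    continue
                length = e - s
                shift = int(rng.integers(1, length))  # zero shift excluded
                idx[sel] = s + (idx[sel] - s + shift) % length
            shifted_trains.append(
                SpikeTrain(train.unit, np.unique(idx), train.channel))
        null[p] = statistic(shifted_trains)
    b = int(np.sum(null >= r_true))
    return {"r_true": r_true, "null_mean": float(null.mean()),
            "null": null, "p": (b + 1) / (n_perm + 1)}


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing z-transform of a correlation, ``atanh(r)``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def r_equivalent(r_true: float, null_r: np.ndarray, n: int,
                 participant: str = "") -> EffectRecord:
    """Correlation effect size: the true r z-scored against its shuffle
    null, with sampling variance 1/(n-3)."""
    null_r = np.asarray(null_r, dtype=float)
    sd = null_r.std()
    if sd == 0:
        raise ValueError("degenerate shuffle null")
    if n <= 3:
        raise ValueError("need n > 3 for the 1/(n-3) variance")
    z = (r_true - null_r.mean()) / sd
    return EffectRecord(participant=participant, effect=float(z),
                        variance=1.0 / (n - 3), n=n)


# ---------------------------------------------------------------------------
# random-effects meta-analysis (REML)

def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                        + np.sum(w * (y - mu) ** 2)))


def random_effects_meta(effects: list[EffectRecord]) -> dict:
    """Random-effects pooling with REML between-study variance.

    The between-study variance tau^2 maximizes the restricted likelihood;
    the pooled mean is inverse-variance weighted with weights
    ``1 / (v_i + tau^2)``.  Returns the pooled estimate, its SE and 95% CI,
    tau^2, and a forest-plot-ready per-study table.
    """
    if len(effects) < 2:
        raise ValueError("meta-analysis requires >= 2 studies")
    y = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("non-positive sampling variance")
    upper = max(10.0 * y.var(ddof=1) if y.var() > 0 else 1.0, 1e-3)
    res = minimize_scalar(_reml_nll, bounds=(0.0, upper), args=(y, v),
                          method="bounded",
                          options={"xatol": 1e-12})
    tau2 = float(res.x)
    if _reml_nll(0.0, y, v) <= res.fun:
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    table = pd.DataFrame({
        "participant": [e.participant for e in effects],
        "effect": y,
        "ci_low": y - 1.96 * np.sqrt(v),
        "ci_high": y + 1.96 * np.sqrt(v),
        "weight": w / w.sum(),
    })
    return {"pooled": pooled, "se": se,
            "ci": (pooled - 1.96 * se, pooled + 1.96 * se),
            "tau2": tau2, "table": table}
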