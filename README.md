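# ripplescale

Multi-scale analysis of transient ripple oscillations (80–120 Hz) in
simultaneous macro-scale intracranial EEG (iEEG) and micro-scale
microelectrode-array (MEA) recordings, together with the spiking activity
of single units.  The package is aimed at electrophysiologists who want a
tested, reusable implementation of the full analysis chain linking
broadband high-frequency activity to discrete ripple events and to the
number, synchrony and phase of underlying spikes — plus a synthetic
session generator with complete ground truth, so every statistic in the
chain can be validated against known effects.

## What it computes

**Detection.** Ripples are detected from the band-passed (80–120 Hz,
second-order Butterworth, zero phase) Hilbert envelope: candidate
intervals where the envelope exceeds 2 SD above the mean amplitude of the
filtered trace, merged when separated by < 15 ms, kept when ≥ 25 ms long
with a peak > 3 SD (strict preset).  A relaxed preset (1 SD / 2 SD /
10 ms) exposes the continuum of smaller, shorter events.  An independent
1/f-referenced detector finds narrowband episodes against a robust
log–log background fit, with instantaneous frequency by frequency
sliding.

**Phase locking.**  The pairwise phase consistency (PPC) of a phase
sample θ₁…θ_N is the mean pairwise cosine

    γ̂ = 2 / (N(N−1)) · Σ_{j<k} cos(θ_j − θ_k),

computed via unit vectors as (|Σ e^{iθ}|² − N)/(N(N−1)); its population
value equals the squared phase-locking value and it carries no
sample-size bias.  PPC is used for spike–field locking spectra (60
log-spaced wavelet frequencies, 2–400 Hz, per trial then averaged, z-scored
against trial-shuffle nulls), for cross-channel ripple-phase alignment
within macro-scale ripples, and for condition contrasts with spike-count
matched subsampling.  Phase convention: the band-passed trough is φ = π.

**Event statistics.**  Cross-correlograms of event peak times with
shift-predictor normalization (synchronization metric: windowed true /
chance mass, 1 = chance), circular-shift coincidence across spatial
scales, a population-spiking burst metric inside vs between ripples,
Hartigan's dip test of bimodality (on a 200-bin density, z-scored against
uniform nulls), sign-flip cluster permutation across frequencies, and a
REML random-effects meta-analysis of per-participant correlation effects
(r-equivalent with sampling variance 1/(n−3)).

## Worked example

```python
import ripplescale as rs
from ripplescale import phasesync
from ripplescale.spectral import band_filter_hilbert

cfg = rs.SimConfig(n_mea_channels=4, n_ieeg_channels=2, n_units=8,
                   trial_count=20, cross_channel_alignment=1.0,
                   locking_kappa=5.0, seed=7)
session = rs.build_session(cfg)

events = rs.detect_ripples(session.lfp, rs.STRICT, channels=[0])
print(len(events), "strict ripples on LFP channel 0")

_, phases = band_filter_hilbert(session.lfp.data, (80, 120), cfg.sampling_rate)
ieeg_events = rs.detect_ripples(session.ieeg, rs.STRICT, channels=[0])
align = phasesync.ripple_alignment_ppc(ieeg_events, phases)
print("mean cross-channel PPC within iEEG ripples: %.2f" % align.mean())
```

prints

```
7 strict ripples on LFP channel 0
mean cross-channel PPC within iEEG ripples: 0.97
```

Seven events pass the strict thresholds in ~100 s of micro-scale signal
(most simulated ripples deliberately sit below them — the relaxed preset
finds those), and because every simulated ripple here is shared (time-
and phase-aligned) across the array, the micro-electrode phases inside
macro-scale ripples are nearly perfectly consistent (PPC close to 1;
chance level is 0).  Regenerating the session with
`cross_channel_alignment=0` drops the alignment PPC to its noise floor.

The same chain runs end to end over a simulated cohort from the command
line:

```
ripplescale run --seed 1 --participants 3 --out report.json
ripplescale simulate --seed 1 --out session.h5
ripplescale detect --in session.h5 --scale lfp --preset relaxed --out events.tsv
```

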