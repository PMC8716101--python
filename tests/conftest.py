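import numpy as np
import pytest

import ripplescale as rs
from ripplescale import simgen
from ripplescale.containers import RippleEvent, TrialTable


@pytest.fixture(scope="session")
def medium_session():
    """Shared mid-sized session: 4 MEA channels, 2 iEEG, 60 trials (~300 s)."""
    cfg = rs.SimConfig(n_mea_channels=4, n_ieeg_channels=2, n_units=6,
                       trial_count=90, seed=2024)
    return rs.build_session(cfg)


@pytest.fixture(scope="session")
def locked_session():
    """Strong-effect session: full alignment, kappa = 5."""
    cfg = rs.SimConfig(n_mea_channels=4, n_ieeg_channels=2, n_units=8,
                       trial_count=20, cross_channel_alignment=1.0,
                       locking_kappa=5.0, seed=7)
    return rs.build_session(cfg)


def make_trials(n_trials: int, trial_len: int, gap: int = 0,
                offset: int = 0) -> TrialTable:
    starts = offset + np.arange(n_trials) * (trial_len + gap)
    return TrialTable(starts, starts + trial_len,
                      starts + int(trial_len * 0.75),
                      np.array(["correct"] * n_trials, dtype=object))


def make_events(times, fs=1000.0, channel=0, dur=30):
    return [RippleEvent(channel, int(t), int(t) + dur, int(t) + dur // 2,
                        4.0, fs) for t in times]


def recall_fraction(events, truth, min_amp=3.5, min_dur_ms=30.0):
    """Fraction of eligible truth events overlapped by a detected event."""
    elig = truth[(truth.amplitude >= min_amp)
                 & ((truth.end - truth.start) >= min_dur_ms)]
    if not len(elig):
        return np.nan, 0
    by_ch = {}
    for e in events:
        by_ch.setdefault(e.channel, []).append(e)
    hits = sum(
        any(e.start < row.end and row.start < e.end
            for e in by_ch.get(int(row.channel), []))
        for _, row in elig.iterrows())
    return hits / len(elig), len(elig)
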