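"""HDF5 session layout and tabular exports.

Layout::

    /ieeg, /lfp     datasets (channels x samples); attrs: sampling_rate, scale
    /spikes/unit<k> spike sample indices; optional "waveforms" (n x 32)
    /trials         start / end / align / label columns
    /truth          ground-truth event table and IED times (simulated data)

Event and trial tables are also exportable as TSV via pandas.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .containers import (GroundTruth, SpikeTrain, SyntheticSession,
                         TimeSeriesRecording, TrialTable)

__all__ = ["save_session", "load_session"]


def save_session(path: str, session: SyntheticSession) -> None:
    with h5py.File(path, "w") as f:
        for name, rec in (("ieeg", session.ieeg), ("lfp", session.lfp)):
            d = f.create_dataset(name, data=rec.data)
            d.attrs["sampling_rate"] = rec.fs
            d.attrs["scale"] = rec.scale
            d.attrs["channels"] = json.dumps(rec.channels)
        g = f.create_group("spikes")
        for train in session.spikes:
            u = g.create_group(train.unit)
            u.create_dataset("indices", data=train.indices)
            u.attrs["channel"] = train.channel
            if train.waveforms is not None:
                u.create_dataset("waveforms", data=train.waveforms)
        t = f.create_group("trials")
        t.create_dataset("start", data=session.trials.start)
        t.create_dataset("end", data=session.trials.end)
        t.create_dataset("align", data=session.trials.align)
        t.create_dataset("label", data=np.array(
            [str(x) for x in session.trials.label], dtype="S16"))
        tr = f.create_group("truth")
        tr.create_dataset("ied_times", data=session.truth.ied_times)
        tr.attrs["spike_lock_phase"] = session.truth.spike_lock_phase
        ev = session.truth.events
        for col in ev.columns:
            tr.create_dataset(f"events/{col}", data=ev[col].to_numpy())


def load_session(path: str) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        recs = {}
        for name in ("ieeg", "lfp"):
            d = f[name]
            recs[name] = TimeSeriesRecording(
                d[()], float(d.attrs["sampling_rate"]),
                json.loads(d.attrs["channels"]), str(d.attrs["scale"]))
        spikes = []
        for unit in sorted(f["spikes"]):
            u = f["spikes"][unit]
            wf = u["waveforms"][()] if "waveforms" in u else None
            spikes.append(SpikeTrain(unit, u["indices"][()],
                                     int(u.attrs["channel"]), wf))
        t = f["trials"]
        trials = TrialTable(t["start"][()], t["end"][()], t["align"][()],
                            np.array([s.decode() for s in t["label"][()]],
                                     dtype=object))
        tr = f["truth"]
        ev = pd.DataFrame({col: tr["events"][col][()]
                           for col in tr["events"]}) if "events" in tr else pd.DataFrame()
        truth = GroundTruth(events=ev, ied_times=tr["ied_times"][()],
                            spike_lock_phase=float(tr.attrs["spike_lock_phase"]))
    return SyntheticSession(ieeg=recs["ieeg"], lfp=recs["lfp"], spikes=spikes,
                            trials=trials, truth=truth)
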