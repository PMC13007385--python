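"""Session container: one HDF5 file per participant + JSON ground truth.

Layout: datasets ``eeg`` (8 x N float64, microvolts), ``schedule``
(structured: run, trial, code_index, start_sample), ``codes`` (n_codes x
n_frames uint8) and per-code onset times; attributes fs, frame_rate,
participant_id.  The generative ParticipantSpec is stored in a plain-text
``<name>.json`` sidecar so ground truth survives independently of HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py

from .codes import BurstCode, CodeSet, pairwise_zero_lag_xcorr
from .simulate import ParticipantSpec, SimulatedSession

__all__ = ["save_session", "load_session"]


def save_session(path, session: SimulatedSession) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=session.eeg)
        f.create_dataset("schedule", data=session.schedule)
        f.create_dataset("codes", data=session.code_set.bits_matrix())
        for i, code in enumerate(session.code_set.codes):
            f.create_dataset(f"code_onsets/{i}", data=code.onsets)
        f.attrs["fs"] = session.fs
        f.attrs["frame_rate"] = session.code_set.frame_rate
        f.attrs["code_duration"] = session.code_set.duration
        f.attrs["participant_id"] = session.participant_id
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(session.truth.to_dict(), indent=1))
    return path


def load_session(path) -> SimulatedSession:
    path = Path(path)
    with h5py.File(path, "r") as f:
        eeg = f["eeg"][()]
        schedule = f["schedule"][()]
        bits = f["codes"][()]
        frame_rate = float(f.attrs["frame_rate"])
        duration = float(f.attrs["code_duration"])
        codes = tuple(
            BurstCode(
                bits=bits[i],
                frame_rate=frame_rate,
                duration=duration,
                onsets=f[f"code_onsets/{i}"][()],
            )
            for i in range(bits.shape[0])
        )
        fs = float(f.attrs["fs"])
        pid = int(f.attrs["participant_id"])
    code_set = CodeSet(codes=codes, max_pairwise_xcorr=pairwise_zero_lag_xcorr(bits))
    sidecar = path.with_suffix(path.suffix + ".json")
    truth = ParticipantSpec.from_dict(json.loads(sidecar.read_text()))
    return SimulatedSession(
        eeg=eeg, schedule=schedule, code_set=code_set, truth=truth,
        fs=fs, participant_id=pid,
    )
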