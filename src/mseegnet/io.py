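"""HDF5 container for epoched trials.

Layout: datasets ``data`` (trials x electrodes x samples, float32),
``labels``, ``subject_id``, ``session_id`` (int64), root attributes ``fs``
and ``electrode_names``.
"""

from __future__ import annotations

import h5py
import numpy as np

from .synthetic import TrialSet

__all__ = ["save_trialset", "load_trialset"]


def save_trialset(trials: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("labels", data=trials.labels)
        f.create_dataset("subject_id", data=trials.subject_id)
        f.create_dataset("session_id", data=trials.session_id)
        f.attrs["fs"] = float(trials.fs)
        f.attrs["electrode_names"] = [str(n) for n in trials.electrode_names]


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs.get("electrode_names", [])]
        return TrialSet(
            data=np.asarray(f["data"]),
            labels=np.asarray(f["labels"]),
            subject_id=np.asarray(f["subject_id"]),
            session_id=np.asarray(f["session_id"]),
            fs=float(f.attrs["fs"]),
            electrode_names=names,
        )
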