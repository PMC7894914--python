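"""HDF5 container for preprocessed tensors.

Layout (one file per dataset):
    /images    float32, (N, 12, 750, 3) — filtered, padded stream tensors
                                          (pre-scaling; the 95x95x3 image
                                          view is derived per fold)
    /labels    int8,    (N,)            — risk class 0/1/2
    /zones     int8,    (N,)            — ACGIH zone 1-12
    /subjects  str,     (N,)            — subject identifiers
    /pad_start int32,   (N,)            — first padded frame per trial
"""

from __future__ import annotations

import h5py
import numpy as np

from .preprocessing import LiftTensor

__all__ = ["save_tensors", "load_tensors"]


def save_tensors(tensors, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "images",
            data=np.stack([t.data for t in tensors]).astype(np.float32),
            compression="gzip",
        )
        f.create_dataset("labels", data=np.array([t.label for t in tensors], dtype=np.int8))
        f.create_dataset("zones", data=np.array([t.zone for t in tensors], dtype=np.int8))
        f.create_dataset(
            "subjects",
            data=np.array([t.subject_id or "" for t in tensors], dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "pad_start", data=np.array([t.pad_start for t in tensors], dtype=np.int32)
        )


def load_tensors(path) -> list[LiftTensor]:
    with h5py.File(path, "r") as f:
        data = f["images"][...]
        labels = f["labels"][...]
        zones = f["zones"][...]
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][...]]
        pad_start = f["pad_start"][...]
    return [
        LiftTensor(
            data=data[i].astype(np.float64),
            pad_start=int(pad_start[i]),
            label=int(labels[i]),
            zone=int(zones[i]),
            subject_id=subjects[i],
        )
        for i in range(len(data))
    ]
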