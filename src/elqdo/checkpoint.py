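"""HDF5 walker checkpoints for restartable runs."""

from __future__ import annotations

import h5py
import numpy as np

__all__ = ["save_walkers", "load_walkers"]


def save_walkers(path, electrons, drudons, weights=None, attrs=None):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("electrons", data=np.asarray(electrons, float))
        fh.create_dataset("drudons", data=np.asarray(drudons, float))
        if weights is not None:
            fh.create_dataset("weights", data=np.asarray(weights, float))
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def load_walkers(path):
    with h5py.File(path, "r") as fh:
        electrons = fh["electrons"][...]
        drudons = fh["drudons"][...]
        weights = fh["weights"][...] if "weights" in fh else None
        attrs = dict(fh.attrs)
    return electrons, drudons, weights, attrs
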