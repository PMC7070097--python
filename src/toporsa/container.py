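"""HDF5 array container with a documented entry layout.

Layout used across the pipeline (one file per stage output):

* ``patterns/subXX``   — conditions x voxels beta patterns per subject
* ``residuals/subXX``  — timepoints x voxels residuals per subject
* ``layerK/stack``     — conditions x H x W x D activations per layer
* ``rdms/...``         — square RDMs
* ``maps/...``         — subjects x H x W correlation maps

Datasets are written with ``track_times=False`` so identical content
yields identical files.  :func:`content_checksum` hashes dataset names,
dtypes, shapes and raw bytes (not HDF5 framing), which is what the run
manifest records for determinism checks.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np


def write_arrays(path, arrays: dict[str, np.ndarray], attrs: dict | None = None) -> None:
    """Write named arrays (nested names allowed, e.g. ``patterns/sub00``)."""
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr), track_times=False)
        if attrs:
            f.attrs["meta"] = json.dumps(attrs, sort_keys=True)


def read_arrays(path, names: list[str] | None = None) -> dict[str, np.ndarray]:
    """Read all (or the named) datasets into memory."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        if names is None:
            names = []
            f.visititems(
                lambda n, obj: names.append(n) if isinstance(obj, h5py.Dataset) else None
            )
        for name in names:
            out[name] = f[name][()]
    return out


def read_meta(path) -> dict:
    with h5py.File(path, "r") as f:
        raw = f.attrs.get("meta")
    return json.loads(raw) if raw else {}


def content_checksum(arrays: dict[str, np.ndarray]) -> str:
    """sha256 over sorted (name, dtype, shape, bytes) of every array."""
    h = hashlib.sha256()
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        h.update(name.encode())
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()


def file_content_checksum(path) -> str:
    """Checksum of an HDF5 file's dataset contents (framing-independent)."""
    return content_checksum(read_arrays(path))


def text_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        h.update(f.read())
    return h.hexdigest()
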