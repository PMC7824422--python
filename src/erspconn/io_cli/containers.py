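"""HDF5 epochs container with bit-exact round-trip and provenance attrs."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from ..types import EpochSet

__all__ = ["write_epochs", "read_epochs"]


def write_epochs(
    path: str | Path,
    epochs: EpochSet,
    provenance: dict | None = None,
) -> Path:
    """Write an EpochSet to an HDF5 container.

    Layout: /data, /time_ms, /labels, /condition, /kept_mask plus root
    attributes fs and a provenance JSON blob (config hash, seed, version).
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.time_ms)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("labels", data=np.array(epochs.labels, dtype=object), dtype=str_dt)
        f.create_dataset(
            "condition",
            data=np.array([str(c) for c in epochs.condition], dtype=object),
            dtype=str_dt,
        )
        f.create_dataset("kept_mask", data=epochs.kept_mask)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["provenance"] = json.dumps(provenance or {}, sort_keys=True)
    return path


def read_epochs(path: str | Path) -> tuple[EpochSet, dict]:
    """Read an EpochSet and its provenance dict back from HDF5."""
    with h5py.File(Path(path), "r") as f:
        epochs = EpochSet(
            f["data"][()],
            f["time_ms"][()],
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]],
            np.array(
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["condition"][()]],
                dtype=object,
            ),
            float(f.attrs["fs"]),
            f["kept_mask"][()],
        )
        provenance = json.loads(f.attrs.get("provenance", "{}"))
    return epochs, provenance
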