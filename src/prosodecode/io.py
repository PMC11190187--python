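"""Readers/writers for the on-disk formats: word-table CSV/TSV,
recording HDF5, and JSON result files."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import Recording

__all__ = [
    "read_word_table",
    "write_word_table",
    "save_recording",
    "load_recording",
    "dump_json",
]


def write_word_table(table: pd.DataFrame, path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False)


def read_word_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def save_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("offsets", data=rec.word_offsets)
        f.create_dataset("fs", data=rec.fs)
        f.attrs["word_table_ref"] = rec.word_table_ref


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            word_offsets=f["offsets"][()],
            word_table_ref=f.attrs.get("word_table_ref", ""),
        )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def dump_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
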