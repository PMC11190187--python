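"""Word-offset-locked epoch extraction and SVD dimensionality reduction.

Continuous recordings are cut into epochs time-locked to word offsets
(time zero = offset) over a half-open window [tmin, tmax).  Offsets closer
than 100 ms to the preceding offset are discarded, as are epochs running
past the edges of the recording.  Dimensionality is reduced by an SVD of
the training epochs, keeping the leading components that explain 99% of
the variance (cumulative squared singular values); the projection fitted
on training epochs is applied unchanged to test epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .synth import Recording

__all__ = ["EpochSet", "SvdReduction", "extract_epochs", "fit_svd_reduction"]

logger = logging.getLogger(__name__)

MIN_OFFSET_GAP_S = 0.1  # discard rule: inter-offset interval below this


@dataclass
class EpochSet:
    """Trial tensor (epochs x channels-or-components x samples)."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to word offset, uniform step 1/fs
    token_ids: np.ndarray
    labels: np.ndarray  # binary closing-boundary label per epoch
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.token_ids = np.asarray(self.token_ids)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != len(self.token_ids) or self.data.shape[0] != len(self.labels):
            raise ValueError("token_ids/labels must match the number of epochs")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times must match the number of samples")

    def __len__(self) -> int:
        return self.data.shape[0]

    def time_window(self, t0: float, t1: float) -> "EpochSet":
        """View restricted to times in [t0, t1)."""
        mask = (self.times >= t0) & (self.times < t1)
        if not mask.any():
            raise ValueError(f"window [{t0}, {t1}) outside epoch time range")
        return EpochSet(
            data=self.data[:, :, mask],
            times=self.times[mask],
            token_ids=self.token_ids,
            labels=self.labels,
            fs=self.fs,
        )

    def select_tokens(self, ids) -> "EpochSet":
        """Epochs for the given token ids, in the given (multiset) order."""
        index = {t: i for i, t in enumerate(self.token_ids)}
        rows = np.array([index[t] for t in ids if t in index], dtype=int)
        kept = [t for t in ids if t in index]
        return EpochSet(
            data=self.data[rows],
            times=self.times,
            token_ids=np.asarray(kept),
            labels=self.labels[rows],
            fs=self.fs,
        )

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("labels", data=np.asarray(self.labels, dtype=int))
            f.create_dataset("token_ids", data=np.asarray(self.token_ids, dtype=int))
            f.attrs["fs"] = self.fs

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                labels=f["labels"][()],
                token_ids=f["token_ids"][()],
                fs=float(f.attrs["fs"]),
            )


@dataclass
class SvdReduction:
    """Spatial projection from channels to leading SVD components."""

    basis: np.ndarray  # channels x components, orthonormal columns
    singular_values: np.ndarray  # full spectrum
    variance_fraction: float  # fraction retained by the kept components

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def transform(self, epochs: EpochSet) -> EpochSet:
        data = np.einsum("ck,ecs->eks", self.basis, epochs.data)
        return EpochSet(
            data=data,
            times=epochs.times,
            token_ids=epochs.token_ids,
            labels=epochs.labels,
            fs=epochs.fs,
        )


def extract_epochs(
    rec: Recording,
    offsets,
    tmin: float,
    tmax: float,
    token_ids=None,
    labels=None,
) -> EpochSet:
    """Cut a recording into offset-locked epochs over [tmin, tmax).

    An offset is discarded when its gap to the previous offset is below
    100 ms (the earlier of the pair is kept); epochs extending past the
    recording are discarded with a logged count.  The sample count is
    round((tmax - tmin) * fs), with times[0] = tmin.
    """
    if tmin >= tmax:
        raise ValueError(f"tmin ({tmin}) must be < tmax ({tmax})")
    offsets = np.asarray(offsets, dtype=float)
    n_off = offsets.size
    token_ids = np.arange(n_off) if token_ids is None else np.asarray(token_ids)
    labels = np.zeros(n_off, dtype=int) if labels is None else np.asarray(labels)

    fs = rec.fs
    n_samp = int(round((tmax - tmin) * fs))
    times = tmin + np.arange(n_samp) / fs
    if n_off == 0:
        return EpochSet(
            data=np.empty((0, rec.data.shape[0], n_samp)),
            times=times,
            token_ids=token_ids,
            labels=labels,
            fs=fs,
        )

    gap_ok = np.ones(n_off, dtype=bool)
    gap_ok[1:] = np.diff(offsets) >= MIN_OFFSET_GAP_S

    starts = np.round((offsets + tmin) * fs).astype(int)
    in_range = (starts >= 0) & (starts + n_samp <= rec.data.shape[1])
    n_edge = int((gap_ok & ~in_range).sum())
    if n_edge:
        logger.info("dropped %d epochs extending past the recording", n_edge)

    keep = gap_ok & in_range
    data = np.stack([rec.data[:, s : s + n_samp] for s in starts[keep]]) if keep.any() else np.empty((0, rec.data.shape[0], n_samp))
    return EpochSet(
        data=data,
        times=times,
        token_ids=token_ids[keep],
        labels=labels[keep],
        fs=fs,
    )


def fit_svd_reduction(train_epochs: EpochSet, cutoff: float = 0.99) -> SvdReduction:
    """Fit the spatial SVD reduction on training epochs only.

    The channels x (epochs * samples) training matrix is decomposed and
    the smallest leading set of components whose cumulative squared
    singular values reach the cutoff fraction of the total is kept.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if len(train_epochs) == 0:
        raise ValueError("cannot fit SVD reduction on an empty epoch set")
    n_e, n_c, n_s = train_epochs.data.shape
    mat = np.transpose(train_epochs.data, (1, 0, 2)).reshape(n_c, n_e * n_s)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    energy = s**2
    total = energy.sum()
    nonzero = energy > total * np.finfo(float).eps * max(mat.shape)
    cum = np.cumsum(energy) / total
    k = int(np.searchsorted(cum, cutoff - 1e-12) + 1)
    k = min(k, int(nonzero.sum()))
    return SvdReduction(
        basis=u[:, :k],
        singular_values=s,
        variance_fraction=float(cum[k - 1]),
    )
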