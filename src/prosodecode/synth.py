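"""Synthetic word tables and multichannel recordings with a planted
prosody-syntax association.

The generator emulates the statistical structure the downstream analysis
assumes: prosodic boundary strengths drawn from a two-component gamma
mixture, closing-phrase-boundary labels whose probability depends on the
latent prosody class, and continuous recordings in which each word offset
is followed (and weakly preceded) by a spatially fixed, class-specific
pattern whose amplitude depends on the prosody-syntax cell of the token.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "Recording",
    "gen_word_table",
    "gen_recording",
    "gen_cohort",
    "cell_gain",
]

#: canonical column order of a word table
WORD_TABLE_COLUMNS = [
    "token_id",
    "talk_id",
    "sentence_id",
    "word",
    "onset_s",
    "offset_s",
    "strength",
    "closing",
    "latent_class",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    The two gamma components and the closing-boundary conditionals default
    to the values characterising the stimulus set (weak component shape
    1.1 / rate 2.8, strong component shape 14 / rate 10.7; closing-boundary
    probability 0.72 given strong prosody, 0.44 given weak). The mixture
    weight of the strong component is a free simulation parameter.

    Gains set the amplitude of the planted class-discriminative signal per
    prosody-syntax cell: coherent cell (strong AND closing), neutral cell
    (weak AND no closing), incoherent/mismatched cells (weak AND closing,
    strong AND no closing). ``pre_gain`` scales the smaller anticipatory
    component peaking before word offset, relative to the post-offset one.
    """

    n_subjects: int = 11
    n_words: int = 600
    gamma1_shape: float = 1.1
    gamma1_rate: float = 2.8
    gamma2_shape: float = 14.0
    gamma2_rate: float = 10.7
    w_strong: float = 0.25
    p_closing_given_strong: float = 0.72
    p_closing_given_weak: float = 0.44
    n_channels: int = 60
    fs: float = 100.0
    gain_coherent: float = 1.2
    gain_neutral: float = 0.8
    gain_incoherent: float = 0.35
    pre_gain: float = 0.5
    noise_sd: float = 1.0
    short_gap_fraction: float = 0.05
    words_per_sentence: int = 10
    n_talks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "w_strong": self.w_strong,
            "p_closing_given_strong": self.p_closing_given_strong,
            "p_closing_given_weak": self.p_closing_given_weak,
            "short_gap_fraction": self.short_gap_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        positives = {
            "gamma1_shape": self.gamma1_shape,
            "gamma1_rate": self.gamma1_rate,
            "gamma2_shape": self.gamma2_shape,
            "gamma2_rate": self.gamma2_rate,
            "noise_sd": self.noise_sd,
            "fs": self.fs,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("gain_coherent", "gain_neutral", "gain_incoherent", "pre_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_words < 0:
            raise ValueError("n_words must be >= 0")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Recording:
    """Continuous multichannel recording with word-offset event times."""

    data: np.ndarray  # channels x samples
    fs: float
    word_offsets: np.ndarray  # seconds, strictly increasing
    word_table_ref: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.word_offsets = np.asarray(self.word_offsets, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if np.any(np.diff(self.word_offsets) <= 0):
            raise ValueError("word offsets must be strictly increasing")
        duration = self.data.shape[1] / self.fs
        if self.word_offsets.size and (
            self.word_offsets[0] < 0 or self.word_offsets[-1] > duration
        ):
            raise ValueError("word offsets outside recording duration")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def gen_word_table(cfg: SynthConfig, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate a word table with the planted prosody-syntax association.

    The latent prosody class (weak/strong) is drawn first; the closing
    label follows the conditional probability of that class and the
    strength is drawn from the class's gamma component.  Offset spacing is
    a shifted exponential with a configurable fraction of gaps forced
    below 100 ms so the epoch discard rule is exercised downstream.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = cfg.n_words
    if n == 0:
        return pd.DataFrame(columns=WORD_TABLE_COLUMNS)

    strong = rng.random(n) < cfg.w_strong
    p_close = np.where(strong, cfg.p_closing_given_strong, cfg.p_closing_given_weak)
    closing = rng.random(n) < p_close
    strength = np.where(
        strong,
        rng.gamma(cfg.gamma2_shape, 1.0 / cfg.gamma2_rate, size=n),
        rng.gamma(cfg.gamma1_shape, 1.0 / cfg.gamma1_rate, size=n),
    )

    # offset-to-offset gaps; a small fraction violates the 100 ms rule
    gaps = 0.12 + rng.exponential(0.25, size=n)
    short = rng.random(n) < cfg.short_gap_fraction
    gaps[short] = rng.uniform(0.03, 0.09, size=int(short.sum()))
    offsets = 0.5 + np.cumsum(gaps)
    durations = 0.8 * gaps
    onsets = offsets - durations

    return pd.DataFrame(
        {
            "token_id": np.arange(n),
            "talk_id": np.arange(n) * cfg.n_talks // max(n, 1),
            "sentence_id": np.arange(n) // cfg.words_per_sentence,
            "word": [f"w{i:05d}" for i in range(n)],
            "onset_s": onsets,
            "offset_s": offsets,
            "strength": strength,
            "closing": closing.astype(int),
            "latent_class": np.where(strong, "strong", "weak"),
        },
        columns=WORD_TABLE_COLUMNS,
    )


def cell_gain(cfg: SynthConfig, strong: bool, closing: bool) -> float:
    """Signal gain of a prosody-syntax cell.

    Matched cells carry the coherent (strong AND closing) or neutral
    (weak AND no closing) gain; the two mismatched cells carry the
    incoherent gain.
    """
    if strong and closing:
        return cfg.gain_coherent
    if not strong and not closing:
        return cfg.gain_neutral
    return cfg.gain_incoherent


def _raised_cosine(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Raised-cosine bump of total support ``width`` peaking at ``peak``."""
    out = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - peak) / width))
    out[np.abs(t - peak) > width / 2.0] = 0.0
    return out


def gen_recording(
    table: pd.DataFrame,
    cfg: SynthConfig,
    subject_seed: int,
    word_table_ref: str = "",
) -> Recording:
    """Generate one subject's recording from a word table.

    Gaussian sensor noise plus, per token, a fixed per-subject spatial
    pattern (one pattern for closing tokens, a different one for
    no-closing tokens) times a raised-cosine profile peaking 100 ms after
    the token's offset, scaled by the token's cell gain; a smaller
    anticipatory component (``pre_gain`` relative amplitude) peaks 100 ms
    before the offset.
    """
    if len(table) == 0:
        raise ValueError("word table is empty")
    rng = np.random.default_rng(subject_seed)

    offsets = table["offset_s"].to_numpy(dtype=float)
    duration = float(offsets[-1]) + 1.0
    n_samples = int(round(duration * cfg.fs))
    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, n_samples))

    # one spatial pattern per syntactic class, fixed within subject
    pat_closing = rng.normal(size=cfg.n_channels)
    pat_closing /= np.linalg.norm(pat_closing)
    pat_none = rng.normal(size=cfg.n_channels)
    pat_none /= np.linalg.norm(pat_none)

    times = np.arange(n_samples) / cfg.fs
    strong = table["latent_class"].to_numpy() == "strong"
    closing = table["closing"].to_numpy().astype(bool)

    for off, s, c in zip(offsets, strong, closing):
        if off > duration:
            raise ValueError("offset beyond recording duration")
        gain = cell_gain(cfg, bool(s), bool(c))
        if gain == 0.0:
            continue
        pattern = pat_closing if c else pat_none
        lo = max(0, int((off - 0.5) * cfg.fs))
        hi = min(n_samples, int((off + 0.5) * cfg.fs))
        t = times[lo:hi] - off
        profile = gain * (
            _raised_cosine(t, peak=0.1, width=0.3)
            + cfg.pre_gain * _raised_cosine(t, peak=-0.1, width=0.2)
        )
        data[:, lo:hi] += np.outer(pattern, profile)

    return Recording(data=data, fs=cfg.fs, word_offsets=offsets, word_table_ref=word_table_ref)


def gen_cohort(
    cfg: SynthConfig, shared_stimuli: bool = True
) -> list[tuple[pd.DataFrame, Recording]]:
    """Generate ``cfg.n_subjects`` (word table, recording) pairs.

    By default every subject hears the same stimulus set (one shared word
    table), mirroring a fixed-stimulus listening study; with
    ``shared_stimuli=False`` each subject gets an independent table.
    Per-subject randomness comes from substreams derived deterministically
    from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    table_seed, *subject_seeds = root.spawn(cfg.n_subjects + 1)
    shared = gen_word_table(cfg, np.random.default_rng(table_seed))
    pairs = []
    for i, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        table = shared if shared_stimuli else gen_word_table(cfg, rng)
        rec_seed = int(rng.integers(2**31))
        rec = gen_recording(table, cfg, rec_seed, word_table_ref=f"subject{i:02d}")
        pairs.append((table, rec))
    return pairs
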