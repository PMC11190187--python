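"""Training pool and cross-condition generalization test sets.

The decoder is trained only on weak-prosody tokens (class-balanced in the
closing label) so it is free of prosodic bias, and generalization is
measured on three class-balanced test sets:

- neutral:    weak AND no-closing  +  weak AND closing
- coherent:   weak AND no-closing  +  strong AND closing
- incoherent: weak AND closing     +  strong AND no-closing

Test tokens never appear in the training pool; a token may be repeated
within a test set (sampling with replacement) only when its cell is
smaller than required, and never across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitDesign", "assign_cell", "build_split", "CONDITIONS", "CELLS"]

CELLS = ("weak_no", "weak_yes", "strong_no", "strong_yes")
CONDITIONS = ("neutral", "coherent", "incoherent")

#: (no-closing cell, closing cell) defining each test condition
_CONDITION_CELLS = {
    "neutral": ("weak_no", "weak_yes"),
    "coherent": ("weak_no", "strong_yes"),
    "incoherent": ("strong_no", "weak_yes"),
}


@dataclass
class SplitDesign:
    """Token-id assignment to the training pool and the three test sets."""

    train_ids: np.ndarray
    test_ids: dict  # condition -> np.ndarray (multiset; duplicates allowed)
    test_size_per_class: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "train_ids": self.train_ids.tolist(),
            "test_ids": {k: v.tolist() for k, v in self.test_ids.items()},
            "test_size_per_class": self.test_size_per_class,
            "seed": self.seed,
        }


def assign_cell(prosody_class: str, closing: int) -> str:
    """Map a token to its prosody x syntax cell.

    weak_no and strong_yes are the statistically co-occurring (matched)
    combinations; weak_yes and strong_no are the mismatched ones.
    """
    if prosody_class not in ("weak", "strong"):
        raise ValueError(f"unassigned or invalid prosody class: {prosody_class!r}")
    return f"{prosody_class}_{'yes' if closing else 'no'}"


def _table_cells(table: pd.DataFrame) -> pd.Series:
    if "excluded" in table.columns and table["excluded"].any():
        raise ValueError("excluded tokens must be dropped before splitting")
    return pd.Series(
        [
            assign_cell(pc, c)
            for pc, c in zip(table["prosody_class"], table["closing"])
        ],
        index=table.index,
    )


def default_test_size(cell_sizes: dict, train_fraction_kept: float = 0.7) -> int:
    """Default per-class test size: the smallest cell, capped so the
    training pool keeps at least ``train_fraction_kept`` of weak tokens."""
    n_weak = cell_sizes["weak_no"] + cell_sizes["weak_yes"]
    # neutral takes 2 weak cells, coherent takes weak_no, incoherent weak_yes
    cap = int(np.floor((1.0 - train_fraction_kept) * n_weak / 4.0))
    return max(1, min(min(cell_sizes.values()), cap))


def build_split(
    table: pd.DataFrame,
    test_size_per_class: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> SplitDesign:
    """Build the balanced training pool and the three balanced test sets.

    Per cell, the total demand across the test sets using it is reserved
    without replacement when the cell is large enough; otherwise the
    unique tokens are dealt across the demanding sets and each set's
    shortfall is topped up by resampling tokens already assigned to that
    same set, so duplicates stay within one set.  All weak tokens not
    reserved for testing form the training pool, with the majority
    closing class downsampled to balance.

    ``table`` needs columns ``token_id``, ``closing``, ``prosody_class``.
    """
    rng = np.random.default_rng(rng)
    cells = _table_cells(table)
    ids_by_cell = {
        c: table.loc[cells == c, "token_id"].to_numpy() for c in CELLS
    }
    cell_sizes = {c: len(v) for c, v in ids_by_cell.items()}
    for c, n in cell_sizes.items():
        if n == 0:
            raise ValueError(f"cell {c} is empty; cannot build the test sets")

    if test_size_per_class is None:
        test_size_per_class = default_test_size(cell_sizes)
    m = int(test_size_per_class)
    if m < 1:
        raise ValueError("test_size_per_class must be >= 1")
    n_weak = cell_sizes["weak_no"] + cell_sizes["weak_yes"]
    if m > n_weak:
        raise ValueError(
            f"test_size_per_class={m} exceeds the weak pool ({n_weak} tokens)"
        )

    # demand per cell = m per (condition, cell) pair using it
    users = {c: [k for k, pair in _CONDITION_CELLS.items() if c in pair] for c in CELLS}
    reserved: dict[str, dict[str, np.ndarray]] = {k: {} for k in CONDITIONS}
    for cell, conds in users.items():
        if not conds:
            continue
        demand = m * len(conds)
        pool = ids_by_cell[cell]
        if len(pool) >= demand:
            take = rng.choice(pool, size=demand, replace=False)
            for i, cond in enumerate(conds):
                reserved[cond][cell] = take[i * m : (i + 1) * m]
        else:
            take = rng.permutation(pool)
            shares = np.array_split(take, len(conds))
            for cond, share in zip(conds, shares):
                if len(share) == 0:
                    raise ValueError(f"cell {cell} too small to populate {cond}")
                extra = rng.choice(share, size=m - len(share), replace=True)
                reserved[cond][cell] = np.concatenate([share, extra])

    test_ids = {
        cond: np.concatenate([reserved[cond][c] for c in _CONDITION_CELLS[cond]])
        for cond in CONDITIONS
    }
    all_reserved = set(np.concatenate(list(test_ids.values())).tolist())

    # training pool: remaining weak tokens, majority class downsampled.
    # May be empty when the test sets exhaust the weak cells (toy scales).
    train_parts = []
    for cell in ("weak_no", "weak_yes"):
        ids = ids_by_cell[cell]
        train_parts.append(ids[~np.isin(ids, list(all_reserved))])
    k = min(len(p) for p in train_parts)
    train_ids = np.concatenate(
        [rng.choice(p, size=k, replace=False) if len(p) > k else p for p in train_parts]
    )
    return SplitDesign(
        train_ids=np.sort(train_ids),
        test_ids=test_ids,
        test_size_per_class=m,
    )
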