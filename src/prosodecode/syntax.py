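"""Constituency-tree reading, closing-node counting, and token filtering.

A word carries a closing phrase boundary when it is the rightmost terminal
of at least one phrase above its own preterminal — equivalently, when the
run of closing brackets after it in the bracketed notation is longer than
one.  Counting includes the preterminal, so every word closes at least one
node and the two classes (closes more than one node vs. closes only its
preterminal) partition all words.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConstituencyTree",
    "parse_bracketed",
    "parse_bracketed_file",
    "closing_node_counts",
    "label_and_filter",
]


@dataclass
class ConstituencyTree:
    """Labeled ordered tree; children are subtrees or terminal strings."""

    label: str
    children: list

    def terminals(self) -> list[str]:
        out = []
        for c in self.children:
            if isinstance(c, ConstituencyTree):
                out.extend(c.terminals())
            else:
                out.append(c)
        return out

    def n_nodes(self) -> int:
        """Number of labeled (nonterminal + preterminal) nodes."""
        return 1 + sum(
            c.n_nodes() for c in self.children if isinstance(c, ConstituencyTree)
        )

    def to_bracketed(self) -> str:
        parts = [
            c.to_bracketed() if isinstance(c, ConstituencyTree) else c
            for c in self.children
        ]
        return f"({self.label} {' '.join(parts)})"


class BracketParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str):
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in "()":
            yield ch, i
            i += 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            yield text[i:j], i
            i = j


def parse_bracketed(text: str) -> ConstituencyTree:
    """Parse one PTB-style bracketed sentence into a ConstituencyTree.

    Raises :class:`BracketParseError` with the offending position on
    unbalanced or empty input.  ``to_bracketed`` reproduces a normalized
    (single-spaced) bracket string, and parse -> serialize -> parse is the
    identity on that normalized form.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise BracketParseError("empty input", 0)

    stack: list[ConstituencyTree] = []
    root: ConstituencyTree | None = None
    i = 0
    while i < len(tokens):
        tok, pos = tokens[i]
        if tok == "(":
            if root is not None and not stack:
                raise BracketParseError("trailing material after root", pos)
            if i + 1 >= len(tokens) or tokens[i + 1][0] in "()":
                raise BracketParseError("expected node label after '('", pos)
            node = ConstituencyTree(label=tokens[i + 1][0], children=[])
            if stack:
                stack[-1].children.append(node)
            stack.append(node)
            i += 2
        elif tok == ")":
            if not stack:
                raise BracketParseError("unbalanced ')'", pos)
            node = stack.pop()
            if not node.children:
                raise BracketParseError(f"node '{node.label}' has no children", pos)
            if not stack:
                root = node
            i += 1
        else:
            if not stack:
                raise BracketParseError("terminal outside any node", pos)
            stack[-1].children.append(tok)
            i += 1
    if stack:
        raise BracketParseError("unbalanced '(': unclosed node", len(text))
    if root is None:
        raise BracketParseError("no tree found", 0)
    return root


def parse_bracketed_file(path) -> list[ConstituencyTree]:
    """Read one bracketed sentence per nonempty line."""
    trees = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_bracketed(line))
    return trees


def closing_node_counts(tree: ConstituencyTree) -> np.ndarray:
    """Number of nodes each terminal closes, in sentence order.

    A node is closed by its rightmost terminal; the count includes the
    word's own preterminal, so every word closes at least one node.  It
    equals the run of ')' after the word in the normalized bracket string,
    and the counts over a sentence sum to the number of nodes in the tree.
    """
    counts: list[int] = []

    def walk(node: ConstituencyTree) -> None:
        for c in node.children:
            if isinstance(c, ConstituencyTree):
                walk(c)
            else:
                counts.append(0)
        counts[-1] += 1  # this node closes at its rightmost terminal

    walk(tree)
    return np.asarray(counts, dtype=int)


def label_and_filter(
    tokens: pd.DataFrame,
    counts,
    strengths=None,
    oov_marker: str = "<unk>",
) -> pd.DataFrame:
    """Assign closing-boundary labels and apply the token filters.

    ``closing`` is 1 iff the word closes more than one node (it is the
    rightmost terminal of at least one phrase), 0 iff it closes only its
    preterminal.  Out-of-dictionary tokens (equal to ``oov_marker``),
    sentence-final tokens, and zero-strength tokens are flagged
    ``excluded`` with a reason (oov / sentence_final / zero_strength) —
    the first applicable reason in that order is recorded.  Counts are
    computed on the full trees, so labeling happens before any removal.

    Parameters
    ----------
    tokens : DataFrame with at least ``word`` and ``sentence_id`` columns.
    counts : closing-node count per token, aligned by position.
    strengths : optional prosodic strengths, aligned by position; if
        omitted, a ``strength`` column of ``tokens`` is used when present.

    Returns the table with ``closing_count``, ``closing``, ``excluded``
    and ``exclusion_reason`` columns added; rows are retained (callers
    drop excluded rows for analysis).
    """
    counts = np.asarray(counts, dtype=int)
    if len(counts) != len(tokens):
        raise ValueError(
            f"counts length {len(counts)} does not match tokens length {len(tokens)}"
        )
    out = tokens.copy()
    if strengths is not None:
        strengths = np.asarray(strengths, dtype=float)
        if len(strengths) != len(tokens):
            raise ValueError("strengths length does not match tokens length")
        out["strength"] = strengths

    out["closing_count"] = counts
    out["closing"] = (counts > 1).astype(int)

    is_oov = out["word"].to_numpy() == oov_marker
    sent_final = np.zeros(len(out), dtype=bool)
    sid = out["sentence_id"].to_numpy()
    if len(out):
        sent_final[:-1] = sid[:-1] != sid[1:]
        sent_final[-1] = True
    zero_strength = (
        out["strength"].to_numpy(dtype=float) == 0.0
        if "strength" in out.columns
        else np.zeros(len(out), dtype=bool)
    )

    reason = np.full(len(out), "", dtype=object)
    reason[zero_strength] = "zero_strength"
    reason[sent_final] = "sentence_final"
    reason[is_oov] = "oov"
    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    return out
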