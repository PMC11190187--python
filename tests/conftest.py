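import numpy as np
import pytest

from prosodecode.synth import SynthConfig, gen_word_table, gen_recording


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config for fast unit tests."""
    return SynthConfig(n_subjects=2, n_words=300, seed=123)


@pytest.fixture(scope="session")
def word_table(small_cfg):
    return gen_word_table(small_cfg)


@pytest.fixture(scope="session")
def recording(small_cfg, word_table):
    return gen_recording(word_table, small_cfg, subject_seed=7)


def random_tree(rng, max_depth=4, max_children=3):
    """Random constituency tree for oracle comparisons."""
    from prosodecode.syntax import ConstituencyTree

    labels = ["S", "NP", "VP", "PP", "ADJP"]
    pos = ["DT", "NN", "VB", "JJ", "IN"]
    words = ["the", "dog", "runs", "big", "on", "cat", "sees"]

    def build(depth):
        if depth >= max_depth or rng.random() < 0.3:
            return ConstituencyTree(
                label=pos[rng.integers(len(pos))],
                children=[words[rng.integers(len(words))]],
            )
        n = rng.integers(1, max_children + 1)
        return ConstituencyTree(
            label=labels[rng.integers(len(labels))],
            children=[build(depth + 1) for _ in range(n)],
        )

    root = build(0)
    if not isinstance(root.children[0], str) and len(root.children) == 1:
        return root
    return root
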