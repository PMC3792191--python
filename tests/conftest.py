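import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from snopair import PeptideWindow, SyntheticConfig, fit, generate_windows
from snopair.windows import ALPHABET, AMINO_ACIDS

# two windows sharing no residue pair at any subsite: all non-center
# positions differ, and the two pairs touching the shared center 'C'
# differ in their other member.
WINDOW_POS = "ACDEFGHIKLCMNPQRSTVWY"
WINDOW_NEG = "YWVTSRQPNMCLKIHGFEDAW"


def random_window(rng: random.Random, length: int = 21, pad_prob: float = 0.1) -> str:
    """A random window over the full 21-letter alphabet with 'C' at the center."""
    chars = [
        "Z" if rng.random() < pad_prob else rng.choice(AMINO_ACIDS)
        for _ in range(length)
    ]
    chars[length // 2] = "C"
    return "".join(chars)


@pytest.fixture
def toy_pair():
    """One positive and one negative window with disjoint pairs everywhere."""
    return PeptideWindow(WINDOW_POS), PeptideWindow(WINDOW_NEG)


@pytest.fixture
def toy_model(toy_pair):
    pos, neg = toy_pair
    return fit([pos], [neg])


@pytest.fixture
def separable_data():
    """Small fully-separable synthetic dataset (deterministic planted residues)."""
    cfg = SyntheticConfig(n_pos=60, n_neg=60, effect_size=1.0, seed=7)
    return generate_windows(cfg)
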