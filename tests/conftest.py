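import numpy as np
import pytest

from hypnodense.core import FIVE_STAGE, Hypnogram, ScorerPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20231163)


@pytest.fixture
def fig1_panel():
    """The single worked epoch: 7 scorers vote N2, 4 vote N1, 1 votes W."""
    votes = ["N2"] * 7 + ["N1"] * 4 + ["W"]
    return ScorerPanel(
        tuple(f"S{i + 1}" for i in range(12)),
        tuple(Hypnogram((v,)) for v in votes),
    )


@pytest.fixture
def small_panel():
    """Three scorers over four epochs (hand-enumerable agreement)."""
    rows = [
        ["W", "W", "N2", "R"],
        ["W", "N1", "N2", "R"],
        ["W", "W", "N2", "N2"],
    ]
    return ScorerPanel(
        ("a", "b", "c"), tuple(Hypnogram(tuple(r)) for r in rows)
    )


def random_panel(rng, n_scorers=4, n_epochs=50):
    """Uniform-random panel over the five stages (for property tests)."""
    hyps = tuple(
        Hypnogram.from_indices(rng.integers(0, 5, n_epochs), FIVE_STAGE)
        for _ in range(n_scorers)
    )
    return ScorerPanel(tuple(f"S{j}" for j in range(n_scorers)), hyps)
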