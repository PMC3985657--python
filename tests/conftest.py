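import numpy as np
import pandas as pd
import pytest

from omegatx.expression import CONTROL, MUTANT, SignalMatrix
from omegatx.io_formats import PromoterSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_matrix():
    """4 genes x 7 samples (4 control, 3 mutant), linear scale."""
    values = pd.DataFrame(
        {
            "CS_1": [100.0, 10.0, 50.0, 7.0],
            "CS_2": [110.0, 12.0, 55.0, 6.5],
            "CS_3": [95.0, 11.0, 48.0, 7.2],
            "CS_4": [105.0, 9.0, 52.0, 7.1],
            "dRpoZ_1": [400.0, 10.5, 13.0, 7.0],
            "dRpoZ_2": [420.0, 11.5, 12.0, 6.9],
            "dRpoZ_3": [390.0, 10.0, 12.5, 7.3],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    groups = {s: CONTROL for s in values.columns[:4]}
    groups.update({s: MUTANT for s in values.columns[4:]})
    return SignalMatrix(values=values, groups=groups)


def make_planted_promoters(offsets, spacers, L=60, background="random", seed=0):
    """Promoters with exact (conservation 1) TATAAT/TTGACA plants."""
    rng = np.random.default_rng(seed)
    sequences = {}
    for i, (m10, gap) in enumerate(zip(offsets, spacers)):
        if background == "random":
            seq = list(rng.choice(list("ACGT"), size=L))
        else:
            seq = list(background * (L // len(background) + 1))[:L]
        m35 = m10 - gap - 6
        for j, b in enumerate("TTGACA"):
            seq[m35 + L + j] = b
        for j, b in enumerate("TATAAT"):
            seq[m10 + L + j] = b
        sequences[f"g{i + 1:03d}"] = "".join(seq)
    return PromoterSet(sequences)


@pytest.fixture
def planted_promoters():
    offsets = [-14, -12, -10, -13, -11, -12]
    spacers = [16, 17, 18, 17, 16, 18]
    return make_planted_promoters(offsets, spacers, seed=7), offsets, spacers
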