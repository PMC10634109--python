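import itertools

import numpy as np
import pytest

from turnover15n.isotopes import NATURAL_ABUNDANCE, ElementalComposition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def enumerate_envelope(comp: ElementalComposition, n15_fraction: float | None = None,
                       length: int | None = None) -> np.ndarray:
    """Independent brute-force isotopologue oracle.

    Enumerates every per-atom isotope assignment of a (tiny) composition and
    accumulates probability mass by nominal mass offset.  Exponential in the
    atom count; only usable on very small compositions.
    """
    per_atom: list[list[tuple[int, float]]] = []
    for elem, count in comp.as_dict().items():
        heavy = NATURAL_ABUNDANCE[elem] if not (elem == "N" and n15_fraction is not None) \
            else (n15_fraction,)
        states = [(0, 1.0 - sum(heavy))] + [(k + 1, p) for k, p in enumerate(heavy)]
        per_atom.extend([states] * count)
    n_channels = length if length is not None else comp.n + 6
    out = np.zeros(n_channels)
    for assignment in itertools.product(*per_atom):
        offset = sum(k for k, _ in assignment)
        if offset < n_channels:
            prob = 1.0
            for _, p in assignment:
                prob *= p
            out[offset] += prob
    return out / out.sum()
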