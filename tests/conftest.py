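import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from penmodel import simdata  # noqa: E402


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated population shared across tests."""
    cfg = simdata.SimConfig(
        n_herds=3,
        cows_per_herd=60,
        n_sires=8,
        years=1,
        pens_per_herd=2,
        lactation_length_days=90,
        milkings_per_day=2,
        seed=1234,
    )
    return simdata.simulate(cfg)


def random_pedigree(rng: np.random.Generator, n: int, p_parents: float = 0.7):
    """Random acyclic pedigree triples (animal, sire, dam) with ids as strings.

    Animal i may take parents among animals with smaller index, so the raw
    listing is already acyclic; callers may shuffle rows to exercise
    reordering.
    """
    animals = [f"A{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i >= 2 and rng.random() < p_parents:
            s, d = rng.choice(i, size=2, replace=False)
            sires.append(f"A{s}")
            dams.append(f"A{d}")
        else:
            sires.append("0")
            dams.append("0")
    return animals, sires, dams
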