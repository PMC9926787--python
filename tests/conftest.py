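import itertools

import numpy as np
import pandas as pd
import pytest

from gennet.datamodel import CONTINUOUS, Dataset
from gennet.screening import FeasibleSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_continuous_dataset(values: np.ndarray, names=None) -> Dataset:
    values = np.atleast_2d(values)
    if names is None:
        names = [f"X{i}" for i in range(values.shape[1])]
    return Dataset(
        frame=pd.DataFrame(values, columns=list(names)),
        kinds={c: CONTINUOUS for c in names},
    )


@pytest.fixture
def worked_feasible() -> FeasibleSet:
    """The four-node possible-parent map used throughout the lattice examples:
    pp(1)={2,4}, pp(2)={3,1}, pp(3)={2}, pp(4)={1}."""
    return FeasibleSet(
        nodes=["1", "2", "3", "4"],
        reduced_pp={"1": ("2", "4"), "2": ("1", "3"), "3": ("2",), "4": ("1",)},
    )


def random_parent_map(names, rng, max_parents=None) -> dict:
    """A random possible-parent map over ``names``."""
    if max_parents is None:
        max_parents = len(names) - 1
    pp = {}
    for v in names:
        others = [u for u in names if u != v]
        k = int(rng.integers(0, max_parents + 1))
        pp[v] = tuple(sorted(rng.choice(others, size=k, replace=False)))
    return pp


def brute_force_generational_orderings(feasible: FeasibleSet) -> list[tuple]:
    """All complete generational orderings by testing every permutation
    prefix-wise against the possible-parent map."""
    out = []
    pp = {v: set(feasible.reduced_pp[v]) for v in feasible.nodes}
    for perm in itertools.permutations(feasible.nodes):
        ok = True
        for i, v in enumerate(perm[1:], start=1):
            if not (pp[v] & set(perm[:i])):
                ok = False
                break
        if ok:
            out.append(perm)
    return out
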