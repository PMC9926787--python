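"""Synthetic ground-truth networks and linear-Gaussian data.

The generator mirrors the study conditions used to evaluate structure
recovery: p nodes are split into independent (p0), source (p1), intermediate
(p2) and sink (p3) roles; a random ordering with sources first and sinks last
guarantees a DAG when each non-source connected node draws 1..indegree_true
parents from the eligible nodes above it.  Data follow a linear structural
equation model: roots and independents are standard normal, children are a
signed linear combination of their parents plus Gaussian noise.  A helper
attaches an exponential proportional-hazards survival outcome for testing the
survival screening and scoring paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import CONTINUOUS, DataError, Dataset, Network

#: Default |beta| range for edge effects; mid-strength signals at N in the
#: hundreds-to-thousands range.
DEFAULT_BETA_RANGE = (0.5, 1.5)
DEFAULT_NOISE_SD = 1.0
DEFAULT_TRUE_INDEGREE = 2

ROLE_INDEPENDENT = "independent"
ROLE_SOURCE = "source"
ROLE_INTERMEDIATE = "intermediate"
ROLE_SINK = "sink"


@dataclass
class SimulationTruth:
    """A generating DAG with node roles, edge coefficients and its ordering."""

    dag: Network
    roles: dict[str, str]
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    ordering: list[str] = field(default_factory=list)

    def validate(self) -> None:
        self.dag.validate()
        children: set[str] = set()
        for v, ps in self.dag.parent_sets.items():
            children.update(ps)
        for v, role in self.roles.items():
            has_parents = len(self.dag.parent_sets[v]) > 0
            has_children = v in children
            if role == ROLE_SOURCE and has_parents:
                raise DataError(f"source {v!r} has parents")
            if role == ROLE_SINK and has_children:
                raise DataError(f"sink {v!r} has children")
            if role == ROLE_INDEPENDENT and (has_parents or has_children):
                raise DataError(f"independent node {v!r} is not isolated")


def default_roles(p: int) -> tuple[int, int, int, int]:
    """A realistic role split: ~20% independent, 30% sources, 20% sinks."""
    if p < 3:
        return (p, 0, 0, 0) if p < 2 else (0, 1, 0, 1)
    p0 = max(0, round(0.2 * p))
    p1 = max(1, round(0.3 * p))
    p3 = max(1, round(0.2 * p))
    p2 = p - p0 - p1 - p3
    if p2 < 0:
        p0 += p2
        p2 = 0
    return p0, p1, p2, p3


def simulate_dag(
    p: int,
    p0: int,
    p1: int,
    p2: int,
    p3: int,
    indegree_true: int = DEFAULT_TRUE_INDEGREE,
    seed: int | np.random.Generator | None = None,
) -> SimulationTruth:
    """Draw a random role-structured DAG on ``p`` nodes.

    Connected nodes are ordered sources first, then intermediates, then
    sinks (each block randomly permuted); every intermediate and sink draws
    between 1 and ``indegree_true`` parents uniformly without replacement
    from the sources/intermediates above it.
    """
    if p0 + p1 + p2 + p3 != p:
        raise DataError("role counts must sum to p")
    if min(p0, p1, p2, p3) < 0 or p < 1:
        raise DataError("role counts must be non-negative and p >= 1")
    if p2 + p3 > 0 and p1 < 1:
        raise DataError("at least one source is required when there are children")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"V{i + 1}" for i in range(p)]
    shuffled = [names[i] for i in rng.permutation(p)]
    independents = shuffled[:p0]
    sources = shuffled[p0 : p0 + p1]
    intermediates = shuffled[p0 + p1 : p0 + p1 + p2]
    sinks = shuffled[p0 + p1 + p2 :]
    roles = {v: ROLE_INDEPENDENT for v in independents}
    roles.update({v: ROLE_SOURCE for v in sources})
    roles.update({v: ROLE_INTERMEDIATE for v in intermediates})
    roles.update({v: ROLE_SINK for v in sinks})
    ordering = (
        [sources[i] for i in rng.permutation(len(sources))]
        + [intermediates[i] for i in rng.permutation(len(intermediates))]
        + [sinks[i] for i in rng.permutation(len(sinks))]
    )
    parent_sets: dict[str, frozenset] = {v: frozenset() for v in names}
    eligible: list[str] = []  # sources/intermediates seen so far, in order
    for v in ordering:
        if roles[v] != ROLE_SOURCE and eligible:
            k = int(rng.integers(1, indegree_true + 1))
            k = min(k, len(eligible))
            chosen = rng.choice(len(eligible), size=k, replace=False)
            parent_sets[v] = frozenset(eligible[i] for i in chosen)
        if roles[v] in (ROLE_SOURCE, ROLE_INTERMEDIATE):
            eligible.append(v)
    truth = SimulationTruth(
        dag=Network(nodes=names, parent_sets=parent_sets),
        roles=roles,
        noise_sd=DEFAULT_NOISE_SD,
        ordering=ordering,
    )
    truth.validate()
    return truth


def simulate_gaussian_data(
    truth: SimulationTruth,
    n: int,
    beta_range: tuple[float, float] = DEFAULT_BETA_RANGE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
) -> Dataset:
    """Sample N rows from the linear-Gaussian structural equation model.

    Each edge gets a coefficient with |beta| uniform in ``beta_range`` and a
    random sign, stored on ``truth.coefficients``; roots and independent
    nodes are standard normal, children add Gaussian noise with sd
    ``noise_sd``.
    """
    if n < 1:
        raise DataError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = truth.dag.nodes
    truth.coefficients = {}
    truth.noise_sd = float(noise_sd)
    for child in names:
        for parent in sorted(truth.dag.parent_sets[child]):
            mag = rng.uniform(beta_range[0], beta_range[1])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.coefficients[(parent, child)] = sign * mag
    values: dict[str, np.ndarray] = {}
    order = [v for v in truth.ordering] + [
        v for v in names if v not in set(truth.ordering)
    ]
    for v in order:
        parents = sorted(truth.dag.parent_sets[v])
        if not parents:
            values[v] = rng.normal(0.0, 1.0, size=n)
        else:
            x = rng.normal(0.0, noise_sd, size=n)
            for parent in parents:
                x = x + truth.coefficients[(parent, v)] * values[parent]
            values[v] = x
    frame = pd.DataFrame({v: values[v] for v in names})
    return Dataset(frame=frame, kinds={v: CONTINUOUS for v in names})


def attach_survival_outcome(
    data: Dataset,
    parent_nodes: list[str],
    effect_sizes: list[float],
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.3,
    seed: int | np.random.Generator | None = None,
    time_col: str = "time",
    status_col: str = "status",
) -> Dataset:
    """Add an exponential proportional-hazards (time, status) pair.

    Event times are exponential with rate ``baseline_hazard * exp(sum
    effect * x)``; independent exponential censoring is tuned so the expected
    censored fraction approximates ``censor_rate``.
    """
    if not (0 <= censor_rate < 1):
        raise DataError("censor_rate must lie in [0, 1)")
    if len(parent_nodes) != len(effect_sizes):
        raise DataError("one effect size per parent node is required")
    unknown = [v for v in parent_nodes if v not in data.columns]
    if unknown:
        raise DataError(f"unknown parent nodes: {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lp = np.zeros(data.n)
    for v, eff in zip(parent_nodes, effect_sizes):
        lp = lp + eff * data.column(v).astype(float)
    rate = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate == 0:
        time, status = event_time, np.ones(data.n)
    else:
        # For independent exponentials, P(censored | rate_i) = c / (c + rate_i).
        def expected_censoring(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + rate))) - censor_rate

        log_c = brentq(expected_censoring, -30.0, 30.0)
        censor_time = rng.exponential(np.exp(-log_c), size=data.n)
        status = (event_time <= censor_time).astype(float)
        time = np.minimum(event_time, censor_time)
    frame = data.frame.copy()
    frame[time_col] = time
    frame[status_col] = status
    kinds = dict(data.kinds)
    kinds[time_col] = CONTINUOUS
    kinds[status_col] = CONTINUOUS
    return Dataset(
        frame=frame,
        kinds=kinds,
        outcome=status_col,
        outcome_type="survival",
        time_col=time_col,
        status_col=status_col,
        levels=dict(data.levels),
    )


def export_truth(truth: SimulationTruth, edges_path, roles_path) -> None:
    """Write the generating edges (with coefficients) and node roles as TSV."""
    rows = [
        (child, parent, truth.coefficients.get((parent, child), np.nan))
        for child, ps in truth.dag.parent_sets.items()
        for parent in sorted(ps)
    ]
    pd.DataFrame(rows, columns=["child", "parent", "beta"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.roles.items()), columns=["node", "role"]
    ).to_csv(roles_path, sep="\t", index=False)
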