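"""Core domain types and tabular/graph I/O.

A :class:`Dataset` wraps an N x p observation table with per-column kinds
(continuous or categorical) and an optional designated outcome, which may be a
continuous column, a binary column, or a survival (time, status) pair.  A
:class:`Network` is a DAG represented as a vector of per-node parent sets,
optionally carrying a consistent node ordering and a total score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
KINDS = (CONTINUOUS, CATEGORICAL)
OUTCOME_TYPES = ("continuous", "binary", "survival")

#: Absolute tolerance below which two scores are treated as tied.
TIE_TOL = 1e-9


class DataError(ValueError):
    """An input table or schema violates the dataset contract."""


class ConfigError(ValueError):
    """A run configuration is internally inconsistent."""


@dataclass
class Dataset:
    """An observation table with column kinds and an optional outcome.

    ``frame`` holds numeric values only: continuous columns as floats and
    categorical columns as integer codes ``0..L-1`` whose original labels are
    kept in ``levels``.  For a survival outcome the network node is the status
    column; the time column is auxiliary and never enters the graph.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    outcome: str | None = None
    outcome_type: str | None = None
    time_col: str | None = None
    status_col: str | None = None
    levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- shape -----------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.frame.shape[0])

    @property
    def p(self) -> int:
        return int(self.frame.shape[1])

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def nodes(self) -> list[str]:
        """Columns that can appear as network nodes (time column excluded)."""
        return [c for c in self.frame.columns if c != self.time_col]

    @property
    def feature_nodes(self) -> list[str]:
        """Network nodes other than the designated outcome."""
        return [c for c in self.nodes if c != self.outcome]

    def kind(self, column: str) -> str:
        return self.kinds[column]

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def n_levels(self, column: str) -> int:
        if column in self.levels:
            return len(self.levels[column])
        return int(len(np.unique(self.frame[column].to_numpy())))

    # -- contract --------------------------------------------------------
    def validate(self) -> None:
        if self.frame.shape[0] < 1 or self.frame.shape[1] < 1:
            raise DataError("dataset must have N >= 1 rows and p >= 1 columns")
        names = list(self.frame.columns)
        if len(set(names)) != len(names):
            raise DataError("duplicate column names")
        missing = [c for c in names if c not in self.kinds]
        if missing:
            raise DataError(f"no kind declared for columns: {missing}")
        for c, k in self.kinds.items():
            if k not in KINDS:
                raise DataError(f"unknown kind {k!r} for column {c!r}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("dataset values must be numeric after encoding")
        if np.isnan(values.astype(float)).any():
            bad = [c for c in names if self.frame[c].isna().any()]
            raise DataError(f"missing values in columns: {bad}")
        if self.outcome_type is not None:
            if self.outcome_type not in OUTCOME_TYPES:
                raise DataError(f"unknown outcome type {self.outcome_type!r}")
            if self.outcome_type == "survival":
                if self.time_col is None or self.status_col is None:
                    raise DataError("survival outcome needs time and status columns")
                for c in (self.time_col, self.status_col):
                    if c not in names:
                        raise DataError(f"missing column {c!r}")
                t = self.frame[self.time_col].to_numpy(dtype=float)
                if not (t > 0).all():
                    raise DataError("survival times must be positive")
                s = self.frame[self.status_col].to_numpy(dtype=float)
                if not np.isin(s, (0.0, 1.0)).all():
                    raise DataError("status values must be 0 or 1")
                if self.outcome is None:
                    self.outcome = self.status_col
            else:
                if self.outcome is None:
                    raise DataError("outcome_type declared without an outcome column")
                if self.outcome not in names:
                    raise DataError(f"missing outcome column {self.outcome!r}")
                if self.outcome_type == "binary":
                    y = self.frame[self.outcome].to_numpy(dtype=float)
                    if not np.isin(y, (0.0, 1.0)).all():
                        raise DataError("binary outcome values must be 0 or 1")
        elif self.outcome is not None:
            raise DataError("outcome column declared without an outcome_type")

    def restricted_to(self, columns: Sequence[str]) -> "Dataset":
        """A view of the dataset keeping ``columns`` (plus any survival pair)."""
        keep = list(columns)
        if self.outcome_type == "survival" and self.status_col in keep:
            if self.time_col not in keep:
                keep = keep + [self.time_col]
        sub = self.frame[keep].copy()
        kinds = {c: self.kinds[c] for c in keep}
        levels = {c: self.levels[c] for c in keep if c in self.levels}
        outcome = self.outcome if self.outcome in keep else None
        return Dataset(
            frame=sub,
            kinds=kinds,
            outcome=outcome,
            outcome_type=self.outcome_type if outcome is not None else None,
            time_col=self.time_col if outcome is not None else None,
            status_col=self.status_col if outcome is not None else None,
            levels=levels,
        )


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    kinds: Mapping[str, str] | None = None,
    outcome: str | None = None,
    outcome_type: str | None = None,
    time: str | None = None,
    status: str | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a header-ed CSV/TSV into a :class:`Dataset`.

    ``kinds`` may declare a kind per column; undeclared numeric columns are
    continuous and undeclared non-numeric columns categorical.  Categorical
    values are mapped to integer codes ``0..L-1`` in sorted label order, with
    the label table stored on the dataset.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = _infer_sep(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate column names in header: {dupes}")
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[0] < 1:
        raise DataError("dataset has no rows")
    if raw.isna().any().any():
        bad = [c for c in raw.columns if raw[c].isna().any()]
        raise DataError(f"missing values in columns: {bad}")
    kinds = dict(kinds or {})
    for c in kinds:
        if c not in raw.columns:
            raise DataError(f"declared column {c!r} not in file")
    for name in (outcome, time, status):
        if name is not None and name not in raw.columns:
            raise DataError(f"declared column {name!r} not in file")

    frame = pd.DataFrame(index=raw.index)
    resolved: dict[str, str] = {}
    levels: dict[str, list] = {}
    for c in raw.columns:
        declared = kinds.get(c)
        numeric = pd.api.types.is_numeric_dtype(raw[c])
        kind = declared or (CONTINUOUS if numeric else CATEGORICAL)
        if kind == CONTINUOUS:
            if not numeric:
                raise DataError(f"non-numeric value in continuous column {c!r}")
            frame[c] = raw[c].astype(float)
        else:
            labs = sorted(raw[c].unique().tolist())
            code = {lab: i for i, lab in enumerate(labs)}
            frame[c] = raw[c].map(code).astype(int)
            levels[c] = labs
        resolved[c] = kind

    if outcome_type == "survival":
        if time is None or status is None:
            raise DataError("survival outcome requires --time and --status columns")
        outcome = outcome or status
    return Dataset(
        frame=frame,
        kinds=resolved,
        outcome=outcome,
        outcome_type=outcome_type,
        time_col=time,
        status_col=status,
        levels=levels,
    )


def write_dataset(data: Dataset, path: str | Path, sep: str | None = None) -> None:
    """Write a dataset back to CSV/TSV, decoding categorical codes to labels."""
    path = Path(path)
    sep = _infer_sep(path, sep)
    out = data.frame.copy()
    for c, labs in data.levels.items():
        out[c] = out[c].map(dict(enumerate(labs)))
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """A DAG as a vector of parent sets, with an optional score and ordering."""

    nodes: list[str]
    parent_sets: dict[str, frozenset[str]]
    total_score: float | None = None
    ordering: list[str] | None = None

    def __post_init__(self) -> None:
        self.parent_sets = {
            v: frozenset(self.parent_sets.get(v, frozenset())) for v in self.nodes
        }

    def edges(self) -> set[tuple[str, str]]:
        """Directed edges as (parent, child) pairs."""
        return {(u, v) for v, ps in self.parent_sets.items() for u in ps}

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())

    def validate(self, indegree: int | None = None) -> None:
        for v, ps in self.parent_sets.items():
            if v in ps:
                raise DataError(f"node {v!r} is its own parent")
            unknown = ps - set(self.nodes)
            if unknown:
                raise DataError(f"parents of {v!r} outside node set: {sorted(unknown)}")
            if indegree is not None and len(ps) > indegree:
                raise DataError(f"node {v!r} exceeds in-degree {indegree}")
        if not self.is_acyclic():
            raise DataError("graph has a directed cycle")
        if self.ordering is not None:
            if sorted(self.ordering) != sorted(self.nodes):
                raise DataError("ordering is not a permutation of the nodes")
            seen: set[str] = set()
            for v in self.ordering:
                if not self.parent_sets[v] <= seen:
                    raise DataError(f"ordering inconsistent with parents of {v!r}")
                seen.add(v)


@dataclass
class RunConfig:
    """Parameters controlling screening, scoring and the DP search."""

    score_type: str = "bic"
    alpha_fdr: float | None = None
    corr_cutoff: float | None = None
    indegree: int = 2
    phenotype_levels: int = 0
    max_tied_networks: int = 32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.score_type not in ("bic", "bge"):
            raise ConfigError(f"unknown score type {self.score_type!r}")
        if (self.alpha_fdr is None) == (self.corr_cutoff is None):
            raise ConfigError("exactly one of alpha_fdr / corr_cutoff must be set")
        if self.alpha_fdr is not None and not (0 < self.alpha_fdr <= 1):
            raise ConfigError("alpha_fdr must lie in (0, 1]")
        if self.corr_cutoff is not None and self.corr_cutoff < 0:
            raise ConfigError("corr_cutoff must be non-negative")
        if self.indegree < 1:
            raise ConfigError("indegree must be >= 1")
        if self.phenotype_levels not in (0, 2, 3):
            raise ConfigError("phenotype_levels must be 0, 2 or 3")
        if self.max_tied_networks < 1:
            raise ConfigError("max_tied_networks must be >= 1")


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------


def _dot_quote(name: str) -> str:
    return '"' + str(name).replace('"', '\\"') + '"'


def write_networks(
    networks: Sequence[Network], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write learned networks as edge-list TSV, Graphviz DOT, or JSON."""
    if not networks:
        raise DataError("no networks to write")
    path = Path(path)
    if fmt == "tsv":
        rows = []
        for idx, net in enumerate(networks):
            for child, parents in net.parent_sets.items():
                for parent in sorted(parents):
                    rows.append((child, parent, idx, net.total_score))
        df = pd.DataFrame(
            rows, columns=["child", "parent", "network_index", "total_score"]
        )
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "dot":
        chunks = []
        for idx, net in enumerate(networks):
            lines = [f"digraph network_{idx} {{"]
            for v in net.nodes:
                lines.append(f"  {_dot_quote(v)};")
            for v, parents in net.parent_sets.items():
                for u in sorted(parents):
                    lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)};")
            lines.append("}")
            chunks.append("\n".join(lines))
        path.write_text("\n".join(chunks) + "\n")
    elif fmt == "json":
        payload = {
            "networks": [
                {
                    "nodes": net.nodes,
                    "parent_sets": {v: sorted(ps) for v, ps in net.parent_sets.items()},
                    "total_score": net.total_score,
                    "ordering": net.ordering,
                }
                for net in networks
            ]
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise DataError(f"unknown output format {fmt!r}")


def read_networks_json(path: str | Path) -> list[Network]:
    """Round-trip reader for the adjacency JSON written by :func:`write_networks`."""
    payload = json.loads(Path(path).read_text())
    nets = []
    for item in payload["networks"]:
        nets.append(
            Network(
                nodes=list(item["nodes"]),
                parent_sets={v: frozenset(ps) for v, ps in item["parent_sets"].items()},
                total_score=item.get("total_score"),
                ordering=item.get("ordering"),
            )
        )
    return nets
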