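"""Structure-recovery metrics: edge confusion, FDR and Hamming distance.

A predicted network is compared to the generating truth either on directed
edges or on skeletons (unordered pairs).  FDR = FP / (FP + TP) with the
no-discoveries case defined as 0; the Hamming distance FP + FN counts the
edge additions and deletions separating the two graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import Network


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    mode: str = "directed"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")
        if self.mode not in ("directed", "undirected"):
            raise MetricsError(f"unknown comparison mode {self.mode!r}")


def _edge_set(network: Network, mode: str) -> set:
    edges = network.edges()
    if mode == "directed":
        return set(edges)
    return {frozenset(e) for e in edges}


def edge_confusion(
    predicted: Network, truth: Network, mode: str = "directed"
) -> ConfusionCounts:
    """Count true/false positives and false negatives between edge sets."""
    if set(predicted.nodes) != set(truth.nodes):
        raise MetricsError("predicted and truth networks have different node sets")
    pred = _edge_set(predicted, mode)
    true = _edge_set(truth, mode)
    return ConfusionCounts(
        tp=len(pred & true), fp=len(pred - true), fn=len(true - pred), mode=mode
    )


def fdr(counts: ConfusionCounts) -> float:
    """FP / (FP + TP); 0 when there are no discoveries."""
    discoveries = counts.fp + counts.tp
    return counts.fp / discoveries if discoveries else 0.0


def hamming(counts: ConfusionCounts) -> int:
    """FP + FN: additions/deletions turning one edge set into the other."""
    return counts.fp + counts.fn


def evaluate_networks(
    predicted: Sequence[Network], truth: Network, mode: str = "directed"
) -> dict[str, float]:
    """Per-tied-network metrics summarized as best (lowest) and mean."""
    if not predicted:
        raise MetricsError("no predicted networks")
    fdrs, hams = [], []
    for net in predicted:
        counts = edge_confusion(net, truth, mode=mode)
        fdrs.append(fdr(counts))
        hams.append(hamming(counts))
    return {
        "fdr_best": min(fdrs),
        "fdr_mean": sum(fdrs) / len(fdrs),
        "hamming_best": min(hams),
        "hamming_mean": sum(hams) / len(hams),
    }


def aggregate_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per (p, N) group plus an overall row across groups.

    ``results`` needs columns ``p`` and ``N``; every other numeric column is
    averaged.  The overall row is the unweighted mean of the group means.
    """
    if len(results) == 0:
        raise MetricsError("no replicate results to aggregate")
    value_cols = [c for c in results.columns if c not in ("p", "N")]
    grouped = (
        results.groupby(["p", "N"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    grouped.insert(2, "replicates", [
        int(((results["p"] == row.p) & (results["N"] == row.N)).sum())
        for row in grouped.itertuples(index=False)
    ])
    overall = {"p": "all", "N": "all", "replicates": int(len(results))}
    for c in value_cols:
        overall[c] = float(grouped[c].mean())
    return pd.concat([grouped, pd.DataFrame([overall])], ignore_index=True)
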