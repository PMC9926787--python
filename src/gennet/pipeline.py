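"""End-to-end learning pipeline: screen -> score -> search -> networks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datamodel import ConfigError, Dataset, Network, RunConfig
from .dp import (
    BestParentsTable,
    SinkLattice,
    compute_best_parents,
    compute_best_sinks,
    compute_local_scores,
    reconstruct_networks,
)
from .scoring import LocalScoreTable
from .screening import (
    FeasibleSet,
    ParentSetMap,
    build_feasible_set,
    build_parent_sets,
    cox_screen,
    feasible_from_parent_map,
    logistic_screen,
    pairwise_association,
)

logger = logging.getLogger(__name__)


@dataclass
class LearnResult:
    networks: list[Network]
    feasible: FeasibleSet
    parent_map: ParentSetMap
    score_table: LocalScoreTable
    best_parents: BestParentsTable
    lattice: SinkLattice
    info: dict = field(default_factory=dict)


def screen(data: Dataset, config: RunConfig) -> ParentSetMap:
    """Build possible-parent sets, routing the outcome through its own test."""
    assoc = pairwise_association(data)
    pp = build_parent_sets(assoc, config, outcome=data.outcome)
    if data.outcome is not None and data.outcome_type in ("binary", "survival"):
        if config.alpha_fdr is None:
            raise ConfigError(
                "binary/survival outcome screening needs an FDR threshold; "
                "set alpha_fdr"
            )
        table = (
            cox_screen(data)
            if data.outcome_type == "survival"
            else logistic_screen(data)
        )
        selected = tuple(
            sorted(table.loc[table["q"] <= config.alpha_fdr, "feature"])
        )
        pp = ParentSetMap(
            pp={**pp.pp, data.outcome: selected}, provenance=pp.provenance
        )
    return pp


def learn_network(data: Dataset, config: RunConfig) -> LearnResult:
    """Run the full pipeline and return optimal network(s) with diagnostics."""
    pp = screen(data, config)
    if config.phenotype_levels > 0:
        if data.outcome is None:
            raise ConfigError("phenotype-driven search requires an outcome column")
        feasible = build_feasible_set(pp, data.outcome, config.phenotype_levels)
    else:
        feasible = feasible_from_parent_map(pp)
    logger.info("feasible set size p_bar = %d", feasible.p_bar)
    table = compute_local_scores(
        data, feasible, score_type=config.score_type, indegree=config.indegree
    )
    bp = compute_best_parents(table, feasible)
    lattice = compute_best_sinks(feasible, bp)
    networks = reconstruct_networks(
        lattice, bp, table, feasible, max_tied=config.max_tied_networks
    )
    complete = lattice.max_level() == feasible.p_bar
    info = {
        "p_bar": feasible.p_bar,
        "n_reachable_subsets": len(lattice.reachable),
        "n_networks": len(networks),
        "best_score": networks[0].total_score if networks else None,
        "complete_ordering_found": complete,
    }
    logger.info(
        "reachable subsets = %d, tied best networks = %d, best score = %s",
        info["n_reachable_subsets"],
        info["n_networks"],
        info["best_score"],
    )
    return LearnResult(
        networks=networks,
        feasible=feasible,
        parent_map=pp,
        score_table=table,
        best_parents=bp,
        lattice=lattice,
        info=info,
    )
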