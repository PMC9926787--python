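"""Possible-parent identification by marginal association screening.

Candidate parent sets are built from pairwise marginal association tests:
Pearson correlation between continuous pairs, one-way ANOVA for a
categorical/continuous pair, and a chi-square independence test for two
categorical columns.  Selection uses either a Benjamini-Hochberg FDR cutoff
over the single family of all tested pairs, or an absolute-correlation cutoff.
Survival and binary outcomes are screened per feature with Cox and logistic
likelihood-ratio tests respectively, since the outcome then has no Pearson
correlation with the features.

Phenotype-driven search reduces the node set to the outcome's ancestors up to
two or three levels (parents, grandparents, great-grandparents), producing the
feasible set actually searched by the dynamic program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CATEGORICAL, CONTINUOUS, ConfigError, DataError, Dataset, RunConfig


class ScreeningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise association
# ---------------------------------------------------------------------------


@dataclass
class PairwiseAssociation:
    """Symmetric matrices of association statistics and raw p-values."""

    nodes: list[str]
    stat: pd.DataFrame
    pvalue: pd.DataFrame

    def pairs(self) -> pd.DataFrame:
        """Upper-triangle pair table (node_a, node_b, statistic, raw_p)."""
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                rows.append((a, b, self.stat.loc[a, b], self.pvalue.loc[a, b]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "statistic", "raw_p"])


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-test p-values for all column pairs."""
    n, p = x.shape
    sd = x.std(axis=0)
    constant = sd <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    if n < 3:
        pval = np.ones((p, p))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval[constant, :] = 1.0
    pval[:, constant] = 1.0
    np.fill_diagonal(pval, 0.0)
    return r, pval


def _mixed_pair_test(
    x: np.ndarray, y: np.ndarray, kind_x: str, kind_y: str
) -> tuple[float, float]:
    if len(x) < 3:
        return 0.0, 1.0
    if kind_x == CONTINUOUS and kind_y == CONTINUOUS:
        if x.std() <= 0 or y.std() <= 0:
            return 0.0, 1.0
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if kind_x == CATEGORICAL and kind_y == CATEGORICAL:
        table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2:
            return 0.0, 1.0
        res = stats.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    # one categorical, one continuous -> one-way ANOVA F-test
    if kind_x == CATEGORICAL:
        codes, values = x, y
    else:
        codes, values = y, x
    if values.std() <= 0:
        return 0.0, 1.0
    groups = [values[codes == c] for c in np.unique(codes)]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        return 0.0, 1.0
    try:
        f, p = stats.f_oneway(*groups)
    except Exception:
        return 0.0, 1.0
    if not np.isfinite(f) or not np.isfinite(p):
        return 0.0, 1.0
    return float(f), float(p)


def pairwise_association(
    data: Dataset, method: str = "auto", nodes: Sequence[str] | None = None
) -> PairwiseAssociation:
    """Test every pair of nodes for marginal association.

    ``method='pearson'`` requires all-continuous nodes; ``'auto'`` dispatches
    on column kinds.  Pairs involving a constant column (or any pair when
    N < 3) are untestable and receive p = 1.
    """
    if nodes is None:
        nodes = [
            c
            for c in data.nodes
            if not (c == data.outcome and data.outcome_type in ("binary", "survival"))
        ]
    nodes = list(nodes)
    kinds = [data.kind(c) for c in nodes]
    all_cont = all(k == CONTINUOUS for k in kinds)
    if method == "pearson" and not all_cont:
        raise ScreeningError("pearson method requires all-continuous nodes")
    p = len(nodes)
    if all_cont:
        x = data.frame[nodes].to_numpy(dtype=float)
        r, pv = _pearson_matrix(x)
    else:
        r = np.zeros((p, p))
        pv = np.ones((p, p))
        np.fill_diagonal(pv, 0.0)
        cols = {c: data.column(c) for c in nodes}
        for i in range(p):
            for j in range(i + 1, p):
                s, q = _mixed_pair_test(
                    cols[nodes[i]], cols[nodes[j]], kinds[i], kinds[j]
                )
                r[i, j] = r[j, i] = s
                pv[i, j] = pv[j, i] = q
    return PairwiseAssociation(
        nodes=nodes,
        stat=pd.DataFrame(r, index=nodes, columns=nodes),
        pvalue=pd.DataFrame(pv, index=nodes, columns=nodes),
    )


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ScreeningError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Parent-set construction
# ---------------------------------------------------------------------------


@dataclass
class ParentSetMap:
    """Per-node possible-parent sets plus the screening evidence behind them."""

    pp: dict[str, tuple[str, ...]]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["node_a", "node_b", "statistic", "raw_p", "q", "selected"]
        )
    )

    def __post_init__(self) -> None:
        for v, parents in self.pp.items():
            if v in parents:
                raise ScreeningError(f"node {v!r} listed as its own possible parent")

    def get(self, node: str) -> tuple[str, ...]:
        return self.pp.get(node, ())


def build_parent_sets(
    assoc: PairwiseAssociation, config: RunConfig, outcome: str | None = None
) -> ParentSetMap:
    """Select associated pairs and convert them to symmetric parent candidacy.

    In FDR mode a pair is associated iff its BH q-value (over the single
    family of all tested pairs) is at most ``alpha_fdr``; in correlation mode
    iff the absolute statistic reaches ``corr_cutoff``.  An associated pair
    (a, b) makes each a candidate parent of the other, except that a
    designated outcome is a sink and never anyone's parent.
    """
    table = assoc.pairs()
    if config.alpha_fdr is not None:
        table["q"] = bh_adjust(table["raw_p"]) if len(table) else []
        table["selected"] = table["q"] <= config.alpha_fdr
    else:
        table["q"] = np.nan
        table["selected"] = table["statistic"].abs() >= config.corr_cutoff
    pp: dict[str, list[str]] = {v: [] for v in assoc.nodes}
    for row in table.itertuples(index=False):
        if not row.selected:
            continue
        a, b = row.node_a, row.node_b
        if b != outcome:
            pp[a].append(b)
        if a != outcome:
            pp[b].append(a)
    return ParentSetMap(
        pp={v: tuple(sorted(set(ps))) for v, ps in pp.items()},
        provenance=table,
    )


# ---------------------------------------------------------------------------
# Outcome screening (survival / binary)
# ---------------------------------------------------------------------------


def null_cox_loglik(time: np.ndarray, status: np.ndarray) -> float:
    """Cox partial log-likelihood of the covariate-free model (Efron ties)."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=float)
    ll = 0.0
    for t in np.unique(time[status == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (status == 1)).sum())
        ll -= sum(np.log(n_risk - l) for l in range(d))
    return ll


def cox_screen(
    data: Dataset,
    features: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Cox proportional-hazards screening for a survival outcome.

    Each feature is fit in its own Cox model (with any shared covariates); the
    p-value is the 1-df likelihood-ratio chi-square against the model without
    the feature, and q-values are BH-adjusted across features.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if data.outcome_type != "survival":
        raise ScreeningError("cox_screen requires a survival outcome")
    time = data.column(data.time_col).astype(float)
    status = data.column(data.status_col).astype(float)
    if status.sum() < 1:
        raise ScreeningError("no events in survival data")
    if features is None:
        features = [
            c for c in data.feature_nodes if c not in set(covariates or ())
        ]
    covariates = list(covariates or ())

    if covariates:
        base = pd.DataFrame({"time": time, "status": status})
        for c in covariates:
            base[c] = data.column(c).astype(float)
        cph0 = CoxPHFitter()
        cph0.fit(base, duration_col="time", event_col="status")
        ll_null = float(cph0.log_likelihood_)
    else:
        ll_null = null_cox_loglik(time, status)

    rows = []
    for feat in features:
        x = data.column(feat).astype(float)
        if x.std() <= 0:
            rows.append((feat, 0.0, 1.0))
            continue
        df = pd.DataFrame({"time": time, "status": status, feat: x})
        for c in covariates:
            df[c] = data.column(c).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="status")
            lr = 2.0 * (float(cph.log_likelihood_) - ll_null)
            pval = float(stats.chi2.sf(max(lr, 0.0), df=1))
            rows.append((feat, lr, pval))
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            warnings.warn(f"Cox fit failed for feature {feat!r}; assigning p = 1")
            rows.append((feat, 0.0, 1.0))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "raw_p"])
    out["q"] = bh_adjust(out["raw_p"])
    return out


def logistic_screen(
    data: Dataset, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-feature logistic-regression LR screening for a binary outcome."""
    import statsmodels.api as sm

    if data.outcome_type != "binary":
        raise ScreeningError("logistic_screen requires a binary outcome")
    y = data.column(data.outcome).astype(float)
    if features is None:
        features = data.feature_nodes
    rows = []
    for feat in features:
        x = data.column(feat).astype(float)
        if x.std() <= 0:
            rows.append((feat, 0.0, 1.0))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            lr = 2.0 * (fit.llf - fit.llnull)
            rows.append((feat, lr, float(stats.chi2.sf(max(lr, 0.0), df=1))))
        except Exception:
            warnings.warn(f"logistic fit failed for feature {feat!r}; assigning p = 1")
            rows.append((feat, 0.0, 1.0))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "raw_p"])
    out["q"] = bh_adjust(out["raw_p"])
    return out


# ---------------------------------------------------------------------------
# Feasible set
# ---------------------------------------------------------------------------


@dataclass
class FeasibleSet:
    """Nodes retained for the search, with parent sets restricted to them."""

    nodes: list[str]
    reduced_pp: dict[str, tuple[str, ...]]
    level_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = set(self.nodes)
        for v in self.nodes:
            self.reduced_pp.setdefault(v, ())
            bad = set(self.reduced_pp[v]) - members
            if bad:
                raise ScreeningError(
                    f"possible parents of {v!r} outside feasible set: {sorted(bad)}"
                )

    @property
    def p_bar(self) -> int:
        return len(self.nodes)


def feasible_from_parent_map(
    pp: ParentSetMap, nodes: Sequence[str] | None = None
) -> FeasibleSet:
    """Feasible set covering all screened nodes (no phenotype reduction)."""
    nodes = list(nodes if nodes is not None else pp.pp.keys())
    members = set(nodes)
    reduced = {v: tuple(x for x in pp.get(v) if x in members) for v in nodes}
    return FeasibleSet(nodes=nodes, reduced_pp=reduced)


def build_feasible_set(pp: ParentSetMap, outcome: str, levels: int) -> FeasibleSet:
    """Restrict the graph to the outcome's ancestors up to ``levels`` levels.

    Level 1 holds the outcome's possible parents, level 2 their possible
    parents not already assigned, and so on; the feasible set is the outcome
    plus levels 1..``levels``, with every parent set intersected with it.
    """
    if levels not in (2, 3):
        raise ScreeningError("phenotype-driven search uses 2 or 3 ancestor levels")
    level_of: dict[str, int] = {outcome: 0}
    current = [v for v in pp.get(outcome) if v != outcome]
    for v in current:
        level_of.setdefault(v, 1)
    for k in range(2, levels + 1):
        nxt: list[str] = []
        for v in current:
            for u in pp.get(v):
                if u not in level_of:
                    level_of[u] = k
                    nxt.append(u)
        current = nxt
    nodes = sorted(level_of, key=lambda v: (level_of[v], v))
    members = set(nodes)
    reduced = {
        v: tuple(x for x in pp.get(v) if x in members and x != outcome) for v in nodes
    }
    return FeasibleSet(nodes=nodes, reduced_pp=reduced, level_of=level_of)
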