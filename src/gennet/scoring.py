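"""Decomposable local scores for node-with-parents families.

Two score functions are provided, both on the "larger is better" scale:

* **BIC** — maximized log-likelihood of the family's conditional model minus
  ``(k/2) ln N`` where ``k`` counts free parameters.  Continuous children use
  a linear-Gaussian regression (MLE variance, so ``k`` = design rank + 1);
  categorical children use a saturated multinomial per observed parent
  configuration; a designated binary or survival outcome uses logistic or Cox
  partial likelihood.
* **BGe** — the Bayesian Gaussian-equivalent log marginal likelihood under a
  normal-Wishart prior, computed per family as the difference of two subset
  marginal likelihoods.  BGe assigns equal scores to Markov-equivalent DAGs.

The total network score is the sum of its local scores (decomposability),
which is what makes the sink-removal dynamic program exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import multigammaln

from .datamodel import CATEGORICAL, CONTINUOUS, DataError, Dataset, Network

NEG_INF = float("-inf")

#: Variance floor below which a Gaussian family is treated as degenerate.
_VAR_FLOOR = 1e-12


class ScoreError(ValueError):
    pass


class DegenerateDataError(ScoreError):
    """The data cannot support the requested fit (e.g. singular scatter)."""


def _design_matrix(data: Dataset, parents: Sequence[str]) -> np.ndarray:
    """Intercept plus parent columns; categorical parents one-hot, drop-first."""
    n = data.n
    cols = [np.ones(n)]
    for par in parents:
        x = data.column(par).astype(float)
        if data.kind(par) == CATEGORICAL:
            n_lev = data.n_levels(par)
            for lev in range(1, n_lev):
                cols.append((data.column(par) == lev).astype(float))
        else:
            cols.append(x)
    return np.column_stack(cols)


def bic_gaussian(node: str, parents: Iterable[str], data: Dataset) -> float:
    """BIC of the linear-Gaussian regression of ``node`` on ``parents``."""
    parents = sorted(set(parents))
    if data.kind(node) != CONTINUOUS:
        raise ScoreError(f"bic_gaussian requires a continuous child, got {node!r}")
    y = data.column(node).astype(float)
    n = data.n
    x = _design_matrix(data, parents)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        warnings.warn(
            f"rank-deficient design for {node!r} | {parents}; "
            "parameter count uses the design rank"
        )
    rss = float(np.sum((y - x @ beta) ** 2))
    sigma2 = rss / n
    if sigma2 < _VAR_FLOOR:
        warnings.warn(f"degenerate (zero-variance) fit for {node!r}; score is -inf")
        return NEG_INF
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = rank + 1  # regression coefficients (incl. intercept) + residual variance
    return ll - 0.5 * k * math.log(n)


def bic_categorical(node: str, parents: Iterable[str], data: Dataset) -> float:
    """BIC of the saturated multinomial of ``node`` given parent configurations."""
    parents = sorted(set(parents))
    if data.kind(node) != CATEGORICAL:
        raise ScoreError(f"bic_categorical requires a categorical child, got {node!r}")
    bad = [p for p in parents if data.kind(p) != CATEGORICAL]
    if bad:
        raise ScoreError(
            f"categorical child {node!r} cannot condition on continuous parents "
            f"{bad}; no conditional model is defined for that direction"
        )
    n = data.n
    child = data.column(node)
    r = data.n_levels(node)
    if parents:
        config = pd.MultiIndex.from_arrays([data.column(p) for p in parents])
        groups = pd.Series(child).groupby(config, sort=False)
        ll = 0.0
        q = 0
        for _, grp in groups:
            q += 1
            counts = grp.value_counts().to_numpy(dtype=float)
            ll += float(np.sum(counts * np.log(counts / counts.sum())))
    else:
        q = 1
        counts = pd.Series(child).value_counts().to_numpy(dtype=float)
        ll = float(np.sum(counts * np.log(counts / n)))
    k = (r - 1) * q
    return ll - 0.5 * k * math.log(n)


def bic_outcome(
    parents: Iterable[str], data: Dataset, outcome_type: str | None = None
) -> float:
    """BIC for the designated outcome: logistic (binary) or Cox (survival).

    The survival penalty scales with the number of events rather than N, the
    effective sample size of the partial likelihood, and counts only the
    regression coefficients (``k`` = number of parents).
    """
    outcome_type = outcome_type or data.outcome_type
    parents = sorted(set(parents))
    if outcome_type == "binary":
        import statsmodels.api as sm

        y = data.column(data.outcome).astype(float)
        x = _design_matrix(data, parents)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            fitted = fit.predict(x)
            if np.all(np.abs(fitted - y) < 1e-8) and len(parents) > 0:
                raise ScoreError("separation")
            ll = float(fit.llf)
        except (ScoreError, Exception):
            warnings.warn(
                f"logistic fit for outcome with parents {parents} is degenerate "
                "(separation or non-convergence); score is -inf"
            )
            return NEG_INF
        k = x.shape[1]  # |parents| + intercept
        return ll - 0.5 * k * math.log(data.n)
    if outcome_type == "survival":
        from lifelines import CoxPHFitter

        from .screening import null_cox_loglik

        time = data.column(data.time_col).astype(float)
        status = data.column(data.status_col).astype(float)
        n_events = int(status.sum())
        if n_events < 1:
            raise ScoreError("no events in survival data")
        if not parents:
            return null_cox_loglik(time, status)
        df = pd.DataFrame({"time": time, "status": status})
        for p in parents:
            df[p] = data.column(p).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="status")
            ll = float(cph.log_likelihood_)
        except Exception:
            warnings.warn(
                f"Cox fit for outcome with parents {parents} failed; score is -inf"
            )
            return NEG_INF
        k = len(parents)
        return ll - 0.5 * k * math.log(n_events)
    raise ScoreError(f"no outcome score defined for outcome type {outcome_type!r}")


# ---------------------------------------------------------------------------
# BGe
# ---------------------------------------------------------------------------


class BgeScorer:
    """BGe local scores over a fixed set of continuous nodes.

    The prior is normal-Wishart with precision matrix ``W ~ Wishart(alpha_w,
    T^{-1})``, ``T = t I``, prior mean ``nu`` set to the sample mean, and mean
    precision scale ``alpha_mu``.  Defaults follow the standard
    score-equivalent parameterization: ``alpha_mu = 1``, ``alpha_w = p + 2``,
    ``t = alpha_mu (alpha_w - p - 1) / (alpha_mu + 1)``.
    """

    def __init__(
        self,
        data: Dataset,
        nodes: Sequence[str] | None = None,
        alpha_mu: float = 1.0,
        alpha_w: float | None = None,
    ) -> None:
        if nodes is None:
            nodes = [c for c in data.nodes if data.kind(c) == CONTINUOUS]
        bad = [c for c in nodes if data.kind(c) != CONTINUOUS]
        if bad:
            raise ScoreError(f"BGe requires continuous nodes; categorical: {bad}")
        self.nodes = list(nodes)
        self._index = {v: i for i, v in enumerate(self.nodes)}
        x = data.frame[self.nodes].to_numpy(dtype=float)
        self.n = x.shape[0]
        self.p = x.shape[1]
        self.alpha_mu = float(alpha_mu)
        self.alpha_w = float(alpha_w if alpha_w is not None else self.p + 2)
        if self.alpha_w <= self.p - 1:
            raise ScoreError("alpha_w must exceed p - 1")
        self.t = self.alpha_mu * (self.alpha_w - self.p - 1) / (self.alpha_mu + 1.0)
        if self.t <= 0:
            raise ScoreError("degrees of freedom too small for a proper prior")
        xbar = x.mean(axis=0)
        centered = x - xbar
        # Prior mean nu equals the sample mean, so the mean-shift term of the
        # posterior scatter vanishes and R = t I + S_N.
        self.r_matrix = self.t * np.eye(self.p) + centered.T @ centered
        self._cache: dict[tuple[int, ...], float] = {(): 0.0}

    def _log_marginal(self, idx: tuple[int, ...]) -> float:
        """Log marginal likelihood of the data restricted to columns ``idx``."""
        if idx in self._cache:
            return self._cache[idx]
        l = len(idx)
        n, t = self.n, self.t
        dof = self.alpha_w - self.p + l
        sub = self.r_matrix[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            raise DegenerateDataError("posterior scatter matrix is not positive definite")
        value = (
            -0.5 * l * n * math.log(math.pi)
            + 0.5 * l * math.log(self.alpha_mu / (self.alpha_mu + n))
            + multigammaln(0.5 * (n + dof), l)
            - multigammaln(0.5 * dof, l)
            + 0.5 * dof * l * math.log(t)
            - 0.5 * (n + dof) * logdet
        )
        self._cache[idx] = value
        return value

    def local(self, node: str, parents: Iterable[str]) -> float:
        """log m(node, parents) = log m(family) - log m(parents)."""
        family = [node, *set(parents)]
        unknown = [v for v in family if v not in self._index]
        if unknown:
            raise ScoreError(
                f"BGe family must be continuous scorer nodes; unknown: {unknown}"
            )
        par_idx = tuple(sorted(self._index[p] for p in set(parents)))
        if self._index[node] in par_idx:
            raise ScoreError(f"node {node!r} cannot be its own parent")
        fam_idx = tuple(sorted(par_idx + (self._index[node],)))
        return self._log_marginal(fam_idx) - self._log_marginal(par_idx)


def bge_local(
    node: str,
    parents: Iterable[str],
    data: Dataset,
    scorer: BgeScorer | None = None,
    **hyper,
) -> float:
    """BGe local score; builds a scorer over the dataset's nodes if not given."""
    if scorer is None:
        scorer = BgeScorer(data, **hyper)
    return scorer.local(node, parents)


# ---------------------------------------------------------------------------
# Dispatch and tables
# ---------------------------------------------------------------------------


def local_score(
    node: str,
    parents: Iterable[str],
    data: Dataset,
    score_type: str = "bic",
    bge_scorer: BgeScorer | None = None,
) -> float:
    """Score the family (node, parents) under the requested score function."""
    parents = sorted(set(parents))
    if node in parents:
        raise ScoreError(f"node {node!r} cannot be its own parent")
    is_outcome = node == data.outcome and data.outcome_type in ("binary", "survival")
    if score_type == "bge":
        if is_outcome:
            raise ScoreError(
                "BGe is defined for all-continuous families; use BIC for "
                "binary/survival outcomes"
            )
        return bge_local(node, parents, data, scorer=bge_scorer)
    if score_type != "bic":
        raise ScoreError(f"unknown score type {score_type!r}")
    if is_outcome:
        return bic_outcome(parents, data)
    if data.kind(node) == CONTINUOUS:
        return bic_gaussian(node, parents, data)
    return bic_categorical(node, parents, data)


@dataclass
class LocalScoreTable:
    """Memoized local scores keyed by (node, parent subset)."""

    scores: dict[str, dict[frozenset, float]]
    score_type: str
    indegree: int

    def get(self, node: str, parents: Iterable[str]) -> float:
        key = frozenset(parents)
        try:
            return self.scores[node][key]
        except KeyError:
            raise ScoreError(f"no score entry for ({node!r}, {sorted(key)})") from None

    def subsets(self, node: str) -> list[frozenset]:
        return list(self.scores[node].keys())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (node, ",".join(sorted(g)), s)
            for node, sub in self.scores.items()
            for g, s in sub.items()
        ]
        return pd.DataFrame(rows, columns=["node", "parents", "score"])


def network_score(network: Network, table: LocalScoreTable) -> float:
    """Total decomposable score: the sum of the network's local scores."""
    total = sum(table.get(v, network.parent_sets[v]) for v in network.nodes)
    network.total_score = total
    return total
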