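"""Two-group differential expression with an empirical-Bayes moderated t-statistic,
Benjamini-Hochberg FDR control, and multi-dataset marker-gene selection.

The model
---------
For probe ``g`` with two groups (``normal`` vs ``BE``) of log2 expression, the
log2 fold change is the difference of group means and the residual variance
``s_g^2`` has ``df_g = n1 + n2 - 2`` degrees of freedom.  Gene variances are
assumed exchangeable with a scaled inverse-chi-square prior
``s_g^2 ~ s0^2 * d0 / chi2(d0)``; the posterior variance

    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

replaces ``s_g^2`` in the t-statistic, which then has ``df_g + d0`` degrees of
freedom.  The hyperparameters ``(d0, s0^2)`` are estimated by matching the
first two moments of ``log s_g^2`` to the implied log-F distribution.

Selection
---------
A gene enters the marker panel when it is present in every dataset considered
and at least one dataset shows ``|logFC|`` above the fold threshold together
with a BH-adjusted p-value below ``alpha``, all qualifying datasets agreeing
in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import (
    DegenerateVarianceError,
    DomainError,
    GroupingError,
)

GROUP_LABELS = ("normal", "BE")

__all__ = [
    "ExpressionDataset",
    "EBayesPrior",
    "SelectionCriteria",
    "ModeratedT",
    "DEResults",
    "log2_fold_change",
    "bh_adjust",
    "estimate_prior",
    "select_genes",
]


@dataclass
class ExpressionDataset:
    """Probe x sample matrix of log2 expression with two-group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes in rows, samples in columns, log2 scale.
    gene_symbols : pandas.Series
        Gene symbol per probe, aligned with ``values.index``.
    groups : pandas.Series
        Group label per sample, values in ``{"normal", "BE"}``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise GroupingError(f"duplicated sample identifiers: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise GroupingError(f"samples without group annotation: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        bad = sorted(set(self.groups) - set(GROUP_LABELS))
        if bad:
            raise GroupingError(f"group labels outside {GROUP_LABELS}: {bad}")
        for label in GROUP_LABELS:
            if (self.groups == label).sum() < 2:
                raise GroupingError(f"group {label!r} has fewer than 2 samples")
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def group_matrix(self, label: str) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == label].index]


@dataclass(frozen=True)
class EBayesPrior:
    """Hyperparameters of the gene-variance prior.

    ``d0`` is the prior degrees of freedom (``inf`` marks the fully pooled
    limit), ``s0_sq`` the prior variance scale.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise DomainError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0) and not (self.d0 == 0):
            raise DomainError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the marker-panel selection rule."""

    lfc_threshold: float = 2.0
    alpha: float = 0.05
    min_significant_datasets: int = 1
    require_all_datasets: bool = True

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise DomainError("lfc_threshold must be >= 0")
        if not (0 <= self.alpha < 1):
            raise DomainError("alpha must lie in [0, 1)")
        if self.min_significant_datasets < 1:
            raise DomainError("min_significant_datasets must be >= 1")


def log2_fold_change(dataset: ExpressionDataset) -> pd.Series:
    """Per-probe log2 fold change, BE minus normal group mean."""
    be = dataset.group_matrix("BE").mean(axis=1)
    normal = dataset.group_matrix("normal").mean(axis=1)
    out = be - normal
    out.name = "logFC"
    return out


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic start 0.5 + 1/x and converges in a handful of steps
    for any positive x.
    """
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Estimate (d0, s0_sq) by moment matching of log s^2.

    With ``s^2 | sigma^2 ~ sigma^2 chi2(df)/df`` and the scaled
    inverse-chi-square prior, ``log s^2`` is a shifted log-F variable whose
    mean and variance involve digamma/trigamma terms of ``df/2`` and
    ``d0/2``; solving the excess-variance equation with the trigamma inverse
    gives ``d0``, and the mean equation then gives ``s0^2``.  An excess
    variance of zero or less yields the pooled limit ``d0 = inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if not ok.any():
        raise DegenerateVarianceError("no positive residual variances to fit the prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = float(_trigamma_inverse(np.array([e_var]))[0])
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, take ``p_(j) * n / j``, enforce monotonicity by a
    cumulative minimum from the largest rank down, cap at 1, and return in
    the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


class ModeratedT:
    """Empirical-Bayes moderated two-sample t model for a two-group dataset.

    Examples
    --------
    >>> model = ModeratedT(dataset)
    >>> res = model.fit()
    >>> res.frame[["logFC", "t_mod", "p", "adj_p"]].head()
    """

    def __init__(self, dataset: ExpressionDataset):
        self.dataset = dataset

    def _group_stats(self):
        ds = self.dataset
        be = ds.group_matrix("BE").to_numpy(dtype=float)
        nm = ds.group_matrix("normal").to_numpy(dtype=float)
        n1 = np.isfinite(nm).sum(axis=1)
        n2 = np.isfinite(be).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(nm, axis=1)
            m2 = np.nanmean(be, axis=1)
            v1 = np.nanvar(nm, axis=1, ddof=1)
            v2 = np.nanvar(be, axis=1, ddof=1)
        df = n1 + n2 - 2
        # pooled residual variance of the two-group linear model
        ss = np.where(n1 > 1, v1 * (n1 - 1), 0.0) + np.where(n2 > 1, v2 * (n2 - 1), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.where(df > 0, ss / np.maximum(df, 1), np.nan)
            stdev_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)
        return m2 - m1, s2, df.astype(float), stdev_unscaled

    def fit(self, prior: EBayesPrior | None = None) -> "DEResults":
        """Fit the model; ``prior`` overrides hyperparameter estimation.

        ``prior=EBayesPrior(0, s0)`` recovers the classical pooled t;
        ``d0=inf`` fully pools every variance to ``s0_sq``.
        """
        logfc, s2, df, su = self._group_stats()
        usable = df >= 1
        if not usable.all():
            warnings.warn(
                f"dropping {int((~usable).sum())} probes with zero residual df",
                stacklevel=2,
            )
        if np.all(~usable | ~np.isfinite(s2) | (s2 <= 0)):
            if not np.any(np.nan_to_num(s2) > 0):
                raise DegenerateVarianceError("all residual variances are zero")
        if prior is None:
            prior = estimate_prior(s2[usable], df[usable])
        d0, s0 = prior.d0, prior.s0_sq
        if np.isinf(d0):
            post_var = np.full_like(s2, s0)
            df_total = np.full_like(df, np.inf)
        else:
            post_var = (d0 * s0 + df * s2) / (d0 + df)
            df_total = df + d0
        with np.errstate(invalid="ignore", divide="ignore"):
            t = logfc / (np.sqrt(post_var) * su)
        p = np.full_like(t, np.nan)
        fin = np.isfinite(t) & usable
        inf_df = fin & np.isinf(df_total)
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
        reg = fin & ~inf_df
        p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), df_total[reg])
        adj = np.full_like(p, np.nan)
        adj[fin] = bh_adjust(p[fin])
        frame = pd.DataFrame(
            {
                "gene_symbol": self.dataset.gene_symbols.to_numpy(),
                "logFC": logfc,
                "t_mod": t,
                "df_total": df_total,
                "p": p,
                "adj_p": adj,
            },
            index=self.dataset.probe_ids,
        )
        frame = frame.loc[usable]
        return DEResults(frame=frame, prior=prior, n_samples=len(self.dataset.groups))


@dataclass
class DEResults:
    """Per-probe differential-expression estimates and the fitted prior."""

    frame: pd.DataFrame
    prior: EBayesPrior
    n_samples: int = 0

    def summary(self, top: int = 10) -> str:
        lines = [
            "Moderated two-sample t (empirical Bayes)",
            f"  probes: {len(self.frame)}   samples: {self.n_samples}",
            f"  prior df d0 = {self.prior.d0:.4g}   prior variance s0^2 = {self.prior.s0_sq:.4g}",
            "",
            self.frame.reindex(self.frame["p"].sort_values().index)
            .head(top)
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="probe_id")


def select_genes(
    evidence: pd.DataFrame, criteria: SelectionCriteria | None = None
) -> pd.DataFrame:
    """Apply the multi-dataset panel-selection rule to a gene evidence table.

    Parameters
    ----------
    evidence : pandas.DataFrame
        Long format with columns ``gene``, ``dataset``, ``logFC``, ``adj_p``,
        ``present`` (boolean) and optionally ``class``.
    criteria : SelectionCriteria

    Returns
    -------
    pandas.DataFrame
        Indexed by gene with columns ``decision`` in
        {selected_up, selected_down, excluded, conflict}, ``n_up``/``n_down``
        qualifying-dataset counts, ``present_in_all``, and ``class`` when
        supplied.
    """
    criteria = criteria or SelectionCriteria()
    if evidence.empty:
        return pd.DataFrame(
            columns=["decision", "n_up", "n_down", "present_in_all"]
        ).rename_axis("gene")
    ev = evidence.copy()
    ev["present"] = ev["present"].astype(bool)
    n_datasets = ev["dataset"].nunique()
    rows = {}
    for gene, sub in ev.groupby("gene", sort=False):
        present_in_all = sub["present"].sum() >= n_datasets
        q = sub[
            sub["present"]
            & (sub["adj_p"] < criteria.alpha)
            & (sub["logFC"].abs() > criteria.lfc_threshold)
        ]
        n_up = int((q["logFC"] > 0).sum())
        n_down = int((q["logFC"] < 0).sum())
        eligible = present_in_all or not criteria.require_all_datasets
        if not eligible:
            decision = "excluded"
        elif n_up > 0 and n_down > 0:
            decision = "conflict"
        elif n_up >= criteria.min_significant_datasets:
            decision = "selected_up"
        elif n_down >= criteria.min_significant_datasets:
            decision = "selected_down"
        else:
            decision = "excluded"
        rows[gene] = {
            "decision": decision,
            "n_up": n_up,
            "n_down": n_down,
            "present_in_all": present_in_all,
        }
        if "class" in sub.columns:
            rows[gene]["class"] = sub["class"].iloc[0]
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")
    return out
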