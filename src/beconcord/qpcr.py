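"""Relative quantification by 2^-ddCt with dual reference genes, group testing,
and direction calling.

Per sample, ``dCt = mean target Ct - mean of the two reference-gene mean Cts``
(the arithmetic mean of Cts equals the geometric mean of linear quantities).
``ddCt`` for a condition is its mean dCt minus the mean dCt of the reference
condition, and the relative quantity is ``RQ = 2^-ddCt``; the reference
condition has RQ 1 by construction.

Group significance is tested on dCt values: a two-sided Student t-test for
two conditions, or many-to-one Dunnett comparisons against the reference
condition when there are more.  The Dunnett adjusted p-value is evaluated
exactly by quadrature over the equicorrelated multivariate-t representation
(the many-to-one contrast correlation always factorises as
``rho_ij = lambda_i * lambda_j``, so a single shared normal factor plus the
pooled-scale chi variable reduces the k-dimensional probability to a 2-D
integral), which covers unbalanced designs as well.

A gene is called ``up``/``down`` only when the fold change reaches the
relevance threshold (two-fold by default, boundary inclusive) *and* the test
is significant; otherwise ``no_change``.  A gene undetected in a condition is
``na`` (no amplification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    InsufficientReplicationError,
    IntegrityError,
    ReferenceIntegrityError,
)

__all__ = [
    "aggregate_replicates",
    "dunnett_pvalue",
    "compare_groups",
    "RelativeQuantifier",
    "QuantResults",
    "call_direction",
    "direction_calls",
]

DIRECTION_TOKENS = ("up", "down", "no_change", "na", "nd")

_CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CT_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"Ct table missing columns: {missing}")
    if table.duplicated(subset=["sample_id", "gene", "replicate"]).any():
        dupes = table[table.duplicated(subset=["sample_id", "gene", "replicate"])]
        raise IntegrityError(
            f"duplicate (sample_id, gene, replicate) rows: {dupes.head().to_dict('records')}"
        )
    ct = table["ct"]
    if ((ct <= 0) & ct.notna()).any():
        raise IntegrityError("Ct values must be positive when present")
    return table


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (sample, gene) with a detection flag.

    A (sample, gene) is undetected when a strict majority of its replicate
    wells are missing; its mean Ct is then missing.  Half missing is not a
    majority, so a duplicate with one missing well keeps the present value.
    """
    table = _validate_ct_table(table)
    grouped = table.groupby(["sample_id", "condition", "gene"], sort=False)["ct"]
    n_total = grouped.size()
    n_missing = grouped.apply(lambda s: int(s.isna().sum()))
    detected = n_missing * 2 <= n_total
    mean_ct = grouped.mean()
    mean_ct[~detected] = np.nan
    # a group whose present replicates are all missing is undetected regardless
    detected = detected & mean_ct.notna()
    out = pd.DataFrame({"ct": mean_ct, "detected": detected}).reset_index()
    return out


def _inner_orthant(u: float, lambdas: np.ndarray, gh_x: np.ndarray, gh_w: np.ndarray) -> float:
    """P(all |lambda_i Z0 + sqrt(1-lambda_i^2) W_i| <= u) by Gauss-Hermite in Z0."""
    z = np.sqrt(2.0) * gh_x
    lam = lambdas[:, None]
    root = np.sqrt(1.0 - lambdas**2)[:, None]
    upper = (u - lam * z[None, :]) / root
    lower = (-u - lam * z[None, :]) / root
    probs = np.clip(stats.norm.cdf(upper) - stats.norm.cdf(lower), 0.0, 1.0)
    prod = np.prod(probs, axis=0)
    return float(np.sum(gh_w * prod) / np.sqrt(np.pi))


def dunnett_pvalue(
    t: float,
    df: float,
    lambdas: Sequence[float],
    n_scale_nodes: int = 256,
    n_factor_nodes: int = 128,
) -> float:
    """Two-sided Dunnett adjusted p-value ``P(max_i |T_i| >= |t|)``.

    ``lambdas[i] = sqrt((1/n0) / (1/n_i + 1/n0))`` carries the one-factor
    correlation structure of the many-to-one contrasts; ``df`` is the pooled
    residual degrees of freedom.  The scale variable ``S = sqrt(chi2_df/df)``
    is integrated by Gauss-Legendre on its probability scale and the shared
    normal factor by Gauss-Hermite.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ConfigurationError("at least one comparison required")
    q = abs(float(t))
    if q == 0.0:
        return 1.0
    if not np.isfinite(q):
        return 0.0
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_factor_nodes)
    if np.isinf(df):
        return 1.0 - _inner_orthant(q, lambdas, gh_x, gh_w)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_scale_nodes)
    # map (-1,1) -> (0,1) probabilities of the chi scale variable
    probs = 0.5 * (gl_x + 1.0)
    weights = 0.5 * gl_w
    s_nodes = stats.chi.ppf(probs, df, scale=1.0 / np.sqrt(df))
    acc = 0.0
    for s, w in zip(s_nodes, weights):
        acc += w * _inner_orthant(q * s, lambdas, gh_x, gh_w)
    return float(min(max(1.0 - acc, 0.0), 1.0))


def _student_t_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Classical two-sided pooled two-sample t-test; zero pooled variance is
    resolved by the mean difference (equal means -> p = 1, unequal -> p = 0)."""
    n1, n2 = len(x), len(y)
    diff = float(np.mean(x) - np.mean(y))
    ss = float(np.var(x, ddof=1) * (n1 - 1) + np.var(y, ddof=1) * (n2 - 1))
    df = n1 + n2 - 2
    if ss == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    s = np.sqrt(ss / df)
    tstat = diff / (s * np.sqrt(1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(tstat), df))


def compare_groups(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
    ref_condition: str,
) -> dict[str, float]:
    """Per-condition p-values of dCt differences against the reference condition.

    Exactly two conditions: two-sided Student t-test.  More: Dunnett
    many-to-one adjusted p-values sharing the pooled residual variance.
    """
    if isinstance(values, pd.DataFrame):
        values = {
            c: sub["delta_ct"].to_numpy(dtype=float)
            for c, sub in values.groupby("condition", sort=False)
        }
    groups = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    if ref_condition not in groups:
        raise ConfigurationError(f"reference condition {ref_condition!r} absent")
    for c, v in groups.items():
        if len(v) < 2:
            raise InsufficientReplicationError(
                f"condition {c!r} has {len(v)} sample(s); need >= 2"
            )
    treatments = [c for c in groups if c != ref_condition]
    if not treatments:
        return {}
    ref = groups[ref_condition]
    if len(treatments) == 1:
        return {treatments[0]: _student_t_pvalue(groups[treatments[0]], ref)}
    # pooled within-group variance across every condition (ANOVA residual)
    all_groups = [ref] + [groups[c] for c in treatments]
    ss = sum(float(np.var(g, ddof=1)) * (len(g) - 1) for g in all_groups)
    df = sum(len(g) for g in all_groups) - len(all_groups)
    n0 = len(ref)
    lambdas = np.array(
        [np.sqrt((1.0 / n0) / (1.0 / len(groups[c]) + 1.0 / n0)) for c in treatments]
    )
    out: dict[str, float] = {}
    if ss == 0.0:
        for c in treatments:
            out[c] = 1.0 if np.mean(groups[c]) == np.mean(ref) else 0.0
        return out
    s2 = ss / df
    for c in treatments:
        n_i = len(groups[c])
        tstat = (np.mean(groups[c]) - np.mean(ref)) / np.sqrt(
            s2 * (1.0 / n_i + 1.0 / n0)
        )
        out[c] = dunnett_pvalue(tstat, df, lambdas)
    return out


@dataclass
class QuantResults:
    """2^-ddCt estimates per (gene, condition) plus per-sample dCt values."""

    frame: pd.DataFrame
    sample_delta_ct: pd.DataFrame
    reference_genes: tuple[str, str]
    reference_condition: str

    def summary(self) -> str:
        lines = [
            "Relative quantification (2^-ddCt)",
            f"  reference genes: {self.reference_genes[0]}/{self.reference_genes[1]}"
            f"   reference condition: {self.reference_condition}",
            "",
            self.frame.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class RelativeQuantifier:
    """Model object computing 2^-ddCt relative quantities from a Ct table.

    Parameters
    ----------
    table : pandas.DataFrame
        Replicate-level Ct records (``sample_id, condition, gene, replicate, ct``).
    reference_genes : pair of str
        The two stable normalisers (default ACTB/GAPDH).
    reference_condition : str
        The untreated/intact baseline condition.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference_genes: Sequence[str] = ("ACTB", "GAPDH"),
        reference_condition: str = "control",
        genes: Sequence[str] | None = None,
    ):
        self.table = _validate_ct_table(table)
        if len(reference_genes) != 2:
            raise ConfigurationError("exactly two reference genes are required")
        self.reference_genes = (str(reference_genes[0]), str(reference_genes[1]))
        if reference_condition not in set(table["condition"]):
            raise ConfigurationError(
                f"reference condition {reference_condition!r} absent from Ct table"
            )
        self.reference_condition = reference_condition
        all_genes = [g for g in table["gene"].unique() if g not in self.reference_genes]
        self.genes = list(genes) if genes is not None else all_genes

    def fit(self) -> QuantResults:
        agg = aggregate_replicates(self.table)
        wide = agg.pivot(index="sample_id", columns="gene", values="ct")
        cond_of = agg.drop_duplicates("sample_id").set_index("sample_id")["condition"]
        cond_of = cond_of.loc[wide.index]
        for ref in self.reference_genes:
            if ref not in wide.columns or wide[ref].isna().any():
                bad = (
                    wide.index[wide[ref].isna()].tolist()
                    if ref in wide.columns
                    else "all samples"
                )
                raise ReferenceIntegrityError(
                    f"reference gene {ref!r} undetected in sample(s): {bad}"
                )
        ref_ct = wide[list(self.reference_genes)].mean(axis=1)
        conditions = list(dict.fromkeys(self.table["condition"]))
        sample_rows = []
        result_rows = []
        for gene in self.genes:
            target = wide[gene] if gene in wide.columns else pd.Series(np.nan, index=wide.index)
            dct = target - ref_ct
            for sample_id, v in dct.items():
                sample_rows.append((sample_id, cond_of.loc[sample_id], gene, v))
            by_cond = {
                c: dct[cond_of == c].dropna().to_numpy() for c in conditions
            }
            baseline_vals = by_cond[self.reference_condition]
            baseline = float(np.mean(baseline_vals)) if len(baseline_vals) else np.nan
            testable = {c: v for c, v in by_cond.items() if len(v) > 0}
            pvals: dict[str, float] = {}
            if (
                len(baseline_vals) >= 2
                and len(testable) >= 2
                and all(len(v) >= 2 for v in testable.values())
            ):
                pvals = compare_groups(testable, self.reference_condition)
            for condition in conditions:
                vals = by_cond[condition]
                detected = len(vals) > 0
                mean_dct = float(np.mean(vals)) if detected else np.nan
                if detected and np.isfinite(baseline):
                    ddct = mean_dct - baseline
                    rq = float(2.0 ** (-ddct))
                else:
                    ddct, rq = np.nan, np.nan
                if condition == self.reference_condition:
                    p = np.nan
                else:
                    p = pvals.get(condition, np.nan)
                result_rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "n_samples": len(vals),
                        "delta_ct": mean_dct,
                        "delta_delta_ct": ddct,
                        "rq": rq,
                        "p": p,
                        "detected": detected,
                    }
                )
        frame = pd.DataFrame(result_rows)
        sample_frame = pd.DataFrame(
            sample_rows, columns=["sample_id", "condition", "gene", "delta_ct"]
        )
        return QuantResults(
            frame=frame,
            sample_delta_ct=sample_frame,
            reference_genes=self.reference_genes,
            reference_condition=self.reference_condition,
        )


def call_direction(
    rq: float,
    p: float,
    detected: bool,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> str:
    """Direction call from relative quantity and significance.

    Undetected -> ``na``.  ``up``/``down`` require both the fold-relevance
    threshold (boundary inclusive: "at least" a two-fold change) and
    ``p < alpha``; anything else is ``no_change``.  A detected gene without a
    computable RQ (no baseline) is ``nd``.
    """
    if fold_threshold < 1:
        raise ConfigurationError("fold_threshold must be >= 1")
    if not detected:
        return "na"
    if not np.isfinite(rq):
        return "nd"
    if np.isfinite(p) and p < alpha:
        if rq >= fold_threshold:
            return "up"
        if rq <= 1.0 / fold_threshold:
            return "down"
    return "no_change"


def direction_calls(
    results: QuantResults,
    condition: str,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene direction calls for one experimental condition.

    A gene undetected in every experimental (non-reference) condition is
    ``na`` for the system regardless of the queried condition.
    """
    frame = results.frame
    if condition not in set(frame["condition"]):
        raise ConfigurationError(f"condition {condition!r} absent from results")
    experimental = frame[frame["condition"] != results.reference_condition]
    never_detected = ~experimental.groupby("gene")["detected"].any()
    sub = frame[frame["condition"] == condition]
    rows = []
    for _, r in sub.iterrows():
        if never_detected.get(r["gene"], False):
            status = "na"
        else:
            status = call_direction(
                r["rq"], r["p"], bool(r["detected"]), fold_threshold, alpha
            )
        rows.append({"gene": r["gene"], "status": status})
    return pd.DataFrame(rows)
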