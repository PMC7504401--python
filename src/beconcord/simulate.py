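"""Synthetic two-group expression matrices and qPCR Ct tables with known truth.

The expression generator draws gene variances from the scaled
inverse-chi-square distribution ``s0_sq * d0 / chi2(d0)`` — the same
hierarchical model the moderated-t stage assumes — so hyperparameter and
effect-size recovery are meaningful tests.  The Ct generator produces
replicate threshold cycles ``Ct = base_ct - log2(fold) + noise`` so that the
downstream 2^-ddCt pipeline recovers the programmed fold change exactly in
the noiseless limit.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionDataset
from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "ExpressionSimSpec",
    "CtSimSpec",
    "simulate_expression",
    "simulate_ct",
    "ct_spec_from_calls",
]


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Specification of a two-group (normal vs BE) log2 expression simulation.

    ``true_logfc`` holds the per-gene log2 effect (0 for null genes); ``d0``
    and ``s0_sq`` parameterise the inverse-chi-square gene-variance prior.
    """

    n_genes: int
    n_per_group: int
    true_logfc: Sequence[float]
    d0: float = 4.0
    s0_sq: float = 0.05
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise DimensionError("n_genes must be >= 1")
        if self.n_per_group < 2:
            raise DimensionError("n_per_group must be >= 2")
        if len(self.true_logfc) != self.n_genes:
            raise DimensionError(
                f"true_logfc has length {len(self.true_logfc)}, expected {self.n_genes}"
            )
        if not (self.d0 > 0):
            raise DimensionError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise DimensionError("s0_sq must be > 0")


@dataclass(frozen=True)
class CtSimSpec:
    """Specification of a replicate-level qPCR Ct simulation.

    ``true_fold`` maps gene -> condition -> linear fold change relative to
    the reference condition (missing entries default to 1).  The two
    ``reference_genes`` are held at fold 1 in every condition; ``na_genes``
    never amplify and emit missing Ct in every replicate.
    """

    genes: Sequence[str]
    conditions: Sequence[str]
    reference_genes: Sequence[str] = ("ACTB", "GAPDH")
    reference_condition: str = "control"
    true_fold: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    base_ct: Mapping[str, float] = field(default_factory=dict)
    default_base_ct: float = 25.0
    noise_sd: float = 0.15
    n_replicates: int = 3
    n_samples: int = 3
    na_genes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_condition not in self.conditions:
            raise ConfigurationError(
                f"reference condition {self.reference_condition!r} absent from conditions"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        missing_refs = [g for g in self.reference_genes if g not in self.genes]
        if missing_refs:
            raise ConfigurationError(f"reference genes not in gene list: {missing_refs}")
        for g, folds in self.true_fold.items():
            for c, f in folds.items():
                if not (f > 0):
                    raise ConfigurationError(f"true_fold must be > 0, got {f} for {g}/{c}")
                if g in self.reference_genes and f != 1.0:
                    raise ConfigurationError(
                        f"reference gene {g} must have true_fold 1 in all conditions"
                    )

    def fold(self, gene: str, condition: str) -> float:
        if gene in self.reference_genes or condition == self.reference_condition:
            return 1.0
        return float(self.true_fold.get(gene, {}).get(condition, 1.0))


def simulate_expression(spec: ExpressionSimSpec):
    """Simulate a two-group log2 expression dataset.

    Returns
    -------
    (ExpressionDataset, dict)
        The dataset and a ground-truth record with the per-gene effect and
        drawn variance.
    """
    rng = np.random.default_rng(spec.seed)
    logfc = np.asarray(spec.true_logfc, dtype=float)
    # scaled inverse-chi-square: s0_sq * d0 / chi2(d0)
    gene_var = spec.s0_sq * spec.d0 / rng.chisquare(spec.d0, size=spec.n_genes)
    sd = np.sqrt(gene_var)[:, None]
    n = spec.n_per_group
    normal = spec.baseline + sd * rng.standard_normal((spec.n_genes, n))
    be = spec.baseline + logfc[:, None] + sd * rng.standard_normal((spec.n_genes, n))
    width = len(str(spec.n_genes))
    probes = [f"P{i + 1:0{width}d}" for i in range(spec.n_genes)]
    genes = [f"GENE{i + 1:0{width}d}" for i in range(spec.n_genes)]
    samples = [f"normal_{i + 1}" for i in range(n)] + [f"BE_{i + 1}" for i in range(n)]
    values = pd.DataFrame(np.hstack([normal, be]), index=probes, columns=samples)
    groups = pd.Series(["normal"] * n + ["BE"] * n, index=samples, name="group")
    dataset = ExpressionDataset(
        values=values,
        gene_symbols=pd.Series(genes, index=probes, name="gene_symbol"),
        groups=groups,
    )
    truth = {
        "true_logfc": dict(zip(genes, logfc.tolist())),
        "gene_variance": dict(zip(genes, gene_var.tolist())),
        "d0": spec.d0,
        "s0_sq": spec.s0_sq,
        "seed": spec.seed,
    }
    return dataset, truth


def simulate_ct(spec: CtSimSpec):
    """Simulate a replicate-level Ct table.

    Non-reference gene ``g`` in condition ``c`` gets replicate
    ``Ct ~ Normal(base_ct(g) - log2(fold(g, c)), noise_sd)``; genes in
    ``na_genes`` emit missing Ct everywhere.

    Returns
    -------
    (pandas.DataFrame, dict)
        Long-format Ct table with columns
        ``sample_id, condition, gene, replicate, ct`` and the ground-truth
        fold table.
    """
    rng = np.random.default_rng(spec.seed)
    na = set(spec.na_genes)
    records = []
    for condition in spec.conditions:
        for s in range(spec.n_samples):
            sample_id = f"{condition}_s{s + 1}"
            for gene in spec.genes:
                base = float(spec.base_ct.get(gene, spec.default_base_ct))
                mean_ct = base - np.log2(spec.fold(gene, condition))
                for rep in range(spec.n_replicates):
                    if gene in na:
                        ct = np.nan
                    else:
                        ct = mean_ct + spec.noise_sd * rng.standard_normal()
                    records.append((sample_id, condition, gene, rep + 1, ct))
    table = pd.DataFrame(
        records, columns=["sample_id", "condition", "gene", "replicate", "ct"]
    )
    truth = {
        "true_fold": {
            g: {c: spec.fold(g, c) for c in spec.conditions} for g in spec.genes
        },
        "na_genes": sorted(na),
        "reference_genes": list(spec.reference_genes),
        "reference_condition": spec.reference_condition,
        "seed": spec.seed,
    }
    return table, truth


def ct_spec_from_calls(
    statuses: Mapping[str, str],
    up_fold: float = 4.0,
    down_fold: float = 0.25,
    reference_genes: Sequence[str] = ("ACTB", "GAPDH"),
    reference_condition: str = "control",
    treated_condition: str = "treated",
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    n_samples: int = 4,
    seed: int = 0,
) -> CtSimSpec:
    """Build a Ct simulation spec that encodes a set of direction calls.

    ``up`` genes get ``up_fold``, ``down`` genes ``down_fold``,
    ``no_change`` fold 1, ``na`` genes never amplify, and ``nd`` genes are
    left off the simulated assay entirely.  With ``noise_sd=0`` the
    downstream direction calling reproduces the encoded statuses exactly.
    """
    genes = list(reference_genes)
    true_fold: dict[str, dict[str, float]] = {}
    na: list[str] = []
    for gene, status in statuses.items():
        if status == "nd":
            continue
        genes.append(gene)
        if status == "na":
            na.append(gene)
        elif status == "up":
            true_fold[gene] = {treated_condition: up_fold}
        elif status == "down":
            true_fold[gene] = {treated_condition: down_fold}
        elif status != "no_change":
            raise ConfigurationError(f"unknown status {status!r} for gene {gene!r}")
    return CtSimSpec(
        genes=genes,
        conditions=[reference_condition, treated_condition],
        reference_genes=tuple(reference_genes),
        reference_condition=reference_condition,
        true_fold=true_fold,
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        n_samples=n_samples,
        na_genes=na,
        seed=seed,
    )
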