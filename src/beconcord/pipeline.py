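"""End-to-end pipeline: selection -> qPCR direction calling -> concordance.

A :class:`PipelineConfig` names the evidence table, one Ct table per model
system, the thresholds and the reference setup.  :func:`run_pipeline`
executes the stages, writes the panel, profile and JSON report plus a run
log and the fully resolved configuration, and returns the report bundle.
Identical configuration (and seed) gives byte-identical report JSON.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .concordance import build_profile_table, combined_concordance, concordance_fraction
from .diffexpr import SelectionCriteria, select_genes
from .exceptions import BeconcordError, ConfigurationError
from .io import read_ct_table, read_evidence, write_json_report
from .qpcr import RelativeQuantifier, direction_calls

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of one pipeline run."""

    evidence: str
    ct_tables: Mapping[str, str] = field(default_factory=dict)
    treated_conditions: Mapping[str, str] = field(default_factory=dict)
    reference_genes: tuple[str, str] = ("ACTB", "GAPDH")
    reference_condition: str = "control"
    lfc_threshold: float = 2.0
    alpha: float = 0.05
    fold_threshold: float = 2.0
    rounding: str = "nearest"
    combined_rounding: str = "floor"
    combine: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ConfigurationError("alpha must lie in [0, 1)")
        if self.lfc_threshold < 0:
            raise ConfigurationError("lfc_threshold must be >= 0")
        if self.fold_threshold < 1:
            raise ConfigurationError("fold_threshold must be >= 1")
        unknown = [s for s in self.combine if s not in self.ct_tables]
        if unknown:
            raise ConfigurationError(f"combine lists unknown systems: {unknown}")

    def to_flat_dict(self) -> dict:
        d = {
            "evidence": self.evidence,
            "reference_genes": ",".join(self.reference_genes),
            "reference_condition": self.reference_condition,
            "lfc_threshold": self.lfc_threshold,
            "alpha": self.alpha,
            "fold_threshold": self.fold_threshold,
            "rounding": self.rounding,
            "combined_rounding": self.combined_rounding,
            "combine": ",".join(self.combine),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        for system, path in self.ct_tables.items():
            d[f"ct_{system}"] = str(path)
        for system, cond in self.treated_conditions.items():
            d[f"condition_{system}"] = cond
        return d

    @classmethod
    def from_flat_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        ct_tables = {
            k[3:]: str(v) for k, v in d.items() if k.startswith("ct_")
        }
        treated = {
            k[len("condition_"):]: str(v)
            for k, v in d.items()
            if k.startswith("condition_")
        }
        refs = d.get("reference_genes", "ACTB,GAPDH")
        if isinstance(refs, str):
            refs = tuple(x.strip() for x in refs.split(",") if x.strip())
        combine = d.get("combine", "")
        if isinstance(combine, str):
            combine = tuple(x.strip() for x in combine.split(",") if x.strip())
        return cls(
            evidence=str(d["evidence"]),
            ct_tables=ct_tables,
            treated_conditions=treated,
            reference_genes=tuple(refs),
            reference_condition=str(d.get("reference_condition", "control")),
            lfc_threshold=float(d.get("lfc_threshold", 2.0)),
            alpha=float(d.get("alpha", 0.05)),
            fold_threshold=float(d.get("fold_threshold", 2.0)),
            rounding=str(d.get("rounding", "nearest")),
            combined_rounding=str(d.get("combined_rounding", "floor")),
            combine=tuple(combine),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "pipeline_out")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run selection, per-system direction calling and concordance scoring."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"beconcord {__version__} (numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, python {platform.python_version()})",
        f"seed: {config.seed}",
    ]

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except BeconcordError as exc:
                log.append(f"[{name}] FAILED: {exc}")
                (out_dir / "run.log").write_text("\n".join(log) + "\n")
                raise BeconcordError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    evidence = stage("select")(lambda: read_evidence(config.evidence))
    criteria = SelectionCriteria(
        lfc_threshold=config.lfc_threshold, alpha=config.alpha
    )
    panel = stage("select")(lambda: select_genes(evidence, criteria))
    selected = panel[panel["decision"].isin(["selected_up", "selected_down"])]
    log.append(
        f"[select] {evidence['gene'].nunique()} genes in -> "
        f"{len(selected)} selected ({int((selected['decision'] == 'selected_up').sum())} up, "
        f"{int((selected['decision'] == 'selected_down').sum())} down)"
    )
    if selected.empty:
        log.append("[select] WARNING: empty selected panel")
    panel.to_csv(out_dir / "panel.tsv", sep="\t")

    calls: dict[str, pd.DataFrame] = {}
    for system, ct_path in config.ct_tables.items():
        def run_system(system=system, ct_path=ct_path):
            table = read_ct_table(ct_path)
            quant = RelativeQuantifier(
                table,
                reference_genes=config.reference_genes,
                reference_condition=config.reference_condition,
            ).fit()
            conditions = [
                c
                for c in table["condition"].unique()
                if c != config.reference_condition
            ]
            condition = config.treated_conditions.get(
                system, conditions[0] if len(conditions) == 1 else None
            )
            if condition is None:
                raise ConfigurationError(
                    f"system {system!r} has several conditions; set condition_{system}"
                )
            quant.to_tsv(out_dir / f"quant_{system}.tsv")
            return direction_calls(
                quant, condition, config.fold_threshold, config.alpha
            )

        calls[system] = stage(f"qpcr:{system}")(run_system)
        counts = calls[system]["status"].value_counts().to_dict()
        log.append(f"[qpcr:{system}] {len(calls[system])} genes called: {counts}")

    report: dict = {
        "config": config.to_flat_dict(),
        "panel": {
            "n_selected": int(len(selected)),
            "n_up": int((selected["decision"] == "selected_up").sum()),
            "n_down": int((selected["decision"] == "selected_down").sum()),
            "genes_up": sorted(selected.index[selected["decision"] == "selected_up"]),
            "genes_down": sorted(
                selected.index[selected["decision"] == "selected_down"]
            ),
        },
        "concordance": {},
    }
    if calls and not selected.empty:
        profile = stage("concordance")(
            lambda: build_profile_table(panel, calls)
        )
        profile.to_tsv(out_dir / "profile.tsv")
        for system in calls:
            rep = concordance_fraction(profile, system, config.rounding)
            report["concordance"][system] = rep.to_dict()
            log.append(
                f"[concordance:{system}] {rep.matches}/{rep.denominator} "
                f"({rep.pct_printed}% {config.rounding})"
            )
        if config.combine:
            rep = combined_concordance(
                profile, config.combine, config.combined_rounding
            )
            report["concordance"]["combined"] = rep.to_dict()
            log.append(
                f"[concordance:combined {'+'.join(config.combine)}] "
                f"{rep.matches}/{rep.denominator} ({rep.pct_printed}% "
                f"{config.combined_rounding})"
            )
    write_json_report(report, out_dir / "report.json")
    config.to_yaml(out_dir / "resolved_config.yaml")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return report
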