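"""Cross-system direction-profile assembly and concordance scoring.

A profile table holds, for each human marker-panel gene, the direction status
observed in each experimental system (human biopsies, Het-1A and EPC2 cell
lines, EGDA rat), using the five-token alphabet
``up / down / no_change / na / nd``.

Concordance of a model system against the human panel counts the genes whose
model status equals the human status.  ``nd`` (not determined) genes leave
the denominator; ``na`` (assayed, no amplification) and ``no_change`` genes
stay in it and can never match, because the human status of a panel gene is
always ``up`` or ``down``.  The combined score over several systems counts a
gene as matched when at least one system matches (set union); its denominator
is the panel minus genes that are ``nd`` in every listed system.

Reported percentages carry a named rounding convention (``nearest`` or
``floor``) alongside the exact fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, DomainError, IntegrityError

__all__ = [
    "STATUS_TOKENS",
    "ProfileTable",
    "ConcordanceReport",
    "build_profile_table",
    "concordance_fraction",
    "combined_concordance",
    "venn_partition",
    "round_pct",
]

STATUS_TOKENS = ("up", "down", "no_change", "na", "nd")

#: Table-5 style symbols accepted on input, mapped to ASCII tokens.
SYMBOL_MAP = {
    "↑": "up",
    "↓": "down",
    "↔": "no_change",
    "n.a.": "na",
    "n.a": "na",
    "n.d.": "nd",
    "n.d": "nd",
}


def normalize_status(token: str) -> str:
    token = str(token).strip()
    token = SYMBOL_MAP.get(token, token)
    if token not in STATUS_TOKENS:
        raise DomainError(f"unknown direction token {token!r}")
    return token


def round_pct(fraction: float, convention: str = "nearest") -> int:
    """Integer percentage under a named convention (``nearest`` rounds half up)."""
    if not (0.0 <= fraction <= 1.0):
        raise DomainError("fraction must lie in [0, 1]")
    if convention == "nearest":
        return int(math.floor(100.0 * fraction + 0.5))
    if convention == "floor":
        return int(math.floor(100.0 * fraction))
    raise ConfigurationError(f"unknown rounding convention {convention!r}")


@dataclass
class ProfileTable:
    """Gene x system direction-status table keyed by panel gene.

    ``frame`` columns: ``gene``, ``class`` (squamous/columnar), ``human``,
    then one column per model system.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "class", "human"}
        missing = required - set(self.frame.columns)
        if missing:
            raise IntegrityError(f"profile table missing columns: {sorted(missing)}")
        if self.frame["gene"].duplicated().any():
            dupes = self.frame.loc[self.frame["gene"].duplicated(), "gene"].tolist()
            raise IntegrityError(f"duplicate panel genes: {dupes}")
        self.frame = self.frame.copy()
        for col in ["human", *self.systems]:
            self.frame[col] = self.frame[col].map(normalize_status)
        bad = self.frame.loc[~self.frame["human"].isin(["up", "down"]), "gene"]
        if len(bad):
            raise IntegrityError(
                f"human panel status must be up or down; offending genes: {bad.tolist()}"
            )

    @property
    def systems(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("gene", "class", "human")]

    @property
    def genes(self) -> list[str]:
        return self.frame["gene"].tolist()

    def status(self, system: str) -> pd.Series:
        if system == "human":
            return self.frame.set_index("gene")["human"]
        if system not in self.systems:
            raise ConfigurationError(f"unknown system {system!r}")
        return self.frame.set_index("gene")[system]

    def match_set(self, system: str) -> set[str]:
        """Genes whose status in ``system`` equals the human direction."""
        s = self.status(system)
        human = self.frame.set_index("gene")["human"]
        return set(s.index[(s == human)])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_profile_table(
    panel: pd.DataFrame,
    calls: Mapping[str, pd.DataFrame],
    systems: Sequence[str] | None = None,
) -> ProfileTable:
    """Assemble a profile table from the selected panel and per-system calls.

    Parameters
    ----------
    panel : pandas.DataFrame
        Indexed by gene with a ``decision`` column (``selected_up`` /
        ``selected_down``) and optionally ``class``; only selected genes are
        kept.
    calls : mapping of system name -> DataFrame with columns gene, status
        Calls referencing non-panel genes are ignored with a warning; a panel
        gene without a call in a system is ``nd`` there.
    """
    selected = panel[panel["decision"].isin(["selected_up", "selected_down"])]
    if selected.empty:
        raise IntegrityError("panel contains no selected genes")
    systems = list(systems) if systems is not None else list(calls)
    rows = {
        gene: {
            "gene": gene,
            "class": row.get("class", ""),
            "human": "up" if row["decision"] == "selected_up" else "down",
            **{s: "nd" for s in systems},
        }
        for gene, row in selected.iterrows()
    }
    for system in systems:
        table = calls.get(system)
        if table is None:
            continue
        seen: dict[str, str] = {}
        for _, rec in table.iterrows():
            gene, status = rec["gene"], normalize_status(rec["status"])
            if gene not in rows:
                warnings.warn(
                    f"call for {gene!r} in system {system!r} ignored: not a panel gene",
                    stacklevel=2,
                )
                continue
            if gene in seen and seen[gene] != status:
                raise IntegrityError(
                    f"conflicting duplicate calls for gene {gene!r} in system {system!r}"
                )
            seen[gene] = status
            rows[gene][system] = status
    frame = pd.DataFrame(list(rows.values()))
    return ProfileTable(frame=frame)


@dataclass
class ConcordanceReport:
    """Match counts and exact fraction of one (or a union of) system(s)."""

    systems: tuple[str, ...]
    matches: int
    denominator: int
    matched_genes: tuple[str, ...]
    rounding: str = "nearest"
    venn: dict = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.matches / self.denominator if self.denominator else float("nan")

    @property
    def pct_printed(self) -> int:
        return round_pct(self.fraction, self.rounding)

    def to_dict(self) -> dict:
        return {
            "systems": list(self.systems),
            "matches": self.matches,
            "denominator": self.denominator,
            "fraction": self.fraction,
            "pct_nearest": round_pct(self.fraction, "nearest"),
            "pct_floor": round_pct(self.fraction, "floor"),
            "rounding": self.rounding,
            "pct_printed": self.pct_printed,
            "matched_genes": sorted(self.matched_genes),
            "venn": {"&".join(k): v for k, v in self.venn.items()} if self.venn else {},
        }


def concordance_fraction(
    profile: ProfileTable, system: str, rounding: str = "nearest"
) -> ConcordanceReport:
    """Direction concordance of one model system against the human panel.

    Denominator: panel genes whose status in the system is not ``nd``.
    """
    status = profile.status(system)
    evaluated = status[status != "nd"]
    matched = profile.match_set(system)
    return ConcordanceReport(
        systems=(system,),
        matches=len(matched),
        denominator=int(len(evaluated)),
        matched_genes=tuple(sorted(matched)),
        rounding=rounding,
    )


def combined_concordance(
    profile: ProfileTable, systems: Iterable[str], rounding: str = "floor"
) -> ConcordanceReport:
    """Union concordance over several systems.

    A gene matches when it matches in at least one listed system; only genes
    that are ``nd`` in every listed system leave the denominator.
    """
    systems = tuple(systems)
    if not systems:
        raise ConfigurationError("at least one system required")
    match_sets = {s: profile.match_set(s) for s in systems}
    matched = set().union(*match_sets.values())
    all_nd = [
        g
        for g in profile.genes
        if all(profile.status(s).loc[g] == "nd" for s in systems)
    ]
    denominator = len(profile.genes) - len(all_nd)
    venn = venn_partition(match_sets) if 2 <= len(systems) <= 3 else {}
    return ConcordanceReport(
        systems=systems,
        matches=len(matched),
        denominator=denominator,
        matched_genes=tuple(sorted(matched)),
        rounding=rounding,
        venn=venn,
    )


def venn_partition(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every exclusive intersection region of 2 or 3 named sets.

    Region keys are tuples of the member set names (in input order); the
    2^k - 1 regions are mutually exclusive and sum to the union cardinality.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ConfigurationError("venn_partition supports exactly 2 or 3 sets")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(set(sets[m]) for m in members))
            outside = set().union(
                *(set(sets[m]) for m in names if m not in members), set()
            )
            out[members] = len(inside - outside)
    return out
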