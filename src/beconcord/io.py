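"""Readers and writers for the package's delimited formats.

Formats
-------
* Expression matrix: TSV, first column ``probe_id``, second ``gene_symbol``,
  remaining columns samples (log2 scale).  Sample annotation: two-column TSV
  ``sample`` / ``group`` with groups in {normal, BE}.
* Ct table: CSV with header ``sample_id,condition,gene,replicate,ct``; an
  empty field or the token ``Undetermined`` (any case) reads as missing.
* Evidence table: CSV with ``gene,class,dataset,logFC,adj_p,present`` rows,
  one row per gene x dataset; absent entries have ``present=0`` and empty
  statistics.
* Profile table: TSV ``gene, class, human, <system>...`` using the ASCII
  direction tokens; the published arrow symbols and ``n.a.``/``n.d.`` are
  accepted on input.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import ProfileTable, normalize_status
from .diffexpr import GROUP_LABELS, ExpressionDataset
from .exceptions import ParseError

__all__ = [
    "canonical_gene",
    "read_expression",
    "write_expression",
    "read_ct_table",
    "write_ct_table",
    "read_evidence",
    "read_profile",
    "write_profile",
    "packaged_evidence",
    "packaged_profile",
    "write_json_report",
]

#: published row labels folded onto canonical panel entries
GENE_ALIASES = {
    "KRT6A, 6B, 6C": "KRT6",
    "KRT6A-C": "KRT6",
    "KRT6A/B/C": "KRT6",
    "MUC3": "MUC3A/B",
}


def canonical_gene(name: str) -> str:
    name = str(name).strip().strip("*")
    upper = name.upper()
    return GENE_ALIASES.get(upper, GENE_ALIASES.get(name, upper))


def read_expression(matrix_path, annotation_path) -> ExpressionDataset:
    """Read an expression matrix plus its sample-to-group annotation."""
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    with open(matrix_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{matrix_path}: empty file") from None
        if len(header) < 3 or header[0] != "probe_id" or header[1] != "gene_symbol":
            raise ParseError(
                f"{matrix_path}:1: header must start with 'probe_id\\tgene_symbol', got {header[:2]}"
            )
        samples = header[2:]
        probes, symbols, rows = [], [], []
        seen: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{matrix_path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            probe = row[0]
            if probe in seen:
                raise ParseError(
                    f"{matrix_path}:{lineno}: duplicate probe {probe!r} "
                    f"(first seen at line {seen[probe]})"
                )
            seen[probe] = lineno
            probes.append(probe)
            symbols.append(row[1])
            try:
                rows.append([float(v) if v != "" else np.nan for v in row[2:]])
            except ValueError as exc:
                raise ParseError(f"{matrix_path}:{lineno}: {exc}") from None
    values = pd.DataFrame(rows, index=probes, columns=samples, dtype=float)

    groups = {}
    with open(annotation_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["sample", "group"]:
            raise ParseError(
                f"{annotation_path}:1: header must be 'sample\\tgroup', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            sample, group = row[0], row[1]
            if group not in GROUP_LABELS:
                raise ParseError(
                    f"{annotation_path}:{lineno}: group {group!r} not in {GROUP_LABELS}"
                )
            groups[sample] = group
    extra = [s for s in groups if s not in samples]
    if extra:
        raise ParseError(
            f"{annotation_path}: annotated samples absent from matrix: {extra}"
        )
    unannotated = [s for s in samples if s not in groups]
    if unannotated:
        raise ParseError(
            f"{annotation_path}: matrix samples missing annotation: {unannotated}"
        )
    return ExpressionDataset(
        values=values,
        gene_symbols=pd.Series(symbols, index=probes, name="gene_symbol"),
        groups=pd.Series(groups, name="group"),
    )


def write_expression(dataset: ExpressionDataset, matrix_path, annotation_path) -> None:
    out = dataset.values.copy()
    out.insert(0, "gene_symbol", dataset.gene_symbols)
    out.to_csv(matrix_path, sep="\t", index_label="probe_id")
    dataset.groups.rename_axis("sample").to_csv(annotation_path, sep="\t", header=["group"])


_MISSING_CT = {"", "undetermined", "na", "n.a.", "nan"}


def read_ct_table(path) -> pd.DataFrame:
    """Read a replicate-level Ct CSV; missing wells read as NaN."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"sample_id": str, "condition": str, "gene": str})
    required = ["sample_id", "condition", "gene", "replicate", "ct"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def parse_ct(v):
        if isinstance(v, str) and v.strip().lower() in _MISSING_CT:
            return np.nan
        return float(v) if pd.notna(v) else np.nan

    table["ct"] = table["ct"].map(parse_ct)
    table["replicate"] = table["replicate"].astype(int)
    return table[required]


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_evidence(path) -> pd.DataFrame:
    """Read a per-gene, per-dataset evidence table (logFC, adj_p, present)."""
    path = Path(path)
    table = pd.read_csv(path)
    required = ["gene", "dataset", "logFC", "adj_p", "present"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    table["gene"] = table["gene"].map(canonical_gene)
    table["present"] = table["present"].astype(bool)
    bad = table[table["present"] & (table["logFC"].isna() | table["adj_p"].isna())]
    if len(bad):
        raise ParseError(
            f"{path}: present rows with missing statistics: {bad['gene'].tolist()}"
        )
    return table


def read_profile(path) -> ProfileTable:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("nd")
    if "gene" not in frame.columns:
        raise ParseError(f"{path}: missing 'gene' column")
    frame["gene"] = frame["gene"].map(canonical_gene)
    for col in frame.columns:
        if col in ("gene", "class"):
            continue
        frame[col] = frame[col].map(normalize_status)
    return ProfileTable(frame=frame)


def write_profile(profile: ProfileTable, path) -> None:
    profile.to_tsv(path)


def packaged_evidence() -> pd.DataFrame:
    """The printed three-dataset evidence table shipped with the package."""
    with resources.as_file(
        resources.files("beconcord.data") / "biopsy_de_evidence.csv"
    ) as p:
        return read_evidence(p)


def packaged_profile() -> ProfileTable:
    """The published cross-system direction-profile fixture."""
    with resources.as_file(
        resources.files("beconcord.data") / "cross_system_profile.tsv"
    ) as p:
        return read_profile(p)


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
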