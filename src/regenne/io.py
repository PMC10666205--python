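"""Readers and writers for the on-disk artifacts: GMT gene sets,
expression tables, phenotype tables, attribution reports.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PathwayCollection,
    PhenotypeTable,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when an input file is malformed."""


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped keeping the first occurrence;
    duplicate pathway names are an error.
    """
    coll = PathwayCollection()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} tab-separated fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}: line {lineno} ({name!r}) lists no genes")
            try:
                coll.add(name, desc, genes)
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if n_lines == 0:
        raise ParseError(f"{path}: empty GMT file")
    return coll


def write_gmt(coll: PathwayCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pw in coll:
            fh.write("\t".join([pw.name, pw.description, *pw.genes]) + "\n")


def _sniff_delimiter(path: str | os.PathLike) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(
    path: str | os.PathLike,
    delimiter: str = "auto",
    impute_policy: str = "reject",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression table: header row of gene symbols, first column
    sample ids, numeric cells (rows = samples unless ``transpose``).

    ``impute_policy`` is ``"reject"`` (any missing cell is an error) or
    ``"gene_mean"`` (missing cells replaced by the column mean of the
    observed entries).
    """
    if delimiter == "auto":
        sep = _sniff_delimiter(path)
    elif delimiter in ("tab", "\t"):
        sep = "\t"
    elif delimiter in ("comma", ","):
        sep = ","
    else:
        raise ValueError(f"unknown delimiter {delimiter!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for col in header:
        key = col.upper()
        if key in seen:
            raise ParseError(f"{path}: duplicate gene column {col!r}")
        seen.add(key)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    try:
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:  # pragma: no cover - pandas coerces
        raise ParseError(f"{path}: non-numeric table: {exc}") from exc
    missing = ~np.isfinite(values)
    if missing.any():
        if impute_policy == "reject":
            i, j = np.argwhere(missing)[0]
            raise ParseError(
                f"{path}: missing/non-numeric value at sample {df.index[i]!r}, "
                f"gene {df.columns[j]!r} (impute_policy='reject')"
            )
        elif impute_policy == "gene_mean":
            for j in np.unique(np.argwhere(missing)[:, 1]):
                col = values[:, j]
                obs = col[np.isfinite(col)]
                if obs.size == 0:
                    raise ParseError(
                        f"{path}: gene {df.columns[j]!r} has no observed values to impute from"
                    )
                col[~np.isfinite(col)] = obs.mean()
        else:
            raise ValueError(f"unknown impute_policy {impute_policy!r}")
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike, sep: str = "\t") -> None:
    expr.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


def read_phenotype(
    path: str | os.PathLike,
    label_map: Mapping[str, int] | None = None,
    delimiter: str = "auto",
) -> PhenotypeTable:
    """Read a two-column table ``sample_id<sep>label``.

    Labels must be 0/1, optionally after applying ``label_map`` (e.g.
    ``{"early": 0, "late": 1}``). Duplicate sample ids are an error.
    """
    sep = _sniff_delimiter(path) if delimiter == "auto" else delimiter
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, label)")
    sids = df.iloc[:, 0].astype(str)
    if sids.duplicated().any():
        dup = sids[sids.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    labels: dict[str, int] = {}
    for sid, raw in zip(sids, df.iloc[:, 1]):
        val = raw
        if label_map is not None and str(raw) in label_map:
            val = label_map[str(raw)]
        try:
            ival = int(val)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: label {raw!r} for sample {sid!r} is not binary")
        if ival not in (0, 1):
            raise ParseError(f"{path}: label {raw!r} for sample {sid!r} is outside {{0, 1}}")
        labels[sid] = ival
    return PhenotypeTable(labels)


def write_phenotype(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, y in pheno.labels.items():
            fh.write(f"{sid}\t{y}\n")


def align(
    expr: ExpressionMatrix, pheno: PhenotypeTable
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Restrict expression and phenotype to their shared samples, both in
    lexicographic sample order. Idempotent."""
    shared = sorted(set(expr.sample_ids) & set(pheno.labels))
    if not shared:
        raise ValidationError("expression and phenotype share no sample ids")
    expr2 = expr.subset_samples(shared)
    pheno2 = PhenotypeTable({s: pheno.labels[s] for s in shared})
    return expr2, pheno2


def write_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
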