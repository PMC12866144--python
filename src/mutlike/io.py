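"""Readers and writers for the package's external formats.

Expression matrices are tab-separated text (first column gene IDs, header row
sample IDs); gene sets use the MSigDB GMT format; clinical, isoform and
dose-response tables are CSV with documented headers; results are serialized
as JSON plus flat TSV tables.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    ClinicalTable,
    DoseResponseMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    IsoformTable,
    ValidationError,
)

log = logging.getLogger("mutlike")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


def read_expression_matrix(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes x samples TSV; the caller declares the scale.

    Duplicate gene rows are collapsed by per-gene maximum (logged); duplicate
    sample columns are an error; any non-numeric cell is a parse error naming
    its coordinates.
    """
    with open(path) as fh:
        header = pd.Index(fh.readline().rstrip("\n").split("\t")[1:])
    if header.has_duplicates:
        raise ParseError(
            f"{path}: duplicate sample ID(s) {header[header.duplicated()].unique().tolist()}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iloc[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if num.isna().to_numpy().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if num.index.has_duplicates:
        n_before = len(num)
        num = num.groupby(level=0, sort=False).max()
        log.warning(
            "%s: collapsed %d duplicate gene rows by per-gene maximum",
            path,
            n_before - len(num),
        )
    return ExpressionMatrix(num, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene ..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no genes"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            try:
                coll.add(GeneSet(name=name, description=desc, genes=tuple(genes)))
            except ValidationError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical CSV with columns sample_id, tp53_status, os_time, os_event."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    try:
        ct = ClinicalTable(df)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e
    counts = ct.tp53_status.value_counts().to_dict()
    log.info("%s: %d samples, tp53_status counts %s", path, len(df), counts)
    return ct


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, index_label="sample_id")


def read_isoforms(path, scale: str = "linear") -> IsoformTable:
    """Read an isoform CSV with columns sample_id, TAp73, dNp73, TP53."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    try:
        return IsoformTable(df.set_index("sample_id"), scale=scale)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_isoforms(table: IsoformTable, path) -> None:
    table.table.to_csv(path, index_label="sample_id")


def read_dose_matrix(path) -> DoseResponseMatrix:
    """Read a dose-response CSV: first row/column are the dose axes."""
    df = pd.read_csv(path, index_col=0)
    try:
        doses1 = df.index.to_numpy(dtype=float)
        doses2 = np.asarray([float(c) for c in df.columns])
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: dose axes must be numeric: {e}") from e
    try:
        return DoseResponseMatrix(doses1, doses2, df.to_numpy(dtype=float))
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_dose_matrix(matrix: DoseResponseMatrix, path) -> None:
    pd.DataFrame(
        matrix.response, index=matrix.doses_drug1, columns=matrix.doses_drug2
    ).to_csv(path, index_label="dose_drug1")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_results(result: dict, path) -> None:
    """Serialize a result mapping as JSON (numpy/pandas-aware)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_config(path) -> AnalysisConfig:
    """Read a YAML/key-value config file into an AnalysisConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig().to_dict())
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
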