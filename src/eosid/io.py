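"""Readers and writers for the package's plain-text formats.

All tabular output is TSV with '.' decimal separator, UTF-8 and LF line
endings, so byte-identical round trips can be asserted.  Gene lists are plain
text, one symbol per line, with ``#`` comment lines.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    CellDifferential,
    ExpressionMatrix,
    GeneList,
    SampleTable,
    normalize_symbol,
)

logger = logging.getLogger("eosid")

#: Packaged transcriptions of the published gene tables.
SPUTUM_TABLE_RESOURCE = "sputum_eos_associated_365.txt"
CORE_TABLE_RESOURCE = "airway_eos_core_57.txt"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, scale: str, collapse: str = "max") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header of sample ids).

    ``scale`` must be declared (``"linear"`` or ``"log2"``); it is never
    guessed from the data.  Duplicate gene rows are collapsed per ``collapse``.
    Raises a parse error naming the offending cell for non-numeric values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"no genes: {path} has an empty data section")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}")
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"missing value at gene {gene!r}")
    matrix = ExpressionMatrix(numeric, scale=scale, collapse=collapse)
    logger.info("read %d genes x %d samples from %s",
                matrix.shape[0], matrix.shape[1], path)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; values keep 10 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        df = matrix.values
        fh.write("gene_id\t" + "\t".join(df.columns) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# sample metadata and differentials
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> SampleTable:
    """Read the sample annotation TSV (sample_id, subject_id, compartment,
    visit, mepolizumab)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable.from_dataframe(df)


def write_sample_metadata(metadata: SampleTable, path) -> None:
    _write_tsv(metadata.to_dataframe(), path)


def read_cell_differentials(path) -> list[CellDifferential]:
    df = pd.read_csv(path, sep="\t")
    classes = [c for c in df.columns if c not in ("sample_id", "total_counted")]
    out = []
    for row in df.itertuples(index=False):
        counts = {c: int(getattr(row, c)) for c in classes}
        out.append(CellDifferential(str(row.sample_id), counts,
                                    int(row.total_counted)))
    return out


def write_cell_differentials(diffs: Iterable[CellDifferential], path) -> None:
    diffs = list(diffs)
    classes = list(diffs[0].counts) if diffs else []
    rows = [{"sample_id": d.sample_id, **d.counts, "total_counted": d.total_counted}
            for d in diffs]
    _write_tsv(pd.DataFrame(rows, columns=["sample_id", *classes, "total_counted"]),
               path)


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def _read_symbol_lines(path_or_text) -> list[str]:
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = Path(path_or_text).read_text(encoding="utf-8")
    symbols = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return symbols


def read_gene_list(path, name: str | None = None, provenance: str = "",
                   allow_empty: bool = False) -> GeneList:
    """Read a plain-text gene list (one symbol per line, '#' comments).

    Symbols are normalized and deduplicated on load; the number of dropped
    duplicates is logged and kept on the returned :class:`GeneList`.  Use
    :func:`count_raw_entries` when the verbatim entry count matters.  An
    empty file is an error unless ``allow_empty`` (an empty selection branch
    is a legitimate result).
    """
    symbols = _read_symbol_lines(path)
    if not symbols and not allow_empty:
        raise ValueError(f"empty gene list: {path}")
    if name is None:
        name = Path(str(path)).stem
    return GeneList(name, symbols, provenance=provenance)


def count_raw_entries(path) -> int:
    """Number of verbatim (pre-deduplication) entries in a gene-list file."""
    return len(_read_symbol_lines(path))


def write_gene_list(genes: GeneList, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if genes.provenance:
            fh.write(f"# {genes.provenance}\n")
        for s in genes:
            fh.write(s + "\n")


def _packaged(resource: str):
    return resources.files("eosid.data").joinpath(resource)


def sputum_eos_gene_list() -> GeneList:
    """The published 365-entry sputum EOS-associated list (deduplicated)."""
    with _packaged(SPUTUM_TABLE_RESOURCE).open("r", encoding="utf-8") as fh:
        return GeneList("sputum_eos_associated",
                        _read_symbol_lines(fh),
                        provenance="published sputum EOS-associated gene table")


def airway_eos_core_gene_list() -> GeneList:
    """The published 57-gene airway-EOS core list (three-way intersection)."""
    with _packaged(CORE_TABLE_RESOURCE).open("r", encoding="utf-8") as fh:
        return GeneList("airway_eos_core",
                        _read_symbol_lines(fh),
                        provenance="published 57-gene airway EOS core table")


def sputum_eos_raw_entry_count() -> int:
    """Verbatim entry count of the packaged sputum table (duplicates kept)."""
    with _packaged(SPUTUM_TABLE_RESOURCE).open("r", encoding="utf-8") as fh:
        return len(_read_symbol_lines(fh))


# ---------------------------------------------------------------------------
# qPCR wells
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "gene", "replicate", "ct"]


def read_qpcr_csv(path) -> pd.DataFrame:
    """Read a qPCR well table CSV with columns sample_id, gene, replicate, ct."""
    df = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {', '.join(missing)}")
    df = df[QPCR_COLUMNS].copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    df["ct"] = df["ct"].astype(float)
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    return df


def write_qpcr_csv(wells: pd.DataFrame, path) -> None:
    wells[QPCR_COLUMNS].to_csv(path, index=False, float_format="%.6g",
                               lineterminator="\n")


# ---------------------------------------------------------------------------
# selection reports
# ---------------------------------------------------------------------------

def write_report(result, out_dir, extra_params: dict | None = None) -> dict:
    """Write a selection result: per-branch gene lists, Venn counts, parameters.

    Outputs (all deterministic for identical input):

    - ``bal_up.txt``, ``mepo_down.txt``, ``sputum_assoc.txt``,
      ``intersection.txt`` — plain-text gene lists;
    - ``venn.json`` — the 7 disjoint region counts;
    - ``params.json`` — thresholds and run parameters.

    Returns the Venn count dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_list(result.bal_up, out / "bal_up.txt")
    write_gene_list(result.mepo_down, out / "mepo_down.txt")
    write_gene_list(result.sputum_assoc, out / "sputum_assoc.txt")
    write_gene_list(result.intersection, out / "intersection.txt")
    counts = result.region_counts()
    _write_json(counts, out / "venn.json")
    params = {
        "thresholds": result.thresholds.as_dict() if result.thresholds else None,
        "gated_subjects": sorted(result.gated_subjects),
        "branch_sizes": {"bal_up": len(result.bal_up),
                         "mepo_down": len(result.mepo_down),
                         "sputum_assoc": len(result.sputum_assoc)},
    }
    if extra_params:
        params.update(extra_params)
    _write_json(params, out / "params.json")
    return counts


# ---------------------------------------------------------------------------
# GEO series-matrix convenience loader (optional; not used by any pipeline
# stage or test fixture — provided for re-analysis of the deposited series)
# ---------------------------------------------------------------------------

def read_geo_series_matrix(path, scale: str = "log2",
                           collapse: str = "max") -> ExpressionMatrix:
    """Parse the expression block of a GEO series-matrix text file.

    Reads the lines between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` (tab-delimited, quoted identifiers) into an
    :class:`ExpressionMatrix`.  Probe-to-symbol annotation is out of scope;
    row ids are kept as provided.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError("not a series-matrix file: table markers not found")
    rows = [l.split("\t") for l in lines[start + 1:end] if l.strip()]
    header = [c.strip('"') for c in rows[0]][1:]
    data = {r[0].strip('"'): [float(x) for x in r[1:]] for r in rows[1:]}
    df = pd.DataFrame.from_dict(data, orient="index", columns=header)
    return ExpressionMatrix(df, scale=scale, collapse=collapse)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def _write_json(obj, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
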