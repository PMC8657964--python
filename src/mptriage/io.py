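"""Readers and writers for the pipeline's plain-text formats.

Matrices and sample sheets travel as TSV; gene annotations as a two-column
TSV or GAF 2.x; ontologies as OBO (see :mod:`mptriage.enrichment`); reports
as JSON.  A GEO series-matrix reader is provided for re-analysis of deposited
data: expression values come from the ``!series_matrix_table`` block and the
sample annotations are parsed from the sample titles with a configurable
regular expression.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .dataset import ExpressionDataset, SampleAnnotation
from .differential import DEGQuad
from .synthetic_data import GroundTruth

#: default pattern for sample titles like ``SCI-MP_8h_rep2`` or ``S-EtOH_0h_rep1``
DEFAULT_TITLE_REGEX = (
    r"(?P<injury>SCI|S)-(?P<medication>EtOH|MP)_(?P<time_h>\d+)h_rep(?P<replicate>\d+)"
)


def _annotation_from_row(row: Mapping) -> SampleAnnotation:
    return SampleAnnotation(
        sample_id=str(row["sample_id"]),
        injury=str(row["injury"]),
        medication=str(row["medication"]),
        time_h=int(row["time_h"]),
        replicate=int(row["replicate"]),
    )


def write_expression_tsv(ds: ExpressionDataset, matrix_path, samples_path) -> None:
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    ds.sample_table().to_csv(samples_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, samples_path) -> ExpressionDataset:
    """Load a gene x sample TSV matrix joined with its sample sheet.

    The matrix's first column is the gene ID; its header row carries sample
    IDs, each of which must appear in the sample sheet.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID in {matrix_path}: {dup!r}")
    sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    by_id = {}
    for _, row in sheet.iterrows():
        ann = _annotation_from_row(row)
        by_id[ann.sample_id] = ann
    missing = [c for c in matrix.columns if c not in by_id]
    if missing:
        raise ValueError(f"samples in matrix missing from sample sheet: {missing}")
    annotations = [by_id[c] for c in matrix.columns]
    return ExpressionDataset(matrix, annotations)


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
    if truth.outlier_samples:
        outlier_path = Path(path).with_suffix(".outliers.txt")
        outlier_path.write_text("\n".join(truth.outlier_samples) + "\n")


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column (gene_id, term_id) TSV -> gene -> terms map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(term)
    return out


def read_annotation_gaf(path) -> dict[str, set[str]]:
    """GAF 2.x -> gene -> terms map (columns 2 = object ID, 5 = GO ID)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed GAF line: {line[:80]!r}")
            out.setdefault(fields[1], set()).add(fields[4])
    return out


def read_geo_series_matrix(
    path, title_regex: str = DEFAULT_TITLE_REGEX
) -> ExpressionDataset:
    """Parse a GEO series-matrix text file into an :class:`ExpressionDataset`.

    Sample metadata are taken from the ``!Sample_title`` line and matched
    against ``title_regex``, which must provide the named groups ``injury``
    (``S``/``sham`` or ``SCI``), ``medication``, ``time_h`` and ``replicate``.
    """
    headers: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                headers[key.lstrip("!")] = [v.strip('"') for v in vals]
    if not table_lines:
        raise ValueError(f"{path}: no !series_matrix_table_begin block found")
    if "Sample_title" not in headers:
        raise ValueError(f"{path}: missing !Sample_title header")
    from io import StringIO

    matrix = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = [c.strip('"') for c in matrix.columns]
    titles = headers["Sample_title"]
    accessions = headers.get("Sample_geo_accession", list(matrix.columns))
    if len(titles) != len(matrix.columns):
        raise ValueError(
            f"{path}: {len(titles)} sample titles but {len(matrix.columns)} data columns"
        )
    pattern = re.compile(title_regex)
    annotations = []
    for col, title in zip(matrix.columns, titles):
        m = pattern.search(title)
        if not m:
            raise ValueError(f"sample title {title!r} does not match the regex")
        injury = "sham" if m.group("injury") in ("S", "sham", "Sham") else "SCI"
        annotations.append(
            SampleAnnotation(
                sample_id=col,
                injury=injury,
                medication=m.group("medication"),
                time_h=int(m.group("time_h")),
                replicate=int(m.group("replicate")),
            )
        )
    del accessions
    return ExpressionDataset(matrix, annotations)


# -- stats / quad / report writers ------------------------------------------


def write_stats_tables(tables: Mapping[int, pd.DataFrame], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t, df in tables.items():
        keep = [c for c in df.columns if not c.startswith("_")]
        df[keep].to_csv(out_dir / f"stats_t{t}h.tsv", sep="\t", index_label="gene_id")


def write_deg_quads(quads: Mapping[int, DEGQuad], path) -> None:
    payload = {str(t): q.to_dict() for t, q in quads.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_deg_quads(path) -> dict[int, DEGQuad]:
    payload = json.loads(Path(path).read_text())
    return {int(t): DEGQuad.from_dict(d) for t, d in payload.items()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
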