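"""Readers and writers for the on-disk formats.

Plain-text formats only: TSV/CSV matrices (genes in rows, samples in
columns), a MatrixMarket-style sparse triplet with gene/sample index files,
GMT gene-set files, and a JSON provenance sidecar.  Readers validate
structure and reject malformed input; they never silently coerce.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationMatrix,
    ProteinMatrix,
    Scale,
)

log = logging.getLogger(__name__)

_BOOL_MAP = {
    "TRUE": 1, "FALSE": 0, "True": 1, "False": 0, "true": 1, "false": 0,
    "1": 1, "0": 0, 1: 1, 0: 0, True: 1, False: 0,
}


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    scale: Scale | str = Scale.raw_counts,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample expression matrix.

    ``format`` is one of ``tsv``, ``csv`` or ``mtx_triplet``.  For the
    triplet format, ``path`` is the triplet file ``<stem>.mtx.tsv`` with
    columns (gene_index, sample_index, value, 1-based) accompanied by
    ``<stem>.genes.txt`` and ``<stem>.samples.txt``; absent entries are 0.
    ``transpose`` accommodates samples-in-rows dialects.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        df = _read_table(path, "\t" if format == "tsv" else ",")
        if transpose:
            df = df.T
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
    elif format == "mtx_triplet":
        stem = str(path)
        for suffix in (".mtx.tsv", ".mtx"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        trip = pd.read_csv(path, sep="\t", comment="%", header=None,
                           names=["gene", "sample", "value"])
        mat = np.zeros((len(genes), len(samples)))
        gi = trip["gene"].to_numpy(int) - 1
        si = trip["sample"].to_numpy(int) - 1
        if (gi < 0).any() or (gi >= len(genes)).any() or (si < 0).any() or (si >= len(samples)).any():
            raise ValueError("triplet index out of range for the gene/sample index files")
        mat[gi, si] = trip["value"].to_numpy()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return ExpressionMatrix(df, Scale(scale))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are deduplicated with a warning; duplicate
    set names and lines with fewer than 3 fields are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical CSV (sample_id in the first column).

    Enums are validated (FAB restricted to the M1/M2/M4/M5 lineages this
    analysis targets); survival times are weeks and must be non-negative; empty
    cells stay missing and are excluded listwise by downstream analyses.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    for col in ("ahd",):
        if col in df:
            df[col] = df[col].map(lambda v: _BOOL_MAP.get(v, v))
    table = ClinicalTable(df)
    missing = table.missingness_report()
    if int(missing.sum()):
        log.info("clinical missingness per column:\n%s", missing[missing > 0])
    return table


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    """Read a binary gene x sample mutation TSV; TRUE/FALSE are coerced to
    1/0, anything else non-binary is an error."""
    df = _read_table(path, "\t")
    df = df.map(lambda v: _BOOL_MAP.get(v, v))
    return MutationMatrix(df)


def write_mutation_matrix(mut: MutationMatrix, path: str | Path) -> None:
    mut.data.to_csv(path, sep="\t", index_label="gene")


def read_protein_matrix(path: str | Path) -> ProteinMatrix:
    df = _read_table(path, "\t")
    return ProteinMatrix(df)


def write_protein_matrix(prot: ProteinMatrix, path: str | Path) -> None:
    prot.data.to_csv(path, sep="\t", index_label="protein")


DRUG_COLUMNS = ("sample_id", "drug", "auc")


def read_drug_response(path: str | Path) -> pd.DataFrame:
    """Long-format drug response table with columns (sample_id, drug, auc);
    AUC is the area under the dose-response curve (higher = more resistant)."""
    df = pd.read_csv(path)
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drug response table requires columns {DRUG_COLUMNS}; missing {missing}")
    df["auc"] = pd.to_numeric(df["auc"], errors="raise")
    return df


def read_omics_tables(
    mutation_path: str | Path,
    protein_path: str | Path,
    drug_path: Optional[str | Path] = None,
) -> tuple[MutationMatrix, ProteinMatrix, Optional[pd.DataFrame]]:
    """Read mutation + protein matrices (and optionally the drug AUC table),
    logging the sample-id intersection sizes."""
    mut = read_mutation_matrix(mutation_path)
    prot = read_protein_matrix(protein_path)
    shared = set(mut.sample_ids) & set(prot.sample_ids)
    log.info("mutation/protein sample intersection: %d samples", len(shared))
    drug = read_drug_response(drug_path) if drug_path is not None else None
    return mut, prot, drug


def read_hox_gene_sets() -> GeneSetCollection:
    """The HOXA and HOXB homeobox cluster gene-symbol sets shipped with the
    package (for scoring real cohorts; synthetic cohorts plant their own)."""
    from importlib.resources import files

    path = files("amldecouple.data").joinpath("hox_clusters.gmt")
    return read_gene_sets_gmt(str(path))


def write_provenance(path: str | Path, **payload) -> None:
    """JSON sidecar recording the configuration, seed and thresholds of a run."""
    from . import __version__

    payload = {"amldecouple_version": __version__, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
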