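"""Readers and writers for the on-disk formats.

Canonical tabular dialect is TSV (UTF-8, header row, "." for missing).
Sparse nucleus matrices use MatrixMarket triplets with two sidecar TSVs
(genes; barcodes + cluster + phase). Gene sets use standard GMT lines,
Ct tables plain CSV. Every reader is the inverse of the matching writer
on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CT_COLUMNS,
    META_COLUMNS,
    AnnotationTable,
    CountTable,
    CtTable,
    GeneSetCollection,
    NucleusMatrix,
)
from .errors import FormatError

log = logging.getLogger("translatome")

MISSING = "."


# ---------------------------------------------------------------- count table

def read_count_table(path, meta_path) -> CountTable:
    """Read a feature x sample TSV plus a sample metadata TSV keyed by sample_id."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {path}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{meta_path}: missing 'sample_id' column")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(
            f"{meta_path}: metadata missing required columns {missing}; "
            f"required: ['sample_id', {', '.join(repr(c) for c in META_COLUMNS)}]"
        )
    meta = meta.set_index("sample_id")
    meta = meta.replace(MISSING, "na")
    meta["replicate"] = meta["replicate"].astype(int)
    float_counts = counts.astype(float, errors="raise")
    return CountTable(float_counts, meta)


def write_count_table(table: CountTable, path, meta_path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="feature_id")
    meta = table.sample_meta.copy()
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ------------------------------------------------------------------ gene sets

def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member1 TAB member2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.warning("gene set %r: %d duplicate member(s) removed", name, len(members) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ------------------------------------------------------------- nucleus matrix

def read_nucleus_matrix(directory) -> NucleusMatrix:
    """Read an MTX triplet bundle: matrix.mtx, genes.tsv, barcodes.tsv."""
    directory = Path(directory)
    mat = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", dtype=str)
    for col in ("barcode", "cluster", "phase"):
        if col not in barcodes.columns:
            raise FormatError(f"barcodes.tsv missing column {col!r}")
    phases = set(barcodes["phase"])
    if len(phases) != 1:
        raise FormatError(f"barcodes.tsv phase column must be constant, got {sorted(phases)}")
    return NucleusMatrix(
        gene_ids=list(genes["gene"]),
        nucleus_ids=list(barcodes["barcode"]),
        counts=mat,
        cluster_labels=barcodes["cluster"].to_numpy(),
        phase=phases.pop(),
    )


def write_nucleus_matrix(m: NucleusMatrix, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts))
    pd.DataFrame({"gene": m.gene_ids}).to_csv(directory / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"barcode": m.nucleus_ids, "cluster": list(map(str, m.cluster_labels)), "phase": m.phase}
    ).to_csv(directory / "barcodes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------- annotations

def read_annotations(path) -> AnnotationTable:
    """TSV with columns symbol, rbp_score ('.'=missing), go_terms (';'-joined), risk_score_present."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("symbol", "rbp_score", "go_terms", "risk_score_present"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation table missing column {col!r}")
    out = pd.DataFrame(index=df["symbol"])
    out["rbp_score"] = [
        float("nan") if v in (MISSING, "", None) or pd.isna(v) else float(v)
        for v in df["rbp_score"]
    ]
    out["go_terms"] = [
        [] if v in (MISSING, "", None) or pd.isna(v) else v.split(";") for v in df["go_terms"]
    ]
    out["risk_score_present"] = df["risk_score_present"].astype(int).astype(bool).to_numpy()
    return AnnotationTable(out)


def write_annotations(ann: AnnotationTable, path) -> None:
    df = pd.DataFrame(
        {
            "symbol": ann.table.index,
            "rbp_score": [
                MISSING if np.isnan(v) else repr(float(v)) for v in ann.table["rbp_score"]
            ],
            "go_terms": [";".join(t) if t else MISSING for t in ann.table["go_terms"]],
            "risk_score_present": ann.table["risk_score_present"].astype(int).to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- Ct table

def read_ct_table(path) -> CtTable:
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: Ct table missing columns {missing}")
    df["tech_replicate"] = df["tech_replicate"].astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    for col in ("fraction", "genotype", "antibody"):
        df[col] = df[col].fillna("na").replace(MISSING, "na")
    return CtTable(df)


def write_ct_table(ct: CtTable, path) -> None:
    ct.table.to_csv(path, index=False)


# ---------------------------------------------------------------- DE results

def write_de_results(df: pd.DataFrame, path) -> None:
    """Write a differential-association result frame (one contrast per file)."""
    cols = ["feature_id", "base_mean", "log2fc", "se", "p", "padj", "dispersion"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep=MISSING)


def read_de_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    return df
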