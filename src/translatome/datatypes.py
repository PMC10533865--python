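"""Core in-memory containers for the pipeline.

Counts are kept in pandas DataFrames (features x samples) with a sample
metadata frame alongside; single-nucleus UMI counts live in a scipy sparse
matrix with gene/barcode/cluster sidecars. Validation happens at
construction so downstream stages can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError

#: allowed categorical metadata values ('na' marks non-applicable)
FRACTIONS = ("input", "monosome", "polysome", "na")
PHASES = ("early", "mid", "late", "na")
GENOTYPES = ("WT", "cKO", "na")
ANTIBODIES = ("RIP", "IgG", "na")

META_COLUMNS = ("fraction", "phase", "genotype", "antibody", "replicate")


def normalize_symbols(symbols) -> list[str]:
    """Uppercase gene symbols for cross-table joins.

    Internally symbols are case-sensitive (human symbols are uppercase,
    mouse capitalized); this single utility is the only place case is
    collapsed, used when joining tables from different species/assays.
    """
    return [str(s).upper() for s in symbols]


@dataclass
class CountTable:
    """Integer feature-by-sample counts plus per-sample metadata.

    ``counts``: DataFrame indexed by feature id, one column per sample.
    ``sample_meta``: DataFrame indexed by sample_id with columns
    fraction/phase/genotype/antibody/replicate, aligned to counts columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r} in count table")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise FormatError(
                "sample metadata missing required columns "
                f"{missing_cols}; required: {list(META_COLUMNS)}"
            )
        absent = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if absent:
            raise FormatError(f"samples {absent} present in counts but absent from metadata")
        # align metadata rows to count columns, preserving column order
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise FormatError(
                f"negative or non-integer count at feature "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        for col, allowed in (
            ("fraction", FRACTIONS),
            ("phase", PHASES),
            ("genotype", GENOTYPES),
            ("antibody", ANTIBODIES),
        ):
            bad_vals = set(self.sample_meta[col]) - set(allowed)
            if bad_vals:
                raise FormatError(f"invalid {col} value(s) {sorted(bad_vals)}; allowed: {allowed}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, mask: pd.Series) -> "CountTable":
        """Return a new table restricted to samples where ``mask`` is True."""
        keep = [s for s in self.counts.columns if bool(mask.loc[s])]
        return CountTable(self.counts[keep].copy(), self.sample_meta.loc[keep].copy())

    def select(self, **criteria) -> "CountTable":
        """Subset samples by metadata equality, e.g. ``select(fraction='polysome')``."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, value in criteria.items():
            mask &= self.sample_meta[key] == value
        return self.subset_samples(mask)


@dataclass
class NucleusMatrix:
    """Sparse gene-by-nucleus UMI counts with cluster labels and a phase tag."""

    gene_ids: list[str]
    nucleus_ids: list[str]
    counts: sp.csr_matrix
    cluster_labels: np.ndarray
    phase: str = "na"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene id in nucleus matrix")
        if len(set(self.nucleus_ids)) != len(self.nucleus_ids):
            raise FormatError("duplicate nucleus barcode")
        if self.counts.shape != (len(self.gene_ids), len(self.nucleus_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.nucleus_ids)} nuclei"
            )
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if self.cluster_labels.shape[0] != len(self.nucleus_ids):
            raise FormatError("cluster label vector length does not match nucleus count")
        if any(not str(c) for c in self.cluster_labels):
            raise FormatError("empty cluster label")
        if (self.counts.data < 0).any():
            raise FormatError("negative UMI count")

    @property
    def clusters(self) -> list[str]:
        return sorted(set(map(str, self.cluster_labels)))

    def cluster_mask(self, cluster: str) -> np.ndarray:
        return np.asarray([str(c) == str(cluster) for c in self.cluster_labels])

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member list, plus descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AnnotationTable:
    """Per-gene annotation: RBP score (NaN = not an RBP candidate), GO term
    names, and membership in the scored risk background."""

    table: pd.DataFrame  # index: symbol; columns: rbp_score, go_terms (list), risk_score_present

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate symbol {dup!r} in annotation table")
        for col in ("rbp_score", "go_terms", "risk_score_present"):
            if col not in self.table.columns:
                raise FormatError(f"annotation table missing column {col!r}")

    def go_terms(self, gene: str) -> list[str]:
        if gene not in self.table.index:
            return []
        terms = self.table.loc[gene, "go_terms"]
        return list(terms) if isinstance(terms, (list, tuple)) else []

    def rbp_score(self, gene: str) -> float:
        if gene not in self.table.index:
            return float("nan")
        return float(self.table.loc[gene, "rbp_score"])

    @property
    def scored_genes(self) -> set[str]:
        """Genes in the scored (risk) background."""
        return set(self.table.index[self.table["risk_score_present"].astype(bool)])


CT_COLUMNS = ("gene", "sample_id", "fraction", "genotype", "antibody", "tech_replicate", "ct")


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold table.

    One row per (gene, biological sample, fraction/antibody stratum,
    technical replicate); ``ct`` is NaN for non-detects.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"Ct table missing columns {missing}")
        key = ["gene", "sample_id", "fraction", "antibody", "tech_replicate"]
        if self.table.duplicated(subset=key).any():
            row = self.table[self.table.duplicated(subset=key)].iloc[0]
            raise FormatError(
                f"duplicate Ct record for gene={row['gene']!r} sample={row['sample_id']!r}"
            )
        ct = self.table["ct"]
        if (ct.dropna() <= 0).any():
            raise FormatError("non-positive Ct value")
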