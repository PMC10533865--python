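"""Single-nucleus cluster utilities: normalization, one-vs-rest marker
detection (Wilcoxon rank-sum with pct.1/pct.2 detection fractions),
cluster-level expression filters, translatome intersection, and pairwise
co-expression fractions.

'Expressing' always means raw UMI count > 0; pct metrics are therefore
identical before and after normalization.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .datatypes import NucleusMatrix, normalize_symbols
from .errors import DesignError

log = logging.getLogger("translatome")

MARKER_COLUMNS = ["gene", "cluster", "avg_log2fc", "pct.1", "pct.2", "p", "p_bonf"]


def normalize_matrix(m: NucleusMatrix, scale: float = 10000.0) -> sp.csr_matrix:
    """Log-library-size normalization: ln(1 + scale * count / column_total).

    Zero-depth nuclei map to all-zero columns. Zeros stay zero, so the
    result keeps the sparsity pattern of the input.
    """
    csc = sp.csc_matrix(m.counts, dtype=float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    inv = np.divide(1.0, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    scaled = csc.multiply(sp.csr_matrix(inv[None, :] * scale))
    scaled = sp.csc_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return sp.csr_matrix(scaled)


def _dense_rows(mat) -> np.ndarray:
    return np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)


def _wilcoxon_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per row (normal approximation with
    tie and continuity correction)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield p=1, not a warning
        res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided",
                                       method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied rows: U at its midpoint, p is 1
    return np.nan_to_num(p, nan=1.0)


def _group_stats(raw: np.ndarray, norm: np.ndarray, mask: np.ndarray):
    pct = (raw[:, mask] > 0).mean(axis=1)
    mean = norm[:, mask].mean(axis=1)
    return pct, mean


def find_all_markers(
    m: NucleusMatrix,
    min_pct: float = 0.10,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    scale: float = 10000.0,
    fc_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest marker detection per cluster.

    A gene is reported for a cluster when it is detected (raw count > 0)
    in at least ``min_pct`` of the cluster's nuclei, its avg_log2fc over
    the rest is at least ``min_lfc``, and the Bonferroni-corrected
    Wilcoxon p is below ``alpha``.
    """
    clusters = m.clusters
    if len(clusters) < 2:
        raise DesignError("marker detection needs >=2 clusters")
    raw = _dense_rows(m.counts)
    norm = _dense_rows(normalize_matrix(m, scale=scale))
    n_genes = raw.shape[0]
    records = []
    for cluster in clusters:
        mask = m.cluster_mask(cluster)
        if mask.sum() < 3:
            log.warning("cluster %s has <3 nuclei; skipped", cluster)
            continue
        pct1, mean_in = _group_stats(raw, norm, mask)
        pct2, mean_out = _group_stats(raw, norm, ~mask)
        lfc = np.log2((mean_in + fc_pseudocount) / (mean_out + fc_pseudocount))
        p = _wilcoxon_rows(norm[:, mask], norm[:, ~mask])
        p_bonf = np.minimum(p * n_genes, 1.0)
        keep = (pct1 >= min_pct) & (lfc >= min_lfc) & (p_bonf < alpha)
        for i in np.flatnonzero(keep):
            records.append((m.gene_ids[i], cluster, lfc[i], pct1[i], pct2[i], p[i], p_bonf[i]))
    out = pd.DataFrame(records, columns=MARKER_COLUMNS)
    log.info("find_all_markers: %d records over %d clusters", len(out), len(clusters))
    return out


def two_group_markers(
    m: NucleusMatrix,
    group1_clusters: set[str],
    group2_clusters: set[str],
    min_pct: float = 0.30,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    scale: float = 10000.0,
    fc_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pooled two-group comparison (group1 over group2), e.g. subplate
    clusters vs all other neuronal clusters.

    The pct cutoff applies to the group-1 (target) pool; the fold-change
    gate is two-sided (|avg_log2fc| >= min_lfc) so down-regulated genes
    remain visible to downstream sign filters.
    """
    overlap = set(group1_clusters) & set(group2_clusters)
    if overlap:
        raise DesignError(f"cluster groups overlap: {sorted(overlap)}")
    if not group1_clusters or not group2_clusters:
        raise DesignError("both cluster groups must be non-empty")
    labels = np.asarray([str(c) for c in m.cluster_labels])
    mask1 = np.isin(labels, sorted(map(str, group1_clusters)))
    mask2 = np.isin(labels, sorted(map(str, group2_clusters)))
    if mask1.sum() < 3 or mask2.sum() < 3:
        raise DesignError("each pooled group needs >=3 nuclei")
    raw = _dense_rows(m.counts)
    norm = _dense_rows(normalize_matrix(m, scale=scale))
    n_genes = raw.shape[0]
    pct1, mean1 = _group_stats(raw, norm, mask1)
    pct2, mean2 = _group_stats(raw, norm, mask2)
    lfc = np.log2((mean1 + fc_pseudocount) / (mean2 + fc_pseudocount))
    p = _wilcoxon_rows(norm[:, mask1], norm[:, mask2])
    p_bonf = np.minimum(p * n_genes, 1.0)
    keep = (pct1 >= min_pct) & (np.abs(lfc) >= min_lfc) & (p_bonf < alpha)
    out = pd.DataFrame(
        {
            "gene": np.asarray(m.gene_ids)[keep],
            "cluster": "group1",
            "avg_log2fc": lfc[keep],
            "pct.1": pct1[keep],
            "pct.2": pct2[keep],
            "p": p[keep],
            "p_bonf": p_bonf[keep],
        },
        columns=MARKER_COLUMNS,
    )
    log.info("two_group_markers: %d of %d genes pass", len(out), n_genes)
    return out


def cluster_expression_filter(
    m: NucleusMatrix,
    genes: set[str],
    min_mean: float = 0.1,
    min_frac: float = 0.30,
    scale: float = 10000.0,
) -> dict[str, set[str]]:
    """Per-cluster gene filter: mean normalized expression > min_mean AND
    fraction of nuclei with raw count > 0 >= min_frac."""
    known = [g for g in genes if g in m.gene_ids]
    dropped = set(genes) - set(known)
    if dropped:
        log.warning("cluster_expression_filter: %d gene(s) not in matrix dropped", len(dropped))
    idx = np.asarray([m.gene_ids.index(g) for g in known], dtype=int)
    out: dict[str, set[str]] = {}
    raw = _dense_rows(m.counts)
    norm = _dense_rows(normalize_matrix(m, scale=scale))
    for cluster in m.clusters:
        mask = m.cluster_mask(cluster)
        passing: set[str] = set()
        if idx.size:
            mean = norm[np.ix_(idx, mask)].mean(axis=1)
            frac = (raw[np.ix_(idx, mask)] > 0).mean(axis=1)
            passing = {known[i] for i in np.flatnonzero((mean > min_mean) & (frac >= min_frac))}
        out[cluster] = passing
    return out


def intersect_translatome(
    calls: pd.DataFrame,
    cluster_filter: dict[str, set[str]],
) -> dict[str, dict[str, set[str]]]:
    """Per-cluster intersection of translational calls with expressed genes.

    Gene namespaces are joined after symbol uppercasing; a gene may appear
    under several clusters.
    """
    result: dict[str, dict[str, set[str]]] = {}
    by_status = {
        status: set(normalize_symbols(calls.loc[calls["status"] == status, "feature_id"]))
        for status in ("derepressed", "repressed")
    }
    for cluster, genes in cluster_filter.items():
        norm_genes = set(normalize_symbols(genes))
        result[cluster] = {
            "derepressed": by_status["derepressed"] & norm_genes,
            "repressed": by_status["repressed"] & norm_genes,
        }
    return result


def coexpression_fractions(m: NucleusMatrix, gene_a: str, gene_b: str) -> pd.DataFrame:
    """Fractions of nuclei per cluster expressing gene A alone, B alone,
    both, or neither (raw count > 0). Fractions sum to 1 per cluster."""
    for gene in (gene_a, gene_b):
        if gene not in m.gene_ids:
            raise ValueError(f"gene {gene!r} not present in matrix")
    raw = _dense_rows(m.counts)
    a = raw[m.gene_ids.index(gene_a)] > 0
    b = raw[m.gene_ids.index(gene_b)] > 0
    rows = []
    for cluster in m.clusters:
        mask = m.cluster_mask(cluster)
        n = int(mask.sum())
        both = int((a & b & mask).sum())
        a_only = int((a & ~b & mask).sum())
        b_only = int((~a & b & mask).sum())
        neither = n - both - a_only - b_only
        rows.append(
            {
                "cluster": cluster,
                "n_nuclei": n,
                "a_only": a_only / n,
                "b_only": b_only / n,
                "both": both / n,
                "neither": neither / n,
            }
        )
    return pd.DataFrame(rows)
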