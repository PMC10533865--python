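"""RBP candidate ranking.

Ranks RNA-binding-protein candidates among subplate-enriched genes by
four filters — (1) present in the RBP candidate list, (2) up-regulated in
subplate vs other neuronal clusters, (3) annotated with >=1 synaptic GO
term, (4) candidate score > 0 — then orders by descending score. Also
provides 2/3-set Venn region accounting for cross-phase comparisons.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import AnnotationTable, NucleusMatrix
from .errors import DesignError
from .markers import two_group_markers

log = logging.getLogger("translatome")

RBP_COLUMNS = ["gene", "phase", "avg_log2fc", "pct.1", "pct.2",
               "n_synaptic_terms", "rbp_score", "rank"]


def sp_vs_neuronal_deg(
    m: NucleusMatrix,
    sp_clusters: set[str],
    neuronal_clusters: set[str],
    min_pct: float = 0.30,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    scale: float = 10000.0,
) -> pd.DataFrame:
    """Pooled subplate vs pooled neuronal differential expression.

    Signed SP-over-neuronal; the percent cutoff (default 30%) applies to
    the SP pool.
    """
    return two_group_markers(
        m,
        group1_clusters=set(sp_clusters),
        group2_clusters=set(neuronal_clusters),
        min_pct=min_pct,
        min_lfc=min_lfc,
        alpha=alpha,
        scale=scale,
    )


def count_synaptic_terms(
    gene: str,
    annotations: AnnotationTable,
    substring: str = "synap",
    term_names: list[str] | None = None,
) -> int:
    """Number of the gene's GO term names matching the synaptic rule.

    Default rule: case-insensitive substring 'synap' (matches both
    'synapse' and 'synaptic' term names); an explicit term name list can
    replace it.
    """
    terms = annotations.go_terms(gene)
    if term_names is not None:
        wanted = {t.lower() for t in term_names}
        return sum(1 for t in terms if t.lower() in wanted)
    needle = substring.lower()
    return sum(1 for t in terms if needle in t.lower())


def filter_and_rank_rbps(
    degs: pd.DataFrame,
    annotations: AnnotationTable,
    phase: str = "na",
    synaptic_substring: str = "synap",
    synaptic_term_names: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the four RBP filters and rank candidates by score.

    Keeps genes that (1) have an RBP score entry, (2) have avg_log2fc > 0,
    (3) have >=1 synaptic GO term, (4) score > 0. Sorted by descending
    score; ties broken by descending avg_log2fc then gene symbol.
    """
    rows = []
    for _, rec in degs.iterrows():
        gene = rec["gene"]
        score = annotations.rbp_score(gene)
        if np.isnan(score):        # (1) not in the RBP candidate list
            continue
        if not rec["avg_log2fc"] > 0:  # (2) up-regulated only
            continue
        n_syn = count_synaptic_terms(gene, annotations, substring=synaptic_substring,
                                     term_names=synaptic_term_names)
        if n_syn < 1:              # (3) synaptic annotation required
            continue
        if not score > 0:          # (4) positive score required
            continue
        rows.append(
            {
                "gene": gene,
                "phase": phase,
                "avg_log2fc": float(rec["avg_log2fc"]),
                "pct.1": float(rec["pct.1"]),
                "pct.2": float(rec["pct.2"]),
                "n_synaptic_terms": int(n_syn),
                "rbp_score": float(score),
            }
        )
    out = pd.DataFrame(rows, columns=RBP_COLUMNS[:-1])
    if len(out):
        out = out.sort_values(
            by=["rbp_score", "avg_log2fc", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    else:
        out["rank"] = pd.Series(dtype=int)
    log.info("filter_and_rank_rbps[%s]: %d candidate(s)", phase, len(out))
    return out


def venn_counts(sets_by_label: dict[str, set[str]]) -> dict[str, int]:
    """Region counts for 2 or 3 labeled sets.

    Keys are '&'-joined sorted label combinations; values count elements
    belonging to exactly that combination. Counts sum to |union|.
    """
    labels = list(sets_by_label.keys())
    if not 2 <= len(labels) <= 3:
        raise DesignError(f"venn_counts supports 2 or 3 sets, got {len(labels)}")
    sets = {lab: set(v) for lab, v in sets_by_label.items()}
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[lab] for lab in combo))
            outside = set.union(set(), *(sets[lab] for lab in labels if lab not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions
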