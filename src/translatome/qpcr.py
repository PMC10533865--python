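"""qPCR ratio statistics.

The polysome/monosome ratio statistic is a triple-differenced cycle
threshold: per gene and biological sample, ΔCt normalizes the target to a
reference gene within each fraction, ΔΔCt = ΔCt(poly) - ΔCt(mono)
captures the polysome/monosome balance (one Ct unit = one 2-fold change),
and ΔΔΔCt centers ΔΔCt on the wild-type group mean so WT averages zero by
construction. A lower polysome Ct (more polysomal material) makes ΔΔΔCt
negative; reporting layers may flip the sign to read as "ratio increased"
(see REPORT_SIGN).

Group comparisons follow a normality gate: Welch's two-sided t when
Shapiro-Wilk accepts normality in both groups, Mann-Whitney otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CtTable

log = logging.getLogger("translatome")

#: multiply ΔΔΔCt by this constant when presenting "polysome/monosome
#: ratio" on the log2 scale (a polysome shift then reads as positive).
REPORT_SIGN = -1.0


@dataclass
class RatioResult:
    gene: str
    values_by_genotype: dict[str, list[float]]
    group_means: dict[str, float] = field(default_factory=dict)
    group_sems: dict[str, float] = field(default_factory=dict)
    test_used: str | None = None
    p: float = float("nan")


def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")


def delta3_ct(ct: CtTable, reference_gene: str) -> list[RatioResult]:
    """Compute per-gene ΔΔΔCt values grouped by genotype.

    Technical replicates are averaged first. Samples missing a fraction
    (or its reference Ct) are dropped for that gene with a warning.
    Raises when no WT sample survives (the centering is undefined).
    """
    df = ct.table.copy()
    mean_ct = (
        df.dropna(subset=["ct"])
        .groupby(["gene", "sample_id", "fraction", "genotype"], as_index=False)["ct"]
        .mean()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index(["sample_id", "fraction"])["ct"]
    results: list[RatioResult] = []
    for gene, sub in mean_ct[mean_ct["gene"] != reference_gene].groupby("gene"):
        ddct: dict[str, list[float]] = {}
        for (sample_id, genotype), per_sample in sub.groupby(["sample_id", "genotype"]):
            strata = per_sample.set_index("fraction")["ct"]
            ok = all(
                f in strata.index and (sample_id, f) in ref.index
                for f in ("monosome", "polysome")
            )
            if not ok:
                log.warning("delta3_ct: gene %s sample %s missing a fraction; dropped",
                            gene, sample_id)
                continue
            d_poly = strata["polysome"] - ref.loc[(sample_id, "polysome")]
            d_mono = strata["monosome"] - ref.loc[(sample_id, "monosome")]
            ddct.setdefault(genotype, []).append(float(d_poly - d_mono))
        if "WT" not in ddct or not ddct["WT"]:
            raise ValueError(f"gene {gene!r}: no WT samples; ΔΔΔCt centering undefined")
        wt_mean = float(np.mean(ddct["WT"]))
        values = {g: [v - wt_mean for v in vals] for g, vals in ddct.items()}
        res = RatioResult(gene=gene, values_by_genotype=values)
        for g, vals in values.items():
            arr = np.asarray(vals)
            res.group_means[g] = float(arr.mean())
            res.group_sems[g] = _sem(arr)
        groups = [g for g in values if g != "WT"]
        if groups:
            other = np.asarray(values[groups[0]])
            cmp = group_compare(np.asarray(values["WT"]), other)
            res.test_used, res.p = cmp["test_used"], cmp["p"]
        results.append(res)
    return results


def group_compare(values_a, values_b, normality_alpha: float = 0.05) -> dict:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group (needs n >= 3; below that the gate defaults
    to Mann-Whitney). Both normal -> Welch two-sided t; otherwise
    two-sided Mann-Whitney. Groups containing tied values are treated as
    non-normal: discrete data are not Gaussian, and Shapiro-Wilk has
    little power to notice at these sample sizes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in comparison")
    normal = False
    has_ties = len(np.unique(a)) < a.size or len(np.unique(b)) < b.size
    if a.size >= 3 and b.size >= 3 and not has_ties:
        pa = scipy.stats.shapiro(a).pvalue
        pb = scipy.stats.shapiro(b).pvalue
        normal = pa > normality_alpha and pb > normality_alpha
    if normal:
        stat = scipy.stats.ttest_ind(a, b, equal_var=False)
        return {"test_used": "welch_t", "p": float(stat.pvalue)}
    stat = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test_used": "mann_whitney", "p": float(stat.pvalue)}


def ratio_results_to_frame(results: list[RatioResult]) -> pd.DataFrame:
    """Long-format table: one row per gene x genotype x biological sample."""
    rows = []
    for res in results:
        for genotype, vals in res.values_by_genotype.items():
            for v in vals:
                rows.append(
                    {
                        "gene": res.gene,
                        "genotype": genotype,
                        "dddct": v,
                        "log2_poly_mono_ratio": REPORT_SIGN * v,
                        "test_used": res.test_used,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows)
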