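"""Simplified negative-binomial Wald engine for two-group differential
association on count tables.

Model: counts for feature g in sample j are NB with mean mu_gj = q_g s_j
(s_j a sample size factor) and variance mu + alpha mu^2 with a single
per-feature dispersion alpha_g shared across groups. The procedure is
deliberately plain — median-of-ratios size factors, method-of-moments
dispersion pooled within groups, a delta-method Wald statistic on the
log2 fold change — with no shrinkage, independent filtering, or outlier
replacement: the downstream biology applies strict thresholds to
unshrunken estimates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CountTable
from .errors import DesignError, NormalizationError

log = logging.getLogger("translatome")

LN2 = np.log(2.0)

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "p", "padj", "dispersion"]


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features (nonzero in every sample) of
    count_gj / geometric-mean_g. A single sample gets factor 1.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=table.counts.columns)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "no feature has nonzero counts in every sample; "
            "consider a pseudo-reference fallback on filtered features"
        )
    sub = counts[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise NormalizationError("non-finite or non-positive size factor")
    return pd.Series(factors, index=table.counts.columns)


def _mom_dispersion(
    norm: np.ndarray, groups: list[np.ndarray], floor: float, mode: str = "pooled"
) -> np.ndarray:
    """Method-of-moments dispersion on normalized counts pooled within groups.

    Solves var = mu + alpha mu^2: residual excess variance over the
    Poisson expectation, weighted by mu^2. ``mode='pooled'`` (default)
    additionally pools the moment sums across features into a single
    shared alpha — at the replicate numbers this assay affords (2-3 per
    group) a per-feature second moment is too noisy to be useful and
    destabilizes the Wald reference. ``mode='per_feature'`` keeps one
    alpha per feature for heterogeneous data. Floored at ``floor``.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        x = norm[:, idx]
        n = x.shape[1]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * m**2
    if mode == "pooled":
        total = num.sum() / den.sum() if den.sum() > 0 else 0.0
        alpha = np.full(norm.shape[0], total)
    elif mode == "per_feature":
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")
    return np.maximum(alpha, floor)


def nb_wald_test(
    table: CountTable,
    group_of,
    dispersion_floor: float = 1e-6,
    pseudocount: float = 0.5,
    dispersion_mode: str = "pooled",
) -> pd.DataFrame:
    """Two-group NB Wald test; returns one row per feature.

    ``group_of`` maps sample id -> 1 or 2; log2fc is group 2 over group 1.
    Features with all-zero counts get missing p/padj and log2fc 0.
    The result frame carries the size factors in ``.attrs['size_factors']``.
    """
    if callable(group_of):
        assignment = {s: group_of(s) for s in table.sample_ids}
    else:
        assignment = dict(group_of)
    g1 = [s for s in table.sample_ids if assignment.get(s) == 1]
    g2 = [s for s in table.sample_ids if assignment.get(s) == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise DesignError(f"each group needs >=2 samples (got {len(g1)} vs {len(g2)})")

    sf = size_factors(table)
    counts = table.counts.to_numpy(dtype=float)
    norm = counts / sf.to_numpy()[None, :]
    cols = list(table.counts.columns)
    idx1 = np.asarray([cols.index(s) for s in g1])
    idx2 = np.asarray([cols.index(s) for s in g2])

    alpha = _mom_dispersion(norm, [idx1, idx2], dispersion_floor, mode=dispersion_mode)
    m1 = norm[:, idx1].mean(axis=1)
    m2 = norm[:, idx2].mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    # delta-method SE of log2(mean): Var(mean_g) = (mu + alpha mu^2)/n,
    # Var(log2 mean) = Var(mean)/(mean ln2)^2; means floored at the
    # pseudocount so zero-mean groups stay finite.
    m1s = np.maximum(m1, pseudocount)
    m2s = np.maximum(m2, pseudocount)
    v1 = m1s + alpha * m1s**2
    v2 = m2s + alpha * m2s**2
    se = np.sqrt(v1 / (len(idx1) * m1s**2) + v2 / (len(idx2) * m2s**2)) / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    all_zero = counts.sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    se[all_zero] = np.nan
    p[all_zero] = np.nan

    padj = adjust_pvalues(p, method="BH")
    out = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "dispersion": alpha,
        }
    )
    out.attrs["size_factors"] = sf
    log.info(
        "nb_wald_test: %d features, %d vs %d samples, %d all-zero",
        len(out), len(g1), len(g2), int(all_zero.sum()),
    )
    return out


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment (BH step-up or Bonferroni).

    Missing (NaN) entries are excluded from m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[valid] = np.minimum(pv * m, 1.0)
        return out
    if method != "BH":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[valid] = result
    return out
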