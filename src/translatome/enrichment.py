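"""Risk-gene enrichment statistics.

The core statistic is a permutation test with a restricted background:
cluster input sets (genes >1.5-fold enriched in a cluster) are compared
against a risk-gene target set by drawing equally sized gene lists from
the background (genes both detected in the phase and carrying association
scores) and counting overlaps. The empirical p is the fraction of draws
with an overlap at least as large as observed; the permutation null for a
set-overlap is exactly hypergeometric, which the tests exploit as a
closed-form oracle. A hypergeometric + BH helper covers plain list
intersections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import adjust_pvalues
from .errors import EnrichmentError

log = logging.getLogger("translatome")


@dataclass
class EnrichmentResult:
    label: str
    observed_overlap: int
    null_mean_overlap: float
    enrichment_rate: float | None  # None when the null mean is 0
    empirical_p: float
    n_iter: int
    seed: int
    input_size: int
    target_size_in_background: int
    background_size: int


def build_input_sets(markers: pd.DataFrame, lfc_cut: float = 0.5849) -> dict[str, set[str]]:
    """Per-cluster input sets: marker genes with avg_log2fc strictly above
    ``lfc_cut`` (0.5849 log2 units = 1.5-fold)."""
    out: dict[str, set[str]] = {}
    for cluster, sub in markers.groupby("cluster"):
        genes = set(sub.loc[sub["avg_log2fc"] > lfc_cut, "gene"])
        out[str(cluster)] = genes
        if not genes:
            log.info("build_input_sets: cluster %s has an empty input set", cluster)
    return out


def restrict_background(detected: set[str], scored: set[str]) -> set[str]:
    """Background = genes detected in the phase AND carrying association scores."""
    background = set(detected) & set(scored)
    if not background:
        raise EnrichmentError("empty background: detected and scored gene sets do not overlap")
    log.info(
        "restrict_background: %d detected ∩ %d scored -> %d background",
        len(detected), len(scored), len(background),
    )
    return background


def permutation_enrichment(
    input_set: set[str],
    target_set: set[str],
    background: set[str],
    n_iter: int = 10000,
    seed: int = 0,
    label: str = "",
    add_one: bool = False,
    chunk: int = 500,
) -> EnrichmentResult:
    """Permutation enrichment of ``input_set`` for ``target_set`` over
    ``background``.

    Each iteration draws |input_set| genes uniformly without replacement
    from the background and counts the overlap with the
    background-restricted target. empirical_p = (#draws with overlap >=
    observed) / n_iter (or the (count+1)/(n_iter+1) convention when
    ``add_one``).
    """
    background = set(background)
    outside = set(input_set) - background
    if outside:
        log.warning("permutation_enrichment[%s]: %d input gene(s) outside background dropped",
                    label, len(outside))
    input_in = set(input_set) & background
    if len(input_in) > len(background):
        raise ValueError("input set larger than background")
    target_in = set(target_set) & background
    observed = len(input_in & target_in)

    bg_list = sorted(background)
    is_target = np.asarray([g in target_in for g in bg_list], dtype=bool)
    k = len(input_in)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    done = 0
    while done < n_iter:
        size = min(chunk, n_iter - done)
        tiles = np.tile(is_target, (size, 1))
        permuted = rng.permuted(tiles, axis=1)
        null[done:done + size] = permuted[:, :k].sum(axis=1)
        done += size
    count = int((null >= observed).sum())
    empirical_p = (count + 1) / (n_iter + 1) if add_one else count / n_iter
    null_mean = float(null.mean())
    rate = observed / null_mean if null_mean > 0 else None
    return EnrichmentResult(
        label=label,
        observed_overlap=observed,
        null_mean_overlap=null_mean,
        enrichment_rate=rate,
        empirical_p=empirical_p,
        n_iter=n_iter,
        seed=seed,
        input_size=k,
        target_size_in_background=len(target_in),
        background_size=len(background),
    )


def hypergeometric_intersection(batch) -> pd.DataFrame:
    """Upper-tail hypergeometric test for a batch of (set_a, set_b, universe)
    triples, BH-adjusted across the batch.

    Elements outside the universe are dropped with a warning.
    """
    rows = []
    for i, (set_a, set_b, universe) in enumerate(batch):
        universe = set(universe)
        if not universe:
            raise ValueError("empty universe")
        a = set(set_a) & universe
        b = set(set_b) & universe
        if len(a) != len(set(set_a)) or len(b) != len(set(set_b)):
            log.warning("hypergeometric_intersection[%d]: elements outside universe dropped", i)
        overlap = len(a & b)
        # P(X >= overlap), X ~ Hypergeom(M=|U|, n=|A|, N=|B|)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, len(universe), len(a), len(b)))
        rows.append({"index": i, "overlap": overlap, "size_a": len(a), "size_b": len(b),
                     "universe": len(universe), "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["padj"] = adjust_pvalues(df["p"].to_numpy(), method="BH")
    return df


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "observed_overlap": r.observed_overlap,
                "null_mean_overlap": r.null_mean_overlap,
                "enrichment_rate": np.nan if r.enrichment_rate is None else r.enrichment_rate,
                "empirical_p": r.empirical_p,
                "n_iter": r.n_iter,
                "seed": r.seed,
                "input_size": r.input_size,
                "target_size_in_background": r.target_size_in_background,
                "background_size": r.background_size,
            }
            for r in results
        ]
    )
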