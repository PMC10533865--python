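"""RIP-seq target calling and cross-species intersection.

Targets are features enriched in the RIP pull-down over the matched IgG
control: log2FC strictly above a species-specific threshold (human 1.7,
mouse 0.5) with adjusted p strictly below alpha. Mouse and human target
sets are intersected per developmental phase after case-normalizing
symbols (or through an explicit ortholog map). RIP-qPCR fold enrichment
uses the 2^-ΔΔCt convention with the IgG stratum as the negative control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CtTable
from .errors import DesignError, MappingError
from .qpcr import group_compare
from .rbp import venn_counts

log = logging.getLogger("translatome")

TARGET_COLUMNS = ["feature_id", "species", "label", "log2fc_rip_vs_igg", "padj", "is_target"]


def call_rip_targets(
    de: pd.DataFrame,
    lfc_thresh: float,
    alpha: float = 0.05,
    species: str = "human",
    label: str = "",
) -> pd.DataFrame:
    """Flag RIP targets in a RIP-vs-IgG contrast (group2 = RIP).

    A feature is a target iff log2fc > lfc_thresh (strict) AND
    padj < alpha (strict). The full list is returned with flags.
    """
    lfc = de["log2fc"].to_numpy(dtype=float)
    padj = de["padj"].to_numpy(dtype=float)
    is_target = (lfc > lfc_thresh) & (padj < alpha) & ~np.isnan(padj)
    out = pd.DataFrame(
        {
            "feature_id": de["feature_id"],
            "species": species,
            "label": label,
            "log2fc_rip_vs_igg": lfc,
            "padj": padj,
            "is_target": is_target,
        },
        columns=TARGET_COLUMNS,
    )
    log.info("call_rip_targets[%s %s]: %d/%d targets at lfc>%g, padj<%g",
             species, label, int(is_target.sum()), len(out), lfc_thresh, alpha)
    return out


def _map_symbols(symbols, ortholog_map: dict[str, str] | None) -> set[str]:
    if ortholog_map is None:
        return {str(s).upper() for s in symbols}
    return {ortholog_map[s] for s in symbols if s in ortholog_map}


def cross_species_intersect(
    mouse_targets: pd.DataFrame,
    human_targets_by_phase: dict[str, pd.DataFrame],
    ortholog_map: dict[str, str] | None = None,
) -> dict[str, dict]:
    """Intersect mouse RIP targets with human targets per phase.

    Only rows flagged ``is_target`` participate. Mouse symbols map to the
    human namespace by case-insensitive identity unless an explicit
    ortholog map is given. Returns, per phase, the shared gene set and
    2-set Venn region counts.
    """
    if ortholog_map is not None:
        keys = list(ortholog_map.keys())
        if len(set(keys)) != len(keys):
            raise MappingError("ortholog map has duplicate mouse keys")
    mouse_set = _map_symbols(
        mouse_targets.loc[mouse_targets["is_target"], "feature_id"], ortholog_map
    )
    out: dict[str, dict] = {}
    for phase, human in human_targets_by_phase.items():
        human_set = {str(s).upper() for s in human.loc[human["is_target"], "feature_id"]}
        shared = mouse_set & human_set
        out[phase] = {
            "shared": shared,
            "venn": venn_counts({"mouse": mouse_set, f"human_{phase}": human_set}),
        }
    return out


def rip_qpcr_enrichment(
    ct: CtTable,
    reference_gene: str,
    negative_controls: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene RIP-qPCR fold enrichment: 2^-ΔΔCt against the IgG stratum.

    Technical replicates are averaged first; ΔCt = Ct_target - Ct_reference
    within each (sample, antibody) stratum; ΔΔCt = ΔCt_RIP - ΔCt_IgG.
    Negative-control genes are reported like any other gene; each target's
    fold values are compared to the pooled negative-control folds via the
    normality-gated two-group test.
    """
    negative_controls = set(negative_controls or ())
    df = ct.table.copy()
    # mean Ct over technical replicates; non-detects (NaN) drop the stratum
    mean_ct = (
        df.dropna(subset=["ct"])
        .groupby(["gene", "sample_id", "antibody"], as_index=False)["ct"]
        .mean()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index(["sample_id", "antibody"])["ct"]
    rows = []
    for gene, sub in mean_ct[mean_ct["gene"] != reference_gene].groupby("gene"):
        folds = []
        for sample_id, per_sample in sub.groupby("sample_id"):
            strata = per_sample.set_index("antibody")["ct"]
            if "RIP" not in strata.index or "IgG" not in strata.index:
                log.warning("rip_qpcr_enrichment: gene %s sample %s missing a RIP/IgG stratum",
                            gene, sample_id)
                continue
            try:
                d_rip = strata["RIP"] - ref.loc[(sample_id, "RIP")]
                d_igg = strata["IgG"] - ref.loc[(sample_id, "IgG")]
            except KeyError:
                log.warning("rip_qpcr_enrichment: reference %s missing for sample %s",
                            reference_gene, sample_id)
                continue
            folds.append(2.0 ** -(d_rip - d_igg))
        if not folds:
            log.warning("rip_qpcr_enrichment: gene %s skipped (no complete sample)", gene)
            continue
        folds = np.asarray(folds, dtype=float)
        rows.append(
            {
                "gene": gene,
                "n_samples": len(folds),
                "fold_values": list(folds),
                "fold_mean": float(folds.mean()),
                "fold_sem": float(folds.std(ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else np.nan,
                "is_negative_control": gene in negative_controls,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) and negative_controls:
        neg_folds = np.concatenate(
            [np.asarray(v) for v, g in zip(out["fold_values"], out["gene"])
             if g in negative_controls] or [np.array([])]
        )
        tests = []
        for _, rec in out.iterrows():
            if rec["gene"] in negative_controls or len(neg_folds) == 0:
                tests.append({"test_used": None, "p": np.nan})
            else:
                tests.append(group_compare(np.asarray(rec["fold_values"]), neg_folds))
        out["test_used"] = [t["test_used"] for t in tests]
        out["p_vs_negative"] = [t["p"] for t in tests]
    return out


def validate_rip_design(meta: pd.DataFrame) -> None:
    """Raise if the contrast has no IgG control samples."""
    if not (meta["antibody"] == "IgG").any():
        raise DesignError("RIP contrast has no IgG control samples")
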