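"""Translational-status classification from polysome-profiling contrasts.

A transcript is evaluated on three contrasts of the same condition pair
(input, monosome, polysome). Transcriptionally unstable transcripts
(significant input change) are set aside; the rest are classified by which
ribosomal fraction they shift toward: toward polysomes = derepressed (more
translationally active), toward monosomes = repressed. Discordant
significant signals are surfaced as ambiguous rather than silently
assigned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CountTable
from .errors import AlignmentError

log = logging.getLogger("translatome")

STATUSES = ("derepressed", "repressed", "unchanged", "input_unstable", "ambiguous")

CALL_COLUMNS = [
    "feature_id", "contrast", "status", "evidence",
    "mono_log2fc", "poly_log2fc", "input_log2fc",
    "mono_padj", "poly_padj", "input_padj",
]


def stable_input_set(de_input: pd.DataFrame, lfc_thresh: float = 1.0, alpha: float = 0.05) -> set[str]:
    """Features whose input levels are transcriptionally stable.

    A feature is *unstable* only when it clears both strict thresholds
    (|log2FC| > lfc_thresh AND padj < alpha); features with missing padj
    are retained as stable.
    """
    if len(de_input) == 0:
        raise ValueError("empty input-contrast result")
    lfc = de_input["log2fc"].to_numpy(dtype=float)
    padj = de_input["padj"].to_numpy(dtype=float)
    unstable = (np.abs(lfc) > lfc_thresh) & (padj < alpha) & ~np.isnan(padj)
    stable = set(de_input.loc[~unstable, "feature_id"])
    log.info("stable_input_set: %d/%d features stable", len(stable), len(de_input))
    return stable


def _evidence(lfc: float, padj: float, up: str, down: str,
              lfc_thresh: float, alpha: float) -> set[str]:
    if np.isnan(padj):
        return set()
    if abs(lfc) > lfc_thresh and padj < alpha:
        return {up} if lfc > 0 else {down}
    return set()


def classify_status(
    de_mono: pd.DataFrame,
    de_poly: pd.DataFrame,
    stable: set[str],
    lfc_thresh: float = 1.0,
    alpha: float = 0.05,
    contrast: str = "",
    de_input: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign a translational status to every feature of the contrast.

    derepressed: evidence within {poly_up, mono_down}; repressed: within
    {mono_up, poly_down}; unchanged: no significant fraction evidence;
    ambiguous: discordant evidence spanning both poles.
    """
    mono = de_mono.set_index("feature_id")
    poly = de_poly.set_index("feature_id")
    if set(mono.index) != set(poly.index):
        raise AlignmentError("monosome and polysome contrasts cover different feature sets")
    inp = de_input.set_index("feature_id") if de_input is not None else None

    rows = []
    for fid in mono.index:
        m_lfc, m_padj = float(mono.at[fid, "log2fc"]), float(mono.at[fid, "padj"])
        p_lfc, p_padj = float(poly.at[fid, "log2fc"]), float(poly.at[fid, "padj"])
        if inp is not None and fid in inp.index:
            i_lfc, i_padj = float(inp.at[fid, "log2fc"]), float(inp.at[fid, "padj"])
        else:
            i_lfc, i_padj = np.nan, np.nan
        if fid not in stable:
            status, ev = "input_unstable", set()
        else:
            ev = _evidence(m_lfc, m_padj, "mono_up", "mono_down", lfc_thresh, alpha)
            ev |= _evidence(p_lfc, p_padj, "poly_up", "poly_down", lfc_thresh, alpha)
            if not ev:
                status = "unchanged"
            elif ev <= {"poly_up", "mono_down"}:
                status = "derepressed"
            elif ev <= {"mono_up", "poly_down"}:
                status = "repressed"
            else:
                status = "ambiguous"
        rows.append(
            {
                "feature_id": fid,
                "contrast": contrast,
                "status": status,
                "evidence": ",".join(sorted(ev)),
                "mono_log2fc": m_lfc,
                "poly_log2fc": p_lfc,
                "input_log2fc": i_lfc,
                "mono_padj": m_padj,
                "poly_padj": p_padj,
                "input_padj": i_padj,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    counts = calls["status"].value_counts().to_dict()
    log.info("classify_status[%s]: %s", contrast, counts)
    return calls


def polysome_baseline(table: CountTable, phase: str = "early") -> set[str]:
    """Features associated with actively translating polysomes in a phase.

    Defined as nonzero polysome counts in every polysome sample of that
    phase — the weakest detection rule consistent with 'associated with'.
    """
    sub = table.select(fraction="polysome", phase=phase)
    if not sub.sample_ids:
        raise ValueError(f"no polysome samples for phase {phase!r}")
    present = (sub.counts.to_numpy() > 0).all(axis=1)
    return set(np.asarray(sub.feature_ids)[present])


def _poly_category(evidence: str) -> str:
    ev = set(evidence.split(",")) if evidence else set()
    if "poly_up" in ev:
        return "Poly up"
    if "poly_down" in ev:
        return "Poly down"
    return "No"


def trajectory_summary(
    calls_by_contrast: dict[str, pd.DataFrame],
    baseline_features: set[str],
    contrasts: list[str] | None = None,
):
    """Cross-tabulate baseline features by polysome direction per contrast.

    Each baseline feature is categorized as 'Poly up' / 'Poly down' / 'No'
    in every later contrast using polysome evidence only. With two
    contrasts the result is a 3x3 crosstab DataFrame; with one, a Series
    of category counts. Marginal sums equal |baseline_features|.
    """
    if contrasts is None:
        contrasts = list(calls_by_contrast.keys())
    for c in contrasts:
        if c not in calls_by_contrast:
            raise ValueError(f"contrast {c!r} missing from calls")
    cats = ["Poly up", "Poly down", "No"]
    features = sorted(baseline_features)
    per_contrast = {}
    for c in contrasts:
        calls = calls_by_contrast[c].set_index("feature_id")
        per_contrast[c] = [
            _poly_category(calls.at[f, "evidence"]) if f in calls.index else "No"
            for f in features
        ]
    if len(contrasts) == 1:
        series = pd.Series(per_contrast[contrasts[0]])
        return series.value_counts().reindex(cats, fill_value=0)
    if len(contrasts) == 2:
        a, b = contrasts
        tab = pd.DataFrame(0, index=cats, columns=cats)
        for ca, cb in zip(per_contrast[a], per_contrast[b]):
            tab.loc[ca, cb] += 1
        tab.index.name, tab.columns.name = a, b
        return tab
    frame = pd.DataFrame(per_contrast)
    return frame.groupby(contrasts).size()
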