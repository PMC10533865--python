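"""Pipeline configuration.

A single YAML document mirrors every threshold used anywhere in the
pipeline, with the published defaults; any value can be overridden from a
user config file. ``config_hash`` feeds the run log so a run's funnel can
be reproduced from its log alone.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "translation": {
        # volcano thresholds: strict |log2FC| > 1 and padj < 0.05
        "lfc_thresh": 1.0,
        "alpha": 0.05,
    },
    "diffexpr": {
        "dispersion_floor": 1e-6,
        "pseudocount": 0.5,  # normalized counts, added inside the fold change
    },
    "markers": {
        "scale": 10000.0,
        "min_pct": 0.10,
        "min_lfc": 0.25,
        "alpha": 0.05,
        "fc_pseudocount": 1.0,  # scale-units, added to normalized means
        "min_mean": 0.1,   # intersection filter: mean normalized expression
        "min_frac": 0.30,  # intersection filter: fraction of nuclei expressing
    },
    "enrichment": {
        "input_lfc_cut": 0.5849,  # log2 of a 1.5-fold cluster enrichment
        "n_iter": 10000,
        "add_one": False,  # (count+1)/(n_iter+1) convention, off by default
    },
    "rbp": {
        "min_pct": 0.30,
        "min_lfc": 0.25,
        "alpha": 0.05,
        "synaptic_substring": "synap",
        "synaptic_term_ids": None,  # explicit term-name list overriding the substring match
    },
    "rip": {
        "lfc_thresh": {"human": 1.7, "mouse": 0.5},
        "alpha": 0.05,
    },
    "pcr": {
        "normality_alpha": 0.05,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, layered over the built-in defaults."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run logs."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
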