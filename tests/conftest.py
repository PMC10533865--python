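import numpy as np
import pandas as pd
import pytest

from translatome.datatypes import CountTable


def make_count_table(counts, feature_ids=None, sample_ids=None, **meta_overrides):
    """Build a CountTable with neutral metadata from a 2-D array."""
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "fraction": meta_overrides.get("fraction", ["na"] * n_samp),
            "phase": meta_overrides.get("phase", ["na"] * n_samp),
            "genotype": meta_overrides.get("genotype", ["na"] * n_samp),
            "antibody": meta_overrides.get("antibody", ["na"] * n_samp),
            "replicate": meta_overrides.get("replicate", list(range(1, n_samp + 1))),
        }
    ).set_index("sample_id")
    return CountTable(pd.DataFrame(counts, index=feature_ids, columns=sample_ids), meta)


def make_de_frame(records):
    """DE result frame from (feature_id, log2fc, padj) triples."""
    rows = []
    for fid, lfc, padj in records:
        rows.append(
            {
                "feature_id": fid,
                "base_mean": 100.0,
                "log2fc": lfc,
                "se": 0.1,
                "p": padj,
                "padj": padj,
                "dispersion": 0.05,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table():
    return make_count_table([[10, 20], [5, 10], [100, 200]], feature_ids=["A", "B", "C"])
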