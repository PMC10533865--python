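from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from translatome.datatypes import NucleusMatrix
from translatome.errors import DesignError
from translatome.markers import (
    cluster_expression_filter,
    coexpression_fractions,
    find_all_markers,
    intersect_translatome,
    normalize_matrix,
    two_group_markers,
)
from translatome.simulate import simulate_nucleus_matrix
from translatome.translation import CALL_COLUMNS


def make_matrix(counts, clusters, genes=None, phase="mid"):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = [f"b{j}" for j in range(counts.shape[1])]
    return NucleusMatrix(genes, barcodes, sp.csr_matrix(counts), np.asarray(clusters), phase)


class TestNormalize:
    def test_stated_formula(self):
        # one gene with count 10 out of a 100-count nucleus at scale 10000
        m = make_matrix([[10], [90]], ["A"])
        norm = normalize_matrix(m, scale=10000).toarray()
        assert norm[0, 0] == pytest.approx(np.log(1 + 1000), abs=1e-4)
        assert norm[0, 0] == pytest.approx(6.9088, abs=1e-3)

    def test_zero_depth_nucleus_maps_to_zero(self):
        m = make_matrix([[0, 3], [0, 1]], ["A", "A"])
        norm = normalize_matrix(m).toarray()
        assert (norm[:, 0] == 0).all()

    def test_depth_invariance(self):
        m1 = make_matrix([[2], [6]], ["A"])
        m2 = make_matrix([[4], [12]], ["A"])
        np.testing.assert_allclose(
            normalize_matrix(m1).toarray(), normalize_matrix(m2).toarray()
        )


def exact_ranksum_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    obs = ranks[:n].sum()
    mean = ranks.sum() * n / len(pooled)
    stats = [
        abs(sum(ranks[list(idx)]) - mean)
        for idx in combinations(range(len(pooled)), n)
    ]
    return np.mean([s >= abs(obs - mean) - 1e-9 for s in stats])


class TestFindAllMarkers:
    def test_perfect_marker(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :4] = 5      # gene 0 only in cluster A
        counts[1, :] = 3       # gene 1 everywhere (depth anchor)
        m = make_matrix(counts, ["A"] * 4 + ["B"] * 4)
        rec = find_all_markers(m, alpha=0.2)
        row = rec[(rec["gene"] == "g0") & (rec["cluster"] == "A")]
        assert len(row) == 1
        assert row["pct.1"].iloc[0] == 1.0 and row["pct.2"].iloc[0] == 0.0

    def test_low_detection_excluded_regardless_of_p(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(3, 200))
        counts[0, :] = 0
        counts[0, :9] = 50     # 9% of the 100-nucleus target cluster
        m = make_matrix(counts, ["A"] * 100 + ["B"] * 100)
        rec = find_all_markers(m, min_pct=0.10)
        assert not ((rec["gene"] == "g0") & (rec["cluster"] == "A")).any()

    def test_wilcoxon_close_to_exact_enumeration_at_4v4(self):
        """Normal-approximation p within 0.05 of the exhaustive p over all
        C(8,4)=70 rank assignments."""
        from translatome.markers import _wilcoxon_rows
        rng = np.random.default_rng(3)
        for _ in range(10):
            # rates high enough that ranks are mostly distinct, as for
            # normalized expression values
            x = rng.poisson(10.0, size=4).astype(float)
            y = rng.poisson(4.0, size=4).astype(float)
            approx = _wilcoxon_rows(x[None, :], y[None, :])[0]
            exact = exact_ranksum_p(x, y)
            assert abs(approx - exact) < 0.05

    def test_single_cluster_rejected(self):
        m = make_matrix([[1, 2]], ["A", "A"])
        with pytest.raises(DesignError):
            find_all_markers(m)

    def test_small_cluster_skipped_with_warning(self, caplog):
        counts = np.ones((2, 6), dtype=int)
        m = make_matrix(counts, ["A"] * 2 + ["B"] * 4)
        with caplog.at_level("WARNING", logger="translatome"):
            find_all_markers(m)
        assert any("skipped" in r.message for r in caplog.records)

    def test_invariant_to_nucleus_order_and_depth(self):
        m, _ = simulate_nucleus_matrix(3, 40, 3, 8.0, 0.3, seed=2, n_genes=100)
        base = find_all_markers(m)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.nucleus_ids))
        dense = m.counts.toarray()[:, perm]
        dense[:, 0] *= 3  # library-size change on one nucleus
        shuffled = NucleusMatrix(
            m.gene_ids, [m.nucleus_ids[i] for i in perm], sp.csr_matrix(dense),
            m.cluster_labels[perm], m.phase,
        )
        again = find_all_markers(shuffled)
        key = ["gene", "cluster"]
        a = base.sort_values(key).reset_index(drop=True)
        b = again.sort_values(key).reset_index(drop=True)
        assert list(a["gene"]) == list(b["gene"])
        # pct metrics depend only on detection, identical under both changes
        np.testing.assert_allclose(a["pct.1"], b["pct.1"])


class TestTwoGroupMarkers:
    def test_overlapping_groups_rejected(self):
        m, _ = simulate_nucleus_matrix(4, 10, 2, 4.0, 0.3, seed=1, n_genes=50)
        with pytest.raises(DesignError):
            two_group_markers(m, {"M0", "M1"}, {"M1", "M2"})

    def test_pct_cutoff_applies_to_target_pool(self):
        counts = np.zeros((2, 40), dtype=int)
        counts[1, :] = 2                      # depth anchor
        counts[0, :5] = 9                     # 25% of the 20 SP nuclei < 30%
        counts[0, 20:] = 0
        m = make_matrix(counts, ["S"] * 20 + ["N"] * 20)
        rec = two_group_markers(m, {"S"}, {"N"}, min_pct=0.30)
        assert "g0" not in set(rec["gene"])

    def test_planted_sp_genes_recovered_with_positive_sign(self):
        m, truth = simulate_nucleus_matrix(4, 60, 4, 8.0, 0.3, seed=5, n_genes=150)
        sp = {"M0"}
        rec = two_group_markers(m, sp, {"M1", "M2", "M3"}, min_pct=0.30)
        found = rec.set_index("gene")
        hits = [g for g in truth["M0"] if g in found.index and found.at[g, "avg_log2fc"] > 0]
        assert len(hits) >= 0.8 * len(truth["M0"])


class TestClusterFilter:
    def test_all_zero_gene_passes_nowhere(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[1, :] = 1
        m = make_matrix(counts, ["A"] * 5 + ["B"] * 5)
        out = cluster_expression_filter(m, {"g0"})
        assert all(len(v) == 0 for v in out.values())

    def test_conjunction_of_mean_and_fraction(self):
        # g0: expressed in 2/10 nuclei (20%) but strongly -> fails fraction
        # g1: expressed in 4/10 (40%) with normalized mean above 0.1 -> passes
        counts = np.zeros((3, 10), dtype=int)
        counts[0, :2] = 50
        counts[1, :4] = 10
        counts[2, :] = 100  # depth anchor
        m = make_matrix(counts, ["A"] * 10)
        # evaluate thresholds directly for the passing gene
        from translatome.markers import normalize_matrix as nm
        norm = nm(m).toarray()
        assert norm[1, :].mean() > 0.1 and (counts[1] > 0).mean() >= 0.3
        out = cluster_expression_filter(m, {"g0", "g1"})
        assert out["A"] == {"g1"}

    def test_unknown_genes_dropped_with_warning(self, caplog):
        m = make_matrix([[1, 1], [1, 1]], ["A", "B"])
        with caplog.at_level("WARNING", logger="translatome"):
            cluster_expression_filter(m, {"g0", "missing"})
        assert any("not in matrix" in r.message for r in caplog.records)


class TestIntersectTranslatome:
    def _calls(self, statuses):
        rows = []
        for fid, status in statuses:
            rows.append({"feature_id": fid, "contrast": "MvE", "status": status,
                         "evidence": "", "mono_log2fc": 0, "poly_log2fc": 0,
                         "input_log2fc": 0, "mono_padj": 1, "poly_padj": 1,
                         "input_padj": 1})
        return pd.DataFrame(rows, columns=CALL_COLUMNS)

    def test_empty_calls(self):
        out = intersect_translatome(self._calls([]), {"L4": {"A"}})
        assert out["L4"] == {"derepressed": set(), "repressed": set()}

    def test_set_semantics_across_clusters(self):
        calls = self._calls([("geneA", "derepressed"), ("geneB", "repressed")])
        filt = {"L4": {"GENEA"}, "L7": {"GENEA", "GENEB"}, "L9": set()}
        out = intersect_translatome(calls, filt)
        assert out["L4"]["derepressed"] == {"GENEA"}
        assert out["L7"] == {"derepressed": {"GENEA"}, "repressed": {"GENEB"}}
        assert out["L9"] == {"derepressed": set(), "repressed": set()}


class TestCoexpression:
    def test_hand_counted_fractions(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :8] = 1   # A in nuclei 0-7
        counts[1, 2:9] = 1  # B in nuclei 2-8
        # both: 2..7 (6), a_only: 0,1 (2), b_only: 8 (1), neither: 9 (1)
        m = make_matrix(counts, ["C"] * 10)
        out = coexpression_fractions(m, "g0", "g1").iloc[0]
        assert (out["a_only"], out["b_only"], out["both"], out["neither"]) == (
            0.2, 0.1, 0.6, 0.1
        )

    def test_mutually_exclusive_genes(self):
        counts = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        m = make_matrix(counts, ["A", "A", "A", "A"])
        assert coexpression_fractions(m, "g0", "g1").iloc[0]["both"] == 0

    def test_fractions_sum_to_one_per_cluster(self):
        m, _ = simulate_nucleus_matrix(3, 30, 2, 4.0, 0.5, seed=11, n_genes=20)
        out = coexpression_fractions(m, m.gene_ids[0], m.gene_ids[1])
        totals = out[["a_only", "b_only", "both", "neither"]].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0)

    def test_missing_gene_named_in_error(self):
        m = make_matrix([[1]], ["A"])
        with pytest.raises(ValueError, match="nope"):
            coexpression_fractions(m, "g0", "nope")
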