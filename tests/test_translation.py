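import numpy as np
import pandas as pd
import pytest

from translatome import diffexpr, translation
from translatome.errors import AlignmentError
from translatome.simulate import SimulationSpec, default_planted_spec, simulate_fraction_counts

from conftest import make_de_frame


def run_pipeline(table, lfc=1.0, alpha=0.05, contrast="MvE"):
    de = {}
    for fraction in ("input", "monosome", "polysome"):
        sub = table.select(fraction=fraction)
        go = {s: 1 if sub.sample_meta.at[s, "phase"] == "early" else 2 for s in sub.sample_ids}
        de[fraction] = diffexpr.nb_wald_test(sub, go)
    stable = translation.stable_input_set(de["input"], lfc, alpha)
    calls = translation.classify_status(de["monosome"], de["polysome"], stable,
                                        lfc, alpha, contrast=contrast)
    return de, stable, calls


class TestStableInputSet:
    def test_exact_null_is_stable(self):
        de = make_de_frame([("A", 0.0, 1.0)])
        assert translation.stable_input_set(de) == {"A"}

    def test_fold_change_without_significance_is_stable(self):
        de = make_de_frame([("A", 1.5, 0.2)])
        assert translation.stable_input_set(de) == {"A"}

    def test_boundary_lfc_exactly_one_is_stable(self):
        de = make_de_frame([("A", 1.0, 0.001)])
        assert translation.stable_input_set(de) == {"A"}

    def test_significant_shift_excluded(self):
        de = make_de_frame([("A", -2.5, 0.001), ("B", 0.1, 0.9)])
        assert translation.stable_input_set(de) == {"B"}

    def test_missing_padj_retained(self):
        de = make_de_frame([("A", 3.0, np.nan)])
        assert translation.stable_input_set(de) == {"A"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            translation.stable_input_set(make_de_frame([]).iloc[0:0])

    def test_planted_input_shift_excluded(self):
        spec = default_planted_spec(n_features=600, n_planted=0, n_input_shifted=100,
                                    effect_log2fc=2.0, dispersion=0.05, seed=17)
        table = simulate_fraction_counts(spec)
        _, stable, _ = run_pipeline(table)
        excluded = spec.planted_input_shifted - stable
        assert len(excluded) / len(spec.planted_input_shifted) >= 0.9


class TestClassifyStatus:
    def _call(self, mono, poly, stable=("A",)):
        return translation.classify_status(
            make_de_frame(mono), make_de_frame(poly), set(stable)
        ).set_index("feature_id")

    @pytest.mark.parametrize(
        "mono,poly,expected,evidence",
        [
            # significantly lower polysome association only -> repressed
            ([("A", 0.1, 0.9)], [("A", -2.0, 0.001)], "repressed", "poly_down"),
            ([("A", -2.0, 0.001)], [("A", 0.1, 0.9)], "derepressed", "mono_down"),
            ([("A", -1.5, 0.01)], [("A", 1.5, 0.01)], "derepressed", "mono_down,poly_up"),
            ([("A", 2.0, 0.01)], [("A", -1.2, 0.01)], "repressed", "mono_up,poly_down"),
            ([("A", 2.0, 0.01)], [("A", 2.0, 0.01)], "ambiguous", "mono_up,poly_up"),
            ([("A", 0.0, 1.0)], [("A", 0.0, 1.0)], "unchanged", ""),
            # boundary: |lfc| exactly at threshold is not evidence
            ([("A", 1.0, 0.001)], [("A", 0.0, 1.0)], "unchanged", ""),
        ],
    )
    def test_status_assignment(self, mono, poly, expected, evidence):
        row = self._call(mono, poly).loc["A"]
        assert row["status"] == expected and row["evidence"] == evidence

    def test_unstable_feature_flagged(self):
        row = self._call([("A", 2.0, 0.001)], [("A", 2.0, 0.001)], stable=()).loc["A"]
        assert row["status"] == "input_unstable" and row["evidence"] == ""

    def test_global_null_all_unchanged(self):
        mono = [(f"F{i}", 0.5, 1.0) for i in range(20)]
        poly = [(f"F{i}", -0.5, 1.0) for i in range(20)]
        calls = translation.classify_status(
            make_de_frame(mono), make_de_frame(poly), {f"F{i}" for i in range(20)}
        )
        assert (calls["status"] == "unchanged").all()

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(AlignmentError):
            translation.classify_status(
                make_de_frame([("A", 0, 1)]), make_de_frame([("B", 0, 1)]), {"A"}
            )

    def test_partition_property(self):
        spec = default_planted_spec(n_features=400, n_planted=40, n_input_shifted=40, seed=3)
        _, _, calls = run_pipeline(simulate_fraction_counts(spec))
        assert len(calls) == 400
        assert calls["feature_id"].is_unique
        assert calls["status"].isin(translation.STATUSES).all()
        assert calls["status"].value_counts().sum() == 400

    def test_antisymmetry_under_condition_swap(self):
        spec = default_planted_spec(n_features=300, n_planted=30, n_input_shifted=0, seed=9)
        table = simulate_fraction_counts(spec)
        de, stable, calls = run_pipeline(table)
        flipped = {}
        for fraction in ("monosome", "polysome"):
            f = de[fraction].copy()
            f["log2fc"] = -f["log2fc"]
            flipped[fraction] = f
        swapped = translation.classify_status(
            flipped["monosome"], flipped["polysome"], stable, 1.0, 0.05
        ).set_index("feature_id")["status"]
        orig = calls.set_index("feature_id")["status"]
        mapping = {"derepressed": "repressed", "repressed": "derepressed",
                   "unchanged": "unchanged", "input_unstable": "input_unstable",
                   "ambiguous": "ambiguous"}
        assert (swapped == orig.map(mapping)).all()

    def test_stricter_thresholds_never_create_calls(self):
        spec = default_planted_spec(n_features=300, n_planted=30, n_input_shifted=0, seed=4)
        table = simulate_fraction_counts(spec)
        de, stable, loose = run_pipeline(table, lfc=1.0, alpha=0.05)
        strict = translation.classify_status(de["monosome"], de["polysome"], stable,
                                             lfc_thresh=1.5, alpha=0.01)
        loose_status = loose.set_index("feature_id")["status"]
        strict_status = strict.set_index("feature_id")["status"]
        moved = (loose_status == "unchanged") & (strict_status != "unchanged")
        assert not moved.any()

    def test_planted_recovery(self):
        spec = default_planted_spec(n_features=800, n_planted=60, n_input_shifted=0,
                                    effect_log2fc=2.0, dispersion=0.05, seed=23)
        _, _, calls = run_pipeline(simulate_fraction_counts(spec))
        status = calls.set_index("feature_id")["status"]
        dere = (status.loc[sorted(spec.planted_derepressed)] == "derepressed").mean()
        repr_ = (status.loc[sorted(spec.planted_repressed)] == "repressed").mean()
        assert dere >= 0.8 and repr_ >= 0.8
        unplanted = status.drop(sorted(spec.planted_derepressed | spec.planted_repressed))
        called = ~unplanted.isin(["unchanged", "input_unstable"])
        assert called.mean() <= 0.15


class TestTrajectory:
    def _calls(self, records, contrast):
        rows = []
        for fid, ev in records:
            rows.append({"feature_id": fid, "contrast": contrast,
                         "status": "unchanged", "evidence": ev,
                         "mono_log2fc": 0, "poly_log2fc": 0, "input_log2fc": 0,
                         "mono_padj": 1, "poly_padj": 1, "input_padj": 1})
        return pd.DataFrame(rows, columns=translation.CALL_COLUMNS)

    def test_empty_baseline_all_zero(self):
        calls = {"MvE": self._calls([("A", "poly_up")], "MvE"),
                 "LvM": self._calls([("A", "")], "LvM")}
        tab = translation.trajectory_summary(calls, set())
        assert tab.to_numpy().sum() == 0

    def test_all_unchanged_concentrates_in_no_no(self):
        feats = [f"F{i}" for i in range(5)]
        calls = {"MvE": self._calls([(f, "") for f in feats], "MvE"),
                 "LvM": self._calls([(f, "") for f in feats], "LvM")}
        tab = translation.trajectory_summary(calls, set(feats))
        assert tab.loc["No", "No"] == 5 and tab.to_numpy().sum() == 5

    def test_marginals_equal_baseline_size(self):
        feats = [f"F{i}" for i in range(8)]
        ev = ["poly_up", "poly_down", "", "poly_up", "", "", "poly_down", ""]
        calls = {"MvE": self._calls(list(zip(feats, ev)), "MvE"),
                 "LvM": self._calls(list(zip(feats, reversed(ev))), "LvM")}
        tab = translation.trajectory_summary(calls, set(feats))
        assert tab.to_numpy().sum() == 8
        assert tab.sum(axis=1).sum() == 8 and tab.sum(axis=0).sum() == 8

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError):
            translation.trajectory_summary({}, set(), contrasts=["MvE"])

    def test_planted_trajectory_counts(self):
        spec = default_planted_spec(n_features=500, n_planted=50, n_input_shifted=0,
                                    effect_log2fc=2.0, dispersion=0.05, seed=31)
        table = simulate_fraction_counts(spec)
        _, _, calls = run_pipeline(table)
        baseline = translation.polysome_baseline(table, phase="early")
        counts = translation.trajectory_summary({"MvE": calls}, baseline)
        planted_up = spec.planted_derepressed & baseline
        planted_down = spec.planted_repressed & baseline
        assert counts["Poly up"] >= 0.8 * len(planted_up)
        assert counts["Poly down"] >= 0.8 * len(planted_down)
        assert counts.sum() == len(baseline)
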