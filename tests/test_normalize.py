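"""Normalization stages: scaling, medians, references, missing filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engagekit.containers import NormalizedMeltTable
from engagekit.normalize import (TPPNormalizer, apply_scaling,
                                 compute_scaling_factors,
                                 filter_missing_pattern,
                                 median_normalize_by_protein,
                                 normalize_dataset, reference_normalize)
from engagekit.synthetic import melt_curve_model

from conftest import make_manifest, make_table


class TestScalingFactors:
    def test_forced_by_formula(self):
        counts = {"c_r1_T40": 100000, "c_r1_T50": 120000, "c_r1_T60": 80000,
                  "c_r1_REF0": 999}
        manifest = make_manifest(conditions=("c",), precursor_counts=counts)
        factors = compute_scaling_factors(manifest)
        assert factors["c_r1_T40"] == pytest.approx(1.0)
        assert factors["c_r1_T50"] == pytest.approx(1.2)
        assert factors["c_r1_T60"] == pytest.approx(0.8)
        assert factors["c_r1_REF0"] == 1.0  # references are never rescaled

    def test_single_run_condition_gets_unit_factor(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0,), n_refs=1)
        factors = compute_scaling_factors(manifest)
        assert factors["c_r1_T40"] == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 10**6), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_mean_factor_is_one_per_condition(self, counts):
        ladder = tuple(40.0 + i for i in range(len(counts)))
        run_counts = {f"c_r1_T{t:g}": n for t, n in zip(ladder, counts)}
        run_counts["c_r1_REF0"] = 12345
        manifest = make_manifest(conditions=("c",), ladder=ladder,
                                 precursor_counts=run_counts)
        factors = compute_scaling_factors(manifest)
        denat = manifest.loc[~manifest["is_reference"], "run_id"]
        assert factors[denat].mean() == pytest.approx(1.0)
        inv = compute_scaling_factors(manifest, invert=True)
        assert (inv[denat] * factors[denat]).round(12).eq(1.0).all()

    def test_zero_count_rejected(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0, 50.0))
        manifest.loc[0, "precursor_count"] = 0
        with pytest.raises(ValueError):
            compute_scaling_factors(manifest)


class TestApplyScaling:
    def test_elementwise_multiply_preserving_missing(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0, 50.0), n_refs=0)
        table = make_table({"P1": [10.0, np.nan]}, list(manifest["run_id"]))
        factors = pd.Series({"c_r1_T40": 1.2, "c_r1_T50": 0.8})
        out = apply_scaling(table, factors)
        assert out.abundance.loc["P1", "c_r1_T40"] == pytest.approx(12.0)
        assert np.isnan(out.abundance.loc["P1", "c_r1_T50"])
        assert out.stage == "scaled"

    def test_unit_factors_are_identity(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0, 50.0), n_refs=0)
        table = make_table({"P1": [3.0, 4.0]}, list(manifest["run_id"]))
        factors = pd.Series(1.0, index=manifest["run_id"])
        out = apply_scaling(table, factors)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_uncovered_run_is_error(self):
        table = make_table({"P1": [1.0, 2.0]}, ["r1", "r2"])
        with pytest.raises(ValueError, match="without scaling factors"):
            apply_scaling(table, pd.Series({"r1": 1.0}))


class TestMedianNormalize:
    def test_divides_by_condition_median(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0, 50.0, 60.0),
                                 n_refs=1)
        table = make_table({"P1": [2.0, 4.0, 8.0, 6.0]},
                           list(manifest["run_id"]), stage="scaled")
        out = median_normalize_by_protein(table, manifest)
        np.testing.assert_allclose(out.abundance.loc["P1"],
                                   [0.5, 1.0, 2.0, 1.5])  # median 4; ref divided too

    def test_all_equal_values_become_one(self):
        manifest = make_manifest(conditions=("c",), n_refs=0)
        table = make_table({"P1": [7.0, 7.0, 7.0]}, list(manifest["run_id"]),
                           stage="scaled")
        out = median_normalize_by_protein(table, manifest)
        assert (out.abundance.loc["P1"] == 1.0).all()

    @given(st.lists(st.floats(0.1, 1e6), min_size=3, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_post_median_is_one(self, values):
        ladder = tuple(40.0 + i for i in range(len(values)))
        manifest = make_manifest(conditions=("c",), ladder=ladder, n_refs=0)
        table = make_table({"P1": values}, list(manifest["run_id"]),
                           stage="scaled")
        out = median_normalize_by_protein(table, manifest)
        assert np.nanmedian(out.abundance.loc["P1"]) == pytest.approx(1.0)

    def test_protein_without_values_is_flagged_not_zeroed(self):
        manifest = make_manifest(conditions=("c",), n_refs=1)
        table = make_table({"P1": [np.nan] * 3 + [5.0]},
                           list(manifest["run_id"]), stage="scaled")
        out = median_normalize_by_protein(table, manifest)
        assert out.abundance.loc["P1"].isna().all()
        assert out.audit["proteins_without_condition_median"] == {"c": ["P1"]}


class TestReferenceNormalize:
    def test_reference_median_divisor(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0,), n_refs=3)
        table = make_table({"P1": [6.0, 2.0, 2.0, 4.0]},
                           list(manifest["run_id"]), stage="median_normalized")
        out = reference_normalize(table, manifest)
        # reference values [2, 2, 4] -> divisor 2
        assert out.abundance.loc["P1", "c_r1_T40"] == pytest.approx(3.0)

    def test_fallback_is_median_of_protein_medians(self):
        manifest = make_manifest(conditions=("c",), ladder=(40.0,), n_refs=1)
        cols = list(manifest["run_id"])
        table = make_table({"A": [1.0, 2.0], "B": [1.0, 8.0],
                            "C": [10.0, np.nan]}, cols,
                           stage="median_normalized")
        out = reference_normalize(table, manifest)
        # protein reference medians {2, 8} -> fallback divisor 5
        assert out.abundance.loc["C", "c_r1_T40"] == pytest.approx(2.0)
        assert out.audit["reference_divisors"]["c"]["fallback_divisor"] == 5.0

    def test_post_op_reference_median_is_one(self):
        rng = np.random.default_rng(0)
        manifest = make_manifest(conditions=("c",), ladder=(40.0, 50.0), n_refs=3)
        cols = list(manifest["run_id"])
        table = make_table({f"P{i}": rng.uniform(0.5, 2.0, len(cols))
                            for i in range(6)}, cols, stage="median_normalized")
        out = reference_normalize(table, manifest)
        ref_cols = [c for c in cols if "REF" in c]
        med = out.abundance[ref_cols].median(axis=1)
        np.testing.assert_allclose(med, 1.0)

    def test_condition_without_references_is_error(self):
        manifest = make_manifest(conditions=("c",), n_refs=0)
        table = make_table({"P1": [1.0, 1.0, 1.0]}, list(manifest["run_id"]),
                           stage="median_normalized")
        with pytest.raises(ValueError, match="no reference runs"):
            reference_normalize(table, manifest)


TEN_LADDER = tuple(40.0 + 2.0 * i for i in range(10))


def missing_filter_oracle(is_missing, max_missing=3, first_k=5):
    """Brute-force row scan of the drop rule."""
    return sum(is_missing) > max_missing and any(is_missing[:first_k])


class TestMissingPatternFilter:
    def run_filter(self, pattern):
        manifest = make_manifest(conditions=("c",), ladder=TEN_LADDER, n_refs=1)
        cols = list(manifest["run_id"])
        values = [np.nan if m else 1.0 for m in pattern] + [1.0]
        table = make_table({"P1": values}, cols, stage="reference_normalized")
        out = filter_missing_pattern(table, manifest)
        denat_cols = [c for c in cols if "REF" not in c]
        dropped = out.abundance.loc["P1", denat_cols].isna().all()
        return dropped and not all(pattern)

    def test_four_missing_all_high_temps_retained(self):
        pattern = [False] * 6 + [True] * 4
        assert not self.run_filter(pattern)

    def test_four_missing_touching_first_five_dropped(self):
        pattern = [True] + [False] * 5 + [True] * 3 + [False]
        assert self.run_filter(pattern)

    def test_three_missing_always_retained(self):
        pattern = [True, False, True, False, True] + [False] * 5
        assert not self.run_filter(pattern)

    @given(st.lists(st.booleans(), min_size=10, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_scan(self, pattern):
        if all(pattern):
            return  # nothing measurable either way
        assert self.run_filter(pattern) == missing_filter_oracle(pattern)

    def test_dropped_curves_recorded(self):
        manifest = make_manifest(conditions=("c",), ladder=TEN_LADDER, n_refs=1)
        cols = list(manifest["run_id"])
        bad = [np.nan] * 4 + [1.0] * 6 + [1.0]
        good = [1.0] * 11
        table = make_table({"BAD": bad, "GOOD": good}, cols,
                           stage="reference_normalized")
        out = filter_missing_pattern(table, manifest)
        assert out.audit["dropped_curves"].to_dict("records") == [
            {"protein_id": "BAD", "condition": "c", "replicate": 1}]


class TestPipelineContracts:
    def test_stage_order_enforced(self):
        manifest = make_manifest(conditions=("c",), n_refs=1)
        table = make_table({"P1": [1.0] * 4}, list(manifest["run_id"]))
        with pytest.raises(ValueError, match="out of order"):
            median_normalize_by_protein(table, manifest)  # raw, not scaled
        with pytest.raises(ValueError, match="out of order"):
            reference_normalize(table, manifest)

    def test_missingness_preserved_until_filter(self, small_sim):
        _, dataset, _ = small_sim
        table = NormalizedMeltTable(dataset.quant.abundance.copy(), "raw")
        factors = compute_scaling_factors(dataset.manifest)
        table = apply_scaling(table, factors)
        table = median_normalize_by_protein(table, dataset.manifest)
        before = dataset.quant.abundance.isna()
        flagged = table.audit["proteins_without_condition_median"]
        skip = {p for plist in flagged.values() for p in plist}
        keep = [p for p in before.index if p not in skip]
        table = reference_normalize(table, dataset.manifest)
        pd.testing.assert_frame_equal(table.abundance.loc[keep].isna(),
                                      before.loc[keep])

    def test_noiseless_pipeline_recovers_model(self, noiseless_sim):
        config, dataset, truth = noiseless_sim
        table = normalize_dataset(dataset)
        denat = dataset.manifest[~dataset.manifest["is_reference"]]
        for _, run in denat.iloc[::7].iterrows():
            cond = run["condition"]
            for pid in dataset.quant.protein_ids[:8]:
                expected = melt_curve_model(run["temperature"],
                                            truth.loc[pid, f"midpoint_{cond}"],
                                            truth.loc[pid, "slope"],
                                            truth.loc[pid, "plateau"])
                got = table.abundance.loc[pid, run["run_id"]]
                assert got == pytest.approx(expected, abs=1e-9)

    def test_transformer_wrapper_matches_functions(self, small_sim):
        _, dataset, _ = small_sim
        expected = normalize_dataset(dataset).abundance
        norm = TPPNormalizer(manifest=dataset.manifest)
        got = norm.fit_transform(dataset.quant.abundance)
        pd.testing.assert_frame_equal(got, expected)
        assert norm.get_params()["max_missing"] == 3
        assert norm.set_params(max_missing=2).max_missing == 2
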