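"""Replicate aggregation, CT filtering, reference stability and -dCT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from penmark.datatypes import CtTable
from penmark.errors import InsufficientDataError
from penmark.quant import (
    aggregate_replicates,
    apply_ct_filter,
    compute_neg_delta_ct,
    fold_change_between_groups,
    normfinder_stability,
    select_reference_genes,
)
from penmark.datatypes import ExpressionMatrix

from conftest import aggregated_ct_from_matrix, make_annotation, make_ct
from oracles import normfinder_bruteforce


def triplicate(sample, assay, cls, values):
    return [(sample, assay, cls, i + 1, v) for i, v in enumerate(values)]


class TestAggregateReplicates:
    def test_mean_of_equal_replicates(self):
        ct = make_ct(triplicate("s1", "a", "mrna_target", [20.0, 20.0, 20.0]))
        out = aggregate_replicates(ct)
        assert out.data["ct"].iloc[0] == 20.0
        assert out.data["n_replicates"].iloc[0] == 3

    def test_mean_and_sd(self):
        ct = make_ct(triplicate("s1", "a", "mrna_target", [19.8, 20.0, 20.2]))
        row = aggregate_replicates(ct).data.iloc[0]
        assert row["ct"] == pytest.approx(20.0)
        assert row["ct_sd"] == pytest.approx(0.2, abs=1e-12)

    def test_all_undetermined_stays_undetermined(self):
        ct = make_ct(triplicate("s1", "a", "mrna_target", [np.nan] * 3))
        row = aggregate_replicates(ct).data.iloc[0]
        assert np.isnan(row["ct"]) and row["n_replicates"] == 0

    def test_partial_undetermined_uses_available(self):
        ct = make_ct(triplicate("s1", "a", "mrna_target", [20.0, np.nan, 22.0]))
        row = aggregate_replicates(ct).data.iloc[0]
        assert row["ct"] == pytest.approx(21.0) and row["n_replicates"] == 2

    def test_optional_outlier_rejection(self):
        vals = [20.0, 20.1, 23.0]  # sd > 0.5, worst replicate 23.0
        ct = make_ct(triplicate("s1", "a", "mrna_target", vals))
        default = aggregate_replicates(ct).data.iloc[0]["ct"]
        robust = aggregate_replicates(ct, "drop_worst_if_sd_gt_0.5").data.iloc[0]["ct"]
        assert default == pytest.approx(np.mean(vals))
        assert robust == pytest.approx(20.05)


class TestCtFilter:
    def test_strictly_below_threshold_kept(self):
        ct = aggregate_replicates(
            make_ct([("s1", "a", "mrna_target", 1, 23.9),
                     ("s1", "b", "mrna_target", 1, 24.0)])
        )
        out = apply_ct_filter(ct, threshold=24.0)
        flags = out.data.set_index("assay_id")["excluded"]
        assert not flags["a"]
        assert flags["b"]

    def test_undetermined_excluded_and_logged(self):
        ct = aggregate_replicates(
            make_ct([("s1", "a", "mrna_target", 1, np.nan)])
        )
        out = apply_ct_filter(ct)
        assert out.data["excluded"].iloc[0]
        assert out.exclusion_log["reason"].iloc[0] == "undetermined"

    def test_scope_limits_filter_to_mrna_panel(self):
        ct = aggregate_replicates(
            make_ct([("s1", "a", "mrna_target", 1, 30.0),
                     ("s1", "m", "mirna_target", 1, 30.0)])
        )
        flags = apply_ct_filter(ct).data.set_index("assay_id")["excluded"]
        assert flags["a"] and not flags["m"]

    def test_empty_table(self):
        ct = CtTable(
            pd.DataFrame(columns=["sample_id", "assay_id", "assay_class",
                                  "replicate_index", "ct"]),
            aggregated=True,
        )
        assert len(apply_ct_filter(ct).data) == 0


class TestNegDeltaCt:
    def test_target_equal_to_reference_mean_is_zero(self):
        mat = pd.DataFrame({"r1": [20.0], "r2": [22.0], "t": [21.0]}, index=["s1"])
        expr = compute_neg_delta_ct(aggregated_ct_from_matrix(mat, "mrna_target"),
                                    ["r1", "r2"])
        assert expr.values.loc["s1", "t"] == pytest.approx(0.0)

    def test_worked_example(self):
        mat = pd.DataFrame({"r1": [20.0], "r2": [22.0], "t": [24.0]}, index=["s1"])
        expr = compute_neg_delta_ct(aggregated_ct_from_matrix(mat, "mrna_target"),
                                    ["r1", "r2"])
        assert expr.values.loc["s1", "t"] == pytest.approx(-3.0)

    def test_one_cycle_below_reference_is_plus_one(self):
        mat = pd.DataFrame({"r1": [20.0], "t": [19.0]}, index=["s1"])
        expr = compute_neg_delta_ct(aggregated_ct_from_matrix(mat, "mrna_target"),
                                    ["r1"])
        assert expr.values.loc["s1", "t"] == pytest.approx(1.0)

    def test_sample_missing_reference_dropped_with_warning(self):
        mat = pd.DataFrame({"r1": [20.0, np.nan], "t": [19.0, 19.0]},
                           index=["s1", "s2"])
        with pytest.warns(UserWarning, match="s2"):
            expr = compute_neg_delta_ct(
                aggregated_ct_from_matrix(mat, "mrna_target"), ["r1"]
            )
        assert expr.samples == ["s1"]

    @given(shift=st.floats(-10, 10), seed=st.integers(0, 1000))
    def test_normalization_invariance_under_sample_shift(self, shift, seed):
        # adding a constant to every CT of a sample leaves -dCT unchanged
        r = np.random.default_rng(seed)
        mat = pd.DataFrame(
            r.normal(20, 1, size=(3, 4)),
            index=["s1", "s2", "s3"],
            columns=["r1", "r2", "t1", "t2"],
        )
        base = compute_neg_delta_ct(
            aggregated_ct_from_matrix(mat, "mrna_target"), ["r1", "r2"]
        )
        shifted = compute_neg_delta_ct(
            aggregated_ct_from_matrix(mat.add(shift), "mrna_target"), ["r1", "r2"]
        )
        assert np.allclose(base.values, shifted.values, atol=1e-9)


class TestFoldChange:
    def _expr(self, met_vals, loc_vals):
        vals = pd.DataFrame(
            {"t": list(met_vals) + list(loc_vals)},
            index=[f"m{i}" for i in range(len(met_vals))]
            + [f"l{i}" for i in range(len(loc_vals))],
        )
        groups = pd.Series(
            ["metastatic"] * len(met_vals) + ["localized"] * len(loc_vals),
            index=vals.index,
        )
        return ExpressionMatrix(vals, ["ref"]), groups

    def test_equal_group_means_fc_one(self):
        expr, g = self._expr([1.0, 2.0], [2.0, 1.0])
        assert fold_change_between_groups(expr, g, "t") == pytest.approx(1.0)

    def test_one_cycle_difference_is_twofold(self):
        expr, g = self._expr([2.0, 2.0], [1.0, 1.0])
        assert fold_change_between_groups(expr, g, "t") == pytest.approx(2.0)

    def test_reported_mirna_fold_change_convention(self):
        # a +1.144-cycle mean difference displays as FC 2.21
        expr, g = self._expr([1.144, 1.144], [0.0, 0.0])
        assert round(fold_change_between_groups(expr, g, "t"), 2) == 2.21

    def test_reciprocal_identity(self, rng):
        expr, g = self._expr(rng.normal(size=5), rng.normal(size=6))
        fwd = fold_change_between_groups(expr, g, "t")
        rev = fold_change_between_groups(
            expr, g, "t", numerator="localized", denominator="metastatic"
        )
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_insufficient_data(self):
        expr, g = self._expr([1.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fold_change_between_groups(expr, g, "t")


def _stability_fixture(matrix: pd.DataFrame, groups):
    ct = aggregated_ct_from_matrix(matrix, "endogenous_candidate")
    ann = make_annotation(matrix.index, groups)
    return ct, ann


class TestReferenceStability:
    def test_all_constant_candidates_score_zero_lexicographic(self):
        samples = [f"s{i}" for i in range(8)]
        mat = pd.DataFrame(20.0, index=samples, columns=["B", "A", "C"])
        ct, ann = _stability_fixture(mat, ["localized"] * 4 + ["metastatic"] * 4)
        sa = normfinder_stability(ct, ["B", "A", "C"], ann)
        assert [r.stability_value for r in sa.results] == [0.0, 0.0, 0.0]
        assert sa.results[0].assay_id == "A"  # tie -> lexicographic
        assert select_reference_genes(sa, 1) == ["A"]

    def test_between_group_shift_degrades_stability(self, rng):
        samples = [f"s{i}" for i in range(12)]
        groups = ["localized"] * 6 + ["metastatic"] * 6
        noise = rng.normal(0, 0.3, size=(12, 2))
        mat = pd.DataFrame(
            {
                "stable": 20.0,
                "shifted": [20.0] * 6 + [21.0] * 6,  # 1-cycle group shift
                "noisy1": 20 + noise[:, 0],
                "noisy2": 20 + noise[:, 1],
            },
            index=samples,
        )
        ct, ann = _stability_fixture(mat, groups)
        sa = normfinder_stability(ct, list(mat.columns), ann)
        vals = {r.assay_id: r.stability_value for r in sa.results}
        assert vals["shifted"] > vals["stable"]
        assert sa.results[0].assay_id == "stable"

    def test_planted_low_variance_pair_selected(self, rng):
        samples = [f"s{i}" for i in range(16)]
        groups = ["localized"] * 8 + ["metastatic"] * 8
        mat = pd.DataFrame(
            {
                "good1": 20 + rng.normal(0, 0.05, 16),
                "good2": 20 + rng.normal(0, 0.05, 16),
                "bad1": 20 + rng.normal(0, 0.5, 16),
                "bad2": 20 + rng.normal(0, 0.5, 16),
                "bad3": 20 + rng.normal(0, 0.5, 16),
            },
            index=samples,
        )
        ct, ann = _stability_fixture(mat, groups)
        sa = normfinder_stability(ct, list(mat.columns), ann)
        assert set(select_reference_genes(sa, 2)) == {"good1", "good2"}

    @given(seed=st.integers(0, 2_000))
    def test_matches_bruteforce_oracle(self, seed):
        r = np.random.default_rng(seed)
        I = int(r.integers(3, 7))
        n1, n2 = int(r.integers(3, 8)), int(r.integers(3, 8))
        samples = [f"s{i}" for i in range(n1 + n2)]
        groups = ["localized"] * n1 + ["metastatic"] * n2
        mat = pd.DataFrame(
            20 + r.normal(0, r.uniform(0.05, 0.8), size=(n1 + n2, I)),
            index=samples,
            columns=[f"c{i}" for i in range(I)],
        )
        ct, ann = _stability_fixture(mat, groups)
        sa = normfinder_stability(ct, list(mat.columns), ann)
        oracle = normfinder_bruteforce(mat.T, dict(zip(samples, groups)))
        for res in sa.results:
            assert res.stability_value == pytest.approx(
                oracle[res.assay_id], abs=1e-10
            )

    def test_too_few_candidates_error(self):
        samples = [f"s{i}" for i in range(6)]
        mat = pd.DataFrame(20.0, index=samples, columns=["A", "B"])
        ct, ann = _stability_fixture(mat, ["localized"] * 3 + ["metastatic"] * 3)
        with pytest.raises(InsufficientDataError):
            normfinder_stability(ct, ["A", "B"], ann)

    def test_high_missingness_candidate_excluded(self, rng):
        samples = [f"s{i}" for i in range(10)]
        mat = pd.DataFrame(
            20 + rng.normal(0, 0.2, size=(10, 4)),
            index=samples,
            columns=["A", "B", "C", "D"],
        )
        mat.loc[mat.index[:4], "D"] = np.nan  # 40% missing
        ct, ann = _stability_fixture(mat, ["localized"] * 5 + ["metastatic"] * 5)
        with pytest.warns(UserWarning, match="D"):
            sa = normfinder_stability(ct, ["A", "B", "C", "D"], ann)
        assert sa.excluded == ["D"]
        assert "D" not in sa.ranked_ids()
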