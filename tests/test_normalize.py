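"""CPM, prevalence filtering, relative quantification, stability, EDA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tbimir.containers import AssayRole, CountMatrix, CqTable
from tbimir.normalize import (
    cpm,
    cv_percent,
    delta_ct_relative,
    eda_summary,
    normfinder_stability,
    prevalence_filter,
    shared_mirna_percent,
    small_rna_input_normalize,
)
from conftest import make_count_matrix


class TestCpm:
    def test_single_mirna_whole_library_scales_to_one_million(self):
        cm = make_count_matrix([[10]])
        assert cpm(cm).iloc[0, 0] == pytest.approx(1_000_000.0)

    def test_equal_counts_split_the_million(self):
        cm = make_count_matrix([[1], [1]])
        assert np.allclose(cpm(cm).to_numpy().ravel(), [500_000.0, 500_000.0])

    def test_matches_per_cell_hand_computation(self, toy_counts):
        result = cpm(toy_counts)
        totals = toy_counts.counts.sum(axis=0)
        for mirna in toy_counts.mirna_ids:
            for sample in toy_counts.sample_ids:
                expected = toy_counts.counts.at[mirna, sample] / totals[sample] * 1e6
                assert result.at[mirna, sample] == pytest.approx(expected, rel=1e-9)

    def test_columns_sum_to_one_million_with_in_matrix_totals(self, toy_counts):
        assert np.allclose(cpm(toy_counts).sum(axis=0), 1e6)

    def test_scale_equivariance(self, toy_counts):
        doubled = CountMatrix(toy_counts.counts * 2, toy_counts.mirna_mapped_total * 2)
        pd.testing.assert_frame_equal(cpm(doubled), cpm(toy_counts))

    def test_zero_total_names_the_sample(self):
        counts = pd.DataFrame([[0, 5]], index=["m"], columns=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            CountMatrix(counts, pd.Series({"bad": 0.0, "ok": 5.0}))


class TestPrevalenceFilter:
    def test_eighty_percent_threshold_on_ten_samples(self):
        baseline = [5] * 10  # keeps every per-sample total positive
        row_kept = [1] * 8 + [0] * 2
        row_dropped = [1] * 7 + [0] * 3
        cm = make_count_matrix([baseline, row_kept, row_dropped],
                               mirnas=["base", "keep", "drop"])
        out = prevalence_filter(cm)
        assert out.mirna_ids == ["base", "keep"]

    def test_full_prevalence_requires_no_zeros(self):
        cm = make_count_matrix([[1, 1, 0], [2, 3, 4]], mirnas=["z", "full"])
        assert prevalence_filter(cm, min_fraction=1.0).mirna_ids == ["full"]

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(0)
        cm = make_count_matrix(rng.poisson(0.8, size=(50, 19)))
        out = prevalence_filter(cm, min_count=1, min_fraction=0.8)
        needed = math.ceil(0.8 * 19)
        expected = [
            m for m in cm.mirna_ids
            if int((cm.counts.loc[m] >= 1).sum()) >= needed
        ]
        assert out.mirna_ids == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cm = make_count_matrix(rng.poisson(1.0, size=(40, 10)))
        once = prevalence_filter(cm)
        twice = prevalence_filter(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_totals_preserved_after_filtering(self):
        cm = make_count_matrix([[5, 5], [0, 0], [3, 3]])
        out = prevalence_filter(cm)
        pd.testing.assert_series_equal(out.mirna_mapped_total, cm.mirna_mapped_total)


class TestDeltaCt:
    def _cq(self, target, ref):
        cq = pd.DataFrame({"t": [target], "miR-28-3p": [ref]}, index=["s"])
        return CqTable(cq, {"miR-28-3p": AssayRole.REFERENCE})

    @pytest.mark.parametrize("target,ref,expected",
                             [(24.0, 24.0, 1.0), (21.0, 24.0, 8.0), (25.0, 24.0, 0.5)])
    def test_closed_form_values(self, target, ref, expected):
        (rel,) = delta_ct_relative(self._cq(target, ref))
        assert rel.value == pytest.approx(expected)

    def test_invariant_to_per_sample_cq_shift(self, toy_cq):
        base = delta_ct_relative(toy_cq)
        shifted = CqTable(toy_cq.cq + 2.5, toy_cq.roles)
        for a, b in zip(base, delta_ct_relative(shifted)):
            assert a.value == pytest.approx(b.value)

    def test_missing_reference_skips_sample_with_warning(self):
        cq = pd.DataFrame({"t": [25.0, 25.0], "miR-28-3p": [24.0, np.nan]},
                          index=["ok", "noref"])
        table = CqTable(cq, {"miR-28-3p": AssayRole.REFERENCE})
        with pytest.warns(UserWarning, match="noref"):
            out = delta_ct_relative(table)
        assert [r.sample_id for r in out] == ["ok"]


class TestNormfinderStability:
    GROUPS = ["A", "A", "A", "B", "B", "B"]

    def test_constant_assay_has_zero_stability_and_ranks_first(self):
        data = pd.DataFrame(
            [[7.0] * 6, [1.0, 5.0, 3.0, 9.0, 2.0, 8.0]],
            index=["stable", "noisy"], columns=[f"s{i}" for i in range(6)],
        )
        results = normfinder_stability(data, self.GROUPS, log_transform=False)
        assert results[0].assay == "stable"
        assert results[0].stability_value == pytest.approx(0.0)

    def test_group_shift_ranks_less_stable(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10.0, 0.5, size=6)
        shifted = base + np.array([0, 0, 0, 4, 4, 4])
        data = pd.DataFrame([base, shifted], index=["flat", "shifted"],
                            columns=[f"s{i}" for i in range(6)])
        results = normfinder_stability(data, self.GROUPS, log_transform=False)
        assert results[0].assay == "flat"

    def test_matches_brute_force_decomposition(self):
        # Independent recomputation of the documented decomposition:
        # pooled within-group variance + bias-corrected between-group
        # variance of group means, stability = sqrt(sum).
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(8, 1, size=(4, 6)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(6)])
        groups = np.array(self.GROUPS)
        results = {r.assay: r for r in
                   normfinder_stability(data, groups, log_transform=False)}
        for assay in data.index:
            row = data.loc[assay].to_numpy()
            means, ss, df = [], 0.0, 0
            for g in ("A", "B"):
                x = row[groups == g]
                means.append(x.mean())
                ss += ((x - x.mean()) ** 2).sum()
                df += len(x) - 1
            intra = ss / df
            inter = max(np.var(means, ddof=1) - intra * np.mean([1 / 3, 1 / 3]), 0.0)
            assert results[assay].intra_group_variance == pytest.approx(intra, abs=1e-8)
            assert results[assay].inter_group_variance == pytest.approx(inter, abs=1e-8)
            assert results[assay].stability_value == pytest.approx(
                math.sqrt(intra + inter), abs=1e-8)

    def test_singleton_group_rejected(self):
        data = pd.DataFrame(np.ones((2, 3)), columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError):
            normfinder_stability(data, ["A", "A", "B"])


class TestInputNormalization:
    def test_equal_concentrations_need_no_dilution(self):
        factors, before, after = small_rna_input_normalize(
            {"a": 0.4, "b": 0.4}, target=0.4)
        assert factors == {"a": 1.0, "b": 1.0}
        assert before == 0.0 and after == 0.0

    def test_factors_are_concentration_over_target(self):
        factors, _, after = small_rna_input_normalize({"a": 0.2, "b": 0.4}, 0.2)
        assert factors == {"a": 1.0, "b": 2.0}
        assert after == pytest.approx(0.0)

    def test_cv_percent_matches_hand_formula(self):
        values = np.array([0.18, 0.4, 1.21])
        expected = 100 * values.std(ddof=1) / values.mean()
        assert cv_percent(values) == pytest.approx(expected, rel=1e-9)

    def test_target_above_minimum_rejected(self):
        with pytest.raises(ValueError):
            small_rna_input_normalize({"a": 0.18, "b": 0.4}, target=0.2)


class TestEdaSummary:
    def test_identical_samples_correlate_perfectly_and_merge_first(self):
        rng = np.random.default_rng(4)
        col = rng.poisson(50, size=20).astype(float)
        data = pd.DataFrame(
            {"s1": col, "s2": col, "s3": rng.poisson(50, size=20).astype(float)}
        )
        summary = eda_summary(data, ["A", "A", "B"])
        assert summary.spearman.at["s1", "s2"] == pytest.approx(1.0)
        # first merge joins the identical pair at distance 0
        assert summary.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert {int(summary.linkage_matrix[0, 0]),
                int(summary.linkage_matrix[0, 1])} == {0, 1}

    def test_rank_one_data_explains_all_variance_in_first_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        data = pd.DataFrame(
            {"s1": base, "s2": 2 * base, "s3": 3.5 * base}
        )
        # log2 breaks exact rank-1; build data collinear after log2(x+1)
        data = pd.DataFrame(np.exp2(np.outer(base, [1.0, 1.2, 1.5])) - 1.0,
                            columns=["s1", "s2", "s3"])
        summary = eda_summary(data, ["A", "A", "B"])
        assert summary.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_venn_counts_match_hand_enumeration(self):
        counts = pd.DataFrame(
            {
                "a1": [3, 0, 1, 0, 2, 0],
                "a2": [1, 0, 0, 0, 5, 0],
                "b1": [2, 4, 0, 0, 1, 0],
                "b2": [0, 1, 0, 0, 3, 0],
            },
            index=[f"m{i}" for i in range(6)],
        )
        summary = eda_summary(counts + 0.0, ["A", "A", "B", "B"], raw_counts=counts)
        venn = summary.venn_counts
        # group A detects m0, m2, m4; group B detects m0, m1, m4
        assert venn["per_group_detected"] == {"A": 3, "B": 3}
        assert venn["detected_total"] == 4
        assert venn["shared_all_groups"] == 2
        assert venn["shared_percent"] == 50

    def test_spearman_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.poisson(30, size=(25, 5)).astype(float),
                            columns=[f"s{i}" for i in range(5)])
        summary = eda_summary(data, ["A", "A", "A", "B", "B"])
        mat = summary.spearman.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_constant_sample_reported_undefined(self):
        data = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [5.0, 5.0, 5.0], "s3": [2.0, 1.0, 4.0]}
        )
        summary = eda_summary(data, ["A", "A", "B"])
        assert summary.constant_samples == ["s2"]
        assert np.isnan(summary.spearman.at["s1", "s2"])


class TestSharedPercent:
    def test_percentage_rounds_to_integer(self):
        assert shared_mirna_percent(748, 723) == 97

    @given(
        total=st.integers(1, 1000),
        shared=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, total, shared):
        if shared > total:
            with pytest.raises(ValueError):
                shared_mirna_percent(total, shared)
        else:
            assert 0 <= shared_mirna_percent(total, shared) <= 100
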