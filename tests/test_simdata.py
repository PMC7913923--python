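"""Generator correctness: planted effects, Poisson limits, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from tbimir.containers import AssayRole, SampleMeta
from tbimir.normalize import delta_ct_relative
from tbimir.qc import assess_dcq
from tbimir.simdata import (
    DdpcrAmplitudeParams,
    SimDesign,
    simulate_copies,
    simulate_count_matrix,
    simulate_cq_table,
    simulate_ddpcr_wells,
    simulate_human_cohort,
)
from tbimir.quant import quantify_well, summarize_replicates

ASSAYS = {
    "miR-9a-3p": AssayRole.TARGET,
    "miR-28-3p": AssayRole.REFERENCE,
    "miR-23a": AssayRole.HEMOLYSIS_23A,
    "miR-451": AssayRole.HEMOLYSIS_451,
}


class TestCountMatrixGenerator:
    def test_null_poisson_design_matches_target_mean(self):
        # 1 miRNA at mean 100 in the Poisson limit: the mean over 1000
        # samples stays within 3 standard errors of 100.
        design = SimDesign(
            group_names=("A",), group_sizes=(1000,), n_mirnas=1,
            baseline_log_mean=math.log(100.0), dispersion=math.inf,
            library_size_range=(1000, 1000), effect_table={},
            mirna_log_sd=0.0, seed=11,
        )
        cm, _ = simulate_count_matrix(design)
        mean = cm.counts.iloc[0].mean()
        se = math.sqrt(100.0 / 1000)
        assert abs(mean - 100.0) < 3 * se

    def test_planted_log2_effect_gives_expected_group_ratio(self):
        # +2 log2 fold in group B: ratio of group means concentrates
        # around 4 (Monte-Carlo interval from NB moments at k=10).
        design = SimDesign(
            group_names=("A", "B"), group_sizes=(200, 200), n_mirnas=1,
            baseline_log_mean=math.log(100.0), dispersion=10.0,
            library_size_range=(1000, 1000),
            effect_table={"marker": {"B": 2.0}},
            mirna_log_sd=0.0, seed=5,
        )
        cm, meta = simulate_count_matrix(design)
        mean_a = cm.counts.loc["marker", meta.samples_in("A")].mean()
        mean_b = cm.counts.loc["marker", meta.samples_in("B")].mean()
        assert 3.5 <= mean_b / mean_a <= 4.6

    def test_totals_equal_column_sums(self):
        cm, _ = simulate_count_matrix(SimDesign(n_mirnas=50, seed=3))
        assert np.array_equal(cm.mirna_mapped_total.to_numpy(),
                              cm.counts.sum(axis=0).to_numpy())

    def test_same_seed_reproduces_identical_matrix(self):
        design = SimDesign(n_mirnas=30, seed=42)
        cm1, meta1 = simulate_count_matrix(design)
        cm2, meta2 = simulate_count_matrix(design)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(meta1.table, meta2.table)

    @pytest.mark.parametrize(
        "bad",
        [
            {"group_sizes": (0, 5, 5, 5)},
            {"dispersion": -1.0},
            {"library_size_range": (100, 50)},
            {"n_mirnas": 1, "effect_table": {"a": {}, "b": {}}},
        ],
    )
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimDesign(**bad)


class TestCqGenerator:
    def _meta(self, n=4, hemolyzed=None):
        table = pd.DataFrame({"group": ["A"] * n}, index=[f"s{i}" for i in range(n)])
        if hemolyzed is not None:
            table["hemolyzed"] = hemolyzed
        return SampleMeta(table)

    def test_noiseless_null_gives_identical_relative_expression(self):
        cq = simulate_cq_table(self._meta(), ASSAYS, noise_sd=0.0, seed=1)
        rel = [r.value for r in delta_ct_relative(cq) if r.assay == "miR-9a-3p"]
        assert len(set(rel)) == 1

    def test_hemolyzed_samples_get_dcq_above_five(self):
        meta = self._meta(hemolyzed=[True, False, True, False])
        cq = simulate_cq_table(meta, ASSAYS, seed=2)
        records = {r.sample_id: r for r in assess_dcq(cq)}
        assert records["s0"].hemolyzed_by_dcq and records["s2"].hemolyzed_by_dcq
        assert not records["s1"].hemolyzed_by_dcq
        assert not records["s3"].hemolyzed_by_dcq

    def test_noiseless_effect_gives_exact_fold_change(self):
        # +3 log2 on the target in group B, no noise: relative expression
        # is exactly 8x the null group's.
        table = pd.DataFrame({"group": ["A", "B"]}, index=["sA", "sB"])
        cq = simulate_cq_table(
            SampleMeta(table), ASSAYS,
            effects={"miR-9a-3p": {"B": 3.0}}, noise_sd=0.0, seed=0,
        )
        rel = {r.sample_id: r.value for r in delta_ct_relative(cq)
               if r.assay == "miR-9a-3p"}
        assert rel["sB"] / rel["sA"] == pytest.approx(8.0)

    def test_missing_reference_assay_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            simulate_cq_table(
                self._meta(), {"miR-23a": AssayRole.HEMOLYSIS_23A,
                               "miR-451": AssayRole.HEMOLYSIS_451},
            )


class TestDdpcrGenerator:
    def _meta(self, n=1):
        return SampleMeta(
            pd.DataFrame({"group": ["A"] * n}, index=[f"s{i}" for i in range(n)])
        )

    def test_zero_copies_gives_empty_well_below_threshold(self):
        wells = simulate_ddpcr_wells(self._meta(), "miR-9a-3p", {"s0": 0.0},
                                     n_droplets=500, replicates=2, seed=1)
        for well in wells:
            n_pos, _ = well.positive_and_total()
            assert n_pos == 0
            assert np.all(well.amplitudes < well.threshold)

    def test_half_occupancy_at_ln2_copies_per_droplet(self):
        # copies = d * ln 2 makes the expected positive fraction exactly
        # one half; the observed count stays inside the binomial 99% CI.
        d = 10_000
        wells = simulate_ddpcr_wells(
            self._meta(), "miR-9a-3p", {"s0": d * math.log(2.0)},
            n_droplets=d, replicates=1, seed=7, emit_amplitudes=False,
        )
        n_pos, n_tot = wells[0].positive_and_total()
        ci = 2.576 * math.sqrt(d * 0.25)
        assert abs(n_pos - d / 2) < ci

    def test_round_trip_recovers_planted_copies(self):
        # quantify(simulate) at 19.2 copies / 15000 droplets, averaged
        # over 500 replicate wells, recovers the planted value.
        wells = simulate_ddpcr_wells(
            self._meta(), "miR-9a-3p", {"s0": 19.2}, n_droplets=15_000,
            replicates=500, seed=3, emit_amplitudes=False,
        )
        mean_copies = np.mean([quantify_well(w) for w in wells])
        assert 18.5 <= mean_copies <= 19.9

    def test_amplitude_and_count_representations_agree(self):
        meta = self._meta()
        common = dict(n_droplets=400, replicates=2, seed=9)
        amp = simulate_ddpcr_wells(meta, "a", {"s0": 100.0},
                                   emit_amplitudes=True, **common)
        cnt = simulate_ddpcr_wells(meta, "a", {"s0": 100.0},
                                   emit_amplitudes=False, **common)
        assert [w.positive_and_total() for w in amp] == \
               [w.positive_and_total() for w in cnt]

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_ddpcr_wells(self._meta(), "a", {"s0": -1.0})

    def test_duplicate_mean_reduces_error_versus_single_well(self):
        # Averaging duplicates beats a single replicate in at least half
        # of the trials (variance reduction).
        meta = self._meta()
        closer = 0
        trials = 300
        for t in range(trials):
            wells = simulate_ddpcr_wells(meta, "a", {"s0": 50.0},
                                         n_droplets=2000, replicates=2,
                                         seed=t, emit_amplitudes=False)
            copies = [quantify_well(w) for w in wells]
            mean_err = abs(np.mean(copies) - 50.0)
            single_err = abs(copies[0] - 50.0)
            closer += mean_err <= single_err
        assert closer / trials >= 0.5


class TestCopiesAndHumanCohort:
    def test_copies_match_group_geometric_means(self):
        table = pd.DataFrame({"group": ["A"] * 2000}, index=[f"s{i}" for i in range(2000)])
        copies = simulate_copies(SampleMeta(table), {"A": 19.2}, log_sd=0.3, seed=1)
        geo_mean = math.exp(np.mean(np.log(copies)))
        assert geo_mean == pytest.approx(19.2, rel=0.05)

    def test_human_cohort_structure(self):
        meta, copies = simulate_human_cohort(seed=0)
        sizes = meta.group_sizes()
        assert sizes == {"control": 14, "mTBI": 15, "sTBI": 2}
        assert set(copies.columns) == {"miR-9-3p", "miR-136-3p"}
        # 11 of 15 mTBI patients planted above the S100B clinical cutoff
        mtbi = meta.table[meta.table.group == "mTBI"]
        assert int((mtbi["s100b"] > 0.1).sum()) == 11

    def test_same_seed_reproduces_human_cohort(self):
        meta1, c1 = simulate_human_cohort(seed=5)
        meta2, c2 = simulate_human_cohort(seed=5)
        pd.testing.assert_frame_equal(meta1.table, meta2.table)
        pd.testing.assert_frame_equal(c1, c2)
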