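"""Trio filtering: callable loci, SBS/indel chains, clonality, rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutload import (
    CallableRegionSet,
    IndelFilterParams,
    SBSFilterParams,
    build_blacklist,
    check_clonality,
    compare_rates,
    compute_callable,
    estimate_rates,
    extrapolate_genome_wide,
    filter_indels,
    filter_sbs,
    intersect_callable,
)
from mutload.records import CALL_COLUMNS, SAMPLE_ROLES, TrioDataset


def make_trio(rows):
    """Rows: dicts with at least chrom/pos/ref/alt; trio-wide defaults filled in."""
    filled = []
    for r in rows:
        base = {
            "chrom": "toy_1",
            "ref": "C",
            "alt": "T",
            "qual": 500.0,
            "filter": "PASS",
            "var_class": "SBS",
        }
        for role in SAMPLE_ROLES:
            base[f"dp_{role}"] = 30
            base[f"ad_{role}"] = 0
            base[f"gq_{role}"] = 99
        base.update(r)
        filled.append(base)
    return TrioDataset(calls=pd.DataFrame(filled, columns=CALL_COLUMNS))


FULL = CallableRegionSet.from_intervals([("toy_1", 0, 10**6)])


class TestComputeCallable:
    def cov(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "depth", "base_quality", "mapping_quality"]
        )

    def test_all_pass(self):
        c = self.cov([("toy_1", 0, 100, 30, 60, 60), ("toy_1", 200, 300, 25, 30, 30)])
        assert compute_callable(c).total_length == 200

    def test_low_depth_excluded(self):
        c = self.cov([("toy_1", 0, 100, 10, 60, 60)])
        assert compute_callable(c).total_length == 0

    def test_mixed_table_keeps_only_passing(self):
        c = self.cov(
            [
                ("toy_1", 0, 100, 30, 60, 60),
                ("toy_1", 100, 250, 19, 60, 60),  # depth below 20
                ("toy_1", 300, 340, 30, 5, 60),  # base quality below 10
                ("toy_1", 400, 470, 30, 60, 60),
                ("toy_1", 500, 530, 21, 11, 10),
            ]
        )
        assert compute_callable(c).total_length == 100 + 70 + 30

    def test_passthrough_region_set(self):
        assert compute_callable(FULL).total_length == FULL.total_length


class TestIntersectCallable:
    def test_idempotent(self):
        a = CallableRegionSet.from_intervals([("toy_1", 0, 50), ("toy_1", 80, 120)])
        assert intersect_callable([a, a]) == a

    def test_basic_overlap(self):
        a = CallableRegionSet.from_intervals([("toy_1", 0, 100)])
        b = CallableRegionSet.from_intervals([("toy_1", 50, 150)])
        out = intersect_callable([a, b])
        assert list(out) == [("toy_1", 50, 100)]
        assert out.total_length == 50

    def test_against_base_membership_oracle(self):
        rng = np.random.default_rng(0)
        size = 10_000

        def random_set():
            marks = rng.random(size) < 0.3
            # derive intervals from the boolean mask
            idx = np.flatnonzero(np.diff(np.concatenate(([0], marks.view(np.int8), [0]))))
            return marks, CallableRegionSet.from_intervals(
                ("toy_1", s, e) for s, e in zip(idx[::2], idx[1::2])
            )

        masks, sets = zip(*(random_set() for _ in range(3)))
        joint = intersect_callable(list(sets))
        expected_mask = masks[0] & masks[1] & masks[2]
        got = joint.contains("toy_1", np.arange(size))
        assert np.array_equal(got, expected_mask)
        # associativity/commutativity
        alt = intersect_callable([sets[2], sets[0], sets[1]])
        assert alt == joint


class TestFilterSBS:
    def test_noise_free_recovery_is_exact(self, trio_exact):
        trio, truth = trio_exact
        joint = intersect_callable(list(trio.callable_regions.values()))
        bl = build_blacklist(trio.panel)
        got = {(m.contig, m.position, m.alt) for m in filter_sbs(trio, joint, bl)}
        want = truth.keys_of_class("culture", var_class="SBS")
        assert got == want

    def test_vaf_threshold_boundary(self):
        trio = make_trio(
            [
                {"pos": 10, "dp_subclone": 100, "ad_subclone": 29},  # VAF 0.29
                {"pos": 20, "dp_subclone": 100, "ad_subclone": 30},  # VAF 0.30
            ]
        )
        got = filter_sbs(trio, FULL, set())
        assert [m.position for m in got] == [20]

    def test_any_reference_evidence_excludes(self):
        trio = make_trio(
            [
                {"pos": 10, "ad_subclone": 15, "ad_reference": 1},
                {"pos": 20, "ad_subclone": 15, "ad_reference": 0},
            ]
        )
        assert [m.position for m in filter_sbs(trio, FULL, set())] == [20]

    def test_clonal_in_clone_excluded(self):
        trio = make_trio(
            [
                {"pos": 10, "ad_subclone": 15, "ad_clone": 14},  # clone VAF ~0.47
                {"pos": 20, "ad_subclone": 15, "ad_clone": 2},  # clone VAF < 0.3
            ]
        )
        assert [m.position for m in filter_sbs(trio, FULL, set())] == [20]

    def test_quality_and_depth_are_strict_thresholds(self):
        trio = make_trio(
            [
                {"pos": 10, "ad_subclone": 15, "qual": 100.0},
                {"pos": 20, "dp_subclone": 20, "ad_subclone": 10},
                {"pos": 30, "ad_subclone": 15},
            ]
        )
        assert [m.position for m in filter_sbs(trio, FULL, set())] == [30]

    def test_blacklisted_position_removed(self):
        trio = make_trio([{"pos": 10, "ad_subclone": 15}, {"pos": 20, "ad_subclone": 15}])
        got = filter_sbs(trio, FULL, {("toy_1", 10)})
        assert [m.position for m in got] == [20]

    def test_empty_callable_yields_empty(self, trio_exact):
        trio, _ = trio_exact
        assert filter_sbs(trio, CallableRegionSet({}), set()) == []

    def test_raising_vaf_threshold_is_monotone(self, trio_noisy):
        trio, _ = trio_noisy
        joint = intersect_callable(list(trio.callable_regions.values()))
        bl = build_blacklist(trio.panel)
        prev = None
        for thr in (0.1, 0.2, 0.3, 0.4, 0.5):
            got = {
                (m.contig, m.position, m.alt)
                for m in filter_sbs(trio, joint, bl, SBSFilterParams(vaf_threshold=thr))
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_output_sorted_deterministically(self, trio_noisy):
        trio, _ = trio_noisy
        joint = intersect_callable(list(trio.callable_regions.values()))
        got = filter_sbs(trio, joint, set())
        keys = [(m.contig, m.position, m.alt) for m in got]
        assert keys == sorted(keys)


class TestFilterIndels:
    def test_noise_free_recovery_is_exact(self, trio_exact):
        trio, truth = trio_exact
        joint = intersect_callable(list(trio.callable_regions.values()))
        got = {(m.contig, m.position, m.alt) for m in filter_indels(trio, joint, set())}
        want = truth.keys_of_class("culture", var_class="indel")
        assert len(want) == 10
        assert got == want

    def test_preexisting_clone_indel_excluded(self):
        trio = make_trio(
            [
                {"pos": 10, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15, "ad_clone": 12},  # clone VAF 0.4
                {"pos": 20, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15},
            ]
        )
        assert [m.position for m in filter_indels(trio, FULL, set())] == [20]

    def test_support_bounds(self):
        trio = make_trio(
            [
                {"pos": 10, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15, "dp_clone": 61},
                {"pos": 20, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 5, "dp_subclone": 9},
                {"pos": 30, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15},
            ]
        )
        assert [m.position for m in filter_indels(trio, FULL, set())] == [30]

    def test_non_pass_and_low_gq_excluded(self):
        trio = make_trio(
            [
                {"pos": 10, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15, "filter": "LowQual"},
                {"pos": 20, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15, "gq_clone": 80},
                {"pos": 30, "ref": "CA", "alt": "C", "var_class": "indel",
                 "ad_subclone": 15},
            ]
        )
        assert [m.position for m in filter_indels(trio, FULL, set())] == [30]

    def test_contig_allow_list(self):
        trio = make_trio(
            [
                {"chrom": "chrX", "pos": 10, "ref": "CA", "alt": "C",
                 "var_class": "indel", "ad_subclone": 15},
            ]
        )
        full = CallableRegionSet.from_intervals([("toy_1", 0, 100), ("chrX", 0, 100)])
        assert filter_indels(trio, full, set(), contigs=["toy_1"]) == []


class TestClonality:
    def test_all_half_passes(self):
        rep = check_clonality([0.5] * 10)
        assert rep.median_vaf == 0.5 and rep.passed

    def test_low_vafs_fail(self):
        assert not check_clonality([0.1] * 10).passed

    def test_binomial_sampling_at_30x_passes(self):
        rng = np.random.default_rng(5)
        failures = 0
        for _ in range(50):
            dp = rng.poisson(30, size=200).clip(min=1)
            vafs = rng.binomial(dp, 0.5) / dp
            failures += not check_clonality(vafs).passed
        assert failures == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            check_clonality([])


class TestExtrapolation:
    def test_identity(self):
        assert extrapolate_genome_wide(50, 2.4e9, 2.4e9) == pytest.approx(50)

    def test_threefold(self):
        assert extrapolate_genome_wide(45, 0.9e9, 2.7e9) == pytest.approx(135)

    def test_real_valued_not_rounded(self):
        # 283 indels over a 0.8 callable fraction extrapolate to 283/0.8
        assert extrapolate_genome_wide(283, 0.8, 1.0) == pytest.approx(353.75)

    def test_zero_callable_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_genome_wide(10, 0, 1e9)

    @given(
        c=st.integers(0, 1000),
        k=st.integers(1, 10),
        frac=st.floats(0.1, 1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c, k, frac):
        g = 1e9
        a = extrapolate_genome_wide(c, frac * g, g) * k
        b = extrapolate_genome_wide(k * c, frac * g, g)
        assert a == pytest.approx(b)


class TestRates:
    def test_per_doubling(self):
        est = estimate_rates(144, 20)
        assert est.mu == pytest.approx(7.2)
        assert est.per_year is None

    def test_zero_count(self):
        est = estimate_rates(0, 50, 44)
        assert est.mu == 0 and est.per_year == 0

    def test_per_year_conversion(self):
        # 7.2 per doubling at a 44-h doubling time: 7.2 * 8766 / 44
        est = estimate_rates(7.2 * 20, 20, 44)
        assert est.per_year == pytest.approx(7.2 * 8766 / 44)
        assert est.per_year == pytest.approx(1434.4, abs=0.1)

    def test_zero_doublings_rejected(self):
        with pytest.raises(ValueError):
            estimate_rates(10, 0)


class TestCompareRates:
    def test_identical_groups_t(self):
        rep = compare_rates({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert rep.test == "t"
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_three_equal_mean_groups(self):
        rep = compare_rates({"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 2, 1]})
        assert rep.test == "anova"
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_pooled_t_against_closed_form(self):
        rep = compare_rates({"a": [1, 2, 3], "b": [4, 5, 6]})
        # pooled-variance t on 6 numbers: t = (2-5)/sqrt(1*(1/3+1/3))
        t_expected = -3.0 / math.sqrt(2.0 / 3.0)
        assert rep.statistic == pytest.approx(t_expected)
        # p from numerical integration of the t(4) density, independent of scipy
        grid = np.linspace(abs(t_expected), 60, 400_000)
        density = (3.0 / 8.0) * (1 + grid**2 / 4) ** (-2.5)
        p_expected = 2 * np.trapezoid(density, grid)
        assert rep.p_value == pytest.approx(p_expected, rel=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_rates({"a": [1.0], "b": [1.0, 2.0]})
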