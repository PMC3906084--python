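"""Caller partitioning, hard filters, and cutoff scans."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from snvcalib import (
    Caller,
    Conjunct,
    DuplicateSiteError,
    FilterSpec,
    MetricProfile,
    RateEstimate,
    SimParams,
    StrandCounts,
    UsageError,
    VariantRecord,
    apply_filter,
    get_preset,
    partition_by_caller,
    partition_rates,
    recommended_filter,
    scan_cutoff,
    simulate_cohort,
)


def sam_rec(pos, ref="A", alt="G", **kw):
    base = dict(td=20, snpq=100.0, mq=60.0, strand=StrandCounts(8, 8, 5, 5))
    base.update(kw)
    return VariantRecord("chr1", pos, ref, alt, Caller.SAMTOOLS, **base)


def gatk_rec(pos, ref="A", alt="G", **kw):
    base = dict(td=20, snpq=400.0, mq=60.0, sb_score=-22.5)
    base.update(kw)
    return VariantRecord("chr1", pos, ref, alt, Caller.GATK, **base)


class TestPartition:
    def test_key_overlap(self):
        a = [sam_rec(100)]
        b = [gatk_rec(100), gatk_rec(5)]
        part = partition_by_caller(a, b)
        assert (len(part.common), len(part.only_a), len(part.only_b)) == (1, 0, 1)
        assert part.n_keys == 2

    def test_allele_aware_keying(self):
        part = partition_by_caller([sam_rec(100, alt="G")], [gatk_rec(100, alt="T")])
        assert len(part.common) == 0
        assert len(part.only_a) == len(part.only_b) == 1

    def test_duplicate_key_within_one_input_rejected(self):
        with pytest.raises(DuplicateSiteError):
            partition_by_caller([sam_rec(100), sam_rec(100)], [])

    def test_merged_pairs_keep_both_callers_metrics(self):
        part = partition_by_caller([sam_rec(100)], [gatk_rec(100)])
        (cv,) = part.common
        assert cv.samtools.caller is Caller.SAMTOOLS
        assert cv.gatk.sb_score == pytest.approx(-22.5)

    def test_rates_pool_specific_sides(self):
        a = [sam_rec(1, validation="validated"), sam_rec(2, validation="failed")]
        b = [gatk_rec(1, validation="validated"), gatk_rec(3, validation="validated")]
        common, specific = partition_rates(partition_by_caller(a, b))
        assert (common.validated, common.total) == (1, 1)
        assert (specific.validated, specific.total) == (1, 2)

    def test_all_common_partition_has_undefined_specific_rate(self):
        _, specific = partition_rates(partition_by_caller([sam_rec(1)], [gatk_rec(1)]))
        assert specific.total == 0 and specific.rate is None

    @given(
        keys_a=st.sets(st.integers(1, 60), max_size=25),
        keys_b=st.sets(st.integers(1, 60), max_size=25),
    )
    def test_partition_conservation(self, keys_a, keys_b):
        """Common/only_a/only_b reconcile with set algebra on the keys."""
        a = [sam_rec(p) for p in keys_a]
        b = [gatk_rec(p) for p in keys_b]
        part = partition_by_caller(a, b)
        assert len(part.common) == len(keys_a & keys_b)
        assert len(part.only_a) == len(keys_a - keys_b)
        assert len(part.only_b) == len(keys_b - keys_a)
        assert part.n_keys == len(keys_a | keys_b)


class TestRecommendedFilter:
    def test_preset_contents(self):
        sam = recommended_filter("samtools")
        assert sam.describe() == "snpq>=40 AND mq>58 AND 20<=af_percent<80"
        gat = get_preset("recommended-gatk")
        assert gat.describe() == "snpq>=300 AND mq>58 AND sb<-10"
        assert sam.on_undefined == "fail"

    def test_samtools_acceptance_and_window_boundary(self):
        spec = recommended_filter("samtools")
        ok = sam_rec(1, snpq=100, mq=60, strand=StrandCounts(8, 8, 5, 5))      # AF 50
        edge = sam_rec(2, snpq=100, mq=60, strand=StrandCounts(8, 8, 8, 2))    # AF 80
        assert spec.evaluate(ok) == (True, False)
        assert spec.evaluate(edge)[0] is False  # upper bound exclusive

    def test_gatk_sb_threshold(self):
        spec = recommended_filter("gatk")
        assert spec.evaluate(gatk_rec(1, snpq=500, mq=60, sb_score=-5.0))[0] is False
        assert spec.evaluate(gatk_rec(2, snpq=500, mq=60, sb_score=-10.5))[0] is True

    def test_mq_strictness(self):
        spec = recommended_filter("samtools")
        assert spec.evaluate(sam_rec(1, mq=58.0))[0] is False  # strictly greater
        relaxed = recommended_filter("samtools", strict_mq=False)
        assert relaxed.evaluate(sam_rec(2, mq=58.0))[0] is True


class TestApplyFilter:
    def test_empty_spec_is_identity(self):
        records = [sam_rec(i, validation="validated") for i in range(1, 5)]
        res = apply_filter(records, FilterSpec(()))
        assert res.n_after == res.n_before == 4
        assert res.rate_after == res.rate_before
        assert res.retained_fraction == 1.0

    def test_undefined_policy(self):
        no_strand = sam_rec(1, strand=None, validation="failed")
        spec = recommended_filter("samtools")
        res = apply_filter([no_strand], spec)
        assert res.n_after == 0 and res.undefined_metric_count == 1
        spec_pass = FilterSpec(spec.conjuncts, on_undefined="pass", caller=spec.caller)
        assert apply_filter([no_strand], spec_pass).n_after == 1
        spec_err = FilterSpec(spec.conjuncts, on_undefined="error", caller=spec.caller)
        with pytest.raises(UsageError):
            apply_filter([no_strand], spec_err)

    def test_planted_separation_fully_removed(self):
        """All-biased false positives are exactly eliminated by the AF window."""
        good = [sam_rec(i, validation="validated", strand=StrandCounts(5, 5, 6, 6))
                for i in range(1, 51)]
        bad = [sam_rec(i, validation="failed", strand=StrandCounts(5, 5, 19, 1))
               for i in range(51, 101)]  # AF 95
        spec = FilterSpec((Conjunct("af_percent", "window", (20, 80)),))
        res = apply_filter(good + bad, spec)
        assert res.n_after == 50
        assert res.rate_after.rate == 1.0

    @given(st.data())
    def test_conjunction_monotonicity(self, data):
        """Appending a conjunct never increases the retained count."""
        cohort = simulate_cohort(SimParams(n_variants=120), seed=5).by_caller("samtools")
        pool = [
            Conjunct("snpq", "ge", data.draw(st.floats(0, 200))),
            Conjunct("mq", "gt", data.draw(st.floats(0, 60))),
            Conjunct("gq", "ge", data.draw(st.floats(0, 99))),
            Conjunct("td", "le", data.draw(st.floats(1, 100))),
            Conjunct("af_percent", "window", (20, 80)),
        ]
        k = data.draw(st.integers(0, len(pool)))
        spec = FilterSpec((), on_undefined=data.draw(st.sampled_from(["fail", "pass"])))
        prev = apply_filter(cohort.records, spec).n_after
        for c in pool[:k]:
            spec = spec.with_conjunct(c)
            cur = apply_filter(cohort.records, spec).n_after
            assert cur <= prev
            prev = cur

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = recommended_filter("gatk")
        path = tmp_path / "spec.yaml"
        spec.save(path)
        assert FilterSpec.load(path) == spec


def brute_force_binwise(lower_edges, estimates, target):
    """Independent oracle: try every edge, check every bin at/above it."""
    for i, t in enumerate(lower_edges):
        tail = estimates[i:]
        if not any(e.total for e in tail):
            continue
        if all(e.total == 0 or e.validated / e.total >= target for e in tail):
            return t
    return None


class TestScanCutoff:
    def test_reference_cutoffs(self, reference_tabs):
        assert scan_cutoff(reference_tabs["set1"], 0.80).chosen_threshold == 80
        assert scan_cutoff(reference_tabs["set3"], 0.80).chosen_threshold == 80
        assert scan_cutoff(reference_tabs["set4"], 0.80).chosen_threshold == 300

    def test_agrees_with_brute_force_on_all_sets(self, reference_tabs):
        from snvcalib import marginal_rates

        for tab in reference_tabs.values():
            for target in (0.5, 0.7, 0.8, 0.9, 0.99):
                report = scan_cutoff(tab, target, "binwise")
                lower = (0.0,) + tab.scheme.snpq_edges
                expected = brute_force_binwise(lower, marginal_rates(tab, "snpq"), target)
                assert report.chosen_threshold == expected

    def test_cumulative_mode_pools_tail(self, reference_tabs):
        report = scan_cutoff(reference_tabs["set3"], 0.877, "cumulative")
        assert report.chosen_threshold == 40  # pooled 150/171 = 87.7%

    def test_all_perfect_profile_selects_lowest_edge(self):
        prof = MetricProfile("snpq", (10.0, 20.0), [RateEstimate(5, 5)] * 3)
        report = scan_cutoff(prof, 0.9, "binwise")
        assert report.chosen_threshold == float("-inf")

    def test_absent_when_no_edge_qualifies(self, reference_tabs):
        assert scan_cutoff(reference_tabs["set2"], 0.95).chosen_threshold is None

    def test_target_domain_checked(self, reference_tabs):
        with pytest.raises(UsageError):
            scan_cutoff(reference_tabs["set1"], 1.5)
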