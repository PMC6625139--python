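"""Caller intersection, depth/VAF/capture filters and TMB."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sebsig.datasets import CAPTURE_MB, load_sebaceous_cohort
from sebsig.filtering import (
    CaptureRegions,
    FilterSummary,
    apply_filters,
    compute_tmb,
    intersect_callers,
    run_snv_filter_chain,
)
from sebsig.variants import SomaticVariant


def snv(pos, depth=100, alt_count=40, chrom="1", ref="A", alt="C"):
    return SomaticVariant(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                          depth=depth, alt_count=alt_count)


@pytest.fixture
def capture():
    return CaptureRegions(intervals=[("1", 0, 1_000_000)])


class TestCaptureRegions:
    def test_overlapping_intervals_merge(self):
        cap = CaptureRegions(intervals=[("1", 0, 100), ("1", 50, 200), ("2", 0, 10)])
        assert cap.total_size == 210
        assert cap.intervals == [("1", 0, 200), ("2", 0, 10)]

    def test_one_based_position_membership(self):
        cap = CaptureRegions(intervals=[("1", 10, 20)])
        # 1-based p is inside [s, e) iff s < p <= e
        assert not cap.contains("1", 10)
        assert cap.contains("1", 11)
        assert cap.contains("1", 20)
        assert not cap.contains("1", 21)

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "cap.bed"
        bed.write_text("1\t0\t100\n1\t50\t200\n")
        assert CaptureRegions.from_bed(bed).total_size == 200


class TestIntersectCallers:
    def test_identity(self):
        vs = [snv(i) for i in range(1, 6)]
        out = intersect_callers(vs, vs)
        assert [v.key for v in out] == [v.key for v in vs]
        assert all(v.callers == {"A", "B"} for v in out)

    def test_disjoint_inputs_give_empty(self):
        assert intersect_callers([snv(1)], [snv(2)]) == []

    def test_depth_taken_from_selected_caller(self):
        a = [snv(1, depth=100, alt_count=50)]
        b = [snv(1, depth=60, alt_count=20)]
        assert intersect_callers(a, b)[0].depth == 100
        assert intersect_callers(a, b, take_from="B")[0].depth == 60

    def test_matches_truth_shared_count(self, sim_sample):
        """On the synthetic pair with 70% caller overlap, the intersection
        equals the truth set's shared-SNV count exactly."""
        from sebsig import io as sio

        sim = sim_sample["sim"]
        a = [v for v in sio.read_vcf(sim.tumor_vcf_a, "A", pass_only=True) if v.is_snv]
        b = [v for v in sio.read_vcf(sim.tumor_vcf_b, "B", pass_only=True) if v.is_snv]
        assert len(intersect_callers(a, b)) == sim.truth.n_shared


class TestApplyFilters:
    def test_minimum_thresholds_are_inclusive(self, capture):
        kept, _ = apply_filters([snv(5, depth=40, alt_count=4)], capture)
        assert len(kept) == 1  # depth 40 and VAF 0.10 both survive

    def test_below_depth_removed(self, capture):
        kept, _ = apply_filters([snv(5, depth=39, alt_count=20)], capture)
        assert kept == []

    def test_below_vaf_removed(self, capture):
        kept, _ = apply_filters([snv(5, depth=100, alt_count=9)], capture)
        assert kept == []

    def test_outside_capture_removed(self):
        cap = CaptureRegions(intervals=[("1", 100, 200)])
        kept, tally = apply_filters([snv(50), snv(150)], cap)
        assert [v.pos for v in kept] == [150]
        assert tally == {"n_pass_depth_vaf": 2, "n_in_capture": 1}

    def test_empty_capture_is_an_error(self):
        with pytest.raises(ValueError, match="capture"):
            apply_filters([snv(5)], CaptureRegions(intervals=[]))

    def test_degraded_variants_are_removed_exactly(self, capture):
        """1,000 passing variants with 100 deliberately degraded below the
        depth threshold leave exactly 900."""
        variants = [snv(i + 1) for i in range(1_000)]
        degraded = [
            dataclasses.replace(v, depth=39, alt_count=15) if i < 100 else v
            for i, v in enumerate(variants)
        ]
        kept, _ = apply_filters(degraded, capture)
        assert len(kept) == 900

    def test_order_independence(self, capture):
        variants = [snv(i + 1, depth=30 + i % 30, alt_count=5 + i % 10)
                    for i in range(200)]
        shuffled = variants.copy()
        random.Random(1).shuffle(shuffled)
        kept_a, _ = apply_filters(variants, capture)
        kept_b, _ = apply_filters(shuffled, capture)
        assert {v.key for v in kept_a} == {v.key for v in kept_b}


class TestTmb:
    def test_basic_ratio(self):
        cap = CaptureRegions(intervals=[("1", 0, 60_000_000)])
        assert compute_tmb(120, cap) == pytest.approx(2.0)

    def test_zero_variants(self, capture):
        assert compute_tmb(0, capture) == 0.0

    def test_cohort_loads_reproduce_published_tmb(self):
        """At the implied 67.25 Mb capture size, every cohort load/TMB pair
        agrees at the printed one-decimal precision."""
        cap = CaptureRegions(intervals=[("1", 0, int(CAPTURE_MB * 1e6))])
        df = load_sebaceous_cohort()
        for _, row in df.iterrows():
            assert round(compute_tmb(row.mutational_load, cap), 1) == row.tmb


class TestFilterChain:
    def test_chain_monotone_invariant_enforced(self):
        with pytest.raises(ValueError, match="monotone"):
            FilterSummary(n_input_a=10, n_input_b=10, n_intersect=5,
                          n_pass_depth_vaf=6, n_in_capture=6, tmb=0.1)

    def test_chain_on_synthetic_sample(self, sim_sample):
        from sebsig import io as sio

        sim = sim_sample["sim"]
        cap = CaptureRegions.from_bed(sim_sample["capture_bed"])
        a = sio.read_vcf(sim.tumor_vcf_a, "A", pass_only=True)
        b = sio.read_vcf(sim.tumor_vcf_b, "B", pass_only=True)
        kept, summary = run_snv_filter_chain(a, b, cap)
        # every simulated SNV passes depth/VAF/capture by construction
        assert summary.n_intersect == sim.truth.n_shared
        assert summary.n_pass_depth_vaf == summary.n_in_capture == len(kept)
        assert len(kept) == sim.truth.n_shared

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(10, 120),
                              st.integers(0, 60)), max_size=40))
    def test_chain_monotone_on_random_inputs(self, raw):
        cap = CaptureRegions(intervals=[("1", 0, 300)])
        variants = [snv(pos, depth=d, alt_count=min(a, d)) for pos, d, a in raw]
        kept, s = run_snv_filter_chain(variants, variants, cap)
        assert s.n_intersect >= s.n_pass_depth_vaf >= s.n_in_capture == len(kept)
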