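"""Synthetic-data generator: placement, conservation, determinism."""

import numpy as np
import pytest

from sebsig.catalog import context_index
from sebsig.simulate import (
    PlacementError,
    SignatureMixture,
    SyntheticSampleSpec,
    generate_reference,
    simulate_catalog,
    simulate_sample,
)


class TestGenerateReference:
    def test_planned_run_is_embedded_verbatim(self):
        seq, loci = generate_reference(
            10_000, microsatellite_plan=[("A", 10, 500)], seed=1
        )
        (locus,) = loci
        assert seq[locus.start : locus.end] == "A" * 10
        assert (locus.unit, locus.n_repeats) == ("A", 10)
        # flanks break the run, so the recorded locus is maximal
        assert seq[locus.start - 1] != "A" and seq[locus.end] != "A"

    def test_empty_plan_gives_no_truth_loci(self):
        _, loci = generate_reference(10_000, seed=1)
        assert loci == []

    def test_same_seed_is_byte_identical(self):
        a, _ = generate_reference(10_000, microsatellite_plan=[("AG", 4, 100)], seed=7)
        b, _ = generate_reference(10_000, microsatellite_plan=[("AG", 4, 100)], seed=7)
        assert a == b

    def test_gc_fraction_is_respected(self):
        seq, _ = generate_reference(50_000, gc_fraction=0.6, seed=2)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.01

    def test_overlapping_plan_raises_instead_of_truncating(self):
        with pytest.raises(PlacementError):
            generate_reference(
                10_000,
                microsatellite_plan=[("A", 10, 500), ("AG", 5, 505)],
                seed=1,
            )

    def test_out_of_range_plan_raises(self):
        with pytest.raises(PlacementError):
            generate_reference(10_000, microsatellite_plan=[("A", 10, 9_995)], seed=1)


class TestSimulateCatalog:
    def test_counts_sum_to_total(self, signature_matrix):
        mix = SignatureMixture(weights={"Signature 1": 1.0}, total_snvs=1_000)
        cat = simulate_catalog(mix, signature_matrix, seed=0)
        assert cat.sum() == 1_000

    def test_expected_mode_reproduces_the_signature_row(self, signature_matrix):
        mix = SignatureMixture(weights={"Signature 6": 1.0}, total_snvs=500)
        cat = simulate_catalog(mix, signature_matrix, expected=True)
        np.testing.assert_allclose(cat / 500, signature_matrix.row("Signature 6"))

    def test_unknown_signature_id_raises(self, signature_matrix):
        mix = SignatureMixture(weights={"Signature 99": 1.0}, total_snvs=10)
        with pytest.raises(KeyError):
            simulate_catalog(mix, signature_matrix, seed=0)

    def test_empirical_frequencies_match_analytic_mixture(self, signature_matrix):
        """At 50k draws the empirical bin frequencies sit within 0.01 of the
        mixture-weighted row combination, cross-checked against a direct
        multinomial oracle built from the same analytic probabilities."""
        mix = SignatureMixture(
            weights={"Signature 1": 0.6, "Signature 6": 0.4}, total_snvs=50_000
        )
        analytic = (
            0.6 * signature_matrix.row("Signature 1")
            + 0.4 * signature_matrix.row("Signature 6")
        )
        cat = simulate_catalog(mix, signature_matrix, seed=42)
        assert np.abs(cat / 50_000 - analytic).max() < 0.01
        # independent oracle: numpy multinomial over the hand-built mixture
        oracle = np.random.default_rng(7).multinomial(50_000, analytic)
        assert np.abs(oracle / 50_000 - cat / 50_000).max() < 0.01

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SignatureMixture(weights={"Signature 1": 0.5}, total_snvs=10)


class TestSimulateSample:
    def test_union_count_equals_truth(self, sim_sample):
        """Conservation: VCF union of both pseudo-callers carries exactly
        the truth-set SNVs."""
        from sebsig import io as sio

        sim = sim_sample["sim"]
        a = sio.read_vcf(sim.tumor_vcf_a, caller="A", pass_only=True)
        b = sio.read_vcf(sim.tumor_vcf_b, caller="B", pass_only=True)
        union = {v.key for v in a if v.is_snv} | {v.key for v in b if v.is_snv}
        truth_keys = {("1", s.pos, s.ref, s.alt) for s in sim.truth.snvs}
        assert union == truth_keys

    def test_caller_split_matches_spec_fraction(self, sim_sample):
        truth = sim_sample["sim"].truth
        n_placed = truth.n_union - 1  # one driver is always dual-caller
        assert truth.n_shared - 1 == round(0.7 * n_placed)

    def test_full_overlap_gives_identical_caller_keys(
        self, reference, signature_matrix, context_cache, tmp_path
    ):
        from sebsig import io as sio

        spec = SyntheticSampleSpec(
            mixture=SignatureMixture(weights={"Signature 1": 1.0}, total_snvs=150),
            n_germline_hets=0,
            caller_overlap=1.0,
            seed=5,
        )
        sim = simulate_sample(
            reference[0], spec, signature_matrix, tmp_path,
            context_index_cache=context_cache,
        )
        a = {v.key for v in sio.read_vcf(sim.tumor_vcf_a, pass_only=True)}
        b = {v.key for v in sio.read_vcf(sim.tumor_vcf_b, pass_only=True)}
        assert a == b and len(a) == 150

    def test_context_fidelity(self, sim_sample, reference):
        """Re-reading the reference at every placed SNV reproduces the
        recorded context bin."""
        seq = reference[0]
        for s in sim_sample["sim"].truth.snvs:
            five, ref, three = seq[s.pos - 2 : s.pos + 1]
            assert ref == s.ref
            assert context_index(ref, s.alt, five, three) == s.context

    def test_byte_identical_under_fixed_seed(
        self, reference, signature_matrix, context_cache, tmp_path, mmr_mixture
    ):
        spec = SyntheticSampleSpec(mixture=mmr_mixture, n_germline_hets=50, seed=9)
        sims = [
            simulate_sample(
                reference[0], spec, signature_matrix, tmp_path / d,
                ms_loci=reference[1], context_index_cache=context_cache,
            )
            for d in ("x", "y")
        ]
        for attr in ("germline_vcf", "tumor_vcf_a", "tumor_vcf_b"):
            va, vb = (getattr(s, attr).read_bytes() for s in sims)
            assert va == vb

    def test_no_loh_means_no_forced_shift(
        self, reference, signature_matrix, context_cache, tmp_path
    ):
        """Without LOH segments every het site's true tumor allele fraction
        stays 0.5, so no site is *constructed* beyond the 0.3 shift."""
        spec = SyntheticSampleSpec(
            mixture=SignatureMixture(weights={"Signature 1": 1.0}, total_snvs=0),
            n_germline_hets=100,
            loh_segments=[],
            seed=13,
        )
        sim = simulate_sample(
            reference[0], spec, signature_matrix, tmp_path,
            context_index_cache=context_cache,
        )
        assert all(not h.in_loh for h in sim.truth.hets)

    def test_germline_vafs_concentrate_near_half(self, sim_sample):
        vafs = [h.germline_alt / h.germline_depth for h in sim_sample["sim"].truth.hets]
        assert 0.45 < np.mean(vafs) < 0.55
        assert all(0.2 < v < 0.8 for v in vafs)

    def test_tumor_snvs_survive_the_filters_by_construction(self, sim_sample):
        for s in sim_sample["sim"].truth.snvs:
            assert s.depth >= 40
            assert s.alt_count / s.depth >= 0.2

    def test_ms_indel_rate_half_hits_some_loci(self, sim_sample):
        truth = sim_sample["sim"].truth
        assert 0 < len(truth.ms_mutated_loci) <= len(sim_sample["loci"])

    def test_overlapping_loh_segments_rejected(self, mmr_mixture):
        with pytest.raises(ValueError, match="overlapping"):
            SyntheticSampleSpec(
                mixture=mmr_mixture,
                loh_segments=[("1", 0, 100, "alt"), ("1", 50, 150, "ref")],
            )
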