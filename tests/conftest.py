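import numpy as np
import pytest

from sebsig.resources import load_signature_matrix
from sebsig.simulate import (
    SignatureMixture,
    SyntheticSampleSpec,
    build_context_position_index,
    generate_reference,
    simulate_sample,
    write_sample_region_files,
)

REF_LENGTH = 100_000

#: Planned microsatellites kept clear of each other; approximate positions
#: land some loci inside exons ([even k, even k + 1000) tiles) and some not.
MS_PLAN = [
    ("A", 12, 4_500),
    ("AG", 6, 24_600),
    ("A", 10, 44_800),
    ("AT", 5, 64_200),
    ("A", 8, 84_700),
    ("CAG", 4, 90_500),
]


@pytest.fixture(scope="session")
def signature_matrix():
    return load_signature_matrix()


@pytest.fixture(scope="session")
def reference():
    seq, loci = generate_reference(REF_LENGTH, microsatellite_plan=MS_PLAN, seed=11)
    return seq, loci


@pytest.fixture(scope="session")
def context_cache(reference):
    return build_context_position_index(reference[0])


@pytest.fixture(scope="session")
def mmr_mixture():
    """Signature mixture on the MMR-deficient composition scale."""
    return SignatureMixture(
        weights={"Signature 1": 0.59, "Signature 6": 0.31, "Signature 15": 0.10},
        total_snvs=1_000,
    )


@pytest.fixture(scope="session")
def sim_sample(tmp_path_factory, reference, signature_matrix, mmr_mixture, context_cache):
    """One fully simulated tumor/normal pair reused across tests.

    200 germline hets, one LOH segment over [L/4, L/2) retaining the
    alternate allele, 70% caller overlap, microsatellite indels at half the
    planned loci, one annotated driver SNV inside the MSH2-like gene.
    """
    seq, loci = reference
    out = tmp_path_factory.mktemp("sim")
    spec = SyntheticSampleSpec(
        mixture=mmr_mixture,
        n_germline_hets=200,
        loh_segments=[("1", REF_LENGTH // 4, REF_LENGTH // 2, "alt")],
        ms_indel_rate=0.5,
        depth_mean=80,
        caller_overlap=0.7,
        seed=3,
    )
    sim = simulate_sample(
        seq,
        spec,
        signature_matrix,
        out,
        ms_loci=loci,
        drivers=[(REF_LENGTH // 4 + 137, "high")],
        context_index_cache=context_cache,
    )
    capture_bed, exon_bed = write_sample_region_files(out, "1", REF_LENGTH)
    return {
        "sim": sim,
        "spec": spec,
        "loci": loci,
        "capture_bed": capture_bed,
        "exon_bed": exon_bed,
        "gene_interval": ("1", REF_LENGTH // 4 + 100, REF_LENGTH // 4 + 6000),
        "driver_pos": REF_LENGTH // 4 + 137,
    }


def rng(seed=0):
    return np.random.default_rng(seed)
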