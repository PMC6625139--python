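"""End-to-end per-sample pipeline gluing the analysis stages together.

Stage order for one tumor/normal pair:

1. read germline VCF and both tumor caller VCFs (PASS records are somatic
   candidates; non-PASS tumor records still feed the LOH VAF lookup);
2. intersect the two callers' SNVs, apply depth/VAF/capture filters,
   compute mutational load and TMB;
3. build the 96-context catalog from the filtered SSNVs and refit
   signature exposures;
4. filter single-caller indels, scan the reference for microsatellites,
   count exonic microsatellite indels and the MSI score;
5. call LOH over germline-het sites and classify the gene-level second
   hit; optionally flag hotspot drivers;
6. assemble the :class:`~sebsig.report.SampleReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import io as sio
from .catalog import build_catalog
from .filtering import CaptureRegions, apply_filters, run_snv_filter_chain
from .loh import gene_second_hit, segment_regions, select_informative_sites
from .microsatellite import count_exonic_ms_indels, find_microsatellites, msi_score
from .refit import RefitConfig, SignatureRefit
from .report import SampleReport, build_sample_report, flag_hotspot_drivers
from .resources import load_signature_matrix


@dataclass
class SampleInputs:
    """File paths for one tumor/normal pair."""

    sample_id: str
    group_label: str
    germline_vcf: Path
    tumor_vcf_a: Path
    tumor_vcf_b: Path
    reference_fasta: Path
    capture_bed: Path
    exon_bed: Path
    gene_bed: Path | None = None  # MMR gene interval for second-hit calling
    signatures_tsv: Path | None = None  # default: packaged matrix
    hotspots_tsv: Path | None = None


@dataclass
class SampleRun:
    """Report plus intermediate objects useful for inspection/plots."""

    report: SampleReport
    filter_summary: object
    catalog: object
    refit_results: object
    het_sites: list
    loh_regions: list
    ms_loci: list


def run_sample(inputs: SampleInputs, min_depth: int = 40, min_vaf: float = 0.10,
               refit_config: RefitConfig | None = None,
               loh_window: int = 10, loh_support: float = 0.5) -> SampleRun:
    capture = CaptureRegions.from_bed(inputs.capture_bed)
    exons = CaptureRegions.from_bed(inputs.exon_bed)
    reference = sio.read_fasta(inputs.reference_fasta)

    tumor_a = sio.read_vcf(inputs.tumor_vcf_a, caller="A", pass_only=True)
    tumor_b = sio.read_vcf(inputs.tumor_vcf_b, caller="B", pass_only=True)
    germline = sio.read_vcf(inputs.germline_vcf, caller="A", pass_only=True)

    # SNV chain: intersection -> depth/VAF -> capture -> load & TMB
    kept_snvs, summary = run_snv_filter_chain(
        tumor_a, tumor_b, capture, min_depth=min_depth, min_vaf=min_vaf
    )

    catalog = build_catalog(kept_snvs, reference)
    refit_results = SignatureRefit(
        catalog,
        load_signature_matrix(inputs.signatures_tsv),
        refit_config,
    ).fit() if catalog.total else None

    # indels: single caller (B), same depth/VAF/capture filters
    indels_b = [v for v in tumor_b if v.is_indel]
    kept_indels, _ = apply_filters(indels_b, capture, min_depth=min_depth, min_vaf=min_vaf)
    ms_loci = []
    for chrom in reference.keys():
        ms_loci.extend(find_microsatellites(str(reference[chrom][:]), chrom=chrom))
    n_exonic_ms = count_exonic_ms_indels(kept_indels, ms_loci, exons)
    score = msi_score(kept_indels, ms_loci) if ms_loci else 0.0

    # LOH and second hit
    vaf_lookup = sio.tumor_vaf_by_locus(inputs.tumor_vcf_a)
    het_sites, _ = select_informative_sites(germline, vaf_lookup)
    regions = segment_regions(het_sites, window_sites=loh_window,
                              min_support_fraction=loh_support)
    second = []
    if inputs.gene_bed is not None:
        gene = sio.read_bed(inputs.gene_bed)[0]
        second = gene_second_hit(regions, kept_snvs + kept_indels,
                                 (gene[0], gene[1], gene[2]))

    flagged = []
    if inputs.hotspots_tsv is not None:
        from .report import HotspotTable

        flagged, _ = flag_hotspot_drivers(
            kept_snvs, HotspotTable.from_tsv(inputs.hotspots_tsv)
        )

    report = build_sample_report(
        inputs.sample_id,
        inputs.group_label,
        mutational_load=summary.n_in_capture,
        tmb=summary.tmb,
        exonic_ms_indels=n_exonic_ms,
        msi_score=score,
        second_hit=second,
        exposures=(
            {s: float(w) for s, w in refit_results.weights.items() if w > 0}
            if refit_results is not None
            else {}
        ),
        flagged_drivers=[f"{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}" for v in flagged],
    )
    return SampleRun(
        report=report,
        filter_summary=summary,
        catalog=catalog,
        refit_results=refit_results,
        het_sites=het_sites,
        loh_regions=regions,
        ms_loci=ms_loci,
    )
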