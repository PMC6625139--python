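"""Reading and writing the pipeline's file formats.

VCF input goes through cyvcf2 (multi-allelic records are split into one
variant per alternate allele); FASTA input through pyfaidx. VAF is derived
from the sample AD field when present, then from an AF field, otherwise
the record is rejected — that precedence is fixed. The simulator's VCF
output is plain VCF 4.2 text with GT:DP:AD, readable by any compliant
parser (the test suite round-trips it through cyvcf2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .variants import SomaticVariant


def read_vcf(path, caller: str = "A", pass_only: bool = False) -> list[SomaticVariant]:
    """Read a single-sample VCF into normalized variants.

    Multi-allelic records are split per alternate allele. ``caller`` tags
    every variant's provenance. ``pass_only`` keeps records whose FILTER is
    PASS/missing (callers tag e.g. germline evidence in FILTER).
    """
    from cyvcf2 import VCF

    out: list[SomaticVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            filt = rec.FILTER or "PASS"
            if pass_only and filt != "PASS":
                continue
            depth, alt_counts = _depth_and_alt_counts(rec)
            impact = rec.INFO.get("IMPACT")
            if isinstance(impact, bytes):
                impact = impact.decode()
            for i, alt in enumerate(rec.ALT):
                out.append(
                    SomaticVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref_allele=rec.REF,
                        alt_allele=alt,
                        depth=depth,
                        alt_count=min(alt_counts[i], depth),
                        callers=frozenset({caller}),
                        impact=impact.lower() if impact else None,
                        filter_status=filt,
                    )
                )
    finally:
        vcf.close()
    return out


def _depth_and_alt_counts(rec) -> tuple[int, list[int]]:
    """(total depth, per-alt read counts); AD takes precedence over AF."""
    ad = rec.format("AD")
    dp = rec.format("DP")
    depth = None
    if dp is not None:
        depth = int(dp[0][0])
    if ad is not None:
        counts = [int(x) for x in ad[0]]
        if depth is None:
            depth = sum(c for c in counts if c >= 0)
        return depth, [max(c, 0) for c in counts[1:]]
    af = rec.format("AF")
    if af is None:
        af = rec.INFO.get("AF")
        if af is not None and not isinstance(af, (tuple, list)):
            af = [af]
    else:
        af = list(af[0])
    if depth is not None and af is not None:
        return depth, [int(round(float(a) * depth)) for a in af]
    raise ValueError(
        f"cannot derive VAF at {rec.CHROM}:{rec.POS}: no AD and no AF/DP fields"
    )


def tumor_vaf_by_locus(path) -> dict[tuple[str, int], float]:
    """Map (chrom, pos) -> tumor VAF over ALL records, PASS or not.

    Non-PASS records matter here: callers report germline-tagged evidence
    at heterozygous sites, which is exactly what the LOH caller needs.
    Multi-allelic loci use the first alternate allele.
    """
    lookup: dict[tuple[str, int], float] = {}
    for v in read_vcf(path, pass_only=False):
        lookup.setdefault((str(v.chrom), v.pos), v.vaf)
    return lookup


@dataclass
class VcfRecord:
    """One line of simulator VCF output (single sample, GT:DP:AD)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "0/1"
    depth: int = 0
    alt_count: int = 0
    filter_status: str = "PASS"
    info: dict = field(default_factory=dict)

    def line(self) -> str:
        info = (
            ";".join(f"{k}={v}" for k, v in sorted(self.info.items()))
            if self.info
            else "."
        )
        ad = f"{self.depth - self.alt_count},{self.alt_count}"
        return "\t".join(
            [
                self.chrom,
                str(self.pos),
                ".",
                self.ref,
                self.alt,
                ".",
                self.filter_status,
                info,
                "GT:DP:AD",
                f"{self.genotype}:{self.depth}:{ad}",
            ]
        )


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=sebsig-simulator
{contigs}##FILTER=<ID=germline,Description="Germline-heterozygous site reported for LOH assessment">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted consequence severity">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(records, path, contig_lengths: dict[str, int], sample: str = "SAMPLE") -> None:
    """Write simulator records as sorted single-sample VCF 4.2 text."""
    contigs = "".join(
        f"##contig=<ID={c},length={n}>\n" for c, n in sorted(contig_lengths.items())
    )
    body = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE.format(contigs=contigs, sample=sample))
        for rec in body:
            fh.write(rec.line() + "\n")


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write chromosomes as FASTA with fixed line width (.fai-compatible)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Open an indexed FASTA (builds the .fai on first access)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            entry = (parts[0], int(parts[1]), int(parts[2]), *parts[3:4])
            out.append(entry)
    return out


def is_finite(x) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)
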