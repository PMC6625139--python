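"""Microsatellite detection, MSI scoring and coding-repeat frameshifts.

The instability score here is a call-level proxy for read-level MSI
tooling: with only caller VCFs available (no alignments), a microsatellite
locus counts as unstable when at least one somatic indel's affected span
overlaps it, and the score is the percentage of scanned loci affected.
The locus scan itself reports maximal tandem runs of 1-5 bp primitive
motifs (homopolymers of >= 5 copies, longer units of >= 3 copies by
default), resolving overlaps in favour of the smaller unit.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .variants import SomaticVariant


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A tandem repeat run; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    unit: str
    n_repeats: int

    def __post_init__(self):
        if self.end - self.start != len(self.unit) * self.n_repeats:
            raise ValueError("locus span inconsistent with unit x repeats")
        if _is_periodic(self.unit):
            raise ValueError(f"motif {self.unit!r} is not primitive")


@dataclass(frozen=True)
class MsiSummary:
    n_loci: int
    n_affected: int
    score: float
    n_exonic_ms_indels: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_periodic(motif: str) -> bool:
    """True if the motif is a whole repetition of a shorter motif."""
    k = len(motif)
    return any(
        k % d == 0 and motif == motif[:d] * (k // d)
        for d in range(1, k)
    )


def find_microsatellites(
    sequence: str,
    chrom: str = "1",
    min_homopolymer: int = 5,
    min_multimer: int = 3,
    max_unit: int = 5,
) -> list[MicrosatelliteLocus]:
    """Scan a chromosome for maximal microsatellite runs.

    For each unit length 1..``max_unit``, maximal non-extendable tandem
    runs of a primitive motif with at least ``min_homopolymer`` (unit 1) or
    ``min_multimer`` (unit >= 2) complete copies are collected; candidates
    overlapping an accepted locus of a smaller unit are discarded. The scan
    is deterministic: unit lengths ascending, positions left to right.
    """
    if min_homopolymer < 2 or min_multimer < 2:
        raise ValueError("repeat-count thresholds must be >= 2")
    seq = sequence.upper()
    n = len(seq)
    accepted: list[MicrosatelliteLocus] = []
    occupied = IntervalTree()
    for k in range(1, max_unit + 1):
        threshold = min_homopolymer if k == 1 else min_multimer
        i = 0
        while i + k * threshold <= n:
            motif = seq[i : i + k]
            if "N" in motif or _is_periodic(motif):
                i += 1
                continue
            # count complete tandem copies starting at i
            j = i + k
            while j + k <= n and seq[j : j + k] == motif:
                j += k
            m = (j - i) // k
            if m >= threshold:
                end = i + k * m
                if not occupied.overlap(i, end):
                    accepted.append(
                        MicrosatelliteLocus(
                            chrom=chrom, start=i, end=end, unit=motif, n_repeats=m
                        )
                    )
                    occupied.addi(i, end)
                i = end  # maximal: nothing containing this run starts inside it
            else:
                i += 1
    accepted.sort(key=lambda l: (l.start, len(l.unit)))
    return accepted


def _locus_tree(loci) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, locus in enumerate(loci):
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, idx)
    return trees


def affected_loci(indels, loci) -> set[int]:
    """Indices of loci whose interval intersects >= 1 indel's affected span."""
    trees = _locus_tree(loci)
    hit: set[int] = set()
    for v in indels:
        if not v.is_indel:
            continue
        tree = trees.get(str(v.chrom))
        if tree is None:
            continue
        start0, end0 = v.affected_span()
        for iv in tree.overlap(start0, end0):
            hit.add(iv.data)
    return hit


def count_exonic_ms_indels(indels, loci, exon_regions) -> int:
    """Indels overlapping both a microsatellite locus and an exon.

    ``exon_regions`` is a :class:`~sebsig.filtering.CaptureRegions`-like
    object exposing ``overlaps(chrom, start0, end0)``. Each indel is
    counted at most once regardless of how many loci it touches.
    """
    trees = _locus_tree(loci)
    count = 0
    for v in indels:
        if not v.is_indel:
            continue
        tree = trees.get(str(v.chrom))
        if tree is None:
            continue
        start0, end0 = v.affected_span()
        if tree.overlap(start0, end0) and exon_regions.overlaps(v.chrom, start0, end0):
            count += 1
    return count


def msi_score(indels, loci) -> float:
    """Percentage of microsatellite loci affected by >= 1 somatic indel.

    Multiple indels at one locus count once (the score is idempotent in
    repeated hits). Raises on an empty locus set.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("no microsatellite loci: MSI score undefined")
    return 100.0 * len(affected_loci(indels, loci)) / len(loci)


def summarize_msi(indels, loci, exon_regions) -> MsiSummary:
    loci = list(loci)
    return MsiSummary(
        n_loci=len(loci),
        n_affected=len(affected_loci(indels, loci)),
        score=msi_score(indels, loci),
        n_exonic_ms_indels=count_exonic_ms_indels(indels, loci, exon_regions),
    )


#: Gene symbols of the coding-microsatellite panel commonly screened for
#: somatic frameshifts in MMR-deficient colorectal/endometrial tumors.
DEFAULT_PANEL_GENES = (
    "TGFBR2", "TAF1B", "AIM2", "ASTE1", "ACVR2", "CASP5", "NDUFC2",
    "SLC22A9", "MSH3", "SMAP1", "OR7E24", "KIAA2018", "JAK1", "C18orf34",
)


def coding_ms_frameshift_report(indels, gene_panel_intervals):
    """Per-gene Frameshift/None table over coding-microsatellite intervals.

    ``gene_panel_intervals`` maps gene symbol -> (chrom, start, end),
    0-based half-open, the gene's coding-microsatellite region. A gene is
    "Frameshift" iff some indel of length not divisible by 3 overlaps its
    interval; otherwise "None".
    """
    import pandas as pd

    status = {}
    for gene, (chrom, start0, end0) in gene_panel_intervals.items():
        hit = False
        for v in indels:
            if not v.is_indel or v.indel_length % 3 == 0:
                continue
            s, e = v.affected_span()
            if str(v.chrom) == str(chrom) and s < end0 and e > start0:
                hit = True
                break
        status[gene] = "Frameshift" if hit else "None"
    return pd.Series(status, name="status").rename_axis("gene")
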