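"""Synthetic tumor/normal exome call sets with known truth.

The study design this generator emulates is a paired FFPE-tumor/blood
exome per lesion: somatic SNVs drawn from a known mutational-signature
mixture and placed at reference positions whose trinucleotide context
matches (searching both strands — the reference is never edited to fit),
germline heterozygous SNPs with binomial allele counts around VAF 0.5,
LOH segments that shift tumor VAFs at germline-het sites toward
homozygosity, microsatellite indels at a controlled per-locus rate, and
two "pseudo-caller" tumor VCFs with a controlled overlap fraction standing
in for the two independent somatic callers.

Everything is driven by one integer seed; identical spec + seed produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import BASES, CONTEXT_LABELS, context_index
from .io import VcfRecord, write_bed, write_fasta, write_vcf
from .microsatellite import MicrosatelliteLocus, _is_periodic
from .refit import SignatureMatrix

#: Default tumor VAF a germline-het site is shifted to inside an LOH
#: segment retaining the alternate allele (1 - this for the reference
#: allele). Models complete allelic loss at ~80% tumor purity; far enough
#: beyond the 0.3-shift calling threshold that truth segments are
#: recoverable at exome depths.
LOH_TARGET_VAF = 0.90


@dataclass(frozen=True)
class SignatureMixture:
    """A known signature composition: id -> fraction, plus a total count."""

    weights: dict
    total_snvs: int

    def __post_init__(self):
        if self.total_snvs < 0:
            raise ValueError("total_snvs must be >= 0")
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("negative mixture weight")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {vals.sum()}, not 1")

    def expected_frequencies(self, signature_matrix: SignatureMatrix) -> np.ndarray:
        """The mixture-weighted combination of signature rows (96 vector)."""
        p = np.zeros(96)
        for sig, w in self.weights.items():
            p += w * signature_matrix.row(sig)  # KeyError for unknown ids
        return p / p.sum()


@dataclass
class SyntheticSampleSpec:
    """Everything that defines one synthetic tumor/normal pair.

    loh_segments: (chrom, start, end, side) with 0-based half-open
    coordinates; ``side`` is "ref" or "alt", the retained allele.
    """

    mixture: SignatureMixture
    n_germline_hets: int = 200
    loh_segments: list = field(default_factory=list)
    ms_indel_rate: float = 0.0
    depth_mean: float = 80.0
    caller_overlap: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ms_indel_rate <= 1.0:
            raise ValueError("ms_indel_rate must be in [0, 1]")
        if not 0.0 <= self.caller_overlap <= 1.0:
            raise ValueError("caller_overlap must be in [0, 1]")
        by_chrom: dict[str, list] = {}
        for seg in self.loh_segments:
            chrom, start, end, side = seg
            if side not in ("ref", "alt"):
                raise ValueError(f"retained side must be 'ref' or 'alt', got {side!r}")
            if end <= start:
                raise ValueError("empty LOH segment")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping LOH segments on {chrom}")


@dataclass(frozen=True)
class TruthSnv:
    pos: int  # 1-based
    ref: str
    alt: str
    context: int  # bin in [0, 96)
    callers: str  # "AB", "A" or "B"
    depth: int
    alt_count: int
    impact: str | None = None


@dataclass(frozen=True)
class TruthHet:
    pos: int  # 1-based
    ref: str
    alt: str
    germline_depth: int
    germline_alt: int
    somatic_depth: int
    somatic_alt: int
    in_loh: bool
    retained_side: str | None


@dataclass
class TruthSet:
    """Ground truth recorded while simulating one sample."""

    chrom: str
    snvs: list
    hets: list
    exposures: dict
    loh_segments: list
    ms_mutated_loci: list  # MicrosatelliteLocus objects that received an indel

    @property
    def n_union(self) -> int:
        return len(self.snvs)

    @property
    def n_shared(self) -> int:
        return sum(1 for s in self.snvs if s.callers == "AB")

    def context_histogram(self, callers: str | None = None) -> np.ndarray:
        """96-bin histogram of placed SNVs (optionally one caller subset)."""
        h = np.zeros(96, dtype=np.int64)
        for s in self.snvs:
            if callers is None or s.callers == callers:
                h[s.context] += 1
        return h

    def to_json(self, path) -> None:
        doc = {
            "chrom": self.chrom,
            "exposures": self.exposures,
            "loh_segments": [list(s) for s in self.loh_segments],
            "snvs": [s.__dict__ for s in self.snvs],
            "hets": [h.__dict__ for h in self.hets],
            "ms_mutated_loci": [l.__dict__ for l in self.ms_mutated_loci],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class SimulatedSample:
    germline_vcf: Path
    tumor_vcf_a: Path
    tumor_vcf_b: Path
    truth: TruthSet
    reference_fasta: Path | None = None


class PlacementError(RuntimeError):
    """A planned feature cannot be placed in the reference."""


def generate_reference(
    length: int,
    gc_fraction: float = 0.41,
    microsatellite_plan=(),
    seed: int = 0,
) -> tuple[str, list[MicrosatelliteLocus]]:
    """Random reference sequence with planned microsatellites embedded.

    ``microsatellite_plan`` entries are (unit, repeat_count, approx_pos);
    each run is placed verbatim at its requested position (0-based start),
    with the flanking base on each side forced to break the run so the
    planned locus is the maximal one. Overlapping or out-of-range plans
    raise :class:`PlacementError` rather than being silently truncated.

    Returns (sequence, truth loci with half-open coordinates).
    """
    if length < 10_000:
        raise ValueError("reference length must be >= 10,000")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = rng.choice(list("ACGT"), size=length, p=p)

    placed: list[MicrosatelliteLocus] = []
    occupied: list[tuple[int, int]] = []
    for unit, n_rep, approx in microsatellite_plan:
        unit = unit.upper()
        if not (1 <= len(unit) <= 5) or any(b not in BASES for b in unit):
            raise ValueError(f"bad microsatellite unit {unit!r}")
        if _is_periodic(unit):
            raise ValueError(f"unit {unit!r} is not primitive")
        start = int(approx)
        end = start + len(unit) * n_rep
        if start < 1 or end > length - 1:
            raise PlacementError(f"locus {unit}x{n_rep} at {start} outside reference")
        for s, e in occupied:
            if start < e + 1 and end + 1 > s:  # +-1: flank bases are reserved too
                raise PlacementError(f"locus {unit}x{n_rep} at {start} overlaps another")
        occupied.append((start, end))
        seq[start:end] = list(unit * n_rep)
        # break the run on both flanks so the planned locus is maximal
        seq[start - 1] = _different_base(rng, unit[-1])
        seq[end] = _different_base(rng, unit[0])
        placed.append(
            MicrosatelliteLocus(chrom="1", start=start, end=end, unit=unit, n_repeats=n_rep)
        )
    placed.sort(key=lambda l: l.start)
    return "".join(seq), placed


def _different_base(rng, avoid: str) -> str:
    choices = [b for b in BASES if b != avoid]
    return choices[int(rng.integers(len(choices)))]


def simulate_catalog(
    mixture: SignatureMixture,
    signature_matrix: SignatureMatrix,
    seed: int | None = None,
    expected: bool = False,
) -> np.ndarray:
    """Draw a 96-bin catalog from a signature mixture.

    Counts are multinomial over the mixture-weighted bin frequencies;
    ``expected=True`` returns the exact expected (fractional) counts
    instead of sampling.
    """
    p = mixture.expected_frequencies(signature_matrix)
    if expected:
        return mixture.total_snvs * p
    rng = np.random.default_rng(seed)
    return rng.multinomial(mixture.total_snvs, p)


def build_context_position_index(sequence: str) -> list[list[tuple[int, str]]]:
    """For each of the 96 bins, the (1-based pos, alt) choices producing it.

    Both strands are considered implicitly: a purine-centred position
    contributes to the pyrimidine-collapsed bin of its reverse complement.
    """
    index: list[list[tuple[int, str]]] = [[] for _ in range(96)]
    seq = sequence.upper()
    for pos0 in range(1, len(seq) - 1):
        five, ref, three = seq[pos0 - 1 : pos0 + 2]
        if any(b not in BASES for b in (five, ref, three)):
            continue
        for alt in BASES:
            if alt == ref:
                continue
            index[context_index(ref, alt, five, three)].append((pos0 + 1, alt))
    return index


class ContextExhaustedError(PlacementError):
    """No unused reference position matches a requested context bin."""


def simulate_sample(
    reference: str,
    spec: SyntheticSampleSpec,
    signature_matrix: SignatureMatrix,
    out_dir,
    chrom: str = "1",
    ms_loci=(),
    drivers=(),
    context_index_cache=None,
) -> SimulatedSample:
    """Write a (germline, tumor A, tumor B) VCF triple plus ground truth.

    * Tumor SNVs are placed at context-matching positions, with depth
      floored at 40 reads and observed VAF floored at 0.2, so every
      simulated SNV survives the depth/VAF filters unless deliberately
      degraded afterwards.
    * A fraction ``spec.caller_overlap`` of tumor SNVs is emitted by both
      pseudo-callers; the remainder alternates between A-only and B-only.
    * Germline hets get binomial(depth, 0.5) allele counts; inside an LOH
      segment the tumor-side allele fraction is :data:`LOH_TARGET_VAF`
      (alternate retained) or 1 - it (reference retained). Tumor VAFs at
      het sites are emitted in tumor VCF A as FILTER=germline records.
    * Each locus in ``ms_loci`` receives a +-1-unit indel with probability
      ``spec.ms_indel_rate``; indels go to tumor VCF B only (the
      indel-capable pseudo-caller).
    * ``drivers`` entries (pos, impact) add high-level annotated SNVs to
      both callers (hotspot/second-hit material), recorded in the truth.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = reference.upper()
    ctx_index = (
        context_index_cache
        if context_index_cache is not None
        else build_context_position_index(seq)
    )

    used: set[int] = set()  # 1-based positions already carrying a feature
    for locus in ms_loci:
        used.update(range(locus.start, locus.end + 2))  # incl. anchor+flank

    # ---- germline heterozygous SNPs --------------------------------------
    hets: list[TruthHet] = []
    loh_lookup = _segment_lookup(spec.loh_segments, chrom)
    candidate_positions = rng.permutation(np.arange(2, len(seq)))  # 1-based, with flanks
    g_records, a_het_records = [], []
    for pos1 in candidate_positions:
        if len(hets) >= spec.n_germline_hets:
            break
        pos1 = int(pos1)
        if pos1 in used or seq[pos1 - 1] not in BASES:
            continue
        used.add(pos1)
        ref = seq[pos1 - 1]
        alt = BASES[int(rng.integers(3))]
        if alt >= ref:  # skip the ref base itself deterministically
            alt = BASES[(BASES.index(alt) + 1) % 4]
        g_depth = max(10, int(rng.poisson(spec.depth_mean)))
        g_alt = int(rng.binomial(g_depth, 0.5))
        seg_side = loh_lookup(pos1)
        if seg_side is None:
            true_vaf = 0.5
        else:
            true_vaf = LOH_TARGET_VAF if seg_side == "alt" else 1.0 - LOH_TARGET_VAF
        s_depth = max(10, int(rng.poisson(spec.depth_mean)))
        s_alt = int(rng.binomial(s_depth, true_vaf))
        hets.append(
            TruthHet(
                pos=pos1, ref=ref, alt=alt,
                germline_depth=g_depth, germline_alt=g_alt,
                somatic_depth=s_depth, somatic_alt=s_alt,
                in_loh=seg_side is not None, retained_side=seg_side,
            )
        )
        g_records.append(
            VcfRecord(chrom=chrom, pos=pos1, ref=ref, alt=alt,
                      depth=g_depth, alt_count=g_alt)
        )
        a_het_records.append(
            VcfRecord(chrom=chrom, pos=pos1, ref=ref, alt=alt,
                      depth=s_depth, alt_count=s_alt, filter_status="germline")
        )

    # ---- somatic SNVs from the signature mixture -------------------------
    bin_counts = rng.multinomial(
        spec.mixture.total_snvs, spec.mixture.expected_frequencies(signature_matrix)
    )
    snvs: list[TruthSnv] = []
    for b in range(96):
        need = int(bin_counts[b])
        if need == 0:
            continue
        pool = [pa for pa in ctx_index[b] if pa[0] not in used]
        if len(pool) < need:
            raise ContextExhaustedError(
                f"context {CONTEXT_LABELS[b]}: need {need} positions, "
                f"only {len(pool)} unused remain"
            )
        picks = rng.choice(len(pool), size=need, replace=False)
        for k in sorted(int(x) for x in picks):
            pos1, alt = pool[k]
            used.add(pos1)
            depth = max(40, int(rng.poisson(spec.depth_mean)))
            true_vaf = rng.uniform(0.3, 0.6)
            alt_count = int(rng.binomial(depth, true_vaf))
            while alt_count / depth < 0.2:
                alt_count = int(rng.binomial(depth, true_vaf))
            snvs.append(
                TruthSnv(pos=pos1, ref=seq[pos1 - 1], alt=alt, context=b,
                         callers="AB", depth=depth, alt_count=alt_count)
            )
    # caller assignment: a caller_overlap fraction shared, rest alternating
    n = len(snvs)
    n_shared = int(round(spec.caller_overlap * n))
    order = rng.permutation(n)
    reassigned = []
    solo_toggle = True
    for rank, idx in enumerate(order):
        s = snvs[int(idx)]
        if rank < n_shared:
            callers = "AB"
        else:
            callers = "A" if solo_toggle else "B"
            solo_toggle = not solo_toggle
        reassigned.append((int(idx), callers))
    for idx, callers in reassigned:
        s = snvs[idx]
        snvs[idx] = TruthSnv(pos=s.pos, ref=s.ref, alt=s.alt, context=s.context,
                             callers=callers, depth=s.depth, alt_count=s.alt_count)

    # ---- driver SNVs (both callers, annotated impact) --------------------
    for pos1, impact in drivers:
        pos1 = int(pos1)
        if pos1 in used:
            raise PlacementError(f"driver position {pos1} already used")
        if not 2 <= pos1 <= len(seq) - 1:
            raise PlacementError(f"driver position {pos1} outside reference")
        used.add(pos1)
        ref = seq[pos1 - 1]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        depth = max(40, int(rng.poisson(spec.depth_mean)))
        alt_count = max(int(rng.binomial(depth, 0.4)), int(np.ceil(0.2 * depth)))
        ctx = context_index(ref, alt, seq[pos1 - 2], seq[pos1])
        snvs.append(
            TruthSnv(pos=pos1, ref=ref, alt=alt, context=ctx, callers="AB",
                     depth=depth, alt_count=alt_count, impact=impact)
        )

    # ---- microsatellite indels (caller B only) ---------------------------
    ms_mutated: list[MicrosatelliteLocus] = []
    b_indel_records = []
    for locus in ms_loci:
        if rng.random() >= spec.ms_indel_rate:
            continue
        k = len(locus.unit)
        anchor0 = locus.start  # first base of the run anchors the indel
        if rng.random() < 0.5:  # deletion of one unit
            ref_allele = seq[anchor0 : anchor0 + 1 + k]
            alt_allele = seq[anchor0]
        else:  # insertion of one unit
            ref_allele = seq[anchor0]
            alt_allele = seq[anchor0] + locus.unit
        depth = max(40, int(rng.poisson(spec.depth_mean)))
        alt_count = max(int(rng.binomial(depth, 0.35)), int(np.ceil(0.2 * depth)))
        b_indel_records.append(
            VcfRecord(chrom=chrom, pos=anchor0 + 1, ref=ref_allele, alt=alt_allele,
                      depth=depth, alt_count=alt_count)
        )
        ms_mutated.append(locus)

    # ---- write the VCF triple -------------------------------------------
    def snv_record(s: TruthSnv) -> VcfRecord:
        info = {"IMPACT": s.impact.upper()} if s.impact else {}
        return VcfRecord(chrom=chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                         depth=s.depth, alt_count=s.alt_count, info=info)

    contigs = {chrom: len(seq)}
    a_records = [snv_record(s) for s in snvs if "A" in s.callers] + a_het_records
    b_records = [snv_record(s) for s in snvs if "B" in s.callers] + b_indel_records
    germline_vcf = out_dir / "germline.vcf"
    tumor_a = out_dir / "tumor_a.vcf"
    tumor_b = out_dir / "tumor_b.vcf"
    write_vcf(g_records, germline_vcf, contigs, sample="NORMAL")
    write_vcf(a_records, tumor_a, contigs, sample="TUMOR")
    write_vcf(b_records, tumor_b, contigs, sample="TUMOR")

    truth = TruthSet(
        chrom=chrom,
        snvs=sorted(snvs, key=lambda s: s.pos),
        hets=sorted(hets, key=lambda h: h.pos),
        exposures=dict(spec.mixture.weights),
        loh_segments=list(spec.loh_segments),
        ms_mutated_loci=ms_mutated,
    )
    fasta = out_dir / "reference.fa"
    write_fasta({chrom: seq}, fasta)
    return SimulatedSample(
        germline_vcf=germline_vcf,
        tumor_vcf_a=tumor_a,
        tumor_vcf_b=tumor_b,
        truth=truth,
        reference_fasta=fasta,
    )


def _segment_lookup(segments, chrom: str):
    segs = [
        (int(s), int(e), side)
        for c, s, e, side in segments
        if str(c) == str(chrom)
    ]

    def lookup(pos1: int):
        pos0 = pos1 - 1
        for s, e, side in segs:
            if s <= pos0 < e:
                return side
        return None

    return lookup


def write_sample_region_files(out_dir, chrom: str, length: int, exon_every: int = 2000,
                              exon_width: int = 1000) -> tuple[Path, Path]:
    """Convenience capture/exon BEDs for a synthetic chromosome.

    Capture covers the whole chromosome; exons tile every ``exon_every``
    bases with ``exon_width``-base intervals.
    """
    out_dir = Path(out_dir)
    capture = out_dir / "capture.bed"
    exons = out_dir / "exons.bed"
    write_bed([(chrom, 0, length)], capture)
    write_bed(
        [
            (chrom, s, min(s + exon_width, length))
            for s in range(0, length, exon_every)
        ],
        exons,
    )
    return capture, exons
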