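"""Somatic variant selection and tumor mutational burden.

The selection chain mirrors a dual-caller exome workflow: SNVs must be
reported by both callers, then every variant must clear a minimum depth
(default 40 reads) and minimum VAF (default 10%, both inclusive) and fall
inside the capture region. Indels, called by one caller only, bypass the
intersection but not the depth/VAF/capture filters. TMB is the number of
surviving SNVs per megabase of merged capture region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .variants import SomaticVariant

DEFAULT_MIN_DEPTH = 40
DEFAULT_MIN_VAF = 0.10


@dataclass
class CaptureRegions:
    """Merged, sorted capture intervals (BED convention: 0-based half-open)."""

    intervals: list = field(default_factory=list)

    def __post_init__(self):
        merged: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            merged.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end))
        for tree in merged.values():
            tree.merge_overlaps(strict=False)  # also merges bookended intervals
        self._trees = merged
        self.intervals = sorted(
            (chrom, iv.begin, iv.end)
            for chrom, tree in merged.items()
            for iv in tree
        )

    @classmethod
    def from_bed(cls, path) -> "CaptureRegions":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start), int(end)))
        return cls(intervals=intervals)

    @property
    def total_size(self) -> int:
        """Bases covered after merging overlaps."""
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Is 1-based position ``pos`` inside the capture?

        A 1-based position p lies in half-open [s, e) iff s < p <= e.
        """
        tree = self._trees.get(str(chrom))
        return bool(tree and tree.overlaps_point(pos - 1))

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        tree = self._trees.get(str(chrom))
        return bool(tree and tree.overlap(start0, end0))


@dataclass
class FilterSummary:
    """Per-sample tallies along the SNV selection chain (non-increasing)."""

    n_input_a: int
    n_input_b: int
    n_intersect: int
    n_pass_depth_vaf: int
    n_in_capture: int
    tmb: float

    def __post_init__(self):
        chain = (self.n_intersect, self.n_pass_depth_vaf, self.n_in_capture)
        if self.n_intersect > min(self.n_input_a, self.n_input_b):
            raise ValueError("intersection larger than an input set")
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"filter chain not monotone: {chain}")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def intersect_callers(variants_a, variants_b, take_from: str = "A"):
    """Variants reported by both callers, matched on (chrom, pos, ref, alt).

    Depth and allele counts are taken from caller A's record by default
    (``take_from="B"`` switches). Output order follows the chosen caller's
    input order; ``callers`` is set to {"A", "B"} on every output record.
    """
    if take_from not in ("A", "B"):
        raise ValueError("take_from must be 'A' or 'B'")
    primary, other = (
        (variants_a, variants_b) if take_from == "A" else (variants_b, variants_a)
    )
    other_keys = {v.key for v in other}
    return [v.with_callers({"A", "B"}) for v in primary if v.key in other_keys]


def apply_filters(
    variants,
    capture: CaptureRegions,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> tuple[list, dict]:
    """Depth/VAF/capture selection; thresholds are inclusive minima.

    Returns (kept variants, tally dict with ``n_pass_depth_vaf`` and
    ``n_in_capture``). An empty capture is an error because it makes TMB
    undefined downstream.
    """
    if min_depth <= 0 or min_vaf <= 0:
        raise ValueError("thresholds must be positive")
    if capture.total_size == 0:
        raise ValueError("empty capture region: TMB is undefined")
    pass_dv = [v for v in variants if v.depth >= min_depth and v.vaf >= min_vaf]
    kept = [v for v in pass_dv if capture.contains(v.chrom, v.pos)]
    return kept, {"n_pass_depth_vaf": len(pass_dv), "n_in_capture": len(kept)}


def compute_tmb(n_variants: int, capture: CaptureRegions) -> float:
    """Mutations per megabase of capture region."""
    if capture.total_size <= 0:
        raise ValueError("capture size must be positive")
    if n_variants < 0:
        raise ValueError("negative variant count")
    return n_variants / (capture.total_size / 1e6)


def run_snv_filter_chain(
    variants_a,
    variants_b,
    capture: CaptureRegions,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    take_from: str = "A",
) -> tuple[list, FilterSummary]:
    """Full SNV chain: intersect callers, filter, compute TMB.

    Only SNVs participate; indels should be filtered separately with
    :func:`apply_filters` (they are single-caller calls).
    """
    snvs_a = [v for v in variants_a if v.is_snv]
    snvs_b = [v for v in variants_b if v.is_snv]
    shared = intersect_callers(snvs_a, snvs_b, take_from=take_from)
    kept, tally = apply_filters(shared, capture, min_depth=min_depth, min_vaf=min_vaf)
    summary = FilterSummary(
        n_input_a=len(snvs_a),
        n_input_b=len(snvs_b),
        n_intersect=len(shared),
        n_pass_depth_vaf=tally["n_pass_depth_vaf"],
        n_in_capture=tally["n_in_capture"],
        tmb=compute_tmb(len(kept), capture),
    )
    return kept, summary
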