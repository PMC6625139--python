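"""Normalized somatic variant records shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


VAR_CLASSES = ("SNV", "insertion", "deletion", "MNV")
IMPACT_LEVELS = ("high", "moderate", "low", "modifier")


@dataclass(frozen=True)
class SomaticVariant:
    """One normalized variant call.

    Coordinates are 1-based (VCF convention); multi-allelic records must be
    split into one ``SomaticVariant`` per alternate allele before use.

    Parameters
    ----------
    chrom, pos : locus of the record (``pos`` points at the first REF base).
    ref_allele, alt_allele : VCF-style alleles (anchored for indels).
    depth : total read depth at the locus.
    alt_count : reads supporting ``alt_allele``.
    callers : subset of {"A", "B"} recording which caller(s) emitted it.
    impact : optional predicted consequence severity
        ("high" | "moderate" | "low" | "modifier").
    filter_status : VCF FILTER ("PASS" for passing records).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    callers: frozenset = field(default_factory=lambda: frozenset({"A"}))
    impact: str | None = None
    filter_status: str = "PASS"

    def __post_init__(self):
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.impact is not None and self.impact not in IMPACT_LEVELS:
            raise ValueError(f"unknown impact {self.impact!r}")

    @property
    def vaf(self) -> float:
        """Variant allele frequency, alt_count / depth (0.0 at zero depth)."""
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def var_class(self) -> str:
        nr, na = len(self.ref_allele), len(self.alt_allele)
        if nr == na:
            return "SNV" if nr == 1 else "MNV"
        return "insertion" if na > nr else "deletion"

    @property
    def key(self) -> tuple:
        """Identity used for caller intersection: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return self.var_class == "SNV"

    @property
    def is_indel(self) -> bool:
        return self.var_class in ("insertion", "deletion")

    @property
    def indel_length(self) -> int:
        """Signed inserted(+)/deleted(-) length; 0 for substitutions."""
        return len(self.alt_allele) - len(self.ref_allele)

    def affected_span(self) -> tuple[int, int]:
        """Reference span the variant changes, 0-based half-open.

        SNV/MNV: the substituted bases. Deletion: the deleted bases
        (anchor excluded). Insertion: the single anchor base, so that an
        insertion inside a repeat run still intersects the run's interval.
        """
        start0 = self.pos - 1
        if self.var_class == "deletion":
            return (start0 + 1, start0 + len(self.ref_allele))
        if self.var_class == "insertion":
            return (start0, start0 + 1)
        return (start0, start0 + len(self.ref_allele))

    def with_callers(self, callers) -> "SomaticVariant":
        return replace(self, callers=frozenset(callers))
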