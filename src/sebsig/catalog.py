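"""96-trinucleotide-context SNV catalogs.

Single-base substitutions are collapsed to the pyrimidine-reference
convention (a G>T call becomes C>A on the opposite strand, with flanks
reverse-complemented), giving 6 substitution classes x 16 flank pairs = 96
context bins. Bin order is substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G) with the 16 flank pairs alphabetical within each class — the row
order of the standard 30-signature probability table, which the refit
stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import SomaticVariant

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: The 96 context labels, e.g. "A[C>A]A", in canonical order.
CONTEXT_LABELS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_index(ref: str, alt: str, five: str, three: str) -> int:
    """Bin index in [0, 96) for a substitution ``five[ref>alt]three``.

    Purine references are reverse-complemented first so that every
    substitution is expressed with a C or T reference base.

    Raises
    ------
    ValueError
        if any base is not one of A/C/G/T or ref == alt.
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    for b in (ref, alt, five, three):
        if len(b) != 1 or b not in BASES:
            raise ValueError(f"non-ACGT base {b!r} in context")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":  # purine reference: flip strand
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    sub = f"{ref}>{alt}"
    return (
        SUBSTITUTIONS.index(sub) * 16 + BASES.index(five) * 4 + BASES.index(three)
    )


def label_to_index(label: str) -> int:
    return _LABEL_TO_INDEX[label]


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Slice ``reference[chrom][start0:end0]`` and return an upper-case str.

    Works for a plain dict of chromosome strings, a single str (treated as
    the only chromosome) and a ``pyfaidx.Fasta``.
    """
    seq = reference if isinstance(reference, str) else reference[chrom]
    return str(seq[start0:end0]).upper()


def classify_context(reference, variant: SomaticVariant) -> int | None:
    """Context bin of an SNV, or ``None`` when a flank is not A/C/G/T.

    The caller is responsible for tallying ``None`` results (unclassifiable
    sites are reported, never raised).
    """
    if not variant.is_snv:
        raise ValueError(f"not an SNV: {variant.ref_allele}>{variant.alt_allele}")
    triplet = _fetch(reference, variant.chrom, variant.pos - 2, variant.pos + 1)
    if len(triplet) != 3:
        return None
    five, ref, three = triplet
    if ref != variant.ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref_allele}, sequence says {ref}"
        )
    try:
        return context_index(ref, variant.alt_allele, five, three)
    except ValueError:
        return None


@dataclass
class TrinucleotideCatalog:
    """Ordered 96-bin SNV count vector plus an unclassifiable tally."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    unclassifiable: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 bins")
        if (self.counts < 0).any():
            raise ValueError("negative catalog count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("all-zero catalog has no frequencies")
        return self.counts / self.total

    def to_series(self):
        import pandas as pd

        return pd.Series(self.counts, index=CONTEXT_LABELS, name="count")

    def to_tsv(self, path) -> None:
        self.to_series().rename_axis("context").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TrinucleotideCatalog":
        import pandas as pd

        s = pd.read_csv(path, sep="\t", index_col=0)["count"]
        return cls(counts=s.reindex(CONTEXT_LABELS).to_numpy())


def build_catalog(variants, reference) -> TrinucleotideCatalog:
    """Build the 96-bin catalog from (already filtered) variants.

    Only SNVs contribute; indels and MNVs are ignored. SNVs whose flanks
    contain non-ACGT bases go to the ``unclassifiable`` tally, so
    ``catalog.total + catalog.unclassifiable`` equals the number of input
    SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    unclassifiable = 0
    for v in variants:
        if not v.is_snv:
            continue
        idx = classify_context(reference, v)
        if idx is None:
            unclassifiable += 1
        else:
            counts[idx] += 1
    return TrinucleotideCatalog(counts=counts, unclassifiable=unclassifiable)
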