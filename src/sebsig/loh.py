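"""Loss-of-heterozygosity calling from paired germline/tumor VAFs.

A site is informative when its germline VAF lies in [0.3, 0.7] (a
confidently heterozygous SNP). The site supports LOH when the tumor VAF
has shifted by strictly more than 0.3 from the germline VAF — i.e. the
site looks homozygous reference (shift toward 0) or homozygous alternative
(shift toward 1) in the tumor. On a single VAF axis the two directions are
jointly equivalent to the absolute-difference test, which is what is
implemented; an optional stricter mode additionally requires the tumor VAF
itself to leave the heterozygous window.

Sites are aggregated into regions with a sliding window over consecutive
informative sites (the published evidence is per-site; the windowing rule
here is this package's own, exposed as parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

GERMLINE_HET_LOW = 0.3
GERMLINE_HET_HIGH = 0.7
LOH_SHIFT = 0.3


@dataclass(frozen=True)
class HetSite:
    """A germline-heterozygous site with its tumor VAF."""

    chrom: str
    pos: int
    germline_vaf: float
    somatic_vaf: float

    @property
    def supports_loh(self) -> bool:
        return call_site_loh(self)


@dataclass
class LOHRegion:
    """A run of consecutive informative sites with an LOH verdict.

    ``start``/``end`` are the 1-based positions of the first and last
    member sites; ``status`` is "LOH", "no-LOH" or "insufficient-data".
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    n_supporting: int
    status: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start after end")
        if self.n_supporting > self.n_sites:
            raise ValueError("more supporting sites than sites")

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """Overlap with a 0-based half-open interval."""
        return self.chrom == str(chrom) and self.start <= end0 and self.end > start0


def is_informative(germline_vaf: float) -> bool:
    """Germline VAF inside the heterozygous window [0.3, 0.7], inclusive."""
    return GERMLINE_HET_LOW <= germline_vaf <= GERMLINE_HET_HIGH


def select_informative_sites(germline_variants, somatic_vaf_by_locus) -> tuple[list[HetSite], int]:
    """Pair germline hets with tumor VAFs at the same loci.

    Parameters
    ----------
    germline_variants : records with ``chrom``, ``pos`` and ``vaf``.
    somatic_vaf_by_locus : mapping (chrom, pos) -> tumor VAF. Loci with no
        tumor record cannot be assessed (no coverage information without
        alignments) and are dropped.

    Returns
    -------
    (sites, n_dropped) where ``n_dropped`` counts germline hets absent from
    the tumor records. Duplicate loci are collapsed to their first record.
    """
    sites: list[HetSite] = []
    seen: set[tuple[str, int]] = set()
    n_dropped = 0
    for g in germline_variants:
        locus = (str(g.chrom), int(g.pos))
        if locus in seen or not is_informative(g.vaf):
            continue
        seen.add(locus)
        if locus not in somatic_vaf_by_locus:
            n_dropped += 1
            continue
        sites.append(
            HetSite(
                chrom=locus[0],
                pos=locus[1],
                germline_vaf=float(g.vaf),
                somatic_vaf=float(somatic_vaf_by_locus[locus]),
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites, n_dropped


def call_site_loh(site: HetSite, require_homozygous_range: bool = False) -> bool:
    """Does this informative site support LOH?

    True iff |somatic_vaf - germline_vaf| > 0.3 (strict: a shift of exactly
    0.30 does not qualify). With ``require_homozygous_range`` the tumor VAF
    must additionally look homozygous (< 0.3 or > 0.7).
    """
    # round-off guard: a shift of exactly 0.30 must not qualify even when
    # binary float subtraction lands an ulp above it (e.g. 0.8 - 0.5)
    shifted = abs(site.somatic_vaf - site.germline_vaf) - LOH_SHIFT > 1e-12
    if not require_homozygous_range:
        return shifted
    homozygous = site.somatic_vaf < GERMLINE_HET_LOW or site.somatic_vaf > GERMLINE_HET_HIGH
    return shifted and homozygous


def segment_regions(
    sites,
    window_sites: int = 10,
    min_support_fraction: float = 0.5,
    require_homozygous_range: bool = False,
) -> list[LOHRegion]:
    """Aggregate ordered sites into per-chromosome LOH regions.

    A sliding window of ``window_sites`` consecutive informative sites is
    LOH-positive when the fraction of supporting sites is at least
    ``min_support_fraction``; overlapping positive windows merge into one
    region. Chromosomes with no positive window yield a single "no-LOH"
    region; chromosomes with fewer sites than the window yield
    "insufficient-data". Duplicate site records are collapsed first.
    """
    if window_sites < 1:
        raise ValueError("window_sites must be >= 1")
    by_chrom: dict[str, list[HetSite]] = {}
    seen = set()
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        if (s.chrom, s.pos) in seen:
            continue
        seen.add((s.chrom, s.pos))
        by_chrom.setdefault(s.chrom, []).append(s)

    regions: list[LOHRegion] = []
    for chrom, chrom_sites in sorted(by_chrom.items()):
        n = len(chrom_sites)
        support = [
            call_site_loh(s, require_homozygous_range=require_homozygous_range)
            for s in chrom_sites
        ]
        if n < window_sites:
            regions.append(
                LOHRegion(
                    chrom=chrom,
                    start=chrom_sites[0].pos,
                    end=chrom_sites[-1].pos,
                    n_sites=n,
                    n_supporting=sum(support),
                    status="insufficient-data",
                )
            )
            continue
        # indices of sites covered by any LOH-positive window
        flagged = [False] * n
        needed = min_support_fraction * window_sites
        running = sum(support[:window_sites])
        for i in range(n - window_sites + 1):
            if i > 0:
                running += support[i + window_sites - 1] - support[i - 1]
            if running >= needed:
                for j in range(i, i + window_sites):
                    flagged[j] = True
        any_loh = False
        i = 0
        while i < n:
            if not flagged[i]:
                i += 1
                continue
            j = i
            while j < n and flagged[j]:
                j += 1
            members = chrom_sites[i:j]
            regions.append(
                LOHRegion(
                    chrom=chrom,
                    start=members[0].pos,
                    end=members[-1].pos,
                    n_sites=j - i,
                    n_supporting=sum(support[i:j]),
                    status="LOH",
                )
            )
            any_loh = True
            i = j
        if not any_loh:
            regions.append(
                LOHRegion(
                    chrom=chrom,
                    start=chrom_sites[0].pos,
                    end=chrom_sites[-1].pos,
                    n_sites=n,
                    n_supporting=sum(support),
                    status="no-LOH",
                )
            )
    return regions


def gene_second_hit(
    regions,
    somatic_variants,
    gene_interval: tuple[str, int, int],
    germline_mutation_pos: int | None = None,
) -> list[str]:
    """Classify the somatic 'second hit' over a gene in a germline carrier.

    Returns the applicable calls in priority order — ``["somatic_mutation"]``
    if a high/moderate-impact somatic variant falls inside the gene,
    ``["LOH"]`` if an LOH region overlaps the gene, both (somatic first)
    when both occur, and ``[]`` (meaning none) otherwise.

    ``gene_interval`` is (chrom, start, end), 0-based half-open.
    ``germline_mutation_pos`` is informational (the carrier's germline hit);
    it does not change the classification.
    """
    chrom, start0, end0 = str(gene_interval[0]), int(gene_interval[1]), int(gene_interval[2])
    calls: list[str] = []
    for v in somatic_variants:
        if v.impact in ("high", "moderate") and str(v.chrom) == chrom and start0 < v.pos <= end0:
            calls.append("somatic_mutation")
            break
    for r in regions:
        if r.status == "LOH" and r.overlaps(chrom, start0, end0):
            calls.append("LOH")
            break
    return calls


def sites_to_dataframe(sites):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "germline_vaf": [s.germline_vaf for s in sites],
            "somatic_vaf": [s.somatic_vaf for s in sites],
            "supports_loh": [s.supports_loh for s in sites],
        }
    )


def plot_sites(sites, path, title: str = "") -> None:
    """Per-chromosome scatter of tumor VAF at germline-het sites.

    Supporting sites are highlighted; the plot mirrors a per-site LOH
    evidence track along the chromosome.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = sites_to_dataframe(sites)
    chroms = sorted(df["chrom"].unique()) if len(df) else []
    fig, axes = plt.subplots(
        max(len(chroms), 1), 1, figsize=(8, 2.2 * max(len(chroms), 1)), squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = df[df["chrom"] == chrom]
        colors = ["crimson" if s else "steelblue" for s in sub["supports_loh"]]
        ax.scatter(sub["pos"], sub["somatic_vaf"], c=colors, s=12)
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.set_ylim(0, 1)
        ax.set_ylabel("tumor VAF")
        ax.set_title(f"{title} chr{chrom}".strip())
    axes.ravel()[-1].set_xlabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
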