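# Methods

This note documents the models and procedures `sebsig` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter at the edges.

## Variant selection and burden

Somatic SNVs must be reported by both of two independent callers (matched
exactly on chrom/pos/ref/alt after splitting multi-allelic records), then
pass a minimum depth of 40 reads and a minimum VAF of 10% — both read as
inclusive thresholds (≥), the plain meaning of "minimum" — and fall
inside the capture region. A 1-based position *p* lies in a BED interval
[s, e) iff s < p ≤ e. Indels come from a single caller, skip the
intersection, and pass the same depth/VAF/capture filters. For
intersected records, depth and allele counts are taken from caller A by
default (configurable); with two callers there is no principled winner,
so the choice is documented rather than guessed.

Tumor mutational burden is filtered SSNVs per megabase of the merged
capture BED. The bundled cohort table carries an implied capture size of
67.25 Mb, back-derived from its load/TMB ratios; it reproduces all six
TMB values at the printed one-decimal precision and is a test fixture,
not a pipeline constant — real runs always derive the denominator from
the supplied BED.

VAF is computed from the AD sample field when present, else from AF × DP,
else the record is rejected. That precedence is fixed and deliberate: AD
is the primary evidence, AF a derived fallback.

## 96-context catalog

Each SNV is classified by its substitution and flanking bases, collapsed
to the pyrimidine-reference strand (purine references are
reverse-complemented together with their flanks). Bin order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with flank pairs
alphabetical within each class — the row order of the standard signature
tables, which the refit assumes. SNVs with non-ACGT flanks are tallied as
unclassifiable, never raised, so catalog total + unclassifiable always
equals the SNV input count. No exome-to-genome trinucleotide
renormalization is applied (none is part of the published workflow this
mirrors); the catalog is used as observed.

## Signature refitting

The refit finds nonnegative exposures *w* over a fixed 30 × 96 signature
matrix maximizing the cosine similarity between the catalog frequency
vector and the reconstruction *wᵀS*. The algorithm is greedy forward
selection: from the empty model, each iteration evaluates every candidate
signature, finding by golden-section search on [0, 1] (tolerance 1e-4)
the convex blend weight α that maximizes the objective for
(1−α)·current + α·candidate; the best candidate is accepted only if it
improves the objective by more than 1e-4, with ties broken toward the
lowest signature index. Cosine similarity is scale-invariant, so the
convex-blend parameterization loses no generality. After convergence,
exposures below 0.06 are zeroed (the conventional discard floor for
refitting tools) and the remainder renormalized to sum to one; the
reported cosine is computed on the floored reconstruction and can sit a
hair below the last accepted iteration's value. A sum-of-squares
objective is available via `RefitConfig(objective="sse")` and agrees
closely on clean mixtures. An all-zero catalog is refused; if flooring
empties the model, the single best-cosine signature is reported with
weight 1.

The packaged signature matrix is **synthetic**: a deterministic Dirichlet
construction (fixed seed, regenerable with
`sebsig.resources.synthetic_signature_matrix`) with sparse, well-separated
rows (maximum pairwise cosine ≈ 0.54) and thematic structure for the
signatures the analysis names — CpG-restricted C>T for signature 1,
distinct C>T-rich profiles for 6 and 15, 5'-T C>T for 7, C>A-rich rows
for 4 and 29. The published 30-signature table is not redistributed;
passing it as a TSV (contexts × signature columns) reproduces the refit
against real signatures. All recovery guarantees quantified in the tests
(mean absolute exposure error, oracle-gap bounds) are statements about
this matrix's separation; closely correlated real signature pairs (e.g.
flat signatures) will refit with more cross-talk than the synthetic rows
do.

## LOH calling

Informative sites are germline variants with VAF in [0.3, 0.7]
(inclusive), paired with the tumor VAF at the same locus; the tumor VAF
comes from the tumor caller's records (including non-PASS
germline-tagged records, the way somatic callers report het evidence),
and sites with no tumor record are dropped and tallied — without
alignments, absence of a record cannot be distinguished from absence of
coverage. A site supports LOH when |tumor VAF − germline VAF| > 0.3,
strictly. On a single VAF axis this absolute-difference test is exactly
the union of the two directional readings (shift toward homozygous
reference or homozygous alternative). The strict boundary is protected
against binary round-off (0.8 − 0.5 evaluates one ulp above 0.3; the
implementation treats it as exactly 0.3, i.e. not supporting). An
optional stricter mode additionally requires the tumor VAF itself to
leave [0.3, 0.7]; the default is shift-only.

Site evidence is aggregated with a 10-site sliding window calling a
window positive at ≥ 50% supporting sites, merging overlapping positive
windows into regions. The windowing rule and its parameters are this
package's own (the per-site evidence plot is the primary output);
both are exposed as arguments. Chromosomes with fewer sites than the
window report "insufficient-data". The second hit over a gene is
"somatic_mutation" when a high/moderate-impact somatic variant falls in
the gene interval, "LOH" when an LOH region overlaps it, both (somatic
listed first) when both occur.

## Microsatellites and MSI

The locus scan reports maximal tandem runs of primitive 1–5 bp motifs:
homopolymers at ≥ 5 copies and longer units at ≥ 3 copies by default
(common scan settings for MSI tooling), resolving overlaps in favour of
the smaller unit, deterministically left to right. The MSI score is the
percentage of scanned loci whose interval intersects at least one somatic
indel's reference-affected span (for insertions, the single anchor base —
chosen so an insertion inside a run intersects it). This is a declared
call-level **proxy** for read-level MSI callers, which test per-locus
repeat-length distributions from alignments; the bundled cohort's
read-level scores are therefore inputs to the group comparison, not
quantities this proxy reproduces. Exonic microsatellite indels are
counted once per indel when the affected span overlaps both a locus and
an exon interval. A panel gene is reported "Frameshift" when an indel of
length not divisible by 3 overlaps its coding-microsatellite interval.

## Group statistics

Group summaries are arithmetic mean and n−1 standard deviation (the
n−1 choice is validated in-tests: the per-lesion combined-signature
values 39/50/34 give SD 8.2, matching the published figure, where the
population SD would give 6.7). The test is the pooled-variance two-tailed
Student's *t* with df = n₁+n₂−2, which reproduces all four published
p-values (0.03, 0.0018, 0.052, 0.08) from the per-sample values and
summaries; Welch's form is available behind a flag. Either group may be
given as raw values or as an (n, mean, SD) summary — the two entry points
agree exactly, and the summary path is what allows comparing against a
group published only as mean ± SD. Two equal constant groups return
t = 0, p = 1; zero pooled variance with unequal means returns p = 0 with
a degeneracy flag.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
per sample: a random reference (selectable GC fraction, default 0.41)
with planned microsatellite runs embedded verbatim and flank-broken so
each planned locus is maximal; germline hets with binomial(depth, 0.5)
allele counts; tumor SNVs drawn multinomially from a known signature
mixture and placed at reference positions whose trinucleotide context
matches, searching both strands — the reference is never edited, which
forces correct strand collapsing downstream; two pseudo-caller VCFs with
a controlled shared fraction (the remainder alternating between
callers); ±1-unit microsatellite indels at truth loci at a controlled
per-locus rate, emitted by the indel-capable caller only; and tumor-side
records at germline het sites written as FILTER=germline lines in caller
A's VCF, mirroring how unfiltered somatic callers report germline
evidence.

Defaults are the study conditions the tests exercise: mean depth 80
(the cohort's germline-side coverage scale), 200 germline hets, 10,000
SNVs for refit recovery and 1,000 for end-to-end runs, and the
MMR-deficient-scale mixture 0.59/0.31/0.10 over signatures 1/6/15
(combined 6+15 = 0.41). Inside an LOH segment the tumor allele fraction
at het sites is set to 0.90 for the retained allele (0.10 for the lost
one), modelling complete allelic loss at ~80% tumor purity: at depth 80
the binomial noise on a VAF difference is ≈ 0.069 SD, so a true shift of
0.40 is called (> 0.3) with probability ≈ 0.94, while a marginal 0.35
shift would be missed nearly a quarter of the time — the target is
placed where complete LOH is recoverable without tuning the caller.
Simulated tumor SNVs are floored at depth 40 and observed VAF 0.2 so
they pass the published filters unless a test degrades them on purpose.
Everything is driven by one integer seed; identical spec + seed gives
byte-identical VCFs.

What the generator does **not** emulate: read-level data (no
FASTQ/BAM, hence no genuine coverage dropout or strand artifacts), FFPE
damage patterns, copy-number beyond the VAF-shift model of LOH, caller
disagreement in allele representation, and subclonal structure. Passing
tests therefore demonstrate correctness of the algorithms under the
assumed statistical model, not robustness to FFPE artifact modes or
caller idiosyncrasies in real exomes.

## Problem sizes in the checks

The standing checks use a 100 kb single-chromosome reference, 20-seed
replicates for the stochastic recovery claims (refit error, LOH
sensitivity/specificity), 10,000-SNV catalogs for exposure recovery, and
a 1,000-SNV pair for end-to-end conservation — sizes at which every
statistical property under test is already stable, as the seed-to-seed
spread in the acceptance output shows.

## Known limitations

* The MSI score is locus-overlap based; it is not comparable in absolute
  value to read-level MSI scores.
* Exposure recovery bounds are specific to the synthetic signature
  matrix's separation (see above).
* The LOH caller cannot see copy-neutral regions with no het-site
  records, and segmentation granularity is limited by het-site density.
* Impact annotation is consumed from an `IMPACT` INFO field when present;
  the built-in fallback rule used for synthetic data is deliberately
  minimal (it does not replace a full consequence predictor).
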