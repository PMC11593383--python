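# Methods

`rohscan` detects runs of homozygosity (ROH) on SNP-array genotypes by the
consecutive-runs method, derives the genomic inbreeding coefficient F_ROH,
and calls ROH islands by z-score outlier thresholding of per-SNP incidence.
This note describes the model, the parameters that matter, the numerical
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Consecutive-runs detection

Markers of one chromosome of one individual are scanned in positional
order.  A run is a maximal stretch of consecutive markers that contains at
most `max_het` heterozygous and `max_missing` missing calls, never has two
adjacent markers more than `max_gap_bp` apart (default 100,000 bp), and
starts and ends on a homozygous non-missing call.  A heterozygous or
missing call that would exceed its allowance terminates the run before that
call; scanning resumes after it.  Runs with fewer than `min_snp` markers
(default 15) or spanning less than the minimum length are discarded *after*
segmentation, so a too-short run still consumes its span.  This is the
consecutive scan in the tradition of Marras-style detectors (detectRUNS'
`consecutiveRUNS`), not a sliding-window method.

The scanner is implemented with cumulative event counts and binary search,
so each run boundary is located in O(log n); the test suite proves it
exactly equivalent to an independent brute-force window enumerator on
hundreds of random chromosomes.

Two properties of this semantics are worth knowing:

* **Over-extension.** A run keeps extending through stochastically
  homozygous background beyond a truly autozygous tract until its
  allowances run out, typically a handful of markers on each side at
  realistic background heterozygosity (~35%).  Boundary accuracy is
  therefore assessed *inward* (markers of the true tract missed), never
  outward.
* **Non-monotone coverage.** Raising `max_het`/`max_missing` enlarges the
  set of feasible windows (a true monotone invariant, tested as such) but
  can *reduce* total covered bp of the left-greedy segmentation: a longer
  first run shifts the resume point and can strand a later stretch.  This
  is a property of consecutive scanning, not a defect of the
  implementation.

## Two-pass calibration of length-class allowances

ROH are grouped into five length classes (1–2, 2–4, 4–8, 8–16, >16 Mb;
half-open intervals, `length_bp = end − start`).  Pass 1 detects all
candidate runs above 1 Mb with permissive allowances (defaults: 12
heterozygotes, 8 missing — the most permissive final-class values, so pass
1 never under-segments relative to pass 2; configurable).  For each
populated class, allowances are calibrated from the pass-1 mean SNP count:

    max_het     = round(mean_snp_count × genotype_error_rate)   (default 0.25%)
    max_missing = round(mean_snp_count × missing_rate)          (default 0.14%)

floored at 1 (`min_allowance`, settable to 0).  "Average length" is read as
mean *SNP count*, not mean bp: at HD-chip density a >16 Mb class of ~5,000
SNPs × 0.0025 gives ~12 allowed heterozygotes, whereas a bp basis would
give thousands.  A bp basis remains available (`calibration_basis="bp"`)
for sensitivity analysis only.  The rounding rule defaults to round-half-up
`nearest`, with `floor` and `ceiling` options, because no single rule is
canonical.  Classes empty in pass 1 inherit the nearest populated class's
allowances with a warning.

Pass 2 re-scans each chromosome once per class with that class's
allowances and minimum length.  Every candidate is assigned to the class
matching its realized length; duplicates across scans are merged.
Overlapping candidates of one individual are reconciled so each genomic
stretch yields one segment: a candidate whose realized length falls inside
the class it was scanned for wins, ties broken by longer segment, then
fewer heterozygotes, then leftmost.  Each final segment honours the
allowances of the scan that produced it.

**Calibration caveat.**  The allowance `round(mean × rate)` sits near the
*median* of a Poisson event count with that mean.  If the true in-run
error/missing rates equal the assumed calibration rates, roughly half of
all true tracts in a class carry more events than the class allows and
fragment.  On real arrays the assumed 0.25% is a deliberately conservative
bound — actual error rates are an order of magnitude lower — so the
allowances are generous in practice.  The synthetic validation, which
plants events *at* the assumed rates as specified, probes exactly this
worst case; see "What the synthetic tests show" below.

## F_ROH

For one individual, `F_ROH = Σ length_bp(ROH) / genome_length_bp`.  The
default denominator is the map-covered autosomal length — the sum over
autosomes of (last − first SNP position) — so numerator and denominator
refer to the same chip; a fixed assembly length can be supplied instead.
Samples with no ROH get F_ROH 0; samples removed by QC appear in no
record.  A per-class partition (`by_class=True`) is provided for
ancient-vs-recent inbreeding displays; no inferential claim is attached to
it.  Only chromosome labels parseable as positive integers (autosomes)
enter ROH scans and the denominator.

## ROH islands

For each population, the per-SNP incidence is the share of individuals
with at least one ROH covering the SNP (segments of one individual never
overlap, so summing segment indicators counts individuals).  Incidence
percentages are standardised with the mean and sd over *all* autosomal
SNPs of that population (population sd, ddof 0; per-chromosome
normalisation is available as an option).  SNPs in the extreme upper tail
of the standard normal — one-sided p < `tail_fraction`, default 1e-5,
i.e. z ≥ 4.2649 — are significant; the upper tail is the relevant one
because islands are high-homozygosity outliers (a two-sided switch
exists).  Uniform incidence (sd = 0) yields no islands and a warning.

Consecutive significant SNPs at most `merge_gap_bp` apart (default
500 kb) merge into an island; bounds are the first/last significant SNP
positions; islands with fewer than `min_island_snps` (default 2)
significant SNPs are dropped.  Both the significant-SNP count and the
total marker count within the bounds are reported, since the field's
"nSNP" convention is ambiguous between the two.  The per-population
threshold percentage is the minimum incidence attained by any significant
SNP.

Islands from different populations whose bp spans overlap on one
chromosome (transitively, any ≥1 bp overlap) are grouped into shared
regions labelled with the set of member populations ("All" when every
analysed population contributes).  A long-form membership table preserves
per-population island counts exactly: counts summed over populations equal
the number of region memberships, an identity the tests assert.

Note that the z-score threshold is *relative* to a population's own
incidence distribution: a population carrying several large islands
inflates its sd and can mask islands that a cleaner population would call.
This is inherent to the thresholding rule and visible in the synthetic
tests when planted islands occupy more than a few percent of the map.

## Quality control

Markers with missing fraction > `--geno` (default 0.1) are removed first;
samples with missing fraction > `--mind` (default 0.1), computed on the
surviving markers, second — the order used by the standard tool, and it
matters (tested on a constructed case).  No minor-allele-frequency filter
is ever applied: rare alleles are informative for homozygosity runs.  QC
is pooled across populations by default, with a per-population variant
(marker dropped if it fails within any one population) available, since
the convention is not universal.

## Synthetic data generator

The generator emulates the structure the pipeline assumes: multi-
chromosome biallelic maps at ~280 SNPs/Mb (HD-chip density), Hardy–
Weinberg background genotypes with SNP-independent allele frequencies
uniform on [0.05, 0.95], autozygous tracts planted directly as homozygous
stretches (the shared allele drawn by frequency), heterozygous genotyping
errors inside tracts at 0.25%, genome-wide missingness at 0.14%, and
island regions where a configurable fraction of a population carries one
shared span (optionally jittered).  Tracts are specified per length class,
as exact lengths, or via a target autozygous genome fraction; in fraction
mode lengths are drawn uniform on 2–16 Mb — the length range that
dominates genomic coverage of autozygosity — and the last tract is trimmed
to hit the target exactly.

Deliberately absent: linkage disequilibrium (detection uses no LD
information), pedigree/coalescent structure, and chip intensity artifacts.
Ground truth records every tract, carrier, error and missing call, and the
generator is byte-reproducible from its seed.

## What the synthetic tests show — and do not

Green across the suite: exact equivalence of the scanner with an
independent enumerator; the calibration arithmetic (mean SNP counts 420 /
840 / 1570 / 3000 / 5600 with the 0.14% missing rate give the allowance
ladder 1, 1, 2, 4, 8); island recovery (a span autozygous in 60% of 50
individuals against a few-percent background is called in 20/20 seeded
replicates at z ≥ 4.2649); the island bookkeeping identity; F_ROH
population ranking; and recovery of planted tracts with exact
classification when error rates are zero.

Measured and reported honestly rather than asserted: with errors planted
*at* the 0.25%/0.14% calibration rates, single-segment recovery of ≥2 Mb
tracts is ~15% and union-of-segments edge recovery ~44%, and planted
autozygous fractions 0.02/0.12 are recovered as ≈0.018/≈0.107 — the
calibration-caveat regime described above, in which allowances sit at the
event-count median and the left-greedy scan enters tracts with partially
spent budgets.  Recovery on real arrays, whose error rates are far below
the assumed bound, is correspondingly better (error-free synthetic runs
recover every tract whole), but the synthetic suite cannot demonstrate
that directly.

## Problem sizes

Validation runs use 50 individuals over 2 × 50 Mb chromosomes at 280
SNPs/Mb (tract recovery, F_ROH), 20 replicates of 50 individuals over 40
Mb (islands), and 100 random chromosomes of ≤200 markers (oracle
equivalence) — sizes chosen so every property is exercised at HD density
while the whole suite stays interactive.

## Known limitations

* Text `.ped` round-trips preserve homozygous/heterozygous/missing status
  but can swap the two homozygous labels at markers where one allele is
  unobserved (the format carries no allele-order metadata); the binary
  dialect round-trips codes exactly.
* Gene annotation is offline-only, against a user-supplied BED/TSV
  snapshot (BED converted from 0-based half-open to the internal 1-based
  inclusive convention); coordinates are treated as opaque and
  assembly-agnostic.
* No sliding-window detection mode, heterozygosity-rich regions, VCF
  input, LD pruning, or pedigree-based inbreeding.
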