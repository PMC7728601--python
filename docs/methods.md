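# Methods

This note documents the models, defaults and numerical choices behind each
component, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Ancestry painting

**Model.** A hybrid cultivar genome is a mosaic of segments inherited from
two progenitor species.  Against each progenitor, windows inside
same-ancestry segments show divergence near the intraspecific scale, while
windows of the other ancestry show roughly the sum of intra- and
interspecific divergence.  Classification therefore needs only the two
window divergences, no haplotype model.

**Divergence.** Observed mismatch proportions *p* (non-ACGT columns are
expected to be excluded upstream) are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − 4p/3), implemented with `log1p` for accuracy at
small *p*; *p* ≥ 0.75 raises a saturation error in scalar use and yields an
undefined window in the table path.

**Thresholds** (all configurable via `ClassificationThresholds`):

| parameter | default | meaning |
|---|---|---|
| `max_assignable_divergence` | 0.014 | the *smaller* divergence must be strictly below this |
| `min_difference` | 0.002 | the two divergences must differ by strictly more |
| `min_aligned` | 100 bp | windows with less alignment are undefined |
| `both_bounded` | False | if True, also bound the larger divergence |

Comparisons are strict; boundary equality yields `unclear` (conservative).
The bound applies to the winning (smaller) divergence only, because that is
the value the assignment is based on; `both_bounded` is provided for the
stricter reading.

**Windowing.** Block counts are pro-rated over the windows a block spans
proportionally to overlap length, rounded half-up.  Terminal partial windows
are kept and classified if they meet `min_aligned`.  All origin fractions
are weighted by window bp, not window count, matching the "% of genome"
interpretation.  Same-query blocks covering the same target bp twice get
first-(leftmost-)block precedence with a warning.

**Tracts and summaries.** Maximal same-call runs merge into tracts; a
junction between tracts of different origin is emitted as a 1-bp BED
interval (the mosaic is only resolved to window precision, so the junction
coordinate, not an uncertainty interval, is reported).  The diploid hybrid
fraction is reported with the full windowed extent as denominator, and
additionally as `fraction_hybrid_of_resolved` over fully resolved windows
only, since both denominators are defensible.

**Smoothing.** `smooth_divergence` wraps LOWESS (tricube-weighted local
linear regression, default span 2% of windows) for display; classification
never uses smoothed values.

## Population genetics

π per site uses the unbiased pairwise estimator 2p̂q̂·n/(n−1) over the
non-missing haplotypes at that site, summed and divided by the *full* window
length in bp (VCFtools convention; windows, not accessible sites, are the
denominator).  Tajima's D uses the classical constants computed from the
full haplotype count 2N; windows with fewer than 3 segregating sites or
fewer than 4 haplotypes are flagged NaN, never dropped.  With missing data
the D statistic is therefore approximate; the test oracles use complete
matrices.

Percentages (allele frequency, genotype classes) are rounded to one decimal,
half away from zero — the convention that reproduces printed values such as
55.6 from 40/72.

The p-distance between samples is Σ|gᵢ−gⱼ|/2 over sites where both are
called, divided by the number of such sites (pairwise deletion maximises
data use).  Heterozygote–heterozygote pairs contribute 0, a declared
convention; VCF2Dis-style tools may differ in this cell.

Neighbor joining follows Saitou–Nei with the Q-criterion; ties break on the
lowest node-creation-order pair, so results are deterministic.  Negative
branch lengths are clamped to zero with the deficit moved to the sibling
branch, preserving the joined pair's path length.  On additive matrices no
clamping triggers and the generating metric is recovered exactly.

## Pan-genome PAV

Absence means covered fraction strictly below 0.20 at depth ≥ 2; exactly 20%
is present.  Orthogroup presence is the any-member rule.  Pan/core curves
are medians (quantiles also reported) over random accession orderings —
medians by default since means are dominated by early orderings; the
permutation count is configurable.

The power-law form P(N) = A·N^γ + C is fitted by nonlinear least squares,
grid-initialised over γ ∈ (0, 1.5] and bounded (|A| ≤ 10·scale,
γ ∈ [10⁻³, 1.5], C ∈ [min(0, min y), 2·max y]) to exclude the degenerate
A → +∞, C → −∞ logarithmic limit that otherwise wins on nearly saturated
curves.  Closedness is flagged when γ < 1 and the fitted end slope
A·γ·N^(γ−1) is below 0.5 genes/accession.  Known limitation: a curve that
saturates exponentially is not a power law, and the fitted end slope can
overestimate the true tail increment, making the flag conservative
(open-biased) on strongly core-dominated matrices.

Favored orthogroups: three pairwise Fisher exact tests per group
(dom–sie, dom–syl, syl–sie), BH-corrected per pair family across groups.
Categories are declared rules: `dom_syl_vs_sie` needs domestica > sieversii
and sylvestris > sieversii both significant; `dom_sie_vs_syl` mirrored;
`dom_only` needs domestica enriched against both wild species and neither
shared pattern; anything else is `none`.

Segment deduplication is a declared CD-HIT *approximation*: greedy
longest-first clustering with a k-mer containment screen and a local
alignment verify (≥ 90% identity over ≥ 90% of the candidate); bit
compatibility with CD-HIT is not claimed.

## Allele-specific expression

Read assignment: a read must align uniquely to the same chromosome in both
haplomes; it is assigned to the haplome with better score and no more
mismatches, at least one strictly better.  Requiring both strictly better
(`strict_both=True`) is available since the conjunction is ambiguous in
prose descriptions of this rule.  Alignment-ambiguous reads fall through to
a majority vote over the phased SNPs they overlap (ties ambiguous, bases
matching neither allele skipped).  Each read ends up assigned exactly once
or ambiguous — never double-counted.

Phasing: a heterozygous biallelic SNP phases directly when both haplome
assemblies show distinct alleles of the call; with one haplome observed, the
other is imputed as the remaining allele; contradictions are dropped.

The ASE test is a Wald test on the log allelic ratio under a
negative-binomial model: per gene × stage, allele means across replicates,
shared method-of-moments dispersion α = max(0, (s²−m)/m²) averaged over the
two alleles, and Var(log μ̂) ≈ (1/n)(1/μ + α) by the delta method.  The
eligibility rule is strict: every replicate's total (A+B) must exceed 10.
BH correction is applied across genes *within* a stage; stages are separate
contrast families and are not additionally corrected.  Significance requires
both adjusted p < α and observed |log₂ ratio| > 1 — the fold criterion is
applied to the raw (pseudo-count 0.5) ratio, not a model estimate, so a
precise but tiny imbalance never counts as ASE.  With a single replicate the
test degrades to an exact binomial test with a warning; biological variance
is then unmodelled.  Dominance classes (consistent-A/B, switching,
single-stage) use only stages with significant calls.

## Rate conversions

All closed forms: µ = D/2T (divergence accrues on both branches), LTR age =
d/2µ (twin LTRs are identical on insertion and diverge on two branches),
and PSMC scaling N₀ = θ₀/(4µs), yearsₖ = 2N₀·g·tₖ, Neₖ = N₀·λₖ with bin size
s (default 100 bp) and generation time g (default 7.5 years, typical of
apples).  The scaling follows standard PSMC output semantics: t in units of
2N₀ generations, λ relative to N₀.

## Synthetic data: what it emulates, and what it does not

The generators state a world and keep it fixed:

* Progenitor pair: random ancestor, each branch substituting at the rate r
  solving 2r(1−r) + (2/3)r² = D so the expected tip-to-tip p-distance equals
  the target exactly (double hits accounted for).  Defaults D = 0.014
  interspecific; intraspecific drift 0.006 (not directly printed for this
  system; inferred from the ~0.8% mean same-origin window divergence and
  kept configurable).
* Mosaic diploid: alternating-origin tracts with geometric (memoryless)
  lengths, mean 2 Mb by default — a scale giving a handful of switches per
  10-Mb chromosome, matching the visual block structure of painted
  cultivars; drift is applied independently per haplome, so same-origin
  haplome pairs diverge at ~2× the intraspecific rate.
* Window observations (fast path): binomial mismatch counts at the
  composition-weighted rates, with cross-species proportions convolved as
  p₁ + p₂ − (4/3)p₁p₂.
* PAV coverage: covered fractions drawn directly (Beta around the
  Poisson-depth expectation 1 − e^(−λ)(1+λ) for present genes, below 0.18
  for absent ones) — the PAV rule consumes only the fraction, so no read
  placement is simulated.
* ASE counts: negative binomial with dispersion 0.05 (typical RNA-seq
  scale), total depth split by the true allelic ratio; 13 stages × 3
  replicates by default, with per-stage overrides for designs with 2 early
  replicates.
* Genotypes: exact fixture mode (reproduces requested genotype counts) and
  Hardy–Weinberg mode.

All randomness derives from one integer seed via documented
(seed, stream-id) substreams, so identical seeds give bit-identical outputs
and generators never perturb one another.

Not emulated: indels and structural variants, alignment gaps/coverage
dropouts in the window path, read-level sequencing error, linkage
disequilibrium between genotype sites, expression correlation across stages.
A green recovery test therefore establishes that the *statistical rules*
behave as specified under their stated assumptions — not that the pipeline
is robust to alignment artefacts or demographic structure absent from the
generator.

## Numerical conventions

Coordinates are 0-based half-open everywhere internally; BED on output;
1-based only in VCF.  Mismatch pro-rating rounds half-up; reported
percentages round half away from zero.  Undefined statistics (Tajima's D,
saturated divergences, empty pairs) are NaN, never silently dropped.
Fisher, Mann–Whitney (tie-corrected, exact for groups ≤ 20) and BH
correction are delegated to scipy/statsmodels; π, Tajima's D, Jukes–Cantor,
neighbor joining and the NB Wald test are implemented here and
cross-checked against enumeration oracles and independent libraries in the
test suite.
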