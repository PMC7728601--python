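# malus

Analysis toolkit for dissecting the genomes of hybrid-origin crops, built
around the questions raised by apple domestication: how much of a cultivar's
diploid genome descends from each wild progenitor species, which genes were
gained or lost across populations, and how the two alleles of a
haplotype-resolved genome behave transcriptionally.

The motivating system is the cultivated apple (*Malus domestica*) and its two
wild progenitors, *M. sieversii* and *M. sylvestris*, but every component is
parameterised and works on any two-progenitor design.

## What it does

**Ancestry painting** (`malus.ancestry`).  Whole-genome alignment blocks
projected onto a target genome are accumulated into non-overlapping windows
(default 50 kb).  Per window, the mismatch proportion *p* against each
progenitor is corrected to a divergence *d* = −(3/4)·ln(1 − 4*p*/3)
(Jukes–Cantor), and the window is assigned to the progenitor with the smaller
*d*, provided that *d* < 1.4% and the two divergences differ by more than
0.2%; otherwise it is `unclear`.  Runs of same-origin windows merge into
ancestry tracts whose boundaries are candidate recombination sites.  Diploid
summaries report the *hybrid fraction*: the share of the genome where the two
haplomes carry different ancestries.

**Population genetics** (`malus.popgen`).  GATK-style hard filters and
VCFtools-style population filters (MAF ≥ 0.05, QUAL ≥ 30, ≤ 10% missing);
per-population allele frequencies and genotype-class proportions; sliding
windows (20 kb / 1 kb step) of nucleotide diversity
π = Σ 2*p̂q̂·n/(n−1) / window bp and Tajima's
D = (π − S/a₁)/√(e₁S + e₂S(S−1)); dosage p-distance matrices with pairwise
deletion; Saitou–Nei neighbor joining.

**Pan-genome PAV** (`malus.pangenome`).  A gene is absent in an accession
when < 20% of its CDS is covered by ≥ 2 reads.  Gene calls collapse to
orthogroups (present if any member is), feed permutation pan/core curves
modelled as P(N) = A·N^γ + C, and species-favored orthogroups are detected
with pairwise Fisher exact tests under Benjamini–Hochberg correction.

**Allele-specific expression** (`malus.ase`).  Reads are assigned to a
haplome by alignment score/mismatch comparison, falling back to a majority
vote over phased heterozygous SNPs.  Replicated allele counts are tested per
gene and stage with a negative-binomial Wald test (method-of-moments
dispersion); a gene shows ASE when the BH-adjusted p < 0.05 **and** the
observed allelic ratio exceeds twofold.  Dominance profiles across stages
and the two interpretation tests (hybrid-ancestry enrichment, upstream-SV
proximity) are included.

**Rates** (`malus.rates`).  µ = D/2T, LTR insertion age = d/2µ, and PSMC
output scaling N₀ = θ₀/(4µs), years = 2N₀·g·t.

**Synthetic data** (`malus.simulate`).  Seeded generators produce every
input the analyses consume — progenitor pairs at 1.4% divergence, diploid
mosaic hybrids with 0.6% intraspecific drift, window observations, PAV
coverage with planted absences, replicated allele counts over the 13-stage
fruit series, and genotype fixtures — together with the ground truth needed
to score recovery.

## Worked example

```bash
python examples/ancestry_painting.py
```

```
per-haplome origin fractions (bp-weighted):
  haplome A: sieversii 0.360, sylvestris 0.640, unclear 0.000
  haplome B: sieversii 0.485, sylvestris 0.515, unclear 0.000
diploid hybrid fraction: 0.425 (planted truth 0.421)
haplome A: 5 ancestry tracts, 4 candidate recombination sites
```

A 10-Mb diploid mosaic is simulated with known tract structure and painted
back from 50-kb window divergences alone.  The per-haplome fractions say how
much of each haplome descends from each progenitor; the hybrid fraction
(42.5% recovered vs. 42.1% planted) is the share of the genome whose two
alleles descend from *different* progenitors — the quantity that makes a
cultivar a living hybrid archive.  The other scripts in `examples/` walk
through the population-genetic, pan-genome, ASE and rate-conversion
components the same way.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the main computations of every component from scratch on seeded
synthetic inputs — mosaic painting with truth comparison, rate conversions,
windowed diversity and NJ tree construction, pan/core curve fitting with
favored-orthogroup detection, and ASE calling — printing a one-line summary
per stage and writing the results manifest to `--out`.
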