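"""Synthetic data generators emulating a hybrid-crop study design.

Every downstream analysis in this package consumes standard tabular or
sequence inputs; the generators here produce those inputs with the
statistical structure the analyses assume, together with the ground truth
needed to score them.  The stated world:

* two progenitor species at ~1.4% interspecific divergence (substitutions
  only, A/C/G/T alphabet),
* a diploid hybrid whose haplomes are recombinant mosaics of the two
  ancestries with ~0.6% intraspecific drift per haplome,
* read-coverage profiles over genes with planted absences (for PAV calling),
* replicated allelic count tables over 13 fruit developmental stages with
  planted imbalance (for ASE calling), and
* population genotype matrices with exactly specified genotype counts or
  Hardy-Weinberg draws.

All randomness derives from a single integer seed; each generator consumes a
documented, disjoint ``(seed, stream-id)`` stream, so identical seeds give
bit-identical outputs and the generators never perturb one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from malus.ancestry import ORIGINS, SIEVERSII, SYLVESTRIS
from malus.popgen import GenotypeMatrix

# documented RNG stream identifiers (second word of the rng seed sequence)
_STREAM_ANCESTRAL = 1
_STREAM_BRANCH_SIE = 2
_STREAM_BRANCH_SYL = 3
_STREAM_MOSAIC = 4
_STREAM_DRIFT_A = 5
_STREAM_DRIFT_B = 6
_STREAM_WINDOW_OBS = 7
_STREAM_PAV = 8
_STREAM_ASE = 9
_STREAM_GENO = 10

#: fruit developmental stages in days after full bloom
DAF_STAGES = (11, 17, 29, 36, 43, 50, 57, 64, 71, 85, 99, 113, 127)

__all__ = [
    "DAF_STAGES",
    "SimulationConfig",
    "MosaicTruth",
    "ProgenitorPair",
    "simulate_progenitor_pair",
    "simulate_hybrid_diploid",
    "simulate_mosaic_truth",
    "simulate_window_observations",
    "simulate_pav_coverage",
    "simulate_ase_counts",
    "simulate_genotype_matrix",
    "combine_mismatch_proportions",
    "p_distance",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SimulationConfig:
    """World parameters for the mosaic-genome generators.

    interspecific_divergence is the target p-distance between the two
    progenitor sequences (default 0.014, the apple scale); the
    intraspecific_divergence (default 0.006) is the drift applied to each
    hybrid haplome relative to its source progenitor.  Tract lengths are
    geometric with mean ``tract_length_mean`` bp.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 1
    interspecific_divergence: float = 0.014
    intraspecific_divergence: float = 0.006
    tract_length_mean: int = 2_000_000
    window_size: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("interspecific_divergence", "intraspecific_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.tract_length_mean < self.window_size:
            raise ValueError("tract_length_mean must be >= window_size")

    def chromosome_sizes(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        sizes = {}
        for i in range(self.n_chromosomes):
            extra = self.genome_length % self.n_chromosomes if i == self.n_chromosomes - 1 else 0
            sizes[f"chr{i + 1}"] = base + extra
        return sizes


class ProgenitorPair(NamedTuple):
    ancestral: dict[str, np.ndarray]
    sieversii: dict[str, np.ndarray]
    sylvestris: dict[str, np.ndarray]
    substitution_map: pd.DataFrame


@dataclass(frozen=True)
class MosaicTruth:
    """Ground-truth ancestry tracts of a simulated diploid.

    ``tracts`` columns: haplome (A/B), chrom, start, end (0-based half-open),
    origin.  Tracts tile each chromosome of each haplome without overlap.
    """

    tracts: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for (hap, chrom), grp in self.tracts.groupby(["haplome", "chrom"]):
            grp = grp.sort_values("start")
            if grp["start"].iloc[0] != 0 or grp["end"].iloc[-1] != self.chrom_sizes[chrom]:
                raise ValueError("truth tracts must span each chromosome")
            if not (grp["end"].iloc[:-1].to_numpy() == grp["start"].iloc[1:].to_numpy()).all():
                raise ValueError("truth tracts must tile without gaps or overlap")

    def origin_fractions(self, haplome: str) -> dict[str, float]:
        sub = self.tracts[self.tracts["haplome"] == haplome]
        bp = (sub["end"] - sub["start"]).to_numpy(float)
        total = bp.sum()
        return {
            o: float(bp[(sub["origin"] == o).to_numpy()].sum() / total) for o in ORIGINS
        }

    def hybrid_fraction(self) -> float:
        """Fraction of the genome where the two haplomes carry different
        ancestries, by exact interval sweep."""
        hybrid_bp = 0
        total = sum(self.chrom_sizes.values())
        for chrom, size in self.chrom_sizes.items():
            segs = {}
            for hap in ("A", "B"):
                sub = self.tracts[
                    (self.tracts["haplome"] == hap) & (self.tracts["chrom"] == chrom)
                ].sort_values("start")
                segs[hap] = list(zip(sub["start"], sub["end"], sub["origin"]))
            cuts = sorted(
                {0, size}
                | {s for s, _, _ in segs["A"]} | {e for _, e, _ in segs["A"]}
                | {s for s, _, _ in segs["B"]} | {e for _, e, _ in segs["B"]}
            )

            def origin_at(hap_segs, pos):
                for s, e, o in hap_segs:
                    if s <= pos < e:
                        return o
                return None

            for lo, hi in zip(cuts[:-1], cuts[1:]):
                if origin_at(segs["A"], lo) != origin_at(segs["B"], lo):
                    hybrid_bp += hi - lo
        return hybrid_bp / total

    def to_bed(self) -> pd.DataFrame:
        bed = self.tracts[["chrom", "start", "end"]].copy()
        bed["name"] = self.tracts["haplome"] + ":" + self.tracts["origin"]
        return bed


def _branch_rate(target: float) -> float:
    """Per-branch substitution probability r such that two branches mutating
    independently at rate r show an expected p-distance equal to ``target``.

    P(diff) = 2 r (1 - r) + (2/3) r^2 (two independent hits coincide with
    probability 1/3 under the equal-rates 4-letter model).
    """
    if target == 0:
        return 0.0
    # -(4/3) r^2 + 2 r - target = 0
    return (2.0 - math.sqrt(4.0 - (16.0 / 3.0) * target)) / (8.0 / 3.0)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site with probability ``rate``; mutated bases move to a
    uniformly chosen different letter.  Returns (mutated copy, hit indices)."""
    out = seq.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64)
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out, hits


def simulate_progenitor_pair(config: SimulationConfig) -> ProgenitorPair:
    """Evolve two progenitor genomes from a random ancestor.

    Each branch substitutes sites at the rate that makes the expected
    p-distance between the two tips equal ``interspecific_divergence``
    exactly (double hits accounted for).  The substitution map records every
    mutated site on both branches.
    """
    if config.interspecific_divergence >= 0.75:
        raise ValueError("divergence >= 0.75 is undefined under Jukes-Cantor")
    rate = _branch_rate(config.interspecific_divergence)
    anc_rng = _rng(config.seed, _STREAM_ANCESTRAL)
    rngs = {SIEVERSII: _rng(config.seed, _STREAM_BRANCH_SIE),
            SYLVESTRIS: _rng(config.seed, _STREAM_BRANCH_SYL)}
    ancestral, tips = {}, {SIEVERSII: {}, SYLVESTRIS: {}}
    records = []
    for chrom, size in config.chromosome_sizes().items():
        anc = anc_rng.integers(0, 4, size=size, dtype=np.uint8)
        ancestral[chrom] = anc
        for species in ORIGINS:
            tip, hits = _mutate(anc, rate, rngs[species])
            tips[species][chrom] = tip
            if hits.size:
                records.append(pd.DataFrame({
                    "lineage": species, "chrom": chrom, "pos": hits,
                    "from_base": anc[hits], "to_base": tip[hits],
                }))
    sub_map = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["lineage", "chrom", "pos", "from_base", "to_base"])
    )
    return ProgenitorPair(ancestral, tips[SIEVERSII], tips[SYLVESTRIS], sub_map)


def _draw_tracts(
    size: int, mean_len: int, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """Alternating-origin tracts with geometric lengths (memoryless
    switching); the first origin is a fair coin flip."""
    origin = ORIGINS[int(rng.integers(0, 2))]
    tracts = []
    pos = 0
    while pos < size:
        length = int(rng.geometric(1.0 / mean_len))
        end = min(pos + length, size)
        tracts.append((pos, end, origin))
        origin = SYLVESTRIS if origin == SIEVERSII else SIEVERSII
        pos = end
    return tracts


def simulate_hybrid_diploid(
    progenitors: ProgenitorPair,
    config: SimulationConfig,
    switch_off: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], MosaicTruth]:
    """Build a diploid whose haplomes are recombinant mosaics of the two
    progenitors, with independent intraspecific drift per haplome.

    ``switch_off=True`` disables recombination (single-tract haplomes),
    useful as a degenerate control.
    """
    sizes = config.chromosome_sizes()
    for chrom, size in sizes.items():
        if progenitors.sieversii[chrom].size != size or progenitors.sylvestris[chrom].size != size:
            raise ValueError("progenitor sequences must match the configured genome")
    mosaic_rng = _rng(config.seed, _STREAM_MOSAIC)
    drift = {"A": _rng(config.seed, _STREAM_DRIFT_A), "B": _rng(config.seed, _STREAM_DRIFT_B)}
    source = {SIEVERSII: progenitors.sieversii, SYLVESTRIS: progenitors.sylvestris}

    haplomes: dict[str, dict[str, np.ndarray]] = {"A": {}, "B": {}}
    rows = []
    for hap in ("A", "B"):
        for chrom, size in sizes.items():
            if switch_off:
                tracts = [(0, size, ORIGINS[int(mosaic_rng.integers(0, 2))])]
            else:
                tracts = _draw_tracts(size, config.tract_length_mean, mosaic_rng)
            seq = np.empty(size, dtype=np.uint8)
            for start, end, origin in tracts:
                seq[start:end] = source[origin][chrom][start:end]
                rows.append({"haplome": hap, "chrom": chrom, "start": start,
                             "end": end, "origin": origin})
            # single-branch drift: every substituted site differs from the
            # source, so the rate equals the target divergence exactly
            seq, _ = _mutate(seq, config.intraspecific_divergence, drift[hap])
            haplomes[hap][chrom] = seq
    truth = MosaicTruth(tracts=pd.DataFrame(rows), chrom_sizes=sizes)
    return haplomes["A"], haplomes["B"], truth


def simulate_mosaic_truth(config: SimulationConfig) -> MosaicTruth:
    """Draw only the ground-truth ancestry mosaic of a diploid (no
    sequences); uses the same RNG stream as :func:`simulate_hybrid_diploid`
    so downstream window observations are exercised identically."""
    rng = _rng(config.seed, _STREAM_MOSAIC)
    rows = []
    for hap in ("A", "B"):
        for chrom, size in config.chromosome_sizes().items():
            for start, end, origin in _draw_tracts(size, config.tract_length_mean, rng):
                rows.append({"haplome": hap, "chrom": chrom, "start": start,
                             "end": end, "origin": origin})
    return MosaicTruth(tracts=pd.DataFrame(rows), chrom_sizes=config.chromosome_sizes())


def combine_mismatch_proportions(p1: float, p2: float) -> float:
    """Expected observable mismatch proportion after two independent
    Jukes-Cantor substitution processes with observable proportions p1, p2:
    p = p1 + p2 - (4/3) p1 p2."""
    return p1 + p2 - (4.0 / 3.0) * p1 * p2


def simulate_window_observations(
    truth: MosaicTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Fast path: draw per-window alignment observations directly from the
    truth mosaic, bypassing sequence simulation.

    Each window carries binomial mismatch counts to both progenitors around
    the divergence implied by its true origin composition: bp copied from a
    progenitor mismatch it at the intraspecific rate and mismatch the other
    species at the convolved intra+inter rate.
    """
    rng = _rng(config.seed, _STREAM_WINDOW_OBS)
    p_same = config.intraspecific_divergence
    p_cross = combine_mismatch_proportions(
        config.intraspecific_divergence, config.interspecific_divergence
    )
    p_to = {  # mismatch proportion to each reference given the tract origin
        SIEVERSII: {"sie": p_same, "syl": p_cross},
        SYLVESTRIS: {"sie": p_cross, "syl": p_same},
    }
    rows = []
    for hap in ("A", "B"):
        for chrom, size in truth.chrom_sizes.items():
            sub = truth.tracts[
                (truth.tracts["haplome"] == hap) & (truth.tracts["chrom"] == chrom)
            ].sort_values("start")
            tr = list(zip(sub["start"], sub["end"], sub["origin"]))
            n_windows = max(1, math.ceil(size / config.window_size))
            for w in range(n_windows):
                start = w * config.window_size
                end = min((w + 1) * config.window_size, size)
                rec = {"haplome": hap, "chrom": chrom, "start": start, "end": end}
                for tag in ("sie", "syl"):
                    mm = 0
                    for s, e, origin in tr:
                        ov = min(end, e) - max(start, s)
                        if ov > 0:
                            mm += int(rng.binomial(ov, p_to[origin][tag]))
                    rec[f"aligned_len_{tag}"] = end - start
                    rec[f"mismatch_{tag}"] = mm
                rows.append(rec)
    obs = pd.DataFrame(rows)
    obs["unalignable"] = (obs["aligned_len_sie"] == 0) & (obs["aligned_len_syl"] == 0)
    return obs


def simulate_pav_coverage(
    gene_models: pd.DataFrame,
    absence_matrix: pd.DataFrame,
    mean_depth: float = 20.0,
    seed: int = 0,
    present_margin: float = 0.05,
    concentration: float = 50.0,
) -> pd.DataFrame:
    """Per-gene covered fractions (at read depth >= 2) with planted absences.

    ``gene_models`` needs columns gene_id and cds_length; ``absence_matrix``
    is genes x accessions booleans, True = planted absent.  Coverage is
    simulated directly as Beta-distributed covered fractions: present genes
    centre on the Poisson-depth expectation P(depth >= 2) = 1 - e^-L(1 + L)
    and are kept above ``0.20 + present_margin``; absent genes draw below
    0.20.  Returns a long table (gene_id, accession, cds_length, covered_bp).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not absence_matrix.dtypes.map(lambda t: t == bool).all():
        raise ValueError("absence_matrix must be boolean (True = absent)")
    rng = _rng(seed, _STREAM_PAV)
    q = 1.0 - math.exp(-mean_depth) * (1.0 + mean_depth)
    q = min(max(q, 1e-6), 1.0 - 1e-9)
    lengths = gene_models.set_index("gene_id")["cds_length"]
    rows = []
    for accession in absence_matrix.columns:
        absent = absence_matrix[accession]
        for gene_id in absence_matrix.index:
            L = int(lengths[gene_id])
            if absent[gene_id]:
                frac = 0.18 * rng.beta(2.0, 5.0)
            else:
                frac = rng.beta(q * concentration, (1.0 - q) * concentration + 1e-9)
                frac = max(frac, 0.20 + present_margin)
            rows.append(
                {"gene_id": gene_id, "accession": accession,
                 "cds_length": L, "covered_bp": int(round(frac * L))}
            )
    return pd.DataFrame(rows)


def simulate_ase_counts(
    n_genes: int,
    stages: Sequence[int] = DAF_STAGES,
    replicates: int = 3,
    dispersion: float = 0.05,
    effect_spec: np.ndarray | None = None,
    seed: int = 0,
    mean_total: float = 100.0,
    replicates_by_stage: Mapping[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated allelic count tables with planted imbalance.

    ``effect_spec`` is an (n_genes, n_stages) array of true log2 allelic
    ratios (A over B); default all zeros (balanced).  Counts for each allele
    are negative binomial with variance mu + dispersion * mu^2 around means
    that split ``mean_total`` according to the stage's true ratio.
    ``replicates_by_stage`` overrides the replicate count for individual
    stages (e.g. {11: 2} mirrors a design with only two early replicates).

    Returns (counts, truth): counts long-form with columns gene, stage, rep,
    count_A, count_B; truth with gene, stage, log2_ratio.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if effect_spec is None:
        effect_spec = np.zeros((n_genes, len(stages)))
    effect_spec = np.asarray(effect_spec, dtype=float)
    if effect_spec.shape != (n_genes, len(stages)):
        raise ValueError("effect_spec must have shape (n_genes, n_stages)")
    rng = _rng(seed, _STREAM_ASE)

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    counts_rows, truth_rows = [], []
    genes = np.arange(n_genes)
    for s_idx, stage in enumerate(stages):
        n_rep = (replicates_by_stage or {}).get(stage, replicates)
        ratio = np.exp2(effect_spec[:, s_idx])
        mu_a = mean_total * ratio / (1.0 + ratio)
        mu_b = mean_total / (1.0 + ratio)
        for rep in range(1, n_rep + 1):
            ca = draw(mu_a)
            cb = draw(mu_b)
            counts_rows.append(pd.DataFrame({
                "gene": genes, "stage": stage, "rep": rep,
                "count_A": ca, "count_B": cb,
            }))
        truth_rows.append(pd.DataFrame({
            "gene": genes, "stage": stage, "log2_ratio": effect_spec[:, s_idx],
        }))
    counts = pd.concat(counts_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return counts, truth


def simulate_genotype_matrix(
    pop_spec: Mapping,
    mode: str = "fixture",
    positions: Sequence[int] | None = None,
    chrom: str = "chr1",
    seed: int = 0,
) -> GenotypeMatrix:
    """Population genotype matrices, either exact fixtures or HW draws.

    fixture mode
        ``pop_spec[pop]`` is one (n_hom_ref, n_het, n_hom_alt) triple, or a
        list of triples (one per site; population size must be constant).
        The produced matrix reproduces the requested genotype counts exactly.
    hw mode
        ``pop_spec[pop] = {"n": samples, "alt_freq": [p per site]}``;
        genotypes drawn under Hardy-Weinberg at the given frequencies.
    """
    if mode not in ("fixture", "hw"):
        raise ValueError("mode must be 'fixture' or 'hw'")
    rng = _rng(seed, _STREAM_GENO)
    samples: list[str] = []
    pops: list[str] = []
    columns: list[np.ndarray] = []

    if mode == "fixture":
        n_sites = None
        for pop, spec in pop_spec.items():
            triples = [spec] if isinstance(spec, tuple) else list(spec)
            if n_sites is None:
                n_sites = len(triples)
            elif len(triples) != n_sites:
                raise ValueError("all populations must specify the same number of sites")
            sizes = {sum(t) for t in triples}
            if len(sizes) != 1:
                raise ValueError(f"population {pop!r}: genotype counts imply varying sizes")
            if any(c < 0 for t in triples for c in t):
                raise ValueError("genotype counts must be non-negative")
            n = sizes.pop()
            block = np.empty((len(triples), n), dtype=np.int8)
            for i, (n_rr, n_ra, n_aa) in enumerate(triples):
                block[i] = [0] * n_rr + [1] * n_ra + [2] * n_aa
            samples += [f"{pop}_{k + 1}" for k in range(n)]
            pops += [pop] * n
            columns.append(block)
    else:
        n_sites = None
        for pop, spec in pop_spec.items():
            n = int(spec["n"])
            freqs = np.atleast_1d(np.asarray(spec["alt_freq"], dtype=float))
            if np.any((freqs < 0) | (freqs > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")
            if n_sites is None:
                n_sites = freqs.size
            elif freqs.size != n_sites:
                raise ValueError("all populations must specify the same number of sites")
            block = rng.binomial(1, freqs[:, None], size=(freqs.size, n)) + rng.binomial(
                1, freqs[:, None], size=(freqs.size, n)
            )
            samples += [f"{pop}_{k + 1}" for k in range(n)]
            pops += [pop] * n
            columns.append(block.astype(np.int8))

    genotypes = np.concatenate(columns, axis=1)
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    return GenotypeMatrix(
        genotypes=genotypes,
        samples=samples,
        populations=np.asarray(pops, dtype=object),
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
    )


def p_distance(seq1: dict[str, np.ndarray] | np.ndarray, seq2) -> float:
    """Observed mismatch proportion between two coded genomes (dicts of
    chromosome arrays, or bare arrays)."""
    if isinstance(seq1, np.ndarray):
        seq1, seq2 = {"_": seq1}, {"_": seq2}
    diff = total = 0
    for chrom, a in seq1.items():
        b = seq2[chrom]
        if a.size != b.size:
            raise ValueError("sequences must have equal length")
        diff += int((a != b).sum())
        total += a.size
    return diff / total
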