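"""Population-genetic summaries over diploid genotype matrices.

Implements the variant filters and statistics used when contrasting a
cultivated population with its wild progenitors: GATK-style hard filters,
VCFtools-style population filters, per-population allele frequencies and
genotype-class proportions, sliding-window nucleotide diversity (pi) and
Tajima's D, dosage p-distance matrices and neighbor-joining trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "FilterResult",
    "hard_filter_variant",
    "population_filter",
    "allele_frequency",
    "genotype_class_proportions",
    "window_stats",
    "nucleotide_diversity_windows",
    "tajimas_d_windows",
    "tajima_constants",
    "p_distance_matrix",
    "neighbor_joining",
    "round_half_away",
]


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype calls coded as alt-allele dosage.

    genotypes : int8 array (n_sites, n_samples); 0/1/2 alt dosage, -1 missing.
    samples : sample identifiers, one per column.
    populations : population label per sample (e.g. domestica / sieversii /
        sylvestris).
    chrom / positions : site coordinates, positions 1-based.
    qual : optional per-site phred quality.
    """

    genotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x samples)")
        n_sites, n_samples = self.genotypes.shape
        if len(self.samples) != n_samples or len(self.populations) != n_samples:
            raise ValueError("sample/population labels must match genotype columns")
        if len(self.chrom) != n_sites or len(self.positions) != n_sites:
            raise ValueError("site coordinates must match genotype rows")
        if self.genotypes.size and (self.genotypes.max() > 2 or self.genotypes.min() < MISSING):
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if np.any(self.positions < 1):
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def sample_mask(self, population: str | None) -> np.ndarray:
        if population is None:
            return np.ones(self.n_samples, dtype=bool)
        mask = self.populations == population
        if not mask.any():
            raise ValueError(f"no samples in population {population!r}")
        return mask

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            populations=self.populations,
            chrom=self.chrom[index],
            positions=self.positions[index],
            qual=None if self.qual is None else np.asarray(self.qual, float)[index],
        )


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


# exclusion rules: (INFO key, comparator, threshold); a missing annotation
# cannot fail its rule
_HARD_RULES = (
    ("QD", "lt", 2.0),
    ("SOR", "gt", 3.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)


def hard_filter_variant(record: Mapping, min_allele_reads: int = 5) -> FilterResult:
    """GATK-style hard filter for a single biallelic SNP record.

    ``record`` is a mapping with optional keys ``qual``, ``info`` (a mapping
    of the site annotations QD/SOR/FS/MQ/MQRankSum/ReadPosRankSum), and
    ``ad_ref``/``ad_alt`` read support.  A record fails if any exclusion
    condition holds (QD < 2, QUAL < 60, SOR > 3, FS > 60, MQ < 40,
    MQRankSum < -12.5, ReadPosRankSum < -8) or if either allele is supported
    by fewer than ``min_allele_reads`` reads.
    """
    if not hasattr(record, "get"):
        raise TypeError("record must be a mapping")
    reasons: list[str] = []
    qual = record.get("qual")
    if qual is not None and qual < 60.0:
        reasons.append("QUAL")
    info = record.get("info") or {}
    for key, op, thr in _HARD_RULES:
        val = info.get(key)
        if val is None:
            continue
        if (op == "lt" and val < thr) or (op == "gt" and val > thr):
            reasons.append(key)
    for key in ("ad_ref", "ad_alt"):
        val = record.get(key)
        if val is not None and val < min_allele_reads:
            reasons.append("allele_support")
            break
    return FilterResult(passed=not reasons, reasons=tuple(reasons))


def _alt_counts(gm: GenotypeMatrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = gm.genotypes[:, mask]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=1)
    return alt.astype(float), 2.0 * called.sum(axis=1)


def population_filter(
    gm: GenotypeMatrix,
    maf: float = 0.05,
    min_qual: float = 30.0,
    max_missing_fraction: float = 0.10,
) -> GenotypeMatrix:
    """VCFtools-style site filter: keep sites with minor-allele frequency
    >= ``maf`` (over non-missing alleles), QUAL >= ``min_qual`` and at most
    ``max_missing_fraction`` missing genotypes (``--max-missing 0.9``
    semantics).  Idempotent."""
    g = gm.genotypes
    missing_frac = (g == MISSING).mean(axis=1)
    alt, total = _alt_counts(gm, np.ones(gm.n_samples, dtype=bool))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    minor = np.fmin(p, 1.0 - p)
    keep = (missing_frac <= max_missing_fraction) & np.isfinite(minor) & (minor >= maf)
    if gm.qual is not None:
        keep &= np.asarray(gm.qual, float) >= min_qual
    return gm.take_sites(np.flatnonzero(keep))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention behind printed percentages
    such as 55.6 from 40/72)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def allele_frequency(gm: GenotypeMatrix, population: str | None, site: int) -> float:
    """Alt-allele frequency (percent, one decimal, half away from zero) in a
    population at site index ``site``; non-missing alleles only."""
    mask = gm.sample_mask(population)
    g = gm.genotypes[site, mask]
    called = g != MISSING
    if not called.any():
        raise ValueError("all genotypes missing at requested site")
    freq = g[called].sum() / (2.0 * called.sum())
    return round_half_away(100.0 * freq)


def genotype_class_proportions(
    gm: GenotypeMatrix, population: str | None, site: int
) -> tuple[float, float, float]:
    """(hom-ref %, het %, hom-alt %) over non-missing samples, one decimal."""
    mask = gm.sample_mask(population)
    g = gm.genotypes[site, mask]
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("all genotypes missing at requested site")
    n = float(g.size)
    return tuple(round_half_away(100.0 * (g == k).sum() / n) for k in (0, 1, 2))


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for n haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _site_pi(gm: GenotypeMatrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site pairwise diversity 2 p q n/(n-1) over non-missing
    haplotypes, and the segregating indicator."""
    alt, total = _alt_counts(gm, mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        n = total
        pi = np.where(n > 1, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1), 0.0)
    seg = (alt > 0) & (alt < total)
    return np.nan_to_num(pi), seg


def window_stats(
    gm: GenotypeMatrix,
    window: int = 20_000,
    step: int = 1_000,
    population: str | None = None,
) -> pd.DataFrame:
    """Sliding-window pi and Tajima's D.

    ``pi`` is the sum of per-site unbiased pairwise diversity divided by the
    full window length in bp.  ``tajima_d`` is the classical normalised
    difference between the pairwise and the segregating-sites estimators of
    theta; it is NaN (undefined, never dropped) for windows with fewer than
    3 segregating sites or fewer than 4 haplotypes.  Constants use the full
    haplotype count 2 x samples; sites with missing calls still contribute
    their non-missing-allele diversity to pi.
    """
    if gm.n_samples == 0:
        raise ValueError("genotype matrix has no samples")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    mask = gm.sample_mask(population)
    n_hap = 2 * int(mask.sum())
    site_pi, seg = _site_pi(gm, mask)

    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        pos0 = gm.positions[on] - 1  # 0-based
        order = np.argsort(pos0)
        pos0 = pos0[order]
        pi_c = site_pi[on][order]
        seg_c = seg[on][order]
        extent = int(pos0.max()) + 1 if len(pos0) else window
        cum_pi = np.concatenate([[0.0], np.cumsum(pi_c)])
        cum_seg = np.concatenate([[0], np.cumsum(seg_c)])
        start = 0
        while start < extent:
            end = start + window
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            pi_total = cum_pi[hi] - cum_pi[lo]
            S = int(cum_seg[hi] - cum_seg[lo])
            d = np.nan
            if S >= 3 and n_hap >= 4:
                k = tajima_constants(n_hap)
                var = k["e1"] * S + k["e2"] * S * (S - 1)
                d = (pi_total - S / k["a1"]) / math.sqrt(var)
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "pi": pi_total / window, "tajima_d": d, "n_segregating": S}
            )
            start += step
    return pd.DataFrame(rows)


def nucleotide_diversity_windows(
    gm: GenotypeMatrix, window: int = 20_000, step: int = 1_000, population: str | None = None
) -> pd.DataFrame:
    return window_stats(gm, window, step, population)[
        ["chrom", "start", "end", "pi", "n_segregating"]
    ]


def tajimas_d_windows(
    gm: GenotypeMatrix, window: int = 20_000, step: int = 1_000, population: str | None = None
) -> pd.DataFrame:
    return window_stats(gm, window, step, population)[
        ["chrom", "start", "end", "tajima_d", "n_segregating"]
    ]


def p_distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise dosage distance: mean of |g_i - g_j| / 2 over sites where both
    samples are called (pairwise deletion).  Pairs with zero overlapping
    sites are NaN."""
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.genotypes.astype(float)
    g[g == MISSING] = np.nan
    n = gm.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            if not both.any():
                d = np.nan
            else:
                d = np.abs(g[both, i] - g[both, j]).sum() / (2.0 * both.sum())
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=gm.samples, columns=gm.samples)


class _Node:
    __slots__ = ("label", "children", "order")

    def __init__(self, label=None, order=0):
        self.label = label
        self.children: list[tuple["_Node", float]] = []
        self.order = order

    def newick(self) -> str:
        if not self.children:
            return str(self.label)
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dist, labels: Sequence[str] | None = None) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick form.

    Agglomerates the pair minimising the Q criterion; ties break
    deterministically on the lowest (i, j) node-creation-order pair.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch so path lengths between the joined pair are preserved.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        dist = dist.to_numpy(float)
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]

    nodes = [_Node(label=labels[i], order=i) for i in range(n)]
    D = D.copy()
    active = list(range(n))
    next_order = n

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: lowest (order_i, order_j) pair among minima
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((nodes[active[i]].order, nodes[active[j]].order))), i, j)
            for i, j in ties
        )
        i, j = best[1], best[2]
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        elif bj < 0:
            bi += bj
            bj = 0.0
        parent = _Node(order=next_order)
        next_order += 1
        parent.children = [(nodes[ai], float(bi)), (nodes[aj], float(bj))]
        new_d = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = new_d
        D[active, -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [D.shape[0] - 1]

    # final unrooted trifurcation: closed-form branch lengths
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = _Node(order=next_order)
    root.children = [
        (nodes[a], max(va, 0.0)),
        (nodes[b], max(vb, 0.0)),
        (nodes[c], max(vc, 0.0)),
    ]
    return root.newick() + ";"
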