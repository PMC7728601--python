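"""Pan-genome presence/absence variation (PAV) analysis.

A gene is called absent in an accession when less than 20% of its coding
region is covered by at least two reads.  Gene-level calls collapse to
orthogroup level (a group is present if any member gene is), feed
permutation-based pan/core accumulation curves modelled with a Tettelin-style
power law, and support Fisher-exact detection of orthogroups favored in one
or two species relative to the remaining one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "call_gene_absence",
    "call_pav_matrix",
    "extract_novel_segments",
    "dedupe_segments",
    "orthogroup_pav",
    "sample_pan_core_curves",
    "PanCurveFit",
    "fit_power_law",
    "favored_orthogroups",
]

ABSENCE_COVERED_FRACTION = 0.20  # strict: absent iff covered fraction < 0.20


def call_gene_absence(covered_bp: float, cds_length: float) -> bool:
    """True (present) unless covered fraction is strictly below 20%."""
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if not 0 <= covered_bp <= cds_length:
        raise ValueError("covered_bp must lie in [0, cds_length]")
    return covered_bp / cds_length >= ABSENCE_COVERED_FRACTION


def call_pav_matrix(coverage: pd.DataFrame) -> pd.DataFrame:
    """Genes x accessions boolean presence matrix from a long coverage table
    (columns gene_id, accession, cds_length, covered_bp)."""
    cov = coverage.copy()
    if (cov["cds_length"] <= 0).any():
        raise ValueError("cds_length must be positive")
    cov["present"] = cov["covered_bp"] / cov["cds_length"] >= ABSENCE_COVERED_FRACTION
    return cov.pivot(index="gene_id", columns="accession", values="present").fillna(False)


def extract_novel_segments(
    contig_length: int,
    aligned_intervals: Sequence[tuple[int, int, float]],
    min_segment: int = 500,
    identity: float = 0.90,
) -> list[tuple[int, int]]:
    """Unaligned (novel) segments of a contig.

    ``aligned_intervals`` are (start, end, identity) on the contig, 0-based
    half-open.  Intervals below the identity cutoff count as unaligned.  The
    novel set is the complement of the union of qualifying intervals, keeping
    only segments strictly longer than ``min_segment`` bp.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    keep = []
    for start, end, ident in aligned_intervals:
        if not (0 <= start < end <= contig_length):
            raise ValueError(f"interval ({start}, {end}) out of contig bounds")
        if ident >= identity:
            keep.append((start, end))
    keep.sort()
    merged: list[list[int]] = []
    for start, end in keep:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    novel = []
    pos = 0
    for start, end in merged + [[contig_length, contig_length]]:
        if start - pos > min_segment:
            novel.append((pos, start))
        pos = max(pos, end)
    return novel


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dedupe_segments(
    segments: Sequence[tuple[str, str]],
    identity: float = 0.90,
    coverage: float = 0.90,
    k: int = 15,
) -> list[str]:
    """Greedy longest-first redundancy removal (CD-HIT-like, approximate).

    A candidate is redundant if, against some already-retained segment, its
    k-mer containment reaches ``coverage * identity`` (screen) and a global
    alignment confirms >= ``identity`` matches over >= ``coverage`` of its
    length.  Returns the ids of retained segments.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5

    ordered = sorted(segments, key=lambda kv: len(kv[1]), reverse=True)
    retained: list[tuple[str, str, set[str]]] = []
    keep_ids = []
    for seg_id, seq in ordered:
        kmers = _kmer_set(seq, k)
        redundant = False
        for _, ref_seq, ref_kmers in retained:
            if not kmers:
                break
            containment = len(kmers & ref_kmers) / len(kmers)
            if containment < coverage * identity * 0.5:
                continue
            aln = aligner.align(ref_seq, seq)
            best = aln[0]
            matched = sum(
                min(te - ts, qe - qs)
                for (ts, te), (qs, qe) in zip(best.aligned[0], best.aligned[1])
            )
            if best.score >= identity * coverage * len(seq) and matched >= coverage * len(seq) * identity:
                redundant = True
                break
        if not redundant:
            retained.append((seg_id, seq, kmers))
            keep_ids.append(seg_id)
    return keep_ids


def orthogroup_pav(
    pav: pd.DataFrame, group_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a gene-level PAV matrix to orthogroup level: a group is
    present in an accession iff any member gene is.  Genes missing from
    ``group_map`` become singleton groups (with a warning)."""
    groups = {}
    unmapped = []
    for gene in pav.index:
        grp = group_map.get(gene)
        if grp is None:
            grp = f"singleton:{gene}"
            unmapped.append(gene)
        groups.setdefault(grp, []).append(gene)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} genes missing from group map; treated as singletons",
            stacklevel=2,
        )
    data = {grp: pav.loc[members].any(axis=0) for grp, members in groups.items()}
    out = pd.DataFrame(data).T
    out.index.name = "orthogroup"
    return out


def sample_pan_core_curves(
    pav: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Pan and core genome sizes versus number of sampled accessions.

    For each of ``n_permutations`` random accession orderings the pan size is
    the cumulative union of present genes and the core size the cumulative
    intersection; medians and the requested quantiles are reported per N.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if pav.shape[1] < 2:
        raise ValueError("need at least 2 accessions")
    rng = np.random.default_rng(seed)
    presence = pav.to_numpy(bool).T  # accessions x genes
    n_acc = presence.shape[0]
    pan = np.empty((n_permutations, n_acc), dtype=np.int64)
    core = np.empty_like(pan)
    for t in range(n_permutations):
        order = rng.permutation(n_acc)
        pan[t] = np.logical_or.accumulate(presence[order], axis=0).sum(axis=1)
        core[t] = np.logical_and.accumulate(presence[order], axis=0).sum(axis=1)
    qlo, qhi = quantiles
    return pd.DataFrame({
        "n_accessions": np.arange(1, n_acc + 1),
        "pan_median": np.median(pan, axis=0),
        "pan_lo": np.quantile(pan, qlo, axis=0),
        "pan_hi": np.quantile(pan, qhi, axis=0),
        "core_median": np.median(core, axis=0),
        "core_lo": np.quantile(core, qlo, axis=0),
        "core_hi": np.quantile(core, qhi, axis=0),
    })


@dataclass(frozen=True)
class PanCurveFit:
    """Power-law fit P(N) = A N^gamma + C of a pan or core curve.

    ``closed`` flags a saturating pan-genome: gamma < 1 with the fitted slope
    at the largest sampled N below ``slope_threshold`` genes/accession.
    ``extrapolation`` continues the fitted curve to 2x the sampled range.
    """

    A: float
    gamma: float
    C: float
    residual_norm: float
    closed: bool
    slope_at_max: float
    extrapolation: pd.DataFrame

    def predict(self, N) -> np.ndarray:
        return self.A * np.asarray(N, float) ** self.gamma + self.C


def fit_power_law(
    n_accessions: np.ndarray,
    sizes: np.ndarray,
    slope_threshold: float = 0.5,
) -> PanCurveFit:
    """Nonlinear least-squares fit of A N^gamma + C to curve medians.

    Grid-initialised over gamma in (0, 1.5]; A may be negative so decaying
    core curves fit with the same functional form.  Requires >= 4 support
    points.  A flat input degenerates to A ~ 0 with a warning.
    """
    N = np.asarray(n_accessions, float)
    y = np.asarray(sizes, float)
    if N.size < 4:
        raise ValueError("need at least 4 support points")

    def model(n, A, gamma, C):
        return A * n**gamma + C

    # physical bounds keep the fit out of the degenerate A -> +inf, C -> -inf
    # logarithmic regime on nearly saturated curves
    scale = max(np.abs(y).max(), 1.0)
    lo = [-10 * scale, 1e-3, min(0.0, y.min())]
    hi = [10 * scale, 1.5, 2 * y.max()]
    best = None
    for g0 in np.arange(0.1, 1.51, 0.1):
        span = N.max() ** g0 - N.min() ** g0
        A0 = (y[-1] - y[0]) / span if span else 1.0
        C0 = y[0] - A0 * N.min() ** g0
        p0 = np.clip([A0, g0, C0], lo, hi)
        try:
            popt, _ = optimize.curve_fit(
                model, N, y, p0=p0, bounds=(lo, hi), maxfev=20_000
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(model(N, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("power-law fit failed to converge from any start")
    (A, gamma, C), residual = best
    if abs(A) < 1e-9 or np.ptp(y) < 1e-12:
        warnings.warn("flat curve: amplitude indistinguishable from zero", stacklevel=2)
    slope = A * gamma * N.max() ** (gamma - 1.0)
    closed = bool(gamma < 1.0 and abs(slope) < slope_threshold)
    n_ext = np.arange(1, int(2 * N.max()) + 1, dtype=float)
    extrapolation = pd.DataFrame({"n_accessions": n_ext, "size": model(n_ext, A, gamma, C)})
    return PanCurveFit(
        A=float(A), gamma=float(gamma), C=float(C), residual_norm=residual,
        closed=closed, slope_at_max=float(slope), extrapolation=extrapolation,
    )


_PAIRS = (
    ("domestica", "sieversii"),
    ("domestica", "sylvestris"),
    ("sylvestris", "sieversii"),
)


def favored_orthogroups(
    group_pav: pd.DataFrame,
    species_labels: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detect orthogroups favored in particular species by presence pattern.

    For each group and species pair a 2x2 Fisher exact test contrasts
    present/absent counts between the species; Benjamini-Hochberg correction
    is applied across groups separately per pair.  Categories (mutually
    exclusive):

    ``dom_syl_vs_sie``  present-enriched in both domestica and sylvestris
    relative to sieversii; ``dom_sie_vs_syl`` the mirror image;
    ``dom_only`` enriched in domestica against both wild species; else
    ``none``.  Groups absent in every accession are skipped.
    """
    species = pd.Series({acc: species_labels[acc] for acc in group_pav.columns})
    counts_present = {}
    counts_total = {}
    for sp in species.unique():
        cols = species.index[species == sp]
        if len(cols) < 2:
            raise ValueError(f"species {sp!r} needs at least 2 accessions")
        counts_present[sp] = group_pav[cols].sum(axis=1).to_numpy(int)
        counts_total[sp] = len(cols)

    keep = group_pav.any(axis=1).to_numpy()
    groups = group_pav.index[keep]
    result = pd.DataFrame(index=groups)
    for sp in counts_present:
        result[f"present_{sp}"] = counts_present[sp][keep]
        result[f"n_{sp}"] = counts_total[sp]

    sig_enriched: dict[tuple[str, str], np.ndarray] = {}
    for sp_a, sp_b in _PAIRS:
        pa, na = counts_present[sp_a][keep], counts_total[sp_a]
        pb, nb = counts_present[sp_b][keep], counts_total[sp_b]
        pvals = np.empty(len(groups))
        odds = np.empty(len(groups))
        for i in range(len(groups)):
            table = [[pa[i], na - pa[i]], [pb[i], nb - pb[i]]]
            odds[i], pvals[i] = stats.fisher_exact(table, alternative="two-sided")
        qvals = multipletests(pvals, method="fdr_bh")[1]
        enriched_a = (pa / na) > (pb / nb)
        result[f"odds_{sp_a}_vs_{sp_b}"] = odds
        result[f"p_{sp_a}_vs_{sp_b}"] = pvals
        result[f"q_{sp_a}_vs_{sp_b}"] = qvals
        sig_enriched[(sp_a, sp_b)] = (qvals < alpha) & enriched_a
        sig_enriched[(sp_b, sp_a)] = (qvals < alpha) & ~enriched_a & (qvals < alpha)

    dom_over_sie = sig_enriched[("domestica", "sieversii")]
    dom_over_syl = sig_enriched[("domestica", "sylvestris")]
    syl_over_sie = sig_enriched[("sylvestris", "sieversii")]
    sie_over_syl = sig_enriched[("sieversii", "sylvestris")]

    category = np.full(len(groups), "none", dtype=object)
    category[dom_over_sie & syl_over_sie] = "dom_syl_vs_sie"
    category[dom_over_syl & sie_over_syl] = "dom_sie_vs_syl"
    dom_only = dom_over_sie & dom_over_syl & (category == "none")
    category[dom_only] = "dom_only"
    result["category"] = category
    result.index.name = "orthogroup"
    return result
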