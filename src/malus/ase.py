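"""Allele-specific expression (ASE) from haplotype-resolved counts.

Reads are assigned to one of the two haplomes either directly (better
alignment score and no more mismatches against one haplome) or, when the
alignments tie, by majority vote over phased heterozygous SNPs they overlap.
Replicated per-gene allele counts are then tested for imbalance with a
negative-binomial Wald test (method-of-moments dispersion): a gene shows ASE
at a stage when the BH-adjusted p-value is below alpha *and* the observed
allelic ratio exceeds twofold.  Follow-up utilities classify allele-dominance
profiles across developmental stages and run the two association tests used
to interpret ASE: over-representation of hybrid-ancestry genes (Fisher) and
proximity of upstream structural variants (Mann-Whitney U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

A, B, AMBIGUOUS = "A", "B", "ambiguous"

__all__ = [
    "assign_read",
    "assign_reads",
    "phase_and_impute",
    "snp_split_read",
    "assignment_balance",
    "ase_test",
    "dominance_profile",
    "ancestry_enrichment_test",
    "sv_proximity_test",
]


def assign_read(
    score_A: float,
    score_B: float,
    mismatches_A: int,
    mismatches_B: int,
    uniquely_aligned_both: bool = True,
    same_chromosome: bool = True,
    strict_both: bool = False,
) -> str:
    """Assign one read to haplome A or B from its two alignments.

    A read must align uniquely to the same chromosome in both haplomes to be
    assignable.  It goes to the haplome with a better score and no more
    mismatches, at least one strictly better (``strict_both=True`` demands
    both strictly better).  Everything else is ambiguous and falls through
    to SNP-based splitting.
    """
    if not (uniquely_aligned_both and same_chromosome):
        return AMBIGUOUS

    def wins(s1, s2, m1, m2):
        if strict_both:
            return s1 > s2 and m1 < m2
        return s1 >= s2 and m1 <= m2 and (s1 > s2 or m1 < m2)

    if wins(score_A, score_B, mismatches_A, mismatches_B):
        return A
    if wins(score_B, score_A, mismatches_B, mismatches_A):
        return B
    return AMBIGUOUS


def assign_reads(evidence: pd.DataFrame, strict_both: bool = False) -> pd.Series:
    """Vectorised :func:`assign_read` over an evidence table with columns
    score_A, score_B, mismatches_A, mismatches_B and (optionally)
    uniquely_aligned_both, same_chromosome."""
    ok = np.ones(len(evidence), dtype=bool)
    for col in ("uniquely_aligned_both", "same_chromosome"):
        if col in evidence.columns:
            ok &= evidence[col].to_numpy(bool)
    sa = evidence["score_A"].to_numpy(float)
    sb = evidence["score_B"].to_numpy(float)
    ma = evidence["mismatches_A"].to_numpy(float)
    mb = evidence["mismatches_B"].to_numpy(float)
    if strict_both:
        a_wins = (sa > sb) & (ma < mb)
        b_wins = (sb > sa) & (mb < ma)
    else:
        a_wins = (sa >= sb) & (ma <= mb) & ((sa > sb) | (ma < mb))
        b_wins = (sb >= sa) & (mb <= ma) & ((sb > sa) | (mb < ma))
    out = np.where(ok & a_wins, A, np.where(ok & b_wins, B, AMBIGUOUS))
    return pd.Series(out, index=evidence.index, name="assignment")


def phase_and_impute(variants: pd.DataFrame) -> pd.DataFrame:
    """Phase heterozygous biallelic SNPs onto the two haplomes.

    ``variants`` columns: chrom, pos (1-based), ref, alt, obs_A, obs_B — the
    base observed in each haplome assembly at the site, or None/NaN when the
    haplotype is unresolved there.  A SNP phases directly when both haplome
    observations are known, distinct, and drawn from {ref, alt}; when exactly
    one is known the other is imputed as the remaining allele of the
    biallelic call.  Conflicting observations (same base in both haplomes, or
    a base outside the call) are dropped.
    """
    rows = []
    for row in variants.itertuples(index=False):
        alleles = {row.ref, row.alt}
        if len(alleles) != 2:
            continue  # not a biallelic SNP
        obs_a = row.obs_A if isinstance(row.obs_A, str) else None
        obs_b = row.obs_B if isinstance(row.obs_B, str) else None
        if obs_a is not None and obs_a not in alleles:
            continue
        if obs_b is not None and obs_b not in alleles:
            continue
        if obs_a is not None and obs_b is not None:
            if obs_a == obs_b:
                continue  # contradiction: both haplomes show the same base
            source = "direct"
        elif obs_a is not None:
            obs_b = (alleles - {obs_a}).pop()
            source = "imputed"
        elif obs_b is not None:
            obs_a = (alleles - {obs_b}).pop()
            source = "imputed"
        else:
            continue
        rows.append({
            "chrom": row.chrom, "pos": row.pos,
            "allele_A": obs_a, "allele_B": obs_b, "source": source,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele_A", "allele_B", "source"])


def snp_split_read(
    read_observations: Iterable[tuple[str, int, str]],
    phased_snps: pd.DataFrame,
) -> str:
    """Assign an alignment-ambiguous read by majority vote over phased SNPs.

    ``read_observations`` yields (chrom, pos, base) for every phased-SNP
    position the read overlaps.  A base matching neither phased allele is
    skipped; ties and reads with zero informative overlaps are ambiguous.
    """
    lookup = {
        (row.chrom, row.pos): (row.allele_A, row.allele_B)
        for row in phased_snps.itertuples(index=False)
    }
    votes_a = votes_b = 0
    for chrom, pos, base in read_observations:
        alleles = lookup.get((chrom, pos))
        if alleles is None:
            continue
        if base == alleles[0]:
            votes_a += 1
        elif base == alleles[1]:
            votes_b += 1
    if votes_a > votes_b:
        return A
    if votes_b > votes_a:
        return B
    return AMBIGUOUS


def assignment_balance(counts: pd.DataFrame) -> pd.DataFrame:
    """Global and per-stage ratio of reads assigned to haplome A over B.

    Unbiased assignment shows ratios near 1.  Gene rows with zero counts for
    both alleles are excluded; a zero B total yields an infinite, flagged
    ratio.
    """
    live = counts[(counts["count_A"] + counts["count_B"]) > 0]
    rows = []
    grouped = [("overall", live)] + [
        (stage, grp) for stage, grp in live.groupby("stage")
    ]
    for label, grp in grouped:
        a, b = grp["count_A"].sum(), grp["count_B"].sum()
        ratio = np.inf if b == 0 else a / b
        rows.append({
            "stage": label, "total_A": int(a), "total_B": int(b),
            "ratio": ratio, "flagged": not (0.5 <= ratio <= 2.0),
        })
    return pd.DataFrame(rows)


def _moments_dispersion(x: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha = (s^2 - m)/m^2, floored at 0."""
    m = x.mean()
    if m <= 0 or x.size < 2:
        return 0.0
    v = x.var(ddof=1)
    return max((v - m) / m**2, 0.0)


def ase_test(
    counts: pd.DataFrame,
    min_total: int = 10,
    fold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call ASE per gene and stage from replicated allele counts.

    ``counts`` is long-form with columns gene, stage, rep, count_A, count_B.
    Gene x stage combinations where any replicate's total (A + B) is not
    strictly greater than ``min_total`` are excluded from testing.  The test
    is a Wald test on the log allelic ratio under a negative-binomial model
    with a shared method-of-moments dispersion per gene x stage; p-values are
    BH-adjusted across genes within each stage.  A call is significant when
    the adjusted p is below ``alpha`` and the observed |log2 ratio| exceeds
    log2(fold).  With a single replicate the test falls back to an exact
    binomial test (with a warning).
    """
    fold_log2 = np.log2(fold)
    out_rows = []
    for stage, grp in counts.groupby("stage"):
        pivot_a = grp.pivot(index="gene", columns="rep", values="count_A")
        pivot_b = grp.pivot(index="gene", columns="rep", values="count_B")
        totals = pivot_a + pivot_b
        eligible = (totals > min_total).all(axis=1) & totals.notna().all(axis=1)
        genes = totals.index[eligible]
        if len(genes) == 0:
            continue
        ca = pivot_a.loc[genes].to_numpy(float)
        cb = pivot_b.loc[genes].to_numpy(float)
        n_rep = ca.shape[1]
        log2_ratio = np.log2((ca.mean(axis=1) + 0.5) / (cb.mean(axis=1) + 0.5))
        if n_rep == 1:
            warnings.warn(
                "single replicate: falling back to an exact binomial test; "
                "biological variance is not accounted for",
                stacklevel=2,
            )
            pvals = np.array([
                stats.binomtest(int(a), int(a + b), 0.5).pvalue
                for a, b in zip(ca[:, 0], cb[:, 0])
            ])
        else:
            ma, mb = ca.mean(axis=1), cb.mean(axis=1)
            disp = np.array([
                0.5 * (_moments_dispersion(ca[i]) + _moments_dispersion(cb[i]))
                for i in range(len(genes))
            ])
            # var(log mean) ~ (1/n) (1/mu + alpha) by the delta method
            se = np.sqrt(
                (1.0 / n_rep) * (1.0 / np.maximum(ma, 0.5) + disp)
                + (1.0 / n_rep) * (1.0 / np.maximum(mb, 0.5) + disp)
            )
            z = (np.log(np.maximum(ma, 0.5)) - np.log(np.maximum(mb, 0.5))) / se
            pvals = 2.0 * stats.norm.sf(np.abs(z))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        significant = (qvals < alpha) & (np.abs(log2_ratio) > fold_log2)
        dominant = np.where(
            significant, np.where(log2_ratio > 0, A, B), "none"
        )
        out_rows.append(pd.DataFrame({
            "gene": genes, "stage": stage, "log2_ratio": log2_ratio,
            "pvalue": pvals, "adjusted_p": qvals,
            "significant": significant, "dominant_allele": dominant,
        }))
    if not out_rows:
        return pd.DataFrame(
            columns=["gene", "stage", "log2_ratio", "pvalue", "adjusted_p",
                     "significant", "dominant_allele"]
        )
    return pd.concat(out_rows, ignore_index=True)


def dominance_profile(ase_calls: pd.DataFrame) -> pd.DataFrame:
    """Classify each gene's allele-dominance pattern across stages.

    consistent-A / consistent-B : significant ASE at >= 2 stages, always the
    same dominant allele; switching : dominant A at some stage and dominant B
    at another (both significant); single-stage : significant at exactly one
    stage; none : no significant stage.
    """
    rows = []
    for gene, grp in ase_calls.groupby("gene"):
        sig = grp[grp["significant"]]
        doms = set(sig["dominant_allele"])
        if len(sig) == 0:
            cls = "none"
        elif len(sig) == 1:
            cls = "single-stage"
        elif doms == {A}:
            cls = "consistent-A"
        elif doms == {B}:
            cls = "consistent-B"
        else:
            cls = "switching"
        rows.append({"gene": gene, "n_significant_stages": len(sig), "class": cls})
    return pd.DataFrame(rows)


def ancestry_enrichment_test(
    hybrid_ancestry: pd.Series | np.ndarray,
    is_ase: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Fisher exact test for over-representation of
    hybrid-ancestry genes (two alleles from different progenitors) among ASE
    genes.  Returns (odds ratio, p)."""
    hybrid = np.asarray(hybrid_ancestry, bool)
    ase_flag = np.asarray(is_ase, bool)
    if hybrid.shape != ase_flag.shape:
        raise ValueError("inputs must align gene-for-gene")
    if hybrid.all() or (~hybrid).all() or ase_flag.all() or (~ase_flag).all():
        raise ValueError("degenerate input: both classes of both factors required")
    table = [
        [int((hybrid & ase_flag).sum()), int((hybrid & ~ase_flag).sum())],
        [int((~hybrid & ase_flag).sum()), int((~hybrid & ~ase_flag).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def sv_proximity_test(
    distances_ase: np.ndarray, distances_other: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided, tie-corrected) comparing upstream-SV
    distances of ASE genes against other genes.  Returns (U, p); completely
    tied input returns p = 1."""
    x = np.asarray(distances_ase, float)
    y = np.asarray(distances_other, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("distances must be non-negative")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if max(x.size, y.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
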