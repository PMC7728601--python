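"""Window-based genome-ancestry painting of a hybrid genome.

A target genome (one haplome of a diploid cultivar, or a haploid consensus)
is compared against the genomes of its two candidate progenitor species via
whole-genome alignment blocks projected onto the target coordinate system.
Mismatch proportions are accumulated in non-overlapping windows, corrected
with the Jukes-Cantor formula, and each window is assigned to the progenitor
with the smaller corrected divergence, subject to two guards:

* the smaller divergence must fall below ``max_assignable_divergence``
  (default 1.4%, the interspecific scale of the system), and
* the two divergences must differ by more than ``min_difference``
  (default 0.2%), otherwise the window is left ``unclear``.

Runs of same-origin windows merge into ancestry tracts whose boundaries mark
candidate recombination sites.  Summaries quantify, per haplome and for the
diploid, how much of the genome derives from each progenitor and how much is
of hybrid origin (the two haplomes assigned to different species).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIEVERSII = "sieversii"
SYLVESTRIS = "sylvestris"
UNCLEAR = "unclear"
ORIGINS = (SIEVERSII, SYLVESTRIS)

__all__ = [
    "SIEVERSII",
    "SYLVESTRIS",
    "UNCLEAR",
    "SaturationError",
    "ClassificationThresholds",
    "PaintingSummary",
    "jukes_cantor_distance",
    "inverse_jukes_cantor",
    "project_to_windows",
    "add_divergence",
    "classify_window",
    "classify_windows",
    "paint_haplome",
    "paint_diploid_observations",
    "recombination_boundaries",
    "summarize_painting",
    "sensitivity_scan",
    "intersect_regions_with_ancestry",
    "smooth_divergence",
]


class SaturationError(ValueError):
    """Raised when a mismatch proportion is at or beyond the p >= 0.75
    saturation point of the Jukes-Cantor model."""


def jukes_cantor_distance(p):
    """Jukes-Cantor corrected divergence d = -(3/4) ln(1 - 4p/3).

    Accepts scalars or arrays of observed mismatch proportions.  ``d >= p``
    always, with equality only at p = 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mismatch proportion must be non-negative")
    if np.any(arr >= 0.75):
        raise SaturationError(
            "mismatch proportion >= 0.75 saturates the Jukes-Cantor model"
        )
    d = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    return float(d) if np.isscalar(p) else d


def inverse_jukes_cantor(d):
    """Expected mismatch proportion for a given corrected divergence."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be non-negative")
    p = 0.75 * (-np.expm1(-(4.0 / 3.0) * arr))
    return float(p) if np.isscalar(d) else p


@dataclass(frozen=True)
class ClassificationThresholds:
    """Rules for assigning a window to a progenitor.

    max_assignable_divergence
        Upper bound the *smaller* divergence must stay below (strict).
    min_difference
        The two divergences must differ by strictly more than this.
    min_aligned
        Windows with fewer aligned columns than this have undefined
        divergence and are always ``unclear``.
    both_bounded
        If True, additionally require the larger divergence below the bound
        (the default bounds only the smaller one, i.e. the winning species).
    """

    max_assignable_divergence: float = 0.014
    min_difference: float = 0.002
    min_aligned: int = 100
    both_bounded: bool = False

    def __post_init__(self) -> None:
        if self.max_assignable_divergence <= 0 or self.min_difference <= 0:
            raise ValueError("divergence thresholds must be positive")
        if self.min_difference >= self.max_assignable_divergence:
            raise ValueError("min_difference must be < max_assignable_divergence")
        if self.min_aligned <= 0:
            raise ValueError("min_aligned must be positive")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def project_to_windows(
    blocks: pd.DataFrame,
    window_size: int,
    min_aligned: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Accumulate alignment blocks into fixed non-overlapping windows.

    ``blocks`` must provide columns ``chrom, start, end, query, aligned_columns,
    mismatches`` with 0-based half-open target coordinates and ``query`` in
    {'sieversii', 'sylvestris'}.  Aligned columns and mismatches of a block are
    pro-rated over the windows it spans proportionally to overlap length and
    rounded half-up.  Blocks for the same query that cover the same target bp
    twice trigger a warning; the earlier (left-sorted) block takes precedence
    and the overlap is trimmed from the later one.

    Returns a window table with per-query aligned/mismatch counts and
    Jukes-Cantor distances ``d_sie``/``d_syl`` (NaN where the aligned length
    is below ``min_aligned`` or the mismatch proportion is saturated).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    required = {"chrom", "start", "end", "query", "aligned_columns", "mismatches"}
    missing = required - set(blocks.columns)
    if missing:
        raise ValueError(f"blocks table missing columns: {sorted(missing)}")
    bad = blocks[(blocks["end"] <= blocks["start"]) | (blocks["mismatches"] > blocks["aligned_columns"])]
    if len(bad):
        raise ValueError("blocks must satisfy end > start and mismatches <= aligned_columns")

    sizes: dict[str, int] = dict(chrom_sizes or {})
    if not sizes:
        for chrom, grp in blocks.groupby("chrom"):
            sizes[str(chrom)] = int(grp["end"].max())

    # accumulators keyed by (chrom, window index, query)
    acc_aligned: dict[tuple, float] = {}
    acc_mm: dict[tuple, float] = {}
    for query in ORIGINS:
        sub = blocks[blocks["query"] == query].sort_values(["chrom", "start", "end"])
        prev_end: dict[str, int] = {}
        for row in sub.itertuples(index=False):
            chrom = str(row.chrom)
            start, end = int(row.start), int(row.end)
            length = end - start
            eff_start = start
            last = prev_end.get(chrom, 0)
            if eff_start < last:
                warnings.warn(
                    f"overlapping {query} blocks on {chrom} at {start}; "
                    "first-block precedence applied",
                    stacklevel=2,
                )
                eff_start = min(last, end)
            prev_end[chrom] = max(last, end)
            if eff_start >= end:
                continue
            # pro-rate counts of the (possibly trimmed) block across windows
            cols_per_bp = row.aligned_columns / length
            mm_per_bp = row.mismatches / length
            w0 = eff_start // window_size
            w1 = (end - 1) // window_size
            for w in range(w0, w1 + 1):
                lo = max(eff_start, w * window_size)
                hi = min(end, (w + 1) * window_size)
                key = (chrom, w, query)
                acc_aligned[key] = acc_aligned.get(key, 0.0) + cols_per_bp * (hi - lo)
                acc_mm[key] = acc_mm.get(key, 0.0) + mm_per_bp * (hi - lo)

    rows = []
    for chrom in sorted(sizes):
        size = sizes[chrom]
        n_windows = max(1, math.ceil(size / window_size))
        for w in range(n_windows):
            start = w * window_size
            end = min((w + 1) * window_size, size)
            rec = {"chrom": chrom, "start": start, "end": end}
            for query, tag in ((SIEVERSII, "sie"), (SYLVESTRIS, "syl")):
                a = acc_aligned.get((chrom, w, query), 0.0)
                m = acc_mm.get((chrom, w, query), 0.0)
                rec[f"aligned_len_{tag}"] = int(_round_half_up(np.asarray(a)))
                rec[f"mismatch_{tag}"] = int(_round_half_up(np.asarray(m)))
            rows.append(rec)
    return add_divergence(pd.DataFrame(rows), min_aligned=min_aligned)


def add_divergence(windows: pd.DataFrame, min_aligned: int = 100) -> pd.DataFrame:
    """Attach Jukes-Cantor distances ``d_sie``/``d_syl`` to a window table
    carrying aligned/mismatch counts.  Windows with fewer than ``min_aligned``
    aligned columns, or saturated mismatch proportions, get NaN (undefined)."""
    windows = windows.copy()
    for tag in ("sie", "syl"):
        aligned = windows[f"aligned_len_{tag}"].to_numpy(float)
        mm = windows[f"mismatch_{tag}"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(aligned > 0, mm / np.maximum(aligned, 1), np.nan)
        d = np.full_like(p, np.nan)
        ok = (aligned >= min_aligned) & np.isfinite(p) & (p < 0.75)
        d[ok] = jukes_cantor_distance(p[ok])
        windows[f"d_{tag}"] = d
    return windows


def classify_window(d_sie, d_syl, thresholds: ClassificationThresholds | None = None) -> str:
    """Assign one window to 'sieversii', 'sylvestris' or 'unclear'.

    The species with the smaller corrected divergence wins iff that smaller
    value is strictly below the assignable bound and the gap between the two
    divergences strictly exceeds ``min_difference``.  Undefined (NaN)
    divergences always yield 'unclear'.
    """
    thr = thresholds or ClassificationThresholds()
    if d_sie is None or d_syl is None or not (np.isfinite(d_sie) and np.isfinite(d_syl)):
        return UNCLEAR
    lo, hi = (d_sie, d_syl) if d_sie <= d_syl else (d_syl, d_sie)
    if lo >= thr.max_assignable_divergence:
        return UNCLEAR
    if thr.both_bounded and hi >= thr.max_assignable_divergence:
        return UNCLEAR
    if abs(d_sie - d_syl) <= thr.min_difference:
        return UNCLEAR
    return SIEVERSII if d_sie < d_syl else SYLVESTRIS


def classify_windows(
    windows: pd.DataFrame, thresholds: ClassificationThresholds | None = None
) -> pd.DataFrame:
    """Vectorised :func:`classify_window` over a window table (adds 'call')."""
    thr = thresholds or ClassificationThresholds()
    d_sie = windows["d_sie"].to_numpy(float)
    d_syl = windows["d_syl"].to_numpy(float)
    defined = np.isfinite(d_sie) & np.isfinite(d_syl)
    lo = np.fmin(d_sie, d_syl)
    hi = np.fmax(d_sie, d_syl)
    assignable = defined & (lo < thr.max_assignable_divergence)
    if thr.both_bounded:
        assignable &= hi < thr.max_assignable_divergence
    assignable &= np.abs(d_sie - d_syl) > thr.min_difference
    call = np.where(
        assignable & (d_sie < d_syl),
        SIEVERSII,
        np.where(assignable & (d_syl < d_sie), SYLVESTRIS, UNCLEAR),
    )
    out = windows.copy()
    out["call"] = call
    return out


def paint_haplome(
    windows: pd.DataFrame, thresholds: ClassificationThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify windows and merge same-origin runs into ancestry tracts.

    Returns ``(calls, tracts)``: the window table with a ``call`` column, and
    a tract table (chrom, start, end, origin, n_windows) in which adjacent
    tracts on a chromosome always differ in origin and tracts tile the
    windowed extent of each chromosome.
    """
    calls = classify_windows(windows, thresholds)
    tracts: list[dict] = []
    for chrom, grp in calls.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur: dict | None = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.call == cur["origin"] and row.start == cur["end"]:
                cur["end"] = row.end
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    tracts.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": row.start,
                    "end": row.end,
                    "origin": row.call,
                    "n_windows": 1,
                }
        if cur is not None:
            tracts.append(cur)
    return calls, pd.DataFrame(tracts, columns=["chrom", "start", "end", "origin", "n_windows"])


def recombination_boundaries(tracts: pd.DataFrame) -> pd.DataFrame:
    """Candidate recombination sites: 1-bp BED intervals at junctions between
    adjacent tracts of different (non-identical) origin."""
    rows = []
    for chrom, grp in tracts.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        prev = None
        for row in grp.itertuples(index=False):
            if prev is not None and prev.origin != row.origin:
                rows.append(
                    {"chrom": chrom, "start": row.start, "end": row.start + 1,
                     "left_origin": prev.origin, "right_origin": row.origin}
                )
            prev = row
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "left_origin", "right_origin"])


@dataclass(frozen=True)
class PaintingSummary:
    """bp-weighted origin fractions for two painted haplomes and the diploid.

    Per-haplome fractions and the diploid fractions each sum to 1.  A diploid
    window is *hybrid* when its two haplome calls are distinct non-unclear
    origins, *homozygous* for a species when both calls agree on it, and
    *unresolved* when either call is unclear.  ``fraction_hybrid_of_resolved``
    re-expresses the hybrid share using only fully resolved windows as the
    denominator (the genome-wide and resolved-only conventions are both
    reported because either denominator is defensible).
    """

    fraction_sieversii: tuple[float, float]
    fraction_sylvestris: tuple[float, float]
    fraction_unclear: tuple[float, float]
    fraction_hybrid: float
    fraction_homo_sie: float
    fraction_homo_syl: float
    fraction_unresolved: float
    fraction_hybrid_of_resolved: float

    def as_dict(self) -> dict:
        return {
            "fraction_sieversii_A": self.fraction_sieversii[0],
            "fraction_sieversii_B": self.fraction_sieversii[1],
            "fraction_sylvestris_A": self.fraction_sylvestris[0],
            "fraction_sylvestris_B": self.fraction_sylvestris[1],
            "fraction_unclear_A": self.fraction_unclear[0],
            "fraction_unclear_B": self.fraction_unclear[1],
            "fraction_hybrid": self.fraction_hybrid,
            "fraction_homo_sie": self.fraction_homo_sie,
            "fraction_homo_syl": self.fraction_homo_syl,
            "fraction_unresolved": self.fraction_unresolved,
            "fraction_hybrid_of_resolved": self.fraction_hybrid_of_resolved,
        }


def _haplome_fractions(calls: pd.DataFrame) -> dict[str, float]:
    bp = (calls["end"] - calls["start"]).to_numpy(float)
    total = bp.sum()
    if total <= 0:
        raise ValueError("painting covers zero bp")
    out = {}
    for origin in (SIEVERSII, SYLVESTRIS, UNCLEAR):
        out[origin] = float(bp[(calls["call"] == origin).to_numpy()].sum() / total)
    return out


def summarize_painting(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> PaintingSummary:
    """Combine two painted haplomes (identical window grids) into per-haplome
    and diploid origin fractions, bp-weighted."""
    grid_cols = ["chrom", "start", "end"]
    a = calls_a.sort_values(grid_cols).reset_index(drop=True)
    b = calls_b.sort_values(grid_cols).reset_index(drop=True)
    if len(a) != len(b) or not all((a[c] == b[c]).all() for c in grid_cols):
        raise ValueError("haplome paintings are not on identical window grids")

    fa = _haplome_fractions(a)
    fb = _haplome_fractions(b)
    bp = (a["end"] - a["start"]).to_numpy(float)
    total = bp.sum()
    ca = a["call"].to_numpy()
    cb = b["call"].to_numpy()
    unresolved = (ca == UNCLEAR) | (cb == UNCLEAR)
    hybrid = ~unresolved & (ca != cb)
    homo_sie = ~unresolved & (ca == cb) & (ca == SIEVERSII)
    homo_syl = ~unresolved & (ca == cb) & (ca == SYLVESTRIS)
    resolved_bp = bp[~unresolved].sum()
    hybrid_bp = bp[hybrid].sum()
    return PaintingSummary(
        fraction_sieversii=(fa[SIEVERSII], fb[SIEVERSII]),
        fraction_sylvestris=(fa[SYLVESTRIS], fb[SYLVESTRIS]),
        fraction_unclear=(fa[UNCLEAR], fb[UNCLEAR]),
        fraction_hybrid=float(hybrid_bp / total),
        fraction_homo_sie=float(bp[homo_sie].sum() / total),
        fraction_homo_syl=float(bp[homo_syl].sum() / total),
        fraction_unresolved=float(bp[unresolved].sum() / total),
        fraction_hybrid_of_resolved=float(hybrid_bp / resolved_bp) if resolved_bp else float("nan"),
    )


def paint_diploid_observations(
    observations: pd.DataFrame, thresholds: ClassificationThresholds | None = None
) -> tuple[PaintingSummary, dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Paint both haplomes of a diploid from a window-observation table
    (columns haplome, chrom, start, end, aligned/mismatch counts) and
    summarise the mosaic.  Returns (summary, calls by haplome, tracts by
    haplome)."""
    thr = thresholds or ClassificationThresholds()
    calls: dict[str, pd.DataFrame] = {}
    tracts: dict[str, pd.DataFrame] = {}
    for hap in ("A", "B"):
        sub = observations[observations["haplome"] == hap].drop(columns=["haplome"])
        if sub.empty:
            raise ValueError(f"no windows for haplome {hap!r}")
        windows = add_divergence(sub, min_aligned=thr.min_aligned)
        calls[hap], tracts[hap] = paint_haplome(windows, thr)
    return summarize_painting(calls["A"], calls["B"]), calls, tracts


def sensitivity_scan(
    blocks: pd.DataFrame,
    window_sizes: Sequence[int] = (5_000, 10_000, 20_000, 30_000, 40_000, 50_000, 60_000, 70_000),
    min_aligned_list: Sequence[int] = (100, 300, 500, 1_000),
    thresholds: ClassificationThresholds | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Repaint one target across a grid of window sizes and minimum aligned
    lengths; one row of origin fractions per parameter combination.

    The returned frame carries ``max_origin_fraction_range`` in ``attrs``:
    the largest spread, over parameter combinations, of any origin fraction
    — small values mean the painting is robust to the windowing choices.
    """
    if not window_sizes or not min_aligned_list:
        raise ValueError("window_sizes and min_aligned_list must be nonempty")
    base = thresholds or ClassificationThresholds()
    rows = []
    for w in window_sizes:
        for m in min_aligned_list:
            thr = ClassificationThresholds(
                max_assignable_divergence=base.max_assignable_divergence,
                min_difference=base.min_difference,
                min_aligned=int(m),
                both_bounded=base.both_bounded,
            )
            windows = project_to_windows(blocks, int(w), min_aligned=int(m), chrom_sizes=chrom_sizes)
            calls = classify_windows(windows, thr)
            frac = _haplome_fractions(calls)
            rows.append(
                {
                    "window_size": int(w),
                    "min_aligned": int(m),
                    "fraction_sieversii": frac[SIEVERSII],
                    "fraction_sylvestris": frac[SYLVESTRIS],
                    "fraction_unclear": frac[UNCLEAR],
                }
            )
    out = pd.DataFrame(rows)
    spread = max(
        out["fraction_sieversii"].max() - out["fraction_sieversii"].min(),
        out["fraction_sylvestris"].max() - out["fraction_sylvestris"].min(),
    )
    out.attrs["max_origin_fraction_range"] = float(spread)
    return out


def intersect_regions_with_ancestry(regions: pd.DataFrame, tracts: pd.DataFrame) -> pd.DataFrame:
    """Assign each BED region the tract origin covering the majority of its bp.

    Ties, and regions whose majority overlap is with unclear tracts or with no
    tract at all, are 'unclear'.  Regions on chromosomes absent from the tract
    table are skipped with a warning.
    """
    known = set(tracts["chrom"].unique())
    rows = []
    for row in regions.itertuples(index=False):
        chrom = row.chrom
        if chrom not in known:
            warnings.warn(f"region on unknown chromosome {chrom!r} skipped", stacklevel=2)
            continue
        sub = tracts[tracts["chrom"] == chrom]
        cover = {SIEVERSII: 0, SYLVESTRIS: 0, UNCLEAR: 0}
        for t in sub.itertuples(index=False):
            ov = min(row.end, t.end) - max(row.start, t.start)
            if ov > 0:
                cover[t.origin] += ov
        uncovered = (row.end - row.start) - sum(cover.values())
        cover[UNCLEAR] += max(0, uncovered)
        best = max(cover.values())
        winners = [o for o, v in cover.items() if v == best]
        origin = winners[0] if len(winners) == 1 else UNCLEAR
        rows.append({"chrom": chrom, "start": row.start, "end": row.end, "origin": origin})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])


def smooth_divergence(
    positions: np.ndarray, divergence: np.ndarray, span: float = 0.02
) -> np.ndarray:
    """Local-regression (LOWESS) smoothing of a divergence track, for display
    only — classification always operates on raw window values."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    positions = np.asarray(positions, float)
    divergence = np.asarray(divergence, float)
    ok = np.isfinite(divergence)
    fitted = lowess(
        divergence[ok], positions[ok], frac=max(span, 3.0 / max(ok.sum(), 3)),
        return_sorted=False,
    )
    out = np.full_like(divergence, np.nan)
    out[ok] = fitted
    return out
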