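"""Decorrelated composite of multiple signals (DCMS) over a genomic grid.

The five per-population statistics (|iHS|, H12, ZHp, pi, Tajima's D) are
averaged into non-overlapping 500 kb grid windows, rank-transformed into
tail-specific empirical p-values, and combined as

    DCMS_j = sum_i w_i * log10((1 - p_ij) / p_ij),   w_i = 1 / sum_k |r_ik|,

where r is the Pearson correlation matrix of the p-value series (the sum
includes k = i, so |r_ii| = 1 bounds every weight at 1).  Perfectly
correlated statistics thus share one vote instead of inflating the
composite.  Scores are calibrated against a Gaussian fitted to their own
mean and standard deviation (upper tail), and windows are called
significant by Benjamini-Hochberg at q < 0.05.

Grid windows are half-open ``[k*grid, (k+1)*grid)`` in bp; a value whose
midpoint falls exactly on a boundary belongs to the right-hand window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: tail direction per statistic for the empirical p transform.  High |iHS|
#: and high H12 mark candidate windows (right tail); swept windows show LOW
#: pooled heterozygosity, LOW Tajima's D and LOW nucleotide diversity, so
#: ZHp, tajima_d and pi are left-tailed.  All directions are overridable.
DEFAULT_TAILS = {"ihs": "right", "H12": "right", "pi": "left", "ZHp": "left", "tajima_d": "left"}

STAT_NAMES = list(DEFAULT_TAILS)


@dataclass
class CompositeWindow:
    chrom: str
    start_bp: int
    end_bp: int
    component_p: dict
    weights: dict
    dcms: float
    p_normal: float = float("nan")
    q: float = float("nan")
    significant: bool = False


def median_smooth(series: np.ndarray, width: int = 3) -> np.ndarray:
    """Running median with shrinking, centered edge windows; width 1 = identity."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if width == 1 or x.size == 0:
        return x.copy()
    half = width // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def aggregate_to_grid(
    scores: pd.DataFrame, grid_bp: int = 500_000, value_col: str = "value"
) -> pd.DataFrame:
    """Mean per grid window of midpoint-assigned native-resolution values.

    ``scores`` needs columns ``chrom``, ``mid_bp`` and ``value_col``.
    Returns columns chrom, start_bp, end_bp, value, n_contrib.
    """
    if scores.empty:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "value", "n_contrib"])
    df = scores.copy()
    df["_win"] = (df["mid_bp"] // grid_bp).astype(int)
    agg = (
        df.groupby(["chrom", "_win"], sort=False)[value_col]
        .agg(["mean", "size"])
        .reset_index()
    )
    return pd.DataFrame(
        {
            "chrom": agg["chrom"],
            "start_bp": agg["_win"] * grid_bp,
            "end_bp": (agg["_win"] + 1) * grid_bp,
            "value": agg["mean"],
            "n_contrib": agg["size"],
        }
    )


def rank_to_p(values: np.ndarray, tail: str) -> np.ndarray:
    """Empirical tail p-values from average ranks, strictly inside (0, 1).

    right tail: p = (N - rank + 1)/(N + 1); left tail: p = rank/(N + 1),
    with average ranks for ties.  NaNs propagate.
    """
    if tail not in ("right", "left"):
        raise ValueError("tail must be 'right' or 'left'")
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least two non-missing values to rank")
    ranks = stats.rankdata(x[ok], method="average")
    if np.unique(x[ok]).size == 1:
        logger.info("all values identical; every empirical p is 0.5")
    if tail == "right":
        out[ok] = (n - ranks + 1) / (n + 1)
    else:
        out[ok] = ranks / (n + 1)
    return out


def build_p_table(
    grids: dict[str, pd.DataFrame], tails: dict[str, str] | None = None
) -> pd.DataFrame:
    """Join per-statistic grid tables and convert each to tail p-values.

    ``grids`` maps statistic name -> aggregate_to_grid output.  Returns one
    row per (chrom, start_bp, end_bp) with a ``p_<stat>`` column each.
    """
    tails = {**DEFAULT_TAILS, **(tails or {})}
    merged: pd.DataFrame | None = None
    for stat, grid in grids.items():
        if grid.empty:
            continue
        cols = grid[["chrom", "start_bp", "end_bp", "value"]].rename(columns={"value": f"v_{stat}"})
        merged = cols if merged is None else merged.merge(cols, how="outer", on=["chrom", "start_bp", "end_bp"])
    if merged is None:
        raise ValueError("no statistics to merge")
    merged = merged.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    for stat in grids:
        col = f"v_{stat}"
        if col not in merged:
            continue
        merged[f"p_{stat}"] = rank_to_p(merged[col].to_numpy(), tails[stat])
    return merged


def dcms_scores(
    p_table: pd.DataFrame, min_components: int = 3
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Composite score per window plus the full-panel decorrelation weights.

    The correlation matrix is Pearson over pairwise-complete window pairs.
    For windows missing components, weights are recomputed from the
    correlation submatrix of the statistics present (so a lone statistic
    carries weight 1); windows with fewer than ``min_components`` present
    are excluded (logged).
    """
    p_cols = [c for c in p_table.columns if c.startswith("p_")]
    stats_present = [c[2:] for c in p_cols]
    if not p_cols:
        raise ValueError("p_table carries no p_<stat> columns")
    P = p_table[p_cols].to_numpy(dtype=float)
    corr = pd.DataFrame(P, columns=stats_present).corr(method="pearson").to_numpy()
    # statistics with undefined correlations (e.g. constant series) get r = 0
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    full_weights = {s: 1.0 / np.abs(corr[i]).sum() for i, s in enumerate(stats_present)}

    rows = []
    n_skipped = 0
    for w in range(P.shape[0]):
        avail = np.flatnonzero(np.isfinite(P[w]))
        if avail.size < min_components:
            n_skipped += 1
            continue
        sub = corr[np.ix_(avail, avail)]
        wts = 1.0 / np.abs(sub).sum(axis=1)
        score = float(
            (wts * np.log10((1.0 - P[w, avail]) / P[w, avail])).sum()
        )
        rows.append(
            {
                "chrom": p_table["chrom"].iat[w],
                "start_bp": int(p_table["start_bp"].iat[w]),
                "end_bp": int(p_table["end_bp"].iat[w]),
                **{p_cols[i]: P[w, i] if np.isfinite(P[w, i]) else np.nan for i in range(len(p_cols))},
                "n_components": int(avail.size),
                "dcms": score,
            }
        )
    if n_skipped:
        logger.info("%d windows below %d available components excluded", n_skipped, min_components)
    scored = pd.DataFrame(rows)
    if len(scored) < 10:
        raise ValueError(
            f"only {len(scored)} scored windows genome-wide; refusing to calibrate"
        )
    return scored.reset_index(drop=True), full_weights


def dcms_single(p: float) -> float:
    """Single-component composite score log10((1-p)/p)."""
    return float(np.log10((1.0 - p) / p))


def significance_call(scored: pd.DataFrame, fdr_q: float = 0.05) -> pd.DataFrame:
    """Gaussian-calibrated upper-tail p, BH q, and the q < fdr_q flag.

    The reference Gaussian uses the sample mean and standard deviation of
    the DCMS scores of this population's windows.
    """
    if len(scored) < 10:
        raise ValueError("need at least 10 windows to calibrate")
    x = scored["dcms"].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance in DCMS scores; calibration undefined")
    z = (x - x.mean()) / sd
    p_normal = stats.norm.sf(z)
    _, q, _, _ = multipletests(p_normal, method="fdr_bh")
    out = scored.copy()
    out["z"] = z
    out["p_normal"] = p_normal
    out["q"] = q
    out["significant"] = q < fdr_q
    return out


def export_candidates(
    called: pd.DataFrame,
    flank_bp: int = 500_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Significant windows +- flank as merged BED records (0-based half-open).

    Internally windows are already half-open [start, end), so the BED start
    is ``max(0, start - flank)`` and the end ``end + flank`` clipped to the
    chromosome size when one is supplied.  Overlapping or bookended records
    merge.  An empty frame is a valid result.
    """
    sig = called[called["significant"]].sort_values(["chrom", "start_bp"])
    records: list[tuple[str, int, int]] = []
    for row in sig.itertuples():
        lo = max(0, int(row.start_bp) - flank_bp)
        hi = int(row.end_bp) + flank_bp
        if chrom_sizes and row.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[row.chrom])
        if records and records[-1][0] == row.chrom and lo <= records[-1][2]:
            records[-1] = (row.chrom, records[-1][1], max(records[-1][2], hi))
        else:
            records.append((str(row.chrom), lo, hi))
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)
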