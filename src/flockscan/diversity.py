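"""Pairwise Weir & Cockerham (1984) FST and LD-decay effective population size.

FST uses the two-population method-of-moments variance components a (among
populations), b (among individuals within populations) and c (within
individuals), with the per-SNP estimate a/(a+b+c) and the overall estimate
as the ratio of sums — the standard multi-locus combination, which weighs
loci by their information content.  Negative estimates, which arise from
sampling noise, are clamped to zero for reporting while the raw values are
retained.

The Ne trajectory follows the LD-decay recipe used by SNeP-style tools:
mean composite r2 in physical-distance bins, a 1/(beta*n) sample-size
correction, a distance -> recombination-rate mapping f(c), and

    Ne(c) = (1 / (4 f(c))) * (1 / r2_adj - alpha),    t = 1 / (2 f(c)),

so short distances inform distant generations and long distances recent
ones.  ``alpha`` is the mutation parameter (2 when mutation is modelled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    population_pair: tuple[str, str]
    per_snp: pd.DataFrame  # columns: id, chrom, pos, theta_raw, theta
    mean_fst: float
    mean_fst_raw: float


def _pop_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP sample size, alt-allele frequency, observed het freq."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2 * np.maximum(n, 1))
        h = (calls == 1).sum(axis=0) / np.maximum(n, 1)
    return n, p, h


def wc_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> FstResult:
    """Two-population Weir & Cockerham FST, per SNP and ratio-of-sums mean.

    SNPs monomorphic across both populations, or with fewer than two
    genotyped samples in either, are skipped.
    """
    ia, ib = g.population_index(pop_a), g.population_index(pop_b)
    n1, p1, h1 = _pop_stats(g.calls[ia])
    n2, p2, h2 = _pop_stats(g.calls[ib])

    usable = (n1 >= 2) & (n2 >= 2)
    pbar_all = np.where(usable, (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1), np.nan)
    usable &= (pbar_all > 0) & (pbar_all < 1)

    r = 2.0
    n_sum = n1 + n2
    nbar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n1**2 + n2**2) / n_sum) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / n_sum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / n_sum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta_raw = np.where(usable & (denom != 0), a / denom, np.nan)

    per_snp = g.variants[["id", "chrom", "pos"]].copy()
    per_snp["theta_raw"] = theta_raw
    per_snp["theta"] = np.clip(theta_raw, 0.0, None)
    per_snp = per_snp[usable].reset_index(drop=True)

    num = np.nansum(np.where(usable, a, 0.0))
    den = np.nansum(np.where(usable, denom, 0.0))
    mean_raw = num / den if den != 0 else float("nan")
    return FstResult(
        population_pair=(pop_a, pop_b),
        per_snp=per_snp,
        mean_fst=max(mean_raw, 0.0) if math.isfinite(mean_raw) else mean_raw,
        mean_fst_raw=mean_raw,
    )


def fst_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise mean FST over all population labels."""
    pops = g.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            val = wc_fst(g, a, b).mean_fst
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


# ---------------------------------------------------------------------------
# LD-decay Ne
# ---------------------------------------------------------------------------


def mapping_linear(d_morgans: np.ndarray) -> np.ndarray:
    """Identity mapping: recombination rate equals map distance."""
    return np.asarray(d_morgans, dtype=float)


def mapping_sved_feldman(d_morgans: np.ndarray) -> np.ndarray:
    """Sved-style drift approximation c = d / (1 + 2 d)."""
    d = np.asarray(d_morgans, dtype=float)
    return d / (1.0 + 2.0 * d)


MAPPING_FUNCTIONS = {"linear": mapping_linear, "sved_feldman": mapping_sved_feldman}


@dataclass
class NeTrajectory:
    bins: pd.DataFrame  # dist_lo_bp, dist_hi_bp, n_pairs, mean_r2, mean_r2_adj, c_morgans, Ne, t_generations
    alpha: float
    mapping: str
    beta: int

    def valid_bins(self) -> pd.DataFrame:
        return self.bins[np.isfinite(self.bins["Ne"])]


def ne_point(r2_adj: float, f_c: float, alpha: float = 2.0) -> float:
    """Single-bin Ne from adjusted r2 and mapped recombination rate."""
    if r2_adj <= 0 or 1.0 / r2_adj - alpha <= 0:
        return float("nan")
    return (1.0 / (4.0 * f_c)) * (1.0 / r2_adj - alpha)


def ne_trajectory(
    g: GenotypeMatrix,
    dist_min_bp: int = 50_000,
    dist_max_bp: int = 4_000_000,
    bin_bp: int = 50_000,
    alpha: float = 2.0,
    mapping: str = "linear",
    beta: int = 2,
    cm_per_mb: float = 1.0,
) -> NeTrajectory:
    """LD-decay Ne over distance bins from within-chromosome SNP pairs.

    ``beta`` is the sample-size correction mode: 1 for phased haplotype
    r2, 2 for unphased composite genotype r2 (the default here, since the
    input is a genotype matrix).  Bins without pairs, or whose adjusted r2
    cannot support a positive Ne, carry NaN and are logged.
    """
    if mapping not in MAPPING_FUNCTIONS:
        raise ValueError(f"unknown mapping {mapping!r}; options {sorted(MAPPING_FUNCTIONS)}")
    fmap = MAPPING_FUNCTIONS[mapping]
    edges = np.arange(dist_min_bp, dist_max_bp + bin_bp, bin_bp)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    n_used = g.n_samples
    for chrom in pd.unique(chroms):
        vidx = np.flatnonzero(chroms == chrom)
        if vidx.size < 2:
            continue
        pos = pos_all[vidx].astype(np.int64)
        x = g.calls[:, vidx].astype(float)
        x[x == MISSING] = np.nan
        # column-standardized; pairwise-complete handled by mean imputation
        mu = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), mu, x)
        sd = x.std(axis=0)
        ok = sd > 0
        xs = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
        pos_ok = pos[ok]
        corr = (xs.T @ xs) / x.shape[0]
        iu, ju = np.triu_indices(pos_ok.size, k=1)
        dist = pos_ok[ju] - pos_ok[iu]
        in_range = (dist >= dist_min_bp) & (dist < dist_max_bp)
        r2 = corr[iu[in_range], ju[in_range]] ** 2
        which = ((dist[in_range] - dist_min_bp) // bin_bp).astype(int)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)

    mid = (edges[:-1] + edges[1:]) / 2.0
    d_morgans = mid * cm_per_mb * 1e-8
    f_c = fmap(d_morgans)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        r2_adj = mean_r2 - 1.0 / (beta * n_used)
        ne = np.where(
            (counts > 0) & (r2_adj > 0) & (1.0 / r2_adj - alpha > 0),
            (1.0 / (4.0 * f_c)) * (1.0 / r2_adj - alpha),
            np.nan,
        )
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.info("%d of %d distance bins had no SNP pairs", n_empty, n_bins)
    bins = pd.DataFrame(
        {
            "dist_lo_bp": edges[:-1],
            "dist_hi_bp": edges[1:],
            "n_pairs": counts,
            "mean_r2": mean_r2,
            "mean_r2_adj": r2_adj,
            "c_morgans": f_c,
            "Ne": ne,
            "t_generations": np.rint(1.0 / (2.0 * f_c)).astype(int),
        }
    )
    return NeTrajectory(bins=bins, alpha=alpha, mapping=mapping, beta=beta)
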