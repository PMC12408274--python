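"""Within-population selection statistics.

Haplotype-based scans (EHH/iHS, H12) run on phased gametes; allele-
frequency scans (ZHp, pi, Tajima's D) run on genotype allele counts and are
therefore phase-free.  All scans emit tidy records that the composite-score
stage merges onto a common genomic grid.

On SNP arrays the ancestral allele is unknown; by default the major allele
over the full dataset stands in for it, which only affects the sign of iHS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genotype_io import MISSING, GenotypeMatrix
from .haplotypes import HaplotypeSet

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05


@njit(cache=True)
def _ihh_kernel(carr: np.ndarray, pos: np.ndarray, focal: int, step: int, cutoff: float):
    """One-sided trapezoid-integrated EHH for one carrier set.

    Walks outward from ``focal``, splitting haplotype identity groups site
    by site; returns (integral, truncated) where ``truncated`` is False
    when EHH stays above the cutoff through the chromosome end.
    """
    n, S = carr.shape
    pairs_tot = n * (n - 1) / 2.0
    group = np.zeros(n, np.int64)
    scratch = np.empty(n, np.int64)
    total = 0.0
    prev_ehh = 1.0
    prev_pos = pos[focal]
    j = focal + step
    while 0 <= j < S:
        for i in range(n):
            scratch[i] = group[i] * 2 + carr[i, j]
        order = np.argsort(scratch)
        label = 0
        prev_key = scratch[order[0]]
        group[order[0]] = 0
        for k in range(1, n):
            v = scratch[order[k]]
            if v != prev_key:
                label += 1
                prev_key = v
            group[order[k]] = label
        counts = np.zeros(label + 1, np.int64)
        for i in range(n):
            counts[group[i]] += 1
        pairs = 0.0
        for c in counts:
            pairs += c * (c - 1) / 2.0
        ehh = pairs / pairs_tot
        d = pos[j] - prev_pos
        if d < 0:
            d = -d
        total += d * (prev_ehh + ehh) / 2.0
        prev_pos = pos[j]
        prev_ehh = ehh
        if ehh < cutoff:
            return total, True
        j += step
    return total, False


@dataclass
class SiteScore:
    chrom: str
    pos: int
    statistic_name: str
    raw: float
    standardized: float
    derived_allele_freq: float


@dataclass
class WindowScore:
    chrom: str
    start_bp: int
    end_bp: int
    statistic_name: str
    value: float
    n_snps: int

    @property
    def mid_bp(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


def _ehh_one_side(carr: np.ndarray, step: int, focal: int) -> tuple[list[int], list[float]]:
    """EHH at successive sites moving outward from ``focal`` (exclusive).

    ``carr`` is the carrier haplotype matrix; returns site indices and EHH
    values, truncated after the first value below the cutoff (that value is
    included so the integral can close the final trapezoid).
    """
    n = carr.shape[0]
    pairs_total = n * (n - 1) // 2
    group = np.zeros(n, dtype=np.int64)
    idxs: list[int] = []
    vals: list[float] = []
    j = focal + step
    S = carr.shape[1]
    while 0 <= j < S:
        group = group * 2 + carr[:, j]
        _, group = np.unique(group, return_inverse=True)
        counts = np.bincount(group)
        ehh = float((counts * (counts - 1) // 2).sum() / pairs_total)
        idxs.append(j)
        vals.append(ehh)
        if ehh < EHH_CUTOFF:
            break
        j += step
    return idxs, vals


def ehh_decay(
    h: HaplotypeSet, focal_index: int, allele: int
) -> list[tuple[int, float]]:
    """EHH profile for carriers of ``allele`` (0 or 1) at the focal site.

    Returns (distance_bp, EHH) pairs on both sides, ordered by signed
    distance, including the focal point at distance 0 with EHH 1.  EHH at a
    site is the probability that two random carrier gametes are identical
    from the focal SNP through that site.
    """
    carriers = h.haplotypes[:, focal_index] == allele
    if carriers.sum() < 2:
        raise ValueError("focal allele carried by fewer than two gametes")
    carr = h.haplotypes[carriers]
    pos = h.positions_bp
    out: list[tuple[int, float]] = []
    li, lv = _ehh_one_side(carr, -1, focal_index)
    for j, v in zip(li, lv):
        out.append((int(pos[j] - pos[focal_index]), v))
    out.reverse()
    out.append((0, 1.0))
    ri, rv = _ehh_one_side(carr, +1, focal_index)
    for j, v in zip(ri, rv):
        out.append((int(pos[j] - pos[focal_index]), v))
    return out


def ihs_scan(
    h: HaplotypeSet,
    maf_min: float = 0.05,
    freq_bin: float = 0.05,
    ancestral_is_major: bool = True,
    ancestral_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Unstandardized iHS per qualifying site of one chromosome.

    raw iHS = ln(iHH_ancestral / iHH_derived); sites where either EHH
    profile reaches the chromosome end above the cutoff are skipped, as are
    sites with MAF below ``maf_min`` or singleton alleles.  Standardization
    is applied afterwards by :func:`standardize_ihs` (per chromosome, in
    derived-allele-frequency bins).

    ``ancestral_freqs`` optionally supplies dataset-wide alternate-allele
    frequencies used to orient alleles (ancestral = major allele).
    """
    n = h.n_gametes
    freq_alt = h.haplotypes.mean(axis=0)
    if ancestral_freqs is not None:
        orient = np.asarray(ancestral_freqs)
    else:
        orient = freq_alt
    # ancestral = major allele under the chosen orientation (tie -> reference)
    if ancestral_is_major:
        anc_allele = np.where(orient > 0.5, 1, 0)
    else:
        anc_allele = np.where(orient > 0.5, 0, 1)
    rows = []
    pos = h.positions_bp
    pos_f = pos.astype(np.float64)
    for j in range(h.n_sites):
        maf = min(freq_alt[j], 1 - freq_alt[j])
        if maf < maf_min:
            continue
        anc = int(anc_allele[j])
        der = 1 - anc
        n_der = int((h.haplotypes[:, j] == der).sum())
        if n_der < 2 or n - n_der < 2:
            continue
        carr_a = np.ascontiguousarray(h.haplotypes[h.haplotypes[:, j] == anc])
        carr_d = np.ascontiguousarray(h.haplotypes[h.haplotypes[:, j] == der])
        ihh_a_l, ok_al = _ihh_kernel(carr_a, pos_f, j, -1, EHH_CUTOFF)
        ihh_a_r, ok_ar = _ihh_kernel(carr_a, pos_f, j, +1, EHH_CUTOFF)
        ihh_d_l, ok_dl = _ihh_kernel(carr_d, pos_f, j, -1, EHH_CUTOFF)
        ihh_d_r, ok_dr = _ihh_kernel(carr_d, pos_f, j, +1, EHH_CUTOFF)
        if not (ok_al and ok_ar and ok_dl and ok_dr):
            continue
        ihh_a = ihh_a_l + ihh_a_r
        ihh_d = ihh_d_l + ihh_d_r
        if ihh_a <= 0 or ihh_d <= 0:
            continue
        rows.append(
            {
                "chrom": h.chrom,
                "pos": int(pos[j]),
                "raw": math.log(ihh_a / ihh_d),
                "derived_allele_freq": n_der / n,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "raw", "derived_allele_freq"])


def standardize_ihs(scores: pd.DataFrame, freq_bin: float = 0.05) -> pd.DataFrame:
    """Z-score raw iHS within (chromosome, derived-frequency-bin) groups.

    Bins with fewer than two sites are dropped (logged); the returned frame
    gains a ``standardized`` column.
    """
    if scores.empty:
        out = scores.copy()
        out["standardized"] = pd.Series(dtype=float)
        return out
    df = scores.copy()
    df["_bin"] = np.minimum(
        (df["derived_allele_freq"] / freq_bin).astype(int), int(1 / freq_bin) - 1
    )
    parts = []
    for (chrom, b), grp in df.groupby(["chrom", "_bin"], sort=False):
        if len(grp) < 2 or grp["raw"].std(ddof=0) == 0:
            logger.debug("iHS bin (%s, %s) with <2 usable sites skipped", chrom, b)
            continue
        z = (grp["raw"] - grp["raw"].mean()) / grp["raw"].std(ddof=0)
        parts.append(grp.assign(standardized=z))
    if not parts:
        out = scores.iloc[0:0].copy()
        out["standardized"] = pd.Series(dtype=float)
        return out
    return (
        pd.concat(parts)
        .drop(columns="_bin")
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------


def h12_scan(h: HaplotypeSet, window_snps: int = 25, step_snps: int = 1) -> list[WindowScore]:
    """Garud H12 in SNP-count windows: (p1+p2)^2 + sum_{i>=3} p_i^2."""
    S = h.n_sites
    if S < window_snps:
        logger.info("chromosome %s shorter than %d SNPs; no H12 windows", h.chrom, window_snps)
        return []
    out = []
    for start in range(0, S - window_snps + 1, step_snps):
        win = h.haplotypes[:, start : start + window_snps]
        _, counts = np.unique(win, axis=0, return_counts=True)
        p = np.sort(counts / h.n_gametes)[::-1]
        if p.size == 1:
            h12 = 1.0
        else:
            h12 = float((p[0] + p[1]) ** 2 + (p[2:] ** 2).sum())
        out.append(
            WindowScore(
                chrom=h.chrom,
                start_bp=int(h.positions_bp[start]),
                end_bp=int(h.positions_bp[start + window_snps - 1]),
                statistic_name="H12",
                value=h12,
                n_snps=window_snps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ZHp
# ---------------------------------------------------------------------------


def _bp_windows(pos_min: int, pos_max: int, window_bp: int, step_bp: int):
    start = (pos_min // step_bp) * step_bp
    while start <= pos_max:
        yield start, start + window_bp
        start += step_bp


def hp_value(n_major: int, n_minor: int) -> float:
    """Pooled heterozygosity 2*sum(maj)*sum(min)/(sum(maj)+sum(min))^2."""
    tot = n_major + n_minor
    if tot == 0:
        return float("nan")
    return 2.0 * n_major * n_minor / tot**2


def zhp_scan(
    g: GenotypeMatrix,
    window_bp: int = 200_000,
    overlap: float = 0.5,
    min_snps: int = 10,
) -> list[WindowScore]:
    """Pooled-heterozygosity Z score in overlapping bp windows.

    Hp per window pools major/minor allele counts over its SNPs; ZHp
    standardizes Hp over all retained windows of the dataset (genome-wide).
    Raises when the Hp variance is zero (standardization undefined).
    """
    step_bp = int(window_bp * (1 - overlap))
    if step_bp <= 0:
        raise ValueError("overlap must be < 1")
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    obs = g.calls != MISSING
    alt = np.where(obs, g.calls, 0).sum(axis=0)
    tot = 2 * obs.sum(axis=0)
    minor = np.minimum(alt, tot - alt)
    major = tot - minor

    windows = []
    for chrom in pd.unique(chroms):
        vidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[vidx]
        for lo, hi in _bp_windows(int(pos.min()), int(pos.max()), window_bp, step_bp):
            sel = vidx[(pos >= lo) & (pos < hi)]
            if sel.size < min_snps:
                continue
            hp = hp_value(int(major[sel].sum()), int(minor[sel].sum()))
            windows.append((str(chrom), lo, hi, hp, sel.size))
    if not windows:
        return []
    hps = np.array([w[3] for w in windows])
    sd = hps.std(ddof=0)
    if sd == 0:
        raise ValueError("Hp identical across all windows; ZHp undefined")
    mu = hps.mean()
    return [
        WindowScore(
            chrom=c, start_bp=lo, end_bp=hi, statistic_name="ZHp",
            value=float((hp - mu) / sd), n_snps=n,
        )
        for (c, lo, hi, hp, n) in windows
    ]


# ---------------------------------------------------------------------------
# pi and Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """The a1,a2,b1,b2,c1,c2,e1,e2 constants for n sampled allele copies."""
    if n < 2:
        raise ValueError("need at least two allele copies")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(pi_sum: float, n_seg: int, n: int) -> float:
    """Tajima's D from the pairwise-diversity sum, segregating sites and n."""
    if n_seg == 0:
        return float("nan")
    k = tajima_constants(n)
    theta_w = n_seg / k["a1"]
    var = k["e1"] * n_seg + k["e2"] * n_seg * (n_seg - 1)
    return (pi_sum - theta_w) / math.sqrt(var)


def window_frequency_stats(
    g: GenotypeMatrix,
    window_bp: int = 300_000,
    min_snps: int = 10,
) -> tuple[list[WindowScore], list[WindowScore]]:
    """Windowed nucleotide diversity and Tajima's D from allele counts.

    Per-site pairwise diversity is ``2 j (N - j) / (N (N - 1))`` with j the
    alternate-allele count among N non-missing allele copies; window pi
    divides the per-site sum by the window span in bp.  Tajima's D uses the
    same pairwise sum, the count of segregating sites, and the standard
    variance constants evaluated at the window's rounded mean N.  Windows
    are non-overlapping; those with fewer than ``min_snps`` SNPs are
    excluded.  Returns (pi_scores, tajima_d_scores).
    """
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    obs = g.calls != MISSING
    j_alt = np.where(obs, g.calls, 0).sum(axis=0).astype(float)
    N = (2 * obs.sum(axis=0)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(N >= 2, 2.0 * j_alt * (N - j_alt) / (N * (N - 1)), np.nan)
    seg = (j_alt > 0) & (j_alt < N)

    pi_scores, d_scores = [], []
    for chrom in pd.unique(chroms):
        vidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[vidx]
        for lo, hi in _bp_windows(int(pos.min()), int(pos.max()), window_bp, window_bp):
            sel = vidx[(pos >= lo) & (pos < hi)]
            if sel.size < min_snps:
                continue
            usable = sel[N[sel] >= 4]
            if usable.size == 0:
                continue
            pi_sum = float(np.nansum(pi_site[usable]))
            pi_scores.append(
                WindowScore(
                    chrom=str(chrom), start_bp=lo, end_bp=hi, statistic_name="pi",
                    value=pi_sum / window_bp, n_snps=int(sel.size),
                )
            )
            s = int(seg[usable].sum())
            n_mean = int(round(N[usable].mean()))
            d = tajima_d(pi_sum, s, n_mean) if s > 0 else float("nan")
            if math.isfinite(d):
                d_scores.append(
                    WindowScore(
                        chrom=str(chrom), start_bp=lo, end_bp=hi,
                        statistic_name="tajima_d", value=d, n_snps=int(sel.size),
                    )
                )
    return pi_scores, d_scores


def window_scores_frame(scores: list[WindowScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
                "stat": s.statistic_name, "value": s.value, "n_snps": s.n_snps,
            }
            for s in scores
        ],
        columns=["chrom", "start_bp", "end_bp", "stat", "value", "n_snps"],
    )
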