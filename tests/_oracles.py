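"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the statistical definitions, deliberately
avoiding the package's own code paths: O(n^2) pairwise loops, per-SNP
scalar arithmetic, and explicit step-up recursion.
"""

from __future__ import annotations

import math

import numpy as np


def ehh_pairwise(haplotypes: np.ndarray, positions: np.ndarray, focal: int, allele: int):
    """EHH by counting pairwise identical carrier haplotypes from focal to x."""
    carriers = haplotypes[haplotypes[:, focal] == allele]
    n = carriers.shape[0]
    pairs_tot = n * (n - 1) // 2
    out = [(0, 1.0)]
    for direction in (-1, +1):
        j = focal + direction
        while 0 <= j < haplotypes.shape[1]:
            lo, hi = sorted((focal, j))
            ident = 0
            for a in range(n):
                for b in range(a + 1, n):
                    if np.array_equal(carriers[a, lo : hi + 1], carriers[b, lo : hi + 1]):
                        ident += 1
            ehh = ident / pairs_tot
            out.append((int(positions[j] - positions[focal]), ehh))
            if ehh < 0.05:
                break
            j += direction
    return sorted(out)


def ihh_pairwise(haplotypes: np.ndarray, positions: np.ndarray, focal: int, allele: int):
    """One value: two-sided trapezoid integral of the pairwise EHH profile.

    Returns (integral, truncated_both_sides).
    """
    carriers = haplotypes[haplotypes[:, focal] == allele]
    n = carriers.shape[0]
    pairs_tot = n * (n - 1) // 2
    total = 0.0
    truncated = True
    for direction in (-1, +1):
        prev_pos, prev_ehh = positions[focal], 1.0
        j = focal + direction
        side_done = False
        while 0 <= j < haplotypes.shape[1]:
            lo, hi = sorted((focal, j))
            ident = sum(
                1
                for a in range(n)
                for b in range(a + 1, n)
                if np.array_equal(carriers[a, lo : hi + 1], carriers[b, lo : hi + 1])
            )
            ehh = ident / pairs_tot
            total += abs(int(positions[j]) - int(prev_pos)) * (prev_ehh + ehh) / 2.0
            prev_pos, prev_ehh = positions[j], ehh
            if ehh < 0.05:
                side_done = True
                break
            j += direction
        truncated = truncated and side_done
    return total, truncated


def h12_string_count(window: np.ndarray) -> float:
    """H12 by literal haplotype-string counting."""
    counts: dict[str, int] = {}
    for row in window:
        key = "".join(map(str, row))
        counts[key] = counts.get(key, 0) + 1
    p = sorted((c / window.shape[0] for c in counts.values()), reverse=True)
    if len(p) == 1:
        return 1.0
    return (p[0] + p[1]) ** 2 + sum(x**2 for x in p[2:])


def pi_pairwise(calls_window: np.ndarray) -> float:
    """Sum over sites of mean pairwise allele differences between copies.

    ``calls_window`` is diploid 0/1/2 codes (no missing); allele copies are
    expanded explicitly and all pairs compared.
    """
    total = 0.0
    for j in range(calls_window.shape[1]):
        copies = []
        for x in calls_window[:, j]:
            copies += [1] * int(x) + [0] * (2 - int(x))
        n = len(copies)
        diff = sum(
            1 for a in range(n) for b in range(a + 1, n) if copies[a] != copies[b]
        )
        total += diff / (n * (n - 1) / 2)
    return total


def tajima_d_direct(pi_sum: float, n_seg: int, n: int) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - n_seg / a1) / math.sqrt(e1 * n_seg + e2 * n_seg * (n_seg - 1))


def wc_fst_per_snp(geno_a: np.ndarray, geno_b: np.ndarray) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components a, b, c for one SNP.

    ``geno_a``/``geno_b`` are 0/1/2 codes (missing = -1) for the two
    populations; scalar arithmetic straight from the published two-
    population formulas.
    """
    r = 2
    stats = []
    for geno in (geno_a, geno_b):
        g = geno[geno >= 0]
        n_i = len(g)
        p_i = g.sum() / (2 * n_i)
        h_i = (g == 1).sum() / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by explicit step-up recursion."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, pvals[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def roh_runlength(
    calls_row: np.ndarray,
    pos: np.ndarray,
    min_snps: int,
    min_length_kb: float,
    max_gap_kb: float,
    density_kb_per_snp: float,
):
    """Run-length ROH scanner for a sample with no heterozygous calls
    anywhere outside candidate runs (every SNP window-eligible)."""
    segs = []
    run: list[int] = []
    for i in range(len(pos)):
        breaks_gap = bool(run) and (pos[i] - pos[run[-1]]) > max_gap_kb * 1000
        if calls_row[i] == 1 or breaks_gap:
            segs.append(run)
            run = []
        if calls_row[i] != 1:
            run.append(i)
    segs.append(run)
    out = []
    for run in segs:
        if len(run) < min_snps:
            continue
        length_kb = (pos[run[-1]] - pos[run[0]] + 1) / 1000
        if length_kb < min_length_kb or length_kb / len(run) > density_kb_per_snp:
            continue
        out.append((int(pos[run[0]]), int(pos[run[-1]]), len(run)))
    return out


def windowed_median(x: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    return np.array(
        [np.median(x[max(0, i - half) : i + half + 1]) for i in range(len(x))]
    )
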