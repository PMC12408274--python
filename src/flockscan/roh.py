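"""Runs of homozygosity and genomic inbreeding coefficients.

ROH detection reconstructs the PLINK ``--homozyg`` scan: a sliding window of
SNPs is classified as a "hit" when it contains at most ``max_het_in_window``
heterozygous and ``max_missing_in_window`` missing calls; a SNP is
ROH-eligible when the fraction of windows covering it that are hits reaches
``window_hit_threshold``; maximal runs of consecutive eligible,
non-heterozygous SNPs are then filtered on SNP count, physical length,
marker density, and maximum inter-SNP gap.

Four inbreeding coefficients are computed per individual:

* ``F_ROH`` — ROH length over the SNP-covered autosomal length;
* ``F_GRM`` — Yang variance-standardized relationship diagonal minus one,
  ``mean_j (x_j - 2 p_j)^2 / (2 p_j (1 - p_j)) - 1``;
* ``F_HOM`` — excess homozygosity over Hardy-Weinberg expectation,
  ``(O_hom - E_hom) / (m - E_hom)``;
* ``F_IS`` — population-level heterozygote deficit ``1 - mean(Ho)/mean(He)``.

Allele frequencies for the frequency-dependent estimators are computed
within the population of each sample; monomorphic markers are excluded
(their standardized deviations are undefined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: ROH length classes in Mb, [lower, upper) with the last unbounded
ROH_CLASSES = [(1.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, math.inf)]
ROH_CLASS_LABELS = ["1-5", "5-10", "10-15", "15-20", ">20"]


@dataclass
class ROHParams:
    """PLINK-style ROH scan parameters (lengths in kb)."""

    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_het_in_window: int = 0
    max_missing_in_window: int = 1
    density_kb_per_snp: float = 150.0
    min_snps: int = 2
    scan_window_snps: int = 50
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        for name in ("min_length_kb", "max_gap_kb", "density_kb_per_snp", "scan_window_snps", "window_hit_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One autozygous run (1-based inclusive bp coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class InbreedingRecord:
    sample_id: str
    population: str
    Ho: float
    F_ROH: float
    F_GRM: float
    F_HOM: float
    F_IS: float
    total_roh_mb: float
    roh_class_totals: dict = field(default_factory=dict)


def l_parameter(
    n_snps: int, n_individuals: int, mean_het: float, alpha: float = 0.05
) -> int:
    """Minimum SNP count per ROH controlling the false-positive run rate.

    ``L = ceil( log(alpha / (n_snps * n_individuals)) / log(1 - mean_het) )``,
    clamped below at 2.  The idea: a run of L homozygous SNPs arises by
    chance with probability ~ (1 - het)^L per start point, and alpha bounds
    the expected number of spurious runs over all SNP x individual starts.
    """
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean_het must lie strictly between 0 and 1")
    if n_snps <= 0 or n_individuals <= 0 or alpha <= 0:
        raise ValueError("n_snps, n_individuals and alpha must be positive")
    ratio = alpha / (n_snps * n_individuals)
    if ratio >= 1.0:
        return 2
    L = math.ceil(math.log(ratio) / math.log(1.0 - mean_het))
    return max(L, 2)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _eligible_snps(calls_row: np.ndarray, params: ROHParams) -> np.ndarray:
    """Hit-proportion eligibility per SNP for one sample on one chromosome."""
    S = calls_row.size
    W = min(params.scan_window_snps, S)
    if W < params.scan_window_snps:
        logger.debug("chromosome shorter than scan window; using truncated window %d", W)
    het = (calls_row == 1).astype(np.int32)
    mis = (calls_row == MISSING).astype(np.int32)
    # windowed sums via cumulative sums; windows start at 0 .. S-W
    csum_h = np.concatenate([[0], np.cumsum(het)])
    csum_m = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(S - W + 1)
    hit = (
        (csum_h[starts + W] - csum_h[starts] <= params.max_het_in_window)
        & (csum_m[starts + W] - csum_m[starts] <= params.max_missing_in_window)
    )
    # per-SNP: windows covering SNP i are starts in [i-W+1, i]
    chit = np.concatenate([[0], np.cumsum(hit.astype(np.int64))])
    lo = np.clip(np.arange(S) - W + 1, 0, S - W)
    hi = np.clip(np.arange(S), 0, S - W)
    n_hits = chit[hi + 1] - chit[lo]
    n_wins = hi - lo + 1
    return n_hits / n_wins >= params.window_hit_threshold


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """PLINK-style ROH scan over every sample and chromosome."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        vidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[vidx]
        for i, sample in enumerate(g.samples):
            row = g.calls[i, vidx]
            elig = _eligible_snps(row, params)
            runnable = elig & (row != 1)  # homozygous or missing
            segments.extend(
                _runs_to_segments(runnable, row, pos, sample.sample_id, str(chrom), params)
            )
    return segments


def _runs_to_segments(
    runnable: np.ndarray,
    row: np.ndarray,
    pos: np.ndarray,
    sample_id: str,
    chrom: str,
    params: ROHParams,
) -> list[ROHSegment]:
    segs = []
    S = runnable.size
    i = 0
    while i < S:
        if not runnable[i]:
            i += 1
            continue
        j = i
        while j + 1 < S and runnable[j + 1] and (pos[j + 1] - pos[j]) <= params.max_gap_kb * 1000:
            j += 1
        segs.extend(_emit(i, j, pos, sample_id, chrom, params))
        i = j + 1
    return segs


def _emit(i: int, j: int, pos, sample_id, chrom, params: ROHParams) -> list[ROHSegment]:
    n = j - i + 1
    length_kb = (pos[j] - pos[i] + 1) / 1000.0
    if (
        n >= params.min_snps
        and length_kb >= params.min_length_kb
        and length_kb / n <= params.density_kb_per_snp
    ):
        return [
            ROHSegment(
                sample_id=sample_id,
                chrom=chrom,
                start_bp=int(pos[i]),
                end_bp=int(pos[j]),
                n_snps=n,
            )
        ]
    return []


def classify_roh(segments: list[ROHSegment]) -> pd.DataFrame:
    """Per-sample Mb totals in the 1-5 / 5-10 / 10-15 / 15-20 / >20 Mb classes."""
    rows: dict[str, dict[str, float]] = {}
    for seg in segments:
        totals = rows.setdefault(seg.sample_id, {lab: 0.0 for lab in ROH_CLASS_LABELS})
        for (lo, hi), lab in zip(ROH_CLASSES, ROH_CLASS_LABELS):
            if lo <= seg.length_mb < hi:
                totals[lab] += seg.length_mb
                break
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=ROH_CLASS_LABELS)
    df.index.name = "sample_id"
    return df.fillna(0.0)


# ---------------------------------------------------------------------------
# inbreeding coefficients
# ---------------------------------------------------------------------------


def covered_autosome_bp(g: GenotypeMatrix) -> int:
    """SNP-covered length: sum over chromosomes of (last - first + 1) bp."""
    total = 0
    for _, grp in g.variants.groupby("chrom", sort=False):
        total += int(grp["pos"].max() - grp["pos"].min() + 1)
    return total


def inbreeding_coefficients(
    g: GenotypeMatrix, segments: list[ROHSegment]
) -> pd.DataFrame:
    """Per-sample Ho, F_ROH, F_GRM, F_HOM plus population-level F_IS.

    Returns a DataFrame with one row per sample; ``F_IS`` is NaN for
    populations with a single sample (logged).
    """
    covered = covered_autosome_bp(g)
    roh_bp = {sid: 0 for sid in g.sample_ids()}
    for seg in segments:
        roh_bp[seg.sample_id] = roh_bp.get(seg.sample_id, 0) + seg.length_bp
    class_totals = classify_roh(segments)

    calls = g.calls
    obs = calls != MISSING
    het = calls == 1
    ho = np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / np.maximum(obs.sum(axis=1), 1), np.nan)

    f_grm = np.full(g.n_samples, np.nan)
    f_hom = np.full(g.n_samples, np.nan)
    f_is = np.full(g.n_samples, np.nan)
    for pop in g.populations:
        idx = g.population_index(pop)
        p = g.allele_frequencies(idx)
        poly = (p > 0) & (p < 1) & np.isfinite(p)
        if not poly.any():
            logger.warning("population %s: no polymorphic markers; F_GRM/F_HOM undefined", pop)
            continue
        pj = p[poly]
        e_het_j = 2 * pj * (1 - pj)
        for i in idx:
            x = calls[i, poly].astype(float)
            ok = x != MISSING
            m = int(ok.sum())
            if m == 0:
                continue
            dev2 = (x[ok] - 2 * pj[ok]) ** 2 / e_het_j[ok]
            f_grm[i] = dev2.mean() - 1.0
            o_hom = float((x[ok] != 1).sum())
            e_hom = float((1 - e_het_j[ok]).sum())
            if m - e_hom != 0:
                f_hom[i] = (o_hom - e_hom) / (m - e_hom)
        if idx.size < 2:
            logger.warning("population %s has a single sample; F_IS undefined", pop)
        else:
            mean_ho = np.nanmean(ho[idx])
            mean_he = float(e_het_j.mean())
            if mean_he > 0:
                f_is[idx] = 1.0 - mean_ho / mean_he

    rows = []
    for i, s in enumerate(g.samples):
        totals = (
            class_totals.loc[s.sample_id].to_dict()
            if s.sample_id in class_totals.index
            else {lab: 0.0 for lab in ROH_CLASS_LABELS}
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "population": s.population,
                "Ho": float(ho[i]),
                "F_ROH": roh_bp[s.sample_id] / covered if covered else np.nan,
                "F_GRM": float(f_grm[i]),
                "F_HOM": float(f_hom[i]),
                "F_IS": float(f_is[i]),
                "total_roh_mb": roh_bp[s.sample_id] / 1e6,
                **{f"roh_{lab}_mb": totals[lab] for lab in ROH_CLASS_LABELS},
            }
        )
    return pd.DataFrame(rows)


def write_hom(segments: list[ROHSegment], g: GenotypeMatrix, path: str | Path) -> None:
    """Export segments as a PLINK-style .hom TSV."""
    pop_of = {s.sample_id: s.population for s in g.samples}
    rows = [
        {
            "FID": pop_of.get(seg.sample_id, "0"),
            "IID": seg.sample_id,
            "CHR": seg.chrom,
            "POS1": seg.start_bp,
            "POS2": seg.end_bp,
            "KB": seg.length_bp / 1000.0,
            "NSNP": seg.n_snps,
        }
        for seg in segments
    ]
    pd.DataFrame(rows, columns=["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP"]).to_csv(
        path, sep="\t", index=False
    )
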