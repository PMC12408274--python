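"""Genotype data model, PLINK-format I/O, and marker/sample filtering.

The in-memory container is :class:`GenotypeMatrix`: a samples x variants
matrix of allele-count codes (0 = a1/a1, 1 = a1/a2, 2 = a2/a2, -1 = missing)
with a variant map held as a pandas DataFrame and one :class:`SampleRecord`
per individual carrying its population label.

Genotype files follow the PLINK 1.9 dialects: whitespace-delimited PED/MAP
text and SNP-major BED/BIM/FAM binary (magic bytes 0x6c 0x1b 0x01).  For
text input the reference allele a1 is the minor allele computed on load
(ties broken toward the lexicographically smaller allele); the BIM file
stores the allele order explicitly, so binary round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: columns of the variant map DataFrame
VARIANT_COLUMNS = ["chrom", "pos", "id", "a1", "a2"]


class PlinkFormatError(ValueError):
    """Malformed or inconsistent PLINK input."""


@dataclass(frozen=True)
class Variant:
    """One biallelic array marker with 1-based bp coordinates."""

    chrom: str
    pos: int
    id: str
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"variant {self.id}: position must be positive")
        if self.a1 == self.a2:
            raise ValueError(f"variant {self.id}: alleles must differ")


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual and its population (breed) label."""

    sample_id: str
    population: str


@dataclass
class GenotypeMatrix:
    """Diploid call matrix with its variant map and sample records.

    ``calls[i, j]`` counts copies of allele ``a2`` carried by sample ``i``
    at variant ``j`` (0/1/2), with ``-1`` for a missing call.
    """

    samples: list[SampleRecord]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in dataset")

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in input order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def population_index(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if s.population == population],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population label: {population!r}")
        return idx

    def allele_frequencies(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele a2 per variant over non-missing calls (NaN if none)."""
        calls = self.calls if sample_index is None else self.calls[sample_index]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def subset(
        self,
        sample_index: np.ndarray | None = None,
        variant_index: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_index is None else np.asarray(sample_index)
        vi = np.arange(self.n_variants) if variant_index is None else np.asarray(variant_index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class QCReport:
    """Record of what a QC pass removed and why."""

    n_samples_in: int
    n_variants_in: int
    n_samples_out: int
    n_variants_out: int
    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": "sample", "id": sid, "reason": f"missing_rate={rate:.4f}"}
            for sid, rate in self.removed_samples
        ] + [{"entity": "variant", "id": vid, "reason": why} for vid, why in self.removed_variants]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, vid, _cm, pos = parts
            elif len(parts) == 3:
                chrom, vid, pos = parts
            else:
                raise PlinkFormatError(f"{path}: bad MAP line: {line!r}")
            rows.append((chrom, int(pos), vid))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    return df


def _load_text(prefix: Path) -> GenotypeMatrix:
    vmap = _read_map(prefix.with_suffix(".map"))
    m = len(vmap)
    samples: list[SampleRecord] = []
    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            samples.append(SampleRecord(sample_id=iid, population=fid))
            al = np.array(parts[6::2], dtype=object)
            bl = np.array(parts[7::2], dtype=object)
            rows_a.append(al)
            rows_b.append(bl)
    if not samples:
        raise PlinkFormatError(f"{prefix}.ped: no samples")
    A = np.vstack(rows_a)
    B = np.vstack(rows_b)

    calls = np.empty((len(samples), m), dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        col_a, col_b = A[:, j], B[:, j]
        obs = (col_a != "0") & (col_b != "0")
        alleles = sorted(set(col_a[obs]) | set(col_b[obs]))
        if len(alleles) > 2:
            raise PlinkFormatError(
                f"variant {vmap['id'][j]}: more than two alleles {alleles}"
            )
        if len(alleles) == 0:
            alleles = ["0", "0"]  # fully missing column; placeholder alleles
            a1, a2 = "N", "M"
        elif len(alleles) == 1:
            a2 = alleles[0]
            a1 = "A" if a2 != "A" else "C"  # placeholder for the unseen allele
        else:
            # a1 = minor allele; frequency tie -> lexicographically smaller
            cnt = {al: int((col_a[obs] == al).sum() + (col_b[obs] == al).sum()) for al in alleles}
            a1, a2 = sorted(alleles, key=lambda al: (cnt[al], al))
            if cnt[a1] == cnt[a2]:
                a1, a2 = sorted(alleles)
        dose = np.where(col_a == a2, 1, 0) + np.where(col_b == a2, 1, 0)
        calls[:, j] = np.where(obs, dose, MISSING)
        a1s.append(a1)
        a2s.append(a2)
    vmap = vmap.assign(a1=a1s, a2=a2s)[VARIANT_COLUMNS]
    return GenotypeMatrix(samples=samples, variants=vmap, calls=calls)


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype codes in a SNP-major BED, per pair of bits:
#   00 -> hom a1 (0), 01 -> missing, 10 -> het (1), 11 -> hom a2 (2)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _load_binary(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    samples = [SampleRecord(sample_id=r.iid, population=r.fid) for r in fam.itertuples()]
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (want SNP-major PLINK BED)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} variants"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts) & 0b11
    codes = two_bit.reshape(m, -1)[:, :n]
    calls = _BED_DECODE[codes].T  # samples x variants
    vmap = bim.assign(pos=bim["pos"].astype(int))[VARIANT_COLUMNS]
    return GenotypeMatrix(samples=samples, variants=vmap, calls=calls.copy())


def load_plink(path_prefix: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Load a PLINK dataset from ``prefix.{ped,map}`` or ``prefix.{bed,bim,fam}``.

    ``format`` is one of ``text``, ``binary``, ``auto`` (binary preferred
    when both file sets exist).
    """
    prefix = Path(path_prefix)
    if format == "auto":
        format = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if format == "binary":
        return _load_binary(prefix)
    if format == "text":
        return _load_text(prefix)
    raise ValueError(f"unknown format {format!r}")


def save_plink(g: GenotypeMatrix, path_prefix: str | Path, format: str = "binary") -> list[Path]:
    """Write ``g`` as PED/MAP (text) or SNP-major BED/BIM/FAM (binary)."""
    if g.n_variants == 0 or g.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = g.variants
    if format == "text":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for r in v.itertuples():
                fh.write(f"{r.chrom}\t{r.id}\t0\t{r.pos}\n")
        a1 = v["a1"].to_numpy()
        a2 = v["a2"].to_numpy()
        first = np.where(g.calls >= 1, a2, a1)
        second = np.where(g.calls == 2, a2, a1)
        miss = g.calls == MISSING
        first = np.where(miss, "0", first)
        second = np.where(miss, "0", second)
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, s in enumerate(g.samples):
                geno = " ".join(
                    f"{first[i, j]} {second[i, j]}" for j in range(g.n_variants)
                )
                fh.write(f"{s.population} {s.sample_id} 0 0 0 -9 {geno}\n")
        return [prefix.with_suffix(".ped"), prefix.with_suffix(".map")]
    if format == "binary":
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for r in v.itertuples():
                fh.write(f"{r.chrom}\t{r.id}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for s in g.samples:
                fh.write(f"{s.population} {s.sample_id} 0 0 0 -9\n")
        n = g.n_samples
        enc = np.zeros_like(g.calls, dtype=np.uint8)
        for code, bits in _BED_ENCODE.items():
            enc[g.calls == code] = bits
        pad = (-n) % 4
        if pad:
            enc = np.vstack([enc, np.zeros((pad, g.n_variants), dtype=np.uint8)])
        enc = enc.T.reshape(g.n_variants, -1, 4)  # snp-major, 4 samples per byte
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (enc << shifts).sum(axis=2).astype(np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
        return [prefix.with_suffix(s) for s in (".bed", ".bim", ".fam")]
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC and marker filtering
# ---------------------------------------------------------------------------


def _is_autosome(chrom: str, n_autosomes: int) -> bool:
    try:
        c = int(chrom)
    except (TypeError, ValueError):
        return False
    return 1 <= c <= n_autosomes


def apply_qc(
    g: GenotypeMatrix,
    sample_max_missing: float = 0.10,
    variant_max_missing: float = 0.05,
    autosomes_only: bool = True,
    n_autosomes: int = 26,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate QC: drop samples, then variants, then non-autosomal markers.

    Sample call-rate is assessed first on the full marker set; variant
    missingness is then computed over the *retained* samples only, so a
    variant failing only because of a bad sample survives once that sample
    is gone.
    """
    for name, thr in (("sample_max_missing", sample_max_missing), ("variant_max_missing", variant_max_missing)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    miss = g.calls == MISSING
    sample_rate = miss.mean(axis=1) if g.n_variants else np.zeros(g.n_samples)
    keep_s = sample_rate <= sample_max_missing
    removed_samples = [
        (g.samples[i].sample_id, float(sample_rate[i])) for i in np.flatnonzero(~keep_s)
    ]
    if not keep_s.any():
        raise ValueError("QC removed every sample; check sample_max_missing")

    variant_rate = miss[keep_s].mean(axis=0)
    keep_v = variant_rate <= variant_max_missing
    removed_variants = [
        (g.variants["id"][j], f"missing_rate={variant_rate[j]:.4f}")
        for j in np.flatnonzero(~keep_v)
    ]
    if autosomes_only:
        auto = g.variants["chrom"].map(lambda c: _is_autosome(c, n_autosomes)).to_numpy()
        for j in np.flatnonzero(keep_v & ~auto):
            removed_variants.append((g.variants["id"][j], "non_autosomal"))
        keep_v &= auto

    out = g.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_v))
    report = QCReport(
        n_samples_in=g.n_samples,
        n_variants_in=g.n_variants,
        n_samples_out=out.n_samples,
        n_variants_out=out.n_variants,
        removed_samples=removed_samples,
        removed_variants=removed_variants,
        thresholds={
            "sample_max_missing": sample_max_missing,
            "variant_max_missing": variant_max_missing,
            "autosomes_only": autosomes_only,
        },
    )
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def genotype_r2(calls: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of genotype codes (composite LD), pairwise-complete."""
    a, b = calls[:, i].astype(float), calls[:, j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained variant indices.

    Within each window every retained pair is checked; while some pair
    exceeds the r2 threshold the pair member with the lower MAF is dropped
    (equal MAF: the later map position).  Windows advance by ``step_snps``
    and never span chromosomes.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    freqs = g.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.ones(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window_snps]
            _prune_window(g.calls, win, keep, maf, r2_threshold)
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return np.flatnonzero(keep)


def _prune_window(
    calls: np.ndarray, win: np.ndarray, keep: np.ndarray, maf: np.ndarray, thr: float
) -> None:
    live = [int(j) for j in win if keep[j]]
    changed = True
    while changed:
        changed = False
        for x in range(len(live)):
            for y in range(x + 1, len(live)):
                i, j = live[x], live[y]
                if not (keep[i] and keep[j]):
                    continue
                if genotype_r2(calls, i, j) > thr:
                    # drop lower-MAF member; ties drop the later position (j)
                    drop = j if (maf[j] <= maf[i] or np.isnan(maf[j])) else i
                    keep[drop] = False
                    changed = True
        live = [j for j in live if keep[j]]
    return


# ---------------------------------------------------------------------------
# Relatedness filtering
# ---------------------------------------------------------------------------


def grm(calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Variance-standardized (Yang) genomic relationship matrix.

    G[i,k] = mean_j (x_ij - 2p_j)(x_kj - 2p_j) / (2 p_j (1-p_j)) over
    non-monomorphic markers; missing calls are imputed at 2p (zero deviation).
    """
    poly = (freqs > 0) & (freqs < 1) & np.isfinite(freqs)
    if not poly.any():
        raise ValueError("no polymorphic markers; relationship matrix undefined")
    x = calls[:, poly].astype(float)
    p = freqs[poly]
    x[x == MISSING] = np.nan
    dev = x - 2 * p
    dev = np.nan_to_num(dev, nan=0.0)
    w = dev / np.sqrt(2 * p * (1 - p))
    return (w @ w.T) / poly.sum()


def kinship_filter(g: GenotypeMatrix, threshold: float = 0.25) -> list[str]:
    """Drop one member of each close-kin pair; returns retained sample ids.

    Relatedness is the off-diagonal of the within-population Yang GRM.  The
    member of a flagged pair with more flagged partners is removed first
    (ties remove the later sample), greedily until no pair exceeds the
    threshold.
    """
    flagged: set[tuple[int, int]] = set()
    for pop in g.populations:
        idx = g.population_index(pop)
        if idx.size < 2:
            continue
        sub = g.calls[idx]
        freqs = g.allele_frequencies(idx)
        G = grm(sub, freqs)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if G[a, b] > threshold:
                    flagged.add((int(idx[a]), int(idx[b])))
    removed: set[int] = set()
    pairs = set(flagged)
    while pairs:
        degree: dict[int, int] = {}
        for a, b in pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = max(degree, key=lambda s: (degree[s], s))  # tie -> later sample
        removed.add(worst)
        pairs = {p for p in pairs if worst not in p}
    return [s.sample_id for i, s in enumerate(g.samples) if i not in removed]
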