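"""Phased haplotype container and phased-VCF round-trip.

Haplotype statistics (EHH/iHS, H12) operate on gametes: a 2n x S matrix of
0/1 alleles per chromosome, with no missing entries — phasing is an input
contract, not something this package performs.  VCF reading goes through
pysam; writing emits minimal plain-text VCF 4.2 with ``0|1``-style GT fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam


@dataclass
class HaplotypeSet:
    """Phased 0/1 alleles for one chromosome.

    Rows of ``haplotypes`` are gametes (two consecutive rows per sample, in
    ``sample_ids`` order); columns align with ``positions_bp`` (ascending,
    1-based).  Allele 1 is the alternate allele of the corresponding variant.
    """

    chrom: str
    positions_bp: np.ndarray
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions_bp.size:
            raise ValueError("haplotype matrix does not align with positions")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("odd gamete count; expected two gametes per sample")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("phased haplotypes must be complete 0/1 alleles")
        if np.any(np.diff(self.positions_bp) < 0):
            raise ValueError("positions must be sorted ascending")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.n_samples)]

    @property
    def n_gametes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.n_gametes // 2

    @property
    def n_sites(self) -> int:
        return self.positions_bp.size

    def gamete_sample(self, gamete_index: int) -> str:
        return self.sample_ids[gamete_index // 2]

    def subset_samples(self, sample_index: np.ndarray) -> "HaplotypeSet":
        sample_index = np.asarray(sample_index, dtype=int)
        rows = np.empty(2 * sample_index.size, dtype=int)
        rows[0::2] = 2 * sample_index
        rows[1::2] = 2 * sample_index + 1
        return HaplotypeSet(
            chrom=self.chrom,
            positions_bp=self.positions_bp,
            haplotypes=self.haplotypes[rows],
            sample_ids=[self.sample_ids[i] for i in sample_index],
        )

    def genotype_dosage(self) -> np.ndarray:
        """Per-sample alternate-allele dosage (n_samples x n_sites)."""
        return (
            self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        ).astype(np.int8)


def write_phased_vcf(
    hapsets: list[HaplotypeSet],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    ref_allele: str = "A",
    alt_allele: str = "C",
) -> Path:
    """Write chromosomes as one plain-text phased VCF (GT fields ``h0|h1``)."""
    path = Path(path)
    if not hapsets:
        raise ValueError("no haplotype sets to write")
    sample_ids = hapsets[0].sample_ids
    for h in hapsets:
        if h.sample_ids != sample_ids:
            raise ValueError("all chromosomes must carry the same samples")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=flockscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for h in hapsets:
            length = (
                chrom_lengths[h.chrom]
                if chrom_lengths and h.chrom in chrom_lengths
                else int(h.positions_bp[-1]) if h.n_sites else 1
            )
            fh.write(f"##contig=<ID={h.chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for h in hapsets:
            a = h.haplotypes[0::2]
            b = h.haplotypes[1::2]
            for j in range(h.n_sites):
                gts = "\t".join(f"{a[i, j]}|{b[i, j]}" for i in range(h.n_samples))
                fh.write(
                    f"{h.chrom}\t{h.positions_bp[j]}\t{h.chrom}_{h.positions_bp[j]}\t"
                    f"{ref_allele}\t{alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
                )
    return path


def read_phased_vcf(path: str | Path) -> list[HaplotypeSet]:
    """Read a phased VCF into one :class:`HaplotypeSet` per chromosome."""
    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            col = np.empty(2 * len(sample_ids), dtype=np.int8)
            for i, sid in enumerate(sample_ids):
                call = rec.samples[sid]
                alleles = call.allele_indices
                if alleles is None or None in alleles or len(alleles) != 2:
                    raise ValueError(
                        f"{path}: missing or non-diploid GT at {rec.chrom}:{rec.pos}"
                    )
                if not call.phased:
                    raise ValueError(f"{path}: unphased GT at {rec.chrom}:{rec.pos}")
                col[2 * i], col[2 * i + 1] = alleles
            pos_list, cols = per_chrom.setdefault(rec.chrom, ([], []))
            pos_list.append(rec.pos)
            cols.append(col)
    return [
        HaplotypeSet(
            chrom=chrom,
            positions_bp=np.array(pos, dtype=np.int64),
            haplotypes=np.column_stack(cols),
            sample_ids=sample_ids,
        )
        for chrom, (pos, cols) in per_chrom.items()
    ]
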