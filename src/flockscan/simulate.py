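"""Forward Wright-Fisher simulator for array-like multi-population SNP data.

One engine covers every scenario the analysis stages need: discrete
generations of diploid populations with size schedules (bottlenecks),
island-model migration, Poisson-crossover recombination at a uniform
1 cM/Mb (configurable), optional directional selection at a single sweep
site (fitness 1 : 1+s : 1+2s), and a small-flock mating option in which a
population is partitioned into persistent flocks and parents are drawn
within flock — the pattern that drives recent autozygosity in smallholder
husbandry.

Founder haplotypes are drawn site-independently from a U-shaped (Beta)
allele-frequency density clipped to a MAF floor — the ascertainment bias a
SNP chip designed on a broad discovery panel carries — so linkage
disequilibrium is built up by drift during the burn-in generations.
Markers that later drift to fixation in a sampled population stay on the
"chip" and are emitted as monomorphic genotypes, exactly as array data
behave.  Every run is fully determined by its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleRecord, VARIANT_COLUMNS, save_plink
from .haplotypes import HaplotypeSet, write_phased_vcf

logger = logging.getLogger(__name__)


@dataclass
class PopulationConfig:
    """One population: label, diploid-size schedule, and sample count.

    ``size`` is either a constant int or a list of ``(from_generation,
    size)`` breakpoints sorted by generation (generation 0 = founders).
    """

    label: str
    size: int | list[tuple[int, int]]
    n_sample: int

    def size_at(self, generation: int) -> int:
        if isinstance(self.size, int):
            return self.size
        current = self.size[0][1]
        for gen, size in self.size:
            if generation >= gen:
                current = size
        return current


@dataclass
class SweepConfig:
    population: str
    chromosome: int  # 0-based chromosome index
    position_bp: int
    s: float
    start_generation: int = 0
    initial_freq: float = 0.1
    stop_at_freq: float | None = None  # switch selection off at near-fixation
    origin_block_bp: int = 2_000_000  # shared ancestral haplotype around the site
    max_retries: int = 5


@dataclass
class DemographyConfig:
    populations: list[PopulationConfig]
    generations: int
    seed: int
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    target_snps: int = 40_000
    snp_spacing_model: str = "jittered"  # or "uniform"
    migration: float | np.ndarray = 0.0
    sweep: SweepConfig | None = None
    mating: str = "random"  # or "small_flock"
    flock_size: int = 10
    cm_per_mb: float = 1.0
    ascertainment_maf: float = 0.02
    founder_beta: float = 0.5  # Beta(b, b) founder frequency density

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in self.populations:
            if p.size_at(0) < 2:
                raise ValueError(f"population {p.label}: size must be >= 2")
        if self.mating not in ("random", "small_flock"):
            raise ValueError("mating must be 'random' or 'small_flock'")

    def migration_matrix(self) -> np.ndarray:
        """Per-gamete source probabilities off the diagonal.

        A scalar rate m follows the Wright island-model convention: each
        gamete is drawn from a metapopulation-wide migrant pool with
        probability m, and the pool includes the source deme — so the
        cross-deme rate is m/k per other deme and the classic
        FST = 1/(4Nm+1) approximation applies.  A full matrix is taken
        as explicit per-pair rates instead.
        """
        k = len(self.populations)
        if np.isscalar(self.migration):
            m = float(self.migration)
            M = np.full((k, k), m / k if k > 1 else 0.0)
            np.fill_diagonal(M, 0.0)
        else:
            M = np.asarray(self.migration, dtype=float)
            if M.shape != (k, k):
                raise ValueError("migration matrix shape must match population count")
        if (M < 0).any() or (M.sum(axis=1) >= 1).any():
            raise ValueError("migration rates must be >= 0 with row sums < 1")
        return M


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    haplotypes: list[HaplotypeSet]
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, str]:
        """Emit PED/MAP, BED/BIM/FAM, phased VCF and the truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = outdir / prefix
        save_plink(self.genotypes, stem, format="text")
        save_plink(self.genotypes, stem, format="binary")
        out = {"plink": str(stem)}
        if self.haplotypes:
            out["vcf"] = str(write_phased_vcf(self.haplotypes, stem.with_suffix(".vcf")))
        manifest = stem.with_suffix(".truth.json")
        manifest.write_text(json.dumps(self.truth, indent=2, default=float))
        out["truth"] = str(manifest)
        return out


def expected_island_fst(N: int, m: float) -> float:
    """Classic island-model equilibrium approximation FST = 1/(4 N m + 1)."""
    if N * m <= 0:
        raise ValueError("N*m must be positive")
    return 1.0 / (4.0 * N * m + 1.0)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def _recombine(
    haps: np.ndarray, parents: np.ndarray, pos_m: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per parent via Poisson crossovers, fully vectorized.

    ``haps`` is (2N, S) for the parental generation; ``parents`` gives the
    diploid parent index per gamete; ``pos_m`` is SNP positions in Morgans.
    """
    G = parents.size
    S = haps.shape[1]
    length_m = float(pos_m[-1] - pos_m[0]) if S > 1 else 0.0
    start = rng.integers(0, 2, size=G)
    n_cross = rng.poisson(length_m, size=G) if length_m > 0 else np.zeros(G, dtype=int)
    flips = np.zeros((G, S), dtype=np.int8)
    total = int(n_cross.sum())
    if total:
        gamete_ids = np.repeat(np.arange(G), n_cross)
        bp = rng.uniform(pos_m[0], pos_m[-1], size=total)
        col = np.searchsorted(pos_m, bp, side="left")
        np.minimum(col, S - 1, out=col)
        np.add.at(flips, (gamete_ids, col), 1)
    phase = (start[:, None] + np.cumsum(flips, axis=1)) % 2
    h0 = haps[2 * parents]
    h1 = haps[2 * parents + 1]
    return np.where(phase == 0, h0, h1).astype(np.int8)


def _choose_parents(
    pop_sizes: list[int],
    dest: int,
    n_gametes: int,
    M: np.ndarray,
    weights: list[np.ndarray | None],
    mating: str,
    flock_size: int,
    offspring_ids: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Source population and diploid parent index for each gamete."""
    k = len(pop_sizes)
    probs = M[dest].copy()
    probs[dest] = 1.0 - probs.sum()
    src = rng.choice(k, size=n_gametes, p=probs)
    parent = np.empty(n_gametes, dtype=np.int64)
    for s in np.unique(src):
        sel = src == s
        n_sel = int(sel.sum())
        if s == dest and mating == "small_flock":
            # offspring inherit their flock block; parents drawn within it
            flocks = offspring_ids[sel] // flock_size
            n_flocks = max(pop_sizes[s] // flock_size, 1)
            flocks = flocks % n_flocks
            lo = flocks * flock_size
            hi = np.minimum(lo + flock_size, pop_sizes[s])
            parent[sel] = lo + (rng.random(n_sel) * (hi - lo)).astype(np.int64)
        elif weights[s] is not None:
            w = weights[s]
            parent[sel] = rng.choice(pop_sizes[s], size=n_sel, p=w)
        else:
            parent[sel] = rng.integers(0, pop_sizes[s], size=n_sel)
    return src, parent


def _simulate_once(config: DemographyConfig, rng: np.random.Generator) -> tuple[list[list[np.ndarray]], list[np.ndarray], list[float], dict]:
    k = len(config.populations)
    n_chrom = config.n_chromosomes
    snps_per_chrom = max(config.target_snps // n_chrom, 2)

    positions: list[np.ndarray] = []
    for _ in range(n_chrom):
        spacing = config.chrom_length_bp / snps_per_chrom
        base = (np.arange(snps_per_chrom) + 0.5) * spacing
        if config.snp_spacing_model == "jittered":
            base = base + rng.uniform(-0.4, 0.4, size=snps_per_chrom) * spacing
        pos = np.sort(np.round(base).astype(np.int64))
        pos = np.maximum(pos, 1)
        pos = np.unique(pos)
        while pos.size < snps_per_chrom:  # re-fill collisions after rounding
            extra = rng.integers(1, config.chrom_length_bp, size=snps_per_chrom - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        positions.append(pos[:snps_per_chrom])

    # chip-style ascertainment: founder frequencies clipped to the MAF floor
    founder_freq = [
        np.clip(
            rng.beta(config.founder_beta, config.founder_beta, size=snps_per_chrom),
            config.ascertainment_maf, 1.0 - config.ascertainment_maf,
        )
        for _ in range(n_chrom)
    ]
    # haps[pop][chrom] -> (2N, S) uint8
    haps: list[list[np.ndarray]] = []
    for p in config.populations:
        n0 = p.size_at(0)
        haps.append(
            [
                (rng.random((2 * n0, snps_per_chrom)) < f).astype(np.int8)
                for f in founder_freq
            ]
        )

    sweep = config.sweep
    sweep_pop = sweep_site = None
    sweep_traj: list[float] = []
    if sweep is not None:
        sweep_pop = next(
            i for i, p in enumerate(config.populations) if p.label == sweep.population
        )
        sweep_site = int(np.argmin(np.abs(positions[sweep.chromosome] - sweep.position_bp)))

    M = config.migration_matrix()
    morgans = [pos * (config.cm_per_mb * 1e-8) for pos in positions]

    for gen in range(1, config.generations + 1):
        if sweep is not None and gen == sweep.start_generation + 1:
            # seed the sweep allele at its starting frequency on ONE ancestral
            # background: carriers copy a single origin gamete's haplotype
            # block around the site, the single-origin standing variant whose
            # rise produces a hard-sweep footprint (hitchhiking needs shared
            # ancestry, not just a shared allele)
            h = haps[sweep_pop][sweep.chromosome]
            pos_c = positions[sweep.chromosome]
            n_g = h.shape[0]
            n_carriers = max(int(round(sweep.initial_freq * n_g)), 1)
            origin = int(rng.integers(0, n_g))
            carriers = rng.choice(n_g, size=n_carriers, replace=False)
            block = np.abs(pos_c - pos_c[sweep_site]) <= sweep.origin_block_bp
            h[:, sweep_site] = 0
            h[np.ix_(carriers, np.flatnonzero(block))] = h[origin, block]
            h[carriers, sweep_site] = 1

        sizes_now = [p.size_at(gen - 1) for p in config.populations]
        weights: list[np.ndarray | None] = [None] * k
        if sweep is not None and gen > sweep.start_generation:
            h = haps[sweep_pop][sweep.chromosome]
            freq_now = float(h[:, sweep_site].mean())
            if sweep.stop_at_freq is None or freq_now < sweep.stop_at_freq:
                dose = h[0::2, sweep_site].astype(float) + h[1::2, sweep_site]
                fit = 1.0 + sweep.s * dose
                weights[sweep_pop] = fit / fit.sum()

        new_haps: list[list[np.ndarray]] = []
        for d in range(k):
            n_new = config.populations[d].size_at(gen)
            n_gam = 2 * n_new
            offspring_ids = np.repeat(np.arange(n_new), 2)
            src, parent = _choose_parents(
                sizes_now, d, n_gam, M, weights, config.mating,
                config.flock_size, offspring_ids, rng,
            )
            chrom_list = []
            for c in range(n_chrom):
                out = np.empty((n_gam, snps_per_chrom), dtype=np.int8)
                for s in np.unique(src):
                    sel = src == s
                    out[sel] = _recombine(haps[s][c], parent[sel], morgans[c], rng)
                chrom_list.append(out)
            new_haps.append(chrom_list)
        haps = new_haps

        if sweep is not None and gen > sweep.start_generation:
            h = haps[sweep_pop][sweep.chromosome]
            sweep_traj.append(float(h[:, sweep_site].mean()))

    truth_extra = {}
    if sweep is not None:
        truth_extra = {
            "sweep_site_index": sweep_site,
            "sweep_position_bp": int(positions[sweep.chromosome][sweep_site]),
            "sweep_trajectory": sweep_traj,
            "sweep_final_freq": sweep_traj[-1] if sweep_traj else 0.0,
        }
    return haps, positions, founder_freq, truth_extra


def simulate(config: DemographyConfig) -> SimulationResult:
    """Run the configured demography and sample an array-like dataset.

    Returns sampled genotypes (unphased codes), truth-phased haplotypes per
    chromosome (all sampled individuals, in sample order), and a truth
    manifest with realized frequencies and sweep status.  If a sweep allele
    is lost, the run restarts from a derived seed up to ``max_retries``
    times before reporting it lost.
    """
    attempt = 0
    while True:
        seed = (config.seed + 1_000_003 * attempt) % (2**31)
        rng = np.random.default_rng(seed)
        haps, positions, founder_freq, truth_extra = _simulate_once(config, rng)
        if config.sweep is None or truth_extra.get("sweep_final_freq", 0.0) > 0.0:
            break
        attempt += 1
        if attempt > config.sweep.max_retries:
            logger.warning("sweep allele lost after %d attempts; reporting as lost", attempt)
            truth_extra["sweep_lost"] = True
            break
        logger.info("sweep allele lost; retrying with derived seed (attempt %d)", attempt)

    # sample individuals per population
    samples: list[SampleRecord] = []
    hap_rows: list[np.ndarray] = []
    for i, p in enumerate(config.populations):
        n_final = p.size_at(config.generations)
        if p.n_sample > n_final:
            raise ValueError(f"population {p.label}: cannot sample {p.n_sample} of {n_final}")
        chosen = rng.choice(n_final, size=p.n_sample, replace=False)
        for j, ind in enumerate(chosen):
            samples.append(SampleRecord(sample_id=f"{p.label}_{j}", population=p.label))
        rows = np.empty(2 * p.n_sample, dtype=np.int64)
        rows[0::2] = 2 * chosen
        rows[1::2] = 2 * chosen + 1
        hap_rows.append(rows)

    snps_per_chrom = positions[0].size
    sample_ids = [s.sample_id for s in samples]
    hapsets: list[HaplotypeSet] = []
    vmaps = []
    for c in range(config.n_chromosomes):
        block = np.vstack([haps[i][c][hap_rows[i]] for i in range(len(config.populations))])
        hapsets.append(
            HaplotypeSet(
                chrom=str(c + 1),
                positions_bp=positions[c],
                haplotypes=block,
                sample_ids=sample_ids,
            )
        )
        vmaps.append(
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "pos": positions[c],
                    "id": [f"snp{c + 1}_{p}" for p in positions[c]],
                    "a1": "A",
                    "a2": "C",
                }
            )
        )
    variants = pd.concat(vmaps, ignore_index=True)[VARIANT_COLUMNS]
    calls = np.hstack([hs.genotype_dosage() for hs in hapsets])
    genotypes = GenotypeMatrix(samples=samples, variants=variants, calls=calls)

    truth = {
        "seed": config.seed,
        "generations": config.generations,
        "populations": {
            p.label: {"final_size": p.size_at(config.generations), "n_sample": p.n_sample}
            for p in config.populations
        },
        "n_variants_ascertained": int(genotypes.n_variants),
        "n_variants_simulated": int(config.n_chromosomes * snps_per_chrom),
        "mating": config.mating,
        **truth_extra,
    }
    return SimulationResult(genotypes=genotypes, haplotypes=hapsets, truth=truth)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny_qc", "roh_runs", "sweep_panel", "two_pop_fst", "bottleneck_ne")


def _fixture_tiny_qc() -> SimulationResult:
    """10 samples x 100 SNPs with planted missingness around the QC cuts."""
    rng = np.random.default_rng(20_240_001)
    n, m = 10, 100
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    # samples 0,1: 15% missing (fail --mind 0.10); others fully called
    for i in (0, 1):
        calls[i, rng.choice(m, size=15, replace=False)] = -1
    # variants 0..4: missing in 1 of the 8 surviving samples (12.5% > 5%)
    for j in range(5):
        calls[2 + j, j] = -1
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * (m - 3) + ["27", "X", "2"],
            "pos": list(range(10_000, 10_000 + 1000 * (m - 3), 1000)) + [5_000, 6_000, 7_000],
            "id": [f"m{j}" for j in range(m)],
            "a1": "A",
            "a2": "C",
        }
    )[VARIANT_COLUMNS]
    samples = [SampleRecord(f"ind{i}", "POP1" if i < 5 else "POP2") for i in range(n)]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    truth = {
        "expect_removed_samples": ["ind0", "ind1"],
        "expect_removed_variant_ids": ["m0", "m1", "m2", "m3", "m4"],
        "expect_non_autosomal_ids": ["m97", "m98"],
    }
    return SimulationResult(genotypes=g, haplotypes=[], truth=truth)


def _fixture_roh_runs() -> SimulationResult:
    """Planted homozygous tracts of 3, 7, 12, 18 and 25 Mb, one per class."""
    spacing = 30_000
    m = 2_500
    pos = np.arange(1, m + 1) * spacing
    rng = np.random.default_rng(20_240_002)
    calls = rng.integers(0, 3, size=(4, m)).astype(np.int8)
    # carrier sample 0: alternate hets outside tracts so no spurious runs
    calls[0] = np.where(np.arange(m) % 2 == 0, 1, 0)
    tracts_mb = [3, 7, 12, 18, 25]
    truth_tracts = []
    cursor = 100
    for mb in tracts_mb:
        n_snps = int(mb * 1e6 / spacing)
        calls[0, cursor : cursor + n_snps] = 0
        truth_tracts.append(
            {"start_bp": int(pos[cursor]), "end_bp": int(pos[cursor + n_snps - 1]), "mb": mb}
        )
        cursor += n_snps + 50
    variants = pd.DataFrame(
        {"chrom": "1", "pos": pos, "id": [f"r{j}" for j in range(m)], "a1": "A", "a2": "C"}
    )[VARIANT_COLUMNS]
    samples = [SampleRecord(f"roh{i}", "ROHPOP") for i in range(4)]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    return SimulationResult(
        genotypes=g, haplotypes=[], truth={"carrier": "roh0", "tracts": truth_tracts}
    )


def _fixture_sweep_panel(seed: int = 7) -> SimulationResult:
    """60 samples, one swept chromosome (s = 0.05) plus a neutral control.

    Deme size 500 keeps neutral drift from mimicking sweep footprints at
    this genome size, and 60 sampled diploids keep the window statistics'
    rank noise below the sweep's signal.  The sweep target sits at the
    center of a 500 kb analysis window so its footprint is not split
    across two windows, and selection switches off at frequency 0.85 —
    the late-sweep regime in which haplotype (iHS, H12) and frequency
    (ZHp, pi, D) statistics are all jointly informative at the site.
    """
    cfg = DemographyConfig(
        populations=[PopulationConfig("SWP", 500, 60)],
        generations=160,
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        target_snps=2_000,
        migration=0.0,
        sweep=SweepConfig(
            population="SWP", chromosome=0, position_bp=10_250_000, s=0.05,
            stop_at_freq=0.85, origin_block_bp=500_000,
        ),
    )
    return simulate(cfg)


def _fixture_two_pop_fst(seed: int = 11) -> SimulationResult:
    """Two demes, N = 500, 4Nm = 5; expected equilibrium FST ~ 1/6."""
    cfg = DemographyConfig(
        populations=[PopulationConfig("D1", 500, 30), PopulationConfig("D2", 500, 30)],
        generations=800,
        seed=seed,
        n_chromosomes=3,
        chrom_length_bp=10_000_000,
        target_snps=900,
        migration=0.0025,
    )
    return simulate(cfg)


def _fixture_bottleneck_ne(seed: int = 13) -> SimulationResult:
    """Constant N = 1000 burn-in, crash to 100 at generation 150."""
    cfg = DemographyConfig(
        populations=[PopulationConfig("BTL", [(0, 1000), (150, 100)], 50)],
        generations=200,
        seed=seed,
        n_chromosomes=3,
        chrom_length_bp=10_000_000,
        target_snps=1_800,
        migration=0.0,
    )
    return simulate(cfg)


def make_fixture(name: str, outdir: str | Path | None = None, seed: int | None = None) -> SimulationResult:
    """Build a named deterministic dataset; optionally write it to disk."""
    builders = {
        "tiny_qc": _fixture_tiny_qc,
        "roh_runs": _fixture_roh_runs,
        "sweep_panel": _fixture_sweep_panel,
        "two_pop_fst": _fixture_two_pop_fst,
        "bottleneck_ne": _fixture_bottleneck_ne,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
    builder = builders[name]
    result = builder(seed) if (seed is not None and name in ("sweep_panel", "two_pop_fst", "bottleneck_ne")) else builder()
    if outdir is not None:
        result.write(outdir, prefix=name)
    return result
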