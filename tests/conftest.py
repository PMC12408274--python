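import numpy as np
import pandas as pd
import pytest

from flockscan.genotype_io import GenotypeMatrix, SampleRecord, VARIANT_COLUMNS
from flockscan.haplotypes import HaplotypeSet
from flockscan.simulate import DemographyConfig, PopulationConfig, make_fixture, simulate


def make_matrix(calls, chrom="1", spacing=10_000, populations=None, start=10_000):
    """GenotypeMatrix from a raw call array with evenly spaced variants."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if isinstance(chrom, str):
        chroms = [chrom] * m
    else:
        chroms = list(chrom)
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": start + spacing * np.arange(m),
            "id": [f"v{j}" for j in range(m)],
            "a1": "A",
            "a2": "C",
        }
    )[VARIANT_COLUMNS]
    pops = populations or ["P1"] * n
    samples = [SampleRecord(f"s{i}", pops[i]) for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def make_haps(haps, spacing=10_000, chrom="1", start=10_000):
    haps = np.asarray(haps, dtype=np.int8)
    return HaplotypeSet(
        chrom=chrom,
        positions_bp=start + spacing * np.arange(haps.shape[1]),
        haplotypes=haps,
    )


@pytest.fixture(scope="session")
def sweep_panel():
    """Default seeded hard-sweep panel (one swept + one neutral chromosome)."""
    return make_fixture("sweep_panel")


@pytest.fixture(scope="session")
def neutral_panel():
    """Neutral constant-size twin of the sweep panel (no selection)."""
    cfg = DemographyConfig(
        populations=[PopulationConfig("NEU", 500, 30)],
        generations=160,
        seed=42,
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        target_snps=2_000,
        migration=0.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_qc():
    return make_fixture("tiny_qc")


@pytest.fixture(scope="session")
def roh_runs():
    return make_fixture("roh_runs")
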