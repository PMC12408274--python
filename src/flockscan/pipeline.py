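"""Config-driven end-to-end run: QC -> ROH -> FST -> Ne -> scans -> DCMS.

The pipeline mirrors the analysis order of a within-population selection
study on array genotypes.  FST and Ne run on the shared (QC'd) dataset;
the five selection statistics and the DCMS composite run per population.
Every stage writes its table into one results directory, the config is
echoed verbatim, and a run log records parameters and seeds so each number
is re-derivable by calling the corresponding module function directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeMatrix, apply_qc, load_plink
from .haplotypes import HaplotypeSet, read_phased_vcf
from .roh import ROHParams, detect_roh, inbreeding_coefficients, l_parameter, write_hom
from .diversity import fst_matrix, ne_trajectory
from .selection import (
    h12_scan,
    ihs_scan,
    standardize_ihs,
    window_frequency_stats,
    window_scores_frame,
    zhp_scan,
)
from .dcms import (
    aggregate_to_grid,
    build_p_table,
    dcms_scores,
    export_candidates,
    median_smooth,
    significance_call,
    write_bed,
)
from .simulate import make_fixture

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "roh", "fst", "ne", "scan", "dcms")

_KNOWN_KEYS = {
    "input_prefix", "input_format", "phased_vcf", "simulate", "outdir", "seed", "stages",
    "qc", "roh", "ne", "scan", "dcms",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    input_prefix: str | None = None
    input_format: str = "auto"
    phased_vcf: str | None = None
    simulate: dict | None = None  # {"fixture": name, "seed": int}
    stages: tuple[str, ...] = ALL_STAGES
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    ne: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    dcms: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        raw = dict(raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "input_prefix": self.input_prefix,
            "input_format": self.input_format,
            "phased_vcf": self.phased_vcf,
            "simulate": self.simulate,
            "stages": list(self.stages),
            "qc": self.qc,
            "roh": self.roh,
            "ne": self.ne,
            "scan": self.scan,
            "dcms": self.dcms,
        }


def _load_inputs(cfg: PipelineConfig) -> tuple[GenotypeMatrix, list[HaplotypeSet]]:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        name = sim.pop("fixture")
        seed = sim.pop("seed", None)
        if sim:
            raise ValueError(f"unknown simulate keys: {sorted(sim)}")
        result = make_fixture(name, seed=seed)
        return result.genotypes, result.haplotypes
    if cfg.input_prefix is None:
        raise ValueError("config needs either 'input_prefix' or a 'simulate' block")
    g = load_plink(cfg.input_prefix, format=cfg.input_format)
    haps = read_phased_vcf(cfg.phased_vcf) if cfg.phased_vcf else []
    return g, haps


def population_scan(
    g: GenotypeMatrix,
    haps: list[HaplotypeSet],
    pop: str,
    scan_cfg: dict | None = None,
    dcms_cfg: dict | None = None,
    outdir: Path | None = None,
) -> pd.DataFrame | None:
    """Five selection statistics + DCMS calls for one population.

    Runs iHS and H12 on the phased haplotypes (restricted to the
    population's samples), ZHp / pi / Tajima's D on its genotypes, merges
    everything onto the 500 kb grid, and returns the significance-called
    window table — or None when too little is computable to calibrate.
    Per-statistic TSVs are written when ``outdir`` is given.
    """
    scan_cfg = scan_cfg or {}
    dcms_cfg = dcms_cfg or {}
    idx = g.population_index(pop)
    sub = g.subset(sample_index=idx)
    wanted = set(sub.sample_ids())
    grids: dict[str, pd.DataFrame] = {}

    # haplotype statistics
    ihs_parts, h12_scores = [], []
    for h in haps:
        pop_rows = np.array([i for i, sid in enumerate(h.sample_ids) if sid in wanted], dtype=int)
        if pop_rows.size < 2:
            continue
        hp = h.subset_samples(pop_rows)
        ihs_parts.append(ihs_scan(hp, maf_min=scan_cfg.get("ihs_maf_min", 0.05)))
        h12_scores.extend(
            h12_scan(hp, window_snps=scan_cfg.get("h12_window_snps", 25))
        )
    grid_bp = dcms_cfg.get("grid_bp", 500_000)
    if ihs_parts:
        raw = pd.concat(ihs_parts, ignore_index=True)
        std = standardize_ihs(raw, freq_bin=scan_cfg.get("ihs_freq_bin", 0.05))
        if not std.empty:
            std = std.assign(abs_ihs=std["standardized"].abs())
            smoothed = []
            for _, grp in std.groupby("chrom", sort=False):
                grp = grp.sort_values("pos")
                smoothed.append(grp.assign(abs_ihs=median_smooth(grp["abs_ihs"].to_numpy(), 3)))
            std = pd.concat(smoothed)
            site_df = std.rename(columns={"pos": "mid_bp"})[["chrom", "mid_bp", "abs_ihs"]]
            grids["ihs"] = aggregate_to_grid(site_df, grid_bp, value_col="abs_ihs")
            if outdir is not None:
                std.to_csv(outdir / f"ihs_{pop}.tsv", sep="\t", index=False)
    if h12_scores:
        df = window_scores_frame(h12_scores)
        df["mid_bp"] = (df["start_bp"] + df["end_bp"]) / 2
        grids["H12"] = aggregate_to_grid(df, grid_bp)
        if outdir is not None:
            df.to_csv(outdir / f"h12_{pop}.tsv", sep="\t", index=False)

    # frequency statistics
    try:
        zhp = zhp_scan(
            sub,
            window_bp=scan_cfg.get("zhp_window_bp", 200_000),
            min_snps=scan_cfg.get("min_snps", 10),
        )
    except ValueError as exc:
        logger.warning("population %s: ZHp skipped (%s)", pop, exc)
        zhp = []
    if zhp:
        df = window_scores_frame(zhp)
        df["mid_bp"] = (df["start_bp"] + df["end_bp"]) / 2
        grids["ZHp"] = aggregate_to_grid(df, grid_bp)
        if outdir is not None:
            df.to_csv(outdir / f"zhp_{pop}.tsv", sep="\t", index=False)
    pi_scores, d_scores = window_frequency_stats(
        sub,
        window_bp=scan_cfg.get("pi_window_bp", 300_000),
        min_snps=scan_cfg.get("min_snps", 10),
    )
    for name, scores in (("pi", pi_scores), ("tajima_d", d_scores)):
        if not scores:
            continue
        df = window_scores_frame(scores)
        df["mid_bp"] = (df["start_bp"] + df["end_bp"]) / 2
        grids[name] = aggregate_to_grid(df, grid_bp)
        if outdir is not None:
            df.to_csv(outdir / f"{name}_{pop}.tsv", sep="\t", index=False)

    if not grids:
        logger.warning("population %s: no scan statistics computable", pop)
        return None
    try:
        p_table = build_p_table(grids)
        scored, weights = dcms_scores(
            p_table, min_components=dcms_cfg.get("min_components", 3)
        )
        called = significance_call(scored, fdr_q=dcms_cfg.get("fdr_q", 0.05))
    except ValueError as exc:
        logger.warning("population %s: DCMS not callable (%s)", pop, exc)
        return None
    called.insert(0, "population", pop)
    if outdir is not None:
        called.to_csv(outdir / f"dcms_{pop}.tsv", sep="\t", index=False)
        bed = export_candidates(called, flank_bp=dcms_cfg.get("flank_bp", 500_000))
        write_bed(bed, outdir / f"candidates_{pop}.bed")
        (outdir / f"dcms_weights_{pop}.json").write_text(json.dumps(weights, indent=2))
    return called


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages; returns the results directory.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages remain on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    log_lines = [f"flockscan {__version__}", f"seed: {cfg.seed}"]
    summary: dict = {"stages": list(cfg.stages)}

    try:
        g, haps = _load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("input", str(exc)) from exc
    summary["n_samples_raw"] = g.n_samples
    summary["n_variants_raw"] = g.n_variants

    if "qc" in cfg.stages:
        try:
            g, report = apply_qc(g, **cfg.qc)
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc
        report.write_tsv(outdir / "qc_report.tsv")
        summary["qc"] = {
            "n_samples_out": report.n_samples_out,
            "n_variants_out": report.n_variants_out,
            "n_samples_removed": len(report.removed_samples),
            "n_variants_removed": len(report.removed_variants),
        }
        kept = set(g.sample_ids())
        haps = [
            h.subset_samples(np.array([i for i, sid in enumerate(h.sample_ids) if sid in kept], dtype=int))
            for h in haps
        ]
        # QC'd haplotype sites may exceed retained variants; restrict columns
        kept_pos = {
            chrom: set(grp["pos"]) for chrom, grp in g.variants.groupby("chrom", sort=False)
        }
        haps = [
            HaplotypeSet(
                chrom=h.chrom,
                positions_bp=h.positions_bp[np.isin(h.positions_bp, sorted(kept_pos.get(h.chrom, set())))],
                haplotypes=h.haplotypes[:, np.isin(h.positions_bp, sorted(kept_pos.get(h.chrom, set())))],
                sample_ids=h.sample_ids,
            )
            for h in haps
            if h.chrom in kept_pos
        ]

    if "roh" in cfg.stages:
        try:
            roh_cfg = dict(cfg.roh)
            params = ROHParams(**roh_cfg) if roh_cfg else None
            if params is None:
                het = float((g.calls == 1).sum() / max((g.calls != -1).sum(), 1))
                het = min(max(het, 1e-6), 1 - 1e-6)
                params = ROHParams(min_snps=l_parameter(g.n_variants, g.n_samples, het))
            segments = detect_roh(g, params)
            table = inbreeding_coefficients(g, segments)
        except Exception as exc:
            raise StageError("roh", str(exc)) from exc
        write_hom(segments, g, outdir / "roh_segments.hom")
        table.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
        summary["roh"] = {
            "n_segments": len(segments),
            "min_snps": params.min_snps,
            "mean_F_ROH_by_pop": table.groupby("population")["F_ROH"].mean().round(6).to_dict(),
        }

    if "fst" in cfg.stages and len(g.populations) > 1:
        try:
            mat = fst_matrix(g)
        except Exception as exc:
            raise StageError("fst", str(exc)) from exc
        mat.to_csv(outdir / "fst_matrix.tsv", sep="\t")
        summary["fst"] = {
            "max": float(np.nanmax(mat.to_numpy())),
            "pairs": {f"{a}|{b}": float(mat.loc[a, b]) for a in mat.index for b in mat.columns if a < b},
        }

    if "ne" in cfg.stages:
        ne_tables = {}
        for pop in g.populations:
            try:
                sub = g.subset(sample_index=g.population_index(pop))
                traj = ne_trajectory(sub, **cfg.ne)
            except Exception as exc:
                raise StageError("ne", str(exc)) from exc
            traj.bins.to_csv(outdir / f"ne_{pop}.tsv", sep="\t", index=False)
            valid = traj.valid_bins()
            ne_tables[pop] = float(valid["Ne"].median()) if len(valid) else float("nan")
        summary["ne"] = {"median_Ne_by_pop": ne_tables}

    if "scan" in cfg.stages or "dcms" in cfg.stages:
        sig_counts = {}
        for pop in g.populations:
            try:
                called = population_scan(g, haps, pop, cfg.scan, cfg.dcms, outdir)
            except Exception as exc:
                raise StageError("scan", str(exc)) from exc
            if called is not None:
                sig_counts[pop] = int(called["significant"].sum())
        summary["dcms"] = {"significant_windows_by_pop": sig_counts}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log_lines.append("completed: " + ", ".join(cfg.stages))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def summary_hash(outdir: str | Path) -> str:
    """SHA-256 over summary.json, for determinism checks."""
    return hashlib.sha256((Path(outdir) / "summary.json").read_bytes()).hexdigest()
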