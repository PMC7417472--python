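"""End-to-end orchestration: simulate → scan → regions → candidates.

A :class:`PipelineConfig` bundles every stage's settings plus one global
seed. :func:`run_pipeline` executes the stages in order, writes each
stage's outputs under one directory, and finishes with a run manifest
recording record counts and wall times. Identical (config, seed) pairs
produce byte-identical data files; the manifest is the only file carrying
timing information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import candidate_filter, genes_in_region, venn_partition
from .io import (
    config_hash,
    read_flat_config,
    write_depths_vcf,
    write_flat_config,
    write_regions_bed,
    write_tsv,
)
from .scan import (
    FilterConfig,
    GenomicRegion,
    SmoothingConfig,
    call_regions,
    compute_scan,
    ed_null_threshold,
    intersect_region_sets,
    read_allele_depths,
    regions_to_frame,
)
from .simcross import SimConfig, simulate_dataset, simulate_deg_table, simulate_gene_models

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineError",
    "run_pipeline",
    "convert_coordinates",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All stage settings plus the global seed.

    ``depths_path`` may point at an existing VCF/TSV to scan real data;
    when it is None the simulation stage generates the input. Candidate
    triage runs when gene models and a DEG table are available (either
    simulated or supplied via paths).
    """

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    n_null_sims: int = 10_000
    ci_level: str = "ci95"
    ed_threshold_method: str = "null_bootstrap"  # or "empirical"
    n_ed_null_genomes: int = 20
    ed_threshold_multiplier: float = 3.0
    merge_gap_bp: int = 500_000
    region_grid_bp: int = 10_000
    sign_convention: str = "s_minus_t"
    contrasts: tuple[str, ...] = ("IRvsTIR", "WGvsTWG")
    depths_path: str | None = None
    gene_models_path: str | None = None
    deg_table_path: str | None = None
    simulate_candidate_inputs: bool = True
    n_sim_genes: int = 200
    n_sim_causal_genes: int = 5

    def flat(self) -> dict[str, str]:
        items: dict[str, str] = {"seed": str(self.seed)}
        for f in dataclasses.fields(SimConfig):
            items[f"sim.{f.name}"] = str(getattr(self.sim, f.name))
        for f in dataclasses.fields(FilterConfig):
            items[f"filters.{f.name}"] = str(getattr(self.filters, f.name))
        for f in dataclasses.fields(SmoothingConfig):
            items[f"smoothing.{f.name}"] = str(getattr(self.smoothing, f.name))
        for name in (
            "n_null_sims",
            "ci_level",
            "ed_threshold_method",
            "n_ed_null_genomes",
            "ed_threshold_multiplier",
            "merge_gap_bp",
            "region_grid_bp",
            "sign_convention",
            "depths_path",
            "gene_models_path",
            "deg_table_path",
            "simulate_candidate_inputs",
            "n_sim_genes",
            "n_sim_causal_genes",
        ):
            items[name] = str(getattr(self, name))
        items["contrasts"] = ",".join(self.contrasts)
        return items

    def hash(self) -> str:
        return config_hash(self.flat())

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        raw = read_flat_config(path)
        cfg = cls()
        for key, value in raw.items():
            if key.startswith("sim."):
                _set_typed(cfg.sim, key[4:], value, key)
            elif key.startswith("filters."):
                _set_typed(cfg.filters, key[8:], value, key)
            elif key.startswith("smoothing."):
                _set_typed(cfg.smoothing, key[10:], value, key)
            elif key == "contrasts":
                cfg.contrasts = tuple(v for v in value.split(",") if v)
            else:
                _set_typed(cfg, key, value, key)
        cfg.sim.seed = cfg.seed
        return cfg


def _set_typed(obj, name: str, value: str, full_key: str) -> None:
    if not hasattr(obj, name):
        raise ValueError(f"unknown config key {full_key!r}")
    current = getattr(obj, name)
    if isinstance(current, bool):
        setattr(obj, name, value.lower() in ("1", "true", "yes"))
    elif isinstance(current, int):
        setattr(obj, name, int(value))
    elif isinstance(current, float):
        setattr(obj, name, float(value))
    elif current is None:
        setattr(obj, name, None if value in ("None", "") else value)
    else:
        setattr(obj, name, value)


@dataclass
class RunManifest:
    """What a run did: config snapshot, versions, counts and wall times."""

    config: dict[str, str]
    config_hash: str
    version: str
    counts: dict[str, int]
    wall_times_s: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def convert_coordinates(region: GenomicRegion, dialect: str) -> tuple[str, int, int]:
    """Convert a region between coordinate dialects.

    ``internal_1based_inclusive`` returns (chrom, start, end) unchanged;
    ``bed_0based_halfopen`` shifts the start down by one. The round trip is
    the identity and the span length is preserved.
    """
    if dialect == "internal_1based_inclusive":
        return (region.chrom, region.start_bp, region.end_bp)
    if dialect == "bed_0based_halfopen":
        return (region.chrom, region.start_bp - 1, region.end_bp)
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


def run_pipeline(config: PipelineConfig, out_dir: str) -> RunManifest:
    """Execute all stages, writing outputs and a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    counts: dict[str, int] = {}
    times: dict[str, float] = {}
    config.sim.seed = config.seed

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            times[name] = round(time.perf_counter() - t0, 3)
            return result

        return wrap

    # --- simulate (or load) allele depths -----------------------------------
    if config.depths_path is None:
        def _simulate():
            ds = simulate_dataset(config.sim)
            pheno = ds.phenotypes.rename("phenotype").reset_index()
            pheno["pool"] = ds.pool_membership.to_numpy()
            write_tsv(pheno, out / "phenotypes.tsv", "phenotypes", cfg_hash, config.seed)
            write_tsv(
                ds.depths, out / "depths.tsv", "allele_depths", cfg_hash, config.seed
            )
            write_depths_vcf(
                ds.depths,
                out / "depths.vcf",
                cfg_hash,
                config.seed,
                contig_lengths={
                    c: config.sim.chrom_length_bp for c in config.sim.chrom_names()
                },
            )
            truth = pd.DataFrame(
                {
                    "key": ["qtl_chrom", "qtl_pos_bp", "qtl_pve"],
                    "value": [
                        config.sim.qtl_chrom,
                        config.sim.qtl_pos_bp,
                        config.sim.qtl_pve,
                    ],
                }
            )
            write_tsv(truth, out / "truth.tsv", "truth", cfg_hash, config.seed)
            return ds

        dataset = _stage("simulate")(_simulate)
        depths_source = str(out / "depths.tsv")
        counts["lines_simulated"] = config.sim.n_lines
        counts["markers_simulated"] = len(dataset.depths)
    else:
        depths_source = config.depths_path

    # --- read + filter ------------------------------------------------------
    depths = _stage("read_depths")(
        lambda: read_allele_depths(depths_source, config.filters)
    )
    fc = depths.attrs.get("filter_counts", {})
    counts["markers_read"] = int(fc.get("parsed", len(depths)))
    counts["markers_kept"] = len(depths)
    counts["markers_filtered"] = counts["markers_read"] - counts["markers_kept"]

    # --- scan ---------------------------------------------------------------
    def _scan():
        pts = compute_scan(
            depths,
            bulk_size=config.sim.bulk_size,
            smoothing=config.smoothing,
            n_sims=config.n_null_sims,
            seed=config.seed,
            sign_convention=config.sign_convention,
        )
        write_tsv(pts, out / "scan.tsv", "scan", cfg_hash, config.seed)
        return pts

    scan_points = _stage("scan")(_scan)

    # --- regions ------------------------------------------------------------
    def _regions():
        delta_regions = call_regions(
            scan_points,
            "delta",
            ci_level=config.ci_level,
            merge_gap_bp=config.merge_gap_bp,
            grid_bp=config.region_grid_bp,
        )
        if config.ed_threshold_method == "null_bootstrap":
            ed_thresh = ed_null_threshold(
                scan_points,
                bulk_size=config.sim.bulk_size,
                smoothing=config.smoothing,
                cm_per_mb=config.sim.cm_per_mb,
                n_genomes=config.n_ed_null_genomes,
                seed=config.seed,
            )
        elif config.ed_threshold_method == "empirical":
            ed_thresh = None  # call_regions falls back to median + k*MAD
        else:
            raise PipelineError(
                f"stage 'regions' failed: unknown ed_threshold_method "
                f"{config.ed_threshold_method!r}"
            )
        ed_regions = call_regions(
            scan_points,
            "ed",
            threshold=ed_thresh,
            threshold_multiplier=config.ed_threshold_multiplier,
            merge_gap_bp=config.merge_gap_bp,
        )
        common = intersect_region_sets(delta_regions, ed_regions)
        all_regions = delta_regions + ed_regions + common
        write_regions_bed(all_regions, out / "regions.bed", cfg_hash, config.seed)
        write_tsv(
            regions_to_frame(all_regions),
            out / "regions.tsv",
            "regions",
            cfg_hash,
            config.seed,
        )
        return delta_regions, ed_regions, common

    delta_regions, ed_regions, common = _stage("regions")(_regions)
    counts["regions_delta"] = len(delta_regions)
    counts["regions_ed"] = len(ed_regions)
    counts["regions_common"] = len(common)

    # --- candidates ---------------------------------------------------------
    if bool(config.gene_models_path) != bool(config.deg_table_path):
        missing = "deg_table_path" if config.gene_models_path else "gene_models_path"
        raise PipelineError(f"stage 'candidates' failed: missing input {missing!r}")
    run_candidates = bool(common) and (
        config.simulate_candidate_inputs
        or (config.gene_models_path and config.deg_table_path)
    )
    if run_candidates:
        def _candidates():
            if config.gene_models_path and config.deg_table_path:
                from .candidates import read_gene_models

                genes = read_gene_models(config.gene_models_path)
                degs = pd.read_csv(config.deg_table_path, sep="\t", comment="#")
            else:
                target = common[0]
                genes = simulate_gene_models(
                    config.n_sim_genes,
                    chrom=target.chrom,
                    chrom_length_bp=config.sim.chrom_length_bp,
                    seed=config.seed,
                )
                in_region = genes_in_region(target, genes)
                causal = list(in_region["gene_id"].iloc[: config.n_sim_causal_genes])
                degs = simulate_deg_table(genes, causal, seed=config.seed)
            region_genes = genes_in_region(common[0], genes)
            cands = candidate_filter(
                region_genes, degs, config.contrasts, annotation=genes
            )
            write_tsv(cands, out / "candidates.tsv", "candidates", cfg_hash, config.seed)
            sets = {
                c: set(
                    degs.loc[
                        (degs["contrast"] == c) & (degs["fdr"] < 0.05), "gene_id"
                    ]
                )
                for c in pd.unique(degs["contrast"])
            }
            venn = venn_partition(sets)
            write_tsv(venn, out / "venn.tsv", "venn", cfg_hash, config.seed)
            return region_genes, cands

        region_genes, cands = _stage("candidates")(_candidates)
        counts["region_genes"] = len(region_genes)
        counts["candidates"] = len(cands)

    write_flat_config(out / "config.txt", config.flat())
    manifest = RunManifest(
        config=config.flat(),
        config_hash=cfg_hash,
        version=__version__,
        counts=counts,
        wall_times_s=times,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
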