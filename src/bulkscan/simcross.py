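"""Synthetic F2 bulked-segregant datasets with known truth.

Simulates a biparental F2 cross segregating a single additive QTL, selects
phenotypic extreme bulks, and draws pooled sequencing read counts, so that
the genome-scan machinery can be exercised end to end without real
sequencing data. The defaults mirror a rice salt-tolerance bulked-segregant
design: 983 F2 lines, extreme bulks of 40 lines each, one QTL explaining
~25% of the phenotypic variance, and ~27.6x mean pooled depth.

Genotypes are coded 0/1/2 as the count of tolerant-parent alleles. Gametes
are generated marker-to-marker along each chromosome with recombination
fractions obtained from physical distance through the Haldane map function
at a configurable cM/Mb rate, so genotypes at linked markers are correlated
the way an F2 scan expects.

All randomness derives from one seed through named per-stage streams
(markers, cross, phenotype, depth, deg, genes); identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimDataset",
    "SimConfigError",
    "BulkTieWarning",
    "stage_rng",
    "simulate_cross",
    "select_bulks",
    "simulate_pool_depths",
    "simulate_dataset",
    "simulate_gene_models",
    "simulate_deg_table",
]

_BASES = np.array(list("ACGT"))

# Fixed spawn keys: each stage gets an independent, reorder-safe stream.
_STREAMS = {"markers": 0, "cross": 1, "phenotype": 2, "depth": 3, "deg": 4, "genes": 5}


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


class BulkTieWarning(UserWarning):
    """Emitted when phenotype ties span a bulk-selection boundary."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named simulation stage.

    Uses a fixed spawn key per stage so stages can be re-run in isolation
    without perturbing each other's streams.
    """
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stage],))
    )


@dataclass
class SimConfig:
    """Generative parameters for a synthetic F2 bulked-segregant study.

    ``qtl_pve`` is the fraction of phenotypic variance explained by the
    additive QTL (default 0.249). ``mean_depth`` is the mean per-SNP,
    per-pool sequencing depth (default 27.6x). ``cm_per_mb`` converts
    physical to genetic distance (default 4 cM/Mb, rice-typical).
    """

    n_lines: int = 983
    bulk_size: int = 40
    n_chrom: int = 1
    chrom_length_bp: int = 30_000_000
    n_snps_per_chrom: int = 5_000
    qtl_chrom: str = "chr1"
    qtl_pos_bp: int = 15_000_000
    qtl_pve: float = 0.249
    mean_depth: float = 27.6
    depth_model: str = "poisson"  # "poisson" (truncated at >=1) or "constant"
    cm_per_mb: float = 4.0
    dominance: float = 0.0  # dominance deviation as a fraction of the additive effect
    phenotype_mean: float = 0.75  # baseline of the relative-trait scale
    residual_sd: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise SimConfigError(f"n_lines must be >= 2, got {self.n_lines}")
        if self.bulk_size < 1 or 2 * self.bulk_size > self.n_lines:
            raise SimConfigError(
                f"bulk_size must satisfy 1 <= 2*bulk_size <= n_lines, got {self.bulk_size}"
            )
        if self.n_chrom < 1:
            raise SimConfigError(f"n_chrom must be >= 1, got {self.n_chrom}")
        if self.chrom_length_bp < 2:
            raise SimConfigError(
                f"chrom_length_bp must be >= 2, got {self.chrom_length_bp}"
            )
        if self.n_snps_per_chrom < 1:
            raise SimConfigError(
                f"n_snps_per_chrom must be >= 1, got {self.n_snps_per_chrom}"
            )
        if not 0.0 <= self.qtl_pve < 1.0:
            raise SimConfigError(f"qtl_pve must be in [0, 1), got {self.qtl_pve}")
        if not 1 <= self.qtl_pos_bp <= self.chrom_length_bp:
            raise SimConfigError(
                f"qtl_pos_bp must be in [1, chrom_length_bp], got {self.qtl_pos_bp}"
            )
        if self.qtl_chrom not in self.chrom_names():
            raise SimConfigError(
                f"qtl_chrom {self.qtl_chrom!r} not among simulated chromosomes"
            )
        if self.mean_depth <= 0:
            raise SimConfigError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.depth_model not in ("poisson", "constant"):
            raise SimConfigError(
                f"depth_model must be 'poisson' or 'constant', got {self.depth_model!r}"
            )
        if self.cm_per_mb <= 0:
            raise SimConfigError(f"cm_per_mb must be > 0, got {self.cm_per_mb}")
        if self.residual_sd <= 0:
            raise SimConfigError(f"residual_sd must be > 0, got {self.residual_sd}")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def additive_effect(self) -> float:
        """Additive effect sized so the QTL explains ``qtl_pve`` of variance.

        With 1:2:1 segregation the centred genotype (g - 1) has variance 1/2,
        so var_QTL = a^2/2 and pve = var_QTL / (var_QTL + sigma_e^2).
        """
        p = self.qtl_pve
        if p == 0:
            return 0.0
        return self.residual_sd * float(np.sqrt(2.0 * p / (1.0 - p)))


@dataclass
class SimDataset:
    """A simulated cross plus everything downstream stages consume.

    ``genotypes`` is an (n_lines, n_markers) int8 array of tolerant-parent
    allele counts; ``markers`` holds chrom/pos/ref/alt per column.
    """

    config: SimConfig
    markers: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: pd.Series
    pool_membership: pd.Series
    qtl_marker_index: int
    depths: pd.DataFrame | None = None

    @property
    def line_ids(self) -> pd.Index:
        return self.phenotypes.index

    def pool_lines(self, pool: str) -> pd.Index:
        return self.pool_membership.index[self.pool_membership == pool]


def _draw_positions(rng: np.random.Generator, length_bp: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length_bp]."""
    if n > length_bp:
        raise SimConfigError("more SNPs requested than available positions")
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.3) + 8))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    if len(pos) > n:
        keep = np.sort(rng.choice(len(pos), size=n, replace=False))
        pos = pos[keep]
    return pos


def _simulate_gametes(
    rng: np.random.Generator, pos_bp: np.ndarray, cm_per_mb: float, n_gametes: int
) -> np.ndarray:
    """Recombinant F1 gametes along one chromosome (alleles in {0,1}).

    Adjacent-marker recombination fraction via Haldane:
    r = (1 - exp(-2d)) / 2 with d the map distance in Morgans.
    """
    n = len(pos_bp)
    d_morgan = np.diff(pos_bp) / 1e6 * cm_per_mb / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    g = np.empty((n_gametes, n), dtype=np.int8)
    g[:, 0] = rng.random(n_gametes) < 0.5
    for j in range(1, n):
        crossover = rng.random(n_gametes) < r[j - 1]
        g[:, j] = g[:, j - 1] ^ crossover
    return g


def simulate_cross(config: SimConfig) -> SimDataset:
    """Simulate marker map, F2 genotypes and phenotypes.

    One marker is placed exactly at ``qtl_pos_bp`` on ``qtl_chrom`` so the
    planted QTL coincides with an observable SNP. Phenotype is
    mu + a*(g - 1) + dominance*a*[g == 1] + e with Gaussian residuals and
    ``a`` sized by :meth:`SimConfig.additive_effect`.

    Pool membership is initialised to "none"; see :func:`select_bulks`.
    """
    config.validate()
    rng_m = stage_rng(config.seed, "markers")
    rng_c = stage_rng(config.seed, "cross")
    rng_p = stage_rng(config.seed, "phenotype")

    marker_frames = []
    genotype_blocks = []
    qtl_index = -1
    offset = 0
    for chrom in config.chrom_names():
        pos = _draw_positions(rng_m, config.chrom_length_bp, config.n_snps_per_chrom)
        if chrom == config.qtl_chrom:
            # replace the nearest marker with one at the exact QTL position
            j = int(np.argmin(np.abs(pos.astype(np.int64) - config.qtl_pos_bp)))
            pos = pos.copy()
            pos[j] = config.qtl_pos_bp
            pos = np.unique(pos)
            j = int(np.searchsorted(pos, config.qtl_pos_bp))
            qtl_index = offset + j
        ref_idx = rng_m.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng_m.integers(1, 4, size=len(pos))) % 4
        marker_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                }
            )
        )
        gametes = _simulate_gametes(rng_c, pos, config.cm_per_mb, 2 * config.n_lines)
        genotype_blocks.append(gametes[0::2] + gametes[1::2])
        offset += len(pos)

    markers = pd.concat(marker_frames, ignore_index=True)
    genotypes = np.concatenate(genotype_blocks, axis=1)
    line_ids = pd.Index([f"L{i + 1:04d}" for i in range(config.n_lines)], name="line_id")

    a = config.additive_effect()
    g_qtl = genotypes[:, qtl_index].astype(float)
    y = (
        config.phenotype_mean
        + a * (g_qtl - 1.0)
        + config.dominance * a * (g_qtl == 1.0)
        + rng_p.normal(0.0, config.residual_sd, size=config.n_lines)
    )
    phenotypes = pd.Series(y, index=line_ids, name="phenotype")
    membership = pd.Series("none", index=line_ids, name="pool")
    return SimDataset(
        config=config,
        markers=markers,
        genotypes=genotypes,
        phenotypes=phenotypes,
        pool_membership=membership,
        qtl_marker_index=qtl_index,
    )


def select_bulks(phenotypes: pd.Series, bulk_size: int) -> pd.Series:
    """Assign extreme-phenotype bulks: T = largest values, S = smallest.

    Ties are broken by stable (value, line_id) order; ties spanning a
    selection boundary trigger a :class:`BulkTieWarning` because the bulk
    composition is then order- rather than phenotype-determined.
    """
    if bulk_size < 1:
        raise ValueError(f"bulk_size must be >= 1, got {bulk_size}")
    if 2 * bulk_size > len(phenotypes):
        raise ValueError(
            f"need at least 2*bulk_size={2 * bulk_size} lines, got {len(phenotypes)}"
        )
    if phenotypes.isna().any():
        raise ValueError("phenotypes contain missing values")

    order = (
        phenotypes.rename("value")
        .reset_index()
        .sort_values(["value", "line_id"], kind="mergesort")
    )
    vals = order["value"].to_numpy()
    k = bulk_size
    if vals[k - 1] == vals[k]:
        warnings.warn(
            "phenotype tie spans the S-pool boundary; selection is by line-id order",
            BulkTieWarning,
            stacklevel=2,
        )
    if vals[-k] == vals[-k - 1]:
        warnings.warn(
            "phenotype tie spans the T-pool boundary; selection is by line-id order",
            BulkTieWarning,
            stacklevel=2,
        )
    membership = pd.Series("none", index=phenotypes.index, name="pool")
    membership.loc[order["line_id"].iloc[:k]] = "S"
    membership.loc[order["line_id"].iloc[-k:]] = "T"
    return membership


def _draw_depths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    if config.depth_model == "constant":
        return np.full(n, max(1, int(round(config.mean_depth))), dtype=np.int64)
    d = rng.poisson(config.mean_depth, size=n)
    while True:  # truncate at >= 1 by redrawing zeros
        zero = d == 0
        if not zero.any():
            return d
        d[zero] = rng.poisson(config.mean_depth, size=int(zero.sum()))


def simulate_pool_depths(
    dataset: SimDataset, config: SimConfig | None = None
) -> pd.DataFrame:
    """Pooled read counts per SNP: binomial sampling at the true pool frequency.

    For each SNP and pool, the true alt (tolerant-parent) allele frequency is
    the mean allele dose over the pool's lines; total depth follows the
    configured depth model and the alt count is Binomial(depth, freq).
    """
    config = config or dataset.config
    rng = stage_rng(config.seed, "depth")
    out = dataset.markers[["chrom", "pos", "ref", "alt"]].copy()
    n = len(out)
    for pool, prefix in (("T", "t"), ("S", "s")):
        lines = dataset.pool_lines(pool)
        if len(lines) == 0:
            raise ValueError(f"pool {pool!r} is empty; run select_bulks first")
        loc = dataset.line_ids.get_indexer(lines)
        freq = dataset.genotypes[loc].sum(axis=0) / (2.0 * len(lines))
        depth = _draw_depths(rng, config, n)
        alt = rng.binomial(depth, freq)
        out[f"{prefix}_ref"] = depth - alt
        out[f"{prefix}_alt"] = alt
    dataset.depths = out
    return out


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full generator: cross + extreme-bulk selection + pooled depths."""
    ds = simulate_cross(config)
    ds.pool_membership = select_bulks(ds.phenotypes, config.bulk_size)
    simulate_pool_depths(ds, config)
    return ds


def simulate_gene_models(
    n_genes: int,
    chrom: str = "chr1",
    chrom_length_bp: int = 30_000_000,
    seed: int = 0,
    mean_length_bp: int = 3_000,
) -> pd.DataFrame:
    """Non-overlapping gene models tiled over one chromosome.

    Returns a frame with gene_id, chrom, start_bp, end_bp (1-based,
    inclusive) and strand, sorted by start.
    """
    rng = stage_rng(seed, "genes")
    if n_genes == 0:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"]
        )
    starts = np.sort(
        _draw_positions(rng, max(chrom_length_bp - 2 * mean_length_bp, n_genes), n_genes)
    )
    lengths = np.maximum(
        (rng.exponential(mean_length_bp, size=n_genes)).astype(np.int64), 200
    )
    ends = starts + lengths
    # clip overlaps so gene i ends before gene i+1 starts
    ends[:-1] = np.minimum(ends[:-1], starts[1:] - 1)
    ends = np.maximum(ends, starts)
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "start_bp": starts.astype(np.int64),
            "end_bp": ends.astype(np.int64),
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )


def simulate_deg_table(
    gene_models: pd.DataFrame,
    causal_genes: Iterable[str],
    contrasts: Sequence[str] = ("TWGvsTIR", "WGvsIR", "IRvsTIR", "WGvsTWG"),
    seed: int = 0,
    causal_contrasts: Sequence[str] = ("IRvsTIR", "WGvsTWG"),
    causal_log2_ratio: float = -2.0,
) -> pd.DataFrame:
    """Differential-expression table with planted positives.

    Causal genes receive FDR < 0.05 and a fixed log2 ratio in the designated
    (within-variety) contrasts; every other gene/contrast cell draws a null
    uniform FDR and a small log2 ratio.
    """
    rng = stage_rng(seed, "deg")
    gene_ids = list(gene_models["gene_id"]) if len(gene_models) else []
    causal = set(causal_genes)
    unknown = causal - set(gene_ids)
    if unknown:
        raise ValueError(f"unknown causal gene ids: {sorted(unknown)}")
    rows = []
    for gene in gene_ids:
        for contrast in contrasts:
            if gene in causal and contrast in causal_contrasts:
                fdr = 10.0 ** rng.uniform(-8.0, -2.0)
                log2 = causal_log2_ratio
            else:
                fdr = rng.uniform(0.0, 1.0)
                log2 = rng.normal(0.0, 0.3)
            rows.append((gene, contrast, log2, fdr))
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2_ratio", "fdr"])
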