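"""Post-scan candidate-gene triage.

Once the genome scan has produced a candidate interval, the remaining steps
are bookkeeping over standard tables: classify differentially expressed
genes (DEGs) by FDR and direction, partition four contrast-specific DEG
sets into their 15 disjoint membership subgroups, intersect gene models
with the QTL interval, keep the region genes that are differentially
expressed in the designated within-variety contrasts, convert qRT-PCR Ct
values to relative expression with the 2^-ddCt rule, and test a single
marker's three genotype classes against the trait by one-way ANOVA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import GenomicRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CONTRASTS",
    "GeneModel",
    "ExpressionAssay",
    "AssociationResult",
    "classify_deg",
    "annotate_degs",
    "venn_partition",
    "genes_in_region",
    "candidate_filter",
    "ddct_relative_expression",
    "genotype_anova",
    "read_gene_models",
]

CONTRASTS = ("TWGvsTIR", "WGvsIR", "IRvsTIR", "WGvsTWG")
FDR_CUTOFF = 0.05  # significant iff fdr < 0.05, i.e. -log10(FDR) > 1.3


@dataclass(frozen=True)
class GeneModel:
    """A gene span (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class ExpressionAssay:
    """One qRT-PCR measurement: target and internal-control Ct values."""

    gene_id: str
    sample: str
    ct_target: float
    ct_reference: float
    condition: str  # "control" or "treatment"

    def delta_ct(self) -> float:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")
        return self.ct_target - self.ct_reference


@dataclass
class AssociationResult:
    """One-way ANOVA of a marker's genotype classes against a trait."""

    marker_id: str
    group_means: dict[str, float]
    f_statistic: float
    p_value: float


def classify_deg(log2_ratio: float, fdr: float) -> tuple[bool, str]:
    """Significance and direction call for one gene/contrast cell.

    Significant iff fdr < 0.05 (strict); direction is "up"/"down" by the
    sign of the log2 ratio, "ns" otherwise. A significant gene with a log2
    ratio of exactly 0 has no direction and is reported "ns" with a warning.
    """
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must be in [0, 1], got {fdr}")
    significant = fdr < FDR_CUTOFF
    if not significant:
        return False, "ns"
    if log2_ratio > 0:
        return True, "up"
    if log2_ratio < 0:
        return True, "down"
    warnings.warn(
        "significant FDR with log2 ratio exactly 0; direction undefined",
        UserWarning,
        stacklevel=2,
    )
    return True, "ns"


def annotate_degs(degs: pd.DataFrame) -> pd.DataFrame:
    """Add ``significant`` and ``direction`` columns to a DEG table."""
    out = degs.copy()
    fdr = out["fdr"].to_numpy(float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("fdr values must be in [0, 1]")
    log2 = out["log2_ratio"].to_numpy(float)
    sig = fdr < FDR_CUTOFF
    direction = np.where(
        ~sig, "ns", np.where(log2 > 0, "up", np.where(log2 < 0, "down", "ns"))
    )
    out["significant"] = sig
    out["direction"] = direction
    return out


def venn_partition(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Disjoint membership subgroups of four (or k) labelled id sets.

    Returns one row per non-empty membership pattern (2^k - 1 rows), with
    the member labels, the id count, and the count as a percentage of the
    union rounded to 2 decimals. Counts sum to the union size by
    construction.
    """
    labels = list(sets)
    as_sets = {lab: set(sets[lab]) for lab in labels}
    union: set = set().union(*as_sets.values()) if as_sets else set()
    rows = []
    for r in range(1, len(labels) + 1):
        for members in combinations(labels, r):
            inside = set.intersection(*(as_sets[m] for m in members)) if members else set()
            outside = set().union(
                *(as_sets[m] for m in labels if m not in members), set()
            )
            count = len(inside - outside)
            pct = round(100.0 * count / len(union), 2) if union else 0.0
            rows.append({"pattern": "&".join(members), "count": count, "pct": pct})
    out = pd.DataFrame(rows, columns=["pattern", "count", "pct"])
    out.attrs["union_size"] = len(union)
    return out


def _as_gene_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start_bp": g.start_bp,
                "end_bp": g.end_bp,
                "strand": g.strand,
            }
            for g in genes
        ],
        columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"],
    )


def genes_in_region(
    region: GenomicRegion, genes, how: str = "any"
) -> pd.DataFrame:
    """Gene models overlapping a region, sorted by start.

    ``how="any"`` keeps genes overlapping the region by >= 1 bp (the
    inclusive convention); ``how="contained"`` requires the full gene span
    inside the region.
    """
    df = _as_gene_frame(genes)
    on_chrom = df["chrom"] == region.chrom
    if how == "any":
        hit = on_chrom & (df["start_bp"] <= region.end_bp) & (
            df["end_bp"] >= region.start_bp
        )
    elif how == "contained":
        hit = on_chrom & (df["start_bp"] >= region.start_bp) & (
            df["end_bp"] <= region.end_bp
        )
    else:
        raise ValueError(f"unknown overlap rule {how!r}")
    return df[hit].sort_values("start_bp", kind="mergesort").reset_index(drop=True)


def candidate_filter(
    region_genes,
    degs: pd.DataFrame,
    contrasts: Sequence[str] = ("IRvsTIR", "WGvsTWG"),
    annotation=None,
) -> pd.DataFrame:
    """Region genes differentially expressed in the designated contrasts.

    Keeps genes significant (FDR < 0.05) in at least one designated
    contrast, annotates the per-contrast direction/log2/FDR, and ranks by
    minimum FDR across the designated contrasts so the output order is
    deterministic.
    """
    genes = _as_gene_frame(region_genes)
    known = set(degs["contrast"].unique())
    unknown = [c for c in contrasts if c not in known]
    if unknown:
        logger.warning("contrasts absent from DEG table: %s", unknown)
    ann = annotate_degs(degs[degs["contrast"].isin(contrasts)])
    if annotation is not None:
        orphans = set(ann["gene_id"]) - set(_as_gene_frame(annotation)["gene_id"])
        if orphans:
            logger.warning(
                "%d DEG gene ids are absent from the gene annotation and are skipped",
                len(orphans),
            )
    rows = []
    for _, gene in genes.iterrows():
        sub = ann[ann["gene_id"] == gene["gene_id"]]
        sig = sub[sub["significant"]]
        if sig.empty:
            continue
        row = {
            "gene_id": gene["gene_id"],
            "chrom": gene["chrom"],
            "start_bp": gene["start_bp"],
            "end_bp": gene["end_bp"],
            "min_fdr": float(sig["fdr"].min()),
        }
        for contrast in contrasts:
            cell = sub[sub["contrast"] == contrast]
            if cell.empty:
                row[f"{contrast}_direction"] = "na"
                row[f"{contrast}_log2"] = float("nan")
                row[f"{contrast}_fdr"] = float("nan")
            else:
                row[f"{contrast}_direction"] = cell["direction"].iloc[0]
                row[f"{contrast}_log2"] = float(cell["log2_ratio"].iloc[0])
                row[f"{contrast}_fdr"] = float(cell["fdr"].iloc[0])
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["min_fdr", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
    return out


def ddct_relative_expression(
    assay_treatment: ExpressionAssay, assay_control: ExpressionAssay
) -> float:
    """Relative expression by the 2^-ddCt rule.

    dCt = Ct(target) - Ct(reference) within each condition;
    ddCt = dCt(treatment) - dCt(control); the fold value is 2^-ddCt.
    """
    if assay_treatment.gene_id != assay_control.gene_id:
        raise ValueError("treatment and control assays must target the same gene")
    ddct = assay_treatment.delta_ct() - assay_control.delta_ct()
    return float(2.0 ** (-ddct))


def genotype_anova(
    genotype_classes: Sequence[str], trait_values: Sequence[float], marker_id: str = ""
) -> AssociationResult:
    """One-way fixed-effects ANOVA of trait values across genotype classes.

    Requires at least two classes with at least two observations each.
    Degenerate input where every value is identical yields F = 0, p = 1.
    """
    classes = np.asarray(genotype_classes)
    values = np.asarray(trait_values, float)
    if len(classes) != len(values):
        raise ValueError("genotype and trait vectors differ in length")
    groups = {}
    for cls in pd.unique(classes):
        groups[str(cls)] = values[classes == cls]
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError(
            "need at least 2 genotype classes with >= 2 observations each; "
            f"got sizes {dict((k, len(v)) for k, v in groups.items())}"
        )
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    if np.ptp(values) == 0:
        return AssociationResult(marker_id, means, 0.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*usable.values())
    f = float(f)
    p = float(p)
    if np.isinf(f):  # perfect between-class separation, zero within-class variance
        p = 0.0
    return AssociationResult(marker_id, means, f, p)


def read_gene_models(path: str) -> pd.DataFrame:
    """Read gene models from GFF3 (type == "gene") or BED6.

    Returns a frame with gene_id, chrom, start_bp, end_bp (1-based,
    inclusive) and strand. BED input is converted from 0-based half-open.
    """
    src = str(path)
    if src.endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            src, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for gene in db.features_of_type("gene"):
            gene_id = gene.attributes.get("ID", [gene.id])[0]
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": gene.seqid,
                    "start_bp": gene.start,
                    "end_bp": gene.end,
                    "strand": gene.strand or ".",
                }
            )
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start_bp", "end_bp", "strand"]
        )
    if src.endswith(".bed"):
        bed = pd.read_csv(
            src,
            sep="\t",
            comment="#",
            header=None,
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        return pd.DataFrame(
            {
                "gene_id": bed["name"],
                "chrom": bed["chrom"],
                "start_bp": bed["start"] + 1,
                "end_bp": bed["end"],
                "strand": bed["strand"].fillna("."),
            }
        )
    raise ValueError(f"unrecognised gene-model format: {src}")
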