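"""Readers/writers and the flat key-value configuration format.

Every output file starts with a comment header carrying the configuration
hash and seed so any result file can be traced to the exact run that
produced it. TSV/BED use ``#`` comment lines; VCF uses ``##`` header lines.
Coordinates are 1-based in VCF/TSV and 0-based half-open in BED.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .scan import GenomicRegion

__all__ = [
    "config_hash",
    "read_flat_config",
    "write_flat_config",
    "write_tsv",
    "write_depths_vcf",
    "write_regions_bed",
]


def config_hash(items: dict) -> str:
    """Short stable hash of a flat config mapping."""
    canon = "\n".join(f"{k}={items[k]}" for k in sorted(items))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def read_flat_config(path: str) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_flat_config(path: str, items: dict) -> None:
    lines = [f"{k} = {items[k]}" for k in sorted(items)]
    Path(path).write_text("\n".join(lines) + "\n")


def _header(tag: str, cfg_hash: str, seed: int) -> str:
    return f"# bulkscan {tag} config_hash={cfg_hash} seed={seed}\n"


def write_tsv(
    df: pd.DataFrame, path: str, tag: str, cfg_hash: str, seed: int
) -> None:
    """TSV with a one-line provenance comment header."""
    with open(path, "w") as fh:
        fh.write(_header(tag, cfg_hash, seed))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_depths_vcf(
    depths: pd.DataFrame,
    path: str,
    cfg_hash: str,
    seed: int,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Minimal biallelic VCF with AD fields for samples T_POOL and S_POOL."""
    contig_lengths = contig_lengths or {
        c: int(depths.loc[depths["chrom"] == c, "pos"].max())
        for c in depths["chrom"].unique()
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=bulkscan config_hash={cfg_hash} seed={seed}\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT_POOL\tS_POOL\n"
        )
        for rec in depths.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t.\tAD\t"
                f"{rec.t_ref},{rec.t_alt}\t{rec.s_ref},{rec.s_alt}\n"
            )


def write_regions_bed(
    regions: list[GenomicRegion], path: str, cfg_hash: str, seed: int
) -> None:
    """Regions as BED (0-based half-open), one line per region."""
    with open(path, "w") as fh:
        fh.write(_header("regions", cfg_hash, seed))
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.method}\n")
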