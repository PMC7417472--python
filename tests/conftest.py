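import numpy as np
import pandas as pd
import pytest

from bulkscan.simcross import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, fully simulated study: 300 lines, 2 chromosomes, 400 SNPs."""
    cfg = SimConfig(
        n_lines=300,
        bulk_size=25,
        n_chrom=2,
        chrom_length_bp=10_000_000,
        n_snps_per_chrom=200,
        qtl_chrom="chr1",
        qtl_pos_bp=5_000_000,
        seed=42,
    )
    return simulate_dataset(cfg)


def make_depths(chrom, pos, t_ref, t_alt, s_ref, s_alt, ref="A", alt="C"):
    """Hand-built allele-depth table in the simulator's TSV dialect."""
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
            "pos": pos,
            "ref": [ref] * n,
            "alt": [alt] * n,
            "t_ref": t_ref,
            "t_alt": t_alt,
            "s_ref": s_ref,
            "s_alt": s_alt,
        }
    )
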