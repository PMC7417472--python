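"""DEG classification, Venn partition, interval-gene triage, ddCt, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkscan.candidates import (
    ExpressionAssay,
    GeneModel,
    candidate_filter,
    classify_deg,
    ddct_relative_expression,
    genes_in_region,
    genotype_anova,
    read_gene_models,
    venn_partition,
)
from bulkscan.scan import GenomicRegion
from bulkscan.simcross import simulate_deg_table, simulate_gene_models


@pytest.mark.parametrize(
    "log2,fdr,expected",
    [
        (-1.2, 0.04, (True, "down")),
        (2.0, 0.049, (True, "up")),
        (3.0, 0.05, (False, "ns")),  # strict inequality at the cutoff
        (0.5, 0.5, (False, "ns")),
    ],
)
def test_classify_deg(log2, fdr, expected):
    assert classify_deg(log2, fdr) == expected


def test_classify_deg_guards():
    with pytest.raises(ValueError):
        classify_deg(1.0, 1.5)
    with pytest.warns(UserWarning, match="direction undefined"):
        assert classify_deg(0.0, 0.01) == (True, "ns")


def test_venn_identical_sets_collapse_to_all_four_subgroup():
    ids = {f"g{i}" for i in range(30)}
    sets = {lab: ids for lab in ("A", "B", "C", "D")}
    table = venn_partition(sets)
    assert len(table) == 15
    nonzero = table[table["count"] > 0]
    assert len(nonzero) == 1
    assert nonzero["pattern"].iloc[0] == "A&B&C&D"
    assert nonzero["count"].iloc[0] == 30
    assert table.attrs["union_size"] == 30


def test_venn_counts_match_per_id_tally():
    rng = np.random.default_rng(0)
    universe = [f"id{i}" for i in range(200)]
    sets = {
        lab: set(rng.choice(universe, size=50, replace=False))
        for lab in ("W", "X", "Y", "Z")
    }
    table = venn_partition(sets).set_index("pattern")
    # exhaustive oracle: classify every id by its membership pattern
    tally: dict[str, int] = {}
    for i in set().union(*sets.values()):
        pat = "&".join(lab for lab in sets if i in sets[lab])
        tally[pat] = tally.get(pat, 0) + 1
    for pat, count in tally.items():
        assert table.loc[pat, "count"] == count
    assert table["count"].sum() == len(set().union(*sets.values()))


@given(
    seeds=st.lists(st.integers(0, 500), min_size=4, max_size=4),
)
@settings(max_examples=50, derandomize=True)
def test_venn_counts_always_sum_to_union(seeds):
    sets = {
        f"S{k}": {f"id{(seed * j) % 97}" for j in range(seed % 23)}
        for k, seed in enumerate(seeds)
    }
    table = venn_partition(sets)
    assert table["count"].sum() == len(set().union(*sets.values()))


def test_genes_in_region_overlap_rules():
    region = GenomicRegion("chr7", 150, 400, "common")
    genes = [
        GeneModel("partial", "chr7", 100, 200),
        GeneModel("outside", "chr7", 401, 500),
        GeneModel("inside", "chr7", 200, 300),
        GeneModel("other_chrom", "chr1", 150, 400),
    ]
    hits = genes_in_region(region, genes)
    assert hits["gene_id"].tolist() == ["partial", "inside"]
    contained = genes_in_region(region, genes, how="contained")
    assert contained["gene_id"].tolist() == ["inside"]


def test_genes_in_region_matches_brute_force_scan():
    genes = simulate_gene_models(50, chrom="chr2", chrom_length_bp=5_000_000, seed=4)
    region = GenomicRegion("chr2", 1_234_567, 3_456_789, "common")
    got = set(genes_in_region(region, genes)["gene_id"])
    want = {
        g.gene_id
        for g in (GeneModel(**r) for r in genes.to_dict("records"))
        if g.chrom == region.chrom
        and g.start_bp <= region.end_bp
        and g.end_bp >= region.start_bp
    }
    assert got == want


def test_candidate_filter_recovers_planted_positives():
    """27 region genes, 5 planted DEGs in a designated contrast -> exactly 5."""
    genes = simulate_gene_models(27, chrom="chr7", chrom_length_bp=222_000, seed=9)
    causal = list(genes["gene_id"].iloc[10:15])
    degs = simulate_deg_table(genes, causal, seed=9, causal_contrasts=("IRvsTIR",))
    # remove chance positives outside the planted set in the designated contrasts
    designated = degs["contrast"].isin(["IRvsTIR", "WGvsTWG"])
    chance = designated & (degs["fdr"] < 0.05) & ~degs["gene_id"].isin(causal)
    degs.loc[chance, "fdr"] = 0.5
    region = GenomicRegion("chr7", 1, 222_000, "common")
    out = candidate_filter(genes_in_region(region, genes), degs)
    assert set(out["gene_id"]) == set(causal)
    assert (out["min_fdr"] < 0.05).all()
    assert (out["IRvsTIR_direction"] == "down").all()
    # ranked by minimum FDR
    assert out["min_fdr"].is_monotonic_increasing


def test_candidate_filter_respects_contrast_scope():
    genes = simulate_gene_models(5, seed=3)
    target = genes["gene_id"].iloc[0]
    degs = pd.DataFrame(
        {
            "gene_id": [target, target],
            "contrast": ["TWGvsTIR", "WGvsIR"],  # only non-designated contrasts
            "log2_ratio": [-3.0, 2.5],
            "fdr": [1e-6, 1e-4],
        }
    )
    region = GenomicRegion("chr1", 1, 30_000_000, "common")
    out = candidate_filter(genes_in_region(region, genes), degs)
    assert out.empty


def test_candidate_filter_output_is_subset_of_region_genes():
    genes = simulate_gene_models(40, seed=11)
    causal = list(genes["gene_id"].iloc[:8])
    degs = simulate_deg_table(genes, causal, seed=11)
    region = GenomicRegion("chr1", 1, 10_000_000, "common")
    region_genes = genes_in_region(region, genes)
    out = candidate_filter(region_genes, degs)
    assert set(out["gene_id"]) <= set(region_genes["gene_id"])


@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_ddct_relative_expression(ddct, expected):
    control = ExpressionAssay("g1", "ctrl", ct_target=24.0, ct_reference=18.0,
                              condition="control")
    treatment = ExpressionAssay("g1", "trt", ct_target=24.0 + ddct,
                                ct_reference=18.0, condition="treatment")
    assert ddct_relative_expression(treatment, control) == pytest.approx(expected)


def test_ddct_swapping_conditions_gives_reciprocal():
    a = ExpressionAssay("g1", "x", 25.0, 18.0, "control")
    b = ExpressionAssay("g1", "y", 22.5, 17.0, "treatment")
    fold = ddct_relative_expression(b, a)
    assert ddct_relative_expression(a, b) == pytest.approx(1.0 / fold)
    with pytest.raises(ValueError, match="same gene"):
        ddct_relative_expression(
            ExpressionAssay("g2", "y", 22.5, 17.0, "treatment"), a
        )


def test_genotype_anova_perfect_separation():
    res = genotype_anova(
        ["AA", "AA", "Aa", "Aa", "aa", "aa"], [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
    )
    assert res.p_value < 0.01
    assert res.group_means == {"AA": 1.0, "Aa": 2.0, "aa": 3.0}


def test_genotype_anova_degenerate_cases():
    flat = genotype_anova(["AA", "AA", "aa", "aa"], [2.0, 2.0, 2.0, 2.0])
    assert flat.f_statistic == 0.0
    assert flat.p_value == 1.0
    with pytest.raises(ValueError, match="classes"):
        genotype_anova(["AA", "AA", "AA"], [1.0, 2.0, 3.0])


def test_genotype_anova_detects_additive_marker():
    """A marker explaining 25% of variance in 199 lines is nearly always hit."""
    rng = np.random.default_rng(0)
    hits = 0
    n, pve = 199, 0.25
    a = np.sqrt(2 * pve / (1 - pve))  # residual sd 1
    for _ in range(100):
        g = rng.binomial(2, 0.5, size=n)
        y = a * (g - 1) + rng.normal(size=n)
        labels = np.array(["AA", "Aa", "aa"])[g]
        res = genotype_anova(labels, y)
        hits += res.p_value < 0.01
    assert hits >= 95


def test_read_gene_models_gff3_and_bed(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr7\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
        "chr7\ttest\tmRNA\t100\t500\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
        "chr7\ttest\tgene\t800\t900\t.\t-\t.\tID=geneB\n"
    )
    genes = read_gene_models(str(gff))
    assert genes["gene_id"].tolist() == ["geneA", "geneB"]
    assert genes["start_bp"].tolist() == [100, 800]

    bed = tmp_path / "genes.bed"
    bed.write_text("chr7\t99\t500\tgeneA\t0\t+\nchr7\t799\t900\tgeneB\t0\t-\n")
    from_bed = read_gene_models(str(bed))
    assert from_bed["start_bp"].tolist() == [100, 800]
    assert from_bed["end_bp"].tolist() == [500, 900]
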