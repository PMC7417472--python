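"""Scan statistics: indices, ED, smoothing, null bounds, ingest filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkscan.scan import (
    BaseFrequencies,
    FilterConfig,
    SmoothingConfig,
    compute_scan,
    delta_null_bounds,
    delta_snp_index,
    ed_threshold,
    euclidean_distance,
    fit_scan,
    read_allele_depths,
    snp_index,
)
from conftest import make_depths


@pytest.mark.parametrize(
    "ref,alt,expected", [(10, 10, 0.5), (0, 20, 1.0), (21, 9, 0.3)]
)
def test_snp_index(ref, alt, expected):
    assert snp_index(ref, alt) == pytest.approx(expected)


def test_snp_index_below_min_depth_is_filtered():
    assert math.isnan(snp_index(2, 3, min_depth=7))
    with pytest.raises(ValueError):
        snp_index(-1, 3)


@pytest.mark.parametrize(
    "t,s,expected", [(0.8, 0.3, -0.5), (0.4, 0.4, 0.0), (0.0, 1.0, 1.0)]
)
def test_delta_snp_index_default_is_s_minus_t(t, s, expected):
    assert delta_snp_index(t, s) == pytest.approx(expected)
    assert delta_snp_index(t, s, "t_minus_s") == pytest.approx(-expected)


def _bf(pool, a, c, g, t):
    return BaseFrequencies(pool, a, c, g, t)


def test_euclidean_distance_closed_forms():
    same = _bf("T", 0.25, 0.25, 0.25, 0.25)
    assert euclidean_distance(same, _bf("S", 0.25, 0.25, 0.25, 0.25)) == 0.0
    fixed_t = _bf("T", 1.0, 0.0, 0.0, 0.0)
    fixed_s = _bf("S", 0.0, 1.0, 0.0, 0.0)
    assert euclidean_distance(fixed_t, fixed_s) == pytest.approx(
        math.sqrt(2.0), abs=1e-9
    )
    t = _bf("T", 0.7, 0.3, 0.0, 0.0)
    s = _bf("S", 0.4, 0.6, 0.0, 0.0)
    assert euclidean_distance(t, s) == pytest.approx(math.sqrt(0.18), abs=1e-9)


def test_euclidean_distance_rejects_bad_frequencies():
    with pytest.raises(ValueError, match="sum to 1"):
        euclidean_distance(
            _bf("T", 0.5, 0.2, 0.0, 0.0), _bf("S", 0.25, 0.25, 0.25, 0.25)
        )


@st.composite
def freq_vectors(draw):
    raw = draw(
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4)
    )
    total = sum(raw)
    a, c, g, t = (x / total for x in raw)
    t = 1.0 - a - c - g  # close the simplex exactly
    return a, c, g, t


@given(x=freq_vectors(), y=freq_vectors(), z=freq_vectors())
@settings(max_examples=100, derandomize=True)
def test_ed_symmetry_and_triangle_inequality(x, y, z):
    fx, fy, fz = _bf("T", *x), _bf("S", *y), _bf("S", *z)
    dxy = euclidean_distance(fx, fy)
    assert dxy == pytest.approx(euclidean_distance(fy, fx), abs=1e-12)
    assert dxy <= euclidean_distance(fx, fz) + euclidean_distance(fz, fy) + 1e-12


def test_delta_and_ed_agree_in_nullity():
    """At a biallelic marker: ED = 0 iff the pool indices match iff Δ = 0."""
    depths = make_depths(
        "chr1",
        pos=[100, 200, 300],
        t_ref=[10, 5, 0],
        t_alt=[10, 15, 20],
        s_ref=[15, 5, 12],
        s_alt=[15, 15, 8],
    )
    pts = compute_scan(depths, bulk_size=5, n_sims=1000, seed=0,
                       smoothing=SmoothingConfig(min_window_snps=1))
    zero_delta = pts["delta_snp_index"].abs() < 1e-12
    zero_ed = pts["ed"] < 1e-12
    same_idx = (pts["snp_index_t"] - pts["snp_index_s"]).abs() < 1e-12
    assert (zero_delta == zero_ed).all()
    assert (zero_delta == same_idx).all()
    assert zero_delta.tolist() == [True, True, False]


# ---------------------------------------------------------------------------
# smoothing


def _brute_force_fit(pos, values, half_width, min_snps):
    """Independent kernel-sum recomputation of the tricube window mean."""
    out = np.full(len(pos), np.nan)
    for i, p in enumerate(pos):
        num = den = 0.0
        count = 0
        for q, v in zip(pos, values):
            if abs(q - p) <= half_width:
                count += 1
                w = (1 - (abs(q - p) / half_width) ** 3) ** 3
                num += w * v
                den += w
        if count >= min_snps and den > 0:
            out[i] = num / den
    return out


def test_fit_scan_preserves_constants():
    depths = make_depths(
        "chr1", pos=list(range(1000, 21000, 1000)),
        t_ref=[10] * 20, t_alt=[10] * 20, s_ref=[20] * 20, s_alt=[0] * 20,
    )
    pts = compute_scan(depths, bulk_size=5, n_sims=1000, seed=0,
                       smoothing=SmoothingConfig(half_width_bp=5000, min_window_snps=1))
    c = math.sqrt(2.0) * 0.5
    assert pts["fitted_ed"].to_numpy() == pytest.approx(np.full(20, c**4), abs=1e-12)
    assert pts["fitted_delta"].to_numpy() == pytest.approx(np.full(20, -0.5), abs=1e-12)


def test_fit_scan_spike_is_flattened_but_peaks_at_spike():
    rng = np.random.default_rng(0)
    n = 1000
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), n, replace=False))
    values = np.zeros(n)
    spike = 500
    values[spike] = 1.0
    df = pd.DataFrame({"chrom": "chr1", "pos": pos, "ed": values,
                       "delta_snp_index": values})
    sm = SmoothingConfig(half_width_bp=1_000_000, ed_power=4.0, min_window_snps=1)
    fitted = fit_scan(df, "ed", sm).to_numpy()
    peak = int(np.nanargmax(fitted))
    assert abs(int(pos[peak]) - int(pos[spike])) <= sm.half_width_bp
    assert fitted[spike] > 0.0
    assert np.nanmax(fitted) < 1.0  # raw spike^p = 1


def test_fit_scan_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    n = 300
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), n, replace=False))
    values = rng.normal(size=n)
    df = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "delta_snp_index": values, "ed": np.abs(values)}
    )
    sm = SmoothingConfig(half_width_bp=200_000, ed_power=4.0, min_window_snps=5)
    got = fit_scan(df, "delta", sm).to_numpy()
    want = _brute_force_fit(pos, values, 200_000, 5)
    np.testing.assert_allclose(got, want, atol=1e-9)
    got_ed = fit_scan(df, "ed", sm).to_numpy()
    want_ed = _brute_force_fit(pos, np.abs(values) ** 4, 200_000, 5)
    np.testing.assert_allclose(got_ed, want_ed, atol=1e-9)


def test_fit_scan_does_not_leak_across_chromosomes():
    pos = list(range(1000, 11000, 1000))
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 10 + ["chr2"] * 10,
            "pos": pos + pos,
            "delta_snp_index": [0.9] * 10 + [0.0] * 10,
            "ed": [1.0] * 10 + [0.0] * 10,
        }
    )
    sm = SmoothingConfig(half_width_bp=1_000_000, min_window_snps=1)
    fitted = fit_scan(df, "delta", sm)
    assert fitted.iloc[10:].to_numpy() == pytest.approx(np.zeros(10), abs=1e-12)


def test_fit_scan_window_below_min_snps_is_undefined():
    df = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 1_000_000, 2_000_000],
         "delta_snp_index": [1.0, 1.0, 1.0], "ed": [1.0, 1.0, 1.0]}
    )
    sm = SmoothingConfig(half_width_bp=10_000, min_window_snps=2)
    assert fit_scan(df, "delta", sm).isna().all()


# ---------------------------------------------------------------------------
# null bounds and ED threshold


def test_null_bounds_deep_depth_matches_normal_approximation():
    """At saturating depth the bound is the sampling-only closed form."""
    ci95, _ = delta_null_bounds(10_000, 10_000, 40, n_sims=20_000, seed=0)
    expected = 1.96 * math.sqrt(2 * 0.25 / 80)  # ~0.155
    assert ci95 == pytest.approx(expected, abs=0.01)


def test_null_bounds_monotone_in_depth():
    lo95, lo99 = delta_null_bounds(10, 10, 40, seed=3)
    hi95, hi99 = delta_null_bounds(100, 100, 40, seed=3)
    assert lo95 >= hi95
    assert lo99 >= hi99
    assert lo99 >= lo95


def test_null_bounds_stable_in_n_sims():
    a, _ = delta_null_bounds(30, 30, 40, n_sims=10_000, seed=1)
    b, _ = delta_null_bounds(30, 30, 40, n_sims=20_000, seed=2)
    assert abs(a - b) < 0.01


def test_null_bounds_rejects_tiny_sim_count():
    with pytest.raises(ValueError):
        delta_null_bounds(30, 30, 40, n_sims=10)


def test_ed_threshold_degenerate_and_gaussian():
    with pytest.warns(UserWarning, match="zero spread"):
        assert ed_threshold(np.ones(200)) == pytest.approx(1.0)
    x = np.random.default_rng(0).normal(size=10_000)
    assert 2.8 <= ed_threshold(x) <= 3.2


def test_ed_threshold_robust_to_single_outlier():
    x = np.random.default_rng(1).normal(size=10_000)
    base = ed_threshold(x)
    x_out = x.copy()
    x_out[0] = 1e6
    assert abs(ed_threshold(x_out) - base) / base < 0.01


# ---------------------------------------------------------------------------
# ingest


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT_POOL\tS_POOL
"""


def test_read_vcf_applies_depth_filter_and_skips_multiallelic(tmp_path):
    records = [
        "chr1\t100\t.\tA\tC\t.\t.\t.\tAD\t10,5\t8,9",
        "chr1\t200\t.\tG\tT\t.\t.\t.\tAD\t1,2\t8,9",  # T depth 3 < 7
        "chr1\t300\t.\tA\tC,G\t.\t.\t.\tAD\t5,5,5\t5,5,5",  # two alts
        "chr1\t400\t.\tT\tA\t.\t.\t.\tAD\t20,0\t0,22",
        "chr1\t500\t.\tC\tG\t.\t.\t.\tAD\t12,9\t7,7",
        "chr1\t600\t.\tC\tA\t.\t.\t.\tAD\t9,3\t6,6",
    ]
    p = tmp_path / "pools.vcf"
    p.write_text(VCF_HEADER + "\n".join(records) + "\n")
    df = read_allele_depths(str(p), FilterConfig(max_depth_percentile=100))
    assert len(df) == 4
    assert 200 not in df["pos"].tolist()
    counts = df.attrs["filter_counts"]
    assert counts["below_min_depth"] == 1
    assert counts["multiallelic_or_malformed"] == 1


def test_read_tsv_matches_generator_counts(tmp_path, small_dataset):
    p = tmp_path / "depths.tsv"
    small_dataset.depths.to_csv(p, sep="\t", index=False)
    filters = FilterConfig(min_pool_depth=7, max_depth_percentile=100)
    df = read_allele_depths(str(p), filters)
    depth_t = small_dataset.depths["t_ref"] + small_dataset.depths["t_alt"]
    depth_s = small_dataset.depths["s_ref"] + small_dataset.depths["s_alt"]
    expected = int(((depth_t >= 7) & (depth_s >= 7)).sum())
    assert len(df) == expected


def test_read_tsv_zero_survivors_is_an_error(tmp_path):
    p = tmp_path / "depths.tsv"
    make_depths("chr1", [100], [1], [1], [1], [1]).to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="no markers"):
        read_allele_depths(str(p))


def test_parent_informative_filter(tmp_path):
    df = make_depths(
        "chr1", pos=[100, 200], t_ref=[10, 10], t_alt=[10, 10],
        s_ref=[10, 10], s_alt=[10, 10],
    )
    df["pt_ref"] = [0, 5]
    df["pt_alt"] = [20, 5]  # marker 2: heterozygous-looking parent
    df["ps_ref"] = [20, 20]
    df["ps_alt"] = [0, 0]
    p = tmp_path / "depths.tsv"
    df.to_csv(p, sep="\t", index=False)
    out = read_allele_depths(str(p), FilterConfig(max_depth_percentile=100))
    assert out["pos"].tolist() == [100]
    assert out.attrs["filter_counts"]["parent_not_informative"] == 1
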