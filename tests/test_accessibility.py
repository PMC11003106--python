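"""Gene/ACR accessibility matrices, Z-scores, master list, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scifiatac.accessibility import (
    acr_accessibility,
    build_acr_master_list,
    cpm,
    cpm_zscore,
    filter_by_cpm,
    gene_accessibility,
    library_correlation,
    specific_features,
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "group"])


def test_gene_window_flanks_strand_aware():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1000], "end": [2000], "strand": ["+"]}
    )
    sites = _sites([("chr1", 600, "g"), ("chr1", 2050, "g"), ("chr1", 2150, "g")])
    counts = gene_accessibility(sites, genes)
    assert counts.iloc[0, 0] == 2  # [500, 2100): 600 and 2050 in, 2150 out
    genes["strand"] = ["-"]
    counts = gene_accessibility(sites, genes)
    # [900, 2500): only 2050 and 2150
    assert counts.iloc[0, 0] == 2
    sites2 = _sites([("chr1", 950, "g")])
    assert gene_accessibility(sites2, genes).iloc[0, 0] == 1


def test_no_sites_gives_zero_rows():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [200], "strand": ["+"]}
    )
    counts = gene_accessibility(_sites([("chr2", 5, "g")]), genes)
    assert (counts.to_numpy() == 0).all()


def test_gene_counts_match_brute_force():
    rng = np.random.default_rng(2)
    genes = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], 40),
            "start": (s := rng.integers(1000, 80_000, 40)),
            "end": s + rng.integers(500, 5_000, 40),
            "strand": rng.choice(["+", "-"], 40),
        }
    )
    sites = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], 4000),
            "pos": rng.integers(0, 100_000, 4000),
            "group": rng.choice(["x", "y"], 4000),
        }
    )
    counts = gene_accessibility(sites, genes)
    for gi, g in genes.iterrows():
        lo = g.start - 500 if g.strand == "+" else g.start - 100
        hi = g.end + 100 if g.strand == "+" else g.end + 500
        for grp in ("x", "y"):
            sub = sites[(sites.group == grp) & (sites.chrom == g.chrom)]
            brute = ((sub.pos >= lo) & (sub.pos < hi)).sum()
            assert counts.at[gi, grp] == brute


def test_cpm_columns_sum_to_million():
    raw = pd.DataFrame({"a": [5, 10, 0], "b": [1, 2, 3]})
    c = cpm(raw)
    np.testing.assert_allclose(c.sum(axis=0), 1e6, rtol=1e-9)


def test_zscore_of_identical_columns_is_zero():
    raw = pd.DataFrame({"a": [5, 10, 1], "b": [5, 10, 1]})
    assert (cpm_zscore(raw).to_numpy() == 0).all()


def test_zscore_sample_sd_arithmetic():
    raw = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [30.0]})
    # single-feature columns: CPM makes all columns 1e6 -> Z = 0
    assert (cpm_zscore(raw).to_numpy() == 0).all()
    # bypass CPM distortion with balanced columns
    raw = pd.DataFrame(
        {"a": [10.0, 90.0], "b": [20.0, 80.0], "c": [30.0, 70.0]}
    )
    z = cpm_zscore(raw)
    np.testing.assert_allclose(z.iloc[0].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)


def test_zscore_rows_standardised():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.integers(1, 100, size=(30, 5)), columns=list("abcde"))
    z = cpm_zscore(raw)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_cpm_zscore_invariant_to_column_scaling():
    rng = np.random.default_rng(1)
    raw = pd.DataFrame(rng.integers(1, 50, size=(20, 4)), columns=list("abcd"))
    scaled = raw.copy()
    scaled["b"] = scaled["b"] * 7
    pd.testing.assert_frame_equal(cpm_zscore(raw), cpm_zscore(scaled.astype(float)))


def test_master_list_disjoint_windows_kept():
    acrs = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "summit": [1000, 1600],
            "count": [10.0, 5.0],
        }
    )
    ml = build_acr_master_list(acrs)
    assert len(ml) == 2
    assert ml["end"].sub(ml["start"]).eq(500).all()


def test_master_list_greedy_merge_keeps_higher_count():
    acrs = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "summit": [1000, 1100],
            "count": [5.0, 9.0],
        }
    )
    ml = build_acr_master_list(acrs)
    assert len(ml) == 1
    assert ml.iloc[0]["summit"] == 1100


def test_master_list_windows_pairwise_disjoint():
    rng = np.random.default_rng(4)
    acrs = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "summit": rng.integers(300, 50_000, 200),
            "count": rng.random(200),
        }
    )
    ml = build_acr_master_list(acrs)
    for _, grp in ml.groupby("chrom"):
        g = grp.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


def test_low_cpm_everywhere_removed():
    windows = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 1000], "end": [500, 1500]}
    )
    # feature 0 scaled so its CPM is (2.9, 2.5, 1.0); feature 1 carries the rest
    raw = pd.DataFrame(
        {
            "g1": [2.9, 1e6 - 2.9],
            "g2": [2.5, 1e6 - 2.5],
            "g3": [1.0, 1e6 - 1.0],
        }
    )
    kept = filter_by_cpm(windows, raw, min_cpm=3.0)
    assert len(kept) == 1
    assert kept.iloc[0]["start"] == 1000


def test_acr_counts_and_filter_pipeline():
    windows = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 1000], "end": [500, 1500]}
    )
    sites = _sites(
        [("chr1", 10, "a")] * 1 + [("chr1", 1100, "a")] * 0
        + [("chr1", 250, "b"), ("chr1", 1200, "b")]
    )
    counts = acr_accessibility(sites, windows)
    assert counts["a"].tolist() == [1, 0]
    assert counts["b"].tolist() == [1, 1]


def test_specific_features_threshold_behaviour():
    z = pd.DataFrame(
        {"a": [1.5, 2.5, 0.0], "b": [-1.5, -0.5, 0.0]},
        index=["f1", "f2", "f3"],
    )
    sets, summary = specific_features(z, z_threshold=2.0)
    assert sets == {"a": ["f2"], "b": []}
    assert summary.set_index("group")["n_specific"].to_dict() == {"a": 1, "b": 0}
    none, _ = specific_features(z, z_threshold=np.inf)
    assert all(len(v) == 0 for v in none.values())


def test_specific_counts_monotone_in_threshold():
    rng = np.random.default_rng(7)
    z = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
    counts = [
        sum(len(v) for v in specific_features(z, t)[0].values())
        for t in (0.5, 1.0, 2.0, 3.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_planted_specific_features_recovered():
    """20% of features spiked in one of eight groups are called specific there.

    A single-group spike among k groups caps at Z = (k-1)/sqrt(k), so k >= 7
    groups are needed for the Z > 2 rule to see it — the regime of the
    multi-genotype / multi-cell-type matrices this call is made on.
    """
    rng = np.random.default_rng(11)
    n, spiked = 500, 100
    raw = pd.DataFrame(
        rng.poisson(50, size=(n, 8)).astype(float), columns=list("abcdefgh")
    )
    raw.iloc[:spiked, 0] *= 8  # strong spike in group 'a'
    sets, _ = specific_features(cpm_zscore(raw), z_threshold=2.0)
    hits = set(sets["a"]) & set(range(spiked))
    assert len(hits) >= 0.9 * spiked
    frac = len(sets["a"]) / n
    assert abs(frac - 0.2) < 0.05


def test_spearman_properties_and_oracle():
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.random(size=(100, 4)), columns=list("wxyz"))
    rho = library_correlation(mat)
    assert np.allclose(np.diag(rho), 1.0)
    assert np.allclose(rho, rho.T)
    # independent oracle: rank then Pearson
    ranks = mat.rank()
    expected = np.corrcoef(ranks.to_numpy(), rowvar=False)
    np.testing.assert_allclose(rho.to_numpy(), expected, atol=1e-12)


def test_spearman_reversed_ranks():
    mat = pd.DataFrame({"u": [1, 2, 3, 4], "v": [8, 6, 4, 2], "w": [1, 3, 2, 4]})
    rho = library_correlation(mat)
    assert rho.at["u", "v"] == pytest.approx(-1.0)
    assert rho.at["u", "u"] == 1.0


def test_constant_column_reported_missing():
    mat = pd.DataFrame({"u": [1, 2, 3], "v": [5, 5, 5]})
    with pytest.warns(UserWarning):
        rho = library_correlation(mat)
    assert np.isnan(rho.at["u", "v"])
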