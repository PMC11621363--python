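"""Single-cell QC, Xa-state calling, skewing, pseudobulk and escape calls."""

import numpy as np
import pandas as pd
import pytest

from xcikit import (
    CellQCParams,
    SimGenome,
    call_xa_state,
    gene_allelic_profile,
    pseudobulk,
    qc_filter,
    skew_summary,
)
from xcikit.scxci import PseudobulkGroup
from xcikit.simulate import ScSimConfig, gen_sc_allele_counts

from conftest import make_adata


# -- QC ----------------------------------------------------------------------


def _qc_adata(n_features, n_counts, mito_pct):
    n = len(n_features)
    obs = pd.DataFrame(
        {"n_features": n_features, "n_counts": n_counts, "mito_pct": mito_pct},
        index=[f"cell{i}" for i in range(n)],
    )
    total = np.full((n, 30), 100)
    return make_adata(total, total // 2, obs=obs)


def test_qc_boundaries_are_strict():
    adata = _qc_adata(
        n_features=[500, 501, 4_999, 5_000],
        n_counts=[5_000] * 4,
        mito_pct=[1.0] * 4,
    )
    kept, report = qc_filter(adata, CellQCParams(min_cells_per_gene=0))
    assert list(kept.obs_names) == ["cell1", "cell2"]
    assert report["removed_features_range"] == 2


def test_qc_mito_just_under_threshold_kept():
    adata = _qc_adata([1000, 1000], [5000, 5000], [9.9, 10.0])
    kept, _ = qc_filter(adata, CellQCParams(min_cells_per_gene=0))
    assert list(kept.obs_names) == ["cell0"]


def test_qc_count_bounds_strict():
    adata = _qc_adata([1000] * 4, [2_000, 2_001, 19_999, 20_000], [1.0] * 4)
    kept, _ = qc_filter(adata, CellQCParams(min_cells_per_gene=0))
    assert list(kept.obs_names) == ["cell1", "cell2"]


def test_qc_gene_filter_requires_strictly_more_cells():
    total = np.zeros((12, 2), dtype=int)
    total[:11, 0] = 5  # gene 0 seen in 11 cells, gene 1 in 10
    total[:10, 1] = 5
    obs = pd.DataFrame(
        {"n_features": [1000] * 12, "n_counts": [5000] * 12, "mito_pct": [1.0] * 12},
        index=[f"cell{i}" for i in range(12)],
    )
    adata = make_adata(total, total, obs=obs)
    kept, _ = qc_filter(adata, CellQCParams(min_cells_per_gene=10))
    assert list(kept.var_names) == ["g0"]


def test_qc_empty_result_raises_with_report():
    adata = _qc_adata([100, 100], [5000, 5000], [1.0, 1.0])
    with pytest.raises(ValueError, match="n_cells_kept"):
        qc_filter(adata)


def test_qc_survivor_count_on_constructed_outliers(genome):
    # 100 cells per genotype with a 7% forced-violation rate -> 93 survive
    cfg = ScSimConfig(
        n_cells_per_genotype=100,
        genotypes=("WT",),
        qc_outlier_rate=0.07,
        doublet_rate=0.0,
        per_cell_depth=(8000.0, 0.005),
        seed=17,
    )
    adata, truth = gen_sc_allele_counts(genome, cfg)
    violators = {bc for bc, v in truth.cells.items() if v["qc_violation"]}
    assert len(violators) == 7
    kept, report = qc_filter(adata)
    assert report["n_cells_kept"] == 93
    assert set(adata.obs_names) - set(kept.obs_names) == violators


# -- Xa calling --------------------------------------------------------------


def test_xa_threshold_boundary_inclusive():
    # x_ratio exactly 0.70 -> STRAIN1_Xa; exactly 0.30 -> STRAIN2_Xa
    total = np.array([[10], [10], [10]])
    s1 = np.array([[7], [3], [5]])
    adata = make_adata(total, s1)
    calls = call_xa_state(adata)
    assert calls["state"].tolist() == ["STRAIN1_Xa", "STRAIN2_Xa", "BIALLELIC_EXCLUDED"]


def test_low_coverage_overrides_ratio():
    adata = make_adata(np.array([[9]]), np.array([[9]]))
    calls = call_xa_state(adata)
    assert calls["state"].iloc[0] == "LOW_COVERAGE"
    assert calls["x_total"].iloc[0] == 9


def test_no_x_genes_is_an_error():
    adata = make_adata(np.array([[5]]), np.array([[5]]), chroms=["chr1"])
    with pytest.raises(ValueError, match="chrX"):
        call_xa_state(adata)


def test_every_cell_gets_exactly_one_state(genome):
    cfg = ScSimConfig(n_cells_per_genotype=200, seed=23)
    adata, _ = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    assert len(calls) == adata.n_obs
    assert calls["state"].isin(
        ["STRAIN1_Xa", "STRAIN2_Xa", "BIALLELIC_EXCLUDED", "LOW_COVERAGE"]
    ).all()
    assert calls["state"].value_counts().sum() == adata.n_obs


def test_strain_relabel_swaps_calls(genome):
    cfg = ScSimConfig(n_cells_per_genotype=150, seed=29)
    adata, _ = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    swapped = adata.copy()
    swapped.layers["strain1"], swapped.layers["strain2"] = (
        adata.layers["strain2"].copy(),
        adata.layers["strain1"].copy(),
    )
    calls_sw = call_xa_state(swapped)
    mapping = {"STRAIN1_Xa": "STRAIN2_Xa", "STRAIN2_Xa": "STRAIN1_Xa"}
    expected = calls["state"].map(lambda s: mapping.get(s, s))
    assert (calls_sw["state"] == expected).all()
    defined = calls["x_total"] > 0
    assert np.allclose(
        calls_sw.loc[defined, "x_ratio"], 1 - calls.loc[defined, "x_ratio"]
    )


# -- skew summary ------------------------------------------------------------


def test_skew_all_one_state():
    calls = pd.DataFrame(
        {"x_total": [100] * 5, "x_ratio": [0.99] * 5, "state": ["STRAIN1_Xa"] * 5},
        index=[f"c{i}" for i in range(5)],
    )
    geno = pd.Series("WT", index=calls.index)
    out = skew_summary(calls, geno)
    s1 = out[(out["genotype"] == "WT") & (out["state"] == "STRAIN1_Xa")]
    assert s1["pct"].iloc[0] == 100.0


def test_skew_percentages_sum_to_100(genome):
    cfg = ScSimConfig(n_cells_per_genotype=300, seed=31)
    adata, _ = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    out = skew_summary(calls, adata.obs["genotype"])
    for gt, grp in out.groupby("genotype"):
        informative = grp[grp["state"] != "LOW_COVERAGE"]
        assert informative["pct"].sum() == pytest.approx(100.0)


def test_skew_recovery_within_binomial_error(genome):
    skew = 0.66
    n = 600
    cfg = ScSimConfig(
        n_cells_per_genotype=n,
        genotypes=("WT",),
        skew=skew,
        doublet_rate=0.0,
        qc_outlier_rate=0.0,
        seed=37,
    )
    adata, truth = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    definite = calls[calls["state"].isin(["STRAIN1_Xa", "STRAIN2_Xa"])]
    frac = (definite["state"] == "STRAIN1_Xa").mean()
    se = np.sqrt(skew * (1 - skew) / n)
    assert abs(frac - skew) <= 3 * se


def test_excluded_cells_match_truth_doublets(genome):
    cfg = ScSimConfig(
        n_cells_per_genotype=400,
        genotypes=("WT",),
        skew=0.5,
        doublet_rate=0.15,
        qc_outlier_rate=0.0,
        seed=41,
    )
    adata, truth = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    mixed = [bc for bc, v in truth.cells.items() if v["mixed_doublet"]]
    # high depth: every mixed-Xa doublet sits near ratio 0.5 and is excluded
    assert (calls.loc[mixed, "state"] == "BIALLELIC_EXCLUDED").all()
    excluded = set(calls.index[calls["state"] == "BIALLELIC_EXCLUDED"])
    assert excluded == set(mixed)


# -- pseudobulk --------------------------------------------------------------


def _simple_group_inputs():
    # gene g0 allele counts per cell: (3,0), (2,1), (1,7)
    total = np.array([[3, 1], [3, 2], [8, 0]])
    s1 = np.array([[3, 0], [2, 1], [1, 0]])
    obs = pd.DataFrame({"genotype": ["WT", "WT", "WT"]}, index=["a", "b", "c"])
    adata = make_adata(total, s1, obs=obs)
    calls = pd.DataFrame(
        {
            "x_total": [4, 4, 8],
            "x_ratio": [0.75, 0.75, 0.125],
            "state": ["STRAIN1_Xa", "STRAIN1_Xa", "STRAIN2_Xa"],
        },
        index=["a", "b", "c"],
    )
    return adata, calls


def test_pseudobulk_additivity():
    adata, calls = _simple_group_inputs()
    groups = pseudobulk(adata, calls)
    g = groups[("WT", "STRAIN1_Xa")]
    assert g.counts.loc["g0"].tolist() == [5, 1]  # (3,0) + (2,1)
    assert g.n_cells == 2


def test_pseudobulk_order_invariance():
    adata, calls = _simple_group_inputs()
    perm = [2, 0, 1]
    shuffled = adata[perm].copy()
    g1 = pseudobulk(adata, calls)[("WT", "STRAIN1_Xa")]
    g2 = pseudobulk(shuffled, calls.iloc[perm])[("WT", "STRAIN1_Xa")]
    pd.testing.assert_frame_equal(g1.counts, g2.counts)


def test_pseudobulk_conservation():
    adata, calls = _simple_group_inputs()
    groups = pseudobulk(adata, calls)
    member = calls["state"] == "STRAIN1_Xa"
    expected = adata.layers["strain1"][member.to_numpy()].sum(axis=0)
    assert (groups[("WT", "STRAIN1_Xa")].counts["strain1"].to_numpy() == expected).all()


def test_pseudobulk_empty_group_warns_with_zeros():
    adata, calls = _simple_group_inputs()
    calls = calls.copy()
    calls["state"] = "STRAIN1_Xa"
    with pytest.warns(UserWarning, match="empty pseudobulk group"):
        groups = pseudobulk(adata, calls)
    assert (groups[("WT", "STRAIN2_Xa")].counts.to_numpy() == 0).all()


def test_group_ratio_is_ratio_of_sums():
    # two cells with gene ratios 0.9 (9/10) and 0.0 (0/90): pooled 9/100
    counts = pd.DataFrame({"strain1": [9], "strain2": [91]}, index=["g0"])
    grp = PseudobulkGroup("WT", "STRAIN1_Xa", counts, 2)
    var = pd.DataFrame({"chrom": ["chrX"]}, index=["g0"])
    prof = gene_allelic_profile({("WT", "STRAIN1_Xa"): grp}, var, min_total=30)
    assert prof["ratio"].iloc[0] == pytest.approx(0.09)
    assert prof["ratio"].iloc[0] != pytest.approx((0.9 + 0.0) / 2)


# -- escape calls ------------------------------------------------------------


def test_profile_calls_by_construction():
    counts = pd.DataFrame(
        {"strain1": [50, 48, 2], "strain2": [50, 2, 48]},
        index=["esc", "sil", "xist"],
    )
    var = pd.DataFrame({"chrom": ["chrX"] * 3}, index=counts.index)
    grp = PseudobulkGroup("WT", "STRAIN1_Xa", counts, 10)
    prof = gene_allelic_profile({("WT", "STRAIN1_Xa"): grp}, var).set_index("gene_id")
    assert prof.loc["esc", "call"] == "escaping"
    assert prof.loc["sil", "call"] == "xa_exclusive"
    assert prof.loc["xist", "call"] == "xi_exclusive"
    # mirrored group: Xa is strain 2, so the labels flip with the ratios
    grp2 = PseudobulkGroup("WT", "STRAIN2_Xa", counts, 10)
    prof2 = gene_allelic_profile({("WT", "STRAIN2_Xa"): grp2}, var).set_index("gene_id")
    assert prof2.loc["sil", "call"] == "xi_exclusive"
    assert prof2.loc["xist", "call"] == "xa_exclusive"


def test_autosomal_genes_get_no_escape_call():
    counts = pd.DataFrame({"strain1": [50], "strain2": [50]}, index=["auto"])
    var = pd.DataFrame({"chrom": ["chr1"]}, index=["auto"])
    grp = PseudobulkGroup("WT", "STRAIN1_Xa", counts, 3)
    prof = gene_allelic_profile({("WT", "STRAIN1_Xa"): grp}, var)
    assert prof["call"].iloc[0] == ""


def test_synthetic_escape_and_xist_recovered(genome):
    cfg = ScSimConfig(n_cells_per_genotype=400, seed=43)
    adata, truth = gen_sc_allele_counts(genome, cfg)
    calls = call_xa_state(adata)
    groups = pseudobulk(adata, calls)
    prof = gene_allelic_profile(groups, adata.var)
    escape_ids = set(adata.uns["escape_gene_ids"])
    informative = prof[(prof["chrom"] == "chrX") & (prof["status"] != "filtered")]
    esc_rows = informative[informative["gene_id"].isin(escape_ids)]
    assert (esc_rows["call"] == "escaping").all()
    xist_rows = informative[informative["gene_id"] == adata.uns["xist_id"]]
    assert (xist_rows["call"] == "xi_exclusive").all()
    silenced = informative[
        ~informative["gene_id"].isin(escape_ids | {adata.uns["xist_id"]})
    ]
    assert (silenced["call"] == "xa_exclusive").mean() >= 0.95
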