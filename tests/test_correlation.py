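"""Correlation screening, permutation significance, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histotranscript import correlation as co
from histotranscript.correlation import Thresholds


def _expr(values: dict[str, list[float]], columns) -> pd.DataFrame:
    return pd.DataFrame(values, index=columns).T


# --- duplicate resolution & transform ---------------------------------------

def test_duplicates_averaged_on_log_scale():
    raw = _expr({"g1": [2 ** 4 - 1, 2 ** 6 - 1]}, ["s1_r1", "s1_r2"])
    s2s = pd.Series({"s1_r1": "s1", "s1_r2": "s1"})
    out = co.resolve_duplicates(raw, s2s)
    assert out.loc["g1", "s1"] == pytest.approx(5.0)    # mean of logs 4 and 6


def test_no_duplicates_is_identity_on_log_scale():
    raw = _expr({"g1": [3.0, 7.0]}, ["a_r1", "b_r1"])
    s2s = pd.Series({"a_r1": "a", "b_r1": "b"})
    out = co.resolve_duplicates(raw, s2s)
    assert np.allclose(out.loc["g1"], np.log2(1 + np.array([3.0, 7.0])))


def test_triplicates_match_mean_oracle(rng):
    vals = rng.uniform(0, 100, 3)
    raw = _expr({"g": vals}, ["x_r1", "x_r2", "x_r3"])
    s2s = pd.Series({c: "x" for c in raw.columns})
    out = co.resolve_duplicates(raw, s2s)
    assert out.loc["g", "x"] == pytest.approx(np.log2(1 + vals).mean())


def test_negative_expression_rejected():
    with pytest.raises(ValueError):
        co.log2p1(_expr({"g": [-1.0]}, ["s"]))


# --- gene filter -------------------------------------------------------------

def test_gene_filter_boundary_and_near_miss():
    """A gene with max median exactly at the threshold is kept; one just
    below (the 6.84-vs-7 case) is excluded; E_T = 0 keeps everything."""
    meta = pd.DataFrame({"tissue_of_max": ["t1", "t1", "t1"],
                         "max_median": [7.0, 6.84, 0.2]},
                        index=["at", "below", "low"])
    kept = co.gene_filter(meta, 7.0)
    assert list(kept) == ["at"]
    assert list(co.gene_filter(meta, 0.0)) == ["at", "below", "low"]


def test_gene_meta_medians_and_argmax():
    expr_log = pd.DataFrame([[1.0, 2.0, 9.0, 11.0]], index=["g"],
                            columns=["a1", "a2", "b1", "b2"])
    tissue = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    meta = co.gene_meta(expr_log, tissue)
    assert meta.loc["g", "tissue_of_max"] == "B"
    assert meta.loc["g", "max_median"] == pytest.approx(10.0)


# --- Pearson screening -------------------------------------------------------

def test_exact_linear_relation_gives_r_one():
    f = pd.DataFrame({"0_0": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    g = pd.DataFrame([2 * f["0_0"] + 3], index=["g1"])
    r = co.correlate(g, f)
    assert r.loc["g1", "0_0"] == pytest.approx(1.0)


def test_pearson_matches_textbook_two_pass_formula(rng):
    x = rng.standard_normal(40)
    y = rng.standard_normal(40)
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert co.pearson(x, y) == pytest.approx(num / den, abs=1e-12)


def test_worked_four_sample_vectors():
    x = np.array([1.0, 2.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 5.0, 9.0])
    assert co.pearson(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


def test_null_correlation_is_small_at_large_n(rng):
    n = 1000
    f = pd.DataFrame({"0_0": rng.standard_normal(n)},
                     index=[f"s{i}" for i in range(n)])
    g = pd.DataFrame([rng.standard_normal(n)], index=["g"], columns=f.index)
    assert abs(co.correlate(g, f).iloc[0, 0]) < 0.1


def test_constant_inputs_are_missing():
    f = pd.DataFrame({"0_0": [1.0, 1.0, 1.0], "0_1": [1, 2, 3.0]},
                     index=list("abc"))
    g = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 4.0, 6.0]], index=["gc", "gv"],
                     columns=list("abc"))
    r = co.correlate(g, f)
    assert np.isnan(r.loc["gc", "0_1"]) and np.isnan(r.loc["gv", "0_0"])
    assert np.isfinite(r.loc["gv", "0_1"])


def test_correlate_requires_three_shared_samples():
    f = pd.DataFrame({"0_0": [1.0, 2.0]}, index=["a", "b"])
    g = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
    with pytest.raises(ValueError):
        co.correlate(g, f)


# --- pair selection ----------------------------------------------------------

def _meta(genes, tissue="T"):
    return pd.DataFrame({"tissue_of_max": tissue, "max_median": 12.0},
                        index=genes)


def test_select_significant_planted_counts():
    r = pd.DataFrame(
        [[0.9, 0.85, 0.2, 0.81], [0.82, 0.1, 0.83, 0.2], [0.1, 0.2, 0.3, 0.4]],
        index=["g1", "g2", "g3"], columns=["0_0", "0_1", "1_0", "1_1"])
    meta = pd.DataFrame({"tissue_of_max": ["A", "B", "A"],
                         "max_median": [12.0, 12.0, 12.0]}, index=r.index)
    pairs, counts = co.select_significant(r, Thresholds(r_t=0.8, e_t=10), meta)
    assert counts == {"pairs": 5, "unique_genes": 2, "unique_features": 4,
                      "unique_tissues": 2}


def test_select_significant_empty_matrix():
    r = pd.DataFrame(index=pd.Index([], name="gene"), columns=["0_0"], dtype=float)
    pairs, counts = co.select_significant(r, Thresholds(), _meta([]))
    assert counts["pairs"] == 0 and pairs.empty


def test_select_counts_monotone_in_thresholds(rng):
    genes = [f"g{i}" for i in range(30)]
    r = pd.DataFrame(rng.uniform(-1, 1, (30, 20)), index=genes,
                     columns=[f"0_{z}" for z in range(20)])
    meta = pd.DataFrame({"tissue_of_max": "T",
                         "max_median": rng.uniform(0, 15, 30)}, index=genes)
    base = co.select_significant(r, Thresholds(r_t=0.8, e_t=10), meta)[1]
    lower_r = co.select_significant(r, Thresholds(r_t=0.6, e_t=10), meta)[1]
    lower_e = co.select_significant(r, Thresholds(r_t=0.8, e_t=5), meta)[1]
    for key in base:
        assert lower_r[key] >= base[key]
        assert lower_e[key] >= base[key]


def test_signed_selection_excludes_negative_pairs():
    r = pd.DataFrame([[0.9, -0.9]], index=["g"], columns=["0_0", "0_1"])
    pairs_abs, _ = co.select_significant(r, Thresholds(r_t=0.8, e_t=0),
                                         _meta(["g"]), use_abs=True)
    pairs_pos, _ = co.select_significant(r, Thresholds(r_t=0.8, e_t=0),
                                         _meta(["g"]), use_abs=False)
    assert len(pairs_abs) == 2 and len(pairs_pos) == 1


# --- permutation test --------------------------------------------------------

def test_perfect_correlation_smallest_attainable_p(rng):
    g = rng.standard_normal(50)
    p = co.permutation_test(g, 2 * g + 1, n_perm=1000, seed=1)
    assert p == pytest.approx(1 / 1001)
    assert p < 1e-3


def test_constant_gene_degenerate_p():
    assert co.permutation_test(np.ones(10), np.arange(10.0)) == 1.0


def test_permutation_p_superuniform_under_null(rng):
    """Null p-values are (super)uniform up to Monte-Carlo error: KS check over
    null pairs with 200 permutations each."""
    n = 30
    ps = [co.permutation_test(rng.standard_normal(n), rng.standard_normal(n),
                              n_perm=200, seed=rng) for _ in range(300)]
    d = stats.kstest(ps, "uniform").statistic
    assert d < 0.1
    assert np.mean(np.asarray(ps) <= 0.05) < 0.09


# --- Fisher transform & reproducibility -------------------------------------

def test_fisher_z_values():
    assert co.fisher_z(0.0) == 0.0
    assert co.fisher_z(0.5) == pytest.approx(0.5493061443)
    with pytest.raises(ValueError):
        co.fisher_z(1.0)


def test_reproducibility_of_identical_vectors(rng):
    r = rng.uniform(-0.9, 0.9, 100)
    rep = co.reproducibility(r, r)
    assert rep["r_scale"] == pytest.approx(1.0)
    assert rep["z_scale"] == pytest.approx(1.0)


# --- partial correlation -----------------------------------------------------

def test_single_tissue_reduces_to_plain_correlation(rng):
    g = rng.standard_normal(40)
    f = g + rng.standard_normal(40)
    t = np.array(["T"] * 40)
    r, p = co.partial_correlation(g, f, t)
    assert r == pytest.approx(co.pearson(g, f), abs=1e-12)
    assert p == pytest.approx(stats.pearsonr(g, f)[1], rel=1e-6)


def test_residualization_equals_within_group_centering(rng):
    """Two-route identity: least-squares residualization on tissue indicators
    equals explicit centering within tissue groups."""
    n = 60
    t = rng.choice(["a", "b", "c"], n)
    g = rng.standard_normal(n) + (t == "a") * 2.0
    f = rng.standard_normal(n) + (t == "b") * 3.0
    r_impl, _ = co.partial_correlation(g, f, t)
    gc, fc = g.copy(), f.copy()
    for lv in np.unique(t):
        gc[t == lv] -= gc[t == lv].mean()
        fc[t == lv] -= fc[t == lv].mean()
    assert r_impl == pytest.approx(co.pearson(gc, fc), abs=1e-10)


def test_planted_tissue_shift_has_no_partial_correlation(rng):
    """Pure tissue-mean shifts plus independent within-group noise: the
    partial correlation is near zero and the CI test does not reject."""
    hits = 0
    for s in range(40):
        r = np.random.default_rng(s)
        t = np.repeat(["a", "b", "c"], 100)
        shift = {"a": 0.0, "b": 4.0, "c": -3.0}
        mu = np.array([shift[x] for x in t])
        g = mu + r.standard_normal(300)
        f = 2 * mu + r.standard_normal(300)
        pr, p = co.partial_correlation(g, f, t)
        if abs(pr) < 0.15 and p > 0.01:
            hits += 1
    assert hits >= 38    # >= 95% of simulations


def test_singleton_tissue_level_allowed(rng):
    g = rng.standard_normal(21)
    f = rng.standard_normal(21)
    t = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
    r, p = co.partial_correlation(g, f, t)
    assert np.isfinite(r) and 0 <= p <= 1


# --- dependency patterns -----------------------------------------------------

def _pattern_pairs(expr_log, fmat, tissue, alpha=0.01):
    pairs = pd.DataFrame({"gene": expr_log.index[:1],
                          "feature": fmat.columns[:1],
                          "r": [0.9]})
    return co.dependency_patterns(pairs, expr_log, fmat, tissue, alpha)


def test_alpha_zero_flags_nothing(rng):
    idx = [f"s{i}" for i in range(30)]
    expr_log = pd.DataFrame([rng.standard_normal(30)], index=["g"], columns=idx)
    fmat = pd.DataFrame({"0_0": rng.standard_normal(30)}, index=idx)
    tissue = pd.Series(["a"] * 15 + ["b"] * 15, index=idx)
    out, counts = _pattern_pairs(expr_log, fmat, tissue, alpha=0.0)
    assert counts["gtf"] == counts["fgt"] == counts["gft"] == 0


def test_marker_pair_flagged_direct_pair_not(rng):
    idx = [f"s{i}" for i in range(300)]
    t = np.repeat(["a", "b", "c"], 100)
    tissue = pd.Series(t, index=idx)
    mu = np.where(t == "a", 3.0, np.where(t == "b", -2.0, 0.0))
    # marker: gene and feature track tissue only
    gm = mu + rng.standard_normal(300)
    fm = 2 * mu + rng.standard_normal(300)
    # direct: gene and feature share a latent that ignores tissue
    lat = rng.standard_normal(300)
    gd = lat + 0.3 * rng.standard_normal(300)
    fd = lat + 0.3 * rng.standard_normal(300)
    expr_log = pd.DataFrame([gm, gd], index=["marker", "direct"], columns=idx)
    fmat = pd.DataFrame({"0_0": fm, "0_1": fd}, index=idx)
    pairs = pd.DataFrame({"gene": ["marker", "direct"],
                          "feature": ["0_0", "0_1"], "r": [0.9, 0.9]})
    out, counts = co.dependency_patterns(pairs, expr_log, fmat, tissue, 0.01)
    assert bool(out.loc[out.gene == "marker", "gtf_indirect"].iloc[0])
    assert not bool(out.loc[out.gene == "direct", "gtf_indirect"].iloc[0])


# --- breakdowns and reports --------------------------------------------------

def _pair_table():
    return pd.DataFrame({
        "gene": ["g1", "g1", "g2", "g3", "g3"],
        "feature": ["29_1", "29_2", "29_9", "12_0", "29_3"],
        "r": [0.9, 0.7, 0.85, 0.8, 0.95],
        "tissue_of_max": ["liver", "liver", "liver", "testis", "testis"],
    })


def test_genes_per_layer_groupby_oracle():
    per_layer = co.genes_per_layer(_pair_table())
    assert per_layer.to_dict() == {12: 1, 29: 3}
    # a gene may hit several layers: layer total >= unique genes
    assert per_layer.sum() >= _pair_table()["gene"].nunique()


def test_single_layer_breakdown():
    t = _pair_table()
    t = t[t.feature.str.startswith("29")]
    bd = co.layer_tissue_breakdown(t)
    assert list(bd.index) == [29]
    assert bd.loc[29].sum() == 3


def test_layer_tissue_breakdown_matches_counting():
    bd = co.layer_tissue_breakdown(_pair_table())
    assert bd.loc[29, "liver"] == 2      # g1, g2
    assert bd.loc[29, "testis"] == 1     # g3
    assert bd.loc[12, "testis"] == 1


def test_annotation_subset_best_feature_argmax():
    ann = pd.DataFrame({"gene": ["g1", "g3", "zz"],
                        "flag": ["developmental_process"] * 3})
    rep = co.annotation_subset(_pair_table(), ann)
    assert list(rep["gene"]) == ["g1", "g3"]
    assert rep.set_index("gene").loc["g1", "feature"] == "29_1"   # r=0.9 > 0.7
    assert rep.set_index("gene").loc["g3", "feature"] == "29_3"


def test_annotation_subset_empty_intersection():
    ann = pd.DataFrame({"gene": ["none"], "flag": ["developmental_process"]})
    assert co.annotation_subset(_pair_table(), ann).empty
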