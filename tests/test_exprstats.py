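"""Normalization, PCA, NB Wald test, BH, independence filter, stage sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spongelinc.exprstats import (CountMatrix, bh_adjust,
                                  de_overlap_clustering, de_table,
                                  independence_filter, ish_candidates,
                                  nb_wald_test, normalize_log, pca_samples,
                                  size_factors, spearman_rho_p,
                                  stage_upregulated_sets)
from spongelinc.genomecontext import NeighborPair


def _design(stages, reps):
    rows = [(f"{s}_r{r}", s, r) for s in stages for r in range(1, reps + 1)]
    return pd.DataFrame(
        {"stage": [s for _, s, _ in rows],
         "replicate": [r for _, _, r in rows]},
        index=pd.Index([l for l, _, _ in rows], name="library"),
    )


# --- size factors ----------------------------------------------------------


def test_identical_libraries_get_unit_factors():
    counts = pd.DataFrame(np.tile([[5], [10], [50]], (1, 4)),
                          columns=list("abcd"))
    assert np.allclose(size_factors(counts), 1.0)


def test_doubling_a_library_doubles_its_factor():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 200, size=(100, 4)),
                          columns=list("abcd"))
    doubled = counts.copy()
    doubled["d"] = counts["d"] * 2
    f0, f1 = size_factors(counts), size_factors(doubled)
    assert np.isclose(f1["d"] / f0["d"],
                      2.0 * (f1["a"] / f0["a"]), rtol=1e-12)


def test_size_factors_match_direct_formula():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(0, 500, size=(50, 6)))
    pos = (counts > 0).all(axis=1)
    logg = np.log(counts[pos]).mean(axis=1)
    expected = [np.median(np.log(counts[pos].iloc[:, j]) - logg)
                for j in range(6)]
    assert np.allclose(size_factors(counts), np.exp(expected))


def test_normalize_log_elementwise():
    counts = pd.DataFrame([[0, 3], [6, 9]], columns=["a", "b"])
    sf = pd.Series([1.0, 3.0], index=["a", "b"])
    out = normalize_log(counts, sf)
    assert out.loc[0, "a"] == 0.0
    assert np.isclose(out.loc[0, "b"], 1.0)  # count == sf -> log2(2) = 1
    assert np.isclose(out.loc[1, "a"], np.log2(7))


# --- PCA -------------------------------------------------------------------


def test_duplicated_library_gets_identical_coordinates():
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.normal(size=(60, 5)),
                       columns=[f"l{i}" for i in range(5)])
    mat["l5"] = mat["l4"]
    coords, _ = pca_samples(mat, top_n=60)
    assert np.allclose(coords.loc["l4"], coords.loc["l5"], atol=1e-9)


def test_variance_fractions_spectral_properties():
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.normal(size=(100, 8)))
    _, frac = pca_samples(mat, top_n=50)
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1.0 + 1e-9


def test_pc1_separates_planted_groups_and_matches_eigendecomposition():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(40, 6)) * 0.01
    base[0, :3] += 10.0  # one strongly separating gene
    mat = pd.DataFrame(base, columns=[f"l{i}" for i in range(6)])
    coords, frac = pca_samples(mat, top_n=40)
    g1, g2 = coords.iloc[:3, 0], coords.iloc[3:, 0]
    assert (g1.min() > g2.max()) or (g2.min() > g1.max())
    x = mat.to_numpy().T
    xc = x - x.mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(xc @ xc.T / (6 - 1)))[::-1]
    assert np.isclose(frac[0], evals[0] / evals.sum(), rtol=1e-8)


def test_top_n_larger_than_gene_count_warns_and_uses_all(caplog):
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.normal(size=(10, 4)))
    coords, _ = pca_samples(mat, top_n=500)
    assert coords.shape[0] == 4


# --- NB Wald ---------------------------------------------------------------


def test_identical_groups_null_identity():
    k = np.array([30.0, 30, 30])
    sf = np.ones(3)
    res = nb_wald_test(k, sf, k, sf)
    assert res.log2_fold_change == 0.0
    assert res.p == pytest.approx(1.0)


def test_all_zero_gene_flagged():
    z = np.zeros(3)
    res = nb_wald_test(z, np.ones(3), z, np.ones(3))
    assert res.p == 1.0 and res.log2_fold_change == 0.0 and res.all_zero


def test_size_factor_offsets_remove_depth_effect():
    """Doubling one group's depth (counts and factors) leaves z unchanged."""
    rng = np.random.default_rng(6)
    k1 = rng.poisson(100, 3).astype(float)
    k2 = rng.poisson(100, 3).astype(float)
    r1 = nb_wald_test(k1, np.ones(3), k2, np.ones(3))
    r2 = nb_wald_test(k1 * 2, 2 * np.ones(3), k2, np.ones(3))
    assert np.isclose(r1.log2_fold_change, r2.log2_fold_change, atol=0.05)


def test_de_table_recovers_planted_fold_change():
    rng = np.random.default_rng(8)
    design = _design(["base", "s1"], 3)
    n = 300
    mu = rng.gamma(2.0, 150.0, n)
    up = np.zeros(n, bool)
    up[:60] = True
    r = 10.0  # dispersion 0.1
    counts = np.empty((n, 6))
    for j in range(3):
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    mu_s = np.where(up, 4 * mu, mu)
    for j in range(3, 6):
        counts[:, j] = rng.negative_binomial(r, r / (r + mu_s))
    cm = CountMatrix(pd.DataFrame(counts.astype(int),
                                  index=[f"g{i}" for i in range(n)],
                                  columns=design.index), design)
    de = de_table(cm)
    de = de.set_index("gene_id")
    found = set(de.index[de["upregulated"]])
    planted = {f"g{i}" for i in range(60)}
    assert len(found & planted) / 60 >= 0.7
    # false positives under control
    assert len(found - planted) <= 0.1 * max(len(found), 1) + 5


# --- BH --------------------------------------------------------------------


def test_bh_single_p_unchanged():
    assert bh_adjust([0.037])[0] == pytest.approx(0.037)


def test_bh_matches_direct_formula():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    m = len(p)
    order = np.argsort(p)
    expected = np.empty(m)
    for rank, i in enumerate(order, start=1):
        expected[i] = min(
            min(m * p[j] / (list(order).index(j) + 1)
                for j in order[rank - 1:]), 1.0)
    assert np.allclose(bh_adjust(p), expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_bounded_and_order_preserving():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=50)
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in rank


# --- stage sets & overlap clustering ---------------------------------------


def _fake_de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "stage", "upregulated"])


def test_no_significant_genes_all_sets_empty():
    de = _fake_de([("g1", "s1", False), ("g1", "s2", False)])
    out = stage_upregulated_sets(de)
    assert all(not s.upregulated for s in out)
    assert all(s.shared_with_all == 0 for s in out)


def test_everywhere_upregulated_gene_in_intersection():
    de = _fake_de([("g1", s, True) for s in ("s1", "s2", "s3")]
                  + [("g2", "s1", True), ("g2", "s2", False),
                     ("g2", "s3", False)])
    out = stage_upregulated_sets(de)
    assert all(s.shared_with_all == 1 for s in out)
    s1 = next(s for s in out if s.stage == "s1")
    assert s1.unique_to_stage == 1  # g2 only in s1


def test_tallies_match_set_arithmetic_oracle():
    rng = np.random.default_rng(10)
    stages = ["a", "b", "c", "d"]
    genes = [f"g{i}" for i in range(30)]
    rows = [(g, s, bool(rng.random() < 0.4)) for g in genes for s in stages]
    out = stage_upregulated_sets(_fake_de(rows))
    sets = {s: {g for g, st, up in rows if st == s and up} for s in stages}
    inter = set.intersection(*sets.values())
    for summary in out:
        others = set().union(*(sets[t] for t in stages
                               if t != summary.stage))
        assert summary.upregulated == sets[summary.stage]
        assert summary.unique_to_stage == len(sets[summary.stage] - others)
        assert summary.shared_with_all == len(inter)


def test_jaccard_identity_and_disjoint():
    dist, _, _ = de_overlap_clustering({"a": {"x"}, "b": {"x"},
                                        "c": {"y", "z"}})
    assert dist.loc["a", "b"] == 0.0
    assert dist.loc["a", "c"] == 1.0


def test_jaccard_matrix_matches_brute_force_and_triangle():
    rng = np.random.default_rng(11)
    universe = [f"g{i}" for i in range(40)]
    sets = {f"s{k}": {g for g in universe if rng.random() < 0.5}
            for k in range(5)}
    dist, _, newick = de_overlap_clustering(sets)
    names = sorted(sets)
    for a, b in itertools.combinations(names, 2):
        u = len(sets[a] | sets[b])
        expect = 0.0 if u == 0 else 1.0 - len(sets[a] & sets[b]) / u
        assert dist.loc[a, b] == pytest.approx(expect)
    for a, b, c in itertools.permutations(names, 3):
        assert dist.loc[a, c] <= dist.loc[a, b] + dist.loc[b, c] + 1e-12
    assert newick.endswith(";") and all(n in newick for n in names)


# --- ISH candidates --------------------------------------------------------


def test_ish_count_boundary():
    design = _design(["a", "b"], 1)
    norm = pd.DataFrame([[39.9, 0.0], [40.0, 0.0]],
                        index=["low", "high"], columns=design.index)
    out = ish_candidates(norm, design)
    assert out == ["high"]


def test_constant_gene_fails_fold_criterion():
    design = _design(["a", "b"], 2)
    norm = pd.DataFrame([[100.0] * 4], index=["flat"], columns=design.index)
    assert ish_candidates(norm, design) == []


def test_ish_matches_predicate_oracle():
    rng = np.random.default_rng(12)
    design = _design(["a", "b", "c"], 2)
    norm = pd.DataFrame(rng.gamma(1.0, 30.0, size=(100, 6)),
                        index=[f"g{i}" for i in range(100)],
                        columns=design.index)
    got = set(ish_candidates(norm, design))
    expected = set()
    for g in norm.index:
        means = [norm.loc[g, design.index[design["stage"] == s]].mean()
                 for s in ("a", "b", "c")]
        if norm.loc[g].max() >= 40 and \
                (max(means) + 1) / (min(means) + 1) >= 20:
            expected.add(g)
    assert got == expected


# --- Spearman & independence filter ----------------------------------------


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(5, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        rho, p = spearman_rho_p(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = stats.pearsonr(rx, ry)[0]
        assert abs(rho - expected) < 1e-12
        rho_sp, p_sp = stats.spearmanr(x, y)
        assert abs(rho - rho_sp) < 1e-12
        assert abs(p - p_sp) < 1e-9


def test_spearman_exact_permutation_small_n():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([1.0, 2, 3, 5, 4, 6])
    rho_t, _ = spearman_rho_p(x, y, method="t")
    rho_e, p_e = spearman_rho_p(x, y, method="exact")
    assert rho_t == pytest.approx(rho_e)
    # exact two-sided tail from full enumeration stays a valid p-value
    assert 0.0 < p_e <= 1.0


def test_constant_profile_raises():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho_p(np.ones(5), np.arange(5.0))


def _profiles(rows, libs):
    return pd.DataFrame.from_dict(rows, orient="index").set_axis(
        [f"l{i}" for i in range(libs)], axis=1)


def test_identical_neighbour_profile_discarded():
    rng = np.random.default_rng(13)
    x = rng.normal(size=12)
    profiles = _profiles({"linc": x, "cod": x}, 12)
    pairs = [NeighborPair("linc", "cod", "upstream", 100)]
    independent, discarded, table = independence_filter(pairs, profiles)
    assert discarded == ["linc"]
    assert table["rho"].iloc[0] == pytest.approx(1.0)


def test_scaling_neighbour_leaves_decision_unchanged():
    rng = np.random.default_rng(14)
    x = rng.normal(size=12)
    y = x + rng.normal(scale=0.3, size=12)
    for scale in (1.0, 0.01, 250.0):
        profiles = _profiles({"linc": x, "cod": y * scale}, 12)
        pairs = [NeighborPair("linc", "cod", "upstream", 100)]
        _, _, table = independence_filter(pairs, profiles)
        assert table["rho"].iloc[0] == pytest.approx(
            stats.spearmanr(x, y)[0], abs=1e-12)


def test_constant_pair_skipped_not_discarded():
    profiles = _profiles({"linc": np.arange(8.0), "cod": np.ones(8)}, 8)
    pairs = [NeighborPair("linc", "cod", "upstream", 5)]
    independent, discarded, table = independence_filter(pairs, profiles)
    assert independent == ["linc"] and not discarded and table.empty
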