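"""Thresholds, imputation, malignancy scoring, meta-features, DE."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scopekit.downstream_analysis import (
    FactorModel,
    bimodal_threshold,
    cluster_cells_by_metafeatures,
    dead_cell_filter,
    differential_expression,
    impute_expression,
    malignancy_score,
    metafeatures,
)
from scopekit.simulator import simulate_expression

# ---------------------------------------------------------------------------
# bimodal threshold


def test_bimodal_threshold_separates_gaussian_mixture():
    rng = np.random.default_rng(0)
    lo = rng.normal(100, 10, 2500)
    hi = rng.normal(1000, 50, 2500)
    thr = bimodal_threshold(np.concatenate([lo, hi]))
    assert 100 < thr < 1000
    misclass = ((lo > thr).sum() + (hi <= thr).sum()) / 5000
    assert misclass < 0.01


def test_bimodal_threshold_scale_equivariant():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(10, 1, 500), rng.normal(100, 5, 500)])
    t1 = bimodal_threshold(x)
    t2 = bimodal_threshold(x * 7.0)
    assert t2 == pytest.approx(7.0 * t1, rel=0.05)


def test_bimodal_threshold_between_point_masses():
    x = np.array([10.0] * 200 + [90.0] * 200)
    thr = bimodal_threshold(x)
    assert 10 < thr < 90


def test_bimodal_threshold_matches_bruteforce_scan_at_high_separation():
    # at >= 5 sigma separation the valley threshold matches an exhaustive
    # misclassification-minimizing scan to within one bin width
    rng = np.random.default_rng(2)
    lo = rng.normal(0, 1, 2000)
    hi = rng.normal(8, 1, 2000)
    x = np.concatenate([lo, hi])
    labels = np.r_[np.zeros(2000), np.ones(2000)]
    thr = bimodal_threshold(x, bins=50)
    bin_width = (x.max() - x.min()) / 50
    best = min(
        np.unique(x), key=lambda c: ((x > c).astype(int) != labels).sum()
    )
    assert abs(thr - best) <= max(bin_width, abs(8 - 0) * 0.2)
    our_err = ((x > thr).astype(int) != labels).sum()
    oracle_err = ((x > best).astype(int) != labels).sum()
    assert our_err <= oracle_err + 0.001 * len(x)


def test_bimodal_threshold_degenerate_unimodal_fails():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError):
        bimodal_threshold(rng.normal(50, 1, 1000))


def test_bimodal_threshold_needs_population():
    with pytest.raises(ValueError, match="100"):
        bimodal_threshold(np.arange(50))


# ---------------------------------------------------------------------------
# dead-cell filter


def test_dead_cell_filter_drops_about_five_percent():
    rng = np.random.default_rng(4)
    x = rng.normal(500, 40, 10000)
    keep = dead_cell_filter(x)
    drop_fraction = 1 - keep.mean()
    assert drop_fraction == pytest.approx(0.05, abs=0.01)
    # matches direct percentile computation from the fitted Gaussian
    from scipy.stats import norm

    mu, sigma = norm.fit(x)
    assert drop_fraction == pytest.approx((x < mu + norm.ppf(0.05) * sigma).mean())


def test_dead_cell_filter_drops_low_outliers():
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(500, 20, 1000), [500 - 5 * 20] * 10])
    keep = dead_cell_filter(x)
    assert not keep[-10:].any()


def test_dead_cell_filter_needs_cells():
    with pytest.raises(ValueError, match="20"):
        dead_cell_filter(np.ones(10))


# ---------------------------------------------------------------------------
# imputation and malignancy


def test_impute_expression_reference_points():
    model = FactorModel(theta=np.array([[0.0], [1.0]]), beta=np.array([[0.0], [10000.0]]))
    imputed = impute_expression(model)
    assert imputed[0, 0] == 0.0  # expected count 0 -> log2(1) = 0
    assert imputed[1, 1] == 1.0  # expected count 10000 -> log2(2) = 1


def test_impute_expression_monotone_and_rank_one():
    rng = np.random.default_rng(6)
    theta = rng.gamma(1, 1, (20, 1))
    beta = rng.gamma(1, 1, (30, 1))
    imputed = impute_expression(FactorModel(theta, beta))
    bumped = impute_expression(FactorModel(theta * 1.1, beta))
    assert (bumped >= imputed).all()
    # rank-one structure pre-log
    pre = theta @ beta.T
    assert np.linalg.matrix_rank(pre) == 1


def test_malignancy_score_zero_for_equal_chromosomes():
    theta = np.ones((200, 1))
    beta = np.ones((10, 1)) * 100
    imputed = impute_expression(FactorModel(theta, beta))
    chr7, chr10 = np.arange(5), np.arange(5, 10)
    scores = imputed[:, chr7].mean(1) - imputed[:, chr10].mean(1)
    assert np.allclose(scores, 0.0)


def test_malignancy_separation_in_high_expression_limit():
    # when expected counts >> 10^4 the score separation approaches
    # log2(1.5) - log2(0.5)
    n = 300
    theta = np.ones((n, 2))
    theta[: n // 2, 1] = 0.0  # non-malignant use factor 0
    theta[n // 2 :, 0] = 0.0  # malignant use factor 1
    beta = np.zeros((10, 2))
    beta[:, 0] = 1e8
    beta[:5, 1] = 1.5e8  # chr7 gain
    beta[5:, 1] = 0.5e8  # chr10 loss
    imputed = impute_expression(FactorModel(theta, beta))
    scores = imputed[:, :5].mean(1) - imputed[:, 5:].mean(1)
    separation = scores[n // 2 :].mean() - scores[: n // 2].mean()
    assert separation == pytest.approx(np.log2(1.5) - np.log2(0.5), abs=1e-3)


def test_malignancy_labels_recover_simulated_aneuploidy():
    counts, gene_info, model, truth = simulate_expression(seed=0)
    imputed = impute_expression(model)
    chrom = gene_info.chromosome.to_numpy()
    call = malignancy_score(
        imputed, np.flatnonzero(chrom == "chr7"), np.flatnonzero(chrom == "chr10")
    )
    assert (call.labels == truth["cells"].malignant.to_numpy()).mean() >= 0.99
    # non-malignant-relative profile: non-malignant cells center at zero
    nonmal = ~truth["cells"].malignant.to_numpy()
    relative = imputed[nonmal] - imputed[nonmal].mean(0)
    assert abs(relative.mean()) < 1e-12


def test_malignancy_requires_gene_sets():
    with pytest.raises(ValueError, match="non-empty"):
        malignancy_score(np.ones((200, 4)), [], [0])


# ---------------------------------------------------------------------------
# meta-features and cell clustering


def _block_features(n=150, rho=0.9, sizes=(6, 5, 5), seed=7):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, len(sizes)))
    cols, blocks = {}, {}
    i = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            name = f"f{i:02d}"
            cols[name] = rho * base[:, b] + np.sqrt(1 - rho**2) * rng.normal(size=n)
            blocks[name] = b
            i += 1
    return pd.DataFrame(cols), blocks


def test_metafeatures_recover_three_blocks():
    feats, blocks = _block_features()
    meta, mapping = metafeatures(feats)
    assert meta.shape[1] == 3
    import itertools

    for a, b in itertools.combinations(feats.columns, 2):
        assert (mapping[a] == mapping[b]) == (blocks[a] == blocks[b])


def test_metafeature_of_singleton_cluster_is_the_zscore():
    feats, _ = _block_features(sizes=(6, 5, 1), seed=8)
    meta, mapping = metafeatures(feats)
    singleton = [f for f in feats.columns if sum(v == mapping[f] for v in mapping.values()) == 1]
    assert singleton == ["f11"]
    z = (feats["f11"] - feats["f11"].mean()) / feats["f11"].std(ddof=0)
    cluster = mapping["f11"]
    np.testing.assert_allclose(meta[f"meta_{cluster}"], z)


def test_metafeatures_drop_constant_and_zscore_normalization():
    feats, _ = _block_features()
    feats["const"] = 3.0
    meta, mapping = metafeatures(feats)
    assert "const" not in mapping
    z = (feats["f00"] - feats["f00"].mean()) / feats["f00"].std(ddof=0)
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1)


def test_cell_clusters_match_phenotype_groups():
    rng = np.random.default_rng(9)
    g1 = rng.normal(0, 0.3, size=(40, 3)) + np.array([2.0, -1.0, 0.5])
    g2 = rng.normal(0, 0.3, size=(40, 3)) + np.array([-2.0, 1.0, -0.5])
    meta = pd.DataFrame(np.vstack([g1, g2]), columns=["size", "shape", "intensity"])
    labels = cluster_cells_by_metafeatures(meta)
    truth = np.r_[np.zeros(40), np.ones(40)]
    assert adjusted_rand_score(truth, labels) == 1.0


def test_duplicated_cells_cluster_together():
    rng = np.random.default_rng(10)
    meta = pd.DataFrame(rng.normal(size=(10, 3)))
    meta = pd.concat([meta, meta.iloc[[0]]], ignore_index=True)
    labels = cluster_cells_by_metafeatures(meta)
    assert labels[0] == labels[-1]


# ---------------------------------------------------------------------------
# differential expression


@pytest.fixture(scope="module")
def null_counts():
    counts, _, _, _ = simulate_expression(
        n_cells=100, n_genes=60, malignant_fraction=0.0, mean_molecules=400, seed=11
    )
    return counts


def test_identical_groups_give_no_discoveries(null_counts):
    a = null_counts.iloc[:50].reset_index(drop=True)
    table = differential_expression(a, a.copy(), seed=0)
    assert (table.p.dropna() > 0.99).all()  # ties + continuity keep p just under 1
    assert (table.FDR.dropna() < 0.05).sum() == 0


def test_shifted_gene_has_smallest_fdr():
    counts, _, _, _ = simulate_expression(
        n_cells=1000, n_genes=50, malignant_fraction=0.0, mean_molecules=500, seed=12
    )
    a = counts.iloc[:500].copy()
    b = counts.iloc[500:].copy()
    a.iloc[:, 7] = a.iloc[:, 7] * 10
    table = differential_expression(a, b, seed=1)
    top = table.sort_values("FDR").iloc[0]
    assert top.gene == counts.columns[7]
    assert top.direction == 1.0


def test_swapping_groups_negates_direction(null_counts):
    a = null_counts.iloc[:50]
    b = null_counts.iloc[50:]
    # equal sizes and matched depths: subsampling is a no-op, so the draws
    # are identical under both orders
    ab = differential_expression(a, b, seed=2)
    ba = differential_expression(b, a, seed=2)
    np.testing.assert_allclose(ab.p.to_numpy(float), ba.p.to_numpy(float), rtol=1e-9)
    tested = ab.direction != 0
    np.testing.assert_allclose(
        ab.direction[tested].to_numpy(), -ba.direction[tested].to_numpy()
    )


def test_all_zero_gene_reported_na(null_counts):
    a = null_counts.iloc[:50].copy()
    b = null_counts.iloc[50:].copy()
    a.iloc[:, 3] = 0
    b.iloc[:, 3] = 0
    table = differential_expression(a, b, seed=3)
    assert np.isnan(table.p.iloc[3]) and np.isnan(table.FDR.iloc[3])


def test_group_size_precondition(null_counts):
    with pytest.raises(ValueError, match="10 cells"):
        differential_expression(null_counts.iloc[:5], null_counts.iloc[5:], seed=0)
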