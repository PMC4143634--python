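import itertools

import numpy as np
import pandas as pd
import pytest

import rarewin as rw
from rarewin.calpha import permutation_p
from rarewin.urn import (
    ConditionalBernoulliSampler,
    UrnModel,
    compute_pcs,
    fit_urn_weights,
    ld_prune,
    make_urn_sampler,
    pairwise_r2,
    sample_case_set,
    stratified_permutation_p,
)


def test_pairwise_r2_extremes(rng):
    g = rng.binomial(2, 0.3, 200).astype(float)
    assert pairwise_r2(g, g) == pytest.approx(1.0)
    assert pairwise_r2(g, 2 - g) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pairwise_r2(g, np.ones_like(g))


def test_pairwise_r2_null_distribution(rng):
    n, m = 500, 40
    G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    r2 = [
        pairwise_r2(G[:, i], G[:, j])
        for i, j in itertools.combinations(range(m), 2)
    ]
    assert np.mean(np.array(r2) < 0.05) >= 0.95


def _matrix_from_dosage(dosage):
    m = dosage.shape[1]
    variants = pd.DataFrame(
        {"chrom": "chr3", "pos": np.arange(1, m + 1) * 100, "id": [f"v{i}" for i in range(m)],
         "ref": "A", "alt": "C", "n_alt_alleles": 1}
    )
    return rw.GenotypeMatrix(dosage=dosage.astype(float), variants=variants,
                             subjects=[f"S{i}" for i in range(dosage.shape[0])])


def test_ld_prune_duplicates_missing_and_thresholds(rng):
    g = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
    other = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
    with_missing = other.copy()
    with_missing[0] = np.nan
    D = np.column_stack([g, g, other, with_missing])
    m = _matrix_from_dosage(D)
    kept = ld_prune(m, r2_max=0.5)
    assert 1 not in kept  # duplicated column pruned
    assert 3 not in kept  # missing call -> excluded up front
    assert set(kept) == {0, 2}
    assert list(ld_prune(m, r2_max=1.0)) == [0, 1, 2]  # all complete variants kept


def test_ld_prune_keeps_independent_variants_at_large_n(rng):
    n, m = 2000, 30
    D = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m))
    kept = ld_prune(_matrix_from_dosage(D), r2_max=0.01)
    assert len(kept) == m


def _stratified_cohort(seed=19, n=200):
    cfg = rw.CohortConfig(
        n_subjects=n, n_subpops=2, fst=0.1, n_common_variants=400,
        n_rv_clusters=1, rvs_per_cluster=15, rv_effect_mix=(0, 0, 1.0),
        or_index_cv=1.0, case_fraction_target=0.55, subpop_shift=(-1.0, 1.0),
        seed=seed,
    )
    matrix, subjects, truth = rw.simulate_cohort(cfg)
    subjects = rw.qc.fill_collapsed_codes(subjects)
    cv_cols = np.where((truth.variants["kind"] != "rv").to_numpy())[0]
    return matrix.take_variants(cv_cols), subjects, truth


def test_compute_pcs_properties():
    panel, _, truth = _stratified_cohort()
    scores = compute_pcs(panel, 5)
    assert scores.shape == (panel.n_subjects, 5)
    assert np.allclose(scores.mean(axis=0), 0, atol=1e-10)  # centred columns
    for j in range(5):  # sign convention
        assert scores[np.argmax(np.abs(scores[:, j])), j] > 0
    corr = np.corrcoef(scores[:, 0], truth.subpop)[0, 1]
    assert abs(corr) > 0.9  # PC1 recovers the subpopulations at fst=0.1
    assert compute_pcs(panel, 0).shape == (panel.n_subjects, 0)


def test_compute_pcs_rank_deficient_warns(rng):
    base = rng.binomial(2, 0.3, size=(12, 2)).astype(float)
    X = np.column_stack([base, base, base])  # rank 2, 6 columns
    with pytest.warns(UserWarning, match="rank"):
        scores = compute_pcs(X, 4)
    assert scores.shape[1] < 4


def test_urn_weights_uniform_reduction_and_clipping(rng):
    status = np.array([2.0] * 8 + [1.0] * 8)
    model = fit_urn_weights(status, np.empty((16, 0)))
    assert np.allclose(model.weights, model.weights[0])  # intercept-only: equal odds

    sep = np.r_[np.ones(8), -np.ones(8)][:, None]  # perfect separation
    model2 = fit_urn_weights(status, sep)
    assert np.all(np.isfinite(model2.weights)) and np.all(model2.weights > 0)
    assert model2.weights.max() <= (1 - 1e-6) / 1e-6 + 1e-6


def test_urn_weights_track_stratification():
    panel, subjects, truth = _stratified_cohort()
    status = subjects.df["affection"].to_numpy(float)
    scores = compute_pcs(panel, 5)
    model = fit_urn_weights(status, scores)
    w = model.weights
    # the liability-shifted (+1) subpopulation must get systematically larger odds
    assert np.median(w[truth.subpop == 1]) > 2 * np.median(w[truth.subpop == 0])


def test_sampler_uniform_symmetry():
    rng = np.random.default_rng(100)
    smp = ConditionalBernoulliSampler(np.ones(4), 2)
    draws = smp.sample_many(rng, 12_000)
    assert np.all(draws.sum(axis=1) == 2)
    keys = draws @ np.array([1, 2, 4, 8])
    _, counts = np.unique(keys, return_counts=True)
    freq = counts / 12_000
    assert len(freq) == 6
    assert np.all(np.abs(freq - 1 / 6) < 0.02)


def test_sampler_two_subjects_direct_odds():
    rng = np.random.default_rng(101)
    hits = sum(sample_case_set([1.0, 3.0], 1, rng)[1] for _ in range(20_000))
    assert hits / 20_000 == pytest.approx(0.75, abs=0.01)


def test_sampler_marginals_match_enumeration():
    rng = np.random.default_rng(102)
    w = np.array([0.4, 1.0, 2.2, 0.9, 3.5, 1.7, 0.6])
    K = 3
    subsets = list(itertools.combinations(range(7), K))
    probs = np.array([np.prod(w[list(s)]) for s in subsets])
    probs /= probs.sum()
    marg = np.zeros(7)
    for s, p in zip(subsets, probs):
        for i in s:
            marg[i] += p
    smp = ConditionalBernoulliSampler(w, K)
    draws = smp.sample_many(rng, 30_000)
    emp = draws.mean(axis=0)
    se = np.sqrt(marg * (1 - marg) / 30_000)
    assert np.all(np.abs(emp - marg) < 4 * se + 1e-3)
    # exact subset probabilities from the table agree with enumeration
    for s, p in list(zip(subsets, probs))[::7]:
        mask = np.isin(np.arange(7), s)
        assert smp.log_prob(mask) == pytest.approx(np.log(p), rel=1e-10)


def test_sampler_invalid_inputs():
    with pytest.raises(ValueError):
        ConditionalBernoulliSampler([1.0, 2.0], 2)  # K must leave a control
    with pytest.raises(ValueError):
        ConditionalBernoulliSampler([1.0, -1.0, 2.0], 1)


def test_stratified_reduces_to_uniform_permutation(rng):
    G = rng.binomial(2, 0.05, size=(40, 5)).astype(float)
    status = np.array([2.0] * 24 + [1.0] * 16)
    model = UrnModel.uniform(40)
    p_urn = stratified_permutation_p(G, status, model, B=300, rng=np.random.default_rng(55))
    p_ref = permutation_p(G, status, B=300, rng=np.random.default_rng(55),
                          sampler=make_urn_sampler(UrnModel.uniform(40)))
    assert p_urn == p_ref  # same seed protocol -> identical p
    # and the uniform-urn law is calibrated like the default sampler
    p_def = permutation_p(G, status, B=300, rng=np.random.default_rng(55))
    assert abs(p_urn - p_def) < 0.25


def test_urn_sampler_rejects_mismatched_cohort(rng):
    G = rng.binomial(2, 0.05, size=(10, 3)).astype(float)
    status = np.array([2.0] * 5 + [1.0] * 5)
    with pytest.raises(ValueError, match="weights"):
        stratified_permutation_p(G, status, UrnModel.uniform(9), B=10, rng=rng)
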