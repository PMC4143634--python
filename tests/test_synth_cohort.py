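import filecmp

import numpy as np
import pytest

import rarewin as rw
from rarewin.assoc import fit_single_marker
from rarewin.synth_cohort import (
    CohortConfig,
    build_gene_track,
    calibrate_intercept,
    simulate_genotypes,
    simulate_phenotypes,
)
from rarewin.windows import classify_gene_membership


def test_config_validation():
    with pytest.raises(ValueError, match="rv_effect_mix"):
        CohortConfig(rv_effect_mix=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError, match="MAF"):
        CohortConfig(rv_freq_range=(0.01, 0.06))
    with pytest.raises(ValueError, match="subpop_shift"):
        CohortConfig(n_subpops=2, subpop_shift=(0.0,))
    with pytest.raises(ValueError, match="fst"):
        CohortConfig(fst=0.7)
    with pytest.raises(ValueError, match="increasing"):
        CohortConfig(n_rv_clusters=2, window_layout=[(200_000, 10_000), (100_000, 10_000)])


def test_homogeneous_frequencies_near_ancestral():
    """fst=0, one subpopulation: sample frequency is a plain binomial draw."""
    cfg = CohortConfig(
        n_subjects=500, n_subpops=1, fst=0.0, n_common_variants=40,
        n_rv_clusters=1, rvs_per_cluster=3, cv_freq_range=(0.5, 0.5),
        or_index_cv=1.0, seed=4,
    )
    matrix, truth = simulate_genotypes(cfg)
    bg = (truth.variants["kind"] == "cv_background").to_numpy()
    freqs = matrix.dosage[:, bg].mean(axis=0) / 2
    se = np.sqrt(0.25 / (2 * cfg.n_subjects))
    assert np.all(np.abs(freqs - 0.5) < 3.5 * se)
    assert abs(freqs.mean() - 0.5) < 3 * se / np.sqrt(bg.sum())


def test_fst_controls_subpopulation_divergence():
    def mean_abs_diff(fst):
        cfg = CohortConfig(n_subjects=20, n_subpops=2, fst=fst,
                           n_common_variants=200, n_rv_clusters=1, seed=42)
        _, truth = simulate_genotypes(cfg)
        return np.abs(truth.variants["freq_subpop0"] - truth.variants["freq_subpop1"]).mean()

    assert mean_abs_diff(0.3) > mean_abs_diff(0.01)


def test_degenerate_zero_frequency_gives_zero_dosage():
    cfg = CohortConfig(n_subjects=50, n_subpops=2, fst=0.2,
                       cv_freq_range=(0.0, 0.0), rv_freq_range=(0.0, 0.0), seed=1)
    matrix, _ = simulate_genotypes(cfg)
    assert np.all(matrix.dosage == 0)


def test_rare_variants_stay_rare_in_expectation(default_cohort):
    _, matrix, _, truth = default_cohort
    rv = (truth.variants["kind"] == "rv").to_numpy()
    assert truth.variants.loc[rv, "ancestral_freq"].max() < 0.05
    sample_maf = np.array(
        [rw.minor_allele_frequency(matrix.dosage[:, j]).maf for j in np.where(rv)[0]]
    )
    assert sample_maf.mean() < 0.05


def test_intercept_calibration_and_reference_subject():
    eta = np.random.default_rng(0).normal(0, 1.5, 5000)
    c = calibrate_intercept(eta, 0.638)
    assert abs((1 / (1 + np.exp(-(c + eta)))).mean() - 0.638) < 1e-8
    # a subject with zero liability contributions has P(case) = sigmoid(intercept)
    assert 1 / (1 + np.exp(-(c + 0.0))) == pytest.approx(1 / (1 + np.exp(-c)))
    with pytest.raises(ValueError, match="saturated"):
        calibrate_intercept(np.full(100, 80.0), 0.2)


def test_case_fraction_hits_target_without_effects():
    cfg = CohortConfig(
        n_subjects=10_000, n_subpops=1, fst=0.0, n_common_variants=5,
        n_rv_clusters=1, rvs_per_cluster=3, rv_effect_mix=(0, 0, 1.0),
        or_index_cv=1.0, case_fraction_target=0.638,
        covariate_effects=rw.CovariateEffects(0, 0, 0, 0), seed=9,
    )
    matrix, truth = simulate_genotypes(cfg)
    subjects = simulate_phenotypes(matrix, truth, cfg)
    affected = rw.qc.fill_collapsed_codes(subjects).df["affection"] == 2
    assert abs(affected.mean() - 0.638) < 0.02


def test_logistic_refit_recovers_planted_effect():
    """OR-3 index CV at n=5000: refit recovers log 3 within 2 SE."""
    cfg = CohortConfig(
        n_subjects=5000, n_subpops=1, fst=0.0, n_common_variants=5,
        n_rv_clusters=1, rvs_per_cluster=3, rv_effect_mix=(0, 0, 1.0),
        or_index_cv=3.0, case_fraction_target=0.5,
        covariate_effects=rw.CovariateEffects(0, 0, 0, 0), seed=13,
    )
    matrix, truth = simulate_genotypes(cfg)
    subjects = simulate_phenotypes(matrix, truth, cfg)
    status = rw.qc.fill_collapsed_codes(subjects).df["affection"].to_numpy(float)
    j = int(np.where(truth.variants["is_index"])[0][0])
    res = fit_single_marker(matrix.dosage[:, j], status)
    assert res.converged
    assert abs(res.beta - np.log(3)) < 2 * res.se


def test_deterministic_under_fixed_seed(tmp_path):
    cfg = CohortConfig(seed=77)
    out = []
    for sub in ("a", "b"):
        matrix, subjects, truth = rw.simulate_cohort(cfg)
        out.append(rw.write_fixture(matrix, subjects, truth, cfg, tmp_path / sub))
    for key in out[0]:
        assert filecmp.cmp(out[0][key], out[1][key], shallow=False), key


def test_hwe_holds_within_subpopulation():
    cfg = CohortConfig(n_subjects=500, n_subpops=1, fst=0.0,
                       n_common_variants=1000, n_rv_clusters=0, seed=3)
    matrix, _ = simulate_genotypes(cfg)
    rej = 0
    for j in range(matrix.n_variants):
        counts = rw.qc.genotype_counts(matrix.dosage[:, j])
        rej += rw.qc.hwe_exact_p(*counts) < 0.01
    assert rej / matrix.n_variants <= 0.015


def test_gene_track_alternates_clusters(default_cohort, fixture_paths):
    cfg, matrix, _, truth = default_cohort
    _, paths = fixture_paths
    track = rw.read_gene_track(paths["bed"])
    index_pos = truth.variants.loc[truth.variants["is_index"], "pos"].tolist()
    flags = [classify_gene_membership(p, track, "chr3") for p in index_pos]
    assert sum(flags) == 5 and len(flags) == 10  # alternating in/out of genes
    empty = rw.GeneTrack(intervals=track.intervals.iloc[:0])
    assert not any(classify_gene_membership(p, empty) for p in index_pos)


def test_write_fixture_refuses_overwrite(tmp_path, default_cohort):
    cfg, matrix, subjects, truth = default_cohort
    rw.write_fixture(matrix, subjects, truth, cfg, tmp_path)
    with pytest.raises(FileExistsError):
        rw.write_fixture(matrix, subjects, truth, cfg, tmp_path)
    rw.write_fixture(matrix, subjects, truth, cfg, tmp_path, overwrite=True)


def test_truth_alignment_and_effect_classes(default_cohort):
    cfg, matrix, _, truth = default_cohort
    tv = truth.variants
    assert list(tv["id"]) == list(matrix.variants["id"])
    rv = tv[tv["kind"] == "rv"]
    counts = rv["effect_class"].value_counts(normalize=True)
    for cls, frac in zip(("deleterious", "protective", "neutral"), cfg.rv_effect_mix):
        assert counts.get(cls, 0.0) == pytest.approx(frac, abs=0.05)
    assert (rv.loc[rv["effect_class"] == "neutral", "log_odds"] == 0).all()
    assert (tv.loc[tv["is_index"], "log_odds"] == np.log(cfg.or_index_cv)).all()
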