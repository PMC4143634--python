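"""Reproducible simulation studies validating the pipeline's operating
characteristics.

Each study regenerates synthetic cohorts from scratch with
:mod:`rarewin.synth_cohort`, runs the relevant stage of the analysis, and
returns summary rates:

* :func:`urn_sampler_tv` — exactness of the conditional-Bernoulli case
  sampler: total-variation distance between the empirical subset distribution
  and the enumerated law.
* :func:`null_calibration` — type-I error of the windowed C-alpha permutation
  test on homogeneous cohorts with no rare-variant effects.
* :func:`stratification_study` — type-I error under confounding (two
  subpopulations with divergent allele frequencies and different disease
  prevalence) for naive permutation versus biased-urn permutation.  PCs are
  computed on the cohort's full common-variant panel: the simulated panel has
  no physical LD, so the LD-pruning step real data needs is a no-op by design
  here.
* :func:`power_study` — rejection rate under the mixture alternative
  (deleterious + protective + neutral rare variants in one window) alongside a
  matched null.

Cohort sizes are desk-scale defaults chosen to make each study run in seconds
to a couple of minutes; see docs/methods.md for the exact scenario parameters
and their rationale.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from . import calpha, qc, urn, windows
from .synth_cohort import CohortConfig, simulate_cohort

__all__ = [
    "urn_sampler_tv",
    "null_calibration",
    "stratification_study",
    "power_study",
]

#: default weight set for the sampler-exactness study: odds spanning roughly
#: two orders of magnitude, as logistic-fitted urn weights typically do under
#: visible stratification
TV_WEIGHTS = (0.1, 0.3, 1.0, 3.0, 9.0, 0.5, 2.0, 6.0)


def urn_sampler_tv(
    seed: int,
    n_draws: int = 20_000,
    weights=TV_WEIGHTS,
    K: int = 4,
) -> dict:
    """Total-variation distance between sampled and exact subset laws.

    Enumerates every size-K subset of the N weighted items, computes its exact
    probability (product of weights, normalised), draws ``n_draws`` case sets,
    and returns the TV distance plus a flag that every draw had exactly K
    members.
    """
    w = np.asarray(weights, dtype=float)
    N = len(w)
    rng = np.random.default_rng(seed)
    subsets = list(itertools.combinations(range(N), K))
    probs = np.array([np.prod(w[list(s)]) for s in subsets])
    probs /= probs.sum()
    sampler = urn.ConditionalBernoulliSampler(w, K)
    draws = sampler.sample_many(rng, n_draws)
    sizes_ok = bool(np.all(draws.sum(axis=1) == K))
    keys = draws @ (1 << np.arange(N))
    counts = Counter(keys.tolist())
    emp = np.array([counts.get(sum(1 << i for i in s), 0) / n_draws for s in subsets])
    tv = 0.5 * float(np.abs(emp - probs).sum())
    return {"tv": tv, "all_draws_size_K": sizes_ok, "n_draws": n_draws, "n_subsets": len(subsets)}


def _single_window_cohort(
    seed: int,
    n_subjects: int,
    effect_mix: tuple[float, float, float],
    fst: float = 0.0,
    n_subpops: int = 1,
    subpop_shift=None,
    n_common_variants: int = 10,
) -> CohortConfig:
    """One rare-variant cluster of 15 variants, no index-CV effect."""
    return CohortConfig(
        n_subjects=n_subjects,
        n_subpops=n_subpops,
        fst=fst,
        n_common_variants=n_common_variants,
        n_rv_clusters=1,
        rvs_per_cluster=15,
        rv_effect_mix=effect_mix,
        or_index_cv=1.0,
        case_fraction_target=0.6 if subpop_shift is None else 0.55,
        subpop_shift=subpop_shift,
        seed=seed,
    )


def _window_test_inputs(config: CohortConfig):
    """Simulate a cohort and return (G_window, status, truth, matrix) or None."""
    matrix, subjects, truth = simulate_cohort(config)
    subjects = qc.fill_collapsed_codes(subjects)
    status = subjects.df["affection"].to_numpy(dtype=float)
    if not (1 <= (status == 2).sum() <= len(status) - 1):
        return None
    index_id = truth.variants.loc[truth.variants["is_index"], "id"].iloc[0]
    spec = windows.extract_window(matrix, index_id, 25_000)
    if not spec.applicable:
        return None
    return windows.window_minor_dosage(matrix, spec), status, truth, matrix


def null_calibration(
    seed: int,
    n_replicates: int = 400,
    n_subjects: int = 150,
    B: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of windowed C-alpha with uniform permutation on null cohorts.

    Cohorts are homogeneous (one subpopulation) with all rare variants
    neutral; each replicate tests the 25-kb window around the cluster's index
    marker with ``B`` uniform permutations.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seeds = ss.generate_state(n_replicates) >> 1  # keep below 2**31
    rej = 0
    n_tested = 0
    for i in range(n_replicates):
        cfg = _single_window_cohort(int(cohort_seeds[i]), n_subjects, (0.0, 0.0, 1.0))
        out = _window_test_inputs(cfg)
        if out is None:
            continue
        G, status, _, _ = out
        p = calpha.permutation_p(G, status, B=B, rng=np.random.default_rng(ss.spawn(1)[0]))
        n_tested += 1
        rej += p < alpha
    return {"rejection_rate": rej / n_tested, "n_tested": n_tested, "alpha": alpha, "B": B}


def stratification_study(
    seed: int,
    n_replicates: int = 200,
    n_subjects: int = 200,
    fst: float = 0.1,
    B: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Naive vs biased-urn type-I error on confounded cohorts.

    Two subpopulations with Balding–Nichols divergence ``fst`` and a
    subpopulation-linked disease prevalence (liability shift of ∓1 log-odds);
    all rare variants are neutral, so any rejection is a stratification
    artefact.  Urn weights come from a logistic fit of status on the first 5
    PCs of the cohort's 400-variant common panel.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seeds = ss.generate_state(n_replicates) >> 1
    naive, adjusted = [], []
    for i in range(n_replicates):
        cfg = _single_window_cohort(
            int(cohort_seeds[i]),
            n_subjects,
            (0.0, 0.0, 1.0),
            fst=fst,
            n_subpops=2,
            subpop_shift=(-1.0, 1.0),
            n_common_variants=400,
        )
        out = _window_test_inputs(cfg)
        if out is None:
            continue
        G, status, truth, matrix = out
        cv_cols = np.where((truth.variants["kind"] != "rv").to_numpy())[0]
        pcs = urn.compute_pcs(matrix.take_variants(cv_cols), 5)
        model = urn.fit_urn_weights(status, pcs)
        rngs = ss.spawn(2)
        p_naive = calpha.permutation_p(G, status, B=B, rng=np.random.default_rng(rngs[0]))
        p_urn = urn.stratified_permutation_p(G, status, model, B=B, rng=np.random.default_rng(rngs[1]))
        naive.append(p_naive < alpha)
        adjusted.append(p_urn < alpha)
    return {
        "naive_rejection": float(np.mean(naive)),
        "urn_rejection": float(np.mean(adjusted)),
        "n_tested": len(naive),
        "alpha": alpha,
        "B": B,
    }


def power_study(
    seed: int,
    sample_sizes: tuple[int, ...] = (250, 1000),
    n_replicates: int = 100,
    B: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Rejection under the mixture alternative vs a matched neutral null.

    Alternative windows carry 50% deleterious (OR 3), 20% protective (OR 1/3)
    and 30% neutral rare variants — the generator's default mixture.
    """
    ss = np.random.SeedSequence(seed)
    out: dict = {"alpha": alpha, "B": B, "n_replicates": n_replicates, "per_n": {}}
    for n in sample_sizes:
        rates = {}
        for label, mix in (("power", (0.5, 0.2, 0.3)), ("null", (0.0, 0.0, 1.0))):
            seeds = ss.generate_state(n_replicates) >> 1
            rej = 0
            tested = 0
            for i in range(n_replicates):
                cfg = _single_window_cohort(int(seeds[i]), n, mix)
                sim = _window_test_inputs(cfg)
                if sim is None:
                    continue
                G, status, _, _ = sim
                p = calpha.permutation_p(G, status, B=B, rng=np.random.default_rng(ss.spawn(1)[0]))
                tested += 1
                rej += p < alpha
            rates[label] = rej / tested
            rates[f"n_tested_{label}"] = tested
        out["per_n"][n] = rates
    return out
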