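"""Stratification-adjusted permutation via biased-urn sampling.

Naive permutation of case/control labels is miscalibrated when the sample
contains subpopulations that differ both in allele frequencies and in disease
prevalence.  The biased-urn correction keeps that structure under the null:

1. build a quasi-independent marker panel by greedy LD pruning (pairwise
   r^2 <= ``r2_max``, variants with any missing call excluded first);
2. run PCA on the standardised panel and keep the first k eigenvectors
   (default 5) as ancestry scores;
3. fit case status on the ancestry scores plus the clinical covariates by
   logistic regression and convert each subject's fitted case probability
   pi_j into an odds weight w_j = pi_j / (1 - pi_j);
4. draw case relabelings of the observed case count K with probability
   proportional to the product of the selected subjects' weights — the
   multivariate Fisher noncentral hypergeometric distribution, also known as
   the conditional Bernoulli law.

Sampling is exact (no rejection, no MCMC): the elementary symmetric
polynomials e_k of the weights are tabulated in log space by the recursion
e_k(w_i..w_N) = e_k(w_{i+1}..w_N) + w_i e_{k-1}(w_{i+1}..w_N), after which
subjects are visited in order and included with their exact conditional
probability given the number of case slots still open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from . import calpha
from .geno_io import GenotypeMatrix

__all__ = [
    "UrnModel",
    "pairwise_r2",
    "ld_prune",
    "compute_pcs",
    "fit_urn_weights",
    "ConditionalBernoulliSampler",
    "sample_case_set",
    "make_urn_sampler",
    "stratified_permutation_p",
]


@dataclass
class UrnModel:
    """Per-subject selection odds and the PC scores they were fit on."""

    weights: np.ndarray
    pc_scores: np.ndarray
    k: int
    converged: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")

    @classmethod
    def uniform(cls, n_subjects: int) -> "UrnModel":
        return cls(
            weights=np.ones(n_subjects),
            pc_scores=np.empty((n_subjects, 0)),
            k=0,
            converged=True,
        )


def pairwise_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed on the subjects non-missing in both; either vector constant on
    that set is an error.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def ld_prune(matrix: GenotypeMatrix, r2_max: float = 0.01, max_lag: int = 500) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns kept variant column indices.

    Variants with any missing call are excluded first ("no missing alleles"),
    as are monomorphic ones.  A candidate is kept iff its r^2 with every
    previously kept variant among the last ``max_lag`` kept is <= ``r2_max``.
    Deterministic.
    """
    D = matrix.dosage
    n = D.shape[0]
    kept: list[int] = []
    kept_z: list[np.ndarray] = []
    for j in range(D.shape[1]):
        col = D[:, j]
        if np.isnan(col).any() or np.ptp(col) == 0:
            continue
        z = (col - col.mean()) / col.std()
        if kept_z:
            block = np.asarray(kept_z[-max_lag:])
            r = block @ z / n
            if np.max(r * r) > r2_max:
                continue
        kept.append(j)
        kept_z.append(z)
    return np.asarray(kept, dtype=int)


def compute_pcs(panel, k: int = 5) -> np.ndarray:
    """Subject scores on the top-k principal components of a genotype panel.

    ``panel`` is a subjects × variants dosage array (or GenotypeMatrix).
    Columns are centred and scaled by sqrt(2 f (1-f)) with f the sample allele
    frequency (the standard genotype standardisation); missing entries are
    mean-imputed; monomorphic columns are dropped.  Scores are the top-k left
    singular vectors, each column's sign fixed so its largest-magnitude entry
    is positive.  If the matrix rank is below k, fewer columns are returned
    with a warning.
    """
    X = panel.dosage if isinstance(panel, GenotypeMatrix) else np.asarray(panel, dtype=float)
    X = X.astype(float).copy()
    if k == 0:
        return np.empty((X.shape[0], 0))
    if X.shape[0] < k + 1 or X.shape[1] < k:
        raise ValueError(f"need >= {k + 1} subjects and >= {k} variants for {k} PCs")
    mu = np.nanmean(X, axis=0)
    ind = np.where(np.isnan(X))
    X[ind] = np.take(mu, ind[1])
    f = mu / 2.0
    sd = np.sqrt(2.0 * f * (1.0 - f))
    poly = sd > 0
    X = (X[:, poly] - mu[poly]) / sd[poly]
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if len(S) else 0.0)
    rank = int((S > tol).sum())
    if rank < k:
        warnings.warn(f"panel rank {rank} < requested {k} PCs; returning {rank}")
        k = rank
    scores = U[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def fit_urn_weights(status, pc_scores, covariates=None) -> UrnModel:
    """Fit per-subject urn weights from ancestry PCs and clinical covariates.

    Logistic regression of case status on the scores (+ covariates); fitted
    probabilities are clipped to [1e-6, 1-1e-6] before conversion to odds so
    weights stay finite even under separation.  Non-convergence is flagged,
    not raised; callers may fall back to ``UrnModel.uniform``.
    """
    s = np.asarray(status, dtype=float)
    y = (s == 2).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both cases and controls")
    pcs = np.asarray(pc_scores, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    blocks = [np.ones((len(y), 1)), pcs]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        blocks.append(C)
    X = np.column_stack(blocks)
    if np.isnan(X).any():
        raise ValueError("missing values in PCs/covariates for urn weight fit")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        pi = np.asarray(res.predict(X), dtype=float)
    except Exception:
        converged = False
        pi = np.full(len(y), y.mean())
    pi = np.clip(pi, 1e-6, 1 - 1e-6)
    return UrnModel(weights=pi / (1 - pi), pc_scores=pcs, k=pcs.shape[1], converged=converged)


class ConditionalBernoulliSampler:
    """Exact fixed-size weighted subset sampler (conditional Bernoulli law).

    Draws subsets S of size K from N items with P(S) proportional to the
    product of the selected weights.  The log elementary symmetric polynomial
    table is built once (O(N K)); each draw is O(N).
    """

    def __init__(self, weights, K: int):
        w = np.asarray(weights, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
        N = len(w)
        if not 1 <= K <= N - 1:
            raise ValueError(f"K={K} must be between 1 and N-1={N - 1}")
        self.N, self.K = N, K
        self.logw = np.log(w)
        # L[i, k] = log e_k(w_i, ..., w_{N-1}); built backward
        L = np.full((N + 1, K + 1), -np.inf)
        L[:, 0] = 0.0
        for i in range(N - 1, -1, -1):
            L[i, 1:] = np.logaddexp(L[i + 1, 1:], self.logw[i] + L[i + 1, :-1])
        self._L = L

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One draw: boolean inclusion vector with exactly K True entries."""
        L, logw, N, K = self._L, self.logw, self.N, self.K
        out = np.zeros(N, dtype=bool)
        remaining = K
        u = rng.random(N)
        for i in range(N):
            if remaining == 0:
                break
            if N - i == remaining:
                out[i:] = True
                break
            p_inc = np.exp(logw[i] + L[i + 1, remaining - 1] - L[i, remaining])
            if u[i] < p_inc:
                out[i] = True
                remaining -= 1
        return out

    def sample_many(self, rng: np.random.Generator, B: int) -> np.ndarray:
        return np.stack([self.sample(rng) for _ in range(B)])

    def log_prob(self, subset_mask) -> float:
        """Exact log-probability of a specific size-K subset (for validation)."""
        mask = np.asarray(subset_mask, dtype=bool)
        if mask.sum() != self.K:
            raise ValueError("subset has the wrong size")
        return float(self.logw[mask].sum() - self._L[0, self.K])


def sample_case_set(weights, K: int, rng: np.random.Generator) -> np.ndarray:
    """One exact draw of a size-K case set with P ∝ product of weights."""
    return ConditionalBernoulliSampler(weights, K).sample(rng)


def make_urn_sampler(model: UrnModel):
    """Adapt an UrnModel to the sampler interface of :func:`calpha.permutation_p`."""
    cache: dict[tuple[int, int], ConditionalBernoulliSampler] = {}

    def sampler(rng: np.random.Generator, n: int, k: int, B: int) -> np.ndarray:
        if n != len(model.weights):
            raise ValueError(
                f"urn model has {len(model.weights)} weights but {n} subjects enter the test"
            )
        key = (n, k)
        if key not in cache:
            cache[key] = ConditionalBernoulliSampler(model.weights, k)
        return cache[key].sample_many(rng, B)

    return sampler


def stratified_permutation_p(
    genotypes,
    status,
    model: UrnModel,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """C-alpha permutation p with biased-urn relabelings.

    Delegates to :func:`rarewin.calpha.permutation_p` with relabelings drawn
    from the conditional Bernoulli law of the urn weights.  With uniform
    weights that law is the uniform permutation null, so the procedure reduces
    to the unadjusted test (and is bit-identical to ``permutation_p`` called
    with the same uniform-urn sampler and rng).
    """
    return calpha.permutation_p(genotypes, status, B=B, rng=rng, sampler=make_urn_sampler(model))
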