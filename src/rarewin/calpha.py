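"""C-alpha overdispersion test for a window of rare variants.

For variant i in a window let n_i be the total number of minor-allele copies
observed in the sample and y_i the number of those copies carried by cases.
Under the null every copy lands in a case independently with probability p0,
the proportion of cases among all subjects, so y_i ~ Binomial(n_i, p0).  Under
the alternative the per-variant case share follows a mixture (some variants
deleterious, some protective, some neutral), which inflates the spread of the
y_i around their binomial expectation.  The test statistic accumulates that
excess spread:

    T = sum_i [ (y_i - n_i p0)^2 - n_i p0 (1 - p0) ]

with null variance

    c = sum_i sum_{u=0}^{n_i} Bin(u; n_i, p0) [ (u - n_i p0)^2 - n_i p0 (1-p0) ]^2

and asymptotic one-sided test Z = T / sqrt(c) against the upper normal tail
(only overdispersion is evidence for the mixture alternative).  Significance
in practice is assessed by permutation of case/control labels with the case
count held fixed; the stratification-aware variant of that permutation lives
in :mod:`rarewin.urn`.

Singletons (n_i = 1) carry no overdispersion information and are removed
upstream; a window needs at least two qualifying rare variants to be testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CAlphaInput",
    "CAlphaResult",
    "case_allele_counts",
    "calpha_T",
    "calpha_variance",
    "calpha_z",
    "permutation_p",
    "run_window_test",
]


@dataclass
class CAlphaInput:
    """Per-variant minor-allele copy counts: y in cases, n in everyone."""

    y: np.ndarray
    n: np.ndarray
    p0: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.y.shape != self.n.shape:
            raise ValueError("y and n must have the same length")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0,1)")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("need 0 <= y_i <= n_i")


@dataclass
class CAlphaResult:
    T: float
    c: float
    Z: float
    p_asymptotic: float
    p_permutation: float  # nan when not computed
    B: int
    n_rv: int
    applicable: bool


def case_allele_counts(genotypes, status) -> CAlphaInput:
    """Tally minor-allele copies overall (n_i) and in cases (y_i).

    ``genotypes``: subjects × variants matrix of minor-allele dosages (nan =
    missing, contributing no copies).  ``status``: per-subject 1/2 codes
    (1 = control, 2 = case); subjects with missing status are dropped.
    p0 is the proportion of cases among subjects, matching the definition the
    test is calibrated to.
    """
    G = np.asarray(genotypes, dtype=float)
    s = np.asarray(status, dtype=float)
    keep = ~np.isnan(s)
    G, s = G[keep], s[keep]
    n_cases = int((s == 2).sum())
    n_controls = int((s == 1).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    G0 = np.nan_to_num(G)
    n = G0.sum(axis=0)
    y = G0[s == 2].sum(axis=0)
    return CAlphaInput(y=y, n=n, p0=n_cases / (n_cases + n_controls))


def calpha_T(inp: CAlphaInput) -> float:
    """The overdispersion statistic T."""
    mu = inp.n * inp.p0
    return float(np.sum((inp.y - mu) ** 2 - inp.n * inp.p0 * (1 - inp.p0)))


def calpha_variance(n, p0: float) -> float:
    """Null variance c of T by exact binomial enumeration.

    Identical n_i are grouped so each distinct copy count is enumerated once.
    """
    n = np.asarray(n, dtype=int)
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0,1)")
    c = 0.0
    for ni, count in zip(*np.unique(n, return_counts=True)):
        u = np.arange(ni + 1)
        w = stats.binom.pmf(u, ni, p0)
        term = (u - ni * p0) ** 2 - ni * p0 * (1 - p0)
        c += count * float(np.sum(w * term**2))
    return c


def calpha_z(T: float, c: float) -> tuple[float, float]:
    """Asymptotic standardisation: Z = T/sqrt(c), one-sided upper-tail p."""
    if c <= 0:
        raise ValueError("variance must be positive")
    Z = T / np.sqrt(c)
    return float(Z), float(stats.norm.sf(Z))


def _uniform_case_sampler(rng: np.random.Generator, n: int, k: int, B: int) -> np.ndarray:
    """B uniform case relabelings with exactly k cases, as a (B, n) bool mask."""
    r = rng.random((B, n))
    idx = np.argpartition(r, k - 1, axis=1)[:, :k]
    mask = np.zeros((B, n), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    return mask


def permutation_p(
    genotypes,
    status,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    sampler=None,
) -> float:
    """Permutation p-value for T with the case count held fixed.

    ``sampler(rng, n_subjects, n_cases, B) -> (B, n) bool mask`` generates the
    relabelings; the default draws uniformly over all case sets of the
    observed size.  p = (1 + #{T_b >= T_obs}) / (1 + B); ties count against
    rejection.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    G = np.asarray(genotypes, dtype=float)
    s = np.asarray(status, dtype=float)
    keep = ~np.isnan(s)
    G, s = G[keep], s[keep]
    inp = case_allele_counts(G, s)
    T_obs = calpha_T(inp)

    G0 = np.nan_to_num(G)
    k = int((s == 2).sum())
    if sampler is None:
        sampler = _uniform_case_sampler
    masks = sampler(rng, G0.shape[0], k, B)
    if masks.shape != (B, G0.shape[0]):
        raise ValueError("sampler returned a mask of the wrong shape")
    if not np.all(masks.sum(axis=1) == k):
        raise ValueError("sampler violated the fixed case count")
    y_perm = masks.astype(float) @ G0  # (B, m)
    mu = inp.n * inp.p0
    const = float(np.sum(inp.n * inp.p0 * (1 - inp.p0)))
    T_perm = ((y_perm - mu) ** 2).sum(axis=1) - const
    tol = 1e-9 * max(1.0, abs(T_obs))
    n_ge = int(np.sum(T_perm >= T_obs - tol))
    return (1 + n_ge) / (1 + B)


def run_window_test(
    genotypes,
    status,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    sampler=None,
) -> CAlphaResult:
    """Full C-alpha result (T, c, Z, asymptotic and permutation p) for a window."""
    inp = case_allele_counts(genotypes, status)
    T = calpha_T(inp)
    c = calpha_variance(inp.n.astype(int), inp.p0)
    if c > 0:
        Z, p_asym = calpha_z(T, c)
    else:
        Z, p_asym = np.nan, np.nan
    p_perm = permutation_p(genotypes, status, B=B, rng=rng, sampler=sampler)
    return CAlphaResult(
        T=T,
        c=c,
        Z=Z,
        p_asymptotic=p_asym,
        p_permutation=p_perm,
        B=B,
        n_rv=len(inp.n),
        applicable=len(inp.n) >= 2,
    )
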