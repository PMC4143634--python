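"""Data-cleaning rules applied before association testing.

Four rules, in order:

1. exclude sites that carry three or more alleles (``n_alt_alleles >= 2``);
2. exclude variants failing an exact Hardy-Weinberg equilibrium test at
   ``p < hwe_alpha`` (default 0.01), computed on all subjects pooled;
3. collapse the per-visit binary indicators (hypertension, smoking, blood
   pressure medication) to 1/2 codes — 2 if the condition is recorded at any
   visit, 1 if every observed visit is negative, missing if no visit observed;
4. record the per-variant minor allele frequency (MAF), the quantity that
   later splits variants into common (MAF >= 0.05) and rare (MAF < 0.05).

The HWE test is the exact conditional test: given the observed allele counts,
the heterozygote count follows a known discrete distribution, and the p-value
sums the probabilities of all outcomes no more probable than the observed one.
Monomorphic variants have p = 1 and are retained (they can never qualify as
common variants or as non-singleton rare variants, so no extra rule is
needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geno_io import GenotypeMatrix, SubjectTable

__all__ = [
    "QCReport",
    "MAFResult",
    "collapse_any_visit",
    "minor_allele_frequency",
    "hwe_exact_p",
    "genotype_counts",
    "apply_qc",
]

_MISSING = float("nan")


def collapse_any_visit(visit_indicators) -> float:
    """Collapse ordered per-visit 0/1/missing indicators to a 1/2/missing code.

    Any observed 1 -> 2 (affected/yes); all observed values 0 -> 1; all
    missing -> missing (nan).
    """
    seen_any = False
    for v in visit_indicators:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v not in (0, 1):
            raise ValueError(f"visit indicator {v!r} outside {{0,1,missing}}")
        if v == 1:
            return 2.0
        seen_any = True
    return 1.0 if seen_any else _MISSING


class MAFResult(NamedTuple):
    maf: float
    minor_allele: str  # "alt" or "ref"


def minor_allele_frequency(dosages) -> MAFResult:
    """Minor allele frequency of an ALT-dosage vector (nan = missing).

    Returns ``min(f, 1-f)`` where ``f`` is the ALT frequency over non-missing
    chromosomes, and which allele is minor ("alt" when f <= 0.5).
    """
    d = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(d)
    n_chrom = 2 * int(obs.sum())
    if n_chrom == 0:
        raise ValueError("all dosages missing")
    f_alt = float(np.nansum(d)) / n_chrom
    if f_alt <= 0.5:
        return MAFResult(f_alt, "alt")
    return MAFResult(1.0 - f_alt, "ref")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one.
    Monomorphic samples return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    n_a = 2 * n_aa + n_Aa  # rare-ish allele counts; symmetry makes label moot
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # heterozygote count h shares the parity of the rare allele count
    hs = np.arange(rare % 2, rare + 1, 2)
    # log P(h) up to a constant: -log((nA-h)/2)! - log h! - log((na-h)/2)! + h log 2
    logp = (
        hs * math.log(2.0)
        - _lgamma_vec((n_A - hs) // 2 + 1)
        - _lgamma_vec(hs + 1)
        - _lgamma_vec((n_a - hs) // 2 + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(hs, n_Aa)]
    mask = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def _lgamma_vec(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def genotype_counts(dosages) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts from an ALT-dosage vector, nan-aware."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


@dataclass
class QCReport:
    """Per-rule exclusion counts and per-variant MAF of the retained set."""

    n_input: int
    n_excluded_multiallelic: int
    n_excluded_hwe: int
    n_monomorphic_retained: int
    n_retained: int
    hwe_alpha: float
    maf: pd.Series = field(repr=False)  # indexed by variant id, retained variants

    def __post_init__(self) -> None:
        n_excluded = self.n_excluded_multiallelic + self.n_excluded_hwe
        if n_excluded + self.n_retained != self.n_input:
            raise ValueError("excluded + retained != input variant count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input",
                    "excluded_multiallelic",
                    "excluded_hwe",
                    "monomorphic_retained",
                    "retained",
                ],
                "count": [
                    self.n_input,
                    self.n_excluded_multiallelic,
                    self.n_excluded_hwe,
                    self.n_monomorphic_retained,
                    self.n_retained,
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fill_collapsed_codes(subjects: SubjectTable) -> SubjectTable:
    """Add the collapsed affection/smoking/medication 1/2 codes."""
    df = subjects.df.copy()
    for name, prefix in (
        ("affection", "htn"),
        ("smoking", "smoke"),
        ("medication", "med"),
    ):
        cols = [f"{prefix}_v{i}" for i in range(1, 5)]
        df[name] = [collapse_any_visit(row) for row in df[cols].itertuples(index=False)]
    return SubjectTable(df=df)


def apply_qc(
    matrix: GenotypeMatrix,
    subjects: SubjectTable,
    hwe_alpha: float = 0.01,
) -> tuple[GenotypeMatrix, SubjectTable, QCReport]:
    """Apply the cleaning rules; return filtered matrix, coded subjects, report."""
    n_input = matrix.n_variants
    multi = matrix.variants["n_alt_alleles"].to_numpy() >= 2

    hwe_fail = np.zeros(n_input, dtype=bool)
    mono = np.zeros(n_input, dtype=bool)
    for i in range(n_input):
        if multi[i]:
            continue
        c = genotype_counts(matrix.dosage[:, i])
        if sum(c) == 0:
            mono[i] = True
            continue
        p = hwe_exact_p(*c)
        if p < hwe_alpha:
            hwe_fail[i] = True
        elif min(2 * c[0] + c[1], 2 * c[2] + c[1]) == 0:
            mono[i] = True

    keep = ~(multi | hwe_fail)
    kept = matrix.take_variants(np.where(keep)[0])

    def _maf_or_nan(col):
        obs = ~np.isnan(col)
        if not obs.any():
            return np.nan
        return minor_allele_frequency(col).maf

    maf = pd.Series(
        [_maf_or_nan(kept.dosage[:, i]) for i in range(kept.n_variants)],
        index=kept.variants["id"].tolist(),
        name="maf",
        dtype=float,
    )
    report = QCReport(
        n_input=n_input,
        n_excluded_multiallelic=int(multi.sum()),
        n_excluded_hwe=int(hwe_fail.sum()),
        n_monomorphic_retained=int((mono & keep).sum()),
        n_retained=int(keep.sum()),
        hwe_alpha=hwe_alpha,
        maf=maf,
    )
    return kept, fill_collapsed_codes(subjects), report
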