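"""Covariate-adjusted logistic single-marker scan over common variants.

Each common variant (sample MAF >= ``maf_min``) is tested one at a time with

    logit P(affected) = b0 + b_g * dosage + covariates

where dosage counts minor-allele copies and the covariates are the clinical
set: smoking, blood pressure medication, age at first visit, and sex.  The
reported p-value is the Wald test on ``b_g``.  No multiple-testing correction
is applied at this stage: the scan exists only to rank variants and pick the
top-K index markers around which rare-variant windows are built.

Missing data are handled complete-case per marker.  Fits that do not converge
or separate perfectly are returned flagged (``converged=False``, p = nan),
never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .geno_io import GenotypeMatrix, SubjectTable
from .qc import minor_allele_frequency

__all__ = [
    "AssocResult",
    "design_covariates",
    "fit_single_marker",
    "run_cv_scan",
    "select_top_k",
]


@dataclass
class AssocResult:
    variant_id: str
    pos: int
    beta: float  # log-odds per minor-allele copy
    se: float
    p: float
    n_used: int
    converged: bool
    message: str = ""


def design_covariates(subjects: SubjectTable) -> pd.DataFrame:
    """Clinical covariate design: smoking, medication, age at first visit, sex.

    The 1/2 collapsed codes are mapped to 0/1 and sex to an is-male indicator;
    requires :func:`rarewin.qc.apply_qc` to have filled the collapsed codes.
    """
    df = subjects.df
    for col in ("smoking", "medication"):
        if col not in df.columns:
            raise ValueError("collapsed codes missing; run qc.apply_qc first")
    return pd.DataFrame(
        {
            "smoking": df["smoking"].astype(float) - 1.0,
            "medication": df["medication"].astype(float) - 1.0,
            "age1": df["age1"].astype(float),
            "male": (df["sex"] == "M").astype(float).where(df["sex"].notna()),
        }
    )


def _flagged(variant_id, pos, n_used, message) -> AssocResult:
    return AssocResult(
        variant_id=variant_id,
        pos=pos,
        beta=np.nan,
        se=np.nan,
        p=np.nan,
        n_used=n_used,
        converged=False,
        message=message,
    )


def fit_single_marker(
    dosage,
    status,
    covariates=None,
    variant_id: str = "",
    pos: int = -1,
) -> AssocResult:
    """Logistic fit of 1/2 affection status on one dosage vector + covariates.

    Newton/IRLS to gradient tolerance 1e-8; Wald test on the dosage
    coefficient.  Rows with any missing required field are dropped.
    """
    d = np.asarray(dosage, dtype=float)
    s = np.asarray(status, dtype=float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((len(d), 0))
    keep = ~(np.isnan(d) | np.isnan(s) | np.isnan(C).any(axis=1))
    d, s, C = d[keep], s[keep], C[keep]
    n_used = int(keep.sum())
    y = (s == 2).astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        return _flagged(variant_id, pos, n_used, "fewer than 2 of each status")
    if np.ptp(d) == 0:
        return _flagged(variant_id, pos, n_used, "constant dosage")
    X = np.column_stack([np.ones(n_used), d, C])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
    except Exception as exc:  # separation, singular Hessian, non-convergence
        return _flagged(variant_id, pos, n_used, f"fit failed: {exc}")
    if not res.mle_retvals.get("converged", False):
        return _flagged(variant_id, pos, n_used, "did not converge")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        return _flagged(variant_id, pos, n_used, "unstable estimate")
    p = float(res.pvalues[1])
    return AssocResult(
        variant_id=variant_id,
        pos=pos,
        beta=beta,
        se=se,
        p=p,
        n_used=n_used,
        converged=True,
    )


def run_cv_scan(
    matrix: GenotypeMatrix,
    subjects: SubjectTable,
    maf_min: float = 0.05,
    covariates: pd.DataFrame | None = None,
) -> list[AssocResult]:
    """Scan all common variants (MAF >= maf_min); results ordered by ascending p.

    Dosages are oriented to count the minor allele before fitting, so effects
    are per minor-allele copy.  ``covariates`` defaults to the clinical set
    from :func:`design_covariates`.
    """
    if covariates is None:
        covariates = design_covariates(subjects)
    C = np.asarray(covariates, dtype=float)
    status = subjects.df["affection"].to_numpy(dtype=float)
    results: list[AssocResult] = []
    for i in range(matrix.n_variants):
        col = matrix.dosage[:, i]
        if np.isnan(col).all():
            continue
        maf, minor = minor_allele_frequency(col)
        if maf < maf_min:
            continue
        d = col if minor == "alt" else 2.0 - col
        v = matrix.variants.iloc[i]
        results.append(
            fit_single_marker(d, status, C, variant_id=str(v["id"]), pos=int(v["pos"]))
        )
    results.sort(key=lambda r: (np.isnan(r.p), r.p if np.isfinite(r.p) else 0.0, r.pos, r.variant_id))
    return results


def select_top_k(results: list[AssocResult], k: int = 10) -> list[AssocResult]:
    """The k most significant converged results; ties broken by position, then id."""
    usable = [r for r in results if r.converged and np.isfinite(r.p)]
    if len(usable) < k:
        raise ValueError(f"only {len(usable)} usable results for top-{k} selection")
    usable.sort(key=lambda r: (r.p, r.pos, r.variant_id))
    return usable[:k]


def scan_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.variant_id for r in results],
            "pos": [r.pos for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "n": [r.n_used for r in results],
            "converged": [r.converged for r in results],
        }
    )
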