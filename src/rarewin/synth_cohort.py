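"""Synthetic case-control cohorts with the structure the pipeline assumes.

The generator emulates a small sequenced cohort of unrelated subjects on one
chromosome: latent subpopulations with divergent allele frequencies, common
variants (some associated with affection status), clusters of rare variants
around those index markers containing a mixture of deleterious, protective and
neutral effects, clinical covariates, and longitudinal (per-visit) binary
phenotypes collapsed to an any-visit affection code.

Genotypes follow the Balding–Nichols model: each variant has an ancestral
frequency p, each subpopulation draws its own frequency from
Beta(p (1-F)/F, (1-p)(1-F)/F) — mean p, variance F p (1-p) — and genotypes are
Hardy-Weinberg within subpopulation.  F (``fst``) is the single divergence
knob; F = 0 gives a homogeneous cohort.

Phenotypes follow a logistic liability: intercept + covariate terms + genetic
terms (log-odds per minor-allele copy) + a per-subpopulation shift.  The
intercept is calibrated by bisection so the expected case fraction hits the
configured target.  Per-visit indicators are derived from the collapsed status
plus visit-level noise, because the analysis only ever uses the collapsed
coding.

Randomness: one master seed, split into independent child streams per stage
(genotypes / phenotypes), so either stage can be regenerated alone and all
outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import (
    GeneTrack,
    GenotypeMatrix,
    SubjectTable,
    SUBJECT_COLUMNS,
    write_subjects,
    write_vcf,
)

__all__ = [
    "CovariateEffects",
    "CohortConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_fixture",
]

_CLUSTER_SPACING = 150_000  # bp between cluster centres; > 2 x 25 kb windows
_CHROM = "chr3"


@dataclass
class CovariateEffects:
    """Log-odds of affection per covariate unit (age is per year, centred)."""

    sex: float = 0.3
    age: float = 0.02
    smoking: float = 0.4
    medication: float = 0.5


@dataclass
class CohortConfig:
    """Scenario parameters for one synthetic cohort.

    Defaults mirror the cohort the pipeline targets: ~103 unrelated subjects
    with a case:control ratio near 60:34, two subpopulations with modest
    divergence, and ten rare-variant clusters around associated index CVs.
    """

    n_subjects: int = 103
    case_fraction_target: float = 60 / 94
    n_subpops: int = 2
    fst: float = 0.05
    n_common_variants: int = 120
    n_rv_clusters: int = 10
    rvs_per_cluster: int = 30
    rv_effect_mix: tuple[float, float, float] = (0.5, 0.2, 0.3)  # del/prot/neutral
    or_deleterious: float = 3.0
    or_protective: float = 1 / 3
    or_index_cv: float = 2.0
    window_layout: list[tuple[int, int]] | None = None  # (index_pos, cluster_span_bp)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    subpop_shift: tuple[float, ...] | None = None  # per-subpop liability shift
    cv_freq_range: tuple[float, float] = (0.1, 0.5)
    rv_freq_range: tuple[float, float] = (0.005, 0.03)
    n_visits: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 < self.case_fraction_target < 1:
            raise ValueError("case_fraction_target must be in (0,1)")
        if self.n_subpops < 1:
            raise ValueError("need at least 1 subpopulation")
        if not 0 <= self.fst <= 0.5:
            raise ValueError("fst must be in [0, 0.5]")
        mix = np.asarray(self.rv_effect_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("rv_effect_mix must be 3 nonnegative reals summing to 1")
        if self.or_deleterious <= 1:
            raise ValueError("or_deleterious must exceed 1")
        if not 0 < self.or_protective < 1:
            raise ValueError("or_protective must lie in (0,1)")
        lo, hi = self.rv_freq_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid rv_freq_range")
        if hi >= 0.05:
            raise ValueError(
                f"rv_freq_range upper bound {hi} cannot yield expected MAF < 0.05"
            )
        if self.subpop_shift is not None and len(self.subpop_shift) != self.n_subpops:
            raise ValueError("subpop_shift length must equal n_subpops")
        if self.window_layout is not None:
            if len(self.window_layout) != self.n_rv_clusters:
                raise ValueError("window_layout length must equal n_rv_clusters")
            pos = [p for p, _ in self.window_layout]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("window_layout index positions must be strictly increasing")

    def layout(self) -> list[tuple[int, int]]:
        if self.window_layout is not None:
            return list(self.window_layout)
        return [
            (100_000 + i * _CLUSTER_SPACING, 50_000) for i in range(self.n_rv_clusters)
        ]

    def chrom_length(self) -> int:
        lay = self.layout()
        last = lay[-1][0] + lay[-1][1] if lay else 0
        return max(last + 100_000, 400_000)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated cohort.

    ``variants`` rows align with the GenotypeMatrix columns: ancestral
    frequency, per-subpopulation frequency, effect class, log-odds, cluster
    membership and index flags.  ``subpop`` holds per-subject labels.
    """

    variants: pd.DataFrame
    subpop: np.ndarray

    def __post_init__(self) -> None:
        classes = {"deleterious", "protective", "neutral"}
        if not set(self.variants["effect_class"]).issubset(classes):
            raise ValueError("unknown effect class")


def _effect_classes(m: int, mix, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation of m variants to 3 classes,
    then a random arrangement within the cluster."""
    mix = np.asarray(mix, dtype=float)
    counts = np.floor(mix * m).astype(int)
    rem = m - counts.sum()
    order = np.argsort(-(mix * m - counts))
    for j in range(rem):
        counts[order[j]] += 1
    labels = np.repeat(np.array(["deleterious", "protective", "neutral"]), counts)
    return rng.permutation(labels)


def simulate_genotypes(config: CohortConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw genotypes and the truth record under the Balding–Nichols model."""
    ss = np.random.SeedSequence(config.seed)
    geno_ss, _ = ss.spawn(2)
    rng = np.random.default_rng(geno_ss)

    n, S = config.n_subjects, config.n_subpops
    subpop = rng.permutation(np.arange(n) % S)

    layout = config.layout()
    L = config.chrom_length()

    # --- variant layout ---------------------------------------------------
    rows = []  # (pos, kind, cluster, is_index)
    cluster_spans = []
    for ci, (center, span) in enumerate(layout):
        half = span // 2
        cluster_spans.append((center - half, center + half))
        rows.append((center, "cv_index", ci, True))
        offsets = rng.choice(np.arange(-half, half + 1), size=config.rvs_per_cluster, replace=False)
        offsets = offsets[offsets != 0]
        while len(offsets) < config.rvs_per_cluster:
            extra = int(rng.integers(-half, half + 1))
            if extra != 0 and extra not in offsets:
                offsets = np.append(offsets, extra)
        for off in offsets:
            rows.append((center + off, "rv", ci, False))
    taken = {p for p, *_ in rows}
    n_bg = config.n_common_variants
    bg_positions = []
    while len(bg_positions) < n_bg:
        cand = rng.integers(1, L + 1, size=n_bg)
        for p in cand:
            p = int(p)
            if p not in taken and not any(a <= p <= b for a, b in cluster_spans):
                bg_positions.append(p)
                taken.add(p)
                if len(bg_positions) == n_bg:
                    break
    for p in bg_positions:
        rows.append((p, "cv_background", -1, False))

    var = pd.DataFrame(rows, columns=["pos", "kind", "cluster", "is_index"])
    var = var.sort_values("pos", kind="stable").reset_index(drop=True)
    m = len(var)

    # --- ancestral frequencies and effects --------------------------------
    is_rv = (var["kind"] == "rv").to_numpy()
    p_anc = np.empty(m)
    p_anc[~is_rv] = rng.uniform(*config.cv_freq_range, size=(~is_rv).sum())
    p_anc[is_rv] = rng.uniform(*config.rv_freq_range, size=is_rv.sum())

    beta = np.zeros(m)
    eff = np.full(m, "neutral", dtype=object)
    for ci in range(len(layout)):
        rv_idx = np.where(is_rv & (var["cluster"].to_numpy() == ci))[0]
        classes = _effect_classes(len(rv_idx), config.rv_effect_mix, rng)
        eff[rv_idx] = classes
        beta[rv_idx[classes == "deleterious"]] = np.log(config.or_deleterious)
        beta[rv_idx[classes == "protective"]] = np.log(config.or_protective)
    idx_mask = var["is_index"].to_numpy()
    beta[idx_mask] = np.log(config.or_index_cv)

    # --- Balding–Nichols subpopulation frequencies ------------------------
    F = config.fst
    freqs = np.empty((S, m))
    if F == 0:
        freqs[:] = p_anc
    else:
        scale = (1 - F) / F
        for s in range(S):
            interior = (p_anc > 0) & (p_anc < 1)
            freqs[s, interior] = rng.beta(
                p_anc[interior] * scale, (1 - p_anc[interior]) * scale
            )
            freqs[s, ~interior] = p_anc[~interior]

    dosage = rng.binomial(2, freqs[subpop, :]).astype(float)

    ids = [f"v{int(p):08d}" for p in var["pos"]]
    variants = pd.DataFrame(
        {
            "chrom": _CHROM,
            "pos": var["pos"].astype(int),
            "id": ids,
            "ref": "A",
            "alt": "C",
            "n_alt_alleles": 1,
        }
    )
    truth_vars = pd.DataFrame(
        {
            "id": ids,
            "pos": var["pos"].astype(int),
            "kind": var["kind"],
            "cluster": var["cluster"].astype(int),
            "is_index": idx_mask,
            "ancestral_freq": p_anc,
            "effect_class": eff,
            "log_odds": beta,
        }
    )
    for s in range(S):
        truth_vars[f"freq_subpop{s}"] = freqs[s]
    matrix = GenotypeMatrix(dosage=dosage, variants=variants, subjects=[f"S{j:04d}" for j in range(n)])
    return matrix, TruthRecord(variants=truth_vars, subpop=subpop)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-10) -> float:
    """Bisection for c with mean(sigmoid(c + eta)) = target."""
    lo, hi = -35.0, 35.0
    f_lo = _sigmoid(lo + eta).mean() - target
    f_hi = _sigmoid(hi + eta).mean() - target
    if f_lo > 0.05 or f_hi < -0.05:
        raise ValueError("liability saturated: intercept cannot reach the target case fraction")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _sigmoid(mid + eta).mean() - target
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotypes(
    matrix: GenotypeMatrix, truth: TruthRecord, config: CohortConfig
) -> SubjectTable:
    """Draw covariates and longitudinal phenotypes from the liability model."""
    ss = np.random.SeedSequence(config.seed)
    _, pheno_ss = ss.spawn(2)
    rng = np.random.default_rng(pheno_ss)
    n = matrix.n_subjects
    if len(truth.subpop) != n:
        raise ValueError("truth record not aligned with the genotype matrix")

    sex_male = rng.random(n) < 0.5
    age = np.clip(rng.normal(50.0, 10.0, size=n), 20.0, 85.0)
    smoker = rng.random(n) < 0.35
    med_user = rng.random(n) < 0.30

    ce = config.covariate_effects
    eta = (
        ce.sex * sex_male
        + ce.age * (age - 50.0)
        + ce.smoking * smoker
        + ce.medication * med_user
    )
    beta = truth.variants["log_odds"].to_numpy()
    nz = beta != 0
    if nz.any():
        eta = eta + np.nan_to_num(matrix.dosage[:, nz]) @ beta[nz]
    if config.subpop_shift is not None:
        eta = eta + np.asarray(config.subpop_shift, dtype=float)[truth.subpop]

    intercept = calibrate_intercept(eta, config.case_fraction_target)
    case = rng.random(n) < _sigmoid(intercept + eta)

    V = config.n_visits
    def visits_from_latent(latent: np.ndarray, p_visit: float) -> np.ndarray:
        """Per-visit 0/1 indicators whose any-visit collapse equals `latent`."""
        out = np.zeros((n, V), dtype=int)
        pos = np.where(latent)[0]
        if len(pos):
            draws = rng.random((len(pos), V)) < p_visit
            none = ~draws.any(axis=1)
            if none.any():
                forced = rng.integers(0, V, size=int(none.sum()))
                draws[np.where(none)[0], forced] = True
            out[pos] = draws.astype(int)
        return out

    htn = visits_from_latent(case, 0.7)
    smoke = visits_from_latent(smoker, 0.85)
    med = visits_from_latent(med_user, 0.85)

    df = pd.DataFrame({"id": matrix.subjects})
    df["sex"] = np.where(sex_male, "M", "F")
    df["age1"] = np.round(age, 1)
    for v in range(V):
        df[f"htn_v{v + 1}"] = htn[:, v]
    for v in range(V):
        df[f"smoke_v{v + 1}"] = smoke[:, v]
    for v in range(V):
        df[f"med_v{v + 1}"] = med[:, v]
    return SubjectTable(df=df[SUBJECT_COLUMNS].copy())


def simulate_cohort(config: CohortConfig) -> tuple[GenotypeMatrix, SubjectTable, TruthRecord]:
    matrix, truth = simulate_genotypes(config)
    subjects = simulate_phenotypes(matrix, truth, config)
    return matrix, subjects, truth


def build_gene_track(truth: TruthRecord, config: CohortConfig) -> GeneTrack:
    """Genes covering alternate clusters: even clusters in-gene, odd not."""
    rows = []
    layout = config.layout()
    for ci, (center, span) in enumerate(layout):
        if ci % 2 == 0:
            half = max(2000, span // 8)
            rows.append((f"G{ci + 1}", _CHROM, center - half, center + half))
    return GeneTrack(
        intervals=pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    )


def write_fixture(
    matrix: GenotypeMatrix,
    subjects: SubjectTable,
    truth: TruthRecord,
    config: CohortConfig,
    out_dir,
    overwrite: bool = False,
) -> dict[str, str]:
    """Emit VCF + BED gene track + subject TSV + truth TSV under ``out_dir``.

    Gene intervals are placed over alternating clusters so half the index
    markers classify as in-gene.  Refuses to overwrite existing files unless
    ``overwrite`` is set.  Files round-trip losslessly through geno_io.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "bed": os.path.join(out_dir, "genes.bed"),
        "subjects": os.path.join(out_dir, "subjects.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    if not overwrite:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
    write_vcf(matrix, paths["vcf"], overwrite=True)
    track = build_gene_track(truth, config)
    with open(paths["bed"], "w") as fh:
        for _, iv in track.intervals.iterrows():
            # back to BED 0-based half-open
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene_id}\n")
    write_subjects(subjects, paths["subjects"], overwrite=True)
    tv = truth.variants.copy()
    tv.insert(0, "row_type", "variant")
    sub = pd.DataFrame(
        {"row_type": "subject", "id": matrix.subjects, "cluster": truth.subpop}
    )
    pd.concat([tv, sub], ignore_index=True).to_csv(paths["truth"], sep="\t", index=False)
    return paths
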