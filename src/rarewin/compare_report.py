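"""In-gene vs not-in-gene comparison and the end-to-end pipeline driver.

For each window size, windows are split by whether their index marker lies in
a gene, each side is tallied into significant (permuted p < alpha) versus not,
and the resulting 2×2 table is tested with Fisher's exact test (two-sided,
probability-mass rule: the p-value sums the probabilities of all tables with
the observed margins that are no more probable than the observed table).
Windows that were not applicable (fewer than two rare variants after singleton
removal) are excluded from the table by default, or optionally counted as
non-significant.

:func:`run_pipeline` chains the whole analysis: ingest → qc → common-variant
scan → top-K index selection → rare-variant windows at each width → C-alpha
with biased-urn permutation → per-width comparisons, writing TSV reports and a
run log.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import assoc, calpha, qc, urn, windows
from .geno_io import read_gene_track, read_subjects, read_vcf

__all__ = [
    "ComparisonResult",
    "PipelineConfig",
    "fisher_exact_two_sided",
    "build_significance_tables",
    "run_pipeline",
]


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]].

    Probability-mass rule with a small relative tolerance on the "no more
    probable" comparison, as implemented by scipy.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(1.0, p))


@dataclass
class ComparisonResult:
    """One window size's 2×2 significance table and Fisher p."""

    width: int
    counts: tuple[int, int, int, int]  # in-gene sig, in-gene not, out sig, out not
    alpha: float
    p: float  # nan when the comparison was skipped
    inapplicable_rule: str
    n_inapplicable: int
    skipped: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count")
        if not self.skipped and not 0 <= self.p <= 1:
            raise ValueError("p outside [0,1]")


def build_significance_tables(
    results: pd.DataFrame,
    alpha: float = 0.05,
    inapplicable_rule: str = "exclude",
) -> list[ComparisonResult]:
    """Per-width 2×2 tables of C-alpha significance by gene membership.

    ``results`` needs columns width, in_gene, applicable, p_permutation.  A
    window counts as significant iff it is applicable and its permuted p is
    below ``alpha``.  Inapplicable windows are dropped (rule "exclude",
    default) or counted as non-significant ("count-nonsignificant").  A width
    with zero applicable windows on either side is skipped with a warning.
    Row order of ``results`` is irrelevant.
    """
    if inapplicable_rule not in ("exclude", "count-nonsignificant"):
        raise ValueError(f"unknown inapplicable_rule {inapplicable_rule!r}")
    out: list[ComparisonResult] = []
    for width in sorted(results["width"].unique()):
        sub = results[results["width"] == width]
        applicable = sub["applicable"].astype(bool)
        n_inapp = int((~applicable).sum())
        if inapplicable_rule == "exclude":
            sub = sub[applicable]
            applicable = applicable[applicable]
        in_gene = sub["in_gene"].astype(bool).to_numpy()
        sig = (
            applicable.to_numpy()
            & (sub["p_permutation"].to_numpy(dtype=float) < alpha)
        )
        a = int((in_gene & sig).sum())
        b = int((in_gene & ~sig).sum())
        c = int((~in_gene & sig).sum())
        d = int((~in_gene & ~sig).sum())
        n_app_in = int((sub["applicable"].astype(bool) & in_gene).sum())
        n_app_out = int((sub["applicable"].astype(bool) & ~in_gene).sum())
        if n_app_in == 0 or n_app_out == 0:
            warnings.warn(
                f"width {width}: no applicable windows on one side; comparison skipped"
            )
            out.append(
                ComparisonResult(
                    width=int(width),
                    counts=(a, b, c, d),
                    alpha=alpha,
                    p=float("nan"),
                    inapplicable_rule=inapplicable_rule,
                    n_inapplicable=n_inapp,
                    skipped=True,
                )
            )
            continue
        out.append(
            ComparisonResult(
                width=int(width),
                counts=(a, b, c, d),
                alpha=alpha,
                p=fisher_exact_two_sided(a, b, c, d),
                inapplicable_rule=inapplicable_rule,
                n_inapplicable=n_inapp,
            )
        )
    return out


@dataclass
class PipelineConfig:
    """Flat configuration for one end-to-end run."""

    vcf: str
    bed: str
    subjects: str
    out_dir: str
    widths: tuple[int, ...] = (1000, 5000, 25000)
    top_k: int = 10
    maf_min: float = 0.05
    maf_max_rv: float = 0.05
    hwe_alpha: float = 0.01
    permutations: int = 1000
    pcs: int = 5
    r2_max: float = 0.01
    alpha: float = 0.05
    inapplicable_rule: str = "exclude"
    use_urn: bool = True
    pca_vcf: str | None = None  # optional separate marker panel for PCA
    seed: int = 0
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "widths" in raw:
            raw["widths"] = tuple(int(w) for w in raw["widths"])
        return cls(**raw)


def _fmt(x, nd=6) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "n/a"
    return f"{x:.{nd}g}"


@dataclass
class ReportBundle:
    window_results: pd.DataFrame
    comparisons: list[ComparisonResult]
    qc_report: qc.QCReport
    scan: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig | str) -> ReportBundle:
    """Run ingest → qc → scan → windows → C-alpha(urn) → comparison; write reports."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    matrix = _stage("ingest/vcf", read_vcf, cfg.vcf)
    track = _stage("ingest/bed", read_gene_track, cfg.bed)
    subjects = _stage("ingest/subjects", read_subjects, cfg.subjects)
    matrix, subjects, qc_report = _stage("qc", qc.apply_qc, matrix, subjects, cfg.hwe_alpha)

    covariates = assoc.design_covariates(subjects)
    scan = _stage("scan", assoc.run_cv_scan, matrix, subjects, cfg.maf_min, covariates)
    top = _stage("top-k", assoc.select_top_k, scan, cfg.top_k)

    status = subjects.df["affection"].to_numpy(dtype=float)

    if cfg.use_urn:
        panel = _stage("ingest/pca-panel", read_vcf, cfg.pca_vcf) if cfg.pca_vcf else matrix
        pruned = _stage("ld-prune", urn.ld_prune, panel, cfg.r2_max)
        pcs = _stage("pca", urn.compute_pcs, panel.take_variants(pruned), cfg.pcs)
        # urn stage keeps subjects complete for status + covariates (PCs have none)
        complete = ~(np.isnan(status) | np.isnan(covariates.to_numpy(dtype=float)).any(axis=1))
        model = _stage(
            "urn-weights",
            urn.fit_urn_weights,
            status[complete],
            pcs[complete],
            covariates.to_numpy(dtype=float)[complete],
        )
        if not model.converged:
            warnings.warn("urn weight fit did not converge; falling back to uniform weights")
            model = urn.UrnModel.uniform(int(complete.sum()))
    else:
        complete = ~np.isnan(status)
        model, pruned, pcs = urn.UrnModel.uniform(int(complete.sum())), None, None

    rows = []
    for r in top:
        for width in cfg.widths:
            spec = _stage(
                f"window/{r.variant_id}/{width}",
                windows.extract_window,
                matrix, r.variant_id, width, cfg.maf_max_rv, track,
            )
            rec = {
                "marker": r.variant_id,
                "pos": r.pos,
                "assoc_p": r.p,
                "width": width,
                "in_gene": spec.in_gene,
                "n_rv": spec.n_rv,
                "applicable": spec.applicable,
                "T": np.nan,
                "Z": np.nan,
                "p_asymptotic": np.nan,
                "p_permutation": np.nan,
            }
            if spec.applicable:
                G = windows.window_minor_dosage(matrix, spec)[complete]
                res = _stage(
                    f"calpha/{r.variant_id}/{width}",
                    calpha.run_window_test,
                    G,
                    status[complete],
                    cfg.permutations,
                    rng,
                    urn.make_urn_sampler(model) if cfg.use_urn else None,
                )
                rec.update(
                    T=res.T, Z=res.Z,
                    p_asymptotic=res.p_asymptotic, p_permutation=res.p_permutation,
                )
            rows.append(rec)
    window_results = pd.DataFrame(rows)
    comparisons = build_significance_tables(window_results, cfg.alpha, cfg.inapplicable_rule)

    paths = _write_reports(cfg, window_results, comparisons, qc_report, scan, model)
    return ReportBundle(
        window_results=window_results,
        comparisons=comparisons,
        qc_report=qc_report,
        scan=assoc.scan_to_frame(scan),
        paths=paths,
    )


def _write_reports(cfg, window_results, comparisons, qc_report, scan, model) -> dict[str, str]:
    os.makedirs(cfg.out_dir, exist_ok=True)
    paths = {
        "windows": os.path.join(cfg.out_dir, "window_results.tsv"),
        "comparisons": os.path.join(cfg.out_dir, "comparisons.tsv"),
        "qc": os.path.join(cfg.out_dir, "qc_report.tsv"),
        "scan": os.path.join(cfg.out_dir, "scan.tsv"),
        "log": os.path.join(cfg.out_dir, "run_log.txt"),
    }
    if not cfg.overwrite:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; set overwrite to replace it")

    wr = window_results.copy()
    for col in ("T", "Z", "p_asymptotic", "p_permutation", "assoc_p"):
        wr[col] = [_fmt(x) for x in wr[col]]
    wr.to_csv(paths["windows"], sep="\t", index=False)

    pd.DataFrame(
        {
            "width": [c.width for c in comparisons],
            "in_gene_sig": [c.counts[0] for c in comparisons],
            "in_gene_nonsig": [c.counts[1] for c in comparisons],
            "not_in_gene_sig": [c.counts[2] for c in comparisons],
            "not_in_gene_nonsig": [c.counts[3] for c in comparisons],
            "n_inapplicable": [c.n_inapplicable for c in comparisons],
            "alpha": [c.alpha for c in comparisons],
            "fisher_p": [_fmt(c.p) for c in comparisons],
        }
    ).to_csv(paths["comparisons"], sep="\t", index=False)

    qc_report.write(paths["qc"])
    assoc.scan_to_frame(scan).to_csv(paths["scan"], sep="\t", index=False, float_format="%.6g")

    import rarewin

    with open(paths["log"], "w") as fh:
        fh.write(f"rarewin {rarewin.__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write("config:\n")
        for k, v in vars(cfg).items():
            fh.write(f"  {k}: {v}\n")
        fh.write(f"urn subjects: {len(model.weights)}\n")
    return paths
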