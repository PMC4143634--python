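"""Readers/writers for the standard formats the pipeline touches.

Genotypes come in as VCF (parsed with cyvcf2), gene spans as BED, subjects as
TSV.  Everything is normalised into three in-memory containers:

* :class:`GenotypeMatrix` — subjects × variants ALT-allele dosage matrix
  (``numpy`` float array, ``nan`` = missing call) plus a variant table.
* :class:`GeneTrack` — gene intervals stored 1-based inclusive (BED's 0-based
  half-open coordinates are converted on import).
* :class:`SubjectTable` — covariates and per-visit binary indicators; the
  collapsed 1/2 affection/smoking/medication codes are filled in by the qc
  stage, not here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "GeneTrack",
    "SubjectTable",
    "read_vcf",
    "write_vcf",
    "read_gene_track",
    "read_subjects",
    "write_subjects",
    "SUBJECT_COLUMNS",
]

#: required column layout of the subject TSV (4 doctor visits)
SUBJECT_COLUMNS = (
    ["id", "sex", "age1"]
    + [f"htn_v{i}" for i in range(1, 5)]
    + [f"smoke_v{i}" for i in range(1, 5)]
    + [f"med_v{i}" for i in range(1, 5)]
)

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "n_alt_alleles"]


@dataclass
class GenotypeMatrix:
    """Subjects × variants ALT-dosage matrix with per-variant metadata.

    ``dosage[j, i]`` is the number of non-reference alleles carried by subject
    ``j`` at variant ``i`` (0, 1 or 2; ``nan`` for a missing call).  Variant
    records are ordered by (chrom, position).
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    subjects: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (subjects x variants)")
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if len(self.subjects) != len(set(self.subjects)):
            raise ValueError("duplicated subject ids")
        v = self.variants
        for chrom, grp in v.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not nondecreasing on {chrom}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, idx) -> "GenotypeMatrix":
        """Subset to the variant columns ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            subjects=list(self.subjects),
        )


@dataclass
class GeneTrack:
    """Gene intervals, 1-based inclusive after import. Overlaps permitted."""

    intervals: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        if len(self.intervals):
            bad = self.intervals["start"] > self.intervals["end"]
            if bad.any():
                raise ValueError("interval with start > end")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SubjectTable:
    """Subject covariates and per-visit indicators.

    ``df`` carries :data:`SUBJECT_COLUMNS`; the qc stage adds the collapsed
    ``affection`` / ``smoking`` / ``medication`` columns coded 2 = yes/affected,
    1 = no/unaffected, ``nan`` = missing.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUBJECT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"subject table missing columns: {missing}")
        ids = self.df["id"].astype(str)
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        sex = self.df["sex"]
        bad = ~(sex.isin(["M", "F"]) | sex.isna())
        if bad.any():
            raise ValueError(f"unknown sex codes: {sorted(sex[bad].unique())}")
        if not pd.api.types.is_numeric_dtype(self.df["age1"]):
            raise ValueError("age1 must be numeric")
        for col in ("affection", "smoking", "medication"):
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if not vals.isin([1, 2]).all():
                    raise ValueError(f"collapsed code {col} outside {{1,2,missing}}")

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].astype(str).tolist()


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields are converted to ALT-allele counts; phased and unphased
    separators are treated identically; any missing allele makes the call
    missing.  Multi-allelic records are retained with ``n_alt_alleles``
    recorded so the qc stage can exclude them.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicated subject ids in VCF header")
    rows = []
    dosage_cols = []
    for rec in vcf:
        alts = rec.ALT or []
        d = np.empty(len(samples), dtype=float)
        for j, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT at {rec.CHROM}:{rec.POS} sample {samples[j]}"
                )
            a, b = alleles
            if a < 0 or b < 0:
                d[j] = np.nan
            else:
                d[j] = (a > 0) + (b > 0)
        dosage_cols.append(d)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                rec.REF,
                ",".join(alts),
                len(alts),
            )
        )
    if rows:
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        dosage = np.column_stack(dosage_cols)
    else:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        dosage = np.empty((len(samples), 0))
    return GenotypeMatrix(dosage=dosage, variants=variants, subjects=samples)


def _gt_string(d: float) -> str:
    if np.isnan(d):
        return "./."
    k = int(round(d))
    return {0: "0/0", 1: "0/1", 2: "1/1"}[k]


def write_vcf(matrix: GenotypeMatrix, path, overwrite: bool = False) -> None:
    """Write a biallelic GenotypeMatrix as a minimal VCF 4.2 text file."""
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if (matrix.variants["n_alt_alleles"] > 1).any():
        raise ValueError("write_vcf only supports biallelic records")
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in matrix.variants["chrom"].unique():
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.subjects)
        + "\n"
    )
    for i, v in matrix.variants.iterrows():
        gts = "\t".join(_gt_string(d) for d in matrix.dosage[:, i])
        buf.write(
            f"{v.chrom}\t{int(v.pos)}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_gene_track(path) -> GeneTrack:
    """Read a BED (0-based half-open, >=4 columns) gene track.

    Coordinates are converted to 1-based inclusive: BED ``(start, end)``
    becomes ``[start+1, end]``.
    """
    try:
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start0", "end0", "gene_id"],
        )
    except pd.errors.EmptyDataError:
        return GeneTrack(
            intervals=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        )
    if (bed["start0"] >= bed["end0"]).any():
        raise ValueError("BED interval with start >= end")
    intervals = pd.DataFrame(
        {
            "gene_id": bed["gene_id"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start0"].astype(int) + 1,
            "end": bed["end0"].astype(int),
        }
    )
    return GeneTrack(intervals=intervals)


def read_subjects(path) -> SubjectTable:
    """Read the subject TSV (id, sex, age1, per-visit htn/smoke/med)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": "string"})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject TSV missing columns: {missing}")
    try:
        df["age1"] = pd.to_numeric(df["age1"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"nonnumeric age1: {exc}") from exc
    visit_cols = [c for c in SUBJECT_COLUMNS if "_v" in c]
    for c in visit_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
        vals = df[c].dropna()
        if not vals.isin([0, 1]).all():
            raise ValueError(f"visit indicator {c} outside {{0,1,missing}}")
    return SubjectTable(df=df[SUBJECT_COLUMNS].copy())


def write_subjects(subjects: SubjectTable, path, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    cols = [c for c in subjects.df.columns if c in SUBJECT_COLUMNS]
    subjects.df[cols].to_csv(path, sep="\t", index=False, na_rep="")
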