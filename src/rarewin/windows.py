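"""Rare-variant windows around index common variants.

A window is the closed interval ``[index_pos - half_width, index_pos +
half_width]`` on the index variant's chromosome.  Its members are the rare
variants (sample MAF < ``maf_max``) inside the interval, excluding the index
variant itself and excluding singletons (variants with exactly one
minor-allele copy in the whole sample, which carry no information for an
overdispersion test).  A window with fewer than two members is marked not
applicable and reported as "n/a" downstream.

Index markers are classified as in-gene when their position falls anywhere
within a gene's 5'-to-3' UTR span (boundaries inclusive), supplied as a gene
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geno_io import GeneTrack, GenotypeMatrix
from .qc import minor_allele_frequency

__all__ = ["WindowSpec", "classify_gene_membership", "extract_window", "window_minor_dosage"]


@dataclass
class WindowSpec:
    """One index variant, its half-width, and the member RVs passing filters."""

    index_id: str
    index_pos: int
    chrom: str
    half_width: int
    member_idx: np.ndarray  # column indices into the source matrix, by position
    minor_is_alt: np.ndarray  # bool per member: whether ALT is the minor allele
    n_rv: int
    in_gene: bool
    applicable: bool

    def __post_init__(self) -> None:
        self.member_idx = np.asarray(self.member_idx, dtype=int)
        self.minor_is_alt = np.asarray(self.minor_is_alt, dtype=bool)
        if self.n_rv != len(self.member_idx):
            raise ValueError("n_rv does not match member count")
        if self.applicable != (self.n_rv >= 2):
            raise ValueError("applicable must equal (n_rv >= 2)")


def classify_gene_membership(pos: int, track: GeneTrack, chrom: str | None = None) -> bool:
    """True iff ``pos`` lies inside any gene interval, boundaries inclusive."""
    iv = track.intervals
    if len(iv) == 0:
        return False
    if chrom is not None:
        iv = iv[iv["chrom"] == chrom]
    return bool(((iv["start"] <= pos) & (pos <= iv["end"])).any())


def extract_window(
    matrix: GenotypeMatrix,
    index_id: str,
    half_width_bp: int,
    maf_max: float = 0.05,
    track: GeneTrack | None = None,
) -> WindowSpec:
    """Build the rare-variant window around one index variant.

    Members must lie within ±``half_width_bp`` of the index position on the
    same chromosome, have MAF < ``maf_max``, and carry at least two
    minor-allele copies in the sample (singleton removal).
    """
    v = matrix.variants
    hits = np.where(v["id"].astype(str).to_numpy() == str(index_id))[0]
    if len(hits) == 0:
        raise KeyError(f"index variant {index_id!r} not found")
    idx = int(hits[0])
    index_pos = int(v["pos"].iloc[idx])
    chrom = str(v["chrom"].iloc[idx])

    pos = v["pos"].to_numpy()
    same_chrom = v["chrom"].astype(str).to_numpy() == chrom
    in_interval = same_chrom & (np.abs(pos - index_pos) <= half_width_bp)
    in_interval[idx] = False  # the index variant is never its own member

    members, minor_alt = [], []
    for j in np.where(in_interval)[0]:
        col = matrix.dosage[:, j]
        if np.isnan(col).all():
            continue
        maf, minor = minor_allele_frequency(col)
        if maf >= maf_max:
            continue
        copies = np.nansum(col) if minor == "alt" else np.nansum(2.0 - col)
        if copies < 2:  # monomorphic or singleton
            continue
        members.append(j)
        minor_alt.append(minor == "alt")

    order = np.argsort(pos[members], kind="stable") if members else np.array([], int)
    members = np.asarray(members, dtype=int)[order]
    minor_alt = np.asarray(minor_alt, dtype=bool)[order]
    in_gene = classify_gene_membership(index_pos, track, chrom) if track is not None else False
    return WindowSpec(
        index_id=str(index_id),
        index_pos=index_pos,
        chrom=chrom,
        half_width=int(half_width_bp),
        member_idx=members,
        minor_is_alt=minor_alt,
        n_rv=len(members),
        in_gene=in_gene,
        applicable=len(members) >= 2,
    )


def window_minor_dosage(matrix: GenotypeMatrix, spec: WindowSpec) -> np.ndarray:
    """Subjects × members matrix of minor-allele dosages for a window."""
    G = matrix.dosage[:, spec.member_idx].copy()
    flip = ~spec.minor_is_alt
    G[:, flip] = 2.0 - G[:, flip]
    return G
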