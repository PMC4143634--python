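"""Published benchmark results for the in-gene vs not-in-gene comparison.

A published chromosome-3 hypertension analysis of this design (ten index
markers — five inside genes, five outside — with rare-variant windows of 1, 5
and 25 kb tested by C-alpha under biased-urn permutation) reported one
permuted p-value per window; windows left with fewer than two rare variants
after singleton removal were reported as not applicable.  Those thirty window
outcomes are reproduced here as plain data so the downstream comparison stage
can be validated against the study's printed Fisher exact p-values (p = 1 for
the 5-kb windows and p = 0.5238 for the 25-kb windows at alpha = 0.05).

Only the window-level outcomes are carried; the study's marker and gene
identifiers are internal to its (non-public) source data and are not
reproduced.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_window_results"]

# (width_bp, in_gene, applicable, permuted p).  "<0.001" is carried as 0.0005,
# which only needs to sit on the correct side of alpha = 0.05.
_ROWS = [
    # index marker 1 (in gene)
    (1000, True, True, 0.090),
    (5000, True, True, 0.276),
    (25000, True, True, 0.629),
    # index marker 2 (in gene)
    (1000, True, True, 0.207),
    (5000, True, True, 0.437),
    (25000, True, True, 0.485),
    # index marker 3 (in gene)
    (1000, True, False, None),
    (5000, True, True, 0.070),
    (25000, True, True, 0.002),
    # index marker 4 (in gene)
    (1000, True, True, 0.367),
    (5000, True, True, 0.507),
    (25000, True, True, 0.329),
    # index marker 5 (in gene)
    (1000, True, False, None),
    (5000, True, True, 0.891),
    (25000, True, True, 0.658),
    # index marker 6 (not in gene)
    (1000, False, True, 0.008),
    (5000, False, True, 0.415),
    (25000, False, True, 0.935),
    # index marker 7 (not in gene)
    (1000, False, False, None),
    (5000, False, True, 0.091),
    (25000, False, True, 0.245),
    # index marker 8 (not in gene)
    (1000, False, True, 0.0005),
    (5000, False, True, 0.037),
    (25000, False, True, 0.041),
    # index marker 9 (not in gene)
    (1000, False, True, 0.407),
    (5000, False, True, 0.440),
    (25000, False, True, 0.009),
    # index marker 10 (not in gene)
    (1000, False, True, 0.227),
    (5000, False, True, 0.161),
    (25000, False, True, 0.030),
]


def published_window_results() -> pd.DataFrame:
    """The benchmark window outcomes as a build_significance_tables input."""
    df = pd.DataFrame(_ROWS, columns=["width", "in_gene", "applicable", "p_permutation"])
    df["p_permutation"] = df["p_permutation"].astype(float)
    return df
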