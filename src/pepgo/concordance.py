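"""Peptide vs. 16S class-abundance concordance (Pearson).

The peptide-derived class relative abundances and an OTU-derived class
table are aligned on the union of class labels (the ``Unclassified``
sink is excluded — 16S sees organisms, not peptides) and compared by
sample Pearson correlation, pooling class x time-point pairs across a
whole experiment by default.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InputError
from .taxonomy import UNCLASSIFIED


def align_classes(
    peptide_table: Mapping[str, float],
    otu_table: Mapping[str, float],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Align two class->fraction maps on their label union.

    Missing entries are zero; ``Unclassified`` is dropped from both.
    Returns ``(labels, peptide_values, otu_values)``.
    """
    labels = sorted(
        (set(peptide_table) | set(otu_table)) - {UNCLASSIFIED}
    )
    if not labels:
        raise InputError("no classes shared after dropping Unclassified")
    v1 = np.array([peptide_table.get(c, 0.0) for c in labels])
    v2 = np.array([otu_table.get(c, 0.0) for c in labels])
    return labels, v1, v2


def pearson_concordance(v1, v2) -> tuple[float, float, int]:
    """Sample Pearson r between aligned abundance vectors.

    Returns ``(r, p, n)`` with the two-sided p-value from the t
    distribution on n-2 degrees of freedom.  Requires n >= 3 and
    nonzero variance in both vectors.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise InputError("vectors must be aligned and one-dimensional")
    n = len(v1)
    if n < 3:
        raise InputError("need at least 3 paired observations")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise InputError("zero variance: correlation undefined")
    res = stats.pearsonr(v1, v2)
    return float(res.statistic), float(res.pvalue), n


def pooled_concordance(
    peptide_tables: Mapping[str, Mapping[str, float]],
    otu_tables: Mapping[str, Mapping[str, float]],
    min_fraction: float | None = None,
) -> tuple[float, float, int]:
    """Experiment-level concordance pooling class x time-point pairs.

    For every run present in both inputs, the class tables are aligned
    and the pairs concatenated, so ``n`` counts classes x pooled time
    points.  ``min_fraction`` optionally reproduces display-style
    filtering: a class enters only if it reaches the threshold in
    either source for that run.
    """
    shared = sorted(set(peptide_tables) & set(otu_tables))
    if not shared:
        raise InputError("no runs shared between peptide and OTU tables")
    xs, ys = [], []
    for run in shared:
        labels, v1, v2 = align_classes(peptide_tables[run], otu_tables[run])
        if min_fraction is not None:
            keep = (v1 >= min_fraction) | (v2 >= min_fraction)
            v1, v2 = v1[keep], v2[keep]
        xs.append(v1)
        ys.append(v2)
    return pearson_concordance(np.concatenate(xs), np.concatenate(ys))
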