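"""RNA-seq count normalization and expressed-gene filtering.

Counts are normalized as counts per million (CPM = count / library size x
1e6) with an optional log2(CPM + 1) transform. The expressed-gene filter
keeps a gene iff some experimental condition has CPM > 1 in at least half of
its samples (inclusive half for odd sizes, strict > 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class CountMatrix:
    """Non-negative integer counts (genes x samples) with per-sample conditions."""

    counts: pd.DataFrame
    conditions: pd.Series  # sample_id -> condition label

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        cond = pd.Series(self.conditions).reindex(self.counts.columns)
        if cond.isna().any():
            missing = list(self.counts.columns[cond.isna()])
            raise ValidationError(f"samples without a condition: {missing[:5]}")
        self.conditions = cond

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)


def cpm(counts: CountMatrix, log2: bool = False) -> ExpressionMatrix:
    """Counts-per-million normalization; log2 variant is log2(CPM + 1).

    Library sizes are column totals before any gene filtering; a zero-total
    sample is an error naming the sample.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total count")
    vals = counts.counts / totals * 1e6
    if log2:
        return ExpressionMatrix(np.log2(vals + 1.0), scale="log2")
    return ExpressionMatrix(vals, scale="linear")


def expressed_gene_filter(counts: CountMatrix, threshold: float = 1.0) -> list:
    """Genes with CPM > threshold in >= half the samples of some condition.

    "At least half" is inclusive (ceil(n/2) for odd n); the CPM comparison is
    strict.
    """
    cpm_vals = cpm(counts).values
    keep = np.zeros(len(cpm_vals), dtype=bool)
    for cond in pd.unique(counts.conditions):
        cols = counts.conditions.index[counts.conditions == cond]
        need = math.ceil(len(cols) / 2)
        n_pass = (cpm_vals[cols] > threshold).sum(axis=1)
        keep |= (n_pass >= need).to_numpy()
    return list(cpm_vals.index[keep])
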