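"""Typed containers shared by every stage of the pipeline.

All containers validate their invariants at construction time and raise
:class:`ValidationError` with a message naming the offending record, so that
malformed inputs are rejected at the boundary rather than deep inside an
analysis.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("linear", "log2")
TP53_STATUSES = ("wt", "mut")


class ValidationError(ValueError):
    """An input violated a container invariant."""


def _check_unique(ids, kind: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} IDs: {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    The scale ("linear" or "log2") is declared by the caller, never guessed:
    all rank-based downstream statistics are invariant to it, but fold changes
    and isoform ratios are not.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x for log2 input)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.power(2.0, self.values), scale="linear")

    def sample(self, sample_id) -> pd.Series:
        return self.values[sample_id]


@dataclass
class GeneSet:
    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set must have a non-empty name")
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} has zero genes")
        self.genes = tuple(self.genes)
        _check_unique(self.genes, f"gene (set {self.name!r})")


@dataclass
class GeneSetCollection:
    """Ordered, name-unique collection of gene sets (the GMT unit)."""

    sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed = {}
        for name, gs in self.sets.items():
            if not isinstance(gs, GeneSet):
                gs = GeneSet(name=name, genes=tuple(gs))
            if gs.name != name:
                raise ValidationError(f"set key {name!r} != set name {gs.name!r}")
            fixed[name] = gs
        self.sets = fixed

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list:
        return list(self.sets)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: TP53 status and overall survival.

    Survival time unit is months throughout the package (TCGA/HOVON
    convention); os_event = 1 means death observed, 0 means censored.
    """

    table: pd.DataFrame  # index: sample_id; columns: tp53_status, os_time, os_event, ...

    REQUIRED = ("tp53_status", "os_time", "os_event")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        bad = set(self.table["tp53_status"]) - set(TP53_STATUSES)
        if bad:
            raise ValidationError(
                f"unknown tp53_status token(s) {sorted(bad)}; expected {TP53_STATUSES}"
            )
        t = pd.to_numeric(self.table["os_time"], errors="coerce")
        if t.isna().any() or (t < 0).any():
            off = self.table.index[(t.isna()) | (t < 0)][0]
            raise ValidationError(f"negative or non-numeric os_time for sample {off!r}")
        ev = set(pd.unique(self.table["os_event"]))
        if not ev <= {0, 1}:
            raise ValidationError(f"os_event must be binary 0/1, got {sorted(ev)}")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def tp53_status(self) -> pd.Series:
        return self.table["tp53_status"]

    @property
    def os_time(self) -> pd.Series:
        return self.table["os_time"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.table["os_event"].astype(int)


ISOFORM_COLUMNS = ("TAp73", "dNp73", "TP53")


@dataclass
class IsoformTable:
    """Per-sample linear-scale expression of the TP73 isoforms and TP53."""

    table: pd.DataFrame  # index: sample_id; columns: TAp73, dNp73, TP53
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        _check_unique(self.table.index, "sample")
        missing = [c for c in ISOFORM_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"isoform table missing columns: {missing}")
        arr = self.table[list(ISOFORM_COLUMNS)].to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            i = int(np.argwhere(~np.isfinite(arr) | (arr < 0))[0][0])
            raise ValidationError(
                f"negative or non-finite isoform value for sample {self.table.index[i]!r}"
            )


@dataclass
class DoseResponseMatrix:
    """Two-drug dose grid of inhibition fractions.

    Rows follow doses_drug1, columns doses_drug2; both axes ascend and start
    at 0 so that row 0 / column 0 are the monotherapy margins and
    response[0, 0] is the untreated well.
    """

    doses_drug1: np.ndarray
    doses_drug2: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.doses_drug1 = np.asarray(self.doses_drug1, dtype=float)
        self.doses_drug2 = np.asarray(self.doses_drug2, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for name, d in (("drug1", self.doses_drug1), ("drug2", self.doses_drug2)):
            if d.ndim != 1 or len(d) < 2:
                raise ValidationError(f"{name} dose axis must be 1-D with >= 2 doses")
            if not np.all(np.diff(d) > 0):
                raise ValidationError(f"{name} doses must be strictly increasing")
            if d[0] != 0:
                raise ValidationError(f"{name} dose axis must start at 0 (monotherapy margin)")
        if self.response.shape != (len(self.doses_drug1), len(self.doses_drug2)):
            raise ValidationError(
                f"response shape {self.response.shape} does not match dose axes "
                f"({len(self.doses_drug1)}, {len(self.doses_drug2)})"
            )
        if np.any(~np.isfinite(self.response)) or np.any(
            (self.response < 0) | (self.response > 1)
        ):
            raise ValidationError("responses must be finite inhibition fractions in [0, 1]")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the discovery pipeline with their defaults.

    Defaults: top 20% quantile for signature truncation, ssGSEA weight
    exponent 0.75, average-linkage clustering cut at k=2, 1,000 bootstrap
    resamplings, 1,000 GSEA permutations, FDR 0.05 for panel selection and
    0.25 for GSEA significance.
    """

    signature_quantile: float = 0.20
    signature_q_threshold: float | None = None  # optional significance gate on the up list
    ssgsea_alpha: float = 0.75
    linkage: str = "ward"
    n_clusters: int = 2
    panel_q_threshold: float = 0.05
    bootstrap_b: int = 1000
    n_permutations: int = 1000
    gsea_q_threshold: float = 0.25
    min_set_coverage: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.signature_quantile <= 1:
            raise ValidationError("signature_quantile must be in (0, 1]")
        if self.bootstrap_b < 1:
            raise ValidationError("bootstrap_b must be >= 1")
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
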