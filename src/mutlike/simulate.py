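"""Seeded generators for synthetic AML cohorts with planted ground truth.

The generators emulate the statistical structure the discovery pipeline
assumes: two independent cohorts with ~10% TP53-mutant samples carrying an
up-regulated gene program, a hidden mut-like subgroup (~22% of wild-type
samples) sharing that program, exponential survival with hazard ordering
mut > mut-like > wt, isoform tables with an elevated dNp73/TAp73 ratio in
the planted subgroup, negative-binomial count matrices, and dose-response
grids under Bliss-null or planted-synergy regimes.

Every generator is a pure function of its parameters and seed; the planted
truth is serialized alongside each dataset.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    DoseResponseMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    IsoformTable,
    ValidationError,
)
from .counts import CountMatrix
from .synergy import MonotherapyFit

# Study-condition defaults: a 200-sample cohort of 2,000 genes with a
# 100-gene program shifted by 1.5 SD in mut and mut-like samples; ~10% of
# samples are TP53-mutant and ~22% of the wild-type samples are mut-like.
DEFAULT_N_SAMPLES = 200
DEFAULT_N_GENES = 2000
DEFAULT_FRAC_MUT = 0.10
DEFAULT_FRAC_MUTLIKE = 0.22
DEFAULT_N_PROGRAM = 100
DEFAULT_EFFECT = 1.5
DEFAULT_HR_MUT = 3.0
DEFAULT_HR_MUTLIKE = 2.0
DEFAULT_MEDIAN_OS_WT = 24.0   # months
DEFAULT_FOLLOW_UP = 120.0     # months of uniform censoring window


@dataclass
class SimulationTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    labels: dict = field(default_factory=dict)          # sample -> wt/mut-like/mut
    program_genes: list = field(default_factory=list)
    effect: float = 0.0
    hazard_ratios: dict = field(default_factory=dict)   # group -> HR vs wt
    isoform_ratio_means: dict = field(default_factory=dict)
    synergy: dict = field(default_factory=dict)
    planted_sets: list = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _plant_labels(n_samples, frac_mut, frac_mutlike_of_wt, rng, prefix="S"):
    n_mut = int(round(frac_mut * n_samples))
    n_wt = n_samples - n_mut
    n_mutlike = int(round(frac_mutlike_of_wt * n_wt))
    if n_mut < 2 or n_mutlike < 1 or n_wt - n_mutlike < 2:
        raise ValidationError(
            f"infeasible fractions for n={n_samples}: "
            f"mut={n_mut}, mut-like={n_mutlike}, wt={n_wt - n_mutlike}"
        )
    labels = np.array(["mut"] * n_mut + ["mut-like"] * n_mutlike + ["wt"] * (n_wt - n_mutlike))
    rng.shuffle(labels)
    sample_ids = [f"{prefix}{i:04d}" for i in range(n_samples)]
    return pd.Series(labels, index=sample_ids, name="planted")


def simulate_cohort(
    n_samples: int = DEFAULT_N_SAMPLES,
    n_genes: int = DEFAULT_N_GENES,
    frac_mut: float = DEFAULT_FRAC_MUT,
    frac_mutlike_of_wt: float = DEFAULT_FRAC_MUTLIKE,
    n_program_genes: int = DEFAULT_N_PROGRAM,
    effect: float = DEFAULT_EFFECT,
    seed: int = 0,
    hr_mut: float = DEFAULT_HR_MUT,
    hr_mutlike: float = DEFAULT_HR_MUTLIKE,
    median_os_wt: float = DEFAULT_MEDIAN_OS_WT,
    follow_up: float = DEFAULT_FOLLOW_UP,
    program_genes: list | None = None,
    sample_prefix: str = "S",
):
    """One synthetic cohort: expression, clinical table and planted truth.

    Expression is log-normal (log2 values Normal(mu_g, 1) with gene baselines
    mu_g ~ Normal(8, 2)); program genes are shifted up by ``effect`` SD in
    mut and mut-like samples. Survival is exponential with the planted
    hazard ordering and uniform censoring over the follow-up window.
    Returns (ExpressionMatrix [log2 scale], ClinicalTable, SimulationTruth).
    """
    if not (0 < frac_mut < 1 and 0 < frac_mutlike_of_wt < 1):
        raise ValidationError("fractions must lie in (0, 1)")
    if n_program_genes >= n_genes:
        raise ValidationError("n_program_genes must be < n_genes")
    rng = np.random.default_rng(seed)
    labels = _plant_labels(n_samples, frac_mut, frac_mutlike_of_wt, rng, prefix=sample_prefix)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if program_genes is None:
        program_genes = list(rng.choice(gene_ids, size=n_program_genes, replace=False))
    else:
        program_genes = list(program_genes)
        if not set(program_genes) <= set(gene_ids):
            raise ValidationError("program_genes must be drawn from the gene universe")
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    vals = rng.normal(baseline[:, None], 1.0, size=(n_genes, n_samples))
    prog_idx = pd.Index(gene_ids).get_indexer(program_genes)
    shifted = (labels != "wt").to_numpy()
    vals[np.ix_(prog_idx, np.where(shifted)[0])] += effect
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=labels.index), scale="log2"
    )

    hr = labels.map({"wt": 1.0, "mut-like": hr_mutlike, "mut": hr_mut}).to_numpy()
    lam = np.log(2.0) / median_os_wt * hr
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, follow_up, size=n_samples)
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "tp53_status": np.where(labels == "mut", "mut", "wt"),
                "os_time": os_time,
                "os_event": os_event,
            },
            index=labels.index,
        )
    )
    truth = SimulationTruth(
        labels=labels.to_dict(),
        program_genes=sorted(program_genes),
        effect=effect,
        hazard_ratios={"mut": hr_mut, "mut-like": hr_mutlike},
        seed=seed,
        params={
            "n_samples": n_samples,
            "n_genes": n_genes,
            "frac_mut": frac_mut,
            "frac_mutlike_of_wt": frac_mutlike_of_wt,
            "n_program_genes": n_program_genes,
            "median_os_wt": median_os_wt,
            "follow_up": follow_up,
        },
    )
    return expr, clinical, truth


def simulate_two_cohorts(seed: int = 0, **kwargs):
    """Two independent cohorts sharing the planted program gene list.

    Cohort-specific gene baselines are drawn independently; sub-seeds derive
    from ``seed``. Returns a list of (expr, clinical, truth) pairs.
    """
    rng = np.random.default_rng(seed)
    n_genes = kwargs.get("n_genes", DEFAULT_N_GENES)
    n_prog = kwargs.get("n_program_genes", DEFAULT_N_PROGRAM)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    program = list(rng.choice(gene_ids, size=n_prog, replace=False))
    out = []
    for c, prefix in enumerate(("A", "B")):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_cohort(
                seed=sub_seed, program_genes=program, sample_prefix=prefix, **kwargs
            )
        )
    return out


def simulate_gene_sets(
    n_decoys: int,
    planted: GeneSet,
    gene_universe: list,
    sizes=(15, 50),
    seed: int = 0,
    n_program_subsets: int = 0,
    subset_size: int = 30,
) -> GeneSetCollection:
    """Decoy gene sets plus the planted signature (and optional subsets).

    Decoys are drawn uniformly from non-program genes. With
    ``n_program_subsets`` > 0, additional sets are random subsets of the
    planted program, emulating a panel of mutually correlated differentially
    enriched programs (stem-cell / TP53-pathway sets in the cohort heatmap).
    """
    rng = np.random.default_rng(seed)
    non_program = sorted(set(gene_universe) - set(planted.genes))
    coll = GeneSetCollection()
    coll.add(planted)
    lo, hi = sizes
    if hi > len(non_program):
        raise ValidationError("decoy sizes exceed the non-program gene universe")
    for i in range(n_decoys):
        k = int(rng.integers(lo, hi + 1))
        genes = tuple(rng.choice(non_program, size=k, replace=False))
        coll.add(GeneSet(name=f"DECOY_{i:03d}", genes=genes, description="decoy"))
    k_sub = min(subset_size, len(planted.genes))
    for i in range(n_program_subsets):
        k = int(rng.integers(max(5, k_sub // 2), k_sub + 1))
        genes = tuple(rng.choice(planted.genes, size=k, replace=False))
        coll.add(
            GeneSet(name=f"PROGRAM_SUBSET_{i:02d}", genes=genes, description="program subset")
        )
    return coll


def simulate_isoforms(
    labels: pd.Series,
    ratio_high_mean: float = 4.0,
    ratio_low_mean: float = 1.0,
    sigma: float = 0.4,
    seed: int = 0,
) -> IsoformTable:
    """Log-normal isoform levels with a higher dNp73/TAp73 ratio planted in
    mut and mut-like samples.

    ``ratio_high_mean`` / ``ratio_low_mean`` are the geometric-mean ratios in
    the planted-high (mut, mut-like) and wt groups.
    """
    if ratio_high_mean <= 0 or ratio_low_mean <= 0:
        raise ValidationError("ratio means must be positive")
    rng = np.random.default_rng(seed)
    n = len(labels)
    high = (labels != "wt").to_numpy()
    tap73 = np.exp(rng.normal(np.log(10.0), sigma, size=n))
    ratio = np.where(high, ratio_high_mean, ratio_low_mean)
    dnp73 = tap73 * ratio * np.exp(rng.normal(0.0, sigma, size=n))
    tp53 = np.exp(rng.normal(np.log(10.0), sigma, size=n))
    return IsoformTable(
        pd.DataFrame(
            {"TAp73": tap73, "dNp73": dnp73, "TP53": tp53}, index=labels.index
        )
    )


def simulate_counts(
    n_genes: int = 2000,
    conditions: dict | None = None,
    mean_library_size: float = 1e6,
    de_fraction: float = 0.1,
    fold_change: float = 4.0,
    dispersion: float = 0.1,
    seed: int = 0,
):
    """Negative-binomial count matrix with planted fold changes.

    ``conditions`` maps condition label -> number of samples (default two
    conditions of 6). A ``de_fraction`` of genes is shifted by
    ``fold_change`` in the last condition. Returns (CountMatrix, truth dict).
    """
    conditions = conditions or {"ctrl": 6, "treat": 6}
    if len(conditions) < 1:
        raise ValidationError("need >= 1 condition")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    base_mean = np.exp(rng.normal(np.log(50.0), 1.5, size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    cond_names = list(conditions)
    cols, labels = [], []
    blocks = []
    for ci, cond in enumerate(cond_names):
        n_c = conditions[cond]
        mu = np.repeat(base_mean[:, None], n_c, axis=1)
        if ci == len(cond_names) - 1 and n_de:
            mu[de_idx] *= fold_change
        lib = rng.lognormal(0.0, 0.1, size=n_c)
        mu = mu * lib * (mean_library_size / (base_mean.sum()))
        r = 1.0 / dispersion
        p = r / (r + mu)
        blocks.append(rng.negative_binomial(r, p))
        cols += [f"{cond}_{i}" for i in range(n_c)]
        labels += [cond] * n_c
    counts = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=cols)
    cm = CountMatrix(counts=counts, conditions=pd.Series(labels, index=cols))
    truth = {
        "de_genes": sorted(np.array(gene_ids)[de_idx].tolist()),
        "fold_change": fold_change,
        "dispersion": dispersion,
        "seed": seed,
    }
    return cm, truth


# Partial-efficacy monotherapies: the Bliss surface then stays below ~0.82,
# leaving headroom so a planted +0.15 combination excess survives the [0, 1]
# response clip instead of being silently truncated at saturating doses.
DEFAULT_CURVE1 = dict(ymin=0.0, ymax=0.60, midpoint=1.0, slope=1.0)
DEFAULT_CURVE2 = dict(ymin=0.0, ymax=0.55, midpoint=0.5, slope=1.2)
DEFAULT_DOSES1 = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
DEFAULT_DOSES2 = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


def simulate_dose_matrix(
    regime: str = "bliss_null",
    delta: float = 0.15,
    curve1: dict | None = None,
    curve2: dict | None = None,
    doses1=DEFAULT_DOSES1,
    doses2=DEFAULT_DOSES2,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Dose-response grid under a Bliss-null or planted-synergy regime.

    Monotherapy margins follow the declared 4PL curves; under
    ``regime='planted_delta'`` every combination well gains ``delta``
    (clipped to [0, 1]). Optional Gaussian noise is clipped likewise.
    Returns (DoseResponseMatrix, truth dict).
    """
    if regime not in ("bliss_null", "planted_delta"):
        raise ValidationError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    c1 = MonotherapyFit(**{**DEFAULT_CURVE1, **(curve1 or {})}, residual=0.0)
    c2 = MonotherapyFit(**{**DEFAULT_CURVE2, **(curve2 or {})}, residual=0.0)
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    y1 = c1.predict(d1)
    y2 = c2.predict(d2)
    resp = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    if regime == "planted_delta":
        comb = np.ix_(np.where(d1 > 0)[0], np.where(d2 > 0)[0])
        resp[comb] = resp[comb] + delta
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    resp = np.clip(resp, 0.0, 1.0)
    matrix = DoseResponseMatrix(d1, d2, resp)
    truth = {
        "regime": regime,
        "delta": delta if regime == "planted_delta" else 0.0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return matrix, truth
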