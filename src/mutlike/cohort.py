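"""Cross-cohort signature derivation and mut-like subgroup calling.

The discovery chain: per-cohort differential expression of TP53-mutant versus
wild-type samples (Mann-Whitney + Benjamini-Hochberg), intersection of the
per-cohort top-quantile up-regulated genes into a signature, ssGSEA
projection on a gene-set panel, panel selection by differential enrichment,
sample clustering on Spearman correlation of enrichment profiles, calling of
the mut-anchored cluster, and bootstrap validation of group enrichment
differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .datatypes import (
    AnalysisConfig,
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)
from .enrichment import ESMatrix, ssgsea_project
from .stats import bh_adjust

log = logging.getLogger("mutlike")

SIGNATURE_NAME = "TP53_AML_SIGNATURE"


class PipelineError(ValueError):
    pass


def _split_groups(expr: ExpressionMatrix, status: pd.Series):
    status = status.reindex(expr.sample_ids)
    if status.isna().any():
        missing = status.index[status.isna()].tolist()
        raise PipelineError(f"tp53_status missing for samples {missing[:5]}")
    mut = status.index[status == "mut"]
    wt = status.index[status == "wt"]
    if len(mut) < 2 or len(wt) < 2:
        raise PipelineError(
            f"need >= 2 samples per group, got mut={len(mut)}, wt={len(wt)}"
        )
    return mut, wt


def differential_expression(expr: ExpressionMatrix, status: pd.Series) -> pd.DataFrame:
    """Per-gene Mann-Whitney differential expression, mut versus wt.

    Returns a DataFrame indexed by gene with log2 fold change of group means
    (pseudocount 1 on the linear scale), the U statistic, two-sided p
    (exact enumeration when both groups have <= 8 samples, otherwise the
    tie-corrected normal approximation) and Benjamini-Hochberg q.
    """
    mut, wt = _split_groups(expr, status)
    lin = expr.to_linear().values
    x = lin[mut].to_numpy(dtype=float)  # genes x n_mut
    y = lin[wt].to_numpy(dtype=float)
    method = "exact" if max(x.shape[1], y.shape[1]) <= 8 else "asymptotic"
    res = mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
    lfc = np.log2(x.mean(axis=1) + 1.0) - np.log2(y.mean(axis=1) + 1.0)
    p = np.minimum(res.pvalue, 1.0)
    df = pd.DataFrame(
        {
            "log2fc": lfc,
            "u_stat": res.statistic,
            "p": p,
            "q": bh_adjust(p),
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=expr.values.index,
    )
    return df


@dataclass
class SignatureDerivation:
    """Provenance of a derived signature: per-cohort tables and top sets."""

    de_tables: list
    per_cohort_top: list
    signature: GeneSet
    quantile: float
    q_threshold: float | None


def derive_signature(
    de_tables: list,
    quantile: float = 0.20,
    q_threshold: float | None = None,
    name: str = SIGNATURE_NAME,
) -> SignatureDerivation:
    """Intersect the per-cohort top-quantile up-regulated genes.

    Per cohort the up-regulated genes (log2fc > 0, optionally gated at BH
    q < ``q_threshold``) are ranked by fold change and truncated to the top
    ``quantile`` fraction; the signature is the intersection across cohorts.
    An empty intersection is a valid (warned) result.
    """
    if len(de_tables) < 2:
        raise PipelineError("signature derivation needs >= 2 cohorts")
    if not 0 < quantile <= 1:
        raise PipelineError("quantile must be in (0, 1]")
    tops = []
    for de in de_tables:
        up = de[de["log2fc"] > 0]
        if q_threshold is not None:
            up = up[up["q"] < q_threshold]
        up = up.sort_values(["log2fc", "p"], ascending=[False, True])
        n_keep = int(np.ceil(quantile * len(up)))
        tops.append(set(up.index[:n_keep]))
    inter = set.intersection(*tops) if tops else set()
    if not inter:
        log.warning("derive_signature: empty intersection across cohorts")
        sig = None
    else:
        sig = GeneSet(name=name, genes=tuple(sorted(inter)), description="derived signature")
    return SignatureDerivation(
        de_tables=de_tables,
        per_cohort_top=tops,
        signature=sig,
        quantile=quantile,
        q_threshold=q_threshold,
    )


def derive_signature_from_cohorts(
    cohorts: list,
    quantile: float = 0.20,
    q_threshold: float | None = None,
) -> SignatureDerivation:
    """Run DE per (ExpressionMatrix, ClinicalTable) cohort, then intersect."""
    de_tables = [
        differential_expression(expr, clin.tp53_status) for expr, clin in cohorts
    ]
    return derive_signature(de_tables, quantile=quantile, q_threshold=q_threshold)


def select_differential_gene_sets(
    es: ESMatrix, status: pd.Series, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-set Mann-Whitney (mut vs wt) on enrichment scores, BH across sets.

    Returns one row per set with p, q, direction and a ``retained`` flag at
    the configured BH threshold.
    """
    status = status.reindex(es.sample_ids)
    mut_cols = [s for s, st in status.items() if st == "mut"]
    wt_cols = [s for s, st in status.items() if st == "wt"]
    if len(mut_cols) < 2 or len(wt_cols) < 2:
        raise PipelineError("panel selection needs >= 2 samples per status group")
    x = es.values[mut_cols].to_numpy()
    y = es.values[wt_cols].to_numpy()
    res = mannwhitneyu(x, y, axis=1, alternative="two-sided", method="asymptotic")
    p = np.minimum(res.pvalue, 1.0)
    q = bh_adjust(p)
    direction = np.where(x.mean(axis=1) > y.mean(axis=1), "up", "down")
    return pd.DataFrame(
        {"p": p, "q": q, "direction": direction, "retained": q < q_threshold},
        index=es.values.index,
    )


def cluster_samples(
    es_panel: pd.DataFrame,
    k: int = 2,
    linkage: str = "ward",
    standardize: bool = True,
):
    """Hierarchically cluster samples on 1 - Spearman of their ES profiles.

    Each set's scores are z-scored across samples first (the heatmap
    convention: without row scaling, uniformly shifted sets carry no profile
    shape). Returns (cluster labels as a Series of 1..k, scipy linkage
    matrix).
    """
    if es_panel.shape[0] < 2:
        raise PipelineError("clustering needs >= 2 panel gene sets")
    if es_panel.shape[1] < k:
        raise PipelineError(f"clustering needs >= k={k} samples")
    mat = es_panel.to_numpy(dtype=float)
    if standardize:
        sd = mat.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = es_panel.index[np.argmax(sd == 0)]
            raise PipelineError(f"gene set {bad!r} has constant ES; cannot standardize")
        mat = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    # Spearman between sample profiles: rank each sample's profile over sets
    ranks = np.apply_along_axis(rankdata, 0, mat)
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        bad = es_panel.columns[np.argmax(sd == 0)]
        raise PipelineError(f"sample {bad!r} has a constant ES profile; Spearman undefined")
    corr = np.corrcoef(ranks, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=es_panel.columns, name="cluster"), z


@dataclass
class MutLikeResult:
    """Per-sample three-way call with its provenance.

    ``labels`` maps each sample to wt / mut-like / mut; status-mut samples
    are always labeled mut, and mut-like samples are the status-wt members of
    the cluster most enriched for status-mut samples.
    """

    labels: pd.Series
    clusters: pd.Series
    mut_cluster: int
    signature_es: pd.Series | None = None
    bootstrap: dict | None = None
    config: dict = field(default_factory=dict)

    @property
    def mutlike_fraction_of_wt(self) -> float:
        wt_status = self.labels[self.labels != "mut"]
        if len(wt_status) == 0:
            return float("nan")
        return float((wt_status == "mut-like").mean())

    def summary(self) -> dict:
        counts = self.labels.value_counts().to_dict()
        return {
            "n_samples": int(len(self.labels)),
            "counts": {k: int(v) for k, v in counts.items()},
            "mut_cluster": int(self.mut_cluster),
            "mutlike_fraction_of_wt": self.mutlike_fraction_of_wt,
        }


def call_mutlike(
    clusters: pd.Series,
    clinical: ClinicalTable,
    tie_break: str | None = None,
) -> MutLikeResult:
    """Label samples wt / mut-like / mut from cluster membership.

    The cluster with the highest fraction of status-mut samples anchors the
    call; its status-wt members become mut-like. A tie in mut fraction is an
    error unless ``tie_break='lowest'`` resolves it to the lowest cluster ID.
    """
    status = clinical.tp53_status.reindex(clusters.index)
    if status.isna().any():
        missing = clusters.index[status.isna()].tolist()
        raise PipelineError(f"tp53_status missing for samples {missing[:5]}")
    if (status == "mut").sum() == 0:
        raise PipelineError("no status-mut samples: no anchor cluster exists")
    frac = (
        pd.DataFrame({"cluster": clusters, "mut": (status == "mut").astype(float)})
        .groupby("cluster")["mut"]
        .mean()
        .sort_index()
    )
    top = frac[frac == frac.max()]
    if len(top) > 1:
        if tie_break == "lowest":
            mut_cluster = int(top.index.min())
            log.warning("call_mutlike: mut-fraction tie resolved to cluster %d", mut_cluster)
        else:
            raise PipelineError(
                f"tie in mut fraction between clusters {top.index.tolist()}; "
                "set tie_break='lowest' to resolve"
            )
    else:
        mut_cluster = int(top.index[0])
    labels = pd.Series("wt", index=clusters.index, name="label")
    labels[(clusters == mut_cluster) & (status == "wt")] = "mut-like"
    labels[status == "mut"] = "mut"
    return MutLikeResult(labels=labels, clusters=clusters, mut_cluster=mut_cluster)


def bootstrap_es(
    es_row: pd.Series,
    labels: pd.Series,
    b: int = 1000,
    seed: int = 0,
) -> dict:
    """Within-group bootstrap of signature enrichment (B resamplings).

    For every label group: mean ES with 2.5/97.5 percentile CI. For every
    ordered group pair: the apparent mean difference and its Harrell-style
    optimism-corrected value (apparent difference minus the mean excess of
    the bootstrap difference over the apparent one).
    """
    if b < 100:
        log.warning("bootstrap_es: B=%d is small for percentile CIs", b)
    labels = labels.reindex(es_row.index)
    groups = {}
    for g in sorted(labels.dropna().unique()):
        vals = es_row[labels == g].to_numpy(dtype=float)
        if len(vals) < 3:
            raise PipelineError(f"group {g!r} has < 3 samples; cannot bootstrap")
        groups[g] = vals
    if len(groups) < 2:
        raise PipelineError("bootstrap needs >= 2 groups")
    rng = np.random.default_rng(seed)
    boot_means = {}
    out = {"b": b, "seed": seed, "groups": {}, "differences": {}}
    for g, vals in groups.items():
        idx = rng.integers(0, len(vals), size=(b, len(vals)))
        bm = vals[idx].mean(axis=1)
        boot_means[g] = bm
        out["groups"][g] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "boot_mean": float(bm.mean()),
            "ci_low": float(np.percentile(bm, 2.5)),
            "ci_high": float(np.percentile(bm, 97.5)),
        }
    names = list(groups)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            apparent = float(groups[g1].mean() - groups[g2].mean())
            boot_diff = boot_means[g1] - boot_means[g2]
            optimism = float(np.mean(boot_diff - apparent))
            out["differences"][f"{g1} - {g2}"] = {
                "apparent": apparent,
                "optimism": optimism,
                "corrected": apparent - optimism,
                "ci_low": float(np.percentile(boot_diff, 2.5)),
                "ci_high": float(np.percentile(boot_diff, 97.5)),
            }
    return out


def classify_cohort(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
    signature_name: str = SIGNATURE_NAME,
) -> MutLikeResult:
    """End-to-end subgroup call on one cohort.

    Projects the collection by ssGSEA, retains the differentially enriched
    panel, clusters samples on Spearman profile correlation, anchors the
    mut cluster, and bootstraps the signature ES across the called groups
    (when the signature set is part of the collection).
    """
    config = config or AnalysisConfig()
    es = ssgsea_project(
        expr, collection, alpha=config.ssgsea_alpha, min_genes=config.min_set_coverage
    )
    panel = select_differential_gene_sets(
        es, clinical.tp53_status, q_threshold=config.panel_q_threshold
    )
    retained = panel.index[panel["retained"]]
    if len(retained) < 2:
        log.warning(
            "classify_cohort: %d set(s) retained at q<%g; clustering on full collection",
            len(retained),
            config.panel_q_threshold,
        )
        retained = es.values.index
    clusters, _tree = cluster_samples(
        es.values.loc[retained], k=config.n_clusters, linkage=config.linkage
    )
    result = call_mutlike(clusters, clinical)
    if signature_name in es.values.index:
        result.signature_es = es.values.loc[signature_name]
        result.bootstrap = bootstrap_es(
            result.signature_es,
            result.labels,
            b=config.bootstrap_b,
            seed=config.seed,
        )
    result.config = config.to_dict()
    return result
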