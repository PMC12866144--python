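"""Single-sample GSEA and preranked GSEA, implemented from first principles.

ssGSEA (Barbie-style) scores one sample against one gene set: genes are
ranked by within-sample expression, rank values 1..N are weighted by
|rank|**alpha, and the enrichment score is the sum over all list positions of
the difference between the weighted in-set cumulative distribution and the
unweighted out-of-set cumulative distribution.

Preranked GSEA scores a signed, externally ranked gene list (e.g. fold
changes) with the weighted Kolmogorov-Smirnov running-sum statistic; the
null is gene-label permutation (random sets of matching size), from which a
normalized enrichment score (NES), a nominal p and an FDR q over the
collection are derived.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, GeneSetCollection

log = logging.getLogger("mutlike")

DEFAULT_ALPHA = 0.75  # ssGSEA weight exponent (GenePattern ssGSEAProjection default)


class EnrichmentError(ValueError):
    pass


@dataclass
class RankedList:
    """Genes ordered by a ranking score, highest first.

    ``scores`` is the ranking metric aligned with ``genes``. For ssGSEA these
    are within-sample rank values (1..N, N = highest expression); for
    preranked GSEA they are signed metrics such as log2 fold changes. Ties in
    the underlying metric receive the average rank value and are ordered
    deterministically by gene ID.
    """

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise EnrichmentError("genes and scores must be aligned")
        if len(np.unique(self.genes)) != len(self.genes):
            raise EnrichmentError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise EnrichmentError("ranking scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise EnrichmentError("scores must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_transform(values: pd.Series) -> RankedList:
    """Rank one sample's expression for ssGSEA scoring.

    Returns genes in descending expression order with rank values 1..N
    (N assigned to the highest expression). Tied expression values share
    their average rank and are ordered by gene ID; an all-constant sample
    degenerates to lexicographic gene order with a warning.
    """
    vals = values.to_numpy(dtype=float)
    genes = values.index.to_numpy()
    if np.all(vals == vals[0]):
        log.warning("rank_transform: all-constant sample; using lexicographic gene order")
    ranks = rankdata(vals, method="average")  # 1 = lowest, N = highest
    # descending expression, ties broken by ascending gene ID
    order = np.lexsort((genes, -vals))
    return RankedList(genes=genes[order], scores=ranks[order])


def ssgsea_score(ranked: RankedList, genes, alpha: float = DEFAULT_ALPHA) -> float:
    """ssGSEA enrichment score of one gene set against one ranked sample.

    ES = sum_i (P_in(i) - P_out(i)) where P_in is the |rank|**alpha-weighted
    cumulative fraction of in-set genes down the list and P_out the
    unweighted cumulative fraction of out-of-set genes.
    """
    member = np.isin(ranked.genes, list(genes))
    k = int(member.sum())
    n = len(ranked)
    if k == 0:
        raise EnrichmentError("gene set has no overlap with the ranked list")
    if k == n:
        raise EnrichmentError("gene set equals the gene universe; P_out undefined")
    w = np.where(member, np.abs(ranked.scores) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~member) / (n - k)
    return float(np.sum(p_in - p_out))


@dataclass
class ESMatrix:
    """Gene sets x samples enrichment scores with scoring metadata."""

    values: pd.DataFrame
    alpha: float
    normalization: str = "none"

    @property
    def set_names(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def ssgsea_project(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = 1,
    normalize: bool = False,
) -> ESMatrix:
    """Project an expression matrix onto a gene-set collection.

    Sets whose overlap with the matrix genes falls below ``min_genes`` are
    dropped with a warning. With ``normalize=True`` scores are divided by the
    range of the full ES matrix (GenePattern's normalized-ES convention).
    """
    gene_index = pd.Index(expr.gene_ids)
    n = len(gene_index)
    usable: list = []
    members: list = []
    for gs in collection:
        mask = gene_index.isin(gs.genes).astype(bool)
        k = int(mask.sum())
        if k < min_genes or k == n:
            log.warning(
                "ssgsea_project: dropping set %r (coverage %d of %d)", gs.name, k, n
            )
            continue
        usable.append(gs.name)
        members.append(mask)
    if not usable:
        raise EnrichmentError("no usable gene sets after coverage filtering")
    member_mat = np.vstack(members)  # sets x genes, in matrix gene order
    set_sizes = member_mat.sum(axis=1)

    vals = expr.values.to_numpy(dtype=float)
    genes = gene_index.to_numpy()
    out = np.empty((len(usable), vals.shape[1]))
    for j in range(vals.shape[1]):
        col = vals[:, j]
        ranks = rankdata(col, method="average")
        order = np.lexsort((genes, -col))
        w_all = np.abs(ranks[order]) ** alpha
        mem = member_mat[:, order]  # sets x positions
        w_in = mem * w_all
        p_in = np.cumsum(w_in, axis=1) / w_in.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~mem, axis=1) / (n - set_sizes)[:, None]
        out[:, j] = np.sum(p_in - p_out, axis=1)
    norm = "none"
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
        norm = "minmax"
    return ESMatrix(
        pd.DataFrame(out, index=usable, columns=expr.sample_ids),
        alpha=alpha,
        normalization=norm,
    )


@dataclass
class GseaResult:
    """Preranked GSEA result for one gene set."""

    name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int
    n_perm: int
    seed: int | None = None


def _running_es(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Signed maximum deviation of the GSEA running sum.

    ``positions`` are 0-based hit positions (sorted), ``weights`` the
    |score|**p weights at those positions.
    """
    k = len(positions)
    wsum = weights.sum()
    if wsum == 0:  # all-zero scores in set: fall back to unweighted hits
        inc = np.full(k, 1.0 / k)
    else:
        inc = weights / wsum
    miss = 1.0 / (n - k)
    cum_in = np.cumsum(inc)
    j = np.arange(k)
    # running sum right after each hit, and right before each hit
    after = cum_in - (positions - j) * miss
    before = np.concatenate(([0.0], cum_in[:-1])) - (positions - j) * miss
    hi_idx = int(np.argmax(after))
    hi = float(after[hi_idx])
    lo_idx = int(np.argmin(before))
    lo = min(float(before[lo_idx]), 0.0)
    # magnitude tie (to rounding): the extreme reached first down the list wins
    tol = 1e-12 * max(1.0, hi, -lo)
    if hi - (-lo) > tol:
        return hi
    if (-lo) - hi > tol:
        return lo
    return lo if positions[lo_idx] - 1 < positions[hi_idx] else hi


def _null_es(
    scores: np.ndarray, k: int, n_perm: int, rng: np.random.Generator, weight: float
) -> np.ndarray:
    """Null ES distribution from random gene sets of size k (label permutation)."""
    n = len(scores)
    absw = np.abs(scores) ** weight
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        out[b] = _running_es(pos, absw[pos], n)
    return out


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with gene-set permutation null.

    Returns one row per set: ES, NES (ES over the mean |null ES| of matching
    sign), nominal p (one-sided null exceedance over all permutations) and
    FDR q computed over the collection from the normalized null and observed
    NES distributions, clipped to [0, 1].
    """
    if n_perm < 100:
        log.warning("preranked_gsea: n_perm=%d is small; p-value resolution is coarse", n_perm)
    n = len(ranked)
    absw = np.abs(ranked.scores) ** weight
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}

    rows = []
    null_nes_all: list = []
    rng = np.random.default_rng(seed)
    for gs in collection:
        pos = np.sort([gene_pos[g] for g in gs.genes if g in gene_pos])
        k = len(pos)
        if k == 0:
            raise EnrichmentError(f"set {gs.name!r} has no overlap with the ranked list")
        if k >= n:
            raise EnrichmentError(f"set {gs.name!r} is not smaller than the gene universe")
        es = _running_es(np.asarray(pos), absw[pos], n)
        null = _null_es(ranked.scores, k, n_perm, rng, weight)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        if es >= 0:
            p = float(np.mean(null >= es))
            nes = es / mean_pos if mean_pos and np.isfinite(mean_pos) else np.nan
        else:
            p = float(np.mean(null <= es))
            nes = es / mean_neg if mean_neg and np.isfinite(mean_neg) else np.nan
        null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        rows.append(dict(name=gs.name, es=es, nes=nes, p=p, size=k))

    df = pd.DataFrame(rows).set_index("name")
    all_null = np.concatenate(null_nes_all)
    obs = df["nes"].to_numpy()
    q = np.empty(len(df))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = np.nan
            continue
        if nes >= 0:
            num = np.mean(all_null >= nes) if len(all_null) else np.nan
            den = np.mean(obs[np.isfinite(obs)] >= nes)
        else:
            num = np.mean(all_null <= nes) if len(all_null) else np.nan
            den = np.mean(obs[np.isfinite(obs)] <= nes)
        q[i] = min(1.0, num / den) if den > 0 else np.nan
    df["fdr_q"] = q
    df["n_perm"] = n_perm
    df["seed"] = seed
    return df


def preranked_gsea_single(
    ranked: RankedList,
    genes,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    name: str = "set",
) -> GseaResult:
    """Convenience wrapper scoring a single gene set."""
    from .datatypes import GeneSet, GeneSetCollection

    coll = GeneSetCollection({name: GeneSet(name=name, genes=tuple(genes))})
    df = preranked_gsea(ranked, coll, n_perm=n_perm, seed=seed, weight=weight)
    row = df.loc[name]
    return GseaResult(
        name=name,
        es=float(row["es"]),
        nes=float(row["nes"]),
        p=float(row["p"]),
        fdr_q=float(row["fdr_q"]),
        size=int(row["size"]),
        n_perm=n_perm,
        seed=seed,
    )
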