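"""Discovery chain: DE, signature, panel selection, clustering, calling."""
import numpy as np
import pandas as pd
import pytest

from mutlike.cohort import (
    PipelineError,
    bootstrap_es,
    call_mutlike,
    cluster_samples,
    derive_signature,
    differential_expression,
    select_differential_gene_sets,
)
from mutlike.datatypes import ClinicalTable, ExpressionMatrix
from mutlike.enrichment import ESMatrix


def _expr(values, genes, samples, scale="linear"):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)


def _clinical(status, times=None, events=None):
    n = len(status)
    return ClinicalTable(
        pd.DataFrame(
            {
                "tp53_status": status,
                "os_time": times if times is not None else np.ones(n),
                "os_event": events if events is not None else np.ones(n, dtype=int),
            },
            index=[f"s{i}" for i in range(n)],
        )
    )


# ---------- differential expression ----------------------------------------

def test_de_exact_enumeration_hand_case():
    """mut (1,2) vs wt (3,4): U=0, exact two-sided p = 2/C(4,2) = 1/3."""
    expr = _expr([[1.0, 2.0, 3.0, 4.0]], ["g"], [f"s{i}" for i in range(4)])
    status = pd.Series(["mut", "mut", "wt", "wt"], index=expr.sample_ids)
    de = differential_expression(expr, status)
    assert de.loc["g", "u_stat"] == 0
    assert de.loc["g", "p"] == pytest.approx(1 / 3)
    assert de.loc["g", "direction"] == "down"


def test_de_identical_groups_mid_u_and_p_one():
    vals = np.tile([5.0, 1.0, 5.0, 1.0], (3, 1))
    expr = _expr(vals, ["g1", "g2", "g3"], [f"s{i}" for i in range(4)])
    status = pd.Series(["mut", "mut", "wt", "wt"], index=expr.sample_ids)
    de = differential_expression(expr, status)
    assert (de["u_stat"] == 2 * 2 / 2).all()
    assert np.allclose(de["p"], 1.0)


def test_de_rejects_tiny_groups():
    expr = _expr([[1.0, 2.0, 3.0]], ["g"], ["s0", "s1", "s2"])
    status = pd.Series(["mut", "wt", "wt"], index=expr.sample_ids)
    with pytest.raises(PipelineError, match=">= 2 samples"):
        differential_expression(expr, status)


# ---------- signature derivation --------------------------------------------

def _de_table(genes, lfc, q=None):
    df = pd.DataFrame(
        {
            "log2fc": lfc,
            "u_stat": 0.0,
            "p": 0.001,
            "q": q if q is not None else 0.001,
            "direction": np.where(np.asarray(lfc) > 0, "up", "down"),
        },
        index=genes,
    )
    return df


def test_signature_is_intersection_of_top_sets():
    # top 3 of 4 up-genes per cohort at quantile 0.75: {A,B,C} and {B,C,D}
    de1 = _de_table(["A", "B", "C", "X"], [4.0, 3.0, 2.0, 1.0])
    de2 = _de_table(["B", "C", "D", "Y"], [4.0, 3.0, 2.0, 1.0])
    deriv = derive_signature([de1, de2], quantile=0.75)
    assert set(deriv.signature.genes) == {"B", "C"}
    assert all(set(deriv.signature.genes) <= top for top in deriv.per_cohort_top)


def test_signature_quantile_one_keeps_all_up_genes():
    de1 = _de_table(["A", "B", "D"], [2.0, 1.0, -1.0])
    de2 = _de_table(["A", "B", "E"], [1.0, 2.0, -2.0])
    deriv = derive_signature([de1, de2], quantile=1.0)
    assert set(deriv.signature.genes) == {"A", "B"}


def test_signature_empty_intersection_is_valid_warned(caplog):
    de1 = _de_table(["A"], [2.0])
    de2 = _de_table(["B"], [2.0])
    with caplog.at_level("WARNING", logger="mutlike"):
        deriv = derive_signature([de1, de2])
    assert deriv.signature is None
    assert any("empty intersection" in r.message for r in caplog.records)


def test_signature_recall_on_planted_program(two_cohorts, signature):
    """Cross-cohort derivation recalls >= 80% of the planted up-program."""
    truth = two_cohorts[0][2]
    planted = set(truth.program_genes)
    got = set(signature.signature.genes)
    recall = len(got & planted) / len(planted)
    assert recall >= 0.8


def test_signature_cohort_order_equivariance(two_cohorts):
    from mutlike.cohort import derive_signature_from_cohorts

    pairs = [(e, c) for e, c, _ in two_cohorts]
    fwd = derive_signature_from_cohorts(pairs)
    rev = derive_signature_from_cohorts(pairs[::-1])
    assert fwd.signature.genes == rev.signature.genes


# ---------- panel selection --------------------------------------------------

def test_select_single_set_bh_equals_raw_p():
    rng = np.random.default_rng(0)
    es = ESMatrix(
        pd.DataFrame(rng.normal(size=(1, 30)), index=["S"], columns=[f"s{i}" for i in range(30)]),
        alpha=0.75,
    )
    status = pd.Series(["mut"] * 10 + ["wt"] * 20, index=es.sample_ids)
    sel = select_differential_gene_sets(es, status)
    assert sel.loc["S", "q"] == pytest.approx(sel.loc["S", "p"])


def test_select_retains_planted_set_controls_decoys():
    rng = np.random.default_rng(1)
    n = 60
    decoys = rng.normal(size=(50, n))
    planted = rng.normal(size=n) + np.r_[np.full(12, 1.5), np.zeros(n - 12)]
    es = ESMatrix(
        pd.DataFrame(
            np.vstack([planted, decoys]),
            index=["PLANTED"] + [f"D{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(n)],
        ),
        alpha=0.75,
    )
    status = pd.Series(["mut"] * 12 + ["wt"] * (n - 12), index=es.sample_ids)
    sel = select_differential_gene_sets(es, status)
    assert sel.loc["PLANTED", "retained"]
    assert sel.loc[[f"D{i}" for i in range(50)], "retained"].sum() <= 3


def test_select_null_calibration_under_shuffled_labels():
    rng = np.random.default_rng(2)
    es = ESMatrix(
        pd.DataFrame(
            rng.normal(size=(40, 50)),
            index=[f"S{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(50)],
        ),
        alpha=0.75,
    )
    retained = 0
    for rep in range(20):
        status = pd.Series(
            rng.permutation(["mut"] * 10 + ["wt"] * 40), index=es.sample_ids
        )
        retained += select_differential_gene_sets(es, status)["retained"].sum()
    # BH at 5% over pure-null sets: a handful of rejections over 800 tests
    assert retained <= 0.05 * 40 * 20


# ---------- clustering --------------------------------------------------------

def test_cluster_recovers_separable_blocks():
    rng = np.random.default_rng(4)
    v = rng.normal(0, 1, 10)
    v -= v.mean()
    block_a = np.tile(v[:, None], (1, 6))
    block_b = np.tile(-v[:, None], (1, 6))
    es = pd.DataFrame(
        np.hstack([block_a, block_b]),
        index=[f"S{i}" for i in range(10)],
        columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
    )
    labels, _ = cluster_samples(es, k=2)
    a_labels = set(labels[[f"a{i}" for i in range(6)]])
    b_labels = set(labels[[f"b{i}" for i in range(6)]])
    assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels


def test_cluster_duplicate_sample_stays_with_twin():
    rng = np.random.default_rng(5)
    es = pd.DataFrame(
        rng.normal(size=(8, 10)),
        index=[f"S{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(10)],
    )
    es["dup"] = es["s0"]
    labels, _ = cluster_samples(es, k=2)
    assert labels["dup"] == labels["s0"]


def test_cluster_constant_profile_is_error():
    es = pd.DataFrame(
        [[1.0, 2.0, 1.0], [2.0, 3.0, 1.0], [3.0, 4.0, 1.0]],
        index=["S1", "S2", "S3"],
        columns=["s1", "s2", "s3"],
    )
    with pytest.raises(PipelineError, match="s3"):
        cluster_samples(es, k=2, standardize=False)


def test_cluster_recovers_planted_partition(classified):
    """ARI between the k=2 cut and the planted program/background partition."""
    sklearn = pytest.importorskip("sklearn.metrics")
    result, truth = classified
    planted = (pd.Series(truth.labels) != "wt").astype(int)
    ari = sklearn.adjusted_rand_score(planted, result.clusters[planted.index])
    assert ari >= 0.8


# ---------- mut-like calling --------------------------------------------------

def test_call_mutlike_by_construction():
    clusters = pd.Series([1, 1, 1, 1, 2, 2], index=[f"s{i}" for i in range(6)])
    clin = _clinical(["mut", "mut", "mut", "wt", "wt", "wt"])
    res = call_mutlike(clusters, clin)
    assert res.labels["s3"] == "mut-like"
    assert (res.labels[["s4", "s5"]] == "wt").all()
    assert (res.labels[["s0", "s1", "s2"]] == "mut").all()
    assert res.mut_cluster == 1


def test_call_mutlike_mut_outside_anchor_cluster_still_mut():
    clusters = pd.Series([1, 1, 2, 2, 2, 2], index=[f"s{i}" for i in range(6)])
    clin = _clinical(["mut", "wt", "mut", "wt", "wt", "wt"])
    res = call_mutlike(clusters, clin)
    assert res.labels["s2"] == "mut"
    assert set(res.labels.unique()) <= {"wt", "mut-like", "mut"}


def test_call_mutlike_requires_mut_anchor_and_flags_ties():
    clusters = pd.Series([1, 1, 2, 2], index=[f"s{i}" for i in range(4)])
    with pytest.raises(PipelineError, match="anchor"):
        call_mutlike(clusters, _clinical(["wt"] * 4))
    tied = _clinical(["mut", "wt", "mut", "wt"])
    with pytest.raises(PipelineError, match="tie"):
        call_mutlike(clusters, tied)
    res = call_mutlike(clusters, tied, tie_break="lowest")
    assert res.mut_cluster == 1


def test_end_to_end_recovery_sensitivity_specificity(classified):
    """Full pipeline recovers the planted mut-like subgroup at >= 0.9/0.9."""
    result, truth = classified
    planted = pd.Series(truth.labels)
    called = result.labels
    sens = ((called == "mut-like") & (planted == "mut-like")).sum() / (planted == "mut-like").sum()
    spec = ((called == "wt") & (planted == "wt")).sum() / (planted == "wt").sum()
    assert sens >= 0.9
    assert spec >= 0.9
    # labels partition the cohort and respect the status constraint
    assert set(called.unique()) == {"wt", "mut-like", "mut"}
    assert ((called == "mut") == (planted == "mut")).all()


# ---------- bootstrap ---------------------------------------------------------

def test_bootstrap_degenerate_identical_values():
    es = pd.Series(np.full(20, 2.5), index=[f"s{i}" for i in range(20)])
    labels = pd.Series(["a"] * 10 + ["b"] * 10, index=es.index)
    out = bootstrap_es(es, labels, b=200, seed=0)
    for g in ("a", "b"):
        assert out["groups"][g]["ci_low"] == out["groups"][g]["ci_high"] == 2.5
    diff = out["differences"]["a - b"]
    assert diff["apparent"] == diff["corrected"] == 0.0
    assert diff["optimism"] == 0.0


def test_bootstrap_determinism():
    rng = np.random.default_rng(0)
    es = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    labels = pd.Series(["a"] * 15 + ["b"] * 15, index=es.index)
    assert bootstrap_es(es, labels, b=300, seed=5) == bootstrap_es(es, labels, b=300, seed=5)


def test_bootstrap_difference_ci_coverage():
    """Percentile CI for a true group difference of 1.0 covers it >= 93% of runs."""
    rng = np.random.default_rng(12)
    covered = 0
    reps = 200
    for _ in range(reps):
        a = rng.normal(1.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        es = pd.Series(np.r_[a, b], index=[f"s{i}" for i in range(100)])
        labels = pd.Series(["a"] * 50 + ["b"] * 50, index=es.index)
        out = bootstrap_es(es, labels, b=1000, seed=int(rng.integers(2**31)))
        d = out["differences"]["a - b"]
        covered += d["ci_low"] <= 1.0 <= d["ci_high"]
    assert covered / reps >= 0.93


def test_bootstrap_group_size_contract():
    es = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
    labels = pd.Series(["a", "a", "b", "b"], index=es.index)
    with pytest.raises(PipelineError, match="< 3 samples"):
        bootstrap_es(es, labels, b=100)


def test_classify_is_deterministic(two_cohorts, panel):
    from mutlike.cohort import classify_cohort
    from mutlike.datatypes import AnalysisConfig

    expr, clin, _ = two_cohorts[0]
    cfg = AnalysisConfig(bootstrap_b=100, seed=3)
    r1 = classify_cohort(expr, clin, panel, config=cfg)
    r2 = classify_cohort(expr, clin, panel, config=cfg)
    pd.testing.assert_series_equal(r1.labels, r2.labels)
    assert r1.bootstrap == r2.bootstrap
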