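"""The JCC score family: weights, the score, classification, controls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jccscore.annotation import AnnotationCatalog
from jccscore.junctions import ObservedJunction, PredictedJunction
from jccscore.scoring import (
    STATUS_INSUFFICIENT,
    STATUS_NO_JUNCTIONS,
    STATUS_NOT_EXPRESSED,
    STATUS_SCORED,
    ScoreConfig,
    WeightFunction,
    classify_gene,
    compare_scores,
    inferential_cv,
    jcc_score,
    permute_counts_within_genes,
    score_all_genes,
)

from conftest import make_tx

STEP = ScoreConfig()  # step(0.75), beta=1


def brute_force_jcc(R, C, omega, weight, beta):
    """Independent scalar evaluation of the score definition."""
    w = [weight(o) for o in omega]
    wr = sum(wi * ri for wi, ri in zip(w, R))
    wc = sum(wi * ci for wi, ci in zip(w, C))
    if beta == 0 or wc == 0:
        s = 1.0
    else:
        s = (wr / wc) ** beta
    return sum(wi * abs(s * ci - ri) for wi, ci, ri in zip(w, C, R)) / wr


# ---------------------------------------------------------------------------
# weight functions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "omega,expected", [(0.75, 1.0), (0.74, 0.0), (1.0, 1.0), (0.0, 0.0)]
)
def test_step_weight(omega, expected):
    assert WeightFunction("step", 0.75)(omega) == expected


def test_ramp_and_logistic_shapes():
    ramp = WeightFunction("ramp", 0.75)
    assert ramp(0.0) == 0.0
    assert ramp(0.375) == pytest.approx(0.5)
    assert ramp(0.75) == 1.0 == ramp(1.0)
    logi = WeightFunction("logistic", 0.75, steepness=20.0)
    assert logi(0.75) == pytest.approx(0.5)
    om = np.linspace(0, 1, 21)
    for f in (ramp, logi, WeightFunction("step", 0.75)):
        vals = f(om)
        assert np.all(np.diff(vals) >= 0)  # nondecreasing
        assert np.all(vals >= 0)


def test_weight_rejects_invalid_omega():
    with pytest.raises(ValueError):
        WeightFunction()(1.5)
    with pytest.raises(ValueError):
        WeightFunction()(-0.1)


# ---------------------------------------------------------------------------
# the score
# ---------------------------------------------------------------------------

def test_disjoint_support_scores_two():
    """Observed reads and predicted coverage on disjoint junction sets give
    the maximal score (100+40+30+30)/100 = 2."""
    score = jcc_score([100, 0, 0, 0], [0, 40, 30, 30], [1, 1, 1, 1], STEP)
    assert score == pytest.approx(2.0)


def test_proportional_prediction_scores_zero():
    score = jcc_score([30, 20, 10], [3, 2, 1], [1, 1, 1], STEP)
    assert score == 0.0


def test_weighted_exclusion_hand_example():
    """Junction 2 has omega 0.5 < 0.75 so only junction 1 contributes:
    s = 10/20 and |0.5*20 - 10| / 10 = 0."""
    score = jcc_score([10, 8], [20, 4], [1.0, 0.5], STEP)
    assert score == 0.0


def test_zero_weighted_reads_raises():
    with pytest.raises(ValueError):
        jcc_score([0, 0], [5, 5], [1, 1], STEP)
    with pytest.raises(ValueError):
        jcc_score([10], [5], [0.2], STEP)  # weight kills the only junction


def test_zero_predicted_mass_scores_one():
    """With beta=1 and no weighted predicted mass, the scale factor is
    defined as 1 and the score is exactly 1."""
    assert jcc_score([50, 10], [0, 0], [1, 1], STEP) == pytest.approx(1.0)


def test_matches_brute_force_on_random_inputs(rng):
    """1,000 random gene configurations agree with an independent scalar
    evaluation of the definition to 1e-12 relative error."""
    for _ in range(1000):
        n = rng.integers(1, 12)
        R = rng.integers(0, 500, size=n).astype(float)
        C = rng.random(n) * 500
        om = rng.random(n)
        beta = int(rng.integers(0, 2))
        kind = ["step", "ramp", "logistic"][rng.integers(0, 3)]
        wf = WeightFunction(kind, 0.75)
        cfg = ScoreConfig(weight=wf, beta=beta)
        expect = None
        w = [wf(o) for o in om]
        if sum(wi * ri for wi, ri in zip(w, R)) <= 0:
            continue
        expect = brute_force_jcc(R, C, om, wf, beta)
        got = jcc_score(R, C, om, cfg)
        assert got == pytest.approx(expect, rel=1e-12)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.integers(0, 1000),
            st.floats(0, 1000, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_score_bounded_by_two_with_scaling(data):
    """With beta = 1 the score always lies in [0, 2]."""
    R = [d[0] for d in data]
    C = [d[1] for d in data]
    om = [d[2] for d in data]
    w = [STEP.weight(o) for o in om]
    if sum(wi * ri for wi, ri in zip(w, R)) <= 0:
        return
    score = jcc_score(R, C, om, STEP)
    assert 0.0 <= score <= 2.0 + 1e-12


def test_scale_invariance_of_predictions(rng):
    """With beta = 1, multiplying every C_j by a positive constant leaves
    the score unchanged."""
    for _ in range(100):
        n = int(rng.integers(2, 10))
        R = rng.integers(1, 100, size=n).astype(float)
        C = rng.random(n) * 50
        om = np.ones(n)
        lam = float(rng.random() * 99 + 0.01)
        a = jcc_score(R, C, om, STEP)
        b = jcc_score(R, lam * C, om, STEP)
        assert a == pytest.approx(b, rel=1e-9)


def test_beta_choices_agree_when_sums_match(rng):
    for _ in range(50):
        n = int(rng.integers(2, 8))
        R = rng.integers(1, 100, size=n).astype(float)
        C = rng.random(n) * 10
        C *= R.sum() / C.sum()  # equal weighted sums (weights all 1)
        om = np.ones(n)
        b0 = jcc_score(R, C, om, ScoreConfig(beta=0))
        b1 = jcc_score(R, C, om, ScoreConfig(beta=1))
        assert b0 == pytest.approx(b1, rel=1e-9)


def test_mass_transfer_decreases_score_linearly():
    """Moving predicted mass delta from an over-predicted junction to an
    under-predicted one lowers the score by exactly 2*delta/sum(R)."""
    R = np.array([10.0, 30.0])
    C = np.array([20.0, 20.0])  # s = 40/40 = 1; junction 1 over, 2 under
    om = np.ones(2)
    delta = 3.0
    before = jcc_score(R, C, om, STEP)
    after = jcc_score(R, C + np.array([-delta, delta]), om, STEP)
    assert before - after == pytest.approx(2 * delta / R.sum(), rel=1e-12)


def test_score_zero_iff_scaled_match(rng):
    for _ in range(50):
        n = int(rng.integers(2, 8))
        R = rng.integers(1, 100, size=n).astype(float)
        lam = float(rng.random() * 5 + 0.1)
        assert jcc_score(R, lam * R, np.ones(n), STEP) == pytest.approx(0, abs=1e-12)
        C = lam * R
        C[0] += 7.0
        assert jcc_score(R, C, np.ones(n), STEP) > 0


# ---------------------------------------------------------------------------
# classification and the gene table
# ---------------------------------------------------------------------------

def _mini_catalog():
    txs = [
        make_tx("T1", "Gexpr", [(0, 100), (200, 300)]),
        make_tx("T2", "Gmono", [(1000, 1500)]),
        make_tx("T3", "Gnoreads", [(2000, 2100), (2200, 2300)]),
    ]
    return AnnotationCatalog.from_transcripts(txs)


def _obs(key, unique, multi=0):
    return ObservedJunction(key=key, unique_count=unique, multi_count=multi)


def test_classify_gene_statuses():
    cat = _mini_catalog()
    key = ("chr1", 100, 200, "+")
    observed = {key: _obs(key, 30)}
    ab = {"T1": 10.0, "T2": 5.0, "T3": 2.0}
    assert classify_gene("Gexpr", cat, ab, observed) == STATUS_SCORED
    assert classify_gene("Gmono", cat, ab, observed) == STATUS_NO_JUNCTIONS
    assert classify_gene("Gnoreads", cat, ab, observed) == STATUS_INSUFFICIENT
    assert classify_gene("Gexpr", cat, {}, observed) == STATUS_NOT_EXPRESSED
    with pytest.raises(KeyError):
        classify_gene("nope", cat, ab, observed)


def test_score_table_filter_edges():
    cat = _mini_catalog()
    key = ("chr1", 100, 200, "+")
    ab = {"T1": 10.0, "T2": 1.0, "T3": 1.0}
    pred = {key: PredictedJunction(key, {"T1": 24.0})}
    # 24 unique reads: filter requires >= 25
    table = score_all_genes(cat, ab, {key: _obs(key, 24)}, pred)
    row = table.set_index("gene_id").loc["Gexpr"]
    assert row.status == STATUS_SCORED and not row.passes_filters
    assert row.unique_junction_reads == 24
    # 100 reads, 80% unique, ratio 0.05: passes
    table = score_all_genes(
        cat, ab, {key: _obs(key, 100, 25)}, pred, {"Gexpr": 0.05}
    )
    row = table.set_index("gene_id").loc["Gexpr"]
    assert row.passes_filters
    assert row.unique_fraction == pytest.approx(0.8)
    assert row.intron_exon_ratio == pytest.approx(0.05)


def test_score_table_statuses_and_jcc_presence():
    cat = _mini_catalog()
    key = ("chr1", 100, 200, "+")
    ab = {"T1": 10.0, "T2": 1.0, "T3": 1.0}
    pred = {key: PredictedJunction(key, {"T1": 30.0})}
    table = score_all_genes(cat, ab, {key: _obs(key, 30)}, pred)
    by = table.set_index("gene_id")
    assert by.loc["Gexpr"].jcc == pytest.approx(0.0)
    assert math.isnan(by.loc["Gmono"].jcc)
    assert by.loc["Gmono"].status == STATUS_NO_JUNCTIONS
    assert by.loc["Gnoreads"].status == STATUS_INSUFFICIENT


# ---------------------------------------------------------------------------
# permutation control
# ---------------------------------------------------------------------------

def test_permutation_preserves_multiset_and_is_seeded():
    txs = [make_tx(f"T{i}", "G", [(i * 100, i * 100 + 50)]) for i in range(3)]
    txs.append(make_tx("S", "Gsingle", [(5000, 5100)]))
    cat = AnnotationCatalog.from_transcripts(txs)
    ab = {"T0": 10.0, "T1": 20.0, "T2": 30.0, "S": 7.0}
    p1 = permute_counts_within_genes(ab, cat, seed=4)
    p2 = permute_counts_within_genes(ab, cat, seed=4)
    assert p1 == p2  # determinism
    assert sorted(p1[t] for t in ("T0", "T1", "T2")) == [10.0, 20.0, 30.0]
    assert p1["S"] == 7.0  # single-transcript gene untouched
    assert any(
        permute_counts_within_genes(ab, cat, seed=s)["T0"] != 10.0
        for s in range(10)
    )


# ---------------------------------------------------------------------------
# inferential CV
# ---------------------------------------------------------------------------

def test_inferential_cv_values():
    txs = [
        make_tx("A", "G1", [(0, 100)]),
        make_tx("B", "G1", [(0, 120)]),
        make_tx("C", "G2", [(500, 600)]),
    ]
    cat = AnnotationCatalog.from_transcripts(txs)
    boot = pd.DataFrame(
        {"r1": [10, 8, 0], "r2": [10, 12, 0], "r3": [10, 10, 0]},
        index=["A", "B", "C"],
    )
    tx_cv, gene_cv = inferential_cv(boot, cat)
    assert tx_cv["A"] == 0.0
    # row (8, 12, 10): sd = 2, mean = 10
    assert tx_cv["B"] == pytest.approx(0.2)
    assert math.isnan(tx_cv["C"])  # all-zero row
    # gene G1 rows sum to (18, 22, 20): sd 2, mean 20
    assert gene_cv["G1"] == pytest.approx(0.1)
    assert math.isnan(gene_cv["G2"])


def test_inferential_cv_two_replicates():
    cat = AnnotationCatalog.from_transcripts([make_tx("A", "G", [(0, 10)])])
    boot = pd.DataFrame({"r1": [8], "r2": [12]}, index=["A"])
    tx_cv, _ = inferential_cv(boot, cat)
    # sd = sqrt(8) = 2.828..., mean = 10
    assert tx_cv["A"] == pytest.approx(0.28284, abs=1e-4)
    with pytest.raises(ValueError):
        inferential_cv(boot[["r1"]], cat)


# ---------------------------------------------------------------------------
# score comparison
# ---------------------------------------------------------------------------

def _table(scores):
    return pd.DataFrame(
        {
            "gene_id": list(scores),
            "jcc": list(scores.values()),
            "status": [STATUS_SCORED] * len(scores),
        }
    )


def test_compare_identical_tables():
    t = _table({"G1": 0.1, "G2": 0.5, "G3": 0.9})
    cmp = compare_scores(t, t)
    assert cmp.pearson == pytest.approx(1.0)
    assert cmp.spearman == pytest.approx(1.0)
    assert cmp.mean_difference == 0.0
    assert (cmp.n_higher, cmp.n_lower, cmp.n_equal) == (0, 0, 3)


def test_compare_shifted_tables():
    a = _table({"G1": 0.1, "G2": 0.5, "G3": 0.9})
    b = _table({"G1": 0.2, "G2": 0.6, "G3": 1.0})
    cmp = compare_scores(a, b)
    assert cmp.mean_difference == pytest.approx(-0.1)
    assert cmp.n_higher == 0 and cmp.n_lower == 3


def test_compare_matches_textbook_correlations():
    a = _table({"G1": 0.1, "G2": 0.7, "G3": 0.3})
    b = _table({"G1": 0.2, "G2": 0.9, "G3": 0.1})
    cmp = compare_scores(a, b)
    x, y = np.array([0.1, 0.7, 0.3]), np.array([0.2, 0.9, 0.1])
    r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert cmp.pearson == pytest.approx(r_hand, rel=1e-12)
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    rho_hand = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
        np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
    )
    assert cmp.spearman == pytest.approx(rho_hand, rel=1e-12)


def test_compare_requires_shared_scored_genes():
    a = _table({"G1": 0.1})
    b = _table({"G2": 0.2})
    with pytest.raises(ValueError):
        compare_scores(a, b)
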