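"""Co-occurrence score, Fisher/BH filtering, weighted edges, disparity backbone."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aenet.cooccurrence import (
    WeightMatrix,
    bh_adjust,
    compare_networks,
    cooccurrence_score,
    disparity_alpha,
    extract_backbone,
    fisher_pair_test,
    pair_counts,
    pair_stats,
    score_network,
    weighted_edges,
)

from oracles import bh_reject_set, disparity_alpha_quadrature, hypergeom_tail_pvalue


def make_ae_events(patient_aes: dict[str, list[str]]) -> pd.DataFrame:
    rows = [
        (p, ae, "AE", 1) for p, aes in patient_aes.items() for ae in aes
    ]
    return pd.DataFrame(rows, columns=["patient_id", "term", "term_type", "count"])


# ---------------------------------------------------------------- pair counts

def test_pair_counts_small():
    table = pair_counts(make_ae_events({"1": ["a", "b"], "2": ["a"]}))
    assert len(table) == 1
    row = table.iloc[0]
    assert (row.ae_i, row.ae_j) == ("a", "b")
    assert (row.n_A, row.n_B, row.n_AB, row.n_tot) == (2, 1, 1, 2)


def test_pair_counts_disjoint_and_vocabulary():
    events = make_ae_events({"1": ["a"], "2": ["b"]})
    table = pair_counts(events, vocabulary=["a", "b", "c"])
    assert len(table) == 3  # 3 choose 2
    assert (table["n_AB"] == 0).all()
    unseen = table[(table.ae_i == "a") & (table.ae_j == "c")]
    assert int(unseen["n_B"].iloc[0]) == 0


# ---------------------------------------------------------------------- score

def test_cooccurrence_score_hand_values():
    assert cooccurrence_score(0, 0, 0, 10) == pytest.approx(0.0)
    assert cooccurrence_score(3, 4, 5, 20) == pytest.approx(1.0)  # log2(4/2)
    # exact independence: n_AB == n_A n_B / n_tot
    assert cooccurrence_score(2, 4, 10, 20) == pytest.approx(0.0)


def test_cooccurrence_score_inconsistent_counts_raise():
    with pytest.raises(ValueError):
        cooccurrence_score(5, 4, 5, 20)
    with pytest.raises(ValueError):
        cooccurrence_score(1, 2, 3, 0)


@given(
    n_tot=st.integers(2, 60),
    data=st.data(),
)
@settings(deadline=None, max_examples=100)
def test_score_symmetric_and_monotone_in_overlap(n_tot, data):
    n_a = data.draw(st.integers(1, n_tot))
    n_b = data.draw(st.integers(1, n_tot))
    hi = min(n_a, n_b)
    lo = max(0, n_a + n_b - n_tot)
    n_ab = data.draw(st.integers(lo, hi))
    assert cooccurrence_score(n_ab, n_a, n_b, n_tot) == pytest.approx(
        cooccurrence_score(n_ab, n_b, n_a, n_tot)
    )
    if n_ab < hi:
        assert cooccurrence_score(n_ab + 1, n_a, n_b, n_tot) > cooccurrence_score(
            n_ab, n_a, n_b, n_tot
        )


# --------------------------------------------------------------------- fisher

def test_fisher_boundary_zero_overlap_is_one():
    assert fisher_pair_test(0, 5, 5, 20) == pytest.approx(1.0)


def test_fisher_full_overlap_matches_enumeration():
    assert fisher_pair_test(5, 5, 5, 10) == pytest.approx(
        hypergeom_tail_pvalue(5, 5, 5, 10)
    )


def test_fisher_agrees_with_scipy_two_sided_and_greater():
    from scipy.stats import fisher_exact

    table = [[4, 1], [2, 8]]
    n_ab, n_a, n_b, n_tot = 4, 5, 6, 15
    assert fisher_pair_test(n_ab, n_a, n_b, n_tot) == pytest.approx(
        fisher_exact(table, alternative="greater")[1]
    )
    assert fisher_pair_test(
        n_ab, n_a, n_b, n_tot, alternative="two-sided"
    ) == pytest.approx(fisher_exact(table, alternative="two-sided")[1])


def test_fisher_negative_cell_raises():
    with pytest.raises(ValueError):
        fisher_pair_test(3, 2, 5, 20)  # n_AB > n_A
    with pytest.raises(ValueError):
        fisher_pair_test(0, 15, 15, 20)  # negative 'neither' cell


def test_fisher_doubling_cells_never_increases_enriched_p():
    """For enriched tables, doubling all cells sharpens (never weakens) evidence."""
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 50:
        n_tot = int(rng.integers(4, 30))
        n_a = int(rng.integers(1, n_tot))
        n_b = int(rng.integers(1, n_tot))
        lo, hi = max(0, n_a + n_b - n_tot), min(n_a, n_b)
        n_ab = int(rng.integers(lo, hi + 1))
        if n_ab * n_tot <= n_a * n_b:  # only enriched tables
            continue
        p1 = fisher_pair_test(n_ab, n_a, n_b, n_tot)
        p2 = fisher_pair_test(2 * n_ab, 2 * n_a, 2 * n_b, 2 * n_tot)
        assert p2 <= p1 + 1e-12
        checked += 1


# ------------------------------------------------------------------------- BH

def test_bh_hand_values():
    assert bh_adjust([0.005], n_tests=1) == pytest.approx([0.005])
    assert bh_adjust([0.01, 0.02, 0.03], n_tests=3) == pytest.approx(
        [0.03, 0.03, 0.03]
    )
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_raw_mode_matches_rank_scaling():
    raw = bh_adjust([0.01, 0.02, 0.03], n_tests=3, monotone=False)
    assert raw == pytest.approx([0.03, 0.03, 0.03])
    raw2 = bh_adjust([0.01, 0.04], n_tests=2, monotone=False)
    assert raw2 == pytest.approx([0.02, 0.04])


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 0.5], n_tests=1)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 40)))
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


def test_bh_rejection_set_matches_brute_force_step_up():
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        p = rng.random(n) ** float(rng.uniform(0.5, 3.0))
        alpha = float(rng.choice([0.01, 0.05, 0.1]))
        adjusted = bh_adjust(p)
        assert np.array_equal(adjusted <= alpha, bh_reject_set(p, alpha))


# -------------------------------------------------------------- score network

def test_score_network_alpha_zero_is_empty(tiny_events):
    g = score_network(tiny_events, alpha=0.0 + 1e-300)
    assert g.number_of_edges() == 0


def test_score_network_detects_planted_pair():
    from aenet.synthetic import generate_cohort, null_config

    cfg = null_config(seed=4, n_patients=400)
    cfg.planted_pairs = [(20, 30, 0.15)]
    g = score_network(generate_cohort(cfg), alpha=0.01)
    assert g.has_edge("AE0020", "AE0030")
    assert g.nodes["AE0020"]["prevalence"] > 0
    stats_table = g.graph["pair_stats"]
    assert len(stats_table) > 0 and {"score", "bh_p"} <= set(stats_table.columns)


def test_observed_pairs_mode_restricts_table():
    events = make_ae_events({"1": ["a", "b"], "2": ["a", "c"]})
    full = pair_stats(events, m_mode="all_pairs")
    observed = pair_stats(events, m_mode="observed_pairs")
    assert len(full) == 3
    assert set(zip(observed.ae_i, observed.ae_j)) == {("a", "b"), ("a", "c")}


# ------------------------------------------------------------- weighted edges

def test_weighted_edges_hand_values():
    w2 = weighted_edges(make_ae_events({"1": ["i", "j"]}))
    assert w2.to_frame().loc["i", "j"] == pytest.approx(1.0)

    w3 = weighted_edges(make_ae_events({"1": ["i", "j", "k"]}))
    frame = w3.to_frame()
    for a, b in (("i", "j"), ("i", "k"), ("j", "k")):
        assert frame.loc[a, b] == pytest.approx(0.5)
    assert np.allclose(np.diag(w3.values), 0.0)


def test_weighted_edges_total_equals_sum_of_burdens():
    """Each patient with n_p > 1 distributes exactly n_p total weight."""
    from aenet.synthetic import generate_cohort, null_config

    events = generate_cohort(null_config(seed=5, n_patients=80))
    aes = events[events.term_type == "AE"]
    n_p = aes.groupby("patient_id")["term"].nunique()
    expected = n_p[n_p > 1].sum()
    w = weighted_edges(events)
    assert w.values.sum() == pytest.approx(float(expected))


def test_single_ae_patients_contribute_nothing():
    w = weighted_edges(make_ae_events({"1": ["i"], "2": ["i", "j"]}))
    assert w.to_frame().loc["i", "j"] == pytest.approx(1.0)


# ------------------------------------------------------------------ disparity

def test_disparity_alpha_hand_values():
    assert disparity_alpha([1.0, 1.0]) == pytest.approx([0.5, 0.5])  # k=2, p=1/2
    assert disparity_alpha([5.0]) == pytest.approx([1.0])  # k=1 never significant
    # p -> 1 drives alpha -> 0
    a = disparity_alpha([999.0, 1e-9])
    assert a[0] == pytest.approx(0.0, abs=1e-6)
    assert a[1] == pytest.approx(1.0, abs=1e-6)


def test_disparity_alpha_matches_quadrature_grid():
    for k in (2, 3, 5, 10, 40):
        for p in np.linspace(0.01, 0.99, 9):
            weights = np.full(k, (1 - p) / (k - 1))
            weights[0] = p
            closed = disparity_alpha(weights)[0]
            assert abs(closed - disparity_alpha_quadrature(p, k)) < 1e-10


def test_disparity_alpha_rejects_bad_input():
    with pytest.raises(ValueError):
        disparity_alpha([])
    with pytest.raises(ValueError):
        disparity_alpha([1.0, 0.0])


# ------------------------------------------------------------------- backbone

def star_weights() -> WeightMatrix:
    """Hub h with one dominant edge (to s) and six uniform spokes."""
    terms = ["h", "s"] + [f"u{i}" for i in range(6)]
    v = len(terms)
    w = np.zeros((v, v))
    w[0, 1] = w[1, 0] = 10.0
    for i in range(2, v):
        w[0, i] = w[i, 0] = 0.5
    return WeightMatrix(terms, w)


def test_backbone_keeps_dominant_star_edge_only():
    w = star_weights()
    g = extract_backbone(w, alpha=0.05, drop_top_prevalent=0)
    assert g.has_edge("h", "s")
    # hub's uniform spokes are not significant from either side
    assert g.number_of_edges() == 1
    # closed-form check of the surviving edge's alpha
    p = 10.0 / 13.0
    assert g.edges["h", "s"]["alpha"] == pytest.approx((1 - p) ** 6)


def test_backbone_alpha_one_keeps_every_edge():
    w = star_weights()
    g = extract_backbone(w, alpha=1.0, drop_top_prevalent=0)
    assert g.number_of_edges() == 7


def test_backbone_drop_most_prevalent():
    w = star_weights()
    prevalence = {t: 1 for t in w.terms} | {"h": 100}
    g = extract_backbone(
        w, alpha=0.05, drop_top_prevalent=1, prevalence=prevalence, n_patients=100
    )
    assert "h" not in g.nodes
    assert g.number_of_edges() == 0


def test_backbone_both_rule_is_stricter():
    w = star_weights()
    either = extract_backbone(w, alpha=0.05, drop_top_prevalent=0, rule="either")
    both = extract_backbone(w, alpha=0.05, drop_top_prevalent=0, rule="both")
    assert set(map(frozenset, both.edges)) <= set(map(frozenset, either.edges))


# ------------------------------------------------------------------ comparison

def test_compare_identical_and_disjoint_networks():
    g = nx.Graph([("a", "b"), ("b", "c")])
    same = compare_networks(g, g.copy())
    assert same.frac_nodes_a == 1.0 and same.frac_edges_b == 1.0
    h = nx.Graph([("x", "y")])
    disjoint = compare_networks(g, h)
    assert disjoint.shared_nodes == 0 and disjoint.shared_edges == 0


def test_compare_edge_direction_ignored():
    a = nx.Graph([("x", "y")])
    b = nx.Graph([("y", "x")])
    assert compare_networks(a, b).shared_edges == 1
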