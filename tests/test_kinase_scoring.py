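"""PWM scoring, ranking, score statistics and shared-kinase tests."""

import itertools

import numpy as np
import pytest

from phospho_turnover.core_io import AA_INDEX, KinasePWM
from phospho_turnover.kinase_scoring import (
    compare_score_sets,
    excess_divergence_fraction,
    extract_window,
    fraction_phosphorylated_by_score_bin,
    kinase_overlap_test,
    rank_kinases,
    score_10mer,
    score_correlation,
)
from phospho_turnover.synthetic_data import simulate_pwms

TENMER = "ACDEFSACDE"


def uniform_pwm(name="U"):
    return KinasePWM(name, np.full((10, 20), 0.05))


def one_hot_pwm(consensus, name="OH", peak=0.9):
    mat = np.empty((10, 20))
    for i, ch in enumerate(consensus):
        row = np.full(20, (1 - peak) / 19)
        row[AA_INDEX[ch]] = peak
        mat[i] = row
    return KinasePWM(name, mat)


# ---------------------------------------------------------------------------
# score_10mer
# ---------------------------------------------------------------------------

def test_uniform_matrix_scores_005():
    assert score_10mer(uniform_pwm(), TENMER) == pytest.approx(0.05)


def test_consensus_match_scores_peak():
    mat = np.zeros((10, 20))
    for i, ch in enumerate(TENMER):
        mat[i, AA_INDEX[ch]] = 1.0
    assert score_10mer(KinasePWM("OH", mat), TENMER) == pytest.approx(1.0)


def test_geometric_mean_hand_computation():
    """Five positions at 0.1 and five at 0.4 give (0.1^5 * 0.4^5)^0.1 = 0.2."""
    mat = np.empty((10, 20))
    for i, ch in enumerate(TENMER):
        p = 0.1 if i < 5 else 0.4
        row = np.full(20, (1 - p) / 19)
        row[AA_INDEX[ch]] = p
        mat[i] = row
    assert score_10mer(KinasePWM("H", mat), TENMER) == pytest.approx(0.2)


def test_padding_scores_position_mean():
    # terminal window: padded columns contribute the row mean (0.05 for a
    # probability row), identical to the uniform-matrix value
    win = extract_window("MSK", 2)
    assert win == "XXXXMSKXXX"
    assert score_10mer(uniform_pwm(), win) == pytest.approx(0.05)


def test_non_acceptor_sixth_position_rejected():
    with pytest.raises(ValueError, match="acceptor"):
        score_10mer(uniform_pwm(), "ACDEFGACDE")


def test_score_monotone_in_matched_probability():
    scores = []
    for p in (0.1, 0.3, 0.6, 0.9):
        mat = np.full((10, 20), (1 - p) / 19)
        for i, ch in enumerate(TENMER):
            mat[i, AA_INDEX[ch]] = p
        scores.append(score_10mer(KinasePWM("M", mat), TENMER))
    assert scores == sorted(scores)


# ---------------------------------------------------------------------------
# rank_kinases
# ---------------------------------------------------------------------------

def test_tie_break_by_name():
    ranked = rank_kinases([uniform_pwm("B"), uniform_pwm("A")], TENMER, k=2)
    assert ranked.top_kinases(2) == ("A", "B")


def test_consensus_beats_uniform():
    ranked = rank_kinases([uniform_pwm("U"), one_hot_pwm(TENMER)], TENMER)
    assert ranked.best_kinase == "OH" and ranked.best_score > 0.5


def test_top_k_matches_brute_force_sort(rng):
    pwms = simulate_pwms(5, concentration=1.0, seed=rng)
    ranked = rank_kinases(pwms, TENMER, k=3)
    full = sorted(((p.kinase, score_10mer(p, TENMER)) for p in pwms
                   if p.acceptor_class == "ST"),
                  key=lambda kv: (-kv[1], kv[0]))
    assert list(ranked.ranked) == full[:3]


def test_y_kinases_only_apply_to_y_acceptors():
    pwms = simulate_pwms(4, seed=1, y_kinase_fraction=0.5)
    st_ranked = rank_kinases(pwms, TENMER)
    y_ranked = rank_kinases(pwms, "ACDEFYACDE")
    assert all(k.startswith("STK") for k in st_ranked.top_kinases(3))
    assert all(k.startswith("YK") for k in y_ranked.top_kinases(3))


def test_k_below_one_is_error():
    with pytest.raises(ValueError):
        rank_kinases([uniform_pwm()], TENMER, k=0)


# ---------------------------------------------------------------------------
# score-set statistics
# ---------------------------------------------------------------------------

def test_identical_sets_p_one():
    m1, m2, p = compare_score_sets([0.3, 0.3], [0.3, 0.3])
    assert (m1, m2, p) == (0.3, 0.3, 1.0)


def test_exact_rank_sum_on_disjoint_triples():
    _, _, p = compare_score_sets([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2 / C(6,3) extreme orderings


def test_perfectly_monotone_pairs_rho_one():
    rho, _ = score_correlation([(0.1, 0.2), (0.2, 0.5), (0.4, 0.9)])
    assert rho == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# excess divergence
# ---------------------------------------------------------------------------

def test_printed_proportions_give_056():
    x = excess_divergence_fraction(0.284, 0.258, 0.291, 0.261)
    assert x == pytest.approx(0.056)


def test_no_excess_when_std_matches_stc_baseline():
    assert excess_divergence_fraction(0.25, 0.25, 0.30, 0.30) == 0.0


def test_terms_floored_at_zero():
    assert excess_divergence_fraction(0.20, 0.25, 0.30, 0.26) == \
        pytest.approx(0.04)


def test_six_pair_toy_table_matches_hand_count():
    # StD-a pairs (a,b): a wins 2/3; StC baseline: a wins 1/3, b wins 1/3;
    # StD-b pairs: b wins 1/3 -> excess = (2/3-1/3) + max(0, 1/3-1/3)
    std_a = [(0.9, 0.1), (0.8, 0.2), (0.1, 0.9)]
    stc = [(0.5, 0.4), (0.4, 0.5), (0.3, 0.3)]
    std_b = [(0.6, 0.2), (0.2, 0.6), (0.7, 0.1)]
    p_std_a = np.mean([a > b for a, b in std_a])
    p_stc_a = np.mean([a > b for a, b in stc])
    p_std_b = np.mean([b > a for a, b in std_b])
    p_stc_b = np.mean([b > a for a, b in stc])
    x = excess_divergence_fraction(p_std_a, p_stc_a, p_std_b, p_stc_b)
    assert x == pytest.approx((2 / 3 - 1 / 3) + 0.0)


# ---------------------------------------------------------------------------
# score bins
# ---------------------------------------------------------------------------

def test_fraction_phosphorylated_increases_with_pwm_truth(rng):
    """When phosphorylation truly follows motif strength, the fraction of
    phosphorylated acceptors rises across best-score bins."""
    scores = rng.beta(1.2, 4, size=4000)
    phospho = rng.random(4000) < scores  # truth generated from the score
    table = fraction_phosphorylated_by_score_bin(scores, phospho, n_bins=5)
    fracs = table.fraction_phosphorylated.to_numpy()
    assert np.all(np.diff(fracs) > 0)


# ---------------------------------------------------------------------------
# kinase overlap permutation test
# ---------------------------------------------------------------------------

def test_degenerate_all_same_kinase():
    pairs = [(("K",), ("K",))] * 4
    nd = kinase_overlap_test(pairs, "best1", 200, seed=0)
    assert nd.observed == 1.0
    assert np.all(nd.replicates == 1.0)
    assert nd.fold == 1.0


def test_two_pair_exhaustive_enumeration():
    """(A,A),(B,B): the 2 permutations give shared fractions {1.0, 0.0}."""
    pairs = [(("A",), ("A",)), (("B",), ("B",))]
    nd = kinase_overlap_test(pairs, "best1", 4000, seed=1)
    assert nd.observed == 1.0
    values, counts = np.unique(nd.replicates, return_counts=True)
    assert set(values) == {0.0, 1.0}
    # each permutation equally likely -> exact p = (identity perms)/2
    assert abs(counts[1] / 4000 - 0.5) < 3 * np.sqrt(0.25 / 4000)
    assert 0.4 < nd.empirical_p < 0.65


def test_top3_mode_counts_any_intersection():
    pairs = [(("A", "B", "C"), ("C", "X", "Y")),
             (("D", "E", "F"), ("Q", "R", "S"))]
    nd = kinase_overlap_test(pairs, "top3", 50, seed=2)
    assert nd.observed == 0.5


def test_fewer_than_two_pairs_is_error():
    with pytest.raises(ValueError):
        kinase_overlap_test([(("A",), ("A",))], "best1", 10, seed=0)
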