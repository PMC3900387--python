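"""Category classification, poly-clusters, abundance bins, proportion tests."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from phospho_turnover.classification import (
    CategorySummary,
    annotation_proportion_test,
    classify_column,
    classify_poly_cluster_overlaps,
    find_poly_clusters,
    proportion_test_from_counts,
    stc_fraction_by_abundance_bins,
    summarize_categories,
)
from conftest import make_aln


# ---------------------------------------------------------------------------
# per-column classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("res_a, res_b, pa, pb, expected", [
    ("S", "A", True, False, "SiD"),
    ("S", "T", True, True, "StC"),
    ("S", "-", True, False, "unalignable"),
    ("S", "T", True, False, "StD"),
    ("T", "Y", False, True, "StD"),
    ("A", "S", False, True, "SiD"),
    ("S", "S", False, False, "background"),
    ("-", "S", False, True, "unalignable"),
    ("A", "A", False, False, "background"),
])
def test_classify_column_rules(res_a, res_b, pa, pb, expected):
    assert classify_column(res_a, res_b, pa, pb) == expected


def test_phospho_on_nonacceptor_is_invariant_error():
    with pytest.raises(ValueError):
        classify_column("A", "S", True, False)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.sampled_from("ASTY-"), st.sampled_from("ASTY-"),
       st.booleans(), st.booleans())
def test_classification_is_species_symmetric(ra, rb, pa, pb):
    """Swapping the two species never changes the category."""
    pa = pa and ra in "STY"
    pb = pb and rb in "STY"
    assert classify_column(ra, rb, pa, pb) == classify_column(rb, ra, pb, pa)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_counts_on_fixture(five_pair_fixture):
    s = summarize_categories(five_pair_fixture)
    assert s.counts["SiD"] == 2
    assert s.counts["StC"] == 1
    assert s.counts["StD"] == 4
    assert s.counts["unalignable"] == 1
    assert s.union_total == 7
    assert s.fractions["StD"] == pytest.approx(4 / 7)


def test_summary_partition_identity(five_pair_fixture):
    s = summarize_categories(five_pair_fixture)
    n_columns = sum(len(a) for a in five_pair_fixture)
    assert sum(s.counts.values()) == n_columns
    assert sum(s.counts[k] for k in ("SiD", "StC", "StD")) == s.union_total
    assert sum(s.fractions.values()) == pytest.approx(1.0)


def test_toy_fraction_enumeration():
    # columns {StC, StD, StD, SiD} -> 0.25 / 0.50 / 0.25
    s = CategorySummary.from_counts(sid=1, stc=1, std=2)
    assert s.union_total == 4
    assert s.fractions == pytest.approx(
        {"SiD": 0.25, "StC": 0.25, "StD": 0.5})


def test_empty_dataset_reports_absent_fractions():
    s = summarize_categories([make_aln("AAK", "AAK")])
    assert s.union_total == 0 and s.fractions is None


def test_single_stc_fraction_is_one():
    s = summarize_categories([make_aln("SAK", "SAK", p_a="100", p_b="100")])
    assert s.fractions["StC"] == 1.0


def test_disorder_stratum_mixed():
    aln = make_aln("S", "S", p_a="1", p_b="1", diso_a="*", diso_b=".")
    s = summarize_categories([aln])
    assert s.disorder_strata["StC"] == {
        "disordered": 0, "ordered": 0, "mixed": 1}


# ---------------------------------------------------------------------------
# poly-S/T/Y clusters
# ---------------------------------------------------------------------------

def test_maximal_run_and_minimum_size():
    aln = make_aln("ASSTYK", "ASAKAA")
    (c,) = find_poly_clusters(aln, "hsa")
    assert (c.start, c.end) == (2, 5)
    assert find_poly_clusters(make_aln("ASAK", "ASAK"), "hsa") == []


def test_cluster_overlap_categories():
    # a-cluster 2-4 with phospho, b-cluster 4-5 without -> StD-c on both
    aln = make_aln("ASTSKK", "AAKTSK", p_a="010000")
    cats = {(c.species, c.start, c.end): c.category
            for c in classify_poly_cluster_overlaps(aln)}
    assert cats[("hsa", 2, 4)] == "StD-c"
    assert cats[("mus", 4, 5)] == "StD-c"


def test_cluster_without_partner_is_sid_c():
    aln = make_aln("ASSKAA", "AAAKSS", p_a="010000", p_b="000010")
    cats = {c.species: c.category
            for c in classify_poly_cluster_overlaps(aln)}
    assert cats == {"hsa": "SiD-c", "mus": "SiD-c"}


@settings(max_examples=80, derandomize=True, deadline=None)
@given(st.text(alphabet="ASTY", min_size=1, max_size=40))
def test_poly_clusters_match_regex_oracle(track):
    aln = make_aln(track + "K", track + "K")
    found = [(c.start, c.end) for c in find_poly_clusters(aln, "hsa")]
    oracle = [(m.start() + 1, m.end())
              for m in re.finditer(r"[STY]{2,}", track + "K")]
    assert found == oracle


# ---------------------------------------------------------------------------
# abundance bins
# ---------------------------------------------------------------------------

def _pp(stc, std):
    return {"StC": stc, "StD": std}


def test_bins_partition_eight_proteins_into_four():
    per_protein = {f"P{i}": _pp(i, 1) for i in range(8)}
    abundance = {f"P{i}": float(i) for i in range(8)}
    table, dropped = stc_fraction_by_abundance_bins(per_protein, abundance, 4)
    assert dropped == []
    assert list(table.n_proteins) == [2, 2, 2, 2]
    # ascending order: bin 1 holds P0, P1
    assert table.StC.tolist() == [1, 5, 9, 13]


def test_constant_fraction_is_invariant_across_bins():
    per_protein = {f"P{i}": _pp(3, 1) for i in range(8)}
    abundance = {f"P{i}": float(i % 3) for i in range(8)}
    table, _ = stc_fraction_by_abundance_bins(per_protein, abundance, 4)
    assert np.allclose(table.stc_fraction, 0.75)


def test_detection_depth_gradient_gives_monotone_bins(rng):
    """Proteins sampled twice as deeply show a higher StC share."""
    per_protein = {}
    abundance = {}
    for i in range(40):
        sens = 0.3 + 0.6 * (i / 39)
        n = 200
        both = rng.binomial(n, sens * sens)
        one = rng.binomial(n, 2 * sens * (1 - sens))
        per_protein[f"P{i:02d}"] = _pp(both, one)
        abundance[f"P{i:02d}"] = float(i)
    table, _ = stc_fraction_by_abundance_bins(per_protein, abundance, 4)
    assert table.stc_fraction.is_monotonic_increasing


def test_more_bins_than_proteins_is_error():
    with pytest.raises(ValueError):
        stc_fraction_by_abundance_bins({"P1": _pp(1, 1)}, {"P1": 1.0}, 4)


# ---------------------------------------------------------------------------
# proportion tests
# ---------------------------------------------------------------------------

def test_identical_site_sets_give_p_one():
    sites = ["P1", "P2", "P3"]
    res = annotation_proportion_test(sites, sites, {"P1"})
    assert res.proportion_1 == res.proportion_2
    assert res.p_value == 1.0


def test_continuity_corrected_chi_square_matches_closed_form():
    res = proportion_test_from_counts(30, 1000, 10, 1000)
    a, b, c, d = 30, 970, 10, 990
    n = a + b + c + d
    stat = n * (abs(a * d - b * c) - n / 2) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))
    assert res.p_value == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-12)


def test_empty_label_overlap_not_applicable():
    res = annotation_proportion_test(["P1", "P2"], ["P3"], {"Q9"})
    assert res.proportion_1 == 0.0 and res.proportion_2 == 0.0
    assert res.p_value is None


def test_empty_site_set_is_error():
    with pytest.raises(ValueError):
        annotation_proportion_test([], ["P1"], {"P1"})
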