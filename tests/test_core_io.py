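"""Site-table and PWM round-trips, peptide mapping, coordinate conversion."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phospho_turnover.core_io import (
    AA20,
    GAP,
    KinasePWM,
    MappingError,
    OrthologAlignment,
    ParseError,
    PhosphoSite,
    map_peptides,
    read_pwms,
    read_site_table,
    site_table_to_string,
    sites_to_columns,
    write_pwms,
)
from conftest import make_aln


# ---------------------------------------------------------------------------
# alignment validation
# ---------------------------------------------------------------------------

def test_direct_field_mapping_with_gap():
    aln = make_aln("STK", "S-K", p_a="100", diso_a="**.")
    assert len(aln) == 3
    assert aln.aa_b[1] == GAP
    assert aln.phospho_b[1] == GAP and aln.diso_b[1] == GAP


@pytest.mark.parametrize("kwargs, match", [
    (dict(aa_a="AK", aa_b="AK", p_a="10"), "non-S/T/Y"),
    (dict(aa_a="SK", aa_b="AKA"), "length"),
    (dict(aa_a="SJ", aa_b="AK"), "unknown residue"),
    (dict(aa_a="--", aa_b="AK"), "all gaps"),
    (dict(aa_a="SK", aa_b="A-", p_b="00"), "gap inconsistency"),
])
def test_invariant_violations_rejected(kwargs, match):
    with pytest.raises(ValueError, match=match):
        make_aln(**kwargs)


# ---------------------------------------------------------------------------
# site-table round trip
# ---------------------------------------------------------------------------

def test_round_trip_is_byte_identical(five_pair_fixture):
    text = site_table_to_string(five_pair_fixture)
    back = read_site_table(io.StringIO(text))
    assert site_table_to_string(back) == text
    assert [a.pair_id for a in back] == [a.pair_id for a in five_pair_fixture]


def test_parse_error_names_pair():
    text = ("pair_id\thsa.aa\thsa.p\thsa.diso\tmus.aa\tmus.p\tmus.diso\n"
            "P9\tA\t1\t*\tA\t0\t*\n")
    with pytest.raises(ParseError, match="P9"):
        read_site_table(io.StringIO(text))


def test_non_contiguous_pair_rows_rejected():
    row = "{}\tS\t0\t*\tS\t0\t*\n"
    text = ("pair_id\thsa.aa\thsa.p\thsa.diso\tmus.aa\tmus.p\tmus.diso\n"
            + row.format("P1") + row.format("P2") + row.format("P1"))
    with pytest.raises(ParseError, match="contiguous"):
        read_site_table(io.StringIO(text))


def test_comments_and_blank_lines_ignored():
    text = ("# a comment\n"
            "pair_id\thsa.aa\thsa.p\thsa.diso\tmus.aa\tmus.p\tmus.diso\n"
            "\n"
            "P1\tS\t1\t*\tT\t1\t.\n")
    (aln,) = read_site_table(io.StringIO(text))
    assert aln.aa_a == "S" and aln.phospho_b == "1"


@st.composite
def alignments(draw):
    n = draw(st.integers(1, 25))
    cols = []
    for _ in range(n):
        ra = draw(st.sampled_from(AA20 + GAP))
        rb = draw(st.sampled_from(AA20 + GAP))
        pa = "-" if ra == GAP else (
            draw(st.sampled_from("01")) if ra in "STY" else "0")
        pb = "-" if rb == GAP else (
            draw(st.sampled_from("01")) if rb in "STY" else "0")
        da = "-" if ra == GAP else draw(st.sampled_from("*."))
        db = "-" if rb == GAP else draw(st.sampled_from("*."))
        cols.append((ra, rb, pa, pb, da, db))
    # ensure neither side is all gaps
    if all(c[0] == GAP for c in cols):
        cols[0] = ("A", cols[0][1], "0", cols[0][3], "*", cols[0][5])
    if all(c[1] == GAP for c in cols):
        cols[0] = (cols[0][0], "A", cols[0][2], "0", cols[0][4], "*")
    return OrthologAlignment(
        "PX", "hsa", "mus",
        "".join(c[0] for c in cols), "".join(c[1] for c in cols),
        "".join(c[2] for c in cols), "".join(c[3] for c in cols),
        "".join(c[4] for c in cols), "".join(c[5] for c in cols))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(alignments())
def test_round_trip_identity_property(aln):
    text = site_table_to_string([aln])
    (back,) = read_site_table(io.StringIO(text))
    assert back == aln


# ---------------------------------------------------------------------------
# peptide mapping
# ---------------------------------------------------------------------------

def test_unique_peptide_maps_to_offset():
    sites, rejected = map_peptides([("ASPK", 2)], {"P1": "MASPK"})
    assert rejected == []
    assert sites == [PhosphoSite("P1", "", 3, "S")]


def test_ambiguous_peptides_rejected():
    proteome = {"P1": "MASPK", "P2": "QASPK", "P3": "MTTKMSPTTK"}
    sites, rejected = map_peptides(
        [("ASPK", 2), ("TTK", 1)], proteome)
    assert sites == []
    reasons = {r["peptide"]: r["reason"] for r in rejected}
    assert reasons == {"ASPK": "ambiguous", "TTK": "ambiguous-within-protein"}


def test_unmatched_peptide_reported_and_il_distinct():
    sites, rejected = map_peptides([("ISPK", 2)], {"P1": "MLSPK"})
    assert sites == [] and rejected[0]["reason"] == "unmatched"


def test_acceptor_offset_out_of_range_is_input_error():
    with pytest.raises(ValueError, match="offset"):
        map_peptides([("ASPK", 9)], {"P1": "MASPK"})


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from(AA20), min_size=6, max_size=30),
       st.integers(0, 5))
def test_mapped_sites_are_phosphorylatable(seq_letters, start):
    """Whatever the proteome, emitted sites sit on S/T/Y residues."""
    seq = "".join(seq_letters)
    pep = seq[start:start + 5]
    acceptors = [i + 1 for i, r in enumerate(pep) if r in "STY"]
    if not acceptors:
        return
    sites, _ = map_peptides([(pep, acceptors[0])], {"P1": seq})
    for s in sites:
        assert s.residue in "STY"
        assert seq[s.position - 1] == s.residue


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def test_sites_to_columns_gap_shift():
    aln = make_aln("AS-TK", "ASATK")
    out = sites_to_columns(aln, [
        PhosphoSite("P1", "hsa", 2, "S"),
        PhosphoSite("P1", "hsa", 3, "T"),
    ])
    assert out.phospho_a == "01-10"  # S at column 2, T at column 4


def test_sites_to_columns_out_of_range_and_mismatch():
    aln = make_aln("AS-TK", "ASATK")
    with pytest.raises(MappingError):
        sites_to_columns(aln, [PhosphoSite("P1", "hsa", 9, "S")])
    with pytest.raises(MappingError, match="expects"):
        sites_to_columns(aln, [PhosphoSite("P1", "hsa", 2, "T")])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(alignments())
def test_coordinate_bijection(aln):
    for sp in ("hsa", "mus"):
        aa = aln.aa(sp)
        for col in range(1, len(aln) + 1):
            if aa[col - 1] == GAP:
                continue
            assert aln.column_of(sp, aln.position_of(sp, col)) == col


# ---------------------------------------------------------------------------
# PWM I/O
# ---------------------------------------------------------------------------

def test_pwm_round_trip(rng):
    mats = [KinasePWM(f"K{i}", rng.dirichlet(np.ones(20), size=10))
            for i in range(3)]
    buf = io.StringIO()
    write_pwms(mats, buf)
    back = read_pwms(io.StringIO(buf.getvalue()))
    assert [p.kinase for p in back] == ["K0", "K1", "K2"]
    for a, b in zip(mats, back):
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-7)


def test_pwm_validation_rejects_bad_rows():
    bad = np.full((10, 20), 0.05)
    bad[3, 0] = 0.5
    with pytest.raises(ValueError, match="sum to 1"):
        KinasePWM("BAD", bad)
    with pytest.raises(ValueError, match="shape"):
        KinasePWM("BAD", np.full((9, 20), 0.05))
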