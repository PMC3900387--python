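"""Shared fixtures: hand-built toy alignments with known category counts."""

from __future__ import annotations

import numpy as np
import pytest

from phospho_turnover.core_io import GAP, OrthologAlignment


def make_aln(aa_a: str, aa_b: str, p_a: str | None = None,
             p_b: str | None = None, diso_a: str | None = None,
             diso_b: str | None = None, pair_id: str = "P1",
             species_a: str = "hsa", species_b: str = "mus",
             ) -> OrthologAlignment:
    """Build an alignment, defaulting phospho to '0' and disorder to '*'."""

    def default(track, aa, fill):
        if track is not None:
            return track
        return "".join(GAP if r == GAP else fill for r in aa)

    return OrthologAlignment(
        pair_id=pair_id, species_a_id=species_a, species_b_id=species_b,
        aa_a=aa_a, aa_b=aa_b,
        phospho_a=default(p_a, aa_a, "0"), phospho_b=default(p_b, aa_b, "0"),
        diso_a=default(diso_a, aa_a, "*"), diso_b=default(diso_b, aa_b, "*"),
    )


@pytest.fixture
def five_pair_fixture() -> list[OrthologAlignment]:
    """Five toy ortholog pairs with hand-enumerated categories.

    Expected: SiD 2, StC 1, StD 4, unalignable 1; union 7.
    """
    return [
        # S column: both phospho -> StC; T column: a only -> StD
        make_aln("ASTK", "ASTK", p_a="0110", p_b="0100", pair_id="P1"),
        # phospho-S vs A -> SiD
        make_aln("MSAK", "MAAK", p_a="0100", pair_id="P2"),
        # phospho-S vs gap -> unalignable
        make_aln("MSTK", "M-TK", p_a="0100", pair_id="P3"),
        # phospho-Y vs F -> SiD; Y/Y unphosphorylated -> background
        make_aln("MYYK", "MYFK", p_a="0010", pair_id="P4"),
        # three StD columns (a-S/b-S, a-S/b-T phospho in b, a-Y/b-Y)
        make_aln("SSTYK", "STTYK", p_a="10010", p_b="01000", pair_id="P5"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
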