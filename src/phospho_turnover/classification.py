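"""Conservation-category classification of aligned phosphosites.

Aligned positions carrying at least one observed phosphosite fall into
three categories:

* **SiD** (site-diverged) — phosphorylated in one species while the other
  species has a non-phosphorylatable residue at the orthologous position;
* **StC** (state-conserved) — phosphorylatable (S/T/Y) in both species and
  reported phosphorylated in both;
* **StD** (state-diverged) — phosphorylatable in both species but reported
  phosphorylated in exactly one.

A phosphosite facing an alignment gap is *unalignable* and is reported
separately, outside the SiD/StC/StD union; columns without any phosphosite
are *background*. The same trichotomy is applied to poly-S/T/Y clusters
(maximal runs of >= 2 consecutive phosphorylatable residues).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GAP,
    PHOSPHO_RESIDUES,
    OrthologAlignment,
    PhosphoSite,
    SiteColumn,
    residue_class,
)

CATEGORIES = ("SiD", "StC", "StD", "background", "unalignable")
PHOSPHO_CATEGORIES = ("SiD", "StC", "StD")

# integer codes used by the vectorized classifier
_BACKGROUND, _SID, _STC, _STD, _UNALIGNABLE = 0, 1, 2, 3, 4
_CODE_TO_NAME = {
    _BACKGROUND: "background", _SID: "SiD", _STC: "StC",
    _STD: "StD", _UNALIGNABLE: "unalignable",
}


def classify_column(res_a: str, res_b: str, phos_a: bool, phos_b: bool) -> str:
    """Classify a single alignment column.

    ``phos_*`` must be False at gaps. Raises if a phospho flag sits on a
    non-phosphorylatable residue.
    """
    for res, phos in ((res_a, phos_a), (res_b, phos_b)):
        if phos and res not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"phospho flag on non-S/T/Y residue {res!r}")
    if phos_a and phos_b:
        return "StC"
    if not phos_a and not phos_b:
        return "background"
    other = res_b if phos_a else res_a
    if other == GAP:
        return "unalignable"
    if other in PHOSPHO_RESIDUES:
        return "StD"
    return "SiD"


@dataclass
class AlignmentArrays:
    """Boolean views of one alignment, precomputed for fast re-classification."""

    pair_id: str
    res_a: np.ndarray  # dtype '<U1'
    res_b: np.ndarray
    sty_a: np.ndarray
    sty_b: np.ndarray
    gap_a: np.ndarray
    gap_b: np.ndarray
    phos_a: np.ndarray
    phos_b: np.ndarray
    diso_a: np.ndarray  # '*'/'.'/'-'
    diso_b: np.ndarray

    @classmethod
    def from_alignment(cls, aln: OrthologAlignment) -> "AlignmentArrays":
        res_a = np.array(list(aln.aa_a))
        res_b = np.array(list(aln.aa_b))
        return cls(
            pair_id=aln.pair_id,
            res_a=res_a,
            res_b=res_b,
            sty_a=np.isin(res_a, list(PHOSPHO_RESIDUES)),
            sty_b=np.isin(res_b, list(PHOSPHO_RESIDUES)),
            gap_a=res_a == GAP,
            gap_b=res_b == GAP,
            phos_a=np.array(list(aln.phospho_a)) == "1",
            phos_b=np.array(list(aln.phospho_b)) == "1",
            diso_a=np.array(list(aln.diso_a)),
            diso_b=np.array(list(aln.diso_b)),
        )


def classify_arrays(
    arr: AlignmentArrays,
    phos_a: np.ndarray | None = None,
    phos_b: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized category codes for every column of one alignment.

    Alternative phospho tracks can be supplied (used by permutation nulls)
    without rebuilding the residue masks.
    """
    pa = arr.phos_a if phos_a is None else phos_a
    pb = arr.phos_b if phos_b is None else phos_b
    if np.any(pa & ~arr.sty_a) or np.any(pb & ~arr.sty_b):
        raise ValueError(f"{arr.pair_id}: phospho flag on non-S/T/Y residue")
    codes = np.full(pa.shape, _BACKGROUND, dtype=np.int8)
    codes[(pa & ~pb & ~arr.gap_b & ~arr.sty_b)
          | (pb & ~pa & ~arr.gap_a & ~arr.sty_a)] = _SID
    codes[(pa & ~pb & arr.sty_b) | (pb & ~pa & arr.sty_a)] = _STD
    codes[(pa & arr.gap_b) | (pb & arr.gap_a)] = _UNALIGNABLE
    codes[pa & pb] = _STC
    return codes


def classify_alignment(aln: OrthologAlignment) -> list[SiteColumn]:
    """Classify every column, returning rich per-column records."""
    arr = AlignmentArrays.from_alignment(aln)
    codes = classify_arrays(arr)
    out = []
    for i in range(len(aln)):
        ra, rb = aln.aa_a[i], aln.aa_b[i]
        out.append(SiteColumn(
            column=i + 1,
            res_a=ra, res_b=rb,
            phos_a=None if ra == GAP else aln.phospho_a[i] == "1",
            phos_b=None if rb == GAP else aln.phospho_b[i] == "1",
            diso_a=aln.diso_a[i], diso_b=aln.diso_b[i],
            category=_CODE_TO_NAME[int(codes[i])],
            residue_class_a=residue_class(ra),
            residue_class_b=residue_class(rb),
        ))
    return out


def is_class_mismatched_stc(col: SiteColumn) -> bool:
    """True for StC columns pairing an S/T with a phospho-Y (or vice versa).

    Such columns still count as StC but are excluded from residue-class
    sensitive analyses (compensation detection).
    """
    return (col.category == "StC"
            and col.residue_class_a != col.residue_class_b)


# ---------------------------------------------------------------------------
# Category summaries
# ---------------------------------------------------------------------------

def _disorder_stratum(da: str, db: str) -> str:
    """Disorder stratum of a column: disordered / ordered / mixed.

    A gap side contributes no information, so the other side's state is
    used; two informative sides that disagree are *mixed*.
    """
    flags = [f for f in (da, db) if f != GAP]
    if all(f == "*" for f in flags):
        return "disordered"
    if all(f == "." for f in flags):
        return "ordered"
    return "mixed"


@dataclass
class CategorySummary:
    """Counts and fractions of conservation categories over a dataset.

    ``union_total`` counts each column with at least one observed
    phosphosite among SiD/StC/StD exactly once (an StC column is one
    position, not two sites), so SiD + StC + StD = union_total.
    Unalignable phosphosites are tallied but sit outside the union.
    """

    counts: dict[str, int]
    union_total: int
    fractions: dict[str, float] | None
    disorder_strata: dict[str, dict[str, int]] = field(default_factory=dict)
    per_protein: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, sid: int, stc: int, std: int,
                    background: int = 0, unalignable: int = 0,
                    ) -> "CategorySummary":
        counts = {"SiD": sid, "StC": stc, "StD": std,
                  "background": background, "unalignable": unalignable}
        union = sid + stc + std
        fractions = None
        if union > 0:
            fractions = {k: counts[k] / union for k in PHOSPHO_CATEGORIES}
        return cls(counts=counts, union_total=union, fractions=fractions)


def summarize_categories(
    alignments: Iterable[OrthologAlignment],
) -> CategorySummary:
    """Count conservation categories across a set of ortholog alignments."""
    counts = {k: 0 for k in CATEGORIES}
    strata = {k: {"disordered": 0, "ordered": 0, "mixed": 0}
              for k in PHOSPHO_CATEGORIES}
    per_protein: dict[str, dict[str, int]] = {}
    for aln in alignments:
        arr = AlignmentArrays.from_alignment(aln)
        codes = classify_arrays(arr)
        pp = {k: 0 for k in CATEGORIES}
        for code, name in _CODE_TO_NAME.items():
            n = int(np.count_nonzero(codes == code))
            counts[name] += n
            pp[name] = n
        per_protein[aln.pair_id] = pp
        for code, name in ((_SID, "SiD"), (_STC, "StC"), (_STD, "StD")):
            for i in np.flatnonzero(codes == code):
                strata[name][_disorder_stratum(aln.diso_a[i], aln.diso_b[i])] += 1
    summary = CategorySummary.from_counts(
        counts["SiD"], counts["StC"], counts["StD"],
        counts["background"], counts["unalignable"])
    summary.disorder_strata = strata
    summary.per_protein = per_protein
    return summary


# ---------------------------------------------------------------------------
# Poly-S/T/Y clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyCluster:
    """A maximal run of >= 2 consecutive S/T/Y residues in one species.

    ``start``/``end`` are 1-based alignment columns, inclusive. Gaps break
    runs.
    """

    species: str
    start: int
    end: int
    contains_phospho: bool
    category: str | None = None


def find_poly_clusters(aln: OrthologAlignment, species: str) -> list[PolyCluster]:
    aa = aln.aa(species)
    phos = aln.phospho(species)
    clusters: list[PolyCluster] = []
    start = None
    for i in range(len(aa) + 1):
        in_run = i < len(aa) and aa[i] in PHOSPHO_RESIDUES
        if in_run and start is None:
            start = i
        elif not in_run and start is not None:
            if i - start >= 2:
                clusters.append(PolyCluster(
                    species=species, start=start + 1, end=i,
                    contains_phospho="1" in phos[start:i]))
            start = None
    return clusters


def classify_poly_cluster_overlaps(aln: OrthologAlignment) -> list[PolyCluster]:
    """Assign the cluster-level trichotomy to both species' clusters.

    Two clusters overlap iff they share at least one alignment column.
    A phospho-containing cluster with no overlapping partner is SiD-c; an
    overlapping pair where both carry phosphosites is StC-c; one where
    exactly one carries a phosphosite is StD-c (both members); anything
    without phosphorylation on either side is background-c.
    """
    ca = find_poly_clusters(aln, aln.species_a_id)
    cb = find_poly_clusters(aln, aln.species_b_id)
    out: list[PolyCluster] = []
    for mine, theirs in ((ca, cb), (cb, ca)):
        for c in mine:
            partners = [o for o in theirs
                        if c.start <= o.end and o.start <= c.end]
            if not partners:
                cat = "SiD-c" if c.contains_phospho else "background-c"
            else:
                partner_phos = any(o.contains_phospho for o in partners)
                if c.contains_phospho and partner_phos:
                    cat = "StC-c"
                elif c.contains_phospho or partner_phos:
                    cat = "StD-c"
                else:
                    cat = "background-c"
            out.append(PolyCluster(c.species, c.start, c.end,
                                   c.contains_phospho, cat))
    return out


def summarize_poly_clusters(
    alignments: Iterable[OrthologAlignment],
) -> dict[str, int]:
    counts = {"SiD-c": 0, "StC-c": 0, "StD-c": 0, "background-c": 0}
    for aln in alignments:
        for c in classify_poly_cluster_overlaps(aln):
            counts[c.category] += 1
    return counts


# ---------------------------------------------------------------------------
# Abundance bins and annotation enrichment
# ---------------------------------------------------------------------------

def stc_fraction_by_abundance_bins(
    per_protein: Mapping[str, Mapping[str, int]],
    abundance: Mapping[str, float],
    k: int = 4,
) -> tuple[pd.DataFrame, list[str]]:
    """State-conservation as a function of protein abundance.

    Proteins are sorted by ascending abundance (ties broken by id) and
    split into ``k`` equal-size bins (remainders go to the lowest bins).
    Each bin reports StC / (StC + StD) over its proteins' conserved
    phosphorylatable columns — the fraction of residue-conserved
    phosphosites whose phosphorylation state is conserved. Proteins
    without an abundance value are dropped and returned separately.
    """
    dropped = sorted(p for p in per_protein if p not in abundance)
    usable = sorted(
        (p for p in per_protein if p in abundance),
        key=lambda p: (abundance[p], p))
    n = len(usable)
    if k < 1 or k > n:
        raise ValueError(f"cannot split {n} proteins into {k} bins")
    base, rem = divmod(n, k)
    sizes = [base + 1 if i < rem else base for i in range(k)]
    rows = []
    start = 0
    for b, size in enumerate(sizes, start=1):
        members = usable[start:start + size]
        start += size
        stc = sum(per_protein[p].get("StC", 0) for p in members)
        std = sum(per_protein[p].get("StD", 0) for p in members)
        frac = stc / (stc + std) if stc + std else np.nan
        rows.append({"bin": b, "n_proteins": size, "StC": stc, "StD": std,
                     "stc_fraction": frac})
    return pd.DataFrame(rows), dropped


@dataclass(frozen=True)
class ProportionTest:
    proportion_1: float
    proportion_2: float
    p_value: float | None  # None when the test is not applicable
    n_1: int
    n_2: int


def proportion_test_from_counts(x1: int, n1: int, x2: int, n2: int,
                                ) -> ProportionTest:
    """Two-sample test of equal proportions with continuity correction.

    The chi-square statistic on the 2x2 table with Yates' continuity
    correction, two-sided (the classic ``prop.test`` behaviour). Degenerate
    tables (an all-zero or all-one margin) are reported as not applicable.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("empty site set")
    p1, p2 = x1 / n1, x2 / n2
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return ProportionTest(p1, p2, None, n1, n2)
    if p1 == p2:
        return ProportionTest(p1, p2, 1.0, n1, n2)
    res = stats.chi2_contingency(table, correction=True)
    return ProportionTest(p1, p2, float(res.pvalue), n1, n2)


def _protein_of(site) -> str:
    if isinstance(site, PhosphoSite):
        return site.protein_id
    if isinstance(site, str):
        return site
    return site[0]


def annotation_proportion_test(
    sites_1: Sequence,
    sites_2: Sequence,
    labeled_proteins: set[str],
) -> ProportionTest:
    """Compare the fraction of two site sets lying in annotated proteins.

    ``sites_*`` may be :class:`PhosphoSite` objects, protein ids, or
    tuples whose first element is a protein id; ``labeled_proteins`` is
    e.g. a housekeeping or tissue-specific protein list.
    """
    if not labeled_proteins:
        raise ValueError("empty annotation label set")
    if not sites_1 or not sites_2:
        raise ValueError("empty site set")
    x1 = sum(1 for s in sites_1 if _protein_of(s) in labeled_proteins)
    x2 = sum(1 for s in sites_2 if _protein_of(s) in labeled_proteins)
    return proportion_test_from_counts(x1, len(sites_1), x2, len(sites_2))
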