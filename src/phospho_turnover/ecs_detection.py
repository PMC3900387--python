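"""Detection of evolutionarily clustered sites (ECS).

An ECS pair is a site-diverged (SiD) phosphosite in species a and a SiD
phosphosite in species b, on the same ortholog pair and of the same
residue class (S/T or Y — the classes never compensate each other), that
sit closer together in the alignment than expected by chance. Such pairs
are candidates for positional turnover: a site lost in one lineage
compensated by a gain nearby in the other.

The chance expectation fixes the a-species sites and re-places the
b-species SiD sites uniformly within their residue x disorder stratum,
excluding *masked* columns — positions phosphorylatable in both species,
which could never host a SiD site. For a grid of odd window lengths L the
colocalization fraction (a-sites with a b-site within (L-1)/2 columns) is
compared with its permutation null; a protein's class is called at the
smallest significant L and the closest cross-species pair in each window
is reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .core_io import GAP, PHOSPHO_RESIDUES, OrthologAlignment, residue_class
from .classification import AlignmentArrays, classify_arrays
from .null_models import as_rng, empirical_p

logger = logging.getLogger(__name__)

DEFAULT_L_VALUES: tuple[int, ...] = tuple(range(3, 82, 2))  # half-window <= 40


@dataclass(frozen=True)
class SidSites:
    """SiD phosphosite columns (1-based) of one residue class."""

    residue_class: str
    a_columns: tuple[int, ...]
    b_columns: tuple[int, ...]

    @property
    def eligible(self) -> bool:
        return bool(self.a_columns) and bool(self.b_columns)


@dataclass
class ColocalizationProfile:
    """Observed and null colocalization fractions over a window grid."""

    pair_id: str
    residue_class: str
    L_values: tuple[int, ...]
    observed_fraction: np.ndarray  # per L
    null_fractions: np.ndarray  # (n_iterations, len(L_values))

    def p_values(self) -> np.ndarray:
        """Add-one upper-tail empirical p per window length."""
        return np.array([
            empirical_p(self.observed_fraction[j], self.null_fractions[:, j])
            for j in range(len(self.L_values))
        ])

    def min_p_test(self) -> tuple[float, int]:
        """Scan-adjusted protein-level p and the index of the calling window.

        Scanning the window grid for the smallest per-L p is itself a
        selection, so the protein-level statistic is min-p over L and its
        null is the same min-p computed for every replicate against the
        replicate ensemble (a max-T style adjustment). Under
        exchangeability of the b-site placements this is calibrated at any
        level. The calling window is the smallest L attaining the minimal
        per-L p.
        """
        n, nL = self.null_fractions.shape
        obs_p = self.p_values()
        # per-replicate per-L upper-tail p against the ensemble
        rep_p = np.empty((n, nL))
        for j in range(nL):
            col = self.null_fractions[:, j]
            srt = np.sort(col)
            # #{f_i >= f} = n - first index of f in sorted order
            rep_p[:, j] = (n - np.searchsorted(srt, col, side="left")) / n
        s_obs = float(obs_p.min())
        s_rep = rep_p.min(axis=1)
        adjusted = (1 + int(np.count_nonzero(s_rep <= s_obs))) / (1 + n)
        best = int(np.flatnonzero(obs_p == obs_p.min())[0])
        return adjusted, best


@dataclass(frozen=True)
class ECSPair:
    """A significant cross-species SiD-SiD clustered pair."""

    pair_id: str
    residue_class: str
    column_a: int
    column_b: int
    distance: int
    window: int  # calling window length L
    empirical_p: float

    def __post_init__(self) -> None:
        if self.distance > (self.window - 1) // 2:
            raise ValueError("pair distance exceeds the calling half-window")


# ---------------------------------------------------------------------------
# SiD site extraction and the masked landing space
# ---------------------------------------------------------------------------

def find_sid_sites_by_class(
    aln: OrthologAlignment,
) -> dict[str, SidSites]:
    """SiD phosphosites split by residue class and phosphorylated species."""
    arr = AlignmentArrays.from_alignment(aln)
    codes = classify_arrays(arr)
    sid = codes == 1
    out = {}
    for cls in ("ST", "Y"):
        a_cols = tuple(
            int(i) + 1 for i in np.flatnonzero(sid & arr.phos_a)
            if residue_class(aln.aa_a[i]) == cls)
        b_cols = tuple(
            int(i) + 1 for i in np.flatnonzero(sid & arr.phos_b)
            if residue_class(aln.aa_b[i]) == cls)
        out[cls] = SidSites(cls, a_cols, b_cols)
    return out


def masked_columns(aln: OrthologAlignment) -> np.ndarray:
    """Boolean mask of columns phosphorylatable in both species.

    These positions can never hold a SiD site and are excluded as landing
    positions in the null.
    """
    arr = AlignmentArrays.from_alignment(aln)
    return arr.sty_a & arr.sty_b


def _landing_strata(
    aln: OrthologAlignment, b_columns: Sequence[int],
) -> list[tuple[np.ndarray, int]]:
    """(landing columns, number of sites to place) per b stratum.

    A stratum is the b residue letter crossed with b's disorder state;
    landing positions are unmasked b columns of that stratum.
    """
    arr = AlignmentArrays.from_alignment(aln)
    masked = arr.sty_a & arr.sty_b
    b_set = list(b_columns)
    strata = []
    for r in PHOSPHO_RESIDUES:
        for d in "*.":
            in_stratum = (arr.res_b == r) & (arr.diso_b == d) & ~masked
            k = sum(1 for c in b_set
                    if aln.aa_b[c - 1] == r and aln.diso_b[c - 1] == d)
            if k == 0:
                continue
            land = np.flatnonzero(in_stratum) + 1  # 1-based columns
            if land.size < k:
                raise RuntimeError(
                    f"{aln.pair_id}: stratum ({r},{d}) has {land.size} landing "
                    f"positions for {k} sites")
            strata.append((land, k))
    return strata


def _min_distances(a_cols: np.ndarray, b_cols: np.ndarray) -> np.ndarray:
    """Per a-site minimum |column difference| to any b column."""
    return np.min(np.abs(a_cols[:, None] - b_cols[None, :]), axis=1)


def _fractions_from_mindist(mind: np.ndarray,
                            half_windows: np.ndarray) -> np.ndarray:
    """Colocalized fraction per window from per-a-site min distances."""
    return (mind[:, None] <= half_windows[None, :]).mean(axis=0)


# ---------------------------------------------------------------------------
# Profiles: Monte-Carlo and exhaustive nulls
# ---------------------------------------------------------------------------

def colocalization_profile(
    aln: OrthologAlignment,
    residue_class: str,
    L_values: Sequence[int] = DEFAULT_L_VALUES,
    n_iterations: int = 1000,
    seed=None,
) -> ColocalizationProfile | None:
    """Observed and permutation-null colocalization fractions.

    Returns None (with a logged reason) when the protein is ineligible for
    the class or a stratum lacks landing room.
    """
    L = np.asarray(L_values, dtype=int)
    if np.any(L < 3) or np.any(L % 2 == 0):
        raise ValueError("window lengths must be odd and >= 3")
    sites = find_sid_sites_by_class(aln)[residue_class]
    if not sites.eligible:
        logger.debug("%s/%s: ineligible (needs SiD sites in both species)",
                     aln.pair_id, residue_class)
        return None
    try:
        strata = _landing_strata(aln, sites.b_columns)
    except RuntimeError as exc:
        logger.debug("skipping %s: %s", aln.pair_id, exc)
        return None
    rng = as_rng(seed)
    a_cols = np.array(sites.a_columns)
    half = (L - 1) // 2

    observed = _fractions_from_mindist(
        _min_distances(a_cols, np.array(sites.b_columns)), half)

    n_b = sum(k for _, k in strata)
    placements = np.empty((n_iterations, n_b), dtype=int)
    j = 0
    for land, k in strata:
        # k draws without replacement per iteration, vectorized
        keys = rng.random((n_iterations, land.size))
        placements[:, j:j + k] = land[np.argsort(keys, axis=1)[:, :k]]
        j += k
    # (n_a, n_iter, n_b) distance tensor; a-site counts are small
    d = np.abs(a_cols[:, None, None] - placements[None, :, :]).min(axis=2)
    null_frac = (d[:, :, None] <= half[None, None, :]).mean(axis=0)

    return ColocalizationProfile(
        pair_id=aln.pair_id, residue_class=residue_class,
        L_values=tuple(int(x) for x in L),
        observed_fraction=observed, null_fractions=null_frac)


def enumerate_null_fractions(
    aln: OrthologAlignment,
    residue_class: str,
    L_values: Sequence[int] = DEFAULT_L_VALUES,
    max_placements: int = 200_000,
) -> np.ndarray | None:
    """Colocalization fractions for *every* b-site placement (exact null).

    Enumerates the product over strata of all landing-position
    combinations. Intended for small instances (tests and calibration);
    refuses to enumerate beyond ``max_placements``.
    """
    from math import comb

    L = np.asarray(L_values, dtype=int)
    sites = find_sid_sites_by_class(aln)[residue_class]
    if not sites.eligible:
        return None
    strata = _landing_strata(aln, sites.b_columns)
    total = 1
    for land, k in strata:
        total *= comb(land.size, k)
    if total > max_placements:
        raise ValueError(f"{total} placements exceed max_placements")
    a_cols = np.array(sites.a_columns)
    half = (L - 1) // 2
    per_stratum = [
        [np.array(c) for c in itertools.combinations(land.tolist(), k)]
        for land, k in strata
    ]
    out = np.empty((total, L.size))
    for i, combo in enumerate(itertools.product(*per_stratum)):
        b_cols = np.concatenate(combo)
        out[i] = _fractions_from_mindist(_min_distances(a_cols, b_cols), half)
    return out


# ---------------------------------------------------------------------------
# Calling ECS pairs
# ---------------------------------------------------------------------------

def _pairs_at_window(
    aln: OrthologAlignment,
    sites: SidSites,
    L: int,
    p: float,
) -> list[ECSPair]:
    half = (L - 1) // 2
    b_cols = np.array(sites.b_columns)
    pairs: list[ECSPair] = []
    seen: set[tuple[int, int]] = set()
    for ca in sites.a_columns:
        d = np.abs(b_cols - ca)
        if d.min() > half:
            continue
        best = int(d.min())
        # equidistant partners break toward the N-terminal (smaller column)
        cb = int(b_cols[d == best].min())
        if (ca, cb) in seen:
            continue
        seen.add((ca, cb))
        pairs.append(ECSPair(
            pair_id=aln.pair_id, residue_class=sites.residue_class,
            column_a=ca, column_b=cb, distance=best,
            window=L, empirical_p=p))
    return pairs


def detect_ecs(
    aln: OrthologAlignment,
    residue_class: str,
    L_values: Sequence[int] = DEFAULT_L_VALUES,
    n_iterations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    profile: ColocalizationProfile | None = None,
) -> list[ECSPair]:
    """ECS pairs for one ortholog pair and residue class.

    The protein's class is called when the scan-adjusted min-p over the
    window grid (:meth:`ColocalizationProfile.min_p_test`) is <= alpha;
    within the calling window around each colocalized a-site the closest
    b-site is reported, each a-site contributing at most one pair.
    """
    if profile is None:
        profile = colocalization_profile(
            aln, residue_class, L_values, n_iterations, seed)
    if profile is None:
        return []
    adjusted_p, j = profile.min_p_test()
    if adjusted_p > alpha:
        return []
    sites = find_sid_sites_by_class(aln)[residue_class]
    return _pairs_at_window(aln, sites, profile.L_values[j], adjusted_p)


def detect_ecs_dataset(
    alignments: Iterable[OrthologAlignment],
    L_values: Sequence[int] = DEFAULT_L_VALUES,
    n_iterations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    max_pairs_per_protein: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """ECS calls over a dataset, with BH-adjusted per-protein p values.

    Proteins yielding more than ``max_pairs_per_protein`` pairs in one
    class are flagged as large clusters and excluded from the table (their
    ids are returned separately), since a dense run of sites makes the
    closest-pair readout uninformative.
    """
    rng = as_rng(seed)
    all_pairs: list[ECSPair] = []
    flagged: list[str] = []
    for aln in alignments:
        for cls in ("ST", "Y"):
            pairs = detect_ecs(aln, cls, L_values, n_iterations, alpha, rng)
            if len(pairs) > max_pairs_per_protein:
                flagged.append(f"{aln.pair_id}/{cls}")
            else:
                all_pairs.extend(pairs)
    if not all_pairs:
        return pd.DataFrame(columns=[
            "pair_id", "residue_class", "column_a", "column_b", "distance",
            "window", "empirical_p", "adjusted_p"]), flagged
    df = pd.DataFrame([{
        "pair_id": p.pair_id, "residue_class": p.residue_class,
        "column_a": p.column_a, "column_b": p.column_b,
        "distance": p.distance, "window": p.window,
        "empirical_p": p.empirical_p,
    } for p in all_pairs])
    # one p per protein/class test; broadcast its BH-adjusted value
    tests = df.groupby(["pair_id", "residue_class"])["empirical_p"].first()
    adjusted = pd.Series(
        _sstats.false_discovery_control(tests.to_numpy(), method="bh"),
        index=tests.index)
    df["adjusted_p"] = [
        adjusted[(r.pair_id, r.residue_class)] for r in df.itertuples()]
    return df, flagged
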