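"""Kinase motif scoring of phosphoacceptor 10-mers and derived statistics.

Each kinase is summarized by a 10 x 20 probability matrix with the
phosphoacceptor at position 6. A 10-mer's score under a matrix is the
geometric mean of the per-position probabilities of its residues — a
length-normalized quantity on (0, 1] that behaves like a motif-match
probability. Windows running past a protein terminus are padded with a
neutral symbol valued at the position-mean probability (1/20 for a proper
probability row), so terminal sites are scored rather than discarded.

On top of the scorer sit the comparative statistics: score-set
comparisons (rank-sum), cross-species score correlations (Spearman), the
excess-divergence fraction that bounds how many state-diverged sites
plausibly diverged in their kinase recognition motif, and permutation
tests for shared kinase assignment between paired sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import classify_alignment
from .core_io import (
    AA_INDEX,
    GAP,
    PAD,
    PHOSPHO_RESIDUES,
    KinasePWM,
    OrthologAlignment,
    residue_class,
)
from .null_models import NullDistribution, _make_null, as_rng

SCORE_FLOOR = 1e-6  # zero matrix entries are floored before taking logs
WINDOW = 10
ACCEPTOR_OFFSET = 5  # 0-based index of the acceptor within the window


@dataclass
class KinaseAssignment:
    """Ranked kinase predictions for one site.

    ``ranked`` is sorted by descending score with ties broken by kinase
    name; ``best_score`` is the top score.
    """

    site: object
    ranked: tuple[tuple[str, float], ...]

    @property
    def best_kinase(self) -> str:
        return self.ranked[0][0]

    @property
    def best_score(self) -> float:
        return self.ranked[0][1]

    def top_kinases(self, k: int) -> tuple[str, ...]:
        return tuple(name for name, _ in self.ranked[:k])


def extract_window(sequence: str, position: int) -> str:
    """The 10-mer around a 1-based acceptor position, PAD-padded at termini."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence")
    i = position - 1
    left = sequence[max(0, i - ACCEPTOR_OFFSET):i]
    right = sequence[i + 1:i + WINDOW - ACCEPTOR_OFFSET]
    return (PAD * (ACCEPTOR_OFFSET - len(left)) + left + sequence[i]
            + right + PAD * (WINDOW - ACCEPTOR_OFFSET - 1 - len(right)))


def score_10mer(pwm: KinasePWM, tenmer: str) -> float:
    """Geometric-mean PWM score of a 10-mer with acceptor at position 6."""
    if len(tenmer) != WINDOW:
        raise ValueError(f"window must have {WINDOW} residues, got {tenmer!r}")
    if tenmer[ACCEPTOR_OFFSET] not in PHOSPHO_RESIDUES:
        raise ValueError(
            f"acceptor residue {tenmer[ACCEPTOR_OFFSET]!r} is not S/T/Y")
    log_sum = 0.0
    for pos, res in enumerate(tenmer):
        if res == PAD or res == GAP:
            p = float(np.mean(pwm.matrix[pos]))
        else:
            try:
                p = float(pwm.matrix[pos, AA_INDEX[res]])
            except KeyError:
                raise ValueError(f"unknown residue {res!r} in window") from None
        log_sum += np.log(max(p, SCORE_FLOOR))
    return float(np.exp(log_sum / WINDOW))


def compatible_pwms(pwms: Sequence[KinasePWM], acceptor: str,
                    ) -> list[KinasePWM]:
    """Matrices applicable to this acceptor: ST-kinases to S/T, Y-kinases to Y."""
    cls = residue_class(acceptor)
    if cls is None:
        raise ValueError(f"acceptor {acceptor!r} is not S/T/Y")
    return [p for p in pwms if p.acceptor_class == cls]


def rank_kinases(pwms: Sequence[KinasePWM], tenmer: str, k: int = 3,
                 site: object = None) -> KinaseAssignment:
    """Top-k kinases for a 10-mer, ties broken by kinase name ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not pwms:
        raise ValueError("at least one PWM required")
    usable = compatible_pwms(pwms, tenmer[ACCEPTOR_OFFSET])
    if not usable:
        raise ValueError(
            f"no PWM compatible with acceptor {tenmer[ACCEPTOR_OFFSET]!r}")
    scored = sorted(
        ((p.kinase, score_10mer(p, tenmer)) for p in usable),
        key=lambda kv: (-kv[1], kv[0]))
    return KinaseAssignment(site=site, ranked=tuple(scored[:k]))


# ---------------------------------------------------------------------------
# Score-set statistics
# ---------------------------------------------------------------------------

def compare_score_sets(scores_1: Sequence[float], scores_2: Sequence[float],
                       ) -> tuple[float, float, float]:
    """Medians plus two-sided rank-sum p for two score sets.

    The exact null distribution is enumerated for small samples
    (combined n <= 20, no ties); otherwise the tie-corrected normal
    approximation with continuity correction is used. An all-identical
    pooled sample carries no ordering information and reports p = 1.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("score sets must be nonempty")
    m1, m2 = float(np.median(s1)), float(np.median(s2))
    pooled = np.concatenate([s1, s2])
    if np.all(pooled == pooled[0]):
        return m1, m2, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (s1.size + s2.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(s1, s2, alternative="two-sided", method=method)
    return m1, m2, float(res.pvalue)


def score_correlation(pairs: Sequence[tuple[float, float]],
                      ) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) on paired scores."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 complete score pairs")
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)


def excess_divergence_fraction(p_std_a_gt_b: float, p_stc_a_gt_b: float,
                               p_std_b_gt_a: float, p_stc_b_gt_a: float,
                               ) -> float:
    """Lower bound on the fraction of StD sites with diverged kinase motifs.

    Each input is the fraction of site pairs (of the named category) whose
    member in the named species outscores its ortholog. The StC proportions
    serve as the no-divergence baseline; the excess of StD over StC is
    summed over the two directions, each term floored at 0.
    """
    for p in (p_std_a_gt_b, p_stc_a_gt_b, p_std_b_gt_a, p_stc_b_gt_a):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return (max(0.0, p_std_a_gt_b - p_stc_a_gt_b)
            + max(0.0, p_std_b_gt_a - p_stc_b_gt_a))


# ---------------------------------------------------------------------------
# Scoring sites across alignments
# ---------------------------------------------------------------------------

def score_alignment_sites(
    alignments: Iterable[OrthologAlignment],
    pwms: Sequence[KinasePWM],
) -> pd.DataFrame:
    """Best PWM score in each species for every StC/StD column.

    One row per qualifying column: pair_id, column, category, the species
    carrying the phosphosite for StD ('both' for StC), the two best
    scores, and the two best kinases. Only columns phosphorylatable in
    both species are scored (SiD and unalignable sites have no orthologous
    acceptor to compare with).
    """
    rows = []
    for aln in alignments:
        seq_a = aln.ungapped_sequence("a")
        seq_b = aln.ungapped_sequence("b")
        for col in classify_alignment(aln):
            if col.category not in ("StC", "StD"):
                continue
            if col.residue_class_a != col.residue_class_b:
                continue  # S/T vs Y pairs score under different kinase sets
            pos_a = aln.position_of("a", col.column)
            pos_b = aln.position_of("b", col.column)
            ass_a = rank_kinases(pwms, extract_window(seq_a, pos_a))
            ass_b = rank_kinases(pwms, extract_window(seq_b, pos_b))
            phospho_in = "both" if col.category == "StC" else (
                "a" if col.phos_a else "b")
            rows.append({
                "pair_id": aln.pair_id, "column": col.column,
                "category": col.category, "phospho_in": phospho_in,
                "score_a": ass_a.best_score, "score_b": ass_b.best_score,
                "kinase_a": ass_a.best_kinase, "kinase_b": ass_b.best_kinase,
                "top3_a": ass_a.top_kinases(3), "top3_b": ass_b.top_kinases(3),
            })
    return pd.DataFrame(rows)


def divergence_excess_from_scores(scored: pd.DataFrame) -> dict:
    """The four outscoring proportions and their excess, from scored sites.

    For sites phosphorylated in species a (StD) the relevant proportion is
    how often the a score exceeds the b score, compared with the same
    proportion among StC sites; symmetrically for b. Ties count as not
    outscoring.
    """
    def frac_gt(df: pd.DataFrame, first: str, second: str) -> float:
        if len(df) == 0:
            return float("nan")
        return float((df[first] > df[second]).mean())

    stc = scored[scored.category == "StC"]
    std_a = scored[(scored.category == "StD") & (scored.phospho_in == "a")]
    std_b = scored[(scored.category == "StD") & (scored.phospho_in == "b")]
    p_std_a = frac_gt(std_a, "score_a", "score_b")
    p_stc_a = frac_gt(stc, "score_a", "score_b")
    p_std_b = frac_gt(std_b, "score_b", "score_a")
    p_stc_b = frac_gt(stc, "score_b", "score_a")
    out = {
        "p_std_a_gt_b": p_std_a, "p_stc_a_gt_b": p_stc_a,
        "p_std_b_gt_a": p_std_b, "p_stc_b_gt_a": p_stc_b,
    }
    if any(np.isnan(v) for v in out.values()):
        out["excess_fraction"] = float("nan")
    else:
        out["excess_fraction"] = excess_divergence_fraction(
            p_std_a, p_stc_a, p_std_b, p_stc_b)
    return out


def fraction_phosphorylated_by_score_bin(
    scores: Sequence[float],
    phosphorylated: Sequence[bool],
    n_bins: int = 5,
) -> pd.DataFrame:
    """Fraction of phosphorylated acceptors per best-score quantile bin."""
    s = np.asarray(scores, dtype=float)
    ph = np.asarray(phosphorylated, dtype=bool)
    if s.size != ph.size or s.size == 0:
        raise ValueError("scores and flags must be nonempty and aligned")
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins, start=1):
        rows.append({
            "bin": b, "n": idx.size,
            "mean_score": float(s[idx].mean()) if idx.size else np.nan,
            "fraction_phosphorylated":
                float(ph[idx].mean()) if idx.size else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared-kinase permutation tests
# ---------------------------------------------------------------------------

def kinase_overlap_test(
    site_pairs: Sequence[tuple],
    mode: str = "best1",
    n_iterations: int | None = None,
    seed=None,
) -> NullDistribution:
    """Do paired sites share kinases more often than label chance allows?

    ``site_pairs`` holds ``(kinases_1, kinases_2)`` tuples of ranked
    kinase names (or :class:`KinaseAssignment` objects). ``best1`` scores
    a pair as shared when the top kinases agree; ``top3`` when the top-3
    lists intersect. The null permutes the second members' assignments
    across pairs (defaults: 10,000 iterations for best1, 100 for top3).
    """
    if mode not in ("best1", "top3"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(site_pairs) < 2:
        raise ValueError("need >= 2 pairs for a permutation null")
    if n_iterations is None:
        n_iterations = 10_000 if mode == "best1" else 100
    rng = as_rng(seed)
    depth = 1 if mode == "best1" else 3

    def top(x) -> tuple[str, ...]:
        if isinstance(x, KinaseAssignment):
            return x.top_kinases(depth)
        return tuple(x[:depth])

    first = [frozenset(top(a)) for a, _ in site_pairs]
    second = [frozenset(top(b)) for _, b in site_pairs]
    n = len(site_pairs)

    def shared_fraction(perm: np.ndarray) -> float:
        return sum(1 for i in range(n) if first[i] & second[perm[i]]) / n

    observed = shared_fraction(np.arange(n))
    if mode == "best1":
        # sets are singletons: integer-encode for a vectorized null
        labels = sorted({next(iter(s)) for s in first}
                        | {next(iter(s)) for s in second})
        enc = {k: i for i, k in enumerate(labels)}
        f = np.array([enc[next(iter(s))] for s in first])
        s = np.array([enc[next(iter(x))] for x in second])
        perms = np.tile(s, (n_iterations, 1))
        perms = rng.permuted(perms, axis=1)
        reps = (perms == f[None, :]).mean(axis=1)
    else:
        reps = np.empty(n_iterations)
        for it in range(n_iterations):
            reps[it] = shared_fraction(rng.permutation(n))
    return _make_null(f"shared_kinase_{mode}", observed, reps)
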