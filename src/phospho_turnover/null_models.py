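"""Stratified permutation nulls for conservation-category counts.

The randomization preserves, within each protein and species, the number
of phosphosites per stratum, where a stratum is the residue identity
(S, T or Y) crossed with the local structural state (disordered or
ordered) taken from that species' own disorder track. Shuffling therefore
destroys only the cross-species coincidence of phosphorylation while
keeping the single-species composition exactly fixed — the property that
makes the StC fold interpretable as state-conservation beyond chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .classification import (
    PHOSPHO_CATEGORIES,
    AlignmentArrays,
    classify_arrays,
    summarize_categories,
)
from .core_io import GAP, PHOSPHO_RESIDUES, OrthologAlignment


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class NullDistribution:
    """An observed statistic with its permutation null."""

    statistic_name: str
    observed: float
    replicates: np.ndarray
    empirical_p: float
    fold: float  # observed / mean(replicates); inf when the null mean is 0

    @property
    def n_iterations(self) -> int:
        return len(self.replicates)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.replicates, q))


def empirical_p(observed: float, replicates: Sequence[float],
                tail: str = "upper") -> float:
    """Add-one empirical p-value: (1 + #{as extreme}) / (1 + n).

    The add-one convention counts the observed configuration as one more
    permutation, so p is never 0 at finite iteration counts.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("replicates must be nonempty")
    if tail == "upper":
        k = int(np.count_nonzero(reps >= observed))
    elif tail == "lower":
        k = int(np.count_nonzero(reps <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + reps.size)


def _make_null(name: str, observed: float, replicates: np.ndarray,
               tail: str = "upper") -> NullDistribution:
    mean = float(np.mean(replicates))
    fold = observed / mean if mean != 0 else float("inf")
    return NullDistribution(
        statistic_name=name,
        observed=float(observed),
        replicates=replicates,
        empirical_p=empirical_p(observed, replicates, tail=tail),
        fold=fold,
    )


# ---------------------------------------------------------------------------
# Stratified shuffling
# ---------------------------------------------------------------------------

def strata_indices(aa: str, diso: str) -> dict[tuple[str, str], np.ndarray]:
    """Column indices (0-based) of the six residue x disorder strata."""
    res = np.array(list(aa))
    dis = np.array(list(diso))
    out = {}
    for r in PHOSPHO_RESIDUES:
        for d in "*.":
            idx = np.flatnonzero((res == r) & (dis == d))
            if idx.size:
                out[(r, d)] = idx
    return out


def _shuffle_track(phos: np.ndarray,
                   strata: dict[tuple[str, str], np.ndarray],
                   rng: np.random.Generator) -> np.ndarray:
    out = phos.copy()
    for idx in strata.values():
        out[idx] = phos[idx][rng.permutation(idx.size)]
    return out


def shuffle_statuses(aln: OrthologAlignment, species: str,
                     seed) -> OrthologAlignment:
    """Uniformly permute one species' phospho flags within each stratum.

    The number of phosphorylated residues per (S/T/Y x disorder) stratum
    of that protein is exactly preserved; within a stratum every placement
    is equally likely.
    """
    rng = as_rng(seed)
    key = aln._species_key(species)
    aa = aln.aa(species)
    phos = np.array(list(aln.phospho(species)))
    shuffled = _shuffle_track(
        phos, strata_indices(aa, aln.diso(species)), rng)
    track = "".join(shuffled)
    if key == "a":
        return replace(aln, phospho_a=track)
    return replace(aln, phospho_b=track)


# ---------------------------------------------------------------------------
# Category-count nulls
# ---------------------------------------------------------------------------

def null_category_distribution(
    alignments: Iterable[OrthologAlignment],
    shuffle_species: str = "b",
    n_iterations: int = 100,
    seed=None,
) -> dict[str, NullDistribution]:
    """Permutation null for SiD / StC / StD counts.

    ``shuffle_species`` is ``"a"``, ``"b"`` (default; the species with the
    shallower phosphoproteome plays the role the randomization was designed
    for) or ``"both"``. Returns one :class:`NullDistribution` per phospho
    category; the empirical p is upper-tailed for StC and StD and
    lower-tailed for SiD would be a user choice — the replicates are kept,
    so any tail can be recomputed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = as_rng(seed)
    alns = list(alignments)
    observed = summarize_categories(alns)

    arrays = [AlignmentArrays.from_alignment(a) for a in alns]
    strata_a = [strata_indices(a.aa_a, a.diso_a) for a in alns] \
        if shuffle_species in ("a", "both") else None
    strata_b = [strata_indices(a.aa_b, a.diso_b) for a in alns] \
        if shuffle_species in ("b", "both") else None
    if shuffle_species not in ("a", "b", "both"):
        raise ValueError(f"unknown shuffle_species {shuffle_species!r}")

    reps = {k: np.empty(n_iterations) for k in PHOSPHO_CATEGORIES}
    code_of = {"SiD": 1, "StC": 2, "StD": 3}
    for it in range(n_iterations):
        totals = {k: 0 for k in PHOSPHO_CATEGORIES}
        for i, arr in enumerate(arrays):
            pa = arr.phos_a
            pb = arr.phos_b
            if strata_a is not None:
                pa = _shuffle_track(pa, strata_a[i], rng)
            if strata_b is not None:
                pb = _shuffle_track(pb, strata_b[i], rng)
            codes = classify_arrays(arr, phos_a=pa, phos_b=pb)
            for name, code in code_of.items():
                totals[name] += int(np.count_nonzero(codes == code))
        for name in PHOSPHO_CATEGORIES:
            reps[name][it] = totals[name]

    return {
        name: _make_null(name, observed.counts[name], reps[name])
        for name in PHOSPHO_CATEGORIES
    }


def null_poly_cluster_distribution(
    alignments: Iterable[OrthologAlignment],
    shuffle_species: str = "b",
    n_iterations: int = 1000,
    seed=None,
) -> dict[str, NullDistribution]:
    """Permutation null for poly-S/T/Y cluster categories.

    Cluster positions are fixed by the residue tracks; only the
    phosphorylation statuses are permuted (stratified as above), so the
    null asks whether phosphosites co-occur in overlapping clusters more
    than placement chance allows.
    """
    from .classification import summarize_poly_clusters

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = as_rng(seed)
    alns = list(alignments)
    observed = summarize_poly_clusters(alns)
    names = ("SiD-c", "StC-c", "StD-c")
    reps = {k: np.empty(n_iterations) for k in names}
    for it in range(n_iterations):
        shuffled = []
        for aln in alns:
            s = shuffle_statuses(aln, "b", rng) if shuffle_species in ("b", "both") \
                else aln
            if shuffle_species in ("a", "both"):
                s = shuffle_statuses(s, "a", rng)
            shuffled.append(s)
        counts = summarize_poly_clusters(shuffled)
        for k in names:
            reps[k][it] = counts[k]
    return {k: _make_null(k, observed[k], reps[k]) for k in names}


def null_report(nulls: dict[str, NullDistribution]) -> dict:
    """JSON-ready summary: observed, null mean, 95% band, fold, p."""
    return {
        name: {
            "observed": nd.observed,
            "null_mean": float(np.mean(nd.replicates)),
            "null_p2.5": nd.percentile(2.5),
            "null_p97.5": nd.percentile(97.5),
            "fold": nd.fold,
            "empirical_p": nd.empirical_p,
            "n_iterations": nd.n_iterations,
        }
        for name, nd in nulls.items()
    }
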