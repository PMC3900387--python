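"""Synthetic ortholog pairs with known phospho-evolutionary structure.

The generator emulates the statistical structure the comparative analysis
assumes: an ancestral protein with S/T/Y content and contiguous disordered
blocks, two descendant sequences derived by independent substitutions and
indels (the ancestor defines the column space, so ground-truth alignment
columns are exact), true phosphorylation states whose cross-species
coupling is controlled by a conservation multiplier rho, imperfect
per-species detection (false negatives) plus a false-positive rate, and
optionally planted compensatory SiD-SiD pairs for recovery experiments.

At conserved phosphorylatable columns the joint truth is

    P(both phosphorylated) = rho * p^2,   P(each) = p,

with p the per-residue phospho density; rho = 1 is independence and
rho > 1 models purifying selection on phosphoregulation. Everything is
deterministic under the config seed, with per-pair substreams keyed by
pair index so earlier pairs are unchanged when ``n_pairs`` grows.

All parameter values are modelling choices of this package, not estimates
from any particular dataset; see the methods note for the rationale
behind each default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    AA20,
    AA_INDEX,
    DISORDERED,
    GAP,
    ORDERED,
    PHOSPHO_RESIDUES,
    KinasePWM,
    OrthologAlignment,
)

_NON_STY = [a for a in AA20 if a not in PHOSPHO_RESIDUES]
# S:T:Y usage roughly as in mammalian proteomes
_STY_WEIGHTS = {"S": 0.51, "T": 0.33, "Y": 0.16}


@dataclass
class SimulationConfig:
    """Parameters of the ortholog-pair generator.

    Defaults describe a mammalian-like comparison: ~16% of residues
    phosphorylatable, ~10% of those reported phosphorylated, ~7%
    per-lineage amino-acid divergence, a 2.5-fold cross-species coupling
    of true phosphorylation, and detection that is about twice as deep in
    species a as in species b.
    """

    n_pairs: int = 100
    length_mean: float = 500.0
    sty_fraction: float = 0.16
    disorder_block_fraction: float = 0.4
    disorder_block_length_mean: float = 30.0
    substitution_rate: float = 0.07
    indel_rate: float = 0.003
    indel_length_mean: float = 3.0
    phospho_density: float = 0.10
    conservation_multiplier: float = 2.5
    detection_sensitivity_a: float = 0.8
    detection_sensitivity_b: float = 0.4
    false_positive_rate: float = 0.005
    n_planted_ecs: int = 0
    planted_ecs_max_distance: int = 10
    species_a_id: str = "spa"
    species_b_id: str = "spb"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "sty_fraction": self.sty_fraction,
            "disorder_block_fraction": self.disorder_block_fraction,
            "substitution_rate": self.substitution_rate,
            "indel_rate": self.indel_rate,
            "phospho_density": self.phospho_density,
            "detection_sensitivity_a": self.detection_sensitivity_a,
            "detection_sensitivity_b": self.detection_sensitivity_b,
            "false_positive_rate": self.false_positive_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.conservation_multiplier < 0:
            raise ValueError("conservation_multiplier must be >= 0")
        if self.n_planted_ecs > self.n_pairs:
            raise ValueError("cannot plant more ECS pairs than proteins")
        if self.planted_ecs_max_distance < 1:
            raise ValueError("planted_ecs_max_distance must be >= 1")
        p = self.phospho_density
        if p > 0 and self.conservation_multiplier * p > 1.0:
            warnings.warn(
                f"conservation_multiplier {self.conservation_multiplier} "
                f"exceeds 1/phospho_density; clipping to {1.0 / p:.3g}",
                stacklevel=2)
            self.conservation_multiplier = 1.0 / p
        if 1.0 - 2.0 * p + self.conservation_multiplier * p * p < -1e-12:
            raise ValueError(
                "infeasible joint: P(neither phosphorylated) would be "
                "negative for this density/multiplier combination")


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one planted effect, for recovery tests."""

    pair_id: str
    kind: str  # ecs_pair | conserved_site | diverged_site
    columns: tuple[int, ...]
    species: tuple[str, ...]


def _pair_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index, stream)))


def _disorder_track(n: int, cfg: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Alternating disorder/order runs with geometric lengths."""
    f = cfg.disorder_block_fraction
    mean_d = max(cfg.disorder_block_length_mean, 1.0)
    if f <= 0.0:
        return np.full(n, ORDERED, dtype="<U1")
    if f >= 1.0:
        return np.full(n, DISORDERED, dtype="<U1")
    mean_o = max(mean_d * (1.0 - f) / f, 1.0)
    out = np.empty(n, dtype="<U1")
    state = DISORDERED if rng.random() < f else ORDERED
    i = 0
    while i < n:
        mean = mean_d if state == DISORDERED else mean_o
        run = int(rng.geometric(1.0 / mean))
        out[i:i + run] = state
        i += run
        state = ORDERED if state == DISORDERED else DISORDERED
    return out


def _ancestor(n: int, cfg: SimulationConfig,
              rng: np.random.Generator) -> np.ndarray:
    res = np.array(
        rng.choice(list(_NON_STY), size=n), dtype="<U1")
    sty = rng.random(n) < cfg.sty_fraction
    letters = np.array(list(_STY_WEIGHTS), dtype="<U1")
    weights = np.array(list(_STY_WEIGHTS.values()))
    res[sty] = rng.choice(letters, size=int(sty.sum()), p=weights / weights.sum())
    return res


def _substitute(res: np.ndarray, rate: float,
                rng: np.random.Generator) -> np.ndarray:
    out = res.copy()
    hit = np.flatnonzero(rng.random(res.size) < rate)
    for i in hit:
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _delete_runs(n: int, cfg: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Boolean deletion mask from geometric-length deletion events."""
    gap = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(rng.random(n) < cfg.indel_rate)
    for s in starts:
        run = int(rng.geometric(1.0 / max(cfg.indel_length_mean, 1.0)))
        gap[s:s + run] = True
    return gap


def _draw_joint_phospho(
    both_sty: np.ndarray, only_a: np.ndarray, only_b: np.ndarray,
    cfg: SimulationConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """True phospho flags with coupling rho at conserved S/T/Y columns."""
    n = both_sty.size
    p = cfg.phospho_density
    rho = cfg.conservation_multiplier
    pa = np.zeros(n, dtype=bool)
    pb = np.zeros(n, dtype=bool)
    # conserved columns: sample the 2x2 joint (p11, p10, p01, p00)
    p11 = rho * p * p
    p10 = p - p11
    u = rng.random(n)
    pa[both_sty] = (u < p11 + p10)[both_sty]
    v = rng.random(n)
    # P(b=1 | a=1) = p11/p ; P(b=1 | a=0) = p10/(1-p)
    cond = np.where(pa, p11 / p if p > 0 else 0.0,
                    p10 / (1.0 - p) if p < 1 else 1.0)
    pb[both_sty] = (v < cond)[both_sty]
    # unpaired phosphorylatable residues are independent
    pa[only_a] = rng.random(n)[only_a] < p
    pb[only_b] = rng.random(n)[only_b] < p
    return pa, pb


def _simulate_pair(index: int, cfg: SimulationConfig) -> OrthologAlignment:
    rng = _pair_rng(cfg.seed, index)
    n = max(30, int(rng.poisson(cfg.length_mean)))
    anc = _ancestor(n, cfg, rng)
    diso = _disorder_track(n, cfg, rng)

    res_a = _substitute(anc, cfg.substitution_rate, rng)
    res_b = _substitute(anc, cfg.substitution_rate, rng)
    del_a = _delete_runs(n, cfg, rng)
    del_b = _delete_runs(n, cfg, rng)
    # a column deleted from both species would vanish from a real
    # alignment; keep the ancestor's copy in neither and drop it
    keep = ~(del_a & del_b)
    res_a, res_b = res_a[keep], res_b[keep]
    del_a, del_b = del_a[keep], del_b[keep]
    diso = diso[keep]
    m = keep.sum()

    sty_a = np.isin(res_a, list(PHOSPHO_RESIDUES)) & ~del_a
    sty_b = np.isin(res_b, list(PHOSPHO_RESIDUES)) & ~del_b
    pa, pb = _draw_joint_phospho(
        sty_a & sty_b, sty_a & ~sty_b, sty_b & ~sty_a, cfg, rng)

    def track(res, gap, phos, dis):
        aa, p, d = [], [], []
        for i in range(m):
            if gap[i]:
                aa.append(GAP); p.append(GAP); d.append(GAP)
            else:
                aa.append(res[i])
                p.append("1" if phos[i] else "0")
                d.append(dis[i])
        return "".join(aa), "".join(p), "".join(d)

    aa_a, p_a, d_a = track(res_a, del_a, pa, diso)
    aa_b, p_b, d_b = track(res_b, del_b, pb, diso)
    return OrthologAlignment(
        pair_id=f"pair{index:05d}",
        species_a_id=cfg.species_a_id, species_b_id=cfg.species_b_id,
        aa_a=aa_a, aa_b=aa_b, phospho_a=p_a, phospho_b=p_b,
        diso_a=d_a, diso_b=d_b)


def _plant_ecs(aln: OrthologAlignment, cfg: SimulationConfig,
               rng: np.random.Generator) -> tuple[OrthologAlignment, PlantedEvent]:
    """Insert one compensatory SiD-SiD pair into an alignment.

    Column c1 becomes an a-only phospho-S facing a non-phosphorylatable
    residue; a nearby column c2 becomes the mirror image in b. Both
    members are SiD of the ST class by construction.
    """
    aa_a, aa_b = list(aln.aa_a), list(aln.aa_b)
    p_a, p_b = list(aln.phospho_a), list(aln.phospho_b)
    both = np.flatnonzero(
        (np.array(aa_a) != GAP) & (np.array(aa_b) != GAP))
    if both.size < 2:
        raise ValueError(f"{aln.pair_id}: too gappy to plant an ECS pair")
    dmax = cfg.planted_ecs_max_distance
    candidates = [c for c in both
                  if np.any((np.abs(both - c) >= 1) & (np.abs(both - c) <= dmax))]
    if not candidates:
        raise ValueError(f"{aln.pair_id}: no column pair within {dmax}")
    c1 = int(candidates[rng.integers(len(candidates))])
    near = both[(np.abs(both - c1) >= 1) & (np.abs(both - c1) <= dmax)]
    c2 = int(near[rng.integers(near.size)])
    aa_a[c1], aa_b[c1], p_a[c1], p_b[c1] = "S", "A", "1", "0"
    aa_a[c2], aa_b[c2], p_a[c2], p_b[c2] = "A", "S", "0", "1"
    planted = replace(
        aln, aa_a="".join(aa_a), aa_b="".join(aa_b),
        phospho_a="".join(p_a), phospho_b="".join(p_b))
    event = PlantedEvent(
        pair_id=aln.pair_id, kind="ecs_pair",
        columns=(c1 + 1, c2 + 1),
        species=(aln.species_a_id, aln.species_b_id))
    return planted, event


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[OrthologAlignment], list[PlantedEvent]]:
    """Generate ortholog alignments carrying TRUE phosphorylation states.

    Detection noise is applied separately by
    :func:`apply_detection_noise`, so the returned tracks are the ground
    truth against which observed categories can be checked.
    """
    alignments = [_simulate_pair(i, cfg) for i in range(cfg.n_pairs)]
    events: list[PlantedEvent] = []
    if cfg.n_planted_ecs:
        picker = _pair_rng(cfg.seed, 0, stream=1_000_003)
        chosen = picker.choice(cfg.n_pairs, size=cfg.n_planted_ecs,
                               replace=False)
        for i in sorted(int(c) for c in chosen):
            rng = _pair_rng(cfg.seed, i, stream=7)
            alignments[i], ev = _plant_ecs(alignments[i], cfg, rng)
            events.append(ev)
    return alignments, events


def apply_detection_noise(
    truth: Sequence[OrthologAlignment],
    cfg: SimulationConfig,
) -> list[OrthologAlignment]:
    """Thin true sites by per-species sensitivity and add false positives.

    Each true site is retained independently with its species' detection
    sensitivity; non-phosphorylated S/T/Y residues acquire a spurious flag
    at the false-positive rate. The input (truth) alignments are left
    untouched so observed and true categories can be compared.
    """
    observed = []
    for i, aln in enumerate(truth):
        rng = _pair_rng(cfg.seed, i, stream=2_000_003)
        new_tracks = {}
        for key, sens in (("a", cfg.detection_sensitivity_a),
                          ("b", cfg.detection_sensitivity_b)):
            aa = aln.aa(key)
            phos = list(aln.phospho(key))
            for j, (r, p) in enumerate(zip(aa, phos)):
                if p == "1":
                    if rng.random() >= sens:
                        phos[j] = "0"
                elif p == "0" and r in PHOSPHO_RESIDUES:
                    if rng.random() < cfg.false_positive_rate:
                        phos[j] = "1"
            new_tracks[key] = "".join(phos)
        observed.append(replace(
            aln, phospho_a=new_tracks["a"], phospho_b=new_tracks["b"]))
    return observed


def write_planted_events(events: Iterable[PlantedEvent], path) -> None:
    """Planted-truth TSV: pair_id, kind, columns, species."""
    with open(path, "wt") as fh:
        fh.write("pair_id\tkind\tcolumns\tspecies\n")
        for ev in events:
            fh.write("\t".join((
                ev.pair_id, ev.kind,
                ",".join(str(c) for c in ev.columns),
                ",".join(ev.species))) + "\n")


# ---------------------------------------------------------------------------
# Synthetic kinase matrices
# ---------------------------------------------------------------------------

def simulate_pwms(
    n_kinases: int,
    concentration: float = 2.0,
    seed=None,
    y_kinase_fraction: float = 0.0,
) -> list[KinasePWM]:
    """Random kinase PWMs from symmetric Dirichlet position vectors.

    Low ``concentration`` gives peaked (informative) motifs, high values
    approach uniform rows. The acceptor row places all mass on S/T, or on
    Y for the trailing ``y_kinase_fraction`` of kinases.
    """
    if n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n_y = int(round(y_kinase_fraction * n_kinases))
    pwms = []
    for i in range(n_kinases):
        mat = rng.dirichlet([concentration] * 20, size=10)
        acceptor = np.zeros(20)
        if i >= n_kinases - n_y:
            acceptor[AA_INDEX["Y"]] = 1.0
            name = f"YK{i:02d}"
        else:
            w = rng.dirichlet([concentration] * 2)
            acceptor[AA_INDEX["S"]] = w[0]
            acceptor[AA_INDEX["T"]] = w[1]
            name = f"STK{i:02d}"
        mat[5] = acceptor
        pwms.append(KinasePWM(name, mat))
    return pwms
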