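# Methods

This note documents the models and procedures implemented in
`phospho_turnover`, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Classification model

A pairwise ortholog alignment carries six per-column tracks: amino acid,
phosphorylation status and disorder state for each species. Categories
are assigned per column:

| a side | b side | category |
|---|---|---|
| phospho-S/T/Y | phospho-S/T/Y | StC |
| phospho-S/T/Y | S/T/Y, not phosphorylated | StD |
| phospho-S/T/Y | non-phosphorylatable residue | SiD |
| phospho-S/T/Y | gap | unalignable |
| no phosphosite on either side | — | background |

Counting is once per column: an StC column contributes one position,
not two sites, so SiD + StC + StD equals the number of columns in the
phosphorylated union. Unalignable sites are excluded from that union
and reported separately; nothing can be said about conservation at a
position the alignment does not pair. With this convention the union of
published human–mouse counts decomposes exactly into the per-species
site totals minus the doubly-counted StC positions, which is the check
implemented in the acceptance tests.

An StC column pairing a phospho-S/T with a phospho-Y is counted StC
(the trichotomy is defined over S/T/Y jointly) but flagged
class-mismatched and excluded from residue-class-sensitive analyses:
S/T and Y sites are chemically distinct substrates, phosphorylated by
disjoint kinase families, and are never allowed to compensate each
other.

## Stratified permutation null

The null for category counts shuffles phosphorylation statuses within
each protein while preserving, exactly, the number of phosphorylated
residues per stratum — residue identity (S, T, Y) crossed with
disordered/ordered state, six strata per species. Stratification
matters because phosphosites concentrate in disordered regions; an
unstratified shuffle would let sites leak into ordered regions and
overstate the conservation signal. Strata are computed per species from
that species' own disorder track, since the shuffle models resampling
within one proteome. By default only species b is shuffled (in an
asymmetric comparison, the shallower phosphoproteome); shuffling both
is available and gives compatible folds.

Defaults: 100 iterations for category nulls, 1000 for poly-cluster
nulls. Empirical p-values use the add-one convention,
p = (1 + #extreme) / (1 + n), so finite permutation runs never report
p = 0.

The fold statistic (observed / null mean) estimates the cross-species
coupling of phosphorylation. It carries a small negative bias of order
(ρ − 1) · S / N, where S is the number of strata and N the
phosphorylatable residue count per protein, because the shuffled site
counts include the coupled sites themselves; at realistic protein
lengths (hundreds of residues) this stays within a few percent and is
covered by the recovery tolerance used in the tests.

## Kinase PWM scoring

A kinase motif is a 10 × 20 probability matrix with the phosphoacceptor
at position 6. The score of a 10-mer is the geometric mean of the
per-position probabilities of its residues. The geometric mean (rather
than a log-odds sum) keeps the score on the (0, 1] probability-like
scale that motif-match classifiers report, and is length-normalized.
Numerical choices:

* zero matrix entries are floored at 1e-6 before taking logs;
* windows running past a protein terminus are padded with a neutral
  symbol scored at the position-mean probability (1/20 for a proper
  probability row), so terminal sites are scored rather than dropped;
* the acceptor position is included in the product (matrices may encode
  S/T versus Y preference);
* S/T-kinase matrices are only applied to S/T acceptors and Y-kinase
  matrices to Y acceptors (a matrix's class is read off its acceptor
  row);
* kinase ranking breaks score ties by kinase name ascending, making
  top-k lists deterministic.

The excess-divergence fraction compares, between StD and StC sites, the
proportion of site pairs whose phosphorylated (or species-a) member
outscores its ortholog. StC pairs — phosphorylated in both species —
provide the baseline asymmetry attributable to chance and to any
species-specific scoring bias; the StD excess over that baseline,
summed over the two directions with each term floored at zero, is a
conservative lower bound on the fraction of StD sites whose kinase
recognition motif has genuinely diverged. Ties count as not
outscoring.

Rank-sum comparisons use the exact null distribution for combined
n ≤ 20 without ties and the tie-corrected normal approximation
otherwise; an all-identical pooled sample reports p = 1. Correlations
are Spearman with average ranks for ties. Proportions are compared with
the two-sample equality-of-proportions chi-square test with Yates'
continuity correction; degenerate 2×2 tables (an empty margin) are
reported as not applicable rather than given an arbitrary p.

## Evolutionarily clustered sites

For each ortholog pair and residue class, the a-species SiD sites are
fixed and the b-species SiD sites are re-placed uniformly within their
residue × disorder stratum, excluding *masked* columns — positions
phosphorylatable in both species, which can never host a SiD site. For
each odd window length L in the grid (default 3–81, i.e. half-windows
up to 40 columns) the colocalization fraction — a-sites with at least
one b-site within (L−1)/2 columns — is compared with 1000 permutation
replicates. Distances are measured in alignment columns.

Scanning the window grid for the smallest per-L p is itself a
selection: measured on 500 null synthetic proteins, calling a protein
whenever any per-L add-one p fell below α = 0.05 produced a 7.8%
per-protein false-call rate. The implemented rule therefore uses the
min-p scan statistic with a max-T style adjustment: the protein-level p
is the fraction of replicates whose own min-p over L (computed against
the replicate ensemble) is at least as small as the observed min-p.
Under exchangeability of the b-site placements this is calibrated at
any level (measured: 4.4% at α = 0.05), at the cost of a second pass
over the replicate matrix. The calling window is the smallest L
attaining the minimal per-L p; within it, each colocalized a-site
reports its closest b-site, equidistant partners breaking toward the
N-terminal side, and each a-site contributes at most one pair.

Proteins yielding more than 10 pairs in one class are flagged as large
clusters and excluded from summary tables — a dense run of sites makes
the closest-pair readout uninformative. Per-protein p-values are
reported raw and Benjamini–Hochberg adjusted across proteins.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any
particular organism: an ancestral sequence with a given S/T/Y fraction
and geometric-length disorder blocks; two descendants derived by
independent substitutions and indels (the ancestor defines the column
space, so ground-truth columns are exact and no re-alignment step can
corrupt them — deletions appear as gaps, and columns deleted in both
descendants are dropped); true phosphorylation drawn per column with
`P(both) = ρ·p²` and marginals p at conserved S/T/Y columns,
independent Bernoulli(p) elsewhere; detection modelled as independent
thinning per species plus a false-positive rate on non-phosphorylated
S/T/Y; and optional planted compensatory SiD–SiD pairs (an a-only
phospho-S facing a non-phosphorylatable residue, mirrored in b within a
bounded distance).

Default parameters and their rationale:

| parameter | default | why |
|---|---|---|
| `length_mean` | 500 | mean mammalian protein length |
| `sty_fraction` | 0.16 | S+T+Y content of mammalian proteomes (S:T:Y drawn 0.51/0.33/0.16) |
| `phospho_density` | 0.10 | reported sites per phosphorylatable residue at current coverage |
| `substitution_rate` | 0.07 | per-lineage amino-acid divergence of human–mouse orthologs |
| `indel_rate`, `indel_length_mean` | 0.003, 3 | sparse short indels |
| `disorder_block_fraction`, block mean | 0.4, 30 | disorder content and segment scale of mammalian proteins |
| `conservation_multiplier` ρ | 2.5 | the state-conservation enrichment scale observed in mammals |
| `detection_sensitivity_a/b` | 0.8 / 0.4 | species a sampled roughly twice as deeply as species b |
| `false_positive_rate` | 0.005 | small spurious-identification rate |

ρ values above 1/p are infeasible (the joint would exceed the marginal)
and are clipped with a warning. Determinism: every pair has its own
RNG substream keyed by (seed, pair index), so growing `n_pairs` leaves
earlier pairs untouched, and one config+seed reproduces a dataset
byte-identically.

What the generator does **not** emulate: realistic substitution
matrices (replacements are uniform over the other 19 residues), linkage
between disorder and S/T/Y content, kinase-motif-driven placement of
true sites, rate variation across sites and proteins, and correlated
(batch) detection noise. Passing recovery tests therefore show that the
estimators are unbiased and calibrated under the stated generative
model — not that real phosphoproteomes satisfy that model.

## Experiment sizes used in the test suite

Parameter recovery runs 500 ortholog pairs at mean length 500 with
perfect detection and 100 null iterations, and requires the StC fold to
recover ρ = 2.5 within 15% and ρ = 1 within [0.85, 1.15]. ECS recovery
plants 100 compensatory pairs at distance ≤ 10 in long (mean 3000
columns), fully disordered, strongly diverged proteins so that every
planted site has at least 30 decoy landing positions — the regime in
which a single planted pair is detectable at α = 0.05 — and requires
≥ 80% exact recovery; calibration measures the false-call rate on 500
unplanted proteins (mean length 800) against the binomial band around
0.05. The shared-kinase test is calibrated over 200 replicates of 100
pairs with 10 kinases and 10,000 permutations each. Exhaustive-
enumeration oracles cover the stratified shuffle (every placement
probability within 3 SE over 10,000 draws) and the ECS p-value (exact
vs Monte-Carlo within 3 binomial SE on instances small enough to
enumerate completely).

## Known limitations

* The site-table dialect requires pairwise alignments; multi-species
  columns must be projected to pairs upstream.
* Unalignable sites are set aside rather than modelled; a gap-aware
  conservation model would need explicit indel histories.
* PWM scores are comparable within a matrix set but are not calibrated
  phosphorylation probabilities; the excess-divergence statistic only
  ever uses them comparatively, which is why it is a lower bound.
* ECS detection reports positional coincidence, not mechanism: it
  cannot distinguish a compensatory gain/loss from an indel shifting an
  otherwise conserved site, which requires outgroup species.
* The fold estimator's small-stratum bias (above) means folds from very
  short proteins should be interpreted cautiously.
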