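# Methods

This note records the models implemented in `tetramap`, the choices made where
the design was genuinely open, and what the simulation-based tests do and do
not demonstrate.

## Genetic model

**Random bivalent pairing.** All estimation assumes an autotetraploid whose
four homologues form two bivalents per meiosis, each of the three possible
pairings `{(1,2),(3,4)}, {(1,3),(2,4)}, {(1,4),(2,3)}` with probability 1/3,
and no crossover interference (Haldane mapping function,
d(cM) = −50·ln(1−2r)). A parent's two-locus gamete distribution for tracked
allele sets S_A, S_B ⊆ {1..4} is computed by enumerating the three pairings
and, per bivalent (h,k), the four transmissions (h,h) and (k,k) with
probability (1−r)/2 each, (h,k) and (k,h) with r/2 each. The result is an
exact polynomial in r of degree ≤ 2 per parent (degree ≤ 4 for the 5×5
offspring table after convolving the two parents), evaluated with rational
coefficients and cached per phase class. A brute-force enumeration oracle in
the test suite reproduces these tables exactly at several rational values of r.

**Phase classes.** Within a parent the phase of a marker pair is fully
determined by the overlap m = |S_A ∩ S_B|: maximal overlap is *coupling*,
minimal is *repulsion*, the intermediate duplex–duplex case is *mixed*.
Combined classes join the two parents ("coupling mixed" etc.). Phases whose
offspring tables are identical for every r (e.g. coupling–repulsion vs
repulsion–coupling of S×S with D×D — the convolution is symmetric in the two
parents) are detected numerically by probing the tables at three values of r
and treated as one equivalence class wherever correctness is scored.

A subtlety worth recording: because the pairing partition is drawn once per
meiosis and shared along the chromosome, dosages of duplex-carrying loci
remain positively correlated even at r = 0.5. Only pairs in which one locus
is simplex decouple completely at independence, and the duplex–duplex "mixed"
phase remains distinguishable from coupling/repulsion at r = 0.5 (coupling
P(1,1) = 1/2 vs mixed 5/12 in the gamete table). The coupling and repulsion
extremes, being complement-symmetric, do coincide at r = 0.5.

## Two-point estimation

The multinomial log-likelihood of the observed 5×5 dosage counts (complete
cases only; counts in cells unreachable under the two marker types are invalid
scores and treated as missing) is maximised over r ∈ [0, 0.5] with Brent's
bounded method (tolerance 1e−6). The fully informative 1:1 × 1:1 coupling
case uses the closed form r̂ = recombinants/total. Probabilities are floored
at 1e−12 inside the logarithm for optimiser stability only; reported
distributions are never floored.

Three degenerate outcomes are handled explicitly:

* **Negative optimum.** When the fitted optimum is at r = 0 but the model
  table extends with nonnegative probabilities to slightly negative r and the
  likelihood keeps rising there, the unconstrained optimum is negative (a
  low-information repulsion situation). The estimate is replaced by the
  sentinel r = 0.499, LOD = 0, phase "unknown", which excludes it from
  ordering.
* **Flat likelihood.** When every populated cell has a model probability
  constant in r, the data carry no information at all and the pair is flagged
  *not estimated*. This happens systematically under fully preferential
  pairing for duplex–simplex pairs whose duplex alleles span exactly one
  preferred bivalent (the duplex parent then always transmits one copy).
* **S×S with S×T repulsion/coupling.** This single combination produces
  essentially random r estimates; its LOD is forced to 0 and it is never
  selected, mirroring its exclusion from mapping.

LOD is the standard two-point score log10 L(r̂) − log10 L(0.5) clipped at 0;
the reference L(0.5) makes the score comparable across phases because the
coupling/repulsion extremes coincide there.

**Phase selection.** MLL takes the arg-max of the log-likelihood over
admissible phases, MINR the arg-min of r̂; sentinels and excluded phases never
win; ties break towards the coupling-most phase (the enumeration order).

**Known bias.** Constraining r̂ to [0, 0.5] and discarding negative-optimum
estimates truncates the noise distribution of low-information estimates:
pooled over all phases the regression of r̂ on true r has slope ≈ 0.82–0.90
rather than 1 (≈ 0.90 restricted to LOD ≥ 3, ≈ 0.94 restricted to correctly
phased pairs) with a small positive intercept, even when the model matches
the simulation exactly. This is a property of the procedure, not an
implementation artefact; the robustness study's meaningful signal — the
*additional* downward bias as preferential pairing grows — is tested
separately.

## Meiosis simulator

One gamete per parent per offspring, each from an independent meiosis.

* **Bivalents** (probability 1−q): pairing drawn with probability
  p + (1−p)/3 for the preferred partition {(1,2),(3,4)} and (1−p)/3 for each
  other; the transmitted chromatid of each bivalent follows a two-state Markov
  walk along the loci with switch probability equal to the Haldane
  recombination fraction of each interval — the exact chromatid-level marginal
  of a no-interference chiasma process.
* **Quadrivalents** (probability q): a cross-type model. Two partner-switch
  points cut the chromosome into three segments, each pairing the four
  chromosomes as one of the three partitions (a random permutation). Chiasmata
  arise within each segment at 2 per Morgan between current partners; each
  exchanges the content of one random chromatid per chromosome on the side of
  the chiasma away from the centromere (position 0 by default, configurable).
  Anaphase I splits the four chromosomes 2:2 uniformly; the gamete takes one
  random chromatid from each chromosome of one pole. Double reduction (both
  transmitted chromatids carrying the same founder segment) emerges from
  crossovers between co-segregating chromosomes, and its rate grows with
  distance from the centromere, as expected. Since the reference simulators'
  quadrivalent geometry is not published in detail, agreement is asserted
  statistically (segregation ratios, DR behaviour), not per-gamete.

The simulator emulates marker layouts with several segregation types sharing
one genetic position (transmission is computed per unique position). It does
**not** emulate genotyping error, null alleles, segregation distortion,
univalents/trivalents, or dosage-calling uncertainty — so passing tests
demonstrate correctness of the estimation machinery under the stated meiotic
models, not robustness to assay artefacts. Missing data can be superimposed
completely at random at a chosen rate.

## Clustering and homologue assignment

Linkage-group identification uses single-linkage components of the LOD graph
(the JoinMap-style grouping): chromosomal clusters emerge at moderate
thresholds (repulsion LOD links homologues of one chromosome), homologue
clusters at higher ones. The LOD ladder records the nested partitions; a
chromosomal cluster splitting into ≠ 4 subclusters is flagged, and resolution
merges fragments by strongest cross-cluster coupling evidence (fallback:
weakest repulsion conflict), reporting anything it cannot fix. All other
marker types are assigned to carrier homologues by counting coupling-phase
linkages (LOD > 3 by default) with the simplex framework markers per
homologue, taking the dosage-many best (ties by summed LOD); duplex alleles
also map their complementary homologue pair. A rescue pass re-assigns
incompletely placed markers using unambiguous full-coupling linkages with any
already-assigned marker.

## Binning and ordering

The minimum resolvable recombination fraction in a population of size N with
missing rate μ is r_min = 1/(2·N_a), N_a = (1−μ)N; the binning LOD threshold
uses the calibrated linear relationship LOD_min = 23.43 + 0.1158·N_a, which
keeps the estimation error of sub-r_min estimates below ~0.01. (The two
published working values, r_min ≈ 0.0022 and LOD ≈ 50.4, imply slightly
different N_a — about 228 vs 233; the implementation derives both from one
N_a and accepts the ~1 % discrepancy.) Bins are single-linkage closures of
qualifying pairs; because chaining is possible, the within-bin maximum r is
reported as a guardrail. The calibration study re-derives the intercept and
slope by simulation: per (N, μ) it takes the most stringent threshold across
marker-type combinations such that estimates above it deviate from the true r
by less than 0.01, then regresses thresholds on N_a.

Ordering minimises the weighted least-squares criterion
Σ w_ij (x_j − x_i − d_ij)² with d = Haldane(r̂) and w = LOD, solved for
nonnegative inter-marker steps (NNLS), which enforces monotone positions.
The search is greedy best-insertion seeded by the strongest-linked triplet,
refined by a window-3 ripple, over three rounds with pairs whose weighted
squared residual exceeds the jump threshold (default 5) down-weighted ×0.1
between rounds. An exhaustive-search oracle (≤ 8 markers) verifies the
heuristic on clean data. Map lengths of simulated homologues come out within
~15 % of truth; the residual inflation stems from the convexity of the
Haldane transform applied to noisy r̂.

## Consensus integration

Homologue maps are oriented along a maximum-spanning-tree walk of the
bridging-marker-count graph, flipping any map whose shared-position
correlation with its already-oriented neighbour is negative. The merge is a
linear programme: consensus positions minimise the mean absolute deviation
from component positions subject to each component's within-window order
constraints (window ≤ K); conflicting constraints are removed greedily
(cheapest edge of each cycle found) until the constraint digraph is acyclic.
The LP (solved with scipy's HiGHS backend) is run for K = 1..K_max (default 8)
and for both global input orientations — the solution is not invariant under
flipping all inputs — and the candidate with minimum mean absolute error δ is
returned with the full candidate log. Concordance is checked by regressing
consensus on component positions (slope, adjusted R²; slopes far from 1
flagged).

## Simulation studies and problem sizes

The three studies default to the full published design (100-locus layouts
spaced 1 cM with all nine types per locus; population sizes 100/200/400; grid
of 11 q-levels and 11 p-levels; the full grid at 100 replicates is 6600
populations) but expose the replicate count and a per-population uniform
subsample of marker pairs as parameters; subsampling pairs estimates the
all-pairs average without bias. The test suite and the acceptance script run
10 replicates with 300–800 pairs per population, which reproduces the phasing
accuracies to within a few percentage points (binomial error at that scale);
the full design remains available through the same functions and the CLI.

**Accuracy scoring.** Phasing accuracy is scored per parental *pairing
situation*: each parent in which both markers segregate contributes one
phase decision, analytically indistinguishable phase groups count as correct,
and pairs with no defined estimate are excluded from the accuracy denominator
and tracked as the not-estimated fraction. Accuracy averages weight each
situation equally. For S×S with S×T, the inestimable repulsion/coupling phase
is excluded from the accuracy calculation.

## Limitations

* Two-point likelihoods only; no multi-point estimation and no
  double-reduction-aware estimators.
* The random-bivalent assumption is hard-coded in the estimator (by design:
  the robustness study quantifies the consequences of violating it).
* The LP conflict-elimination is greedy, not provably minimal.
* Simulated data lack genotyping error and null alleles; real-data
  performance depends additionally on dosage-calling quality.
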