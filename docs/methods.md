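# Methods

This note documents the models and algorithms implemented in `mycosym`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions a user auditing results should know
about.

## Occurrence data model

A survey is two tables: a *sample registry* (every collected plant sample,
colonized or not, with species/genus/clade and country/subregion) and a
*detection table* (one row per sample × fungal-taxon detection, tagged with
the fungal lineage and a singleton flag). Uncolonized samples are
first-class because detection rates need true denominators; they cannot be
recovered from detections alone. Percentages are rounded half-up to integer
percent, matching the convention of printed survey tables (e.g. 12.5% → 13%).
Species identified only to genus (names ending in " sp.") count once per
genus and set a "minimum species count" flag.

The per-clade diversity ratio (`taxa_per_colonized_sample`) is the number of
distinct non-singleton delimited taxa observed in a clade divided by the
clade's colonized-sample count, to one decimal — a simple sampling-effort
correction for comparing fungal diversity across unevenly sampled hosts.

## Bipartite networks

`build_incidence` links plant *species* (not samples) to fungal taxa: cell
(i, j) is 1 if at least one sample of species i carried taxon j, and the
parallel weight matrix counts supporting samples. Connectance is the filled
fraction of the binary matrix — unique species-level links, not sample-level
weights, which reconciles an association count of ~80 samples with a ~13%
connectance on a 14 × 21 matrix. Singletons are retained as columns. Empty
rows/columns cannot occur by construction.

### Nestedness

Three statistics, all computed on the binary matrix:

* **NODF** — for each ordered pair of rows (and columns) with strictly
  decreasing totals, the percentage of the poorer line's partners shared
  with the richer line; pairs with equal totals contribute 0. Component
  values (rows/columns) and their combined mean are reported. Verified
  exactly against vegan's implementation.
* **Matrix temperature T** — the isocline construction: the matrix is
  mapped into the unit square, the isocline of perfect nestedness
  `y(x) = 1 − (1 − (1−x)^p)^{1/p}` is calibrated so the area above it equals
  the fill, each unexpected presence (below it) or absence (above it) scores
  the squared relative distance to the isocline along its ±45° diagonal, and
  T = 100 × mean unexpectedness / 0.04145 (the maximal-unexpectedness
  constant), clipped to [0, 100]. Rows/columns are ordered by the standard
  iterative refinement (lines ranked by squared rank positions of their
  presences and absences). **Ordering caveat:** margin ties make this
  ordering — in every published implementation — slightly unstable; the
  reference program resolves ties at random and its T varies by roughly ±1°
  (occasionally more) between runs on the same matrix. Here ties are broken
  deterministically (first occurrence), so repeated calls are bit-identical,
  but permuting the input rows/columns can still shift T by a comparable
  margin. T values should therefore be read with a tolerance of a degree or
  two, which is also the scale of disagreement between published programs.
  A perfectly nested matrix scores 0 only when its stair profile hugs the
  isocline (e.g. the diagonal stair); a convex stair can score slightly
  above 0 while NODF/BR call it perfectly nested.
* **BR discrepancy** — after packing rows and columns by descending totals
  (stable sort on ties), the number of presences falling outside each row's
  leftmost-r_i prefix. 0 iff the packed matrix is a perfect stair. Programs
  that additionally search over tied column orders can report values smaller
  by a few units; the fixed-packing definition used here is deterministic.

### CE null model and significance

Null replicates draw each cell independently with probability
`½(row fill + column fill)` ("null model 2"). Significance is one-sided in
the direction of greater nestedness — upper tail for NODF, lower tail for T
and BR — with the add-one estimator `p = (1 + b)/(n_rep + 1)` (999
replicates by default) so p is never exactly 0, plus a Z score against the
null mean/sd. Replicates with an empty row or column are redrawn up to 30
times; for sparse matrices (where a fully non-degenerate draw is
practically unreachable — a row with a single presence is empty in ~e⁻¹ of
draws) the final draw is kept and empty lines are dropped before the metric
is evaluated, mirroring how observed incidence matrices discard empty
margins. Redraw and trim counts are logged.

### Modularity and roles

The bipartite graph is scored with the standard unipartite modularity
`Q = Σ_s [l_s/L − (d_s/2L)²]` (the convention of the classic annealing
program; no bipartite-specific Q). Simulated annealing proposes, per
temperature, `f·S²` single-node moves and `f·S` collective moves (random
merges and random bisections of modules), accepting improvements always and
worsenings with probability `exp(ΔQ/T)`; temperature cools by the factor
`c` from `T0` until it falls below 10⁻⁴ or 50 consecutive temperatures pass
with no acceptance. Defaults are `T0 = 10`, `c = 0.999`, `f = 1.0`; the
best-seen partition is returned, and runs are bit-identical for a fixed
seed. On all ≤10-node graphs tested the annealed Q equals the exhaustive
maximum over set partitions. Tests and the reproduction script use shorter
schedules (e.g. `T0 = 1`, `c = 0.97–0.99`) on their small/medium graphs;
these reach the same optima on small instances at a fraction of the cost.

Significance compares observed Q with degree-preserving randomizations
(side-respecting double edge swaps, ≥10·L successful swaps per replicate,
rejecting swaps that would create multi-edges), each annealed with the same
schedule; `Z = (Q_obs − mean)/sd` and p is the upper normal tail.

Node roles: participation coefficient `PC_i = 1 − Σ_s (k_is/k_i)²` and
within-module degree `z_i` standardized within the node's module
(population sd; undefined in degree-constant modules and then treated as 0).
Hubs have z > 2.5 (connector hubs additionally PC > 0.30); non-hubs are
ultra-peripheral (PC ≤ 0.05), peripheral (PC ≤ 0.62) or non-hub connectors
(PC > 0.62). Generalists are nodes with PC > 0.62 or z > 2.5; all others
are specialists. (Some survey write-ups state these two thresholds with the
coordinates transposed — "PC ≤ 2.5 and RD ≤ 0.62"; the canonical role
taxonomy assigns 2.5 to z and 0.62 to PC, which is what is implemented.)

## GMYC species delimitation

Input: a rooted binary ultrametric tree (root-to-tip depths equal within
rtol 10⁻⁶; the model needs directed time, so rooted input is required even
though some method descriptions say "unrooted"). For a threshold age t*,
branching events older than t* belong to a Yule-type diversification
process with per-interval rate `λ₁·S^{p₁}` (S = species lineages; after the
threshold S stays at the number of delimited entities), and younger events
to within-species coalescents with summed rate `λ₂·Σ_j [n_j(n_j−1)/2]^{p₂}`.
Inter-event waiting times are exponential with the summed rate of the two
processes; the final interval to the contemporaneous tips contributes only
its survival term. Candidate thresholds are exactly the internal-node ages
(the likelihood is piecewise constant between events) plus a degenerate
single-cluster threshold above the root; the latter makes the one-process
null a special case (λ₁ → 0), so the likelihood ratio is nonnegative by
construction. Rates (and by default the exponents, bounded [0, 2]) are
maximized by L-BFGS-B per threshold from two starts; the null is a single
coalescent-family process over the whole tree. The LRT uses χ² with df 3 by
default (configurable — the df convention is not universal).

Entities crossing the threshold with one tip are singletons; per the
standard protocol, if the first fit delimits singletons the model is refit
with them pruned and the pruned tips are carried into the final report
(first-pass result kept, with a warning, if pruning would leave < 3 tips).

Sequence utilities: exact-duplicate haplotype collapsing (terminal gaps
ignored; greedy first-match) and clone-representative selection at > 98%
pairwise identity (matches / non-gap-pair columns) under single linkage,
keeping the longest sequence per group.

### Calibration experiments

* **Type-I error:** 100 pure-coalescent genealogies (one species, 20 tips);
  the LRT at α = 0.05 rejects in ≤ 10% of replicates (measured ~2–8%).
* **Partition recovery:** mixed trees with 10 species (Yule rate 1), 8 tips
  per species, per-pair coalescent rate 100. An unconditioned Yule tree
  regularly places its youngest speciation within the coalescent scale
  (youngest internode ~ Exp(n·λ)), and no threshold model can separate such
  a pair; since the experiment targets the method's designed operating
  regime, replicates are redrawn until the youngest speciation is ≥ 3×
  older than the deepest within-species coalescence. Under that
  strong-separation condition the delimited partition matches truth with
  ARI ≥ 0.9 in ≥ 98% of 50 replicates; without it, recovery drops to
  ~72–86% — a property of the sampling regime, not of the optimizer (the
  merged solutions have genuinely higher likelihood).

## Ancestral reconstruction

Binary presence/absence characters on a genus-level tree. The symmetric
one-parameter model has `P(change) = ½(1 − e^{−2qt})`; the asymmetric model
has separate gain (q01) and loss (q10) rates via the matrix exponential.
Likelihoods use Felsenstein pruning with per-node rescaling and equal root
priors (½, ½) — configurable in principle; the equal-prior convention makes
log likelihoods comparable to R's `ace` up to an additive log 2 (ace sums
unweighted conditional likelihoods at the root). Rates are optimized on a
log scale within [10⁻⁹, 100]; the asymmetric fit is seeded from the
symmetric MLE and falls back to it if optimization underperforms (the
models are nested). The asymmetry LRT uses χ² df 1 and picks the
one-parameter model when p > 0.05. Marginal node probabilities use the
re-rooting (up/down message) construction and are verified against joint
enumeration on small trees.

Parsimony is two-pass Fitch with an ACCTRAN resolution; when the root set
is ambiguous without an outgroup, absence (state 0) is preferred. Gains
(0→1) and losses (1→0) are counted per branch; branches that remain
ambiguous widen a reported min–max range. Event counting on ML
reconstructions thresholds marginals at 0.5. As q → 0 the ML event counts
converge to parsimony's (checked at q = 10⁻⁶).

The bundled genus-level liverwort tree (`mycosym.datasets.genus_tree`) is a
hand-curated consensus topology of multi-marker liverwort phylogenies with
**synthetic unit branch lengths** — adequate for parsimony and for
illustrating the ML machinery, but its ML rate estimates should not be
interpreted as divergence-time-calibrated. The Petalophyllaceae tip is
labelled *Sewardiella* (placed via its only confamilial genus,
*Petalophyllum*). On this tree the bundled Glomeromycotina scoring yields
exactly one gain (at the ancestor of the non-Haplomitriopsida liverworts)
and five losses; the *Takakia* outgroup (hosting neither lineage) resolves
the root.

## Accumulation and richness

Exact analytic sample-based rarefaction and the incidence-based bootstrap
richness estimator (formulas in the README), with coverage = 100·S_obs/S_boot
and a singletons-included/excluded toggle producing the two conventional
curve variants. The analytic curve equals the mean over random sample
orders (checked against a permutation oracle and against vegan). Note that
adding a duplicate of a taxon-poor sample *can* lower S(m) at fixed m — the
expectation is over a sampling distribution that now contains a redundant
sample — while S_obs and the curve endpoint are unchanged; claims that
duplication can never decrease the curve are false in general.

## Synthetic data

`mycosym.simulate` provides: perfectly nested stair matrices (strictly
decreasing margins where the fill permits); planted block-modular Bernoulli
matrices; occurrence surveys with configurable clade mix (default roughly
11/61/28% across the three liverwort clades, as in a broad survey),
colonization and dual-colonization probabilities, regional taxon endemism
and automatic singleton flagging; mixed Yule/coalescent ultrametric trees
with recorded true species assignments (within-species genealogies grafted
below the species tips, terminal branches padded so the tree stays
ultrametric); and binary characters evolved under the symmetric Markov
model. All generators take one seed, use a single numpy Generator, and are
bit-reproducible.

What the generators do **not** emulate: phylogenetic signal in host choice,
geographic autocorrelation beyond country-level endemism, sequencing or
PCR detection error, abundance (everything is presence/absence), and
among-lineage rate variation. Passing tests on synthetic data therefore
validate the algorithms and their statistical calibration, not the
biological fidelity of any particular survey.

## Problem sizes used in tests and the reproduction script

Oracle suites use 50 random instances each (6×6 matrices for NODF/BR,
≤10-node graphs for modularity); delimitation calibration uses 100 null
simulations at 20 tips and 50 recovery simulations at 80 tips; rate
recovery uses 100 characters on 200-tip trees; the demonstration network
pipeline runs a 350-sample single-region survey with 199-replicate nulls
and 10 modularity randomizations and short annealing schedules. These sizes
were chosen to give stable statistics while keeping a full run in the
minutes range on one CPU; all of them are parameters, and the published
defaults (999/100 replicates, T0 = 10 with 0.999 cooling) remain the
package defaults.

## Known limitations

* T's ordering-tie variance (above); compare T across implementations only
  to within a couple of degrees.
* The GMYC likelihood follows the summed-rate interval convention; absolute
  log-likelihood values are not comparable to implementations that
  attribute per-event rates differently, though threshold choice and the
  LRT behave equivalently in the calibration experiments.
* `fit_asym` optimizes a 2-parameter likelihood that can be flat on small
  trees; the LRT is then conservative by construction (falls back to the
  nested symmetric optimum).
* The annealing Q-landscape for graphs beyond a few hundred nodes may need
  longer schedules than the defaults used in the tests; the published
  default schedule is recommended for real analyses.
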