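# Methods

## Phase-space recurrence

A multivariate time series is treated as a sampled trajectory of a
dynamical system: the m observed variables at time i form the state vector
y_i of an m-dimensional phase space, with no time-delay embedding — the
observed variables *are* the coordinates. Two time points recur when their
state vectors are within ε of each other,

    R_ij(ε) = Θ(ε − ‖y_i − y_j‖),  i ≠ j,

with Euclidean, Chebyshev or Manhattan norms. The recurrence condition is
closed (D_ij ≤ ε): the Heaviside convention at zero is ambiguous, and the
closed form makes threshold selection exact on tied distances. The
recurrence rate RR(ε) is the fraction of recurrent off-diagonal cells;
`epsilon_for_target_rr` inverts the empirical RR step function by returning
the ⌈target·P⌉-th order statistic of the P = N(N−1)/2 pair distances, so
RR(ε) ≥ target always holds and the achieved rate is reported alongside.
No Theiler window is applied by default (an optional parameter excludes
pairs closer in time than a chosen lag).

## Networks

The recurrence matrix is the adjacency matrix of an undirected, simple
ε-recurrence network (ε-RN) whose edge density equals RR. Zeroing the
upper triangle instead yields the **cumulative recurrence network** (cRN):
a directed graph with edges i→j only for j < i, weighted by the recurrence
time i − j in samples (a distance-weight variant is available). Because
every vertex property of a cRN derives from edges into the past, the cRN
supports real-time monitoring: what is computed at day t never looks ahead.

### The real-time contract, precisely

Quantities that are free of the series length N — the recurrence structure
restricted to days ≤ t, cRN edges and weights, out-degree, out-strength and
out-clustering at a fixed ε, and all windowed indicators (whose ε is
re-derived inside each window) — are bit-identical under truncation of the
future. Quantities normalized by the current length (degree density
k/(N−1), closeness with the N−1 disconnection floor) rescale as N grows,
and an ε derived from a whole-series RR target depends on all data; these
are length-relative by definition, not violations of causality.

## Local and global measures

Per vertex: degree k_i; degree density ρ_i = k_i/(N−1) (a localized
recurrence rate); local clustering C_i = Σ_{j,h} A_ij A_ih A_jh / (k_i(k_i−1))
with C_i := 0 for k_i < 2 (avoids 0/0); closeness c_i = [mean_j l_ij]^−1;
local efficiency e_i = inverse geometric mean of l_ij, with the harmonic
form (mean of 1/l_ij) behind a flag — the geometric form follows the prose
definition ("inverse geometric mean"), the harmonic form is common
elsewhere in the recurrence-network literature. Shortest paths l_ij are
unweighted hop counts; pairs that cannot reach each other are assigned
l_ij = N − 1, which floors closeness at 1/(N−1). This convention matters:
disconnection is the rule, not the exception, in ε-RNs at low recurrence
rates.

Global measures average the local ones: edge density ρ = mean ρ_i, global
clustering C = mean C_i, transitivity T = 3·triangles/triples (computed on
the symmetrized simple graph; the standard ratio), average path length
L = mean(1/c_i), global efficiency E = [mean e_i]^−1. On the edgeless
N-node graph L = E = N − 1 by the flooring convention.

On directed cRNs (`directed_mode="out"`): degrees and neighborhoods come
from out-edges only, paths follow edge directions, and the inter-neighbor
links in the clustering numerator are evaluated on the symmetrized
adjacency so that C_i remains the fraction of ε-close pairs among the
vertex's (past) neighbors. Strength is the sum of out-edge weights, i.e.
total recurrence time into the past.

## Multiplex comparison

M subsystem networks over the identical, time-aligned node set form a
multiplex recurrence network. The giant NM × NM supra-adjacency matrix is
never built; all statistics are projections:

* **Inter-layer mutual information** I_αβ = Σ p(a,b) log[p(a,b)/(p(a)p(b))]
  over the node-wise joint frequency table of degrees, in **nats** (natural
  log; the choice of base is a unit, stated here once). In strength mode
  the (out-)strengths are first binned per layer into B = 10 equal-frequency
  (quantile) bins — robust to heavy-tailed strength distributions,
  deterministic, and nested under halving of B so that coarser binning can
  only lose information. A layer with a constant degree/strength vector has
  zero entropy and contributes I = 0 by convention (the limit of the
  formula), with a warning.
* **Inter-layer correlation** R_αβ: Pearson r of the node-aligned vectors;
  undefined (NaN, with a warning) for constant vectors.
* **Edge overlap** ω = Σ_i Σ_{j>i} Σ_α A_ij^α / (M · #union-edges): the
  fraction of multiplex edge slots occupied. Directed layers are
  symmetrized for the unordered-pair sum and weights are ignored. ω = 1
  iff all layers share an identical edge set; ω = 1/M for pairwise-disjoint
  layers.

## Windowed early-warning indicators

In every right-aligned window of `window` days (default 7 — short enough
to act on in a monitoring setting) each subsystem's rows become a window
cRN with ε re-derived *inside the window* to hit a fixed RR target
(default 0.05), so the indicator tracks geometry rather than density
drift; a fixed ε per subsystem is available instead. Three layer-similarity
traces are recorded per window: average edge overlap, mean strength-MI and
mean strength-correlation. Windows in which any subsystem has fewer than 3
distinct state vectors yield missing values rather than errors. The
windowed engine computes out-degrees/strengths directly from the condensed
recurrence mask (identical to building the graph, verified in tests)
because tens of thousands of windows are evaluated per analysis. The
engine uses the Euclidean norm.

The classical critical-slowing-down baseline — windowed sample variance
(ddof = 1) and lag-1 autocorrelation, default window 30 days — is provided
for comparison. The lag-1 autocorrelation of a window is the Pearson
correlation of (x_1..x_{w−1}) with (x_2..x_w); a zero-variance window
yields a missing value.

### Surrogate bands and flags

Reference bands come from `n_surrogates` (default 19) surrogate series,
each applying one joint row permutation to all subsystems: `shuffle`
destroys all temporal structure; `block` permutes whole blocks of
`block_length` rows (default 7), preserving short-range dependence. The
band is the per-time ⌈q·n⌉-th order statistic across surrogates — with 19
surrogates at q = 0.95, the per-time maximum, which under row
exchangeability is exceeded by chance exactly 5% of the time for
continuous-valued indicators. A day is flagged when an indicator
**strictly** exceeds the band; flags within `lead_window` (default 14)
days before a supplied event day are annotated as pre-event.

Two calibration caveats, both consequences of the method rather than
implementation choices:

1. *Discreteness.* In 7-day windows at RR 0.05 each layer has exactly two
   edges, so edge overlap (and, less severely, binned-strength MI) takes
   few distinct values; ties with the band count as non-exceedance, making
   strict flagging conservative for those measures. The
   strength-correlation indicator has the richest value set and is the one
   whose null exceedance rate sits at the nominal level.
2. *Nonstationarity.* Surrogates built from a series that contains a large
   level shift mix rows from both regimes into every window; the shared
   regime structure aligns all layers in the surrogates too and inflates
   the band. Monitoring is therefore best evaluated causally — band and
   trace computed from the data observed so far — which is also the only
   view available in real time. The benchmark below does exactly that.

## Transition networks

Connected components of the undirected ε-RN with at least `min_size`
members (default 2) become recurring phases; each phase's profile is the
per-variable **median** of its member coordinates (robust to the bounded
ordinal scale), and phases are numbered by descending frequency with ties
broken by the earliest member time index. All remaining time points form a
residual class with its own label, so the label sequence covers every
observation and the empirical transition matrix P_ab = c_ab / Σ_b c_ab is
row-stochastic wherever a row has outgoing transitions. Dropping the
residual class marginalizes its row/column and renormalizes. The transition
network keeps edges with P_ab ≥ 0.10 by default (display threshold only).
Component-based phase extraction is one deterministic, parameter-light
operationalization of "recurring phase"; clique-based or density-based
groupings would give finer partitions.

## Data preparation

Pipeline order: **select → aggregate to 1/day → rescale/recode → impute**.
Imputing on the final daily scale matches the analysis resolution. The
support criterion keeps a variable iff its missing fraction is strictly
below 5% and the zero fraction of its first-differenced series is strictly
below 33% (insufficient dynamics otherwise), unless the variable is
explicitly exempted for theoretical relevance. Daily aggregation takes the
arithmetic mean of each day's non-missing observations and spans every
calendar day between the first and last timestamp. Rescaling maps each
variable's observed range affinely onto [1, 7] (configurable); constant
variables map to the midpoint; reverse-coded variables are then reflected
(v → lo + hi − v). Imputation is seeded chained regression (scikit-learn's
iterative imputer: round-robin regressions, 10 sweeps, tolerance 1e-3,
imputed cells clipped to the scale range), restricted to variables of the
same subsystem so each phase space is completed from its own dimensions.
It is deterministic given the seed. Predictive-mean matching and multiple
imputation are out of scope.

## Synthetic regime-shift generator

The generator emulates the *shape* of long experience-sampling records:
238 days of six subsystems (6/4/3/4/4/4 variables) of 1–7 ordinal ratings,
2% missing completely at random, 25% of variables reverse-scored, and a
regime shift at day 127. Latent dynamics per variable are AR(1)
(coefficient 0.3, innovation sd 1.3) plus a shared AR(1) common factor
with heterogeneous loadings. Over the 14 days before the shift the system
approaches a tipping point of the shared mode along a linear ramp: the
factor loading rises (0.1 → 2.0), its innovation gain rises (×1 → ×2,
critical fluctuations) and its AR coefficient rises (0.6 → 0.95, critical
slowing down); the schedule relaxes symmetrically over the 14 days after
the shift, when the system settles into a new regime whose observed level
is 2 scale points higher. Latent values are projected onto the ordinal
scale as clip(round(4 + 1.6·z + shift), 1, 7); the projection gain is
chosen so that most variables pass the 33% differenced-zeros support
criterion, as in real rating data with adequate dynamics. A weekly state
scalar (base 10, step +10 at the first week boundary at or after the
shift, bounded uniform noise) stands in for an infrequently administered
symptom scale.

What the generator does **not** emulate: item-specific response styles,
time-of-day structure within days, autocorrelated missingness (a
block-missing mode approximates halted measurement), floor/ceiling
asymmetries, or any psychometric model of a disorder. Passing the
benchmark therefore shows that the pipeline detects rising geometric
coherence produced by a shared critical mode under ordinal projection and
missingness — not that it detects transitions in any particular clinical
population.

An i.i.d. standard-normal generator (`gen_iid_null`) provides the
exchangeable null for band calibration; a continuous null is used so that
calibration is not confounded by the tie-conservatism discussed above.

## Problem sizes and defaults used in the shipped checks

Oracle comparisons use 200 random graphs with N ≤ 30 (exhaustive cubic
loops stay cheap there). Band calibration uses 50 seeds of a 120-day,
3×3-variable null with 19 surrogates. The early-warning benchmark uses 20
seeds of the default 238-day generator: the full preparation pipeline, the
7-day windowed trace and a 19-surrogate shuffle band computed from the
first 127 days (the real-time view), plus a four-segment post-hoc
comparison (baseline / pre / transition ±14 days / post). These sizes are
the package's reference configuration; all are parameters of the
corresponding functions.

## Known limitations

* Line-structure recurrence measures (determinism, laminarity), joint and
  cross recurrence, and time-delay embedding are out of scope.
* The ε-per-window policy makes indicator values comparable across windows
  but means ε itself is a moving quantity; the log records its range.
* MI estimates on 7-point windows are strongly biased upward in absolute
  terms; the indicators are meaningful as *relative* traces against their
  own surrogate band, not as absolute information estimates.
* Whole-series surrogate bands are anticonservative in the presence of
  strong nonstationarity (see above); prefer causal evaluation or block
  surrogates.
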