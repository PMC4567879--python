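# Methods

This note records the models implemented in `trophoscale`, the
conventions and numerical choices they depend on, and the limits of
what the synthetic test data can show.

## Web assembly from a metaweb

A local web for a sampling unit is the metaweb subgraph induced on the
taxa observed there, built under the co-occurrence assumption: taxa
linked anywhere are linked wherever they co-occur. This can only
overestimate local link density; it never invents links absent from the
metaweb. The fixed order of operations is

1. induce the subgraph on (catalog ∩ metaweb) taxa;
2. drop taxa with no links to *other* taxa in the subgraph (a self-link
   alone does not save a taxon, and by default the drop is a single
   pass — iterating to a fixed point can orphan further taxa and is
   available via `iterate_drop`);
3. inject the ubiquitous basal resources with all their metaweb links
   to the retained taxa and among themselves.

Because dropping precedes injection, a consumer whose only links run to
a ubiquitous resource is removed before injection could rescue it. This
ordering is deliberate and changes results; the alternative (inject
first) inflates small webs. Catalog taxa missing from the metaweb are
warnings, not errors, since field names drift from reference lists.

Webs with fewer than `min_trophic_species` (default 10) trophic species
are excluded from analysis: below that size, structural null models
have systematically large errors, so normalized comparisons are not
meaningful. The threshold applies to aggregated (trophic-species)
counts, not taxonomic counts.

## Trophic-species aggregation

Taxa with identical prey sets *and* identical predator sets collapse to
one node. Equivalence is evaluated on the raw sets in a single pass,
self-links included — a cannibal and an otherwise-identical
non-cannibal differ in both sets and are not merged, and two mutual
predators are never merged because each appears in the other's prey
set. Class representatives are the lexicographically smallest member,
which makes outputs deterministic. The operation is idempotent: after
merging, no two nodes can share both sets.

## The eighteen properties

Fundamental: S, L, L/S, and directed connectance C = L/S² (self-links
count once). Structural, with the conventions that matter:

- **Top/Int/Bas** partition taxa by presence of prey and predators,
  ignoring self-links, so the three fractions always sum to 1 and a
  lone cannibal is basal.
- **Herb** requires a nonempty non-self diet contained in the basal
  set; a cannibalistic grazer stays a herbivore.
- **Omn** counts consumers whose prey span at least two distinct
  *shortest* (integer) trophic levels. With fractional levels nearly
  every polyphage would qualify; integer levels follow the classical
  convention. Configuration of this choice is deliberate — see
  Limitations.
- **Loop** is the fraction of taxa inside strongly connected components
  of size ≥ 2. Cannibalism is reported separately as **Can**; a
  directed 3-cycle has Loop = 1 but contributes nothing to Can.
- **LinkSD, GenSD, VulSD** are sample standard deviations (divisor
  n − 1; a `ddof` switch gives the population form) of degree,
  generality, and vulnerability normalized by L/S (total degree by
  2L/S). A self-link adds one to both generality and vulnerability.
- **TL** is the mean short-weighted trophic level: the per-taxon
  average of (a) 1 + shortest prey-chain length to a basal taxon and
  (b) the prey-averaged level solving TL_i = 1 + mean over i's non-self
  prey of TL_j with basal taxa fixed at 1. The linear system is solved
  densely; excluding self-links from the prey mean keeps it
  well-conditioned. Re-substitution of the solution satisfies the
  defining equation to below 1e−9 in the test suite. A web in which
  some consumer has no chain to any basal taxon has no defined levels
  ("unrooted loop"); TL and Omn are then recorded as missing and the
  collection run continues.
- **MaxSim** is the mean over taxa of the maximum trophic similarity
  (shared prey + shared predators over the union of both) to any other
  taxon; an empty union scores 0.
- **Path** averages shortest path length over *connected* unordered
  pairs of the undirected projection. Assembled webs are usually
  connected; averaging over unreachable pairs would otherwise dominate
  the statistic.
- **Clust** averages, over taxa with at least two undirected neighbors,
  the number of directed links among the neighbor set divided by
  k(k − 1). Nodes with fewer than two neighbors are excluded from the
  mean rather than counted as zero.

All properties are invariant under taxon relabeling, and the whole set
is verified against an independent brute-force implementation
(pure-Python set arithmetic, Floyd–Warshall, dense solve) on a hundred
random webs per run of the test suite.

## Niche-model ensembles and model error

The niche model draws n_i ~ Uniform[0,1], a feeding range
r_i = n_i·x_i with x_i ~ Beta(1, β), and a range center
c_i ~ Uniform[r_i/2, min(n_i, 1 − r_i/2)]; species i eats every j with
n_j inside the range. β = 1/(2C) − 1 makes the expected consumed
fraction of the niche axis 2C·E[n] = C, so realized connectance is
centered on the target; the smallest-n species is forced basal (r = 0).
Candidate webs are rejected whole if any taxon is isolated, the
undirected projection is disconnected, or realized C misses the target
by more than a relative tolerance (default 5%, budget 10,000 draws).
Webs too sparse to connect at all (C·S² < S − 1) are rejected up front
with a clear error, and the pipeline skips model errors for such webs.
Measured over 1000 accepted webs at S = 30, C = 0.15, mean realized
connectance sits within ±0.01 of the target.

For each empirical web, an ensemble (default 1000 webs) matched to its
S and C yields per-property medians and 2.5/97.5 percentiles (linear
interpolation — with 1000 samples the bounds depend on the rule, so it
is fixed and shared with the boxplot quartiles). Model error is

    ME = (median − value) / (q97.5 − median)   if value > median
    ME = (median − value) / (median − q2.5)    if value < median

which is 0 at the median, ∓1 exactly at the band edges, and |ME| > 1
iff the value lies outside the central 95% of the ensemble. Negative ME
means the model underestimates the empirical value. A zero-width
half-band with a non-median value yields a signed infinity sentinel.
Ensembles are cached by (S, L), which determines C exactly.

## Power-law scaling and residual variation

Each property P is fit across the whole collection (pooled over scales,
since residuals are then compared *between* scales) as
P ~ log₁₀(S) + log₁₀(C). Properties bounded in [0,1] use a
quasi-binomial GLM with logit link — proportions of exactly 0 or 1
enter untouched; no nudging. Strictly positive unbounded properties
(LinkSD, GenSD, VulSD, TL, Path) use ordinary least squares on
log₁₀(P), an explicit power law; nonpositive observations are excluded
from the fit and flagged. A constant property is flagged degenerate
with zero slopes. Residual variation RV = observed − fitted on the
property's natural scale, so RV plots are comparable with raw-value
plots; negative RV means the scaling model overestimates. Parameter
recovery holds to ±0.15 on 200-web collections with logit noise of
SD 0.1, and exactly (1e−8) for noise-free power laws.

## The synthetic archipelago

The generator emulates a nested intertidal survey: a niche-model
metaweb (defaults S = 131, C = 0.053, taxa labeled in niche order) with
the 7 lowest-niche taxa designated ubiquitous basal resources, sampled
as 339 quadrats (0.25 m²) on 39 transects (37.5 m²), five sites
(0.23 km²), four locales (0.88 km²), and one archipelago catalog
(23.5 km²) — six orders of magnitude of area.

Occupancy is an incidence-function model. Each non-ubiquitous taxon
gets a per-quadrat incidence p_i ~ Beta(a, b) (defaults a = 0.2,
b = 2.0: most taxa are locally rare, a few widespread), and its
detection probability in a unit of area A is

    q_i(A) = 1 − (1 − p_i)^((A/A0)^z),   A0 = 0.25 m², z = 0.45.

The exponent z < 1 encodes conspecific spatial aggregation: doubling
area does not double the number of effectively independent quadrats.
With z = 1 detection saturates by the site scale and the species–area
relationship collapses; z = 0.45 was chosen, together with (a, b), by
matching the expected per-scale richness ladder analytically (using
E[(1−p)^m] = B(a, b+m)/B(a, b)) to a realistic span of roughly one
order of magnitude in mean trophic-species richness from quadrat to
archipelago, and then frozen.

Incidence is rank-coupled to the niche axis by default (the sorted
incidence draws are assigned in reverse niche order), reflecting the
standard occupancy–trophic-rank relationship: basal resources and
grazers are abundant and widespread, higher predators rare and patchy.
This skew is what makes small catalogs trophically dense — quadrat webs
concentrate in the low-niche region where co-occurring taxa are linked
— so mean connectance falls from quadrat to archipelago, the empirical
signature of fine-grained sampling. With independent (uncoupled)
incidence the richness ladder survives but connectance is nearly flat
across scales.

Quadrat presences are independent Bernoulli(p_i) draws; transect
catalogs are exact unions of their quadrats; site, locale, and
archipelago catalogs are drawn directly from q_i(A), emulating separate
timed-search protocols; the archipelago catalog additionally absorbs
every taxon detected at any unit, and ubiquitous taxa appear in every
catalog. True incidences are persisted so tests can correlate detection
frequency with p_i.

What the generator does *not* emulate: spatial autocorrelation among
neighboring units, tidal-height or habitat covariates, abundance
dynamics, detection differences among search protocols beyond the area
exponent, and diet-driven co-occurrence beyond the incidence–niche rank
coupling. Passing tests on synthetic data therefore demonstrate that
the pipeline's statistics behave correctly under a known
species–area/occupancy process, not that any particular empirical
system satisfies these assumptions.

## Pipeline summaries and determinism

Per-scale comparisons use Tukey boxplot statistics — quartiles by
linear interpolation (the same rule as the ensemble percentiles),
whiskers at the most extreme data within 1.5·IQR of the box, outliers
beyond — computed for the raw values, the MEs, and the RVs; both mean
and median columns are emitted. All randomness flows from one integer
seed through spawned child generators, so a pipeline rerun with the
same configuration is byte-identical. Default problem sizes (ensembles
of 1000; the full 388-catalog synthetic design) run in minutes on one
core; the test suite uses reduced designs (ensembles of tens of webs,
~45-taxon metawebs) chosen to exercise every code path at interactive
speed.

## Known limitations

- The exact variants of two properties are not settled in the
  comparative literature: omnivory (integer shortest levels vs
  fractional levels) and clustering (directed counting over k(k−1) vs
  undirected; exclusion vs zero-scoring of low-degree nodes). The
  implemented defaults are stated above; both are isolated in single
  functions and easy to switch.
- The quasi-binomial GLM treats MaxSim and Clust means as proportions,
  which respects their bounds but is heuristic for means of ratios.
- ME normalization degenerates when an ensemble half-band has zero
  width (sentinel infinities), which occurs for properties pinned at a
  bound (e.g. Loop ≡ 0 in small sparse ensembles).
- Assembly monotonicity holds for links (a larger catalog never loses a
  link) but not for all derived properties; connectance in particular
  is non-monotone in catalog size by design.
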