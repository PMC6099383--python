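# Methods

This note documents the models implemented in `divrates`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Per-capita fossil rates (`divrates.fossil`)

Taxon ranges (FAD/LAD in Ma) are binned into uniform, contiguous,
half-open intervals `[older, younger)` whose origin is the smallest
multiple of the bin duration at or above the oldest FAD, so grids of
different granularity stay aligned at 0 Ma.  Within an interval every
overlapping taxon falls in exactly one boundary-crosser category (Nbt,
NbL, NFt, NFL); a FAD exactly on an edge is credited to the older
interval.  The per-capita estimators are

    q = -ln(Nbt / (Nbt + NbL)) / dt,    p = -ln(Nbt / (Nbt + NFt)) / dt,

with r = p - q, eps = q/p, tau = p + q.  Singletons (NFL) are counted and
reported but never enter the formulas; intervals with no bottom-boundary
crossers are flagged undefined, excluded from summaries, and logged.
These estimators are unbiased under constant rates regardless of the
diversity trajectory, which is what the recovery tests exploit.

The canonical summary statistic is the across-granularity mean of
per-granularity medians (bin durations 0.5, 1.0, 2.5 and 5.0 Myr by
default); means and SDs are averaged the same way.  The single scalar
`epsilon` handed to downstream stages is the summarized relative
extinction.

## Method-of-moments clade rates and richness envelopes (`divrates.moments`)

With extinction fraction eps and clade age t, the stem estimator is
`r = ln(n(1-eps)+eps)/t`; the crown estimator is the survival-conditioned
closed form that reduces to `ln(n/2)/t` at eps = 0.  Both are strictly
increasing in n and decreasing in t (property-tested).

The expected-richness envelope treats the clade size at age t as a linear
birth-death outcome.  For crown ages the clade starts as two lineages;
each unconditioned lineage has the Raup geometric-with-atom law, and the
total is conditioned on clade survival (N >= 1).  For stem ages the size
of a surviving single lineage is geometric.  Bounds are integer
quantiles: the lower bound is the floor of the 2.5% quantile, never below
the minimal clade size (2 crown / 1 stem); the upper bound is the
smallest n whose cumulative probability reaches 97.5%.  An alternative
conditioning on survival of *both* basal lineages is available
(`conditioning="both"`), as are other levels.

At the published anchor (r from the 100,000-species scenario at crown age
190.4 Myr and eps = 0.751, evaluated at 50 Myr) this convention gives
[2, 217], one species below the published upper bound of 218; the CDF at
n = 217 is 0.975062, i.e. 6e-5 above the cutoff, so the printed value is
sensitive to rounding of the rate.  The envelope is validated against
1e5 conditioned Gillespie simulations to within one species on each
bound.

Trait pooling finds the most inclusive monophyletic single-category tip
groups (paraphyletic categories split into several groups); pairwise
group comparisons report mean-rate ratios (row mean / column mean) with
Tukey-HSD adjusted p-values via `scipy.stats.tukey_hsd`, cross-checked
against statsmodels in the tests.  Total-richness scenarios rescale
per-clade counts proportionally.

## Calibration bounds (`divrates.calibration`)

The ghost-lineage (or penultimate-distance) time G is the gap between two
first occurrences; the offset is the older one.  The node-age prior is an
offset lognormal whose *real-space* mean is G/2 and real-space SD is
1.814 Myr, converted by moment matching (`sigma^2 = ln(1 + s^2/m^2)`,
`mu = ln m - sigma^2/2`).  Whether the source procedure intended log-scale
parameters instead is not decidable from the published numbers alone, so
`parameterization="log_params"` is exposed; real-space moments are the
default because "a mean set to half the ghost lineage time" reads most
naturally as a statement about the distribution of missing time in Myr.
The 5%/95% quantiles give minimum/maximum bounds; a zero ghost time
degrades to a minimum-only calibration at the offset.  Output is a
treePL-style configuration block; running a dating tool is out of scope.

## Shift detection (`divrates.shifts`)

A model is a partition of branches into rate classes, each with constant
(b, d).  The per-class log-likelihood is an exact factorization of the
reconstructed-process density, generalized to unresolved terminal clades:

* each branch from age `t_top` to `t_bot` contributes
  `log p1(t_top) - log p1(t_bot)`, with
  `p1(t) = r^2 e^{-rt} / (b - d e^{-rt})^2` the probability of exactly one
  surviving descendant lineage;
* each split contributes `log b` (the root's split is conditioned on, not
  modeled; a root polytomy of c children contributes c-2 splits);
* each unresolved tip with richness n and stem age t contributes the
  *unconditioned* clade-size probability
  `P_s(t) (1-beta) beta^{n-1}`, which equals `p1(t)` exactly at n = 1.
  Keeping the survival factor `P_s` is essential: the
  survival-conditioned geometric alone drops a penalty per tip and drives
  fitted relative extinction to 1.

Optionally (default on) the background class is further conditioned on
survival of the two root lineages.  Class likelihoods are separable, so
classes are fitted independently by Nelder-Mead over `(ln r, logit eps)`
with five starts (eps in {0.05, 0.5, 0.9} with a method-of-moments rate
initializer, plus seeded jitters) and a one-dimensional pure-birth refit
whenever eps collapses to the boundary.  Rates are capped at 10 events
per Myr per lineage for both r and b (the eps range shrinks accordingly
at high r).  The cap is not cosmetic: the density is unbounded for
degenerate rate classes of near-zero duration (a very young cherry), both
directly in r and through eps -> 1 at fixed r, and without the cap the
search occasionally accepts such two-tip classes with turnover in the
hundreds.  Ten per Myr is an order of magnitude above the fastest
radiations reported in the macroevolutionary literature.

The stepwise search starts from one class and greedily adds shifts.
Every non-root branch generates a stem-placement candidate (branch +
subtree recolored) and every internal branch additionally a
node-placement candidate (subtree and the node's split only).
Candidates are ranked by a cheap fit of the new class alone (donor
classes keep their parameters); the top five are refitted in full
(affected classes only — separability makes this exact) and the best is
accepted iff AICc improves by more than the threshold.  Ties within 1e-6
prefer the older branch, then the lexicographically smallest
bipartition.  `k = 3 * n_classes - 1` (two rates per class plus one
location per shift) and the AICc sample size is the number of likelihood
contributions: internal backbone nodes plus unresolved tips.  Thresholds
are user inputs; the published values are keyed by tip count (234 -> 6.7,
45 -> 2.3) and the original size-calibrated threshold curve is not
reimplemented.

Shifts are matched across bootstrap trees by the bipartition (subtended
tip set) of the shifted branch; the summary reports the detection
frequency, the mean rate difference `delta_r` between the shifted class
and its surrounding class (magnitude), and its sign (direction).

## Trend slicing (`divrates.trends`)

Branch-associated rates (r, eps, tau — identities hold per branch, before
any averaging) are averaged within 1-Myr intervals anchored at 0 Ma.  A
branch contributes to every interval its age span overlaps with positive
duration.  The default statistic is the unweighted mean over contributing
branches, the closest reading of averaging "parameters of all branches
intersecting an interval"; it is *not* invariant to subdividing a branch
into collinear segments (tested to fail), and `weight_by_overlap=True`
restores that invariance.  Group trends restrict to branches whose
subtended tips all lie in one trait group, which includes the group's
stem branch; per-slice means are computed per tree and then averaged
across trees.

## Synthetic data (`divrates.simulate`)

Trees come from a forward Gillespie birth-death simulation with budding
speciation, pruned to the reconstructed (extant) tree and conditioned on
two or more survivors by redrawing (cap 1000 attempts, then an error —
the cap limits, but cannot remove, conditioning bias at high d/b).  The
present is either a fixed duration or the moment a target extant count is
reached (declared strictly between events, so no zero-length branches).
A planted shift attaches to the next lineage born after its trigger
(count or time), so the shifted rates hold from the very start of that
lineage's stem — matching stem-placement shift semantics — and clade-size
constraints on the planted subtree are enforced by redrawing.

Fossil ranges come from the species-level version of the same process:
each birth founds a new taxon while the mother persists, the concept
under which boundary-crosser origination equals b.  Complete preservation
reports true lifespans (extant taxa have LAD = 0); thinned preservation
samples each lifespan with a Poisson rate and drops unsampled taxa.
Trait maps color nested clade transitions over an oogamous-nonmotile
background (ON -> AN -> AM), mirroring nested life-history/motility
transitions.

What the generators do not emulate: heterogeneous preservation through
time, taxonomic error in richness tables, non-ultrametric dating error,
and gradual (non-discrete) rate variation.  Passing recovery tests
therefore show estimator correctness under the model's own assumptions,
not robustness to the ways real catalogs and trees violate them.

## Problem sizes and fixed conditions in the tests

* Fossil-rate recovery: b = 0.1, d = 0.075, complete preservation, about
  16,000 taxa over 240 Myr (>= 5000 required), bins 0.5/1/2.5/5 Myr;
  relative extinction recovered within ±0.08 of 0.75 and p, q within two
  Monte-Carlo SEs of b, d.
* Shift detection: 20 trees with a planted 5x shift (b 0.05 -> 0.25,
  150 tips, planted at 50 extant lineages, planted clade constrained to
  20–120 tips) and 20 shift-free Yule trees, threshold 6.7.  Measured:
  sole-exact recovery 16/20, specificity 19/20.  The recovery misses are
  not search failures: in each the AICc optimum is a neighboring
  bipartition one to three tips away (early-diverging members of the
  planted clade that happened not to speciate look like background), an
  identifiability limit of breakpoint placement at this signal strength.
* Envelope validation: 1e5 Gillespie replicates of a crown clade at
  r = 0.0525, eps = 0.751, t = 50 Myr, conditioned on survival.

## Known limitations

* The stepwise search is greedy with a cheap-ranking stage; it can in
  principle accept a locally best shift whose exact breakpoint differs
  from the global optimum, and it has no backward (shift-removal) step.
* Absolute log-likelihoods depend on the root-survival conditioning flag;
  comparisons are only meaningful within one setting.
* The fossil estimators assume uniform bins; stage-boundary grids,
  preservation-rate modeling and three-timer variants are out of scope.
* `clade_rates` reports NaN stem ages for clades whose MRCA is the root
  (no stem branch exists).
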