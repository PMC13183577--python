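# Methods

`tspforage` analyses open-arena traveling-salesperson (TSP) foraging in
rodents: a rat is released into a circular arena (1 m diameter) containing
baited targets and forages until every bait is retrieved.  The package
scores coded trials against exact optimal routes, runs the factorial
statistics of a 2 (strain) x 2 (sex) x 3 (route-strategy category) design,
classifies microglia morphotypes from segmented masks, and simulates every
input it consumes with known ground truth.

## Geometry and configurations

Targets are points in a centred coordinate system (cm, y up).  Eight
configurations are bundled: two four-target baselines and six larger
layouts in three strategy categories —

* **L-P (hull/perimeter)**: targets ring the arena; walking the convex
  hull is optimal;
* **L-NN (nearest neighbour)**: a chain with growing gaps, partially
  interior; greedy transitions to the closest remaining target are
  optimal while the hull walk is at least 3% longer;
* **Global**: layouts on which both local heuristics are at least 3–4%
  longer than the optimum, so only whole-configuration planning succeeds.

No canonical coordinates exist for these layouts, so the bundled ones
are *reconstructions*: candidate layouts were sampled under
each category's design rule and accepted only when the exact solver
verified the rule (these checks are re-run in the test suite).  Results that depend on one specific historical layout cannot be
reproduced from these; all downstream claims are therefore properties (calibration, power,
identities), not digit-matching.

## Route models

The optimal route is the shortest **open Hamiltonian path** with free
endpoints — rats are not required to return to their entry point.  Closed
tours and anchored searches are options.  The solver is a Held–Karp
dynamic programme over target subsets, exact up to n = 20 (the task uses
at most 10).  Symmetric layouts admit ties, so the solver backtracks
*all* optima within a tolerance (default `1e-9 x length`) and exposes the
union of their undirected edges; a transition is credited as "optimal" if
its edge lies in that union — the most permissive deterministic reading
when manual scoring conventions may differ in their tie-breaking.  An
exhaustive-permutation oracle (n <= 9) provides the independent
cross-check.  Greedy ties go to the lowest target id.

## Behavioural scoring

The contact sequence (consecutive repeats collapsed — zero-length
transitions would corrupt the rate and the distance-weighted optimality
fraction) defines the transitions; travel distance is the sum of straight
inter-target segments, not the tracked path, which is used only for
velocity.  Definitions: a **revisit** is a contact with a target whose
bait was retrieved strictly earlier; a **skip** is a contact on a
still-baited target with no retrieval at that moment (a later success
does not erase it); **span** counts distinct targets contacted and
retrieved before the first revisit; **PAO** is reported both as a
difference in cm and as a percentage of the optimal length (the headline
form); **rate** = travel distance / number of transitions; **PropOpt**
and the distance-on-optimal fraction use undirected edge membership in
the optimal edge union.  Revisits are additionally normalised per target
because configurations range from 4 to 10 targets.  Trials with fewer
than two distinct contacts leave transition-dependent fields `NaN`
(undefined, never zero).

## Statistics

Behavioural measures are averaged per rat within each strategy category
(baselines excluded) and analysed with a univariate split-plot ANOVA:
strain and sex between subjects, strategy within.  Between effects are
tested against subjects-within-groups; within effects against the
subject x strategy residual.  Sums of squares are Type III under
sum-to-zero coding, computed directly from the projection algebra and
validated against R's `aov` with an `Error(rat/strategy)` stratum.  With
three within-subject levels sphericity can fail, so Greenhouse–Geisser
corrected p-values are reported alongside uncorrected ones.

When rats miss cells (velocity, when some trials lack tracks) a linear
mixed model with a random intercept per rat replaces the ANOVA.  Each
fixed term is tested by a Wald F with *containment* denominator degrees
of freedom (between terms: subjects minus between-parameters; within
terms: residual observations minus strategy-involving parameters).  On
complete balanced data this reproduces the split-plot F table exactly,
which is the property the design requires; a Satterthwaite approximation
would differ only under strong imbalance and is not exposed by the
fitting backend.

Percent hypertrophic microglia per (rat, region) is analysed with a 2x2
between-subjects ANOVA, Type III (validated against `car::Anova`),
because per-region animal counts are unequal.  Alpha is 0.05 throughout
with no multiplicity correction across the eight behavioural measures —
a deliberate convention; treat isolated significant interactions
accordingly.

## Microglia morphotypes

Circularity is `perimeter^2 / (4*pi*area)`: exactly 1 for a disc, 4/pi
for a square, larger for irregular boundaries.  This is the only reading
under which the fixed 1.03 ceiling meaningfully selects near-circular
somata.  The perimeter uses the Crofton estimator, so rasterised discs
converge to 1 (within 1% at radius 50 px); note Crofton underestimates
axis-aligned polygon perimeters by up to ~5%, which is irrelevant at the
1.03 decision boundary but visible on synthetic squares.  The decision
tree runs in fixed order: circularity <= 1.03 -> ramified; else fewer
than 3 processes -> amoeboid; else hypertrophic.

A process is a skeleton branch leaving the soma, the soma being the
maximal inscribed disc (centre and radius from the Euclidean distance
transform).  Skeleton fragments shorter than 4 px outside the soma are
treated as discretisation spurs.  Both the soma rule and the spur cutoff
are implementation choices — the commercial imaging packages in this space
do not document their rules; only the 1.03 and <3 thresholds are
portable.  Cells touching the image border are excluded by default
(truncated processes bias the class).  Masks are assumed to be extracted
cell bodies plus retained processes; stain-based segmentation is out of
scope.

## Synthetic data

The generator's defaults define the reference cohort: 36 rats (2 strains x
2 sexes x 9), eight configurations each in pseudorandom per-rat order.

Each simulated rat samples, per step, one of four policies (optimal-route
following, nearest neighbour, hull walk, uniform random) from its
strategy-weight simplex, then samples the next target by a softmax over
the chosen policy's preference ranks, `P ∝ exp(-rank/T)`; temperature T
is a continuous adherence dial (T = 0 recovers the deterministic
policy).  Retrieval fails with probability `p_skip` per contact, giving a
geometric number of failures per target, `E[failures] = n p/(1-p)` — the
closed form the tests check (the scored skip count sits slightly below
it because consecutive re-contacts of the last remaining target collapse
into one visit bout).  Trial speed is a truncated normal; a 10 Hz
straight-segment track is emitted, so measured velocity equals the drawn
speed.

Two memory-error channels exist.  The *window* channel forgets depleted
targets beyond the `memory_capacity` most recent, letting the route
policy steer the agent back to them; its revisit rate therefore depends
on the strategy mixture, and deterministic greedy with zero capacity can
livelock (a step cap guards this).  The *lapse* channel visits a
uniformly drawn depleted target with probability `p_lapse` per step,
independent of the policy.  The default cohort uses the lapse channel
(capacity unlimited, `p_lapse` = 0.06) precisely because it decouples
memory errors from route adherence: pilot cohorts using window
forgetting alone showed the strain gap in strategy weights leaking into
the revisit measure, which contradicts the intended
route-impaired/memory-intact pattern.

Default cell parameters: optimal-route weight 0.59 (WKY) vs 0.41 (SHR),
remainder split over NN/hull/random (0.3/0.2/0.5 of the rest); T = 0.3;
`p_skip` 0.035 (males) vs 0.01 (females); speeds 20.4 vs 12.4 cm/s
(SHR vs WKY, realistic group means for these strains); identical memory in all cells.  The
strain gap was calibrated once by pilot simulation of the weight ->
PropOpt mapping (slope ~0.44 per unit weight; between-rat SD ~0.09) to
give the strain main effect ~0.8 analytic power at nine rats per cell;
the realised empirical power over the frozen 500-replicate sweep is
0.83, with revisits-per-target and span at the 5% null rate.

Microglia masks are wavy discs (sinusoidal boundary modulation plus
noise-scaled random modes) with thick radial processes: ramified =
near-circular soma (circularity ~1.01, margin below the 1.03 ceiling,
no attached processes — circularity is measured on the body, and any
attached process would dominate the perimeter); amoeboid = strongly
modulated soma with 0–2 processes; hypertrophic = enlarged modulated
soma with 4–6 processes.  Noiseless shapes respect every threshold with
margin, so classification recovers generator labels perfectly;
accuracy degrades monotonically (within Monte-Carlo slack) as boundary
noise grows.

What the generator does **not** emulate: continuous-path realism
(thigmotaxis, wall-following), learning across trials, inter-rat
parameter heterogeneity beyond trial noise, staining artefacts,
overlapping or out-of-focus cells.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under the stated generative
model, not performance on real video or histology.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately chosen
sizes: solver cross-validation on hundreds of random 4–8-target layouts
(exhaustive enumeration stays cheap there), ANOVA calibration on
1,500–2,000 null replicates (99% binomial band around 0.05), power on
200–500 replicate cohorts of 36 rats, morphotype recovery on 600–1,000
cells.  Tie tolerances: route-length ties within `1e-9 x optimum`;
distance comparisons in greedy models break ties by target id.  All
randomness flows from explicit seeds; identical run configuration and
seed reproduce output bundles byte for byte.

## Known limitations

* Bundled configurations are reconstructions, not the published layouts.
* The exact solver refuses n > 20; this is a task-scale tool, not a TSP
  library.
* The mixed model's containment df is exact only for balanced data;
  heavy imbalance shifts p-values slightly relative to Satterthwaite.
* Morphotype thresholds (1.03, <3 processes) are taken as fixed
  conventions; the soma and spur rules around them are this package's
  own and will not numerically match any particular commercial imaging
  package.
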