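# Methods

This note documents the models, parameter choices and numerical
conventions behind `ngra`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Exposure model

Chronic exposure follows the observed-individual-mean (OIM) convention:
each survey subject's daily intakes are averaged over their recall days
(two by default), and the population distribution is the set of these
per-subject means. OIM is non-parametric and makes no usual-intake
correction; with two recall days it overstates between-person variance
in the tails, which is acceptable for ranking on the mean but means the
weighted p95 should be read as a survey statistic, not a usual-intake
percentile.

Units are fixed throughout: amounts in g/day, concentrations in mg/kg
commodity, body weight in kg, so intake in μg/kg bw/day follows from
1 g × 1 mg/kg = 1 μg without conversion factors.

**Censoring.** Non-detects are substituted, not modelled: 0 in the
lower-bound scenario, the censoring limit (LOD for results below
detection, LOQ for results below quantification) in the upper bound.
The upper bound is the decision default, as the conservative choice for
prioritization. No parametric left-censored likelihood is attempted.

**Concentration pooling.** Per substance × commodity, all samples are
pooled to their scenario-resolved arithmetic mean before intake
calculation. This is the standard chronic-exposure convention (chronic
risk depends on the long-run mean residue, not on which market sample a
subject happens to eat); sample-level resampling would only widen the
acute tail, which is out of scope.

**Food translation.** Consumed foods expand to raw commodities by the
translation percentages (which may exceed 100 for concentrated foods).
Processing factors are deliberately not applied. Foods without a
translation entry contribute nothing and are reported in a diagnostic
list — never silently dropped. Subjects who consume no contributing food
stay in the distribution with OIM = 0: the chronic population includes
non-consumers.

**Weighted summaries.** The survey-weighted mean is Σwᵢxᵢ/Σwᵢ. Weighted
quantiles interpolate linearly over cumulative weights with sorted
observation *i* placed at position pᵢ = (Cᵢ − wᵢ)/(S − wᵢ) (Cᵢ the
inclusive cumulative weight, S the total), clamped at the extremes. This
definition reduces exactly to the standard linear-interpolation
(type-7) quantile when all weights are equal, which is the property the
test suite pins (e.g. p95 of {1…100} = 95.05). Survey-weight definitions
differ across software; any monotone definition would rank substances
identically on the mean, which is what prioritization uses.

**Exposure statistic.** The statistic compared against the TTC defaults
to the upper-bound weighted mean and is configurable to the median or
p95. The choice matters only near HQ = 1; the test scenarios plant
effects far from that boundary precisely so conclusions do not hinge on
it.

## TTC decision tree

Steps run strictly in order with short-circuiting: exclusion →
genotoxicity → organophosphate/carbamate → Cramer class. The ordering is
load-bearing: a genotoxic organophosphate receives 0.0025, not 0.3.
Thresholds are 0.0025 / 0.3 / 1.5 / 9 / 30 μg/kg bw/day. The 9 (Cramer
II) tier is implemented even though it is rarely populated in practice.

The genotoxicity consensus treats the two endpoints separately: an
endpoint is positive when ≥ 2 of the 3 model families (DEREK, ISS,
OASIS) flag it, and the substance is genotoxic when either endpoint is
positive. The consensus is monotone by construction (adding an alert can
never remove genotoxicity), verified exhaustively over all 2⁶ profiles.

Alert booleans and Cramer classes are *inputs*: the external profilers
(DEREK Nexus, the OECD Toolbox profilers, ToxTree) are commercial or
out-of-scope software, and re-deriving them would change the science
being implemented. The consensus rule, the substructure filter and the
threshold mapping — the decision logic itself — are implemented here.

**Substructure modes.** The literal SMARTS match exactly the published
patterns:

```
phosphate  [OX1]=[PX4]([OX2][!#1])([OX2][!#1])[OX2][!#1]
carbamate  [!#1][OX2]C(=O)[NX3;H0]
```

A free P–OH does not count as a substituent (the ester oxygen must have
a non-hydrogen neighbour), and the carbamate nitrogen must carry no
hydrogen. These literal patterns miss two chemically obvious families
that the 0.3 tier is meant to capture: P=S thiophosphates (dimethoate,
malathion) and mono-substituted N–H carbamates (carbaryl-like). The
relaxed mode therefore tolerates sulfur at any of the four phosphate
oxygen positions and a single N–H on the carbamate nitrogen. Literal is
the default (it is what the published filter states); relaxed is offered
because the published 0.3-tier substance lists imply a broader match was
applied in practice. Literal hits are a strict subset of relaxed hits,
enforced by construction and tested.

## Prioritization

HQ = exposure / TTC. Comparisons follow the printed inequalities
exactly: HQ **strictly** > 1 for the TTC-applicable priority list,
exposure **≥** 0.5 μg/kg bw/day (inclusive) for the TTC-excluded list.
A substance with zero exposure (possible in the lower-bound scenario
under full censoring) has HQ = 0 and is never a priority. The four lists
(priority, excluded-priority, unevaluated, not-priority) always
partition the substance set — a conservation property asserted at run
time and under randomized testing.

Screening selection takes the top-k HQ per TTC class with k = 10 for the
0.0025 class and 2 elsewhere; classes 9 and 30 get the same k = 2 as the
other non-genotoxic classes for symmetry. Ties (absent at realistic
precision) break by descending exposure, then ascending substance code,
making the selection deterministic and idempotent.

## HTS normalization

Raw readouts map to a potency scale that increases with toxicological
potency: identity for composite scores and percentages, −log10 for
concentration readouts, N − rank + 1 for ranks. LELs are treated like
AC50s (both are concentrations; the log transform applies to
concentration values as a class). Actives are then min-max scaled to
[0, 100] per model dataset. Only the top anchor (most potent = 100) is
externally specified; anchoring the least potent active at 0 is this
package's choice, documented here, and any strictly increasing affine
alternative would preserve every within-model ordering. Consequences
worth knowing: normalized scores are invariant to concentration-unit
changes and to positive affine rescaling of score readouts, and they are
comparable *as ranks* across models but not as absolute potencies.
Inactive (`not_active`) and untested (`not_tested`) substances are
distinct states, never conflated, and both carry no score.

## Synthetic data

The generator emulates the *structure* of the real inputs: sparse
substance × commodity coverage, log-normal concentrations with a
configurable non-detect fraction (default 0.3), gamma-distributed
consumption amounts (shape 2, scale 60 g), truncated-normal body
weights (70 ± 12 kg, clipped to 40–120), uniform survey weights in
[0.5, 2] normalized to mean 1, and exactly two recall days per subject.
Defaults are 200 subjects and 14 substances across the five class
suffixes — deliberately desk-scale stand-ins for a survey of thousands.

Each substance is planted on a decision-tree branch and an exposure
tier. The branch is realized by construction (consensus-positive alert
profiles for genotoxic plants, pattern-matching structures for
organophosphate/carbamate plants, pattern-avoiding structures
elsewhere) and *verified at generation time* by running the decision
tree, so a failing pipeline test cannot be a generator artifact. The
exposure tier is calibrated against the realized diary: the generator
measures the survey-weighted mean commodity intake per kg body weight
and sets the log-normal concentration level so the expected mean
exposure is 20× the branch threshold (high tier) or 0.02× (low tier).
LOD and LOQ sit at 0.6× and 1.2× the concentration level, so censoring
substitution perturbs exposure by less than a factor of two in either
scenario — far smaller than the planted 1000× separation between tiers,
which is why plant recovery is exact across seeds and scenarios. A
planted substance whose measured commodities nobody consumes raises a
generation error rather than silently vanishing.

What passing these tests shows: the pipeline's arithmetic, decision
logic, ordering and bookkeeping are correct, deterministic and
conservation-safe. What they do not show: performance on real data —
the generator has no food-consumption correlation structure, no
seasonality, no market-basket realism, and its planted effects are far
from the HQ = 1 boundary where real prioritizations are sensitive to
the censoring scenario and the choice of exposure statistic.

## Numerical conventions and degenerate inputs

- Weighted quantile of a single observation is that observation;
  quantiles clamp outside the position range.
- Min-max normalization with all-equal potencies (or one active) gives
  100 to every active; extremes are anchored exactly (100.0 and 0.0) so
  floating-point rounding cannot push a score outside [0, 100].
- OIM of an empty day set, empty active sets, non-positive
  concentrations for log transforms, and weight/subject mismatches are
  errors, not silent defaults.
- CSV writers emit full-precision `repr` floats, which is what makes
  write → read round-trips exact and runs byte-reproducible.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; no global state.

## Known limitations

- The OIM model is a survey-statistic summary, not a usual-intake model
  (no BBN/LNN-style variance correction); acute exposure is out of
  scope.
- Cramer classification and alert profiling are consumed as inputs; the
  pipeline cannot evaluate a bare structure without them.
- The per-substance loop computes exposure independently per substance;
  cumulative or mixture assessment is not attempted.
- Real-data headline counts (how many substances pass each funnel
  stage) depend on proprietary databases and are not reproduced here;
  the funnel report exists to make such counts auditable on any input.
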