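# Methods

## Model

`mmle` implements an incidence-based, discrete-time multistate Markov
analysis of multimorbidity and disability at ages 60+.  The state space has
four living states ordered by severity — no disease, one disease,
disability-free multimorbidity (DFMM), disabling multimorbidity (DMM) — and
absorbing death.  Severity never decreases: the seven tracked chronic
diseases are ever-diagnosed, disability within multimorbidity is treated as
non-reversing, and death is absorbing, so the permitted transitions form a
partial order with structural zeros everywhere else.  Disability observed
with fewer than two diseases is recorded descriptively but does not alter
the state.

Assumptions worth stating plainly: the process is first-order Markov given
age and stratum; waves are evenly spaced (Δ = 2 or 3 years) and the age grid
matches the wave spacing; transition probabilities depend on age through a
linear log-odds term; strata (sex, education) have separate regimes but no
shared parameters; attrition is ignorable given the observed state
(estimation uses observed adjacent-wave pairs only).

## Coding rules

Eligibility starts at the first wave aged 60+.  Carry-forward overrides any
"no" or missing disease answer after an earlier "yes" on living rows; death
rows carry no items.  Living rows still missing any disease or ADL item
after carry-forward are dropped (complete case) and counted.  States are
assigned from (vital status, disease count, any-ADL-difficulty), then recoded
to the running maximum severity within each person; a living row after a
death row is a data error.  Adjacent-wave pairs are kept when wave indices
are consecutive and ages, floored to the Δ-spaced grid anchored at 60, are
exactly Δ apart; wave-gap and age-gap exclusions, single-wave persons and
recode counts are all tallied in an audit object.  Mid-interval deaths enter
as the destination at the following wave; exact death dates are not used.
Persons re-entering after a skipped wave contribute their later adjacent
pairs.  The `no_hypertension` variant drops hypertension from the disease
count (six-disease multimorbidity definition) and can only shift mass away
from the multimorbid states.

## Estimation

One weighted multinomial logit per living origin state and stratum, with
"remain in origin" as the reference (always permitted) and design matrix
[1, age−60] (a quadratic term is a config option; with zero age variance the
slope is dropped with a warning).  Survey weights enter score and
information as a pseudo-likelihood; the default coefficient covariance is
the robust sandwich H⁻¹(Σᵢ uᵢuᵢᵀ)H⁻¹, approximating design-based variance,
with the model-based H⁻¹ as an option.  Newton–Raphson with step-halving
starts at zero; convergence requires a relative log-likelihood change below
1e−10 within 200 iterations, and a zero-deviance fit or a linear predictor
beyond ±30 is reported as separation rather than returned.  Permitted
destinations never observed in a stratum stay structural zeros with a
warning; cells under 30 pairs warn as small.  Fitting per origin (rather
than one pooled model with interactions) gives an equivalent fit with
simpler structural-zero bookkeeping.  Because transitions are conditionally
independent given the current state and age, the product over a person's
pairs is the true path likelihood — no clustering correction is needed
beyond the sandwich.

## Life-table construction

Occupancy starts as a point mass at age 60 and is propagated by the
matrices; each Δ-year interval is credited to the state occupied at its
start (the standard discrete-time occupancy-sum construction; a midpoint
variant would add ≈Δ/2 mostly to the entry state and is intentionally not
the default).  After the last grid age (A_max = 100 by default) everyone
transitions to death, closing the finite grid; an immediate-death chain
therefore yields LE = Δ, spent in the start state.  Conditional expectancies
e(s→k) are averaged with the baseline distribution π, the survey-weighted
share of living person-waves in each state at ages 60–69 (the band average
guards against small age-60 cells).  Aggregates — multimorbidity-free LE,
MMLE, total LE — and percent-of-LE shares are computed from unrounded
values; LE equals the four-state sum to 1e−9 by construction.  Datasets with
different Δ are built on their own grids and compared on the expectancy
scale.

## Uncertainty

The pipeline (coefficients → matrices → occupancies → expectancies →
aggregates) is smooth, so Var(q) = gᵀVg with g the central-difference
gradient (step max(1e−5, 1e−5|β|)) and V block-diagonal over origin models,
which are fitted on disjoint pair subsets.  One finite-difference sweep
serves all quantities, making the gradient of an aggregate exactly the sum
of its components' gradients.  When π is estimated from the panel it carries
a person-clustered linearization covariance, and an additional independent
π-gradient block enters the variance; a π supplied as known shares
contributes nothing.  This baseline block was added because coefficient-only
propagation measurably undercovers (≈90–92% against a nominal 95% in
recovery studies; ≈94–95% with it).  Intervals are estimate ± 1.96·SE;
negative lower bounds on nonnegative quantities are set to zero and flagged.
A parametric bootstrap (multivariate-normal coefficient and π draws at the
estimate, percentile intervals, near-PSD repair with a logged warning) is
the independent check on the delta method.  Gap intervals between strata
assume independence — strata are fitted on disjoint samples — and are
labelled as such; gaps are not clamped since they may be negative.  No
significance test is attached to the cumulative-(dis)advantage flags; they
are point comparisons reported with their intervals.

## Synthetic ground truth

The generator draws latent paths from known per-stratum logit coefficients
and decorates them into survey-style records.  Its defaults emulate a
harmonized aging panel: 2-year waves, grid-aligned entry ages decaying from
60 (oldest entries ~88), entry-state distributions near observed origin
tables (more multimorbidity among women), lognormal person weights
(σ = 0.3), and state-independent 10% wave-on-wave attrition (within the
6–18% range such surveys report; a state-dependent knob exists because
real attrition is plausibly health-selective).  Anchor coefficients imply,
for a low-educated man at 60, roughly 12% one-disease incidence, 2% direct
multimorbidity onset and 2% two-year mortality, with log-odds age slopes of
0.08/yr (mortality) and 0.02–0.05/yr (morbidity); women carry higher
morbidity and lower mortality, education lowers both and attenuates the
female morbidity excess, producing a larger sex gap in MMLE among the
low-educated.  Disease/ADL decoration uses fixed per-person nested chains so
flags are monotone and coding round-trips the latent states exactly; only
some chains lead with hypertension, so the sensitivity variant reclassifies
part, not all, of the multimorbid records.  Each person's path is a pure
function of the scenario seed and person index (pre-drawn uniform rows),
independent of simulation order.

What the generator does not emulate — and hence what passing tests cannot
show about real data: proxy reporting and recall error, health-selective
attrition (unless the knob is turned), complex sampling designs beyond
scalar weights, reporting reversals that are not simple carry-forward
violations, and between-wave timing irregularities.

## Validation studies and problem sizes

Three oracle studies back the pipeline (run by `scripts/acceptance.py` and
the acceptance tests): matrix expectancies agree with 100,000-lifetime
microsimulation within 3 Monte-Carlo SEs on every bundled scenario stratum;
a 200-replicate recovery study on n = 5,000 single-stratum panels recovers
true MMLE with |bias| well under 2% and ≈95% delta-interval coverage; and a
single-living-state constant-hazard chain matches the truncated geometric
closed form Δ(1−(1−q)ⁿ)/q to machine precision.  The recovery estimand uses
the model-implied 60–69 band distribution weighted by survival × observation
retention, matching what the survey estimator targets under state-independent
attrition.  These sizes keep the full validation suite around two minutes on
one CPU while leaving Monte-Carlo error well below the tolerances checked.

## Known limitations

Linear age effects can misstate very-old-age transition probabilities; the
quadratic option is untested against real data.  The independence
approximation between π̂ and the fitted coefficients (both come from the same
panel) leaves residual undercoverage of roughly one point.  Education-level
small cells in survey-sized panels produce structural zeros and wide
intervals, mirroring the sparse-data caveats of the survey setting.  The
package does not implement Sullivan-method estimation, design-based
replicate-weight variance, instrumental ADLs, or reversible disability.
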