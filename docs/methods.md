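# Methods

This note documents the model implemented in `emobook`, the choices made
where the design was genuinely open, and what the shipped tests do and do
not demonstrate.

## Model overview

A group of `N = 20` primate-like agents lives on a 300 m × 300 m torus
(continuous coordinates, minimal wrap-around distances).  One simulated
minute of model time represents one minute of the active day; 12 h = 1
day, 7 days = 1 week, 50 weeks = 1 year.  The standard run is two years
(504,000 min) preceded by a four-week stabilization period (21,600 min),
with observation restricted to the final year; the package's scaled
default for quick experiments (`scaled_config()`) is one week of
stabilization plus four recorded weeks.

Execution is strictly sequential and event-driven.  Each agent owns one
pending self-activation in a priority queue; the earliest activation runs
first, with deterministic tie-breaking by (time, agent id, insertion
order).  On every event, *all* agents' time-dependent state — the three
emotion variables, `PARTNER_SAT` and `LIKE` — is advanced to the current
time before any decision.  Waiting times are drawn from normal
distributions with SD equal to 5 % of the mean, truncated below at 0.01
min.  Reactions (being attacked: immediate; receiving a signal or
observing an escalated fight: 0.1 min) can only pull a pending activation
earlier.  All randomness flows through one seeded generator, so a
(config, seed) pair reproduces a run bit for bit.

## Emotions

Each variable moves piecewise-linearly toward a context-specific limit
without overshooting (so split integrations compose exactly — the
semigroup property the tests assert).  Context precedence is
groom-receive > groom-give > dominant-in-proximity > default; being
groomed by several partners at once has the same effect as by one.

| context | arousal | anxiety | satisfaction |
|---|---|---|---|
| default | → 0.09 + 0.15·(1−satisfaction), 0.02/min | → 0 at 0.002/min | → 0 at 0.02/min |
| groom give | → 0.05 at 0.03/min | → 0 at 0.01/min | → 1 at 0.05/min |
| groom receive | → 0.03 at 0.05/min | → 0 at 0.02/min | → 1 at 0.1/min |
| dominant within 5 m | → 0.5 at 0.02/min | → 0.25 at 0.002/min | (default) |

The anxiety and satisfaction rates (0.002, 0.01, 0.02, 0.05, 0.1 per
minute) and the arousal baseline 0.09 with default rate 0.02/min are the
model's canonical constants.  The grooming arousal limits/rates and the
dominant-proximity limits are package choices (the originals are only
described qualitatively: grooming lowers arousal "faster and further"
than the default decay; a nearby dominant raises it); they are exposed in
`ModelConfig` and were fixed before the emergent-pattern experiments.

The default-context arousal limit includes a restlessness term,
`0.09 + low_sat_arousal_gain·(1−satisfaction)` with gain 0.15: a lack of
recent affiliation leaves an individual slightly more aroused and
therefore more active.  This implements the stated design that low
satisfaction both raises grooming motivation and shifts the balance from
resting toward activity.  Without it the high-selectivity regime is
bistable in a degenerate way: once bonds decay, arousal settles at the
floor and the group freezes permanently.  At initialization the limits
equal the baseline levels (0.09 / 0 / 0), adjusted only for
dominant-in-proximity, matching the published initial conditions.

Instantaneous (point) effects use package defaults ordered by stimulus
impact — receiving an attack (+0.20 arousal) outweighs observing a fight
or receiving an aggressive signal (+0.05); appeasing signals lower
elevated arousal but never below 0.09; anxiety deltas are half the
arousal deltas, with fight outcome ±(0.05 win / 0.10 loss).  All are
config fields.

## Attitudes

`FEAR_ij = myDOM_j − myDOM_i` is fixed, exactly antisymmetric, and spans
±0.95 for the even 1/N … 1.0 dominance spacing.  `PARTNER_SAT_ij` rises
at 0.1/min while j grooms i, decays at 0.02/min otherwise, and is capped
by i's own satisfaction.  `LIKE_ij` jumps up to `PARTNER_SAT_ij` when
overtaken and otherwise relaxes as a weighted mean with history weight
`LHW = 720` min.  Note that `LHW` behaves as a half-life only for a
single update spanning a full day; under the event-frequency updating
actually used, the compounded decay approaches the closed-form product
`LIKE₀·∏ LHW/(LHW+Δtₖ) ≈ LIKE₀·e^(−t/LHW)` — about 0.37/day rather than
0.5/day.  The tests pin both regimes (the one-step worked example
0.8 → 0.4, and the product oracle); the discrepancy is inherited from the
model's definition and deliberately not "fixed".

## Action selection

At an activation with no pending movement and no grouping need, the agent
builds a weight for every eligible (behavior, partner) pair over its ≤10
nearest perceived candidates, adds rest and random-walk weights,
normalizes and samples once.

* Affiliation (groom ≤1 m, affiliative signal ≤5 m, approach ≤50 m):
  `base · [(1−LPS) + LPS·LIKE_ij] · [m₀ + (1−m₀)·mot]` with
  `mot = (9·anxiety + (1−satisfaction))/10` and floor `m₀ = 0.3`.  At
  `LPS = 0` LIKE is causally inert (the null-model property is asserted
  on full event traces).
* Aggression (attack ≤1 m, aggressive signal ≤5 m):
  `base · σ(−(FEAR−θ)/s)` with `θ = −0.3·anxiety` and `s` shrinking from
  0.15 to 0.05 as anxiety rises — anxious agents attack similar/higher
  ranks less and much lower ranks more.
* Submission (leave ≤1 m, submissive signal ≤5 m) and avoidance (≤5 m):
  rising sigmoids in FEAR, zero for FEAR ≤ 0 (strictly unidirectional);
  the avoidance threshold (0.8) sits far right of the submission
  threshold (0.5), so only much-higher ranks are avoided.
* Arousal multiplies every non-rest weight; rest is constant.  Scanning
  (view 360° until the next activation) is decided only when rest is
  chosen, with probability logistic in arousal (midpoint 0.62, slope
  0.13).

These parametric families are the smallest ones satisfying every stated
qualitative property of the published probability curves (whose exact
closed forms are not public); every shape parameter is in `ModelConfig`.
A counter-attack uses the same aggression weight *after* the attack's
anxiety increase, which makes it conservative; escalated fights resolve
by `w = DOM_i/(DOM_i+DOM_j)` (a logistic-in-difference alternative is
selectable), the loser flees, and bystanders within 5 m are aroused,
reoriented and activated shortly after.

Movement runs in 3-second steps of 1.8 m (0.6 m/s), re-aimed at the
target each step; bouts end on arrival (approach), on escaping the
opponent's 5 m radius (flee/leave/avoid), when grouping criteria are
satisfied again, or stochastically with stop chance 0.21 per step
(calibrated to a ~6 m mean bout distance).  After every bout the
dominant-in-proximity context of all agents is re-evaluated.  Grouping
(fewer than 3 others within 20 m at 360°, or anyone beyond 100 m)
pre-empts action selection and approaches a uniformly random member.

## Observation and statistics

Only the final recording window is observed.  Dyadic behavior counts and
grooming minutes are divided by each 3.5-day interval's 42 h to give
hourly rates, then averaged over intervals; emotions, the LIKE matrix and
one-zero proximity (within 1 m) are sampled at interval boundaries.
Grooming bouts merge give/receive role switches with no gap; bouts are
truncated at window edges.  Group statistics:

* **up/down index**: per individual (excluding extreme ranks),
  `up/(up+down)` of partner-count-normalized rates toward higher- vs
  lower-ranking members.
* **tau_rw**: row-wise Kendall correlation between an actor→receiver
  matrix and its transpose, `Σ Sᵢ / Σ max|Sᵢ|` with tau-b tie correction
  per row; all-tied rows contribute zero to both sums.
* **Shannon evenness** `H* = e^H/(N−1)`: the denominator is the number of
  *possible partners* (19), not the group size, because a perfectly
  uniform distribution over all partners must give `H* = 1`; a config
  flag is not provided — the alternative convention would make the
  endpoint examples false.

All three are verified against naive brute-force implementations to
1e−12 on random matrices.

## Calibration

The relative behavior weights (`gg/afs/app/att/ags/le/ss/av/rndw/rest`),
the stop chance, the rest schedule mean and the scanning curve are not
derivable from first principles; the shipped defaults were tuned, at the
null selectivity setting and scaled duration, until nine group-level
behavioral frequencies fell within one standard deviation of surveyed
empirical macaque data (grooming given/received min/h, % time grooming,
bout duration, approach/attack/aggressive-signal rates, movement bout
distance, % time scanning; the table ships in
`emobook/data/empirical_targets.csv`).  `calibrate()` re-runs this
procedure as a seeded random search and stops when all residuals are
below one SD or the budget is exhausted.

## What the tests show — and what they do not

The emergent-pattern tests run 5 replicates per selectivity level at the
scaled duration (1 + 4 weeks), chosen so the full suite completes on one
CPU in minutes.  They establish directions, not magnitudes: subordinates
groom more, are more aroused/anxious, and aggress less (attacks plus
aggressive signals combined — attack rates alone become noisy at the
highest selectivity, where overall activity is low); similar-ranking
dyads are closer, groom more and fight more than distant-ranking dyads;
and grooming evenness falls while reciprocity rises monotonically with
LPS.

Known limitations.  At `LPS = 0.99` the affiliation network is fragile:
with a one-day LIKE half-life and near-total partner selectivity, a group
holds only a handful of bonds, and stochastic gaps can let them decay, so
total grooming at the highest selectivity falls well below its
lower-selectivity levels rather than recovering.  The synthetic group has
no kinship, sex structure, foraging or dominance dynamics, and emotional
bookkeeping integrates grooming only — so none of the tests speak to
those aspects of real macaque groups.  Results at the scaled duration are
noisier than year-long recordings; directional assertions average over
replicates for that reason.
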