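# Methods

## Model and estimands

Two waves of a rotating- or split-panel survey are treated as simple random
samples `s_t` (size `n_t`) and `s_{t+1}` (size `n_{t+1}`) with overlap panel
`s_11` (size `n_11`); `s_10` and `s_01` are the single-wave remainders.  For
a study variable measured as `y` at wave *t* and `x` at wave *t+1*:

* The **net-change** estimator is the difference of the full-wave means.
  Its variance is

      V(δ̂) = σ_x²/n_t + σ_y²/n_{t+1} − 2 σ_xy n_11 / (n_t n_{t+1}),

  so the required wave-t size at overlap fraction γ = n_11/n_t and
  wave-size ratio r = n_t/n_{t+1} is

      n_t = (σ_x² + r σ_y² − 2 γ r ρ σ_x σ_y) / δ² · C,

  with C = (Z_{1−α(/2)} + Z_{1−β})² the critical factor.  (We keep the
  convention of pairing σ_x² with `n_t`, following the variance formula as
  commonly printed; for r = 1, the case of all worked designs, the
  labelling is immaterial.)  For a binary outcome the variance and
  covariance terms are replaced by `P(1−P)` and `P_XY − P_t P_{t+1}`.

* The **gross-change** estimator is the mean of the paired differences
  `y − x` over `s_11`, with a common paired variance σ_o² at both waves, so

      n_11 = 2 σ_o² (1 − ρ) / Δ² · C′,

  and the binomial analogue for proportions.  Both gross formulas are the
  γ = 1, r = 1 specialisation of the net formulas with common variance —
  the test suite asserts this reduction identity to 1e−9 over random draws.

The covariance is always parameterised as ρ σ_x σ_y; the null value of
every test is a zero change, and detectable changes enter the formulas only
through δ², Δ², so they are stored as magnitudes (test direction is an
analysis-stage concern, handled by the simulator's `direction` flag).

## Second-wave planning

When `n_t` is already fixed, the net-change variance is inverted for
`n_{t+1}` directly:

    n_{t+1} = C (n_t σ_y² − 2 n_11 ρ σ_x σ_y) / (n_t δ² − σ_x² C).

The denominator is positive only when `n_t` alone exceeds the single-sample
requirement `σ_x² C / δ²`; otherwise the design is infeasible and the
solver raises (`first-wave sample too small`) rather than returning a
negative size.  A negative *numerator* (huge overlap, strong correlation)
means any `n_{t+1} ≥ n_11` suffices; the solver returns `n_11` with an
`overlap already sufficient` warning instead of silently clamping.
Back-substituting the raw (pre-ceiling) solution into the variance formula
reproduces δ²/C to 1e−9; this is a tested invariant.

## The sequential search

No closed form yields `n_t`, `n_11`, `n_{t+1}` when all three are free, so
the dual problem is solved in stages: `n_11` from the gross requirement
(ceiled first — candidate overlap fractions use the integer panel size),
then candidates `n_i = n_11 + i + j`, i = 1, 2, …, where

    j = round(θ n_11 / (1 − θ)),   0 ≤ θ < 1,

is an exclusive lower bound on the fresh share `n_10` (θ = 0: the fresh
share may start at 1; θ = 0.5: it starts above `n_11`).  At each candidate
the approximate power of the net test is

    power_i = Φ( δ / sqrt(V_i) − Z_{1−α(/2)} ),
    V_i = deff · (σ_x²/n_i + σ_y²/n_{i,t+1} − 2 n_11 ρ σ_x σ_y /(n_i n_{i,t+1})),

with `n_{i,t+1} = ceil(n_i / r)`.  For r = 1 this is the familiar
`Z_{1−α(/2)} − sqrt(n δ² / (σ_x² + σ_y² − 2γρσ_xσ_y))` statistic.

**Stop rule.** The default stops at the first candidate whose approximate
power, rounded to two decimals, reaches the target — i.e. power ≥ target −
0.005.  A strict rule (power ≥ target exactly) is available via
`stop_rule="strict"`; on the continuous reference design the rounded rule
stops at n_t = 83 (power 0.7955) and the strict rule at n_t = 85 (power
0.8002).  The rounded rule is the default because it reproduces the
reference designs on both outcome scales, including their iteration counts;
the suite tests both rules.

**r ≠ 1.** The base algorithm assumes equal waves.  Our generalisation
indexes candidates by `n_t`, sets `n_{t+1} = ceil(n_t/r)`, and floors the
candidates at `max(n_11, ceil(r·n_11))` so that both waves can contain the
overlap panel; for r = 1 the floor is `n_11` and the base iteration count
is unchanged.

**Inflation.** Fielded sizes are `ceil(n_11/RR_11)` and
`ceil((n_t−n_11)/RR_10)`.  Powers are reported at the completed-interview
sizes, not the inflated ones: the inflation buys back the interviews lost
to nonresponse, it does not add power.  The design effect multiplies the
SRS variance (equivalently, the required size) everywhere, so sequential
and closed-form answers scale identically in `deff`.

## Monte-Carlo verification

The simulator draws panels with the exact `s_10/s_11/s_01` structure.
Continuous outcomes: paired units from a bivariate normal with the stated
marginal variances and correlation, single-wave units from the matching
marginals.  Binary outcomes: paired units from the four-cell joint
(`p_11 = P_XY`, `p_10 = P_t − P_XY`, `p_01 = P_{t+1} − P_XY`, remainder
`p_00`), validated against the Fréchet bounds
`max(0, P_t+P_{t+1}−1) ≤ P_XY ≤ min(P_t, P_{t+1})`.

Analysis-stage tests are z-tests with plug-in moments (ddof = 1): the net
test assembles the variance from the full-wave sample variances and the
sample covariance of the paired subset; the gross test uses the paired
differences only (perturbing single-wave units leaves it bit-identical —
tested).  For one-sided tests the rejection direction is the hypothesized
sign of (wave-t mean − wave-t+1 mean), supplied by the caller.

One master seed spawns per-replicate `SeedSequence` substreams, so
replicate k is identical regardless of how many replicates run.  With
10,000 replicates the Monte-Carlo standard error of a power near 0.8 is
about 0.004; the suite checks empirical power against the design-stage
approximation, type-I error against the nominal level (within three MC
standard errors each), estimator unbiasedness, and agreement of the mean
plug-in variance with the empirical variance of the estimate (within 5%).

What the generator does *not* emulate: clustered or weighted designs (the
design effect is a scalar inflation, never a simulated structure),
stochastic attrition (only flat completion-rate inflation), non-normal
continuous outcomes, and more than two waves.  Passing simulations
therefore validate the formulas under their own assumptions, not the
behaviour of any particular field survey.

A deliberate asymmetry: the net and gross requirements of a design are
stated with moments that need not be mutually consistent as one
data-generating process (the continuous reference design pairs net
variances 100/75 with a gross common variance of 200).  The simulator
verifies each test under its own spec's generator, mirroring how the two
requirements enter the calculators as separate inputs.

## Numerical choices and degenerate inputs

* Ceilings are applied once, after all real-valued algebra; reported
  `n_raw` is the pre-ceiling value.
* A non-positive formula value (e.g. ρ → 1 in the gross formula) returns
  n = 1 with a warning — a sample of zero is meaningless for estimation.
* A non-positive net variance term (possible when γ·r·ρ is large with
  unequal variances) raises rather than returning a complex or negative
  size.
* `power > alpha` is enforced at spec construction; quantiles come from
  `scipy.stats.norm.ppf` (accurate far beyond the 6 decimals needed).
* The iteration cap (default 10⁶) exists only as a plumbing safeguard; the
  error message names the last achieved power.
* The lower bound j uses conventional half-up rounding of θ·n_11/(1−θ).

## Problem sizes used in the checks

The reference designs are desk-scale (n_t ≤ 83), so the full suite,
including the 10,000-replicate empirical power and type-I checks, runs in
well under a minute; the acceptance script's quantities are deterministic
and complete in seconds.

## Known limitations

Infinite-population SRS formulas (no finite-population correction); one
outcome per run (no stratum-specific parameters); no joint optimisation of
(n_11, n_t) under a cost function — the overlap is fixed by the gross
requirement, as in the underlying algorithm; data cumulation across waves
and rotation schedules beyond two waves are out of scope.
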