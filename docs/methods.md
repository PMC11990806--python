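# Methods

## Scope and model

`nanoshelf` models the thermal aging of a colloidal nanoparticle suspension
as a sequence of unidirectional stages: within a stage, a quality indicator
(supernatant iron after centrifugation, DLS Z-average diameter, PDI)
changes approximately linearly with time, and stage boundaries mark a
change of mechanism (e.g. iron is first co-sequestered by growing clusters,
then released as they degrade). Shelf life is defined as the time for an
indicator to cross a percent-change acceptance limit, and is transported
between temperatures by the empirical Van't Hoff (Q10) rule

    C(t) = A^((t_exp − t)/10) · C_exp

with `A` the fold-change in rate per 10 °C. The exponent uses the Celsius
temperature *difference*, so it is independent of the temperature scale's
origin; Arrhenius computations, by contrast, always use kelvin.

The rule is a heuristic, valid over moderate temperature ranges when a
single activated process dominates. The package therefore never asserts its
validity: it computes the two-point Arrhenius activation energy from rate
constants at the stress and storage temperatures,

    E_A = R · T₁T₂/(T₁−T₂) · ln(k₁/k₂),        R = 8.314 J/(mol·K),

and the energy a given `A` implies at the mean kelvin temperature,
`E_A = R·T²·ln(A)/10` (the standard Q10–Arrhenius link, obtained by
differencing the Arrhenius exponent over a 10-degree step and linearising),
and reports both with a relative-difference verdict at a caller-chosen
tolerance. `R = 8.31` can be passed for literal replication of older
calculations. Rate constants fed into this comparison, when derived from
stage fits, use the convention k = |slope| / (value at stage start) — the
fractional first-order rate a linear stage implies at its start; when a
published rate pair is supplied directly, its units need only be consistent
between the two points, since only the ratio enters.

## Stage segmentation

Breakpoints are found by exhaustive search over sample times: each
candidate split shares its boundary sample between the two segments, each
segment gets an independent ordinary least-squares line
(`scipy.stats.linregress`), and the candidate minimising the total squared
error wins. At least 3 points are required per segment (so ≥ 6 overall),
and the two-stage model is accepted only when it reduces the SSE by more
than 20 % relative to a single line — an explicit criterion standing in for
visual stage identification. A flat SSE profile (a perfect single line) is
flagged degenerate and left unsplit. Stages are labelled by slope sign; a
stage whose total fitted change is below `flat_tol` (default 2 %) of the
mean level is labelled flat, matching the relative index change
conventionally treated as "no change" in turbidimetric monitoring.

Linear fits are parameterised in absolute time: the intercept is the value
of the fitted line at t = 0, so a threshold crossing is simply
t = (target − intercept)/slope. Crossings falling outside the fitted window
are permitted (sparse sampling often brackets rather than hits the limit)
but always flagged as extrapolated; crossings at negative time and
zero-slope stages raise.

## Coefficient refinement

Given the stress-test crossing `C_exp` at `t_exp` and an observed
storage-temperature crossing, `A` is refined by bisection on the strictly
monotone map A ↦ C(A) within caller-supplied bounds (default [1.5, 6]),
stopping when the predicted time matches the observation to a relative
tolerance (default 1e−6; the closed form
A = exp(ln(observed/C_exp)·10/(t_exp−t_obs)) serves as an independent
cross-check in the tests). The pipeline report also tabulates a diagnostic
grid of candidate coefficients with their predicted durations, mirroring
the manual "selection method" a bench scientist would use.

## Stern–Volmer quenching

Relative fluorescence intensity rfi(q) = F₀/F(q) is modelled as
1 + k·q with the intercept fixed at 1 (the model has no free intercept);
the estimator is the through-origin least-squares slope on (q, rfi−1) over
the q > 0 points, k = Σq(rfi−1)/Σq². Q is in µM Fe³⁺, so k is in µM⁻¹
(values quoted per mole differ by a factor 10⁶); C₅₀ = 1/k.

The standard error is *not* the iid residual formula. Fluorescence
intensities carry multiplicative noise, so rfi = F₀/F inherits (i) a
per-point error with standard deviation proportional to rfi and (ii) a
shared error from the q = 0 baseline, perfectly correlated across the
ladder and largely collinear with the slope — the iid formula misses both
and produces badly anticonservative intervals. Writing the error vector as
e = ε₀u − diag(u)ε with u the rfi profile, the slope error is qᵀe/qᵀq,
giving Var(k̂) = σ²[(qᵀu)² + Σq²u²]/(qᵀq)²; σ² is estimated from the
residual sum of squares divided by its expectation coefficient
‖(I−P)u‖² + tr(D(I−P)D) under the same model (P the projection onto q).
Simulated coverage of the nominal 95 % interval k̂ ± 1.96·k_se at 2 %
multiplicative noise over 500 seeded ladders is 94.6 % (k = 4) and 95.6 %
(k = 2).

A free-intercept OLS fit runs alongside as a linearity diagnostic; its
intercept deviating from 1 by more than 5 % raises a warning flag
(curvature, inner-filter effects, or baseline drift). Mechanism
classification compares k at two temperatures with a Welch-style two-sided
test (Satterthwaite degrees of freedom from the two fits, α default 0.05):
non-significant difference → static quenching; significant increase with
temperature → dynamic; significant decrease → static with an explanatory
note (collisional quenching cannot slow with temperature). Ladders with
negligible quenching fit to k ≈ 0 with a low R² rather than being rejected.

## Turbidity and morphometry

Turbidity follows I = I₀·e^(−τl), τ = ln(I₀/I)/l, τ = n·C. The per-particle
cross-section is C = Qπd² by default for replication of the source
convention; a `convention="geometric"` switch selects the textbook
geometric cross-section Qπd²/4. Instrument "turbidity index" readings
(optical densities) are compared as raw indices via
100·(start − end)/start, without unit conversion. Cluster-area sets are
summarised by median and quartiles using numpy's linear-interpolation
quantile convention; fold changes are ratios of medians.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, which makes recovery tests sharp but bounds what they demonstrate:

- **Kinetics**: piecewise-linear mean with one breakpoint, additive
  Gaussian noise, values clipped at 0 (and to [0, 1] for PDI). Default
  study conditions mirror the stress-test design: iron starting at
  12 µg/mL falling at 0.0771 µg/mL/min, a breakpoint inside a 120-min
  window at 70 °C, and a storage counterpart at 8 °C whose time axis (and
  breakpoint) is stretched, and slopes divided, by A^(ΔT/10) — so
  noiseless crossing times scale by exactly that factor. Recovery tests
  use 13 evenly spaced samples per series rather than the sparse 4-point
  bench schedule, the density needed for the breakpoint search's
  3-points-per-segment minimum with headroom; noise defaults to ~2 % of
  the initial level, a typical colorimetric/DLS repeatability figure,
  as no channel variances are published.
- **Quenching**: F(q) = F₀/(1 + kq) with multiplicative Gaussian noise on
  every point including the baseline.
- **Turbidity**: transmitted fraction exp(−(τ + drift·t)·l) plus additive
  noise, clipped to (0, 1].
- **Cluster areas**: lognormal with the prescribed median (median of a
  lognormal is e^μ, so areas = median·e^(σZ)).

Identical seeds give bit-identical output (`numpy.random.default_rng`);
paired series draw the storage replicate from seed+1. Real data deviate
from these idealisations — kinetics need not be piecewise linear, DLS noise
is not Gaussian-additive, quenching can curve upward under combined
static/dynamic mechanisms — so passing recovery tests certify the inference
machinery, not the adequacy of the linear-stage model for any particular
formulation.

## Numerical choices and degenerate inputs

- Canonical time unit is minutes; storage days convert as 1 d = 1440 min;
  months render as 30.44 d.
- CSV dialect: comma-separated, dot decimal, UTF-8, header required;
  floats written at 17 significant digits and parsed with round-trip
  precision so write∘read is the identity.
- Replicate rows (a `replicate` column) are averaged per time point on
  load; duplicate unlabelled timestamps within a condition are rejected.
- Missing channel cells are allowed per row; operations needing a channel
  reject series lacking it rather than imputing.
- Scientific invariant violations (PDI outside [0, 1], single-sample
  series, protein mass with no protein) are reported as findings by
  `validate_series`, not exceptions, so suspect exports remain inspectable.
- Breakpoint ties in SSE resolve to the earliest candidate; both the
  search and its brute-force test oracle use this rule.
- Corona thickness is the raw Z-average difference (with − without
  albumin), not halved; negative differences are flagged `no_corona`
  rather than raised.
- Bisection is capped at 200 iterations; non-bracketing bounds raise
  rather than silently clamping.

## Known limitations

- Exactly one breakpoint per series (at most two stages); multi-stage
  kinetics would need recursive splitting.
- The Van't Hoff refinement uses a single observed crossing; no uncertainty
  on `A` is propagated from the stage-fit standard errors.
- Arrhenius validation is strictly two-point; no multi-temperature
  regression.
- The quenching model is the linear Stern–Volmer form: no inner-filter
  correction, binding stoichiometry, or lifetime analysis.
- TEM segmentation, instrument raw formats, and DLS cumulant internals are
  out of scope; the package consumes their tabular outputs.
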