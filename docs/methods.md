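# Methods

This note documents the models, estimators and numerical choices behind
`mnexcite`, and what the simulator-based validation does and does not show
about real HD-EMG data.

## Discharge-rate smoothing

Instantaneous rates are `1/ISI` for each closed inter-spike interval,
placed at the **interval midpoint**. `1/ISI` estimates the mean rate over
the interval, which a drifting discharge attains mid-interval; end-aligned
placement would lag the rising limb and lead the falling limb of a ramp,
and because ΔF subtracts a falling-limb value from a rising-limb value the
two half-ISI lags *add*, deflating ΔF by roughly the rate slope times one
ISI (measured on the simulator: −0.11/−0.19/−0.26 pps at i20/i40/i60 for
end-aligned placement, ~0 for midpoint placement).

The continuous curve is ε-support-vector regression (RBF kernel) on the
rate points, evaluated on a 100 Hz grid over the unit's active interval
[first spike, last spike] and never extrapolated further. Defaults:

| parameter | default | rationale |
|---|---|---|
| C | 50 | enough capacity to follow ramp modulation; insensitive ±an order of magnitude |
| ε | 0.01 pps | a wide insensitive tube (e.g. 0.1 pps) lets the fit sit systematically off the trend, adding ~±0.15 pps point errors |
| kernel length scale | 0.25 × median pairwise rate-point distance, clipped to [0.35, 1.2] s | adapts to train duration; the floor prevents ringing across sparse ISIs, the cap bounds boundary bias |
| grid | 100 Hz | ≫ discharge-rate bandwidth |

All smoothing parameters are config-overridable and recorded in the run
manifest. The time axis is centred before fitting, making the curve
invariant to the trial's time origin. A degenerate (constant-rate) unit
yields a constant curve; units with fewer than 4 rate points are flagged
unsmoothable and counted.

Known limitation: within a half kernel width of the activity boundaries
the fit is one-sided and can carry ~0.2 pps bias on steep ramps; this is
visible in the i60 validation numbers below.

## Events, bins

Recruitment threshold is the torque (as %MVT, from the 15 Hz zero-phase
2nd-order Butterworth-filtered trace) at a unit's first discharge;
derecruitment torque likewise at the last discharge; peak discharge rate
is the smoothed-curve maximum. Thresholds bin as (0,20], (20,40],
(40,60] %MVT; units above 60 %MVT are excluded from binned analyses with a
reason recorded.

## Paired-unit ΔF

ΔF = control smoothed rate at test recruitment − at test derecruitment
(positive under hysteresis; negative values retained). Eligibility, all
configurable and logged: control threshold below test's; control recruited
≥ 1.0 s earlier; control derecruited after the test unit; control
modulation ≥ 0.5 pps within the test window; curve–curve correlation
≥ 0.7 on a common 100 Hz grid. These thresholds are conventional values in
the paired-motor-unit literature, not a verbatim replication of any one
study's settings. ΔF is computed per contraction and averaged per test
unit over its eligible controls, then over trials of the same intensity
(units are tracked within, not across, intensities).

## Brace height

The ascending trajectory (smoothed rate vs torque, recruitment → peak
discharge, truncated at the torque peak and flagged if peak discharge
falls later; non-monotone torque is projected onto its running-maximum
envelope and flagged) is normalised so each axis's endpoint span maps to
[0, 1]. In that frame the recruitment→peak reference segment is the unit
square's diagonal, the right triangle's hypotenuse has length √2, and the
perpendicular deviation of a point (x, y) is (y − x)/√2. Brace height is
the maximal **above-line** deviation expressed as % of the hypotenuse:
(y − x)/2 × 100. Normalising makes the metric invariant to affine
rescaling of either axis — without it, a "perpendicular" distance across
pps and %MVT would be unit-dependent.

Exclusions are a deterministic filter (no manual review): brace height
> 100 %rTri, or a negative slope of the normalised recruitment-point →
brace-point segment. A trajectory lying entirely below the reference line
takes the negative-slope path. "Negative recruitment-to-brace-height
slope" is interpreted as the slope of that normalised segment; this is one
of several defensible readings and is fixed here.

## Robust mixed-effects statistics

Per bin: `outcome ~ group × intensity + sex` (treatment coding) with a
participant random intercept. Fitting is Huber M-estimation (tuning
constant 1.345, 95% normal efficiency) by iteratively reweighted Henderson
equations; residuals are standardised by their MAD each iteration and the
update stops when coefficients move < 1e−8 (relative). The variance ratio
λ = σ²ₑ/σ²_b is estimated once by a MAD-robustified moment method
(cluster-demeaned residual scale; between-cluster variance of mean
residuals corrected for the within contribution) and held fixed — in the
balanced-ish designs here the fixed effects are insensitive to λ, and a
Gaussian cross-check against a standard random-intercept ML fit agrees to
< 0.05 pps. A singular system or a design with fewer than two
participants per group raises an explicit convergence error.

Estimated marginal means are linear combinations of the coefficients with
sex balanced 50/50. Contrast uncertainty comes from a **cluster bootstrap
resampling participants** with replacement (a resample missing a group
level is redrawn and counted), with bias-corrected-and-accelerated (BCa)
intervals; the acceleration term uses leave-one-participant-out jackknife.
Bootstrap refits reuse the original λ and warm-start at the point
estimate. Resampling participants (not motor units) respects the nesting
of units within participants; the alternative unit-level bootstrap would
understate between-participant variance. Coefficient tables carry
model-based (naive) standard errors; the bootstrap intervals are the ones
to trust for contrasts.

Percent differences are reported with the subtrahend group as denominator
((a − b)/b × 100); reporting precision is 2 decimals for differences and
the nearest integer for percents.

Association models: `ΔF ~ measure × sex × intensity` (+ body mass for
peak torque), participant random intercept, same robust fit; per-stratum
slopes from linear combinations. R²m/R²c are squared correlations between
the observed outcome and the fixed-effects / full-model predictions. A
predictor must be present for ≥ 80% of participants; models are
complete-case with counts logged.

## The simulator

A pool of `n_units = 40` motoneurons per participant × intensity:
thresholds θᵢ exponentially spaced over [3, peak − 2] %MVT (many low-, few
high-threshold units, 5% multiplicative jitter); rate gains ~N(0.5, 0.08)
pps/%MVT (floor 0.15); minimum rate 7 pps; saturation 28 pps. A common
drive tracks the triangular target; unit *i* fires while the drive exceeds
θᵢ before its first spike and θᵢ − Δθᵢ afterwards, at rate
`min(rate_min + gain·(D − θ_eff), rate_sat)`. The effective-threshold drop
Δθᵢ is the injected PIC-like hysteresis; it is capped at θᵢ − 0.5 so every
unit has a defined derecruitment on the ramp. Spikes step by `1/rate`
(midpoint-refined) with multiplicative log-normal ISI jitter (CV 0.10 by
default). ISI CV ≈ 0.1 is typical of steady voluntary contractions;
decomposition yield is thinned with a threshold-increasing probability
(0.35 + 0.4·θ/peak) so trials contribute roughly 10–30 "decomposed" units,
and PNR values are drawn N(35, 3²) dB so the ≥ 30 dB filter removes a few
percent. Group profiles scale Δθ with intensity — sarcopenic
4.8 %MVT flat; control 6.5 × (1.0/1.12/1.27); athlete
6.8 × (1.0/1.20/1.45) — chosen once so simulated cohort ΔF levels
(≈ 2.4 pps flat; 3.2→4.0; 3.4→4.7) resemble the phenotype contrast the
package is designed to analyse. Participant covariates (gait speeds,
handgrip, chair-rise power, …) are drawn from group-level normal
distributions consistent with the SDOC screen.

Because rates are affine in drive, ΔF has the closed form
`gain_c · Δθ_test` away from saturation (`analytic_deltaf`). Two oracle
variants are used deliberately:

* **`analytic_deltaf`** — exact threshold crossings; the estimand. Used
  for mean-bias and monotonicity checks.
* **`model_deltaf_at`** — control model rate at the test unit's *observed*
  first/last spikes. A spiking unit's last discharge precedes the true
  derecruitment crossing by up to one ISI; that observation-discretization
  gap deflates any spike-based ΔF by up to ~gain · ramp rate · ISI
  (≈ 0.15 pps at i20, more at faster ramps) and no estimator can remove
  it. Per-pair accuracy is therefore judged against `model_deltaf_at`
  (isolating smoothing error, < 0.05 pps at i20), while the bias against
  the exact estimand stays bounded by the mean-bias checks (< 0.2 pps
  noise-free, < 0.5 pps at ISI CV 0.1).

What the simulator does *not* emulate: decomposition errors (missed or
spurious spikes), participant-level random effects in discharge
parameters, drive–torque mismatch (torque equals drive plus optional white
noise), rate adaptation, or physiologically detailed PIC channel dynamics.
Passing the validation suite therefore shows the estimator chain is
correct for its stated model, not that real-data ΔF is unbiased.

## Validation studies (problem sizes)

* ΔF accuracy: one 25-unit noise-free i20 pool (~200 eligible pairs);
  noisy bias over two ISI-CV-0.1 pools (~400 pairs).
* Hysteresis sweep: Δθ ∈ {0,…,6} %MVT, 15-unit noise-free pools,
  thresholds starting at 8 %MVT so the Δθ cap never binds.
* Brace height: 100 random monotone synthetic trajectories vs an exact
  point-to-segment oracle (< 0.1 %rTri).
* Group-pattern recovery: 6 + 6 + 6 participants, one trial per intensity,
  B = 500 BCa bootstrap on the rt0–20 bin.
* Null calibration: 100 replicates of a 3 × 8-participant null cohort
  drawn directly from the mixed-model data-generating process, B = 200;
  the fraction of 95% group contrasts excluding zero is ≤ 10%.

These sizes were chosen as the smallest that make the checks statistically
meaningful; all scale up via configuration.
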