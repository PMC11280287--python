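# Methods

## Scope and model assumptions

The package analyzes Franz diffusion-cell IVPT data under the standard
pseudo-infinite-dose assumptions: a homogeneous membrane of thickness *h*
with constant diffusivity *D* and donor/membrane partition coefficient *K*,
a well-stirred receptor acting as a perfect sink, and a donor whose
concentration *C* is effectively constant over the experiment. Under these
assumptions the cumulative amount crossing unit area follows the classical
series solution

    Q(t) = K·C·h · [ D·t/h² − 1/6 − (2/π²) Σ_{n≥1} ((−1)ⁿ/n²) e^(−D·n²π²·t/h²) ]

whose late-time asymptote is J·(t − T_lag) with J = K·C·D/h and
T_lag = h²/(6D). The analysis side never fits this full curve; like the
laboratory practice it mirrors, it uses only the terminal linear segment
(slope → flux, x-intercept → lag) and the algebraic relations
Kp = J/C, D = h²/(6·T_lag), Css = A·J/Cl. Donor depletion is deliberately
not corrected for in the estimators; it exists only as a stressor in the
simulator's finite-dose mode.

## Sampling-replacement correction

Withdrawing an aliquot Vᵢ at each sampling time removes drug that later
samples no longer see. The correction
Qₙ = (V·Cₙ + Σᵢ₌₁ⁿ⁻¹ Vᵢ·Cᵢ)/A restores exactly the mass removed, and on
noiseless simulated runs with dilution enabled it reproduces the true
cumulative curve to machine precision (the test suite asserts < 10⁻⁹
relative at every sampling time). The naive cumulation V·Cₙ/A strictly
underestimates the truth from the second sample on; this ordering is
asserted as an invariant.

## Terminal linear-segment selection

The published convention — "the linear segment of the permeation profile
with R² > 0.95" — underdetermines the segment: on an exact Fickian curve
sampled at the reference schedule {0, 1, 2, 4, 6, 8, 22, 24} h, even the
full 8-point window reaches R² ≈ 0.998 at lag 1.33 h while its x-intercept
is biased ~30% low, because the early burn-in points lie below the
asymptote. Simply taking the longest window above the threshold is
therefore not a usable rule. `fit_steady_state` instead:

1. starts from the longest terminal window (ending at the last sample,
   ≥ `min_points` = 3 points) with R² ≥ `r2_threshold` (default 0.95);
2. iteratively drops points earlier than `burn_in_multiple` (default 2) ×
   the currently fitted lag and refits, to a fixed point. The factor 2
   comes from the transient: the slowest mode decays as
   e^(−π²·t/(6·T_lag)), so by t ≈ 2·T_lag the curve is within ~4% of its
   asymptote and the residual intercept bias is small;
3. reports the longest terminal window at/after the converged start that
   still meets the R² threshold, so the published threshold remains a hard
   constraint on the reported segment.

On noiseless reference-schedule data this recovers flux within 0.03%/1.2%
and lag within 0.5%/5.8% at true lags of 1.33/4.0 h; under 5% assay noise
(100 seeds) the median relative error is ≈ 2.6% for Kp and ≈ 11% for D.
Lags much longer than ~4 h are not reliably estimable from a 24 h
experiment at this schedule — steady state is simply not reached — and the
test suite checks long-lag recovery only at denser sampling.

Degenerate inputs: a profile with zero variance in a window is treated as
a perfect constant fit (R² = 1) so that an all-flat profile fails with
"non-positive flux" rather than "not linear". A negative fitted lag
(possible under noise) is reported raw and flagged; the clamped value 0 is
carried for display, and the replicate is excluded from the D = h²/(6t)
transform rather than silently clamped into it.

## Averaging conventions

Group summaries compute every metric per replicate and then average
(SD with n−1 denominator), which is the convention consistent with
reporting an SD for nonlinear transforms like D and Css. Because 1/lag is
convex, transform-then-average and average-then-transform differ
(Jensen); both are exposed via `summarize_group(..., order=)`, defaulting
to per-replicate. The Css column accepts a `dense_factor`
(N_dense/n_actual) so plasma-level predictions can be reported on the
dense-packing scale used in microneedle extrapolations; with the published
inputs (flux 1.69 µg/sq·cm/h, pore area 9267.40 sq·µm, 100 channels,
0.64 sq·cm, 118 mL/h) this chain gives 989.1 µg/L, within 0.02% of the
published 988.92 (which used the unrounded dense flux).

`required_array_area` is the exact algebraic inversion of the Css
relation, A = Css·Cl/(1000·J). Note that with the documented dense flux it
gives 0.218 sq·cm for the fast arm against a published 0.36 ± 0.11 sq·cm;
the published array sizes are not reconstructible from the stated
relation and inputs, so the function implements the inversion and leaves
the discrepancy visible rather than matching the printed number.

## Dense-channel extrapolation and geometry

N_dense = round-half-up(10⁸/ā) with ā the mean pore area in sq·µm (both
published counts, 10,791 and 11,673, confirm nearest-integer rounding).
The default actual channel count is the rounded observed count per group
(69 and 100 in the reference study), overridable everywhere it is used.
Area fractions use the square needle base side for the base-area fraction;
total channel area is mean pore area × channel count, reported in both
sq·µm and sq·cm. The Pore Permeability Index is consumed as supplied
per-pore values (its defining formula is proprietary to the acquisition
software); only descriptive statistics are computed, with zero-intensity
pores counted separately but included in n.

## Skin integrity and statistics

Skin resistance follows the series-circuit relation
Rs = Vs·RL/(A·(Vo−Vs)) with defaults Vo = 100 mV and RL = 100 kΩ; it is
strictly increasing in Vs and diverges at Vs → Vo, so the simulator's
inversion Vs = Vo·Rs·A/(RL + Rs·A) can hit any finite target exactly.
Group comparisons use scipy: two-sided Student's t by default (Welch by
flag — the equal-variance choice matches the named test, not a judgement
that variances are equal), one-way ANOVA, and Tukey's HSD for family-wise
control. The suite verifies on 1000 null simulations (4 groups, n = 4)
that both the ANOVA rejection rate and the Tukey family-wise error sit at
0.05 ± 0.02, and that Tukey-adjusted p-values never undercut the
unadjusted pairwise p on the same contrast.

## Disposition conventions

Topical selectivity TS = 100·Qs/(Qs+Q24) and total delivery Qs+Q24 are
computed per replicate, then averaged. Delivery efficiency ships in two
conventions because published tables commonly divide the per-area total
(µg/sq·cm) directly by the dose in µg: the default "reported" convention
reproduces that reading (efficiency numerically equals total delivery for
a 100 µg dose) and logs a warning about the dimensional looseness; the
"strict" convention multiplies by the permeation area first. They agree
only at A = 1 sq·cm.

## Rheology readouts

The LVE limit is the largest strain whose G′ stays within a tolerance
(default 5%) of the low-strain plateau, the plateau being the mean of the
first three points. The flow point (G′ = G″) is interpolated linearly in
log–log coordinates, matching the log-spaced acquisition of amplitude
sweeps. Thixotropic recovery is the ratio of window means of G′: the full
pre-shear interval (default 0–100 s) against the last 50 s of the recovery
phase — instruments do not agree on point-value vs window-mean
definitions, so the windows are explicit parameters; recovery above 100%
(post-shear stiffening) is allowed.

## Synthetic data

The generator's defaults are the reference study conditions: sampling at
{0, 1, 2, 4, 6, 8, 22, 24} h, V = 5 mL, Vᵢ = 0.3 mL, A = 0.64 sq·cm,
C = 1000 µg/mL, h = 0.031 cm, Cl = 118 mL/h, n = 4 replicates, and a
membrane truth taken from the fast microneedle arm (lag 1.33 h → D =
1.204×10⁻⁴ sq·cm/h; flux 1.69 µg/sq·cm/h → K = 0.435). The Fickian series
is truncated when a term falls below 10⁻¹² of the leading term
(≥ 9 significant digits at all reference time points). Assay noise is
multiplicative lognormal with a mean-one CV parameterization, keeping
concentrations positive. The finite-dose mode integrates the diffusion PDE
with a depleting well-mixed donor by an explicit finite-volume scheme
(default 40 cells, dt = 0.2·dx²/D; a user-supplied unstable step raises an
error carrying the stable step), which conserves donor + membrane +
receptor mass to machine precision by construction.

What the simulator does **not** emulate: skin heterogeneity and follicular
transport, microchannel-closure kinetics, receptor back-pressure
(sink-condition violations), assay drift or limit-of-quantification
censoring. Passing recovery tests therefore demonstrate estimator
correctness under Fickian conditions with multiplicative noise — not
robustness to every failure mode of real skin data.

## Problem sizes in the test suite

Recovery and calibration checks use 100 simulated replicates (seeds
1–100) and 1000 null ANOVA simulations respectively; the pore-statistics
law-of-large-numbers check pools 2000 ten-pore arrays. These sizes give
standard errors comfortably below the asserted tolerances while keeping
the default suite quick to run.

## Known limitations

* Lag (hence D) is ill-determined when T_lag approaches the tail of the
  sampling schedule; the fit will error out (no qualifying window) or
  return a visibly biased lag rather than refuse — inspect
  `segment_start_index` and R².
* The dense-channel extrapolation assumes flux strictly proportional to
  open channel count, ignoring channel interaction and edge effects.
* The reported manifest intentionally omits wall-clock timestamps so that
  identical inputs produce byte-identical report directories.
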