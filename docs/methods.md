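# Methods

## Scope and flow

The package analyses one laboratory visit per athlete — a submaximal
incremental treadmill roller-skiing test followed by a maximal self-paced
time trial (TT) — and one field biathlon competition, producing per-athlete
energetics and per-sex cohort statistics. The chain per athlete is:

1. reference-stage selection → gross efficiency (GE);
2. exponential lactate model → oxygen uptake at 4 mmol·L⁻¹ (V̇O₂@4mmol);
3. TT series → V̇O₂peak (best 3 × 10-s rolling mean);
4. TT average power → aerobic/anaerobic partition → accumulated O₂ deficit
   (AOD).

Sexes are analysed strictly separately. The two sexes ski different
inclines, distances and speeds, so GE, TT power and TT metabolic rates are
summarised per sex but never tested across sexes; t-tests, effect sizes and
normality reports are computed only for protocol-independent variables.

## Energetics

External power is v·m_sys·g·(sin α + μ_R cos α). Defaults: g = 9.81 m·s⁻²;
μ_R = 0.0224 (NNN binding, female protocol) and 0.0216 (SNS, male protocol),
per-protocol configurable; equipment mass defaults to 0 kg because the
laboratory tests are skied without a rifle, so per-kg quantities use body
mass alone.

Aerobic metabolic rate uses the caloric equivalent 4184·(1.1·RER + 3.9)/60
W per L·min⁻¹ of V̇O₂, which at RER = 1.00 is 20.92 kJ per litre of O₂. The
equivalent is undefined above RER 1.00 (non-metabolic CO₂), so values above
1.00 raise unless the caller explicitly opts into clamping.

Reference stage: the stage with RER closest to 1.00 from below; ties go to
the later (higher-workload) stage, the one nearest race intensity.

TT partition: MR_req = PO_tt/(GE/100) with GE from the reference stage;
MR_ae from the time-weighted mean of the 10-s TT V̇O₂ samples at RER fixed
to 1.00 (supramaximal work is treated as fully carbohydrate-fuelled); the
final sample is weighted by its actual duration. A flag can exclude leading
onset samples; the default includes them, since the mean-V̇O₂ convention
integrates the whole trial. A trapezoidal integration of the per-sample
MR_ae trace is provided as an independent oracle; on plateau-kinetics traces
the two agree within 0.5%. Negative MR_an (a sub-maximal trial) is returned
with a flag rather than raised, so degenerate inputs don't abort a cohort
run. AOD = 0.047801 mL O₂ per joule of anaerobic energy.

## Lactate threshold

Model: La = a·exp(b·V̇O₂), two parameters, fitted on V̇O₂ per kg so the
inverted threshold is on the reported scale. A log-linear regression of
ln(La) on V̇O₂ initialises a nonlinear least-squares refinement on the
lactate scale — fitting on the raw scale avoids down-weighting the
high-lactate stages that pin down the threshold region. An additive-offset
variant was considered and rejected as unidentifiable from 3–5 stages. A
flag can exclude the first (near-baseline) point; default off. The threshold
inversion ln(threshold/a)/b is exact by construction. V̇O₂peak uses an
unweighted 3-sample window with no interpolation: missing samples are an
error, not something to paper over.

## Statistics

Student's pooled t (not Welch; a Welch option exists) with df = n₁+n₂−2.
Cohen's d uses the root-mean-square of the two SDs, which equals the
df-pooled SD at equal group sizes; magnitude bands trivial/small/moderate/
large/very large with boundaries 0.2/0.6/1.2 assigned to the higher band and
2.0 to "large" (the top band is strictly > 2.0). Blockwise regression fits
nested OLS models adding one predictor per block in a fixed order —
(V̇O₂peak or V̇O₂@4mmol), relative anaerobic energy contribution E_an (%),
GE — and reports each predictor's increment in R²; increments sum to the
full-model R² by construction and the overall p is the full-model F test.
E_an enters as a percentage of required energy rather than absolute AOD (an
absolute option exists) because the relative contribution is the
protocol-independent quantity. Fractional utilisation (% of V̇O₂max) is
computed per athlete and then summarised, not derived from group means.
p-values are reported unadjusted; no multiple-testing correction is applied.
Shapiro–Wilk statistics are reported per variable and sex but never gate the
analysis.

## Synthetic cohort

The generator emulates a two-sex elite-biathlete study (default n = 14 per
sex). Four standardized physiological latents per athlete — V̇O₂max, GE,
anaerobic capacity (AOD), fractional utilisation — are independent standard
normals scaled to per-sex marginals:

| trait | female | male | units |
|---|---|---|---|
| V̇O₂max | 55.6 ± 4.1 | 66.0 ± 3.2 | mL·kg⁻¹·min⁻¹ |
| GE | 16.6 ± 0.8 | 18.4 ± 1.1 | % |
| fractional utilisation | 82.1 ± 3.6 | 81.3 ± 3.9 | % of V̇O₂max |
| AOD | 49.2 ± 9.9 | 57.7 ± 15.5 | mL·kg⁻¹ |
| competition speed | 4.7 ± 0.3 | 6.1 ± 0.2 | m·s⁻¹ |

Standardized competition (BC) speed is a linear combination of the latents
plus independent residual. The first three loadings are square roots of each
trait's target share of BC-speed variance — female 31/35/1%, male 21/31/0%
for V̇O₂max/GE/AOD, giving population R² 0.67 and 0.52 for the three-block
regression — and the fourth is solved analytically so the threshold uptake
(frac·V̇O₂max, linearised) carries its own target share (30% female, 35%
male). Because the latents are independent, these shares are population
parameters fixed at construction, not quantities tuned on generated samples;
the implied population TT–BC correlation comes out near 0.7. Draws are
clipped to physiologic bounds (V̇O₂max 35–90 mL·kg⁻¹·min⁻¹, GE 12–24%,
utilisation 65–95%), which are ≥3 SD from the means and so negligibly
distort the marginals.

**Submaximal test**: 4-min stages from 7 km·h⁻¹ at 3.5° (female) or
8 km·h⁻¹ at 4.5° (male), +2 km·h⁻¹ per stage. Stage V̇O₂ solves the fixed
point between the athlete's GE (oxygen cost) and an RER that rises linearly
from 0.85 at 50% to 1.05 at 100% of V̇O₂max. Lactate lies exactly on the
athlete's exponential curve, anchored at 4 mmol·L⁻¹ at the athlete's
fractional utilisation and 1 mmol·L⁻¹ at 55% V̇O₂max. HR, RPE and V̇E follow
simple intensity ramps sufficient to drive the four-criterion stop rule
(RER > 1.0, V̇E/V̇O₂ > 30, HR ≥ 90% HR_max, RPE ≥ 16); a stage demanding
more than V̇O₂max becomes a final, capped, non-steady-state stage. A minimum
of three stages is enforced (the lactate model needs three points) and a
maximum of six.

**Time trial**: the finish time solves the energy balance
distance·demand/GE = ∫MR_ae + AOD/0.047801, with V̇O₂ rising
mono-exponentially (τ = 25 s) from 40% of V̇O₂max — the athlete arrives
warmed up from the re-warm-up with race-pace efforts — to 100%. With mean
female traits this yields ≈191 s for 900 m at 3.5° and with mean male traits
≈194 s for 1000 m at 4.5°, inside the published 190 ± 13 / 198 ± 12 ranges
without any fitting to TT time. The recorded series holds exact 10-s
interval means of the trajectory, so with zero noise the analysis pipeline's
time-weighted mean recovers the generating aerobic energy exactly and every
laboratory-derived quantity closes on its latent value — the key
validation property separating estimation error from biology.

**Noise defaults**: V̇O₂ measurement σ = 1.5 mL·kg⁻¹·min⁻¹, lactate σ = 0.2
mmol·L⁻¹, RER σ = 0.01, and a 10% day-to-day CV on anaerobic capacity (the
field reports high AOD variability but no usable within-athlete variance, so
this value is a judgement call and is flagged as unvalidated).

## What the generator does not emulate

Real breath-by-breath noise structure (drift, outlier breaths), pacing
dynamics and lap-by-lap terrain, rifle carriage, day-to-day aerobic
variation, and any skewness or censoring in the trait distributions — the
latents are Gaussian. Passing recovery tests therefore demonstrates that the
analysis chain is unbiased and well-calibrated under the stated model, not
that it is robust to every artefact of real gas-exchange data.

## Numerical choices and edge cases

Energy-balance root finding uses Brent's method on [0, 3600] s with 1e-10
absolute tolerance; an unreachable balance (supply cannot cover demand, or
anaerobic capacity alone exceeds demand) raises. Reference-stage ties break
late; RER exactly 1.00 is eligible. The t-test returns p = 1 for identical
constant groups and raises for unequal constant groups. Blockwise increments
are clipped at zero against floating dust (nested R² is mathematically
non-decreasing) and a rank check names the offending predictor on collinear
designs. Report formatting follows field convention: one decimal for
physiological means, two for r and effect sizes, three for p.

## Problem sizes

Default analyses use n = 14 per sex, matching the emulated study design.
Calibration tests use cohorts of 2000–5000 athletes to pin the generator's
marginals within ~2 standard errors; repeated-cohort properties (correlation
and R² spread, type-I error, qualitative significance patterns) use 30–200
seeds at the study's n = 14, and 2000 replicates for the t-test null — sizes
chosen so sampling error is small relative to the asserted tolerances.
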