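# Methods

## Kinetic model

Protein pools are modeled with zero-order synthesis and first-order
degradation.  For a protein with amount `A(t)` in a culture growing
exponentially at `K_dil` (day⁻¹),

    dA/dt      = K_s(t) − K_d(t)·A
    dL/dt      = −K_d(t)·L

where `L` is the unlabeled (light) sub-pool: after the transfer to the
heavy-nitrogen medium no light protein is made, so the light pool only
decays.  The measurable quantities are `RIA = (A − L)/A` and the abundance
fold change `FCP(t) = A(t)/A(0)`.  In balanced growth
(`K_s = (K_d + K_dil)·A`), `L/A = e^{−(K_d + K_dil)(t − t_label)}`, which
gives the working equations: `−ln(1 − RIA)` is linear in time with slope
`K_loss = K_d + K_dil`, and `FCP = e^{K_dil t}`.  Out of balance, the product
`FCP·(1 − RIA) = L(t)/A(0)` still decays with `K_d` alone, which is why
the transition-phase estimator regresses `−ln(FCP(t)·(1−RIA(t)))` on time;
this identity holds for arbitrary time-varying synthesis as long as `K_d`
is constant over the fitted window, and the fitted slope is a window
average of `K_d(t)` otherwise.

Both incorporation regressions keep a free intercept.  Labeling starts 8 h
before the nominal experiment start, so `RIA(0) > 0` and a
through-the-origin fit would bias slopes upward; with the intercept the
estimate is exact on balanced-growth data regardless of the pre-labeling
chase length.

Replicate slopes are combined by arithmetic mean, and the replicate
relative standard error (RSTDE, 100·sd/|mean| with the n−1 sd) is computed
on the same slopes, so the QC statistic and the combined estimate refer to
the same quantity.  `1 − RIA` is floored at 1e−6 before logarithms and the
affected points are flagged; fully saturated series therefore produce
finite but flagged fits rather than failures.

## Isotope envelopes and RIA estimation

Envelopes are modeled at nominal (unit) mass resolution: per element the
isotope-offset distribution (binomial for C/H/N, trinomial for O/S) is
convolved across atoms, and elements are convolved together, truncating at
`N_atoms + 6` channels and renormalizing.  Natural abundances are ¹³C
0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038/¹⁸O 0.00205, ³³S 0.0075/³⁴S
0.0421, overridable per call.  Elemental compositions come from the
standard residue formulas plus one water (via pyteomics).

RIA is defined operationally as the heavy-population mixture weight: the
observed envelope is fit by non-negative least squares as
`w_L·(natural envelope) + w_H·(envelope with ¹⁵N at enrichment p)` for each
`p` on a grid (default 0.90–0.999, step 0.001; the simulator's medium
enrichment defaults to 0.98), the best-residual `p` wins with ties broken
toward lower enrichment, and `RIA = w_H/(w_L + w_H)`.  The mixture reading
was chosen over peak-partitioning heuristics because it is exact on the
generative model and degrades gracefully under channel noise; on noise-free
mixtures it inverts the forward model to < 1e−6 and it is monotone in the
true heavy fraction.

## What the simulator emulates — and what it does not

The generator reproduces the statistical structure the estimators assume:
exponential culture growth with log-normal weight noise; an 8 h
pre-labeling chase; per-protein piecewise-constant `K_d(t)` and specific
synthesis rate `σ(t)` (so `K_s = σ·A_0·e^{K_dil(t−t_label)}` tracks culture
growth and `σ = K_d + K_dil` is balanced growth); treatment excursions over
the 0–16 h window (synthesis burst + stabilization, or degradation increase
+ synthesis drop); mean-one multiplicative log-normal noise (CV parameter,
default 10%) applied to the light/heavy channel sums of RIA measurements
and to AUC values; Bernoulli missingness per measurement; technical
duplicate injections; and transcript pulse profiles whose baselines track
protein abundance with scatter sized for a cross-gene log–log R² near 0.4
in the growth state.  Trajectories are integrated piecewise-analytically
(each segment has a closed form), which the tests cross-check against an
independent fine-step RK4 integrator.

Defaults reflect the emulated study design: sampling grids
{−8, 0, 1, 2, 4, 16, 28, 40, 64, 88} h (growth), {0, 2, 4, 6, 8, 16, 24,
32, 48, 72, 96} h (treatment), {0, 1, 3, 16, 17, 19, 32} h (abundance);
3 biological replicates × 2 technical injections; ground-truth `K_d` drawn
log-uniform over 0.01–1.5 day⁻¹ to span the slow/intermediate/fast classes;
`K_dil` = 0.25 day⁻¹.

Not emulated: chromatography and ionization physics, charge states,
interference/co-elution, retention-time drift, heteroscedastic or
correlated noise across channels, incomplete precursor-pool enrichment
dynamics (the medium enrichment is a fixed constant), and biological
replicate-to-replicate kinetic variation.  Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to every artifact of real LC–MS data.

## Analysis defaults and numerical choices

* Internal time unit is days (rates in day⁻¹); all interfaces take hours
  and convert by /24.  Output tables round rates to 3 decimals.
* Coverage: peptides need RIA at ≥ 5 time points in one replicate (steady
  state) or ≥ 4 (transition); protein RIA is the median over surviving
  proteotypic peptides, and the same coverage rule is applied to the
  aggregated protein series.
* QC: RSTDE ≤ 40%, median R² ≥ 0.5, ≥ 2 replicates; steady-state
  conditions additionally require a positive mean `K_loss`, while negative
  transition-phase `K_d` is legitimate (a stabilized pool).
* `K_s/A` is evaluated at t = 2 days (configurable) and is undefined at
  `K_d = 0` — callers get an explicit rejection, not a limit value.
* The FCP quadratic is fitted in hours on the median fold changes at
  {0, 1, 3, 16} h; the responsiveness gate (any of the 1, 3, 16 h medians
  > 1.5 or < 0.75) is evaluated on the measured medians, not on the model
  extremum, since the evaluation time is genuinely ambiguous; both the gate
  band and the evaluation are configurable.  The same modeled FCP is shared
  across biological replicates.
* Transition `K_s` values are the general synthesis formula evaluated at
  {2, 4, 6, 8, 16} h with the shared FCP model and the combined `K_d`.
* Abundance: technical injections are averaged on the log₂ scale within
  biological replicates before statistics; Student's t is equal-variance;
  the permutation-FDR test uses `d = Δmean/(pooled SE + S0)` with S0 = 0.1,
  1000 label permutations (exhaustive when fewer exist), and declares
  features significant above the smallest |d| cutoff whose estimated FDR
  (median permutation exceedances over observed exceedances) is ≤ 0.05.
  The estimator is deliberately the plain median-exceedance form without a
  π₀ correction; it is conservative, and at 3 replicates per group its
  power for 3-SD shifts is modest — group sizes of about six measurements
  are needed for high power at FDR 0.05.
* Protein:transcript ratios: log₁₀ → Z-score across the time series → +5 →
  protein/transcript.  The +5 shift keeps both transformed series positive
  so ratios stay sign-stable; the transform order is fixed but the shift is
  a parameter.
* Clustering: Euclidean distance, average linkage, cut at k = 2 by
  default; rows with missing values are dropped and labeled −1.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
recovery checks use 100 proteins on the study grids, FDR calibration uses
1000 features × 3 replicates × 1000 permutations, and the exhaustive
isotopologue oracle is applied to ≤ 3-residue compositions where
enumeration is exact and cheap.  The analysis scripts default to a 40
protein panel, which keeps a full virtual study under a few seconds.

## Known limitations

* The transition-phase estimator assumes a constant `K_d` over the fitted
  window; genuinely time-varying degradation is reported as a window
  average.
* The quadratic FCP model is an interpolation device; extrapolating it
  beyond 16 h is unsupported.
* Fixed medium enrichment: if the real precursor pool equilibrates slowly,
  early-time RIA is underestimated and `K_loss` slopes inherit a small
  bias that the free intercept only partly absorbs.
* The permutation-FDR cutoff is data-dependent; with very few features or
  replicates the permutation space is too coarse for a 5% FDR and the
  procedure returns no significant features rather than an anti-conservative
  cutoff.
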