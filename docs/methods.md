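# Methods

`cellwalk` implements the quantitative core of a live-cell study of how
glucocorticoid treatment inhibits epithelial cell migration: single-cell
walk statistics modelled with the α-stable family, fluorescence
cross-correlation spectroscopy (FCCS) quantification of a
receptor–enzyme interaction, microtubule growth-speed tertile analysis,
and a rank-sum scan for the earliest time a treatment effect appears.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Track kinematics

A trajectory is a cell's time-ordered planar positions (µm, minutes).
Step length between consecutive acquisitions is the Euclidean distance
`c = sqrt(a² + b²)` on the x/y increments. Two displacement notions are
kept separate because the field's figure legends use "total
displacement" for the *path length*:

* `total_displacement` — the sum of step lengths (overall distance
  moved);
* `net_displacement` — straight-line start→end distance, used for rose
  plots.

The triangle inequality guarantees `total ≥ net`; this is enforced as a
test invariant, not an assumption. Tracks are filtered by mean speed
(path length over tracked duration) with a *strict* threshold, 2.5
µm/min by default, mirroring the "above 2.5 µm/min" convention used to
discard stationary debris; the boundary value is rejected. A 25 µm
object-size filter common in tracking software is recorded in the
filter config for provenance but never applied — no images pass through
this package. Missing frames inside a track are allowed: the step is
computed across the gap and speeds are normalised by the actual elapsed
time. Cumulative-distance matrices index by frame count from each
track's start on a shared frame interval; ragged lengths encode tracks
that end early.

## α-stable step-length model

Pooled step lengths are fitted with the four-parameter stable family
S(α, β, γ, δ): stability exponent α ∈ (0, 2] (α = 2 is Gaussian, α = 1
Cauchy; smaller α means heavier tails and more rare long "searching"
relocations), skewness β ∈ [−1, 1], scale γ > 0 (µm), location δ (µm).
Internally parameters are stored in Nolan's continuous S0 form; results
report both S0 and the classical S1 location with an explicit tag,
because toolboxes differ and the two δ values differ by
`β·γ·tan(πα/2)`.

Density and distribution functions are evaluated through
`scipy.stats.levy_stable` (numerical inversion of the characteristic
function, exact at the Gaussian/Cauchy limits). Tests cross-check the
density against an independent direct quadrature of the
characteristic-function integral.

**Estimator.** A quantile initialisation (median location; IQR/1.654
scale) standardises the sample, after which the parameters are obtained
by regression on the empirical characteristic function (ECF)
φ̂(t) = mean(exp(itx)):

1. `log(−log|φ̂(t)|²)` is linear in `log t` with slope α and intercept
   `log(2γ^α)`; an ordinary least-squares fit on frequencies
   `t_k = πk/25` gives α̂ and a scale correction.
2. The ECF phase is linear in `t` and `sign(t)|t|^α`, with coefficients
   δ and `β·tan(πα/2)`; a second regression on `t_l = πl/50` gives β̂
   and a location correction.

The sample is re-standardised and the two regressions repeated (at most
six rounds, stopping when the incremental corrections fall below 1e-4).
The number of modulus frequencies grows as tails get heavier
(`K ≈ 9 + 28(1.9 − α̂)`, clipped to [9, 40]), since heavy tails
concentrate |φ| information at low frequencies; the phase regression
uses half as many points. Near α = 2 skewness is unidentifiable
(`tan(πα/2) → 0`) and β̂ is set to 0. Estimates are clipped to the
valid ranges. A full-table quantile estimator was deliberately not
embedded: the regression re-estimates α every round, so the
initialisation only needs to be consistent, not efficient. A local
maximum-likelihood polish (Nelder–Mead on the S1 density) is available
behind `fit(refine_mle=True)` but is not the default — at n = 15,000 it
is orders of magnitude slower for a negligible accuracy gain (the ECF
estimator's mean α bias is below 0.01 at that size).

**Support mismatch.** Step lengths are non-negative but the stable
family lives on ℝ. Following the upstream analysis convention, the fit
is applied to the raw sample with no truncation correction; the fitted
CDF mass below zero is reported as a diagnostic
(`StableStepResults.mass_below_zero`). For realistic walk parameters
this mass is a few percent and biases the fit only slightly (the
round-trip test budgets for it).

**Resampling protocol.** Parameter uncertainty follows the study's
protocol: resample with replacement into subsets (default 100 subsets
of 15,000 values), refit each, report per-parameter mean ± sd. One
documented generator seed controls the resampling. Bootstrap sds shrink
roughly as subset_size^(−1/2), which is asserted as a monotonicity
test.

**Empirical PDFs** for overlay plots use Freedman–Diaconis bins by
default (the bin rule is configurable; none is canonical upstream),
normalised to unit area.

## FCCS binding analysis

The correlation model is the standard 3-D diffusion form with a fixed
structural parameter S = 4 (axial/lateral ratio of the confocal
volume) and up to two diffusing components, optionally multiplied by a
triplet-relaxation factor:

    G(τ) = [1 + T/(1−T)·e^(−τ/τ_T)] · (1/N) ·
           Σ_i f_i (1 + τ/τ_Di)^(−1) (1 + τ/(S²τ_Di))^(−1/2)

Autocorrelation curves are fitted with two components plus triplet;
cross-correlation curves with one component (the complex is a single
species) and no triplet. Fitting is bounded least squares restarted
from a fixed 5×5 logarithmic grid of diffusion-time pairs over
[1e-5, 1] s (5 starts for one component), keeping the best solution, so
results are reproducible without a stochastic optimiser. Weights are
inverse-variance when per-run replicate curves are available, uniform
otherwise. A curve with no measurable amplitude raises a fit error
rather than returning an unbounded N.

The amplitude used downstream, `G0 = 1/N`, is the *triplet-corrected*
zero-lag diffusion amplitude — the quantity whose inverse is mean
occupancy — not the raw model value at τ = 0 (which would be
1/(N(1−T))). Taking G0 from the fitted model rather than the first
measured lag suppresses afterpulsing artifacts; a first-lag option
exists behind a flag.

Concentrations follow from the effective confocal volume V_eff =
0.57 fL (an instrument calibration constant): `[total] =
1/(G0·N_A·V_eff)` per channel and `[complex] =
Gx0/(Gg0·Gr0·N_A·V_eff)`. The complex is capped at the smaller total
(with a logged warning) and a cross amplitude exceeding the smaller
autocorrelation amplitude by more than 5% is rejected as unphysical.

**Relative cross-correlation.** RCC = 100·Gx0/Gg0 (%). From the
amplitude relations, Gx0/Gg0 = [complex]/[red]_total — the fraction of
the red-labelled species (the receptor) in complex, which is the bound
fraction the measurement reports. Whether the upstream convention
normalised by the green or red channel cannot be pinned down; the
reference channel is switchable (`reference="red"`). Values are clipped
to [0, 100] with a warning.

**Quality control.** Measurements fail QC iff counts-per-molecule are
below 1 kHz or photobleaching exceeds 10% in either channel; both
rules are strict, so boundary values pass.

**Kd fit.** QC-passing points whose total green or total red
concentration lies more than 3 sd from the sample mean are excluded in
a single pass (no iterative re-exclusion — iteration is not part of the
stated rule). Note a small-sample caveat: the largest achievable
z-score in a sample of n points is (n−1)/√n, so the rule can only ever
flag anything for n ≥ 11; it is intended for cohorts of ≥30 cells. The
bound fraction y = [complex]/[green]_total is then regressed on the
unbound bait x = [red]_total − [complex] through the single-site
isotherm y = x/(K_d + x) by bounded least squares (K_d ≥ 0). The
confidence interval is t-based from the least-squares covariance,
truncated at zero; a profile-likelihood (F-test) interval is available
for asymmetric fits. Two fits are compared by the highest level of a
CI ladder (0.95, 0.99, 0.999, 0.9999) at which their intervals are
disjoint, reported as a significance grade or "n.s.".

## Group statistics

**Tertile analysis.** The reference condition's growth-speed events are
split at their 1/3 and 2/3 empirical quantiles (inclusive linear
interpolation, the default quantile definition in numpy; alternatives
would shift edges by at most one order statistic). Bins are
left-open/right-closed with ties assigned downward. The same edges are
applied to every other condition, so per-bin counts and medians are
directly comparable; reference bins are balanced to within one event by
construction (exact ties can break this, which the validation flags).

**Rank-sum scan.** At each shared time point the cumulative distances
of treated and vehicle cells still tracked at that point are compared
with a two-sided Mann–Whitney/Wilcoxon test — exact when both arms have
≤50 cells and no ties, the tie-corrected normal approximation otherwise
(cohorts of ~1000 cells make the exact distribution pointless, small
synthetic tests benefit from exactness). The earliest significant time
is the first point with p < α (default 0.0001) *and* treated median
below vehicle median; the directionality requirement can be switched
off. **No multiple-testing correction is applied across the scan** —
the procedure is a per-time-point threshold scan by design, which is
why the default α is four orders of magnitude below 0.05. Cells whose
tracks end early are dropped from later time points only.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
validated. All are bit-reproducible: one run seed, with per-cell
substreams derived as `default_rng([seed, stream, cell])` so results do
not depend on iteration order.

* **Stable sampler** — Chambers–Mallows–Stuck construction, S1 form,
  shifted to the requested S0 parameters. Tests check it against
  scipy's independent stable quantiles and the Gaussian limit.
* **Lévy-walk cohorts** — per frame, a step length drawn from the
  condition's stable law rejection-resampled to ≥0 and an isotropic
  heading. Rejection (rather than truncating the fitted law) keeps the
  pooled sample i.i.d.; it deliberately mismatches the fit's ℝ support,
  which is why round-trip tolerances are looser than raw estimator
  accuracy. A law with more than 50% negative mass is refused. Default
  vehicle parameters (α=1.5, β=0.5, γ=0.8, δ=2.6 µm per 10-min frame)
  give a median step of ~2.6 µm, matching the printed control medians
  for brightfield tracking; the treated default (α=1.6, γ=0.6, δ=2.4)
  suppresses the long-step tail and shifts the distribution left, the
  reported treatment signature. Treated conditions can switch
  parameters at a configurable frame to emulate dosing mid-experiment.
* **FCCS experiments** — totals drawn uniformly from expression ranges
  (green 20–80 nM, red 10–400 nM), complex set by the exact isotherm
  root `c = [(g+r+K_d) − sqrt((g+r+K_d)² − 4gr)]/2`, amplitudes by
  inverting the concentration relations, and curves synthesised from
  the correlation model with multiplicative Gaussian noise of
  lag-independent sd (default 2%) — not a photophysical photon-noise
  model. The lag grid defaults to 160 log-spaced points over 1 µs–1 s,
  the ~8-points-per-octave density of multi-tau correlators; much
  sparser grids leave N partially degenerate with the triplet fraction
  under noise. Positive control (tandem fusion) forces complex =
  totals; negative control (independent species) forces complex = 0
  with residual baseline fluctuations. QC failures (low CPM or high
  bleaching) are injected at a configurable rate.
* **Growth speeds** — log-normal events (median 17.2 µm/min, log-sd
  0.45, matching the printed comet-speed medians), with treated events
  above the reference's upper-tertile edge multiplied by a shift factor
  (default 1.05 ≈ the printed fast-bin median ratio 27.6/26.2).

**What passing tests show — and do not.** The generators reproduce the
*statistical structure* the analyses assume: heavy-tailed i.i.d. steps,
isotherm-consistent binding tables, ideal-form correlation curves with
homoscedastic noise, log-normal speed events. Real imaging data adds
segmentation/tracking errors, temporally correlated steps, photophysics
(blinking, bleaching within a run), detector afterpulsing and
cross-talk, and cell-to-cell heterogeneity — none of which are
emulated. Passing tests therefore validate the estimators and the
pipeline plumbing under the stated models, not robustness to every
imaging artifact.

## Problem sizes and numerical choices

Validation runs use the protocol sizes where stated (15,000-value
subsets; 9,149/9,669 growth events; ~30-cell FCCS cohorts; 100
cells/arm for scan detection) and 20 replicates where a count of
successes is reported, with the resampling protocol's 100 subsets
scaled to 20 for replicated recovery studies. Tolerances frozen in
tests (α bias ±0.03 at n=15,000; γ within 5%; N within 1%/5%
noise-free/noisy; CI coverage ≥17/20) were verified by pilot simulation
before being fixed. Other numerics: ECF regression stops at 1e-4
incremental corrections; curve fits use xtol=ftol=gtol=1e-12; the KS
diagnostic interpolates the fitted CDF on a 257-point tan-spaced grid
(dense in the body, sparse in the flat tails); stable PDF evaluation
inherits scipy's piecewise quadrature with its default tolerances.

## Known limitations

* The stable fit ignores the non-negativity of step lengths (by
  design, to mirror the upstream procedure); for laws with substantial
  negative mass the reported diagnostic should be consulted.
* The Kd confidence interval is symmetric (t-based); for small, noisy
  cohorts the profile interval is more faithful.
* Cross-talk, background and afterpulsing corrections are out of
  scope; amplitudes are assumed pre-corrected.
* The scan's earliest significant time is a threshold crossing, not a
  change-point estimate: with strong effects it lags the true onset by
  however long the cumulative-distance distributions need to separate,
  and it inherits the no-multiplicity-correction semantics.
* 3-D tracks, pixel-level processing, and comet detection/linking are
  not handled; inputs are assumed to be already-tracked tables.
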