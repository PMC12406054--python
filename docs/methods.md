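# Methods

`gazedcm` implements a complete effective-connectivity analysis of scene
encoding under free vs. fixed viewing: a three-region bilinear dynamic
causal model (DCM), subject-level Bayesian inversion, hierarchical group
inference over a predefined modulatory model space, behavioral measures of
memory strength and gaze reinstatement, and a canonical variate analysis
(CVA) linking the two.  Because the underlying fMRI data are not public,
every stage is exercised on synthetic data with planted ground truth; the
validation studies in `gazedcm.studies` measure what the pipeline can and
cannot recover at desk scale.

## Generative model

Neuronal states of the occipital pole (OCP), parahippocampal place area
(PPA) and hippocampus (HPC) follow the bilinear state equation

    dz/dt = (A + Σ_j u_j B_j) z + C u

with one driving input (all encoding trials, mean-centered so that `A` is
the *average* coupling across conditions) and one modulatory input (the
free-viewing trials, uncentered).  Between-region entries are rates in Hz
and combine additively.  Self-connections live on a unitless log scale:
the effective diagonal is `-0.5 exp(a + Σ u_j b_j)`, so modulation enters
*inside* the exponent and a negative self-modulation is disinhibitory
(greater sensitivity to input).  The full design couples OCP↔PPA and
PPA↔HPC reciprocally, modulates the same seven entries (3 self + 4
between), and drives only the OCP.

Two conventions deserve note because they are invisible in most write-ups
but necessary for the model to behave:

- **Exogenous input scaling.** The integrator applies the driving term as
  `C u / 16`, the convention under which published C values of order
  0.1–1 produce small neuronal excursions.  Without it, a mean-centered
  driving input implies a sustained negative baseline drive
  (≈ −0.55 × 0.638 Hz) under which the blood-flow equation has no fixed
  point and flow collapses within seconds.  The exposed
  `neuronal_derivative` operation keeps the plain equation
  `dz/dt = Jz + Cu` (instantaneous rate per unit input); the scaling is a
  property of the integrated cascade.
- **Log-space hemodynamics.** Per region, the balloon–windkessel cascade
  (vasodilatory signal, inflow f, venous volume v, deoxyhemoglobin q) is
  integrated in (s, log f, log v, log q), which keeps f, v, q positive
  under negative drive.  Constants are the canonical published values
  (κ=0.64 s⁻¹, γ=0.32 s⁻¹, τ=2 s, α=0.32, E₀=0.4, V₀=4%); only the
  transit time, signal decay, and a BOLD gain ε are free, as per-region
  log-scalings with tight priors.  BOLD is reported in percent signal
  change: `100 V₀ ε (k₁(1−q) + k₂(1−q/v) + k₃(1−v))` with k₁=7E₀, k₂=2,
  k₃=2E₀−0.2.

Integration is fixed-step 4th-order Runge–Kutta at dt = TR/16 (TR = 2 s),
inputs piecewise-constant per microtime bin; states reset to baseline at
run boundaries and runs are concatenated within condition.  Halving dt
changes sampled BOLD by < 1e-3 % signal on grid-aligned designs.  The
inner loop is numba-compiled; a pure-NumPy implementation of the
hemodynamic cascade (`hemodynamic_bold`) is kept for oracle checks against
`scipy.integrate.solve_ivp`.

## Subject-level inversion (variational Laplace)

The observation model is `y = g(θ) + X₀β + ε` with per-run intercept and
linear-drift confounds X₀ (projected out of data and prediction) and
Gaussian noise with one free log-precision λ_r per region.  The Laplace
free energy F = accuracy − complexity is maximized by Gauss–Newton steps
on θ (finite-difference Jacobian, central differences with step 1e-4 by
default, forward differences selectable) with step-halving (≤16) so
accepted steps never decrease F, alternating with Newton/EM updates of λ.
Convergence: ΔF < 0.01 nats on 4 consecutive iterations, cap 128.  The
posterior covariance is the inverse curvature at the optimum; F is the
evidence bound used for all model comparison.

Numerical choices that differ from naive defaults, and why:

- **Data normalization.** The confound-projected series is scaled to unit
  pooled sd (prediction scaled identically — a pure change of units), so
  the noise-precision hyperprior N(0, 16) is centered on the data's own
  scale.  λ is additionally bounded to ±8 so exactly-zero-residual
  (noise-free, zero-signal) fits stay finite.
- **Prior variances.** Connectivity entries (A, B, C, raw scale) get
  variance 1; hemodynamic log-scalings 1/256; disabled entries exactly 0.
  Tighter connectivity priors (e.g. 1/16) were evaluated and rejected: the
  group effects this analysis is designed to detect include magnitudes up
  to |−2.44|, which such priors place 10 prior sd from zero; at realistic
  noise the posterior then settles in shrunken trade-off configurations
  with wrong-signed self-modulations.
- **Degenerate trajectories** (exploratory parameters that blow up the
  cascade) are detected inside the integrator and treated as rejected
  step candidates rather than errors.

## Group level: PEB, BMR, families, BMA

PEB models the subject parameters as `θ_s ~ N(X_s β, Σ_b)` with
`Σ_b = e^γ · (1/16) I` and a scalar log-scale γ (prior N(0, 4); β prior
N(0, 1)).  Crucially, subjects enter through their implicit *likelihoods*
— posterior precision minus prior precision, in information form,
projected to the PSD cone — not their raw posteriors; pooling posteriors
would count the shared shrinkage prior once per subject and bias group
means toward zero.  β is updated in closed form given γ; γ by a line
search on the free energy.

Bayesian Model Reduction computes, in closed form, the posterior and
evidence change of any model whose prior only shrinks variances (pruned
entries: mean 0, variance 1e-8), via the Gaussian identity
`ΔF = log ∫ q(θ) p_reduced(θ)/p_full(θ) dθ`.  On conjugate linear models
this matches the analytic evidence difference to 1e-6; on the nonlinear
DCM it tracks explicit re-inversion to a fraction of a nat for mild
(single-parameter) reductions — the regime in which the greedy automatic
search operates — and degrades for reductions that remove strongly
supported parameters, as expected for a local-Gaussian approximation.

The modulatory space enumerates all 2⁷ = 128 on/off patterns of the seven
modulated entries and partitions them into families by which directional
sets they engage (bottom-up = {OCP→PPA, PPA→HPC}, top-down = {PPA→OCP,
HPC→PPA}, self): null, BU, TD, BIDIR, SELF, BU+SELF, TD+SELF, BIDIR+SELF,
with sizes 1/3/3/9/7/21/21/63.  Family inference gives each family equal
prior mass (1/8, uniform within family; the null model is its own
singleton family) so it is not biased by family size.  BMA averages the
winning family's reduced posteriors with evidence weights; a parameter's
Pp is the summed posterior model probability of members in which it is
switched on.  For the endogenous (A) and driving (C) parameters, the
automatic search greedily prunes single parameters while evidence
improves and reports the BMA over all models visited.  Subject-level
estimates are finally re-derived with the group posterior as empirical
prior (Gaussian conjugate update), shrinking them toward the group means.

## Behavioral measures

Recognition responses for previously viewed images score 2 / 1 / 0 / −1
(high-confidence hit / low-confidence hit / low-confidence miss /
high-confidence miss); lures are not scoreable.  Gaze maps are sums of
isotropic Gaussian bumps at fixation locations weighted by duration, on a
1-px grid, smoothing σ defaulting to 63 px (≈1° of visual angle at the
study geometry of 500 px ≈ 7.95°).  Smoothing uses mirrored boundaries:
with zero-padding the shared soft-edge profile correlates any two maps
positively (null mean ≈ +0.15 Fisher-z); with mirroring the expected map
is flat for spatially uniform scanpaths and the null is centered (|mean|
< 0.01).  Similarity is the Fisher-z Pearson correlation of flattened
maps, clipped at |r| = 0.999 so identical maps stay finite; maps are not
renormalized (Pearson correlation is scale-invariant).  The control score
is the mean similarity to 50 randomly drawn (seeded, without replacement)
encoding maps of the same subject and condition, excluding the matched
image; reinstatement is matched minus control.  Per subject, both
measures aggregate to free-minus-fixed means, then mean-center across
subjects.

## Association statistics

CVA standardizes the X block (connectivity), centers Y (behavior), and
takes the SVD of the cross-covariance whitened by the within-set
covariances.  Loadings are correlations of the original variables with
the canonical variates; shared variance of function i is 100 r_i².  Two
significance routes are reported: Bartlett's χ² on Wilks' Λ and a seeded
permutation test (≥1999 permutations of Y's rows); the permutation p is
authoritative at the study's N — Bartlett is asymptotic.  Its type-I rate
under the null is 5% ± 2% (400 replicates, N=36).  Per-connection
scene-vs-scrambled contrasts are paired t tests with Benjamini–Hochberg
adjustment over the seven connections, plus the Greenhouse–Geisser-
corrected image-type × connection repeated-measures omnibus (via
pingouin).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's schedule exactly (runs of 500 s task
window + 10 s lead-in + 12.4 s tail; 72 images/run, 36 free + 36 fixed in
seeded pseudo-random order; 4 s images; inter-trial fixation crosses
uniform on 1.72–4.16 s; TR = 2 s; 6 scene + 2 scrambled runs at full
scale).  Group connectivity means default to the published scene and
scrambled estimates; subjects deviate by truncated (±2 sd) Gaussian
draws with sd 0.25, redrawn if the neuronal system is not dynamically
stable (spectral abscissa above −0.02 Hz with the modulator off or fully
on) — a constraint real brains satisfy trivially but that truncates the
deviation distribution by a small fraction of the sd.  Observation noise
is a single per-scan sd (default 0.15% signal, the pooled noise-free
signal sd at the group means, i.e. SNR ≈ 1); scanner noise does not adapt
to regional signal, so the HPC — whose evoked signal is ≈4× weaker — is
effectively observed at lower SNR, exactly as in real data.

Fixations: free trials draw Poisson(10) locations per 4-s trial from an
image-specific two-component spatial mixture shared across subjects;
fixed trials place 1–3 fixations within 25 px of the central cross.
Retrieval (always free viewing) replays the encoding scanpath plus
Gaussian jitter (default 20 px) for a per-subject fraction of free-viewed
images and draws fresh scanpaths otherwise.  Memory responses realize
each subject's target mean score binomially with confidence independent
of accuracy.  Both the memory advantage and the replay fraction load on
the standardized mean of the PPA and HPC self-modulations at target
correlations 0.6 and 0.5, so the downstream CVA has a known effect to
find.  Not emulated: image content and saliency, saccade kinematics,
center bias, attention/vigilance drift, physiological noise and motion.
Passing tests therefore show the *pipeline* recovers what it is supposed
to from data obeying the model — not that the model is true of brains.

## What the validation studies show

At the full task's scene data size (6 runs ≈ 1570 scans, 12 subjects,
SNR ≈ 1) the full chain recovers every planted modulatory sign with
BMA Pp ≥ 0.999 and close magnitudes.  The acceptance-scale studies run at
a deliberately reduced 200 scans per subject, where two information
limits appear honestly: pooled planted-vs-recovered correlation for the
between-region endogenous couplings is ≈0.79–0.89 across seeds (the
HPC-related couplings carry little information at this scan count), and
the PPA self-modulation is unidentifiable (its free-trial gain is
absorbed by the OCP→PPA and HPC→PPA modulations), so its BMA Pp stays
near 0.4 regardless of seed.  Family-wise inference is robust at the same
scale: the generating BIDIR+SELF family wins in 9/10 seeded cohorts.  The
problem sizes used by the tests and the acceptance script (cohorts of 12,
200 scans, 200 Monte-Carlo images, 400 permutation-calibration
replicates) are the package's chosen desk-scale study conditions.

## Known limitations

- Laplace/GN inversion finds a local optimum from the prior mean; no
  multistart.
- BMR accuracy degrades for strong (multi-parameter, well-supported)
  reductions; the automatic search's single-parameter steps stay in its
  accurate regime.
- The PEB between-subject covariance is a single scaled identity; no
  per-parameter variance components.
- Permutation p-values for canonical functions beyond the first compare
  same-index correlations, a practical (slightly conservative) choice.
- No slice-timing, motion, or physiological-noise modelling: the package
  consumes ROI time series, not images.
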