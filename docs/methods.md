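# Methods

This package reconstructs latent directed network structures from
trial-segmented multichannel neural recordings.  The chain is: gaze-based
trial screening → artifact-trial rejection → ICA source separation →
sliding-window multitrial VAR → spectral causality (dDTF) → event-related
causality (ERC) → ternary significant-difference maps (ΔERC) → a 3-way
tensor pooled over comparisons, time-frequency and connections →
constrained PARAFAC → graph statistics and shuffle-based inference.
A synthetic-data generator with planted directed couplings provides ground
truth for every stage.

## Task model and trial screening

Trials follow a Waiting (2.5 s) → Context (1.5 s) → Response (3 s) timeline.
A trial is classed C+ when the eye position stays within the screen area for
strictly more than 80% of the samples in the first 0.5 s of the Context
period; everything else (including eyes-closed and out-of-range samples) is
C−.  The strict inequality matters at the boundary: an exact 80% fraction is
C−.

## Artifact rejection

A trial is rejected when any channel's band-averaged log Welch power
(bands 1–4, 4–8, 8–30, 30–80, 80–120 Hz) lies more than 4 robust z-units
(median/MAD) above the cross-trial median.  This is a deliberately simple,
fully documented stand-in for toolbox-specific spectral rejection
heuristics: it catches broadband bursts at z ≈ 20 while leaving genuine
band-limited condition effects (z ≲ 2 under the generator's amplitude
variability) untouched.

## Source separation

Channels are reduced to m sources, with m the smallest count of covariance
eigenvalues reaching 90% of total variance.  FastICA (fixed-point
negentropy) runs from 20 random initializations; all components are pooled
and clustered by average linkage on 1 − |corr| of their source series, and
each cluster's centrotype is kept with a stability index (mean within-cluster
|corr|).  Signs are fixed so each component's largest-magnitude channel
weight is positive; sources are unit variance.  Component screening removes
kurtosis outliers (default 15 robust z-units) and band-spectrum outliers
(default 20).  The robust z-scores carry absolute scale floors (1.0
kurtosis unit; 0.25 log10 power units) because with few components the
cross-component MAD can collapse to near zero, in which case any genuine
diversity — e.g. a narrowband source among broadband ones — would explode
the z-score and be discarded as an "abnormal spectrum".  Burst-artifact
components still exceed the floored thresholds by an order of magnitude.

## Windowed VAR and dDTF

Signals are locally stationarized per condition ensemble (per-trial linear
detrend, per-trial z-score, pointwise ensemble normalization across trials).
Normalizing per condition rather than per trial type keeps one fixed
normalization under label shuffles; the generator plants no evoked
component, so the distinction carries no signal here.  Exact idempotence of
the three-step recipe is impossible (a second detrend perturbs at
O(1/√T)); the ensemble moments, however, are reproduced exactly.

Windows default to 250 ms length / 50 ms step, converted to samples by
round-half-up (63 and 13 samples at 250 Hz).  The sample-budget rule is
read as "parameters ≤ 10% of scalar samples", i.e. w·n·k ≥ 10·k²·p; both
this and the literal one-line form are reported, with a flag when they
disagree.  The VAR order is chosen by AIC with the standard multivariate
normalization (penalty 2k²p/T over vector observations, all candidate
orders fitted on a common sample); model validation covers residual
whiteness (portmanteau), a simulation-based consistency score (lag-0/1
cross-correlations, pass ≥ 80%), and per-channel KPSS level stationarity.

Per window, DTF, full-frequency DTF, partial coherence and dDTF = ffDTF × χ
are computed from H(f) = (I − Σ A_m e^(−i2πfm/fs))⁻¹ on a 19-bin linear
frequency grid (4–120 Hz by default).  All values are amplitudes in [0, 1];
ffDTF satisfies Σ_sources Σ_f ffDTF² = 1 per sink and window.

Per-trial lagged Gram matrices are precomputed once per window
(`WindowEnsembleStats`), so trial bootstraps and label shuffles refit every
windowed VAR by small weighted solves instead of revisiting the samples.

## ERC and ΔERC

ERC(t, f) = 10·log10(dDTF(t, f) / median over baseline windows of dDTF),
with the baseline = all windows fully inside the Waiting-period interval
(default 0.25–2.25 s).  Nonpositive medians are floored at 1e-12 (silently
for identically-zero cells such as self-connections, with a warning
otherwise).

ΔERC contrasts two trial types per cell (connection × window × frequency):
trials are resampled within each type (multinomial bootstrap, default 200
replicates), the windowed VARs are refitted from the precomputed
statistics, and the ERC difference distribution gives the test.  The
default test converts the observed difference and bootstrap SE into a
two-sided normal-tail p-value; a pure percentile p-value (available as
`method="percentile"`) has floor 2/(n_boot+1) and cannot cross a
Benjamini–Hochberg step-up threshold over thousands of cells at any
feasible bootstrap count.  BH-FDR at α = 0.05 runs across all off-diagonal
cells of one comparison; surviving cells carry the sign of the observed
difference.  The nine ordered pairings (context contrasts under each
response; response contrasts under each context) × two conditions give 18
comparisons.

## Tensor and PARAFAC

ΔERC maps pool into an 18 × (windows·bins) × (Σ_s k_s(k_s−1)) ternary
tensor (condition-major comparison order; window-major time-frequency
order; per-subject connection blocks, (source, sink) row-major).  PARAFAC
is alternating least squares with the comparison mode unconstrained
(absorbing all scale and sign) and nonnegativity on the other two modes,
solved per row by active-set NNLS through a Cholesky reformulation of the
normal equations.  Convergence is a 1e-6 relative change in fit; after
convergence the comparison mode is re-solved exactly against the final
fixed modes, so the reported loadings are the least-squares fixed point.
Initialization is either direct-trilinear (GRAM on two random slab
aggregates) or best-of-100 random orthogonal restarts (short pilot runs,
best iterate refined to full tolerance).

Core consistency (CORCONDIA) scores the least-squares Tucker core implied
by the fitted loadings against the superdiagonal ideal; the rank scan
selects the largest R whose consistency stays at or above 80% while R+1
falls below (consistency clamped at 0 for the rule), flagging the selection
when no R qualifies.

## Inference

Loading significance: trial-type labels are permuted within each condition,
the whole dDTF → ERC → ΔERC → tensor chain is rebuilt (50 shuffles by
default), and comparison-mode loadings are re-estimated with the other two
modes fixed.  The two-sided rank-based permutation p-value is compared with
α = 0.05; at 50 shuffles the achievable floor is 2/51 ≈ 3.9%, which the
exchangeability calibration test reproduces.  An interpolated-quantile
variant was measured anti-conservative (~9% at nominal 5%) and is not used.

Activation levels solve least squares for six per-trial-type levels per
condition from the significant pairwise differences only; the minimum-norm
solution anchors the involved types at mean zero.  Inter-structure
dependencies are Pearson correlations (n = 6: three comparisons × two
conditions per family) between structures' loading vectors, with two-sided
p-values for the no-correlation null.

## Synthetic generator

Latent sources are damped AR(2) resonators (pole radius exp(−π·bw/fs),
resonance at the band center); per-source innovation SDs equalize the
stationary variances analytically so the 90% variance rule retains all
sources.  Scheduled directed couplings add lag-1 cross-terms during task
intervals for matching trial types; every assembled coefficient set is
stability-checked (companion spectral radius < 1) at build time.  Channels
are a random well-conditioned mixture plus observation noise; a lognormal
per-trial amplitude factor (σ = 0.25) emulates trial-to-trial cortical
power fluctuation without touching the causality structure (dDTF is
scale-invariant); 5% of trials carry a 0.5 s broadband burst at 5× channel
SD; gaze traces realize a target on-screen fraction exactly (to one sample)
inside the screening window.

The default schedule plants five structures: a context-graded β coupling
(s0→s1, 20 Hz, Context; strengths 0.30/0.20/0.10 for Ch/Cm/Cw), an
Rf-only high-γ coupling (s2→s3, 85 Hz, Response), a generalized-context β
coupling for the social contexts (s4→s5, 18 Hz, Context), its Rf-gated
re-activation (s4→s5, Response) and a reversed α coupling (s1→s0, 11 Hz,
Response, C+ ∧ Rf).  All couplings act on C+ trials only.  Coupling
strengths are the one free quantity no study value fixes; they are set so
that planted contrasts are comfortably detectable at desk scale while
staying below the trial-artifact screen.

What the generator does *not* emulate: cortical geometry and volume
conduction, evoked (phase-locked) components, nonstationary oscillatory
bursts, 1/f broadband background, or realistic gaze dynamics.  Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not performance on real electrophysiology.

## Problem sizes in the test suite

The default generator configuration (3 subjects, 12 channels, 120
trials/type, 150 windows × 19 bins) mirrors the study's proportions; the
test suite and acceptance checks run reduced configurations chosen as the
package's own desk-scale defaults: integration tests use 1–2 subjects, 8
channels, 6 sources, ~50–100 trials/type, a 500 ms window step, 10
frequency bins, 100–200 bootstrap replicates and 24–25 shuffles; the FDR
calibration uses 20 replicate null datasets; the rank scan check uses
18×60×80 tensors over 20 seeds.  Statistical conclusions (FDR level,
permutation level, rank selection, structure recovery) are size-stable
properties, not artifacts of these choices.

## Known limitations

* dDTF carries no analytic null; all inference is resampling-based.
* The bootstrap-z ΔERC test assumes an approximately normal difference
  distribution; heavy-tailed deviations would be better served by the
  percentile method at a much larger bootstrap count.
* PARAFAC on ultra-sparse ternary tensors has genuine local-optimum
  structure; the restart scheme mitigates but does not eliminate it, and
  core consistency on such tensors is routinely strongly negative even at
  the planted rank.
* Per-subject PARAFAC refits are not implemented; subjects enter only
  through the pooled tensor's connection blocks.
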