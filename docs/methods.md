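# Methods

## Task structure (`mbdecide.task`)

Each synthetic subject performs three 250-trial blocks: 210 sequential
response trials, 20 one-second reward screens and 20 choice screens. Stimuli
are shown for 3 s plus uniform jitter in 59 ms steps up to ±474 ms, with a
237 ms inter-trial interval; the reward screen is followed by a 2–8 s delay
(truncated exponential, mean 4 s) before the 5 s choice window. The event
clock therefore fits inside one 400-volume scan at TR 2.37 s (~885 s of
events vs 948 s of scan).

**Transition matrices.** Four 4×4 row-stochastic matrices govern the image
stream, each taking effect at the rounded-up quarters of the 750 global
trial positions (trials 188, 376 and 563). Matrices are drawn by sampling
rows from a flat Dirichlet and Sinkhorn-balancing them to doubly stochastic
(rows renormalized last), which forces a uniform stationary distribution so
image frequencies equalize over the medium term; candidates whose
off-diagonal entries span less than 0.25 are rejected so each matrix exposes
a wide range of conditional probabilities. The exact spread floor and the
Dirichlet concentration are configurable; the published design defers its
matrix-generation constraints to earlier work, so this procedure is this
package's own construction satisfying the two stated priorities.

**Choice rounds.** Per session, 20 rounds with lengths drawn from a
truncated exponential on [1, 8] with mean 4, rounded, then repaired by ±1
steps on uniformly chosen rounds until they sum to exactly 80 — preserving
the distribution's shape while meeting the exact total. The rewarded image
and dollar value ($1–$5) are uniform; the two options are drawn without
replacement from the three non-rewarded images. Round start positions are
uniform over the feasible slots given the 30-trial probe-free prefix and a
minimum gap of one plain sequential trial between rounds. After a choice is
entered the next image — the outcome — is drawn from the *chosen* image's
row; the chosen image itself is never displayed.

`assemble_session` accepts a chooser callback so a behavioral model can make
the choices during generation; this keeps the simulated decisions and the
outcome images they trigger on one consistent belief trajectory. The default
chooser picks uniformly.

## Learning model (`mbdecide.learning`)

Both processes start from uniform (0.25) rows — a maximum-entropy prior that
also pins the first-trial prediction at 0.25 for testing. Learning continues
through choice rounds, including the chosen→outcome transition, and the
learner is never told about matrix replacements (no reset). The chain also
continues across the rest breaks between sessions.

Forward entropy is reported in nats (the log base only rescales regressors
and all comparisons are internal). The per-trial forward prediction and its
entropy are taken from the matrix *after* the current trial's update, i.e.
they condition on everything seen up to and including the current image;
the conditional probability of the current image ("surprise") is taken
before its update.

Derivatives of every traced quantity with respect to the transformed rate
x = logit(α) are computed by differentiating the update rule through time:

    D[i,·] ← (1 − α) D[i,·] + α(1 − α) (onehot(j) − T_old[i,·])

with the α(1−α) factor from the chain rule through the logistic map. This
exact recursion is the production path; central finite differences are kept
as the test oracle (agreement to <1e-6 on random 200-trial sequences). The
per-trial recursion is compiled with numba; a full 630-trial trace costs
~25 µs, which is what makes multi-start maximum likelihood and the recovery
suites cheap.

## Behavior (`mbdecide.behavior`)

**Reaction times** are generated (and fit) by a linear model: intercept +
slope × P(observed image) + a stimulus-self-transition effect + per-image
offsets + a linear trial trend, with Gaussian noise. The slope default is
−44 ms per unit probability (0.44 ms per percentage point). The noise SD
default is 15 ms. This value is deliberately below plausible raw
trial-to-trial RT variability: the descriptive Gaussian likelihood used here
understates the structure of real response times, and at realistic noise
(~80–100 ms) the two learning processes are not separable from 630 trials at
this effect size, contradicting the qualitative finding the generator is
meant to emulate (a decisively better two-process fit in every subject). The
default was therefore calibrated once so that both processes are
identifiable per subject and the recovery tolerances of the fitting stage
hold; treat absolute evidence magnitudes from synthetic RTs as
scale-dependent. Error (3%) and miss (1%) trials are flagged and excluded
from likelihoods.

**Choices** inside the synthetic subject are produced online by a single
slow-process learner feeding the sampling rule — the study condition that
choices are explained by one slow rate — while RTs reflect the two-process
combination. The sampling parameter N enters the Gaussian-approximate rule
as a real number (default 4.675); the enumeration oracle requires an integer
and splits ties evenly. Reward magnitude cancels in the sampling rule (both
options target the same goal) and enters only the softmax alternative.

## Fitting (`mbdecide.fitting`)

Rates are optimized in logit space; the two-process model parameterizes the
fast rate as slow-plus-positive-gap, which enforces α_slow < α_fast and
removes label switching. Multi-start L-BFGS (10 random restarts by default;
the heavy recovery suites use 5, which measurement showed gives the same
medians) with regression coefficients and the noise SD profiled out in
closed form for RT models.

Laplace log evidence: ll\* + (d/2) ln 2π − ½ ln det H − ln V, with H the
finite-difference Hessian of the negative log-likelihood over the *natural*
parameters and V the uniform-prior volume — [0,1] for rates and the weight,
±1000 ms for regression coefficients, (0, 500] ms for the noise SD,
(0, 50] for N (bounds recorded in each fit report). If any model's Hessian
for a subject is not positive definite (or not finite), BIC-based scores
(−BIC/2, BIC = −2 ll + d ln n) replace the Laplace values for *all* of that
subject's models, never a mixed comparison. Subjects whose nuisance-only
"constant" RT model beats every candidate by BIC are excluded. The
fixed-effects refit shares the learning parameters and (for RT) pooled
regression coefficients across subjects.

## Synthetic cohort and BOLD (`mbdecide.cohort`)

Cross-subject parameters are Gaussian, truncated to validity: slow rate
0.10 ± 0.05, fast rate 0.507 ± 0.10, slow weight 0.7 ± 0.14, draws
4.675 ± 1.25. The slow-rate center and SD and the draws distribution follow
the reported behavioral fits; the fast-rate center follows the reported
striatal entropy rate; the weight's fitted value is not legible in the
source material, so 0.7 (toward the slow process) is this package's default;
SDs without a reported value default to 20% of the mean.

Synthetic BOLD is ROI-level only: amplitude-scaled, HRF-convolved model
regressors on the TR grid (2.37 s, 400 volumes per scan) plus stationary
AR(1) noise (lag-1 coefficient 0.3, typical at this TR and deliberately
mismatched to the unwhitened OLS default to stress it). The default noise
SD of 0.03 at unit amplitude puts a parametric modulator's single-scan t
near 3 — a well-placed ROI effect; real whole-brain data are far noisier,
which is one reason passing recovery here does not certify voxelwise
performance. No volumetric images, motion, or spatial smoothing are
synthesized.

## GLM and learning-rate read-out (`mbdecide.glm`)

Events are delta functions convolved with the canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6; 16 bins per TR oversampling, via
nilearn). Parametric modulators are mean-centered before convolution so the
onset column absorbs the mean response. Data and design are high-pass
filtered with a discrete-cosine basis (128 s cutoff).

The main-effects design (GLM1) places, on valid sequential onsets, the
modulators RT → conditional probability → forward entropy → ∂entropy/∂x in
serial orthogonalization order (each column orthogonalized, after filtering,
against the earlier columns of its family — so shared variance is credited
to nuisance first); choice onsets carry RT, reward value, difficulty and its
derivative; outcome onsets carry RT, RPE and its derivative; missed, error,
self-transition and right-hand trials get nuisance onset columns. Outcome
trials are modeled in their own onset family and removed from the sequential
family to avoid duplicated onsets. The image-specific design (GLM2) uses
per-category nuisance onsets (which span the sequential presentations, so no
aggregate sequential onset column is added), the four anticipated-next-image
probabilities on sequential onsets and the four per-category difficulties on
choice onsets, with orthogonalization disabled.

The learning rate implied by a timeseries: per subject,
x̂ = β_deriv / k + logit(α₀) with k the group-mean main-effect β (this
normalizer couples subjects' estimates — a property inherited from the
procedure, noted, not "fixed"); the group estimate is sigmoid(mean x̂) with
SEM bounds mapped through the sigmoid, and all tests are run in x space.
α₀ defaults to the midpoint of the transformed slow and fast rates
(logit-space midpoint of 0.10 and 0.50 → α₀ = 0.25), the point that
minimizes worst-case linearization error over the rates of interest.

## What the recovery suites do and do not show

The generator reproduces the task's combinatorial structure, the stated
learning/choice/RT/BOLD generative chain, and parameter scales anchored to
reported values. It does not emulate heavy-tailed RT distributions,
post-error slowing, attentional lapses, learning-rate drift, voxel selection
(the source of the reported selection bias toward α₀ — the attenuation seen
here comes only from linearization and measurement noise), motion artifacts,
or physiological BOLD confounds. Green recovery therefore certifies the
estimators' correctness and calibration under their own assumptions, not
their robustness on raw experimental data.

Problem sizes in the test and acceptance runs — 20 subjects at 630 trials /
60 probes for behavioral recovery, 10 seeds per direction for model
recovery, a 6-subject panel × 20 noise replications for the BOLD recovery —
were chosen as the smallest sizes at which the medians under test are stable
across seeds.

## Numerical choices

Sigmoid saturation is clipped at 1e-9 when mapping optimizer proposals to
rates; choice likelihoods are clipped at 1e-10; the RT noise SD has a 1e-6
floor; Sinkhorn balancing declares failure after 10,000 sweeps; rank
deficiency in a design is detected at a 1e-8 relative QR threshold and
reported with the offending column's name. Ties in the enumeration oracle
count half. Truncated-exponential rates (round lengths, delays) are solved
with Brent's method. Zero-variance inputs to group t-tests raise rather
than return NaN, except exact equality with the reference, which returns
t = 0, p = 1.
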