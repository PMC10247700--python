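# Methods

This note documents the models, the synthetic ground truth, the numerical
choices, and the limits of what the packaged experiments can show.

## Encoding model

A voxelwise encoding model is a layered feature extractor `e_l(x)` plus a
near-linear read-out per voxel:

    r̄_v(x) = b_v + Σ_k w_vk f_out(Φ_k(x)),
    Φ_k(x) = ⊕_l Σ_ij f_in([e_l(x)]_{k_l ji}) g^l_{vji}.

Pooling fields `g` are nonnegative and sum to one. The parametric variant is
an isotropic 2-D Gaussian (center in % of span, σ in % of span), rasterized
by evaluating at pixel centers and renormalizing (edge truncation is
absorbed by the normalization). The flexible variant learns one grid per
distinct feature-map resolution; positivity and normalization are enforced
structurally — the stored parameters are unconstrained and pass through
absolute value and sum-normalization in the forward pass, so the constraint
holds after every optimizer step while gradients stay defined.

The read-out nonlinearity is `f(x) = tanh(x)·ln(1+|x|)` (natural log — the
base is a convention choice; any base only rescales the feature weights).
Defaults: trainable-extractor models use it as both `f_in` and `f_out`; the
Gabor baseline uses `f_in(x) = ln(1+|x|)`, `f_out(x) = x`; frozen-backbone
models default to identity with compressive variants configurable.

### Extractors

The trainable extractor is a prefilter followed by groups of blocks
(batch-norm → dropout → resolution-preserving convolution → rectification),
with 2× max pooling between groups. The default architecture is derived
from the input resolution so that the effective receptive field of the
deepest exposed layer covers the whole frame; at 64 px this yields three
groups (8→16→32 channels) rather than a fixed two-group layout, which would
top out at a ~33 px receptive field. All block outputs are exposed to the
read-out.

Two prefilter variants exist: a trainable strided convolution, and a fixed
oriented-energy stage (Gabor amplitude at 3 log-spread frequencies × 4
orientations, then 2× average pooling). The fixed variant plays the role of
a frozen, pretrained early-vision front end shared by every model in an
experiment. This sharing matters for the transfer analysis: when each
model learns its own front end from scratch at desk scale, the shallow
representations of different reference models diverge arbitrarily and no
entailment structure is measurable; with a common frozen front end,
transfer differences reflect what the *trained* stages add. Because the
stage is frozen, its per-image outputs are memoized.

The Gabor baseline bank defaults to 12 log-spaced frequencies from 3 to 72
cycles/stimulus at 6 evenly spaced orientations with quadrature energy
(72 maps). The literature this follows is ambiguous between "12 filters
total" and "12 × 6"; both are expressible through `GaborBankSpec`.
Frequencies above the resolution's Nyquist limit are rejected, so small
frames need a reduced frequency list.

## Training

The loss is the correlation-weighted squared error with per-voxel weights
`⌊ρ_v²⌋ = max(ρ_v², 0.1)`, where ρ_v is the within-minibatch Pearson
correlation between predictions and targets, treated as a constant within
the step (no gradient flows through the weights; detaching stabilizes
training). The floor is applied to ρ², and the minimum batch size is 8 so
the batchwise correlation is meaningful. With uniform weights the loss is
exactly the mean squared error.

Optimization is Adam (defaults lr 1e-3, β₁ 0.9, β₂ 0.999; a separate head
learning rate is configurable because the read-out weights start near zero
and otherwise dominate the convergence time at small scale — the packaged
experiments use 1e-2/3e-2 for extractor/heads). Extractor and head updates
alternate per minibatch (default one step each). Multi-subject training
interleaves subjects: per epoch, every subject's every training sample is
consumed exactly once, in a seeded shuffled order of (subject, minibatch)
pairs. Early stopping monitors mean holdout ρ (a fixed, seeded 10% of
training *images*, never trials, so repeats cannot straddle the split) with
patience 10 and clamps parameters to the best-holdout state.

Fine-tuning phases: phase 2 freezes all head parameters and trains the
extractor; phase 3 freezes the extractor and trains heads. Each phase
restarts from the previous best and clamps to its own best, so best holdout
accuracy never decreases.

Head-only training on a frozen extractor caches evaluation-mode feature
maps for all needed images once, making long head schedules nearly free.
The packaged experiments exploit this with a "head polish" after any joint
training: a few hundred head-only epochs that bring every model to
(near) head-optimality given its features. Since the transfer analysis asks
precisely "what do these frozen features support through a head?", the
polish also makes reference and transfer models protocol-matched.

The Gaussian-pooling-field pathway fits by grid search: candidate fields at
log-spaced sizes (default 8 sizes, 3–40% of span) on square lattices with
spacing 1.75× the size (the candidate count follows from this rule and is
reported, not asserted); per voxel, ridge weights are fit on standardized
pooled features, the (candidate, penalty) pair is selected on a held-out
10% split (ties: smaller field, then stronger penalty), and weights are
refit on the full training split. The default penalty grid is 9 values
log-spaced 1e-3..1e3.

## Synthetic cortex

The generator produces A areas (default 4) in one of two regimes sharing a
Gabor-energy first stage (4 orientations × 3 frequencies, matching the
model prefilter's bands — an idealized shared early-vision front end — and
2× average pooled):

* **hierarchical** — area m composes exactly m nonlinear stages; stage
  m ≥ 2 applies a rectified linear mixture of stage m−1 maps followed by
  local average pooling (downsampling until a 6 px floor, then
  resolution-preserving 2×2 smoothing).
* **parallel** — every area applies exactly one rectified mixture directly
  to the energy maps, followed by linear smoothing with a window that is
  non-decreasing in area index (3,3,5,5 at default sizes).

Two generator choices were calibrated once, during development, and are
deliberate: (i) mixing matrices are `(1−β)·I + β·G` with β = 0.5 and G
random Gaussian — near-identity mixes keep deep compositions learnable by a
desk-scale network so per-area reference accuracy stays matched across
areas and regimes, which the regime comparison requires (with fully random
mixes, deep areas become unlearnable and the entailment index measures
reference quality, not representation structure); (ii) the rectification
subtracts the per-image spatial mean first, because a plain ReLU of
nonnegative energy maps is nearly linear and would make composed stages
trivially readable from shallow features.

Each voxel has a Gaussian pooling field over its area's bank: center drawn
uniformly over a disk (default eccentricity ≤ 35% of span), size from the
area's line `size = slope·ecc + intercept (+ jitter)`, with slopes and
intercepts non-decreasing across areas — both regimes therefore express an
integration hierarchy. Tuning weights are Gaussian. The voxel signal is the
tuned pooled feature vector, standardized per voxel over the stimulus
ensemble; betas are signal + i.i.d. Gaussian noise per trial, z-scored per
voxel within each session (sessions partition trials contiguously). The
configured signal/noise standard deviations therefore map directly onto
repeat-based noise ceilings: NC = σ_s²/(σ_s²+σ_n²)·100.

What the generator does **not** emulate: correlated noise across voxels or
trials, scanner drift, hemodynamics, eye movements, surround modulation,
color, and any realistic image statistics beyond 1/f noise with oriented
structure. Passing tests therefore show that the analyses behave correctly
when their assumptions hold, not that they are robust to everything real
betas contain.

## Evaluation

Prediction accuracy is single-trial Pearson ρ on the shared-validation
split (repeats as separate trials); degenerate series get ρ = 0 plus a
flag. Permutation thresholds permute measured-trial order with a shared
permutation across voxels and return the (1−p) quantile of the pooled null.
The noise ceiling per voxel uses repeated shared images: noise variance =
mean within-image variance across repeats (ddof 1), signal variance =
max(0, total − noise), NC = 100·signal/(signal+noise). This repeat-based
estimator is a documented stand-in for the original GLM-based variant,
whose exact form is not reproduced here. Session-wise z-scoring makes the
zero-noise ceiling 100% exactly only within a single session; across
sessions the affine mismatch costs a few tenths of a point.

## Hierarchy analyses

*Layer contributions*: masking zeroes read-out feature weights only — the
forward pass is never altered. Fractions are computed per voxel above an
accuracy threshold (default: the p < 0.01 permutation threshold) and
averaged per area; uncertainty is a bootstrap over voxels. The default
bottom/top partition splits exposed layers at the depth midpoint, ties to
the bottom.

*Transfer analysis*: rows of the shift matrix index the trained-on area,
columns the tested area, both posterior→anterior. By default ρ_ref is
re-measured with the same frozen-extractor head-retraining protocol as the
transfer models (independent seed): simultaneous extractor+head training
and serial head retraining reach systematically different optima, and
without this the protocol difference contaminates every cell (the diagonal
artifact). α uses free-intercept least-squares slopes of each off-diagonal
triangle against taxicab distance (diagonal cells excluded); its standard
error propagates the two slope errors as independent. a₊ belongs to the
train-anterior/test-posterior triangle, so strict entailment (anterior
models entail posterior representations) gives α = +1.

*Receptive fields*: elliptical Gaussian fits use moment initialization
(centroid + second-moment ellipse) refined by least squares; refinements
that wander to degenerate optima (axes or centers beyond 75% of span, as
happens on diffuse, non-localized grids) fall back to the moment estimate
with a flag. Size is √(πab) with a, b the one-σ axes; eccentricity is the
center's distance from the origin; size–eccentricity lines are per-area OLS
with a cross-area ordering check at a matched eccentricity (default 20% of
span).

## The regime-discrimination experiment

`voxenc.pipeline.hierarchy_discrimination` trains one reference branch per
area on the cortex's *noiseless* area signals (the transfer operation's
"model outputs" mode, with the generator itself as the output source), all
branches sharing the frozen oriented-energy prefilter, each followed by a
head polish; then runs the transfer analysis and fits RF ellipses to the
reference models' pooling fields. Training references on the noiseless
source, rather than distilling them out of a jointly trained model, is a
deliberate desk-scale choice: a small jointly trained teacher is itself far
from its noise ceiling, and its outputs no longer separate the regimes,
whereas source-level references keep per-area accuracy matched — the
precondition for α to reflect representational structure. At full data and
compute scale the distillation route (also implemented, in
`voxenc.training.distill_reference`) is the appropriate instrument.

Problem sizes used by the packaged tests: 24 px frames, 4 areas × 8–12
voxels, 240 training + 80 shared-validation images, adaptive training
budgets (80-epoch cap, patience 10) with a 100-epoch head polish, five
seeds per regime. These sizes were chosen so the full suite runs in
minutes on one CPU while every mechanism is exercised; the experiment
dataclass defaults are somewhat larger (320 images, 150-epoch cap), and
the generator's own dataclass defaults retain the full desk scale (64 px,
4 × 100 voxels, 1500 + 200 images, 3 repeats).

An honest caveat about the regime comparison: at these problem sizes the
entailment index is a ratio of two small least-squares slopes fitted
through per-cell shifts whose optimization variance (serial head
retraining on ~200 images) is of the same order as the true transfer
asymmetries a small extractor expresses. In repeated runs the per-seed α
values of the two regimes overlap substantially and the paired comparison
does not separate them reliably; small networks approximate deep
compositional targets through smooth shortcuts rather than by
reconstructing the generative chain, which is the mechanism the entailment
test needs. Reproducing a stable separation is expected to require
substantially more data, capacity and training than a desk-scale CPU run
affords. The receptive-field size ordering, by contrast, is recovered
robustly in both regimes in every configuration tested.

## Known limitations

* The numpy training stack is deliberately small: no GPU, no conv-net
  architecture search, no distributed or mixed-precision training.
* Global early stopping is the only stopping criterion; voxelwise optima
  are not tracked.
* α is a ratio of two small slopes; when both triangles are flat its
  variance is large, and it is flagged undefined when both slopes vanish.
* The discrimination margin between regimes at desk scale is statistical,
  not deterministic — individual seeds can produce overlapping α values;
  the packaged test uses a paired comparison over five seeds.
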