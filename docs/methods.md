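# Methods

`dualmatch` implements a heterogeneous transfer-learning pipeline for
small-sample medical-image classification: two frozen source networks
(standing in for a natural-image network and a microscopy-tile network)
guide the training of a small target CNN through an *adaptive feature
matching* loss; the trained target is algebraically collapsed into plain
convolutions and used as a per-patient feature extractor; a sparse
Bayesian extreme-learning-machine (ELM) bagging ensemble classifies the
patients.  This note records the model, the defaults, and the design
choices made where the design was genuinely open.

## Feature matching between source and target networks

Let `S_k^m(x)` be the m-th tapped feature map of frozen source network
`k ∈ {1, 2}` and `T_θ^n(x)` the n-th tapped map of the target network,
both evaluated on the *target-task* input `x`.  For every candidate layer
pair `(m, n)` three small learnable pieces govern transfer:

* **adapter** `r_υ`: a pointwise (1×1) convolution projecting the target
  tap to the source layer's channel count.  Identity-initialized on the
  overlapping channels; needed only during training.
* **channel weights** `w_c = softmax(linear(GAP(S_k^m)))`: a single
  zero-initialized linear layer on the per-channel global means of the
  source map, so weights start uniform and always lie on the simplex.
  They decide *which* source feature maps deserve attention.
* **pair weight** `λ = ReLU6(linear(GAP(S_k^m)))`: one linear layer,
  clipped to `[0, 6]`.  It decides *where* (between which layers)
  transfer happens.  The bias is initialized to 1 so that λ starts in
  the linear region of ReLU6; a zero start would pin λ at the clip
  boundary with zero gradient and no transfer could begin.

The per-pair loss is `(1/HW) Σ_c w_c Σ_ij (r(T^n) − S^m)²`, averaged over
the batch; the total matching loss sums `λ`-weighted pair losses over
both sources, and training minimizes
`L_total = L_org + ς·L_wfm` with cross-entropy `L_org` and trade-off
`ς = 0.5` by default.

Open points resolved here: the candidate set `P_k` defaults to **all**
stage combinations (the pair weights learn to silence useless ones); a
`diagonal` profile restricting to same-stage pairs exists for cheap
runs and is the pipeline default.  When source and target taps disagree
spatially, the frozen source map is bilinearly resized to the target
geometry, preserving target-side geometry.  λ is not normalized across
pairs.  The plain (un-weighted) l2 distance is treated as motivation
only; only the weighted form is implemented.

## Four-stage training

Each outer step reuses one mini-batch through four stages:

1. one momentum-SGD step on `(θ, υ)` minimizing `L_total`;
2. `T` steps on `(θ, υ)` minimizing `L_wfm` alone (default `T = 2`);
3. one step on `(θ, υ)` minimizing `L_org` alone;
4. one Adam step on the matching heads `(∅, Φ)` driven by the change in
   `L_org`.

So `(θ, υ)` receive exactly `T + 2` updates per step and the heads
exactly one.  Stage 4 uses a **first-order, feature-space
meta-gradient**: for each pair, the alignment
`g_p = ⟨∂L_org/∂T^n, ∂ℓ_p/∂T^n⟩` measures whether pulling the target
toward that source layer also lowers the task loss; one optimizer step
on the surrogate `−Σ_p g_p · λ_p(Φ) · ℓ̂_p(∅) / |sg(λ_p ℓ̂_p)|` then
raises λ (and re-weights channels) for aligned pairs and lowers it for
misaligned ones.  This avoids second derivatives through the inner
updates entirely; it is coarser than differentiating through the
parameter update but has the same sign structure and costs one extra
backward pass plus a closed-form adapter transpose per pair.

Full-scale optimizer settings (momentum SGD lr 1e-4, momentum 0.9,
weight decay 1e-5 for `(θ, υ)`; Adam lr 1e-4, weight decay 1e-4 for the
heads; batch 200) are the config defaults; the desk profile uses
lr 0.02, batch 6–8 and a handful of epochs so toy networks move within
minutes.  Convergence is a fixed epoch budget plus optional early stop
on 10 epochs of non-improving validation loss.

## Diverse branch block and reparameterization

The target's convolutions are diverse branch blocks: four batch-
normalized branches — 1×1; 1×1→BN→K×K; 1×1→BN→K×K average pool; K×K —
summed.  "Same" padding `(K−1)/2`, odd K only, common stride.  By
homogeneity and additivity of convolution the block collapses exactly
into one `D×C×K×K` kernel plus bias: each BN folds into its conv as
`F′ = (γ/σ)F`, `b′ = β − μγ/σ` with `σ = sqrt(running_var + 1e-5)`;
sequential branches merge via `F_KxK ⊗ TRANS(F_1x1)`; the pool becomes a
`1/K²` depth-aligned kernel scaled by its BN.  One subtlety: inside the
sequential branches the intermediate map is padded with the BN's
bias-at-zero value `β − μγ/σ`, not zero, because the merged kernel pads
the *original* input with zeros, and a zero input patch emerges from the
1×1+BN stage carrying exactly that bias.  Evaluation-mode outputs of
block and collapsed conv then agree to float32 roundoff (observed
~1e-5; the suite asserts < 1e-4 across 50 random configurations).

The desk backbone is a stage-wise toy CNN (default widths 8/16/32/64,
two blocks per stage, first one stride 2 → 240 feature kernels); a
ResNet18-style variant with every main-path convolution replaced by a
DBB (1×1 shortcut projections left plain) is provided and exposes
3904 reparameterized kernels.

## Synthetic study data

The real study conditions (ImageNet-scale pretraining, TCGA whole-slide
tiles, two CT cohorts) are not reproducible at desk scale, so the
generator emulates their *structure*: each class is a fixed-phase
oriented grating plus a per-class blob count plus band-limited noise.
The fixed phase separates class means in pixel space (a logistic probe
on raw pixels exceeds 0.9 training accuracy at the stated sizes), which
is what makes all directional tests decidable; it also means passing
tests demonstrate the machinery works on separable textures, **not**
that the paper's cohort-level accuracies are reproduced.  Patients are
slice stacks (3–6 three-channel 224×224 images built from consecutive
raw slices); synthetic slides place near-white tiles on a 224 grid at a
controlled blank fraction.  All generators are bit-reproducible from
explicit seeds.

Desk study conditions in the default pipeline: 16 images/class/source
task at 48 px, 20 training + 16 test patients, target training at 96 px
on diagonal pairs for 2 epochs.  At these conditions both the transfer
model and the ς = 0 baseline typically reach ceiling on the held-out
patients, so the paired 3-seed comparison passes as "transfer never
hurts" (median difference ≥ 0) rather than a measured gain; harder
conditions can be configured.

## Sparse Bayesian ELM ensemble

Binary labels are treated as {0, 1} regression targets under a Gaussian
likelihood (the l1 view of the objective is superseded by the ARD
prior; the l1 coefficient is recorded as metadata only).  The hidden
layer is fixed random normal (default width 100, logistic sigmoid; a
`linear`/`identity` option turns the machine into plain ARD
regression).  With `A = diag(α)`:

    Σ = (A + βXᵀX)⁻¹,   m = βΣXᵀt,
    γ_i = 1 − α_i Σ_ii,  α_i ← γ_i/m_i²,  β⁻¹ ← ‖t − Xm‖²/(N − Σγ_i),

iterated until `‖Δm‖_∞ < 1e-6` (max 300 iterations; non-convergence
returns with the flag unset).  α is initialized at 1, β at `1/var(t)`;
α is capped at 1e8 and weights at the cap are pruned to exactly zero; β
is capped at 1e10 and a relative jitter retry guards the Cholesky solve
at extreme β on separable data.  The printed re-estimate for α with an
extra `A` factor in the denominator is dimensionally inconsistent with
the standard ARD fixed point; the classical `γ_i/m_i²` form is
implemented, validated by the evidence-ascent property and a
closed-form Gaussian-marginal cross-check.

The ensemble bags M = 10 machines (bootstrap fraction 1.0, per-base
seeds derived from the master seed); the combiner is one more sparse
Bayes fit whose design matrix is the continuous base scores (not class
decisions).  Scores are thresholded at 0.5.

## Feature extraction and screening

After reparameterization every collapsed kernel is a feature detector:
per slice, its pre-activation output map is global-mean pooled; the
patient vector is the mean over slices (invariant to slice order), of
length L = kernel count.  Screening uses a two-sided Mann–Whitney U test
(midrank ties; tie-corrected normal approximation with continuity
correction; exact permutation enumeration when the pooled sample is
≤ 12), keeping features with p < 0.05 on the **training cohort only**
(to avoid leakage).  No multiple-testing correction by default —
Benjamini–Hochberg sits behind a flag.  Selected features are z-scored
on the training cohort before classification; clinical/CT-finding
columns, when provided, are one-hot encoded and concatenated on patient
id.

## Evaluation

AUC is rank-based pairwise concordance (half credit for ties), so it
equals the Mann–Whitney U of the scores divided by `n1·n0` — asserted as
a cross-module identity.  The 95% CI is a stratified percentile
bootstrap (2000 resamples by default, seeded); DeLong is deliberately
not implemented.  Threshold metrics (precision, sensitivity,
specificity, accuracy, F1) come from confusion counts at threshold 0.5;
zero-denominator rates are NaN.  Evaluation is per patient, never per
slice.

## Numerical substrate and limitations

All networks run on a compact reverse-mode autograd over numpy
(im2col convolution, train/eval batch normalization, constant-value
padding, SGD/Adam), float32 throughout; fits and statistics use
float64 via scipy.  Known limitations: no grouped/dilated/even-kernel
convolutions; the Gaussian-likelihood ELM is regression-on-labels, not
a probit/logistic model; the meta-gradient is a feature-space
first-order approximation; synthetic textures cannot expose failure
modes of real CT/WSI data (scanner noise, registration, class overlap),
so cohort-level published AUCs are out of scope by construction.
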