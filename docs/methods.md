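# Methods

## The model

`retscreen` implements a transformer encoder for colour fundus images in
which the *range* of self-attention, not the token resolution, defines the
hierarchy. An image is standardised, masked to its circular field of view
(FOV), resized to H×W and cut into N = HW/P² non-overlapping P×P patches.
Each flattened patch z_i ∈ R^{P²C} is projected by a learnable matrix W_p
into an E-dimensional token and a learnable positional embedding p_i is
added:

    t_i = W_p z_i + p_i.

Every one of the L encoder layers computes, per head, two row-stochastic
attention matrices from the same scaled dot-product logits
q_i·k_j/√d: a **global** softmax over all N tokens and a **local** softmax
normalised only over the Chebyshev-radius-r neighbourhood of token i on the
2-D patch grid. They are combined convexly with a depth-dependent
coefficient α(l) ∈ [0, 1]:

    ã_ij = α(l) a_ij,global + (1 − α(l)) a_ij,local,

which is again row-stochastic with no renormalisation, because a convex
combination of probability vectors is a probability vector. α(l) grows
monotonically with depth, so early layers aggregate locally (fine lesions:
microaneurysm- and haemorrhage-scale structure) and deep layers aggregate
globally (anatomical context). Values are aggregated with ã, heads are
concatenated and merged by an E×E matrix, and a position-wise feed-forward
pair (W_1, W_2, GELU) with a residual completes the layer.

Token means are pooled at selected depths l_1 < … < l_K and fused with
softmax-normalised learnable weights β_k (non-negative, summing to one by
construction) into a single representation h = Σ_k β_k h^(k). A linear
projection W_s maps h into a compact screening space of dimension D, and an
independent sigmoid classifier per disease produces ŷ_c = σ(w_c·r) — no
softmax over classes, so co-occurring diseases are representable. The
training loss is the (sum-over-classes) binary cross-entropy; single-disease
screening is the C = 1 special case.

## Residual structure: two variants

The encoder layer is defined with a *single* residual around the whole
attention→feed-forward block and no layer normalisation:

    t_i^(l) = t_i^(l−1) + W_2 φ(W_1 s_i^(l)).

This literal form is the default and is the form checked token-for-token
against a naive nested-loop reference implementation in the tests. It is,
however, hard to optimise in deeper stacks, so a `stabilized` flag switches
to conventional pre-layer-norm sub-blocks (residual around attention and
around the feed-forward separately). Training defaults to `stabilized=True`;
all oracle/equivalence tests run with it off. Both variants share the
attention path, so the attention-map invariants (row-stochasticity, local
support, endpoint reductions) hold identically in both.

## α schedule

Two modes:

* `fixed_linear` (default): α(l) = l/L — monotone, parameter-free,
  reproducible. The last layer is purely global.
* `learnable_monotone`: α(l) = σ(b + Σ_{j<l} softplus(u_j)) with learnable
  b and u — monotone by construction, trained jointly with everything else.

A third mode, `fixed_constant`, exists for ablations: α ≡ 1 recovers a
plain global ViT encoder bit-for-bit on the attention path; α ≡ 0 recovers
a purely neighbourhood-restricted encoder.

## Gradients and optimisation

The whole model — encoder, fusion weights, screening head, optionally the
monotone α parameterisation — is implemented in numpy with hand-derived
analytic gradients (softmax rows, convex mixtures, layer norm, GELU via the
exact Gaussian CDF, weight-tied head projections). The test suite checks
every parameter group against central finite differences at 1e-4 relative
tolerance in both residual variants.

Training minimises the empirical risk over augmented mini-batches with
AdamW (β = (0.9, 0.999), ε = 1e-8, decoupled weight decay 1e-2; positional
tables, layer-norm gains/offsets and fusion/α logits are exempt from
decay). A `plain_sgd` mode implements the bare update Θ ← Θ − η∇L verbatim
and is used to verify the printed update rule exactly. The learning rate
follows η_t = η_0 γ^t; `decay_unit` selects whether t counts epochs
(default, γ = 0.97) or steps — per-step decay at realistic step counts
annihilates the rate, hence the epoch default. Early stopping monitors
validation loss (patience 10) and restores the best-epoch snapshot.
Augmentation (applied to training samples only) comprises horizontal and
vertical flips, rotation uniform in ±15°, and multiplicative brightness /
mean-anchored contrast jitter of ±10% inside the FOV; masks are transformed
identically and labels are untouched.

Desk-scale defaults: 64×64 images, P = 8 (N = 64 tokens), E = 64, 4 heads,
L = 4, fusion depths {2, 4}, D = 32, neighbourhood radius 1, batch 16,
lr0 = 5e-3, 30 epochs. A `full` preset records the publication-scale
geometry (512×512, P = 16, E = 768, L = 12, 12 heads, lr 1e-4); it is
GPU-scale and not exercised by the tests.

## Synthetic data: what it emulates, and what it does not

Real screening corpora cannot ship with a test suite, so the generator
builds fundus-*like* images with exhaustive ground truth: a circular FOV on
a zero background, an orange base colour with per-sample jitter, a linear
illumination gradient of random direction, a pale optic-disc blob at fixed
eccentricity, dark vessel-like random walks radiating from the disc, and
planted lesions — `bright_spot` (yellow Gaussian discs on R/G: exudate
surrogate) and `dark_blob` (intensity depressions: haemorrhage surrogate).
Class labels are defined by construction (label c = 1 iff ≥ 1 lesion of
class c was planted), lesion masks are exact, and an ordinal severity grade
is the staircase min(4, lesions // 2) over five grades. Patients are
emulated as groups of 1–3 images; splits are drawn at the group level so no
patient spans two partitions.

Default study conditions: two lesion classes at prevalences 0.45 and 0.30
(abnormals in the minority, as in screening populations), 2–5 lesions of
radius 2.5–5 px per positive image, additive amplitude 0.35–0.60,
illumination gradient strength 0.15, sensor noise sd 0.02. Lesion centres
are rejection-sampled so each lesion lies fully inside the FOV and lesions
never overlap (making the mask area exactly the sum of logged per-lesion
areas). The optic disc is chromatically distinct from bright-spot lesions
(pale/whitish vs yellow), as in real anatomy; without that distinction the
bright-spot class is dominated by an unlearnable confound rather than by
encoder quality.

What passing tests therefore show: the architecture, gradients, training
loop, thresholds, metrics, robustness and interpretability machinery are
correct and the model can learn localized-pathology detection end to end.
What they do not show: performance on real fundus photographs — real
lesions are textured and heterogeneous, acquisition artefacts are device
specific, and disease co-occurrence is structured; none of that is
reproduced here.

## Evaluation choices

* Decision thresholds are fixed per class on the validation split by
  maximising Youden's J over observed probabilities, ties resolved toward
  the higher threshold.
* Metrics: per-class confusion-derived accuracy, sensitivity, specificity
  and F1, macro-averaged without prevalence weighting; AUROC is the rank
  statistic with half credit for ties (a class that is single-valued on the
  evaluated set is excluded from the macro mean with a warning).
* Robustness: brightness up/down, mean-anchored contrast reduction,
  Gaussian blur and additive Gaussian noise at ordered severity levels;
  performance drop is the clean metric minus the mean degraded metric in
  percentage points. The *stability index* is the fraction of samples whose
  thresholded per-class decisions are identical across the clean image and
  every degradation level — this operationalisation was chosen because the
  index is used narratively as "consistent predictions across degradation
  levels".
* Attention alignment: a patch-level saliency is the attention *received*
  by each token (column mean of the final layer's mixed maps over heads and
  query rows — received rather than emitted, because mean pooling weights a
  token by how much the sequence attends to it). The saliency mass is
  partitioned into lesion-overlapping patches (relevant-region coverage),
  patches fully outside the FOV (misaligned focus) and the in-FOV remainder
  (diffuse attention); the three fractions sum to one by construction. The
  uniform-attention baseline for coverage is the lesion patch fraction.
* Cross-domain retention: 100 × (cross-domain metric / in-domain metric),
  uncapped. The desk-scale stand-in for a dataset shift is a second
  generator configuration with stronger illumination gradients, denser
  vasculature and smaller lesions.

## Numerical details and edge cases

* Softmax rows are computed with max-shift; masked (local) rows reuse the
  globally shifted exponentials and fall back to an independently shifted
  masked computation if an entire support row underflows. Off-support
  entries are exact zeros.
* Convex mixing at the endpoints is bitwise: α = 0 returns the local maps,
  α = 1 the global maps, with no arithmetic residue.
* Probabilities are clipped to [1e-7, 1 − 1e-7] inside the losses, which
  are undefined at {0, 1}.
* Parameter initialisation: truncated normal (±2 sd) for all projection
  matrices with configurable sd (`init_sd`), zeros for the positional table
  and fusion logits (equal β at start), unit gains for layer norms. The
  desk default is sd 0.1 — at E = 64 the conventional ViT value of 0.02
  leaves initial features too weak for lesion detectors to form within a
  30-epoch budget; the GPU-scale preset keeps 0.02. Everything flows from
  one integer seed, and identical (config, seed) pairs reproduce results
  bit-for-bit, including dataset generation and augmentation.
* Degenerate inputs raise informative errors rather than propagating NaNs:
  zero-variance channels, non-binary masks, empty attention supports,
  single-class validation columns, lesions larger than the FOV, truncated
  or version-mismatched checkpoints.

## Known limitations

* Detector formation for the bright-spot class is the hard part of the
  desk-scale task (a mean-pooled representation must learn to amplify rare
  lesion tokens) and is seed-dependent within the 30-epoch budget: across
  the three replication seeds one run typically fails to form the detector
  (held-out AUROC near chance for that class) while the others exceed 0.97.
  The replication protocol reports per-seed results for this reason.
* The literal residual form (no layer norm) is faithful but optimises
  poorly beyond a few layers; training quality rests on the `stabilized`
  variant.
* The naive-reference oracle covers the literal form only; the stabilised
  variant is verified through gradient checks and invariants, not a second
  forward implementation.
* The severity grade is generated and stored but the default heads screen
  the two lesion classes; severity grading is exposed as one-vs-rest
  utilities rather than a trained five-grade benchmark.
* Parameter counts, latency and throughput of the publication-scale
  configuration are out of scope at desk scale.
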