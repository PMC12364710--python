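# Methods

This note documents the models, numerical choices and study conditions
behind `capbrain`, and what the synthetic validation does and does not show
about real data.

## The analysis model

The pipeline treats a sentence-encoder embedding of a scene's captions as a
candidate representational code for visual cortex and asks three questions:

1. **Representational agreement (RSA).** Do stimulus-pair dissimilarities
   among voxel patterns match those among caption embeddings? Dissimilarity
   is Pearson correlation distance, `1 − r`, between patterns. Because a
   full RDM over ~10,000 stimuli is impractical, stimuli are partitioned
   into disjoint random subsets of exactly 100 (a remainder that cannot fill
   a subset is discarded, so 10,000 / 6,234 / 5,445 stimuli give 100 / 62 /
   54 splits); brain and model RDMs are built per subset, their upper
   triangles (4,950 pairs at n = 100) correlated, and the correlations
   averaged on the raw r scale. The searchlight variant runs this inside a
   sphere of radius 6 voxels centred on every in-brain voxel, keeping
   spheres with strictly more than 50% of their lattice points inside the
   brain and dropping out-of-mask points from the pattern.
2. **Encoding/decoding.** A linear map between mean caption embeddings and
   voxel responses, fit by fractional ridge regression. Encoding predicts
   each voxel from the embedding; decoding predicts each embedding dimension
   from (ROI-restricted) voxel responses, and a predicted embedding is
   turned into a caption by retrieving the best-correlated dictionary entry.
3. **Model adjudication.** Competing feature models (full-caption mean
   embedding, multi-hot categories, word-average embeddings, POS-filtered
   word averages) are compared on noise-ceiling-corrected RSA, with paired
   two-tailed t-tests across participants and Benjamini–Hochberg FDR across
   the family of pairwise comparisons.

### Preprocessing

Single-trial betas are z-scored per voxel within each scanning session
(removing session-level gain and offset drifts), then averaged over each
stimulus's repetitions. Only stimuli with the full repetition count
(3 by default) are retained. A session with a single trial is an error; a
voxel constant within a session has an undefined z-score and is set to 0
with a warning.

### Fractional ridge regression

Ridge is reparameterized by the fraction `f = ‖b(γ)‖/‖b_OLS‖` of the
coefficient norm retained. Along the SVD `X = USVᵀ`, the ridge solution is
`b(γ) = V diag(s/(s²+γ)) Uᵀy`; its norm is strictly decreasing in γ, so
each requested fraction has a unique γ, found by a vectorized bisection on
log γ (80 iterations, machine-precision accurate; validated against a dense
γ-grid oracle). Fraction 1 is OLS exactly (minimum-norm if rank deficient,
with a warning). The CV estimator evaluates 20 fractions (0.05–1.00 in
steps of 0.05) with 5-fold cross-validation — folds are contiguous blocks
of the shuffled training order under a fixed seed — scores them by held-out
Pearson r per target, selects per target with ties going to the smallest
(most regularizing) fraction, and refits on all training data. Intercepts
are handled by centring X and Y on training statistics and restoring the
offset at prediction.

Fraction selection is per *target*: per voxel in encoding, per embedding
dimension in decoding.

### Noise ceilings

- **RSA:** each participant's shared-stimulus RDM is correlated with the
  element-wise mean RDM of the other participants. A model that predicts a
  participant as well as the average of the remaining humans has reached the
  ceiling. Correction is by the ratio `r / ceiling`; participants with a
  non-positive ceiling are excluded from correction (sign-flipping a noise
  estimate would manufacture signal). A subtraction-based correction was
  the alternative; the ratio is used because it makes "model as good as the
  average human" exactly 1 regardless of the ROI's reliability scale.
- **Decoding:** the mean leave-one-out consistency of the five caption
  embeddings (each caption against the mean of the other four).

### Group inference

One-sample (or paired-difference) two-tailed t-tests across participants per
location, BH step-up FDR across locations at α = 0.05, significance mask
`q ≤ α`. Locations with zero variance across participants at a non-null
mean have undefined p and are excluded from the FDR family with a warning;
zero variance exactly at the null yields t = 0, p = 1. Sentence-contrast
maps are deliberately left uncorrected (they are exploratory predictions,
not inferential maps).

### Degenerate-input policies

- Zero-variance pattern in an RDM: distances to it set to the neutral value
  1, warned.
- Constant training target: zero weights, smallest fraction, flagged;
  evaluation propagates NaN.
- Dictionary entries that are constant vectors score −∞ (never retrieved);
  an all-constant dictionary is an error.
- Lookup ties break to the lowest entry index; rank ties break by stimulus
  index. Dictionary scoring runs in fixed-size blocks; the result is
  independent of block size.

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-participant
natural-scenes fMRI study with ground truth retained:

- **Scenes.** Scene i has latent content `z_i ~ N(0, I_k)`; a fixed
  semi-orthogonal map A sends it to the true embedding `e_i = A z_i`. The
  default is a full-rank latent (k = d): with k < d only the projection of
  voxel weights onto the latent image is identifiable from embeddings, so
  parameter recovery is impossible in principle; k < d remains available
  for low-rank experiments. A is semi-orthogonal so embedding dimensions
  are isotropic and disjoint embedding subspaces carry independent scene
  information.
- **Captions.** 5 per scene, `e_i` plus iid Gaussian jitter (sd 0.3 by
  default — inter-rater variability); the pipeline consumes their mean.
- **Categories.** m = 8 binary labels, each a thresholded fixed random
  readout of the latent at a ~30% base rate. This guarantees the intended
  asymmetry by construction: categories are (approximately) linearly
  decodable from embeddings, while embeddings cannot be recovered from the
  coarse binary code.
- **Words.** Each caption carries tagged word vectors: nouns are a fixed
  linear image of the latent plus noise (they carry scene content), verbs
  are pure noise. POS-filtered features therefore separate nouns from verbs
  by construction.
- **Brain.** A 3-D voxel grid partitioned into slab regions, each selective
  for a disjoint block of embedding dimensions (`W_true` rows supported on
  that block, optional isotropic leakage). Trial betas are
  `gain_s · (W_true e_i) + offset_s + ε`, with per-session uniform gains
  and offsets (which within-session z-scoring must remove — tests verify
  RDMs agree across sessions with 10× gain differences) and homoscedastic
  Gaussian voxel noise. Noise can be set by SNR, defined as per-voxel
  signal variance over noise variance; voxels with no signal get the mean
  signal sd of responsive voxels so they behave as pure-noise voxels rather
  than degenerate constants.
- **Cohort.** All participants share grid geometry, region layout and the
  shared stimulus set; unique stimulus sets are mutually exclusive; per-
  participant weights are the group template plus optional Gaussian jitter.
  One global seed expands into per-component child streams through
  `numpy.random.SeedSequence` spawning in a fixed order, so every generator
  is bit-reproducible.

### Reference study conditions

Validation studies (see `capbrain.experiments`) use: 8 participants, 600
stimuli each (100 shared + 500 unique), a 10 × 5 × 4 grid (200 voxels, two
regions), d = 32 embeddings, 5 captions with jitter sd 0.3, 3 repetitions
over 4 sessions with gains in [0.9, 1.1] and offsets in [−0.3, 0.3], and
SNR 10. These sizes keep the full structure of the large-scale experiment
(shared/unique split, session nuisances, region selectivity) at a scale
where the complete battery runs in seconds on one CPU. The zero-noise
retrieval study switches off measurement noise, caption jitter and session
nuisances; the contrast-localization study uses 2 participants and 200
unique stimuli per run.

### What passing tests do and do not show

The generator is linear-Gaussian: real caption embeddings are not Gaussian,
real voxel noise is neither homoscedastic nor independent across voxels,
real hemodynamic preprocessing is absent (betas are generated directly),
and real caption dictionaries contain semantically clustered entries rather
than manifold samples plus isotropic distractors. Passing recovery tests
shows the estimators are correct under the model's own assumptions — it
does not certify performance on real data. The control-model ordering
(caption mean > word average > multi-hot) holds *by construction* of the
generator and demonstrates that the comparison machinery can detect such an
ordering; it is not evidence about real brains.

## The cosine readout probe

Decodability between representations is probed with a linear readout fit by
minimizing mean cosine distance: initialized at the least-squares solution
and refined by full-batch Adam (learning rate 0.01, uphill steps rejected
with rate halving, stop when the relative loss decrease falls below 1e-6 or
after 2,000 iterations), so the training loss is monotone non-increasing.
The comparison floor is the cosine similarity achieved by always predicting
the mean training target on the same test items. Zero-norm target rows
carry no direction and are excluded with a warning.

## Known limitations

- Pearson-distance RDMs are undefined for constant patterns; the neutral
  value 1 is a pragmatic choice that slightly biases subset correlations
  toward 0 when degenerate patterns occur (e.g. all-zero multi-hot rows).
- The searchlight assumes an isotropic voxel grid; radii are in voxel
  units.
- `roi_model_comparison` applies one feature model across all ROIs; a model
  matched to a single region's generative geometry should be evaluated
  against that region's ROI only.
- The fraction grid is bounded below at 0.05; targets wanting stronger
  shrinkage saturate at the grid edge.
- Real-encoder adapters (sentence encoders, word vectors, POS taggers) are
  intentionally out of the hermetic core; the `TextEncoder` protocol
  defines the contract they must satisfy.
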