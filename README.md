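# capbrain

**Linking sentence-caption embeddings to visually evoked brain activity.**

`capbrain` is a tested, reusable implementation of an analysis pipeline for
asking whether the representational space of a sentence encoder (the
embeddings of scene captions) aligns with the representational space of
visual cortex in a large-scale natural-scenes fMRI experiment. It provides:

- **Subset-sampled searchlight RSA** — representational dissimilarity
  matrices (RDMs) from single-trial beta weights (z-scored within scanning
  session, averaged over each stimulus's three repetitions), pairwise
  dissimilarity `1 − Pearson r`, stimuli partitioned into disjoint random
  subsets of 100 (so 10,000 stimuli yield 100 independent correlation
  estimates that are averaged), repeated inside a sphere of radius 6 voxels
  around every brain voxel.
- **Leave-one-out noise ceilings** — a participant's RDM correlated with the
  mean RDM of the other participants on the stimuli everyone saw; for
  decoding, the internal consistency of the five captions per scene.
- **Voxelwise encoding and decoding** via **fractional ridge regression**:
  ridge parameterized by the fraction `f = ‖b_ridge‖/‖b_OLS‖` of the
  coefficient norm retained, with `f` selected per target from 20 candidates
  (0.05–1.00) by 5-fold cross-validation. Encoding maps the mean caption
  embedding `x ∈ R^d` to voxel responses `y = ĥx`; decoding is the inverse
  map, followed by **dictionary-lookup caption reconstruction** (retrieve
  the dictionary entry whose embedding best correlates with the prediction).
- **Control feature models** — multi-hot category vectors, averaged
  word-level embeddings, part-of-speech-filtered word averages — and
  **noise-ceiling-corrected model comparison** with paired two-tailed
  t-tests across participants and Benjamini–Hochberg FDR control.
- A first-class **synthetic cohort generator** with known ground truth
  (latent scene content, caption jitter, region-selective voxel weights,
  session gain/offset nuisances, Gaussian measurement noise), so every
  estimator in the pipeline can be validated by parameter recovery.

The regression core is written as scikit-learn estimators
(`FractionalRidgeCV`, `EncodingModel`, `DecodingModel`, `CosineReadout`)
that compose with sklearn pipelines and model selection; analysis steps are
plain functions over lightweight dataclasses.

## Worked example

```python
import numpy as np
import capbrain as cb

# simulate a cohort: 3 participants, 50 shared + 200 unique scenes each,
# 120 voxels in two selective regions, SNR 10
cohort = cb.make_cohort(n_participants=3, n_shared=50, n_unique=200,
                        grid_shape=(6, 5, 4), d=32, snr=10, seed=0)
scenes = cohort.scenes
pos = {s: i for i, s in enumerate(scenes.scene_ids)}

# preprocess participant 0: z-score within session, average repetitions
part = cohort.participants[0]
avg = cb.preprocess_betas(part.trials)
X = scenes.mean_embedding[[pos[s] for s in avg.stimulus_ids]]
test = np.isin(avg.stimulus_ids, cohort.shared_ids)

# voxelwise encoding model (fractional ridge, 20 fractions, 5-fold CV)
enc = cb.fit_encoding_model(X[~test], avg.values[~test], seed=0)
r = cb.evaluate_encoding(enc, X[test], avg.values[test])
print(f"encoding: median test r = {np.nanmedian(r):.3f}")

# decode embeddings from brain activity and reconstruct captions
dec = cb.fit_decoding_model(avg.values[~test], X[~test], seed=0)
shared = scenes.select([pos[s] for s in avg.stimulus_ids[test]])
dic = cb.build_caption_dictionary(shared, n_distractors=1000, seed=1)
res = cb.reconstruct_captions(dec, avg.values[test], X[test], dic,
                              stimulus_ids=avg.stimulus_ids[test])
hits = np.mean([res.best_entry_ids[i] == dic.entry_ids[dic.target_rows[s]]
                for i, s in enumerate(res.stimulus_ids)])
print(f"decoding: mean prediction score = {res.scores.mean():.3f}, "
      f"top-1 retrieval = {100 * hits:.0f}%")

# caption-consistency noise ceiling for the decoder
ceil = cb.caption_noise_ceiling(shared.caption_embeddings)
print(f"caption noise ceiling = {ceil.mean():.3f}")
```

Output:

```
encoding: median test r = 0.971
decoding: mean prediction score = 0.974, top-1 retrieval = 100%
caption noise ceiling = 0.947
```

The encoding model explains most response variance at SNR 10
(median held-out r = 0.97); the decoder's predicted embeddings correlate
with the target caption embeddings at r = 0.97 — above the 0.95
inter-caption consistency ceiling because the decoder targets the 5-caption
mean rather than single captions — and the dictionary lookup retrieves the
correct caption for every test scene among 1,050 entries.

For model comparison, `cb.roi_model_comparison` returns a tidy table of raw
and ceiling-corrected correlations per model/participant/ROI plus pairwise
BH-corrected tests; `cb.searchlight_rsa` and `cb.searchlight_contrast`
produce the volumetric equivalents (exportable to NIfTI via `capbrain.io`).

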