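"""End-to-end synthetic study runs used for validation and reporting.

Each function generates a cohort at the package's reference study
conditions, runs the full analysis path (preprocessing, fitting,
evaluation), and returns the headline numbers together with the problem
size.  All randomness flows from the single ``seed`` argument through
:class:`numpy.random.SeedSequence` children.

Reference conditions: 8 participants, 600 stimuli each (100 shared across
all participants and 500 unique), a 10 x 5 x 4 voxel grid (200 voxels, two
selective regions), 32-dimensional embeddings, 5 captions per scene with
inter-rater jitter sd 0.3, 3 repetitions over 4 sessions with mild session
gain/offset drifts, and per-voxel noise at signal-to-noise (variance) ratio
10.  These sizes preserve the structure of a large-scale natural-scenes
experiment at desk scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import (
    FeatureMatrix,
    averaged_word_features,
    build_caption_dictionary,
    dictionary_lookup,
    fit_decoding_model,
    fit_encoding_model,
    make_cohort,
    make_scenes,
    mean_caption_embedding,
    preprocess_betas,
    readout_probe,
    roi_model_comparison,
)
from .encode import ContrastSpec, evaluate_encoding, sentence_contrast

REFERENCE_COHORT = dict(
    n_participants=8,
    n_shared=100,
    n_unique=500,
    grid_shape=(10, 5, 4),
    n_regions=2,
    d=32,
    snr=10,
    caption_noise=0.3,
    n_reps=3,
    n_sessions=4,
    gain_range=(0.9, 1.1),
    offset_range=(-0.3, 0.3),
)


def _participant_xy(cohort, i):
    avg = preprocess_betas(cohort.participants[i].trials)
    pos = {s: j for j, s in enumerate(cohort.scenes.scene_ids)}
    X = cohort.scenes.mean_embedding[[pos[s] for s in avg.stimulus_ids]]
    is_shared = np.isin(avg.stimulus_ids, cohort.shared_ids)
    return avg, X, is_shared


def recovery_study(seed: int, subset_size: int = 100) -> dict:
    """Parameter recovery and ceiling-corrected RSA at reference conditions.

    Fits one encoding model per participant (train on unique stimuli, test
    on shared), measures the mean correlation between fitted and generative
    voxel weights, and runs a whole-brain ceiling-corrected RSA comparison
    of the generative-truth model (noiseless template responses) against a
    random-feature control.
    """
    cohort = make_cohort(seed=seed, **REFERENCE_COHORT)
    scenes = cohort.scenes
    responses, weight_r, test_r = [], [], []
    for i in range(cohort.n_participants):
        avg, X, is_shared = _participant_xy(cohort, i)
        responses.append(avg)
        model = fit_encoding_model(X[~is_shared], avg.values[~is_shared], seed=0)
        W = cohort.participants[i].brain.W_true
        rows = [
            np.corrcoef(model.coef_[v], W[v])[0, 1]
            for v in range(W.shape[0])
            if np.linalg.norm(W[v]) > 0
        ]
        weight_r.append(np.mean(rows))
        test_r.append(np.nanmean(
            evaluate_encoding(model, X[is_shared], avg.values[is_shared])
        ))

    brain0 = cohort.participants[0].brain
    truth = FeatureMatrix(
        values=brain0.noiseless_responses(scenes.true_embedding),
        model_name="generative-truth", stimulus_ids=scenes.scene_ids,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    control = FeatureMatrix(
        values=rng.normal(size=(scenes.n_scenes, 16)),
        model_name="random-control", stimulus_ids=scenes.scene_ids,
    )
    roi = {"whole-brain": np.ones(brain0.n_voxels, dtype=bool)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate control-feature subsets
        table = roi_model_comparison(
            responses, cohort.shared_ids, roi,
            {"truth": truth, "control": control},
            subset_size=subset_size, seed=seed,
        )
    by_model = table.scores.groupby("model")[["corrected_r", "ceiling"]].mean()
    return dict(
        weight_recovery_r=float(np.mean(weight_r)),
        encoding_test_r=float(np.mean(test_r)),
        truth_corrected_rsa=float(by_model.loc["truth", "corrected_r"]),
        control_corrected_rsa=float(by_model.loc["control", "corrected_r"]),
        noise_ceiling=float(by_model.loc["truth", "ceiling"]),
        n_stimuli=int(REFERENCE_COHORT["n_shared"] + REFERENCE_COHORT["n_unique"]),
        n_participants=cohort.n_participants,
    )


def perfect_retrieval_study(seed: int) -> dict:
    """Zero-noise decoding with an exact dictionary: top-1 retrieval accuracy.

    A noiseless, jitter-free cohort; decoder trained on unique stimuli,
    evaluated on shared; the dictionary holds exactly the true embeddings of
    the shared test scenes.
    """
    params = dict(REFERENCE_COHORT)
    params.update(n_participants=2, snr=None, noise_sd=0.0, caption_noise=0.0,
                  gain_range=(1.0, 1.0), offset_range=(0.0, 0.0))
    cohort = make_cohort(seed=seed, **params)
    avg, X, is_shared = _participant_xy(cohort, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficient noiseless design
        model = fit_decoding_model(avg.values[~is_shared], X[~is_shared], seed=0)
        preds = model.predict(avg.values[is_shared])
    shared_ids = avg.stimulus_ids[is_shared]
    pos = {s: j for j, s in enumerate(cohort.scenes.scene_ids)}
    shared_scenes = cohort.scenes.select(np.array([pos[s] for s in shared_ids]))
    dic = build_caption_dictionary(shared_scenes, n_distractors=0,
                                   paraphrase_jitter=0.0, seed=seed)
    ids, _ = dictionary_lookup(preds, dic)
    hits = [
        ids[j] == dic.entry_ids[dic.target_rows[sid]]
        for j, sid in enumerate(shared_ids)
    ]
    return dict(top1_accuracy_pct=100.0 * float(np.mean(hits)),
                n_test=len(shared_ids))


def feature_ordering_study(seed: int, subset_size: int = 100) -> dict:
    """Ceiling-corrected RSA of the three caption-derived feature models.

    Full-caption mean embeddings vs multi-hot category vectors vs the mean
    over all word-level vectors, each against whole-brain responses.
    """
    cohort = make_cohort(seed=seed, **REFERENCE_COHORT)
    scenes = cohort.scenes
    responses = [_participant_xy(cohort, i)[0]
                 for i in range(cohort.n_participants)]
    models = {
        "caption_mean": mean_caption_embedding(scenes),
        "multi_hot": FeatureMatrix(values=scenes.categories.astype(float),
                                   model_name="multi-hot",
                                   stimulus_ids=scenes.scene_ids),
        "word_mean": averaged_word_features(scenes),
    }
    roi = {"whole-brain": np.ones(cohort.participants[0].brain.n_voxels,
                                  dtype=bool)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero multi-hot rows
        table = roi_model_comparison(responses, cohort.shared_ids, roi, models,
                                     subset_size=subset_size, seed=seed)
    by_model = table.scores.groupby("model")["corrected_r"].mean()
    return {name: float(by_model[name]) for name in models} | {
        "n_participants": cohort.n_participants
    }


def readout_asymmetry_study(seed: int, n_runs: int = 10,
                            n_scenes: int = 300) -> dict:
    """Linear decodability probes between embeddings and category labels.

    Categories are coarse functions of the scene content, so a cosine
    readout recovers them from embeddings; the reverse direction loses the
    fine-grained embedding information.
    """
    children = np.random.SeedSequence(seed).spawn(n_runs)
    e2c, c2e, e2e, floors = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero category rows
        for i, child in enumerate(children):
            s = make_scenes(n_scenes, d=32, m=8, caption_noise=0.3, seed=child)
            emb = s.mean_embedding
            cats = s.categories.astype(float)
            r1 = readout_probe(emb, cats, seed=i)
            e2c.append(r1.test_cosine)
            floors.append(r1.floor)
            c2e.append(readout_probe(cats, emb, seed=i).test_cosine)
            e2e.append(readout_probe(emb, emb, seed=i).test_cosine)
    return dict(
        emb_to_cat_cosine=float(np.mean(e2c)),
        emb_to_cat_floor=float(np.mean(floors)),
        cat_to_emb_cosine=float(np.mean(c2e)),
        emb_to_emb_cosine=float(np.mean(e2e)),
        n_runs=n_runs,
    )


def contrast_localization_study(seed: int, n_runs: int = 3) -> dict:
    """Sentence contrasts targeting one region's embedding subspace.

    Condition sentences load +/- on region 0's embedding dimensions; the
    resulting predicted-activity contrast should concentrate inside region 0.
    Reports the ratio of mean |contrast| inside vs outside the region.
    """
    children = np.random.SeedSequence(seed).spawn(n_runs)
    ratios = []
    for run, child in enumerate(children):
        params = dict(REFERENCE_COHORT)
        params.update(n_participants=2, n_unique=200)
        cohort = make_cohort(seed=child, **params)
        brain = cohort.participants[0].brain
        models = []
        for i in range(cohort.n_participants):
            avg, X, is_shared = _participant_xy(cohort, i)
            models.append(fit_encoding_model(X[~is_shared],
                                             avg.values[~is_shared], seed=0))
        d = cohort.scenes.embedding_dim
        a = np.zeros((5, d))
        a[:, brain.regions[0].embedding_dims] = 1.0
        res = sentence_contrast(models, ContrastSpec(condition_a=a,
                                                     condition_b=-a))
        in0 = brain.region_voxel_mask("region0")
        ratios.append(np.abs(res.per_participant[:, in0]).mean()
                      / np.abs(res.per_participant[:, ~in0]).mean())
    return dict(in_vs_out_abs_contrast_ratio=float(np.mean(ratios)),
                n_runs=n_runs)
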