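"""Brain-to-embedding decoding and dictionary-lookup caption reconstruction.

The decoder is the inverse of the encoding model: a linear map from voxel
responses (restricted to a region-of-interest mask) to the mean caption
embedding, fit with the same fractional-ridge machinery, the regularization
fraction selected per embedding dimension by cross-validation.  Decoding
quality per test stimulus is the Pearson r between the predicted and target
embeddings.  Its natural ceiling is the internal consistency of the captions
themselves: leave one caption out, correlate its embedding with the mean of
the others, average.  A caption is reconstructed by looking up the
dictionary entry whose embedding correlates best with the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ridge import FractionalRidgeCV
from .syndata import Dictionary
from .utils import pearson, pearson_rows


class DecodingModel(FractionalRidgeCV):
    """Voxel-to-embedding linear map, fraction selected per embedding dim.

    ``fit(X, Y)`` takes voxel responses X (n_stimuli, p_roi) and target
    embeddings Y (n_stimuli, d).
    """


def fit_decoding_model(
    brain_responses,
    embeddings: np.ndarray,
    roi_mask: np.ndarray | None = None,
    fractions=None,
    k_folds: int = 5,
    seed: int | None = None,
) -> DecodingModel:
    """Fit a decoder from (optionally ROI-restricted) responses to embeddings.

    ``roi_mask`` selects voxel columns (boolean or index array); by default
    all in-brain voxels are used.
    """
    X = np.asarray(getattr(brain_responses, "values", brain_responses), float)
    if roi_mask is not None:
        X = X[:, roi_mask]
    return DecodingModel(fractions=fractions, cv=k_folds, random_state=seed).fit(
        X, embeddings
    )


def prediction_score(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson r between a predicted and a target embedding (NaN if constant)."""
    return pearson(pred, target)


def prediction_scores(preds: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Row-wise prediction scores for a batch of test stimuli."""
    return pearson_rows(preds, targets)


def caption_noise_ceiling(caption_embeddings: np.ndarray) -> np.ndarray:
    """Per-stimulus inter-caption consistency ceiling.

    For each stimulus with c >= 3 captions: correlate each caption's
    embedding with the mean embedding of the other c - 1 captions and
    average the c correlations.
    """
    caps = np.asarray(caption_embeddings, dtype=float)
    if caps.ndim != 3:
        raise ValueError("expected (n_stimuli, n_captions, d) caption embeddings")
    n, c, _ = caps.shape
    if c < 3:
        raise ValueError("need at least 3 captions per stimulus")
    total = caps.sum(axis=1, keepdims=True)
    out = np.empty(n)
    for i in range(n):
        rs = [
            pearson(caps[i, j], (total[i, 0] - caps[i, j]) / (c - 1))
            for j in range(c)
        ]
        out[i] = np.nanmean(rs)
    return out


def dictionary_lookup(
    pred: np.ndarray, dictionary: Dictionary, block_size: int = 4096
):
    """Dictionary entry (or entries) best correlated with the prediction(s).

    Similarity is Pearson correlation (centred, hence scale- and
    offset-invariant, unlike raw cosine).  Ties break to the lowest entry
    index.  Entries are scored in fixed-size blocks so memory stays bounded;
    the result is independent of ``block_size``.
    """
    if dictionary.n_entries == 0:
        raise ValueError("dictionary is empty")
    preds = np.atleast_2d(np.asarray(pred, dtype=float))
    emb = dictionary.embeddings
    if preds.shape[1] != emb.shape[1]:
        raise ValueError("prediction dimension does not match dictionary")

    pc = preds - preds.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1, keepdims=True)
    pn[pn == 0.0] = np.nan
    pc = pc / pn

    best_score = np.full(preds.shape[0], -np.inf)
    best_idx = np.zeros(preds.shape[0], dtype=int)
    any_valid = False
    for start in range(0, emb.shape[0], block_size):
        block = emb[start : start + block_size]
        bc = block - block.mean(axis=1, keepdims=True)
        bn = np.linalg.norm(bc, axis=1)
        valid = bn > 0.0
        if not valid.any():
            continue
        any_valid = True
        scores = np.full((preds.shape[0], block.shape[0]), -np.inf)
        scores[:, valid] = pc @ (bc[valid] / bn[valid, None]).T
        blk_best = np.argmax(scores, axis=1)  # first max -> lowest index
        blk_score = scores[np.arange(preds.shape[0]), blk_best]
        improve = blk_score > best_score  # strict: earlier blocks keep ties
        best_idx[improve] = blk_best[improve] + start
        best_score[improve] = blk_score[improve]
    if not any_valid:
        raise ValueError("all dictionary entries are constant vectors")

    ids = dictionary.entry_ids[best_idx]
    if np.asarray(pred).ndim == 1:
        return ids[0], float(best_score[0])
    return ids, best_score


def rank_predictions(scores: np.ndarray) -> np.ndarray:
    """Rank test stimuli by prediction score: rank 0 is the best prediction.

    Ties break by stimulus index; with n test stimuli the worst rank is
    n - 1 and the ranks are a permutation of 0..n-1.  NaN scores sort last.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    key = np.where(np.isnan(scores), -np.inf, scores)
    order = np.lexsort((np.arange(scores.size), -key))
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(scores.size)
    return ranks


@dataclass
class LookupResult:
    """Per-test-stimulus decoding summary."""

    stimulus_ids: np.ndarray
    predicted: np.ndarray  # (n, d)
    scores: np.ndarray  # Pearson r to target embedding
    best_entry_ids: np.ndarray
    ranks: np.ndarray


def reconstruct_captions(
    model: DecodingModel,
    brain_test,
    target_embeddings: np.ndarray,
    dictionary: Dictionary,
    stimulus_ids: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
) -> LookupResult:
    """Decode test responses, score against targets, and look up captions."""
    X = np.asarray(getattr(brain_test, "values", brain_test), float)
    if roi_mask is not None:
        X = X[:, roi_mask]
    preds = model.predict(X)
    scores = prediction_scores(preds, target_embeddings)
    if np.any(~np.isfinite(scores)):
        warnings.warn("constant predicted or target embedding(s); score NaN",
                      stacklevel=2)
    best_ids, _ = dictionary_lookup(preds, dictionary)
    if stimulus_ids is None:
        stimulus_ids = np.arange(preds.shape[0])
    return LookupResult(
        stimulus_ids=np.asarray(stimulus_ids),
        predicted=preds,
        scores=scores,
        best_entry_ids=best_ids,
        ranks=rank_predictions(scores),
    )
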