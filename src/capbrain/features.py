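"""Control feature models: caption means, multi-hot categories, word averages.

These are the comparison representations pitted against the full-caption
sentence embedding in model-comparison RSA: binary multi-hot category
vectors, the mean over all word-level embeddings of all captions, and
part-of-speech-filtered word averages (nouns only, verbs only).  Real text
encoders, word-vector tables and POS taggers live behind the
:class:`TextEncoder` protocol so the core stays hermetic; the synthetic
scene generator supplies ground-truth-tagged word vectors directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .syndata import SceneSet, TaggedWords


@dataclass
class FeatureMatrix:
    """One feature vector per stimulus, for RDM construction."""

    values: np.ndarray  # (n_stimuli, q)
    model_name: str
    stimulus_ids: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.values.shape[0] != len(self.stimulus_ids):
            raise ValueError("one row per stimulus required")

    def select(self, ids: np.ndarray) -> "FeatureMatrix":
        pos = {sid: i for i, sid in enumerate(self.stimulus_ids)}
        idx = np.array([pos[s] for s in ids])
        return FeatureMatrix(
            values=self.values[idx],
            model_name=self.model_name,
            stimulus_ids=np.asarray(ids),
        )


@runtime_checkable
class TextEncoder(Protocol):
    """Adapter contract for a real sentence encoder (same input, same output)."""

    deterministic: bool

    def encode(self, texts: list[str]) -> np.ndarray: ...


def mean_caption_embedding(scenes_or_captions, name: str = "caption-mean") -> FeatureMatrix:
    """Arithmetic mean of the per-caption embeddings (inter-rater averaging)."""
    if isinstance(scenes_or_captions, SceneSet):
        caps = scenes_or_captions.caption_embeddings
        ids = scenes_or_captions.scene_ids
    else:
        caps = np.asarray(scenes_or_captions, dtype=float)
        ids = np.arange(caps.shape[0])
    if caps.ndim != 3 or caps.shape[1] < 1:
        raise ValueError("expected (n_stimuli, n_captions >= 1, d) embeddings")
    return FeatureMatrix(values=caps.mean(axis=1), model_name=name, stimulus_ids=ids)


def multi_hot_features(
    labels, n_categories: int | None = None, stimulus_ids=None,
    name: str = "multi-hot",
) -> FeatureMatrix:
    """Binary category-presence vectors (0s with 1s for present categories).

    ``labels`` is either an (n, m) binary matrix or a list of per-stimulus
    category-id collections over a fixed universe of ``n_categories``.
    All-zero rows (no categories) are legal but warned, since their pattern
    correlations downstream are degenerate.
    """
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        values = labels.astype(float)
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("binary label matrix must contain only 0/1")
    else:
        if n_categories is None:
            raise ValueError("n_categories required for label-id lists")
        values = np.zeros((len(labels), n_categories))
        for i, cats in enumerate(labels):
            for c in cats:
                if not 0 <= c < n_categories:
                    raise ValueError(f"unknown category id {c}")
                values[i, c] = 1.0
    if np.any(values.sum(axis=1) == 0):
        warnings.warn(
            "stimuli with no categories present (all-zero rows); downstream "
            "correlation distances will use the neutral-value policy",
            stacklevel=2,
        )
    if stimulus_ids is None:
        stimulus_ids = np.arange(values.shape[0])
    return FeatureMatrix(values=values, model_name=name,
                         stimulus_ids=np.asarray(stimulus_ids))


def _iter_scene_words(word_vectors):
    """Yield per-scene lists of TaggedWords from a SceneSet or raw nesting."""
    if isinstance(word_vectors, SceneSet):
        return word_vectors.word_vectors
    return word_vectors


def averaged_word_features(
    word_vectors, neutral_vector: np.ndarray | None = None, stimulus_ids=None,
    name: str = "word-mean",
) -> FeatureMatrix:
    """Mean embedding over all words of all captions of each stimulus.

    A stimulus with no words at all falls back to the neutral vector (the
    analogue of embedding a semantically empty placeholder word), so every
    stimulus still has a feature row for RSA.
    """
    return pos_filtered_features(
        word_vectors, keep=None, neutral_vector=neutral_vector,
        stimulus_ids=stimulus_ids, name=name,
    )


def pos_filtered_features(
    word_vectors,
    keep: set[str] | None,
    neutral_vector: np.ndarray | None = None,
    stimulus_ids=None,
    name: str | None = None,
) -> FeatureMatrix:
    """Mean over words whose POS tag is in ``keep`` (None keeps every word).

    Scenes whose filtered word set is empty get the neutral fallback vector
    and are counted in a warning.
    """
    if neutral_vector is None:
        if isinstance(word_vectors, SceneSet):
            neutral_vector = word_vectors.neutral_word_vector
        else:
            raise ValueError("neutral_vector required for raw word-vector input")
    scenes = _iter_scene_words(word_vectors)
    neutral = np.asarray(neutral_vector, dtype=float)
    rows, n_fallback = [], 0
    for per_caption in scenes:
        vecs = []
        for tw in per_caption:
            if not isinstance(tw, TaggedWords):
                tw = TaggedWords(*tw)
            sel = (
                np.ones(len(tw.tags), dtype=bool)
                if keep is None
                else np.array([t in keep for t in tw.tags])
            )
            if tw.vectors.shape[1] != neutral.size:
                raise ValueError("word vector dimension mismatch with neutral vector")
            if sel.any():
                vecs.append(tw.vectors[sel])
        if vecs:
            rows.append(np.vstack(vecs).mean(axis=0))
        else:
            rows.append(neutral.copy())
            n_fallback += 1
    if n_fallback:
        warnings.warn(
            f"{n_fallback} stimuli had no words after filtering; neutral "
            "fallback vector used",
            stacklevel=2,
        )
    if stimulus_ids is None:
        stimulus_ids = (
            word_vectors.scene_ids
            if isinstance(word_vectors, SceneSet)
            else np.arange(len(rows))
        )
    if name is None:
        name = "word-mean" if keep is None else "word-" + "+".join(sorted(keep))
    return FeatureMatrix(
        values=np.vstack(rows), model_name=name, stimulus_ids=np.asarray(stimulus_ids)
    )
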