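"""Voxelwise linear encoding from caption embeddings.

An encoding model predicts each voxel's average response from the mean
caption embedding of the stimulus, using fractional ridge regression with
the regularization fraction selected per voxel by 5-fold cross-validation
(20 fractions, 0.05 to 1.00).  Evaluation is the per-voxel Pearson r between
predicted and observed responses on a held-out test set (the shared stimuli
in a cohort).  The same machinery supports interparticipant agreement maps,
sentence-contrast predictions, and cross-participant generalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ridge import FractionalRidgeCV
from .utils import pearson_columns


class EncodingModel(FractionalRidgeCV):
    """Embedding-to-voxel linear map with per-voxel CV'd ridge fraction.

    ``fit(X, Y)`` takes stimulus embeddings X (n_stimuli, d) and average
    voxel responses Y (n_stimuli, p).  After fitting, ``coef_`` is the
    (p, d) weight matrix h-hat and ``best_fraction_`` the per-voxel selected
    regularization fraction.
    """

    @property
    def weights_(self) -> np.ndarray:
        return self.coef_


def fit_encoding_model(
    X: np.ndarray,
    Y,
    fractions=None,
    k_folds: int = 5,
    seed: int | None = None,
) -> EncodingModel:
    """Fit an :class:`EncodingModel`; ``Y`` may be an AvgResponses or array."""
    Y = getattr(Y, "values", Y)
    return EncodingModel(fractions=fractions, cv=k_folds, random_state=seed).fit(X, Y)


def evaluate_encoding(model: EncodingModel, X_test: np.ndarray, Y_test) -> np.ndarray:
    """Per-voxel Pearson r between predicted and observed test responses.

    Voxels flagged degenerate during training propagate NaN.
    """
    Y_test = np.asarray(getattr(Y_test, "values", Y_test), dtype=float)
    if X_test.shape[0] < 3:
        raise ValueError("need at least 3 test stimuli")
    r = pearson_columns(model.predict(X_test), Y_test)
    flagged = getattr(model, "degenerate_targets_", None)
    if flagged is not None:
        r = np.where(flagged, np.nan, r)
    return r


def interparticipant_agreement(responses: list[np.ndarray]) -> np.ndarray:
    """Per-voxel agreement of each participant with the mean of the others.

    ``responses`` holds one (n_shared_stimuli, p) matrix per participant over
    the same stimuli in the same order.  Entry (i, v) is the Pearson r
    between participant i's voxel-v responses and the average of the other
    participants' responses at that voxel.
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 participants")
    stack = np.stack([np.asarray(getattr(r, "values", r), float) for r in responses])
    n = stack.shape[0]
    out = np.empty((n, stack.shape[2]))
    total = stack.sum(axis=0)
    for i in range(n):
        others_mean = (total - stack[i]) / (n - 1)
        out[i] = pearson_columns(stack[i], others_mean)
    return out


@dataclass
class ContrastSpec:
    """Two sets of sentence embeddings defining a predicted-activity contrast."""

    condition_a: np.ndarray  # (n_a, d)
    condition_b: np.ndarray  # (n_b, d)

    def __post_init__(self):
        self.condition_a = np.atleast_2d(np.asarray(self.condition_a, float))
        self.condition_b = np.atleast_2d(np.asarray(self.condition_b, float))
        if self.condition_a.size == 0 or self.condition_b.size == 0:
            raise ValueError("both conditions need at least one sentence")
        if self.condition_a.shape[1] != self.condition_b.shape[1]:
            raise ValueError("conditions must share embedding dimension")


@dataclass
class ContrastResult:
    per_participant: np.ndarray  # (n_participants, p)
    t: np.ndarray  # (p,)
    p: np.ndarray  # (p,) two-tailed, uncorrected by design


def sentence_contrast(models: list[EncodingModel], spec: ContrastSpec) -> ContrastResult:
    """Predicted-activity contrast between two sentence sets.

    Per participant, the voxelwise mean predicted activity for condition A
    minus condition B; the group map is an uncorrected two-tailed one-sample
    t-test across participants (this map is deliberately left without FDR
    correction, unlike all other group maps).
    """
    maps = []
    for model in models:
        if spec.condition_a.shape[1] != model.coef_.shape[1]:
            raise ValueError("sentence embedding dimension mismatch with model")
        a = model.predict(spec.condition_a).mean(axis=0)
        b = model.predict(spec.condition_b).mean(axis=0)
        maps.append(a - b)
    maps = np.stack(maps)
    if maps.shape[0] >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_1samp(maps, 0.0, axis=0)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        zero = maps.std(axis=0, ddof=1) == 0
        t[zero & np.isclose(maps.mean(axis=0), 0)] = 0.0
        p[zero & np.isclose(maps.mean(axis=0), 0)] = 1.0
    else:
        t = np.full(maps.shape[1], np.nan)
        p = np.full(maps.shape[1], np.nan)
    return ContrastResult(per_participant=maps, t=t, p=p)


def cross_participant_encode(
    models: list[EncodingModel],
    X_test: np.ndarray,
    Y_tests: list,
    train_participant: int,
    test_participant: int,
) -> np.ndarray:
    """Evaluate participant i's encoding model on participant j's test data."""
    if train_participant == test_participant:
        raise ValueError("cross-participant evaluation requires i != j")
    return evaluate_encoding(models[train_participant], X_test, Y_tests[test_participant])


def cross_participant_matrix(
    models: list[EncodingModel], X_test: np.ndarray, Y_tests: list
) -> np.ndarray:
    """(n, n) matrix of mean test r; row = training participant, col = test.

    The diagonal holds within-participant evaluation for reference.
    """
    n = len(models)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.nanmean(evaluate_encoding(models[i], X_test, Y_tests[j]))
    return out
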