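"""Model adjudication: noise-ceiling-corrected ROI comparisons, searchlight
contrasts, and frozen-feature readout probes.

ROI comparisons divide each participant's subset-sampled RSA correlation by
that participant's leave-one-out noise ceiling (computed on the shared
stimuli within the same ROI), then test pairwise model differences with
paired two-tailed t-tests across participants, Benjamini-Hochberg corrected
across the whole family of pairwise comparisons.  The readout probe asks
whether one representation is linearly decodable from another: a linear map
fit by minimizing cosine distance, scored by test cosine similarity against
the floor of always predicting the mean training target.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .rsa import (
    RDM,
    AvgResponses,
    GroupResult,
    compute_rdm,
    group_inference,
    partition_stimuli,
    rsa_noise_ceiling,
    sampled_rsa,
)


@dataclass
class ModelComparisonTable:
    """Tidy per-(model, participant, ROI) scores and pairwise tests."""

    scores: pd.DataFrame  # model, participant, roi, raw_r, ceiling, corrected_r
    pairwise: pd.DataFrame  # model_a, model_b, roi, mean_diff, t, p, q


def roi_model_comparison(
    responses: list[AvgResponses],
    shared_ids: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    models: dict[str, object],
    subset_size: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ModelComparisonTable:
    """Noise-ceiling-corrected RSA comparison of feature models per ROI.

    ``responses`` holds each participant's average responses over their own
    stimuli (shared stimuli included); ``models`` maps a name to a
    FeatureMatrix (with ``select``/``values``) or an RDM covering every
    stimulus.  Per participant, ROI and model, the subset-sampled RSA r is
    divided by that participant's ROI noise ceiling; participants with a
    non-positive ceiling are excluded from correction with a warning.  One
    stimulus partition per participant is reused across ROIs and models.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    n_part = len(responses)
    shared_ids = np.asarray(shared_ids)

    # per-ROI leave-one-out ceilings on the shared stimuli
    ceilings: dict[str, np.ndarray] = {}
    for roi, mask in roi_masks.items():
        rdms = []
        for resp in responses:
            pos = {sid: i for i, sid in enumerate(resp.stimulus_ids)}
            idx = np.array([pos[s] for s in shared_ids])
            rdms.append(
                compute_rdm(
                    AvgResponses(
                        values=resp.values[np.ix_(idx, np.flatnonzero(np.asarray(mask)))]
                        if np.asarray(mask).dtype == bool
                        else resp.values[np.ix_(idx, np.asarray(mask))],
                        stimulus_ids=shared_ids,
                    )
                )
            )
        ceilings[roi] = rsa_noise_ceiling(rdms)

    partitions = [
        partition_stimuli(resp.stimulus_ids, subset_size, s)
        for resp, s in zip(
            responses, np.random.SeedSequence(seed).generate_state(n_part)
        )
    ]

    rows = []
    for pi, resp in enumerate(responses):
        for roi, mask in roi_masks.items():
            vox = (
                np.flatnonzero(np.asarray(mask))
                if np.asarray(mask).dtype == bool
                else np.asarray(mask)
            )
            ceiling = ceilings[roi][pi]
            for name, model in models.items():
                if isinstance(model, RDM):
                    model_for_resp = model
                else:
                    model_for_resp = model.select(resp.stimulus_ids).values
                res = sampled_rsa(
                    resp, model_for_resp, partition=partitions[pi], voxels=vox
                )
                if ceiling > 0:
                    corrected = res.mean_r / ceiling
                else:
                    corrected = np.nan
                rows.append(
                    dict(
                        model=name,
                        participant=pi,
                        roi=roi,
                        raw_r=res.mean_r,
                        ceiling=ceiling,
                        corrected_r=corrected,
                    )
                )
    scores = pd.DataFrame(rows)
    if (scores["ceiling"] <= 0).any():
        warnings.warn(
            "participant(s) with non-positive noise ceiling excluded from "
            "ceiling correction",
            stacklevel=2,
        )

    # pairwise paired t-tests on corrected r, BH across the whole family
    pair_rows = []
    for roi in roi_masks:
        sub = scores[scores.roi == roi]
        wide = sub.pivot(index="participant", columns="model", values="corrected_r")
        for a, b in itertools.combinations(models.keys(), 2):
            diff = (wide[a] - wide[b]).dropna().to_numpy()
            if diff.size >= 2 and diff.std(ddof=1) > 0:
                t, p = stats.ttest_1samp(diff, 0.0)
            elif diff.size >= 2:
                t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.nan, np.nan)
            else:
                t, p = np.nan, np.nan
            pair_rows.append(
                dict(model_a=a, model_b=b, roi=roi,
                     mean_diff=float(diff.mean()) if diff.size else np.nan,
                     t=t, p=p)
            )
    pairwise = pd.DataFrame(pair_rows)
    ok = pairwise["p"].notna()
    pairwise["q"] = np.nan
    if ok.any():
        _, q, _, _ = multipletests(pairwise.loc[ok, "p"], alpha=alpha,
                                   method="fdr_bh")
        pairwise.loc[ok, "q"] = q
    return ModelComparisonTable(scores=scores, pairwise=pairwise)


def searchlight_contrast(
    maps_a: np.ndarray, maps_b: np.ndarray, alpha: float = 0.05
) -> GroupResult:
    """Group test of per-center differences between two searchlight maps.

    ``maps_a`` and ``maps_b`` are (n_participants, n_centers) arrays over
    identical sphere centers.  Centers missing (NaN) in either map for a
    participant are excluded pairwise; swapping the maps negates t exactly.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, float))
    maps_b = np.atleast_2d(np.asarray(maps_b, float))
    if maps_a.shape != maps_b.shape:
        raise ValueError("contrast maps must share participants and centers")
    return group_inference(maps_a - maps_b, alpha=alpha)


class CosineReadout(BaseEstimator, RegressorMixin):
    """Linear readout fit by minimizing mean cosine distance to targets.

    Initialized at the least-squares solution, then refined by full-batch
    Adam on the cosine-distance loss until the relative loss change drops
    below ``tol`` (training loss is monitored and decreases monotonically up
    to that tolerance).  Target rows with zero norm carry no cosine
    direction and are excluded from fitting with a warning.

    Attributes
    ----------
    coef_ : (n_targets_dim, n_features) weights; intercept_ : (n_targets_dim,).
    loss_history_ : training cosine-distance per accepted iteration.
    """

    def __init__(
        self,
        lr: float = 0.01,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.lr = lr
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _cosine_loss_grad(pred, T_unit):
        eps = 1e-12
        norms = np.linalg.norm(pred, axis=1, keepdims=True) + eps
        u = pred / norms
        cos = np.einsum("ij,ij->i", u, T_unit)
        loss = float(np.mean(1.0 - cos))
        grad_pred = -(T_unit - cos[:, None] * u) / norms / pred.shape[0]
        return loss, grad_pred

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(y, dtype=float).T).T
        norms = np.linalg.norm(Y, axis=1)
        keep = norms > 0
        if not keep.all():
            warnings.warn(
                f"{int((~keep).sum())} zero-norm target row(s) excluded from "
                "cosine fitting",
                stacklevel=2,
            )
        Xf, Yf = X[keep], Y[keep]
        T_unit = Yf / np.linalg.norm(Yf, axis=1, keepdims=True)

        Xa = np.hstack([Xf, np.ones((Xf.shape[0], 1))])
        W = np.linalg.lstsq(Xa, Yf, rcond=None)[0]  # (p + 1, t)

        m = np.zeros_like(W)
        v = np.zeros_like(W)
        b1, b2, eps = 0.9, 0.999, 1e-8
        loss, _ = self._cosine_loss_grad(Xa @ W, T_unit)
        history = [loss]
        lr = self.lr
        for it in range(1, self.max_iter + 1):
            pred = Xa @ W
            loss, gp = self._cosine_loss_grad(pred, T_unit)
            grad = Xa.T @ gp
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            mh = m / (1 - b1**it)
            vh = v / (1 - b2**it)
            W_new = W - lr * mh / (np.sqrt(vh) + eps)
            new_loss, _ = self._cosine_loss_grad(Xa @ W_new, T_unit)
            if new_loss > history[-1]:  # reject uphill step, shrink rate
                lr *= 0.5
                m[:] = 0.0
                v[:] = 0.0
                if lr < 1e-8:
                    break
                continue
            W = W_new
            rel = (history[-1] - new_loss) / max(abs(history[-1]), 1e-12)
            history.append(new_loss)
            if rel < self.tol:
                break
        self.coef_ = W[:-1].T
        self.intercept_ = W[-1]
        self.loss_history_ = np.asarray(history)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef_.T + self.intercept_

    def score(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
        """Mean cosine similarity between predictions and targets."""
        return float(np.mean(cosine_rows(self.predict(X), np.asarray(y, float))))


def cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity; zero-norm rows give 0."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    out = np.zeros(a.shape[0])
    ok = denom > 0
    out[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / denom[ok]
    return out


@dataclass
class ReadoutResult:
    """Decodability probe outcome: fitted readout vs mean-target floor."""

    test_cosine: float
    floor: float
    readout: CosineReadout


def mean_target_floor(Y_train: np.ndarray, Y_test: np.ndarray) -> float:
    """Cosine similarity achieved by always predicting the mean training target."""
    mean_t = np.asarray(Y_train, float).mean(axis=0)
    preds = np.broadcast_to(mean_t, np.asarray(Y_test).shape)
    return float(np.mean(cosine_rows(preds, Y_test)))


def readout_probe(
    features: np.ndarray,
    targets: np.ndarray,
    train_fraction: float = 0.8,
    seed: int | None = None,
    **readout_kwargs,
) -> ReadoutResult:
    """Can ``targets`` be read out linearly from frozen ``features``?

    Splits stimuli into disjoint train/test sets, fits a
    :class:`CosineReadout`, and reports mean test cosine similarity next to
    the mean-training-target floor (computed on the same test items).
    """
    X = np.asarray(features, float)
    Y = np.asarray(targets, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and targets must share stimuli")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = X.shape[0]
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError("split leaves too few train or test stimuli")
    tr, te = order[:n_train], order[n_train:]
    readout = CosineReadout(random_state=seed, **readout_kwargs).fit(X[tr], Y[tr])
    return ReadoutResult(
        test_cosine=readout.score(X[te], Y[te]),
        floor=mean_target_floor(Y[tr], Y[te]),
        readout=readout,
    )
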