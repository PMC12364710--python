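"""Fractional ridge regression with per-target cross-validated fraction selection.

Fractional ridge reparameterizes ridge regression by the *fraction*
f = ||b_ridge|| / ||b_OLS|| of the coefficient norm retained after shrinkage,
instead of the raw penalty strength gamma.  Working along the SVD of the
design matrix X = U S V', the ridge solution for penalty gamma is

    b(gamma) = V diag(s / (s^2 + gamma)) U' y,

whose norm decreases monotonically in gamma, so for every requested fraction
there is a unique gamma, found here by a vectorized bisection.  Fraction 1
is exactly ordinary least squares (minimum-norm OLS if X is rank deficient).

:class:`FractionalRidgeCV` selects, independently for every target column,
the fraction from a grid (default 0.05 to 1.00 in steps of 0.05, i.e. 20
candidates) that maximizes mean cross-validated Pearson correlation between
predictions and held-out data, then refits on all training data at the
selected fraction.  Ties go to the smallest fraction (most regularization).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .utils import pearson_columns

DEFAULT_FRACTIONS = np.round(np.arange(1, 21) * 0.05, 10)

_RANK_TOL = 1e-10


def _svd_design(X: np.ndarray):
    """Thin SVD of the design with near-zero singular values dropped."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * _RANK_TOL if s.size and s[0] > 0 else np.zeros_like(s, bool)
    rank_deficient = int(keep.sum()) < min(X.shape)
    return U[:, keep], s[keep], Vt[keep], rank_deficient


def _coef_norms(s: np.ndarray, uty: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """||b(gamma)|| for each target; gamma broadcast against targets.

    s: (r,), uty: (r, t), gamma: (..., t) -> norms (..., t)
    """
    shrink = s[:, None] / (s[:, None] ** 2 + gamma[..., None, :])
    return np.sqrt(np.einsum("...rt,rt->...t", shrink**2, uty**2))


def _gamma_for_fractions(
    s: np.ndarray, uty: np.ndarray, fractions: np.ndarray
) -> np.ndarray:
    """Solve for the ridge penalty achieving each requested norm fraction.

    Returns gamma with shape (n_fractions, n_targets).  Bisection on
    log-gamma; the norm ratio is strictly decreasing in gamma, so the root
    is unique.  Targets with zero OLS norm get gamma = 0 (coefficients are
    zero at any penalty).
    """
    fractions = np.asarray(fractions, dtype=float)
    n_frac, n_t = fractions.size, uty.shape[1]
    ols_norm = np.sqrt(((uty / s[:, None]) ** 2).sum(axis=0))
    target = fractions[:, None] * ols_norm[None, :]  # (F, T)

    gamma = np.zeros((n_frac, n_t))
    solve = (ols_norm > 0)[None, :] & (fractions[:, None] < 1.0)
    if not solve.any():
        return gamma

    lo = np.full((n_frac, n_t), np.log(s[-1] ** 2) - 60.0)
    hi = np.full((n_frac, n_t), np.log(s[0] ** 2) + 60.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        norms = _coef_norms(s, uty, np.exp(mid))
        too_big = norms > target  # norm too large -> need more penalty
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    gamma[solve] = np.exp(0.5 * (lo + hi))[solve]
    return gamma


def fractional_ridge_path(
    X: np.ndarray, Y: np.ndarray, fractions: np.ndarray | None = None
) -> np.ndarray:
    """Ridge coefficients achieving each norm fraction, for every target.

    Parameters
    ----------
    X : (n, p) design, assumed column-centred.
    Y : (n, t) targets, assumed centred (intercepts are handled by callers).
    fractions : requested coefficient-norm fractions in (0, 1].

    Returns
    -------
    coefs : (n_fractions, p, t) array; ``coefs[i, :, j]`` has L2 norm equal to
        ``fractions[i]`` times the (minimum-norm) OLS norm of target j.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    if fractions is None:
        fractions = DEFAULT_FRACTIONS
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")

    U, s, Vt, rank_deficient = _svd_design(X)
    if rank_deficient and np.any(fractions == 1.0):
        warnings.warn(
            "design is rank deficient; fraction 1 returns the minimum-norm "
            "least-squares solution",
            stacklevel=2,
        )
    uty = U.T @ Y  # (r, t)
    gamma = _gamma_for_fractions(s, uty, fractions)  # (F, t)
    shrink = s[None, :, None] / (s[None, :, None] ** 2 + gamma[:, None, :])
    c = shrink * uty[None, :, :]  # (F, r, t)
    return np.einsum("pr,frt->fpt", Vt.T, c)


class FractionalRidgeCV(BaseEstimator, RegressorMixin):
    """Multi-target fractional ridge with per-target CV fraction selection.

    Parameters
    ----------
    fractions : array-like or None
        Candidate coefficient-norm fractions in (0, 1]. Default: 0.05 to 1.00
        in increments of 0.05 (20 candidates).
    cv : int
        Number of folds; folds are contiguous blocks of the shuffled training
        order, fixed by ``random_state``.
    random_state : int or None
        Seed for the fold shuffle.

    Attributes
    ----------
    coef_ : (n_targets, n_features) refit weights at each target's best fraction.
    intercept_ : (n_targets,) intercepts (train means; X and Y are centred
        internally and the offset restored at prediction).
    best_fraction_ : (n_targets,) selected fraction per target.
    cv_scores_ : (n_fractions, n_targets) mean held-out Pearson r.
    degenerate_targets_ : boolean mask of targets constant in training, which
        get zero weights and the smallest fraction.
    """

    def __init__(self, fractions=None, cv: int = 5, random_state: int | None = None):
        self.fractions = fractions
        self.cv = cv
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        grid = DEFAULT_FRACTIONS if self.fractions is None else np.asarray(
            self.fractions, dtype=float
        )
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("fractions must be a non-empty 1-D sequence")
        if np.any(grid <= 0) or np.any(grid > 1):
            raise ValueError("fractions must lie in (0, 1]")
        return np.sort(grid)

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(y, dtype=float).T).T
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and y have incompatible first dimensions")
        if n <= self.cv:
            raise ValueError(f"need more than cv={self.cv} training samples, got {n}")
        grid = self._grid()
        n_frac, n_t = grid.size, Y.shape[1]

        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc, Yc = X - x_mean, Y - y_mean

        degenerate = Yc.std(axis=0) == 0.0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} target(s) constant in training; "
                "assigned zero weights and the smallest fraction",
                stacklevel=2,
            )

        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        scores = np.zeros((n_frac, n_t))
        counts = np.zeros((n_frac, n_t))
        for tr, va in folds.split(Xc):
            coefs = fractional_ridge_path(
                Xc[tr] - Xc[tr].mean(axis=0),
                Yc[tr] - Yc[tr].mean(axis=0),
                grid,
            )
            Xva = Xc[va] - Xc[tr].mean(axis=0)
            for i in range(n_frac):
                pred = Xva @ coefs[i]
                r = pearson_columns(pred, Yc[va])
                ok = np.isfinite(r)
                scores[i, ok] += r[ok]
                counts[i, ok] += 1.0
        with np.errstate(invalid="ignore"):
            scores = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)

        # argmax returns the first maximum; grid is ascending, so ties go to
        # the smallest (most regularizing) fraction
        best_idx = np.argmax(scores, axis=0)
        best_idx[degenerate] = 0

        coef = np.zeros((p, n_t))
        for i in np.unique(best_idx):
            cols = np.flatnonzero((best_idx == i) & ~degenerate)
            if cols.size:
                path = fractional_ridge_path(Xc, Yc[:, cols], grid[i : i + 1])
                coef[:, cols] = path[0]

        self.n_features_in_ = p
        self.coef_ = coef.T
        self.intercept_ = y_mean - x_mean @ coef
        self.best_fraction_ = grid[best_idx]
        self.cv_scores_ = scores
        self.degenerate_targets_ = degenerate
        self.grid_ = grid
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def score(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
        """Mean per-target Pearson r between predictions and targets."""
        Y = np.atleast_2d(np.asarray(y, dtype=float).T).T
        r = pearson_columns(self.predict(X), Y)
        return float(np.nanmean(r))
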