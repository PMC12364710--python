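"""Representational similarity analysis: RDMs, subset sampling, searchlights,
noise ceilings and group inference.

The pipeline mirrors the standard large-scale fMRI RSA workflow: single-trial
betas are z-scored per voxel within each scanning session, averaged over each
stimulus's repetitions, and pattern dissimilarity between stimulus pairs is
1 - Pearson r.  Because full RDMs over ~10,000 stimuli are impractical,
stimuli are partitioned into disjoint random subsets of 100; brain and model
RDMs are built and correlated per subset and the correlations averaged over
subsets (raw r scale).  The searchlight repeats this inside a sphere of
radius 6 voxels around every in-brain voxel, keeping spheres with strictly
more than half of their lattice points inside the brain.  The per-participant
noise ceiling is the correlation between a participant's RDM on the shared
stimuli and the element-wise mean RDM of the other participants.  Group maps
are one-sample two-tailed t-tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .utils import pearson


@dataclass
class AvgResponses:
    """Per-stimulus average response patterns (one row per stimulus)."""

    values: np.ndarray  # (n_stimuli, p_voxels)
    stimulus_ids: np.ndarray

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]


@dataclass
class RDM:
    """Symmetric Pearson-correlation-distance matrix over stimuli."""

    values: np.ndarray  # (n, n), entries in [0, 2], zero diagonal
    stimulus_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class SphereIndex:
    """A searchlight sphere: center coordinate plus in-mask member voxels."""

    center: tuple[int, int, int]
    members: np.ndarray  # indices into the in-brain voxel axis


@dataclass
class GroupResult:
    """Per-location group statistics with BH-FDR control."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray
    alpha: float


# ---------------------------------------------------------------------------
# preprocessing and RDMs
# ---------------------------------------------------------------------------

def preprocess_betas(trials, required_reps: int | None = None) -> AvgResponses:
    """Z-score betas within session per voxel, then average repetitions.

    Stimuli with fewer than the full repetition count (the maximum observed,
    or ``required_reps`` if given) are dropped.  A constant voxel within a
    session has an undefined z-score; it is set to 0 with a warning.  A
    session containing a single trial is an error.
    """
    betas = np.asarray(trials.betas, dtype=float)
    z = np.empty_like(betas)
    n_flagged = 0
    for s in np.unique(trials.session_id):
        rows = trials.session_id == s
        if rows.sum() < 2:
            raise ValueError(
                f"session {s} has a single trial; within-session z-scoring "
                "is undefined"
            )
        block = betas[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        const = sd == 0.0
        n_flagged += int(const.sum())
        sd = np.where(const, 1.0, sd)
        zb = (block - mu) / sd
        zb[:, const] = 0.0
        z[rows] = zb
    if n_flagged:
        warnings.warn(
            f"{n_flagged} constant voxel/session block(s); z-scores set to 0",
            stacklevel=2,
        )

    ids, counts = np.unique(trials.stimulus_id, return_counts=True)
    full = counts.max() if required_reps is None else required_reps
    keep = ids[counts == full]
    values = np.empty((keep.size, betas.shape[1]))
    for i, sid in enumerate(keep):
        values[i] = z[trials.stimulus_id == sid].mean(axis=0)
    return AvgResponses(values=values, stimulus_ids=keep)


def compute_rdm(responses: AvgResponses, subset=None) -> RDM:
    """Pairwise Pearson correlation distances (1 - r) between patterns.

    Zero-variance patterns have undefined correlations; their off-diagonal
    distances are set to the neutral value 1 with a warning.
    """
    values, ids = responses.values, responses.stimulus_ids
    if subset is not None:
        subset = np.asarray(subset)
        pos = {sid: i for i, sid in enumerate(ids)}
        idx = np.array([pos[s] for s in subset])
        values, ids = values[idx], ids[idx]
    n, p = values.shape
    if n < 3:
        raise ValueError("need at least 3 stimuli for an RDM")
    if p < 2:
        raise ValueError("need at least 2 voxels for pattern correlations")

    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    degenerate = norms == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance pattern(s); their "
            "distances set to the neutral value 1",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, norms)
    r = (centred @ centred.T) / np.outer(safe, safe)
    dist = 1.0 - r
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, 2.0)
    return RDM(values=dist, stimulus_ids=ids)


def rdm_correlation(a: RDM, b: RDM) -> float:
    """Pearson r between the upper-triangular vectors of two RDMs."""
    if a.n != b.n or np.any(a.stimulus_ids != b.stimulus_ids):
        raise ValueError("RDMs must share stimulus ids in the same order")
    return pearson(a.upper_triangle(), b.upper_triangle())


# ---------------------------------------------------------------------------
# subset-sampled RSA
# ---------------------------------------------------------------------------

def partition_stimuli(
    stimulus_ids: np.ndarray, subset_size: int, seed=None
) -> list[np.ndarray]:
    """Disjoint random subsets of exactly ``subset_size`` stimuli.

    Stimuli are drawn without replacement until the pool is exhausted; a
    final incomplete remainder is discarded, so 10,000 stimuli at subset
    size 100 give 100 splits, 6,234 give 62 and 5,445 give 54.
    """
    n = len(stimulus_ids)
    if subset_size < 3:
        raise ValueError("subset_size must be >= 3")
    if n < subset_size:
        raise ValueError(f"{n} stimuli cannot fill one subset of {subset_size}")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.Generator) else np.random.SeedSequence(seed)
    )
    order = rng.permutation(n)
    n_splits = n // subset_size
    return [order[i * subset_size : (i + 1) * subset_size] for i in range(n_splits)]


def _model_rdm_for_subset(model, responses: AvgResponses, idx: np.ndarray) -> RDM:
    """Model RDM restricted to the subset ``idx`` of the response stimuli.

    ``model`` may be a full RDM over the same stimuli, or a feature matrix
    (n_stimuli x q) aligned with the response stimulus order.
    """
    sub_ids = responses.stimulus_ids[idx]
    if isinstance(model, RDM):
        pos = {sid: i for i, sid in enumerate(model.stimulus_ids)}
        rows = np.array([pos[s] for s in sub_ids])
        return RDM(
            values=model.values[np.ix_(rows, rows)], stimulus_ids=sub_ids
        )
    features = np.asarray(model, dtype=float)
    if features.shape[0] != responses.n_stimuli:
        raise ValueError("feature matrix must have one row per stimulus")
    return compute_rdm(AvgResponses(values=features[idx], stimulus_ids=sub_ids))


@dataclass
class SampledRSAResult:
    mean_r: float
    n_splits: int
    split_r: np.ndarray


def sampled_rsa(
    responses: AvgResponses,
    model,
    subset_size: int = 100,
    seed=None,
    partition: list[np.ndarray] | None = None,
    voxels: np.ndarray | None = None,
) -> SampledRSAResult:
    """Subset-sampled RSA between brain responses and a model.

    The stimuli are partitioned into disjoint random subsets of exactly
    ``subset_size``; per subset, brain and model RDMs are computed and their
    upper triangles correlated; the mean over subsets (raw r scale) is
    returned.  Pass ``partition`` to reuse one partition across spheres and
    models; pass ``voxels`` to restrict patterns to a voxel subset.
    """
    if partition is None:
        partition = partition_stimuli(responses.stimulus_ids, subset_size, seed)
    values = responses.values if voxels is None else responses.values[:, voxels]
    rs = []
    for idx in partition:
        brain = compute_rdm(
            AvgResponses(values=values[idx], stimulus_ids=responses.stimulus_ids[idx])
        )
        model_rdm = _model_rdm_for_subset(model, responses, idx)
        rs.append(rdm_correlation(brain, model_rdm))
    rs = np.asarray(rs)
    return SampledRSAResult(
        mean_r=float(np.nanmean(rs)), n_splits=len(partition), split_r=rs
    )


# ---------------------------------------------------------------------------
# searchlight
# ---------------------------------------------------------------------------

def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets within Euclidean distance ``radius``."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def searchlight_spheres(
    mask: np.ndarray, radius: float = 6, min_inside_fraction: float = 0.5
) -> list[SphereIndex]:
    """One sphere per in-brain voxel, pruned by in-mask coverage.

    A sphere is kept only if strictly more than ``min_inside_fraction`` of
    its lattice points fall inside the mask (points beyond the volume bounds
    count as outside); out-of-mask points are excluded from the members.
    Member indices refer to the flat in-brain voxel axis (C order), matching
    response matrices built from the same mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(radius)
    vol_index = np.full(mask.shape, -1, dtype=int)
    vol_index[mask] = np.arange(mask.sum())

    spheres = []
    for center in np.argwhere(mask):
        pts = center[None, :] + offsets
        inb = np.all((pts >= 0) & (pts < mask.shape), axis=1)
        members = np.full(pts.shape[0], -1, dtype=int)
        members[inb] = vol_index[tuple(pts[inb].T)]
        members = members[members >= 0]
        if members.size / offsets.shape[0] > min_inside_fraction:
            spheres.append(SphereIndex(center=tuple(center), members=members))
    return spheres


def searchlight_rsa(
    responses: AvgResponses,
    model,
    spheres: list[SphereIndex],
    subset_size: int = 100,
    seed=None,
) -> np.ndarray:
    """Subset-sampled RSA inside every searchlight sphere.

    One stimulus partition is drawn and reused across all spheres (and should
    be reused across models being contrasted), so every location and model
    sees identical stimulus subsets.  Returns the per-center mean r, NaN for
    spheres with fewer than 2 member voxels.
    """
    partition = partition_stimuli(responses.stimulus_ids, subset_size, seed)
    # model RDMs per subset are sphere-independent; compute once
    model_ut = [
        _model_rdm_for_subset(model, responses, idx).upper_triangle()
        for idx in partition
    ]
    out = np.full(len(spheres), np.nan)
    for si, sph in enumerate(spheres):
        if sph.members.size < 2:
            continue
        rs = []
        for idx, m_ut in zip(partition, model_ut):
            brain = compute_rdm(
                AvgResponses(
                    values=responses.values[np.ix_(idx, sph.members)],
                    stimulus_ids=responses.stimulus_ids[idx],
                )
            )
            rs.append(pearson(brain.upper_triangle(), m_ut))
        out[si] = np.nanmean(rs)
    return out


def statmap_to_volume(
    spheres: list[SphereIndex], values: np.ndarray, grid_shape
) -> np.ndarray:
    """Scatter per-sphere statistics back into a 3-D volume (NaN elsewhere)."""
    vol = np.full(tuple(grid_shape), np.nan)
    for sph, v in zip(spheres, values):
        vol[sph.center] = v
    return vol


# ---------------------------------------------------------------------------
# noise ceiling and group inference
# ---------------------------------------------------------------------------

def rsa_noise_ceiling(rdms: list[RDM]) -> np.ndarray:
    """Leave-one-out RDM noise ceiling per participant.

    Each participant's ceiling is the Pearson r between their shared-stimulus
    RDM (upper triangle) and the element-wise mean of the other participants'
    RDMs: a model reaching it predicts the participant as well as the average
    of the remaining humans does.
    """
    if len(rdms) < 3:
        raise ValueError("need at least 3 participants for a noise ceiling")
    ids = rdms[0].stimulus_ids
    for r in rdms[1:]:
        if np.any(r.stimulus_ids != ids):
            raise ValueError("all RDMs must share stimulus ids in order")
    uts = np.stack([r.upper_triangle() for r in rdms])
    n = uts.shape[0]
    return np.array(
        [
            pearson(uts[i], uts[np.arange(n) != i].mean(axis=0))
            for i in range(n)
        ]
    )


def group_inference(
    values: np.ndarray, alpha: float = 0.05, null: float = 0.0
) -> GroupResult:
    """One-sample two-tailed t-tests across participants with BH-FDR.

    ``values`` is (n_participants, n_locations); participants missing a
    location (NaN) are excluded pairwise.  Locations with zero variance
    across participants and a mean different from the null have undefined
    p-values: they are flagged (NaN) and excluded from the FDR family with a
    warning.  Zero variance *at* the null yields t = 0, p = 1.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    n_loc = values.shape[1]
    t = np.full(n_loc, np.nan)
    p = np.full(n_loc, np.nan)
    n_degenerate = 0
    for j in range(n_loc):
        col = values[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2:
            continue
        if col.std(ddof=1) == 0.0:
            if np.isclose(col.mean(), null):
                t[j], p[j] = 0.0, 1.0
            else:
                n_degenerate += 1
            continue
        res = stats.ttest_1samp(col, null)
        t[j], p[j] = res.statistic, res.pvalue
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} location(s) with zero variance across "
            "participants; excluded from the FDR family",
            stacklevel=2,
        )

    q = np.full(n_loc, np.nan)
    sig = np.zeros(n_loc, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
        sig[ok] = q_ok <= alpha
    return GroupResult(t=t, p=p, q=q, sig=sig, alpha=alpha)
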