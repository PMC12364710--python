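"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a large-scale natural-scenes fMRI study: each scene
has a low-dimensional latent content vector; a fixed linear map sends the
latent into caption-embedding space (the "true" scene embedding); several
captions per scene are the true embedding plus inter-rater jitter; binary
category labels are thresholded linear readouts of the latent (so categories
are linearly decodable from embeddings, but embeddings are not recoverable
from categories); voxels on a 3-D grid respond linearly to the true
embedding through region-specific ground-truth weights, with per-session
gain/offset nuisances and Gaussian noise, three repetitions per stimulus.
Ground truth (latents, maps, weights) is retained for parameter-recovery
tests.

All generators are deterministic given their seed: one global seed is
expanded into per-component child streams via ``numpy.random.SeedSequence``
spawning in a fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .utils import as_seed_sequence, rng_children


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TaggedWords:
    """Word-level embedding surrogates for one caption, with POS tags."""

    vectors: np.ndarray  # (n_words, d_w)
    tags: list[str]

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.tags):
            raise ValueError("one tag per word vector required")


@dataclass
class SceneSet:
    """Stimuli with ground-truth latents, caption embeddings and labels.

    ``mean_embedding`` is the arithmetic mean over the caption axis; the
    ``true_embedding`` (latent pushed through the fixed map) is kept for
    recovery tests and never exposed to estimators in a real analysis.
    """

    scene_ids: np.ndarray  # (n,) str
    latent: np.ndarray  # (n, k)
    embedding_map: np.ndarray  # (d, k) latent -> embedding
    true_embedding: np.ndarray  # (n, d)
    caption_embeddings: np.ndarray  # (n, n_captions, d)
    mean_embedding: np.ndarray  # (n, d)
    word_vectors: list[list[TaggedWords]]  # per scene, per caption
    categories: np.ndarray  # (n, m) in {0, 1}
    neutral_word_vector: np.ndarray = field(default=None)  # (d_w,)

    @property
    def n_scenes(self) -> int:
        return len(self.scene_ids)

    @property
    def embedding_dim(self) -> int:
        return self.true_embedding.shape[1]

    def select(self, index: np.ndarray) -> "SceneSet":
        """Subset of scenes by positional index, preserving order."""
        index = np.asarray(index)
        return replace(
            self,
            scene_ids=self.scene_ids[index],
            latent=self.latent[index],
            true_embedding=self.true_embedding[index],
            caption_embeddings=self.caption_embeddings[index],
            mean_embedding=self.mean_embedding[index],
            word_vectors=[self.word_vectors[i] for i in index],
            categories=self.categories[index],
        )


@dataclass
class Region:
    """A rectangular voxel block selective for a subset of embedding dims."""

    name: str
    block: tuple[slice, slice, slice]
    embedding_dims: np.ndarray


@dataclass
class BrainModel:
    """Ground-truth generative model of one participant's voxel grid."""

    grid_shape: tuple[int, int, int]
    in_brain: np.ndarray  # (x, y, z) bool
    region_id: np.ndarray  # (x, y, z) int, -1 = unassigned
    regions: list[Region]
    W_true: np.ndarray  # (p_voxels, d); rows ordered by flat in-brain index
    noise_sd: np.ndarray  # (p_voxels,)

    @property
    def n_voxels(self) -> int:
        return int(self.in_brain.sum())

    @property
    def voxel_coords(self) -> np.ndarray:
        """(p, 3) grid coordinates of in-brain voxels, C-order."""
        return np.argwhere(self.in_brain)

    def region_voxel_mask(self, name: str) -> np.ndarray:
        """Boolean mask over the in-brain voxel axis for one region."""
        rid = [r.name for r in self.regions].index(name)
        return self.region_id[self.in_brain] == rid

    def noiseless_responses(self, embeddings: np.ndarray) -> np.ndarray:
        """(n_stimuli, p) responses W_true @ e with no noise or nuisances."""
        return embeddings @ self.W_true.T


@dataclass
class TrialResponses:
    """Trial-level voxel betas with session/repetition/stimulus bookkeeping."""

    betas: np.ndarray  # (n_trials, p)
    session_id: np.ndarray  # (n_trials,) int
    stimulus_id: np.ndarray  # (n_trials,) str
    repetition: np.ndarray  # (n_trials,) int

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]


@dataclass
class Dictionary:
    """Caption look-up dictionary: targets (one per scene) plus distractors."""

    entry_ids: np.ndarray  # (n_entries,) str
    texts: np.ndarray  # (n_entries,) synthetic tokens
    embeddings: np.ndarray  # (n_entries, d)
    target_rows: dict[str, int]  # scene id -> row of its paraphrase entry

    def __post_init__(self):
        if len(np.unique(self.entry_ids)) != len(self.entry_ids):
            raise ValueError("entry_ids must be unique")

    @property
    def n_entries(self) -> int:
        return len(self.entry_ids)


@dataclass
class Participant:
    brain: BrainModel
    trials: TrialResponses
    scene_ids: np.ndarray  # stimuli this participant saw


@dataclass
class Cohort:
    scenes: SceneSet  # full scene pool
    participants: list[Participant]
    shared_ids: np.ndarray
    unique_ids: list[np.ndarray]  # per participant

    @property
    def n_participants(self) -> int:
        return len(self.participants)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_scenes(
    n_scenes: int,
    k: int | None = None,
    d: int = 32,
    n_captions: int = 5,
    caption_noise: float = 0.3,
    m: int = 8,
    d_w: int | None = None,
    n_nouns: int = 3,
    n_verbs: int = 2,
    word_noise: float = 0.3,
    category_rate: float = 0.3,
    seed: int | None = None,
) -> SceneSet:
    """Generate a scene set with captions, tagged words and category labels.

    The true embedding of scene i is ``A @ latent_i`` for a fixed random map
    A; caption j adds iid Gaussian jitter of sd ``caption_noise`` (inter-rater
    variability).  Category c fires when a fixed random readout of the latent
    exceeds its ``1 - category_rate`` population quantile.  Noun word vectors
    are a fixed linear image of the latent plus noise (they carry scene
    content); verb word vectors are pure noise.

    By default the latent is full rank (``k = d``), so ground-truth voxel
    weights are identifiable from embeddings and every downstream estimator
    can recover its generative parameters in the low-noise limit; pass
    ``k < d`` to study low-rank scene structure (then only the projection of
    the weights onto the latent image is recoverable).
    """
    if k is None:
        k = d
    if n_scenes <= 0 or k <= 0 or d <= 0 or m <= 0:
        raise ValueError("dimensions must be positive")
    if n_captions < 2:
        raise ValueError("need at least 2 captions per scene")
    if caption_noise < 0:
        raise ValueError("caption_noise must be non-negative")
    if k > d:
        raise ValueError("latent dimension k may not exceed embedding dim d")
    d_w = d if d_w is None else d_w

    rng_map, rng_lat, rng_cap, rng_catg, rng_word = rng_children(seed, 5)

    # semi-orthogonal map: embedding dims are isotropic, so disjoint
    # embedding subspaces carry independent scene information
    A = np.linalg.qr(rng_map.normal(size=(d, k)))[0]
    latent = rng_lat.normal(size=(n_scenes, k))
    true_emb = latent @ A.T
    captions = true_emb[:, None, :] + caption_noise * rng_cap.normal(
        size=(n_scenes, n_captions, d)
    )
    mean_emb = captions.mean(axis=1)

    C = rng_catg.normal(size=(m, k))
    score = latent @ C.T
    thresh = np.quantile(score, 1.0 - category_rate, axis=0)
    categories = (score > thresh).astype(np.uint8)

    B_noun = rng_word.normal(size=(d_w, k)) / np.sqrt(k)
    word_vectors: list[list[TaggedWords]] = []
    for i in range(n_scenes):
        per_caption = []
        for _ in range(n_captions):
            nouns = latent[i] @ B_noun.T + word_noise * rng_word.normal(
                size=(n_nouns, d_w)
            )
            verbs = rng_word.normal(size=(n_verbs, d_w))
            per_caption.append(
                TaggedWords(
                    vectors=np.vstack([nouns, verbs]),
                    tags=["noun"] * n_nouns + ["verb"] * n_verbs,
                )
            )
        word_vectors.append(per_caption)

    width = max(4, len(str(n_scenes - 1)))
    ids = np.array([f"scene{i:0{width}d}" for i in range(n_scenes)])
    return SceneSet(
        scene_ids=ids,
        latent=latent,
        embedding_map=A,
        true_embedding=true_emb,
        caption_embeddings=captions,
        mean_embedding=mean_emb,
        word_vectors=word_vectors,
        categories=categories,
        neutral_word_vector=np.zeros(d_w),
    )


def split_grid_regions(
    grid_shape: tuple[int, int, int], n_regions: int, d: int
) -> list[Region]:
    """Partition the grid into slabs along x, each selective for a disjoint
    contiguous block of embedding dimensions."""
    nx = grid_shape[0]
    if n_regions > nx or n_regions > d:
        raise ValueError("more regions than grid slabs or embedding dims")
    x_edges = np.linspace(0, nx, n_regions + 1).astype(int)
    d_edges = np.linspace(0, d, n_regions + 1).astype(int)
    return [
        Region(
            name=f"region{r}",
            block=(slice(x_edges[r], x_edges[r + 1]), slice(None), slice(None)),
            embedding_dims=np.arange(d_edges[r], d_edges[r + 1]),
        )
        for r in range(n_regions)
    ]


def build_brain_model(
    grid_shape: tuple[int, int, int],
    regions: list[Region],
    d: int,
    noise_sd: float | np.ndarray = 1.0,
    leakage: float = 0.0,
    in_brain: np.ndarray | None = None,
    seed: int | None = None,
) -> BrainModel:
    """Build a voxel grid whose regions read out disjoint embedding subspaces.

    Voxels in region r have ground-truth weight rows supported on that
    region's embedding dimensions, plus isotropic ``leakage`` on all
    dimensions.  In-brain voxels in no region have zero weights (pure-noise
    voxels); rows outside ``in_brain`` are zero by construction.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid_shape entries must be positive")
    in_brain = (
        np.ones(grid_shape, dtype=bool) if in_brain is None else in_brain.astype(bool)
    )
    if in_brain.shape != grid_shape:
        raise ValueError("in_brain mask shape must match grid_shape")

    region_id = np.full(grid_shape, -1, dtype=int)
    for rid, reg in enumerate(regions):
        block = np.zeros(grid_shape, dtype=bool)
        block[reg.block] = True
        block &= in_brain
        if np.any(region_id[block] != -1):
            raise ValueError(f"region {reg.name!r} overlaps a previous region")
        if np.any(np.asarray(reg.embedding_dims) >= d):
            raise ValueError(f"region {reg.name!r} references embedding dims >= d")
        region_id[block] = rid
    region_id[~in_brain] = -1

    rng = np.random.default_rng(as_seed_sequence(seed))
    p = int(in_brain.sum())
    W = np.zeros((p, d))
    flat_region = region_id[in_brain]
    for rid, reg in enumerate(regions):
        rows = np.flatnonzero(flat_region == rid)
        dims = np.asarray(reg.embedding_dims)
        W[np.ix_(rows, dims)] = rng.normal(size=(rows.size, dims.size)) / np.sqrt(
            dims.size
        )
        if leakage > 0:
            W[rows] += leakage * rng.normal(size=(rows.size, d)) / np.sqrt(d)

    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (p,)).copy()
    if np.any(noise < 0):
        raise ValueError("noise_sd must be non-negative")
    return BrainModel(
        grid_shape=grid_shape,
        in_brain=in_brain,
        region_id=region_id,
        regions=list(regions),
        W_true=W,
        noise_sd=noise,
    )


def noise_sd_for_snr(brain: BrainModel, scenes: SceneSet, snr: float) -> np.ndarray:
    """Per-voxel noise sd giving signal-variance / noise-variance = ``snr``.

    Voxels with no signal (zero weight rows) get the mean signal sd of the
    responsive voxels, so they behave as pure-noise voxels rather than
    degenerate constants.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signal = brain.noiseless_responses(scenes.true_embedding)
    sig_sd = signal.std(axis=0)
    floor = sig_sd[sig_sd > 0].mean() if np.any(sig_sd > 0) else 1.0
    sig_sd = np.where(sig_sd > 0, sig_sd, floor)
    return sig_sd / np.sqrt(snr)


def simulate_trial_responses(
    brain: BrainModel,
    scenes: SceneSet,
    n_reps: int = 3,
    n_sessions: int = 1,
    gain_range: tuple[float, float] = (1.0, 1.0),
    offset_range: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> TrialResponses:
    """Simulate trial-level betas: gain_s * (W_true @ e_i) + offset_s + noise.

    Each scene is presented ``n_reps`` times; trials are shuffled and split
    into ``n_sessions`` contiguous blocks, each with its own multiplicative
    gain and additive offset (scanner-state nuisances that within-session
    z-scoring removes).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if scenes.embedding_dim != brain.W_true.shape[1]:
        raise ValueError(
            f"embedding dim {scenes.embedding_dim} does not match "
            f"brain weights ({brain.W_true.shape[1]})"
        )
    n_trials = scenes.n_scenes * n_reps
    if n_trials < 2 * n_sessions:
        raise ValueError("need at least 2 trials per session")

    rng_order, rng_sess, rng_noise = rng_children(seed, 3)
    stim_idx = np.repeat(np.arange(scenes.n_scenes), n_reps)
    repetition = np.tile(np.arange(n_reps), scenes.n_scenes)
    order = rng_order.permutation(n_trials)
    stim_idx, repetition = stim_idx[order], repetition[order]

    edges = np.linspace(0, n_trials, n_sessions + 1).astype(int)
    session = np.empty(n_trials, dtype=int)
    for s in range(n_sessions):
        session[edges[s] : edges[s + 1]] = s
    gains = rng_sess.uniform(*gain_range, size=n_sessions)
    offsets = rng_sess.uniform(*offset_range, size=n_sessions)

    signal = brain.noiseless_responses(scenes.true_embedding)  # (n_scenes, p)
    betas = gains[session, None] * signal[stim_idx] + offsets[session, None]
    betas = betas + brain.noise_sd[None, :] * rng_noise.normal(size=betas.shape)
    return TrialResponses(
        betas=betas,
        session_id=session,
        stimulus_id=scenes.scene_ids[stim_idx],
        repetition=repetition,
    )


def build_caption_dictionary(
    scenes: SceneSet,
    n_distractors: int = 0,
    distractor_spread: float = 1.0,
    paraphrase_jitter: float = 0.0,
    seed: int | None = None,
) -> Dictionary:
    """Look-up dictionary: one paraphrase entry per scene plus distractors.

    The paraphrase entry for scene i is its true embedding plus optional
    jitter.  Distractors are drawn from the same generative embedding space
    (a fresh latent through the scene map) plus isotropic off-manifold spread.
    Entry order is targets first, then distractors, deterministic given seed.
    """
    if n_distractors < 0:
        raise ValueError("n_distractors must be >= 0")
    rng = np.random.default_rng(as_seed_sequence(seed))
    d = scenes.embedding_dim
    k = scenes.latent.shape[1]

    targets = scenes.true_embedding + paraphrase_jitter * rng.normal(
        size=(scenes.n_scenes, d)
    )
    z = rng.normal(size=(n_distractors, k))
    distractors = z @ scenes.embedding_map.T + distractor_spread * rng.normal(
        size=(n_distractors, d)
    )

    ids = np.concatenate(
        [
            np.char.add("cap:", scenes.scene_ids),
            np.array([f"distractor{i:06d}" for i in range(n_distractors)]),
        ]
    )
    texts = np.char.add("synthetic-caption ", ids)
    return Dictionary(
        entry_ids=ids,
        texts=texts,
        embeddings=np.vstack([targets, distractors]),
        target_rows={sid: i for i, sid in enumerate(scenes.scene_ids)},
    )


def make_cohort(
    n_participants: int = 8,
    n_shared: int = 100,
    n_unique: int = 100,
    participant_weight_jitter: float = 0.0,
    grid_shape: tuple[int, int, int] = (12, 8, 4),
    n_regions: int = 2,
    k: int | None = None,
    d: int = 32,
    n_captions: int = 5,
    caption_noise: float = 0.3,
    m: int = 8,
    noise_sd: float | None = 1.0,
    snr: float | None = None,
    leakage: float = 0.0,
    n_reps: int = 3,
    n_sessions: int = 2,
    gain_range: tuple[float, float] = (1.0, 1.0),
    offset_range: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> Cohort:
    """Generate a multi-participant cohort over a shared scene pool.

    All participants share grid geometry, region layout and the shared
    stimuli; each additionally sees a mutually exclusive unique set.  Their
    ground-truth weights are the group template plus iid Gaussian jitter of
    sd ``participant_weight_jitter`` (individual differences).  If ``snr``
    is given it overrides ``noise_sd`` via :func:`noise_sd_for_snr`.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    n_pool = n_shared + n_participants * n_unique

    seeds = as_seed_sequence(seed).spawn(2 + 2 * n_participants)
    scenes = make_scenes(
        n_pool,
        k=k,
        d=d,
        n_captions=n_captions,
        caption_noise=caption_noise,
        m=m,
        seed=seeds[0],
    )
    regions = split_grid_regions(grid_shape, n_regions, d)
    template = build_brain_model(
        grid_shape, regions, d=d, noise_sd=noise_sd or 0.0, leakage=leakage,
        seed=seeds[1],
    )

    shared_idx = np.arange(n_shared)
    shared_ids = scenes.scene_ids[shared_idx]
    participants: list[Participant] = []
    unique_ids: list[np.ndarray] = []
    for i in range(n_participants):
        rng_w = np.random.default_rng(seeds[2 + 2 * i])
        W = template.W_true + participant_weight_jitter * rng_w.normal(
            size=template.W_true.shape
        )
        brain = replace(template, W_true=W)
        own_idx = np.concatenate(
            [
                shared_idx,
                n_shared + i * n_unique + np.arange(n_unique),
            ]
        )
        own_scenes = scenes.select(own_idx)
        if snr is not None:
            brain = replace(brain, noise_sd=noise_sd_for_snr(brain, own_scenes, snr))
        trials = simulate_trial_responses(
            brain,
            own_scenes,
            n_reps=n_reps,
            n_sessions=n_sessions,
            gain_range=gain_range,
            offset_range=offset_range,
            seed=seeds[3 + 2 * i],
        )
        participants.append(
            Participant(brain=brain, trials=trials, scene_ids=own_scenes.scene_ids)
        )
        unique_ids.append(scenes.scene_ids[n_shared + i * n_unique :][:n_unique])
    return Cohort(
        scenes=scenes,
        participants=participants,
        shared_ids=shared_ids,
        unique_ids=unique_ids,
    )
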