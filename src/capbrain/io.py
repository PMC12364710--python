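"""File interfaces: HDF5 cohorts, CSV scene tables, NIfTI volumes, configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .syndata import (
    BrainModel,
    Cohort,
    Dictionary,
    Participant,
    Region,
    SceneSet,
    TrialResponses,
)


def save_cohort(path, cohort: Cohort) -> None:
    """Write a cohort (betas, indices, ground truth) to HDF5.

    Word-level vectors are regenerable from the generator seed and are not
    serialized; everything the analysis consumes is.
    """
    s = cohort.scenes
    with h5py.File(path, "w") as f:
        g = f.create_group("scenes")
        str_dt = h5py.string_dtype()
        g.create_dataset("scene_ids", data=s.scene_ids.astype(object), dtype=str_dt)
        for name in ("latent", "embedding_map", "true_embedding",
                     "caption_embeddings", "mean_embedding", "categories"):
            g.create_dataset(name, data=getattr(s, name))
        f.create_dataset("shared_ids", data=cohort.shared_ids.astype(object),
                         dtype=str_dt)
        for i, part in enumerate(cohort.participants):
            gp = f.create_group(f"participant{i}")
            gp.create_dataset("scene_ids", data=part.scene_ids.astype(object),
                              dtype=str_dt)
            gp.create_dataset("unique_ids",
                              data=cohort.unique_ids[i].astype(object),
                              dtype=str_dt)
            gb = gp.create_group("brain")
            gb.attrs["grid_shape"] = part.brain.grid_shape
            gb.create_dataset("in_brain", data=part.brain.in_brain)
            gb.create_dataset("region_id", data=part.brain.region_id)
            gb.create_dataset("W_true", data=part.brain.W_true)
            gb.create_dataset("noise_sd", data=part.brain.noise_sd)
            for r in part.brain.regions:
                gr = gb.create_group(f"region/{r.name}")
                gr.attrs["block"] = [
                    (sl.start or 0, sl.stop if sl.stop is not None else -1)
                    for sl in r.block
                ]
                gr.create_dataset("embedding_dims", data=np.asarray(r.embedding_dims))
            gt = gp.create_group("trials")
            gt.create_dataset("betas", data=part.trials.betas)
            gt.create_dataset("session_id", data=part.trials.session_id)
            gt.create_dataset("stimulus_id",
                              data=part.trials.stimulus_id.astype(object),
                              dtype=str_dt)
            gt.create_dataset("repetition", data=part.trials.repetition)


def load_cohort(path) -> Cohort:
    """Read a cohort written by :func:`save_cohort` (word vectors omitted)."""
    def _str(ds):
        return np.array([x.decode() if isinstance(x, bytes) else x for x in ds[()]])

    with h5py.File(path, "r") as f:
        g = f["scenes"]
        scenes = SceneSet(
            scene_ids=_str(g["scene_ids"]),
            latent=g["latent"][()],
            embedding_map=g["embedding_map"][()],
            true_embedding=g["true_embedding"][()],
            caption_embeddings=g["caption_embeddings"][()],
            mean_embedding=g["mean_embedding"][()],
            word_vectors=[],
            categories=g["categories"][()],
        )
        participants, unique_ids = [], []
        i = 0
        while f"participant{i}" in f:
            gp = f[f"participant{i}"]
            gb = gp["brain"]
            grid_shape = tuple(int(x) for x in gb.attrs["grid_shape"])
            regions = []
            if "region" in gb:
                for name in gb["region"]:
                    gr = gb[f"region/{name}"]
                    block = tuple(
                        slice(int(a), None if b == -1 else int(b))
                        for a, b in gr.attrs["block"]
                    )
                    regions.append(Region(name=name, block=block,
                                          embedding_dims=gr["embedding_dims"][()]))
            brain = BrainModel(
                grid_shape=grid_shape,
                in_brain=gb["in_brain"][()].astype(bool),
                region_id=gb["region_id"][()],
                regions=regions,
                W_true=gb["W_true"][()],
                noise_sd=gb["noise_sd"][()],
            )
            gt = gp["trials"]
            trials = TrialResponses(
                betas=gt["betas"][()],
                session_id=gt["session_id"][()],
                stimulus_id=_str(gt["stimulus_id"]),
                repetition=gt["repetition"][()],
            )
            participants.append(
                Participant(brain=brain, trials=trials,
                            scene_ids=_str(gp["scene_ids"]))
            )
            unique_ids.append(_str(gp["unique_ids"]))
            i += 1
        shared_ids = _str(f["shared_ids"])
    return Cohort(scenes=scenes, participants=participants,
                  shared_ids=shared_ids, unique_ids=unique_ids)


def scenes_to_csv(path, scenes: SceneSet) -> None:
    """Tabular scene summary: ids, category labels, latent coordinates."""
    df = pd.DataFrame({"scene_id": scenes.scene_ids})
    for j in range(scenes.categories.shape[1]):
        df[f"category{j}"] = scenes.categories[:, j]
    for j in range(scenes.latent.shape[1]):
        df[f"latent{j}"] = scenes.latent[:, j]
    df.to_csv(path, index=False)


def save_dictionary(path, dictionary: Dictionary, texts_csv=None) -> None:
    """Dictionary to HDF5 (ids + embeddings) with optional sidecar text CSV."""
    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype()
        f.create_dataset("entry_ids", data=dictionary.entry_ids.astype(object),
                         dtype=str_dt)
        f.create_dataset("embeddings", data=dictionary.embeddings)
        g = f.create_group("target_rows")
        g.create_dataset("scene_ids",
                         data=np.array(list(dictionary.target_rows)).astype(object),
                         dtype=str_dt)
        g.create_dataset("rows",
                         data=np.array(list(dictionary.target_rows.values())))
    if texts_csv is not None:
        pd.DataFrame(
            {"entry_id": dictionary.entry_ids, "text": dictionary.texts}
        ).to_csv(texts_csv, index=False)


def volume_to_nifti(path, volume: np.ndarray, voxel_size_mm: float = 1.8) -> None:
    """Write a 3-D volume as NIfTI with an isotropic diagonal affine."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def averaged_volumes_to_nifti(path, responses, brain: BrainModel,
                              voxel_size_mm: float = 1.8) -> None:
    """Per-stimulus averaged responses as a 4-D NIfTI over the brain grid."""
    values = np.asarray(getattr(responses, "values", responses), float)
    vols = np.full(brain.grid_shape + (values.shape[0],), np.nan)
    coords = brain.voxel_coords
    vols[coords[:, 0], coords[:, 1], coords[:, 2], :] = values.T
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vols, affine), str(path))


def load_config(path) -> dict:
    """Generator/analysis parameters from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
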