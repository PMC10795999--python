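"""File-format adapters: YAML configs, TSV tables, NIfTI volumes, NPZ stacks.

Thin wrappers keeping on-disk conventions in one place: trajectory
geometry as YAML keyed by :class:`~loomsight.stimgeom.TrajectorySpec`
fields, projected paths and eccentricity profiles as TSV, frame
stacks and null distributions as NPZ/NPY, and beta maps / ROI masks
as NIfTI (RAS+, voxel size carried in the affine).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .roistats import BetaMap
from .stimgeom import FrameSequence, ProjectedPath, TrajectorySpec

__all__ = [
    "load_trajectory_yaml",
    "save_path_tsv",
    "load_path_tsv",
    "save_frames_npz",
    "load_frames_npz",
    "save_beta_map",
    "load_beta_map",
    "load_mask",
]


def load_trajectory_yaml(path) -> TrajectorySpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return TrajectorySpec(**cfg)


def save_path_tsv(path: ProjectedPath, out) -> None:
    path.to_frame().to_csv(out, sep="\t", index=False)


def load_path_tsv(path) -> ProjectedPath:
    df = pd.read_csv(path, sep="\t")
    return ProjectedPath(
        frame_times=df["frame_time"].to_numpy(),
        angular_x=df["ang_x_deg"].to_numpy(),
        angular_y=df["ang_y_deg"].to_numpy(),
        angular_size=df["ang_size_deg"].to_numpy(),
    )


def save_frames_npz(frames: FrameSequence, out) -> None:
    np.savez_compressed(
        out,
        frames=frames.frames,
        pixel_pitch=frames.pixel_pitch,
        frame_rate=frames.frame_rate,
        background_level=frames.background_level,
    )


def load_frames_npz(path) -> FrameSequence:
    with np.load(path) as z:
        return FrameSequence(
            frames=z["frames"],
            pixel_pitch=float(z["pixel_pitch"]),
            frame_rate=float(z["frame_rate"]),
            background_level=float(z["background_level"]),
        )


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def save_beta_map(beta_map: BetaMap, out) -> None:
    img = nib.Nifti1Image(
        beta_map.data.astype(np.float32), _affine(beta_map.voxel_size_mm)
    )
    nib.save(img, str(out))


def load_beta_map(path, subject_id: str = "", condition: str = "") -> BetaMap:
    img = nib.load(str(path))
    voxel = float(np.abs(img.affine[0, 0]))
    return BetaMap(
        data=np.asarray(img.get_fdata(), dtype=float),
        voxel_size_mm=voxel,
        subject_id=subject_id,
        condition=condition,
    )


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5
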