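"""3-D reconstruction of segmented sweeps.

Stacks the per-frame predicted label maps of an ordered sweep into a labeled
voxel volume at uniform z spacing (no inter-frame registration: the sweep is
assumed steady), optionally smooths each class with a 3-D morphological
closing, and extracts one triangle surface mesh per class by marching cubes
on a lightly Gaussian-smoothed binary mask.  Volumes are written as NIfTI,
meshes as PLY/STL, plus a JSON scene file carrying the display palette
(red carotid, blue trachea, green thyroid, yellow NoV, purple esophagus).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .phantom import CLASS_COLORS, CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = ["VolumeLabelMap", "stack_predictions", "extract_mesh", "export"]


@dataclass
class VolumeLabelMap:
    """z-stacked label maps with voxel spacing (dz, dy, dx)."""

    values: np.ndarray  # (Z, Y, X) integer
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    def class_voxels(self, c: int) -> int:
        return int((self.values == c).sum())


def stack_predictions(
    label_frames: list[np.ndarray],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    closing_radius: int = 1,
) -> VolumeLabelMap:
    """Stack ordered frames along z; optional per-class 3-D closing.

    Closing (radius in voxels; 0 disables) fills small inter-frame gaps in
    each foreground class; filled voxels are only written where the volume
    is background, so existing labels are never overwritten.
    """
    if len(label_frames) < 2:
        raise ValueError("a volume needs at least 2 frames")
    shapes = {f.shape for f in label_frames}
    if len(shapes) != 1:
        raise ValueError(f"frames differ in shape: {shapes}")
    vol = np.stack(label_frames).astype(np.uint8)
    if closing_radius > 0:
        ball = _ball(closing_radius)
        for c in np.unique(vol):
            if c == 0:
                continue
            mask = vol == c
            closed = ndimage.binary_closing(mask, structure=ball)
            vol[closed & (vol == 0)] = c
    return VolumeLabelMap(vol, tuple(spacing))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz * zz + yy * yy + xx * xx <= r * r


def extract_mesh(
    vol: VolumeLabelMap, c: int, smooth_sigma: float = 1.0
) -> trimesh.Trimesh:
    """Marching-cubes surface of class ``c`` in world units.

    The binary mask is padded (so surfaces close at the volume border),
    Gaussian-smoothed with ``smooth_sigma`` voxels, and contoured at level
    0.5.  An absent class yields an empty mesh with a warning.
    """
    mask = (vol.values == c).astype(np.float32)
    if mask.sum() == 0:
        logger.warning("class %d absent from volume; empty mesh", c)
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    pad = max(2, int(np.ceil(2 * smooth_sigma)))
    mask = np.pad(mask, pad)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(mask, smooth_sigma)
        # very small structures can be smoothed below the iso-level; fall
        # back to the raw mask so they still produce a surface
        if smoothed.max() > 0.5:
            mask = smoothed
    verts, faces, _, _ = measure.marching_cubes(mask, level=0.5, spacing=vol.spacing)
    verts -= np.array(vol.spacing) * pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()  # orient faces outward so enclosed volume is positive
    if not mesh.is_watertight:
        logger.warning("class %d mesh is not watertight", c)
    return mesh


def export(
    vol: VolumeLabelMap,
    meshes: dict[int, trimesh.Trimesh],
    out_dir: str | Path,
    formats: tuple[str, ...] = ("ply", "stl"),
) -> dict:
    """Write the volume (NIfTI, spacing in the header), one mesh file per
    present class and format, and a scene JSON with the class palette."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    # NIfTI convention is (x, y, z): transpose the (z, y, x) volume
    img = nib.Nifti1Image(vol.values.transpose(2, 1, 0).astype(np.uint8), affine)
    vol_path = out_dir / "labels.nii"
    nib.save(img, vol_path)
    scene = {"volume": vol_path.name, "spacing_zyx": list(vol.spacing), "classes": {}}
    for c, mesh in meshes.items():
        name = CLASS_NAMES[c]
        entry = {"class_index": int(c), "color_rgb": list(CLASS_COLORS[name]), "files": []}
        if len(mesh.faces) > 0:
            for fmt in formats:
                path = out_dir / f"{name}.{fmt}"
                mesh.export(path)
                entry["files"].append(path.name)
        scene["classes"][name] = entry
    (out_dir / "scene.json").write_text(json.dumps(scene, indent=2, sort_keys=True))
    return scene


def load_volume(path: str | Path) -> VolumeLabelMap:
    """Read back a NIfTI label volume written by :func:`export`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    z = img.affine[2, 2]
    y = img.affine[1, 1]
    x = img.affine[0, 0]
    return VolumeLabelMap(data, (abs(float(z)), abs(float(y)), abs(float(x))))
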