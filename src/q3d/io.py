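"""Volume, atlas, transform and table IO.

Volumes travel as multi-page TIFF (8/16-bit or float32, voxel spacing in the
ImageJ metadata block) or NIfTI (spacing carried in the header zooms, stored
in millimetres per NIfTI convention and exposed here in micrometres).
Spacing is never silently defaulted: a TIFF without spacing metadata must be
read with an explicit ``spacing_um``.

Coordinates in every table are 0-based voxel indices; physical positions are
index times spacing with a voxel-corner origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .atlas_space import AffineTransform, LabelAtlas
from .restoration import Volume3D
from .segmentation import DetectedObject, ObjectSet

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _kind(path: Path) -> str:
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _TIFF_SUFFIXES):
        return "tiff"
    raise ValueError(f"unknown volume extension: {path.name}")


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    if _kind(path) == "nifti":
        spacing_mm = np.asarray(vol.spacing_um) / 1000.0
        affine = np.diag(list(spacing_mm) + [1.0])
        data = vol.values
        if data.dtype == np.float64:
            data = data.astype(np.float32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(spacing_mm)
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, str(path))
    else:
        data = vol.values
        if data.dtype == np.float64:
            data = data.astype(np.float32)
        sx, sy, sz = vol.spacing_um
        tifffile.imwrite(
            str(path),
            np.ascontiguousarray(data),
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    return path


def read_volume(path: str | Path, spacing_um: tuple[float, float, float] | None = None,
                channel: str = "") -> Volume3D:
    path = Path(path)
    if _kind(path) == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if spacing_um is None:
            zooms = img.header.get_zooms()[:3]
            spacing_um = tuple(float(z) * 1000.0 for z in zooms)
        return Volume3D(data, spacing_um, channel)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if spacing_um is None:
            meta = tif.imagej_metadata or {}
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            sz = meta.get("spacing")
            if xres is None or yres is None or sz is None:
                raise ValueError(
                    f"{path.name} carries no voxel spacing metadata; pass spacing_um explicitly"
                )
            sx = xres.value[1] / xres.value[0]
            sy = yres.value[1] / yres.value[0]
            spacing_um = (float(sx), float(sy), float(sz))
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    return Volume3D(data, spacing_um, channel)


def write_transform(transform: AffineTransform, path: str | Path) -> Path:
    path = Path(path)
    payload = transform.to_dict()
    payload["convention"] = (
        "row-major 3x3 matrix + offset acting on 0-based downsampled voxel bins"
    )
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_transform(path: str | Path) -> AffineTransform:
    return AffineTransform.from_dict(json.loads(Path(path).read_text()))


def write_atlas(atlas: LabelAtlas, volume_path: str | Path, table_path: str | Path) -> None:
    spacing_mm = atlas.spacing_um / 1000.0
    affine = np.diag([spacing_mm] * 3 + [1.0])
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), affine)
    img.header.set_zooms((spacing_mm,) * 3)
    nib.save(img, str(volume_path))
    atlas.regions.to_csv(table_path, index=False)


def read_atlas(volume_path: str | Path, table_path: str | Path) -> LabelAtlas:
    img = nib.load(str(volume_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    spacing_um = float(img.header.get_zooms()[0]) * 1000.0
    regions = pd.read_csv(table_path)
    return LabelAtlas(labels, spacing_um, regions)


_OBJECTS_HEADER = (
    "# columns: id, x_vox, y_vox, z_vox (0-based voxel coords, corner origin), "
    "voxel_count, volume_um3, peak_intensity\n"
)


def write_objects(objects: ObjectSet, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_OBJECTS_HEADER)
        for k, v in sorted((provenance or {}).items()):
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# spacing_um: {list(objects.spacing_um)}\n")
        objects.to_dataframe().to_csv(fh, index=False)
    return path


def read_objects(path: str | Path) -> ObjectSet:
    path = Path(path)
    spacing = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# spacing_um:"):
                spacing = tuple(json.loads(line.split(":", 1)[1]))
    if spacing is None:
        raise ValueError(f"{path.name} lacks the spacing_um header line")
    df = pd.read_csv(path, comment="#")
    objs = [
        DetectedObject(
            id=int(r.id),
            centroid_vox=(float(r.x_vox), float(r.y_vox), float(r.z_vox)),
            voxel_count=int(r.voxel_count),
            volume_um3=float(r.volume_um3),
            peak_intensity=float(r.peak_intensity),
        )
        for r in df.itertuples()
    ]
    return ObjectSet(objs, spacing)


__all__ = [
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "read_atlas",
    "write_atlas",
    "read_objects",
    "write_objects",
]
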