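"""File round-tripping for volumes, masks, Raman scans and ground truth.

Volumes travel as multi-page TIFF with the voxel size in ImageJ-style
metadata; scans as TSV (first column wavenumber, remaining columns pixels
in row-major order) with a JSON sidecar; ground truth as JSON (arrays are
converted to lists; boolean masks to index lists).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .types import CellMask, GroundTruth, RamanScan, VoxelVolume


def save_volume(path, vol: VoxelVolume) -> None:
    dz, dy, dx = vol.voxel_size
    tifffile.imwrite(
        path,
        vol.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def load_volume(path) -> VoxelVolume:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ij = tif.imagej_metadata or {}
        dz = float(ij.get("spacing", 1.0))
        page = tif.pages[0]
        def _res(tag):
            v = page.tags.get(tag)
            if v is None:
                return 1.0
            num, den = v.value
            return den / num if num else 1.0
        dx = _res("XResolution")
        dy = _res("YResolution")
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data.astype(float), (dz, dy, dx))


def save_mask(path, mask: CellMask) -> None:
    dz, dy, dx = mask.voxel_size
    tifffile.imwrite(
        path,
        mask.data.astype(np.uint8) * 255,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def load_mask(path) -> CellMask:
    vol = load_volume(path)
    return CellMask(vol.data > 0, vol.voxel_size)


def save_scan(path_tsv, scan: RamanScan) -> None:
    """Write a scan as TSV (wavenumber column + one column per pixel,
    row-major) plus a JSON sidecar with shape and state."""
    path_tsv = Path(path_tsv)
    lines, points, n_ch = scan.cube.shape
    flat = scan.cube.reshape(lines * points, n_ch).T  # channels × pixels
    table = np.column_stack([scan.wavenumbers, flat])
    header = "wavenumber_cm1\t" + "\t".join(
        f"px_{i:05d}" for i in range(lines * points)
    )
    np.savetxt(path_tsv, table, delimiter="\t", header=header, comments="")
    sidecar = {
        "lines": lines,
        "points": points,
        "state": sorted(scan.state),
        "valid": np.flatnonzero(~scan.valid.ravel()).tolist(),  # invalid pixel ids
    }
    path_tsv.with_suffix(path_tsv.suffix + ".json").write_text(json.dumps(sidecar))


def load_scan(path_tsv) -> RamanScan:
    path_tsv = Path(path_tsv)
    table = np.loadtxt(path_tsv, delimiter="\t", skiprows=1)
    sidecar = json.loads(path_tsv.with_suffix(path_tsv.suffix + ".json").read_text())
    lines, points = sidecar["lines"], sidecar["points"]
    w = table[:, 0]
    cube = table[:, 1:].T.reshape(lines, points, w.size)
    valid = np.ones(lines * points, dtype=bool)
    valid[sidecar.get("valid", [])] = False
    return RamanScan(cube, w, state=set(sidecar.get("state", [])),
                     valid=valid.reshape(lines, points))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        if obj.dtype == bool:
            return {"__mask_shape__": list(obj.shape),
                    "true_indices": np.flatnonzero(obj.ravel()).tolist()}
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_ground_truth(path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(_jsonable(dataclasses.asdict(gt))))
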