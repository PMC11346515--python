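"""Reading and writing of every external format the pipeline touches.

Conventions enforced throughout the package:

* arrays are indexed ``(x, y, z)``; on disk (multipage TIFF) page = z,
  row = y, column = x, so stacks are transposed on the way in and out;
* physical coordinates are nanometres, voxel indices 0-based, and the
  centre of voxel ``i`` sits at ``(i + 0.5) * spacing``;
* BED intervals are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh


@dataclass
class VoxelVolume:
    """A 3D grayscale grid with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D scalar array indexed ``(x, y, z)``.
    spacing:
        Physical voxel size ``(sx, sy, sz)`` in nanometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer-labelled segmentation on the same grid as its source volume.

    Label 0 is background; labels are non-negative integers.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# image stacks


def read_stack(path: str | Path, spacing: tuple[float, float, float] | None = None) -> VoxelVolume:
    """Read a multipage TIFF (or raw + JSON sidecar) into a :class:`VoxelVolume`.

    ``spacing`` must be supplied for TIFFs (never silently assumed
    isotropic); a ``.raw`` file takes it from its sidecar when omitted.
    """
    path = Path(path)
    if path.suffix == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw stack {path} needs a sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
        if spacing is None:
            spacing = meta.get("spacing")
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ValueError(f"expected a grayscale stack, got shape {pages.shape}")
        # pages are (z, y, x) -> (x, y, z)
        data = np.ascontiguousarray(pages.transpose(2, 1, 0))
    if spacing is None:
        raise ValueError("voxel spacing must be supplied (nm per axis, x,y,z)")
    return VoxelVolume(data, spacing)


def write_stack(vol: VoxelVolume | LabelMap, path: str | Path) -> None:
    """Write a volume or label map as multipage TIFF (page = z)."""
    data = vol.data if isinstance(vol, VoxelVolume) else vol.labels
    if isinstance(vol, LabelMap):
        data = data.astype(np.uint16 if data.max(initial=0) < 2**16 else np.uint32)
    tifffile.imwrite(Path(path), np.ascontiguousarray(data.transpose(2, 1, 0)))


def read_labels(path: str | Path, spacing: tuple[float, float, float]) -> LabelMap:
    vol = read_stack(path, spacing)
    return LabelMap(vol.data.astype(np.int64), spacing)


# ---------------------------------------------------------------------------
# measurement tables

MEASUREMENT_COLUMNS = [
    "label",
    "identity",
    "volume_um3",
    "surface_um2",
    "length_um",
    "mean_width_um",
    "sd_width_um",
    "n_width_samples",
    "centromere_fraction",
    "arm_ratio",
    "class",
]


def write_measurements(objects, path: str | Path) -> pd.DataFrame:
    """Write per-chromosome morphometry records as CSV, one row per object.

    Unmeasured fields are written empty, never fabricated.
    """
    rows = []
    for obj in objects:
        rows.append(
            {
                "label": obj.label,
                "identity": obj.identity if obj.identity is not None else "",
                "volume_um3": obj.volume,
                "surface_um2": obj.surface_area,
                "length_um": obj.length,
                "mean_width_um": obj.mean_width,
                "sd_width_um": obj.sd_width,
                "n_width_samples": len(obj.width_samples) if obj.width_samples is not None else 0,
                "centromere_fraction": obj.centromere_fraction,
                "arm_ratio": obj.arm_ratio,
                "class": obj.morphology_class,
            }
        )
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    table.to_csv(path, index=False)
    return table


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | Path):
    """Parse a BED3+ file into ``(chrom, start, end)`` tuples.

    Coordinates are 0-based half-open; overlapping records are preserved
    unmerged (merging is a separate operation in
    :func:`mitovol.identity_density.merge_intervals`).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from err
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            intervals.append((chrom, start, end))
    return intervals


def write_bed(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# landmark tables

LANDMARK_COLUMNS = ["name", "kind", "chromosome_id", "sister_id", "arm", "x_nm", "y_nm", "z_nm"]
LANDMARK_KINDS = {"centrosome", "kinetochore", "telomere"}


def read_landmarks(path: str | Path) -> pd.DataFrame:
    """Read a landmark CSV (centrosomes, kinetochores, telomeres; nm)."""
    table = pd.read_csv(path, dtype={"chromosome_id": str, "sister_id": str, "arm": str})
    missing = {"kind", "x_nm", "y_nm", "z_nm"} - set(table.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    bad = set(table["kind"]) - LANDMARK_KINDS
    if bad:
        raise ValueError(f"unknown landmark kinds: {sorted(bad)}")
    return table


def write_landmarks(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LANDMARK_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# meshes


def write_mesh_ply(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Export a triangle mesh (vertices in nm) as ASCII PLY."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
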