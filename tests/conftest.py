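"""Shared fixtures and independent geometric oracles.

The oracles here deliberately avoid the package's own rasterization and
quadrature code paths: capsule volumes are computed by supersampled
voxel-centre counting against the exact point-to-segment distance.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitovol import phantom, segment3d
from mitovol.volio import LabelMap


def point_segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each point to the segment p0-p1."""
    d = p1 - p0
    t = np.clip((points - p0) @ d / (d @ d), 0.0, 1.0)
    closest = p0 + t[:, None] * d
    return np.linalg.norm(points - closest, axis=1)


def supersampled_capsule_volume_um3(
    p0, p1, radius_nm: float, spacing, supersample: int = 5
) -> float:
    """Voxelized volume of a capsule at ``spacing / supersample`` resolution.

    Independent oracle for the phantom rasterizer and the threshold-based
    volume measurement.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    fine = np.asarray(spacing, dtype=float) / supersample
    lo = np.minimum(p0, p1) - radius_nm - fine
    hi = np.maximum(p0, p1) + radius_nm + fine
    axes = [
        (np.arange(int(np.floor(lo[k] / fine[k])), int(np.ceil(hi[k] / fine[k]))) + 0.5) * fine[k]
        for k in range(3)
    ]
    total = 0
    # slab by slab along x to bound memory
    yz = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1).reshape(-1, 2)
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        total += int((point_segment_distance(pts, p0, p1) <= radius_nm).sum())
    return total * np.prod(fine) / 1e9


@pytest.fixture(scope="session")
def rod_phantom():
    """Noise-free straight chromatid, r = 340 nm, L = 7 µm, 25x25x60 nm grid."""
    spec = phantom.straight_rod_spec(noise_sd=0)
    vol, labels, truth = phantom.generate_phantom(spec)
    return spec, vol, labels, truth


@pytest.fixture(scope="session")
def rod_labelmap(rod_phantom) -> LabelMap:
    _, _, labels, _ = rod_phantom
    return labels


@pytest.fixture(scope="session")
def nine_chromosome_phantom():
    """The nine size-identifiable chromosomes (1-5, 19-22) as a cohesed
    complement phantom with class-consistent constriction positions."""
    names = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr19", "chr20", "chr21", "chr22"]
    contents = [248.4, 242.7, 201.1, 193.6, 182.0, 61.7, 66.2, 45.1, 51.3]
    # constriction positions chosen to give meta / submeta / acro arm ratios
    positions = [0.5, 0.33, 0.48, 0.3, 0.3, 0.47, 0.5, 0.18, 0.2]
    spec = phantom.complement_spec(
        contents,
        names=names,
        mb_per_um=85.0,
        radius_nm=250.0,
        constriction_positions=positions,
        constriction_factor=0.75,
        noise_sd=12.0,
        seed=11,
    )
    vol, labels, truth = phantom.generate_phantom(spec)
    return spec, vol, labels, truth


@pytest.fixture(scope="session")
def segmented_nine(nine_chromosome_phantom):
    spec, vol, _, truth = nine_chromosome_phantom
    labels, info = segment3d.segment(vol, segment3d.SegmentationConfig(bin_factors=(1, 1, 1)))
    return spec, labels, info, truth
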