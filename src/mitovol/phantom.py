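"""Synthetic voxelized mitotic-cell phantoms with analytic ground truth.

A phantom is a set of tubular chromatids — smooth tubes of ~0.68 µm width
with an optional centromeric constriction — rasterized onto an anisotropic
voxel grid with chromosome/cytoplasm grayscale contrast and additive
Gaussian noise.  Because every chromatid has a closed-form (quadrature)
volume, surface area, centreline length and width, phantoms serve as the
ground-truth oracle for the whole segmentation and morphometry pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volio import LabelMap, VoxelVolume

#: analysis-grid voxel spacing in nm (x, y, z)
DEFAULT_SPACING = (25.0, 25.0, 60.0)
#: default chromatid radius in nm (diameter 0.68 µm, the mean single-chromatid width)
DEFAULT_RADIUS = 340.0


@dataclass
class ChromatidSpec:
    """Geometry and DNA content of one synthetic chromatid.

    The centreline is a C1 piecewise-polynomial curve through
    ``control_points`` (nm).  The radius along arc length s is

        r(s) = base_radius * (1 - (1 - constriction_factor) * g(s))

    with g a Gaussian bump at ``centromere_position`` (sd = 5% of arc
    length), so ``constriction_factor`` is the radius multiplier at the
    primary constriction.  The tube is closed with hemispherical caps.
    """

    control_points: Sequence[Sequence[float]]
    base_radius: float = DEFAULT_RADIUS
    centromere_position: float = 0.5
    constriction_factor: float = 1.0
    dna_content_mb: float = float("nan")
    name: str | None = None

    CONSTRICTION_SD_FRACTION = 0.05

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[0] < 2:
            raise ValueError("need at least 2 control points of 3 coordinates")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not 0.0 <= self.centromere_position <= 1.0:
            raise ValueError("centromere_position must lie in [0, 1]")
        if not 0.0 < self.constriction_factor <= 1.0:
            raise ValueError("constriction_factor must lie in (0, 1]")
        if self.arc_length() <= 4 * self.base_radius:
            raise ValueError("arc length must exceed 4 x base_radius")

    # -- centreline geometry -------------------------------------------------

    def _spline(self):
        pts = self.control_points
        chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        if chord[-1] <= 0:
            raise ValueError("degenerate control polygon")
        if len(pts) == 2:
            return lambda t: pts[0] + np.outer(np.atleast_1d(t) / chord[-1], pts[1] - pts[0]), chord[-1]
        spline = CubicSpline(chord, pts, axis=0)
        return spline, chord[-1]

    def sample_centerline(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (points, arc positions) resampled at ~uniform arc step (nm)."""
        spline, t_max = self._spline()
        # oversample in parameter, then re-space by cumulative arc length
        t = np.linspace(0.0, t_max, max(64, int(8 * t_max / step)))
        pts = np.asarray(spline(t))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(seg)]
        total = s[-1]
        n = max(2, int(np.ceil(total / step)) + 1)
        s_uniform = np.linspace(0.0, total, n)
        out = np.column_stack([np.interp(s_uniform, s, pts[:, k]) for k in range(3)])
        return out, s_uniform

    def arc_length(self) -> float:
        spline, t_max = self._spline()
        t = np.linspace(0.0, t_max, 2048)
        pts = np.asarray(spline(t))
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def radius_at(self, s: np.ndarray, total: float | None = None) -> np.ndarray:
        """Radius (nm) at arc positions ``s`` (nm)."""
        total = self.arc_length() if total is None else total
        s = np.asarray(s, dtype=float)
        sd = self.CONSTRICTION_SD_FRACTION * total
        bump = np.exp(-0.5 * ((s - self.centromere_position * total) / sd) ** 2)
        return self.base_radius * (1.0 - (1.0 - self.constriction_factor) * bump)

    # -- analytic ground truth ----------------------------------------------

    def true_volume_um3(self) -> float:
        """Tube volume by quadrature of pi r(s)^2 plus hemispherical caps (µm³)."""
        total = self.arc_length()
        s = np.linspace(0.0, total, 4096)
        r = self.radius_at(s, total)
        body = np.trapezoid(np.pi * r**2, s)
        caps = (2.0 / 3.0) * np.pi * (r[0] ** 3 + r[-1] ** 3)
        return float((body + caps) / 1e9)

    def true_surface_um2(self) -> float:
        """Lateral area by quadrature of 2 pi r(s) plus cap areas (µm²).

        Ignores the (small) slope term of the constriction profile.
        """
        total = self.arc_length()
        s = np.linspace(0.0, total, 4096)
        r = self.radius_at(s, total)
        body = np.trapezoid(2.0 * np.pi * r, s)
        caps = 2.0 * np.pi * (r[0] ** 2 + r[-1] ** 2)
        return float((body + caps) / 1e6)


@dataclass
class PhantomSpec:
    """Full description of a synthetic mitotic-cell stack."""

    chromatids: list[ChromatidSpec] = field(default_factory=list)
    grid_shape: tuple[int, int, int] = (128, 128, 32)
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    intensity_chromosome: float = 170.0
    intensity_cytoplasm: float = 90.0
    noise_sd: float = 12.0
    landmarks: np.ndarray | None = None  # centrosome positions, nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_chromosome == self.intensity_cytoplasm:
            raise ValueError("chromosome and cytoplasm intensities must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(f <= 0 for f in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    def to_yaml(self, path) -> None:
        doc = {
            "grid_shape": list(self.grid_shape),
            "voxel_spacing": list(self.voxel_spacing),
            "intensity_chromosome": self.intensity_chromosome,
            "intensity_cytoplasm": self.intensity_cytoplasm,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "landmarks": None if self.landmarks is None else np.asarray(self.landmarks).tolist(),
            "chromatids": [
                {
                    "control_points": np.asarray(c.control_points, dtype=float).tolist(),
                    "base_radius": float(c.base_radius),
                    "centromere_position": float(c.centromere_position),
                    "constriction_factor": float(c.constriction_factor),
                    "dna_content_mb": float(c.dna_content_mb),
                    "name": c.name,
                }
                for c in self.chromatids
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        chromatids = [ChromatidSpec(**c) for c in doc.pop("chromatids", [])]
        doc["grid_shape"] = tuple(doc["grid_shape"])
        doc["voxel_spacing"] = tuple(doc["voxel_spacing"])
        if doc.get("landmarks") is not None:
            doc["landmarks"] = np.asarray(doc["landmarks"], dtype=float)
        return cls(chromatids=chromatids, **doc)


@dataclass
class GroundTruth:
    """Analytic per-chromatid truth plus the exact rasterized label map."""

    volumes_um3: np.ndarray
    surfaces_um2: np.ndarray
    lengths_um: np.ndarray
    widths_um: np.ndarray
    dna_content_mb: np.ndarray
    names: list
    label_map: LabelMap
    landmarks: np.ndarray | None = None

    @property
    def total_volume_um3(self) -> float:
        return float(self.volumes_um3.sum())


def voxel_centers(index_ranges, spacing):
    """Physical centres (nm) of voxels in the given per-axis index ranges."""
    axes = [(np.arange(lo, hi) + 0.5) * s for (lo, hi), s in zip(index_ranges, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _rasterize(chromatid: ChromatidSpec, grid_shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices (N,3) whose centres fall inside the chromatid tube."""
    step = 0.4 * min(spacing)
    pts, s = chromatid.sample_centerline(step)
    radii = chromatid.radius_at(s, s[-1])
    rmax = radii.max()
    lo = pts.min(axis=0) - rmax
    hi = pts.max(axis=0) + rmax
    ranges = []
    for ax in range(3):
        i0 = int(np.floor(lo[ax] / spacing[ax])) - 1
        i1 = int(np.ceil(hi[ax] / spacing[ax])) + 1
        if i0 < 0 or i1 > grid_shape[ax]:
            raise ValueError(
                f"chromatid {chromatid.name or ''} exceeds grid bounds on axis {ax} "
                f"(needs indices [{i0}, {i1}), grid has {grid_shape[ax]})"
            )
        ranges.append((max(i0, 0), min(i1, grid_shape[ax])))
    centers = voxel_centers(ranges, spacing)
    dist, idx = cKDTree(pts).query(centers, workers=-1)
    inside = dist <= radii[idx]
    offsets = np.array([r[0] for r in ranges])
    shape = tuple(r[1] - r[0] for r in ranges)
    local = np.array(np.unravel_index(np.nonzero(inside)[0], shape)).T
    return local + offsets, np.asarray(inside)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, LabelMap, GroundTruth]:
    """Rasterize a :class:`PhantomSpec` into a grayscale stack + truth.

    Voxel membership is decided by voxel-centre inclusion (no partial
    volumes), matching the hard-threshold measurement model downstream.
    Identical specs (including seed) give bit-identical output.
    Overlapping chromatids raise, since the ground-truth label would be
    ambiguous.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    vols, surfs, lens, widths, mbs, names = [], [], [], [], [], []
    for i, chromatid in enumerate(spec.chromatids, start=1):
        idx, _ = _rasterize(chromatid, spec.grid_shape, spec.voxel_spacing)
        ix, iy, iz = idx.T
        clash = labels[ix, iy, iz]
        if np.any(clash > 0):
            other = int(clash[clash > 0][0])
            raise ValueError(f"chromatids {other} and {i} overlap: ground truth would be ambiguous")
        labels[ix, iy, iz] = i
        vols.append(chromatid.true_volume_um3())
        surfs.append(chromatid.true_surface_um2())
        lens.append(chromatid.arc_length() / 1e3)
        widths.append(2 * chromatid.base_radius / 1e3)
        mbs.append(chromatid.dna_content_mb)
        names.append(chromatid.name)

    rng = np.random.default_rng(spec.seed)
    data = np.where(labels > 0, spec.intensity_chromosome, spec.intensity_cytoplasm).astype(float)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(np.rint(data), 0, 255).astype(np.uint8)

    label_map = LabelMap(labels, spec.voxel_spacing)
    truth = GroundTruth(
        volumes_um3=np.array(vols),
        surfaces_um2=np.array(surfs),
        lengths_um=np.array(lens),
        widths_um=np.array(widths),
        dna_content_mb=np.array(mbs),
        names=names,
        label_map=label_map,
        landmarks=None if spec.landmarks is None else np.asarray(spec.landmarks, dtype=float),
    )
    return VoxelVolume(data, spec.voxel_spacing), label_map, truth


def capped_tube_truth(radius: float, length: float) -> tuple[float, float]:
    """Closed-form volume (µm³) and area (µm²) of a cylinder with hemispherical caps.

    ``radius`` and ``length`` are in nm; ``length`` is the cylindrical part
    (length 0 degenerates to a sphere).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if length < 0:
        raise ValueError("length must be non-negative")
    volume = np.pi * radius**2 * length + (4.0 / 3.0) * np.pi * radius**3
    area = 2.0 * np.pi * radius * length + 4.0 * np.pi * radius**2
    return float(volume / 1e9), float(area / 1e6)


# ---------------------------------------------------------------------------
# canned phantom layouts


def straight_rod_spec(
    length_nm: float = 7000.0,
    radius_nm: float = DEFAULT_RADIUS,
    spacing=DEFAULT_SPACING,
    constriction_factor: float = 1.0,
    centromere_position: float = 0.5,
    noise_sd: float = 0.0,
    margin_voxels: int = 4,
    seed: int = 0,
) -> PhantomSpec:
    """One straight chromatid along x, sized to its own minimal grid."""
    sx, sy, sz = spacing
    pad = radius_nm + margin_voxels * max(spacing)
    p0 = np.array([pad, pad, pad])
    p1 = p0 + np.array([length_nm, 0.0, 0.0])
    shape = (
        int(np.ceil((p1[0] + pad) / sx)),
        int(np.ceil((p0[1] + pad) / sy)),
        int(np.ceil((p0[2] + pad) / sz)),
    )
    chromatid = ChromatidSpec(
        [p0, p1],
        base_radius=radius_nm,
        constriction_factor=constriction_factor,
        centromere_position=centromere_position,
    )
    return PhantomSpec([chromatid], grid_shape=shape, voxel_spacing=spacing, noise_sd=noise_sd, seed=seed)


def complement_spec(
    dna_contents_mb: Sequence[float],
    names: Sequence[str] | None = None,
    mb_per_um: float = 66.0,
    radius_nm: float = DEFAULT_RADIUS,
    constriction_positions: Sequence[float] | None = None,
    constriction_factor: float = 0.75,
    spacing=DEFAULT_SPACING,
    noise_sd: float = 12.0,
    curvature_nm: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A chromosome complement laid out in rows, lengths set by DNA content.

    Each entry gets a tube of arc length ``2 * Mb / mb_per_um`` µm (the
    replicated, cohesed DNA content over the linear packing ratio), an
    optional centromeric constriction, and an optional in-plane bow of
    ``curvature_nm`` sagitta.  ``radius_nm`` may be a scalar or one value
    per chromatid (smaller chromosomes are slightly thinner in vivo).
    """
    contents = np.asarray(dna_contents_mb, dtype=float)
    lengths_nm = 2.0 * contents / mb_per_um * 1e3
    n = len(contents)
    radii = np.broadcast_to(np.asarray(radius_nm, dtype=float), (n,))
    if names is None:
        names = [f"obj{i+1}" for i in range(n)]
    if constriction_positions is None:
        constriction_positions = [0.5] * n
    sx, sy, sz = spacing
    r_ref = float(radii.max())
    pad = r_ref + 5 * max(spacing)
    gap = 2 * r_ref + 4 * max(spacing)
    row_pitch = 2 * r_ref + 4 * max(spacing) + abs(curvature_nm)
    # wrap chromatids into rows so the grid stays roughly square in-plane
    max_row_nm = max(lengths_nm.max() + 2 * pad, np.sqrt((lengths_nm + gap).sum() * row_pitch))
    chromatids = []
    x = pad
    y = pad + abs(curvature_nm)
    z = pad
    max_x = 0.0
    for i in range(n):
        L = lengths_nm[i]
        if x > pad and x + L + pad > max_row_nm:
            x = pad
            y += row_pitch
        p0 = np.array([x, y, z])
        p2 = p0 + np.array([L, 0.0, 0.0])
        if curvature_nm > 0:
            mid = (p0 + p2) / 2 + np.array([0.0, -curvature_nm, 0.0])
            pts = [p0, mid, p2]
        else:
            pts = [p0, p2]
        chromatids.append(
            ChromatidSpec(
                pts,
                base_radius=float(radii[i]),
                centromere_position=constriction_positions[i],
                constriction_factor=constriction_factor,
                dna_content_mb=contents[i],
                name=names[i],
            )
        )
        max_x = max(max_x, p2[0])
        x = p2[0] + gap + 2 * r_ref
    shape = (
        int(np.ceil((max_x + pad) / sx)),
        int(np.ceil((y + pad + abs(curvature_nm)) / sy)),
        int(np.ceil((z + pad) / sz)),
    )
    return PhantomSpec(
        chromatids, grid_shape=shape, voxel_spacing=spacing, noise_sd=noise_sd, seed=seed
    )
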