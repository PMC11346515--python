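"""Volume, surface, centreline, width and centromere measurements."""

import numpy as np
import pytest

from mitovol import morphometry, segment3d
from mitovol.phantom import (
    ChromatidSpec,
    PhantomSpec,
    capped_tube_truth,
    generate_phantom,
    straight_rod_spec,
)
from mitovol.volio import LabelMap

SPACING = (25.0, 25.0, 60.0)
VOXEL_DIAGONAL_NM = float(np.linalg.norm(SPACING))


def _labelmap_from_truth(labels) -> LabelMap:
    return LabelMap(labels.labels.astype(np.int32), labels.spacing)


class TestVolume:
    def test_single_voxel_unit_conversion(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        lm = LabelMap(labels, SPACING)
        assert morphometry.measure_volume(lm, 1) == pytest.approx(3.75e-5)

    def test_rod_volume_matches_analytic_truth(self, rod_labelmap):
        v = morphometry.measure_volume(rod_labelmap, 1)
        truth, _ = capped_tube_truth(340.0, 7000.0)
        assert v == pytest.approx(truth, rel=0.02)

    def test_equals_integer_voxel_enumeration(self, rod_labelmap):
        count = sum(
            1
            for x in range(rod_labelmap.labels.shape[0])
            for y in range(0, rod_labelmap.labels.shape[1], 7)
            if (rod_labelmap.labels[x, y] == 1).any()
        )  # cheap spot check is not the oracle; the exact one follows
        exact = int((rod_labelmap.labels == 1).sum())
        assert morphometry.measure_volume(rod_labelmap, 1) == exact * 25 * 25 * 60 / 1e9

    def test_invariant_to_label_permutation_and_translation(self, rod_labelmap):
        v1 = morphometry.measure_volume(rod_labelmap, 1)
        permuted = LabelMap(
            np.where(rod_labelmap.labels == 1, 5, 0).astype(np.int32), rod_labelmap.spacing
        )
        assert morphometry.measure_volume(permuted, 5) == v1
        translated = LabelMap(np.roll(rod_labelmap.labels, 3, axis=1), rod_labelmap.spacing)
        assert morphometry.measure_volume(translated, 1) == v1

    def test_absent_label_is_an_error(self, rod_labelmap):
        with pytest.raises(ValueError):
            morphometry.measure_volume(rod_labelmap, 99)


class TestSurfaceArea:
    def test_single_voxel_face_counting_closed_form(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        lm = LabelMap(labels, SPACING)
        expected = (2 * 25 * 25 + 4 * 25 * 60) / 1e6
        assert morphometry.measure_surface_area(lm, 1, method="voxel_faces") == pytest.approx(expected)

    def test_sphere_marching_cubes_within_3_percent(self):
        r, s = 500.0, 12.5
        n = int(2 * (r + 4 * s) / s)
        ax = (np.arange(n) + 0.5) * s
        c = ax.mean()
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        binary = (gx - c) ** 2 + (gy - c) ** 2 + (gz - c) ** 2 <= r * r
        lm = LabelMap(binary.astype(np.int32), (s, s, s))
        area = morphometry.measure_surface_area(lm, 1)
        assert area == pytest.approx(4 * np.pi * r**2 / 1e6, rel=0.03)

    def test_voxel_faces_upper_bounds_marching_cubes(self, rod_labelmap):
        mc = morphometry.measure_surface_area(rod_labelmap, 1)
        vf = morphometry.measure_surface_area(rod_labelmap, 1, method="voxel_faces")
        assert vf >= mc

    def test_border_touching_label_is_closed(self):
        labels = np.ones((4, 4, 3), dtype=np.int32)
        lm = LabelMap(labels, SPACING)
        area = morphometry.measure_surface_area(lm, 1, method="voxel_faces")
        expected = 2 * (4 * 25 * 4 * 25 + 4 * 25 * 3 * 60 + 4 * 25 * 3 * 60) / 1e6
        assert area == pytest.approx(expected)


class TestBinningSensitivity:
    def test_constant_phantom_volume_identical_across_factors(self):
        from mitovol.volio import VoxelVolume

        data = np.full((40, 40, 8), 90.0)
        data[10:30, 10:30, 2:6] = 170.0
        vol = VoxelVolume(data, SPACING)
        table = morphometry.binning_sensitivity(vol, 130.0, [(1, 1, 1), (2, 2, 2)])
        assert table.volume_um3.iloc[0] == pytest.approx(table.volume_um3.iloc[1])

    def test_volume_stable_while_area_varies_strongly(self):
        # the resolution trade-off: same stack, same threshold, binning
        # {1,2,4}: volume moves < 5% while the apparent surface area of the
        # noisy boundary changes by > 20% and shrinks as binning coarsens
        spec = straight_rod_spec(noise_sd=25.0, seed=2)
        vol, _, _ = generate_phantom(spec)
        table = morphometry.binning_sensitivity(
            vol, 130.0, [(1, 1, 1), (2, 2, 1), (4, 4, 2)], min_object_voxels=20
        )
        v = table.volume_um3.to_numpy()
        a = table.surface_um2.to_numpy()
        assert (v.max() - v.min()) / v.mean() < 0.05
        assert (a.max() - a.min()) / a.mean() > 0.20
        assert a[0] > a[-1]

    def test_needs_two_settings(self, rod_phantom):
        _, vol, _, _ = rod_phantom
        with pytest.raises(ValueError):
            morphometry.binning_sensitivity(vol, 130.0, [(1, 1, 1)])


class TestCenterline:
    def test_straight_rod_length(self, rod_labelmap):
        line = morphometry.centerline_of(rod_labelmap, 1)
        length = morphometry.polyline_length_um(line)
        assert length == pytest.approx(7.0, rel=0.05)

    def test_sphere_degenerates_to_zero_length(self):
        s = (25.0, 25.0, 25.0)
        ax = (np.arange(60) + 0.5) * 25.0
        c = ax.mean()
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        binary = (gx - c) ** 2 + (gy - c) ** 2 + (gz - c) ** 2 <= 500.0**2
        lm = LabelMap(binary.astype(np.int32), s)
        line = morphometry.centerline_of(lm, 1)
        assert morphometry.polyline_length_um(line) == 0.0

    def test_long_curved_chromatid_recovered(self):
        # an S-shaped 13.4 µm chromatid, the scale of the longest early
        # prometaphase chromosome arm
        pts = np.array(
            [[800, 2000, 600], [4000, 3400, 600], [8000, 800, 900], [12000, 3000, 600]], float
        )
        probe = ChromatidSpec(pts, base_radius=340)
        scale = 13400.0 / probe.arc_length()
        pts = (pts - [800, 800, 600]) * scale + [900, 1200, 660]
        chromatid = ChromatidSpec(pts, base_radius=340)
        grid = (int((pts[:, 0].max() + 900) / 25), int((pts[:, 1].max() + 1200) / 25), 28)
        spec = PhantomSpec([chromatid], grid_shape=grid, voxel_spacing=SPACING, noise_sd=0.0)
        _, labels, truth = generate_phantom(spec)
        lm = _labelmap_from_truth(labels)
        length = morphometry.polyline_length_um(morphometry.centerline_of(lm, 1))
        assert truth.lengths_um[0] == pytest.approx(13.4, abs=0.01)
        assert length == pytest.approx(13.4, rel=0.05)

    def test_rotation_invariance_at_isotropic_spacing(self):
        s = (25.0, 25.0, 25.0)
        lengths = []
        for angle in (0.0, 20.0, 45.0, 70.0):
            a = np.deg2rad(angle)
            d = np.array([np.cos(a), np.sin(a), 0.0])
            p0 = np.array([800.0, 800.0, 500.0])
            p1 = p0 + 7000.0 * d
            grid = (int((p1[0] + 900) / 25), int((p1[1] + 900) / 25), 54)
            spec = PhantomSpec(
                [ChromatidSpec([p0, p1], base_radius=340)],
                grid_shape=grid,
                voxel_spacing=s,
                noise_sd=0.0,
            )
            _, labels, _ = generate_phantom(spec)
            lm = _labelmap_from_truth(labels)
            lengths.append(morphometry.polyline_length_um(morphometry.centerline_of(lm, 1)))
        lengths = np.asarray(lengths)
        assert (lengths.max() - lengths.min()) / lengths.mean() < 0.01


class TestWidthProfile:
    @pytest.mark.parametrize("radius", [200.0, 340.0, 500.0])
    def test_width_matches_diameter_within_voxel_diagonal(self, radius):
        spec = straight_rod_spec(radius_nm=radius, noise_sd=0.0)
        _, labels, _ = generate_phantom(spec)
        lm = _labelmap_from_truth(labels)
        line = morphometry.centerline_of(lm, 1)
        widths = morphometry.width_profile(lm, 1, line, n=10)
        assert len(widths) == 10
        assert abs(widths.mean() * 1e3 - 2 * radius) <= VOXEL_DIAGONAL_NM

    def test_default_chromatid_width_scale(self, rod_labelmap):
        line = morphometry.centerline_of(rod_labelmap, 1)
        widths = morphometry.width_profile(rod_labelmap, 1, line, n=10)
        assert widths.mean() == pytest.approx(0.68, abs=VOXEL_DIAGONAL_NM / 1e3)

    def test_n_zero_is_a_defined_noop(self, rod_labelmap):
        line = morphometry.centerline_of(rod_labelmap, 1)
        assert len(morphometry.width_profile(rod_labelmap, 1, line, n=0)) == 0


class TestDetectCentromere:
    def _constricted(self, position, factor=0.6, length=9000.0):
        spec = straight_rod_spec(
            length_nm=length, noise_sd=0.0, constriction_factor=factor, centromere_position=position
        )
        _, labels, _ = generate_phantom(spec)
        lm = _labelmap_from_truth(labels)
        line = morphometry.centerline_of(lm, 1)
        return morphometry.detect_centromere(lm, 1, line)

    def test_symmetric_constriction_is_metacentric(self):
        c, ratio, cls = self._constricted(0.5)
        assert c == pytest.approx(0.5, abs=0.05)
        assert ratio == pytest.approx(1.0, abs=0.15)
        assert cls == "metacentric"

    def test_quarter_position_gives_arm_ratio_three(self):
        c, ratio, cls = self._constricted(0.25)
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_unconstricted_rod_has_no_centromere(self, rod_labelmap):
        line = morphometry.centerline_of(rod_labelmap, 1)
        c, ratio, cls = morphometry.detect_centromere(rod_labelmap, 1, line)
        assert c is None
        assert cls == "unknown"

    def test_classification_bands(self):
        # constrictions at 0.5 / 0.3 / 0.15 -> metacentric / submetacentric /
        # acrocentric, the karyotype triage used to identify chromosomes
        for position, expected in [(0.5, "metacentric"), (0.3, "submetacentric"), (0.15, "acrocentric")]:
            _, _, cls = self._constricted(position, length=12000.0)
            assert cls == expected, position


def test_parameter_recovery_on_randomized_complement():
    """Measured (volume, length, width) on a randomized seeded complement
    recover ground truth within (2%, 5%, one voxel diagonal)."""
    rng = np.random.default_rng(21)
    contents = rng.uniform(80.0, 200.0, size=5)
    from mitovol.phantom import complement_spec

    spec = complement_spec(
        contents, mb_per_um=85.0, radius_nm=300.0, constriction_factor=1.0, noise_sd=12.0, seed=21
    )
    vol, _, truth = generate_phantom(spec)
    labels, _ = segment3d.segment(vol, segment3d.SegmentationConfig(bin_factors=(1, 1, 1)))
    objects = morphometry.measure_all(labels)
    assert len(objects) == len(contents)
    # match measured objects to truth by centroid x-order is fragile; match by length
    measured = sorted(objects, key=lambda o: o.length)
    order = np.argsort(truth.lengths_um)
    for obj, idx in zip(measured, order):
        assert obj.volume == pytest.approx(truth.volumes_um3[idx], rel=0.02)
        assert obj.length == pytest.approx(truth.lengths_um[idx], rel=0.05)
        assert abs(obj.mean_width - truth.widths_um[idx]) * 1e3 <= VOXEL_DIAGONAL_NM
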