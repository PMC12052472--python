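import numpy as np
import pytest
from scipy.stats import spearmanr

from eggscore import (
    MetricSettings,
    SynthParams,
    TriangleMesh,
    bin_areas,
    dne,
    make_section,
    orientation,
    score,
    slope,
)
from eggscore.errors import MetricError, ParameterError, UndefinedOrientationError
from eggscore.mesh import submesh
from eggscore.metrics import read_score_csv, write_score_csv

CLOSED = MetricSettings(dne_outlier_fraction=0.0, boundary_discard="none")
FAST = dict(grid_resolution=6.0)


def tilt(mesh, degrees, about="x"):
    th = np.radians(degrees)
    c, s = np.cos(th), np.sin(th)
    rot = {
        "x": np.array([[1, 0, 0], [0, c, -s], [0, s, c]]),
        "z": np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
    }[about]
    return TriangleMesh(mesh.vertices @ rot.T, mesh.faces)


def tilted_plane(azimuth_deg, tilt_deg=20.0):
    """Small plane whose upward normal points toward the given azimuth."""
    az = np.radians(azimuth_deg)
    t = np.radians(tilt_deg)
    normal = np.array(
        [np.sin(t) * np.cos(az), np.sin(t) * np.sin(az), np.cos(t)]
    )
    # two in-plane directions
    u = np.cross(normal, [0, 0, 1.0])
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    verts = np.array([-u - w, u - w, u + w, -u + w])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    mesh = TriangleMesh(verts, faces)
    if mesh.face_normals[0] @ normal < 0:
        mesh = TriangleMesh(verts, faces[:, ::-1])
    return mesh


class TestDNE:
    def test_flat_plane_has_zero_energy(self, flat_section):
        total, _ = dne(flat_section.mesh, CLOSED)
        assert total == pytest.approx(0.0, abs=1e-8)

    def test_icosphere_matches_8pi(self, icosphere):
        total, _ = dne(icosphere, CLOSED)
        assert total == pytest.approx(8 * np.pi, rel=0.02)

    def test_scale_invariance(self, icosphere):
        total, _ = dne(icosphere, CLOSED)
        scaled = TriangleMesh(icosphere.vertices * 3.0, icosphere.faces)
        total3, _ = dne(scaled, CLOSED)
        assert total3 == pytest.approx(total, rel=1e-6)

    def test_additivity_of_face_contributions(self, ornamented_section):
        total, energies = dne(ornamented_section.mesh)
        retained = sum(fe.contribution for fe in energies if fe.skip_reason is None)
        assert total == pytest.approx(retained, rel=1e-12)

    def test_degenerate_face_skipped_not_fatal(self):
        # a zero-area sliver among valid faces
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0], [0.5, 0.5, 0.3]],
            dtype=float,
        )
        faces = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 4]])  # face 1 degenerate
        total, energies = dne(TriangleMesh(verts, faces), CLOSED)
        reasons = {fe.face_index: fe.skip_reason for fe in energies}
        assert reasons[1] == "singular G"
        assert np.isfinite(total)

    def test_outlier_fraction_drops_top_contributions(self, ornamented_section):
        lo, _ = dne(ornamented_section.mesh, MetricSettings(dne_outlier_fraction=0.01))
        hi, _ = dne(ornamented_section.mesh, MetricSettings(dne_outlier_fraction=0.0))
        assert lo < hi


class TestSlope:
    def test_horizontal_plane_is_zero(self, flat_section):
        mean, _ = slope(flat_section.mesh)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_tilted_plane_30_degrees(self, flat_section):
        mean, _ = slope(tilt(flat_section.mesh, 30.0))
        assert mean == pytest.approx(30.0, abs=1e-6)

    def test_hemisphere_area_weighted_mean_is_one_radian(self, icosphere):
        hemi = submesh(icosphere, icosphere.face_centroids[:, 2] > 0)
        settings = MetricSettings(
            slope_weighting="area", boundary_discard="none", dne_outlier_fraction=0.0
        )
        mean, _ = slope(hemi, settings)
        assert mean == pytest.approx(np.degrees(1.0), rel=0.01)

    def test_per_face_slopes_bounded(self, ornamented_section):
        mean, slopes = slope(ornamented_section.mesh)
        assert np.all(slopes >= 0.0)
        assert np.all(slopes <= 90.0)
        assert mean <= slopes.max()


class TestBinAreas:
    @pytest.mark.parametrize("azimuth,expected_bin", [(10.0, 1), (100.0, 3)])
    def test_single_normal_mesh_fills_one_bin(self, azimuth, expected_bin):
        mesh = tilted_plane(azimuth)
        bins = bin_areas(mesh, CLOSED)
        assert bins.area_of(expected_bin) == pytest.approx(mesh.total_area, rel=1e-9)
        assert bins.areas.sum() == pytest.approx(mesh.total_area, rel=1e-9)

    def test_horizontal_plane_fully_excluded(self, flat_section):
        bins = bin_areas(flat_section.mesh, CLOSED)
        assert np.all(bins.areas == 0.0)
        assert bins.excluded_area > 0

    def test_conservation(self, ornamented_section):
        settings = MetricSettings()
        bins = bin_areas(ornamented_section.mesh, settings)
        from eggscore.metrics import _retained_mask

        retained = _retained_mask(ornamented_section.mesh, settings)
        retained &= ornamented_section.mesh.face_areas > 0
        total = ornamented_section.mesh.face_areas[retained].sum()
        assert bins.total_area == pytest.approx(total, rel=1e-6)

    def test_long_axis_azimuth_rotates_the_frame(self):
        mesh = tilted_plane(10.0)
        shifted = bin_areas(
            mesh,
            MetricSettings(
                long_axis_azimuth=180.0,
                boundary_discard="none",
                dne_outlier_fraction=0.0,
            ),
        )
        # frame rotated by -90: azimuth 10 appears at 280 -> bin 7
        assert shifted.area_of(7) == pytest.approx(mesh.total_area, rel=1e-9)


class TestOrientation:
    def test_along_axis_grooves_score_plus_100(self, vgroove_along):
        assert orientation(vgroove_along.mesh) == pytest.approx(100.0, abs=1e-12)

    def test_cross_axis_grooves_score_minus_100(self, vgroove_across):
        assert orientation(vgroove_across.mesh) == pytest.approx(-100.0, abs=1e-12)

    def test_rotationally_symmetric_cone_scores_zero(self):
        # fine cone: z = -r, normals evenly distributed over all azimuths
        n_theta, n_r = 256, 12
        thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        verts = [[0.0, 0.0, 0.0]]
        for i in range(1, n_r + 1):
            r = i / n_r
            verts.extend([[r * np.cos(t), r * np.sin(t), -r] for t in thetas])
        faces = []
        for t in range(n_theta):
            faces.append([0, 1 + t, 1 + (t + 1) % n_theta])
        for i in range(n_r - 1):
            base = 1 + i * n_theta
            nxt = base + n_theta
            for t in range(n_theta):
                t2 = (t + 1) % n_theta
                faces.append([base + t, nxt + t, nxt + t2])
                faces.append([base + t, nxt + t2, base + t2])
        cone = TriangleMesh(np.array(verts), np.array(faces))
        assert orientation(cone, CLOSED) == pytest.approx(0.0, abs=0.5)

    def test_antisymmetry_under_90_degree_rotation(self, ornamented_section):
        omega = orientation(ornamented_section.mesh, CLOSED)
        rotated = tilt(ornamented_section.mesh, 90.0, about="z")
        omega_rot = orientation(rotated, CLOSED)
        assert omega_rot == pytest.approx(-omega, abs=1.0)

    def test_bounds(self, ornamented_section):
        omega = orientation(ornamented_section.mesh)
        assert -100.0 <= omega <= 100.0

    def test_flat_surface_orientation_undefined(self, flat_section):
        with pytest.raises(UndefinedOrientationError):
            orientation(flat_section.mesh)


class TestMonotonicityLadders:
    """Generator parameter ladders must move each metric monotonically
    (Spearman rho = 1 across a 4-step ladder)."""

    def test_ridge_anisotropy_increases_abs_orientation(self):
        omegas = [
            abs(
                orientation(
                    make_section(
                        SynthParams(node_amplitude=0.15, ridge_amplitude=ra, seed=5, **FAST)
                    ).mesh
                )
            )
            for ra in (0.0, 0.1, 0.2, 0.4)
        ]
        assert spearmanr(omegas, range(4)).statistic == pytest.approx(1.0)

    def test_amplitude_increases_mean_slope(self):
        means = [
            slope(
                make_section(
                    SynthParams(node_amplitude=a, ridge_amplitude=a, seed=5, **FAST)
                ).mesh
            )[0]
            for a in (0.05, 0.1, 0.2, 0.4)
        ]
        assert spearmanr(means, range(4)).statistic == pytest.approx(1.0)

    def test_node_density_increases_dne(self):
        totals = [
            dne(
                make_section(
                    SynthParams(node_count=nc, ridge_amplitude=0.0, seed=5, **FAST)
                ).mesh
            )[0]
            for nc in (5, 15, 40, 80)
        ]
        assert spearmanr(totals, range(4)).statistic == pytest.approx(1.0)


class TestScore:
    def test_record_assembles_metrics_and_metadata(self, ornamented_section):
        rec = score(ornamented_section)
        assert rec.egg_id == ornamented_section.egg_id
        assert rec.zone == ornamented_section.zone
        assert rec.complexity >= 0
        assert 0 <= rec.relief <= 90
        assert -100 <= rec.orientation <= 100

    def test_flat_disc_propagates_orientation_error_with_section_id(
        self, flat_section
    ):
        with pytest.raises(MetricError, match=flat_section.section_id):
            score(flat_section)

    def test_csv_round_trip(self, tmp_path, ornamented_section, vgroove_along):
        records = [score(ornamented_section), score(vgroove_along)]
        p = tmp_path / "score.csv"
        write_score_csv(records, p, MetricSettings())
        back = read_score_csv(p)
        assert len(back) == 2
        for orig, rt in zip(records, back):
            assert rt.section_id == orig.section_id
            assert rt.complexity == orig.complexity
            assert rt.orientation == orig.orientation


class TestSettingsValidation:
    def test_bin_geometry_must_cover_the_circle(self):
        with pytest.raises(ParameterError):
            MetricSettings(bin_count=8, bin_width=40.0)

    def test_unknown_boundary_rule_rejected(self):
        with pytest.raises(ParameterError):
            MetricSettings(boundary_discard="middle")
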