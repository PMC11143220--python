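"""Conformational descriptors, superposition, shape anisotropy, kinetics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyclokit import (
    CDBuildParams,
    GuestSchedule,
    Selection,
    Trajectory,
    build_cd_frame,
    build_complex_trajectory,
    cavity_volume,
    center_of_geometry,
    center_of_mass,
    circularity,
    conformational_report,
    detect_entry_time,
    distance_timeseries,
    gyration_shape,
    kabsch_superpose,
    leading_end,
    rim_area,
    rim_height,
    rmsf,
    rsa_from_eigenvalues,
    select,
)
from cyclokit.exceptions import ValidationError
from cyclokit.geometry import CDTopology
from cyclokit.io_formats import Frame

# Printed conformational-descriptor rows (A_PHR, A_MID, A_SHR nm^2; h12,
# h16 nm; Vc nm^3) for the seven hosts, each with and without the guest.
TABLE_ROWS = [
    (1.10, 0.83, 1.32, 0.22, 0.33, 0.55),
    (1.14, 0.84, 1.28, 0.22, 0.33, 0.56),
    (1.05, 0.79, 1.20, 0.18, 0.27, 0.42),
    (1.16, 0.85, 1.30, 0.23, 0.33, 0.57),
    (1.02, 0.72, 1.16, 0.15, 0.24, 0.35),
    (1.11, 0.83, 1.37, 0.21, 0.33, 0.55),
    (1.04, 0.76, 1.16, 0.17, 0.27, 0.40),
    (1.27, 0.84, 1.29, 0.23, 0.35, 0.61),
    (1.00, 0.80, 1.25, 0.19, 0.29, 0.45),
    (0.97, 0.83, 1.39, 0.20, 0.33, 0.52),
    (1.05, 0.70, 1.08, 0.12, 0.22, 0.30),
    (1.28, 0.85, 1.31, 0.22, 0.34, 0.60),
    (1.06, 0.72, 1.12, 0.13, 0.21, 0.30),
    (1.19, 0.85, 1.39, 0.21, 0.34, 0.58),
]


def frame_of(points, box=None):
    n = len(points)
    return Frame(["C"] * n, ["X"] * n, [1] * n, np.asarray(points, float),
                 box=box)


class TestCenters:
    def test_cog_midpoint(self):
        f = frame_of([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(
            center_of_geometry(f, Selection([0, 1])), [1, 0, 0])

    def test_cog_single_atom(self):
        f = frame_of([[3, 4, 5]])
        np.testing.assert_allclose(center_of_geometry(f, Selection([0])),
                                   [3, 4, 5])

    def test_cog_minimum_image_wrap(self):
        f = frame_of([[0.1, 0, 0], [9.9, 0, 0]], box=np.array([10., 10., 10.]))
        cog = center_of_geometry(f, Selection([0, 1]))
        assert cog[0] == pytest.approx(0.0, abs=1e-12)

    def test_com_equals_cog_for_equal_masses(self):
        f = frame_of([[0, 0, 0], [1, 1, 1], [2, 0, 1]])
        sel = Selection([0, 1, 2])
        np.testing.assert_allclose(center_of_mass(f, sel, np.ones(3)),
                                   center_of_geometry(f, sel))

    def test_com_weighted_unit_segment(self):
        f = frame_of([[0, 0, 0], [1, 0, 0]])
        com = center_of_mass(f, Selection([0, 1]), np.array([1.0, 3.0]))
        assert com[0] == pytest.approx(0.75)


class TestRims:
    def test_regular_heptagon_area_closed_form(self):
        r = 0.5509
        theta = 2 * np.pi * np.arange(7) / 7
        f = frame_of(np.c_[r * np.cos(theta), r * np.sin(theta), np.zeros(7)])
        expected = 3.5 * r**2 * np.sin(2 * np.pi / 7)
        assert rim_area(f, Selection(np.arange(7))) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.830, abs=5e-4)

    def test_unit_square(self):
        f = frame_of([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert rim_area(f, [0, 1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_coincident_ring(self):
        f = frame_of([[1, 1, 1]] * 5)
        assert rim_area(f, np.arange(5)) == 0.0

    def test_planar_ring_equals_shoelace_projection(self, rng):
        # random convex planar polygon (inscribed in an ellipse), rotated in 3-D
        angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
        pts2 = np.c_[1.4 * np.cos(angles), 0.8 * np.sin(angles)]
        shoelace = 0.5 * abs(np.sum(
            pts2[:, 0] * np.roll(pts2[:, 1], -1)
            - np.roll(pts2[:, 0], -1) * pts2[:, 1]))
        rot = Rotation.random(random_state=7).as_matrix()
        pts3 = np.c_[pts2, np.zeros(9)] @ rot.T + np.array([1.0, -2.0, 3.0])
        assert rim_area(frame_of(pts3), np.arange(9)) == pytest.approx(
            shoelace, abs=1e-12)

    def test_circularity_heptagon_modes(self):
        theta = 2 * np.pi * np.arange(7) / 7
        f = frame_of(np.c_[np.cos(theta), np.sin(theta), np.zeros(7)])
        sel = Selection(np.arange(7))
        assert circularity(f, sel, "radial") == pytest.approx(1.0, abs=1e-12)
        assert circularity(f, sel, "pairwise") == pytest.approx(
            np.sin(np.pi / 7) / np.sin(3 * np.pi / 7), abs=1e-12)

    def test_circularity_ellipse_axis_ratio(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        f = frame_of(np.c_[0.6 * np.cos(theta), 0.54 * np.sin(theta),
                           np.zeros(36)])
        assert circularity(f, np.arange(36)) == pytest.approx(0.90, abs=1e-9)

    def test_rim_height_coplanar_and_invariance(self, ideal_cd):
        # concentric coplanar rings share a center of mass: zero height
        theta = 2 * np.pi * np.arange(6) / 6
        inner = np.c_[0.5 * np.cos(theta), 0.5 * np.sin(theta), np.zeros(6)]
        outer = np.c_[0.9 * np.cos(theta), 0.9 * np.sin(theta), np.zeros(6)]
        f = frame_of(np.vstack([inner, outer]))
        h = rim_height(f, Selection(np.arange(6)), Selection(np.arange(6, 12)),
                       np.ones(6), np.ones(6))
        assert h == pytest.approx(0.0, abs=1e-12)
        frame, topo = ideal_cd
        h16 = rim_height(frame, topo.mid, topo.phr)
        shifted = frame.copy()
        shifted.positions = shifted.positions + np.array([5.0, -3.0, 2.0])
        assert rim_height(shifted, topo.mid, topo.phr) == pytest.approx(
            h16, abs=1e-12)


class TestCavityVolume:
    @pytest.mark.parametrize("row", [TABLE_ROWS[0], TABLE_ROWS[10]])
    def test_printed_rows_reproduced_at_two_decimals(self, row):
        a_phr, a_mid, a_shr, h12, h16, vc = row
        assert round(cavity_volume(a_phr, a_mid, a_shr, h12, h16), 2) == vc

    def test_all_rows_within_rounding_tolerance(self):
        errors = [abs(cavity_volume(*row[:5]) - row[5]) for row in TABLE_ROWS]
        assert max(errors) <= 0.015

    def test_zero_heights(self):
        assert cavity_volume(1.0, 1.0, 1.0, 0.0, 0.0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            cavity_volume(-1.0, 1.0, 1.0, 0.1, 0.1)


class TestConformationalReport:
    def test_zero_noise_builder_round_trip(self, ideal_cd):
        frame, topo = ideal_cd
        frames = []
        for k in range(5):
            f = frame.copy()
            f.time = float(k)
            frames.append(f)
        records, mean = conformational_report(Trajectory(frames), topo,
                                              window_fraction=1.0)
        p = CDBuildParams()
        from cyclokit.synthetic_data import polygon_area

        for r in records + [mean]:
            assert r.a_mid == pytest.approx(polygon_area(p.r_mid, 7), abs=1e-12)
            assert r.h12 == pytest.approx(0.22, abs=1e-12)
            assert r.h16 == pytest.approx(0.33, abs=1e-12)
            assert r.omega_o1 == pytest.approx(1.0, abs=1e-12)
            assert r.h == pytest.approx(0.55, abs=1e-12)

    def test_window_fraction_selects_trailing_frames(self):
        # drifting host: radii inflate linearly in time
        frames = []
        topo = None
        for k in range(10):
            scale = 1.0 + 0.05 * k
            f, topo = build_cd_frame(CDBuildParams(
                r_phr=0.634 * scale, r_mid=0.551 * scale, r_shr=0.695 * scale))
            f.time = float(k)
            frames.append(f)
        traj = Trajectory(frames)
        _, mean_all = conformational_report(traj, topo, window_fraction=1.0)
        _, mean_tail = conformational_report(traj, topo, window_fraction=0.1)
        assert mean_tail.a_mid > mean_all.a_mid

    def test_jittered_mean_within_three_se(self):
        n = 1000
        rng = np.random.default_rng(8)
        base, topo = build_cd_frame(CDBuildParams())
        frames = []
        for k in range(n):
            f = base.copy()
            f.time = float(k)
            f.positions = f.positions + rng.normal(0, 0.005, f.positions.shape)
            frames.append(f)
        records, mean = conformational_report(Trajectory(frames), topo,
                                              window_fraction=1.0)
        h12s = np.array([r.h12 for r in records])
        se = h12s.std(ddof=1) / np.sqrt(n)
        # noise biases h12 upward slightly (norm of a noisy vector); allow
        # the bias magnitude plus sampling error
        assert abs(mean.h12 - 0.22) < 3 * se + 0.005


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, t, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_rigid_motion(self, rng):
        pts = rng.normal(size=(10, 3))
        true_rot = Rotation.random(random_state=5).as_matrix()
        moved = pts @ true_rot.T + np.array([1.0, 2.0, -0.5])
        rot, t, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-10
        np.testing.assert_allclose(rot @ true_rot, np.eye(3), atol=1e-9)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = rng.normal(size=(8, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_known_two_triangle_rmsd(self):
        # isoceles triangles differing by a pure stretch along x
        a = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        b = np.array([[-2.0, 0, 0], [2.0, 0, 0], [0, 1.0, 0]])
        # optimal alignment is identity (shapes share symmetry axes)
        _, _, rmsd = kabsch_superpose(a, b)
        d = np.array([1.0, 1.0, 0.0])  # per-point displacement magnitudes
        assert rmsd == pytest.approx(np.sqrt(np.mean(d**2)), abs=1e-9)


def _brute_force_rmsf(coords):
    """Independent RMSF oracle using scipy for the superpositions."""
    def fit_all(slabs, ref):
        out = []
        for x in slabs:
            rot, loss = Rotation.align_vectors(ref - ref.mean(0),
                                               x - x.mean(0))
            out.append((x - x.mean(0)) @ rot.as_matrix().T + ref.mean(0))
        return np.array(out)

    fitted = fit_all(coords, coords[0])
    mean = fitted.mean(axis=0)
    fitted = fit_all(coords, mean)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


class TestRmsf:
    def _traj(self, coords):
        frames = []
        for k, c in enumerate(coords):
            f = frame_of(c)
            f.time = float(k)
            frames.append(f)
        return Trajectory(frames)

    def test_static_trajectory_is_zero(self, rng):
        c = rng.normal(size=(5, 3))
        traj = self._traj([c] * 4)
        prof = rmsf(traj, Selection(np.arange(5)))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_matches_brute_force_definition(self, rng):
        coords = rng.normal(size=(5, 6, 3))
        traj = self._traj(list(coords))
        prof = rmsf(traj, Selection(np.arange(6)))
        np.testing.assert_allclose(prof.rmsf, _brute_force_rmsf(coords),
                                   atol=1e-9)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        sigma = 0.02
        rng = np.random.default_rng(3)
        base, topo = build_cd_frame(CDBuildParams())
        coords = base.positions[None] + rng.normal(
            0, sigma, (500, base.n_atoms, 3))
        traj = self._traj(list(coords))
        prof = rmsf(traj, Selection(np.arange(base.n_atoms)))
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestGyrationShape:
    def test_collinear_chain_is_one(self):
        f = frame_of(np.c_[np.arange(10), np.zeros(10), np.zeros(10)])
        assert gyration_shape(f, Selection(np.arange(10))).rsa == pytest.approx(
            1.0, abs=1e-12)

    def test_cube_vertices_are_zero(self):
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                            for z in (-1, 1)], dtype=float)
        s = gyration_shape(frame_of(corners), Selection(np.arange(8)))
        assert s.rsa == pytest.approx(0.0, abs=1e-12)
        assert s.rg == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_direct_eigenvalue_evaluation(self):
        assert rsa_from_eigenvalues([4.0, 1.0, 1.0]) == pytest.approx(0.25)

    def test_rg_squared_is_trace(self, ideal_cd):
        frame, topo = ideal_cd
        s = gyration_shape(frame, topo.all_atoms())
        assert s.rg**2 == pytest.approx(s.eigenvalues.sum(), abs=1e-12)
        assert 0.0 <= s.rsa <= 1.0

    def test_rotation_translation_invariance(self, ideal_cd, rng):
        frame, topo = ideal_cd
        s0 = gyration_shape(frame, topo.all_atoms())
        a0 = rim_area(frame, topo.rim_indices("O1"))
        rot = Rotation.random(random_state=11).as_matrix()
        moved = frame.copy()
        moved.positions = frame.positions @ rot.T + np.array([1.0, 2.0, 3.0])
        s1 = gyration_shape(moved, topo.all_atoms())
        assert s1.rsa == pytest.approx(s0.rsa, abs=1e-9)
        np.testing.assert_allclose(s1.eigenvalues, s0.eigenvalues, atol=1e-9)
        assert rim_area(moved, topo.rim_indices("O1")) == pytest.approx(
            a0, abs=1e-9)


class TestKinetics:
    def test_identical_selections_zero_distance(self, ideal_cd):
        frame, topo = ideal_cd
        traj = Trajectory([frame])
        _, d = distance_timeseries(traj, topo.mid, topo.mid)
        assert d[0] == 0.0

    def test_minimum_image_distance(self):
        f = frame_of([[0.5, 0, 0], [9.5, 0, 0]], box=np.array([10., 10., 10.]))
        traj = Trajectory([f])
        _, d = distance_timeseries(traj, Selection([0]), Selection([1]))
        assert d[0] == pytest.approx(1.0)

    def test_never_below_threshold(self):
        t = np.arange(10.0)
        d = np.full(10, 2.0)
        assert detect_entry_time(t, d, 1.0, 3).entry_time is None

    def test_step_function_with_persistence(self):
        t = np.arange(20.0)
        d = np.where(t < 7, 2.0, 0.2)
        ev = detect_entry_time(t, d, 1.0, 5)
        assert ev.entry_time == 7.0

    def test_spurious_dip_rejected(self):
        t = np.arange(100.0)
        d = 2.0 - 1.5 / (1 + np.exp(-(t - 60) / 2))
        d[20] = 0.1  # one-frame artifact
        ev = detect_entry_time(t, d, 1.0, 10)
        assert ev.entry_time is not None and 55 <= ev.entry_time <= 65

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValidationError):
            detect_entry_time(np.array([0.0, 2.0, 1.0]), np.zeros(3), 1.0)

    @pytest.mark.parametrize("orientation,rim,expected_end", [
        ("ketone_first", "SHR", "ketone"),
        ("hydroxyl_first", "PHR", "hydroxyl"),
    ])
    def test_leading_end_by_construction(self, orientation, rim, expected_end):
        sched = GuestSchedule(t_entry=20.0, orientation=orientation,
                              approach_rim=rim)
        traj, topo, guest, _ = build_complex_trajectory(
            CDBuildParams(), sched, n_frames=40, dt=1.0, box=5.0, seed=0)
        times, dists = distance_timeseries(traj, guest, topo.all_atoms())
        ev = detect_entry_time(times, dists, 0.75, 3)
        ends = {"hydroxyl": select(traj[0], "HC", {"OHG"}),
                "ketone": select(traj[0], "HC", {"OKG"})}
        end, detected_rim = leading_end(traj, topo, ends, ev)
        assert end == expected_end
        assert detected_rim == rim

    def test_symmetric_tie_breaks_toward_shr(self):
        # symmetric host, guest dead-center: both rims equidistant
        p = CDBuildParams(z_phr=-0.25, z_shr=0.25,
                          r_phr=0.6, r_mid=0.55, r_shr=0.6)
        frame, topo = build_cd_frame(p)
        g = np.array([[0, 0, -0.05], [0, 0, 0.05]])
        n = frame.n_atoms
        names = list(frame.names) + ["OHG", "OKG"]
        resn = list(frame.residue_names) + ["HC", "HC"]
        resi = list(frame.residue_ids) + [99, 99]
        full = Frame(names, resn, resi, np.vstack([frame.positions, g]))
        traj = Trajectory([full])
        ends = {"hydroxyl": Selection([n]), "ketone": Selection([n + 1])}
        ev = detect_entry_time(np.array([0.0]), np.array([0.0]), 1.0, 1)
        with pytest.warns(UserWarning, match="tie"):
            _, rim = leading_end(traj, topo, ends, ev)
        assert rim == "SHR"


class TestTopology:
    def test_tsv_round_trip(self, tmp_path, ideal_cd):
        _, topo = ideal_cd
        p = topo.to_tsv(tmp_path / "topo.tsv")
        back = CDTopology.from_tsv(p)
        assert back.units == topo.units

    def test_detect_from_names(self, ideal_cd):
        frame, topo = ideal_cd
        detected = CDTopology.detect(frame)
        assert detected.n_units == 7
        np.testing.assert_array_equal(detected.rim_indices("O6"),
                                      topo.rim_indices("O6"))
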