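"""Phase-map, singularity, tracking and meander-ellipse tests."""

import numpy as np
import pytest

from atrialab.phase import (TipTrajectory, detect_singularities,
                            enclosing_ellipse, phase_map, track_tip)
from atrialab.synth import gen_spiral_movie


def _analytic_defect_movie(x0=0.955, y0=0.945, chirality=1, nx=64, ny=64,
                           dx=0.03, nt=60):
    """Rotating field with an exact winding-number defect at (x0, y0)."""
    t = np.arange(nt, dtype=float)
    ys, xs = np.meshgrid(np.arange(ny) * dx, np.arange(nx) * dx, indexing="ij")
    theta = chirality * np.arctan2(ys - y0, xs - x0)
    v = np.cos(theta[None] - 2 * np.pi * 0.05 * t[:, None, None])
    return t, v, dx


class TestPhaseMap:
    def test_sinusoid_phase_advances_at_signal_frequency(self):
        f = 0.02
        t = np.arange(0.0, 400.0, 1.0)
        v = np.sin(2 * np.pi * f * t)[:, None, None] * np.ones((1, 3, 3))
        pm = phase_map(t, v)
        slope = np.polyfit(t[50:-50], np.unwrap(pm.phase[:, 1, 1])[50:-50], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_phase_is_amplitude_invariant(self):
        t, v, dx = _analytic_defect_movie()
        a = phase_map(t, v, dx)
        b = phase_map(t, 7.5 * v, dx)
        # compare on the circle (identical up to 2*pi wrapping at +-pi)
        d = np.angle(np.exp(1j * (a.phase - b.phase)))
        assert np.max(np.abs(d)) < 1e-9

    def test_time_reversal_flips_rotation_chirality(self):
        """Playing the movie backwards reverses the detected rotor chirality."""
        t, v, dx = _analytic_defect_movie(x0=0.955, y0=0.945, chirality=1)
        fwd = phase_map(t, v, dx)
        rev = phase_map(t, v[::-1], dx)
        chi_f = detect_singularities(fwd, 30)[0][2]
        chi_r = detect_singularities(rev, 30)[0][2]
        assert chi_f == -chi_r

    def test_constant_node_is_masked(self):
        t, v, dx = _analytic_defect_movie(nt=32)
        v = v.copy()
        v[:, 0, 0] = 3.3
        pm = phase_map(t, v, dx)
        assert pm.mask[0, 0, 0]
        assert not pm.mask[0, 5, 5]


class TestSingularities:
    def test_single_defect_found_at_centre_with_chirality(self):
        t, v, dx = _analytic_defect_movie(x0=0.955, y0=0.945, chirality=1)
        pm = phase_map(t, v, dx)
        sings = detect_singularities(pm, 30)
        assert len(sings) == 1
        x, y, chi = sings[0]
        assert abs(x - 0.955) <= 1.5 * dx and abs(y - 0.945) <= 1.5 * dx

    def test_figure_eight_pair_has_zero_charge(self):
        mov = gen_spiral_movie(lambda t: [(0.6, 1.0, 1), (1.3, 1.0, -1)],
                               duration=30.0)
        pm = phase_map(mov.t, mov.v, dx=mov.dx)
        sings = detect_singularities(pm, 15)
        assert sum(chi for _, _, chi in sings) == 0

    def test_smooth_gradient_field_has_no_singularities(self):
        t = np.arange(40.0)
        ys, xs = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        v = np.cos(0.2 * xs[None] + 0.1 * ys[None] - 0.3 * t[:, None, None])
        pm = phase_map(t, v)
        assert detect_singularities(pm, 20) == []

    def test_charge_conserved_between_frames(self):
        """Total chirality only changes via boundaries or pair events."""
        mov = gen_spiral_movie(lambda t: [(0.6, 1.0, 1), (1.3, 1.0, -1)],
                               duration=60.0)
        pm = phase_map(mov.t, mov.v, dx=mov.dx)
        charges = [sum(c for _, _, c in detect_singularities(pm, k))
                   for k in range(5, 55)]
        assert len(set(charges)) == 1


class TestTracking:
    def test_stationary_defect_yields_single_still_track(self):
        t, v, dx = _analytic_defect_movie(nt=100)
        pm = phase_map(t, v, dx)
        tracks = track_tip(pm)
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.t.size == 100
        assert np.hypot(tr.x.max() - tr.x.min(), tr.y.max() - tr.y.min()) < 2 * dx

    def test_scripted_circular_path_recovered(self):
        # tip speed kept small against the rotation period: the Hilbert
        # estimate acquires a radial bias for fast-translating tips
        R, c = 0.45, 0.96
        mov = gen_spiral_movie(
            lambda t: (c + R * np.cos(2 * np.pi * t / 240),
                       c + R * np.sin(2 * np.pi * t / 240)),
            duration=480.0)
        pm = phase_map(mov.t, mov.v, dx=mov.dx)
        tr = track_tip(pm)[0]
        truth = np.array([p[0][:2] for p in
                          [mov.tips[int(tt)] for tt in tr.t]])
        rms = np.sqrt(np.mean((tr.x - truth[:, 0]) ** 2
                              + (tr.y - truth[:, 1]) ** 2))
        assert rms < mov.dx

    def test_far_apart_defects_never_merge(self):
        mov = gen_spiral_movie(lambda t: [(0.5, 0.5, 1), (1.4, 1.4, 1)],
                               duration=60.0)
        pm = phase_map(mov.t, mov.v, dx=mov.dx)
        tracks = track_tip(pm)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.x) < 0.2 and np.ptp(tr.y) < 0.2


class TestEnclosingEllipse:
    def test_circle_gives_pi_r_squared(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        ell = enclosing_ellipse(pts)
        assert ell.area == pytest.approx(np.pi, rel=0.005)

    def test_identical_points_degenerate_zero_area(self):
        ell = enclosing_ellipse(np.tile([[1.0, 2.0]], (10, 1)))
        assert ell.degenerate
        assert ell.area == 0.0

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        assert enclosing_ellipse(pts).degenerate

    def test_rectangle_corners_match_brute_force_oracle(self):
        """2 x 1 rectangle corners: compare with a grid-search minimal ellipse."""
        pts = np.array([[-1.0, -0.5], [1.0, -0.5], [1.0, 0.5], [-1.0, 0.5]])
        ell = enclosing_ellipse(pts, tol=1e-6)
        # brute force over axis-aligned ellipses (symmetry makes centre 0):
        # smallest pi*a*b with (x/a)^2+(y/b)^2 <= 1 for all corners
        best = np.inf
        for a in np.linspace(1.0, 2.5, 600):
            s = 1.0 - 1.0 / a ** 2
            if s <= 0:
                continue
            b = np.sqrt(0.25 / s)
            if all((x / a) ** 2 + (y / b) ** 2 <= 1 + 1e-9 for x, y in pts):
                best = min(best, np.pi * a * b)
        assert ell.area == pytest.approx(best, rel=0.01)

    def test_interior_point_leaves_area_unchanged(self):
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([2 * np.cos(th), np.sin(th)])
        base = enclosing_ellipse(pts, tol=1e-6).area
        inside = np.vstack([pts, [[0.1, 0.05]]])
        assert enclosing_ellipse(inside, tol=1e-6).area == pytest.approx(
            base, rel=1e-3)

    def test_exterior_point_never_shrinks_area(self):
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        base = enclosing_ellipse(pts, tol=1e-6).area
        outside = np.vstack([pts, [[2.5, 0.0]]])
        assert enclosing_ellipse(outside, tol=1e-6).area >= base * (1 - 1e-6)

    def test_contains_all_trajectory_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        ell = enclosing_ellipse(pts, tol=1e-6)
        c, (a, b), ang = ell.center, ell.semi_axes, ell.orientation
        rot = np.array([[np.cos(ang), np.sin(ang)],
                        [-np.sin(ang), np.cos(ang)]])
        q = (pts - c) @ rot.T
        r = (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2
        assert np.mean(r <= 1.0 + 1e-2) >= 0.99
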