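"""Monodomain solver and S1-S2 pipeline tests.

Full-model tissue physics is checked on small strips (diffusion oracle,
conduction-velocity anisotropy, refinement); protocol classification and
the vulnerable-window scan run on the fast Barkley surrogate plugged into
the same stepper.
"""

from dataclasses import replace

import numpy as np
import pytest

import atrialab.courtemanche as cm
from atrialab.cell import ModelSpec
from atrialab.tissue import (CFLError, CrossFieldProtocol, TissueGrid,
                             cfl_limit, run_cross_field, scan_vw,
                             steady_state_1hz, step_monodomain, _laplacian)

BARKLEY_PROTO = CrossFieldProtocol(
    s1_count=2, s1_bcl=300.0, s2_size=(1.2, 1.6), interval=120.0,
    amplitude=2.0, duration=1.0, post_s2=400.0, dt=0.05, snapshot_dt=2.0)


def _barkley_grid():
    return TissueGrid(size=(3.0, 3.0), dx=0.03, model="barkley")


def _planar_activation(grid, dt, stim_rows, t_max):
    stim = np.zeros((grid.ny, grid.nx))
    stim[:, :stim_rows] = 40.0
    act = np.full((grid.ny, grid.nx), np.nan)
    t = 0.0
    while t < t_max:
        step_monodomain(grid, dt, stim if t < 2.0 else None)
        t += dt
        new = (grid.v > grid.active_level) & np.isnan(act)
        act[new] = t
    return act


def _planar_cv(dx, dt, along=True, length=2.0):
    size = (length, 0.24) if along else (0.24, length)
    g = TissueGrid(size=size, dx=dx, model="courtemanche")
    stim = np.zeros((g.ny, g.nx))
    n = max(2, int(round(0.12 / dx)))
    if along:
        stim[:, :n] = 40.0
    else:
        stim[:n, :] = 40.0
    act = np.full((g.ny, g.nx), np.nan)
    t = 0.0
    while t < 60.0:
        step_monodomain(g, dt, stim if t < 2.0 else None)
        t += dt
        new = (g.v > -40) & np.isnan(act)
        act[new] = t
    line = act[g.ny // 2, :] if along else act[:, g.nx // 2]
    i1, i2 = int(0.5 / dx), int(1.5 / dx)
    return 1.0 / (line[i2] - line[i1])  # cm/ms over 1 cm


class TestDiffusionOperator:
    def test_uniform_resting_tissue_is_a_fixed_point(self):
        g = TissueGrid(size=(0.9, 0.9), dx=0.03, model="courtemanche")
        v0 = g.v.copy()
        lap = np.empty_like(v0)
        _laplacian(v0, lap, g.dxx, g.dyy, g.dxy, g.dx)
        assert np.max(np.abs(lap)) < 1e-12
        for _ in range(200):  # 4 ms of full reaction-diffusion stepping
            step_monodomain(g, 0.02)
        # spatial uniformity is preserved exactly (diffusion adds nothing)
        assert np.max(np.abs(g.v - g.v.mean())) < 1e-6

    def test_gaussian_profile_follows_heat_kernel(self):
        """Pure diffusion (no reaction): sigma^2 grows by 2 D t within 1%."""
        dx, d = 0.01, 0.001
        x = np.arange(301) * dx
        sig0 = 0.15
        v = np.tile(np.exp(-((x - 1.5) ** 2) / (2 * sig0 ** 2)), (9, 1))
        lap = np.empty_like(v)
        dt, t_end = 0.01, 50.0
        for _ in range(int(t_end / dt)):
            _laplacian(v, lap, d, d, 0.0, dx)
            v += dt * lap
        prof = v[4]
        sig2 = np.sum(prof * (x - 1.5) ** 2) / np.sum(prof)
        assert sig2 == pytest.approx(sig0 ** 2 + 2 * d * t_end, rel=0.01)

    def test_cfl_violation_refused_with_bound(self):
        g = _barkley_grid()
        with pytest.raises(CFLError):
            step_monodomain(g, 10.0 * cfl_limit(g))


class TestConductionVelocity:
    @pytest.fixture(scope="class")
    def cvs(self):
        return {
            ("L", 0.015): _planar_cv(0.015, 0.01, along=True),
            ("T", 0.015): _planar_cv(0.015, 0.01, along=False),
            ("L", 0.0075): _planar_cv(0.0075, 0.005, along=True),
        }

    def test_longitudinal_cv_in_physiological_band(self, cvs):
        assert 0.060 <= cvs[("L", 0.015)] <= 0.075  # 60-75 cm/s

    def test_anisotropy_ratio_follows_sqrt_conductivity_ratio(self, cvs):
        ratio = cvs[("T", 0.015)] / cvs[("L", 0.015)]
        assert ratio == pytest.approx(np.sqrt(0.35), rel=0.05)

    def test_spatial_refinement_changes_cv_under_3pct(self, cvs):
        assert cvs[("L", 0.0075)] == pytest.approx(cvs[("L", 0.015)], rel=0.03)

    def test_time_refinement_changes_activation_map_under_1pct(self):
        maps = []
        for dt in (0.01, 0.005):
            g = TissueGrid(size=(1.2, 0.24), dx=0.03, model="courtemanche")
            act = _planar_activation(g, dt, 4, 25.0)
            maps.append(act)
        m0, m1 = maps
        ok = np.isfinite(m0) & np.isfinite(m1)
        # < 1% per node, above the +-dt quantisation floor of activation times
        tol = np.maximum(0.01 * m1[ok], 0.03)
        assert np.all(np.abs(m0[ok] - m1[ok]) < tol)


class TestCrossField:
    @pytest.fixture(scope="class")
    def outcomes(self):
        out = {}
        for iv in (60.0, 120.0, 250.0):
            out[iv] = run_cross_field(_barkley_grid(),
                                      replace(BARKLEY_PROTO, interval=iv))
        return out

    def test_s2_in_refractory_tissue_blocks(self, outcomes):
        assert outcomes[60.0].label == "block"

    def test_s2_on_the_refractory_tail_initiates_reentry(self, outcomes):
        out = outcomes[120.0]
        assert out.label == "reentry"
        assert out.cycles >= 2
        assert out.lifespan > 0

    def test_s2_after_full_recovery_propagates(self, outcomes):
        assert outcomes[250.0].label == "propagation"

    def test_sustained_flag_tracks_lifespan(self, outcomes):
        out = outcomes[120.0]
        assert out.sustained == (
            out.lifespan >= BARKLEY_PROTO.post_s2 - 2 * BARKLEY_PROTO.snapshot_dt)

    def test_mirrored_s2_mirrors_the_wave_pattern(self):
        """Reflecting the S2 region about the vertical midline reflects V."""
        def run(mirror):
            g = _barkley_grid()
            s1 = np.zeros((g.ny, g.nx))
            s1[:2, :] = 2.0
            s2 = np.zeros((g.ny, g.nx))
            s2[:54, :40] = 2.0
            if mirror:
                s2 = s2[:, ::-1]
            t = 0.0
            while t < 180.0:
                stim = None
                if t < 1.0:
                    stim = s1
                elif 120.0 <= t < 121.0:
                    stim = s2
                step_monodomain(g, 0.05, stim)
                t += 0.05
            return g.v.copy()

        a = run(False)
        b = run(True)
        np.testing.assert_allclose(a, b[:, ::-1], atol=1e-8)


class TestVulnerableWindowScan:
    def test_window_located_with_classes(self):
        coarse = np.array([60.0, 100.0, 140.0, 180.0, 220.0])
        vw = scan_vw(_barkley_grid, BARKLEY_PROTO, coarse, fine_step=5.0,
                     class_step=20.0)
        assert vw.lower is not None
        assert vw.width > 0
        fr = vw.class_fractions()
        assert sum(fr.values()) == pytest.approx(1.0)
        labels = {lab for lab, _, _ in vw.lifespans.values()}
        assert "reentry" in labels

    def test_empty_window_is_valid(self):
        coarse = np.array([280.0, 320.0])
        vw = scan_vw(_barkley_grid, BARKLEY_PROTO, coarse)
        assert vw.lower is None and vw.width == 0.0


class TestGridSetup:
    def test_geometry_defaults_match_study(self):
        g = TissueGrid()
        assert (g.nx, g.ny) == (167, 167)  # 5 cm at 300 um
        assert g.dxx == pytest.approx(0.0022)
        assert g.dyy == pytest.approx(0.35 * 0.0022)

    def test_invalid_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            TissueGrid(anisotropy=1.5)

    def test_1hz_steady_state_differs_from_rest(self):
        y = steady_state_1hz(ModelSpec("WT", "RA"), nbeats=3)
        assert y.shape == (cm.N_STATES,)
        assert abs(y[0] - cm.initial_state()[0]) < 10.0
        assert not np.allclose(y, cm.initial_state())
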