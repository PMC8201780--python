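"""2D anisotropic monodomain tissue: solver and S1-S2 vulnerability pipeline.

The membrane model on each node is either the full atrial cell model
(`model="courtemanche"`, any region x mutation) or the two-variable Barkley
excitable medium (`model="barkley"`), a fast surrogate with the same wave
phenomenology (planar waves, block, spiral re-entry) used for protocol and
analytics testing where the full model would take hours.

Numerics: first-order operator splitting — reaction (Rush-Larsen for gates,
forward Euler otherwise) then explicit 9-point anisotropic diffusion with
no-flux boundaries.  ``dt`` must respect the explicit diffusion stability
bound; the solver refuses otherwise.

Space in cm, time in ms.  The printed tissue conductivity of the study
(0.0022 S/(cm pF)) cannot be converted to a diffusion coefficient without a
surface-to-volume constant, so the longitudinal diffusivity ``D_L`` is an
explicit constant calibrated to put the longitudinal conduction velocity in
the physiological 60-75 cm/s band; the transverse diffusivity is
``anisotropy * D_L`` (conductivity-ratio convention, 0.35, giving a velocity
ratio of sqrt(0.35) ~ 0.59).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import courtemanche as cm
from .cell import ModelSpec, pace_cell

__all__ = [
    "TissueGrid",
    "CrossFieldProtocol",
    "S1S2Outcome",
    "VulnerableWindow",
    "SnapshotStore",
    "step_monodomain",
    "run_cross_field",
    "scan_vw",
    "steady_state_1hz",
    "cfl_limit",
]

D_L_DEFAULT = 0.0022   # cm^2/ms, calibrated: WT RA longitudinal CV ~ 70 cm/s


class CFLError(ValueError):
    """Time step exceeds the explicit diffusion stability bound."""


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _laplacian(v, out, dxx, dyy, dxy, h):
    """Anisotropic diffusion operator with mirrored (no-flux) boundaries."""
    ny, nx = v.shape
    inv_h2 = 1.0 / (h * h)
    for i in range(ny):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < ny - 1 else ny - 2
        for j in range(nx):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < nx - 1 else nx - 2
            vxx = v[i, jp] - 2.0 * v[i, j] + v[i, jm]
            vyy = v[ip, j] - 2.0 * v[i, j] + v[im, j]
            vxy = 0.25 * (v[ip, jp] - v[ip, jm] - v[im, jp] + v[im, jm])
            out[i, j] = (dxx * vxx + dyy * vyy + 2.0 * dxy * vxy) * inv_h2


@njit(cache=True)
def _step_crn(Y, lap, dt, stim, mp, reg, ach, dxx, dyy, dxy, h):
    """One reaction + diffusion step of the atrial-cell tissue."""
    ny, nx = Y.shape[0], Y.shape[1]
    inf = np.empty(15)
    tau = np.empty(15)
    do = np.empty(6)
    cur = np.empty(13)
    for i in range(ny):
        for j in range(nx):
            cm._step_rl(Y[i, j], dt, stim[i, j], mp, reg, ach,
                        inf, tau, do, cur)
    v = Y[:, :, 0].copy()
    _laplacian(v, lap, dxx, dyy, dxy, h)
    for i in range(ny):
        for j in range(nx):
            Y[i, j, 0] += dt * lap[i, j]


@njit(cache=True)
def _step_barkley(u, w, lap, dt, stim, a, b, eps, tau, dxx, dyy, dxy, h):
    ny, nx = u.shape
    _laplacian(u, lap, dxx, dyy, dxy, h)
    for i in range(ny):
        for j in range(nx):
            uu = u[i, j]
            thr = (w[i, j] + b) / a
            du = uu * (1.0 - uu) * (uu - thr) / (eps * tau) + lap[i, j] + stim[i, j]
            dw = (uu - w[i, j]) / tau
            u[i, j] = min(max(uu + dt * du, 0.0), 1.0)
            w[i, j] += dt * dw


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass
class TissueGrid:
    """Homogeneous 2D tissue patch.

    Defaults give the study geometry: 5 cm x 5 cm at 300 um spacing
    (167 x 167 nodes), fibres along +x, conductivity anisotropy 0.35.
    """

    size: tuple = (5.0, 5.0)     # cm (x, y)
    dx: float = 0.03             # cm (300 um)
    d_l: float = D_L_DEFAULT     # cm^2/ms
    anisotropy: float = 0.35     # sigma_T / sigma_L
    fiber_angle: float = 0.0     # rad from +x
    model: str = "courtemanche"
    spec: ModelSpec = field(default_factory=ModelSpec)
    barkley: tuple = (0.75, 0.02, 0.02, 20.0)   # a, b, eps, tau (ms)
    d_barkley: float = 1.0e-3             # cm^2/ms for the surrogate

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if not 0.0 < self.anisotropy <= 1.0:
            raise ValueError("anisotropy ratio must be in (0, 1]")
        # 5 cm at 300 um -> 167 x 167 nodes
        self.nx = int(round(self.size[0] / self.dx))
        self.ny = int(round(self.size[1] / self.dx))
        d_long = self.d_l if self.model == "courtemanche" else self.d_barkley
        d_t = self.anisotropy * d_long
        c, s = math.cos(self.fiber_angle), math.sin(self.fiber_angle)
        self.dxx = d_long * c * c + d_t * s * s
        self.dyy = d_long * s * s + d_t * c * c
        self.dxy = (d_long - d_t) * c * s
        self.reset()

    def reset(self, state: np.ndarray | None = None):
        """Set every node to the resting (or supplied) membrane state."""
        if self.model == "courtemanche":
            y0 = state if state is not None else cm.initial_state()
            self.Y = np.tile(y0, (self.ny, self.nx, 1)).astype(np.float64)
        elif self.model == "barkley":
            self.U = np.zeros((self.ny, self.nx))
            self.W = np.zeros((self.ny, self.nx))
        else:
            raise ValueError(f"unknown tissue model {self.model!r}")
        self._lap = np.empty((self.ny, self.nx))
        self.t = 0.0

    @property
    def v(self) -> np.ndarray:
        """Activation field: membrane potential (mV) or Barkley u."""
        return self.Y[:, :, 0] if self.model == "courtemanche" else self.U

    @property
    def rest_level(self) -> float:
        return -81.0 if self.model == "courtemanche" else 0.0

    @property
    def active_level(self) -> float:
        return -40.0 if self.model == "courtemanche" else 0.5


def cfl_limit(grid: TissueGrid) -> float:
    """Largest stable dt for the explicit diffusion update."""
    return grid.dx ** 2 / (2.0 * (grid.dxx + grid.dyy) + 4.0 * abs(grid.dxy))


def step_monodomain(grid: TissueGrid, dt: float,
                    stim: np.ndarray | None = None) -> None:
    """Advance the tissue one operator-split step (stim in pA/pF)."""
    if dt > cfl_limit(grid):
        raise CFLError(
            f"dt={dt} ms exceeds the stability bound {cfl_limit(grid):.4g} ms")
    if stim is None:
        stim = np.zeros((grid.ny, grid.nx))
    if grid.model == "courtemanche":
        mp, reg = grid.spec.arrays()
        _step_crn(grid.Y, grid._lap, dt, stim, mp, reg, grid.spec.ach,
                  grid.dxx, grid.dyy, grid.dxy, grid.dx)
    else:
        a, b, eps, tau = grid.barkley
        _step_barkley(grid.U, grid.W, grid._lap, dt, stim, a, b, eps, tau,
                      grid.dxx, grid.dyy, grid.dxy, grid.dx)
    grid.t += dt


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossFieldProtocol:
    """S1-S2 cross-field stimulation (defaults: study protocol).

    The S1-S2 interval is measured from the onset of the last S1; the S2
    rectangle sits in the bottom-left corner with node-inclusive edges.
    """

    s1_count: int = 10
    s1_bcl: float = 1000.0               # ms
    s1_width: float = 0.06               # cm, planar strip at the bottom edge
    s2_size: tuple = (1.8, 2.6)          # cm (x, y)
    interval: float = 220.0              # ms from onset of the last S1
    amplitude: float = 100.0             # pA/pF
    duration: float = 2.0                # ms
    post_s2: float = 5000.0              # ms simulated after S2
    dt: float = 0.01                     # ms
    snapshot_dt: float = 1.0             # ms

    def __post_init__(self):
        if self.duration <= 0 or self.s1_bcl <= 0 or self.post_s2 <= 0:
            raise ValueError("protocol durations must be > 0")
        if self.interval < 0:
            raise ValueError("S1-S2 interval must be >= 0")


@dataclass
class SnapshotStore:
    t: np.ndarray
    v: np.ndarray                # (nt, ny, nx) float32
    dx: float


@dataclass
class S1S2Outcome:
    interval: float
    label: str                   # block | reentry | propagation
    lifespan: float              # ms from S2 (reentry only, else 0)
    cycles: int
    snapshots: SnapshotStore
    sustained: bool = False


@dataclass
class VulnerableWindow:
    spec_label: str
    lower: float | None
    upper: float | None
    lifespans: dict              # interval -> (label, lifespan, sustained)

    @property
    def width(self) -> float:
        if self.lower is None:
            return 0.0
        return self.upper - self.lower

    def class_fractions(self) -> dict:
        """Fractions of reentry intervals per lifespan class."""
        spans = [(ls, sus) for (lab, ls, sus) in self.lifespans.values()
                 if lab == "reentry"]
        n = len(spans)
        if n == 0:
            return {"lt_1s": 0.0, "1_to_5s": 0.0, "sustained": 0.0}
        lt1 = sum(1 for ls, sus in spans if ls < 1000.0 and not sus)
        sus = sum(1 for ls, s in spans if s)
        mid = n - lt1 - sus
        return {"lt_1s": lt1 / n, "1_to_5s": mid / n, "sustained": sus / n}


def steady_state_1hz(spec: ModelSpec, nbeats: int = 61) -> np.ndarray:
    """Single-cell 1-Hz steady state used to pre-load the tissue."""
    y = cm.initial_state()
    mp, reg = spec.arrays()
    nrec = int(round(1000.0 / 0.02)) // 5
    v_out = np.empty((nbeats, nrec))
    st = np.empty((nrec, cm.N_STATES))
    cm._pace(y, 1000.0, nbeats, 20.0, 2.0, 0.02, mp, reg, spec.ach, 5,
             v_out, nbeats - 1, st)
    return y


def _masks(grid: TissueGrid, protocol: CrossFieldProtocol):
    s1 = np.zeros((grid.ny, grid.nx))
    rows = max(1, int(round(protocol.s1_width / grid.dx)))
    s1[:rows, :] = protocol.amplitude
    s2 = np.zeros((grid.ny, grid.nx))
    ny2 = int(round(protocol.s2_size[1] / grid.dx)) + 1
    nx2 = int(round(protocol.s2_size[0] / grid.dx)) + 1
    s2[:ny2, :nx2] = protocol.amplitude
    return s1, s2


def run_cross_field(grid: TissueGrid, protocol: CrossFieldProtocol,
                    reset: bool = True,
                    initial: np.ndarray | None = None) -> S1S2Outcome:
    """Run the S1-S2 cross-field protocol and classify the outcome.

    block: the S2 response dies without exciting tissue beyond the S2
    region; propagation: the S2 wave travels without chiral rotation;
    reentry: a phase singularity completes at least two cycles.  The rotor
    lifespan is the time from S2 to the last detected singularity.
    """
    from .phase import phase_map, track_tip

    if reset:
        grid.reset(initial)
    s1_mask, s2_mask = _masks(grid, protocol)
    zero = np.zeros_like(s1_mask)
    t_s2 = (protocol.s1_count - 1) * protocol.s1_bcl + protocol.interval
    t_end = t_s2 + protocol.post_s2
    dt = protocol.dt
    nsteps = int(round(t_end / dt))
    snap_every = max(1, int(round(protocol.snapshot_dt / dt)))
    snaps, times = [], []
    s2_on = None
    for k in range(nsteps):
        t = k * dt
        stim = zero
        tb = t % protocol.s1_bcl
        if (t < protocol.s1_count * protocol.s1_bcl and tb < protocol.duration):
            stim = s1_mask
        if t_s2 <= t < t_s2 + protocol.duration:
            stim = s2_mask if stim is zero else stim + s2_mask
        step_monodomain(grid, dt, stim)
        if t >= t_s2 and (k % snap_every == 0):
            snaps.append(grid.v.astype(np.float32).copy())
            times.append(t)
        if not np.isfinite(grid.v).all():
            raise RuntimeError(f"numerical blow-up at t={t:.2f} ms")
    store = SnapshotStore(t=np.array(times), v=np.array(snaps), dx=grid.dx)
    label, lifespan, cycles = _classify(store, grid, protocol, s2_mask)
    sustained = bool(label == "reentry"
                     and lifespan >= protocol.post_s2 - 2 * protocol.snapshot_dt)
    return S1S2Outcome(interval=protocol.interval, label=label,
                       lifespan=lifespan, cycles=cycles, snapshots=store,
                       sustained=sustained)


def _classify(store: SnapshotStore, grid: TissueGrid,
              protocol: CrossFieldProtocol, s2_mask: np.ndarray):
    from .phase import phase_map, track_tip

    v = store.v.astype(np.float64)
    active = grid.active_level
    # re-excitation probe: a band just beyond the S2 rectangle's +x edge,
    # where the conditioning S1 wave has already passed by the time S2 fires
    ny2 = int(s2_mask[:, 0].astype(bool).sum())
    nx2 = int(s2_mask[0, :].astype(bool).sum())
    band = v[:, : max(ny2 // 2, 1), nx2 + 2: nx2 + 8]
    crossed = (band[1:] > active) & (band[:-1] <= active)
    reexcited = bool(crossed.any())
    movie = phase_map(store.t, v, dx=store.dx)
    tracks = track_tip(movie, min_duration=10 * protocol.snapshot_dt)
    cycles = 0
    lifespan = 0.0
    if tracks:
        tr = tracks[0]
        cycles = _count_cycles(store, tr, active)
        last = max(t.t[-1] for t in tracks)
        lifespan = float(last - store.t[0])
    if cycles >= 2:
        return "reentry", lifespan, cycles
    if reexcited:
        return "propagation", 0.0, cycles
    return "block", 0.0, cycles


def _count_cycles(store: SnapshotStore, tr, active_level: float) -> int:
    """Activation recurrences at a probe ring node near the tip track."""
    cx = float(np.median(tr.x)) / store.dx
    cy = float(np.median(tr.y)) / store.dx
    ny, nx = store.v.shape[1:]
    best = 0
    for radius in (6, 10, 14):
        for ang in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            px = int(round(cx + radius * np.cos(ang)))
            py = int(round(cy + radius * np.sin(ang)))
            if not (0 <= px < nx and 0 <= py < ny):
                continue
            series = store.v[:, py, px]
            k0 = np.searchsorted(store.t, tr.t[0])
            k1 = np.searchsorted(store.t, tr.t[-1], side="right")
            s = series[k0:k1]
            up = np.sum((s[1:] > active_level) & (s[:-1] <= active_level))
            best = max(best, int(up))
    return best


def scan_vw(make_grid, protocol: CrossFieldProtocol,
            coarse: np.ndarray, fine_step: float = 1.0,
            class_step: float = 2.0,
            initial: np.ndarray | None = None) -> VulnerableWindow:
    """Locate the vulnerable window by a coarse-to-fine interval scan.

    ``make_grid()`` returns a fresh tissue for each run.  Reentry-positive
    coarse intervals seed boundary bisection to ``fine_step`` resolution;
    lifespan classes are then evaluated every ``class_step`` ms inside the
    window.  An empty window is a valid result.
    """
    results: dict[float, S1S2Outcome] = {}

    def outcome(iv: float) -> S1S2Outcome:
        iv = round(float(iv), 6)
        if iv not in results:
            grid = make_grid()
            results[iv] = run_cross_field(
                grid, replace(protocol, interval=iv), initial=initial)
        return results[iv]

    hits = [iv for iv in coarse if outcome(iv).label == "reentry"]
    if not hits:
        spans = {iv: (r.label, r.lifespan, r.sustained)
                 for iv, r in sorted(results.items())}
        return VulnerableWindow(spec_label=_grid_label(make_grid()),
                                lower=None, upper=None, lifespans=spans)
    lo, hi = min(hits), max(hits)
    step = float(coarse[1] - coarse[0]) if len(coarse) > 1 else fine_step

    def bisect(inside, outside):
        while abs(inside - outside) > fine_step:
            mid = round((inside + outside) / 2.0 / fine_step) * fine_step
            if mid in (inside, outside):
                break
            if outcome(mid).label == "reentry":
                inside = mid
            else:
                outside = mid
        return inside

    lo = bisect(lo, lo - step)
    hi = bisect(hi, hi + step)
    for iv in np.arange(lo, hi + class_step / 2, class_step):
        outcome(iv)
    spans = {iv: (r.label, r.lifespan, r.sustained)
             for iv, r in sorted(results.items())}
    return VulnerableWindow(spec_label=_grid_label(make_grid()),
                            lower=lo, upper=hi, lifespans=spans)


def _grid_label(grid: TissueGrid) -> str:
    return grid.spec.label if grid.model == "courtemanche" else "barkley"
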