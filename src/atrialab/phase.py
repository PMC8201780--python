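"""Phase analysis of tissue voltage movies: singularities, tips, meander.

The phase of each node is the angle of the analytic signal (Hilbert
transform) of its mean-subtracted voltage series.  A phase singularity is
an elementary 2x2 node loop whose wrapped phase differences wind by +-2*pi;
its time course is the rotor tip trajectory, and the minimum-area
enclosing ellipse of that trajectory quantifies rotor meander.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PhaseMovie",
    "TipTrajectory",
    "MeanderEllipse",
    "phase_map",
    "detect_singularities",
    "track_tip",
    "enclosing_ellipse",
]


@dataclass
class PhaseMovie:
    t: np.ndarray                # (nt,)
    phase: np.ndarray            # (nt, ny, nx), radians in (-pi, pi]
    dx: float = 1.0
    mask: np.ndarray | None = None   # True where phase is undefined


@dataclass
class TipTrajectory:
    """Time-stamped singularity track of constant chirality."""

    t: np.ndarray                # ms
    x: np.ndarray                # physical units (e.g. cm)
    y: np.ndarray
    chirality: int

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class MeanderEllipse:
    center: np.ndarray
    semi_axes: np.ndarray        # (a, b)
    orientation: float           # rad
    area: float                  # pi*a*b
    degenerate: bool = False


def phase_map(t: np.ndarray, v: np.ndarray, dx: float = 1.0) -> PhaseMovie:
    """Per-node Hilbert phase of a voltage movie (nt, ny, nx).

    Each node series is mean-subtracted before the analytic signal is
    taken; nodes that are constant in time have no defined phase and are
    masked.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 3 or v.shape[0] < 4:
        raise ValueError("movie must be (nt, ny, nx) with nt >= 4")
    centred = v - v.mean(axis=0, keepdims=True)
    flat = np.ptp(v, axis=0) < 1e-12
    analytic = hilbert(centred, axis=0)
    phase = np.angle(analytic)
    mask = np.broadcast_to(flat, v.shape)
    return PhaseMovie(t=np.asarray(t, dtype=float), phase=phase, dx=dx,
                      mask=mask)


def _wrap(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def detect_singularities(movie: PhaseMovie, frame: int):
    """Phase singularities of one frame as (x, y, chirality) tuples.

    Sums the wrapped phase differences around every elementary 2x2 loop;
    windings of +-2*pi mark singularities, located at the loop centroid.
    """
    ph = movie.phase[frame]
    # loop through corners (i,j) -> (i,j+1) -> (i+1,j+1) -> (i+1,j) -> back
    d1 = _wrap(ph[:-1, 1:] - ph[:-1, :-1])
    d2 = _wrap(ph[1:, 1:] - ph[:-1, 1:])
    d3 = _wrap(ph[1:, :-1] - ph[1:, 1:])
    d4 = _wrap(ph[:-1, :-1] - ph[1:, :-1])
    winding = d1 + d2 + d3 + d4
    if movie.mask is not None:
        m = movie.mask[frame]
        bad = m[:-1, :-1] | m[:-1, 1:] | m[1:, :-1] | m[1:, 1:]
        winding = np.where(bad, 0.0, winding)
    iy, ix = np.nonzero(np.abs(winding) > np.pi)  # |sum| ~ 2*pi
    out = []
    for yy, xx in zip(iy, ix):
        chi = 1 if winding[yy, xx] > 0 else -1
        sx, sy = _subgrid_position(ph, yy, xx)
        out.append(((xx + sx) * movie.dx, (yy + sy) * movie.dx, chi))
    return out


def _subgrid_position(ph, iy, ix):
    """Sub-grid singularity location inside a winding 2x2 plaquette.

    The singularity is the zero of the bilinearly interpolated analytic
    signal e^(i*phase); a couple of Newton steps from the plaquette centre
    refine the centroid estimate.
    """
    z = np.exp(1j * ph[iy:iy + 2, ix:ix + 2])
    z00, z01 = z[0, 0], z[0, 1]
    z10, z11 = z[1, 0], z[1, 1]
    s = t = 0.5  # s along x, t along y
    for _ in range(8):
        f = (z00 * (1 - s) * (1 - t) + z01 * s * (1 - t)
             + z10 * (1 - s) * t + z11 * s * t)
        dfs = (z01 - z00) * (1 - t) + (z11 - z10) * t
        dft = (z10 - z00) * (1 - s) + (z11 - z01) * s
        jac = np.array([[dfs.real, dft.real], [dfs.imag, dft.imag]])
        try:
            step = np.linalg.solve(jac, [f.real, f.imag])
        except np.linalg.LinAlgError:
            break
        s, t = s - step[0], t - step[1]
        if not (np.isfinite(s) and np.isfinite(t)):
            return 0.5, 0.5
        if abs(step[0]) + abs(step[1]) < 1e-10:
            break
    return float(np.clip(s, 0.0, 1.0)), float(np.clip(t, 0.0, 1.0))


def track_tip(movie: PhaseMovie, max_jump_per_ms: float | None = None,
              min_duration: float = 10.0):
    """Link per-frame singularities into tip trajectories.

    Greedy nearest-neighbour linking with a same-chirality constraint and a
    maximum jump of 5 grid spacings per ms; tracks shorter than
    ``min_duration`` (ms) are discarded.  Returns trajectories sorted by
    duration (longest, the principal rotor, first).
    """
    t = movie.t
    if max_jump_per_ms is None:
        max_jump_per_ms = 5.0 * movie.dx
    active: list[dict] = []
    done: list[dict] = []
    for k in range(t.size):
        sings = detect_singularities(movie, k)
        used = [False] * len(sings)
        next_active = []
        for tr in active:
            dt = t[k] - tr["t"][-1]
            limit = max_jump_per_ms * max(dt, 1e-9)
            best, best_d = None, np.inf
            for i, (x, y, chi) in enumerate(sings):
                if used[i] or chi != tr["chi"]:
                    continue
                d = np.hypot(x - tr["x"][-1], y - tr["y"][-1])
                if d < best_d:
                    best, best_d = i, d
            if best is not None and best_d <= limit:
                x, y, chi = sings[best]
                used[best] = True
                tr["t"].append(t[k]); tr["x"].append(x); tr["y"].append(y)
                next_active.append(tr)
            else:
                done.append(tr)
        for i, (x, y, chi) in enumerate(sings):
            if not used[i]:
                next_active.append({"t": [t[k]], "x": [x], "y": [y], "chi": chi})
        active = next_active
    done.extend(active)
    tracks = [
        TipTrajectory(t=np.array(tr["t"]), x=np.array(tr["x"]),
                      y=np.array(tr["y"]), chirality=tr["chi"])
        for tr in done
        if (tr["t"][-1] - tr["t"][0]) >= min_duration or len(tr["t"]) == t.size
    ]
    tracks.sort(key=lambda tr: -tr.duration)
    return tracks


def enclosing_ellipse(traj, tol: float = 1e-3, max_iter: int = 2000) -> MeanderEllipse:
    """Minimum-area (Loewner-John) enclosing ellipse of a tip trajectory.

    Khachiyan's algorithm on the trajectory points; the returned area is
    pi*a*b in the squared units of the coordinates.  Fewer than three
    non-collinear points give a degenerate zero-area result.
    """
    pts = traj.points if isinstance(traj, TipTrajectory) else np.asarray(traj, float)
    pts = np.atleast_2d(pts)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 3 or _collinear(uniq):
        c = pts.mean(axis=0)
        return MeanderEllipse(center=c, semi_axes=np.zeros(2), orientation=0.0,
                              area=0.0, degenerate=True)
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T       # (3, n)
    u = np.full(n, 1.0 / n)
    err = np.inf
    it = 0
    while err > tol and it < max_iter:
        x_mat = q @ np.diag(u) @ q.T
        m = np.einsum("ij,ji->i", q.T @ np.linalg.inv(x_mat), q)
        j = int(np.argmax(m))
        step = (m[j] - d - 1.0) / ((d + 1.0) * (m[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = np.linalg.norm(new_u - u)
        u = new_u
        it += 1
    center = pts.T @ u
    cov = pts.T @ np.diag(u) @ pts - np.outer(center, center)
    a_mat = np.linalg.inv(cov) / d
    evals, evecs = np.linalg.eigh(a_mat)
    semi = 1.0 / np.sqrt(evals)          # descending semi-axes after sort
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    v0 = evecs[:, order[0]]
    return MeanderEllipse(center=center, semi_axes=semi,
                          orientation=float(np.arctan2(v0[1], v0[0])),
                          area=float(np.pi * semi[0] * semi[1]))


def _collinear(pts: np.ndarray, tol: float = 1e-12) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[-1] <= tol * max(1.0, s[0])
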