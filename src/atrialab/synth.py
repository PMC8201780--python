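"""Synthetic data generators: clamp datasets, stylised AP pulses, spiral movies.

These make every analysis stage testable without external data: clamp
datasets with known ground-truth parameters and additive gaussian noise,
analytic action-potential pulses with known APD90, and scripted
spiral-phase voltage movies with known rotor-tip position at every frame.
All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clamp import ClampDataset, ClampProtocol, simulate_clamp
from .params import MutationParameterSet

__all__ = ["gen_clamp_dataset", "gen_ap_pulse", "gen_spiral_movie", "SpiralMovie"]


def gen_clamp_dataset(true_params: MutationParameterSet | None,
                      channel: str = "IKr",
                      protocol: ClampProtocol | None = None,
                      noise_sd: float = 0.0,
                      seed: int = 0) -> tuple[ClampDataset, MutationParameterSet]:
    """Clamp dataset simulated from known parameters plus gaussian noise.

    Values are ``simulate_clamp(true_params) + N(0, sd^2)``; the
    uncertainty column is ``sd`` (or a 5%-of-|value| floor when sd = 0).
    Returns the dataset together with the ground-truth record.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    p = true_params or MutationParameterSet()
    ds = simulate_clamp(p, protocol, channel)
    df = ds.df.copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        df["value"] = df["value"] + rng.normal(0.0, noise_sd, size=len(df))
        df["uncertainty"] = noise_sd
    else:
        df["uncertainty"] = np.maximum(0.05 * df["value"].abs(), 1e-6)
    return ClampDataset(df, protocol=ds.protocol), p


def gen_ap_pulse(shape: str = "square", amplitude: float = 100.0,
                 duration: float = 250.0, v_rest: float = -80.0,
                 dt: float = 0.1, total: float | None = None,
                 time_scale: float = 1.0):
    """Stylised AP voltage trace with analytically known APD90.

    square: plateau of ``duration`` then instant return (APD90 = duration).
    triangular: instant upstroke then linear repolarisation over
    ``duration`` (APD90 = 0.9 * duration).
    spike_and_dome: piecewise template (spike, notch, dome, repolarisation)
    whose timing stretches with ``time_scale``.
    Returns ``(t, v)``.
    """
    if total is None:
        total = duration * time_scale + 100.0
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, v_rest)
    t0 = 2.0  # stimulus-free onset offset
    if shape == "square":
        on = (t >= t0) & (t < t0 + duration * time_scale)
        v[on] = v_rest + amplitude
    elif shape == "triangular":
        tt = (t - t0) / time_scale
        on = (tt >= 0) & (tt < duration)
        v[on] = v_rest + amplitude * (1.0 - tt[on] / duration)
    elif shape == "spike_and_dome":
        tt = (t - t0) / time_scale
        knots = np.array([0.0, 2.0, 8.0, 40.0, 0.75 * duration, duration])
        levels = v_rest + amplitude * np.array([1.0, 0.62, 0.72, 0.70, 0.35, 0.0])
        on = (tt >= 0) & (tt <= duration)
        v[on] = np.interp(tt[on], knots, levels)
        v[t < t0] = v_rest
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    return t, v


@dataclass
class SpiralMovie:
    """Voltage movie with scripted rotor tips.

    ``v`` has shape (nt, ny, nx); ``tips`` maps frame index to the list of
    scripted (x, y, chirality) tips, in the same physical units as ``dx``.
    """

    t: np.ndarray
    v: np.ndarray
    dx: float
    tips: list


def gen_spiral_movie(tip_path, frequency: float = 0.05, nx: int = 64,
                     ny: int = 64, dx: float = 0.03, duration: float = 200.0,
                     frame_dt: float = 1.0, amplitude: float = 50.0,
                     wavelength: float = 1.0, offset: float = -20.0) -> SpiralMovie:
    """Archimedean-spiral voltage movie around one or more scripted tips.

    ``tip_path(t)`` returns either ``(x, y)`` (single clockwise tip) or a
    list of ``(x, y, chirality)``.  The voltage is ``offset + A*cos(theta)``
    with ``theta`` the sum of spiral phases ``chirality*atan2(dy, dx) +
    2*pi*(r/wavelength - frequency*t)`` over tips; the scripted tip
    positions are stored per frame.
    """
    t = np.arange(0.0, duration, frame_dt)
    ys, xs = np.meshgrid(np.arange(ny) * dx, np.arange(nx) * dx, indexing="ij")
    v = np.empty((t.size, ny, nx))
    tips = []
    for k, tk in enumerate(t):
        p = tip_path(tk)
        if isinstance(p, tuple) and len(p) == 2:
            p = [(p[0], p[1], 1)]
        theta = np.zeros((ny, nx))
        for (x0, y0, chi) in p:
            r = np.hypot(xs - x0, ys - y0)
            theta += chi * np.arctan2(ys - y0, xs - x0) + 2 * np.pi * (
                r / wavelength)
        theta -= 2 * np.pi * frequency * tk
        v[k] = offset + amplitude * np.cos(theta)
        tips.append([(float(x0), float(y0), int(chi)) for (x0, y0, chi) in p])
    return SpiralMovie(t=t, v=v, dx=dx, tips=tips)
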