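"""Single-cell biomarker pipeline: pacing, APD90, restitution, alternans.

The study protocol paces each of the twelve region x genotype cell models for
61 beats (60 s of 1-Hz stabilisation plus the analysis beat) with 2-ms,
20-pA/pF stimuli; the action potential and currents of the final beat supply
the biomarkers.  Restitution curves record the beat-61 APD90 at each basic
cycle length (BCL) of an independent pacing run, and their maximum slope is
an arrhythmia-susceptibility index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import ModelSpec, PaceResult, pace_cell

__all__ = [
    "PacingProtocol",
    "RestitutionCurve",
    "pace_train",
    "apd90",
    "restitution",
    "max_slope",
    "detect_alternans",
    "biomarker_delta",
    "biomarkers",
]


@dataclass(frozen=True)
class PacingProtocol:
    """Constant-BCL stimulus train (defaults: study protocol)."""

    bcl: float = 1000.0          # ms
    n_beats: int = 61
    amplitude: float = 20.0      # pA/pF
    duration: float = 2.0        # ms
    dt: float = 0.01             # ms, fixed-step integrator
    out_dt: float = 0.1          # ms, recording cadence


@dataclass
class BeatAnalysis:
    """Biomarkers of one analysed beat."""

    spec: ModelSpec
    protocol: PacingProtocol
    apd90: float
    peak_ikr: float              # pA
    peak_ito: float              # pA
    v_rest: float
    v_peak: float
    captured: bool
    apd_last_beats: np.ndarray   # APD90 of the trailing beats (ends at analysis beat)
    steady_error: float          # |APD90(analysis) - APD90(previous)| in ms
    result: PaceResult


class ApdUndefinedError(ValueError):
    """The trace holds no action potential or no 90% crossing."""


def apd90(t: np.ndarray, v: np.ndarray) -> float:
    """APD90 of a single-AP voltage trace.

    Measured from the time of maximum upstroke velocity to the crossing of
    ``V90 = Vpeak - 0.9*(Vpeak - Vrest)``, with Vrest the pre-stimulus
    voltage (first sample) and linear interpolation between samples.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.size < 4:
        raise ValueError("t and v must be equal-length arrays (>= 4 samples)")
    dv = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dv))
    t_up = t[i_up]
    v_rest = v[0]
    i_peak = int(np.argmax(v))
    v_peak = v[i_peak]
    if v_peak - v_rest < 10.0:
        raise ApdUndefinedError("no action potential in trace")
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.nonzero(v[i_peak:] <= v90)[0]
    if below.size == 0:
        raise ApdUndefinedError("no 90% repolarisation crossing before trace end")
    i = i_peak + below[0]
    if i == 0 or v[i] == v[i - 1]:
        t90 = t[i]
    else:
        # linear interpolation across the crossing sample pair
        t90 = t[i - 1] + (v[i - 1] - v90) / (v[i - 1] - v[i]) * (t[i] - t[i - 1])
    return float(t90 - t_up)


def _beat_apds(res: PaceResult, n: int) -> np.ndarray:
    """APD90 of the last ``n`` beats; NaN where undefined (failed capture)."""
    t = res.t_beat
    out = np.full(n, np.nan)
    for k, row in enumerate(res.v[-n:]):
        try:
            out[k] = apd90(t, row)
        except (ApdUndefinedError, ValueError):
            pass
    return out


def pace_train(spec: ModelSpec, protocol: PacingProtocol = PacingProtocol(),
               n_trailing: int = 12) -> BeatAnalysis:
    """Pace to steady behaviour and analyse the final (61st) beat.

    A failed capture (no AP on the analysis beat) is reported through
    ``captured=False`` rather than an exception.
    """
    res = pace_cell(spec, bcl=protocol.bcl, nbeats=protocol.n_beats,
                    amplitude=protocol.amplitude, duration=protocol.duration,
                    dt=protocol.dt, out_dt=protocol.out_dt)
    apds = _beat_apds(res, min(n_trailing, protocol.n_beats))
    t = res.t_beat
    v = res.analysis_v
    captured = np.isfinite(apds[-1])
    steady = abs(apds[-1] - apds[-2]) if np.isfinite(apds[-2:]).all() else np.nan
    return BeatAnalysis(
        spec=spec, protocol=protocol,
        apd90=float(apds[-1]) if captured else np.nan,
        peak_ikr=float(res.current("IKr").max()),
        peak_ito=float(res.current("Ito").max()),
        v_rest=float(v[0]), v_peak=float(v.max()),
        captured=bool(captured),
        apd_last_beats=apds, steady_error=float(steady), result=res,
    )


def detect_alternans(apds: np.ndarray, threshold: float = 2.0,
                     min_sign_changes: int = 8) -> bool:
    """Beat-to-beat APD alternans flag over the trailing beats.

    Uses the last 11 APD values (10 consecutive differences): flags when the
    mean absolute difference exceeds ``threshold`` (ms) and the differences
    alternate in sign for at least ``min_sign_changes`` of the 9 adjacent
    difference pairs.  NaNs (failed captures) suppress the flag.
    """
    a = np.asarray(apds, dtype=float)
    if a.size < 11:
        raise ValueError("need at least 11 trailing APD values")
    a = a[-11:]
    if not np.all(np.isfinite(a)):
        return False
    d = np.diff(a)
    if np.mean(np.abs(d)) <= threshold:
        return False
    sign_changes = int(np.sum(d[:-1] * d[1:] < 0))
    return sign_changes >= min(min_sign_changes, d.size - 1)


@dataclass
class RestitutionCurve:
    """APD90 restitution: beat-61 APD90 against BCL.

    ``apd_alt`` stores the two alternating APD branches (last two beats) so
    alternating points keep both values; ``alternans`` flags them.
    """

    spec: ModelSpec
    bcl: np.ndarray
    apd: np.ndarray
    apd_alt: np.ndarray          # shape (n, 2): APD of beats 60 and 61
    alternans: np.ndarray        # bool per BCL
    captured: np.ndarray         # bool per BCL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bcl_ms": self.bcl, "apd90_ms": self.apd,
            "apd90_prev_ms": self.apd_alt[:, 0],
            "alternans": self.alternans, "captured": self.captured,
        })


def restitution(spec: ModelSpec, bcl_min: float = 300.0, bcl_max: float = 1700.0,
                step: float = 10.0, protocol: PacingProtocol = PacingProtocol(),
                alternans_threshold: float = 2.0) -> RestitutionCurve:
    """Restitution curve from independent 61-beat runs at each BCL.

    Every BCL starts from the same rested initial state; the beat-61 APD90 is
    recorded, alternans is flagged from the trailing 11 beats, and BCLs with
    failed capture are flagged rather than raising.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    bcls = np.arange(bcl_min, bcl_max + step / 2, step)
    n = bcls.size
    apd = np.full(n, np.nan)
    apd_alt = np.full((n, 2), np.nan)
    alt = np.zeros(n, dtype=bool)
    cap = np.zeros(n, dtype=bool)
    for i, bcl in enumerate(bcls):
        res = pace_cell(spec, bcl=float(bcl), nbeats=protocol.n_beats,
                        amplitude=protocol.amplitude, duration=protocol.duration,
                        dt=protocol.dt, out_dt=protocol.out_dt)
        apds = _beat_apds(res, 11)
        apd[i] = apds[-1]
        apd_alt[i] = apds[-2:]
        cap[i] = np.isfinite(apds[-1])
        try:
            alt[i] = detect_alternans(apds, threshold=alternans_threshold)
        except ValueError:
            alt[i] = False
    return RestitutionCurve(spec=spec, bcl=bcls, apd=apd, apd_alt=apd_alt,
                            alternans=alt, captured=cap)


def max_slope(curve: RestitutionCurve, exclude_alternans: bool = True) -> float:
    """Maximum centred finite-difference slope dAPD90/dBCL of the curve.

    Alternans-flagged and uncaptured BCLs are excluded.
    """
    keep = curve.captured & np.isfinite(curve.apd)
    if exclude_alternans:
        keep &= ~curve.alternans
    b = curve.bcl[keep]
    a = curve.apd[keep]
    if b.size < 2:
        raise ValueError("fewer than two usable restitution points")
    return float(np.max(np.gradient(a, b)))


def biomarkers(mutation: str, region: str,
               protocol: PacingProtocol = PacingProtocol()) -> BeatAnalysis:
    return pace_train(ModelSpec(mutation, region), protocol)


def biomarker_delta(mutant: BeatAnalysis, wt: BeatAnalysis,
                    mutant_slope: float | None = None,
                    wt_slope: float | None = None) -> pd.DataFrame:
    """Percent changes of the biomarkers, mutant relative to wild type.

    Both runs must share region and protocol.  Slopes are optional (they
    need a full restitution scan).
    """
    if mutant.spec.region != wt.spec.region:
        raise ValueError("runs are from different regions")
    if mutant.protocol != wt.protocol:
        raise ValueError("runs used different pacing protocols")

    def pct(m, w):
        return 100.0 * (m - w) / w

    rows = {
        "apd90": pct(mutant.apd90, wt.apd90),
        "peak_ikr": pct(mutant.peak_ikr, wt.peak_ikr),
        "peak_ito": pct(mutant.peak_ito, wt.peak_ito),
    }
    if mutant_slope is not None and wt_slope is not None:
        rows["max_slope"] = pct(mutant_slope, wt_slope)
    return pd.DataFrame(
        {"biomarker": list(rows), "pct_change": list(rows.values()),
         "mutation": mutant.spec.mutation, "region": mutant.spec.region}
    )
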