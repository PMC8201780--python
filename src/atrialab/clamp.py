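"""Voltage-clamp observables of the parameterised I_Kr / I_to channels.

This module provides the channel-level view used for fitting: steady-state
and time-constant curves derived from the mutation-parameterised rate
constants (``x_inf = alpha/(alpha+beta)``, ``tau = 1/(alpha+beta)``, with
the Q10 factor retained for the oi gate), and simulated step protocols that
produce the quantities experimental electrophysiologists report —
activating/tail currents, I-V relationships, deactivation time constants
and steady-state inactivation curves.

Because a clamped gate is first order at fixed voltage, each protocol
segment relaxes in closed form; protocol simulation is exact up to the
output sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import courtemanche as cm
from .params import MutationParameterSet

__all__ = [
    "ClampDataset",
    "ClampProtocol",
    "IKR_PROTOCOL",
    "IKR_PROTOCOL_SHORT",
    "ITO_PROTOCOL",
    "gate_curves",
    "simulate_clamp",
    "predict_quantity",
    "sensitivity_scan",
    "QUANTITIES",
]

EK_CLAMP = cm.RTF * np.log(cm.KO / 139.0)   # Nernst potential at reference K levels

QUANTITIES = ("activating_peak", "tail_peak", "deactivation_tau",
              "iv_peak", "ss_inactivation")

_UNITS = {
    "activating_peak": "pA/pF",
    "tail_peak": "pA/pF",
    "iv_peak": "pA/pF",
    "deactivation_tau": "ms",
    "ss_inactivation": "norm",
}


@dataclass(frozen=True)
class ClampProtocol:
    """Step/tail voltage-clamp protocol.

    ``step_voltages`` are the depolarising (or hyperpolarising) test steps
    from ``holding``; for inactivation protocols they are the prepulse
    voltages and ``test_voltage`` is the fixed test step.
    """

    holding: float = -80.0                   # mV
    step_voltages: tuple = tuple(range(-60, 61, 10))
    step_duration: float = 2000.0            # ms
    tail_voltage: float = -40.0              # mV
    tail_duration: float = 2000.0            # ms
    test_voltage: float = 40.0               # mV (inactivation protocols)
    test_duration: float = 500.0             # ms
    tail_voltages: tuple = tuple(range(-120, -29, 5))   # deactivation scan
    #: oi-gate time-constant scan: recovery side (-120..-60) plus the decay
    #: of the transient at depolarised test voltages
    recovery_voltages: tuple = tuple(range(-120, -59, 10)) + (0, 20, 40)

    def __post_init__(self):
        if self.step_duration <= 0 or self.tail_duration <= 0 or self.test_duration <= 0:
            raise ValueError("protocol durations must be > 0")


#: I_Kr: 2-s steps, tail at -40 mV; deactivation tau read at -120..-30 mV
IKR_PROTOCOL = ClampProtocol()
#: short-step I_Kr variant: 250-ms steps leave activation far from steady
#: state, so the currents carry activation-kinetics information
IKR_PROTOCOL_SHORT = ClampProtocol(step_duration=250.0, tail_duration=500.0)
#: I_to: 500-ms steps; inactivation via 1-s prepulses then a +40 mV test
#: step; recovery-from-inactivation tau read at -120..-60 mV
ITO_PROTOCOL = ClampProtocol(step_voltages=tuple(range(-40, 61, 10)),
                             step_duration=500.0, tail_duration=500.0,
                             tail_voltages=tuple(range(-90, 11, 10)))


class ClampDataset:
    """Tabular clamp records: (channel, quantity, voltage, value, uncertainty, weight).

    The same schema serves experimental uploads, simulated output and
    synthetic fixtures, so they are interchangeable as fitting targets.
    """

    COLUMNS = ("channel", "quantity", "voltage_mV", "value", "units",
               "uncertainty", "weight")

    def __init__(self, df: pd.DataFrame, validate: bool = True,
                 protocol: "ClampProtocol | None" = None):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"clamp dataset missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        #: protocol under which the records were measured/simulated (optional)
        self.protocol = protocol
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValueError("clamp dataset needs at least one record")
        if not np.all(np.isfinite(df["voltage_mV"])):
            raise ValueError("voltages must be finite")
        if not np.all(df["uncertainty"] > 0):
            raise ValueError("uncertainties must be > 0")
        if not np.all(df["weight"] >= 0):
            raise ValueError("weights must be >= 0")
        bad = set(df["quantity"]) - set(QUANTITIES)
        if bad:
            raise ValueError(f"unknown quantities: {sorted(bad)}")

    @classmethod
    def from_records(cls, records: list[dict], channel: str,
                     protocol: "ClampProtocol | None" = None) -> "ClampDataset":
        df = pd.DataFrame(records)
        df["channel"] = channel
        if "units" not in df:
            df["units"] = df["quantity"].map(_UNITS)
        if "weight" not in df:
            df["weight"] = 1.0
        return cls(df[list(cls.COLUMNS)], protocol=protocol)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClampDataset":
        return cls(pd.read_csv(path))

    def groups(self):
        """Iterate (channel, quantity) -> sub-frame."""
        return self.df.groupby(["channel", "quantity"], sort=False)

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# Gate curves
# ---------------------------------------------------------------------------

def _rates(gate: str, v: np.ndarray, params: MutationParameterSet | None):
    v = np.atleast_1d(np.asarray(v, dtype=float))
    alpha = np.empty_like(v)
    beta = np.empty_like(v)
    for i, vi in enumerate(v):
        alpha[i], beta[i] = cm.gate_rates(gate, float(vi), params)
    return alpha, beta


def gate_curves(gate: str, params: MutationParameterSet | None,
                voltages: np.ndarray):
    """Steady-state and time-constant curves of a parameterised gate.

    Returns ``(x_inf, tau)`` with ``x_inf = alpha/(alpha+beta)`` and
    ``tau = 1/(alpha+beta)`` (divided by the Q10 factor for the oi gate,
    matching the temperature scaling used in the cell model).
    """
    voltages = np.atleast_1d(np.asarray(voltages, dtype=float))
    if voltages.size == 0:
        raise ValueError("voltage grid must be non-empty")
    alpha, beta = _rates(gate, voltages, params)
    x_inf = alpha / (alpha + beta)
    tau = 1.0 / (alpha + beta)
    if gate == "oi":
        tau = tau / cm.KQ10
    return x_inf, tau


def _oa_curves(voltages: np.ndarray):
    """Baseline oa activation gate (not mutation-parameterised)."""
    v = np.asarray(voltages, dtype=float)
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    inf = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tau = 1.0 / ((a + b) * cm.KQ10)
    return inf, tau


# ---------------------------------------------------------------------------
# Quantity predictions (closed-form segment relaxation)
# ---------------------------------------------------------------------------

def _ikr_density(v, xr, p):
    """I_Kr density (pA/pF) with instantaneous rectification."""
    rect = 1.0 + np.exp((v + 15.0 + p.p7r) / (22.4 * p.p8r))
    return p.p6r * cm.G_KR * xr * (v - EK_CLAMP) / rect


def _ito_density(v, oa, oi, p):
    return p.p6t * cm.G_TO * oa ** 3 * oi * (v - EK_CLAMP)


def predict_quantity(params: MutationParameterSet | None, channel: str,
                     quantity: str, voltages: np.ndarray,
                     protocol: ClampProtocol | None = None,
                     peak_mode: str = "end_of_step",
                     tau_mode: str = "analytic") -> np.ndarray:
    """Model value of one clamp quantity at the requested voltages.

    ``peak_mode``: for slowly activating I_Kr the "activating peak" is the
    end-of-step current by default ("max_during_step" is also available).
    ``tau_mode``: deactivation tau analytically (1/(alpha+beta)) or from a
    mono-exponential fit of the simulated tail ("fit"); the two agree for a
    first-order gate.
    """
    p = params or MutationParameterSet()
    voltages = np.atleast_1d(np.asarray(voltages, dtype=float))
    if channel == "IKr":
        proto = protocol or IKR_PROTOCOL
        inf_h, _ = gate_curves("xr", p, [proto.holding])
        xr0 = inf_h[0]
        inf_s, tau_s = gate_curves("xr", p, voltages)
        xr_end = inf_s + (xr0 - inf_s) * np.exp(-proto.step_duration / tau_s)
        if quantity in ("activating_peak", "iv_peak"):
            if peak_mode == "end_of_step":
                return _ikr_density(voltages, xr_end, p)
            t = np.linspace(0.0, proto.step_duration, 400)
            xr_t = inf_s[:, None] + (xr0 - inf_s[:, None]) * np.exp(-t / tau_s[:, None])
            cur = _ikr_density(voltages[:, None], xr_t, p)
            return np.max(np.abs(cur), axis=1) * np.sign(voltages - EK_CLAMP)
        if quantity == "tail_peak":
            vt = proto.tail_voltage
            inf_t, tau_t = gate_curves("xr", p, [vt])
            t = np.linspace(0.0, proto.tail_duration, 400)
            xr_t = inf_t[0] + (xr_end[:, None] - inf_t[0]) * np.exp(-t / tau_t[0])
            cur = _ikr_density(vt, xr_t, p)
            k = np.argmax(np.abs(cur), axis=1)
            return cur[np.arange(cur.shape[0]), k]
        if quantity == "deactivation_tau":
            if tau_mode == "analytic":
                _, tau = gate_curves("xr", p, voltages)
                return tau
            return _fit_tail_tau(p, voltages, proto)
        raise ValueError(f"quantity {quantity!r} undefined for IKr")

    if channel == "Ito":
        proto = protocol or ITO_PROTOCOL
        if quantity in ("activating_peak", "iv_peak"):
            return _ito_peak(p, voltages, proto.holding, proto.step_duration)
        if quantity == "deactivation_tau":
            # recovery-from-inactivation time constant of the oi gate
            _, tau = gate_curves("oi", p, voltages)
            return tau
        if quantity == "ss_inactivation":
            # 1-s prepulse at each voltage, then peak current at the test step
            inf_h, _ = gate_curves("oi", p, [proto.holding])
            inf_p, tau_p = gate_curves("oi", p, voltages)
            oi_pre = inf_p + (inf_h[0] - inf_p) * np.exp(-1000.0 / tau_p)
            peaks = _ito_peak(p, np.full(1, proto.test_voltage), proto.holding,
                              proto.test_duration, oi0=oi_pre)
            m = np.max(np.abs(peaks))
            if m == 0:
                return np.zeros_like(peaks)
            return peaks / m
        raise ValueError(f"quantity {quantity!r} undefined for Ito")

    raise ValueError(f"unknown channel {channel!r}; expected 'IKr' or 'Ito'")


def _ito_peak(p, voltages, holding, duration, oi0=None):
    """Peak I_to during a step: oa activates while oi inactivates."""
    voltages = np.atleast_1d(voltages)
    inf_oa_h, _ = _oa_curves(np.array([holding]))
    inf_oi_h, _ = gate_curves("oi", p, [holding])
    if oi0 is None:
        oi0 = np.full(voltages.shape, inf_oi_h[0])
    else:
        oi0 = np.atleast_1d(oi0)
        if voltages.size == 1 and oi0.size > 1:
            voltages = np.full(oi0.shape, voltages[0])
    inf_oa, tau_oa = _oa_curves(voltages)
    inf_oi, tau_oi = gate_curves("oi", p, voltages)
    # dense early sampling resolves fast inactivation transients
    t_max = min(duration, 120.0)
    t = np.concatenate([np.linspace(0.0, min(12.0, t_max), 360),
                        np.linspace(min(12.0, t_max), t_max, 120)])
    oa_t = inf_oa[:, None] + (inf_oa_h[0] - inf_oa[:, None]) * np.exp(-t / tau_oa[:, None])
    oi_t = inf_oi[:, None] + (oi0[:, None] - inf_oi[:, None]) * np.exp(-t / tau_oi[:, None])
    cur = _ito_density(voltages[:, None], oa_t, oi_t, p)
    k = np.argmax(np.abs(cur), axis=1)
    return cur[np.arange(cur.shape[0]), k]


def _fit_tail_tau(p, voltages, proto):
    """Mono-exponential fit of the simulated tail decay at each voltage."""
    from scipy.optimize import curve_fit

    inf_h, _ = gate_curves("xr", p, [proto.holding])
    # depolarise to +20 to populate the gate, then deactivate at each voltage
    inf_s, tau_s = gate_curves("xr", p, [20.0])
    xr_act = inf_s[0] + (inf_h[0] - inf_s[0]) * np.exp(-proto.step_duration / tau_s[0])
    out = np.empty(voltages.shape)
    for i, vt in enumerate(voltages):
        inf_t, tau_t = gate_curves("xr", p, [vt])
        t = np.linspace(0.0, max(5.0 * tau_t[0], 50.0), 500)
        xr_t = inf_t[0] + (xr_act - inf_t[0]) * np.exp(-t / tau_t[0])
        y = _ikr_density(vt, xr_t, p)
        y0, y_inf = y[0], y[-1]
        if abs(y0 - y_inf) < 1e-12:
            out[i] = np.nan  # non-decaying tail: flagged
            continue

        def mono(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c

        popt, _ = curve_fit(mono, t, y, p0=[y0 - y_inf, tau_t[0], y_inf],
                            maxfev=10000)
        out[i] = abs(popt[1])
    return out


def simulate_clamp(params: MutationParameterSet | None,
                   protocol: ClampProtocol | None = None,
                   channel: str = "IKr",
                   peak_mode: str = "end_of_step",
                   tau_mode: str = "analytic") -> ClampDataset:
    """Full simulated clamp dataset for one channel under a protocol.

    I_Kr: activating and tail currents per step voltage plus deactivation
    tau per tail voltage.  I_to: peak I-V per step voltage plus the
    normalised steady-state inactivation curve per prepulse voltage.
    Deterministic; records where a tail fails to decay carry NaN values and
    are flagged through the value itself.
    """
    p = params or MutationParameterSet()
    recs = []
    if channel == "IKr":
        proto = protocol or IKR_PROTOCOL
        sv = np.asarray(proto.step_voltages, dtype=float)
        for q in ("activating_peak", "tail_peak"):
            vals = predict_quantity(p, channel, q, sv, proto, peak_mode, tau_mode)
            recs += [dict(quantity=q, voltage_mV=v, value=x)
                     for v, x in zip(sv, vals)]
        tv = np.asarray(proto.tail_voltages, dtype=float)
        taus = predict_quantity(p, channel, "deactivation_tau", tv, proto,
                                peak_mode, tau_mode)
        recs += [dict(quantity="deactivation_tau", voltage_mV=v, value=x)
                 for v, x in zip(tv, taus)]
    elif channel == "Ito":
        proto = protocol or ITO_PROTOCOL
        sv = np.asarray(proto.step_voltages, dtype=float)
        vals = predict_quantity(p, channel, "iv_peak", sv, proto)
        recs += [dict(quantity="iv_peak", voltage_mV=v, value=x)
                 for v, x in zip(sv, vals)]
        pv = np.asarray(proto.tail_voltages, dtype=float)
        inact = predict_quantity(p, channel, "ss_inactivation", pv, proto)
        recs += [dict(quantity="ss_inactivation", voltage_mV=v, value=x)
                 for v, x in zip(pv, inact)]
        rv = np.asarray(proto.recovery_voltages, dtype=float)
        taus = predict_quantity(p, channel, "deactivation_tau", rv, proto)
        recs += [dict(quantity="deactivation_tau", voltage_mV=v, value=x)
                 for v, x in zip(rv, taus)]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    for r in recs:
        r["uncertainty"] = max(0.05 * abs(r["value"]), 1e-6)
    return ClampDataset.from_records(recs, channel=channel, protocol=proto)


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity scan
# ---------------------------------------------------------------------------

def sensitivity_scan(param_name: str, channel: str, quantity: str,
                     voltages: np.ndarray,
                     values: np.ndarray | None = None,
                     protocol: ClampProtocol | None = None) -> pd.DataFrame:
    """One-at-a-time scan of a single parameter over an observable curve.

    All other parameters stay at identity.  The default range is 0.1 to 5.0
    in steps of 0.1 (50 values).  Returns a long-format frame
    (param, param_value, voltage_mV, value).
    """
    from .params import PARAM_NAMES, SHIFT_PARAMS

    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}")
    if values is None:
        values = np.arange(0.1, 5.001, 0.1)
    values = np.asarray(values, dtype=float)
    if param_name not in SHIFT_PARAMS and np.any(values <= 0):
        raise ValueError(f"{param_name} is scale-like; scan values must be > 0")
    rows = []
    for val in values:
        p = MutationParameterSet(**{param_name: float(val)}, label="scan")
        obs = predict_quantity(p, channel, quantity, voltages, protocol)
        rows.append(pd.DataFrame({
            "param": param_name, "param_value": val,
            "voltage_mV": np.atleast_1d(voltages), "value": obs,
        }))
    return pd.concat(rows, ignore_index=True)
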