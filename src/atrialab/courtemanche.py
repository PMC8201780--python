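"""Human atrial myocyte model with mutation-parameterised I_Kr and I_to.

The baseline is the Courtemanche-Ramirez-Nattel human atrial action-potential
model (21 state variables: membrane potential, 15 gates, Na/K/Ca
concentrations and the three Ca-handling compartments), extended with the
acetylcholine-activated potassium current I_KACh of the Kneller lineage.

Two gates carry the mutation parameterisation:

* ``xr`` (I_Kr activation): rates ``alpha_xr = p0r*0.0003*(V+14.1+p1r) /
  (1-exp(-(V+14.1+p1r)/(5*p2r)))`` and ``beta_xr = p3r*7.3898e-5*
  (V-3.3328+p4r)/(exp((V-3.3328+p4r)/(5.1237*p5r))-1)``.
* ``oi`` (I_to inactivation): ``alpha_oi = p0t/(18.53+exp((V+113.7+p1t)/
  (10.95*p2t)))`` and ``beta_oi = p3t/(35.56+exp(-(V+1.26+p4t)/(7.44*p5t)))``.

In the cell model the modified rates enter through the gate time constants
(``tau = 1/(alpha+beta)``, with the Q10 factor retained for oi) while the
steady-state activation/inactivation curves keep the baseline sigmoids, as
in the original model formulation; the channel-level view used for fitting
voltage-clamp data (``clamp`` module) instead derives the steady state from
the same rates as ``alpha/(alpha+beta)``.  ``p6r``/``p6t`` scale the maximal
conductances and ``p7r``/``p8r`` shift/reslope the instantaneous
rectification of I_Kr.  All removable singularities of the rate expressions
are handled by their analytic limits.

Currents are in pA (densities times Cm = 100 pF), voltages in mV, time in ms,
concentrations in mM.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import MutationParameterSet, RegionProfile, get_mutation, get_region

__all__ = [
    "CellConstants",
    "STATE_NAMES",
    "GATE_NAMES",
    "CURRENT_NAMES",
    "initial_state",
    "gate_rates",
    "i_kr",
    "i_to",
    "i_kach",
    "cell_derivatives",
    "IntegrationError",
]

# physical constants
R_GAS = 8.3143        # J / (mol K)
TEMP = 310.0          # K
FARADAY = 96.4867     # C / mmol
RTF = R_GAS * TEMP / FARADAY

CM = 100.0            # membrane capacitance, pF
V_CELL = 20100.0      # um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

KO = 5.4              # mM
NAO = 140.0
CAO = 1.8

G_NA = 7.8            # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874
KM_NAI = 10.0
KM_KO = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

K_REL = 30.0
K_UP = 0.00092
I_UP_MAX = 0.005
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0

TRPN_MAX = 0.07
KM_TRPN = 0.0005
CMDN_MAX = 0.05
KM_CMDN = 0.00238
CSQN_MAX = 10.0
KM_CSQN = 0.8

KQ10 = 3.0            # temperature scaling of the I_to / I_Kur gate kinetics

ACH_DEFAULT = 0.005   # uM

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)
GATE_NAMES = STATE_NAMES[1:16]
N_STATES = 21
N_GATES = 15

CURRENT_NAMES = (
    "INa", "IK1", "Ito", "IKur", "IKr", "IKs", "ICaL",
    "IpCa", "INaK", "INaCa", "IbNa", "IbCa", "IKACh",
)
N_CURRENTS = 13

# published resting initial conditions of the baseline model
_Y0 = np.array([
    -81.18,       # V
    2.908e-3,     # m
    9.649e-1,     # h
    9.775e-1,     # j
    3.043e-2,     # oa
    9.992e-1,     # oi
    4.966e-3,     # ua
    9.986e-1,     # ui
    3.296e-5,     # xr
    1.869e-2,     # xs
    1.367e-4,     # d
    9.996e-1,     # f
    7.755e-1,     # fca
    0.0,          # u  (effectively zero at rest)
    1.0,          # v
    9.992e-1,     # w
    1.117e1,      # Nai
    1.39e2,       # Ki
    1.013e-4,     # Cai
    1.488,        # Caup
    1.488,        # Carel
], dtype=np.float64)

IDENTITY_MP = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1],
                       dtype=np.float64)
RA_REG = np.ones(6, dtype=np.float64)


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


class CellConstants:
    """Bundle of baseline constants plus the acetylcholine concentration.

    The numeric constants of the baseline model are module-level and fixed;
    this object carries the few run-time knobs (ACh dose, capacitance) and
    provides the Nernst potentials for a given ionic state.
    """

    def __init__(self, ach: float = ACH_DEFAULT, cm: float = CM):
        if ach < 0:
            raise ValueError("ACh concentration must be >= 0 uM")
        self.ach = float(ach)
        self.cm = float(cm)

    @staticmethod
    def e_k(ki: float, ko: float = KO) -> float:
        return RTF * math.log(ko / ki)

    @staticmethod
    def e_na(nai: float, nao: float = NAO) -> float:
        return RTF * math.log(nao / nai)

    @staticmethod
    def e_ca(cai: float, cao: float = CAO) -> float:
        return 0.5 * RTF * math.log(cao / cai)


def initial_state() -> np.ndarray:
    """Published resting state of the baseline model (copy)."""
    return _Y0.copy()


# ---------------------------------------------------------------------------
# Rate functions (scalar, numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rates_xr(V, p0r, p1r, p2r, p3r, p4r, p5r):
    xa = V + 14.1 + p1r
    ca = 5.0 * p2r
    if abs(xa) < 1e-6:
        alpha = p0r * 0.0003 * ca
    else:
        alpha = p0r * 0.0003 * xa / (1.0 - math.exp(-xa / ca))
    xb = V - 3.3328 + p4r
    cb = 5.1237 * p5r
    if abs(xb) < 1e-6:
        beta = p3r * 7.3898e-5 * cb
    else:
        beta = p3r * 7.3898e-5 * xb / (math.exp(xb / cb) - 1.0)
    return alpha, beta


@njit(cache=True)
def _rates_oi(V, p0t, p1t, p2t, p3t, p4t, p5t):
    alpha = p0t / (18.53 + math.exp((V + 113.7 + p1t) / (10.95 * p2t)))
    beta = p3t / (35.56 + math.exp(-(V + 1.26 + p4t) / (7.44 * p5t)))
    return alpha, beta


@njit(cache=True)
def _eval_model(y, mp, reg, ach, inf, tau, dother, cur):
    """Gate targets, concentration/voltage derivatives and currents.

    inf/tau: per-gate steady state and time constant (length 15, gate order).
    dother:  [dV (no stimulus), dNai, dKi, dCai, dCaup, dCarel].
    cur:     currents in pA, order CURRENT_NAMES.
    """
    V = y[0]
    m = y[1]; h = y[2]; j = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; v = y[14]; w = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]; caup = y[19]; carel = y[20]

    ek = RTF * math.log(KO / ki)
    ena = RTF * math.log(NAO / nai)
    eca = 0.5 * RTF * math.log(CAO / cai)

    # --- fast Na gates
    xa = V + 47.13
    if abs(xa) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * xa / (1.0 - math.exp(-0.1 * xa))
    bm = 0.08 * math.exp(-V / 11.0)
    inf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)

    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.135 * math.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
    inf[1] = ah / (ah + bh)
    tau[1] = 1.0 / (ah + bh)

    if V >= -40.0:
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.1212 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    inf[2] = aj / (aj + bj)
    tau[2] = 1.0 / (aj + bj)

    # --- I_to gates: oa baseline form, oi rate form with mutation parameters
    aoa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    tau[3] = 1.0 / ((aoa + boa) * KQ10)

    # mutation parameters act on the rates and hence on tau; the cell-level
    # steady state keeps the baseline sigmoid (see module docstring)
    aoi, boi = _rates_oi(V, mp[9], mp[10], mp[11], mp[12], mp[13], mp[14])
    inf[4] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))
    tau[4] = 1.0 / ((aoi + boi) * KQ10)

    # --- I_Kur gates
    aua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    bua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf[5] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    tau[5] = 1.0 / ((aua + bua) * KQ10)

    aui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    bui = math.exp((V - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    tau[6] = 1.0 / ((aui + bui) * KQ10)

    # --- xr: rate form with mutation parameters
    axr, bxr = _rates_xr(V, mp[0], mp[1], mp[2], mp[3], mp[4], mp[5])
    inf[7] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    tau[7] = 1.0 / (axr + bxr)

    # --- xs
    xb = V - 19.9
    if abs(xb) < 1e-6:
        axs = 4e-5 * 17.0
        bxs = 3.5e-5 * 9.0
    else:
        axs = 4e-5 * xb / (1.0 - math.exp(-xb / 17.0))
        bxs = 3.5e-5 * xb / (math.exp(xb / 9.0) - 1.0)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))
    tau[8] = 0.5 / (axs + bxs)

    # --- L-type Ca gates
    xd = V + 10.0
    if abs(xd) < 1e-6:
        tau[9] = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        ed = math.exp(-xd / 6.24)
        tau[9] = (1.0 - ed) / (0.035 * xd * (1.0 + ed))
    inf[9] = 1.0 / (1.0 + math.exp(-(V + 10.0) / 8.0))

    inf[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    inf[11] = 1.0 / (1.0 + cai / 0.00035)
    tau[11] = TAU_F_CA

    # --- currents (pA)
    i_na = CM * G_NA * m * m * m * h * j * (V - ena)
    i_k1 = CM * reg[4] * G_K1 * (V - ek) / (1.0 + math.exp(0.07 * (V + 80.0)))
    i_to_ = CM * reg[3] * mp[15] * G_TO * oa * oa * oa * oi * (V - ek)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    i_kur = CM * g_kur * ua * ua * ua * ui * (V - ek)
    i_kr_ = (CM * reg[1] * mp[6] * G_KR * xr * (V - ek)
             / (1.0 + math.exp((V + 15.0 + mp[7]) / (22.4 * mp[8]))))
    i_ks = CM * reg[5] * G_KS * xs * xs * (V - ek)
    i_cal = CM * reg[0] * G_CAL * d * f * fca * (V - 65.0)
    i_pca = CM * I_PCA_MAX * cai / (0.0005 + cai)

    fvrt = V / RTF
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * fvrt) + 0.0365 * sigma * math.exp(-fvrt))
    i_nak = (CM * I_NAK_MAX * f_nak * (KO / (KO + KM_KO))
             / (1.0 + (KM_NAI / nai) ** 1.5))
    i_naca = (CM * I_NACA_MAX
              * (math.exp(GAMMA * fvrt) * nai ** 3 * CAO
                 - math.exp((GAMMA - 1.0) * fvrt) * NAO ** 3 * cai)
              / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)
                 * (1.0 + K_SAT * math.exp((GAMMA - 1.0) * fvrt))))
    i_bna = CM * G_B_NA * (V - ena)
    i_bca = CM * G_B_CA * (V - eca)

    if ach > 0.0:
        # dose-response constants are calibrated for [ACh] in mM; the API
        # takes uM (physiological doses are quoted in uM)
        i_kach = (CM * reg[2] * (10.0 / (1.0 + 9.13652 / (1e-3 * ach) ** 0.477811))
                  * (0.0517 + 0.4516 / (1.0 + math.exp((V + 59.53) / 17.18)))
                  * (V - ek))
    else:
        i_kach = 0.0

    cur[0] = i_na; cur[1] = i_k1; cur[2] = i_to_; cur[3] = i_kur
    cur[4] = i_kr_; cur[5] = i_ks; cur[6] = i_cal; cur[7] = i_pca
    cur[8] = i_nak; cur[9] = i_naca; cur[10] = i_bna; cur[11] = i_bca
    cur[12] = i_kach

    # --- Ca handling and the SR release gates
    i_rel = K_REL * u * u * v * w * (carel - cai)
    i_tr = (caup - carel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_up_leak = I_UP_MAX * caup / CA_UP_MAX

    fn = 1e-12 * V_REL * i_rel - (5e-13 / FARADAY) * (0.5 * i_cal - 0.2 * i_naca)
    inf[12] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[12] = TAU_U
    inf[13] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau[13] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))

    xw = V - 7.9
    if abs(xw) < 1e-6:
        tau[14] = 6.0 * 0.2 / 1.3
    else:
        ew = math.exp(-xw / 5.0)
        tau[14] = 6.0 * (1.0 - ew) / ((1.0 + 0.3 * ew) * xw)
    inf[14] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))

    # --- concentration and voltage derivatives
    dother[1] = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) / (FARADAY * V_I)
    dother[2] = (2.0 * i_nak - i_k1 - i_to_ - i_kur - i_kr_ - i_ks - i_kach) / (FARADAY * V_I)
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) / (2.0 * FARADAY * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    dother[3] = b1 / b2
    dother[4] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dother[5] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2)

    i_ion = (i_na + i_k1 + i_to_ + i_kur + i_kr_ + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca + i_kach)
    dother[0] = -i_ion / CM


@njit(cache=True)
def _step_rl(y, dt, stim, mp, reg, ach, inf, tau, dother, cur):
    """One Rush-Larsen (gates) + forward-Euler (V, concentrations) step.

    ``stim`` in pA/pF, depolarising positive.
    """
    _eval_model(y, mp, reg, ach, inf, tau, dother, cur)
    for g in range(N_GATES):
        y[1 + g] = inf[g] + (y[1 + g] - inf[g]) * math.exp(-dt / tau[g])
    y[0] += dt * (dother[0] + stim)
    y[16] += dt * dother[1]
    y[17] += dt * dother[2]
    y[18] += dt * dother[3]
    y[19] += dt * dother[4]
    y[20] += dt * dother[5]


@njit(cache=True)
def _pace(y, bcl, nbeats, amp, dur, dt, mp, reg, ach, stride,
          v_out, state_beat, state_out):
    """Pace ``nbeats`` beats at fixed BCL; record V every ``stride`` steps.

    v_out: (nbeats, nrec) voltage record, sample 0 = beat onset (pre-stimulus).
    state_out: (nrec, 21) full state of beat index ``state_beat`` (0-based).
    Returns 0 on success, 1 if the state went non-finite.
    """
    nsteps = int(round(bcl / dt))
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    dother = np.empty(6)
    cur = np.empty(N_CURRENTS)
    for b in range(nbeats):
        r = 0
        for k in range(nsteps):
            if k % stride == 0:
                v_out[b, r] = y[0]
                if b == state_beat:
                    for s in range(N_STATES):
                        state_out[r, s] = y[s]
                r += 1
            t_in_beat = k * dt
            stim = amp if t_in_beat < dur else 0.0
            _step_rl(y, dt, stim, mp, reg, ach, inf, tau, dother, cur)
        if not math.isfinite(y[0]):
            return 1
    return 0


@njit(cache=True)
def _currents_along(states, mp, reg, ach):
    """Currents (pA) at each recorded state row."""
    n = states.shape[0]
    out = np.empty((n, N_CURRENTS))
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    dother = np.empty(6)
    cur = np.empty(N_CURRENTS)
    for i in range(n):
        _eval_model(states[i], mp, reg, ach, inf, tau, dother, cur)
        for c in range(N_CURRENTS):
            out[i, c] = cur[c]
    return out


@njit(cache=True)
def _run_schedule(y, t_end, stim_on, stim_off, stim_amp, dt, mp, reg, ach,
                  stride, v_out, t_out):
    """Integrate to ``t_end`` under a list of stimulus windows."""
    nsteps = int(round(t_end / dt))
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    dother = np.empty(6)
    cur = np.empty(N_CURRENTS)
    r = 0
    nw = stim_on.shape[0]
    for k in range(nsteps):
        t = k * dt
        if k % stride == 0:
            v_out[r] = y[0]
            t_out[r] = t
            r += 1
        stim = 0.0
        for wdx in range(nw):
            if stim_on[wdx] <= t < stim_off[wdx]:
                stim = stim_amp[wdx]
        _step_rl(y, dt, stim, mp, reg, ach, inf, tau, dother, cur)
        if not math.isfinite(y[0]):
            return k
    if r < v_out.shape[0]:
        v_out[r] = y[0]
        t_out[r] = nsteps * dt
        r += 1
    return -1


# ---------------------------------------------------------------------------
# Python-facing operations
# ---------------------------------------------------------------------------

def _mp_array(params: MutationParameterSet | None) -> np.ndarray:
    if params is None:
        return IDENTITY_MP.copy()
    return params.as_array()


def _reg_array(region: RegionProfile | None) -> np.ndarray:
    if region is None:
        return RA_REG.copy()
    return region.as_array()


def gate_rates(gate: str, V: float, params: MutationParameterSet | None = None):
    """Forward/backward rate constants (ms^-1) of the ``xr`` or ``oi`` gate.

    Removable singularities of the xr rates are evaluated by their analytic
    limits, so the returned rates are finite and positive for any finite V.
    """
    mp = _mp_array(params)
    if not np.isfinite(V):
        raise ValueError("V must be finite")
    if gate == "xr":
        return _rates_xr(V, mp[0], mp[1], mp[2], mp[3], mp[4], mp[5])
    if gate == "oi":
        return _rates_oi(V, mp[9], mp[10], mp[11], mp[12], mp[13], mp[14])
    raise ValueError(f"unknown gate {gate!r}; parameterised gates are 'xr', 'oi'")


def i_kr(V, xr, consts: CellConstants | None = None,
         params: MutationParameterSet | None = None,
         region: RegionProfile | None = None, ki: float = 139.0):
    """I_Kr in pA at voltage V for activation-gate value ``xr``."""
    c = consts or CellConstants()
    mp = _mp_array(params)
    reg = _reg_array(region)
    ek = c.e_k(ki)
    rect = 1.0 + np.exp((V + 15.0 + mp[7]) / (22.4 * mp[8]))
    return c.cm * reg[1] * mp[6] * G_KR * xr * (V - ek) / rect


def i_to(V, oa, oi, consts: CellConstants | None = None,
         params: MutationParameterSet | None = None,
         region: RegionProfile | None = None, ki: float = 139.0):
    """I_to in pA: cubic in oa activation, linear in oi inactivation."""
    c = consts or CellConstants()
    mp = _mp_array(params)
    reg = _reg_array(region)
    ek = c.e_k(ki)
    return c.cm * reg[3] * mp[15] * G_TO * oa ** 3 * oi * (V - ek)


def i_kach(V, consts: CellConstants | None = None,
           region: RegionProfile | None = None, ki: float = 139.0):
    """Acetylcholine-activated K current in pA (0 when [ACh] = 0)."""
    c = consts or CellConstants()
    reg = _reg_array(region)
    if c.ach == 0.0:
        return 0.0 * np.asarray(V) if np.ndim(V) else 0.0
    ek = c.e_k(ki)
    dose = 10.0 / (1.0 + 9.13652 / (1e-3 * c.ach) ** 0.477811)
    vdep = 0.0517 + 0.4516 / (1.0 + np.exp((V + 59.53) / 17.18))
    return c.cm * reg[2] * dose * vdep * (V - ek)


def cell_derivatives(t, state, stim: float = 0.0,
                     consts: CellConstants | None = None,
                     params: MutationParameterSet | None = None,
                     region: RegionProfile | None = None) -> np.ndarray:
    """Full 21-component ODE right-hand side (stim in pA/pF, depolarising)."""
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components")
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t}")
    c = consts or CellConstants()
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    dother = np.empty(6)
    cur = np.empty(N_CURRENTS)
    _eval_model(y, _mp_array(params), _reg_array(region), c.ach,
                inf, tau, dother, cur)
    dy = np.empty(N_STATES)
    dy[0] = dother[0] + stim
    dy[1:16] = (inf - y[1:16]) / tau
    dy[16:21] = dother[1:6]
    return dy
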