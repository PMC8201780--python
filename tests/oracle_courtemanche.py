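"""Independently coded baseline atrial-model right-hand side.

A second, structurally different transcription of the published human
atrial myocyte model (plus the acetylcholine-activated K current) used as
the oracle for identity-parameter equivalence tests.  Pure numpy, written
as one flat function of named locals; no code is shared with the package
kernels.
"""

import numpy as np

R = 8.3143
T = 310.0
F = 96.4867
CM = 100.0
VI = 13668.0
VUP = 1109.52
VREL = 96.48
KO, NAO, CAO = 5.4, 140.0, 1.8


def derivatives(y, stim=0.0, ach=0.005, region=(1.0,) * 6):
    """dy/dt for the 21-state baseline model (identity mutation parameters).

    region = multipliers for (ICaL, IKr, IKACh, Ito, IK1, IKs).
    """
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     nai, ki, cai, caup, carel) = y
    r_cal, r_kr, r_kach, r_to, r_k1, r_ks = region
    rtf = R * T / F
    ek = rtf * np.log(KO / ki)
    ena = rtf * np.log(NAO / nai)
    eca = rtf / 2.0 * np.log(CAO / cai)

    # currents (pA)
    ina = CM * 7.8 * m ** 3 * h * j * (V - ena)
    ik1 = CM * r_k1 * 0.09 * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0)))
    ito = CM * r_to * 0.1652 * oa ** 3 * oi * (V - ek)
    gkur = 0.005 + 0.05 / (1.0 + np.exp((15.0 - V) / 13.0))
    ikur = CM * gkur * ua ** 3 * ui * (V - ek)
    ikr = CM * r_kr * 0.029411765 * xr * (V - ek) / (
        1.0 + np.exp((V + 15.0) / 22.4))
    iks = CM * r_ks * 0.12941176 * xs ** 2 * (V - ek)
    ical = CM * r_cal * 0.12375 * d * f * fca * (V - 65.0)
    ipca = CM * 0.275 * cai / (0.0005 + cai)
    fv = F * V / (R * T)
    sig = (np.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = (1.0 + 0.1245 * np.exp(-0.1 * fv) + 0.0365 * sig * np.exp(-fv)) ** -1
    inak = CM * 0.59933874 * fnak * (1.0 / (1.0 + (10.0 / nai) ** 1.5)) * (
        KO / (KO + 1.5))
    inaca = (CM * 1600.0
             * (np.exp(0.35 * fv) * nai ** 3 * CAO
                - np.exp(-0.65 * fv) * NAO ** 3 * cai)
             / ((87.5 ** 3 + NAO ** 3) * (1.38 + CAO)
                * (1.0 + 0.1 * np.exp(-0.65 * fv))))
    ibna = CM * 0.0006744375 * (V - ena)
    ibca = CM * 0.001131 * (V - eca)
    if ach > 0:
        ach_mm = ach * 1e-3
        ikach = (CM * r_kach * 10.0 / (1.0 + 9.13652 * ach_mm ** -0.477811)
                 * (0.0517 + 0.4516 / (1.0 + np.exp((V + 59.53) / 17.18)))
                 * (V - ek))
    else:
        ikach = 0.0

    # gate kinetics (tau in ms, inf dimensionless)
    def lim(num, den, fallback):
        return fallback if abs(den) < 1e-12 else num / den

    a_m = lim(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)
    if V < -40.0:
        a_h = 0.135 * np.exp((V + 80.0) / -6.8)
        b_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        a_j = ((-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1)))
        a_j = 0.0
        b_j = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))

    a_oa = 0.65 / (np.exp((V + 10.0) / -8.5) + np.exp((V - 30.0) / -59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    oa_inf = (1.0 + np.exp((V + 20.47) / -17.54)) ** -1
    tau_oa = 1.0 / (3.0 * (a_oa + b_oa))
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp((V + 1.26) / -7.44))
    oi_inf = (1.0 + np.exp((V + 43.1) / 5.3)) ** -1
    tau_oi = 1.0 / (3.0 * (a_oi + b_oi))
    a_ua = 0.65 / (np.exp((V + 10.0) / -8.5) + np.exp((V - 30.0) / -59.0))
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    ua_inf = (1.0 + np.exp((V + 30.3) / -9.6)) ** -1
    tau_ua = 1.0 / (3.0 * (a_ua + b_ua))
    a_ui = (21.0 + np.exp((V - 185.0) / -28.0)) ** -1
    b_ui = np.exp((V - 158.0) / 16.0)
    ui_inf = (1.0 + np.exp((V - 99.45) / 27.48)) ** -1
    tau_ui = 1.0 / (3.0 * (a_ui + b_ui))
    a_xr = lim(0.0003 * (V + 14.1), 1.0 - np.exp((V + 14.1) / -5.0), 0.0015)
    b_xr = lim(7.3898e-5 * (V - 3.3328), np.exp((V - 3.3328) / 5.1237) - 1.0,
               7.3898e-5 * 5.1237)
    xr_inf = (1.0 + np.exp((V + 14.1) / -6.5)) ** -1
    tau_xr = 1.0 / (a_xr + b_xr)
    a_xs = lim(4e-5 * (V - 19.9), 1.0 - np.exp((V - 19.9) / -17.0), 4e-5 * 17.0)
    b_xs = lim(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0)
    xs_inf = (1.0 + np.exp((V - 19.9) / -12.7)) ** -0.5
    tau_xs = 0.5 / (a_xs + b_xs)
    d_inf = (1.0 + np.exp((V + 10.0) / -8.0)) ** -1
    if abs(V + 10.0) < 1e-12:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e10 = np.exp((V + 10.0) / -6.24)
        tau_d = (1.0 - e10) / (0.035 * (V + 10.0) * (1.0 + e10))
    f_inf = (1.0 + np.exp((V + 28.0) / 6.9)) ** -1
    tau_f = 9.0 / (0.0197 * np.exp(-0.0337 ** 2 * (V + 10.0) ** 2) + 0.02)
    fca_inf = (1.0 + cai / 0.00035) ** -1
    tau_fca = 2.0

    # SR and calcium buffering
    irel = 30.0 * u ** 2 * v * w * (carel - cai)
    itr = (caup - carel) / 180.0
    iup = 0.005 / (1.0 + 0.00092 / cai)
    iupleak = 0.005 * caup / 15.0
    fn = 1e-12 * VREL * irel - 5e-13 / F * (0.5 * ical - 0.2 * inaca)
    u_inf = (1.0 + np.exp((fn - 3.4175e-13) / -13.67e-16)) ** -1
    v_inf = 1.0 - (1.0 + np.exp((fn - 6.835e-14) / -13.67e-16)) ** -1
    tau_v = 1.91 + 2.09 * (1.0 + np.exp((fn - 3.4175e-13) / -13.67e-16)) ** -1
    if abs(V - 7.9) < 1e-12:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        e79 = np.exp((V - 7.9) / -5.0)
        tau_w = 6.0 * (1.0 - e79) / ((1.0 + 0.3 * e79) * (V - 7.9))
    w_inf = 1.0 - (1.0 + np.exp((V - 40.0) / -17.0)) ** -1

    b1 = ((2.0 * inaca - ipca - ical - ibca) / (2.0 * F * VI)
          + (VUP * (iupleak - iup) + irel * VREL) / VI)
    b2 = (1.0 + 0.07 * 0.0005 / (cai + 0.0005) ** 2
          + 0.05 * 0.00238 / (cai + 0.00238) ** 2)

    itot = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak
            + inaca + ibna + ibca + ikach)
    return np.array([
        -itot / CM + stim,
        a_m * (1.0 - m) - b_m * m,
        a_h * (1.0 - h) - b_h * h,
        a_j * (1.0 - j) - b_j * j,
        (oa_inf - oa) / tau_oa,
        (oi_inf - oi) / tau_oi,
        (ua_inf - ua) / tau_ua,
        (ui_inf - ui) / tau_ui,
        (xr_inf - xr) / tau_xr,
        (xs_inf - xs) / tau_xs,
        (d_inf - d) / tau_d,
        (f_inf - f) / tau_f,
        (fca_inf - fca) / tau_fca,
        (u_inf - u) / 8.0,
        (v_inf - v) / tau_v,
        (w_inf - w) / tau_w,
        (-3.0 * inak - 3.0 * inaca - ibna - ina) / (F * VI),
        (2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach) / (F * VI),
        b1 / b2,
        iup - iupleak - itr * VREL / VUP,
        (itr - irel) / (1.0 + 10.0 * 0.8 / (carel + 0.8) ** 2),
    ])
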