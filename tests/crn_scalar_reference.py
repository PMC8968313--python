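"""Literal scalar transcription of the Courtemanche–Ramirez–Nattel human
atrial cell model, used as an independent oracle for the vectorized kernel.

Every expression is written out one cell at a time with ``math.exp``,
following the published equations directly (piecewise branches as if/else).
This module must stay independent of atrialab's implementation: it imports
nothing from the package.
"""

import math

R = 8.3143
T = 310.0
F = 96.4867
CM = 100.0
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48
K_O = 5.4
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_CAP_MAX = 0.275

K_REL = 30.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_U = 8.0
TAU_F_CA = 2.0
K_Q10 = 3.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

STATE_ORDER = ("vm", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
               "d", "f", "f_ca", "u", "v", "w",
               "na_i", "k_i", "ca_i", "ca_up", "ca_rel")


def _clip(x, lo=-700.0, hi=700.0):
    return lo if x < lo else hi if x > hi else x


def crn_currents_scalar(y, scales=None):
    """All membrane currents (pA/pF) for one state vector ``y`` (dict or
    sequence in STATE_ORDER). ``scales`` maps current names to factors."""
    if not isinstance(y, dict):
        y = dict(zip(STATE_ORDER, y))
    s = {k: 1.0 for k in ("na", "to", "cal", "kur", "k1", "ncx", "kr", "ks")}
    if scales:
        if hasattr(scales, "as_dict"):
            scales = scales.as_dict()
        s.update(scales)
    exp = math.exp
    rtf = R * T / F
    vm = y["vm"]

    e_na = rtf * math.log(NA_O / y["na_i"])
    e_k = rtf * math.log(K_O / y["k_i"])
    e_ca = rtf / 2.0 * math.log(CA_O / y["ca_i"])

    i_na = s["na"] * G_NA * y["m"] ** 3 * y["h"] * y["j"] * (vm - e_na)
    i_k1 = s["k1"] * G_K1 * (vm - e_k) / (1.0 + exp(0.07 * (vm + 80.0)))
    i_to = s["to"] * G_TO * y["oa"] ** 3 * y["oi"] * (vm - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + exp(-(vm - 15.0) / 13.0))
    i_kur = s["kur"] * g_kur * y["ua"] ** 3 * y["ui"] * (vm - e_k)
    i_kr = s["kr"] * G_KR * y["xr"] * (vm - e_k) / (1.0 + exp((vm + 15.0) / 22.4))
    i_ks = s["ks"] * G_KS * y["xs"] ** 2 * (vm - e_k)
    i_cal = s["cal"] * G_CAL * y["d"] * y["f"] * y["f_ca"] * (vm - 65.0)

    sigma = (exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * exp(-0.1 * vm / rtf)
                   + 0.0365 * sigma * exp(-vm / rtf))
    i_nak = (I_NAK_MAX * f_nak * K_O / (K_O + KM_K_O)
             / (1.0 + (KM_NA_I / y["na_i"]) ** 1.5))

    e1 = exp(GAMMA * vm / rtf)
    e2 = exp((GAMMA - 1.0) * vm / rtf)
    i_ncx = s["ncx"] * I_NACA_MAX * (
        e1 * y["na_i"] ** 3 * CA_O - e2 * NA_O ** 3 * y["ca_i"]) / (
        (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * e2))

    i_b_na = G_B_NA * (vm - e_na)
    i_b_ca = G_B_CA * (vm - e_ca)
    i_p_ca = I_CAP_MAX * y["ca_i"] / (0.0005 + y["ca_i"])

    total = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
             + i_nak + i_ncx + i_b_na + i_b_ca + i_p_ca)
    return {"i_na": i_na, "i_k1": i_k1, "i_to": i_to, "i_kur": i_kur,
            "i_kr": i_kr, "i_ks": i_ks, "i_cal": i_cal, "i_nak": i_nak,
            "i_ncx": i_ncx, "i_b_na": i_b_na, "i_b_ca": i_b_ca,
            "i_p_ca": i_p_ca, "total": total}


def crn_gates_scalar(y, scales=None):
    """Gate steady states / time constants and concentration derivatives for
    one state (literal transcription of the rate equations)."""
    if not isinstance(y, dict):
        y = dict(zip(STATE_ORDER, y))
    cur = crn_currents_scalar(y, scales)
    exp = math.exp
    vm = y["vm"]
    inf = {}
    tau = {}

    if abs(vm + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (vm + 47.13) / (1.0 - exp(-0.1 * (vm + 47.13)))
    b_m = 0.08 * exp(-vm / 11.0)
    tau["m"] = 1.0 / (a_m + b_m)
    inf["m"] = a_m / (a_m + b_m)

    if vm < -40.0:
        a_h = 0.135 * exp(-(vm + 80.0) / 6.8)
        b_h = 3.56 * exp(0.079 * vm) + 3.1e5 * exp(0.35 * vm)
        a_j = ((-1.2714e5 * exp(0.2444 * vm) - 3.474e-5 * exp(-0.04391 * vm))
               * (vm + 37.78) / (1.0 + exp(0.311 * (vm + 79.23))))
        b_j = 0.1212 * exp(-0.01052 * vm) / (1.0 + exp(-0.1378 * (vm + 40.14)))
    else:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + exp(-(vm + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * exp(-2.535e-7 * vm) / (1.0 + exp(-0.1 * (vm + 32.0)))
    tau["h"] = 1.0 / (a_h + b_h)
    inf["h"] = a_h / (a_h + b_h)
    tau["j"] = 1.0 / (a_j + b_j)
    inf["j"] = a_j / (a_j + b_j)

    a_oa = 0.65 / (exp(-(vm + 10.0) / 8.5) + exp(-(vm - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + exp((vm + 82.0) / 17.0))
    tau["oa"] = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf["oa"] = 1.0 / (1.0 + exp(-(vm + 20.47) / 17.54))

    a_oi = 1.0 / (18.53 + exp((vm + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + exp(-(vm + 1.26) / 7.44))
    tau["oi"] = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf["oi"] = 1.0 / (1.0 + exp((vm + 43.1) / 5.3))

    tau["ua"] = tau["oa"]
    inf["ua"] = 1.0 / (1.0 + exp(-(vm + 30.3) / 9.6))

    a_ui = 1.0 / (21.0 + exp(-(vm - 185.0) / 28.0))
    b_ui = exp((vm - 158.0) / 16.0)
    tau["ui"] = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf["ui"] = 1.0 / (1.0 + exp((vm - 99.45) / 27.48))

    if abs(vm + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (vm + 14.1) / (1.0 - exp(-(vm + 14.1) / 5.0))
    if abs(vm - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (vm - 3.3328) / (exp((vm - 3.3328) / 5.1237) - 1.0)
    tau["xr"] = 1.0 / (a_xr + b_xr)
    inf["xr"] = 1.0 / (1.0 + exp(-(vm + 14.1) / 6.5))

    if abs(vm - 19.9) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * (vm - 19.9) / (1.0 - exp(-(vm - 19.9) / 17.0))
        b_xs = 3.5e-5 * (vm - 19.9) / (exp((vm - 19.9) / 9.0) - 1.0)
    tau["xs"] = 0.5 / (a_xs + b_xs)
    inf["xs"] = 1.0 / math.sqrt(1.0 + exp(-(vm - 19.9) / 12.7))

    inf["d"] = 1.0 / (1.0 + exp(-(vm + 10.0) / 8.0))
    if abs(vm + 10.0) < 1e-10:
        tau["d"] = 4.579 / 2.0
    else:
        e624 = exp(-(vm + 10.0) / 6.24)
        tau["d"] = (1.0 - e624) / (0.035 * (vm + 10.0) * (1.0 + e624))

    inf["f"] = 1.0 / (1.0 + exp((vm + 28.0) / 6.9))
    tau["f"] = 9.0 / (0.0197 * exp(-(0.0337 ** 2) * (vm + 10.0) ** 2) + 0.02)

    inf["f_ca"] = 1.0 / (1.0 + y["ca_i"] / 0.00035)
    tau["f_ca"] = TAU_F_CA

    i_rel = K_REL * y["u"] ** 2 * y["v"] * y["w"] * (y["ca_rel"] - y["ca_i"])
    fn = 1e3 * (1e-15 * V_REL * i_rel
                - 1e-15 * CM / (2.0 * F) * (0.5 * cur["i_cal"]
                                            - 0.2 * cur["i_ncx"]))
    au = _clip(-(fn - 3.4175e-13) / 13.67e-16)
    av = _clip(-(fn - 6.835e-14) / 13.67e-16)
    inf["u"] = 1.0 / (1.0 + exp(au))
    tau["u"] = TAU_U
    inf["v"] = 1.0 - 1.0 / (1.0 + exp(av))
    tau["v"] = 1.91 + 2.09 / (1.0 + exp(au))

    inf["w"] = 1.0 - 1.0 / (1.0 + exp(-(vm - 40.0) / 17.0))
    if abs(vm - 7.9) < 1e-10:
        tau["w"] = 6.0 * 0.2 / 1.3
    else:
        e79 = exp(-(vm - 7.9) / 5.0)
        tau["w"] = 6.0 * (1.0 - e79) / ((1.0 + 0.3 * e79) * (vm - 7.9))

    i_tr = (y["ca_up"] - y["ca_rel"]) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / y["ca_i"])
    i_up_leak = I_UP_MAX * y["ca_up"] / CA_UP_MAX

    dna = (-3.0 * cur["i_nak"] - 3.0 * cur["i_ncx"] - cur["i_b_na"]
           - cur["i_na"]) * CM / (V_I * F)
    dk = (2.0 * cur["i_nak"] - cur["i_k1"] - cur["i_to"] - cur["i_kur"]
          - cur["i_kr"] - cur["i_ks"]) * CM / (V_I * F)
    b1 = ((2.0 * cur["i_ncx"] - cur["i_p_ca"] - cur["i_cal"] - cur["i_b_ca"])
          * CM / (2.0 * V_I * F)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (y["ca_i"] + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (y["ca_i"] + KM_CMDN) ** 2)
    dca = b1 / b2
    dca_up = i_up - i_up_leak - i_tr * V_REL / V_UP
    dca_rel = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                                / (y["ca_rel"] + KM_CSQN) ** 2)
    dconc = {"na_i": dna, "k_i": dk, "ca_i": dca, "ca_up": dca_up,
             "ca_rel": dca_rel}
    return inf, tau, dconc
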