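"""Courtemanche–Ramirez–Nattel (CRN) human atrial action potential model.

The CRN model describes the atrial myocyte with 21 state variables: membrane
potential, 15 Hodgkin–Huxley-type gates, and 5 ionic concentrations
(intracellular Na+, K+, Ca2+ plus SR uptake/release compartment Ca2+).
Equations and constants follow the published CRN formulation; everything here
is vectorized over nodes so the same kernel drives single-cell protocols and
tissue simulations.

Disease and drug electrophysiology enter exclusively through
:class:`CurrentScaleSet` — multiplicative factors on channel conductances and
the Na+/Ca2+ exchanger. Three literature-derived presets are provided:

``af_remodeling``
    Chronic-AF electrical remodeling: I_Na −10%, I_to −70%, I_CaL −50%,
    I_Kur −50%, I_K1 +100%, I_NCX +40%.
``fibrosis``
    Fibrotic myocytes relative to normal: I_K1 −50%, I_CaL −50%, I_Na −40%.
``flecainide``
    High-dose (15 μM) flecainide as static block: I_to −5%, I_CaL −5%,
    I_Kr −30%, I_Na −45%. Rate-dependent Na-channel kinetics are not modeled.

Presets compose by element-wise multiplication (:func:`compose_scales`), e.g.
fibrotic tissue in an AF-remodeled atrium carries the product of both sets.

Integration uses the Rush–Larsen exponential update for gates and forward
Euler for voltage and concentrations; dt ≤ 0.1 ms is enforced, 0.02 ms is the
conventional choice for CRN tissue runs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "GATE_NAMES",
    "CONCENTRATION_NAMES",
    "STATE_NAMES",
    "CellState",
    "CurrentScaleSet",
    "preset_scales",
    "compose_scales",
    "scales_from_dict",
    "ionic_currents",
    "step_cell",
    "resting_state",
    "measure_apd",
    "restitution_protocol",
    "IntegrationError",
    "NoActionPotentialError",
]

# ---------------------------------------------------------------------------
# Physical constants and CRN parameters (units: mV, ms, mM, pA/pF, nS/pF)
# ---------------------------------------------------------------------------
R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY

CM = 100.0              # membrane capacitance, pF
V_I = 13668.0           # intracellular volume, um^3
V_UP = 1109.52          # SR uptake compartment volume, um^3
V_REL = 96.48           # SR release compartment volume, um^3

K_O = 5.4               # extracellular K+, mM
NA_O = 140.0            # extracellular Na+, mM
CA_O = 1.8              # extracellular Ca2+, mM

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

SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0

GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
              "d", "f", "f_ca", "u", "v", "w")
CONCENTRATION_NAMES = ("na_i", "k_i", "ca_i", "ca_up", "ca_rel")
STATE_NAMES = ("vm",) + GATE_NAMES + CONCENTRATION_NAMES

# Published CRN resting initial conditions (quiescent steady state).
_RESTING = {
    "vm": -81.18,
    "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1,
    "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2,
    "d": 1.367e-4, "f": 9.996e-1, "f_ca": 7.755e-1,
    "u": 2.35e-112, "v": 1.0, "w": 9.992e-1,
    "na_i": 11.17, "k_i": 139.0, "ca_i": 1.013e-4,
    "ca_up": 1.488, "ca_rel": 1.488,
}


class IntegrationError(RuntimeError):
    """Raised when a time step produces a non-finite or runaway state."""


class NoActionPotentialError(ValueError):
    """Raised when a voltage trace contains no detectable upstroke."""


class CellState:
    """Full CRN state for ``n`` cells, stored as a (21, n) float64 array.

    Rows follow :data:`STATE_NAMES`; each state variable is accessible as an
    attribute view (``state.vm``, ``state.ca_i``, ...). A single cell is just
    ``n == 1``.
    """

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 1:
            data = data[:, None]
        if data.shape[0] != len(STATE_NAMES):
            raise ValueError(
                f"state array must have {len(STATE_NAMES)} rows, got {data.shape}")
        self.data = data

    @classmethod
    def resting(cls, n: int = 1) -> "CellState":
        """Published CRN resting state replicated for ``n`` cells."""
        col = np.array([_RESTING[k] for k in STATE_NAMES])
        return cls(np.repeat(col[:, None], n, axis=1))

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "CellState":
        return CellState(self.data.copy())

    def __getattr__(self, name):
        try:
            idx = STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.data[idx]

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        if not np.all(np.isfinite(self.data)):
            raise ValueError("state invariant violated: non-finite entries")
        vm = self.data[0]
        if np.any(vm <= -100.0) or np.any(vm >= 60.0):
            raise ValueError("state invariant violated: vm outside (-100, 60) mV")
        for g in GATE_NAMES:
            arr = self.data[STATE_NAMES.index(g)]
            if np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ValueError(f"state invariant violated: gate {g} outside [0, 1]")
        for c in CONCENTRATION_NAMES:
            arr = self.data[STATE_NAMES.index(c)]
            if np.any(arr <= 0.0):
                raise ValueError(f"state invariant violated: concentration {c} <= 0")


# ---------------------------------------------------------------------------
# Current scaling presets
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CurrentScaleSet:
    """Multiplicative factors on CRN currents; 1.0 means unmodified.

    Slots exist for every current the presets may touch plus I_Ks; pump and
    background currents are never scaled by any preset.
    """

    na: float = 1.0     # fast Na+ current I_Na
    to: float = 1.0     # transient outward K+ current I_to
    cal: float = 1.0    # L-type Ca2+ current I_CaL
    kur: float = 1.0    # ultrarapid delayed rectifier I_Kur
    k1: float = 1.0     # inward rectifier I_K1
    ncx: float = 1.0    # Na+/Ca2+ exchanger I_NCX
    kr: float = 1.0     # rapid delayed rectifier I_Kr
    ks: float = 1.0     # slow delayed rectifier I_Ks

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"scale factor {f.name}={v!r} must be finite and >= 0")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_PRESETS = {
    "baseline": CurrentScaleSet(),
    # Chronic-AF electrical remodeling of the atrial myocyte.
    "af_remodeling": CurrentScaleSet(na=0.90, to=0.30, cal=0.50, kur=0.50,
                                     k1=2.00, ncx=1.40),
    # Fibrotic myocytes relative to normal cells.
    "fibrosis": CurrentScaleSet(k1=0.50, cal=0.50, na=0.60),
    # High-dose (15 uM) flecainide, static block only.
    "flecainide": CurrentScaleSet(to=0.95, cal=0.95, kr=0.70, na=0.55),
}


def preset_scales(preset: str) -> CurrentScaleSet:
    """Return the named conductance-scaling preset.

    Parameters
    ----------
    preset : {'baseline', 'af_remodeling', 'fibrosis', 'flecainide'}
    """
    try:
        return _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {sorted(_PRESETS)}") from None


def compose_scales(a: CurrentScaleSet, b: CurrentScaleSet) -> CurrentScaleSet:
    """Element-wise product of two scale sets (commutative, associative)."""
    return CurrentScaleSet(**{k: av * getattr(b, k) for k, av in a.as_dict().items()})


def scales_from_dict(d: dict) -> CurrentScaleSet:
    """Build a scale set from a mapping; unspecified currents stay at 1.0."""
    known = {f.name for f in fields(CurrentScaleSet)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown current name(s) {sorted(bad)}; expected {sorted(known)}")
    return replace(CurrentScaleSet(), **d)


# ---------------------------------------------------------------------------
# The CRN kernel
# ---------------------------------------------------------------------------
def _safe_div(num, den, limit):
    """num/den with a supplied limit value where |den| underflows.

    The singular points of the CRN rate expressions (removable singularities
    of the form x/(1-exp(-x))) are replaced by their analytic limits.
    """
    den = np.asarray(den, dtype=np.float64)
    tiny = np.abs(den) < 1e-10
    out = np.divide(num, np.where(tiny, 1.0, den))
    return np.where(tiny, limit, out)


def _crn_kernel(state: CellState, scales):
    """Evaluate all CRN currents, gate targets/time constants, and
    concentration derivatives at ``state``.

    ``scales`` is any object with attributes na/to/cal/kur/k1/ncx/kr/ks that
    are scalars or (n,) arrays (broadcast against the state).

    Returns ``(currents, gate_inf, gate_tau, conc_dot)`` where ``currents``
    maps current names (pA/pF) to arrays and includes ``'total'``.
    """
    d_ = state.data
    vm = d_[0]
    m, h, j, oa, oi, ua, ui, xr, xs, dgate, fgate, f_ca, u, v, w = (
        d_[1 + i] for i in range(15))
    na_i, k_i, ca_i, ca_up, ca_rel = (d_[16 + i] for i in range(5))

    exp = np.exp

    e_na = RTF * np.log(NA_O / na_i)
    e_k = RTF * np.log(K_O / k_i)
    e_ca = 0.5 * RTF * np.log(CA_O / ca_i)

    # -- membrane currents (pA/pF) ------------------------------------------
    i_na = scales.na * G_NA * m ** 3 * h * j * (vm - e_na)
    i_k1 = scales.k1 * G_K1 * (vm - e_k) / (1.0 + exp(0.07 * (vm + 80.0)))
    i_to = scales.to * G_TO * oa ** 3 * oi * (vm - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + exp(-(vm - 15.0) / 13.0))
    i_kur = scales.kur * g_kur * ua ** 3 * ui * (vm - e_k)
    i_kr = scales.kr * G_KR * xr * (vm - e_k) / (1.0 + exp((vm + 15.0) / 22.4))
    i_ks = scales.ks * G_KS * xs ** 2 * (vm - e_k)
    i_cal = scales.cal * G_CAL * dgate * fgate * f_ca * (vm - 65.0)

    f_nak = 1.0 / (1.0 + 0.1245 * exp(-0.1 * vm / RTF)
                   + 0.0365 * SIGMA_NAK * exp(-vm / RTF))
    i_nak = (I_NAK_MAX * f_nak * K_O / (K_O + KM_K_O)
             / (1.0 + (KM_NA_I / na_i) ** 1.5))

    ef1 = exp(GAMMA * vm / RTF)
    ef2 = exp((GAMMA - 1.0) * vm / RTF)
    i_ncx = scales.ncx * I_NACA_MAX * (
        ef1 * na_i ** 3 * CA_O - ef2 * NA_O ** 3 * ca_i) / (
        (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * ef2))

    i_b_na = G_B_NA * (vm - e_na)
    i_b_ca = G_B_CA * (vm - e_ca)
    i_p_ca = I_CAP_MAX * ca_i / (0.0005 + ca_i)

    i_total = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
               + i_nak + i_ncx + i_b_na + i_b_ca + i_p_ca)

    # -- SR calcium fluxes (mM/ms) ------------------------------------------
    i_rel = K_REL * u ** 2 * v * w * (ca_rel - ca_i)
    i_tr = (ca_up - ca_rel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX

    # -- gate steady states and time constants ------------------------------
    n = d_.shape[1]
    gate_inf = np.empty((15, n))
    gate_tau = np.empty((15, n))

    a_m = _safe_div(0.32 * (vm + 47.13), 1.0 - exp(-0.1 * (vm + 47.13)), 3.2)
    b_m = 0.08 * exp(-vm / 11.0)
    gate_tau[0] = 1.0 / (a_m + b_m)
    gate_inf[0] = a_m * gate_tau[0]

    low_v = vm < -40.0
    a_h = np.where(low_v, 0.135 * exp(-(vm + 80.0) / 6.8), 0.0)
    b_h = np.where(low_v,
                   3.56 * exp(0.079 * vm) + 3.1e5 * exp(0.35 * vm),
                   1.0 / (0.13 * (1.0 + exp(-(vm + 10.66) / 11.1))))
    gate_tau[1] = 1.0 / (a_h + b_h)
    gate_inf[1] = a_h * gate_tau[1]

    a_j = np.where(
        low_v,
        (-1.2714e5 * exp(0.2444 * vm) - 3.474e-5 * exp(-0.04391 * vm))
        * (vm + 37.78) / (1.0 + exp(0.311 * (vm + 79.23))),
        0.0)
    b_j = np.where(
        low_v,
        0.1212 * exp(-0.01052 * vm) / (1.0 + exp(-0.1378 * (vm + 40.14))),
        0.3 * exp(-2.535e-7 * vm) / (1.0 + exp(-0.1 * (vm + 32.0))))
    gate_tau[2] = 1.0 / (a_j + b_j)
    gate_inf[2] = a_j * gate_tau[2]

    a_oa = 0.65 / (exp(-(vm + 10.0) / 8.5) + exp(-(vm - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + exp((vm + 82.0) / 17.0))
    gate_tau[3] = 1.0 / ((a_oa + b_oa) * K_Q10)
    gate_inf[3] = 1.0 / (1.0 + exp(-(vm + 20.47) / 17.54))

    a_oi = 1.0 / (18.53 + exp((vm + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + exp(-(vm + 1.26) / 7.44))
    gate_tau[4] = 1.0 / ((a_oi + b_oi) * K_Q10)
    gate_inf[4] = 1.0 / (1.0 + exp((vm + 43.1) / 5.3))

    # ua shares its rate expressions with oa
    gate_tau[5] = gate_tau[3]
    gate_inf[5] = 1.0 / (1.0 + exp(-(vm + 30.3) / 9.6))

    a_ui = 1.0 / (21.0 + exp(-(vm - 185.0) / 28.0))
    b_ui = exp((vm - 158.0) / 16.0)
    gate_tau[6] = 1.0 / ((a_ui + b_ui) * K_Q10)
    gate_inf[6] = 1.0 / (1.0 + exp((vm - 99.45) / 27.48))

    a_xr = _safe_div(0.0003 * (vm + 14.1),
                     1.0 - exp(-(vm + 14.1) / 5.0), 0.0015)
    b_xr = _safe_div(7.3898e-5 * (vm - 3.3328),
                     exp((vm - 3.3328) / 5.1237) - 1.0, 3.7836118e-4)
    gate_tau[7] = 1.0 / (a_xr + b_xr)
    gate_inf[7] = 1.0 / (1.0 + exp(-(vm + 14.1) / 6.5))

    a_xs = _safe_div(4e-5 * (vm - 19.9), 1.0 - exp(-(vm - 19.9) / 17.0), 0.00068)
    b_xs = _safe_div(3.5e-5 * (vm - 19.9), exp((vm - 19.9) / 9.0) - 1.0, 0.000315)
    gate_tau[8] = 0.5 / (a_xs + b_xs)
    gate_inf[8] = 1.0 / np.sqrt(1.0 + exp(-(vm - 19.9) / 12.7))

    gate_inf[9] = 1.0 / (1.0 + exp(-(vm + 10.0) / 8.0))
    e624 = exp(-(vm + 10.0) / 6.24)
    gate_tau[9] = _safe_div(1.0 - e624, 0.035 * (vm + 10.0) * (1.0 + e624),
                            4.579 / 2.0)

    gate_inf[10] = 1.0 / (1.0 + exp((vm + 28.0) / 6.9))
    gate_tau[10] = 9.0 / (0.0197 * exp(-(0.0337 ** 2) * (vm + 10.0) ** 2) + 0.02)

    gate_inf[11] = 1.0 / (1.0 + ca_i / 0.00035)
    gate_tau[11] = TAU_F_CA

    # SR release gating driven by Fn (flux through the release junction).
    # The sigmoid arguments span many decades; clip to keep exp() in range
    # (the sigmoids are fully saturated long before +/-700).
    fn = 1e3 * (1e-15 * V_REL * i_rel
                - 1e-15 * CM / (2.0 * FARADAY) * (0.5 * i_cal - 0.2 * i_ncx))
    arg_u = np.clip(-(fn - 3.4175e-13) / 13.67e-16, -700.0, 700.0)
    arg_v = np.clip(-(fn - 6.835e-14) / 13.67e-16, -700.0, 700.0)
    gate_inf[12] = 1.0 / (1.0 + exp(arg_u))
    gate_tau[12] = TAU_U
    gate_inf[13] = 1.0 - 1.0 / (1.0 + exp(arg_v))
    gate_tau[13] = 1.91 + 2.09 / (1.0 + exp(arg_u))

    gate_inf[14] = 1.0 - 1.0 / (1.0 + exp(-(vm - 40.0) / 17.0))
    e79 = exp(-(vm - 7.9) / 5.0)
    gate_tau[14] = _safe_div(6.0 * (1.0 - e79),
                             (1.0 + 0.3 * e79) * (vm - 7.9), 6.0 * 0.2 / 1.3)

    # -- concentration derivatives (mM/ms) ----------------------------------
    conc_dot = np.empty((5, n))
    conc_dot[0] = (-3.0 * i_nak - 3.0 * i_ncx - i_b_na - i_na) * CM / (V_I * FARADAY)
    conc_dot[1] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (V_I * FARADAY)
    b1 = ((2.0 * i_ncx - i_p_ca - i_cal - i_b_ca) * CM / (2.0 * V_I * FARADAY)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    conc_dot[2] = b1 / b2
    conc_dot[3] = i_up - i_up_leak - i_tr * V_REL / V_UP
    conc_dot[4] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)

    currents = {
        "i_na": i_na, "i_k1": i_k1, "i_to": i_to, "i_kur": i_kur,
        "i_kr": i_kr, "i_ks": i_ks, "i_cal": i_cal, "i_nak": i_nak,
        "i_ncx": i_ncx, "i_b_na": i_b_na, "i_b_ca": i_b_ca, "i_p_ca": i_p_ca,
        "total": i_total,
    }
    return currents, gate_inf, gate_tau, conc_dot


def ionic_currents(state: CellState, scales: CurrentScaleSet | object = None,
                   validate: bool = True) -> dict:
    """All CRN membrane currents (pA/pF) at ``state`` under ``scales``.

    Returns a dict of per-current arrays plus ``'total'``, the signed sum
    (outward positive). Scaled currents are exactly the factor times the
    unscaled current; pump and background currents are never scaled.
    """
    if scales is None:
        scales = CurrentScaleSet()
    if validate:
        state.validate()
    currents, _, _, _ = _crn_kernel(state, scales)
    return currents


def step_cell(state: CellState, dt: float, i_stim=0.0,
              scales: CurrentScaleSet | object = None,
              check: bool = True) -> CellState:
    """Advance the CRN state by one time step.

    Gates use the Rush–Larsen exponential rule; vm and concentrations use
    forward Euler. ``i_stim`` (pA/pF, scalar or per-cell array) is added to
    the total membrane current — depolarizing stimuli are negative.
    """
    if not 0.0 < dt <= 0.1:
        raise ValueError(f"dt={dt} ms outside (0, 0.1]")
    if scales is None:
        scales = CurrentScaleSet()
    currents, gate_inf, gate_tau, conc_dot = _crn_kernel(state, scales)

    new = np.empty_like(state.data)
    new[0] = state.data[0] - dt * (currents["total"] + i_stim)
    # Rush-Larsen keeps gates inside [0, 1] unconditionally
    decay = np.exp(-dt / gate_tau)
    new[1:16] = gate_inf + (state.data[1:16] - gate_inf) * decay
    new[16:21] = state.data[16:21] + dt * conc_dot

    if check and not np.all(np.isfinite(new[0])):
        bad = int(np.flatnonzero(~np.isfinite(new[0]))[0])
        raise IntegrationError(f"non-finite membrane potential at cell {bad}")
    return CellState(new)


def resting_state(scales: CurrentScaleSet | object = None,
                  equilibrate_ms: float = 2000.0, dt: float = 0.05,
                  n: int = 1) -> CellState:
    """Quiescent steady state under ``scales``.

    Integrates the published resting state without stimulus until transients
    from the conductance modification decay.
    """
    state = CellState.resting(n)
    for _ in range(int(round(equilibrate_ms / dt))):
        state = step_cell(state, dt, 0.0, scales, check=False)
    return state


# ---------------------------------------------------------------------------
# Action potential metrics and restitution
# ---------------------------------------------------------------------------
def measure_apd(vm_trace: np.ndarray, dt: float,
                repol_fraction: float = 0.9) -> float:
    """Action potential duration (ms) of the first AP in a voltage trace.

    Duration runs from the maximum-dV/dt instant to the first subsequent
    crossing of ``rest + (1 - repol_fraction) * amplitude``, with linear
    interpolation between samples. ``repol_fraction=0.9`` gives APD90.
    """
    if not 0.0 < repol_fraction < 1.0:
        raise ValueError("repol_fraction must be in (0, 1)")
    vm = np.asarray(vm_trace, dtype=float)
    if vm.ndim != 1 or vm.size < 3:
        raise NoActionPotentialError("trace too short")
    dv = np.diff(vm)
    if np.max(dv) <= 0 or np.ptp(vm) < 1e-9:
        raise NoActionPotentialError("no upstroke found in trace")
    k_up = int(np.argmax(dv))          # steepest rise between k_up and k_up+1
    # resting level: minimum over a short pre-upstroke window (the sample at
    # k_up itself already sits on the upstroke at coarse sampling)
    lookback = max(1, int(round(5.0 / dt)))
    rest = float(np.min(vm[max(0, k_up - lookback):k_up + 1]))
    amplitude = np.max(vm[k_up:]) - rest
    if amplitude <= 0:
        raise NoActionPotentialError("no upstroke found in trace")
    threshold = rest + (1.0 - repol_fraction) * amplitude
    k_peak = k_up + int(np.argmax(vm[k_up:]))
    below = np.flatnonzero(vm[k_peak:] < threshold)
    if below.size == 0:
        raise NoActionPotentialError("trace never repolarizes below threshold")
    k1 = k_peak + below[0]
    k0 = k1 - 1
    # linear interpolation of the downward crossing
    frac = (vm[k0] - threshold) / (vm[k0] - vm[k1])
    t_cross = (k0 + frac) * dt
    return t_cross - k_up * dt


def restitution_protocol(scales: CurrentScaleSet | object = None,
                         s1_cl: float = 600.0,
                         s2_intervals=(150.0, 200.0, 300.0, 400.0, 600.0),
                         n_s1: int = 8, dt: float = 0.05,
                         stim_amplitude: float = -20.0,
                         stim_duration: float = 2.0,
                         repol_fraction: float = 0.9):
    """Single-cell S1–S2 restitution: one (DI, APD) pair per capturing S2.

    After ``n_s1`` conditioning beats at cycle length ``s1_cl`` an extrasystole
    is delivered at each coupling interval in ``s2_intervals``. The diastolic
    interval is the time from APD90-repolarization of the last S1 beat to the
    S2 upstroke; non-capturing S2 (no AP with peak above 0 mV) are omitted.

    All S2 variants are integrated as one vectorized cell batch.
    """
    s2_intervals = [float(s) for s in s2_intervals]
    if len(s2_intervals) == 0:
        return []
    if s1_cl < 100.0 or any(s < 100.0 for s in s2_intervals):
        raise ValueError("s1_cl and all s2 intervals must be >= 100 ms")
    if n_s1 < 8:
        raise ValueError("at least 8 conditioning S1 beats are required")
    if scales is None:
        scales = CurrentScaleSet()

    ncell = len(s2_intervals)
    state = resting_state(scales, equilibrate_ms=1000.0, dt=dt, n=ncell)

    last_s1 = (n_s1 - 1) * s1_cl
    s2_onsets = np.array([last_s1 + s for s in s2_intervals])
    total_ms = float(np.max(s2_onsets)) + 500.0
    nsteps = int(round(total_ms / dt))
    sample_every = max(1, int(round(0.5 / dt)))   # 0.5-ms trace resolution
    trace = np.empty((nsteps // sample_every + 1, ncell))
    times = np.empty(nsteps // sample_every + 1)
    ks = 0

    for k in range(nsteps):
        t = k * dt
        stim = np.zeros(ncell)
        beat = int(t // s1_cl)
        if beat < n_s1 and (t - beat * s1_cl) < stim_duration:
            stim[:] = stim_amplitude
        in_s2 = (t >= s2_onsets) & (t < s2_onsets + stim_duration)
        stim[in_s2] = stim_amplitude
        if k % sample_every == 0:
            trace[ks] = state.vm
            times[ks] = t
            ks += 1
        state = step_cell(state, dt, stim, scales, check=False)
    trace = trace[:ks]
    times = times[:ks]
    trace_dt = sample_every * dt

    pairs = []
    for i, s2 in enumerate(s2_intervals):
        vm = trace[:, i]
        # APD of the last S1 beat
        w0 = np.searchsorted(times, last_s1 - 1.0)
        w1 = np.searchsorted(times, s2_onsets[i] - 1.0)
        try:
            apd_s1 = measure_apd(vm[w0:w1], trace_dt, repol_fraction)
        except NoActionPotentialError:
            continue
        # S2 response
        w2 = np.searchsorted(times, s2_onsets[i] - 1.0)
        seg = vm[w2:]
        if seg.size < 5 or np.max(seg) <= 0.0:
            continue                       # no capture
        try:
            apd_s2 = measure_apd(seg, trace_dt, repol_fraction)
        except NoActionPotentialError:
            continue
        di = s2 - apd_s1
        if di <= 0:
            continue
        pairs.append((di, apd_s2))
    return pairs
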