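"""AF wave-dynamics metrics: DF maps, COV-DF, AFCL, Smax, outcome
classification, and wave-break detection at PVI gaps.

Dominant frequency (DF) is the frequency of maximal power of a node's
voltage signal — a surrogate for the local activation rate — computed from a
detrended, Hann-tapered periodogram over a 6-s analysis window and searched
in the physiological 1–20 Hz band. COV-DF (the coefficient of variation of
per-node DFs over a region, in %) indexes the spatial heterogeneity of the
activation rate. AFCL is the mean interval between successive local
activations. Smax is the maximal slope of the action-potential-duration
restitution curve, obtained per node by fitting the mono-exponential
``APD = A - B exp(-DI/tau)`` to in-fibrillation (DI, APD) pairs; the slope
at the smallest observed diastolic interval, ``(B/tau) exp(-DI_min/tau)``,
is reported. Slopes above 1 favor alternans and wave-break.

Outcomes after an intervention are classified as AF termination (tissue
quiescent at the end of the observation), conversion to atrial tachycardia
(sustained but regular and spectrally uniform activity), or sustained AF;
"defragmentation" is termination-or-conversion.

Wave-breaks at PVI gaps are scored from phase singularities: the
instantaneous phase comes from a delayed-coordinate embedding of the local
voltage, and a singularity is a ±2π winding of that phase around an
elementary mesh triangle near the gap exit shortly after a wavefront
transits the corridor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from atrialab.geometry import (AtrialMesh, LesionSet, TISSUE_CODES,
                               PV_REGION_IDS)
from atrialab.ionic import measure_apd, NoActionPotentialError
from atrialab.solver import SimulationResult

__all__ = [
    "DFMap", "OutcomeReport", "dominant_frequency", "df_map", "cov_df",
    "mean_afcl", "smax_map", "fit_restitution", "classify_outcome",
    "detect_gap_wavebreaks", "phase_singularities", "highest_df_site",
    "NoDominantFrequencyError",
]

DF_BAND_HZ = (1.0, 20.0)


class NoDominantFrequencyError(ValueError):
    """Trace has no spectral content (zero variance in the window)."""


@dataclass
class DFMap:
    """Per-node dominant frequency (Hz); NaN outside ``valid``."""

    df_hz: np.ndarray
    valid: np.ndarray
    window_ms: tuple
    resolution_hz: float

    @property
    def values(self) -> np.ndarray:
        return self.df_hz[self.valid]


@dataclass
class OutcomeReport:
    """Per-scenario wave-dynamics summary.

    For terminated episodes the rate/frequency metrics are not applicable
    and are reported as None.
    """

    classification: str                      # sustained_af | terminated | converted_to_at
    mean_afcl_ms: float | None = None
    mean_df_hz: float | None = None
    mean_df_extra_pv_hz: float | None = None
    mean_df_intra_pv_hz: float | None = None
    cov_df_percent: float | None = None
    mean_smax: float | None = None
    cycle_length_cov_percent: float | None = None
    gap_wavebreaks: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "classification": self.classification,
            "mean_afcl_ms": self.mean_afcl_ms,
            "mean_df_hz": self.mean_df_hz,
            "mean_df_extra_pv_hz": self.mean_df_extra_pv_hz,
            "mean_df_intra_pv_hz": self.mean_df_intra_pv_hz,
            "cov_df_percent": self.cov_df_percent,
            "mean_smax": self.mean_smax,
            "cycle_length_cov_percent": self.cycle_length_cov_percent,
        }
        for gid, rec in sorted(self.gap_wavebreaks.items()):
            d[f"breaks[{gid}]"] = rec.get("break_count")
        return d


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------
def dominant_frequency(trace: np.ndarray, sample_rate_hz: float,
                       window_start_ms: float = None,
                       window_end_ms: float = None,
                       band_hz=DF_BAND_HZ) -> float:
    """DF (Hz) of a voltage trace: peak of the periodogram (linear detrend,
    Hann taper) in ``band_hz``; ties resolve to the lower frequency.

    ``window_start_ms``/``window_end_ms`` select the analysis window within
    the trace (trace sample 0 is time 0); the window must be >= 1 s long.
    """
    v = np.asarray(trace, dtype=float)
    if window_start_ms is not None or window_end_ms is not None:
        i0 = 0 if window_start_ms is None else int(round(
            window_start_ms * sample_rate_hz / 1000.0))
        i1 = v.size if window_end_ms is None else int(round(
            window_end_ms * sample_rate_hz / 1000.0))
        if i0 < 0 or i1 > v.size:
            raise ValueError("analysis window outside trace")
        v = v[i0:i1]
    if v.size < sample_rate_hz:          # < 1 s of signal
        raise ValueError("analysis window must be at least 1 s long")
    if np.ptp(v) < 1e-12:
        raise NoDominantFrequencyError("constant trace has no dominant frequency")
    freqs, power = sps.periodogram(v, fs=sample_rate_hz, window="hann",
                                   detrend="linear")
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not sel.any():
        raise NoDominantFrequencyError("no spectral bins in the search band")
    fsel, psel = freqs[sel], power[sel]
    return float(fsel[np.argmax(psel)])   # argmax returns first (lowest) max


def df_map(result: SimulationResult,
           window_ms: tuple = (17000.0, 23000.0)) -> DFMap:
    """Per-node DF over the analysis window; nodes without any activation in
    the window (and unrecorded/ablated nodes) are masked invalid."""
    t0, t1 = float(window_ms[0]), float(window_ms[1])
    if t0 < result.start_ms or t1 > result.start_ms + result.duration_ms + 1e-6:
        raise ValueError("analysis window outside the recording")
    fs = 1000.0 / result.sample_interval_ms
    nmesh = len(result.activation_times)
    df = np.full(nmesh, np.nan)
    valid = np.zeros(nmesh, dtype=bool)
    i0 = int(round((t0 - result.start_ms) * fs / 1000.0))
    i1 = int(round((t1 - result.start_ms) * fs / 1000.0))
    for pos, nid in enumerate(result.node_ids):
        acts = result.activation_times[nid]
        if len(acts) == 0 or not np.any((acts >= t0) & (acts <= t1)):
            continue
        try:
            df[nid] = dominant_frequency(result.traces[pos, i0:i1], fs)
            valid[nid] = True
        except (NoDominantFrequencyError, ValueError):
            continue
    return DFMap(df, valid, (t0, t1), 1000.0 / (t1 - t0))


def cov_df(dfmap: DFMap, region_mask: np.ndarray = None,
           top_decile: bool = False) -> float:
    """Coefficient of variation of per-node DF over a region, in percent:
    ``100 * sample SD / mean``.

    By default all valid nodes of the region enter; ``top_decile=True``
    restricts to the highest-DF decile (an alternative reading of
    "high-DF" spatial variability).
    """
    sel = dfmap.valid.copy()
    if region_mask is not None:
        sel &= np.asarray(region_mask, dtype=bool)
    vals = dfmap.df_hz[sel]
    if top_decile:
        k = max(2, int(np.ceil(0.1 * vals.size)))
        vals = np.sort(vals)[-k:]
    if vals.size < 2:
        raise ValueError("COV-DF needs at least 2 valid nodes in the region")
    return float(100.0 * np.std(vals, ddof=1) / np.mean(vals))


# ---------------------------------------------------------------------------
# Cycle lengths
# ---------------------------------------------------------------------------
def _pooled_intervals(result: SimulationResult, region_mask, window_ms):
    t0, t1 = window_ms
    pooled = []
    for nid in range(len(result.activation_times)):
        if region_mask is not None and not region_mask[nid]:
            continue
        acts = result.activation_times[nid]
        acts = acts[(acts >= t0) & (acts <= t1)]
        if len(acts) >= 2:
            pooled.append(np.diff(acts))
    return np.concatenate(pooled) if pooled else np.empty(0)


def mean_afcl(result: SimulationResult, region_mask: np.ndarray = None,
              window_ms: tuple = (17000.0, 23000.0)) -> float | None:
    """Mean AF cycle length (ms): consecutive activation intervals pooled
    over the region's nodes; None when no node has >= 2 activations."""
    iv = _pooled_intervals(result, region_mask, window_ms)
    if iv.size == 0:
        return None
    return float(np.mean(iv))


# ---------------------------------------------------------------------------
# Restitution slope (Smax)
# ---------------------------------------------------------------------------
def _exp_restitution(di, a, b, tau):
    return a - b * np.exp(-di / tau)


def fit_restitution(pairs) -> dict:
    """Least-squares fit of ``APD = A - B exp(-DI/tau)`` to (DI, APD) pairs.

    Returns A, B, tau, DI_min and ``smax = (B/tau) exp(-DI_min/tau)``, the
    restitution slope at the shortest observed diastolic interval. A flat
    relation (APD variance ~ 0) short-circuits to smax = 0.
    """
    pairs = np.asarray(pairs, dtype=float)
    di, apd = pairs[:, 0], pairs[:, 1]
    if di.size < 3:
        raise ValueError("need at least 3 (DI, APD) pairs")
    if np.ptp(apd) < 1e-9:
        return {"a": float(apd[0]), "b": 0.0, "tau": np.inf,
                "di_min": float(di.min()), "smax": 0.0}

    # Separable least squares: for fixed tau the model is linear in (A, B),
    # so profile the SSE over a tau grid and refine the best cell. This is
    # deterministic and far cheaper than a general nonlinear solver when
    # fitting every mesh node.
    def sse_ab(tau):
        x = np.exp(-di / tau)
        X = np.column_stack([np.ones_like(x), -x])
        coef, res, *_ = np.linalg.lstsq(X, apd, rcond=None)
        pred = X @ coef
        return float(np.sum((apd - pred) ** 2)), coef

    taus = np.geomspace(2.0, 1000.0, 60)
    errs = [sse_ab(t)[0] for t in taus]
    k = int(np.argmin(errs))
    lo = taus[max(0, k - 1)]
    hi = taus[min(len(taus) - 1, k + 1)]
    for _ in range(40):                      # golden-section refinement
        m1 = lo + 0.382 * (hi - lo)
        m2 = lo + 0.618 * (hi - lo)
        if sse_ab(m1)[0] <= sse_ab(m2)[0]:
            hi = m2
        else:
            lo = m1
    tau = 0.5 * (lo + hi)
    _, (a, b) = sse_ab(tau)
    a, b = float(a), float(b)
    b = max(b, 0.0)
    di_min = float(di.min())
    return {"a": a, "b": b, "tau": float(tau), "di_min": di_min,
            "smax": (b / tau) * np.exp(-di_min / tau)}


def _node_restitution_pairs(trace, times, acts, repol_fraction=0.9):
    """(DI, APD) pairs from one node's activation sequence during AF.

    APD of each activation is measured from the recorded trace between
    consecutive upstrokes; DI is the preceding inter-activation interval
    minus the preceding APD.
    """
    dt = times[1] - times[0]
    apds = []
    for k in range(len(acts) - 1):
        i0 = int(np.searchsorted(times, acts[k] - 2.0))
        i1 = int(np.searchsorted(times, acts[k + 1]))
        try:
            apds.append(measure_apd(trace[i0:i1], dt, repol_fraction))
        except NoActionPotentialError:
            apds.append(np.nan)
    pairs = []
    for k in range(len(apds) - 1):
        if not np.isfinite(apds[k]) or not np.isfinite(apds[k + 1]):
            continue
        di = (acts[k + 1] - acts[k]) - apds[k]
        if di > 0:
            pairs.append((di, apds[k + 1]))
    return pairs


def smax_map(result: SimulationResult,
             window_ms: tuple = (17000.0, 23000.0),
             min_pairs: int = 5) -> np.ndarray:
    """Per-node Smax from in-AF restitution pairs; NaN where fewer than
    ``min_pairs`` pairs are extractable or the fit fails."""
    t0, t1 = window_ms
    times = result.times
    nmesh = len(result.activation_times)
    out = np.full(nmesh, np.nan)
    for pos, nid in enumerate(result.node_ids):
        acts = result.activation_times[nid]
        acts = acts[(acts >= t0) & (acts <= t1)]
        if len(acts) < min_pairs + 1:
            continue
        pairs = _node_restitution_pairs(result.traces[pos], times, acts)
        if len(pairs) < min_pairs:
            continue
        try:
            out[nid] = fit_restitution(pairs)["smax"]
        except (RuntimeError, ValueError):
            continue
    return out


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------
def classify_outcome(result: SimulationResult,
                     observation_ms: float = 32000.0,
                     analysis_window_ms: tuple = None,
                     mesh: AtrialMesh = None,
                     at_clcv_percent: float = 10.0,
                     at_covdf_percent: float = 5.0,
                     quiescent_tail_ms: float = 2000.0) -> OutcomeReport:
    """Classify the end state of an observation run.

    terminated
        no activation on any non-ablated node in the final
        ``quiescent_tail_ms`` of the observation;
    converted_to_at
        pooled cycle-length CV < ``at_clcv_percent`` % AND COV-DF over valid
        nodes < ``at_covdf_percent`` % (regular, spectrally uniform rhythm);
    sustained_af
        everything else.

    The three classes are mutually exclusive and exhaustive. Rate metrics
    are computed over ``analysis_window_ms`` (default: the final 6 s of the
    observation) and reported per region when ``mesh`` (or ``result.mesh``)
    is available.
    """
    mesh = mesh if mesh is not None else result.mesh
    end = result.start_ms + result.duration_ms
    if observation_ms > end + 1e-6:
        raise ValueError("result does not cover the observation window")
    if analysis_window_ms is None:
        analysis_window_ms = (max(result.start_ms, observation_ms - 6000.0),
                              observation_ms)

    tail0 = observation_ms - quiescent_tail_ms
    any_tail = any(
        len(a) and np.any((a >= tail0) & (a <= observation_ms))
        for a in result.activation_times)
    if not any_tail:
        return OutcomeReport("terminated",
                             metadata={"analysis_window_ms": analysis_window_ms})

    iv = _pooled_intervals(result, None, analysis_window_ms)
    clcv = (100.0 * np.std(iv, ddof=1) / np.mean(iv)) if iv.size >= 2 else None
    dfm = df_map(result, analysis_window_ms)
    try:
        cov = cov_df(dfm)
    except ValueError:
        cov = None

    if (clcv is not None and cov is not None
            and clcv < at_clcv_percent and cov < at_covdf_percent):
        cls = "converted_to_at"
    else:
        cls = "sustained_af"

    mean_df = float(np.nanmean(dfm.df_hz[dfm.valid])) if dfm.valid.any() else None
    extra = intra = None
    if mesh is not None:
        pvmask = np.isin(mesh.region, PV_REGION_IDS)
        ev = dfm.valid & ~pvmask
        iv_ = dfm.valid & pvmask
        extra = float(np.nanmean(dfm.df_hz[ev])) if ev.any() else None
        intra = float(np.nanmean(dfm.df_hz[iv_])) if iv_.any() else None

    smax = smax_map(result, analysis_window_ms)
    mean_smax = float(np.nanmean(smax)) if np.isfinite(smax).any() else None
    return OutcomeReport(
        cls,
        mean_afcl_ms=mean_afcl(result, None, analysis_window_ms),
        mean_df_hz=mean_df,
        mean_df_extra_pv_hz=extra,
        mean_df_intra_pv_hz=intra,
        cov_df_percent=cov,
        mean_smax=mean_smax,
        cycle_length_cov_percent=None if clcv is None else float(clcv),
        metadata={"analysis_window_ms": analysis_window_ms},
    )


# ---------------------------------------------------------------------------
# Phase singularities and gap wave-breaks
# ---------------------------------------------------------------------------
def _instantaneous_phase(traces: np.ndarray, sample_ms: float,
                         tau_ms: float = 10.0) -> np.ndarray:
    """Phase from a delayed-coordinate embedding: for each node,
    ``phi(t) = atan2(v(t - tau) - <v>, v(t) - <v>)``."""
    lag = max(1, int(round(tau_ms / sample_ms)))
    v = traces - traces.mean(axis=1, keepdims=True)
    ph = np.arctan2(v[:, :-lag], v[:, lag:])
    return ph


def phase_singularities(result: SimulationResult, mesh: AtrialMesh = None,
                        window_ms: tuple = None, tau_ms: float = 10.0,
                        node_subset: np.ndarray = None,
                        winding_tol: float = 1e-3,
                        min_rho_mv: float = 10.0):
    """Detect phase singularities: elementary triangles around which the
    instantaneous phase winds by ±2π.

    Returns a list of ``(time_ms, triangle_index, winding_sign)``.
    ``node_subset`` (boolean mask over mesh nodes) restricts the search to
    triangles whose nodes all lie in the subset. ``min_rho_mv`` rejects
    detections where the embedding trajectory sits near its origin (the
    phase is undefined there and flickers during uniform repolarization).
    """
    mesh = mesh if mesh is not None else result.mesh
    if mesh is None:
        raise ValueError("a mesh is required for singularity detection")
    pos_of = {int(n): i for i, n in enumerate(result.node_ids)}
    tri_ok = []
    tri_pos = []
    for ti, tri in enumerate(mesh.triangles):
        if node_subset is not None and not all(node_subset[t] for t in tri):
            continue
        if all(int(t) in pos_of for t in tri):
            tri_ok.append(ti)
            tri_pos.append([pos_of[int(t)] for t in tri])
    if not tri_ok:
        return []
    tri_pos = np.asarray(tri_pos)

    times = result.times
    if window_ms is None:
        i0, i1 = 0, result.traces.shape[1]
    else:
        i0 = int(np.searchsorted(times, window_ms[0]))
        i1 = int(np.searchsorted(times, window_ms[1]))
    seg = result.traces[:, i0:i1]
    ph = _instantaneous_phase(seg, result.sample_interval_ms, tau_ms)
    # embedding radius: distance of (v(t), v(t - tau)) from the origin
    lag = max(1, int(round(tau_ms / result.sample_interval_ms)))
    dev = seg - seg.mean(axis=1, keepdims=True)
    rho = np.minimum(np.abs(dev[:, :-lag]), np.abs(dev[:, lag:]))

    def wrap(x):
        return (x + np.pi) % (2 * np.pi) - np.pi

    a = ph[tri_pos[:, 0]]
    b = ph[tri_pos[:, 1]]
    c = ph[tri_pos[:, 2]]
    winding = wrap(b - a) + wrap(c - b) + wrap(a - c)
    # the winding is computed from the three vertex phases, so all three
    # must be well-defined
    rho_ok = np.minimum(np.minimum(rho[tri_pos[:, 0]], rho[tri_pos[:, 1]]),
                        rho[tri_pos[:, 2]]) >= min_rho_mv
    hits = (np.abs(np.abs(winding) - 2 * np.pi)
            < 2 * np.pi * winding_tol + 1e-6) & rho_ok
    out = []
    tt, kk = np.nonzero(hits)
    for trow, kcol in zip(tt, kk):
        out.append((float(times[i0 + kcol]), int(tri_ok[trow]),
                    int(np.sign(winding[trow, kcol]))))
    return out


def detect_gap_wavebreaks(result: SimulationResult, mesh: AtrialMesh,
                          lesions: LesionSet,
                          search_radius_mm: float = 5.0,
                          transit_window_ms: float = 30.0,
                          break_window_ms: float = 50.0,
                          tau_ms: float = 10.0) -> dict:
    """Per-gap wavefront transits and wave-breaks at the corridor exit.

    A transit is a paired activation of the corridor's PV-side and LA-side
    sentinel nodes within ``transit_window_ms``; its direction follows the
    activation order (``pv_to_la`` or ``la_to_pv``). A wave-break is scored
    when a phase singularity appears within ``search_radius_mm`` of the gap
    within ``break_window_ms`` after the transit.

    Returns ``{gap_id: {"transits", "break_count", "directions"}}``.
    """
    if not lesions.gaps:
        raise ValueError("lesion set contains no gaps")
    pts = mesh.points[:, :2]
    recorded = np.zeros(mesh.n_nodes, dtype=bool)
    recorded[result.node_ids] = True
    out = {}
    for gap in lesions.gaps:
        ring = lesions.ring(gap.ring_name)
        center = ring.point_at(gap.arc_pos_mm)
        inner_pt = ring.point_at(gap.arc_pos_mm, offset=-(ring.width_mm))
        outer_pt = ring.point_at(gap.arc_pos_mm, offset=+(ring.width_mm))

        def sentinel(target):
            cand = np.flatnonzero(recorded)
            return int(cand[np.argmin(np.linalg.norm(pts[cand] - target,
                                                     axis=1))])

        n_in = sentinel(inner_pt)
        n_out = sentinel(outer_pt)
        t_in = np.asarray(result.activation_times[n_in])
        t_out = np.asarray(result.activation_times[n_out])
        transits = []
        for ta in t_in:
            k = np.argmin(np.abs(t_out - ta)) if len(t_out) else None
            if k is None:
                break
            tb = t_out[k]
            if abs(tb - ta) <= transit_window_ms:
                direction = "pv_to_la" if ta <= tb else "la_to_pv"
                transits.append((min(ta, tb), max(ta, tb), direction))

        near = np.linalg.norm(pts - center, axis=1) <= search_radius_mm
        sing = phase_singularities(result, mesh, None, tau_ms,
                                   node_subset=near & recorded)
        sing_times = np.asarray([s[0] for s in sing])
        break_count = 0
        directions = []
        for t0, t1, direction in transits:
            if len(sing_times) and np.any((sing_times >= t0)
                                          & (sing_times <= t1 + break_window_ms)):
                break_count += 1
                directions.append(direction)
        out[gap.gap_id] = {"transits": len(transits),
                           "break_count": break_count,
                           "directions": directions}
    return out


# ---------------------------------------------------------------------------
# Highest-DF site
# ---------------------------------------------------------------------------
def highest_df_site(dfmap: DFMap, mesh: AtrialMesh,
                    lesions: LesionSet = None,
                    exclusion_radius_mm: float = 3.0) -> int:
    """Node with maximal DF outside the gap exclusion zones (gap corridors
    dilated by ``exclusion_radius_mm``); ties break to the lowest node id."""
    sel = dfmap.valid & (mesh.tissue != TISSUE_CODES["ablated"])
    if lesions is not None:
        pts = mesh.points[:, :2]
        for gap in lesions.gaps:
            ring = lesions.ring(gap.ring_name)
            center = ring.point_at(gap.arc_pos_mm)
            half = gap.arc_width_mm / 2.0 + exclusion_radius_mm
            sel &= np.linalg.norm(pts - center, axis=1) > half
    if not sel.any():
        raise ValueError("no valid node outside the exclusion zones")
    vals = np.where(sel, dfmap.df_hz, -np.inf)
    return int(np.argmax(vals))   # argmax -> first (lowest id) on ties
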