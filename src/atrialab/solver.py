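"""Monodomain reaction–diffusion propagation on triangulated atrial sheets.

The transmembrane potential obeys ``dV/dt = -I_ion(state)/Cm + div(D grad V)``
with an anisotropic diffusivity tensor ``D = d_t I + (d_l - d_t) f f^T``
aligned with the local fiber direction ``f``. Space is discretized with
linear (P1) finite elements on the triangle mesh — zero-flux boundary
conditions arise naturally at the sheet border and at ablated-tissue
interfaces — and time with operator splitting: a Rush–Larsen/Euler reaction
step per cell followed by an explicit diffusion step (sub-stepped when the
explicit stability limit demands it).

Ablated nodes are removed from the diffusion domain entirely: they carry no
state, exchange no current, and record no activations — a permanent
conduction block.

Units: mm, ms, mV; diffusivity in mm^2/ms; conduction velocity in m/s
(numerically equal to mm/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy import sparse

from atrialab.geometry import AtrialMesh, TISSUE_CODES
from atrialab.ionic import (
    CellState, CurrentScaleSet, IntegrationError, compose_scales,
    preset_scales, resting_state, _crn_kernel,
)

__all__ = [
    "DEFAULT_STIM_AMPLITUDE", "DEFAULT_STIM_DURATION",
    "StimulusEvent", "SimulationResult", "ScaleField",
    "scale_field_for_mesh", "build_diffusion_operator", "run_tissue",
    "measure_cv", "calibrate_diffusion", "af_induction_protocol",
    "NoPropagationError", "CalibrationError",
]

# 2x the measured 2-ms diastolic threshold (~-11 pA/pF) of the baseline cell
DEFAULT_STIM_AMPLITUDE = -22.0   # pA/pF
DEFAULT_STIM_DURATION = 2.0      # ms
ACTIVATION_THRESHOLD = -40.0     # mV, upward crossing
ACTIVATION_REFRACTORY = 50.0     # ms


class NoPropagationError(RuntimeError):
    """A probe never activated — no propagating wavefront reached it."""


class CalibrationError(RuntimeError):
    """Conduction-velocity calibration could not bracket the target."""


@dataclass(frozen=True)
class StimulusEvent:
    """Current injection on a node set: negative amplitude depolarizes."""

    nodes: tuple
    onset_ms: float
    duration_ms: float = DEFAULT_STIM_DURATION
    amplitude: float = DEFAULT_STIM_AMPLITUDE

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset_ms < 0:
            raise ValueError("stimulus onset must be >= 0")


@dataclass
class ScaleField:
    """Per-node conductance factors: one (n,) array per scaled current."""

    na: np.ndarray
    to: np.ndarray
    cal: np.ndarray
    kur: np.ndarray
    k1: np.ndarray
    ncx: np.ndarray
    kr: np.ndarray
    ks: np.ndarray

    @classmethod
    def uniform(cls, scales: CurrentScaleSet, n: int) -> "ScaleField":
        return cls(**{k: np.full(n, v) for k, v in scales.as_dict().items()})

    def subset(self, idx) -> "ScaleField":
        return ScaleField(**{f.name: getattr(self, f.name)[idx]
                             for f in dc_fields(self)})


def scale_field_for_mesh(mesh: AtrialMesh,
                         tissue_scales: CurrentScaleSet | str = "af_remodeling",
                         fibrosis_composed: bool = True,
                         extra: CurrentScaleSet | None = None) -> ScaleField:
    """Per-node scale sets from the mesh's tissue labels.

    Normal nodes carry ``tissue_scales``; fibrotic nodes carry the fibrosis
    preset composed onto it (default) or the fibrosis preset alone when
    ``fibrosis_composed=False``. ``extra`` (e.g. flecainide) is composed onto
    every node.
    """
    if isinstance(tissue_scales, str):
        tissue_scales = preset_scales(tissue_scales)
    fib = preset_scales("fibrosis")
    fib_scales = compose_scales(tissue_scales, fib) if fibrosis_composed else fib
    if extra is not None:
        tissue_scales = compose_scales(tissue_scales, extra)
        fib_scales = compose_scales(fib_scales, extra)
    n = mesh.n_nodes
    sf = ScaleField.uniform(tissue_scales, n)
    fmask = mesh.tissue == TISSUE_CODES["fibrotic"]
    for name, val in fib_scales.as_dict().items():
        getattr(sf, name)[fmask] = val
    return sf


# ---------------------------------------------------------------------------
# Diffusion operator
# ---------------------------------------------------------------------------
class DiffusionOperator:
    """Discrete anisotropic Laplacian ``L = -M^{-1} K`` on active nodes.

    ``matrix`` acts on the active-node voltage vector; ``active`` maps back
    to mesh node ids. ``stable_dt`` is the explicit-Euler stability limit.
    """

    def __init__(self, matrix, active: np.ndarray, stable_dt: float):
        self.matrix = matrix
        self.active = active
        self.stable_dt = stable_dt

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v


def build_diffusion_operator(mesh: AtrialMesh, d_longitudinal: float,
                             d_transverse: float | None = None,
                             node_d_scale: np.ndarray | None = None) -> DiffusionOperator:
    """Assemble the P1 finite-element diffusion operator over non-ablated
    nodes with fiber-aligned anisotropy.

    Triangles containing an ablated node are excluded from the integration
    domain, which realizes zero-flux conditions at lesion interfaces; the
    uniform field is exactly in the operator's null space (row sums zero).
    """
    if d_transverse is None:
        d_transverse = d_longitudinal
    if not d_longitudinal >= d_transverse > 0:
        raise ValueError("require d_longitudinal >= d_transverse > 0")
    active = mesh.active()
    if not active.any():
        raise ValueError("mesh has no non-ablated nodes")
    gid = -np.ones(mesh.n_nodes, dtype=np.int64)
    gid[active] = np.arange(active.sum())

    tri = mesh.triangles
    keep = active[tri].all(axis=1)
    tri = tri[keep]
    p = mesh.points[:, :2]
    a, b, c = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    # P1 shape-function gradients
    det = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
           - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    area = 0.5 * np.abs(det)
    g = np.empty((len(tri), 3, 2))
    g[:, 0, 0] = b[:, 1] - c[:, 1]
    g[:, 0, 1] = c[:, 0] - b[:, 0]
    g[:, 1, 0] = c[:, 1] - a[:, 1]
    g[:, 1, 1] = a[:, 0] - c[:, 0]
    g[:, 2, 0] = a[:, 1] - b[:, 1]
    g[:, 2, 1] = b[:, 0] - a[:, 0]
    g /= det[:, None, None]

    # per-triangle conductivity tensor from averaged node fibers
    f = mesh.fibers[tri].mean(axis=1)[:, :2]
    nrm = np.linalg.norm(f, axis=1)
    bad = nrm < 1e-9
    f[bad] = (1.0, 0.0)
    nrm[bad] = 1.0
    f /= nrm[:, None]
    dl, dt_ = d_longitudinal, d_transverse
    dxx = dt_ + (dl - dt_) * f[:, 0] ** 2
    dyy = dt_ + (dl - dt_) * f[:, 1] ** 2
    dxy = (dl - dt_) * f[:, 0] * f[:, 1]
    if node_d_scale is not None:
        # e.g. slowed conduction in fibrotic patches
        tri_scale = np.asarray(node_d_scale)[tri].mean(axis=1)
        dxx = dxx * tri_scale
        dyy = dyy * tri_scale
        dxy = dxy * tri_scale

    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            kij = area * (g[:, i, 0] * (dxx * g[:, j, 0] + dxy * g[:, j, 1])
                          + g[:, i, 1] * (dxy * g[:, j, 0] + dyy * g[:, j, 1]))
            rows.append(gid[tri[:, i]])
            cols.append(gid[tri[:, j]])
            vals.append(kij)
    nact = int(active.sum())
    K = sparse.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(nact, nact)).tocsr()
    # lumped mass
    mlump = np.zeros(nact)
    for i in range(3):
        np.add.at(mlump, gid[tri[:, i]], area / 3.0)
    mlump[mlump <= 0] = 1.0           # isolated active nodes: inert rows
    L = -sparse.diags(1.0 / mlump) @ K
    L = L.tocsr()
    # explicit-Euler stability via Gershgorin on M^-1 K
    radius = np.abs(L).sum(axis=1).max()
    stable_dt = 2.0 / radius if radius > 0 else np.inf
    return DiffusionOperator(L, active, float(stable_dt))


# ---------------------------------------------------------------------------
# Simulation result container
# ---------------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Recorded voltage traces, activation times, and protocol metadata.

    ``traces`` is (n_recorded, n_samples) float32; ``node_ids`` are the mesh
    ids of the recorded (active) nodes. ``activation_times`` has one array
    per mesh node (empty for ablated/unrecorded nodes).
    """

    sample_interval_ms: float
    node_ids: np.ndarray
    traces: np.ndarray
    activation_times: list
    duration_ms: float
    start_ms: float = 0.0
    metadata: dict = field(default_factory=dict)
    mesh: AtrialMesh | None = None
    final_state: CellState | None = None

    @property
    def times(self) -> np.ndarray:
        return self.start_ms + np.arange(self.traces.shape[1]) * self.sample_interval_ms

    def trace_of(self, node_id: int) -> np.ndarray:
        pos = np.searchsorted(self.node_ids, node_id)
        if pos >= len(self.node_ids) or self.node_ids[pos] != node_id:
            raise KeyError(f"node {node_id} was not recorded")
        return self.traces[pos]

    def concatenate(self, later: "SimulationResult") -> "SimulationResult":
        """Splice a continuation run onto this one (shared recording grid)."""
        if abs(later.start_ms - (self.start_ms + self.duration_ms)) > 1e-6:
            raise ValueError("continuation does not start where this result ends")
        common, ia, ib = np.intersect1d(self.node_ids, later.node_ids,
                                        return_indices=True)
        acts = []
        for nid in range(len(self.activation_times)):
            acts.append(np.concatenate([self.activation_times[nid],
                                        later.activation_times[nid]]))
        # the continuation's first sample re-records this run's last state
        return SimulationResult(
            self.sample_interval_ms, common,
            np.hstack([self.traces[ia], later.traces[ib][:, 1:]]),
            acts, self.duration_ms + later.duration_ms, self.start_ms,
            {**self.metadata, **later.metadata}, later.mesh,
            later.final_state)

    def save(self, path) -> None:
        import json
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces, compression="gzip")
            f.create_dataset("node_ids", data=self.node_ids)
            f.create_dataset("activation_offsets", data=np.cumsum(
                [0] + [len(a) for a in self.activation_times]))
            if self.activation_times:
                flat = np.concatenate(self.activation_times) \
                    if any(len(a) for a in self.activation_times) else np.empty(0)
            else:
                flat = np.empty(0)
            f.create_dataset("activation_flat", data=flat)
            if self.final_state is not None:
                f.create_dataset("final_state", data=self.final_state.data)
            f.attrs["sample_interval_ms"] = self.sample_interval_ms
            f.attrs["duration_ms"] = self.duration_ms
            f.attrs["start_ms"] = self.start_ms
            f.attrs["metadata"] = json.dumps(self.metadata, default=str)

    @classmethod
    def load(cls, path, mesh: AtrialMesh | None = None) -> "SimulationResult":
        import json
        import h5py

        with h5py.File(path, "r") as f:
            off = f["activation_offsets"][:]
            flat = f["activation_flat"][:]
            acts = [flat[off[i]:off[i + 1]] for i in range(len(off) - 1)]
            final = CellState(f["final_state"][:]) if "final_state" in f else None
            return cls(float(f.attrs["sample_interval_ms"]),
                       f["node_ids"][:], f["traces"][:], acts,
                       float(f.attrs["duration_ms"]),
                       float(f.attrs["start_ms"]),
                       json.loads(f.attrs["metadata"]), mesh, final)


class _ScaleView:
    """Attribute adapter presenting active-node slices to the CRN kernel."""

    __slots__ = ("na", "to", "cal", "kur", "k1", "ncx", "kr", "ks")

    def __init__(self, sf: ScaleField, idx):
        for name in self.__slots__:
            setattr(self, name, getattr(sf, name)[idx])


# ---------------------------------------------------------------------------
# Tissue integration
# ---------------------------------------------------------------------------
def run_tissue(mesh: AtrialMesh,
               node_scales: ScaleField | CurrentScaleSet | str,
               stimuli,
               duration_ms: float,
               dt_ms: float = 0.02,
               record_interval_ms: float = 1.0,
               d_longitudinal: float = 0.1,
               d_transverse: float | None = None,
               initial_state: CellState | None = None,
               start_ms: float = 0.0,
               record_nodes=None,
               equilibrate_ms: float = 1000.0,
               metadata: dict | None = None,
               early_stop_nodes=None,
               early_stop_margin_ms: float = 5.0,
               node_d_scale: np.ndarray | None = None,
               last_activation: np.ndarray | None = None) -> SimulationResult:
    """Integrate the monodomain model and record traces + activations.

    Operator splitting per ``dt_ms``: one reaction step (Rush–Larsen gates,
    Euler voltage/concentrations) then one explicit diffusion step,
    sub-stepped if ``dt_ms`` exceeds the diffusion stability limit. The
    activation detector runs online on every active node: upward crossing of
    −40 mV with a 50-ms refractory period.

    ``initial_state`` must cover the active nodes (checkpoint/resume);
    otherwise all active nodes start from the quiescent steady state of the
    modal scale set.
    """
    if not 0 < dt_ms <= 0.1:
        raise ValueError("dt must be in (0, 0.1] ms")
    nrec = record_interval_ms / dt_ms
    if abs(nrec - round(nrec)) > 1e-9:
        raise ValueError("record_interval_ms must be a multiple of dt_ms")
    nrec = int(round(nrec))

    if isinstance(node_scales, str):
        node_scales = preset_scales(node_scales)
    if isinstance(node_scales, CurrentScaleSet):
        node_scales = ScaleField.uniform(node_scales, mesh.n_nodes)

    op = build_diffusion_operator(mesh, d_longitudinal, d_transverse,
                                  node_d_scale)
    active_idx = np.flatnonzero(op.active)
    nact = len(active_idx)
    scales = _ScaleView(node_scales, active_idx)

    if initial_state is None:
        # equilibrate a single representative cell, replicate
        base = CurrentScaleSet(**{k: float(np.median(getattr(scales, k)))
                                  for k in _ScaleView.__slots__})
        one = resting_state(base, equilibrate_ms=equilibrate_ms, dt=0.05)
        state = CellState(np.repeat(one.data, nact, axis=1))
    else:
        if initial_state.n == mesh.n_nodes:
            state = CellState(initial_state.data[:, active_idx].copy())
        elif initial_state.n == nact:
            state = initial_state.copy()
        else:
            raise ValueError("initial_state size matches neither mesh nor "
                             "active node count")

    n_sub = max(1, int(np.ceil(dt_ms / (0.9 * op.stable_dt))))
    sub_dt = dt_ms / n_sub

    if record_nodes is None:
        rec_ids = active_idx
    else:
        rec_ids = np.asarray(sorted(set(int(i) for i in record_nodes)))
        rec_ids = rec_ids[op.active[rec_ids]]
    rec_pos = np.searchsorted(active_idx, rec_ids)

    nsteps = int(round(duration_ms / dt_ms))
    nsamples = nsteps // nrec + 1
    traces = np.empty((len(rec_ids), nsamples), dtype=np.float32)

    # stimulus bookkeeping: map each event to active-node positions
    stim_events = []
    for ev in stimuli:
        nodes = np.unique(np.asarray(ev.nodes, dtype=np.int64))
        nodes = nodes[op.active[nodes]]
        stim_events.append((ev, np.searchsorted(active_idx, nodes)))

    if last_activation is None:
        last_act = np.full(nact, -np.inf)
    else:
        last_act = np.asarray(last_activation, dtype=float)
        if last_act.shape[0] == mesh.n_nodes:
            last_act = last_act[active_idx].copy()
        elif last_act.shape[0] != nact:
            raise ValueError("last_activation size mismatch")
        else:
            last_act = last_act.copy()
    act_lists: list = [[] for _ in range(nact)]
    vm = state.data[0]
    stim = np.zeros(nact)

    if early_stop_nodes is not None:
        es_pos = np.searchsorted(
            active_idx, np.asarray(sorted(early_stop_nodes), dtype=np.int64))
        es_pos = es_pos[es_pos < nact]
    stop_at = np.inf

    ksample = 0
    actual_duration = duration_ms
    for k in range(nsteps + 1):
        t = start_ms + k * dt_ms
        if k % nrec == 0 and ksample < nsamples:
            traces[:, ksample] = vm[rec_pos]
            ksample += 1
            if early_stop_nodes is not None and t < stop_at:
                if all(len(act_lists[i]) for i in es_pos):
                    stop_at = t + early_stop_margin_ms
        if k == nsteps or t >= stop_at:
            actual_duration = t - start_ms
            break
        # stimulus assembly
        stim[:] = 0.0
        for ev, pos in stim_events:
            if ev.onset_ms <= t < ev.onset_ms + ev.duration_ms and len(pos):
                stim[pos] += ev.amplitude
        # reaction
        prev_vm = vm.copy()
        currents, gate_inf, gate_tau, conc_dot = _crn_kernel(state, scales)
        d_ = state.data
        d_[0] -= dt_ms * (currents["total"] + stim)
        decay = np.exp(-dt_ms / gate_tau)
        d_[1:16] = gate_inf + (d_[1:16] - gate_inf) * decay
        d_[16:21] += dt_ms * conc_dot
        # diffusion
        vm = d_[0]
        for _ in range(n_sub):
            vm += sub_dt * (op.matrix @ vm)
        d_[0] = vm
        # online activation detection
        crossed = (prev_vm < ACTIVATION_THRESHOLD) & (vm >= ACTIVATION_THRESHOLD)
        if crossed.any():
            tnow = t + dt_ms
            idx = np.flatnonzero(crossed & (tnow - last_act >= ACTIVATION_REFRACTORY))
            for i in idx:
                act_lists[i].append(tnow)
            last_act[idx] = tnow
        if k % 200 == 0 and np.max(np.abs(vm)) > 200.0:
            bad = int(active_idx[np.argmax(np.abs(vm))])
            raise IntegrationError(
                f"numerical blow-up (|vm|>200 mV) at t={t:.2f} ms, node {bad}")

    activation_times = [np.empty(0)] * mesh.n_nodes
    for i, gidx in enumerate(active_idx):
        activation_times[gidx] = np.asarray(act_lists[i])

    meta = {"dt_ms": dt_ms, "d_longitudinal": d_longitudinal,
            "d_transverse": d_transverse if d_transverse is not None
            else d_longitudinal,
            "n_substeps_diffusion": n_sub,
            "n_stimuli": len(stim_events)}
    if metadata:
        meta.update(metadata)
    return SimulationResult(record_interval_ms, rec_ids,
                            traces[:, :ksample], activation_times,
                            actual_duration, start_ms, meta, mesh,
                            CellState(state.data.copy()))


# ---------------------------------------------------------------------------
# Conduction velocity
# ---------------------------------------------------------------------------
def measure_cv(result: SimulationResult, probe_a: int, probe_b: int) -> float:
    """Conduction velocity (m/s) from first-activation times of two probes
    aligned with the propagation direction."""
    if probe_a == probe_b:
        raise ValueError("probes must be distinct nodes")
    if result.mesh is None:
        raise ValueError("result carries no mesh; cannot compute distance")
    ta = result.activation_times[probe_a]
    tb = result.activation_times[probe_b]
    if len(ta) == 0 or len(tb) == 0:
        raise NoPropagationError(
            f"probe {probe_a if len(ta) == 0 else probe_b} never activated")
    dist_mm = float(np.linalg.norm(result.mesh.points[probe_a]
                                   - result.mesh.points[probe_b]))
    dt = abs(float(tb[0]) - float(ta[0]))
    if dt <= 0:
        raise NoPropagationError("probes activated simultaneously")
    return dist_mm / dt   # mm/ms == m/s


def _planar_cv(mesh: AtrialMesh, scales, d: float, dt_ms: float,
               anisotropy: float) -> float:
    """CV of a planar wave launched from the left edge, probed at 30%/70%
    of the sheet width at mid-height."""
    pts = mesh.points
    x0 = pts[:, 0].min()
    width = pts[:, 0].max() - x0
    ymid = np.median(pts[:, 1])
    edge = np.flatnonzero((pts[:, 0] < x0 + 1.5) & mesh.active())
    if len(edge) == 0:
        raise NoPropagationError("no active nodes on the stimulus edge")

    def nearest(x, y):
        cand = np.flatnonzero(mesh.active())
        return int(cand[np.argmin(np.linalg.norm(
            pts[cand, :2] - [x, y], axis=1))])

    pa = nearest(x0 + 0.3 * width, ymid)
    pb = nearest(x0 + 0.7 * width, ymid)
    dist = np.linalg.norm(pts[pa] - pts[pb])
    duration = 20.0 + dist / 0.08    # reach even at 0.08 m/s
    # strong wide stimulus: capture must not depend on d (electrotonic load)
    stim = StimulusEvent(tuple(edge), onset_ms=2.0, duration_ms=3.0,
                         amplitude=-80.0)
    res = run_tissue(mesh, scales, [stim], duration, dt_ms=dt_ms,
                     record_interval_ms=1.0, d_longitudinal=d,
                     d_transverse=d / anisotropy,
                     record_nodes=[pa, pb], equilibrate_ms=200.0,
                     early_stop_nodes=[pa, pb])
    return measure_cv(res, pa, pb)


def calibrate_diffusion(mesh: AtrialMesh, target_cv_m_s: float,
                        tolerance: float = 0.05,
                        scales: CurrentScaleSet | str = "baseline",
                        dt_ms: float = 0.05,
                        anisotropy: float = 1.0,
                        d_bracket=(0.02, 0.6),
                        max_iter: int = 30):
    """Bisect the longitudinal diffusivity until the planar-wave CV matches
    ``target_cv_m_s`` within relative ``tolerance``.

    Returns ``(d, achieved_cv)``. CV grows monotonically with d (≈ sqrt(d)),
    so plain bisection on the bracket suffices; the bracket is expanded a few
    times before giving up.
    """
    if not 0.1 < target_cv_m_s < 1.5:
        raise ValueError("target CV must lie in (0.1, 1.5) m/s")
    if isinstance(scales, str):
        scales = preset_scales(scales)

    def cv_of(d):
        try:
            return _planar_cv(mesh, scales, d, dt_ms, anisotropy)
        except NoPropagationError:
            return 0.0

    lo, hi = d_bracket
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    expand = 0
    while cv_lo > target_cv_m_s and expand < 4:
        lo /= 4.0
        cv_lo = cv_of(lo)
        expand += 1
    while cv_hi < target_cv_m_s and expand < 8:
        hi *= 4.0
        cv_hi = cv_of(hi)
        expand += 1
    if not (cv_lo <= target_cv_m_s <= cv_hi):
        raise CalibrationError(
            f"could not bracket target {target_cv_m_s} m/s: "
            f"cv({lo})={cv_lo:.3f}, cv({hi})={cv_hi:.3f}")
    d = 0.5 * (lo + hi)
    for _ in range(max_iter):
        d = 0.5 * (lo + hi)
        cv = cv_of(d)
        if cv > 0 and abs(cv - target_cv_m_s) / target_cv_m_s <= tolerance:
            return d, cv
        if cv < target_cv_m_s:
            lo = d
        else:
            hi = d
    raise CalibrationError("bisection did not converge within max_iter")


# ---------------------------------------------------------------------------
# AF induction pacing protocol
# ---------------------------------------------------------------------------
def af_induction_protocol(pacing_nodes,
                          start_cl_ms: float = 200.0,
                          end_cl_ms: float = 120.0,
                          decrement_ms: float = 10.0,
                          beats_per_level: int = 8,
                          t0_ms: float = 0.0,
                          amplitude: float = DEFAULT_STIM_AMPLITUDE,
                          duration_ms: float = DEFAULT_STIM_DURATION):
    """Burst-pacing ramp used to induce AF: ``beats_per_level`` beats at each
    cycle length from ``start_cl_ms`` down to ``end_cl_ms`` inclusive.

    With the defaults (200→120 ms, step 10, 8 beats) the scheduled span is
    8 × (200+190+...+120) = 11,520 ms.
    """
    if start_cl_ms < end_cl_ms:
        raise ValueError("start cycle length must be >= end cycle length")
    if decrement_ms <= 0:
        raise ValueError("decrement must be > 0")
    if beats_per_level == 0:
        return []          # pacing disabled (quiescent control scenarios)
    span = start_cl_ms - end_cl_ms
    nlev = span / decrement_ms
    if abs(nlev - round(nlev)) > 1e-9:
        raise ValueError("(start - end) must be divisible by the decrement")
    pacing_nodes = tuple(int(n) for n in pacing_nodes)
    events = []
    t = float(t0_ms)
    cl = start_cl_ms
    for _ in range(int(round(nlev)) + 1):
        for _ in range(beats_per_level):
            events.append(StimulusEvent(pacing_nodes, t, duration_ms, amplitude))
            t += cl
        cl -= decrement_ms
    return events


def protocol_span_ms(events) -> float:
    """Total scheduled duration of a pacing protocol (sum of cycle lengths,
    i.e. time from the first onset to the end of the last scheduled cycle)."""
    if not events:
        return 0.0
    onsets = np.array([e.onset_ms for e in events])
    diffs = np.diff(np.sort(onsets))
    last_cl = diffs[-1] if len(diffs) else 0.0
    return float(onsets.max() - onsets.min() + last_cl)
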