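"""Scenario orchestration: substrate build, CV calibration, AF induction,
virtual interventions, observation, and wave-dynamics reporting.

A scenario follows the study timeline: build the fibrotic AF-remodeled
substrate → calibrate tissue diffusivity to a target conduction velocity →
apply a pre-induction lesion set (none, complete PVI, or PVI with 2-mm gaps)
→ induce AF with a decremental burst-pacing ramp → observe → analyze a
late window (DF, COV-DF, AFCL, Smax) and classify the outcome.

Rescue interventions (gap filling, highest-DF focal ablation, flecainide)
operate on ongoing AF: the run is checkpointed at the intervention time, the
substrate or the channel scaling is modified, and the simulation resumes to
the end of the observation.

Desk-scale defaults (a 50 × 50 mm sheet at 400 μm, 10-s observation with a
5–9-s analysis window) keep one scenario within minutes on one CPU; the
``paper_scale()`` preset restores the full protocol (235 μm target edge,
11.52-s induction ramp, 32-s observation, 17–23-s window) for cluster use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from atrialab.dynamics import (OutcomeReport, classify_outcome,
                               detect_gap_wavebreaks, df_map, highest_df_site)
from atrialab.geometry import (AtrialMesh, LesionSet, apply_lesions,
                               build_idealized_la, fill_gaps,
                               generate_fibrosis, make_focal_lesion,
                               make_pvi_lesions)
from atrialab.ionic import CellState, preset_scales
from atrialab.solver import (ScaleField, SimulationResult, StimulusEvent,
                             af_induction_protocol, calibrate_diffusion,
                             run_tissue, scale_field_for_mesh)

__all__ = [
    "ScenarioConfig", "ScenarioResult", "Checkpoint",
    "run_scenario", "run_comparison", "resume",
]

INTERVENTIONS = ("none", "cpvi", "pvi_gap", "fill_gaps",
                 "focal_highest_df", "flecainide")
STAGED_INTERVENTIONS = ("fill_gaps", "focal_highest_df", "flecainide")


@dataclass
class ScenarioConfig:
    """Full description of one simulated experiment."""

    # geometry
    width_mm: float = 50.0
    height_mm: float = 50.0
    target_edge_um: float = 400.0
    pv_radius_mm: float = 4.0
    # fibrosis
    fibrosis_density: float = 0.20
    fibrosis_cluster_radius_mm: float = 3.0
    # ionic presets
    tissue_preset: str = "af_remodeling"
    fibrosis_composed: bool = True
    # conduction
    target_cv_m_s: float = 0.40
    cv_tolerance: float = 0.05
    d_longitudinal: float | None = None      # skip calibration when set
    anisotropy: float = 2.0                  # d_long / d_trans
    fibrotic_d_factor: float = 0.5
    # induction protocol
    pacing_start_cl_ms: float = 200.0
    pacing_end_cl_ms: float = 120.0
    pacing_decrement_ms: float = 10.0
    beats_per_level: int = 3
    pacing_radius_mm: float = 1.5
    # intervention
    intervention: str = "none"
    intervention_time_ms: float = 6000.0
    gap_width_mm: float = 2.0
    gaps_per_model: int = 4
    focal_radius_mm: float = 3.0
    fill_gap_ids: tuple | None = None        # None = the wave-breaking gaps
    # observation / analysis
    observation_ms: float = 10000.0
    analysis_window_ms: tuple = (5000.0, 9000.0)
    # solver
    dt_ms: float = 0.025
    record_interval_ms: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.intervention not in INTERVENTIONS:
            raise ValueError(f"unknown intervention {self.intervention!r}; "
                             f"expected one of {INTERVENTIONS}")
        t0, t1 = self.analysis_window_ms
        if not (0 <= t0 < t1 <= self.observation_ms):
            raise ValueError("analysis window must lie within the observation")
        if self.intervention in STAGED_INTERVENTIONS and not (
                0 < self.intervention_time_ms < self.observation_ms):
            raise ValueError("intervention time must fall inside the "
                             "observation")

    @classmethod
    def paper_scale(cls, **overrides) -> "ScenarioConfig":
        """Full-protocol preset: fine mesh, 8 beats/level ramp, 32-s
        observation, 17–23-s analysis window. Hours of CPU at full size."""
        base = dict(target_edge_um=235.0, beats_per_level=8,
                    observation_ms=32000.0,
                    analysis_window_ms=(17000.0, 23000.0),
                    intervention_time_ms=14000.0, dt_ms=0.02)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Checkpoint:
    """Complete tissue state at a point in time, sufficient to resume."""

    mesh: AtrialMesh
    lesions: LesionSet | None
    scale_field: ScaleField
    state: CellState                    # over the mesh's full node set
    time_ms: float
    last_activation: np.ndarray         # per mesh node, -inf if never
    d_longitudinal: float
    d_transverse: float
    config: ScenarioConfig | None = None


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    report: OutcomeReport
    result: SimulationResult
    mesh: AtrialMesh
    lesions: LesionSet | None
    d_longitudinal: float
    extras: dict = field(default_factory=dict)


def _pacing_site_nodes(mesh: AtrialMesh, radius_mm: float) -> np.ndarray:
    """Pacing disc in the LA body near the left-superior PV ostium (the
    clinical trigger neighborhood), clipped to active body nodes."""
    meta = mesh.meta
    if "pv_centers" in meta:
        cx, cy = meta["pv_centers"]["pv1"]
        ring_r = meta.get("ring_radius_mm", 6.0)
        target = np.array([cx, min(cy + ring_r + 3.0,
                                   meta["height_mm"] - 2.0)])
    else:
        target = np.array([2.0, np.median(mesh.points[:, 1])])
    pts = mesh.points[:, :2]
    ok = mesh.active() & (mesh.region == 0)
    if not ok.any():
        ok = mesh.active()
    cand = np.flatnonzero(ok)
    center = cand[np.argmin(np.linalg.norm(pts[cand] - target, axis=1))]
    nodes = cand[np.linalg.norm(pts[cand] - pts[center], axis=1) <= radius_mm]
    return nodes


def _node_d_scale(mesh: AtrialMesh, factor: float) -> np.ndarray | None:
    if factor == 1.0:
        return None
    s = np.ones(mesh.n_nodes)
    s[mesh.tissue == 1] = factor
    return s


def _full_state(mesh: AtrialMesh, result: SimulationResult) -> CellState:
    """Embed the active-node final state into a full-mesh state array."""
    full = CellState.resting(mesh.n_nodes)
    act_idx = np.flatnonzero(mesh.active())
    full.data[:, act_idx] = result.final_state.data
    return full


def _run_phase(mesh, scale_field, stimuli, t0, t1, cfg, d_long,
               initial_state=None, last_activation=None):
    from atrialab import solver as _s

    node_d = _node_d_scale(mesh, cfg.fibrotic_d_factor)
    return run_tissue(
        mesh, scale_field, stimuli, duration_ms=t1 - t0, dt_ms=cfg.dt_ms,
        record_interval_ms=cfg.record_interval_ms,
        d_longitudinal=d_long, d_transverse=d_long / cfg.anisotropy,
        initial_state=initial_state, start_ms=t0,
        node_d_scale=node_d, last_activation=last_activation)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Execute one scenario end-to-end and return the outcome report with
    all intermediate artifacts."""
    cfg = config
    mesh = build_idealized_la(cfg.width_mm, cfg.height_mm, cfg.target_edge_um,
                              cfg.pv_radius_mm, seed=cfg.seed)
    mesh = generate_fibrosis(mesh, cfg.fibrosis_density,
                             cfg.fibrosis_cluster_radius_mm,
                             seed=cfg.seed + 1)

    # conduction calibration on the pristine substrate
    if cfg.d_longitudinal is not None:
        d_long = cfg.d_longitudinal
    else:
        d_long, _ = calibrate_diffusion(
            mesh, cfg.target_cv_m_s, cfg.cv_tolerance,
            scales=preset_scales(cfg.tissue_preset), dt_ms=max(cfg.dt_ms, 0.05),
            anisotropy=cfg.anisotropy)

    # pre-induction lesions
    lesions = None
    if cfg.intervention == "cpvi":
        lesions = make_pvi_lesions(mesh, with_gaps=False,
                                   gap_width_mm=cfg.gap_width_mm)
    elif cfg.intervention in ("pvi_gap",) + tuple(STAGED_INTERVENTIONS):
        lesions = make_pvi_lesions(mesh, with_gaps=True,
                                   gap_width_mm=cfg.gap_width_mm,
                                   gaps_per_model=cfg.gaps_per_model)
    lesioned = apply_lesions(mesh, lesions) if lesions is not None else mesh

    sf = scale_field_for_mesh(lesioned, cfg.tissue_preset,
                              cfg.fibrosis_composed)
    pacing = _pacing_site_nodes(lesioned, cfg.pacing_radius_mm)
    stimuli = af_induction_protocol(
        pacing, cfg.pacing_start_cl_ms, cfg.pacing_end_cl_ms,
        cfg.pacing_decrement_ms, cfg.beats_per_level)

    extras = {}
    if cfg.intervention in STAGED_INTERVENTIONS:
        t_int = cfg.intervention_time_ms
        res_a = _run_phase(lesioned, sf, stimuli, 0.0, t_int, cfg, d_long)
        ck = Checkpoint(lesioned, lesions, sf, _full_state(lesioned, res_a),
                        t_int, _full_last_activation(lesioned, res_a),
                        d_long, d_long / cfg.anisotropy, cfg)
        res_b, lesioned, lesions, extras = _apply_staged(
            ck, cfg, res_a, stimuli)
        result = res_a.concatenate(res_b)
    else:
        result = _run_phase(lesioned, sf, stimuli, 0.0, cfg.observation_ms,
                            cfg, d_long)

    report = classify_outcome(result, cfg.observation_ms,
                              cfg.analysis_window_ms, mesh=lesioned)
    if lesions is not None and lesions.gaps:
        try:
            report.gap_wavebreaks = detect_gap_wavebreaks(
                result, lesioned, lesions)
        except ValueError:
            pass
    report.metadata.update({"seed": cfg.seed, "intervention": cfg.intervention,
                            "d_longitudinal": d_long})
    return ScenarioResult(cfg, report, result, lesioned, lesions, d_long,
                          extras)


def _full_last_activation(mesh: AtrialMesh, result: SimulationResult):
    la = np.full(mesh.n_nodes, -np.inf)
    for nid, acts in enumerate(result.activation_times):
        if len(acts):
            la[nid] = acts[-1]
    return la


def _apply_staged(ck: Checkpoint, cfg: ScenarioConfig,
                  res_a: SimulationResult, stimuli):
    """Apply a rescue intervention to ongoing AF and run to observation end."""
    mesh, lesions, sf = ck.mesh, ck.lesions, ck.scale_field
    extras = {}
    t_int = ck.time_ms
    if cfg.intervention == "flecainide":
        sf = scale_field_for_mesh(mesh, cfg.tissue_preset,
                                  cfg.fibrosis_composed,
                                  extra=preset_scales("flecainide"))
    elif cfg.intervention == "fill_gaps":
        if cfg.fill_gap_ids is not None:
            to_fill = list(cfg.fill_gap_ids)
        else:
            look_back = (max(res_a.start_ms, t_int - 2000.0), t_int)
            wb = detect_gap_wavebreaks(res_a, mesh, lesions)
            to_fill = [g for g, rec in wb.items() if rec["break_count"] > 0]
            extras["gap_wavebreaks_pre"] = wb
        extras["filled_gaps"] = to_fill
        lesions = fill_gaps(lesions, to_fill)
        mesh = apply_lesions(mesh, lesions)
        sf = scale_field_for_mesh(mesh, cfg.tissue_preset,
                                  cfg.fibrosis_composed)
    elif cfg.intervention == "focal_highest_df":
        win = (max(res_a.start_ms, t_int - 3000.0), t_int)
        dfm = df_map(res_a, win)
        site = highest_df_site(dfm, mesh, lesions,
                               exclusion_radius_mm=cfg.focal_radius_mm)
        extras["focal_site"] = site
        focal = make_focal_lesion(mesh, site, cfg.focal_radius_mm)
        lesions = lesions.merged(focal) if lesions is not None else focal
        mesh = apply_lesions(mesh, focal)
        sf = scale_field_for_mesh(mesh, cfg.tissue_preset,
                                  cfg.fibrosis_composed)

    res_b = _run_phase(mesh, sf, stimuli, t_int, cfg.observation_ms, cfg,
                       ck.d_longitudinal,
                       initial_state=ck.state,
                       last_activation=ck.last_activation)
    return res_b, mesh, lesions, extras


def resume(checkpoint: Checkpoint, new_intervention: str = "none",
           stimuli=()) -> SimulationResult:
    """Continue a checkpointed run to the configured observation end.

    With ``new_intervention='none'`` the continuation reproduces an
    uninterrupted run bit-for-bit; other interventions change only the
    lesion labels/domain (``fill_gaps``, ``focal_highest_df``) or the scale
    sets (``flecainide``).
    """
    cfg = checkpoint.config
    if cfg is None:
        raise ValueError("checkpoint carries no scenario config")
    cfg = replace(cfg, intervention=new_intervention,
                  intervention_time_ms=checkpoint.time_ms)
    if new_intervention == "none":
        return _run_phase(checkpoint.mesh, checkpoint.scale_field, stimuli,
                          checkpoint.time_ms, cfg.observation_ms, cfg,
                          checkpoint.d_longitudinal,
                          initial_state=checkpoint.state,
                          last_activation=checkpoint.last_activation)
    res_b, _, _, _ = _apply_staged(checkpoint, cfg, _empty_result(checkpoint),
                                   stimuli)
    return res_b


def _empty_result(ck: Checkpoint) -> SimulationResult:
    n = ck.mesh.n_nodes
    return SimulationResult(1.0, np.arange(n), np.zeros((n, 0), np.float32),
                            [np.empty(0)] * n, 0.0, ck.time_ms, {}, ck.mesh,
                            ck.state)


# ---------------------------------------------------------------------------
# Batch comparison
# ---------------------------------------------------------------------------
_DELTA_COLUMNS = ("mean_df_hz", "mean_afcl_ms", "mean_smax")


def run_comparison(batch, baseline_index: int = 0,
                   precomputed=None) -> pd.DataFrame:
    """Run (or take precomputed) scenarios and tabulate their outcome
    metrics with Δ-columns relative to a designated baseline scenario.

    Scenarios with differing geometry seeds are flagged with a warning —
    paired comparisons expect a shared substrate.
    """
    batch = list(batch)
    if len(batch) < 2:
        raise ValueError("a comparison needs at least 2 scenarios")
    seeds = {c.seed for c in batch}
    if len(seeds) > 1:
        warnings.warn("scenarios use different geometry seeds; comparisons "
                      "are not substrate-paired")
    results = precomputed if precomputed is not None else [
        run_scenario(c) for c in batch]
    rows = []
    for cfg, sr in zip(batch, results):
        row = {"intervention": cfg.intervention, "seed": cfg.seed,
               **sr.report.to_dict()}
        row["defragmented"] = sr.report.classification in (
            "terminated", "converted_to_at")
        rows.append(row)
    table = pd.DataFrame(rows)
    base = table.iloc[baseline_index]
    for col in _DELTA_COLUMNS:
        if col in table.columns:
            table[f"delta_{col}"] = table[col] - base[col]
    return table
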