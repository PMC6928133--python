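"""AF induction, virtual ablation, termination detection and protocol ranking.

The per-atrium virtual experiment: induce fibrillatory activity by rapid
pacing at Bachmann's bundle (24 stimuli, 8 each at cycle lengths 200, 190
and 180 ms), observe for 4 s, apply one of five ablation lesion sets, then
continue and report whether — and how quickly — every wavelet is
extinguished (90% repolarization of the entire chamber).  The lesion set
with the fastest termination wins.

If rapid pacing does not yield sustained activity (small or slowly
conducting atria have a narrow inducibility window), a documented cross-field
S1–S2 fallback seeds a reentrant wave directly; results flag which induction
route produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import ionic, lesions
from .cfae import CfaeMap, compute_cfae_map
from .geometry import MonolayerMesh
from .propagation import (
    ACTIVATION_THRESHOLD_MV,
    DEFAULT_TISSUE_STIM,
    Recording,
    SolverParams,
    Stimulus,
    TissueSimulator,
)

NOT_TERMINATED = math.inf


@dataclass
class PacingProtocol:
    """Programmed stimulation train for AF induction.

    Defaults reproduce the induction protocol: 8 beats at each of 200, 190
    and 180 ms cycle length (24 stimuli) at Bachmann's bundle.
    """

    site: str = "bachmann_site"
    cycle_lengths_ms: tuple[float, ...] = (200.0, 190.0, 180.0)
    beats_per_cycle_length: int = 8
    pulse_amplitude: float = DEFAULT_TISSUE_STIM
    pulse_duration_ms: float = 2.0

    @property
    def n_stimuli(self) -> int:
        return len(self.cycle_lengths_ms) * self.beats_per_cycle_length

    def stimulus_times(self, start: float = 0.0) -> np.ndarray:
        """Onset time of every pulse (ms)."""
        t = start
        out = []
        for cl in self.cycle_lengths_ms:
            for _ in range(self.beats_per_cycle_length):
                out.append(t)
                t += cl
        return np.asarray(out)

    @property
    def train_duration_ms(self) -> float:
        return float(sum(cl * self.beats_per_cycle_length for cl in self.cycle_lengths_ms))


@dataclass
class RunConfig:
    """Configuration of one virtual-ablation experiment."""

    pacing: PacingProtocol = field(default_factory=PacingProtocol)
    solver: SolverParams = field(default_factory=SolverParams)
    wait_after_pacing_ms: float = 4000.0      # ablation applied at pacing end + 4 s
    horizon_ms: float = 25000.0               # post-ablation observation window
    sustained_window_ms: float = 1000.0       # activity check after the train
    lesion_width_mm: float = lesions.DEFAULT_LESION_WIDTH_MM
    cfae_cl_threshold_ms: float = lesions.DEFAULT_CFAE_CL_THRESHOLD_MS
    cfae_area_cap: float = lesions.DEFAULT_CFAE_AREA_CAP
    cfae_window_ms: float = 4000.0            # tail of the pre-ablation segment
    repol_fraction: float = 0.9
    #: induction routes tried in order until one yields sustained activity
    induction_routes: tuple[str, ...] = ("pacing", "s1s2", "phase_seed")
    stim_radius_mm: float = 3.0


@dataclass
class SimulationResult:
    """Outcome of one protocol run on one atrium."""

    protocol: str
    induced: bool
    terminated: bool
    time_to_termination_ms: float       # from ablation onset; inf if not terminated
    ablated_area_mm2: float = 0.0
    n_ablated_nodes: int = 0
    induction_method: str = "pacing"
    snapshots: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "induced": self.induced,
            "terminated": self.terminated,
            "time_to_termination_ms": (
                None if not self.terminated else self.time_to_termination_ms
            ),
            "ablated_area_mm2": self.ablated_area_mm2,
            "n_ablated_nodes": self.n_ablated_nodes,
            "induction_method": self.induction_method,
        }
        return d


# ---------------------------------------------------------------------------
# Induction
# ---------------------------------------------------------------------------


def _site_nodes(sim: TissueSimulator, site: str, radius_mm: float) -> np.ndarray:
    lm = sim.mesh.surface.landmark_sets
    if site not in lm:
        raise KeyError(f"pacing site landmark '{site}' not on mesh")
    seeds = lm[site]
    seeds = seeds[~sim.mesh.nonconductive_mask[seeds]]
    if len(seeds) == 0:
        raise KeyError(f"pacing site '{site}' has no conductive nodes")
    centre = sim.mesh.surface.vertices[seeds].mean(axis=0)
    v = sim.mesh.surface.vertices
    near = np.flatnonzero(
        (np.linalg.norm(v - centre, axis=1) <= radius_mm) & ~sim.mesh.nonconductive_mask
    )
    return near if len(near) else seeds


def _is_sustained(recording: Recording, check_every_ms: float = 100.0) -> bool:
    """Sustained activity: >= 1 depolarized node at every 100 ms checkpoint."""
    if len(recording.times) == 0:
        return False
    t0 = recording.times[0]
    checks = np.arange(t0, recording.times[-1] + 1e-9, check_every_ms)
    idx = np.searchsorted(recording.times, checks)
    idx = np.clip(idx, 0, len(recording.times) - 1)
    return bool((recording.n_depolarized[idx] > 0).all())


def induce_af(
    sim: TissueSimulator,
    protocol: PacingProtocol | None = None,
    sustained_window_ms: float = 1000.0,
    stim_radius_mm: float = 3.0,
    record_full: bool = False,
) -> tuple[bool, Recording]:
    """Deliver the rapid-pacing train and test for sustained activity.

    Returns ``(induced, recording)`` where the recording covers the train
    plus the ``sustained_window_ms`` observation tail.  ``induced`` is true
    when at least one node is depolarized at every 100 ms checkpoint of the
    tail.
    """
    if protocol is None:
        protocol = PacingProtocol()
    nodes = _site_nodes(sim, protocol.site, stim_radius_mm)
    t0 = sim.state.t
    stimuli = [
        Stimulus(nodes, start=t, duration=protocol.pulse_duration_ms,
                 amplitude=protocol.pulse_amplitude)
        for t in protocol.stimulus_times(t0)
    ]
    sim.run(protocol.train_duration_ms, stimuli)
    tail_rec = sim.run(sustained_window_ms, record_full=record_full)
    return _is_sustained(tail_rec), tail_rec


def s1s2_cross_field(
    sim: TissueSimulator,
    s2_delays_ms: tuple[float, ...] = (150.0, 170.0, 190.0, 210.0, 230.0),
    sustained_window_ms: float = 1000.0,
    record_full: bool = False,
) -> tuple[bool, Recording]:
    """Cross-field S1–S2 reentry initiation (documented induction fallback).

    S1 excites a planar wave from one pole of the chamber; S2 depolarizes an
    orthogonal half-field at a delay inside the vulnerable window, breaking
    the S1 waveback into a reentrant wavefront.  Delays are scanned in order
    and the first sustained outcome is kept.
    """
    v = sim.mesh.surface.vertices
    axis0 = v[:, 0]
    axis1 = v[:, 2]
    s1_nodes = np.flatnonzero(
        (axis0 < np.quantile(axis0, 0.06)) & ~sim.mesh.nonconductive_mask
    )
    s2_nodes = np.flatnonzero(
        (axis1 > np.quantile(axis1, 0.5)) & ~sim.mesh.nonconductive_mask
    )
    base = sim.state.copy()
    combined: Recording | None = None
    for delay in s2_delays_ms:
        sim.state = base.copy()
        t0 = sim.state.t
        stimuli = [
            Stimulus(s1_nodes, start=t0, duration=2.0),
            Stimulus(s2_nodes, start=t0 + delay, duration=4.0),
        ]
        sim.run(delay + 100.0, stimuli)
        tail_rec = sim.run(sustained_window_ms, record_full=record_full)
        combined = tail_rec if combined is None else combined
        if _is_sustained(tail_rec):
            return True, tail_rec
    return False, combined


def seed_phase_reentry(
    sim: TissueSimulator,
    cycle_ms: float = 230.0,
    cap_radius_mm: float = 14.0,
    cap_phase_ms: float = 40.0,
    sustained_window_ms: float = 1000.0,
    record_full: bool = False,
) -> tuple[bool, Recording]:
    """Seed a perimitral rotating wave by phase-distributed initialization.

    Every conductive node is set to the state of a steadily paced cell at a
    phase proportional to its angle around the mitral-annulus axis, which
    launches a macro-reentrant wave around the annulus that typically breaks
    up into fibrillatory wavelets on the PV-perforated posterior wall.  The
    polar cap opposite the annulus, where all phases would meet, is set to a
    single mid-plateau phase so it recovers as one block.  Standard
    initialization for anatomical reentry when programmed stimulation fails
    to induce.
    """
    mesh = sim.mesh
    v = mesh.surface.vertices
    ann_c = v[mesh.surface.landmark_sets["mitral_annulus"]].mean(axis=0)
    centroid = v.mean(axis=0)
    axis = ann_c - centroid
    axis /= np.linalg.norm(axis)
    e1 = np.cross(axis, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, np.array([0.0, 1.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    r = v - ann_c
    phi = np.arctan2(r @ e2, r @ e1) % (2.0 * np.pi)
    rho = np.linalg.norm(r - np.outer(r @ axis, axis), axis=1)

    traj = ionic.ap_trajectory(sim.cell_params, cycle_ms, dt=sim.solver.dt)
    n_ph = traj.shape[0]
    phase_idx = ((phi / (2.0 * np.pi)) * n_ph).astype(np.int64) % n_ph
    phase_idx[rho < cap_radius_mm] = int(cap_phase_ms)
    cond = ~mesh.nonconductive_mask
    sim.state.states[cond] = traj[phase_idx[cond]]

    tail_rec = sim.run(sustained_window_ms, record_full=record_full)
    return _is_sustained(tail_rec), tail_rec


# ---------------------------------------------------------------------------
# Termination detection
# ---------------------------------------------------------------------------


def detect_termination(
    recording: Recording,
    resting_vm: float,
    repol_fraction: float = 0.9,
) -> tuple[bool, float]:
    """Total wavelet extinction: every node repolarized, with no re-activation.

    A node counts as repolarized once its Vm has recovered ``repol_fraction``
    of the excursion from the recording's peak voltage back to rest.  Returns
    ``(terminated, time_ms)`` where the time is the earliest sample from
    which the whole tissue stays repolarized through the end of the
    recording; ``(False, inf)`` if activity persists at the horizon.
    """
    if len(recording.times) == 0:
        return True, 0.0
    peak = float(max(recording.vmax.max(), ACTIVATION_THRESHOLD_MV))
    threshold = resting_vm + (1.0 - repol_fraction) * (peak - resting_vm)
    above = recording.vmax > threshold
    if not above.any():
        return True, float(recording.times[0])
    last = int(np.flatnonzero(above)[-1])
    if last == len(above) - 1:
        return False, NOT_TERMINATED
    return True, float(recording.times[last + 1])


def rank_lesion_sets(results: list[SimulationResult]) -> list[SimulationResult]:
    """Order protocols by outcome: fastest termination first.

    Terminated runs sort by ascending time to termination; non-terminated
    runs go last.  Ties break by fewer ablated nodes, then by the canonical
    protocol order.
    """
    if not results:
        raise ValueError("no results to rank")

    def proto_rank(name: str) -> int:
        try:
            return lesions.PROTOCOL_NAMES.index(name)
        except ValueError:
            return len(lesions.PROTOCOL_NAMES)

    return sorted(
        results,
        key=lambda r: (
            0 if r.terminated else 1,
            r.time_to_termination_ms if r.terminated else math.inf,
            r.n_ablated_nodes,
            proto_rank(r.protocol),
        ),
    )


def best_protocol(results: list[SimulationResult]) -> SimulationResult | None:
    """The winning lesion set, or None when nothing terminated."""
    ranked = rank_lesion_sets(results)
    return ranked[0] if ranked[0].terminated else None


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


class VirtualAblationStudy:
    """Shared-induction driver for running several protocols on one atrium.

    Induction and the 4 s pre-ablation segment are computed once; each
    protocol then branches from the saved pre-ablation tissue state, so
    protocol outcomes are directly comparable (identical fibrillatory state
    at ablation onset).
    """

    def __init__(
        self,
        mesh: MonolayerMesh,
        cell_params: ionic.CellParams,
        config: RunConfig | None = None,
        diffusivity: float | None = None,
    ):
        self.mesh = mesh
        self.config = config or RunConfig()
        if diffusivity is not None:
            self.config = replace(
                self.config, solver=replace(self.config.solver, diffusivity=diffusivity)
            )
        self.cell_params = cell_params
        self.sim = TissueSimulator(mesh, cell_params, self.config.solver)
        self._baseline = None
        self._baseline_t = None
        self.induced: bool | None = None
        self.induction_method = "pacing"
        self.cfae_map: CfaeMap | None = None
        self.pre_recording: Recording | None = None

    def prepare(self) -> bool:
        """Induce AF and advance to ablation onset; returns the induction flag.

        Ablation onset is the end of induction plus the pre-ablation wait
        (4 s by default).  The tail of the pre-ablation segment is recorded
        in full for CFAE cycle-length mapping.
        """
        cfg = self.config
        self.induced = False
        tail = None
        for route in cfg.induction_routes:
            self.induction_method = route
            if route == "pacing":
                self.induced, tail = induce_af(
                    self.sim, cfg.pacing, cfg.sustained_window_ms, cfg.stim_radius_mm,
                    record_full=True,
                )
            elif route == "s1s2":
                self.induced, tail = s1s2_cross_field(
                    self.sim, sustained_window_ms=cfg.sustained_window_ms,
                    record_full=True,
                )
            elif route == "phase_seed":
                self.induced, tail = seed_phase_reentry(
                    self.sim, sustained_window_ms=cfg.sustained_window_ms,
                    record_full=True,
                )
            else:
                raise ValueError(f"unknown induction route '{route}'")
            if self.induced:
                break
        if tail is None:
            raise ValueError("config lists no induction routes")
        remaining = max(cfg.wait_after_pacing_ms - cfg.sustained_window_ms, 0.0)
        rec = self.sim.run(remaining, record_full=True) if remaining > 0 else None
        full = tail if rec is None else tail.extend(rec)
        self.pre_recording = full
        window_lo = max(full.times[0], full.times[-1] - cfg.cfae_window_ms)
        self.cfae_map = compute_cfae_map(full, (window_lo, float(full.times[-1])))
        # AF must still be running at ablation onset for a meaningful branch
        self.induced = bool(self.induced and _is_sustained(full))
        self._baseline = self.sim.state.copy()
        self._baseline_t = self.sim.state.t
        return self.induced

    def run_protocol(self, protocol_name: str, record_full: bool = False) -> SimulationResult:
        """Apply one lesion set at ablation onset and observe to the horizon."""
        if self._baseline is None:
            self.prepare()
        cfg = self.config
        lesion = lesions.build_protocol_lesions(
            self.mesh,
            protocol_name,
            cfae_map=self.cfae_map,
            width_mm=cfg.lesion_width_mm,
            cl_threshold=cfg.cfae_cl_threshold_ms,
            area_cap_fraction=cfg.cfae_area_cap,
        )
        if not self.induced:
            return SimulationResult(
                protocol=protocol_name,
                induced=False,
                terminated=False,
                time_to_termination_ms=NOT_TERMINATED,
                ablated_area_mm2=lesion.area_mm2,
                n_ablated_nodes=len(lesion.nodes),
                induction_method=self.induction_method,
            )
        self.sim.state = self._baseline.copy()
        self.sim.ablate(lesion.nodes)
        # chunked observation with early exit: once no node has been
        # depolarized for 100 ms the deterministic tissue cannot re-fire
        rec: Recording | None = None
        elapsed = 0.0
        quiet_ms = 100.0
        while elapsed < cfg.horizon_ms:
            chunk = min(500.0, cfg.horizon_ms - elapsed)
            r = self.sim.run(chunk, record_full=record_full)
            rec = r if rec is None else rec.extend(r)
            elapsed += chunk
            n_quiet = int(round(quiet_ms / cfg.solver.sample_interval))
            if len(rec.times) > n_quiet and (rec.n_depolarized[-n_quiet:] == 0).all():
                break
        terminated, t_term = detect_termination(
            rec, self.sim.resting_vm, cfg.repol_fraction
        )
        # undo the ablation on the simulator for the next protocol branch
        self.sim.state = self._baseline.copy()
        self.sim.state.ablated_mask[:] = False
        self.sim._operator = None
        return SimulationResult(
            protocol=protocol_name,
            induced=True,
            terminated=terminated,
            time_to_termination_ms=(
                t_term - self._baseline_t if terminated else NOT_TERMINATED
            ),
            ablated_area_mm2=lesion.area_mm2,
            n_ablated_nodes=len(lesion.nodes),
            induction_method=self.induction_method,
        )

    def run_all(self, protocols: tuple[str, ...] = lesions.PROTOCOL_NAMES) -> list[SimulationResult]:
        self.prepare()
        return [self.run_protocol(p) for p in protocols]


def run_protocol(
    mesh: MonolayerMesh,
    protocol_name: str,
    cell_params: ionic.CellParams,
    config: RunConfig | None = None,
    diffusivity: float | None = None,
) -> SimulationResult:
    """One-shot convenience wrapper: induce, wait 4 s, ablate, observe."""
    study = VirtualAblationStudy(mesh, cell_params, config, diffusivity)
    return study.run_protocol(protocol_name)
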