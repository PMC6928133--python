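"""Monodomain reaction-diffusion solver on the atrial monolayer.

The membrane potential obeys dVm/dt = D_eff * L(Vm) - (I_ion + I_s), where L
is a node-area-lumped cotangent Laplacian on the triangulated surface and
D_eff is a single effective diffusivity (mm^2/ms).  The membrane
surface-to-volume ratio and specific capacitance of the continuous
formulation are folded into D_eff, which is fixed by calibrating the planar
conduction velocity on a reference strip (the only tissue-scale constraint
the model imposes; the target is 0.4 m/s, the human atrial value).

Time stepping is first-order operator splitting with a fixed dt: explicit
diffusion followed by the per-node ionic update (Rush-Larsen / Euler kernel
shared with the single-cell integrator).  Non-conductive nodes (mitral
annulus) carry no state; ablated nodes are re-clamped to -80.6 mV every
step, which both blocks conduction and sinks current like scarred tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import ionic
from .geometry import MonolayerMesh, rectangular_strip

DEFAULT_DIFFUSIVITY = 0.1  # mm^2/ms, order-of-magnitude start for calibration
DEFAULT_TISSUE_STIM = -60.0  # pA/pF, robust supra-threshold tissue stimulus
ACTIVATION_THRESHOLD_MV = -40.0


@dataclass
class SolverParams:
    """Monodomain solver settings.

    diffusivity : effective diffusivity D_eff (mm^2/ms); calibrate with
        :func:`calibrate_diffusion` rather than setting by hand.
    dt : time step (ms) shared by diffusion and reaction.
    sample_interval : voltage sampling cadence (ms) for recordings.
    """

    diffusivity: float = DEFAULT_DIFFUSIVITY
    dt: float = ionic.DEFAULT_DT_MS
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.diffusivity <= 0 or self.dt <= 0 or self.sample_interval <= 0:
            raise ValueError("all solver parameters must be positive")


@dataclass
class Stimulus:
    """Square current pulse applied to a node set.

    Times in ms relative to the simulation clock; amplitude in pA/pF
    (inward/depolarizing is negative).
    """

    nodes: np.ndarray
    start: float
    duration: float = 2.0
    amplitude: float = DEFAULT_TISSUE_STIM

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


@dataclass
class Recording:
    """Sampled summary of a tissue run.

    ``vmax``/``n_depolarized`` summarize the conductive, non-ablated tissue
    per sample; ``vm`` optionally keeps the full per-node voltage matrix
    (float32) for CFAE mapping and activation-time analysis.
    """

    times: np.ndarray
    vmax: np.ndarray
    n_depolarized: np.ndarray
    vm: np.ndarray | None = None

    def extend(self, other: "Recording") -> "Recording":
        vm = None
        if self.vm is not None and other.vm is not None:
            vm = np.vstack([self.vm, other.vm])
        return Recording(
            np.concatenate([self.times, other.times]),
            np.concatenate([self.vmax, other.vmax]),
            np.concatenate([self.n_depolarized, other.n_depolarized]),
            vm,
        )


@dataclass
class TissueState:
    """Per-node cell states plus conduction masks and the simulation clock."""

    states: np.ndarray            # (n_nodes, 21)
    ablated_mask: np.ndarray      # bool
    nonconductive_mask: np.ndarray
    t: float = 0.0

    @property
    def vm(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def active_nodes(self) -> np.ndarray:
        return np.flatnonzero(~self.ablated_mask & ~self.nonconductive_mask)

    def copy(self) -> "TissueState":
        return TissueState(
            self.states.copy(), self.ablated_mask.copy(), self.nonconductive_mask.copy(), self.t
        )


def make_tissue_state(mesh: MonolayerMesh, resting: ionic.CellState) -> TissueState:
    """Uniform tissue at the given resting cell state."""
    states = np.tile(resting.values, (mesh.n_nodes, 1))
    return TissueState(
        states=states,
        ablated_mask=np.zeros(mesh.n_nodes, dtype=bool),
        nonconductive_mask=mesh.nonconductive_mask.copy(),
    )


# ---------------------------------------------------------------------------
# Diffusion operator
# ---------------------------------------------------------------------------


def build_diffusion_operator(
    mesh: MonolayerMesh, excluded_mask: np.ndarray | None = None
) -> sp.csr_matrix:
    """Assemble the symmetric surface Laplacian L = W - diag(W 1).

    Rows and columns of non-conductive (and any additionally excluded, e.g.
    ablated) nodes are zeroed so no flux enters or leaves them.  The operator
    has zero row sums on the interior, hence a uniform field lies in its null
    space.  Divide by the lumped node areas to obtain the diffusion rate.
    """
    mask = mesh.nonconductive_mask.copy()
    if excluded_mask is not None:
        mask |= excluded_mask
    if mask.all():
        raise ValueError("all nodes are non-conductive; no tissue to simulate")
    w = mesh.adjacency.tolil(copy=True)
    blocked = np.flatnonzero(mask)
    w[blocked, :] = 0.0
    w[:, blocked] = 0.0
    w = w.tocsr()
    deg = np.asarray(w.sum(axis=1)).ravel()
    free = ~mask
    isolated = np.flatnonzero(free & (deg == 0))
    if len(isolated):
        warnings.warn(
            f"{len(isolated)} isolated conductive node(s), e.g. node {isolated[0]}",
            RuntimeWarning,
            stacklevel=2,
        )
    lap = w - sp.diags(deg)
    return lap.tocsr()


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


def step_tissue(
    state: TissueState,
    operator: sp.csr_matrix,
    inv_area: np.ndarray,
    params: SolverParams,
    cell_params_scaled: np.ndarray,
    stimuli: list[Stimulus] | None = None,
) -> None:
    """Advance the tissue one time step in place (diffusion then reaction).

    ``inv_area`` is 1/node_area (1/mm^2); ablated nodes are re-clamped to the
    ablation potential at the end of the step.
    """
    vm = state.states[:, 0]
    vm += params.dt * params.diffusivity * inv_area * (operator @ vm)

    istim = np.zeros(len(vm))
    if stimuli:
        for s in stimuli:
            if s.active(state.t):
                istim[s.nodes] += s.amplitude

    ionic.step_states_subset(
        state.states, state.active_nodes, cell_params_scaled, params.dt, istim
    )
    if state.ablated_mask.any():
        state.states[state.ablated_mask, 0] = ionic.ABLATION_CLAMP_MV
    state.t += params.dt


def apply_ablation(state: TissueState, lesion_nodes: np.ndarray) -> TissueState:
    """Clamp the lesion nodes to -80.6 mV for the remainder of the run.

    Idempotent; the empty set is a no-op.  Returns ``state`` for chaining.
    """
    lesion_nodes = np.asarray(lesion_nodes, dtype=np.int64)
    if len(lesion_nodes) == 0:
        return state
    state.ablated_mask[lesion_nodes] = True
    state.states[lesion_nodes, 0] = ionic.ABLATION_CLAMP_MV
    return state


class TissueSimulator:
    """Convenience driver binding a mesh, cell model and solver settings.

    Rebuilds the diffusion operator lazily whenever the ablated set changes,
    so clamped lesions also carry no diffusive flux.
    """

    def __init__(
        self,
        mesh: MonolayerMesh,
        cell_params: ionic.CellParams,
        solver: SolverParams | None = None,
        resting: ionic.CellState | None = None,
    ):
        self.mesh = mesh
        self.cell_params = cell_params
        self._scaled = cell_params.scaled()
        self.solver = solver or SolverParams()
        # explicit-diffusion stability: dt * D * max_i(deg_i / a_i) must stay
        # below 1 (spectral bound of the area-lumped Laplacian)
        deg = np.asarray(mesh.adjacency.sum(axis=1)).ravel()
        lam = float(np.max(deg / mesh.node_area))
        dt_max = 1.0 / max(self.solver.diffusivity * lam, 1e-12)
        if self.solver.dt > dt_max:
            raise ValueError(
                f"dt = {self.solver.dt} ms exceeds the explicit stability bound "
                f"{dt_max:.4g} ms for D = {self.solver.diffusivity} on this mesh"
            )
        if resting is None:
            resting = ionic.find_resting_state(cell_params, dt=self.solver.dt)
        self.resting_vm = resting.Vm
        self.state = make_tissue_state(mesh, resting)
        self._inv_area = 1.0 / mesh.node_area
        self._operator: sp.csr_matrix | None = None

    @property
    def operator(self) -> sp.csr_matrix:
        if self._operator is None:
            self._operator = build_diffusion_operator(self.mesh, self.state.ablated_mask)
        return self._operator

    def ablate(self, nodes: np.ndarray) -> None:
        apply_ablation(self.state, nodes)
        self._operator = None

    def run(
        self,
        duration_ms: float,
        stimuli: list[Stimulus] | None = None,
        record_full: bool = False,
    ) -> Recording:
        """Advance ``duration_ms`` and return the sampled recording."""
        p = self.solver
        n_steps = int(round(duration_ms / p.dt))
        every = max(1, int(round(p.sample_interval / p.dt)))
        n_samp = n_steps // every
        active = self.state.active_nodes
        times = np.empty(n_samp)
        vmax = np.empty(n_samp)
        ndep = np.empty(n_samp, dtype=np.int64)
        vm_full = (
            np.empty((n_samp, self.mesh.n_nodes), dtype=np.float32) if record_full else None
        )
        op = self.operator
        k = 0
        for step in range(1, n_steps + 1):
            step_tissue(self.state, op, self._inv_area, p, self._scaled, stimuli)
            if step % every == 0:
                v = self.state.vm
                times[k] = self.state.t
                va = v[active]
                vmax[k] = va.max() if len(va) else self.resting_vm
                ndep[k] = int((va > ACTIVATION_THRESHOLD_MV).sum())
                if vm_full is not None:
                    vm_full[k] = v
                k += 1
            if step % (every * 50) == 0 and not np.isfinite(self.state.vm[active]).all():
                bad = active[~np.isfinite(self.state.vm[active])][0]
                raise FloatingPointError(
                    f"non-finite Vm at node {int(bad)}, t = {self.state.t:.2f} ms"
                )
        return Recording(times[:k], vmax[:k], ndep[:k], vm_full[:k] if vm_full is not None else None)


# ---------------------------------------------------------------------------
# Activation times and conduction-velocity calibration
# ---------------------------------------------------------------------------


def activation_times(recording: Recording, threshold: float = ACTIVATION_THRESHOLD_MV) -> np.ndarray:
    """First upward threshold crossing per node (ms); NaN if never activated.

    Requires a full-voltage recording.
    """
    if recording.vm is None:
        raise ValueError("activation_times needs a full-voltage recording")
    vm = recording.vm
    above = vm > threshold
    first = np.argmax(above, axis=0)
    never = ~above.any(axis=0)
    t = recording.times[first].astype(float)
    t[never] = np.nan
    return t


def measure_planar_cv(
    diffusivity: float,
    cell_params: ionic.CellParams,
    resting: ionic.CellState,
    strip: MonolayerMesh | None = None,
    dt: float = ionic.DEFAULT_DT_MS,
    stim_amplitude: float = DEFAULT_TISSUE_STIM,
) -> float:
    """Planar conduction velocity (m/s) on the reference strip.

    Stimulates the x=0 edge and takes the wavefront speed from mean
    activation times at 25% and 75% of the strip length.
    """
    if strip is None:
        strip = rectangular_strip()
    solver = SolverParams(diffusivity=diffusivity, dt=dt, sample_interval=0.5)
    sim = TissueSimulator(strip, cell_params, solver, resting=resting)
    x = strip.surface.vertices[:, 0]
    length = x.max()
    spacing = np.diff(np.unique(np.round(x, 6)))[0]
    stim_nodes = np.flatnonzero(x < max(1.5, 1.1 * spacing))
    # chunked run with early exit once the far end has activated
    budget = length / 50.0 * 1000.0 + 40.0  # worst case 0.05 m/s
    far = x > 0.9 * length
    rec = sim.run(40.0, [Stimulus(stim_nodes, start=0.0)], record_full=True)
    while rec.times[-1] < budget:
        if (rec.vm[:, far] > ACTIVATION_THRESHOLD_MV).any(axis=0).all():
            break
        rec = rec.extend(sim.run(40.0, record_full=True))
    at = activation_times(rec)
    tol = max(1.0, 0.6 * spacing)
    a1 = at[np.abs(x - 0.25 * length) < tol]
    a3 = at[np.abs(x - 0.75 * length) < tol]
    if len(a1) == 0 or len(a3) == 0 or np.isnan(a1).all() or np.isnan(a3).all():
        raise RuntimeError("wavefront did not traverse the strip; diffusivity too low?")
    t1 = np.nanmean(a1)
    t2 = np.nanmean(a3)
    if not np.isfinite(t1) or not np.isfinite(t2) or t2 <= t1:
        raise RuntimeError("wavefront did not traverse the strip; diffusivity too low?")
    return float(0.5 * length / (t2 - t1))  # mm/ms == m/s


def calibrate_diffusion(
    target_cv: float = 0.4,
    cell_params: ionic.CellParams | None = None,
    strip: MonolayerMesh | None = None,
    tolerance: float = 0.02,
    max_iter: int = 20,
    dt: float = ionic.DEFAULT_DT_MS,
) -> tuple[float, float]:
    """Find the effective diffusivity giving the target planar CV (m/s).

    Uses the continuum scaling CV proportional to sqrt(D) as a fixed-point
    update, which converges in a few iterations.  Returns ``(D, achieved_cv)``
    with the achieved CV within ``tolerance`` (relative) of the target.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    if cell_params is None:
        cell_params = ionic.apply_af_remodeling(ionic.CellParams())
    resting = ionic.find_resting_state(cell_params, dt=dt)
    if strip is None:
        strip = rectangular_strip()
    def cv_of(d: float) -> float:
        try:
            return measure_planar_cv(d, cell_params, resting, strip, dt=dt)
        except RuntimeError:
            return 0.0  # discrete conduction block

    # bracket the target: raise D until the strip conducts faster than the
    # target (escaping the coarse-mesh conduction-block regime if needed),
    # keeping the last slower D as the lower bound
    d_hi = DEFAULT_DIFFUSIVITY
    cv_hi = cv_of(d_hi)
    for _ in range(16):
        if cv_hi >= target_cv:
            break
        d_hi *= 2.0
        cv_hi = cv_of(d_hi)
    else:
        raise RuntimeError("target CV unreachable: no diffusivity conducts fast enough")
    if abs(cv_hi - target_cv) / target_cv <= tolerance:
        return d_hi, cv_hi
    d_lo = d_hi / 2.0 if d_hi > DEFAULT_DIFFUSIVITY else d_hi / 4.0
    cv_lo = cv_of(d_lo)

    best = (d_hi, cv_hi)
    for _ in range(max_iter):
        # secant in log-D where both brackets conduct, else bisection
        if cv_lo > 0.0 and cv_hi > cv_lo:
            w = (target_cv - cv_lo) / (cv_hi - cv_lo)
            w = min(max(w, 0.15), 0.85)
            d_mid = np.exp(np.log(d_lo) + w * (np.log(d_hi) - np.log(d_lo)))
        else:
            d_mid = np.sqrt(d_lo * d_hi)
        cv_mid = cv_of(d_mid)
        if cv_mid > 0.0 and abs(cv_mid - target_cv) < abs(best[1] - target_cv):
            best = (d_mid, cv_mid)
        if cv_mid > 0.0 and abs(cv_mid - target_cv) / target_cv <= tolerance:
            return float(d_mid), float(cv_mid)
        if cv_mid < target_cv:
            d_lo, cv_lo = d_mid, cv_mid
        else:
            d_hi, cv_hi = d_mid, cv_mid
    raise RuntimeError(
        f"calibration did not reach {target_cv} m/s within {tolerance:.0%} "
        f"(best CV {best[1]:.3f} m/s at D={best[0]:.4g})"
    )


def stable_dt(
    mesh: MonolayerMesh,
    diffusivity: float,
    safety: float = 0.8,
    cap: float = ionic.DEFAULT_DT_MS,
) -> float:
    """Largest safe explicit time step (ms) for this mesh and diffusivity."""
    deg = np.asarray(mesh.adjacency.sum(axis=1)).ravel()
    lam = float(np.max(deg / mesh.node_area))
    return float(min(cap, safety / max(diffusivity * lam, 1e-12)))


def mean_edge_length(mesh: MonolayerMesh) -> float:
    e = mesh.surface.edges()
    v = mesh.surface.vertices
    return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())


def calibrate_for_mesh(
    mesh: MonolayerMesh,
    target_cv: float = 0.4,
    cell_params: ionic.CellParams | None = None,
    dt: float = ionic.DEFAULT_DT_MS,
) -> tuple[float, float]:
    """Calibrate the diffusivity on a strip whose resolution matches ``mesh``.

    The numerical conduction velocity of an under-resolved wavefront depends
    on the node spacing, so the calibration strip must share the tissue
    mesh's mean edge length for the calibrated CV to transfer.  Returns
    ``(D, achieved_cv)``.
    """
    h = mean_edge_length(mesh)
    strip = rectangular_strip(
        length_mm=max(40.0, 18.0 * h), width_mm=max(8.0, 5.0 * h), spacing_mm=h
    )
    return calibrate_diffusion(target_cv, cell_params, strip, dt=dt)
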