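"""Cycle-length mapping of simulated AF voltage recordings.

Complex fractionated atrial electrograms (CFAE) are clinically identified by
short local activation cycle lengths.  Here the per-node mean cycle length
(CL) is computed from the simulated transmembrane voltage: an activation is
an upward crossing of -40 mV separated from the previous one by at least a
50 ms refractory interval, and the CL is the mean inter-activation interval
inside the analysis window.  Nodes with fewer than two activations have an
undefined CL, stored as +inf so they are never selected for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .propagation import ACTIVATION_THRESHOLD_MV, Recording

DEFAULT_REFRACTORY_MS = 50.0


@dataclass
class CfaeMap:
    """Per-node mean activation cycle length (ms) over a recording window."""

    cycle_length: np.ndarray      # ms; +inf where undefined
    activation_count: np.ndarray  # int per node
    window: tuple[float, float]   # (start ms, end ms)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.cycle_length)


def detect_activations(
    vm_trace: np.ndarray,
    times: np.ndarray,
    threshold: float = ACTIVATION_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Activation times: upward threshold crossings with refractory separation.

    The trace must be uniformly sampled.  Returns an array of times (ms);
    empty if the trace never crosses the threshold upward.
    """
    vm = np.asarray(vm_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    up = np.flatnonzero((vm[:-1] <= threshold) & (vm[1:] > threshold))
    if len(up) == 0:
        return np.empty(0)
    out = [times[up[0] + 1]]
    for k in up[1:]:
        if times[k + 1] - out[-1] >= refractory_ms:
            out.append(times[k + 1])
    return np.asarray(out)


def compute_cfae_map(
    recording: Recording,
    window: tuple[float, float] | None = None,
    threshold: float = ACTIVATION_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> CfaeMap:
    """Per-node mean inter-activation interval over the window.

    ``recording`` must carry the full voltage matrix.  ``window`` defaults to
    the whole recording and must lie inside it.
    """
    if recording.vm is None:
        raise ValueError("CFAE mapping needs a full-voltage recording")
    t = recording.times
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] outside recording span [{t[0]}, {t[-1]}]"
        )
    sel = (t >= lo) & (t <= hi)
    tw = t[sel]
    vm = recording.vm[sel]
    n = vm.shape[1]
    cl = np.full(n, np.inf)
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        acts = detect_activations(vm[:, i], tw, threshold, refractory_ms)
        counts[i] = len(acts)
        if len(acts) >= 2:
            cl[i] = float(np.mean(np.diff(acts)))
    return CfaeMap(cycle_length=cl, activation_count=counts, window=(lo, hi))
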