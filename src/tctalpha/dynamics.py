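"""Nonlinear-dynamics analysis of the thalamic output.

The attractor reached from the zero initial state is classified from the
post-transient extrema of the (noise-free) V_tcr series: a run whose
peak-to-peak amplitude over the analysis window stays below a tolerance
is a point attractor, anything else a limit cycle.  Bifurcation diagrams
sweep one connectivity constant with a fresh zero-state run per value
(no continuation, so no hysteresis assumptions are imported), and the
critical point of a label change is refined by bisection.

Bifurcation analysis is run with the drives frozen at their means: the
means define the deterministic skeleton whose attractors are being
counted, and extrema of a stochastic run would not form a clean
one-or-two-branch diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import STATE_NAMES, MembranePotentials, membrane_potentials
from .params import Connectivity, ModelParameters
from .simulate import SimulationConfig, Trajectory, euler_integrate
from .spectral import set_swept_parameter

__all__ = [
    "ExtremaSummary",
    "BifurcationDiagram",
    "steady_extrema",
    "classify_attractor",
    "bifurcation_sweep",
    "locate_hopf",
    "phase_portrait",
    "cycle_frequency",
    "write_diagram_csv",
]

#: default peak-to-peak tolerance (mV) separating point from cycle
DEFAULT_AMPLITUDE_TOL = 1e-4

#: fraction of the post-transient window (taken from the end) analysed
ANALYSIS_WINDOW_FRAC = 0.5


@dataclass(frozen=True)
class ExtremaSummary:
    """Steady-state local extrema of the thalamic output (mV)."""

    local_max_values: np.ndarray
    local_min_values: np.ndarray
    amplitude: float

    @property
    def n_extrema(self) -> int:
        """1 for a steady value, 2 for an oscillation."""
        return 1 if self.amplitude == 0 or len(self.local_min_values) == 0 else 2

    @property
    def max_value(self) -> float:
        """Median of detected local maxima (robust to residual transient)."""
        return float(np.median(self.local_max_values))

    @property
    def min_value(self) -> float:
        return float(np.median(self.local_min_values)) \
            if len(self.local_min_values) else self.max_value


@dataclass(frozen=True)
class BifurcationDiagram:
    """Extrema and attractor label per swept parameter value."""

    param_name: str
    param_values: np.ndarray
    extrema: list[ExtremaSummary]
    labels: list[str]
    critical_value: float | None


def steady_extrema(traj: Trajectory, transient: float | None = None,
                   tol: float = DEFAULT_AMPLITUDE_TOL) -> ExtremaSummary:
    """Local extrema of post-transient V_tcr via discrete-derivative sign changes.

    Only the last :data:`ANALYSIS_WINDOW_FRAC` of the post-transient
    window is used.  If the peak-to-peak amplitude there is below
    ``tol`` the run is reported as a single steady value.
    """
    _, v = traj.post_transient(transient)
    v = v[int(len(v) * (1 - ANALYSIS_WINDOW_FRAC)):]
    if v.size * traj.dt < 1.0:
        raise ValueError("analysis window shorter than 1 s")
    amp = float(v.max() - v.min())
    if amp < tol:
        c = float(np.median(v))
        return ExtremaSummary(np.array([c]), np.array([]), 0.0)
    d = np.diff(v)
    s = np.sign(d)
    s[s == 0] = 1
    turns = np.diff(s)
    maxima = v[1:-1][turns[: len(v) - 2] < 0] if len(v) > 2 else np.array([])
    minima = v[1:-1][turns[: len(v) - 2] > 0] if len(v) > 2 else np.array([])
    if maxima.size == 0:  # monotone drift, treat endpoints as the extrema
        maxima = np.array([v.max()])
    if minima.size == 0:
        minima = np.array([v.min()])
    return ExtremaSummary(maxima, minima, amp)


def classify_attractor(ex: ExtremaSummary,
                       tol: float = DEFAULT_AMPLITUDE_TOL) -> str:
    """``"point"`` iff the steady amplitude is below ``tol``, else ``"limit_cycle"``."""
    return "point" if ex.amplitude < tol else "limit_cycle"


def _probe(param_name: str, value: float, p: ModelParameters, C: Connectivity,
           sim_cfg: SimulationConfig, tol: float) -> tuple[ExtremaSummary, str]:
    pi, Ci = set_swept_parameter(param_name, value, p, C)
    cfg = sim_cfg.replace(noise_on=False, n_realizations=1, record_states=False)
    traj = euler_integrate(pi, Ci, cfg)
    ex = steady_extrema(traj, tol=tol)
    return ex, classify_attractor(ex, tol)


def bifurcation_sweep(param_name: str, lo: float, hi: float, step: float,
                      p: ModelParameters, C: Connectivity,
                      sim_cfg: SimulationConfig,
                      tol: float = DEFAULT_AMPLITUDE_TOL,
                      refine: bool = True,
                      tol_param: float = 0.05) -> BifurcationDiagram:
    """Noise-free bifurcation diagram over ``[lo, hi]`` with spacing ``step``.

    Each value gets a fresh zero-state run.  If the attractor label
    changes along the sweep, the first change is refined by
    :func:`locate_hopf` to within ``tol_param``; with no change the
    diagram is returned with ``critical_value=None``.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    values = np.arange(lo, hi + step / 2, step)
    extrema, labels = [], []
    for val in values:
        ex, lab = _probe(param_name, float(val), p, C, sim_cfg, tol)
        extrema.append(ex)
        labels.append(lab)
    critical = None
    for i in range(len(values) - 1):
        if labels[i] != labels[i + 1]:
            if refine:
                critical = locate_hopf(param_name,
                                       (float(values[i]), float(values[i + 1])),
                                       p, C, sim_cfg, tol_param, tol=tol)
            else:
                critical = float(0.5 * (values[i] + values[i + 1]))
            break
    return BifurcationDiagram(param_name=param_name, param_values=values,
                              extrema=extrema, labels=labels,
                              critical_value=critical)


def locate_hopf(param_name: str, bracket: tuple[float, float],
                p: ModelParameters, C: Connectivity,
                sim_cfg: SimulationConfig, tol_param: float = 0.05,
                tol: float = DEFAULT_AMPLITUDE_TOL) -> float:
    """Bisection on the attractor label; returns the bracket midpoint.

    Each probe is a fresh zero-state noise-free run.  The bracket
    endpoints must classify differently.
    """
    a, b = float(bracket[0]), float(bracket[1])
    _, la = _probe(param_name, a, p, C, sim_cfg, tol)
    _, lb = _probe(param_name, b, p, C, sim_cfg, tol)
    if la == lb:
        raise ValueError(
            f"bracket endpoints both classify as {la!r}; no transition inside")
    while b - a > tol_param:
        mid = 0.5 * (a + b)
        _, lm = _probe(param_name, mid, p, C, sim_cfg, tol)
        if lm == la:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def phase_portrait(traj: Trajectory, pair: tuple[str, str],
                   C: Connectivity | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Post-transient planar curve ``(a(t), b(t))`` for two named series.

    Valid names are the 18 state components, ``"v_tcr"`` and the other
    membrane-potential names (lower case, e.g. ``"v_py"``); potentials
    other than ``v_tcr`` need recorded states and the connectivity.
    """
    def series(name: str) -> np.ndarray:
        if name == "v_tcr":
            i0 = int(round(traj.config.transient / traj.dt))
            return traj.v_tcr[i0:]
        if name in STATE_NAMES:
            if traj.states is None:
                raise ValueError("trajectory was run without state recording")
            i0 = int(round(traj.config.transient / traj.dt))
            return traj.states[i0:, STATE_NAMES.index(name)]
        pot_names = tuple(n.lower() for n in MembranePotentials.names)
        if name in pot_names:
            if traj.states is None or C is None:
                raise ValueError("potentials need recorded states and connectivity")
            i0 = int(round(traj.config.transient / traj.dt))
            idx = pot_names.index(name)
            return np.array([
                membrane_potentials(s, C).as_array()[idx]
                for s in traj.states[i0:]])
        raise KeyError(
            f"unknown series {name!r}; valid: {STATE_NAMES + ('v_tcr',) + pot_names}")

    return series(pair[0]), series(pair[1])


def cycle_frequency(traj: Trajectory, transient: float | None = None) -> float:
    """Fundamental frequency (Hz) from upward mean-crossings of V_tcr.

    Independent of any spectral estimate; returns 0 for a steady run.
    """
    t, v = traj.post_transient(transient)
    if v.size < 2:
        raise ValueError("post-transient window empty")
    m = v - v.mean()
    up = np.flatnonzero((m[:-1] < 0) & (m[1:] >= 0))
    if len(up) < 2:
        return 0.0
    span = (up[-1] - up[0]) * traj.dt
    return float((len(up) - 1) / span)


def write_diagram_csv(path, diag: BifurcationDiagram) -> None:
    """Delimited text: parameter value, n_extrema, max, min, label."""
    import pandas as pd

    rows = [{
        diag.param_name: val,
        "n_extrema": ex.n_extrema,
        "max": ex.max_value,
        "min": ex.min_value,
        "label": lab,
    } for val, ex, lab in zip(diag.param_values, diag.extrema, diag.labels)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
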