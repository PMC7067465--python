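"""Fixed-step stochastic simulation of the TCT model.

The model is integrated with the forward Euler method from a zero
initial state, the convention for neural mass simulations where the
initial transient is discarded anyway.  Extrinsic drives are Gaussian
white noise redrawn independently at every integration step (variance
``phi`` per step by default; an optional spectral-density mode scales
the variance by ``1/dt``), or frozen at their means for deterministic
runs.  Ensembles use deterministic per-realization child seeds so that
any realization can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernel import euler_loop
from .model import STATE_NAMES, pack_coefficients
from .params import Connectivity, ModelParameters

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationDivergedError",
    "child_seed",
    "draw_drives",
    "euler_integrate",
    "run_ensemble",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_npz",
    "read_trajectory_npz",
]

#: forward-Euler accuracy guard: dt must stay below the fastest time
#: constant divided by this factor
_DT_GUARD_FACTOR = 5.0

#: divergence guard on |state| (mV); far above physiological scale
DIVERGENCE_GUARD = 1e6


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and ensemble settings.

    ``dt``, ``duration`` and ``transient`` in seconds.  With
    ``noise_on=False`` the drives are the constant means ``mu_r`` and
    ``mu_c``.  ``noise_as_density=True`` interprets ``phi`` as a
    spectral density, sampling with variance ``phi/dt`` instead of
    ``phi`` per step.  ``record_states=False`` keeps only the thalamic
    output series, which is what long sweeps need.
    """

    dt: float = 1e-4
    duration: float = 20.0
    transient: float = 5.0
    seed: int = 0
    noise_on: bool = True
    n_realizations: int = 50
    noise_as_density: bool = False
    record_states: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.transient < self.duration:
            raise ValueError("need 0 <= transient < duration")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


class SimulationDivergedError(RuntimeError):
    """Raised when a state component exceeds the divergence guard."""


@dataclass(frozen=True)
class Trajectory:
    """One simulation run on a uniform time grid.

    ``states`` has shape (n_points, 18) in :data:`~tctalpha.model.STATE_NAMES`
    order, or is ``None`` when state recording was disabled.  ``v_tcr`` is
    the thalamic module output, the membrane potential of the TCR
    population, recomputable exactly from ``states`` and the
    connectivity.
    """

    t: np.ndarray
    states: np.ndarray | None
    v_tcr: np.ndarray
    dt: float
    seed: int
    config: SimulationConfig

    def post_transient(self, transient: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(t, v_tcr) with the initial ``transient`` seconds dropped."""
        tr = self.config.transient if transient is None else transient
        i0 = int(round(tr / self.dt))
        return self.t[i0:], self.v_tcr[i0:]


def child_seed(seed: int, *key: int) -> int:
    """Deterministic child seed for realization/sweep indices (< 2**31)."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2**31))


def draw_drives(cfg: SimulationConfig, p: ModelParameters, n_steps: int,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-step retinal and cortico-cortical drive series (spikes/s).

    Independent Gaussian samples ``N(mu_r, phi_r)`` and ``N(mu_c, phi_c)``;
    constant means when ``noise_on`` is false.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if p.phi_r < 0 or p.phi_c < 0:
        raise ValueError("drive variances must be >= 0")
    if not cfg.noise_on:
        return (np.full(n_steps, p.mu_r), np.full(n_steps, p.mu_c))
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scale = 1.0 / cfg.dt if cfg.noise_as_density else 1.0
    u_r = p.mu_r + np.sqrt(p.phi_r * scale) * rng.standard_normal(n_steps)
    u_c = p.mu_c + np.sqrt(p.phi_c * scale) * rng.standard_normal(n_steps)
    return u_r, u_c


def _check_dt(cfg: SimulationConfig, p: ModelParameters) -> None:
    limit = min(p.tau_if, p.tau_e_thal) / _DT_GUARD_FACTOR
    if cfg.dt >= limit:
        raise ValueError(
            f"dt={cfg.dt} too coarse for Euler accuracy: need "
            f"dt < min(tau_if, tau_e_thal)/{_DT_GUARD_FACTOR} = {limit:g} s")


def euler_integrate(p: ModelParameters, C: Connectivity,
                    cfg: SimulationConfig) -> Trajectory:
    """Forward-Euler integration from zero initial state.

    The drive value is held constant within each step.  Raises
    :class:`SimulationDivergedError` if any state magnitude exceeds
    ``DIVERGENCE_GUARD``, naming the offending step and parameter set.
    """
    _check_dt(cfg, p)
    n = cfg.n_steps
    u_r, u_c = draw_drives(cfg, p, n)
    H, tau, sig, c = pack_coefficients(p, C)
    x = np.zeros(18)
    v_out = np.empty(n + 1)
    if cfg.record_states:
        states = np.empty((n + 1, 18))
    else:
        states = np.empty((1, 18))
    bad_step = euler_loop(x, cfg.dt, H, tau, sig, c, u_r, u_c, v_out,
                          states, cfg.record_states, DIVERGENCE_GUARD)
    if bad_step >= 0:
        raise SimulationDivergedError(
            f"state exceeded {DIVERGENCE_GUARD:g} mV at step {bad_step} "
            f"(t={bad_step * cfg.dt:.4f} s); parameters: {p}, connectivity: {C}")
    t = np.arange(n + 1) * cfg.dt
    return Trajectory(t=t, states=states if cfg.record_states else None,
                      v_tcr=v_out, dt=cfg.dt, seed=cfg.seed, config=cfg)


def run_ensemble(p: ModelParameters, C: Connectivity,
                 cfg: SimulationConfig) -> list[Trajectory]:
    """Seeded ensemble of independent realizations.

    Realization ``k`` runs :func:`euler_integrate` with the deterministic
    child seed ``child_seed(cfg.seed, k)``, so results do not depend on
    execution order and any member can be recomputed alone.
    """
    out = []
    for k in range(cfg.n_realizations):
        sub = cfg.replace(seed=child_seed(cfg.seed, k), n_realizations=1)
        try:
            out.append(euler_integrate(p, C, sub))
        except SimulationDivergedError as err:
            raise SimulationDivergedError(
                f"realization {k}: {err}") from err
    return out


# ---------------------------------------------------------------------------
# trajectory serialisation


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    """Headered tab-delimited text: time, 18 states, v_tcr (one row/point)."""
    if traj.states is None:
        header = "t\tv_tcr"
        data = np.column_stack([traj.t, traj.v_tcr])
    else:
        header = "t\t" + "\t".join(STATE_NAMES) + "\tv_tcr"
        data = np.column_stack([traj.t, traj.states, traj.v_tcr])
    np.savetxt(path, data, delimiter="\t", header=header, comments="",
               fmt="%.17g")


def read_trajectory_csv(path: str | Path, cfg: SimulationConfig | None = None) -> Trajectory:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    t = data[:, 0]
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    states = data[:, 1:19] if data.shape[1] == 20 else None
    v = data[:, -1]
    cfg = cfg or SimulationConfig(dt=dt or 1e-4, duration=max(t[-1], dt or 1e-4))
    return Trajectory(t=t, states=states, v_tcr=v, dt=dt, seed=cfg.seed, config=cfg)


def write_trajectory_npz(path: str | Path, traj: Trajectory) -> None:
    """Compact binary container, lossless at double precision."""
    np.savez_compressed(
        path, t=traj.t, v_tcr=traj.v_tcr, dt=traj.dt, seed=traj.seed,
        states=traj.states if traj.states is not None else np.empty((0, 18)),
        config=np.array(repr(dataclasses.asdict(traj.config))))


def read_trajectory_npz(path: str | Path) -> Trajectory:
    import ast

    with np.load(path, allow_pickle=False) as z:
        cfg = SimulationConfig(**ast.literal_eval(str(z["config"])))
        states = z["states"]
        return Trajectory(
            t=z["t"], states=None if states.size == 0 else states,
            v_tcr=z["v_tcr"], dt=float(z["dt"]), seed=int(z["seed"]), config=cfg)
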