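"""Config-driven experiments reproducing the package's standard analyses.

Each experiment id names a standard figure-level analysis of the model:
a stochastic peak-alpha-power sweep, a noise-free bifurcation diagram,
the robustness family of C_fte sweeps at several C_lte values, or the
phase-plane/time-series panels.  Running an experiment writes headered
tab-delimited result tables plus a manifest recording the fully
resolved configuration, so that every number in the tables can be
recomputed from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import bifurcation_sweep, phase_portrait, write_diagram_csv
from .params import (Connectivity, ModelParameters, default_connectivity,
                     default_parameters, load_config, save_config)
from .simulate import SimulationConfig, euler_integrate
from .spectral import (SpectralConfig, peak_power_sweep, set_swept_parameter,
                       write_sweep_csv)

__all__ = ["ExperimentSpec", "run_experiment", "EXPERIMENTS"]

#: default sweep grids: (parameter, lo, hi, step); steps resolve the
#: narrowest transition widths of interest with >= 4 grid points
SWEEPS = {
    "C_fte": (25.0, 45.0, 0.25),
    "C_lfi": (5.0, 25.0, 0.05),
    "C_pxe": (98.0, 118.0, 0.5),
    "C_tii": (5.45, 17.45, 0.1),
}

#: experiment id -> (kind, parameter, extra)
EXPERIMENTS = {
    "fig2": ("power_sweep", "C_fte", None),
    "fig3": ("bifurcation", "C_fte", None),
    "fig5": ("power_sweep_family", "C_fte", ("C_lte", (35.0, 40.0, 45.0, 50.0))),
    "fig6": ("power_sweep", "C_lfi", None),
    "fig7": ("bifurcation", "C_lfi", None),
    "fig9": ("power_sweep", "C_pxe", None),
    "fig10": ("bifurcation", "C_pxe", None),
    "fig12": ("power_sweep", "C_tii", None),
    "fig13": ("bifurcation", "C_tii", None),
    "phase-panels": ("phase", "C_fte", (30.0, 35.0, 35.1, 40.0)),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully serialisable description of one experiment run."""

    experiment: str
    seed: int = 0
    out_dir: str | Path = "results"
    config_file: str | None = None          # parameter file overriding defaults
    overrides: dict = field(default_factory=dict)   # named parameter overrides
    sweep: tuple | None = None              # (lo, hi, step) overriding default
    fast: bool = False                      # reduced ensemble/duration

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _base(spec: ExperimentSpec) -> tuple[ModelParameters, Connectivity,
                                         SimulationConfig, SpectralConfig]:
    if spec.config_file:
        p, C = load_config(spec.config_file)
    else:
        p, C = default_parameters(), default_connectivity()
    for name, value in spec.overrides.items():
        p, C = set_swept_parameter(name, float(value), p, C)
    if spec.fast:
        sim = SimulationConfig(duration=10.0, transient=3.0, seed=spec.seed,
                               n_realizations=10)
    else:
        sim = SimulationConfig(seed=spec.seed)
    return p, C, sim, SpectralConfig()


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run one named experiment; returns the manifest (also written to disk)."""
    if spec.experiment not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {spec.experiment!r}; valid ids: "
            f"{sorted(EXPERIMENTS)}")
    kind, param, extra = EXPERIMENTS[spec.experiment]
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p, C, sim, spec_cfg = _base(spec)
    lo, hi, step = spec.sweep or SWEEPS[param]
    t0 = time.time()
    files: list[str] = []

    if kind == "power_sweep":
        values = np.arange(lo, hi + step / 2, step)
        df = peak_power_sweep(param, values, p, C, sim, spec_cfg)
        f = out / f"{spec.experiment}_peak_power_{param}.tsv"
        write_sweep_csv(f, df)
        files.append(f.name)
    elif kind == "power_sweep_family":
        fam_param, fam_values = extra
        values = np.arange(lo, hi + step / 2, step)
        for fv in fam_values:
            pf, Cf = set_swept_parameter(fam_param, fv, p, C)
            df = peak_power_sweep(param, values, pf, Cf, sim, spec_cfg)
            f = out / f"{spec.experiment}_peak_power_{param}_{fam_param}_{fv:g}.tsv"
            write_sweep_csv(f, df)
            files.append(f.name)
    elif kind == "bifurcation":
        diag = bifurcation_sweep(param, lo, hi, step, p, C, sim)
        f = out / f"{spec.experiment}_bifurcation_{param}.tsv"
        write_diagram_csv(f, diag)
        files.append(f.name)
        crit = out / f"{spec.experiment}_critical_{param}.txt"
        crit.write_text(f"{param}_critical\t"
                        f"{diag.critical_value if diag.critical_value is not None else 'NA'}\n")
        files.append(crit.name)
    elif kind == "phase":
        for val in extra:
            pv, Cv = set_swept_parameter(param, val, p, C)
            cfg = sim.replace(noise_on=False, record_states=True)
            traj = euler_integrate(pv, Cv, cfg)
            a, b = phase_portrait(traj, ("x_tcr1", "v_tcr"), Cv)
            t, v = traj.post_transient()
            f = out / f"{spec.experiment}_{param}_{val:g}.tsv"
            np.savetxt(f, np.column_stack([t, a, b]), delimiter="\t",
                       header="t\tx_tcr1\tv_tcr", comments="", fmt="%.10g")
            files.append(f.name)

    cfg_file = out / f"{spec.experiment}_config.yml"
    save_config(cfg_file, p, C)
    files.append(cfg_file.name)
    manifest = {
        "experiment": spec.experiment,
        "spec": spec.resolved(),
        "sweep": [lo, hi, step],
        "simulation": dataclasses.asdict(sim),
        "spectral": dataclasses.asdict(spec_cfg),
        "library_version": __version__,
        "files": files,
        "runtime_s": round(time.time() - t0, 3),
    }
    (out / f"{spec.experiment}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
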