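"""Parameter containers for the thalamo-cortico-thalamic (TCT) model.

The model couples a thalamic module (retinal input, thalamo-cortical relay
TCR, inhibitory interneurons IN, reticular nucleus TRN) to a cortical
module (pyramidal cells PY, excitatory interneurons eIN, slow and fast
inhibitory interneurons sIN/fIN).  Three kinds of constants parameterise
it:

* :class:`SigmoidParams` — the static potential-to-rate nonlinearity
  shared by all populations;
* :class:`ModelParameters` — synaptic gains ``H`` (mV), PSP time
  constants ``tau`` (seconds internally; the bundled config file uses
  milliseconds) and the statistics of the two extrinsic Gaussian drives;
* :class:`Connectivity` — the 23 dimensionless synaptic connection
  strengths ``C_xyz`` (percentage of total synapses, T = 100), named by
  target population ``x``, source population ``y`` and synapse type
  ``z``.

``default_parameters()`` / ``default_connectivity()`` load the bundled
default file, which reproduces the model's reference parameter tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "SigmoidParams",
    "ModelParameters",
    "Connectivity",
    "default_parameters",
    "default_connectivity",
    "load_config",
    "save_config",
]

#: config keys holding time constants, stored in ms in files, seconds in memory
_TAU_KEYS = ("tau_e_thal", "tau_e_cort", "tau_i", "tau_il", "tau_if")


@dataclass(frozen=True)
class SigmoidParams:
    """Constants of the sigmoid converting membrane potential to firing rate.

    ``S(V) = 2 e0 / (1 + exp(v (s0 - V)))`` — output in the open interval
    (0, 2 e0), equal to ``e0`` at the firing threshold ``s0``.
    """

    v: float = 0.56    # steepness, 1/mV
    e0: float = 2.5    # half-maximum discharge rate, spikes/s
    s0: float = 6.0    # firing threshold, mV

    def __post_init__(self) -> None:
        if not (self.v > 0 and self.e0 > 0):
            raise ValueError("sigmoid steepness v and rate e0 must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """Gains, time constants and drive statistics of the TCT model.

    Excitatory constants are module specific: the retinal and TCR blocks
    use the thalamic pair ``(He_thal, tau_e_thal)``; the cortico-cortical,
    PY and eIN blocks use the cortical pair ``(He_cort, tau_e_cort)``.
    IN and TRN share the thalamic inhibitory pair, sIN and fIN carry the
    cortical slow/fast inhibitory kinetics.
    """

    sigmoid: SigmoidParams = dataclasses.field(default_factory=SigmoidParams)
    He_thal: float = 3.25       # mV
    He_cort: float = 2.7        # mV
    Hi_thal: float = 22.0       # mV
    Hil: float = 4.5            # mV
    Hif: float = 39.0           # mV
    tau_e_thal: float = 0.010   # s
    tau_e_cort: float = 0.025   # s
    tau_i: float = 0.025        # s
    tau_il: float = 0.050       # s
    tau_if: float = 0.003       # s
    mu_r: float = 5.0           # spikes/s
    phi_r: float = 0.05         # (spikes/s)^2
    mu_c: float = 13.0          # spikes/s
    phi_c: float = 0.05         # (spikes/s)^2

    def __post_init__(self) -> None:
        for name in ("He_thal", "He_cort", "Hi_thal", "Hil", "Hif",
                     "tau_e_thal", "tau_e_cort", "tau_i", "tau_il", "tau_if"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.phi_r < 0 or self.phi_c < 0:
            raise ValueError("drive variances phi_r, phi_c must be >= 0")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        """Names of the scalar fields (sigmoid fields listed as v, e0, s0)."""
        own = tuple(f.name for f in dataclasses.fields(cls) if f.name != "sigmoid")
        return tuple(f.name for f in dataclasses.fields(SigmoidParams)) + own


@dataclass(frozen=True)
class Connectivity:
    """The 23 synaptic connection strengths ``C_xyz`` of the TCT circuit.

    Naming: ``x`` target, ``y`` source, ``z`` type (e/i).  Population
    codes: t TCR, i IN, n TRN, p PY, x eIN, l sIN, f fIN, r retinal,
    c cortico-cortical, s self.  All values dimensionless and >= 0;
    a zero simply removes that pathway.
    """

    # thalamic module
    C_tre: float = 7.1
    C_tii: float = 15.45
    C_tni: float = 15.45
    C_tpe: float = 62.0
    C_ire: float = 47.4
    C_isi: float = 23.6
    C_ipe: float = 29.0
    C_nte: float = 35.0
    C_nsi: float = 15.0
    C_npe: float = 50.0
    # cortical module
    C_pce: float = 1.0
    C_pte: float = 80.0
    C_pxe: float = 108.0
    C_pli: float = 33.75
    C_pfi: float = 108.0
    C_xte: float = 100.0
    C_xpe: float = 135.0
    C_lte: float = 40.0
    C_lpe: float = 33.75
    C_lfi: float = 13.5
    C_fte: float = 40.0
    C_fpe: float = 40.5
    C_fli: float = 13.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"connectivity {f.name} must be >= 0")

    def replace(self, **changes) -> "Connectivity":
        return dataclasses.replace(self, **changes)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


def _read_yaml(path: str | Path | None) -> dict:
    if path is None:
        text = resources.files("tctalpha.data").joinpath("defaults.yml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter file must be a flat key/value mapping")
    return data


def load_config(path: str | Path | None = None) -> tuple[ModelParameters, Connectivity]:
    """Read a flat YAML parameter file (``None`` loads the bundled defaults).

    Keys are the model's symbol names (``C_fte``, ``tau_if``, ``mu_r``, ...).
    Time constants are interpreted as milliseconds and converted to seconds.
    Keys missing from the file keep their default values.
    """
    data = _read_yaml(path)
    cnames = set(Connectivity.names())
    conn_kw, par_kw, sig_kw = {}, {}, {}
    sig_fields = {f.name for f in dataclasses.fields(SigmoidParams)}
    par_fields = {f.name for f in dataclasses.fields(ModelParameters)} - {"sigmoid"}
    for key, value in data.items():
        value = float(value)
        if key in cnames:
            conn_kw[key] = value
        elif key in sig_fields:
            sig_kw[key] = value
        elif key in par_fields:
            if key in _TAU_KEYS:
                value *= 1e-3
            par_kw[key] = value
        else:
            raise KeyError(
                f"unknown parameter {key!r}; valid keys are the connectivity "
                f"names {sorted(cnames)} and model fields "
                f"{sorted(sig_fields | par_fields)}"
            )
    params = ModelParameters(sigmoid=SigmoidParams(**sig_kw), **par_kw)
    return params, Connectivity(**conn_kw)


def save_config(path: str | Path, p: ModelParameters, c: Connectivity) -> None:
    """Write a flat YAML parameter file (time constants back in ms)."""
    out: dict[str, float] = {}
    for name in Connectivity.names():
        out[name] = getattr(c, name)
    for f in dataclasses.fields(SigmoidParams):
        out[f.name] = getattr(p.sigmoid, f.name)
    for f in dataclasses.fields(ModelParameters):
        if f.name == "sigmoid":
            continue
        val = getattr(p, f.name)
        if f.name in _TAU_KEYS:
            val *= 1e3
        out[f.name] = val
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def default_parameters() -> ModelParameters:
    """The bundled default :class:`ModelParameters`."""
    return load_config(None)[0]


def default_connectivity() -> Connectivity:
    """The bundled default :class:`Connectivity`."""
    return load_config(None)[1]
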