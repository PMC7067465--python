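"""State layout and right-hand side of the TCT neural mass model.

Each of the nine population blocks (retinal, cortico-cortical, TCR, IN,
TRN, PY, eIN, sIN, fIN) is a second-order linear synaptic filter

    x1' = x2
    x2' = (H / tau) * u(t) - (2 / tau) * x2 - (1 / tau^2) * x1

whose input ``u`` is the extrinsic drive for the two input blocks and the
sigmoid-transformed membrane potential ``S(V)`` for the seven interior
populations.  The membrane potential of each interior population is the
signed, connectivity-weighted sum of presynaptic PSP outputs ``x1``
(excitatory terms positive, inhibitory negative).

The 18-component state vector is frozen in :data:`STATE_NAMES` order and
used by every serialisation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Connectivity, ModelParameters, SigmoidParams

__all__ = [
    "STATE_NAMES",
    "POPULATIONS",
    "MembranePotentials",
    "sigmoid",
    "membrane_potentials",
    "derivatives",
    "pack_coefficients",
]

#: frozen order of the state vector: PSP output (x1, mV) and its time
#: derivative (x2, mV/s) for each population block
STATE_NAMES: tuple[str, ...] = (
    "x_ret1", "x_ret2",
    "x_cc1", "x_cc2",
    "x_tcr1", "x_tcr2",
    "x_in1", "x_in2",
    "x_trn1", "x_trn2",
    "x_py1", "x_py2",
    "x_ein1", "x_ein2",
    "x_sin1", "x_sin2",
    "x_fin1", "x_fin2",
)

#: block order used for packed per-population coefficient vectors
POPULATIONS: tuple[str, ...] = (
    "ret", "cc", "tcr", "in", "trn", "py", "ein", "sin", "fin")


@dataclass(frozen=True)
class MembranePotentials:
    """Postsynaptic membrane potentials of the seven interior populations (mV)."""

    V_tcr: float
    V_in: float
    V_trn: float
    V_py: float
    V_ein: float
    V_sin: float
    V_fin: float

    names = ("V_tcr", "V_in", "V_trn", "V_py", "V_ein", "V_sin", "V_fin")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names])


def sigmoid(V, p: SigmoidParams):
    """Potential-to-rate sigmoid ``S(V) = 2 e0 / (1 + exp(v (s0 - V)))``.

    Strictly increasing, bounded in (0, 2 e0), equal to ``e0`` at the
    firing threshold ``s0``.  Accepts scalars or arrays; rejects
    non-finite potentials.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    out = 2.0 * p.e0 / (1.0 + np.exp(p.v * (p.s0 - V)))
    return float(out) if out.ndim == 0 else out


def membrane_potentials(state, C: Connectivity) -> MembranePotentials:
    """Membrane potentials as connectivity-weighted sums of PSP outputs.

    ``state`` is an 18-vector in :data:`STATE_NAMES` order.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (18,):
        raise ValueError(f"state must have shape (18,), got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("state must be finite")
    ret1, cc1 = s[0], s[2]
    tcr1, in1, trn1 = s[4], s[6], s[8]
    py1, ein1, sin1, fin1 = s[10], s[12], s[14], s[16]
    return MembranePotentials(
        V_tcr=C.C_tre * ret1 + C.C_tpe * py1 - C.C_tii * in1 - C.C_tni * trn1,
        V_in=C.C_ire * ret1 + C.C_ipe * py1 - C.C_isi * in1,
        V_trn=C.C_nte * tcr1 + C.C_npe * py1 - C.C_nsi * trn1,
        V_py=(C.C_pce * cc1 + C.C_pte * tcr1 + C.C_pxe * ein1
              - C.C_pli * sin1 - C.C_pfi * fin1),
        V_ein=C.C_xpe * py1 + C.C_xte * tcr1,
        V_sin=C.C_lpe * py1 + C.C_lte * tcr1 - C.C_lfi * fin1,
        V_fin=C.C_fpe * py1 + C.C_fte * tcr1 - C.C_fli * sin1,
    )


def pack_coefficients(p: ModelParameters, C: Connectivity):
    """Pack parameters into flat arrays for the integration kernel.

    Returns ``(H, tau, sig, c)`` where ``H``/``tau`` hold the gain and
    time constant of each block in :data:`POPULATIONS` order, ``sig`` is
    ``(v, e0, s0)`` and ``c`` the 23 connectivity constants in
    :meth:`Connectivity.names` order.
    """
    H = np.array([p.He_thal, p.He_cort, p.He_thal, p.Hi_thal, p.Hi_thal,
                  p.He_cort, p.He_cort, p.Hil, p.Hif])
    tau = np.array([p.tau_e_thal, p.tau_e_cort, p.tau_e_thal, p.tau_i,
                    p.tau_i, p.tau_e_cort, p.tau_e_cort, p.tau_il, p.tau_if])
    sig = np.array([p.sigmoid.v, p.sigmoid.e0, p.sigmoid.s0])
    c = np.array([getattr(C, n) for n in Connectivity.names()])
    return H, tau, sig, c


def derivatives(state, u_ret: float, u_cc: float,
                p: ModelParameters, C: Connectivity) -> np.ndarray:
    """Time derivative of the full 18-component state (reference implementation).

    ``u_ret`` and ``u_cc`` are the instantaneous extrinsic drive rates
    (spikes/s) entering the retinal and cortico-cortical blocks.  The
    compiled integration kernel is tested against this function.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (18,):
        raise ValueError(f"state must have shape (18,), got {s.shape}")
    if not (np.all(np.isfinite(s)) and np.isfinite(u_ret) and np.isfinite(u_cc)):
        raise ValueError("state and drives must be finite")
    V = membrane_potentials(s, C)
    H, tau, _, _ = pack_coefficients(p, C)
    rates = np.array([
        u_ret,
        u_cc,
        sigmoid(V.V_tcr, p.sigmoid),
        sigmoid(V.V_in, p.sigmoid),
        sigmoid(V.V_trn, p.sigmoid),
        sigmoid(V.V_py, p.sigmoid),
        sigmoid(V.V_ein, p.sigmoid),
        sigmoid(V.V_sin, p.sigmoid),
        sigmoid(V.V_fin, p.sigmoid),
    ])
    x1, x2 = s[0::2], s[1::2]
    d = np.empty(18)
    d[0::2] = x2
    d[1::2] = H / tau * rates - 2.0 / tau * x2 - x1 / tau**2
    return d
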