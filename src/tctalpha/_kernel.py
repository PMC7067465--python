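"""Compiled forward-Euler inner loop (numba).

The kernel advances the packed 18-dimensional state with a fixed step,
holding each drive sample constant within its step, and writes the
thalamic output V_tcr at every step.  Full state recording is optional
so that long ensemble sweeps need not allocate the (n_steps, 18) array.

Returns the index of the first step at which any state component
exceeded the divergence guard, or -1 on success.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def euler_loop(x, dt, H, tau, sig, c, u_r, u_c, v_out, states_out,
               record_states, guard):
    vv = sig[0]
    ee0 = sig[1]
    ss0 = sig[2]
    (tre, tii, tni, tpe, ire, isi, ipe, nte, nsi, npe, pce, pte, pxe, pli,
     pfi, xte, xpe, lte, lpe, lfi, fte, fpe, fli) = (
        c[0], c[1], c[2], c[3], c[4], c[5], c[6], c[7], c[8], c[9], c[10],
        c[11], c[12], c[13], c[14], c[15], c[16], c[17], c[18], c[19],
        c[20], c[21], c[22])
    n = u_r.shape[0]
    v_out[0] = tre * x[0] + tpe * x[10] - tii * x[6] - tni * x[8]
    if record_states:
        for j in range(18):
            states_out[0, j] = x[j]
    inp = np.empty(9)
    for k in range(n):
        V_tcr = tre * x[0] + tpe * x[10] - tii * x[6] - tni * x[8]
        V_in = ire * x[0] + ipe * x[10] - isi * x[6]
        V_trn = nte * x[4] + npe * x[10] - nsi * x[8]
        V_py = pce * x[2] + pte * x[4] + pxe * x[12] - pli * x[14] - pfi * x[16]
        V_ein = xpe * x[10] + xte * x[4]
        V_sin = lpe * x[10] + lte * x[4] - lfi * x[16]
        V_fin = fpe * x[10] + fte * x[4] - fli * x[14]
        inp[0] = u_r[k]
        inp[1] = u_c[k]
        inp[2] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_tcr)))
        inp[3] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_in)))
        inp[4] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_trn)))
        inp[5] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_py)))
        inp[6] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_ein)))
        inp[7] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_sin)))
        inp[8] = 2.0 * ee0 / (1.0 + np.exp(vv * (ss0 - V_fin)))
        bad = False
        for j in range(9):
            x1 = x[2 * j]
            x2 = x[2 * j + 1]
            nx1 = x1 + dt * x2
            nx2 = x2 + dt * (H[j] / tau[j] * inp[j]
                             - 2.0 / tau[j] * x2 - x1 / tau[j] ** 2)
            x[2 * j] = nx1
            x[2 * j + 1] = nx2
            if not (-guard < nx1 < guard):
                bad = True
        v_out[k + 1] = tre * x[0] + tpe * x[10] - tii * x[6] - tni * x[8]
        if record_states:
            for j in range(18):
                states_out[k + 1, j] = x[j]
        if bad:
            return k
    return -1
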