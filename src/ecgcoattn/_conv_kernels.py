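"""Numba kernels for same-padded stride-1 2-D convolution (channels-first).

The inner loops run along the time axis with unit stride, so the compiler
vectorizes the row updates; weight taps and the current output row stay in
registers/L1.  All kernels are single-threaded and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["conv_forward", "conv_grad_weight"]


@njit(fastmath=True, cache=False)
def conv_forward(ap, w, b, y):
    """y[n,o,h,t] = b[o] + sum_{c,i,j} ap[n,c,h+i,t+j] * w[o,c,i,j].

    ``ap`` is the already-padded input (N, C, H+kh-1, W+kw-1).
    """
    n_batch, co, h_out, w_out = y.shape
    _, c_in, kh, kw = w.shape
    for n in range(n_batch):
        for o in range(co):
            for h in range(h_out):
                yrow = y[n, o, h]
                yrow[:] = b[o]
                for c in range(c_in):
                    for i in range(kh):
                        xrow = ap[n, c, h + i]
                        for j in range(kw):
                            k = w[o, c, i, j]
                            for t in range(w_out):
                                yrow[t] += k * xrow[t + j]


@njit(fastmath=True, cache=False)
def conv_grad_weight(ap, dy, dw):
    """dw[o,c,i,j] += sum_{n,h,t} ap[n,c,h+i,t+j] * dy[n,o,h,t]."""
    n_batch, co, h_out, w_out = dy.shape
    _, c_in, kh, kw = dw.shape
    for n in range(n_batch):
        for o in range(co):
            for h in range(h_out):
                dyrow = dy[n, o, h]
                for c in range(c_in):
                    for i in range(kh):
                        xrow = ap[n, c, h + i]
                        for j in range(kw):
                            acc = np.float32(0.0)
                            for t in range(w_out):
                                acc += dyrow[t] * xrow[t + j]
                            dw[o, c, i, j] += acc
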