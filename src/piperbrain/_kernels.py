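"""Numba kernel for the transit -> brain linear cascade.

State: transit concentration T, brain concentration B, running integral
I = int B dt.  Dynamics between grid nodes, with forcing u(t) interpolated
linearly within each step:

    T' = u(t) - a T
    B' = a T - b B
    I' = B

The per-step update below is the exact solution for linear-in-t forcing, so
accuracy is limited only by how well the grid resolves curvature of u.
"""

import numpy as np
from numba import njit

__all__ = ["lag_cascade"]


@njit(cache=True)
def lag_cascade(t, u, a, b, T0, B0, I0):
    n = t.size
    T = np.empty(n)
    B = np.empty(n)
    I = np.empty(n)
    T[0] = T0
    B[0] = B0
    I[0] = I0
    bma = b - a
    for k in range(n - 1):
        h = t[k + 1] - t[k]
        if h <= 0.0:
            T[k + 1] = T[k]
            B[k + 1] = B[k]
            I[k + 1] = I[k]
            continue
        u0 = u[k]
        c = (u[k + 1] - u0) / h
        Ea = np.exp(-a * h)
        Eb = np.exp(-b * h)
        alpha = T[k] - u0 / a + c / (a * a)
        beta = u0 / a - c / (a * a)
        gamma = c / a
        T[k + 1] = alpha * Ea + beta + gamma * h
        B[k + 1] = B[k] * Eb + a * (
            alpha * (Ea - Eb) / bma
            + beta * (1.0 - Eb) / b
            + gamma * (h / b - (1.0 - Eb) / (b * b))
        )
        I[k + 1] = (
            I[k]
            + B[k] * (1.0 - Eb) / b
            + a
            * (
                alpha * ((1.0 - Ea) / a - (1.0 - Eb) / b) / bma
                + beta * (h - (1.0 - Eb) / b) / b
                + gamma
                * (h * h / (2.0 * b) - h / (b * b) + (1.0 - Eb) / (b * b * b))
            )
        )
    return T, B, I
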