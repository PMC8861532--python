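"""Numba-accelerated asymmetric-least-squares baseline.

Same algorithm as :func:`spermraman.preprocess.als_baseline` (which is the
scipy-banded reference implementation), specialized to the ALS system:
``(W + lam * D2^T D2) z = W y`` with only the main diagonal changing
between reweighting iterations.  The symmetric pentadiagonal system is
solved by an LDL^T factorization, batched over the scans of one cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _penta_solve(a0, a1, a2, b):
    """Solve A z = b for symmetric pentadiagonal A via LDL^T.

    ``a0`` is the main diagonal (n), ``a1`` the first off-diagonal (n-1),
    ``a2`` the second (n-2).  A must be positive definite (true for the
    ALS normal equations).
    """
    n = a0.size
    d = np.empty(n)
    l1 = np.empty(n)  # L[i, i-1], l1[0] unused
    l2 = np.empty(n)  # L[i, i-2], l2[0:2] unused
    d[0] = a0[0]
    l1[1] = a1[0] / d[0]
    d[1] = a0[1] - l1[1] * l1[1] * d[0]
    for i in range(2, n):
        l2[i] = a2[i - 2] / d[i - 2]
        l1[i] = (a1[i - 1] - l2[i] * l1[i - 1] * d[i - 2]) / d[i - 1]
        d[i] = a0[i] - l1[i] * l1[i] * d[i - 1] - l2[i] * l2[i] * d[i - 2]
    u = np.empty(n)
    u[0] = b[0]
    u[1] = b[1] - l1[1] * u[0]
    for i in range(2, n):
        u[i] = b[i] - l1[i] * u[i - 1] - l2[i] * u[i - 2]
    z = np.empty(n)
    z[n - 1] = u[n - 1] / d[n - 1]
    z[n - 2] = u[n - 2] / d[n - 2] - l1[n - 1] * z[n - 1]
    for i in range(n - 3, -1, -1):
        z[i] = u[i] / d[i] - l1[i + 1] * z[i + 1] - l2[i + 2] * z[i + 2]
    return z


@njit(cache=True)
def als_batch(Y, lam, p, n_iter):
    """ALS baselines for each row of the scans x channels array `Y`."""
    m, n = Y.shape
    Z = np.empty_like(Y)
    # lam * D2^T D2 bands
    diag = np.full(n, 6.0 * lam)
    diag[0] = diag[n - 1] = lam
    diag[1] = diag[n - 2] = 5.0 * lam
    off1 = np.full(n - 1, -4.0 * lam)
    off1[0] = off1[n - 2] = -2.0 * lam
    off2 = np.full(n - 2, lam)
    for s in range(m):
        y = Y[s]
        w = np.ones(n)
        z = y.copy()
        for _ in range(n_iter):
            z = _penta_solve(diag + w, off1, off2, w * y)
            changed = False
            for i in range(n):
                wi = p if y[i] > z[i] else 1.0 - p
                if wi != w[i]:
                    w[i] = wi
                    changed = True
            if not changed:
                break
        Z[s] = z
    return Z
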