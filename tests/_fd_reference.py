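"""Brute-force finite-difference reference for the radial pressure problem.

Independent of the closed-form solver: discretizes
P'' + (nu/r) P' = beta^2(r) (P - P_SS(r)) region by region with central
second-order differences, places grid nodes exactly on the interfaces and
enforces continuity of the one-sided (second-order) derivatives there,
uses symmetry at r = 0 and a one-sided Neumann condition at the outer
radius, and sharpens the result by Richardson extrapolation of two
nested grids.
"""

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla


def _fd_once(radii, beta2s, psss, nu, m0):
    """One solve with ~m0 intervals in the narrowest region."""
    lengths = np.diff(radii)
    ms = np.maximum(4, np.round(m0 * lengths / lengths.min()).astype(int))
    hs = lengths / ms
    # grid with interface nodes exactly present
    r_parts = [np.linspace(radii[k], radii[k + 1], ms[k] + 1)
               for k in range(len(lengths))]
    r = np.concatenate([r_parts[0]] + [p[1:] for p in r_parts[1:]])
    n = r.size
    iface = np.cumsum(ms)[:-1]          # interface node indices

    A = sparse.lil_matrix((n, n))
    rhs = np.zeros(n)
    bounds = np.concatenate([[0], np.cumsum(ms)])
    for k in range(len(lengths)):
        b2, ps, h = beta2s[k], psss[k], hs[k]
        lo, hi = bounds[k], bounds[k + 1]
        for i in range(lo + 1, hi):
            if i in iface:
                continue
            A[i, i - 1] = 1.0 / h**2 - nu / (2.0 * r[i] * h)
            A[i, i] = -2.0 / h**2 - b2
            A[i, i + 1] = 1.0 / h**2 + nu / (2.0 * r[i] * h)
            rhs[i] = -b2 * ps
    # r = 0 symmetry
    b2, ps, h = beta2s[0], psss[0], hs[0]
    A[0, 0] = -2.0 * (1.0 + nu) / h**2 - b2
    A[0, 1] = 2.0 * (1.0 + nu) / h**2
    rhs[0] = -b2 * ps
    # interfaces: one-sided second-order derivative continuity
    for k, i in enumerate(iface):
        hL, hR = hs[k], hs[k + 1]
        A[i, i - 2] = 1.0 / (2.0 * hL)
        A[i, i - 1] = -4.0 / (2.0 * hL)
        A[i, i] = 3.0 / (2.0 * hL) + 3.0 / (2.0 * hR)
        A[i, i + 1] = -4.0 / (2.0 * hR)
        A[i, i + 2] = 1.0 / (2.0 * hR)
        rhs[i] = 0.0
    # outer Neumann, one-sided second order
    h = hs[-1]
    A[n - 1, n - 3] = 1.0 / (2.0 * h)
    A[n - 1, n - 2] = -4.0 / (2.0 * h)
    A[n - 1, n - 1] = 3.0 / (2.0 * h)
    rhs[n - 1] = 0.0
    return r, spla.spsolve(A.tocsc(), rhs)


def solve_radial_fd(geom, coeffs, nu=2, m0=500, richardson=True):
    """Return (r, P); Richardson-extrapolated from grids m0 and 2*m0."""
    radii = np.array([0.0, geom.Rnt, geom.Rvt, geom.Rht])
    beta2s = [c.beta2 for c in coeffs]
    psss = [c.PSS for c in coeffs]
    r, Pc = _fd_once(radii, beta2s, psss, nu, m0)
    if not richardson:
        return r, Pc
    rf, Pf = _fd_once(radii, beta2s, psss, nu, 2 * m0)
    return r, (4.0 * Pf[::2] - Pc) / 3.0
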