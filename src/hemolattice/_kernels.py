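"""Hot loops of the lattice-Boltzmann update (numba).

One simulation step is: MRT collision on every node, streaming on all
non-outlet fluid nodes with interpolated bounce-back closing the links cut
by the vessel surface, then wholesale replacement of the outflow-node
distributions by non-equilibrium extrapolation.  Collision is applied as
``f' = A f + B f_eq`` with constant 19x19 matrices ``A = I - M^-1 S M`` and
``B = M^-1 S M`` so the same code path serves MRT and (uniform-S) BGK.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def collide(f, fc, A, B, cx, cy, cz, w, n_monitor):
    """MRT collision on all nodes; returns (max |u|^2, min rho).

    Applied as ``fc = f + B (f_eq - f)`` with ``B = M^-1 S M`` (equivalent
    to ``A f + B f_eq`` since ``A = I - B``, at half the flops).  The
    stability monitor (max velocity, min density) covers the first
    ``n_monitor`` nodes — the actively evolved set; outflow rows are
    boundary-condition copies.
    """
    n, q = f.shape
    d = np.empty(q)
    umax2 = 0.0
    rhomin = 1e30
    for node in range(n):
        rho = 0.0
        jx = 0.0
        jy = 0.0
        jz = 0.0
        for i in range(q):
            fi = f[node, i]
            rho += fi
            jx += cx[i] * fi
            jy += cy[i] * fi
            jz += cz[i] * fi
        if rho < rhomin and node < n_monitor:
            rhomin = rho
        inv = 1.0 / rho
        ux = jx * inv
        uy = jy * inv
        uz = jz * inv
        usq = ux * ux + uy * uy + uz * uz
        if usq > umax2 and node < n_monitor:
            umax2 = usq
        for i in range(q):
            cu = cx[i] * ux + cy[i] * uy + cz[i] * uz
            feq = w[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
            d[i] = feq - f[node, i]
        for i in range(q):
            acc = f[node, i]
            for j in range(q):
                acc += B[i, j] * d[j]
            fc[node, i] = acc
    return umax2, rhomin


@njit(cache=True, fastmath=True)
def stream(fc, fnew, srcidx, opp, qlink, ibb_coef, ibb_inlet, uw_mag, n_active):
    """Streaming with interpolated (Bouzidi) bounce-back on cut links.

    ``srcidx[n, i]`` is the fluid index of the node at ``x - c_i`` or -1 if
    that node is solid.  A -1 source means direction ``i`` is the reflection
    of the cut link ``j = opp[i]`` with wall fraction ``qlink[n, j]``; the
    moving-wall momentum term uses the precomputed geometric coefficient
    ``ibb_coef[n, j] = (2 w_j rho0 / cs^2) (c_i . n_inlet)`` scaled by the
    instantaneous inlet speed ``uw_mag[ibb_inlet[n, j]]`` (zero on walls).
    Returns the number of thin-geometry fallbacks to the q=1/2 form.
    """
    q = fc.shape[1]
    fallbacks = 0
    inlet_mass = 0.0
    for node in range(n_active):
        fnew[node, 0] = fc[node, 0]
        for i in range(1, q):
            src = srcidx[node, i]
            if src >= 0:
                fnew[node, i] = fc[src, i]
            else:
                j = opp[i]
                qv = qlink[node, j]
                mw = ibb_coef[node, j]
                is_inlet = mw != 0.0
                if is_inlet:
                    mw *= uw_mag[ibb_inlet[node, j]]
                if qv < 0.5:
                    up = srcidx[node, j]  # node at x + c_i
                    if up >= 0:
                        fnew[node, i] = (
                            2.0 * qv * fc[node, j]
                            + (1.0 - 2.0 * qv) * fc[up, j]
                            + mw
                        )
                    else:
                        # one-node-thick region: fall back to q = 1/2 form
                        fnew[node, i] = fc[node, j] + mw
                        fallbacks += 1
                else:
                    inv2q = 0.5 / qv
                    fnew[node, i] = (
                        inv2q * fc[node, j]
                        + (2.0 * qv - 1.0) * inv2q * fc[node, i]
                        + mw * inv2q
                    )
                if is_inlet:
                    # net mass entering through this inlet link this step
                    inlet_mass += fnew[node, i] - fc[node, j]
    return fallbacks, inlet_mass


@njit(cache=True, fastmath=True)
def outlet_update(f, out_nodes, out_nbr, rho_target, A, cx, cy, cz, w):
    """Non-equilibrium extrapolation at outflow nodes.

    ``f_i(x) = f_i^eq(rho_target, u_nb) + [(I - Omega) f^neq](x_nb)`` where
    ``x_nb`` is the interior neighbour along the surface normal and
    ``A = I - Omega``.
    """
    q = f.shape[1]
    feq = np.empty(q)
    neq = np.empty(q)
    for k in range(out_nodes.shape[0]):
        o = out_nodes[k]
        nb = out_nbr[k]
        rho = 0.0
        jx = 0.0
        jy = 0.0
        jz = 0.0
        for i in range(q):
            fi = f[nb, i]
            rho += fi
            jx += cx[i] * fi
            jy += cy[i] * fi
            jz += cz[i] * fi
        inv = 1.0 / rho
        ux = jx * inv
        uy = jy * inv
        uz = jz * inv
        usq = ux * ux + uy * uy + uz * uz
        for i in range(q):
            cu = cx[i] * ux + cy[i] * uy + cz[i] * uz
            poly = 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
            neq[i] = f[nb, i] - w[i] * rho * poly
            feq[i] = w[i] * rho_target * poly
        for i in range(q):
            acc = feq[i]
            for j in range(q):
                acc += A[i, j] * neq[j]
            f[o, i] = acc
    return 0


@njit(cache=True)
def moments(f, cx, cy, cz):
    """Per-node density and velocity (lattice units)."""
    n, q = f.shape
    rho = np.empty(n)
    u = np.empty((n, 3))
    for node in range(n):
        r = 0.0
        jx = 0.0
        jy = 0.0
        jz = 0.0
        for i in range(q):
            fi = f[node, i]
            r += fi
            jx += cx[i] * fi
            jy += cy[i] * fi
            jz += cz[i] * fi
        rho[node] = r
        u[node, 0] = jx / r
        u[node, 1] = jy / r
        u[node, 2] = jz / r
    return rho, u
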