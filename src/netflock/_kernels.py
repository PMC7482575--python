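"""Numba inner loops for the two time-steppers.

Both kernels advance the state in place over a chunk of steps and record
the polarization after every step. Noise is pre-generated by the caller's
``numpy.random.Generator`` (one uniform draw per agent per step), so runs
are reproducible and chunking does not change the draw order.

The VN kernel works entirely in heading unit vectors: the new heading is
the (normalised) neighbourhood vector sum rotated by the noise angle, so
no transcendental function is evaluated inside the loop — the per-step
noise rotations ``(cos(eta*xi), sin(eta*xi))`` arrive precomputed.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(theta):
    """Wrap an angle to (-pi, pi]; fast path for small excursions."""
    while theta > np.pi:
        theta -= TWO_PI
    while theta <= -np.pi:
        theta += TWO_PI
    return theta


@njit(cache=True)
def vn_chunk(c, s, indptr, indices, noise, psi_out, out_offset):
    """Synchronous Vicsek-Network updates over ``noise.shape[0]`` steps.

    ``c``/``s`` hold the per-agent heading unit vectors (updated in place);
    ``noise`` carries the per-step noise angles ``eta * xi``. Each agent's
    new heading is the angle of the vector sum of its own and its
    neighbours' unit vectors plus the noise angle; a vector sum of exactly
    zero keeps the previous heading (before noise).
    """
    n = c.shape[0]
    steps = noise.shape[0]
    new_c = np.empty(n)
    new_s = np.empty(n)
    for t in range(steps):
        for i in range(n):
            sx = c[i]
            sy = s[i]
            for q in range(indptr[i], indptr[i + 1]):
                j = indices[q]
                sx += c[j]
                sy += s[j]
            r = np.sqrt(sx * sx + sy * sy)
            if r == 0.0:
                sx = c[i]
                sy = s[i]
                r = 1.0
            delta = noise[t, i]
            cn = np.cos(delta)
            sn = np.sin(delta)
            new_c[i] = (sx * cn - sy * sn) / r
            new_s[i] = (sx * sn + sy * cn) / r
        px = 0.0
        py = 0.0
        for i in range(n):
            c[i] = new_c[i]
            s[i] = new_s[i]
            px += c[i]
            py += s[i]
        psi_out[out_offset + t] = np.sqrt(px * px + py * py) / n


@njit(cache=True)
def ae_chunk(
    x, y, theta, ei, ej, rest,
    v0, alpha, beta, kappa, dt,
    noise, psi_out, out_offset,
):
    """Forward-Euler active-elastic updates over ``noise.shape[0]`` steps.

    Spring forces are linear in the bond extension; the projection on the
    heading modulates speed, the projection on the left-normal torques the
    heading. ``noise`` arrives pre-scaled to the per-step heading kick
    ``dt * eta * xi`` (plain Euler). A coincident linked pair contributes
    zero force. Returns the index of the first step producing a non-finite
    state, or -1 if the chunk completed.
    """
    n = x.shape[0]
    ne = ei.shape[0]
    steps = noise.shape[0]
    fx = np.empty(n)
    fy = np.empty(n)
    c = np.empty(n)
    s = np.empty(n)
    for i in range(n):
        c[i] = np.cos(theta[i])
        s[i] = np.sin(theta[i])
    for t in range(steps):
        for i in range(n):
            fx[i] = 0.0
            fy[i] = 0.0
        for e in range(ne):
            i = ei[e]
            j = ej[e]
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            d = np.sqrt(dx * dx + dy * dy)
            if d > 0.0:
                f = kappa * (d - rest[e]) / d
                fx[i] += f * dx
                fy[i] += f * dy
                fx[j] -= f * dx
                fy[j] -= f * dy
        ok = True
        px = 0.0
        py = 0.0
        for i in range(n):
            ci = c[i]
            si = s[i]
            fn = fx[i] * ci + fy[i] * si          # along heading
            fp = -fx[i] * si + fy[i] * ci         # along left normal (+90 deg)
            x[i] += dt * (v0 + alpha * fn) * ci
            y[i] += dt * (v0 + alpha * fn) * si
            theta[i] = _wrap(theta[i] + dt * beta * fp + noise[t, i])
            if not (np.isfinite(x[i]) and np.isfinite(y[i]) and np.isfinite(theta[i])):
                ok = False
            c[i] = np.cos(theta[i])
            s[i] = np.sin(theta[i])
            px += c[i]
            py += s[i]
        if not ok:
            return t
        psi_out[out_offset + t] = np.sqrt(px * px + py * py) / n
    return -1
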