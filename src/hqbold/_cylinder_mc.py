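"""Random-cylinder Monte Carlo spin-dephasing kernels.

Protons perform a Gaussian random walk around randomly oriented infinite
cylinders (blood vessels) and accumulate precession phase from the
extravascular dipole field of each cylinder (and the uniform internal offset
when inside one).  Each proton owns an independent vessel environment:
cylinders are laid down with uniform spatial density inside a sphere of
radius ``rs_factor * radius`` centred on the proton's start position, until
the target intravascular volume fraction is reached.  This samples the field
distribution of a dilute random vessel suspension without periodic-boundary
artefacts.

Phases are accumulated *per unit susceptibility difference*: the cylinder
field is strictly linear in the susceptibility shift, so a single simulated
trajectory set can be rescaled exactly to any hematocrit/saturation.  The
susceptibility convention is the cgs one in which the extravascular offset is
``2 pi gamma dchi B0 (R/rho)^2 sin^2(theta) cos(2 phi)`` and the matching
static-dephasing rate is ``R2' = vf * gamma (4/3) pi dchi B0``.

Distances are micrometres, times milliseconds, angular rates rad/s.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["make_environments", "walk_phases", "attenuation_from_phases"]


def make_environments(
    n_env: int,
    radius: float,
    vf_ref: float,
    rs_factor: float,
    gamma: float,
    b0: float,
    rng: np.random.Generator,
):
    """Generate per-proton cylinder environments.

    Returns arrays ``(points, e1, e2, c_ext, w_in, n_cyl)`` where ``points``
    is a point on each cylinder axis, ``e1``/``e2`` span the plane
    perpendicular to the axis (``e1`` along the projection of B0), ``c_ext``
    is the extravascular field prefactor ``2 pi gamma B0 sin^2(theta) R^2``
    per unit susceptibility and ``w_in`` the uniform internal offset.
    """
    r_s = rs_factor * radius
    v_sphere = 4.0 / 3.0 * np.pi * r_s**3
    target = vf_ref * v_sphere

    # Draw a generous fixed pool of candidate cylinders per environment and
    # keep a prefix whose summed in-sphere volume reaches the target.
    n_expect = vf_ref * rs_factor**2
    n_max = int(np.ceil(3.0 * n_expect + 25))

    u = rng.standard_normal((n_env, n_max, 3))
    u /= np.linalg.norm(u, axis=2, keepdims=True)

    # Perpendicular offset of the axis from the sphere centre: uniform
    # density of axes in space corresponds to b ~ sqrt(U) on [0, r_s].
    b = r_s * np.sqrt(rng.random((n_env, n_max)))
    w = rng.standard_normal((n_env, n_max, 3))
    w -= np.sum(w * u, axis=2, keepdims=True) * u
    wn = np.linalg.norm(w, axis=2, keepdims=True)
    # Degenerate draws (w parallel to u) are vanishingly rare; regularize.
    w /= np.where(wn < 1e-12, 1.0, wn)
    points = b[..., None] * w

    chord = 2.0 * np.sqrt(np.maximum(r_s**2 - b**2, 0.0))
    vol = np.pi * radius**2 * chord
    cumvol = np.cumsum(vol, axis=1)
    n_cyl = np.minimum(
        np.array([np.searchsorted(cumvol[i], target) for i in range(n_env)]) + 1,
        n_max,
    ).astype(np.int64)

    cos_t = u[..., 2]
    sin2_t = 1.0 - cos_t**2
    zhat = np.zeros_like(u)
    zhat[..., 2] = 1.0
    e1 = zhat - cos_t[..., None] * u
    e1n = np.linalg.norm(e1, axis=2, keepdims=True)
    # Axis parallel to B0: field vanishes (sin^2 theta = 0); any frame works.
    fallback = np.cross(u, np.array([1.0, 0.0, 0.0]))
    fbn = np.linalg.norm(fallback, axis=2, keepdims=True)
    fallback /= np.where(fbn < 1e-12, 1.0, fbn)
    e1 = np.where(e1n < 1e-9, fallback, e1 / np.where(e1n < 1e-12, 1.0, e1n))
    e2 = np.cross(u, e1)

    c_ext = 2.0 * np.pi * gamma * b0 * sin2_t * radius**2
    w_in = 2.0 * np.pi * gamma * b0 * (cos_t**2 - 1.0 / 3.0)
    return (
        np.ascontiguousarray(points),
        np.ascontiguousarray(e1),
        np.ascontiguousarray(e2),
        np.ascontiguousarray(c_ext),
        np.ascontiguousarray(w_in),
        n_cyl,
    )


@njit(cache=True)
def walk_phases(
    seed, n_steps, dt_ms, sigma, r2, points, e1, e2, c_ext, w_in, n_cyl, ckpt_steps
):
    """Random-walk all protons; return cumulative phases at checkpoints.

    ``sigma`` is the per-axis step standard deviation ``sqrt(2 D dt)``.
    ``ckpt_steps`` are ascending 1-based step counts at which the cumulative
    phase (per unit susceptibility) is recorded.  Also returns a boolean
    flag per proton marking an intravascular start position.
    """
    np.random.seed(seed)
    n_protons = points.shape[0]
    n_ck = ckpt_steps.shape[0]
    phases = np.zeros((n_protons, n_ck))
    inside0 = np.zeros(n_protons, np.bool_)
    for i in range(n_protons):
        nc = n_cyl[i]
        x = 0.0
        y = 0.0
        z = 0.0
        for k in range(nc):
            dx = x - points[i, k, 0]
            dy = y - points[i, k, 1]
            dz = z - points[i, k, 2]
            a = dx * e1[i, k, 0] + dy * e1[i, k, 1] + dz * e1[i, k, 2]
            b = dx * e2[i, k, 0] + dy * e2[i, k, 1] + dz * e2[i, k, 2]
            if a * a + b * b < r2:
                inside0[i] = True
                break
        phase = 0.0
        ck = 0
        for s in range(n_steps):
            w = 0.0
            for k in range(nc):
                dx = x - points[i, k, 0]
                dy = y - points[i, k, 1]
                dz = z - points[i, k, 2]
                a = dx * e1[i, k, 0] + dy * e1[i, k, 1] + dz * e1[i, k, 2]
                b = dx * e2[i, k, 0] + dy * e2[i, k, 1] + dz * e2[i, k, 2]
                rho2 = a * a + b * b
                if rho2 < r2:
                    w += w_in[i, k]
                else:
                    w += c_ext[i, k] * (a * a - b * b) / (rho2 * rho2)
            phase += w * dt_ms * 1e-3
            x += sigma * np.random.normal()
            y += sigma * np.random.normal()
            z += sigma * np.random.normal()
            while ck < n_ck and s + 1 == ckpt_steps[ck]:
                phases[i, ck] = phase
                ck += 1
    return phases, inside0


@njit(cache=True)
def attenuation_from_phases(phases, scale):
    """Magnitude attenuation ``|<exp(i * scale * phi)>|`` per grid column.

    ``phases`` has shape (n_grid, n_protons) with extravascular protons only.
    """
    m, n = phases.shape
    out = np.empty(m)
    for j in range(m):
        cr = 0.0
        ci = 0.0
        for i in range(n):
            ph = scale * phases[j, i]
            cr += np.cos(ph)
            ci += np.sin(ph)
        out[j] = np.sqrt(cr * cr + ci * ci) / n
    return out
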