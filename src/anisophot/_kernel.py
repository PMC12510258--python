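"""Compiled photon-transport kernel.

Single-threaded numba kernel implementing tensor-scattering photon random
walks in a layered slab (z >= 0 into the medium).  Each photon carries its
own counter-based RNG stream keyed by (seed, photon index), so results do
not depend on launch order.

Direction-dependent scattering rate (tensor frame components s):
  model 0 ("norm"):      mu_s(s) = sqrt((mu_x s_x)^2 + (mu_y s_y)^2 + (mu_z s_z)^2)
  model 1 ("quadratic"): mu_s(s) = mu_x s_x^2 + mu_y s_y^2 + mu_z s_z^2
Both reduce to the principal component along each axis.

Absorption is applied continuously along the path (microscopic
Beer-Lambert with the local layer's mu_a); scattering trajectories are
never altered by absorption, which makes the spatial profile shape of a
mu_a = 0 run exactly reusable by exponential reweighting.
"""

import math

import numpy as np
from numba import njit

U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# accounting slots
ACC_ESCAPED_GRID = 0
ACC_ESCAPED_OUT = 1
ACC_ABSORBED = 2
ACC_TRANSMITTED = 3
ACC_TERMINATED = 4
ACC_ROULETTE_GAIN = 5
ACC_N = 6


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _rng_next(state):
    state = state + U64(0x9E3779B97F4A7C15)
    return state, _mix64(state)


@njit(cache=True, inline="always")
def _uniform(state):
    state, z = _rng_next(state)
    return state, float(z >> U64(11)) * _INV53


@njit(cache=True, inline="always")
def _tensor_rate(ux, uy, uz, rot, mu, model):
    # rotate lab direction into the tensor frame
    sx = rot[0, 0] * ux + rot[0, 1] * uy + rot[0, 2] * uz
    sy = rot[1, 0] * ux + rot[1, 1] * uy + rot[1, 2] * uz
    sz = rot[2, 0] * ux + rot[2, 1] * uy + rot[2, 2] * uz
    if model == 0:
        ax = mu[0] * sx
        ay = mu[1] * sy
        az = mu[2] * sz
        return math.sqrt(ax * ax + ay * ay + az * az)
    return mu[0] * sx * sx + mu[1] * sy * sy + mu[2] * sz * sz


@njit(cache=True, inline="always")
def _hg_cost(g, u):
    if g < 1e-8:
        return 1.0 - 2.0 * u
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - frac * frac) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, inline="always")
def _fresnel_r(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def propagate_kernel(
    n_photons,
    seed,
    u0x, u0y, u0z,
    z_edges,          # (n_layers+1,) layer boundaries, z_edges[0] = 0
    mu_s,             # (n_layers, 3)
    g_l,              # (n_layers,)
    mu_a_l,           # (n_layers,)
    n_l,              # (n_layers,)
    v_l,              # (n_layers,) transport speed mm/ps
    rot,              # (n_layers, 3, 3) lab -> tensor frame
    tensor_model,     # 0 norm, 1 quadratic
    ambient_n,
    x0, y0, pitch, nx, ny,
    t_edges,          # (nt+1,)
    intensity,        # (nx, ny, nt) output, pre-zeroed
    accounting,       # (ACC_N,) output, pre-zeroed
    w_min, roulette_factor,
):
    n_layers = mu_s.shape[0]
    nt = t_edges.shape[0] - 1
    t_max = t_edges[nt]
    v_fast = v_l[0]
    for il in range(n_layers):
        if v_l[il] > v_fast:
            v_fast = v_l[il]

    for ip in range(n_photons):
        state = _mix64(U64(seed) * U64(0x9E3779B97F4A7C15) ^ (U64(ip) + U64(0x5851F42D4C957F2D)))
        x = 0.0
        y = 0.0
        z = 1e-12
        ux = u0x
        uy = u0y
        uz = u0z
        w = 1.0
        t = 0.0
        layer = 0
        alive = True

        state, u = _uniform(state)
        tau = -math.log(u + 1e-300)

        while alive:
            rate = _tensor_rate(ux, uy, uz, rot[layer], mu_s[layer], tensor_model)
            step = tau / rate
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                d_b = (z_edges[layer + 1] - z) / uz
            elif uz < 0.0:
                d_b = (z_edges[layer] - z) / uz
            else:
                d_b = 1e30
            if d_b < 0.0:
                d_b = 0.0

            if step < d_b:
                # full flight inside the layer, then scatter
                x += ux * step
                y += uy * step
                z += uz * step
                t += step / v_l[layer]
                if mu_a_l[layer] > 0.0:
                    dw = w * (1.0 - math.exp(-mu_a_l[layer] * step))
                    w -= dw
                    accounting[ACC_ABSORBED] += dw
                if t > t_max or t + z / v_fast > t_max:
                    accounting[ACC_TERMINATED] += w
                    alive = False
                    break
                # Henyey-Greenstein deflection about the current direction
                state, u = _uniform(state)
                cost = _hg_cost(g_l[layer], u)
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                state, u = _uniform(state)
                phi = 2.0 * math.pi * u
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if abs(uz) > 0.99999:
                    nux = sint * cosp
                    nuy = sint * sinp
                    nuz = cost if uz > 0.0 else -cost
                else:
                    denom = math.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                    nuz = -sint * cosp * denom + uz * cost
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
                state, u = _uniform(state)
                tau = -math.log(u + 1e-300)
                # Russian roulette on low-weight photons
                if w < w_min:
                    state, u = _uniform(state)
                    if u < 1.0 / roulette_factor:
                        accounting[ACC_ROULETTE_GAIN] += w * (roulette_factor - 1.0)
                        w *= roulette_factor
                    else:
                        accounting[ACC_ROULETTE_GAIN] -= w
                        alive = False
                        break
            else:
                # truncate the flight at the boundary
                x += ux * d_b
                y += uy * d_b
                z += uz * d_b
                t += d_b / v_l[layer]
                tau -= rate * d_b
                if tau < 0.0:
                    tau = 0.0
                if mu_a_l[layer] > 0.0:
                    dw = w * (1.0 - math.exp(-mu_a_l[layer] * d_b))
                    w -= dw
                    accounting[ACC_ABSORBED] += dw
                if t > t_max:
                    accounting[ACC_TERMINATED] += w
                    alive = False
                    break
                going_up = uz < 0.0
                if going_up:
                    z = z_edges[layer]
                    n2 = ambient_n if layer == 0 else n_l[layer - 1]
                else:
                    z = z_edges[layer + 1]
                    if layer == n_layers - 1:
                        # deepest boundary; only reachable when finite, i.e.
                        # the caller asked for an absorbing bottom escape
                        accounting[ACC_TRANSMITTED] += w
                        alive = False
                        break
                    n2 = n_l[layer + 1]
                n1 = n_l[layer]
                cos_i = abs(uz)
                refl = _fresnel_r(n1, n2, cos_i)
                state, u = _uniform(state)
                if u < refl:
                    uz = -uz
                else:
                    if n1 != n2:
                        eta = n1 / n2
                        sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
                        cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                        ux *= eta
                        uy *= eta
                        uz = cos_t if uz > 0.0 else -cos_t
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                    if going_up:
                        if layer == 0:
                            # escaped through the top surface: detect
                            it = -1
                            for k in range(nt):
                                if t_edges[k] <= t < t_edges[k + 1]:
                                    it = k
                                    break
                            ix = int(math.floor((x - x0) / pitch))
                            iy = int(math.floor((y - y0) / pitch))
                            if it >= 0 and 0 <= ix < nx and 0 <= iy < ny:
                                intensity[ix, iy, it] += w
                                accounting[ACC_ESCAPED_GRID] += w
                            else:
                                accounting[ACC_ESCAPED_OUT] += w
                            alive = False
                            break
                        layer -= 1
                    else:
                        layer += 1
    return intensity, accounting
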