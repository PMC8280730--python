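"""Numba-compiled inner kernels for the bonded energy model and the BAOAB
Langevin integrator.

These reproduce exactly the arithmetic of :mod:`dummycure.mm` (same
functional forms, same guards at linear angles/dihedrals); :func:`available`
reports whether the compiled path can be used, and the MM engine falls back
to the vectorized numpy implementation otherwise (results agree to within
floating-point roundoff; trajectories are reproducible per backend).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    available = True
except ImportError:  # pragma: no cover
    available = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


_EPS = 1e-12


@njit(cache=False, fastmath=False)
def energy_grad(x, b_idx, b_k, b_0, a_idx, a_k, a_0,
                d_idx, d_k, d_n, d_delta, i_idx, i_k, i_0, grad):
    """Total bonded energy; fills ``grad`` in place.  Angles in radians."""
    n = x.shape[0]
    for i in range(n):
        grad[i, 0] = 0.0
        grad[i, 1] = 0.0
        grad[i, 2] = 0.0
    e_tot = 0.0

    for t in range(b_idx.shape[0]):
        i, j = b_idx[t, 0], b_idx[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _EPS:
            r = _EPS
        dr = r - b_0[t]
        e_tot += b_k[t] * dr * dr
        c = 2.0 * b_k[t] * dr / r
        grad[i, 0] += c * dx; grad[i, 1] += c * dy; grad[i, 2] += c * dz
        grad[j, 0] -= c * dx; grad[j, 1] -= c * dy; grad[j, 2] -= c * dz

    for t in range(a_idx.shape[0]):
        i, j, k = a_idx[t, 0], a_idx[t, 1], a_idx[t, 2]
        rijx = x[i, 0] - x[j, 0]; rijy = x[i, 1] - x[j, 1]; rijz = x[i, 2] - x[j, 2]
        rkjx = x[k, 0] - x[j, 0]; rkjy = x[k, 1] - x[j, 1]; rkjz = x[k, 2] - x[j, 2]
        nij = np.sqrt(rijx * rijx + rijy * rijy + rijz * rijz)
        nkj = np.sqrt(rkjx * rkjx + rkjy * rkjy + rkjz * rkjz)
        if nij < _EPS:
            nij = _EPS
        if nkj < _EPS:
            nkj = _EPS
        cosv = (rijx * rkjx + rijy * rkjy + rijz * rkjz) / (nij * nkj)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        theta = np.arccos(cosv)
        dth = theta - a_0[t]
        e_tot += a_k[t] * dth * dth
        sin2 = 1.0 - cosv * cosv
        if sin2 < _EPS:
            sin2 = _EPS
        sinv = np.sqrt(sin2)
        coef = 2.0 * a_k[t] * dth
        uix = rijx / nij; uiy = rijy / nij; uiz = rijz / nij
        ukx = rkjx / nkj; uky = rkjy / nkj; ukz = rkjz / nkj
        dti_x = (cosv * uix - ukx) / (nij * sinv)
        dti_y = (cosv * uiy - uky) / (nij * sinv)
        dti_z = (cosv * uiz - ukz) / (nij * sinv)
        dtk_x = (cosv * ukx - uix) / (nkj * sinv)
        dtk_y = (cosv * uky - uiy) / (nkj * sinv)
        dtk_z = (cosv * ukz - uiz) / (nkj * sinv)
        grad[i, 0] += coef * dti_x; grad[i, 1] += coef * dti_y; grad[i, 2] += coef * dti_z
        grad[k, 0] += coef * dtk_x; grad[k, 1] += coef * dtk_y; grad[k, 2] += coef * dtk_z
        grad[j, 0] -= coef * (dti_x + dtk_x)
        grad[j, 1] -= coef * (dti_y + dtk_y)
        grad[j, 2] -= coef * (dti_z + dtk_z)

    n_d = d_idx.shape[0]
    n_i = i_idx.shape[0]
    for t in range(n_d + n_i):
        if t < n_d:
            i, j, k, l = d_idx[t, 0], d_idx[t, 1], d_idx[t, 2], d_idx[t, 3]
        else:
            s = t - n_d
            i, j, k, l = i_idx[s, 0], i_idx[s, 1], i_idx[s, 2], i_idx[s, 3]
        b1x = x[j, 0] - x[i, 0]; b1y = x[j, 1] - x[i, 1]; b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]; b2y = x[k, 1] - x[j, 1]; b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]; b3y = x[l, 1] - x[k, 1]; b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if nb2 < _EPS:
            nb2 = _EPS
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        ysin = m1x * n2x + m1y * n2y + m1z * n2z
        xcos = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(ysin, xcos)
        if t < n_d:
            if d_n[t] >= 1:
                arg = d_n[t] * phi - d_delta[t]
                e_tot += d_k[t] * (1.0 + np.cos(arg))
                dEdphi = -d_k[t] * d_n[t] * np.sin(arg)
            else:
                dphi = phi - d_delta[t]
                dphi = dphi - 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
                e_tot += d_k[t] * dphi * dphi
                dEdphi = 2.0 * d_k[t] * dphi
        else:
            s = t - n_d
            dphi = phi - i_0[s]
            dphi = dphi - 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
            e_tot += i_k[s] * dphi * dphi
            dEdphi = 2.0 * i_k[s] * dphi
        sq1 = n1x * n1x + n1y * n1y + n1z * n1z
        sq2 = n2x * n2x + n2y * n2y + n2z * n2z
        if sq1 < _EPS:
            sq1 = _EPS
        if sq2 < _EPS:
            sq2 = _EPS
        c1 = nb2 / sq1
        c2 = -nb2 / sq2
        tix = c1 * n1x; tiy = c1 * n1y; tiz = c1 * n1z
        tlx = c2 * n2x; tly = c2 * n2y; tlz = c2 * n2z
        s1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        tjx = -(1.0 + s1) * tix + s2 * tlx
        tjy = -(1.0 + s1) * tiy + s2 * tly
        tjz = -(1.0 + s1) * tiz + s2 * tlz
        tkx = -(tix + tjx + tlx)
        tky = -(tiy + tjy + tly)
        tkz = -(tiz + tjz + tlz)
        grad[i, 0] += dEdphi * tix; grad[i, 1] += dEdphi * tiy; grad[i, 2] += dEdphi * tiz
        grad[j, 0] += dEdphi * tjx; grad[j, 1] += dEdphi * tjy; grad[j, 2] += dEdphi * tjz
        grad[k, 0] += dEdphi * tkx; grad[k, 1] += dEdphi * tky; grad[k, 2] += dEdphi * tkz
        grad[l, 0] += dEdphi * tlx; grad[l, 1] += dEdphi * tly; grad[l, 2] += dEdphi * tlz

    return e_tot


@njit(cache=False, fastmath=False)
def baoab_chunk(x, v, f, invm_acc, sigma, c1, c2, dt, noise,
                b_idx, b_k, b_0, a_idx, a_k, a_0,
                d_idx, d_k, d_n, d_delta, i_idx, i_k, i_0,
                save_interval, frames, energies, kinetic, frame_offset, grad):
    """Run ``noise.shape[0]`` BAOAB steps in place; save frames periodically.

    ``invm_acc`` is ACC/m per atom (kcal/mol force -> A/fs^2 acceleration),
    ``sigma`` the per-atom thermal velocity scale, ``c1``/``c2`` the OU decay
    and noise coefficients.  Returns the number of frames written.
    """
    nsteps = noise.shape[0]
    nat = x.shape[0]
    isave = frame_offset
    for step in range(nsteps):
        for i in range(nat):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        if c2 > 0.0:
            for i in range(nat):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * sigma[i] * noise[step, i, d]
        for i in range(nat):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
        e = energy_grad(x, b_idx, b_k, b_0, a_idx, a_k, a_0,
                        d_idx, d_k, d_n, d_delta, i_idx, i_k, i_0, grad)
        for i in range(nat):
            for d in range(3):
                f[i, d] = -grad[i, d] * invm_acc[i]
                v[i, d] += 0.5 * dt * f[i, d]
        if (step + 1) % save_interval == 0:
            ke2 = 0.0  # 2 * kinetic energy in amu A^2/fs^2; scaled by caller
            for i in range(nat):
                for d in range(3):
                    frames[isave, i, d] = x[i, d]
                    ke2 += v[i, d] * v[i, d] / invm_acc[i]
            energies[isave] = e
            kinetic[isave] = ke2
            isave += 1
    return isave
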