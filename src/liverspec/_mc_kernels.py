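"""Compiled photon-transport kernels.

Single-threaded weighted Monte Carlo in a homogeneous semi-infinite medium
(z >= 0) with a two-fiber probe at the surface.  Detection uses azimuthal
averaging: the trajectory distribution is rotationally symmetric about the
vertical axis through each packet's launch point, so a packet exiting the
surface inside the acceptance cone at radial displacement r from its launch
point hits the detector face for a computable arc of rotations.  Each
in-cone exit therefore contributes its weight times that arc fraction to
the detected estimators (and the complement to the escaped ledger), and its
path is deposited into the sampling map after rotation onto a uniformly
drawn detector-hitting azimuth.  This is an exact azimuthal integral, not
an approximation; it leaves all expectations and the weight ledger intact
while cutting the variance of detection-conditioned scores by the inverse
arc fraction.  Kernels are self-contained so a fixed seed reproduces runs
bit-for-bit.
"""

import numpy as np
from numba import njit

__all__ = ["fresnel_unpolarized", "hg_cosine", "propagate", "white_paths"]


@njit(cache=True)
def fresnel_unpolarized(cos_i, n1, n2):
    """Unpolarized Fresnel power reflectance for incidence cosine ``cos_i``
    going from index ``n1`` into ``n2``.  Total internal reflection -> 1."""
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def hg_cosine(g, u):
    """Henyey-Greenstein deflection cosine from a uniform variate ``u``."""
    if g > -1e-6 and g < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, ct, phi):
    """Rotate unit direction by deflection cosine ``ct`` and azimuth ``phi``."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = st * cp
        nuy = st * sp
        nuz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nuz = -st * cp * den + uz * ct
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, inline="always")
def _arc_fraction(rho, r, b):
    """Fraction of rotations (about the launch axis) for which a point at
    radial displacement ``r`` lands inside a disk of radius ``b`` whose
    center is ``rho`` away from the launch point.  Also returns the arc
    half-width (radians)."""
    if rho + r <= b:
        return 1.0, np.pi
    if r >= rho + b or rho >= r + b:
        return 0.0, 0.0
    carg = (rho * rho + r * r - b * b) / (2.0 * rho * r)
    if carg >= 1.0:
        return 0.0, 0.0
    if carg <= -1.0:
        return 1.0, np.pi
    delta = np.arccos(carg)
    return delta / np.pi, delta


@njit(cache=True)
def propagate(seed, n_photons,
              mu_a, mu_s, g, n_tissue, n_ambient,
              src_r, det_r, sep, cos_launch, cos_accept,
              track_map, nx, nz, voxel, x_min, slab_half,
              fl_nz, fl_dz, fl_radius,
              roulette_thresh, roulette_surv, max_path,
              det_cap, path_cap):
    """Run ``n_photons`` packets; return ledger, detection records and maps.

    Ledger buckets (launched-weight units, one unit per photon): specular,
    absorbed, detected, escaped, terminated (path cap) and the net Russian
    roulette bookkeeping (killed minus boosted), summing exactly to
    ``n_photons``.
    """
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    rsp = fresnel_unpolarized(1.0, n_ambient, n_tissue)

    specular = 0.0
    absorbed = 0.0
    detected = 0.0
    escaped = 0.0
    terminated = 0.0
    roulette_net = 0.0

    n_det = 0
    det_x = np.zeros(det_cap)
    det_y = np.zeros(det_cap)
    det_cos = np.zeros(det_cap)
    det_w = np.zeros(det_cap)
    det_len = np.zeros(det_cap)
    det_zmax = np.zeros(det_cap)

    svmap = np.zeros(nx * nz)
    vx = np.zeros(path_cap)
    vy = np.zeros(path_cap)
    vz = np.zeros(path_cap)
    fluence_acc = np.zeros(fl_nz)
    fl_r2 = fl_radius * fl_radius
    march = 0.5 * voxel

    for ip in range(n_photons):
        # launch: uniform over the source fiber disk, cone uniform in solid
        # angle, specular entry loss deducted analytically
        while True:
            x0 = (2.0 * np.random.random() - 1.0) * src_r
            y0 = (2.0 * np.random.random() - 1.0) * src_r
            if x0 * x0 + y0 * y0 <= src_r * src_r:
                break
        px = x0
        py = y0
        pz = 0.0
        uz = 1.0 - np.random.random() * (1.0 - cos_launch)
        st = np.sqrt(max(0.0, 1.0 - uz * uz))
        phi = 2.0 * np.pi * np.random.random()
        ux = st * np.cos(phi)
        uy = st * np.sin(phi)
        w = 1.0 - rsp
        specular += rsp
        plen = 0.0
        zmax = 0.0
        nv = 0
        if track_map:
            vx[0] = px
            vy[0] = py
            vz[0] = 0.0
            nv = 1
        alive = True

        while alive:
            s = -np.log(1.0 - 0.999999999999 * np.random.random()) / mu_t
            while s > 0.0 and alive:
                db = -pz / uz if uz < 0.0 else 1e30
                seg = db if db < s else s
                px += ux * seg
                py += uy * seg
                pz = 0.0 if db < s else pz + uz * seg
                plen += seg
                if pz > zmax:
                    zmax = pz
                if track_map and nv < path_cap:
                    vx[nv] = px
                    vy[nv] = py
                    vz[nv] = pz
                    nv += 1
                if db < s:
                    s -= seg
                    ci = -uz
                    if np.random.random() < fresnel_unpolarized(
                            ci, n_tissue, n_ambient):
                        uz = -uz  # internally reflected, continue the step
                    else:
                        alive = False
                        if ci < cos_accept:
                            escaped += w
                            continue
                        ex = px - x0
                        ey = py - y0
                        r = np.sqrt(ex * ex + ey * ey)
                        cx = sep - x0
                        cy = -y0
                        rho = np.sqrt(cx * cx + cy * cy)
                        frac, delta = _arc_fraction(rho, r, det_r)
                        if frac <= 0.0:
                            escaped += w
                            continue
                        wdet = w * frac
                        detected += wdet
                        escaped += w - wdet
                        # rotate the exit (and, for the map, the whole
                        # path) onto a uniformly drawn detector-hitting
                        # azimuth about the launch axis
                        alpha_c = np.arctan2(cy, cx)
                        alpha0 = np.arctan2(ey, ex) if r > 0.0 else alpha_c
                        alpha = alpha_c + (2.0 * np.random.random() - 1.0) \
                            * delta
                        cb = np.cos(alpha - alpha0)
                        sb = np.sin(alpha - alpha0)
                        rex = x0 + cb * ex - sb * ey
                        rey = y0 + sb * ex + cb * ey
                        if n_det < det_cap:
                            det_x[n_det] = rex
                            det_y[n_det] = rey
                            det_cos[n_det] = ci
                            det_w[n_det] = wdet
                            det_len[n_det] = plen
                            det_zmax[n_det] = zmax
                        n_det += 1
                        if track_map:
                            ax = vx[0]
                            ay = vy[0]
                            az = vz[0]
                            rax = x0 + cb * (ax - x0) - sb * (ay - y0)
                            ray = y0 + sb * (ax - x0) + cb * (ay - y0)
                            for k in range(1, nv):
                                bx2 = vx[k]
                                by2 = vy[k]
                                bz2 = vz[k]
                                rbx = x0 + cb * (bx2 - x0) - sb * (by2 - y0)
                                rby = y0 + sb * (bx2 - x0) + cb * (by2 - y0)
                                dxs = rbx - rax
                                dys = rby - ray
                                dzs = bz2 - az
                                slen = np.sqrt(dxs * dxs + dys * dys
                                               + dzs * dzs)
                                ylo = ray if ray < rby else rby
                                yhi = ray if ray > rby else rby
                                if (slen > 0.0 and ylo <= slab_half
                                        and yhi >= -slab_half):
                                    inv = 1.0 / slen
                                    t = 0.0
                                    while t <= slen:
                                        yy = ray + dys * inv * t
                                        if -slab_half <= yy <= slab_half:
                                            ix = int((rax + dxs * inv * t
                                                      - x_min) / voxel)
                                            iz = int((az + dzs * inv * t)
                                                     / voxel)
                                            if 0 <= ix < nx and 0 <= iz < nz:
                                                # track-length estimator:
                                                # weight x dwell length
                                                svmap[ix * nz + iz] += \
                                                    wdet * march
                                        t += march
                                rax = rbx
                                ray = rby
                                az = bz2
                else:
                    s = 0.0
                if plen > max_path and alive:
                    terminated += w
                    alive = False
            if not alive:
                break
            # interaction: deposit absorbed weight, scatter, roulette
            dw = w * (mu_a / mu_t)
            absorbed += dw
            if dw > 0.0 and px * px + py * py <= fl_r2:
                izf = int(pz / fl_dz)
                if izf < fl_nz:
                    fluence_acc[izf] += dw
            w -= dw
            ct = hg_cosine(g, np.random.random())
            ux, uy, uz = _rotate(ux, uy, uz, ct,
                                 2.0 * np.pi * np.random.random())
            if w < roulette_thresh:
                if np.random.random() < roulette_surv:
                    boost = w / roulette_surv - w
                    roulette_net -= boost
                    w = w / roulette_surv
                else:
                    roulette_net += w
                    alive = False

    nkeep = n_det if n_det < det_cap else det_cap
    return (specular, absorbed, detected, escaped, terminated, roulette_net,
            n_det,
            det_x[:nkeep], det_y[:nkeep], det_cos[:nkeep], det_w[:nkeep],
            det_len[:nkeep], det_zmax[:nkeep],
            svmap.reshape(nx, nz), fluence_acc)


@njit(cache=True)
def white_paths(seed, n_photons, mu_s, g, n_tissue, n_ambient,
                src_r, det_r, sep, cos_launch, cos_accept, max_path, cap):
    """Zero-absorption transport for the accelerated ("white") forward model.

    Records, for every in-cone surface exit with a nonzero detector arc
    fraction, the pair (arc fraction, path length).  The detected fraction
    at absorption ``mu_a`` then follows by Beer-Lambert reweighting:
    ``R = (1 - specular) * sum(frac * exp(-mu_a * L)) / n_photons``.
    """
    np.random.seed(seed)
    fr = np.zeros(cap)
    ll = np.zeros(cap)
    nrec = 0
    for _ in range(n_photons):
        while True:
            x0 = (2.0 * np.random.random() - 1.0) * src_r
            y0 = (2.0 * np.random.random() - 1.0) * src_r
            if x0 * x0 + y0 * y0 <= src_r * src_r:
                break
        px = x0
        py = y0
        pz = 0.0
        uz = 1.0 - np.random.random() * (1.0 - cos_launch)
        st = np.sqrt(max(0.0, 1.0 - uz * uz))
        phi = 2.0 * np.pi * np.random.random()
        ux = st * np.cos(phi)
        uy = st * np.sin(phi)
        plen = 0.0
        alive = True
        while alive:
            s = -np.log(1.0 - 0.999999999999 * np.random.random()) / mu_s
            while s > 0.0 and alive:
                db = -pz / uz if uz < 0.0 else 1e30
                seg = db if db < s else s
                px += ux * seg
                py += uy * seg
                plen += seg
                if db < s:
                    pz = 0.0
                    s -= seg
                    ci = -uz
                    if np.random.random() < fresnel_unpolarized(
                            ci, n_tissue, n_ambient):
                        uz = -uz
                    else:
                        alive = False
                        if ci >= cos_accept and nrec < cap:
                            ex = px - x0
                            ey = py - y0
                            r = np.sqrt(ex * ex + ey * ey)
                            cx = sep - x0
                            cy = -y0
                            rho = np.sqrt(cx * cx + cy * cy)
                            frac, _ = _arc_fraction(rho, r, det_r)
                            if frac > 0.0:
                                fr[nrec] = frac
                                ll[nrec] = plen
                                nrec += 1
                else:
                    pz += uz * seg
                    s = 0.0
                if plen > max_path and alive:
                    alive = False
            if not alive:
                break
            ct = hg_cosine(g, np.random.random())
            ux, uy, uz = _rotate(ux, uy, uz, ct,
                                 2.0 * np.pi * np.random.random())
    return fr[:nrec], ll[:nrec]
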