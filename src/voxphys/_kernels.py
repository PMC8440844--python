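"""Numba kernels shared by the body-cover dynamics, glottal flow and
wave-reflection tract modules.

The same scalar helpers back both the public per-operation APIs (used by the
tests) and the fused 800-ms simulation loop (used by the Monte Carlo batch
generator), so the fast path cannot drift from the audited one.

Geometry convention: the glottal half-width of cover mass *i* varies linearly
along the membranous fold, ``h_i(y) = o_i + (y/L) * xi02``, where ``o_i`` is
the anterior-end offset (prephonatory offset + dynamic displacement) and
``xi02`` the half-width increment at the vocal processes.  Both cover masses
share the slope, so the flow-limiting profile is simply the one with the
smaller offset.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NJIT = dict(cache=True, fastmath=True)


@njit(**_NJIT)
def lin_open_integral(h_a: float, h_p: float, L: float):
    """Integral of max(h, 0) along a linear half-width profile and open length.

    ``h_a``/``h_p`` are the half-widths at the anterior (y=0) and posterior
    (y=L) ends.  Returns ``(integral [m^2], open_length [m])``.
    """
    if h_a >= 0.0 and h_p >= 0.0:
        return 0.5 * (h_a + h_p) * L, L
    if h_a <= 0.0 and h_p <= 0.0:
        return 0.0, 0.0
    if h_p > 0.0:  # anterior contact, posterior open
        ell = L * h_p / (h_p - h_a)
        return 0.5 * h_p * ell, ell
    ell = L * h_a / (h_a - h_p)  # posterior contact, anterior open
    return 0.5 * h_a * ell, ell


@njit(**_NJIT)
def lin_penetration_integral(h_a: float, h_p: float, L: float):
    """Integral of max(-h, 0) along the profile and the contact length."""
    integ, open_len = lin_open_integral(-h_a, -h_p, L)
    return integ, open_len


@njit(**_NJIT)
def solve_flow_scalar(dp: float, ag: float, z_sum: float, kt: float, rho: float) -> float:
    """Physically admissible root of the glottal pressure balance.

    ``dp`` is twice the difference of the incident wave pressures,
    ``z_sum = z_sub + z_sup`` the sum of the characteristic impedances, and the
    kinetic (Bernoulli) loss is ``kt * rho * U^2 / (2 ag^2)`` with the sign of
    the transglottal drive.  Continuous in every argument; zero area gives
    zero flow.
    """
    if ag <= 0.0:
        return 0.0
    a = kt * rho / (2.0 * ag * ag)
    if dp >= 0.0:
        return (-z_sum + np.sqrt(z_sum * z_sum + 4.0 * a * dp)) / (2.0 * a)
    return -(-z_sum + np.sqrt(z_sum * z_sum - 4.0 * a * dp)) / (2.0 * a)


@njit(**_NJIT)
def tract_half_pass(f, b, nf, nb, refl, att):
    """One half-sample propagation/scattering pass over the tract interior.

    Waves cross one section (attenuation ``att``) and scatter at the junction
    at its far end with reflection coefficients ``refl[i]`` between sections
    ``i`` and ``i+1``.  End elements ``nf[0]`` and ``nb[-1]`` are left for the
    boundary handlers.
    """
    n = f.shape[0]
    for i in range(n - 1):
        fi = att * f[i]
        bi1 = att * b[i + 1]
        r = refl[i]
        nf[i + 1] = (1.0 + r) * fi - r * bi1
        nb[i] = r * fi + (1.0 - r) * bi1


@njit(**_NJIT)
def mass_accels(x, v, p_drive_l, p_drive_u, cfg, o_l, o_u, xi02):
    """Accelerations of (lower, upper, body) masses plus collision diagnostics.

    ``cfg`` is the packed parameter vector (see ``tbcm.pack_config``).
    Returns ``(a_l, a_u, a_b, F_col_l, F_col_u, ell_l, ell_u)``.
    """
    m_l, m_u, m_b = cfg[0], cfg[1], cfg[2]
    k_l, k_u, k_b, k_c = cfg[3], cfg[4], cfg[5], cfg[6]
    d_l, d_u, d_b = cfg[7], cfg[8], cfg[9]
    eta = cfg[10]
    kcol_l, kcol_u = cfg[11], cfg[12]
    dcol_l, dcol_u = cfg[13], cfg[14]
    T_l, T_u, L = cfg[15], cfg[16], cfg[17]

    x_l, x_u, x_b = x[0], x[1], x[2]
    v_l, v_u, v_b = v[0], v[1], v[2]

    # nonlinear body-referenced springs
    s_l = x_l - x_b
    s_u = x_u - x_b
    f_spring_l = k_l * s_l * (1.0 + eta * s_l * s_l) + d_l * (v_l - v_b)
    f_spring_u = k_u * s_u * (1.0 + eta * s_u * s_u) + d_u * (v_u - v_b)
    f_couple = k_c * (x_l - x_u)
    f_body = k_b * x_b * (1.0 + eta * x_b * x_b) + d_b * v_b

    # zipper collision: penetration integrals of each cover profile
    pen_l, ell_l = lin_penetration_integral(o_l, o_l + xi02, L)
    pen_u, ell_u = lin_penetration_integral(o_u, o_u + xi02, L)
    F_col_l = kcol_l * pen_l
    F_col_u = kcol_u * pen_u

    a_l = (p_drive_l * L * T_l + F_col_l - dcol_l * (ell_l / L) * v_l - f_spring_l - f_couple) / m_l
    a_u = (p_drive_u * L * T_u + F_col_u - dcol_u * (ell_u / L) * v_u - f_spring_u + f_couple) / m_u
    a_b = (f_spring_l + f_spring_u - f_body) / m_b
    return a_l, a_u, a_b, F_col_l, F_col_u, ell_l, ell_u


@njit(**_NJIT)
def simulate_core(
    cfg,            # packed mechanical config (see tbcm.pack_config)
    xi02, x_l0off, x_u0off, a_pgo,
    kt, rho, c,
    A_sub, refl_sub, A_sup, refl_sup,
    att, r_lung, pl_scale, lip_b0, lip_b1, lip_a1,
    PL, n_steps, dt, ramp_steps,
):
    """Fused sustained-phonation loop.

    Mechanical state advances at ``1/dt``; the wave-reflection tracts advance
    in two half-sample passes per step (section length = c*dt/2).  Returns
    ``(Ug, Ps, Pe, Pc, Pout, blowup_index)`` with ``blowup_index = -1`` when
    the run stayed finite.
    """
    ns = A_sub.shape[0]
    ne = A_sup.shape[0]
    z_s = rho * c / A_sub[ns - 1]
    z_e = rho * c / A_sup[0]
    T_l, T_u, L = cfg[15], cfg[16], cfg[17]

    f_sub = np.zeros(ns)
    b_sub = np.zeros(ns)
    f_sup = np.zeros(ne)
    b_sup = np.zeros(ne)
    nf_sub = np.zeros(ns)
    nb_sub = np.zeros(ns)
    nf_sup = np.zeros(ne)
    nb_sup = np.zeros(ne)

    x = np.zeros(3)
    v = np.zeros(3)

    Ug = np.zeros(n_steps)
    Ps = np.zeros(n_steps)
    Pe = np.zeros(n_steps)
    Pc = np.zeros(n_steps)
    Pout = np.zeros(n_steps)

    lip_x1 = 0.0  # radiation filter memories
    lip_y1 = 0.0
    ps_tot = 0.0
    pe_tot = 0.0

    for n in range(n_steps):
        if n < ramp_steps:
            pl_now = PL * (n + 1.0) / ramp_steps
        else:
            pl_now = PL

        # ---- mechanics at the full rate -------------------------------
        o_l = x[0] + x_l0off
        o_u = x[1] + x_u0off

        area_l2, _ = lin_open_integral(o_l, o_l + xi02, L)
        area_u2, _ = lin_open_integral(o_u, o_u + xi02, L)
        o_min = min(o_l, o_u)
        area_m2, _ = lin_open_integral(o_min, o_min + xi02, L)
        a_l_area = 2.0 * area_l2
        a_m = 2.0 * area_m2
        a_g = a_m + a_pgo

        _, open_l = lin_open_integral(o_l, o_l + xi02, L)
        _, open_u = lin_open_integral(o_u, o_u + xi02, L)
        alpha_l = open_l / L
        alpha_u = open_u / L

        if a_l_area > 1e-12:
            ratio = a_m / a_l_area
            p_l_open = ps_tot - (ps_tot - pe_tot) * ratio * ratio
        else:
            p_l_open = ps_tot
        p_drive_l = alpha_l * p_l_open + (1.0 - alpha_l) * ps_tot
        p_drive_u = alpha_u * pe_tot

        a_l, a_u, a_b, F_col_l, F_col_u, ell_l, ell_u = mass_accels(
            x, v, p_drive_l, p_drive_u, cfg, o_l, o_u, xi02
        )
        # truncated-Taylor (position) + explicit Euler (velocity) update
        x[0] += v[0] * dt + 0.5 * a_l * dt * dt
        x[1] += v[1] * dt + 0.5 * a_u * dt * dt
        x[2] += v[2] * dt + 0.5 * a_b * dt * dt
        v[0] += a_l * dt
        v[1] += a_u * dt
        v[2] += a_b * dt

        contact_area = ell_l * T_l + ell_u * T_u
        if contact_area > 0.0:
            Pc[n] = (F_col_l + F_col_u) / contact_area
        else:
            Pc[n] = 0.0

        # ---- acoustics: two half-sample passes ------------------------
        u_now = 0.0
        for half in range(2):
            fg = att * f_sub[ns - 1]   # incident at the glottis, subglottal side
            bg = att * b_sup[0]        # incident at the glottis, supraglottal side
            u_now = solve_flow_scalar(2.0 * (fg - bg), a_g, z_s + z_e, kt, rho)
            ps_tot = 2.0 * fg - z_s * u_now
            pe_tot = 2.0 * bg + z_e * u_now

            tract_half_pass(f_sub, b_sub, nf_sub, nb_sub, refl_sub, att)
            tract_half_pass(f_sup, b_sup, nf_sup, nb_sup, refl_sup, att)

            # lung end: absorbing termination driven by lung pressure
            # (pl_scale normalizes the Thevenin source so the zero-flow
            # steady subglottal pressure equals the lung pressure exactly)
            bl = att * b_sub[0]
            nf_sub[0] = r_lung * bl + (1.0 - r_lung) * 0.5 * pl_now * pl_scale
            # glottal ends
            nb_sub[ns - 1] = fg - z_s * u_now
            nf_sup[0] = bg + z_e * u_now
            # lip end: first-order inertive radiation load
            fl = att * f_sup[ne - 1]
            y = lip_b0 * fl + lip_b1 * lip_x1 - lip_a1 * lip_y1
            lip_x1 = fl
            lip_y1 = y
            nb_sup[ne - 1] = y
            Pout[n] = fl + y

            for i in range(ns):
                f_sub[i] = nf_sub[i]
                b_sub[i] = nb_sub[i]
            for i in range(ne):
                f_sup[i] = nf_sup[i]
                b_sup[i] = nb_sup[i]

        Ug[n] = u_now
        Ps[n] = ps_tot
        Pe[n] = pe_tot

        if not (np.isfinite(x[0]) and np.isfinite(ps_tot) and np.isfinite(u_now)):
            return Ug, Ps, Pe, Pc, Pout, n

    return Ug, Ps, Pe, Pc, Pout, -1
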