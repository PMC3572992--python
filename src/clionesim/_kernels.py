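"""Compiled numerical kernels: network right-hand side, adaptive embedded
Runge-Kutta integration with transmitter-pulse events, and tangent-space
propagation for Lyapunov spectra.

State vector layout for a network of N cells and E chemical synapses::

    y[8*i + 0..7] = V, mB, hB, m, h, n, mCa, [Ca]   of cell i
    y[8*N + e]    = open-channel fraction r          of chemical synapse e

The stepper is a Dormand-Prince 5(4) embedded pair with PI-free standard
step control.  Transmitter pulses and protocol switches are handled as step
boundaries: the step size is clamped so that no trial step straddles a pulse
offset or a stimulus-change time, which keeps the vector field smooth within
every step.  Pulse onsets are detected at accepted-step boundaries from the
interpolated upward crossing of the presynaptic spike threshold; because the
maximum step is capped at 0.5 ms, an onset is registered at most a fraction
of a millisecond after the true crossing.
"""

import numpy as np
from numba import njit

NV = 8  # state variables per cell

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = _A[6].copy()  # 5th-order weights (FSAL)
_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_STEP_UNDERFLOW = 2


SMOOTH_K_ON = 0.2  # per ms: rise rate of the smooth release state


@njit(cache=True, fastmath=False)
def network_rhs(
    t, y, dy,
    n_cells, g8, cm, e_na, e_k, e_b, e_ca,
    tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
    c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
    gp_a, gp_b, gp_g,
    i_ext, smooth, c_pulse,
):
    """Full network derivative.

    In pulsed mode (smooth == 0) c_t holds the current rectangular-pulse
    transmitter level per chemical synapse.  In smooth mode the state vector
    carries one extra release variable s per cell (appended after the r
    block); s relaxes quickly toward 1 while the presynaptic potential is
    above the spike threshold and decays with the pulse duration's time
    constant, so [T] = T_max * s is a smooth counterpart of the retriggered
    rectangular pulse with the same time integral per spike.
    """
    n8 = NV * n_cells
    n_syn = c_pre.shape[0]
    # coupling currents accumulated per cell (depolarizing positive)
    iacc = np.empty(n_cells)
    for i in range(n_cells):
        iacc[i] = i_ext[i]
    for e in range(n_syn):
        r = y[n8 + e]
        v_post = y[NV * c_post[e]]
        iacc[c_post[e]] -= c_g[e] * r * (v_post - c_e[e])
        if smooth != 0:
            T = c_tmax[e] * y[n8 + n_syn + c_pre[e]]
        else:
            T = c_t[e]
        dy[n8 + e] = c_alpha[e] * T * (1.0 - r) - c_beta_[e] * r
    if smooth != 0:
        for i in range(n_cells):
            V = y[NV * i]
            s = y[n8 + n_syn + i]
            gate = 1.0 / (1.0 + np.exp(-V / 3.0))
            dy[n8 + n_syn + i] = SMOOTH_K_ON * gate * (1.0 - s) - s / c_pulse[i]
    for j in range(gp_a.shape[0]):
        va = y[NV * gp_a[j]]
        vb = y[NV * gp_b[j]]
        iacc[gp_a[j]] += gp_g[j] * (vb - va)
        iacc[gp_b[j]] += gp_g[j] * (va - vb)
    for i in range(n_cells):
        o = NV * i
        V = y[o]
        mB = y[o + 1]
        hB = y[o + 2]
        m = y[o + 3]
        h = y[o + 4]
        n = y[o + 5]
        mCa = y[o + 6]
        Ca = y[o + 7]
        i_k = g8[i, 0] * (V - e_k[i])
        i_na = g8[i, 1] * (V - e_na[i])
        i_nav = g8[i, 2] * (V - e_na[i]) / (1.0 + np.exp(-0.2 * (V + 45.0)))
        i_b = g8[i, 3] * mB * hB * (V - e_b[i])
        i_nattx = g8[i, 4] * m * m * m * h * (V - e_na[i])
        i_ktea = g8[i, 5] * n * n * n * n * (V - e_k[i])
        i_ca = g8[i, 6] * mCa * mCa * (V - e_ca[i])
        i_caca = (
            g8[i, 7]
            * (V - e_ca[i])
            / (1.0 + np.exp(0.06 * (V + 45.0)))
            / (1.0 + np.exp(k_beta * (Ca - beta_ca)))
        )
        i_mem = i_k + i_na + i_nav + i_b + i_nattx + i_ktea + i_ca + i_caca
        dy[o] = (iacc[i] - i_mem) / cm[i]
        dy[o + 1] = (1.0 / (1.0 + np.exp(0.4 * (V + 34.0))) - mB) / tau[0]
        dy[o + 2] = (1.0 / (1.0 + np.exp(-0.55 * (V + 43.0))) - hB) / tau[1]
        dy[o + 3] = (1.0 / (1.0 + np.exp(-0.4 * (V + 31.0))) - m) / tau[2]
        dy[o + 4] = (1.0 / (1.0 + np.exp(0.25 * (V + 45.0))) - h) / tau[3]
        dy[o + 5] = (1.0 / (1.0 + np.exp(-0.18 * (V + 25.0))) - n) / tau[4]
        dy[o + 6] = (1.0 / (1.0 + np.exp(-0.2 * V)) - mCa) / tau[5]
        dy[o + 7] = rho * (-k_ca_flux * i_ca - k_s * Ca)


@njit(cache=True, fastmath=False)
def network_jvp(
    y, w, out,
    n_cells, g8, cm, e_na, e_k, e_b, e_ca,
    tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
    c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_pulse,
    gp_a, gp_b, gp_g,
):
    """Analytic Jacobian-vector products J(y) @ w for the smooth-release
    network field (one tangent vector per column of w)."""
    n8 = NV * n_cells
    n_syn = c_pre.shape[0]
    k = w.shape[1]
    for col in range(k):
        for i in range(n8 + n_syn + n_cells):
            out[i, col] = 0.0
    for i in range(n_cells):
        o = NV * i
        V = y[o]
        mB = y[o + 1]
        hB = y[o + 2]
        m = y[o + 3]
        h = y[o + 4]
        n = y[o + 5]
        mCa = y[o + 6]
        Ca = y[o + 7]
        phi = 1.0 / (1.0 + np.exp(-0.2 * (V + 45.0)))
        dphi = 0.2 * phi * (1.0 - phi)
        A = 1.0 / (1.0 + np.exp(0.06 * (V + 45.0)))
        dA = -0.06 * A * (1.0 - A)
        B = 1.0 / (1.0 + np.exp(k_beta * (Ca - beta_ca)))
        dB = -k_beta * B * (1.0 - B)
        # d(i_mem)/dV
        dI_dV = (
            g8[i, 0]
            + g8[i, 1]
            + g8[i, 2] * (phi + (V - e_na[i]) * dphi)
            + g8[i, 3] * mB * hB
            + g8[i, 4] * m * m * m * h
            + g8[i, 5] * n * n * n * n
            + g8[i, 6] * mCa * mCa
            + g8[i, 7] * (A + (V - e_ca[i]) * dA) * B
        )
        dI_dmB = g8[i, 3] * hB * (V - e_b[i])
        dI_dhB = g8[i, 3] * mB * (V - e_b[i])
        dI_dm = 3.0 * g8[i, 4] * m * m * h * (V - e_na[i])
        dI_dh = g8[i, 4] * m * m * m * (V - e_na[i])
        dI_dn = 4.0 * g8[i, 5] * n * n * n * (V - e_k[i])
        dI_dmCa = 2.0 * g8[i, 6] * mCa * (V - e_ca[i])
        dI_dCa = g8[i, 7] * (V - e_ca[i]) * A * dB
        # gating steady-state slopes: x_inf = 1/(1+exp(a(V-c))) -> -a x(1-x)
        xb = 1.0 / (1.0 + np.exp(0.4 * (V + 34.0)))
        dxb = -0.4 * xb * (1.0 - xb)
        xhb = 1.0 / (1.0 + np.exp(-0.55 * (V + 43.0)))
        dxhb = 0.55 * xhb * (1.0 - xhb)
        xm = 1.0 / (1.0 + np.exp(-0.4 * (V + 31.0)))
        dxm = 0.4 * xm * (1.0 - xm)
        xh = 1.0 / (1.0 + np.exp(0.25 * (V + 45.0)))
        dxh = -0.25 * xh * (1.0 - xh)
        xn = 1.0 / (1.0 + np.exp(-0.18 * (V + 25.0)))
        dxn = 0.18 * xn * (1.0 - xn)
        xc = 1.0 / (1.0 + np.exp(-0.2 * V))
        dxc = 0.2 * xc * (1.0 - xc)
        dICa_dV = g8[i, 6] * mCa * mCa
        dICa_dmCa = 2.0 * g8[i, 6] * mCa * (V - e_ca[i])
        for col in range(k):
            wv = w[o, col]
            out[o, col] += (
                -dI_dV * wv - dI_dmB * w[o + 1, col] - dI_dhB * w[o + 2, col]
                - dI_dm * w[o + 3, col] - dI_dh * w[o + 4, col]
                - dI_dn * w[o + 5, col] - dI_dmCa * w[o + 6, col]
                - dI_dCa * w[o + 7, col]
            ) / cm[i]
            out[o + 1, col] += (dxb * wv - w[o + 1, col]) / tau[0]
            out[o + 2, col] += (dxhb * wv - w[o + 2, col]) / tau[1]
            out[o + 3, col] += (dxm * wv - w[o + 3, col]) / tau[2]
            out[o + 4, col] += (dxh * wv - w[o + 4, col]) / tau[3]
            out[o + 5, col] += (dxn * wv - w[o + 5, col]) / tau[4]
            out[o + 6, col] += (dxc * wv - w[o + 6, col]) / tau[5]
            out[o + 7, col] += rho * (
                -k_ca_flux * (dICa_dV * wv + dICa_dmCa * w[o + 6, col])
                - k_s * w[o + 7, col]
            )
    # chemical synapses: r kinetics plus coupling current into the post cell
    for e in range(n_syn):
        pre = c_pre[e]
        post = c_post[e]
        op = NV * post
        r = y[n8 + e]
        s = y[n8 + n_syn + pre]
        T = c_tmax[e] * s
        v_post = y[op]
        for col in range(k):
            out[n8 + e, col] += (
                -(c_alpha[e] * T + c_beta_[e]) * w[n8 + e, col]
                + c_alpha[e] * c_tmax[e] * (1.0 - r) * w[n8 + n_syn + pre, col]
            )
            out[op, col] += (
                -c_g[e] * r * w[op, col]
                - c_g[e] * (v_post - c_e[e]) * w[n8 + e, col]
            ) / cm[post]
    # release states
    for i in range(n_cells):
        V = y[NV * i]
        s = y[n8 + n_syn + i]
        sig = 1.0 / (1.0 + np.exp(-V / 3.0))
        dsig = sig * (1.0 - sig) / 3.0
        for col in range(k):
            out[n8 + n_syn + i, col] += (
                SMOOTH_K_ON * dsig * (1.0 - s) * w[NV * i, col]
                - (SMOOTH_K_ON * sig + 1.0 / c_pulse[i]) * w[n8 + n_syn + i, col]
            )
    # gap junctions
    for j in range(gp_a.shape[0]):
        a = gp_a[j]
        b = gp_b[j]
        for col in range(k):
            dwa = w[NV * a, col]
            dwb = w[NV * b, col]
            out[NV * a, col] += gp_g[j] * (dwb - dwa) / cm[a]
            out[NV * b, col] += gp_g[j] * (dwa - dwb) / cm[b]


@njit(cache=True)
def _error_norm(y, y5, err, rtol, atol):
    s = 0.0
    for i in range(y.shape[0]):
        sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
        q = err[i] / sc
        s += q * q
    return np.sqrt(s / y.shape[0])


@njit(cache=True)
def integrate_network(
    y0, t1, rtol, atol, h_max,
    n_cells, g8, cm, e_na, e_k, e_b, e_ca,
    tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
    c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_pulse,
    gp_a, gp_b, gp_g,
    ev_times, ev_i,
    dt_out, spike_thresh, refractory, smooth,
):
    """Integrate the network from t=0 to t1 (ms).

    Returns (status, t_reached, y_final, V_out[n_cells, n_out],
    spike_times, spike_cells, n_spikes, ranges) where ranges rows hold the
    running (min, max) of gating variables, calcium and synaptic r over all
    accepted steps.
    """
    dim = y0.shape[0]
    n8 = NV * n_cells
    n_syn = c_pre.shape[0]
    n_out = int(np.floor(t1 / dt_out)) + 1
    v_out = np.empty((n_cells, n_out))
    for i in range(n_cells):
        v_out[i, 0] = y0[NV * i]
    out_idx = 1

    cap = 4096
    spike_t = np.empty(cap)
    spike_c = np.empty(cap, dtype=np.int64)
    n_spk = 0
    last_spk = np.full(n_cells, -1e18)
    pulse_end = np.full(n_cells, -1.0)

    # ranges: 0 gating min, 1 gating max, 2 Ca min, 3 Ca max, 4 r min, 5 r max
    ranges = np.array([1e18, -1e18, 1e18, -1e18, 1e18, -1e18])

    k_stage = np.empty((7, dim))
    y = y0.copy()
    ytmp = np.empty(dim)
    y5 = np.empty(dim)
    errv = np.empty(dim)
    c_t = np.zeros(n_syn)

    t = 0.0
    h = 0.01
    h_min = 1e-10
    ev_idx = 0
    i_ext = ev_i[0].copy()

    # FSAL: first derivative
    network_rhs(t, y, k_stage[0], n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
                gp_a, gp_b, gp_g, i_ext, smooth, c_pulse)

    while t < t1 - 1e-12:
        # step boundary: end time, protocol events, active pulse offsets
        t_stop = t1
        if ev_idx + 1 < ev_times.shape[0] and ev_times[ev_idx + 1] < t_stop:
            t_stop = ev_times[ev_idx + 1]
        if smooth == 0:
            for i in range(n_cells):
                pe = pulse_end[i]
                if pe > t + 1e-12 and pe < t_stop:
                    t_stop = pe
        if h > h_max:
            h = h_max
        if t + h > t_stop:
            h = t_stop - t
        if h < h_min:
            return (STATUS_STEP_UNDERFLOW, t, y, v_out[:, :out_idx],
                    spike_t[:n_spk], spike_c[:n_spk], n_spk, ranges)

        # transmitter levels for this step
        if smooth == 0:
            for e in range(n_syn):
                if pulse_end[c_pre[e]] > t + 1e-12:
                    c_t[e] = c_tmax[e]
                else:
                    c_t[e] = 0.0

        # DP5 stages (k1 already in k_stage[0])
        for s in range(1, 7):
            for i in range(dim):
                acc = 0.0
                for q in range(s):
                    acc += _A_FLAT[s * 7 + q] * k_stage[q, i]
                ytmp[i] = y[i] + h * acc
            network_rhs(t + _C_ARR[s] * h, ytmp, k_stage[s],
                        n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                        tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                        c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
                        gp_a, gp_b, gp_g, i_ext, smooth, c_pulse)
        for i in range(dim):
            acc5 = 0.0
            acc4 = 0.0
            for q in range(7):
                acc5 += _B5_ARR[q] * k_stage[q, i]
                acc4 += _B4_ARR[q] * k_stage[q, i]
            y5[i] = y[i] + h * acc5
            errv[i] = h * (acc5 - acc4)
        err = _error_norm(y, y5, errv, rtol, atol)

        if err <= 1.0 or h <= h_min * 2.0:
            # accept
            finite = True
            for i in range(dim):
                if not np.isfinite(y5[i]):
                    finite = False
                    break
            if not finite:
                return (STATUS_NONFINITE, t, y, v_out[:, :out_idx],
                        spike_t[:n_spk], spike_c[:n_spk], n_spk, ranges)
            t_new = t + h
            # dense output by linear interpolation (h <= dt_out by default)
            while out_idx < n_out and out_idx * dt_out <= t_new + 1e-9:
                tg = out_idx * dt_out
                w = (tg - t) / h if h > 0 else 1.0
                for i in range(n_cells):
                    v_out[i, out_idx] = (1.0 - w) * y[NV * i] + w * y5[NV * i]
                out_idx += 1
            # spike / pulse-trigger detection
            for i in range(n_cells):
                v0 = y[NV * i]
                v1 = y5[NV * i]
                if v0 < spike_thresh and v1 >= spike_thresh:
                    tc = t + h * (spike_thresh - v0) / (v1 - v0)
                    if tc - last_spk[i] >= refractory:
                        last_spk[i] = tc
                        if n_spk >= cap:
                            cap *= 2
                            new_t = np.empty(cap)
                            new_c = np.empty(cap, dtype=np.int64)
                            new_t[:n_spk] = spike_t[:n_spk]
                            new_c[:n_spk] = spike_c[:n_spk]
                            spike_t = new_t
                            spike_c = new_c
                        spike_t[n_spk] = tc
                        spike_c[n_spk] = i
                        n_spk += 1
                        pulse_end[i] = tc + c_pulse[i]
            # invariant ranges
            for i in range(n_cells):
                o = NV * i
                for q in range(1, 7):
                    v = y5[o + q]
                    if v < ranges[0]:
                        ranges[0] = v
                    if v > ranges[1]:
                        ranges[1] = v
                ca = y5[o + 7]
                if ca < ranges[2]:
                    ranges[2] = ca
                if ca > ranges[3]:
                    ranges[3] = ca
            for e in range(n_syn):
                r = y5[n8 + e]
                if r < ranges[4]:
                    ranges[4] = r
                if r > ranges[5]:
                    ranges[5] = r
            for i in range(dim):
                y[i] = y5[i]
            t = t_new
            for i in range(dim):
                k_stage[0, i] = k_stage[6, i]  # FSAL
            # protocol event crossing
            if ev_idx + 1 < ev_times.shape[0] and t >= ev_times[ev_idx + 1] - 1e-9:
                ev_idx += 1
                for i in range(n_cells):
                    i_ext[i] = ev_i[ev_idx, i]
                # stimulus changed: k1 must be re-evaluated
                if smooth == 0:
                    for e in range(n_syn):
                        if pulse_end[c_pre[e]] > t + 1e-12:
                            c_t[e] = c_tmax[e]
                        else:
                            c_t[e] = 0.0
                network_rhs(t, y, k_stage[0], n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                            tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                            c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
                            gp_a, gp_b, gp_g, i_ext, smooth, c_pulse)
            elif smooth == 0:
                # pulse set changed (new spikes or pulse offsets): refresh k1
                changed = False
                for e in range(n_syn):
                    t_on = c_tmax[e] if pulse_end[c_pre[e]] > t + 1e-12 else 0.0
                    if t_on != c_t[e]:
                        changed = True
                        c_t[e] = t_on
                if changed:
                    network_rhs(t, y, k_stage[0], n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                                tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                                c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
                                gp_a, gp_b, gp_g, i_ext, smooth, c_pulse)
            # step-size update
            if err > 1e-10:
                fac = 0.9 * err ** (-0.2)
            else:
                fac = 5.0
            if fac > 5.0:
                fac = 5.0
            h = h * fac
        else:
            fac = 0.9 * err ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h = h * fac
        if h > h_max:
            h = h_max

    return (STATUS_OK, t, y, v_out, spike_t[:n_spk], spike_c[:n_spk], n_spk, ranges)


# flattened tableau constants for njit use
_A_FLAT = _A.flatten()
_C_ARR = _C
_B5_ARR = _B5
_B4_ARR = _B4


@njit(cache=True)
def integrate_tangent(
    y0, w0, t1, renorm_dt, rtol, atol, h_max,
    n_cells, g8, cm, e_na, e_k, e_b, e_ca,
    tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
    c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_pulse,
    gp_a, gp_b, gp_g,
    i_ext,
):
    """Propagate the flow plus k tangent vectors with QR renormalization.

    Uses the smooth (sigmoidal) transmitter-release variant so the vector
    field is continuously differentiable; Jacobian-vector products are
    formed by forward finite differences around the flow trajectory at every
    Runge-Kutta stage.  Returns (status, log-stretch sums[k], checkpoint
    times, running exponent estimates[n_check, k]).
    """
    dim = y0.shape[0]
    k = w0.shape[1]
    n_check = int(np.floor(t1 / renorm_dt + 1e-9))
    log_sum = np.zeros(k)
    conv_t = np.empty(n_check)
    conv = np.empty((n_check, k))

    y = y0.copy()
    w = w0.copy()
    c_t = np.zeros(c_pre.shape[0])

    f0 = np.empty(dim)
    jtmp = np.empty((dim, k))
    ky = np.empty((7, dim))
    kw = np.empty((7, dim, k))
    ytmp = np.empty(dim)
    wtmp = np.empty((dim, k))
    y5 = np.empty(dim)
    w5 = np.empty((dim, k))
    errv = np.empty(dim)

    t = 0.0
    h = 0.01
    h_min = 1e-10

    for chk in range(n_check):
        t_stop = (chk + 1) * renorm_dt
        while t < t_stop - 1e-12:
            if h > h_max:
                h = h_max
            if t + h > t_stop:
                h = t_stop - t
            if h < h_min:
                return (STATUS_STEP_UNDERFLOW, log_sum, conv_t[:chk], conv[:chk])
            for s in range(7):
                if s == 0:
                    for i in range(dim):
                        ytmp[i] = y[i]
                        for j in range(k):
                            wtmp[i, j] = w[i, j]
                else:
                    for i in range(dim):
                        acc = 0.0
                        for q in range(s):
                            acc += _A_FLAT[s * 7 + q] * ky[q, i]
                        ytmp[i] = y[i] + h * acc
                        for j in range(k):
                            accw = 0.0
                            for q in range(s):
                                accw += _A_FLAT[s * 7 + q] * kw[q, i, j]
                            wtmp[i, j] = w[i, j] + h * accw
                network_rhs(t + _C_ARR[s] * h, ytmp, f0,
                            n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                            tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                            c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax, c_t,
                            gp_a, gp_b, gp_g, i_ext, 1, c_pulse)
                for i in range(dim):
                    ky[s, i] = f0[i]
                network_jvp(ytmp, wtmp, jtmp,
                            n_cells, g8, cm, e_na, e_k, e_b, e_ca,
                            tau, rho, k_ca_flux, k_s, k_beta, beta_ca,
                            c_pre, c_post, c_g, c_e, c_alpha, c_beta_, c_tmax,
                            c_pulse, gp_a, gp_b, gp_g)
                for i in range(dim):
                    for j in range(k):
                        kw[s, i, j] = jtmp[i, j]
            for i in range(dim):
                acc5 = 0.0
                acc4 = 0.0
                for q in range(7):
                    acc5 += _B5_ARR[q] * ky[q, i]
                    acc4 += _B4_ARR[q] * ky[q, i]
                y5[i] = y[i] + h * acc5
                errv[i] = h * (acc5 - acc4)
                for j in range(k):
                    accw = 0.0
                    for q in range(7):
                        accw += _B5_ARR[q] * kw[q, i, j]
                    w5[i, j] = w[i, j] + h * accw
            err = _error_norm(y, y5, errv, rtol, atol)
            if err <= 1.0 or h <= h_min * 2.0:
                for i in range(dim):
                    if not np.isfinite(y5[i]):
                        return (STATUS_NONFINITE, log_sum, conv_t[:chk], conv[:chk])
                for i in range(dim):
                    y[i] = y5[i]
                    for j in range(k):
                        w[i, j] = w5[i, j]
                t = t + h
                if err > 1e-10:
                    fac = 0.9 * err ** (-0.2)
                else:
                    fac = 5.0
                if fac > 5.0:
                    fac = 5.0
                h = h * fac
            else:
                fac = 0.9 * err ** (-0.2)
                if fac < 0.2:
                    fac = 0.2
                h = h * fac
        # QR renormalization
        q_mat, r_mat = np.linalg.qr(w)
        for j in range(k):
            d = r_mat[j, j]
            if d < 0:
                d = -d
                for i in range(dim):
                    q_mat[i, j] = -q_mat[i, j]
            if d < 1e-300:
                d = 1e-300
            log_sum[j] += np.log(d)
        for i in range(dim):
            for j in range(k):
                w[i, j] = q_mat[i, j]
        conv_t[chk] = t
        for j in range(k):
            conv[chk, j] = log_sum[j] / t
    return (STATUS_OK, log_sum, conv_t, conv)
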