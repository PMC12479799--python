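"""Compiled inner loop of the glucoregulatory model.

State vector (units in brackets):

    S1, S2  subcutaneous rapid-acting insulin depot [mU] (two compartments)
    I       plasma insulin above basal [mU/L]
    X       remote insulin action [1/min]
    Q1, Q2  gut glucose [mmol] (two absorption compartments)
    G       plasma glucose [mmol/L]

Dynamics (fixed-step classical Runge-Kutta):

    S1' = -S1/tau_I                      S2' = (S1 - S2)/tau_I
    I'  = S2/(tau_I V_I) - k_e I
    X'  = -p2 X + p2 S_I (I + k_b B)
    Q1' = -Q1/tau_m                      Q2' = (Q1 - Q2)/tau_m
    G'  = -(S_G + X) G + S_G G_b + Q2/(tau_m V_G)

Boluses are impulses into S1 (mU); meals are impulses into Q1 (mmol,
already scaled by the meal-type bioavailability f).  The once-daily
long-acting basal dose B (units/day) enters as a constant plasma-insulin
contribution k_b * B.
"""

import numpy as np
from numba import njit

# parameter vector layout
P_SI, P_SG, P_GB, P_P2, P_TAUI, P_KE, P_VI, P_KB, P_TAUM, P_VG = range(10)


@njit(cache=False)
def _rhs(s1, s2, i_, x, q1, q2, g, SI, SG, Gb, p2, tauI, ke, VI, kb, tauM, VG, Ib):
    d_s1 = -s1 / tauI
    d_s2 = (s1 - s2) / tauI
    d_i = s2 / (tauI * VI) - ke * i_
    d_x = -p2 * x + p2 * SI * (i_ + Ib)
    d_q1 = -q1 / tauM
    d_q2 = (q1 - q2) / tauM
    d_g = -(SG + x) * g + SG * Gb + q2 / (tauM * VG)
    return d_s1, d_s2, d_i, d_x, d_q1, d_q2, d_g


@njit(cache=False)
def integrate(y0, n_steps, dt, p, basal, bolus_step, bolus_mU, meal_step, meal_mmol):
    """Integrate ``n_steps`` RK4 steps of size ``dt`` minutes.

    ``bolus_step`` / ``meal_step`` are sorted step indices at which the
    corresponding impulse is applied (before the step is taken).  Returns
    the full state trajectory, shape ``(n_steps + 1, 7)``.
    """
    SI = p[P_SI]; SG = p[P_SG]; Gb = p[P_GB]; p2 = p[P_P2]
    tauI = p[P_TAUI]; ke = p[P_KE]; VI = p[P_VI]; kb = p[P_KB]
    tauM = p[P_TAUM]; VG = p[P_VG]
    Ib = kb * basal

    out = np.empty((n_steps + 1, 7))
    s1, s2, i_, x, q1, q2, g = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6]
    out[0, 0] = s1; out[0, 1] = s2; out[0, 2] = i_; out[0, 3] = x
    out[0, 4] = q1; out[0, 5] = q2; out[0, 6] = g

    bi = 0
    mi = 0
    nb = bolus_step.shape[0]
    nm = meal_step.shape[0]
    for k in range(n_steps):
        while bi < nb and bolus_step[bi] == k:
            s1 += bolus_mU[bi]
            bi += 1
        while mi < nm and meal_step[mi] == k:
            q1 += meal_mmol[mi]
            mi += 1

        a1, a2, a3, a4, a5, a6, a7 = _rhs(s1, s2, i_, x, q1, q2, g,
                                          SI, SG, Gb, p2, tauI, ke, VI, kb, tauM, VG, Ib)
        h = 0.5 * dt
        b1, b2, b3, b4, b5, b6, b7 = _rhs(s1 + h * a1, s2 + h * a2, i_ + h * a3,
                                          x + h * a4, q1 + h * a5, q2 + h * a6, g + h * a7,
                                          SI, SG, Gb, p2, tauI, ke, VI, kb, tauM, VG, Ib)
        c1, c2, c3, c4, c5, c6, c7 = _rhs(s1 + h * b1, s2 + h * b2, i_ + h * b3,
                                          x + h * b4, q1 + h * b5, q2 + h * b6, g + h * b7,
                                          SI, SG, Gb, p2, tauI, ke, VI, kb, tauM, VG, Ib)
        d1, d2, d3, d4, d5, d6, d7 = _rhs(s1 + dt * c1, s2 + dt * c2, i_ + dt * c3,
                                          x + dt * c4, q1 + dt * c5, q2 + dt * c6, g + dt * c7,
                                          SI, SG, Gb, p2, tauI, ke, VI, kb, tauM, VG, Ib)
        w = dt / 6.0
        s1 += w * (a1 + 2 * b1 + 2 * c1 + d1)
        s2 += w * (a2 + 2 * b2 + 2 * c2 + d2)
        i_ += w * (a3 + 2 * b3 + 2 * c3 + d3)
        x += w * (a4 + 2 * b4 + 2 * c4 + d4)
        q1 += w * (a5 + 2 * b5 + 2 * c5 + d5)
        q2 += w * (a6 + 2 * b6 + 2 * c6 + d6)
        g += w * (a7 + 2 * b7 + 2 * c7 + d7)
        if g < 0.0:
            g = 0.0
        # remote action saturates well above any physiological value; the
        # cap keeps the fixed-step scheme stable at extreme fit candidates
        if x > 0.4:
            x = 0.4
        elif x < 0.0:
            x = 0.0

        out[k + 1, 0] = s1; out[k + 1, 1] = s2; out[k + 1, 2] = i_
        out[k + 1, 3] = x; out[k + 1, 4] = q1; out[k + 1, 5] = q2
        out[k + 1, 6] = g
    return out
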