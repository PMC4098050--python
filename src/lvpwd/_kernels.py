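"""Numba kernels for the 1D monodomain cable simulation.

Two cell models share the cable/driver code:

* ``tp06`` — the ten Tusscher–Panfilov (2006) human left-ventricular
  cardiomyocyte model, full kinetics, with endocardial / midmyocardial /
  epicardial parameter variants (cell_type 0/1/2).
* ``surrogate`` — a two-current (inward/outward) phenomenological membrane
  model in the Mitchell–Schaeffer form, used where hundreds of fiber runs are
  needed; its repolarization time constant carries the transmural
  heterogeneity and the I_Kr-block response.

Integration: forward Euler for the membrane potential and concentrations,
Rush–Larsen (exponential) steps for Hodgkin–Huxley gates.  The cable term is
an explicit central difference with no-flux boundaries.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# --- physical constants (tp06 reference values) ---
R_GAS = 8314.472
FARADAY = 96485.3415
TEMP = 310.0
RTONF = R_GAS * TEMP / FARADAY

# reference morphometry the concentration factors are expressed in
V_C = 16404.0      # cytoplasm volume, um^3
V_SR = 1094.0
V_SS = 54.68
CM_REF_PF = 185.0  # membrane capacitance paired with V_C

STATE_SIZE_TP06 = 19
# state layout: V, m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass,
#               Cai, CaSR, CaSS, Nai, Ki, Rq


@njit(cache=True)
def tp06_initial_state(n_nodes):
    y = np.empty((STATE_SIZE_TP06, n_nodes))
    y[0, :] = -86.2     # V (mV)
    y[1, :] = 0.0       # m
    y[2, :] = 0.75      # h
    y[3, :] = 0.75      # j
    y[4, :] = 0.0       # xr1
    y[5, :] = 1.0       # xr2
    y[6, :] = 0.0       # xs
    y[7, :] = 0.0       # r
    y[8, :] = 1.0       # s
    y[9, :] = 0.0       # d
    y[10, :] = 1.0      # f
    y[11, :] = 1.0      # f2
    y[12, :] = 1.0      # fcass
    y[13, :] = 0.00007  # Cai (mM)
    y[14, :] = 1.3      # CaSR
    y[15, :] = 0.00007  # CaSS
    y[16, :] = 7.67     # Nai
    y[17, :] = 138.3    # Ki
    y[18, :] = 1.0      # Rq (ryanodine-receptor closed fraction)
    return y


@njit(cache=True, fastmath=True)
def _tp06_node(y, i, cell_type, dt, Ko, Nao, Cao, gkr_scale, cfac, istim):
    """Advance the membrane kinetics of node ``i`` by one step.

    Returns dV/dt (mV/ms) from the ionic currents + stimulus; the caller adds
    diffusion and performs the Euler update of V.
    """
    V = y[0, i]
    m = y[1, i]; h = y[2, i]; j = y[3, i]
    xr1 = y[4, i]; xr2 = y[5, i]; xs = y[6, i]
    r = y[7, i]; s = y[8, i]
    d = y[9, i]; f = y[10, i]; f2 = y[11, i]; fcass = y[12, i]
    Cai = y[13, i]; CaSR = y[14, i]; CaSS = y[15, i]
    Nai = y[16, i]; Ki = y[17, i]; Rq = y[18, i]

    # conductances per cell type: 0 endo, 1 mid (M), 2 epi
    GNa = 14.838
    GK1 = 5.405
    GKr = 0.153 * gkr_scale
    pKNa = 0.03
    if cell_type == 0:
        Gto = 0.073
        GKs = 0.392
    elif cell_type == 1:
        Gto = 0.294
        GKs = 0.098
    else:
        Gto = 0.294
        GKs = 0.392
    GCaL = 3.98e-5
    GbNa = 0.00029
    GbCa = 0.000592
    GpCa = 0.1238
    KpCa = 0.0005
    GpK = 0.0146
    knak = 2.724
    KmK = 1.0
    KmNa = 40.0
    knaca = 1000.0
    KmNai = 87.5
    KmCa = 1.38
    ksat = 0.1
    gam = 0.35

    Ek = RTONF * math.log(Ko / Ki)
    Ena = RTONF * math.log(Nao / Nai)
    Eks = RTONF * math.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    Eca = 0.5 * RTONF * math.log(Cao / Cai)

    # fast sodium
    INa = GNa * m * m * m * h * j * (V - Ena)

    # L-type calcium (GHK-like driving term around +15 mV)
    vm15 = V - 15.0
    if abs(vm15) < 1e-6:
        vm15 = 1e-6
    expv = math.exp(2.0 * vm15 / RTONF)
    ICaL = (GCaL * d * f * f2 * fcass * 4.0 * vm15 * (FARADAY / RTONF)
            * (0.25 * CaSS * expv - Cao) / (expv - 1.0))

    # transient outward
    Ito = Gto * r * s * (V - Ek)

    # rapid delayed rectifier
    IKr = GKr * math.sqrt(Ko / 5.4) * xr1 * xr2 * (V - Ek)

    # slow delayed rectifier
    IKs = GKs * xs * xs * (V - Eks)

    # inward rectifier
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - Ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - Ek + 100.0))
            + math.exp(0.1 * (V - Ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - Ek))))
    IK1 = GK1 * math.sqrt(Ko / 5.4) * ak1 / (ak1 + bk1) * (V - Ek)

    # Na/Ca exchanger
    evf = math.exp(gam * V / RTONF)
    evf1 = math.exp((gam - 1.0) * V / RTONF)
    INaCa = (knaca * (evf * Nai ** 3 * Cao - evf1 * Nao ** 3 * Cai * 2.5)
             / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao) * (1.0 + ksat * evf1)))

    # Na/K pump
    INaK = (knak * Ko * Nai
            / ((Ko + KmK) * (Nai + KmNa)
               * (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
                  + 0.0353 * math.exp(-V / RTONF))))

    IpCa = GpCa * Cai / (Cai + KpCa)
    IpK = GpK * (V - Ek) / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - Ena)
    IbCa = GbCa * (V - Eca)

    Iion = INa + ICaL + Ito + IKr + IKs + IK1 + INaCa + INaK + IpCa + IpK + IbNa + IbCa

    # --- gates: Rush-Larsen exponential steps ---
    minf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    taum = am * bm
    hinf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tauh = 1.0 / (ah + bh)
    jinf = hinf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tauj = 1.0 / (aj + bj)

    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1
    xr2inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tauxs = axs * bxs + 80.0

    rinf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    taur = 9.5 * math.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    if cell_type == 0:  # endo
        sinf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        taus = (85.0 * math.exp(-(V + 45.0) ** 2 / 320.0)
                + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    dinf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    taud = ad * bd + gd
    finf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tauf = (1102.5 * math.exp(-(V + 27.0) ** 2 / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
            + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)
    f2inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * math.exp(-(V + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
             + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))
    css_r = (CaSS / 0.05) ** 2
    fcassinf = 0.6 / (1.0 + css_r) + 0.4
    taufcass = 80.0 / (1.0 + css_r) + 2.0

    y[1, i] = minf + (m - minf) * math.exp(-dt / taum)
    y[2, i] = hinf + (h - hinf) * math.exp(-dt / tauh)
    y[3, i] = jinf + (j - jinf) * math.exp(-dt / tauj)
    y[4, i] = xr1inf + (xr1 - xr1inf) * math.exp(-dt / tauxr1)
    y[5, i] = xr2inf + (xr2 - xr2inf) * math.exp(-dt / tauxr2)
    y[6, i] = xsinf + (xs - xsinf) * math.exp(-dt / tauxs)
    y[7, i] = rinf + (r - rinf) * math.exp(-dt / taur)
    y[8, i] = sinf + (s - sinf) * math.exp(-dt / taus)
    y[9, i] = dinf + (d - dinf) * math.exp(-dt / taud)
    y[10, i] = finf + (f - finf) * math.exp(-dt / tauf)
    y[11, i] = f2inf + (f2 - f2inf) * math.exp(-dt / tauf2)
    y[12, i] = fcassinf + (fcass - fcassinf) * math.exp(-dt / taufcass)

    # --- calcium subsystem ---
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / CaSR) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    rate = k2 * CaSS + 0.005
    rinf_q = 0.005 / rate
    y[18, i] = rinf_q + (Rq - rinf_q) * math.exp(-dt * rate)
    O = k1 * CaSS * CaSS * Rq / (0.06 + k1 * CaSS * CaSS)
    Irel = 0.102 * O * (CaSR - CaSS)
    Ileak = 0.00036 * (CaSR - Cai)
    Iup = 0.006375 / (1.0 + (0.00025 / Cai) ** 2)
    Ixfer = 0.0038 * (CaSS - Cai)

    inv_vcf = cfac * CM_REF_PF / (V_C * FARADAY)
    bufc = 1.0 / (1.0 + 0.2 * 0.001 / (Cai + 0.001) ** 2)
    dCai = bufc * ((Ileak - Iup) * V_SR / V_C + Ixfer
                   - (IbCa + IpCa - 2.0 * INaCa) * inv_vcf * 0.5)
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (CaSR + 0.3) ** 2)
    dCaSR = bufsr * (Iup - Irel - Ileak)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / (CaSS + 0.00025) ** 2)
    dCaSS = bufss * (-ICaL * inv_vcf * 0.5 * V_C / V_SS
                     + Irel * V_SR / V_SS - Ixfer * V_C / V_SS)
    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * inv_vcf
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + istim) * inv_vcf

    y[13, i] = Cai + dt * dCai
    y[14, i] = CaSR + dt * dCaSR
    y[15, i] = CaSS + dt * dCaSS
    y[16, i] = Nai + dt * dNai
    y[17, i] = Ki + dt * dKi

    return -(Iion + istim)


@njit(cache=True)
def run_tp06(y, cell_type, D, dx, dt, period_ms, n_beats,
             stim_amp, stim_dur_ms, n_stim_nodes,
             Ko, Nao, Cao, gkr_scale, cfac,
             record_every_ms, paced):
    """Pace a tp06 fiber and record V(x, t) of the final cycle.

    ``y`` is the (19, n) state array (modified in place); returns the recorded
    (n_samples, n_nodes) voltage field of the last cycle and a status flag
    (0 ok, 1 numerical blow-up).
    """
    n = y.shape[1]
    steps_per_beat = int(round(period_ms / dt))
    rec_stride = max(int(round(record_every_ms / dt)), 1)
    n_rec = steps_per_beat // rec_stride
    Vrec = np.empty((n_rec, n))
    dcoef = D * dt / (dx * dx)
    dvdt = np.empty(n)
    status = 0
    for beat in range(n_beats):
        irec = 0
        for step in range(steps_per_beat):
            t_in_beat = step * dt
            stim_on = paced and (t_in_beat < stim_dur_ms)
            for i in range(n):
                istim = stim_amp if (stim_on and i < n_stim_nodes) else 0.0
                dvdt[i] = _tp06_node(y, i, cell_type[i], dt,
                                     Ko, Nao, Cao, gkr_scale, cfac, istim)
            # explicit diffusion with no-flux boundaries
            for i in range(n):
                vl = y[0, i - 1] if i > 0 else y[0, 1] if n > 1 else y[0, 0]
                vr = y[0, i + 1] if i < n - 1 else y[0, n - 2] if n > 1 else y[0, 0]
                lap = vl - 2.0 * y[0, i] + vr
                newv = y[0, i] + dt * dvdt[i] + dcoef * lap
                y[0, i] = newv
                if abs(newv) > 200.0 or newv != newv:
                    status = 1
            if status == 1:
                return Vrec, status
            if beat == n_beats - 1 and step % rec_stride == 0 and irec < n_rec:
                for i in range(n):
                    Vrec[irec, i] = y[0, i]
                irec += 1
    return Vrec, status


# ---------------------------------------------------------------------------
# two-current surrogate (Mitchell-Schaeffer form)

# kinetics (ms); tau_close carries transmural heterogeneity and drug response
MS_TAU_IN = 0.3
MS_TAU_OUT = 6.0
MS_TAU_OPEN = 120.0
MS_U_GATE = 0.13
# monotone endo > mid > epi so repolarization runs epi -> endo as one front,
# giving a clean upright T wave (the detailed model carries M-cell kinetics)
MS_TAU_CLOSE = (205.0, 190.0, 175.0)   # endo, mid, epi
# fractional repolarization prolongation per unit I_Kr block; fixed once by
# matching the detailed tp06 fiber's QT response at ~61% block
# (dQT/QT = 0.065), see docs/methods.md
MS_BLOCK_GAIN = 0.11
MS_K_SENS = 0.2                         # d log(tau_close) / d log(K_ref/K)
MS_V_REST = -86.2
MS_V_AMP = 117.0


@njit(cache=True)
def run_ms(u, hgate, tau_close, D, dx, dt, period_ms, n_beats,
           stim_amp, stim_dur_ms, n_stim_nodes, record_every_ms, paced):
    """Pace a two-current surrogate fiber; record u(x, t) of the final cycle."""
    n = u.shape[0]
    steps_per_beat = int(round(period_ms / dt))
    rec_stride = max(int(round(record_every_ms / dt)), 1)
    n_rec = steps_per_beat // rec_stride
    Urec = np.empty((n_rec, n))
    dcoef = D * dt / (dx * dx)
    status = 0
    for beat in range(n_beats):
        irec = 0
        for step in range(steps_per_beat):
            t_in_beat = step * dt
            stim_on = paced and (t_in_beat < stim_dur_ms)
            for i in range(n):
                ui = u[i]
                hi = hgate[i]
                J = hi * ui * ui * (1.0 - ui) / MS_TAU_IN - ui / MS_TAU_OUT
                if stim_on and i < n_stim_nodes:
                    J += stim_amp
                if ui < MS_U_GATE:
                    hgate[i] = 1.0 + (hi - 1.0) * math.exp(-dt / MS_TAU_OPEN)
                else:
                    hgate[i] = hi * math.exp(-dt / tau_close[i])
                ul = u[i - 1] if i > 0 else u[1] if n > 1 else u[0]
                ur = u[i + 1] if i < n - 1 else u[n - 2] if n > 1 else u[0]
                lap = ul - 2.0 * ui + ur
                u[i] = ui + dt * J + dcoef * lap
                if u[i] != u[i] or abs(u[i]) > 5.0:
                    status = 1
            if status == 1:
                return Urec, status
            if beat == n_beats - 1 and step % rec_stride == 0 and irec < n_rec:
                for i in range(n):
                    Urec[irec, i] = u[i]
                irec += 1
    return Urec, status
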