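"""Right-hand side of the integrated cardiorespiratory model.

The model couples, in a closed feedback loop:

* pressure-driven ventilation of a single alveolar compartment behind a
  volume-dependent airway resistance (``R = r_base + alpha*(v_ref - V_A)``),
* diffusive O2/CO2 exchange across the alveolar membrane into a pulmonary
  capillary compartment, with a series dead space,
* a lumped R-C (Windkessel) circulation with two time-varying-elastance
  ventricles, ideal one-way valves, and systemic / cerebral / pulmonary
  branches,
* tissue O2 consumption and CO2 production with ideal-mixing (CSTR) gas
  compartments and transport-delayed arterial signals,
* affine chemoreceptors feeding a self-sustained respiratory rhythm
  generator, a first-order respiratory actuator (pleural pressure), a
  polynomial heart-period law and a vasodilation sigmoid.

All state resides in a flat float64 vector (indices ``IS_*`` below); all
parameters in the flat vector produced by
:func:`cardioresp.params.pack_parameters`.  The kernels are compiled with
numba when available and run as plain Python otherwise; results are
identical.  There is no randomness anywhere in the model.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (  # noqa: F401  (re-exported index constants)
    NPAR,
    SubjectParameters,
    EnvironmentInput,
    ParameterError,
    pack_parameters,
)
from . import params as _pidx

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

IS_V_A = 0        # alveolar volume, L
IS_P_ACT = 1      # respiratory muscle (actuator) pressure above resting tone, mmHg
IS_R_P = 2        # controller output (drive to lung muscles), dimensionless
IS_PHI_R = 3      # respiratory rhythm phase (unwrapped; cycles = floor)
IS_PHI_C = 4      # cardiac phase (unwrapped)
IS_F_D_O2 = 5     # dead-space dry gas fractions
IS_F_D_CO2 = 6
IS_F_A_O2 = 7     # alveolar dry gas fractions
IS_F_A_CO2 = 8
IS_C_PC_O2 = 9    # pulmonary end-capillary blood gas content, mL/mL
IS_C_PC_CO2 = 10
IS_C_SA_O2 = 11   # systemic arterial
IS_C_SA_CO2 = 12
IS_C_SV_O2 = 13   # systemic tissue / venous
IS_C_SV_CO2 = 14
IS_C_CT_O2 = 15   # cerebral / carotid tissue
IS_C_CT_CO2 = 16
IS_C_MV_O2 = 17   # mixed venous (right heart + pulmonary artery CSTR)
IS_C_MV_CO2 = 18
IS_V_LV = 19      # blood compartment volumes, mL
IS_V_RV = 20
IS_V_SA = 21
IS_V_SV = 22
IS_V_PA = 23
IS_V_PV = 24

NSTATE = 25
BLOOD_VOLUME_SLICE = slice(IS_V_LV, IS_V_PV + 1)

STATE_NAMES = [
    "v_alveolar", "p_act", "r_p", "phi_resp", "phi_cardiac",
    "f_dead_o2", "f_dead_co2", "f_alv_o2", "f_alv_co2",
    "c_pc_o2", "c_pc_co2", "c_sa_o2", "c_sa_co2", "c_sv_o2", "c_sv_co2",
    "c_ct_o2", "c_ct_co2", "c_mv_o2", "c_mv_co2",
    "v_lv", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv",
]

# maneuver modes for the RHS (spirometry overrides the controller output)
MODE_NORMAL = 0
MODE_INSPIRE = 1
MODE_EXPIRE = 2

P_WATER = 47.0  # mmHg, alveolar water vapour pressure at 37 C
STPD_PER_BTPS = 713.0 / 863.0   # mL STPD per mL BTPS at P_atm = 760
BTPS_PER_STPD = 1.0 / STPD_PER_BTPS

# packed-parameter indices (IP_*) injected as module globals so the
# compiled kernels can treat them as compile-time constants
for _k, _v in vars(_pidx).items():
    if _k.startswith("IP_"):
        globals()[_k] = _v
del _k, _v


# ---------------------------------------------------------------------------
# elementary sub-models (numba kernels, callable from Python too)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _airway_resistance(alpha, v_alveolar, r_base, v_ref, r_floor):
    r = r_base + alpha * (v_ref - v_alveolar)
    if r < r_floor:
        r = r_floor
    return r


@njit(cache=True)
def _recoil_pressure(v_a, e_total, v0, c_hi, w_hi, x_hi):
    """Static elastic recoil of lungs+chest, mmHg (positive outward drive
    of expiration).  Linear below the tidal range with an exponential
    stiffening that engages near total lung capacity."""
    x = v_a - v0
    return e_total * x + c_hi * math.exp((x - x_hi) / w_hi)


@njit(cache=True)
def _hill_saturation(p, p50, n):
    if p <= 0.0:
        return 0.0
    r = (p / p50) ** n
    return r / (1.0 + r)


@njit(cache=True)
def _o2_pressure(c, cap, p50, n):
    """Invert the Hill O2 dissociation curve (content -> partial pressure)."""
    s = c / cap
    if s < 1.0e-6:
        s = 1.0e-6
    elif s > 0.9995:
        s = 0.9995
    return p50 * (s / (1.0 - s)) ** (1.0 / n)


@njit(cache=True)
def _co2_pressure(c, intercept, slope):
    p = (c - intercept) / slope
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _elastance_activation(phase, systole_fraction):
    """Trigonometric activation in [0, 1]; phase is cycle fraction."""
    ph = phase % 1.0
    if ph < systole_fraction:
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * ph / systole_fraction))
    return 0.0


@njit(cache=True)
def _heart_period(u_h, t0, h1, h2, t_min, t_max):
    """Polynomial heart-period law, clipped to the physiological band."""
    t = t0 * (1.0 - h1 * u_h - h2 * u_h * abs(u_h))
    if t < t_min:
        t = t_min
    elif t > t_max:
        t = t_max
    return t


@njit(cache=True)
def _vaso_scale(hr, lo, hi, width, hr0):
    """Bounded sigmoid of heart rate multiplying systemic resistance."""
    return lo + (hi - lo) / (1.0 + math.exp((hr - hr0) / width))


@njit(cache=True)
def _delay_lookup(hist, n_filled, t0, dt, t_query, initial):
    """Linearly interpolated lookup in a fixed-grid signal history.

    Before the start of the recorded history the initial condition is
    extended backwards, so warm-up never raises."""
    if n_filled <= 0:
        return initial
    tq = t_query - t0
    if tq <= 0.0:
        return initial
    x = tq / dt
    i = int(x)
    if i >= n_filled - 1:
        return hist[n_filled - 1]
    w = x - i
    return hist[i] * (1.0 - w) + hist[i + 1] * w


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------


@njit(cache=True)
def _full_rhs(t, y, p, fio2, met_scale, p_atm,
              sensed_o2, sensed_co2, mode, man, dy):
    """Evaluate the full state derivative in-place into ``dy``.

    ``sensed_o2``/``sensed_co2`` are the transport-delayed chemoreceptor
    inputs (carotid O2 content, arterial CO2 partial pressure) supplied by
    the integrator from its history buffer.  ``mode``/``man`` implement the
    spirometry override of the controller output (see protocols module).
    Returns (q, heart_period) for convenience.
    """
    # ---------------- ventilation: pressure-driven flow ----------------
    v_a = y[IS_V_A]
    r_aw = _airway_resistance(p[IP_ALPHA], v_a, p[IP_R_AIRWAY_BASE],
                              p[IP_V_REF], p[IP_R_FLOOR])
    recoil = _recoil_pressure(v_a, p[IP_E_TOTAL], p[IP_V_UNLOADED],
                              p[IP_STIFF_C], p[IP_STIFF_W], p[IP_STIFF_X0])
    p_mus = -(p[IP_P0_MUS] + y[IS_P_ACT])
    p_alv = p_atm + recoil + p_mus
    q = (p_atm - p_alv) / r_aw          # L/s, inflow positive
    if mode == MODE_EXPIRE:
        # effort-independent maximal expiratory flow (dynamic airway
        # compression): bounded by kappa * recoil / R_upstream, where the
        # upstream (peripheral) segment carries the volume-dependent part
        # of the airway resistance
        r_up = p[IP_FLOW_LIMIT_BETA] * p[IP_R_AIRWAY_BASE] \
            + p[IP_ALPHA] * (p[IP_V_REF] - v_a)
        if r_up < p[IP_R_FLOOR]:
            r_up = p[IP_R_FLOOR]
        q_env = p[IP_FLOW_LIMIT_KAPPA] * (recoil if recoil > 0.0 else 0.0) / r_up
        if q < -q_env:
            q = -q_env
            p_alv = p_atm - q * r_aw
    dy[IS_V_A] = q

    # ---------------- chemoreceptors (affine, delayed inputs) ----------
    u_o2 = p[IP_G_O2] * (p[IP_SET_O2] - sensed_o2)
    u_co2 = p[IP_G_CO2] * (sensed_co2 - p[IP_SET_CO2])
    u = u_o2 + u_co2
    if u < p[IP_U_MIN]:
        u = p[IP_U_MIN]
    elif u > p[IP_U_MAX]:
        u = p[IP_U_MAX]

    # ---------------- respiratory rhythm generator ---------------------
    f_resp = p[IP_F0] * (1.0 + p[IP_K_FREQ] * u)
    if f_resp < p[IP_F_MIN]:
        f_resp = p[IP_F_MIN]
    amp = p[IP_A0] * (1.0 + p[IP_K_AMP] * u)
    if amp < 0.0:
        amp = 0.0
    dy[IS_PHI_R] = f_resp
    ph = y[IS_PHI_R] % 1.0
    duty = p[IP_DUTY_INSP]
    if ph < duty:
        burst = amp * math.sin(math.pi * ph / duty)
    else:
        burst = 0.0
    dy[IS_R_P] = (burst - y[IS_R_P]) / p[IP_TAU_RP]

    # ---------------- respiratory actuator (pleural pressure) ----------
    if mode == MODE_INSPIRE:
        dy[IS_P_ACT] = (man[0] - y[IS_P_ACT]) / man[1]
    elif mode == MODE_EXPIRE:
        dy[IS_P_ACT] = (man[2] - y[IS_P_ACT]) / man[3]
    else:
        dy[IS_P_ACT] = (p[IP_G_ACT] * y[IS_R_P] - y[IS_P_ACT]) / p[IP_TAU_ACT]

    # ---------------- heart period, elastances, vasodilation -----------
    u_h = p[IP_W_HEART_O2] * u_o2 + p[IP_W_HEART_CO2] * u_co2
    t_heart = _heart_period(u_h, p[IP_T0], p[IP_H1], p[IP_H2],
                            p[IP_T_MIN], p[IP_T_MAX])
    dy[IS_PHI_C] = 1.0 / t_heart
    act = _elastance_activation(y[IS_PHI_C], p[IP_SYSTOLE_FRACTION])
    e_lv = p[IP_EMIN_LV] + (p[IP_EMAX_LV] - p[IP_EMIN_LV]) * act
    e_rv = p[IP_EMIN_RV] + (p[IP_EMAX_RV] - p[IP_EMIN_RV]) * act
    hr = 60.0 / t_heart
    r_sys = p[IP_R_SYSTEMIC] * _vaso_scale(
        hr, p[IP_VASO_LO], p[IP_VASO_HI],
        p[IP_VASO_WIDTH], p[IP_VASO_HR0])

    # ---------------- circulation: R-C circuit with one-way valves -----
    p_lv = e_lv * (y[IS_V_LV] - p[IP_VU_LV])
    p_rv = e_rv * (y[IS_V_RV] - p[IP_VU_RV])
    p_sa = (y[IS_V_SA] - p[IP_VU_SA]) / p[IP_C_SA]
    p_sv = (y[IS_V_SV] - p[IP_VU_SV]) / p[IP_C_SV]
    p_pa = (y[IS_V_PA] - p[IP_VU_PA]) / p[IP_C_PA]
    p_pv = (y[IS_V_PV] - p[IP_VU_PV]) / p[IP_C_PV]

    dp = p_pv - p_lv
    q_mv = dp / p[IP_R_MITRAL] if dp > 0.0 else 0.0
    dp = p_lv - p_sa
    q_av = dp / p[IP_R_AORTIC] if dp > 0.0 else 0.0
    q_sys = (p_sa - p_sv) / r_sys
    q_cer = (p_sa - p_sv) / p[IP_R_CEREBRAL]
    dp = p_sv - p_rv
    q_tv = dp / p[IP_R_TRICUSPID] if dp > 0.0 else 0.0
    dp = p_rv - p_pa
    q_pav = dp / p[IP_R_PULM_VALVE] if dp > 0.0 else 0.0
    q_pul = (p_pa - p_pv) / p[IP_R_PA]

    dy[IS_V_LV] = q_mv - q_av
    dy[IS_V_SA] = q_av - q_sys - q_cer
    dy[IS_V_SV] = q_sys + q_cer - q_tv
    dy[IS_V_RV] = q_tv - q_pav
    dy[IS_V_PA] = q_pav - q_pul
    dy[IS_V_PV] = q_pul - q_mv

    # ---------------- alveolar & dead-space gas stores ------------------
    p_dry = p_alv - P_WATER
    p_ao2 = y[IS_F_A_O2] * p_dry
    p_aco2 = y[IS_F_A_CO2] * p_dry
    p_pc_o2 = _o2_pressure(y[IS_C_PC_O2], p[IP_O2_CAPACITY],
                           p[IP_P50], p[IP_HILL_N])
    p_pc_co2 = _co2_pressure(y[IS_C_PC_CO2], p[IP_CO2_INTERCEPT],
                             p[IP_CO2_SLOPE])
    j_o2 = p[IP_D_O2] * (p_ao2 - p_pc_o2)     # mL STPD/s into blood
    j_co2 = p[IP_D_CO2] * (p_aco2 - p_pc_co2)  # negative: out of blood

    v_d = p[IP_V_DEAD]
    if q > 0.0:  # inspiration: ambient -> dead space -> alveoli
        dy[IS_F_D_O2] = q * (fio2 - y[IS_F_D_O2]) / v_d
        dy[IS_F_D_CO2] = q * (0.0 - y[IS_F_D_CO2]) / v_d
        adv_o2 = q * (y[IS_F_D_O2] - y[IS_F_A_O2])
        adv_co2 = q * (y[IS_F_D_CO2] - y[IS_F_A_CO2])
    else:        # expiration: alveoli -> dead space -> ambient
        dy[IS_F_D_O2] = -q * (y[IS_F_A_O2] - y[IS_F_D_O2]) / v_d
        dy[IS_F_D_CO2] = -q * (y[IS_F_A_CO2] - y[IS_F_D_CO2]) / v_d
        adv_o2 = 0.0
        adv_co2 = 0.0
    dy[IS_F_A_O2] = (adv_o2 - j_o2 * BTPS_PER_STPD * 1.0e-3) / v_a
    dy[IS_F_A_CO2] = (adv_co2 - j_co2 * BTPS_PER_STPD * 1.0e-3) / v_a

    # ---------------- blood gas transport (CSTR chain) ------------------
    ms = met_scale
    v_pc = p[IP_V_PC]
    dy[IS_C_PC_O2] = (q_pul * (y[IS_C_MV_O2] - y[IS_C_PC_O2]) + j_o2) / v_pc
    dy[IS_C_PC_CO2] = (q_pul * (y[IS_C_MV_CO2] - y[IS_C_PC_CO2]) + j_co2) / v_pc

    v_sam = p[IP_V_SA_MIX]
    dy[IS_C_SA_O2] = q_av * (y[IS_C_PC_O2] - y[IS_C_SA_O2]) / v_sam
    dy[IS_C_SA_CO2] = q_av * (y[IS_C_PC_CO2] - y[IS_C_SA_CO2]) / v_sam

    v_tis = p[IP_V_TISSUE]
    dy[IS_C_SV_O2] = (q_sys * (y[IS_C_SA_O2] - y[IS_C_SV_O2])
                      - p[IP_VO2_SYSTEMIC] * ms) / v_tis
    dy[IS_C_SV_CO2] = (q_sys * (y[IS_C_SA_CO2] - y[IS_C_SV_CO2])
                       + p[IP_VCO2_SYSTEMIC] * ms) / v_tis

    v_ct = p[IP_V_CEREBRAL]
    dy[IS_C_CT_O2] = (q_cer * (y[IS_C_SA_O2] - y[IS_C_CT_O2])
                      - p[IP_VO2_CEREBRAL] * ms) / v_ct
    dy[IS_C_CT_CO2] = (q_cer * (y[IS_C_SA_CO2] - y[IS_C_CT_CO2])
                       + p[IP_VCO2_CEREBRAL] * ms) / v_ct

    q_ven = q_sys + q_cer
    if q_ven > 1.0e-9:
        c_mix_o2 = (q_sys * y[IS_C_SV_O2] + q_cer * y[IS_C_CT_O2]) / q_ven
        c_mix_co2 = (q_sys * y[IS_C_SV_CO2] + q_cer * y[IS_C_CT_CO2]) / q_ven
    else:
        c_mix_o2 = y[IS_C_SV_O2]
        c_mix_co2 = y[IS_C_SV_CO2]
    v_mvm = p[IP_V_MV_MIX]
    dy[IS_C_MV_O2] = q_tv * (c_mix_o2 - y[IS_C_MV_O2]) / v_mvm
    dy[IS_C_MV_CO2] = q_tv * (c_mix_co2 - y[IS_C_MV_CO2]) / v_mvm

    return q, t_heart


# ---------------------------------------------------------------------------
# Python-facing operations (validated wrappers over the kernels)
# ---------------------------------------------------------------------------


def airway_resistance(alpha: float, v_alveolar: float, r_base: float,
                      v_ref: float = 6.0, r_floor: float = 0.05) -> float:
    """Volume-dependent airway resistance ``r_base + alpha*(v_ref - V_A)``.

    ``alpha`` expresses small-airways disease severity: at ``alpha = 0`` the
    resistance is the constant healthy value; at positive ``alpha`` the
    airways narrow as the lung empties.  Clamped below at ``r_floor`` so the
    law stays physical above the reference volume.
    """
    if r_base <= 0:
        raise ParameterError("r_base must be positive")
    if alpha < 0:
        raise ParameterError("alpha must be non-negative")
    if v_alveolar <= 0:
        raise ParameterError("v_alveolar must be positive")
    return float(_airway_resistance(alpha, v_alveolar, r_base, v_ref, r_floor))


def lung_mechanics_rhs(v_alveolar: float, p_act: float,
                       subject: SubjectParameters,
                       p_atm: float = 760.0):
    """Ventilation sub-model: returns ``(dV_A/dt, q, p_alveolar)``.

    The alveolar pressure is reconstructed algebraically from the elastic
    recoil and the muscle (pleural) pressure; air flows down the
    atmosphere-alveolus pressure gradient through the airway resistance
    (inflow positive, so the lung inflates exactly when alveolar pressure is
    below atmospheric).
    """
    r = airway_resistance(subject.alpha, v_alveolar, subject.r_airway_base,
                          subject.v_ref, subject.r_floor)
    recoil = _recoil_pressure(v_alveolar, subject.e_total, subject.v_unloaded,
                              subject.stiff_c, subject.stiff_w, subject.stiff_x0)
    p_alv = p_atm + recoil - (subject.p0_mus + p_act)
    q = (p_atm - p_alv) / r
    return q, q, p_alv


def gas_exchange_rhs(v_alveolar: float, f_alv, c_pc, q: float, fio2: float,
                     f_dead, subject: SubjectParameters, p_alv: float = 760.0):
    """Diffusive alveolar-capillary exchange plus advection.

    Parameters are the alveolar dry-gas fractions ``f_alv = (O2, CO2)``, the
    capillary contents ``c_pc``, the airflow ``q`` and dead-space fractions.
    Returns ``(df_alv, dc_pc_diffusive, flux)`` where ``flux`` is the
    (O2, CO2) membrane flux in mL STPD/s (positive into blood).
    """
    g = subject.gas_params
    p_dry = p_alv - P_WATER
    p_a = (f_alv[0] * p_dry, f_alv[1] * p_dry)
    p_b = (_o2_pressure(c_pc[0], g.o2_capacity, g.p50, g.hill_n),
           _co2_pressure(c_pc[1], g.co2_intercept, g.co2_slope))
    flux = (g.d_o2 * (p_a[0] - p_b[0]), g.d_co2 * (p_a[1] - p_b[1]))
    if q > 0:
        adv = (q * (f_dead[0] - f_alv[0]), q * (f_dead[1] - f_alv[1]))
    else:
        adv = (0.0, 0.0)
    df_alv = tuple((adv[i] - flux[i] * BTPS_PER_STPD * 1e-3) / v_alveolar
                   for i in range(2))
    dc_pc = tuple(flux[i] / g.v_pc for i in range(2))
    return df_alv, dc_pc, flux


def time_varying_elastance(cardiac_phase: float, heart_params) -> tuple:
    """Ventricular elastances at a given cardiac phase in [0, 1).

    A raised-cosine activation over the systolic fraction of the cycle
    interpolates continuously between the diastolic minimum and systolic
    maximum; the function is periodic in the phase.
    """
    act = _elastance_activation(cardiac_phase, heart_params.systole_fraction)
    e_lv = heart_params.emin_lv + (heart_params.emax_lv - heart_params.emin_lv) * act
    e_rv = heart_params.emin_rv + (heart_params.emax_rv - heart_params.emin_rv) * act
    return e_lv, e_rv


def circulation_rhs(volumes, subject: SubjectParameters, elastances,
                    systemic_resistance_scale: float = 1.0):
    """Windkessel circuit: volume derivatives, pressures and flows.

    ``volumes`` = (V_lv, V_rv, V_sa, V_sv, V_pa, V_pv) in mL;
    ``elastances`` = (E_lv, E_rv).  Valves are ideal one-way resistive
    elements.  The six volume derivatives sum to zero identically (closed
    circuit).  Returns ``(dvolumes, pressures, flows)`` with pressures and
    flows as dicts keyed by compartment / path name.
    """
    v_lv, v_rv, v_sa, v_sv, v_pa, v_pv = volumes
    if min(volumes) < 0:
        raise ParameterError("negative blood compartment volume")
    c = subject.circulation_params
    h = subject.heart_params
    e_lv, e_rv = elastances
    pr = {
        "lv": e_lv * (v_lv - h.vu_lv),
        "rv": e_rv * (v_rv - h.vu_rv),
        "sa": (v_sa - c.vu_sa) / c.c_sa,
        "sv": (v_sv - c.vu_sv) / c.c_sv,
        "pa": (v_pa - c.vu_pa) / c.c_pa,
        "pv": (v_pv - c.vu_pv) / c.c_pv,
    }
    fl = {
        "mitral": max(0.0, pr["pv"] - pr["lv"]) / c.r_mitral,
        "aortic": max(0.0, pr["lv"] - pr["sa"]) / c.r_aortic,
        "systemic": (pr["sa"] - pr["sv"]) / (c.r_systemic * systemic_resistance_scale),
        "cerebral": (pr["sa"] - pr["sv"]) / c.r_cerebral,
        "tricuspid": max(0.0, pr["sv"] - pr["rv"]) / c.r_tricuspid,
        "pulm_valve": max(0.0, pr["rv"] - pr["pa"]) / c.r_pulm_valve,
        "pulmonary": (pr["pa"] - pr["pv"]) / subject.r_pa,
    }
    dv = (
        fl["mitral"] - fl["aortic"],
        fl["tricuspid"] - fl["pulm_valve"],
        fl["aortic"] - fl["systemic"] - fl["cerebral"],
        fl["systemic"] + fl["cerebral"] - fl["tricuspid"],
        fl["pulm_valve"] - fl["pulmonary"],
        fl["pulmonary"] - fl["mitral"],
    )
    return dv, pr, fl


def blood_transport_rhs(contents, flows, flux_lung, subject: SubjectParameters,
                        metabolic_scale: float = 1.0):
    """Convective gas transport with tissue metabolism and CSTR mixing.

    ``contents``: dict with keys pc/sa/sv/ct/mv, each an (O2, CO2) pair;
    ``flows``: dict from :func:`circulation_rhs`; ``flux_lung``: membrane
    flux (O2, CO2) mL STPD/s.  Returns derivative dict of the same shape.
    At zero metabolic scale only convective terms remain.
    """
    g = subject.gas_params
    m = subject.metabolism
    ms = metabolic_scale
    q_pul, q_av = flows["pulmonary"], flows["aortic"]
    q_sys, q_cer, q_tv = flows["systemic"], flows["cerebral"], flows["tricuspid"]
    q_ven = q_sys + q_cer
    if q_ven > 1e-9:
        c_mix = tuple((q_sys * contents["sv"][i] + q_cer * contents["ct"][i]) / q_ven
                      for i in range(2))
    else:
        c_mix = contents["sv"]
    met_sv = (-m.vo2_systemic * ms, m.vco2_systemic * ms)
    met_ct = (-m.vo2_cerebral * ms, m.vco2_cerebral * ms)
    return {
        "pc": tuple((q_pul * (contents["mv"][i] - contents["pc"][i]) + flux_lung[i])
                    / g.v_pc for i in range(2)),
        "sa": tuple(q_av * (contents["pc"][i] - contents["sa"][i]) / g.v_sa_mix
                    for i in range(2)),
        "sv": tuple((q_sys * (contents["sa"][i] - contents["sv"][i]) + met_sv[i])
                    / g.v_tissue for i in range(2)),
        "ct": tuple((q_cer * (contents["sa"][i] - contents["ct"][i]) + met_ct[i])
                    / g.v_cerebral for i in range(2)),
        "mv": tuple(q_tv * (c_mix[i] - contents["mv"][i]) / g.v_mv_mix
                    for i in range(2)),
    }


def transport_delay(history_t, history_v, tau: float, t: float,
                    initial: float | None = None) -> float:
    """Value of a recorded signal at ``t - tau``.

    ``history_t`` must be an increasing uniform grid.  Between samples the
    signal is interpolated linearly; before the recorded span the initial
    condition is extended backwards (reproducible warm-up).
    """
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    ht = np.asarray(history_t, dtype=float)
    hv = np.asarray(history_v, dtype=float)
    if ht.size == 0:
        raise ParameterError("empty history")
    if initial is None:
        initial = float(hv[0])
    dt = ht[1] - ht[0] if ht.size > 1 else 1.0
    return float(_delay_lookup(hv, hv.size, ht[0], dt, t - tau, initial))


def sensors_and_controllers(sensed_o2: float, sensed_co2: float,
                            phi_resp: float, r_p: float,
                            subject: SubjectParameters):
    """Chemoreflex block: sensor signals, controller derivatives, heart
    period and the systemic vasodilation factor.

    ``sensed_o2`` is the delayed carotid O2 content (mL/mL), ``sensed_co2``
    the delayed arterial CO2 partial pressure (mmHg).  Returns a dict with
    the chemoreceptor deviation signals, the respiratory rhythm frequency
    and amplitude, ``dphi_resp``, ``dr_p``, the clipped heart period and the
    vasodilation scale factor.
    """
    c = subject.control_params
    h = subject.heart_params
    u_o2 = c.g_o2 * (c.set_o2 - sensed_o2)
    u_co2 = c.g_co2 * (sensed_co2 - c.set_co2)
    u = min(max(u_o2 + u_co2, c.u_min), c.u_max)
    f_resp = max(c.f_min, c.f0 * (1.0 + c.k_freq * u))
    amp = max(0.0, c.a0 * (1.0 + c.k_amp * u))
    ph = phi_resp % 1.0
    burst = amp * math.sin(math.pi * ph / c.duty_insp) if ph < c.duty_insp else 0.0
    u_h = c.w_heart_o2 * u_o2 + c.w_heart_co2 * u_co2
    t_heart = _heart_period(u_h, h.t0, c.h1, c.h2, h.t_min, h.t_max)
    return {
        "u_o2": u_o2,
        "u_co2": u_co2,
        "u": u,
        "f_resp": f_resp,
        "amplitude": amp,
        "dphi_resp": f_resp,
        "dr_p": (burst - r_p) / c.tau_rp,
        "heart_period": t_heart,
        "vaso_scale": _vaso_scale(60.0 / t_heart, c.vaso_lo, c.vaso_hi,
                                  c.vaso_width, c.vaso_hr0),
    }


def respiratory_actuator_rhs(r_p: float, p_act: float,
                             subject: SubjectParameters) -> float:
    """First-order response of the respiratory muscles to the neural drive.

    At zero drive the actuator relaxes to its resting tone (``p_act = 0``),
    which produces passive exhalation with flow decaying asymptotically to
    zero.
    """
    c = subject.control_params
    return (c.g_act * r_p - p_act) / c.tau_act


def assemble_full_rhs(t: float, state: np.ndarray, subject: SubjectParameters,
                      env: EnvironmentInput,
                      sensed_o2: float | None = None,
                      sensed_co2: float | None = None) -> np.ndarray:
    """Full state derivative at (t, state); pure and deterministic.

    Without an explicit history the delayed chemoreceptor inputs default to
    the instantaneous compartment values (zero-delay evaluation), which is
    how the algebraic examples and consistency checks use this entry point.
    The integrator supplies properly delayed values instead.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (NSTATE,):
        raise ParameterError(f"state must have shape ({NSTATE},)")
    if y[IS_V_A] < subject.v_unloaded:
        raise ParameterError("ventilation: alveolar volume below unloaded volume")
    if min(y[BLOOD_VOLUME_SLICE]) < 0:
        raise ParameterError("circulation: negative compartment volume")
    p = pack_parameters(subject)
    if sensed_o2 is None:
        sensed_o2 = float(y[IS_C_CT_O2])
    if sensed_co2 is None:
        sensed_co2 = float(_co2_pressure(y[IS_C_SA_CO2],
                                         subject.gas_params.co2_intercept,
                                         subject.gas_params.co2_slope))
    dy = np.zeros(NSTATE)
    man = np.zeros(4)
    _full_rhs(t, y, p, env.fio2(t), env.metabolic_scale, env.p_atm,
              sensed_o2, sensed_co2, MODE_NORMAL, man, dy)
    return dy
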