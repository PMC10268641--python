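"""Parameter registry for one virtual subject and its environment.

Unit conventions (used consistently across the package):

==========================  =============================
quantity                    unit
==========================  =============================
lung volumes                L (BTPS)
airflow q                   L/s  (inflow positive)
airway resistance           mmHg·s/L
lung elastance E_T          mmHg/L
airway / alveolar pressure  mmHg absolute (atmosphere = 760)
blood pressures             mmHg gauge
blood volumes               mL
blood flows                 mL/s
vascular resistances        mmHg·s/mL
vascular compliances        mL/mmHg
ventricular elastances      mmHg/mL
gas content in blood        mL gas (STPD) / mL blood
gas partial pressures       mmHg
metabolic rates             mL gas (STPD) / s
delays, time constants      s
==========================  =============================

The healthy defaults below are the frozen product of a one-time calibration
of the integrated model against standard resting physiology (heart rate
64 beats/min, respiratory rate 11.7 breaths/min, systemic arterial flow
69 mL/s, arterial pressure swinging between roughly 70 and 95 mmHg, forced
vital capacity 4 L).  They define the reference subject; disease is applied
on top of them by :func:`cardioresp.protocols.apply_copd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict

import numpy as np

__all__ = [
    "CirculationParams",
    "HeartParams",
    "GasParams",
    "Metabolism",
    "ControlParams",
    "Delays",
    "SubjectParameters",
    "EnvironmentInput",
    "healthy_subject",
    "pack_parameters",
    "NPAR",
]


class ParameterError(ValueError):
    """Raised when a physiological parameter violates its bounds."""


# ---------------------------------------------------------------------------
# nested parameter groups
# ---------------------------------------------------------------------------


@dataclass
class CirculationParams:
    """Lumped R-C (Windkessel) circulation: resistances, compliances and
    unstressed volumes of the systemic, cerebral and pulmonary circuits."""

    r_mitral: float = 0.006       # mmHg·s/mL, mitral valve path
    r_aortic: float = 0.02        # aortic valve + proximal aorta
    r_tricuspid: float = 0.006
    r_pulm_valve: float = 0.015
    r_systemic: float = 1.08876    # systemic periphery (descending)
    r_cerebral: float = 6.0099      # cerebral/carotid branch
    c_sa: float = 2.72109             # systemic arteries
    c_sv: float = 120.0            # systemic veins
    c_pa: float = 4.0             # pulmonary arteries
    c_pv: float = 16.0            # pulmonary veins
    vu_sa: float = 500.0          # unstressed volumes, mL
    vu_sv: float = 2051.62
    vu_pa: float = 50.0
    vu_pv: float = 350.0
    total_blood_volume: float = 4600.0


@dataclass
class HeartParams:
    """Time-varying elastance ventricles and heart-period controller band."""

    t0: float = 0.9375            # baseline heart period, s (64 beats/min)
    t_min: float = 0.3            # clip band, s
    t_max: float = 2.0
    emax_lv: float = 2.8          # mmHg/mL
    emin_lv: float = 0.06
    vu_lv: float = 15.0
    emax_rv: float = 5.0
    emin_rv: float = 0.087165
    vu_rv: float = 15.0
    systole_fraction: float = 0.3  # fraction of cycle spent in systole


@dataclass
class GasParams:
    """Membrane diffusing capacities, dissociation constants and the
    effective gas-mixing volumes of the blood compartments."""

    d_o2: float = 0.9             # mL STPD/(s·mmHg), alveolar membrane
    d_co2: float = 3.5
    o2_capacity: float = 0.2      # mL O2/mL blood at full saturation
    p50: float = 26.0             # mmHg, half-saturation of the Hill curve
    hill_n: float = 2.7
    co2_intercept: float = 0.2    # linearised CO2 dissociation: c = a + b·P
    co2_slope: float = 0.007      # (mL/mL)/mmHg
    v_dead: float = 0.12          # series dead-space volume, L
    v_pc: float = 90.0            # pulmonary capillary mixing volume, mL
    v_sa_mix: float = 150.0       # left heart + arterial mixing (CSTR), mL
    v_tissue: float = 2000.0      # systemic tissue + venous gas store, mL
    v_cerebral: float = 250.0     # cerebral tissue gas store, mL
    v_mv_mix: float = 180.0       # right heart + pulmonary artery CSTR, mL


@dataclass
class Metabolism:
    """Resting tissue gas-exchange rates (scaled by the environment)."""

    vo2_systemic: float = 3.35    # mL O2/s consumed by systemic tissues
    vco2_systemic: float = 2.68   # mL CO2/s produced
    vo2_cerebral: float = 0.82
    vco2_cerebral: float = 0.656


@dataclass
class ControlParams:
    """Chemoreflex, respiratory rhythm generator, actuator, heart-period
    polynomial and vasodilation sigmoid.

    The O2 chemoreceptor is affine in the O2 *content* of the
    carotid/cerebral compartment (the saturation curve upstream provides the
    physiological steepening of the response at low oxygen); the CO2
    chemoreceptor is affine in the delayed arterial CO2 partial pressure.
    """

    set_o2: float = 0.127502         # carotid O2 content setpoint, mL/mL
    set_co2: float = 43.3027         # arterial P_CO2 setpoint, mmHg
    g_o2: float = 30.0            # drive per (mL/mL) O2 content deficit
    g_co2: float = 0.06           # drive per mmHg CO2 excess
    u_min: float = -0.8           # clip band of the summed chemical drive
    u_max: float = 5.0
    f0: float = 0.195             # baseline respiratory rhythm, breaths/s
    f_min: float = 0.05
    k_freq: float = 0.45          # frequency gain on chemical drive
    k_amp: float = 0.5            # amplitude gain on chemical drive
    a0: float = 0.49835              # baseline burst amplitude (dimensionless)
    duty_insp: float = 0.35       # inspiratory fraction of the cycle
    tau_rp: float = 0.06          # controller output relaxation, s
    g_act: float = 3.0            # actuator static gain, mmHg per unit R_p
    tau_act: float = 0.25         # actuator (lung muscle) time constant, s
    h1: float = 0.12              # heart-period polynomial, linear term
    h2: float = 0.015             # quadratic term
    w_heart_o2: float = 1.0       # afferent weights entering the polynomial
    w_heart_co2: float = 0.3
    vaso_lo: float = 0.8          # vasodilation sigmoid asymptotes
    vaso_hi: float = 1.2
    vaso_width: float = 18.0      # beats/min
    vaso_hr0: float = 64.0


@dataclass
class Delays:
    """Circulatory transport delays of the sensed arterial signals."""

    peripheral: float = 2.0       # lung -> carotid body, s
    central: float = 8.0          # lung -> central (medullary) receptor, s


# ---------------------------------------------------------------------------
# the subject
# ---------------------------------------------------------------------------

# Resting respiratory muscle tone (mmHg).  Its value fixes the healthy
# functional residual capacity at p0/E_T; see docs/methods.md.
P0_MUS = 6.325

# High-inflation parenchymal stiffening g(x) = c_hi * exp((x - x_hi)/w_hi)
# added to the linear recoil, x = V_A - V_0.  Engages only near total lung
# capacity; negligible (< 0.01 mmHg) over the tidal range.
X_HI = 5.0
W_HI = 0.5
C_HI = 0.2875 / (1.0 - float(np.exp(-0.35 / W_HI)))


@dataclass
class SubjectParameters:
    """All fixed physiological constants of one virtual subject.

    The four COPD-severity parameters live at the top level:
    ``alpha`` (airway severity, Eq. ``R = r_base + alpha*(v_ref - V_A)``),
    ``v_unloaded`` and ``e_total`` (hyperinflation), and ``r_pa``
    (pulmonary arterial resistance).
    """

    r_airway_base: float = 1.0    # mmHg·s/L
    alpha: float = 0.0            # mmHg·s/L per L of volume deficit
    v_ref: float = 6.0            # L, reference volume of the airway law
    e_total: float = 2.5          # mmHg/L
    v_unloaded: float = 0.0       # L
    r_pa: float = 0.198           # mmHg·s/mL
    r_floor: float = 0.05         # lower clamp on airway resistance
    flow_limit_kappa: float = 0.4015  # maximal-expiratory-flow coefficient
    flow_limit_beta: float = 0.65   # upstream fraction of the base resistance
    p0_mus: float = P0_MUS
    stiff_c: float = C_HI
    stiff_w: float = W_HI
    stiff_x0: float = X_HI
    circulation_params: CirculationParams = field(default_factory=CirculationParams)
    heart_params: HeartParams = field(default_factory=HeartParams)
    gas_params: GasParams = field(default_factory=GasParams)
    metabolism: Metabolism = field(default_factory=Metabolism)
    control_params: ControlParams = field(default_factory=ControlParams)
    delays: Delays = field(default_factory=Delays)

    def validate(self) -> None:
        """Check positivity and bound invariants; raise ParameterError."""
        errors = []
        if self.r_airway_base <= 0:
            errors.append("r_airway_base must be > 0")
        if self.alpha < 0:
            errors.append("alpha must be >= 0")
        if self.v_unloaded < 0:
            errors.append("v_unloaded must be >= 0")
        for name in ("v_ref", "e_total", "r_pa", "r_floor", "p0_mus",
                     "flow_limit_kappa", "flow_limit_beta"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        c = self.circulation_params
        for f in fields(c):
            if getattr(c, f.name) <= 0:
                errors.append(f"circulation_params.{f.name} must be > 0")
        h = self.heart_params
        for name in ("t0", "t_min", "t_max", "emax_lv", "emin_lv",
                     "emax_rv", "emin_rv", "systole_fraction"):
            if getattr(h, name) <= 0:
                errors.append(f"heart_params.{name} must be > 0")
        if h.emax_lv <= h.emin_lv or h.emax_rv <= h.emin_rv:
            errors.append("heart_params: emax must exceed emin")
        if not (h.t_min < h.t0 < h.t_max):
            errors.append("heart_params: t0 must lie inside [t_min, t_max]")
        g = self.gas_params
        for f in fields(g):
            if getattr(g, f.name) <= 0:
                errors.append(f"gas_params.{f.name} must be > 0")
        m = self.metabolism
        for f in fields(m):
            if getattr(m, f.name) < 0:
                errors.append(f"metabolism.{f.name} must be >= 0")
        d = self.delays
        if d.peripheral < 0 or d.central < 0:
            errors.append("delays must be >= 0")
        if errors:
            raise ParameterError("; ".join(errors))

    def copy(self) -> "SubjectParameters":
        return replace(
            self,
            circulation_params=replace(self.circulation_params),
            heart_params=replace(self.heart_params),
            gas_params=replace(self.gas_params),
            metabolism=replace(self.metabolism),
            control_params=replace(self.control_params),
            delays=replace(self.delays),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def healthy_subject() -> SubjectParameters:
    """The calibrated healthy reference subject."""
    p = SubjectParameters()
    p.validate()
    return p


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentInput:
    """Inspired-gas schedule and metabolic scaling.

    ``fio2_times``/``fio2_values`` define a piecewise-constant inspired O2
    fraction: value ``fio2_values[i]`` applies for
    ``t >= fio2_times[i]`` (times strictly increasing, first entry is the
    value before the first switch as well).
    """

    fio2_times: tuple = (0.0,)
    fio2_values: tuple = (0.21,)
    metabolic_scale: float = 1.0
    p_atm: float = 760.0

    def validate(self) -> None:
        t = np.asarray(self.fio2_times, dtype=float)
        v = np.asarray(self.fio2_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ParameterError("fio2 schedule arrays must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("fio2_times must be strictly increasing")
        if np.any(v <= 0) or np.any(v > 1):
            raise ParameterError("fio2 values must lie in (0, 1]")
        if self.metabolic_scale <= 0:
            raise ParameterError("metabolic_scale must be > 0")
        if self.p_atm <= 47.0:
            raise ParameterError("p_atm must exceed water vapour pressure")

    def fio2(self, t: float) -> float:
        """Inspired O2 fraction at time ``t``."""
        idx = int(np.searchsorted(np.asarray(self.fio2_times), t, side="right")) - 1
        return float(self.fio2_values[max(idx, 0)])


def constant_fio2(value: float = 0.21) -> EnvironmentInput:
    env = EnvironmentInput(fio2_times=(0.0,), fio2_values=(float(value),))
    env.validate()
    return env


# ---------------------------------------------------------------------------
# flat packing for the compiled kernels
# ---------------------------------------------------------------------------

_PACK_ORDER = [
    # mechanics
    ("r_airway_base",), ("alpha",), ("v_ref",), ("r_floor",),
    ("e_total",), ("v_unloaded",), ("p0_mus",), ("flow_limit_kappa",), ("flow_limit_beta",),
    ("stiff_c",), ("stiff_w",), ("stiff_x0",),
    # gas
    ("gas_params", "v_dead"),
    ("gas_params", "o2_capacity"), ("gas_params", "p50"), ("gas_params", "hill_n"),
    ("gas_params", "co2_intercept"), ("gas_params", "co2_slope"),
    ("gas_params", "d_o2"), ("gas_params", "d_co2"),
    ("gas_params", "v_pc"), ("gas_params", "v_sa_mix"), ("gas_params", "v_tissue"),
    ("gas_params", "v_cerebral"), ("gas_params", "v_mv_mix"),
    # metabolism
    ("metabolism", "vo2_systemic"), ("metabolism", "vco2_systemic"),
    ("metabolism", "vo2_cerebral"), ("metabolism", "vco2_cerebral"),
    # circulation
    ("circulation_params", "r_mitral"), ("circulation_params", "r_aortic"),
    ("circulation_params", "r_tricuspid"), ("circulation_params", "r_pulm_valve"),
    ("circulation_params", "r_systemic"), ("circulation_params", "r_cerebral"),
    ("r_pa",),
    ("circulation_params", "c_sa"), ("circulation_params", "c_sv"),
    ("circulation_params", "c_pa"), ("circulation_params", "c_pv"),
    ("circulation_params", "vu_sa"), ("circulation_params", "vu_sv"),
    ("circulation_params", "vu_pa"), ("circulation_params", "vu_pv"),
    ("heart_params", "emax_lv"), ("heart_params", "emin_lv"), ("heart_params", "vu_lv"),
    ("heart_params", "emax_rv"), ("heart_params", "emin_rv"), ("heart_params", "vu_rv"),
    ("heart_params", "systole_fraction"),
    # control
    ("heart_params", "t0"), ("heart_params", "t_min"), ("heart_params", "t_max"),
    ("control_params", "set_o2"), ("control_params", "set_co2"),
    ("control_params", "g_o2"), ("control_params", "g_co2"),
    ("control_params", "u_min"), ("control_params", "u_max"),
    ("control_params", "f0"), ("control_params", "f_min"),
    ("control_params", "k_freq"), ("control_params", "k_amp"),
    ("control_params", "a0"), ("control_params", "duty_insp"),
    ("control_params", "tau_rp"),
    ("control_params", "g_act"), ("control_params", "tau_act"),
    ("control_params", "h1"), ("control_params", "h2"),
    ("control_params", "w_heart_o2"), ("control_params", "w_heart_co2"),
    ("control_params", "vaso_lo"), ("control_params", "vaso_hi"),
    ("control_params", "vaso_width"), ("control_params", "vaso_hr0"),
    ("delays", "peripheral"), ("delays", "central"),
]

NPAR = len(_PACK_ORDER)

# named indices into the packed vector (IP_R_AIRWAY_BASE, IP_ALPHA, ...)
_globals = globals()
for _i, _path in enumerate(_PACK_ORDER):
    _globals["IP_" + "_".join(p.upper() for p in _path[-1:])] = _i
del _globals, _i, _path


def pack_parameters(subject: SubjectParameters) -> np.ndarray:
    """Flatten a SubjectParameters into the float64 vector used by the
    compiled right-hand side.  Validates first."""
    subject.validate()
    out = np.empty(NPAR, dtype=np.float64)
    for i, path in enumerate(_PACK_ORDER):
        obj = subject
        for name in path:
            obj = getattr(obj, name)
        out[i] = float(obj)
    return out
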