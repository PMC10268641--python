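"""Forward simulation to the time-periodic stationary state (TPSS).

The model is a delay-differential system: the chemoreceptor inputs are
transport-delayed copies of arterial/carotid signals.  It is integrated
with an embedded Bogacki-Shampine Runge-Kutta 3(2) pair (relative
tolerance 1e-6, maximum step 5 ms so the cardiac cycle is always resolved)
while the sensed signals are committed to a fixed 10 ms history grid at
every accepted step; delayed values are linearly interpolated from that
grid.  Before the recorded history begins, the initial condition is
extended backwards, giving a reproducible warm-up without a DDE solver.
Everything is deterministic: identical inputs produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SubjectParameters, EnvironmentInput, ParameterError, pack_parameters
from . import model as m
from .model import njit, NSTATE, MODE_NORMAL

__all__ = [
    "SimulationError",
    "SimulationResult",
    "TpssSummary",
    "Simulator",
    "simulate",
    "detect_breaths",
    "detect_heartbeats",
    "tpss_summary",
    "DEFAULT_INITIAL_STATE",
]

HIST_DT = 0.01        # s, history grid for delayed signals
DEFAULT_DT_OUT = 0.02  # s, output stride
DEFAULT_RTOL = 1.0e-6
DEFAULT_H_MAX = 5.0e-3

STATUS_OK = 0
STATUS_PLATEAU = 1
STATUS_STEP_COLLAPSE = 2
STATUS_NONPHYSICAL = 3


class SimulationError(RuntimeError):
    """Integration failure, annotated with time and failing subsystem."""


# Initial conditions of the healthy reference subject near its stationary
# state (frozen; versioned with the default parameter set).  Runs from this
# state show no unsettled slow dynamics after the standard 500 s settling
# window, and normal breathing is established within a few cycles.
DEFAULT_INITIAL_STATE = np.array([
    2.737295,      # v_alveolar, L
    1.042788,      # p_act, mmHg
    0.466137,      # r_p
    0.151521,      # phi_resp (fractional part)
    0.611485,      # phi_cardiac (fractional part)
    0.196779, 0.010237,   # dead space O2/CO2 fractions
    0.131174, 0.060224,   # alveolar fractions
    0.193031, 0.510370,   # pulmonary capillary content, mL/mL
    0.192713, 0.508096,   # arterial
    0.144518, 0.542265,   # systemic venous/tissue
    0.127517, 0.555895,   # cerebral
    0.141896, 0.544310,   # mixed venous
    113.950274, 94.847281,    # V_lv, V_rv, mL
    720.945955, 2897.534590,  # V_sa, V_sv
    133.643727, 449.078174,   # V_pa, V_pv
])


# ---------------------------------------------------------------------------
# compiled integration core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate_core(t0, t_end, y, p, fio2_t, fio2_v, met_scale, p_atm,
                    mode, man, rtol, atol, h_max, v_floor,
                    hist_o2, hist_co2, hist_n, hist_t0,
                    tau_p, tau_c, init_o2, init_co2,
                    out_t, out_y, dt_out,
                    stop_plateau, plateau_eps, plateau_hold):
    """Advance the state from t0 to t_end.  Returns
    (status, t_final, hist_n, n_out, subsystem_code)."""
    t = t0
    n_out = 0
    # store the initial point
    out_t[n_out] = t
    for i in range(NSTATE):
        out_y[n_out, i] = y[i]
    n_out += 1
    next_out = t0 + dt_out

    # fio2 lookup (piecewise constant, few entries: linear scan)
    def _fio2(tt):
        val = fio2_v[0]
        for i in range(fio2_t.shape[0]):
            if tt >= fio2_t[i]:
                val = fio2_v[i]
            else:
                break
        return val

    dy1 = np.zeros(NSTATE)
    dy2 = np.zeros(NSTATE)
    dy3 = np.zeros(NSTATE)
    dy4 = np.zeros(NSTATE)
    y2 = np.zeros(NSTATE)
    y3 = np.zeros(NSTATE)
    ynew = np.zeros(NSTATE)

    so = _sense_o2(hist_o2, hist_n, hist_t0, t - tau_p, init_o2)
    sc = _sense_o2(hist_co2, hist_n, hist_t0, t - tau_c, init_co2)
    q1, _th = m._full_rhs(t, y, p, _fio2(t), met_scale, p_atm,
                          so, sc, mode, man, dy1)
    h = min(h_max, 1.0e-4)
    plateau_since = -1.0

    while t < t_end - 1.0e-12:
        if h > t_end - t:
            h = t_end - t
        # --- stages (Bogacki-Shampine 3(2), FSAL) ---
        th = t + 0.5 * h
        for i in range(NSTATE):
            y2[i] = y[i] + 0.5 * h * dy1[i]
        so = _sense_o2(hist_o2, hist_n, hist_t0, th - tau_p, init_o2)
        sc = _sense_o2(hist_co2, hist_n, hist_t0, th - tau_c, init_co2)
        m._full_rhs(th, y2, p, _fio2(th), met_scale, p_atm, so, sc, mode, man, dy2)

        th = t + 0.75 * h
        for i in range(NSTATE):
            y3[i] = y[i] + 0.75 * h * dy2[i]
        so = _sense_o2(hist_o2, hist_n, hist_t0, th - tau_p, init_o2)
        sc = _sense_o2(hist_co2, hist_n, hist_t0, th - tau_c, init_co2)
        m._full_rhs(th, y3, p, _fio2(th), met_scale, p_atm, so, sc, mode, man, dy3)

        for i in range(NSTATE):
            ynew[i] = y[i] + h * ((2.0 / 9.0) * dy1[i] + (1.0 / 3.0) * dy2[i]
                                  + (4.0 / 9.0) * dy3[i])
        th = t + h
        so = _sense_o2(hist_o2, hist_n, hist_t0, th - tau_p, init_o2)
        sc = _sense_o2(hist_co2, hist_n, hist_t0, th - tau_c, init_co2)
        q4, _ = m._full_rhs(th, ynew, p, _fio2(th), met_scale, p_atm,
                            so, sc, mode, man, dy4)

        # --- embedded error estimate ---
        errnorm = 0.0
        for i in range(NSTATE):
            e = h * ((-5.0 / 72.0) * dy1[i] + (1.0 / 12.0) * dy2[i]
                     + (1.0 / 9.0) * dy3[i] + (-1.0 / 8.0) * dy4[i])
            ay = abs(y[i])
            ayn = abs(ynew[i])
            scale = atol[i] + rtol * (ay if ay > ayn else ayn)
            r = e / scale
            errnorm += r * r
        errnorm = np.sqrt(errnorm / NSTATE)

        if errnorm <= 1.0 or h <= 1.0e-9:
            # accept
            if ynew[m.IS_V_A] < v_floor:
                return STATUS_NONPHYSICAL, t, hist_n, n_out, 1
            for i in range(m.IS_V_LV, m.IS_V_PV + 1):
                if ynew[i] < 0.0:
                    return STATUS_NONPHYSICAL, t, hist_n, n_out, 3
            t_new = t + h
            # commit history grid points in (t, t_new]
            while hist_t0 + hist_n * HIST_DT <= t_new + 1.0e-12:
                tg = hist_t0 + hist_n * HIST_DT
                if tg < t - 1.0e-9:
                    hist_n += 1
                    continue
                w = 0.0 if h <= 0 else (tg - t) / h
                if w < 0.0:
                    w = 0.0
                c_ct = y[m.IS_C_CT_O2] * (1.0 - w) + ynew[m.IS_C_CT_O2] * w
                c_sa = y[m.IS_C_SA_CO2] * (1.0 - w) + ynew[m.IS_C_SA_CO2] * w
                hist_o2[hist_n] = c_ct
                hist_co2[hist_n] = m._co2_pressure(
                    c_sa, p[m.IP_CO2_INTERCEPT], p[m.IP_CO2_SLOPE])
                hist_n += 1
            # store output grid points in (t, t_new]
            while next_out <= t_new + 1.0e-12:
                w = 0.0 if h <= 0 else (next_out - t) / h
                if w > 1.0:
                    w = 1.0
                out_t[n_out] = next_out
                for i in range(NSTATE):
                    out_y[n_out, i] = y[i] * (1.0 - w) + ynew[i] * w
                n_out += 1
                next_out += dt_out
            t = t_new
            for i in range(NSTATE):
                y[i] = ynew[i]
                dy1[i] = dy4[i]          # FSAL
            # plateau detection on the airflow of the accepted point
            if stop_plateau:
                if abs(q4) < plateau_eps:
                    if plateau_since < 0.0:
                        plateau_since = t
                    elif t - plateau_since >= plateau_hold:
                        if out_t[n_out - 1] < t - 1.0e-12:
                            out_t[n_out] = t
                            for i in range(NSTATE):
                                out_y[n_out, i] = y[i]
                            n_out += 1
                        return STATUS_PLATEAU, t, hist_n, n_out, 0
                else:
                    plateau_since = -1.0
        # step-size update
        if errnorm > 0.0:
            fac = 0.9 * errnorm ** (-1.0 / 3.0)
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        else:
            fac = 5.0
        h *= fac
        if h > h_max:
            h = h_max
        if h < 1.0e-10:
            return STATUS_STEP_COLLAPSE, t, hist_n, n_out, 0

    # final point
    if n_out == 0 or out_t[n_out - 1] < t - 1.0e-12:
        out_t[n_out] = t
        for i in range(NSTATE):
            out_y[n_out, i] = y[i]
        n_out += 1
    return STATUS_OK, t, hist_n, n_out, 0


@njit(cache=True)
def _sense_o2(hist, n_filled, t0, t_query, initial):
    return m._delay_lookup(hist, n_filled, t0, HIST_DT, t_query, initial)


_SUBSYSTEM = {0: "none", 1: "ventilation", 3: "circulation"}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class TpssSummary:
    """Arithmetic means over the trailing averaging window of a run."""

    heart_rate: float            # beats/min
    respiratory_rate: float      # breaths/min
    minute_ventilation: float    # L/min (inhaled volume per minute)
    mean_p_pa: float             # mmHg
    mean_arterial_pressure: float  # mmHg
    mean_arterial_flow: float    # mL/s (systemic branch)
    window_s: float

    def to_dict(self) -> dict:
        return {
            "heart_rate": self.heart_rate,
            "respiratory_rate": self.respiratory_rate,
            "minute_ventilation": self.minute_ventilation,
            "mean_p_pa": self.mean_p_pa,
            "mean_arterial_pressure": self.mean_arterial_pressure,
            "mean_arterial_flow": self.mean_arterial_flow,
            "window_s": self.window_s,
        }


@dataclass
class SimulationResult:
    """Dense state trajectory plus lazily derived physiological signals."""

    t: np.ndarray                 # s, strictly increasing
    states: np.ndarray            # (n, NSTATE)
    subject: SubjectParameters
    env: EnvironmentInput
    _derived: dict = field(default_factory=dict, repr=False)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, m.STATE_NAMES.index(name)]

    def __len__(self) -> int:
        return self.t.shape[0]

    def _compute_derived(self) -> None:
        s = self.subject
        c = s.circulation_params
        y = self.states
        v_a = y[:, m.IS_V_A]
        r = np.maximum(s.r_floor,
                       s.r_airway_base + s.alpha * (s.v_ref - v_a))
        x = v_a - s.v_unloaded
        recoil = s.e_total * x + s.stiff_c * np.exp((x - s.stiff_x0) / s.stiff_w)
        p_alv = self.env.p_atm + recoil - (s.p0_mus + y[:, m.IS_P_ACT])
        q = (self.env.p_atm - p_alv) / r
        p_sa = (y[:, m.IS_V_SA] - c.vu_sa) / c.c_sa
        p_sv = (y[:, m.IS_V_SV] - c.vu_sv) / c.c_sv
        p_pa = (y[:, m.IS_V_PA] - c.vu_pa) / c.c_pa
        p_pv = (y[:, m.IS_V_PV] - c.vu_pv) / c.c_pv
        ctrl = s.control_params
        # delayed chemoreceptor inputs reconstructed from the trajectory
        d = s.delays
        c_ct = y[:, m.IS_C_CT_O2]
        p_co2 = np.maximum(0.0, (y[:, m.IS_C_SA_CO2] - s.gas_params.co2_intercept)
                           / s.gas_params.co2_slope)
        t0 = self.t[0]
        sens_o2 = np.interp(self.t - d.peripheral, self.t, c_ct,
                            left=c_ct[0], right=c_ct[-1])
        sens_co2 = np.interp(self.t - d.central, self.t, p_co2,
                             left=p_co2[0], right=p_co2[-1])
        u_o2 = ctrl.g_o2 * (ctrl.set_o2 - sens_o2)
        u_co2 = ctrl.g_co2 * (sens_co2 - ctrl.set_co2)
        u_h = ctrl.w_heart_o2 * u_o2 + ctrl.w_heart_co2 * u_co2
        hp = s.heart_params
        t_heart = np.clip(hp.t0 * (1.0 - ctrl.h1 * u_h - ctrl.h2 * u_h * np.abs(u_h)),
                          hp.t_min, hp.t_max)
        hr = 60.0 / t_heart
        vaso = ctrl.vaso_lo + (ctrl.vaso_hi - ctrl.vaso_lo) / (
            1.0 + np.exp((hr - ctrl.vaso_hr0) / ctrl.vaso_width))
        q_sys = (p_sa - p_sv) / (c.r_systemic * vaso)
        q_cer = (p_sa - p_sv) / c.r_cerebral
        self._derived.update(
            airflow=q, p_alveolar=p_alv, airway_resistance=r,
            p_sa=p_sa, p_sv=p_sv, p_pa=p_pa, p_pv=p_pv,
            q_systemic=q_sys, q_cerebral=q_cer,
            heart_period=t_heart, heart_rate_signal=hr,
            chemical_drive=np.clip(u_o2 + u_co2, ctrl.u_min, ctrl.u_max),
        )

    def derived(self, name: str) -> np.ndarray:
        if not self._derived:
            self._compute_derived()
        return self._derived[name]

    @property
    def airflow(self) -> np.ndarray:
        """Airflow q in L/s, inflow positive."""
        return self.derived("airflow")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, window_s: float) -> "SimulationResult":
        """Trailing sub-result covering the final ``window_s`` seconds."""
        if window_s > self.duration:
            raise ParameterError("window longer than simulated span")
        i0 = int(np.searchsorted(self.t, self.t[-1] - window_s))
        return SimulationResult(self.t[i0:], self.states[i0:], self.subject, self.env)

    def to_frame(self):
        """Time series as a pandas DataFrame (states + derived signals)."""
        import pandas as pd

        data = {"time_s": self.t}
        for i, name in enumerate(m.STATE_NAMES):
            data[name] = self.states[:, i]
        for name in ("airflow", "p_alveolar", "p_sa", "p_pa",
                     "q_systemic", "q_cerebral", "heart_period"):
            data[name] = self.derived(name)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# the simulator session
# ---------------------------------------------------------------------------


class Simulator:
    """Stateful integration session.

    Carries the state vector and the delayed-signal history across
    successive segments, so protocols can switch the environment (hypoxia
    staircase) or the actuator mode (spirometry maneuver) mid-run without
    losing the delay history.
    """

    def __init__(self, subject: SubjectParameters,
                 env: EnvironmentInput | None = None,
                 y0: np.ndarray | None = None,
                 rtol: float = DEFAULT_RTOL,
                 h_max: float = DEFAULT_H_MAX,
                 dt_out: float = DEFAULT_DT_OUT):
        subject.validate()
        self.subject = subject
        self.env = env if env is not None else EnvironmentInput()
        self.env.validate()
        self.p = pack_parameters(subject)
        self.y = np.array(DEFAULT_INITIAL_STATE if y0 is None else y0,
                          dtype=float).copy()
        if self.y.shape != (NSTATE,):
            raise ParameterError(f"initial state must have shape ({NSTATE},)")
        self.t = 0.0
        self.rtol = float(rtol)
        self.h_max = float(h_max)
        self.dt_out = float(dt_out)
        self.atol = self._default_atol()
        # delayed-signal history
        self._hist_cap = 4096
        self._hist_o2 = np.zeros(self._hist_cap)
        self._hist_co2 = np.zeros(self._hist_cap)
        g = subject.gas_params
        self._init_o2 = float(self.y[m.IS_C_CT_O2])
        self._init_co2 = max(0.0, (self.y[m.IS_C_SA_CO2] - g.co2_intercept)
                             / g.co2_slope)
        self._hist_o2[0] = self._init_o2
        self._hist_co2[0] = self._init_co2
        self._hist_n = 1
        self._segments_t: list[np.ndarray] = []
        self._segments_y: list[np.ndarray] = []

    @staticmethod
    def _default_atol() -> np.ndarray:
        atol = np.full(NSTATE, 1.0e-8)
        atol[m.IS_V_LV:m.IS_V_PV + 1] = 1.0e-4   # mL-scale volumes
        atol[m.IS_F_D_O2:m.IS_C_MV_CO2 + 1] = 1.0e-9  # fractions & contents
        return atol

    def _ensure_hist(self, t_end: float) -> None:
        need = int(t_end / HIST_DT) + 8
        if need > self._hist_cap:
            new_cap = max(need, 2 * self._hist_cap)
            for name in ("_hist_o2", "_hist_co2"):
                old = getattr(self, name)
                buf = np.zeros(new_cap)
                buf[: old.shape[0]] = old
                setattr(self, name, buf)
            self._hist_cap = new_cap

    def run(self, duration: float, mode: int = MODE_NORMAL,
            man: np.ndarray | None = None,
            stop_on_plateau: bool = False,
            plateau_eps: float = 0.01, plateau_hold: float = 0.3) -> int:
        """Advance by ``duration`` seconds; returns the integration status."""
        if duration <= 0:
            raise ParameterError("duration must be > 0")
        t_end = self.t + duration
        self._ensure_hist(t_end)
        n_max = int(duration / self.dt_out) + 4
        out_t = np.empty(n_max)
        out_y = np.empty((n_max, NSTATE))
        man_arr = np.zeros(4) if man is None else np.asarray(man, dtype=float)
        fio2_t = np.asarray(self.env.fio2_times, dtype=float)
        fio2_v = np.asarray(self.env.fio2_values, dtype=float)
        v_floor = max(self.subject.v_unloaded, 1.0e-3)
        d = self.subject.delays
        status, t_fin, hist_n, n_out, subsys = _integrate_core(
            self.t, t_end, self.y, self.p, fio2_t, fio2_v,
            self.env.metabolic_scale, self.env.p_atm,
            mode, man_arr, self.rtol, self.atol, self.h_max, v_floor,
            self._hist_o2, self._hist_co2, self._hist_n, 0.0,
            d.peripheral, d.central, self._init_o2, self._init_co2,
            out_t, out_y, self.dt_out,
            stop_on_plateau, plateau_eps, plateau_hold,
        )
        self._hist_n = hist_n
        self.t = t_fin
        self._segments_t.append(out_t[:n_out].copy())
        self._segments_y.append(out_y[:n_out].copy())
        if status == STATUS_STEP_COLLAPSE:
            raise SimulationError(f"step size collapsed at t = {t_fin:.3f} s")
        if status == STATUS_NONPHYSICAL:
            raise SimulationError(
                f"nonphysical state at t = {t_fin:.3f} s "
                f"(subsystem: {_SUBSYSTEM.get(subsys, 'unknown')})")
        return status

    def result(self) -> SimulationResult:
        """Concatenated trajectory over all segments run so far."""
        if not self._segments_t:
            raise SimulationError("no segments have been run")
        ts, ys = [self._segments_t[0]], [self._segments_y[0]]
        for t_seg, y_seg in zip(self._segments_t[1:], self._segments_y[1:]):
            # segment start duplicates the previous segment end
            ts.append(t_seg[1:] if t_seg.shape[0] > 1 else t_seg[:0])
            ys.append(y_seg[1:] if y_seg.shape[0] > 1 else y_seg[:0])
        return SimulationResult(np.concatenate(ts), np.concatenate(ys),
                                self.subject, self.env)


def simulate(subject: SubjectParameters, env: EnvironmentInput | None = None,
             duration_s: float = 700.0, output_stride: float = DEFAULT_DT_OUT,
             y0: np.ndarray | None = None, rtol: float = DEFAULT_RTOL,
             h_max: float = DEFAULT_H_MAX) -> SimulationResult:
    """Simulate the closed-loop model for ``duration_s`` seconds.

    Deterministic: the same inputs give bit-identical trajectories.  The
    default 700 s covers the standard protocol (500 s settling plus a 200 s
    analysis window).
    """
    sim = Simulator(subject, env, y0=y0, rtol=rtol, h_max=h_max,
                    dt_out=output_stride)
    sim.run(duration_s)
    return sim.result()


# ---------------------------------------------------------------------------
# breath / beat extraction
# ---------------------------------------------------------------------------


@dataclass
class Breath:
    start: float
    end: float
    inhaled_volume: float   # L
    exhaled_volume: float   # L


def detect_breaths(result: SimulationResult, hysteresis: float = 0.01):
    """Delimit breaths at negative-to-positive airflow zero crossings.

    A crossing only counts after the flow has been below ``-hysteresis``
    and once it exceeds ``+hysteresis`` (robust to numerical ripple around
    zero).  Per-breath volumes are the signed integrals of the airflow.
    Returns a possibly empty list of :class:`Breath`.
    """
    t = result.t
    q = result.airflow
    armed = False
    starts = []
    last_neg = 0
    for i in range(q.shape[0]):
        if q[i] < -hysteresis:
            armed = True
            last_neg = i
        elif armed and q[i] > hysteresis:
            # linear interpolation of the upward zero crossing
            j = i
            while j > last_neg and q[j - 1] > 0.0:
                j -= 1
            if j > 0:
                tz = t[j - 1] + (t[j] - t[j - 1]) * (0.0 - q[j - 1]) / (q[j] - q[j - 1])
            else:
                tz = t[j]
            starts.append(tz)
            armed = False
    if len(starts) < 2:
        return []
    breaths = []
    for a, b in zip(starts[:-1], starts[1:]):
        mask = (t >= a) & (t <= b)
        tt, qq = t[mask], q[mask]
        if tt.shape[0] < 3:
            continue
        inhaled = float(np.trapezoid(np.maximum(qq, 0.0), tt))
        exhaled = float(-np.trapezoid(np.minimum(qq, 0.0), tt))
        breaths.append(Breath(float(a), float(b), inhaled, exhaled))
    return breaths


def detect_heartbeats(result: SimulationResult):
    """Beat times (cardiac-phase wrap events) and instantaneous heart rate.

    Returns ``(beat_times, hr)`` with ``hr[i] = 60 / (beat_times[i+1] -
    beat_times[i])`` in beats/min.
    """
    t = result.t
    phi = result.state("phi_cardiac")
    n0 = int(np.floor(phi[0]))
    beats = []
    k = n0 + 1
    for i in range(1, phi.shape[0]):
        while phi[i] >= k:
            # linear interpolation of the integer crossing
            tz = t[i - 1] + (t[i] - t[i - 1]) * (k - phi[i - 1]) / (phi[i] - phi[i - 1])
            beats.append(tz)
            k += 1
    beats = np.asarray(beats)
    if beats.shape[0] < 2:
        return beats, np.empty(0)
    hr = 60.0 / np.diff(beats)
    return beats, hr


def tpss_summary(result: SimulationResult, window_s: float = 200.0) -> TpssSummary:
    """Summary of the time-periodic stationary state.

    Arithmetic means over the trailing ``window_s`` seconds: heart rate from
    detected beats, respiratory rate from breath delimitation, minute
    ventilation as total inhaled volume per minute, plus mean pulmonary and
    systemic arterial pressures and the mean systemic arterial flow.
    """
    w = result.window(window_s)
    beats, hr = detect_heartbeats(w)
    if beats.shape[0] >= 2:
        heart_rate = 60.0 * (beats.shape[0] - 1) / (beats[-1] - beats[0])
    else:
        raise SimulationError("averaging window contains fewer than 2 beats")
    breaths = detect_breaths(w)
    if len(breaths) >= 1:
        span = breaths[-1].end - breaths[0].start
        resp_rate = 60.0 * len(breaths) / span
        minute_vent = sum(b.inhaled_volume for b in breaths) / (span / 60.0)
    else:
        resp_rate = 0.0
        minute_vent = 0.0
    return TpssSummary(
        heart_rate=float(heart_rate),
        respiratory_rate=float(resp_rate),
        minute_ventilation=float(minute_vent),
        mean_p_pa=float(np.mean(w.derived("p_pa"))),
        mean_arterial_pressure=float(np.mean(w.derived("p_sa"))),
        mean_arterial_flow=float(np.mean(w.derived("q_systemic"))),
        window_s=float(window_s),
    )
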