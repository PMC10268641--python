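"""In-silico experimental protocols.

* :func:`run_spirometry` -- deep-inhalation / forced-expiration maneuver
  with FVC, FEV1 ratio, PEFR, TLC and FRC extraction,
* :func:`run_hypoxia_staircase` -- stepwise reduction of inspired O2,
* :func:`apply_copd` -- parameter adaptation for the three COPD
  manifestations (small-airways disease, emphysema, pulmonary
  hypertension),
* calibration routines that invert the forward model to recover the
  disease-severity parameters from their diagnostic criteria.

The spirometry maneuver replaces the controller output at the actuator
input with a prescribed two-phase drive: a deep-inhalation target held
until the lung volume plateaus (total lung capacity), then a forced
expiratory drive for a fixed 6 s window.  The drive amplitudes are fixed
constants of the default configuration, anchored once so the healthy
subject produces a forced vital capacity of 4 L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SubjectParameters, EnvironmentInput, ParameterError
from . import model as m
from .simulate import (
    simulate,
    Simulator,
    SimulationResult,
    SimulationError,
    tpss_summary,
    STATUS_PLATEAU,
)

__all__ = [
    "SpirometryReport",
    "SpirometryManeuver",
    "CopdFlags",
    "ManeuverError",
    "CalibrationError",
    "run_spirometry",
    "extract_spirometry",
    "run_hypoxia_staircase",
    "apply_copd",
    "calibrate_airway",
    "calibrate_emphysema",
    "calibrate_pulmonary",
    "COPD_ALPHA",
    "COPD_V_UNLOADED",
    "COPD_E_TOTAL",
    "COPD_R_PA",
]

# Table of COPD parameter adaptations (disease-state values; healthy values
# are the subject defaults).
COPD_ALPHA = 0.205        # mmHg·s/L², small-airways severity
COPD_V_UNLOADED = 1.05    # L, emphysematous unloaded lung volume
COPD_E_TOTAL = 2.75       # mmHg/L, hyperinflated chest elastance
COPD_R_PA = 0.370         # mmHg·s/mL, pulmonary-hypertensive resistance


class ManeuverError(SimulationError):
    """Spirometry maneuver failed (e.g. no inhalation plateau)."""


class CalibrationError(RuntimeError):
    """A severity-parameter calibration failed to converge or bracket."""


@dataclass
class CopdFlags:
    """Which COPD manifestations are switched on for a virtual subject."""

    small_airways: bool = False
    emphysema: bool = False
    pulmonary_hypertension: bool = False

    def label(self) -> str:
        parts = []
        if self.small_airways:
            parts.append("SA")
        if self.emphysema:
            parts.append("E")
        if self.pulmonary_hypertension:
            parts.append("PH")
        return "+".join(parts) if parts else "healthy"


def apply_copd(subject: SubjectParameters, flags: CopdFlags) -> SubjectParameters:
    """Copy of ``subject`` with the enabled COPD adaptations applied.

    small_airways sets the airway severity coefficient alpha; emphysema
    raises the unloaded lung volume and chest elastance; pulmonary
    hypertension raises the pulmonary arterial resistance.  Disabled flags
    leave the healthy values untouched.
    """
    out = subject.copy()
    if flags.small_airways:
        out.alpha = COPD_ALPHA
    if flags.emphysema:
        out.v_unloaded = COPD_V_UNLOADED
        out.e_total = COPD_E_TOTAL
    if flags.pulmonary_hypertension:
        out.r_pa = COPD_R_PA
    return out


# ---------------------------------------------------------------------------
# spirometry
# ---------------------------------------------------------------------------


@dataclass
class SpirometryManeuver:
    """Fixed drive constants of the virtual spirometry maneuver.

    The inhalation target is the static muscle pressure (above resting
    tone) that inflates the healthy lung to its 5 L total capacity; the
    expiratory target empties it to a 1 L residual volume so that the
    healthy forced vital capacity is 4 L.
    """

    settle_s: float = 50.5       # normal breathing before the maneuver
    insp_target: float = 6.7461  # mmHg above resting tone
    tau_insp: float = 0.8        # s, inhalation drive time constant
    max_inhale_s: float = 10.0   # plateau must be reached within this
    exp_target: float = -3.825   # mmHg (partial release of the tone)
    tau_exp: float = 0.079        # s, expiratory drive time constant
    exhale_s: float = 6.0        # forced-expiration window
    plateau_eps: float = 0.01    # L/s, |q| threshold for the TLC plateau
    plateau_hold: float = 0.3    # s the flow must stay inside the band


@dataclass
class SpirometryReport:
    """Outcome of the forced expiratory maneuver."""

    fvc: float           # L, total expired volume
    fev1_ratio: float    # volume expired in the first second / FVC
    pefr: float          # L/s, peak expiratory flow rate
    tlc: float           # L, volume at the end of the deep inhalation
    frc: float           # L, lowermost point of normal breathing cycles
    t1: float            # s, start of deep inhalation
    t2: float            # s, start of forced expiration
    expired_volume: np.ndarray   # L, cumulative from t2
    expiratory_flow: np.ndarray  # L/s, -q aligned with expired_volume

    def validate(self) -> None:
        ok = (0.0 < self.fev1_ratio <= 1.0 and self.pefr > 0
              and self.tlc > self.frc > 0 and self.fvc <= self.tlc)
        if not ok:
            raise ParameterError("inconsistent spirometry report")


def extract_spirometry(t: np.ndarray, q: np.ndarray, t2: float,
                       tlc: float, frc: float, t1: float = 0.0) -> SpirometryReport:
    """Build a SpirometryReport from an expiratory flow record.

    ``t``/``q`` must cover the forced expiration starting at ``t2``; the
    expired volume is the running integral of ``-q`` from ``t2``.  Pure
    function, independent of the simulator (unit-tested against closed-form
    flow profiles).
    """
    mask = t >= t2
    te = t[mask]
    qe = q[mask]
    if te.shape[0] < 3:
        raise ParameterError("expiration record too short")
    ve = np.concatenate([[0.0], np.cumsum(np.diff(te) * 0.5 * (-qe[1:] - qe[:-1]))])
    fvc = float(ve[-1])
    if fvc <= 0:
        raise ParameterError("no expired volume")
    fev1 = float(np.interp(t2 + 1.0, te, ve))
    pefr = float(np.max(-qe))
    report = SpirometryReport(
        fvc=fvc, fev1_ratio=fev1 / fvc, pefr=pefr, tlc=tlc, frc=frc,
        t1=t1, t2=t2, expired_volume=ve, expiratory_flow=-qe,
    )
    report.validate()
    return report


def _maneuver_airflow(result: SimulationResult, subject: SubjectParameters,
                      t2: float) -> np.ndarray:
    """Airflow trace with the forced-expiration flow limit applied.

    During the forced maneuver the expiratory flow is bounded by the
    effort-independent maximum ``kappa * recoil / R_upstream`` (dynamic
    airway compression), mirroring the integration kernel; the
    pressure-driven flow of the normal-breathing segments is returned
    unchanged.
    """
    q = result.airflow.copy()
    v_a = result.state("v_alveolar")
    x = v_a - subject.v_unloaded
    recoil = subject.e_total * x + subject.stiff_c * np.exp(
        (x - subject.stiff_x0) / subject.stiff_w)
    r_up = np.maximum(subject.r_floor,
                      subject.flow_limit_beta * subject.r_airway_base
                      + subject.alpha * (subject.v_ref - v_a))
    q_env = subject.flow_limit_kappa * np.maximum(recoil, 0.0) / r_up
    mask = result.t >= t2
    q[mask] = np.maximum(q[mask], -q_env[mask])
    return q


def run_spirometry(subject: SubjectParameters,
                   env: EnvironmentInput | None = None,
                   maneuver: SpirometryManeuver | None = None,
                   return_result: bool = False):
    """Virtual spirometry test.

    Simulates settled normal breathing, then overrides the controller
    output with the deep-inhalation drive until the lung volume plateaus
    (TLC), then switches to the forced-expiration drive.  FRC is the
    lowermost lung volume of the pre-maneuver breathing cycles.
    """
    man = maneuver or SpirometryManeuver()
    sim = Simulator(subject, env, dt_out=0.005)
    sim.run(man.settle_s)
    t1 = sim.t
    man_arr = np.array([man.insp_target, man.tau_insp,
                        man.exp_target, man.tau_exp])
    status = sim.run(man.max_inhale_s, mode=m.MODE_INSPIRE, man=man_arr,
                     stop_on_plateau=True, plateau_eps=man.plateau_eps,
                     plateau_hold=man.plateau_hold)
    if status != STATUS_PLATEAU:
        raise ManeuverError(
            f"no inhalation plateau within {man.max_inhale_s:.1f} s")
    t2 = sim.t
    sim.run(man.exhale_s, mode=m.MODE_EXPIRE, man=man_arr)
    result = sim.result()

    v_a = result.state("v_alveolar")
    tlc = float(np.max(v_a))
    # FRC: lowermost point of the last pre-maneuver breathing cycles
    pre = (result.t >= max(0.0, t1 - 12.0)) & (result.t <= t1)
    frc = float(np.min(v_a[pre]))
    q = _maneuver_airflow(result, subject, t2)
    report = extract_spirometry(result.t, q, t2, tlc, frc, t1)
    if return_result:
        return report, result
    return report


# ---------------------------------------------------------------------------
# hypoxia staircase
# ---------------------------------------------------------------------------


def run_hypoxia_staircase(subject: SubjectParameters, levels,
                          dwell_s: float = 300.0, window_s: float = 200.0,
                          metabolic_scale: float = 1.0):
    """Stepwise reduction of the inspired O2 fraction.

    ``levels`` must be non-increasing within (0, 0.21].  Each level is held
    for ``dwell_s`` seconds (state carried across steps); the summary of
    each level is taken over the trailing ``window_s`` seconds of its
    dwell.  Returns a list of :class:`TpssSummary`, one per level.
    """
    levels = [float(v) for v in levels]
    if not levels:
        raise ParameterError("levels must be non-empty")
    if any(not (0.0 < v <= 0.21) for v in levels):
        raise ParameterError("levels must lie in (0, 0.21]")
    if any(b > a for a, b in zip(levels, levels[1:])):
        raise ParameterError("levels must be non-increasing")
    if dwell_s < 300.0:
        raise ParameterError("dwell_s must be >= 300 s")
    if window_s >= dwell_s:
        raise ParameterError("window_s must be shorter than dwell_s")
    times = [i * dwell_s for i in range(len(levels))]
    env = EnvironmentInput(fio2_times=tuple(times), fio2_values=tuple(levels),
                           metabolic_scale=metabolic_scale)
    env.validate()
    sim = Simulator(subject, env)
    for level in levels:
        try:
            sim.run(dwell_s)
        except SimulationError as exc:
            raise SimulationError(
                f"integration failed at inspired O2 level {level:.3f}: {exc}"
            ) from exc
    # summary i over the trailing window of level i's dwell
    out = []
    full = sim.result()
    for i, level in enumerate(levels):
        t_hi = times[i] + dwell_s
        mask = (full.t >= t_hi - window_s - 1e-9) & (full.t <= t_hi + 1e-9)
        seg = SimulationResult(full.t[mask], full.states[mask],
                               full.subject, full.env)
        out.append(tpss_summary(seg, window_s=seg.duration - 1e-9))
    return out


# ---------------------------------------------------------------------------
# calibration of disease-severity parameters
# ---------------------------------------------------------------------------


def calibrate_airway(subject: SubjectParameters, target_fev1_ratio: float,
                     alpha_hi: float = 2.0, tol: float = 1.0e-3,
                     max_iter: int = 60) -> float:
    """Airway-severity coefficient alpha at which the spirometry FEV1
    ratio equals ``target_fev1_ratio`` (bisection on alpha).

    The FEV1 ratio decreases monotonically in alpha, so a simple bisection
    on [0, alpha_hi] converges; tolerance is on the FEV1 ratio.
    """
    if not (0.0 < target_fev1_ratio < 1.0):
        raise CalibrationError("target FEV1 ratio must lie in (0, 1)")

    def f(alpha: float) -> float:
        s = subject.copy()
        s.alpha = alpha
        return run_spirometry(s).fev1_ratio - target_fev1_ratio

    f_lo = f(0.0)
    if f_lo < 0:
        raise CalibrationError(
            "healthy FEV1 ratio already below the target; nothing to calibrate")
    f_hi = f(alpha_hi)
    if f_hi > 0:
        raise CalibrationError(
            f"target FEV1 ratio not bracketed for alpha in [0, {alpha_hi}]")
    lo, hi = 0.0, alpha_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if fm > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1.0e-4:
            return 0.5 * (lo + hi)
    return 0.5 * (lo + hi)


def calibrate_emphysema(subject: SubjectParameters, delta_frc_L: float,
                        delta_tlc_L: float, tol_L: float = 0.010,
                        max_iter: int = 100):
    """Unloaded lung volume and chest elastance reproducing given
    increases of FRC and TLC over the healthy subject.

    Damped Newton iteration on the residual vector (ΔFRC - target,
    ΔTLC - target) with a finite-difference Jacobian, re-simulating the
    spirometry maneuver from identical initial conditions at every
    evaluation (deterministic, smooth objective).  Tolerance 10 mL.
    """
    if delta_frc_L < 0 or delta_tlc_L < 0:
        raise CalibrationError("volume deltas must be >= 0")
    base = run_spirometry(subject)
    frc0, tlc0 = base.frc, base.tlc

    def resid(v0: float, et: float) -> np.ndarray:
        s = subject.copy()
        s.v_unloaded = max(v0, 0.0)
        s.e_total = et
        rep = run_spirometry(s)
        return np.array([rep.frc - frc0 - delta_frc_L,
                         rep.tlc - tlc0 - delta_tlc_L])

    x = np.array([subject.v_unloaded + delta_frc_L * 0.9,
                  subject.e_total + 0.1])
    if delta_frc_L == 0 and delta_tlc_L == 0:
        x = np.array([subject.v_unloaded, subject.e_total])
    r = resid(*x)
    step_fd = np.array([0.02, 0.02])
    for it in range(max_iter):
        if np.max(np.abs(r)) < tol_L:
            return float(x[0]), float(x[1])
        jac = np.empty((2, 2))
        for j in range(2):
            xp = x.copy()
            xp[j] += step_fd[j]
            jac[:, j] = (resid(*xp) - r) / step_fd[j]
        try:
            dx = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError as exc:
            raise CalibrationError(f"singular Jacobian: {exc}") from exc
        # damping: halve until the residual norm decreases
        lam = 1.0
        for _ in range(6):
            xn = x + lam * dx
            if xn[1] <= 0.5:       # elastance must stay physical
                lam *= 0.5
                continue
            rn = resid(*xn)
            if np.linalg.norm(rn) < np.linalg.norm(r):
                break
            lam *= 0.5
        else:
            xn = x + lam * dx
            rn = resid(*xn)
        x, r = xn, rn
    raise CalibrationError(
        f"no convergence in {max_iter} iterations; residuals {r} L")


def calibrate_pulmonary(subject: SubjectParameters, target_mean_ppa: float,
                        r_hi: float = 0.8, tol_mmHg: float = 0.1,
                        duration_s: float = 110.0, window_s: float = 10.0) -> float:
    """Pulmonary arterial resistance giving a target mean pulmonary artery
    pressure.

    Protocol: breathe normal air at resting metabolic rate for 110 s and
    average the pulmonary artery pressure over the last 10 s; root-find on
    the resistance (bisection with secant acceleration via brentq).
    """
    from scipy.optimize import brentq

    def mean_ppa(r_pa: float) -> float:
        s = subject.copy()
        s.r_pa = r_pa
        res = simulate(s, duration_s=duration_s)
        w = res.window(window_s)
        return float(np.mean(w.derived("p_pa")))

    lo = subject.r_pa
    f_lo = mean_ppa(lo) - target_mean_ppa
    if f_lo >= 0:
        raise CalibrationError(
            "target mean P_pa must exceed the baseline value")
    f_hi = mean_ppa(r_hi) - target_mean_ppa
    if f_hi <= 0:
        raise CalibrationError(
            f"target mean P_pa not bracketed for r_pa in [{lo}, {r_hi}]")
    root = brentq(lambda r: mean_ppa(r) - target_mean_ppa, lo, r_hi,
                  xtol=1e-4, rtol=1e-6)
    # tolerance check on the pressure itself
    if abs(mean_ppa(root) - target_mean_ppa) > tol_mmHg:
        raise CalibrationError("root found but pressure tolerance not met")
    return float(root)
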