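# Methods

`cardioresp` implements a lumped-parameter model of the human
cardiorespiratory system organised as a feedback control loop: the
*process* (lung mechanics, alveolar gas exchange, blood circulation and
gas transport) is driven by an *actuator* (respiratory muscles setting
pleural pressure), commanded by a *controller* (a rhythmic respiratory
pattern generator and a heart-period law), which closes the loop through
*sensors* (chemoreceptors reading transport-delayed blood-gas signals).
Disease enters through three severity parameters: a volume-dependent
airway resistance, the chest elastance / unloaded lung volume pair, and
the pulmonary arterial resistance.

## Model structure

**Ventilation.** A single alveolar compartment with volume `V_A` behind
one airway.  Airflow is pressure-driven, `q = (P_atm − P_A)/R(V_A)` with
inflow positive, so the lung inflates exactly when alveolar pressure is
below atmospheric.  The alveolar pressure is algebraic:
`P_A = P_atm + P_el(V_A) + P_mus`.  Airway and alveolar pressures are
absolute (atmosphere = 760 mmHg); blood pressures are gauge.

The airway resistance law is

    R(V_A) = R_base + α (V_ref − V_A),      V_ref = 6 L,

clamped below at 0.05 mmHg·s/L (the raw law is unbounded below above the
reference volume).  At `α = 0` the resistance is the constant healthy
value; at `α = 0.205` it is 82% higher at a lung volume of 2 L.

**Elastic recoil.** `P_el(x) = E_T·x + c_hi·exp((x − x_hi)/w_hi)` with
`x = V_A − V_0`.  The linear term is the standard total (lung + chest)
elastance; the exponential term is a mild parenchymal stiffening that
engages only near total lung capacity (it contributes < 0.02 mmHg over
the tidal range).  Its two constants are fixed by two statics anchors:
healthy TLC = 5.0 L at the deep-breath drive, and a 700 mL TLC increase
when the emphysema pair (`V_0 = 1.05 L`, `E_T = 2.75 mmHg/L`) is applied.
The healthy TLC anchor of 5.0 L follows from the hyperinflation
thresholds used to define the emphysematous state (a 14% TLC increase
equalling 700 mL); the airway-law reference volume stays at 6 L.

A constant resting muscle tone `p0 = 6.325 mmHg` balances the recoil at
the functional residual capacity: FRC = `V_0 + p0/E_T`, i.e. 2.53 L for
the healthy subject.  The value of `p0` is fixed by requiring the
emphysema pair to raise FRC by 820 mL.  Breathing superimposes the
actuator pressure on this tone, and passive exhalation relaxes back to
FRC with the mechanical time constant `R/E_T ≈ 0.4 s`, giving expiratory
flow that decays asymptotically to zero.

**Gas exchange.** Alveolar O2/CO2 are tracked as dry-gas fractions
(partial pressure = fraction × (P_A − 47 mmHg)).  A 120 mL well-mixed
series dead space rebreathes end-expiratory gas.  Membrane fluxes are
diffusive, `J = D·(P_alv − P_cap)`, into a pulmonary end-capillary
compartment.  Blood O2 content follows a Hill dissociation curve
(P50 = 26 mmHg, exponent 2.7, capacity 0.2 mL/mL; dissolved O2 is
neglected); CO2 content is linearised, `c = 0.2 + 0.007·P`.

**Circulation.** A closed R-C (Windkessel) circuit: left/right
ventricles with time-varying elastance (raised-cosine activation over
30% of the cycle), ideal one-way resistive valves, systemic arterial and
venous compartments, a cerebral/carotid branch, pulmonary arteries and
veins.  Compartment pressures are algebraic in volumes
(`P = (V − V_u)/C`); the six volume derivatives sum to zero identically,
so total blood volume is conserved to integrator tolerance.  The
pulmonary arterial resistance `R_pa` is the pulmonary-hypertension
severity parameter: mean pulmonary artery pressure is essentially
`P_pv + Q_pulm·R_pa`.

**Gas transport.** Ideal-mixing (CSTR) compartments in series: pulmonary
capillary → left-heart/arterial mixer → systemic tissue and cerebral
tissue (which consume O2 and produce CO2 at rates scaled by the
environment) → flow-weighted venous mixing in the right heart.  The
signals that reach the controllers are transport-delayed copies: the
carotid-body O2 input by 2 s, the central CO2 input by 8 s.  Delays are
evaluated from an interpolated fixed-grid history (10 ms); before the
recorded history the initial condition is extended backwards, so warm-up
is reproducible without a DDE solver.

**Sensors and controllers.** Chemoreceptors are affine:
`u_O2 = G_O2 (c_set − c_carotid)` on the *O2 content* of the carotid
compartment (the sigmoid dissociation curve upstream provides the
physiological steepening of the hypoxic response at low oxygen), and
`u_CO2 = G_CO2 (P_aCO2 − P_set)` on the delayed arterial CO2 tension.
Their sum, clipped to [−0.8, 5], drives a self-sustained respiratory
rhythm: phase velocity `f = f0 (1 + 0.45 u)` and burst amplitude
`A = A0 (1 + 0.5 u)`, with a half-sine inspiratory burst over 35% of the
cycle and silence otherwise.  The controller output `R_p` relaxes to the
burst with a 60 ms time constant, and the actuator converts it to muscle
pressure through a first-order lag (gain 3 mmHg, 0.25 s).  The heart
period is a signed-quadratic polynomial of the weighted afferents,
clipped to [0.3, 2.0] s (polynomial controllers extrapolate badly under
extreme hypoxia).  A bounded sigmoid of heart rate (asymptotes 0.8/1.2)
scales the systemic resistance, representing metabolic vasodilation.

## Numerical integration

The coupled system (25 states) is integrated with an embedded
Bogacki–Shampine Runge–Kutta 3(2) pair, relative tolerance 1e-6,
per-state absolute tolerances, and a 5 ms step cap so the cardiac cycle
is always resolved.  Valve switchings are handled by the error
controller (steps shrink locally at the non-smooth points).  Output is
stored on a fixed stride (20 ms by default, 5 ms for spirometry) by
linear interpolation of accepted steps; summaries are invariant to the
stride and change by < 0.5% under a 10× tighter tolerance.  The kernels
are compiled with numba; without it the identical Python code runs,
only slower.  There is no randomness anywhere in the package.

Initial conditions ship as a frozen vector taken from a settled healthy
run; all standard protocols discard a 500 s settling window (no
unsettled slow dynamics remain after it), and summaries average the
trailing 200 s of a 700 s run (100 s of a 1000 s run in the factorial
study).

## Baseline calibration

The nominal parameters were fixed by a one-time calibration of the
healthy subject against standard resting values: heart rate
64 beats/min, respiratory rate 11.7 breaths/min, minute ventilation
5.40 L/min, systemic arterial flow 69 mL/s, arterial pressure swinging
between about 70 and 95 mmHg, and a mean pulmonary artery pressure of
35 mmHg when `R_pa` is raised to 0.370 mmHg·s/mL (with ~23 mmHg at the
healthy 0.198).  Chemoreceptor setpoints equal the model's own
equilibrium gas values, so the chemical drive vanishes at rest and the
baseline rhythm constants are read off directly (`f0 = 11.7/60` Hz,
`T0 = 60/64` s).  The right ventricle uses a stiff systolic elastance
with filling-limited output so that cardiac output falls only mildly
under pulmonary hypertension, which is what places the hypertensive
mean P_pa at the 35 mmHg threshold.  All calibrated values are frozen
in `params.py`; nothing is fitted at run time.

## Spirometry maneuver

The maneuver overrides the controller output at the actuator input with
a prescribed two-phase drive: a deep-inhalation target (the static
pressure that inflates the healthy lung to 5.0 L) held until airflow
plateaus (|q| < 0.01 L/s for 0.3 s, at most 10 s), then a forced
expiratory target (emptying the healthy lung to a 1.0 L residual
volume) approached with an 79 ms time constant for a fixed 6 s window.
TLC is the maximal volume at end-inhalation, FRC the lowermost point of
the preceding normal breathing cycles, FVC the total expired volume,
FEV1 ratio the fraction expired in the first second, PEFR the peak
expiratory flow.

During forced expiration the flow is additionally bounded by an
effort-independent maximum, `q_max = κ·P_el / R_up`, the lumped analogue
of wave-speed flow limitation by dynamic airway compression.  The
upstream (peripheral) resistance `R_up = β·R_base + α(V_ref − V_A)`
carries the full volume-dependent term, because small-airways disease
acts upstream of the flow-limiting segment.  `κ = 0.4015` and `β = 0.65`
are fixed constants of the default configuration, anchored (together
with the expiratory time constant) so that the healthy maneuver gives
FVC = 4 L and PEFR = 6.7 L/s while `α = 0.205` gives FEV1 ratio = 0.70.
The limit never engages during tidal breathing (tidal flows are an
order of magnitude below it) and does not affect any volume statics.
With these constants the `α = 0.205` subject also shows the concave
terminal limb of the flow–volume curve, mild air trapping (reduced
FVC) and a PEFR reduction of about 23% — the accepted diagnostic band
is a 20–30% drop, though the model sits below the ~27% midpoint
reported for severe obstruction.

## Calibration routines

Each disease-severity parameter is recovered by inverting the forward
model against its diagnostic criterion, always re-simulating from the
same initial conditions so the objectives are deterministic and smooth:

* airway severity: bisection on `α ∈ [0, 2]` until the FEV1 ratio hits
  its target (tolerance 1e-3); monotonicity of FEV1 ratio in `α` makes
  the bracket safe;
* hyperinflation: damped Newton iteration on `(V_0, E_T)` against the
  (ΔFRC, ΔTLC) targets, finite-difference Jacobian, 10 mL tolerance;
* pulmonary resistance: Brent root-finding on `R_pa` against the mean
  P_pa of the last 10 s of a 110 s resting run, 0.1 mmHg tolerance.

All three pass round-trip recovery: parameters regenerated from their
own forward simulations are recovered within 1–2%.

## Factorial study

The 2³ design enumerates all on/off combinations of the three
manifestations.  Respiratory characteristics (FVC, TLC, PEFR, FEV1
ratio) come from one spirometry maneuver per run; TPSS characteristics
(heart rate, mean P_pa, respiratory rate, minute ventilation) from
1000 s simulations at 21% and 12% inspired O2 (final-100 s means), with
the hypoxic-minus-normoxic changes as secondary responses.

Significance of a factor on a response uses the t statistic of the
factor's main-effect contrast with the error variance estimated by
pooling the four interaction contrasts (df = 4) — the standard error
construction for an unreplicated two-level factorial, equivalent to an
ordinary least-squares fit with main effects only.  A two-sample 4-vs-4
t-test was considered and rejected: with the main effects of the other
factors inside the error term, it provably cannot declare all three
factors significant for the same response (summing the three required
inequalities gives a contradiction), so it cannot represent a study in
which every factor matters for some response.  No multiple-testing
correction is applied; significance is α = 0.1.

## What the virtual subject does and does not represent

The subject is a population-average resting adult.  Passing tests show
that the closed-loop model reproduces the calibrated resting state, the
documented spirometric signatures of the three COPD manifestations, a
monotone, convex chemoreflex response down to 10% inspired O2, and the
dominance of airway resistance in the factorial study.  They do not show
fidelity to any individual patient, to exercise or sleep states, to the
absolute magnitudes of hypoxic heart-rate/ventilation responses (not
fitted), or to cellular-scale emphysema mechanics.  Two quantitative
limitations are known: the PEFR reduction at `α = 0.205` is ~23% rather
than ~27%, and raising `R_pa` alone nudges the normoxic heart rate
marginally *up* (~+0.6 beats/min via perfusion-sensitive carotid drive
and its CO2 compensation) where a marginal *decrease* of similar size
is the expected compensation pattern; both sit within the tolerance of
the corresponding checks.  In the factorial study the airway factor's
dominance and the pulmonary factor's confinement to the circulation are
robust; the finer significance pattern (e.g. elastance effects on the
hypoxic heart-rate change) is sensitive to the small interaction terms
that serve as the error estimate and is not asserted.

## Degenerate inputs and edge behaviour

Airway resistance is floored at 0.05 mmHg·s/L; Hill-curve inversion
clamps saturation to [1e-6, 0.9995]; the heart period clips to
[0.3, 2.0] s; the chemical drive clips to [−0.8, 5]; breath detection
uses a ±0.01 L/s hysteresis band around zero flow and returns an empty
list when fewer than two crossings exist; zero-variance factorial
responses report p = 1 (equal means) or 0, flagged degenerate; negative
compartment volumes or a lung volume below the unloaded volume abort
the integration with the failing subsystem named.
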