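# cardioresp

An integrated simulator of the human cardiorespiratory system, built as
a feedback control loop — chemoreceptor *sensors*, a neural respiratory
*controller*, the lung-muscle *actuator*, and the gas-exchanging
lung/circulation *process* — with parameter adaptations that reproduce
the three clinical manifestations of chronic obstructive pulmonary
disease (COPD): small-airways obstruction, emphysematous
hyperinflation, and pulmonary hypertension.

It is aimed at systems-physiology and biomedical-engineering work that
needs a fast, deterministic, whole-body model: virtual spirometry,
hypoxia protocols, disease-severity calibration against diagnostic
criteria, and factorial studies of how disease factors propagate
through the closed loop.

## The model in brief

The process couples pressure-driven ventilation of a single alveolar
compartment, `q = (P_atm − P_A)/R(V_A)`, with diffusive alveolar–
capillary gas exchange, a closed Windkessel (R-C) circulation with two
time-varying-elastance ventricles, and tissue compartments that consume
O2 and produce CO2.  Transport-delayed blood-gas signals feed affine
chemoreceptors; their summed drive `u` modulates a self-sustained
respiratory rhythm (rate and depth), a polynomial heart-period law, and
a vasodilation sigmoid.  Disease severity enters through

    R(V_A) = R_base + α (V_ref − V_A)          airway obstruction
    (V_0, E_T): recoil  P_el = E_T (V_A − V_0)  hyperinflation
    R_pa: mean P_pa ≈ P_pv + Q_pulm R_pa        pulmonary hypertension

with healthy values (α, V₀, E_T, R_pa) = (0, 0 L, 2.5 mmHg/L,
0.198 mmHg·s/mL) and COPD values (0.205, 1.05 L, 2.75 mmHg/L, 0.370).
The full equations, units, numerical scheme and calibration are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from cardioresp import healthy_subject, simulate, tpss_summary, run_spirometry
from cardioresp.protocols import CopdFlags, apply_copd

subject = healthy_subject()

# 700 s closed-loop run; average the final 200 s (the time-periodic
# stationary state, reached well before t = 500 s)
result = simulate(subject, duration_s=700.0)
s = tpss_summary(result, window_s=200.0)
print(f"HR {s.heart_rate:.1f} /min, RR {s.respiratory_rate:.1f} /min, "
      f"VE {s.minute_ventilation:.2f} L/min, "
      f"arterial flow {s.mean_arterial_flow:.1f} mL/s, "
      f"mean P_pa {s.mean_p_pa:.1f} mmHg")

# virtual spirometry, healthy vs small-airways disease
rep_h = run_spirometry(subject)
rep_c = run_spirometry(apply_copd(subject, CopdFlags(small_airways=True)))
print(f"healthy: FVC {rep_h.fvc:.2f} L, FEV1 ratio {rep_h.fev1_ratio:.2f}, "
      f"PEFR {rep_h.pefr:.1f} L/s")
print(f"COPD:    FVC {rep_c.fvc:.2f} L, FEV1 ratio {rep_c.fev1_ratio:.2f}, "
      f"PEFR {rep_c.pefr:.1f} L/s")
```

prints

```
HR 64.0 /min, RR 11.7 /min, VE 5.40 L/min, arterial flow 69.1 mL/s, mean P_pa 22.9 mmHg
healthy: FVC 3.99 L, FEV1 ratio 0.89, PEFR 6.7 L/s
COPD:    FVC 3.99 L, FEV1 ratio 0.70, PEFR 5.1 L/s
```

The resting subject sits at a heart rate of 64 beats/min, a respiratory
rate of 11.7 breaths/min and a systemic arterial flow of 69 mL/s, with
arterial pressure swinging between roughly 70 and 95 mmHg over the
cardiac cycle.  The forced maneuver yields the 4 L healthy vital
capacity; setting the airway-severity coefficient to α = 0.205 drops
the FEV1 ratio to the 0.70 diagnostic threshold and cuts peak
expiratory flow by about a quarter.

## Command line

Each subcommand wraps one library protocol and writes delimited-text
time series plus `key = value` summaries:

```bash
cardioresp simulate   --duration 700 --out run          # TPSS time series + summary
cardioresp spirometry --copd small_airways --out sa     # report + spirogram
cardioresp hypoxia    --o2-levels 0.21,0.17,0.13,0.10   # staircase summaries
cardioresp calibrate  pulmonary --target 35             # invert R_pa from mean P_pa
cardioresp doe        --out study                       # 8-run factorial + effects
cardioresp fixtures   --out fixtures/                   # canned scenario configs
```

Configuration files are INI text with `[subject]`, `[environment]`,
`[protocol]` and `[integrator]` sections; unknown keys are rejected by
name.  See `cardioresp fixtures` for ready-made examples.

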