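"""2^3 factorial study of COPD manifestations.

Eight simulations enumerate every on/off combination of the three disease
factors (small-airways severity, emphysema, pulmonary-hypertensive
resistance).  Respiratory characteristics (FVC, TLC, PEFR, FEV1 ratio)
come from the virtual spirometry maneuver; TPSS characteristics (heart
rate, pulmonary artery pressure, respiratory rate, minute ventilation)
from extended simulations under normoxic and hypoxic inspired O2, with
hypoxic-minus-normoxic changes as the secondary responses.

Significance of each factor is assessed with a t statistic on the factor's
main-effect contrast, using the pooled interaction contrasts (three
two-factor plus one three-factor, 4 degrees of freedom) as the error
estimate -- the standard error construction for an unreplicated two-level
factorial.  No multiple-testing correction is applied; the significance
threshold is alpha = 0.1.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .params import SubjectParameters, EnvironmentInput
from .protocols import CopdFlags, apply_copd, run_spirometry
from .simulate import simulate, tpss_summary

__all__ = [
    "FACTORS",
    "RESPIRATORY_RESPONSES",
    "TPSS_RESPONSES",
    "build_design",
    "collect_characteristics",
    "factor_ttests",
]

FACTORS = ("small_airways", "emphysema", "pulmonary_hypertension")
RESPIRATORY_RESPONSES = ("fvc", "tlc", "pefr", "fev1_ratio")
TPSS_RESPONSES = ("heart_rate", "p_pa", "respiratory_rate", "minute_ventilation")

SIGNIFICANCE_ALPHA = 0.1


def build_design() -> pd.DataFrame:
    """The full 2^3 design in canonical (standard) order.

    Column values are 0/1 factor levels; ``small_airways`` varies fastest.
    Row 0 is the all-healthy run.
    """
    rows = [
        {"small_airways": sa, "emphysema": e, "pulmonary_hypertension": ph}
        for ph, e, sa in itertools.product((0, 1), repeat=3)
    ]
    df = pd.DataFrame(rows, columns=list(FACTORS))
    df.insert(0, "run", range(len(df)))
    df["label"] = [
        CopdFlags(bool(r.small_airways), bool(r.emphysema),
                  bool(r.pulmonary_hypertension)).label()
        for r in df.itertuples()
    ]
    return df


def flags_for_row(row) -> CopdFlags:
    return CopdFlags(bool(row["small_airways"]), bool(row["emphysema"]),
                     bool(row["pulmonary_hypertension"]))


def collect_characteristics(design: pd.DataFrame, subject: SubjectParameters,
                            o2_levels=(0.21, 0.12), tpss_duration_s: float = 1000.0,
                            tpss_window_s: float = 100.0) -> pd.DataFrame:
    """Run the eight-case study and tabulate all responses.

    Per run: one spirometry maneuver (respiratory characteristics) and one
    extended simulation per inspired-O2 level (TPSS characteristics, means
    of the trailing window).  Adds ``delta_*`` columns with the
    hypoxic-minus-normoxic changes when two levels are given.
    """
    records = []
    for _, row in design.iterrows():
        flags = flags_for_row(row)
        subj = apply_copd(subject, flags)
        rec = dict(row)
        try:
            rep = run_spirometry(subj)
        except Exception as exc:
            raise RuntimeError(f"run {row['run']} ({flags.label()}): spirometry "
                               f"failed: {exc}") from exc
        rec.update(fvc=rep.fvc, tlc=rep.tlc, pefr=rep.pefr,
                   fev1_ratio=rep.fev1_ratio)
        for level in o2_levels:
            env = EnvironmentInput(fio2_times=(0.0,), fio2_values=(float(level),))
            try:
                res = simulate(subj, env, duration_s=tpss_duration_s)
            except Exception as exc:
                raise RuntimeError(
                    f"run {row['run']} ({flags.label()}): TPSS simulation at "
                    f"FiO2={level} failed: {exc}") from exc
            summ = tpss_summary(res, tpss_window_s)
            tag = f"o2_{int(round(level * 100)):02d}"
            rec[f"heart_rate_{tag}"] = summ.heart_rate
            rec[f"p_pa_{tag}"] = summ.mean_p_pa
            rec[f"respiratory_rate_{tag}"] = summ.respiratory_rate
            rec[f"minute_ventilation_{tag}"] = summ.minute_ventilation
        records.append(rec)
    table = pd.DataFrame(records)
    if len(o2_levels) == 2:
        hi = f"o2_{int(round(o2_levels[0] * 100)):02d}"
        lo = f"o2_{int(round(o2_levels[1] * 100)):02d}"
        for resp in TPSS_RESPONSES:
            table[f"delta_{resp}"] = table[f"{resp}_{lo}"] - table[f"{resp}_{hi}"]
    return table


def factor_ttests(table: pd.DataFrame, responses=None) -> pd.DataFrame:
    """Per-factor significance tests on a balanced 2^3 response table.

    For every response and factor, the main effect is the difference of
    means between the factor's high and low runs.  Its standard error is
    estimated from the four interaction contrasts pooled as error (each
    main and interaction contrast of a balanced two-level design has equal
    variance), giving a t statistic with 4 degrees of freedom.

    Degenerate case: if the pooled interaction variance is exactly zero the
    p-value is reported as 1 when the factor effect is also zero and 0
    otherwise, and the row is flagged ``degenerate``.

    Returns a tidy frame with columns response, factor, effect, t, p,
    significant (p < 0.1) and degenerate; row order is sorted and therefore
    invariant to the ordering of the input runs.
    """
    if responses is None:
        responses = [c for c in table.columns
                     if c not in ("run", "label", *FACTORS)
                     and np.issubdtype(table[c].dtype, np.number)]
    need = set(FACTORS)
    if not need.issubset(table.columns):
        raise ValueError(f"table must contain factor columns {sorted(need)}")
    tab = table.sort_values(list(FACTORS)).reset_index(drop=True)
    if len(tab) != 8 or tab.duplicated(list(FACTORS)).any():
        raise ValueError("table must contain the 8 distinct 2^3 runs")
    signs = {f: np.where(tab[f].to_numpy() > 0, 1.0, -1.0) for f in FACTORS}
    inter = [
        signs[FACTORS[0]] * signs[FACTORS[1]],
        signs[FACTORS[0]] * signs[FACTORS[2]],
        signs[FACTORS[1]] * signs[FACTORS[2]],
        signs[FACTORS[0]] * signs[FACTORS[1]] * signs[FACTORS[2]],
    ]
    rows = []
    for resp in responses:
        y = tab[resp].to_numpy(dtype=float)
        eps = 1e-12 * max(1.0, float(np.max(np.abs(y))))
        int_effects = np.array([float(c @ y) / 4.0 for c in inter])
        var_eff = float(np.mean(int_effects ** 2))  # variance of an effect
        for f in FACTORS:
            effect = float(signs[f] @ y) / 4.0
            degenerate = var_eff <= eps ** 2
            if degenerate:
                p = 1.0 if abs(effect) <= eps else 0.0
                tstat = 0.0 if abs(effect) <= eps else np.inf * np.sign(effect)
            else:
                tstat = effect / np.sqrt(var_eff)
                p = 2.0 * stats.t.sf(abs(tstat), df=4)
            rows.append({
                "response": resp,
                "factor": f,
                "effect": effect,
                "t": float(tstat),
                "p": float(p),
                "significant": bool(p < SIGNIFICANCE_ALPHA),
                "degenerate": degenerate,
            })
    out = pd.DataFrame(rows).sort_values(["response", "factor"]).reset_index(drop=True)
    return out
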