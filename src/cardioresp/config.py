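"""Configuration files, canned fixture scenarios and serialization.

Config files are INI-style key-value text with sections ``[subject]``,
``[environment]``, ``[protocol]`` and ``[integrator]``.  All values use
the package unit table (see :mod:`cardioresp.params`).  Unknown keys are
rejected by name so typos cannot silently fall back to defaults.

Time series are written as comma-separated text with a units header row;
summaries as ``key = value`` text.  All floating point output uses six
significant digits, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field

from .params import (
    SubjectParameters,
    EnvironmentInput,
    ParameterError,
    healthy_subject,
)
from .protocols import CopdFlags, apply_copd

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "dump_config",
    "write_outputs",
    "write_timeseries",
    "write_summary",
    "read_timeseries",
    "fixtures",
]

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid or unknown configuration content; lists all violations."""


# keys accepted in [subject]: the COPD-severity parameters plus flags
_SUBJECT_FLOAT_KEYS = {
    "r_airway_base", "alpha", "v_ref", "e_total", "v_unloaded", "r_pa",
}
_SUBJECT_FLAG_KEYS = {"small_airways", "emphysema", "pulmonary_hypertension"}

_ENV_KEYS = {"fio2", "fio2_times", "fio2_values", "metabolic_scale", "p_atm"}

_PROTOCOL_KEYS = {
    "name", "duration_s", "window_s", "o2_levels", "dwell_s",
    "target_fev1_ratio", "target_mean_ppa", "delta_frc_L", "delta_tlc_L",
    "tpss_duration_s", "tpss_window_s",
}

_INTEGRATOR_KEYS = {"rtol", "h_max", "output_stride"}

_PROTOCOL_NAMES = {"simulate", "spirometry", "hypoxia", "calibrate", "doe"}


@dataclass
class RunConfig:
    """A fully validated run request: subject, environment, protocol."""

    subject: SubjectParameters = field(default_factory=healthy_subject)
    env: EnvironmentInput = field(default_factory=EnvironmentInput)
    protocol: str = "simulate"
    settings: dict = field(default_factory=dict)
    rtol: float = 1.0e-6
    h_max: float = 5.0e-3
    output_stride: float = 0.02

    def validate(self) -> None:
        self.subject.validate()
        self.env.validate()
        if self.protocol not in _PROTOCOL_NAMES:
            raise ConfigError(f"unknown protocol name: {self.protocol!r}")
        if self.rtol <= 0 or self.h_max <= 0 or self.output_stride <= 0:
            raise ConfigError("integrator settings must be positive")


def _parse_floats(text: str):
    return tuple(float(v) for v in text.replace(",", " ").split())


def loads_config(text: str) -> RunConfig:
    """Parse and validate a config given as a string (see load_config)."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"config parse error: {exc}") from exc

    errors: list[str] = []
    known_sections = {"subject", "environment", "protocol", "integrator"}
    for sec in cp.sections():
        if sec not in known_sections:
            errors.append(f"unknown section [{sec}]")

    subject = healthy_subject()
    flags = CopdFlags()
    if cp.has_section("subject"):
        for key, val in cp.items("subject"):
            if key in _SUBJECT_FLOAT_KEYS:
                try:
                    setattr(subject, key, float(val))
                except ValueError:
                    errors.append(f"subject.{key}: not a number: {val!r}")
            elif key in _SUBJECT_FLAG_KEYS:
                setattr(flags, key, val.strip().lower() in ("1", "true", "on", "yes"))
            else:
                errors.append(f"unknown key subject.{key}")
    subject = apply_copd(subject, flags) if (
        flags.small_airways or flags.emphysema or flags.pulmonary_hypertension
    ) else subject

    env_kwargs: dict = {}
    if cp.has_section("environment"):
        for key, val in cp.items("environment"):
            if key not in _ENV_KEYS:
                errors.append(f"unknown key environment.{key}")
                continue
            try:
                if key == "fio2":
                    env_kwargs["fio2_times"] = (0.0,)
                    env_kwargs["fio2_values"] = (float(val),)
                elif key in ("fio2_times", "fio2_values"):
                    env_kwargs[key] = _parse_floats(val)
                else:
                    env_kwargs[key] = float(val)
            except ValueError:
                errors.append(f"environment.{key}: not numeric: {val!r}")
    env = EnvironmentInput(**env_kwargs)

    protocol = "simulate"
    settings: dict = {}
    if cp.has_section("protocol"):
        for key, val in cp.items("protocol"):
            if key not in _PROTOCOL_KEYS:
                errors.append(f"unknown key protocol.{key}")
                continue
            if key == "name":
                protocol = val.strip()
            elif key == "o2_levels":
                settings[key] = _parse_floats(val)
            else:
                try:
                    settings[key] = float(val)
                except ValueError:
                    errors.append(f"protocol.{key}: not numeric: {val!r}")

    integ = {"rtol": 1.0e-6, "h_max": 5.0e-3, "output_stride": 0.02}
    if cp.has_section("integrator"):
        for key, val in cp.items("integrator"):
            if key not in _INTEGRATOR_KEYS:
                errors.append(f"unknown key integrator.{key}")
                continue
            try:
                integ[key] = float(val)
            except ValueError:
                errors.append(f"integrator.{key}: not numeric: {val!r}")

    cfg = RunConfig(subject=subject, env=env, protocol=protocol,
                    settings=settings, **integ)
    try:
        cfg.validate()
    except (ParameterError, ConfigError) as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file.

    An empty file yields all defaults: the healthy subject breathing 21%
    O2 with the standard 700 s protocol.
    """
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to INI text (round-trips exactly)."""
    cp = configparser.ConfigParser()
    s = cfg.subject
    cp["subject"] = {k: FLOAT_FMT % getattr(s, k)
                     for k in sorted(_SUBJECT_FLOAT_KEYS)}
    cp["environment"] = {
        "fio2_times": " ".join(FLOAT_FMT % v for v in cfg.env.fio2_times),
        "fio2_values": " ".join(FLOAT_FMT % v for v in cfg.env.fio2_values),
        "metabolic_scale": FLOAT_FMT % cfg.env.metabolic_scale,
        "p_atm": FLOAT_FMT % cfg.env.p_atm,
    }
    proto = {"name": cfg.protocol}
    for k, v in sorted(cfg.settings.items()):
        proto[k] = (" ".join(FLOAT_FMT % x for x in v)
                    if isinstance(v, (tuple, list)) else FLOAT_FMT % v)
    cp["protocol"] = proto
    cp["integrator"] = {
        "rtol": FLOAT_FMT % cfg.rtol,
        "h_max": FLOAT_FMT % cfg.h_max,
        "output_stride": FLOAT_FMT % cfg.output_stride,
    }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def write_timeseries(frame, path) -> None:
    """Comma-separated time series with a units header row."""
    units = {
        "time_s": "s", "v_alveolar": "L", "p_act": "mmHg", "r_p": "-",
        "phi_resp": "-", "phi_cardiac": "-",
        "airflow": "L/s", "p_alveolar": "mmHg_abs",
        "p_sa": "mmHg", "p_pa": "mmHg",
        "q_systemic": "mL/s", "q_cerebral": "mL/s", "heart_period": "s",
        "v_lv": "mL", "v_rv": "mL", "v_sa": "mL", "v_sv": "mL",
        "v_pa": "mL", "v_pv": "mL",
    }
    cols = list(frame.columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write(",".join(units.get(c, "-") for c in cols) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(",".join(FLOAT_FMT % v for v in row) + "\n")


def read_timeseries(path):
    """Read back a file written by :func:`write_timeseries`."""
    import pandas as pd

    return pd.read_csv(path, skiprows=[1])


def write_summary(mapping: dict, path) -> None:
    """Structured key-value summary file (one ``key = value`` per line)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in mapping:
            val = mapping[key]
            if isinstance(val, float):
                fh.write(f"{key} = {FLOAT_FMT % val}\n")
            else:
                fh.write(f"{key} = {val}\n")


def write_outputs(artifact, path_timeseries=None, path_summary=None) -> list:
    """Write a simulation result, spirometry report or summary to files.

    Returns the list of files written.  Output is bitwise stable for
    identical inputs (fixed float formatting, fixed column order).
    """
    from .simulate import SimulationResult, TpssSummary, tpss_summary
    from .protocols import SpirometryReport

    written = []
    if isinstance(artifact, SimulationResult):
        if path_timeseries:
            write_timeseries(artifact.to_frame(), path_timeseries)
            written.append(path_timeseries)
        if path_summary:
            window = min(200.0, artifact.duration / 2.0)
            write_summary(tpss_summary(artifact, window).to_dict(), path_summary)
            written.append(path_summary)
    elif isinstance(artifact, TpssSummary):
        if path_summary:
            write_summary(artifact.to_dict(), path_summary)
            written.append(path_summary)
    elif isinstance(artifact, SpirometryReport):
        if path_summary:
            write_summary({
                "fvc": artifact.fvc, "fev1_ratio": artifact.fev1_ratio,
                "pefr": artifact.pefr, "tlc": artifact.tlc,
                "frc": artifact.frc, "t1": artifact.t1, "t2": artifact.t2,
            }, path_summary)
            written.append(path_summary)
        if path_timeseries:
            import pandas as pd

            frame = pd.DataFrame({
                "expired_volume": artifact.expired_volume,
                "expiratory_flow": artifact.expiratory_flow,
            })
            with open(path_timeseries, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("expired_volume,expiratory_flow\nL,L/s\n")
                for a, b in zip(artifact.expired_volume, artifact.expiratory_flow):
                    fh.write(f"{FLOAT_FMT % a},{FLOAT_FMT % b}\n")
            written.append(path_timeseries)
    else:
        raise TypeError(f"cannot serialize {type(artifact).__name__}")
    return written


# ---------------------------------------------------------------------------
# fixture scenarios
# ---------------------------------------------------------------------------


def fixtures() -> dict:
    """Named canned scenarios: the four subject archetypes plus all-COPD.

    Each value is valid config text; the test suite and the command line
    both consume these.
    """
    base = "[protocol]\nname = simulate\nduration_s = 700\n"
    return {
        "healthy": base,
        "small_airways": "[subject]\nsmall_airways = on\n" + base,
        "emphysema": "[subject]\nemphysema = on\n" + base,
        "pulmonary_hypertension": (
            "[subject]\npulmonary_hypertension = on\n" + base),
        "all_copd": ("[subject]\nsmall_airways = on\nemphysema = on\n"
                     "pulmonary_hypertension = on\n" + base),
    }
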