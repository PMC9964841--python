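"""Config and CSV serialization.

Parameter sets travel as flat key-value YAML mappings with exactly the
keys ``A, alpha, beta, b, n, q, H, mu, sigma, delta, rho, chi, tau_p,
phi, period_years``; calibration targets use their field names the same
way. Steady states serialize to a single-row CSV with a fixed column
order. Every writer here has a reader that restores the object
losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationTargets
from .core import SteadyState
from .errors import DomainError
from .params import ModelParams, PolicyParams, PRESETS

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "write_params",
    "read_params",
    "write_targets",
    "read_targets",
    "steady_state_to_csv",
    "steady_state_from_csv",
    "load_preset",
]

_MODEL_KEYS = tuple(f.name for f in fields(ModelParams))
_POLICY_KEYS = tuple(f.name for f in fields(PolicyParams))
PARAM_KEYS = _MODEL_KEYS + _POLICY_KEYS


def params_to_dict(params: ModelParams, policy: PolicyParams) -> dict[str, float]:
    """Flatten a parameter pair into one record with the canonical keys."""
    return {**asdict(params), **asdict(policy)}


def params_from_dict(record: dict) -> tuple[ModelParams, PolicyParams]:
    """Rebuild (ModelParams, PolicyParams) from a flat record."""
    unknown = set(record) - set(PARAM_KEYS)
    if unknown:
        raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
    missing = (set(PARAM_KEYS) - {"period_years"}) - set(record)
    if missing:
        raise DomainError(f"missing parameter keys: {sorted(missing)}")
    model = ModelParams(**{k: float(record[k]) for k in _MODEL_KEYS if k in record})
    policy = PolicyParams(**{k: float(record[k]) for k in _POLICY_KEYS})
    return model, policy


def write_params(path, params: ModelParams, policy: PolicyParams) -> None:
    Path(path).write_text(
        yaml.safe_dump(params_to_dict(params, policy), sort_keys=False)
    )


def read_params(path) -> tuple[ModelParams, PolicyParams]:
    record = yaml.safe_load(Path(path).read_text())
    if not isinstance(record, dict):
        raise DomainError(f"config {path} is not a flat key-value mapping")
    return params_from_dict(record)


def write_targets(path, targets: CalibrationTargets) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(targets), sort_keys=False))


def read_targets(path) -> CalibrationTargets:
    record = yaml.safe_load(Path(path).read_text())
    if not isinstance(record, dict):
        raise DomainError(f"config {path} is not a flat key-value mapping")
    names = {f.name for f in fields(CalibrationTargets)}
    unknown = set(record) - names
    if unknown:
        raise DomainError(f"unknown target keys: {sorted(unknown)}")
    return CalibrationTargets(**{k: float(v) for k, v in record.items()})


def steady_state_to_csv(path, ss: SteadyState) -> None:
    """Single-row CSV in the fixed documented column order."""
    frame = pd.DataFrame(
        [[getattr(ss, c) for c in SteadyState.CSV_COLUMNS]],
        columns=list(SteadyState.CSV_COLUMNS),
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def steady_state_from_csv(path) -> SteadyState:
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != list(SteadyState.CSV_COLUMNS):
        raise DomainError(f"unexpected steady-state CSV columns in {path}")
    row = frame.iloc[0]
    kwargs = {c: (str(row[c]) if c == "mode" else float(row[c])) for c in SteadyState.CSV_COLUMNS}
    return SteadyState(**kwargs)


def load_preset(name: str) -> tuple[ModelParams, PolicyParams]:
    """Look up a named parameter preset (e.g. ``china2020``)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise DomainError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()
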