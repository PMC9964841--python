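"""Comparative statics and policy experiments on the closed-form steady state.

Everything here evaluates the as-printed steady state over parameter
grids: one- and two-dimensional sweeps (emission intensity rho,
abatement efficiency chi, the tax rate tau_p, the health-spending share
phi), location of the tax rate that maximizes a chosen steady-state
outcome, central-difference comparative-statics signs, and the
rho-versus-chi effect-magnitude comparison. Grid points where an
admissibility assumption fails are masked, not errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import (
    SteadyState,
    check_assumptions,
    steady_state_as_printed,
)
from .errors import DomainError, EnvolgError, InvalidRegimeError
from .params import ModelParams, PolicyParams

__all__ = [
    "SweepResult",
    "OptimalTaxResult",
    "SignResult",
    "OUTCOMES",
    "sweep_1d",
    "sweep_2d",
    "policy_threshold",
    "optimal_tax",
    "comparative_statics_sign",
    "effect_magnitude_comparison",
]

#: Steady-state outcomes reported by sweeps, keyed by short name.
OUTCOMES = {
    "k": "k_star",
    "y": "y_star",
    "P": "P_star",
    "h": "h_star",
    "pi": "pi_star",
    "s_hat": "s_hat_star",
    "r_annual": "r_annual",
}

_SWEEPABLE_MODEL = {"rho", "chi"}
_SWEEPABLE_POLICY = {"tau_p", "phi"}

#: Default sweep grids (100 points each), overridable per call.
DEFAULT_GRIDS = {
    "tau_p": (0.005, 0.30),
    "phi": (0.05, 0.95),
    "rho": (0.01, 0.12),
    "chi": (0.5, 1.2),
}


def _apply(params: ModelParams, policy: PolicyParams, name: str, value: float):
    if name in _SWEEPABLE_MODEL:
        return params.with_(**{name: value}), policy
    if name in _SWEEPABLE_POLICY:
        return params, policy.with_(**{name: value})
    raise DomainError(
        f"cannot sweep over {name!r}; choose one of "
        f"{sorted(_SWEEPABLE_MODEL | _SWEEPABLE_POLICY)}"
    )


def _evaluate_point(params, policy) -> tuple[SteadyState | None, str]:
    """Steady state at one grid point, or (None, violated-assumption label)."""
    report = check_assumptions(params, policy)
    if not report.assumption1_ok:
        return None, "assumption1"
    if not report.assumption2_ok:
        return None, "assumption2"
    return steady_state_as_printed(params, policy), ""


@dataclass(frozen=True)
class SweepResult:
    """Outcomes of a parameter sweep.

    ``frame`` has one row per grid point: the swept parameter value(s),
    one column per outcome (NaN where invalid), a ``valid`` flag, and
    the name of the violated assumption where invalid.
    """

    swept: tuple[str, ...]
    frame: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per (grid point, outcome) pair."""
        ids = list(self.swept) + ["valid", "violated"]
        value_cols = [c for c in self.frame.columns if c not in ids]
        return self.frame.melt(
            id_vars=ids, value_vars=value_cols,
            var_name="outcome", value_name="value",
        )

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    def valid_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]]


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("empty sweep grid")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise DomainError("sweep grid must be strictly increasing")
    return grid


def default_grid(name: str, num: int = 100) -> np.ndarray:
    lo, hi = DEFAULT_GRIDS[name]
    return np.linspace(lo, hi, num)


def sweep_1d(
    params: ModelParams,
    policy: PolicyParams,
    name: str,
    grid=None,
) -> SweepResult:
    """Steady-state outcomes along a grid of one parameter."""
    grid = _check_grid(default_grid(name) if grid is None else grid)
    rows = []
    for v in grid:
        p, pol = _apply(params, policy, name, float(v))
        ss, violated = _evaluate_point(p, pol)
        row = {name: float(v), "valid": ss is not None, "violated": violated}
        for short, attr in OUTCOMES.items():
            row[short] = getattr(ss, attr) if ss is not None else math.nan
        rows.append(row)
    cols = [name, "valid", "violated"] + list(OUTCOMES)
    return SweepResult(swept=(name,), frame=pd.DataFrame(rows, columns=cols))


def sweep_2d(
    params: ModelParams,
    policy: PolicyParams,
    tau_grid=None,
    phi_grid=None,
) -> SweepResult:
    """Outcome surfaces over the product grid of (tau_p, phi)."""
    tau_grid = _check_grid(default_grid("tau_p") if tau_grid is None else tau_grid)
    phi_grid = _check_grid(default_grid("phi") if phi_grid is None else phi_grid)
    rows = []
    for phi in phi_grid:
        for tau in tau_grid:
            pol = policy.with_(tau_p=float(tau), phi=float(phi))
            ss, violated = _evaluate_point(params, pol)
            row = {
                "tau_p": float(tau), "phi": float(phi),
                "valid": ss is not None, "violated": violated,
            }
            for short, attr in OUTCOMES.items():
                row[short] = getattr(ss, attr) if ss is not None else math.nan
            rows.append(row)
    cols = ["tau_p", "phi", "valid", "violated"] + list(OUTCOMES)
    return SweepResult(swept=("tau_p", "phi"), frame=pd.DataFrame(rows, columns=cols))


def policy_threshold(params: ModelParams, policy: PolicyParams | None = None):
    """Tax-rate thresholds governing the sign of health-share effects.

    Returns ``(tau_bar, assumption2_bound)`` where
    ``tau_bar = rho/[chi*(1-n*q)*(1-alpha)]`` is the threshold at which
    the effect of the health-spending share on capital, survival, and
    saving flips sign, and the second element is the Assumption-2 upper
    bound ``rho/[chi*(1-phi)*(1-n*q)*(1-alpha)]`` (None when no policy
    is supplied). The threshold always lies below the bound.
    """
    if params.chi <= 0:
        raise DomainError("chi must be positive to form the policy threshold")
    denom = params.chi * (1.0 - params.nq) * (1.0 - params.alpha)
    tau_bar = params.rho / denom
    bound = None if policy is None else params.rho / (denom * (1.0 - policy.phi))
    return tau_bar, bound


@dataclass(frozen=True)
class OptimalTaxResult:
    """Location of the outcome-maximizing environmental tax rate."""

    objective: str
    tau_m: float
    value: float
    interval: tuple[float, float]
    interior: bool
    converged: bool


def optimal_tax(
    params: ModelParams,
    phi: float,
    objective: str = "k",
    *,
    coarse_points: int = 512,
    eps: float = 1e-6,
) -> OptimalTaxResult:
    """Maximize a steady-state outcome over the admissible tax rates.

    The admissible interval is ``(eps, min(1, Assumption-2 bound) - eps)``.
    A coarse grid scan locates the best bracket, refined by bounded
    scalar optimization. ``interior`` is False when the maximum sits at
    an endpoint (as it does for the survival probability, which is
    monotone in the tax rate).
    """
    if objective not in OUTCOMES:
        raise DomainError(f"unknown objective {objective!r}; choose from {sorted(OUTCOMES)}")
    attr = OUTCOMES[objective]
    policy0 = PolicyParams(tau_p=0.5, phi=phi)
    _, bound = policy_threshold(params, policy0)
    hi = min(1.0, bound) - eps
    lo = eps
    if hi <= lo:
        raise DomainError(f"admissible tax interval is empty: bound {bound:.4g} <= {eps}")

    def f(tau: float) -> float:
        ss = steady_state_as_printed(params, PolicyParams(tau_p=tau, phi=phi))
        v = getattr(ss, attr)
        if not math.isfinite(v):
            raise EnvolgError(f"objective {objective} non-finite at tau_p={tau:.6g}")
        return v

    grid = np.linspace(lo, hi, coarse_points)
    values = np.array([f(t) for t in grid])
    i = int(np.argmax(values))
    if i == 0 or i == coarse_points - 1:
        # Monotone up to the boundary: report the endpoint.
        return OptimalTaxResult(
            objective=objective, tau_m=float(grid[i]), value=float(values[i]),
            interval=(lo, hi), interior=False, converged=True,
        )
    res = minimize_scalar(
        lambda t: -f(t), bounds=(grid[i - 1], grid[i + 1]), method="bounded",
        options={"xatol": 1e-12},
    )
    return OptimalTaxResult(
        objective=objective, tau_m=float(res.x), value=float(-res.fun),
        interval=(lo, hi), interior=True, converged=bool(res.success),
    )


@dataclass(frozen=True)
class SignResult:
    """Central-difference derivative of a steady-state outcome."""

    wrt: str
    objective: str
    derivative: float
    sign: int
    step: float
    richardson_gap: float


def comparative_statics_sign(
    params: ModelParams,
    policy: PolicyParams,
    wrt: str,
    objective: str = "k",
    step: float | None = None,
) -> SignResult:
    """Sign of d(outcome)/d(parameter) at a point, by central difference.

    The default step is 1e-5 of the parameter value; a half-step
    Richardson evaluation is reported as a consistency diagnostic.
    Raises :class:`DomainError` when either stencil point leaves the
    admissible region, suggesting a smaller step.
    """
    if objective not in OUTCOMES:
        raise DomainError(f"unknown objective {objective!r}")
    attr = OUTCOMES[objective]
    base = getattr(params, wrt, None)
    if base is None:
        base = getattr(policy, wrt, None)
    if base is None:
        raise DomainError(f"unknown parameter {wrt!r}")
    h = abs(base) * 1e-5 if step is None else step

    def f(v: float) -> float:
        try:
            p, pol = _apply(params, policy, wrt, v)
            return getattr(steady_state_as_printed(p, pol), attr)
        except (InvalidRegimeError, DomainError) as exc:
            raise DomainError(
                f"stencil point {wrt}={v:.6g} is inadmissible ({exc}); "
                "use a smaller step"
            ) from exc

    d = (f(base + h) - f(base - h)) / (2 * h)
    d_half = (f(base + h / 2) - f(base - h / 2)) / h
    gap = abs(d - d_half) / max(abs(d_half), 1e-300)
    return SignResult(
        wrt=wrt, objective=objective, derivative=d,
        sign=int(np.sign(d)), step=h, richardson_gap=gap,
    )


def effect_magnitude_comparison(
    params: ModelParams,
    policy: PolicyParams,
    delta: float,
) -> pd.DataFrame:
    """Compare outcome responses to equal-sized changes in rho and chi.

    For each of the headline outcomes (h*, pi*, saving rate, y*), the
    absolute change between the steady states at ``rho +/- delta`` is
    set against the change at ``chi +/- delta``. One row per outcome
    with a boolean ``rho_dominates``.
    """
    outcomes = {"h": "h_star", "pi": "pi_star", "s_hat": "s_hat_star", "y": "y_star"}

    def span(name: str) -> dict[str, float]:
        base = getattr(params, name)
        lo = steady_state_as_printed(params.with_(**{name: base - delta}), policy)
        hi = steady_state_as_printed(params.with_(**{name: base + delta}), policy)
        return {short: abs(getattr(hi, a) - getattr(lo, a)) for short, a in outcomes.items()}

    d_rho, d_chi = span("rho"), span("chi")
    rows = [
        {
            "outcome": short,
            "abs_change_rho": d_rho[short],
            "abs_change_chi": d_chi[short],
            "rho_dominates": d_rho[short] > d_chi[short],
        }
        for short in outcomes
    ]
    return pd.DataFrame(rows)
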