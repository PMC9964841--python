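"""Transition-path simulation.

The economy's state is (k, P, h): capital per labor, the pollution
stock, and the health stock inherited from the previous generation.
Within a period the order of resolution is prices -> fiscal split ->
health update -> survival -> savings; the next period's stocks then
follow from the capital-market clearing law ``k' = s/n`` and the
pollution law. The simulator doubles as the oracle for the
self-consistent steady state: its long-run limit is that fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import core
from .errors import DomainError, InvalidRegimeError
from .params import EconomyState, ModelParams, PolicyParams

__all__ = ["Trajectory", "ConvergenceReport", "simulate", "convergence_report"]

#: Column order of a trajectory frame (one row per period).
TRAJECTORY_COLUMNS = (
    "period",
    "k",
    "P",
    "h",
    "pi",
    "w",
    "R_period",
    "g",
    "m",
    "s",
    "s_hat",
    "y",
    "dependency_ratio",
)

#: Relative-change threshold below which the path is declared converged.
CONVERGENCE_TOL = 1e-10


@dataclass(frozen=True)
class Trajectory:
    """A simulated transition path.

    ``frame`` holds one row per period (T+1 rows for T transitions,
    including the initial period); ``converged`` is True if the maximum
    relative change of (k, P, h) dropped below the convergence
    tolerance at some period, and ``periods_to_converge`` records the
    first such period (None if never).
    """

    frame: pd.DataFrame
    converged: bool
    periods_to_converge: int | None

    def final_state(self) -> EconomyState:
        row = self.frame.iloc[-1]
        return EconomyState(
            k=float(row["k"]), P=float(row["P"]), h=float(row["h"]),
            period_index=int(row["period"]),
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def read_csv(path) -> "Trajectory":
        frame = pd.read_csv(path, float_precision="round_trip")
        conv, at = _detect_convergence(frame)
        return Trajectory(frame=frame, converged=conv, periods_to_converge=at)


def _detect_convergence(frame: pd.DataFrame) -> tuple[bool, int | None]:
    for i in range(1, len(frame)):
        prev, cur = frame.iloc[i - 1], frame.iloc[i]
        rel = max(
            abs(cur["k"] - prev["k"]) / max(abs(prev["k"]), 1e-300),
            abs(cur["P"] - prev["P"]) / max(abs(prev["P"]), 1e-300),
            abs(cur["h"] - prev["h"]) / max(abs(prev["h"]), 1e-300),
        )
        if rel < CONVERGENCE_TOL:
            return True, int(frame.iloc[i]["period"])
    return False, None


def simulate(
    params: ModelParams,
    policy: PolicyParams,
    initial: EconomyState,
    T: int,
) -> Trajectory:
    """Simulate ``T`` transitions from ``initial``.

    ``initial.h`` is the pre-period health stock h_{-1}; the first
    row already reflects the period-0 health update. The returned frame
    has ``T + 1`` rows. Raises :class:`InvalidRegimeError` if the state
    leaves the admissible region (non-positive capital or pollution),
    naming the offending period.
    """
    if T < 1:
        raise DomainError(f"T must be at least 1, got {T}")
    core._require_admissible(params, policy)

    k, P, h_prev = initial.k, initial.P, initial.h
    rows = []
    converged = False
    converged_at: int | None = None
    for t in range(T + 1):
        if k <= 0 or P <= 0:
            raise InvalidRegimeError(
                f"state left the admissible region at period {t}: k={k:.6g}, P={P:.6g}"
            )
        R, w = core.factor_prices(k, params)
        g, m = core.fiscal_split(w, params, policy)
        h = core.health_update(h_prev, g, P, params)
        pi = core.survival_probability(h, params.b)
        hh = core.household_solution(w, pi, R, params, policy)
        rows.append(
            {
                "period": t,
                "k": k,
                "P": P,
                "h": h,
                "pi": pi,
                "w": w,
                "R_period": R,
                "g": g,
                "m": m,
                "s": hh.s,
                "s_hat": hh.s_hat,
                "y": params.A * k ** params.alpha,
                "dependency_ratio": core.dependency_ratio(pi, params.n),
            }
        )
        if t >= 1 and not converged:
            prev = rows[t - 1]
            rel = max(
                abs(k - prev["k"]) / max(abs(prev["k"]), 1e-300),
                abs(P - prev["P"]) / max(abs(prev["P"]), 1e-300),
                abs(h - prev["h"]) / max(abs(prev["h"]), 1e-300),
            )
            if rel < CONVERGENCE_TOL:
                converged, converged_at = True, t
        if t < T:
            P = core.pollution_transition(P, k, params, policy)
            k = hh.s / params.n
            h_prev = h
    frame = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    return Trajectory(frame=frame, converged=converged, periods_to_converge=converged_at)


@dataclass(frozen=True)
class ConvergenceReport:
    """Fixed-point residuals and path diagnostics at the end of a run.

    Residuals are relative errors of the three steady-state identities
    at the final state: the capital law ``s/n = k``, the pollution law
    ``P' (P, k) = P``, and the health law ``h'(h, g, P) = h``.
    """

    converged: bool
    periods_to_converge: int | None
    residual_capital: float
    residual_pollution: float
    residual_health: float
    k_monotone_increasing: bool
    k_monotone_decreasing: bool


def convergence_report(
    trajectory: Trajectory, params: ModelParams, policy: PolicyParams
) -> ConvergenceReport:
    """Residuals of the steady-state identities at the final simulated state."""
    frame = trajectory.frame
    if len(frame) == 0:
        raise DomainError("empty trajectory")
    row = frame.iloc[-1]
    k, P, h = float(row["k"]), float(row["P"]), float(row["h"])
    s = float(row["s"])
    g = float(row["g"])
    res_k = abs(s / params.n - k) / max(abs(k), 1e-300)
    res_P = abs(core.pollution_transition(P, k, params, policy) - P) / max(abs(P), 1e-300)
    res_h = abs(core.health_update(h, g, P, params) - h) / max(abs(h), 1e-300)
    dk = frame["k"].diff().dropna()
    return ConvergenceReport(
        converged=trajectory.converged,
        periods_to_converge=trajectory.periods_to_converge,
        residual_capital=res_k,
        residual_pollution=res_P,
        residual_health=res_h,
        k_monotone_increasing=bool((dk >= 0).all()),
        k_monotone_decreasing=bool((dk <= 0).all()),
    )
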