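"""Structural and policy parameters of the three-period OLG economy.

The economy is populated by households living through childhood, a
working period, and retirement; one model period spans ``period_years``
(30 by default). Production is Cobb-Douglas in capital and labor,
pollution is a stock fed by output and drained by natural absorption and
public abatement, and health human capital — which determines the
probability of surviving through old age — accumulates from public
health spending relative to the pollution stock.

Two assumptions bound the admissible region:

* Assumption 1 (``rho < chi``): a unit of abatement spending removes at
  least as much pollution as a unit of output emits.
* Assumption 2 (``rho - chi*(1-phi)*tau_p*(1-n*q)*(1-alpha) > 0``):
  abatement does not drive the steady-state pollution stock to zero or
  below, which bounds the admissible environmental tax rate from above.

Basic range constraints are enforced at construction; the two
assumptions are checked by :func:`envolg.core.check_assumptions` and
enforced by the equilibrium evaluators, so that diagnostics can be
produced for inadmissible combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import DomainError

__all__ = ["ModelParams", "PolicyParams", "EconomyState", "china2020", "china2020_q_text"]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


@dataclass(frozen=True)
class ModelParams:
    """The twelve structural parameters.

    Parameters
    ----------
    A : float
        Total factor productivity per model period (dimensionless, > 0).
    alpha : float
        Output elasticity of capital, in (0, 1).
    beta : float
        Time-discount factor over one period, in (0, 1).
    b : float
        Survival-probability adjustment parameter, in (0, 1); the upper
        asymptote of the survival function.
    n : float
        Children per adult (fractional allowed), > 0.
    q : float
        Child-rearing cost per child as a share of working income, in
        (0, 1); ``n * q`` must stay below 1.
    H : float
        Health-accumulation technology level, > 0.
    mu : float
        Health depreciation rate per period, in (0, 1).
    sigma : float
        Output elasticity of (health spending / pollution) in health
        accumulation, > 0.
    delta : float
        Natural pollution absorption rate per period, in (0, 1).
    rho : float
        Pollution emitted per unit of output, >= 0.
    chi : float
        Pollution removed per unit of abatement spending, >= 0.
    period_years : float
        Calendar length of one model period in years (default 30).
    """

    A: float
    alpha: float
    beta: float
    b: float
    n: float
    q: float
    H: float
    mu: float
    sigma: float
    delta: float
    rho: float
    chi: float
    period_years: float = 30.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "b", "mu", "delta", "q"):
            v = getattr(self, name)
            _require(0.0 < v < 1.0, f"{name} must lie in (0, 1), got {v}")
        _require(self.n > 0.0, f"n must be positive, got {self.n}")
        _require(0.0 < self.n * self.q < 1.0, f"n*q must lie in (0, 1), got {self.n * self.q}")
        _require(self.A > 0.0, f"A must be positive, got {self.A}")
        _require(self.H > 0.0, f"H must be positive, got {self.H}")
        _require(self.sigma > 0.0, f"sigma must be positive, got {self.sigma}")
        _require(self.rho >= 0.0, f"rho must be non-negative, got {self.rho}")
        _require(self.chi >= 0.0, f"chi must be non-negative, got {self.chi}")
        _require(self.period_years > 0.0, f"period_years must be positive, got {self.period_years}")

    @property
    def nq(self) -> float:
        """Total child-rearing cost share of working income."""
        return self.n * self.q

    def with_(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PolicyParams:
    """The two policy instruments.

    Parameters
    ----------
    tau_p : float
        Environmental tax rate on after-childcare wage income, in (0, 1).
    phi : float
        Fraction of public revenue devoted to health spending (the rest
        funds pollution abatement), in (0, 1).
    """

    tau_p: float
    phi: float

    def __post_init__(self) -> None:
        _require(0.0 < self.tau_p < 1.0, f"tau_p must lie in (0, 1), got {self.tau_p}")
        _require(0.0 < self.phi < 1.0, f"phi must lie in (0, 1), got {self.phi}")

    def with_(self, **kwargs: float) -> "PolicyParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EconomyState:
    """Per-labor state of the economy at one period.

    ``h`` is the health stock inherited from the previous generation
    (the state variable entering the current period's health update).
    """

    k: float
    P: float
    h: float
    period_index: int = 0

    def __post_init__(self) -> None:
        _require(self.k > 0.0, f"k must be positive, got {self.k}")
        _require(self.P > 0.0, f"P must be positive, got {self.P}")
        _require(self.h >= 0.0, f"h must be non-negative, got {self.h}")
        _require(self.period_index >= 0, "period_index must be non-negative")


def china2020(q: float | None = None) -> tuple[ModelParams, PolicyParams]:
    """The China-2020 base-case calibration.

    TFP and the health technology grow at 4.5 % per year compounded over
    a 30-year period; pollution absorbs naturally at 10 % per year. The
    child-cost share defaults to ``q = 0.10``; pass ``q=0.12`` for the
    alternative value discussed alongside the base case (see
    :func:`china2020_q_text`).
    """
    growth = 1.045 ** 30
    params = ModelParams(
        A=growth,
        alpha=0.60,
        beta=0.99 ** 30,
        b=0.88,
        n=0.65,
        q=0.10 if q is None else q,
        H=growth,
        mu=0.85,
        sigma=0.50,
        delta=0.96,
        rho=0.06,
        chi=0.85,
        period_years=30.0,
    )
    policy = PolicyParams(tau_p=0.046, phi=0.86)
    return params, policy


def china2020_q_text() -> tuple[ModelParams, PolicyParams]:
    """Variant of the base case with the alternative child-cost share q = 0.12."""
    return china2020(q=0.12)


#: Registry of named parameter presets usable from configs and the CLI.
PRESETS = {
    "china2020": china2020,
    "china2020_q012": china2020_q_text,
}
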