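"""Primitive model equations and closed-form steady states.

The model's building blocks are:

* a survival function ``pi(h) = b*h/(1+h)`` mapping health human
  capital to the probability of living through old age;
* a health accumulation law ``h' = (1-mu)*h + H*(g/P)**sigma`` driven by
  public health spending ``g`` relative to the pollution stock ``P``;
* Cobb-Douglas production ``y = A*k**alpha`` with competitive factor
  prices;
* a log-utility household choosing savings given its survival odds,
  with annuitized returns on savings;
* a balanced government budget splitting environmental tax revenue
  between health spending (share ``phi``) and pollution abatement
  (share ``1-phi``);
* a pollution stock law with natural absorption and abatement.

Two steady-state evaluators are provided. ``steady_state_as_printed``
evaluates the published closed-form expressions for k*, P*, pi*, and
the saving rate literally; it is the canonical mode and reproduces the
published China-2020 baseline. ``steady_state_self_consistent`` instead
solves the joint fixed point of the primitive transition laws by damped
iteration. The two differ by a small finite amount because the printed
closed forms for k* and pi* place the absorption factor delta**sigma
slightly differently than composing the primitive laws does; both modes
are exposed and the gap is measurable (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConvergenceError, DomainError, InvalidRegimeError
from .params import ModelParams, PolicyParams

__all__ = [
    "HouseholdSolution",
    "SteadyState",
    "AssumptionReport",
    "survival_probability",
    "health_update",
    "factor_prices",
    "household_solution",
    "fiscal_split",
    "pollution_transition",
    "dependency_ratio",
    "annualize_gross_return",
    "check_assumptions",
    "steady_state_as_printed",
    "steady_state_self_consistent",
]


# ---------------------------------------------------------------------------
# Primitive equations
# ---------------------------------------------------------------------------

def survival_probability(h: float, b: float) -> float:
    """Probability of surviving through old age given health stock ``h``.

    ``pi = b*h/(1+h)``: strictly increasing and concave in ``h``,
    bounded in ``[0, b)`` with asymptote ``b``.
    """
    if h < 0:
        raise DomainError(f"health stock must be non-negative, got {h}")
    if not 0 < b < 1:
        raise DomainError(f"survival adjustment b must lie in (0, 1), got {b}")
    return b * h / (1.0 + h)


def health_update(h_prev: float, g: float, P: float, params: ModelParams) -> float:
    """One-period health human capital accumulation.

    ``h = (1-mu)*h_prev + H*(g/P)**sigma``: the parent generation's
    health depreciates at rate ``mu`` and is topped up by public health
    spending per unit of pollution exposure.
    """
    if P <= 0:
        raise DomainError(f"pollution stock must be positive, got {P}")
    if g < 0:
        raise DomainError(f"health spending must be non-negative, got {g}")
    if h_prev < 0:
        raise DomainError(f"health stock must be non-negative, got {h_prev}")
    return (1.0 - params.mu) * h_prev + params.H * (g / P) ** params.sigma


def factor_prices(k: float, params: ModelParams) -> tuple[float, float]:
    """Competitive gross capital return and wage at capital per labor ``k``.

    ``R = alpha*A*k**(alpha-1)`` and ``w = (1-alpha)*A*k**alpha``; the
    Euler identity ``R*k + w = A*k**alpha`` holds exactly.
    """
    if k <= 0:
        raise DomainError(f"capital per labor must be positive, got {k}")
    R = params.alpha * params.A * k ** (params.alpha - 1.0)
    w = (1.0 - params.alpha) * params.A * k ** params.alpha
    return R, w


@dataclass(frozen=True)
class HouseholdSolution:
    """Optimal household plan for one generation.

    ``s_hat`` is the saving rate out of after-tax wage income,
    ``s / (w*(1-tau_p))``.
    """

    c_young: float
    c_old: float
    s: float
    s_hat: float
    u: float


def household_solution(
    w: float,
    pi_next: float,
    R_next: float,
    params: ModelParams,
    policy: PolicyParams,
) -> HouseholdSolution:
    """Solve the household's log-utility savings problem.

    With survival probability ``pi_next`` and annuitized return
    ``R_next/pi_next`` on savings, the optimal saving level is

    ``s = beta*pi/(1 + beta*pi) * w*(1-n*q)*(1-tau_p)``

    and young consumption absorbs the rest of disposable income. When
    ``pi_next = 0`` there is no old age to provide for: savings are zero
    and old-age consumption is defined as zero.
    """
    if w <= 0:
        raise DomainError(f"wage must be positive, got {w}")
    if not 0 <= pi_next < 1:
        raise DomainError(f"survival probability must lie in [0, 1), got {pi_next}")
    if R_next <= 0:
        raise DomainError(f"gross return must be positive, got {R_next}")
    disposable = w * (1.0 - params.nq) * (1.0 - policy.tau_p)
    bpi = params.beta * pi_next
    s = bpi / (1.0 + bpi) * disposable
    c_young = disposable - s
    if pi_next > 0 and s > 0:
        c_old = s * R_next / pi_next
        u = math.log(c_young) + bpi * math.log(c_old)
    else:
        # pi = 0 (or underflowed savings): no old age to provide for.
        c_old = 0.0
        s = 0.0
        u = math.log(c_young)
    s_hat = bpi * (1.0 - params.nq) / (1.0 + bpi)
    return HouseholdSolution(c_young=c_young, c_old=c_old, s=s, s_hat=s_hat, u=u)


def fiscal_split(w: float, params: ModelParams, policy: PolicyParams) -> tuple[float, float]:
    """Split environmental tax revenue into health spending and abatement.

    Revenue per worker is ``tau_p * w * (1-n*q)``; the share ``phi``
    funds public health (``g``), the rest abatement (``m``). The split
    is exact: ``g + m`` equals revenue to the last bit.
    """
    if w <= 0:
        raise DomainError(f"wage must be positive, got {w}")
    revenue = policy.tau_p * w * (1.0 - params.nq)
    g = policy.phi * revenue
    m = revenue - g
    return g, m


def _net_emission_coefficient(params: ModelParams, policy: PolicyParams) -> float:
    """Net pollution emitted per unit of output after abatement.

    ``rho - chi*(1-phi)*tau_p*(1-n*q)*(1-alpha)``; Assumption 2 requires
    this to be positive.
    """
    return params.rho - params.chi * (1.0 - policy.phi) * policy.tau_p * (
        1.0 - params.nq
    ) * (1.0 - params.alpha)


def pollution_transition(P: float, k: float, params: ModelParams, policy: PolicyParams) -> float:
    """One-period pollution stock update.

    ``P' = (1-delta)*P + [rho - chi*(1-phi)*tau_p*(1-n*q)*(1-alpha)] * A*k**alpha``.

    Raises :class:`InvalidRegimeError` if the update would drive the
    stock to zero or below, which signals a violated Assumption 2
    (abatement exceeding gross emissions).
    """
    if P <= 0:
        raise DomainError(f"pollution stock must be positive, got {P}")
    if k <= 0:
        raise DomainError(f"capital per labor must be positive, got {k}")
    coeff = _net_emission_coefficient(params, policy)
    P_next = (1.0 - params.delta) * P + coeff * params.A * k ** params.alpha
    if P_next <= 0:
        raise InvalidRegimeError(
            "pollution stock driven non-positive: Assumption 2 "
            f"(rho - chi*(1-phi)*tau_p*(1-n*q)*(1-alpha) > 0) fails; "
            f"net emission coefficient = {coeff:.6g}"
        )
    return P_next


def dependency_ratio(pi: float, n: float) -> float:
    """Old-age dependency ratio: surviving old per young, ``pi / n``."""
    if n <= 0:
        raise DomainError(f"fertility must be positive, got {n}")
    if not 0 <= pi <= 1:
        raise DomainError(f"survival probability must lie in [0, 1], got {pi}")
    return pi / n


def annualize_gross_return(R_period: float, period_years: float) -> float:
    """Geometric-mean annual net rate from a gross per-period return.

    ``r = R_period**(1/period_years) - 1``.
    """
    if R_period <= 0:
        raise DomainError(f"gross return must be positive, got {R_period}")
    if period_years <= 0:
        raise DomainError(f"period length must be positive, got {period_years}")
    return R_period ** (1.0 / period_years) - 1.0


# ---------------------------------------------------------------------------
# Assumption diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssumptionReport:
    """Pass/fail diagnostics for the model's two admissibility assumptions.

    ``tau_p_bound`` is the Assumption-2 upper bound on the tax rate,
    ``rho / [chi*(1-phi)*(1-n*q)*(1-alpha)]``; ``policy_threshold`` is
    the smaller threshold ``rho / [chi*(1-n*q)*(1-alpha)]`` at which the
    comparative-statics signs of the health-spending share flip.
    """

    assumption1_ok: bool
    assumption2_ok: bool
    net_emission_coefficient: float
    tau_p_bound: float
    policy_threshold: float

    @property
    def all_ok(self) -> bool:
        return self.assumption1_ok and self.assumption2_ok


def check_assumptions(params: ModelParams, policy: PolicyParams) -> AssumptionReport:
    """Report whether Assumptions 1 and 2 hold, with the tax-rate bounds."""
    coeff = _net_emission_coefficient(params, policy)
    denom = params.chi * (1.0 - params.nq) * (1.0 - params.alpha)
    if denom > 0:
        threshold = params.rho / denom
        bound = params.rho / (denom * (1.0 - policy.phi))
    else:
        threshold = math.inf
        bound = math.inf
    return AssumptionReport(
        assumption1_ok=params.rho < params.chi,
        assumption2_ok=coeff > 0,
        net_emission_coefficient=coeff,
        tau_p_bound=bound,
        policy_threshold=threshold,
    )


def _require_admissible(params: ModelParams, policy: PolicyParams) -> AssumptionReport:
    report = check_assumptions(params, policy)
    if not report.assumption1_ok:
        raise InvalidRegimeError(
            f"Assumption 1 (rho < chi) fails: rho={params.rho}, chi={params.chi}"
        )
    if not report.assumption2_ok:
        raise InvalidRegimeError(
            "Assumption 2 (positive steady-state pollution) fails: "
            f"net emission coefficient = {report.net_emission_coefficient:.6g}; "
            f"requires tau_p < {report.tau_p_bound:.6g}"
        )
    return report


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """Full record of a stationary equilibrium (per-labor quantities)."""

    k_star: float
    y_star: float
    P_star: float
    h_star: float
    pi_star: float
    s_hat_star: float
    w_star: float
    R_period: float
    r_annual: float
    g_star: float
    m_star: float
    dependency_ratio: float
    mode: str

    #: Fixed column order used by the CSV serializer.
    CSV_COLUMNS = (
        "mode",
        "k_star",
        "y_star",
        "P_star",
        "h_star",
        "pi_star",
        "s_hat_star",
        "w_star",
        "R_period",
        "r_annual",
        "g_star",
        "m_star",
        "dependency_ratio",
    )


def _printed_blocks(params: ModelParams, policy: PolicyParams) -> tuple[float, float]:
    """The two recurring composites of the closed forms.

    ``X = phi*tau_p*(1-n*q)*(1-alpha)`` (health-spending share of
    output) and ``Y = rho - chi*(1-phi)*tau_p*(1-n*q)*(1-alpha)`` (net
    emission per unit of output).
    """
    base = policy.tau_p * (1.0 - params.nq) * (1.0 - params.alpha)
    X = policy.phi * base
    Y = params.rho - params.chi * (1.0 - policy.phi) * base
    return X, Y


def pi_star_printed(params: ModelParams, policy: PolicyParams) -> float:
    """Closed-form steady-state survival probability (as-printed mode).

    ``pi* = b*delta^sigma*H*X^sigma / (mu*Y^sigma + H*X^sigma)`` with
    ``X`` and ``Y`` the composites of :func:`_printed_blocks`. Note that
    the absorption factor ``delta^sigma`` multiplies the numerator only.
    """
    X, Y = _printed_blocks(params, policy)
    s = params.sigma
    num = params.b * params.delta ** s * params.H * X ** s
    den = params.mu * Y ** s + params.H * X ** s
    return num / den


def s_hat_star_printed(params: ModelParams, policy: PolicyParams) -> float:
    """Closed-form steady-state saving rate (as-printed mode).

    Algebraically equal to ``beta*pi*(1-n*q)/(1+beta*pi)`` with ``pi``
    from :func:`pi_star_printed`.
    """
    X, Y = _printed_blocks(params, policy)
    s = params.sigma
    bds = params.b * params.delta ** s
    num = params.beta * bds * params.H * (1.0 - params.nq) * X ** s
    den = params.mu * Y ** s + (1.0 + params.beta * bds) * params.H * X ** s
    return num / den


def k_star_printed(params: ModelParams, policy: PolicyParams) -> float:
    """Closed-form steady-state capital per labor (as-printed mode)."""
    X, Y = _printed_blocks(params, policy)
    p, s = params, params.sigma
    tau, phi = policy.tau_p, policy.phi
    num = (
        p.A * p.beta * p.b * p.H * p.delta ** s
        * (phi * tau) ** s
        * (1.0 - tau)
        * (1.0 - p.nq) ** (1.0 + s)
        * (1.0 - p.alpha) ** (1.0 + s)
    )
    den = p.n * p.mu * Y ** s + p.n * (1.0 + p.beta) * p.H * p.delta ** s * X ** s
    return (num / den) ** (1.0 / (1.0 - p.alpha))


def _assemble(
    params: ModelParams,
    policy: PolicyParams,
    k: float,
    P: float,
    h: float,
    pi: float,
    s_hat: float,
    mode: str,
) -> SteadyState:
    R, w = factor_prices(k, params)
    g, m = fiscal_split(w, params, policy)
    return SteadyState(
        k_star=k,
        y_star=params.A * k ** params.alpha,
        P_star=P,
        h_star=h,
        pi_star=pi,
        s_hat_star=s_hat,
        w_star=w,
        R_period=R,
        r_annual=annualize_gross_return(R, params.period_years),
        g_star=g,
        m_star=m,
        dependency_ratio=dependency_ratio(pi, params.n),
        mode=mode,
    )


def steady_state_as_printed(params: ModelParams, policy: PolicyParams) -> SteadyState:
    """Evaluate the published closed-form steady state literally.

    k*, P*, pi*, and the saving rate come from the closed forms; the
    health stock is the fixed point of the accumulation law at the
    steady-state spending-to-pollution ratio, ``h* = (H/mu)*(g*/P*)**sigma``.
    All remaining quantities (output, factor prices, fiscal split,
    annualized return, dependency ratio) follow from k*.
    """
    _require_admissible(params, policy)
    X, Y = _printed_blocks(params, policy)
    k = k_star_printed(params, policy)
    y = params.A * k ** params.alpha
    P = Y * y / params.delta
    # g*/P* = delta*X/Y, independent of k: output cancels.
    h = (params.H / params.mu) * (params.delta * X / Y) ** params.sigma
    pi = pi_star_printed(params, policy)
    s_hat = s_hat_star_printed(params, policy)
    return _assemble(params, policy, k, P, h, pi, s_hat, mode="as_printed")


def steady_state_self_consistent(
    params: ModelParams,
    policy: PolicyParams,
    *,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> SteadyState:
    """Joint fixed point of the primitive transition laws.

    Iterates the one-period map (prices -> fiscal split -> health update
    -> survival -> savings -> capital and pollution laws) from the
    as-printed steady state until the relative change of (k, P, h)
    falls below ``tol``. A damping factor of 0.5 is applied to the
    capital update whenever the update direction flips, to suppress
    oscillation. This mode satisfies every primitive law exactly at its
    fixed point but differs slightly from the as-printed closed forms.
    """
    _require_admissible(params, policy)
    start = steady_state_as_printed(params, policy)
    k, P, h = start.k_star, start.P_star, start.h_star
    prev_dk = 0.0
    for _ in range(max_iter):
        R, w = factor_prices(k, params)
        g, _m = fiscal_split(w, params, policy)
        h_new = health_update(h, g, P, params)
        pi = survival_probability(h_new, params.b)
        hh = household_solution(w, pi, R, params, policy)
        k_new = hh.s / params.n
        P_new = pollution_transition(P, k, params, policy)
        dk = k_new - k
        if dk * prev_dk < 0:  # oscillation: damp the capital step
            k_new = k + 0.5 * dk
        prev_dk = dk
        rel = max(
            abs(k_new - k) / max(abs(k), 1e-300),
            abs(P_new - P) / max(abs(P), 1e-300),
            abs(h_new - h) / max(abs(h), 1e-300),
        )
        k, P, h = k_new, P_new, h_new
        if rel < tol:
            pi = survival_probability(h, params.b)
            bpi = params.beta * pi
            s_hat = bpi * (1.0 - params.nq) / (1.0 + bpi)
            return _assemble(params, policy, k, P, h, pi, s_hat, mode="self_consistent")
    raise ConvergenceError(
        f"steady-state fixed point not converged after {max_iter} iterations "
        f"(last state k={k:.6g}, P={P:.6g}, h={h:.6g})"
    )
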