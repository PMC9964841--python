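"""Primitive equations and closed-form steady states."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import envolg
from envolg import (
    DomainError,
    InvalidRegimeError,
    ModelParams,
    PolicyParams,
    annualize_gross_return,
    check_assumptions,
    dependency_ratio,
    factor_prices,
    fiscal_split,
    health_update,
    household_solution,
    pollution_transition,
    steady_state_as_printed,
    steady_state_self_consistent,
    survival_probability,
)
from envolg.core import pi_star_printed, s_hat_star_printed


# ---------------------------------------------------------------------------
# Survival function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "h, b, expected",
    [(0.0, 0.88, 0.0), (1.0, 0.88, 0.44), (1e9, 0.88, pytest.approx(0.88, abs=1e-6))],
)
def test_survival_known_points(h, b, expected):
    assert survival_probability(h, b) == expected


@given(h=st.floats(0, 1e6), b=st.floats(0.01, 0.99))
@settings(max_examples=200, derandomize=True)
def test_survival_bounded_and_increasing(h, b):
    pi = survival_probability(h, b)
    assert 0.0 <= pi < b
    assert survival_probability(h + 1.0, b) > pi


def test_survival_rejects_negative_health():
    with pytest.raises(DomainError):
        survival_probability(-0.1, 0.88)


# ---------------------------------------------------------------------------
# Health accumulation
# ---------------------------------------------------------------------------

def test_health_update_pure_depreciation(base_params):
    # g = 0: only the depreciated parental stock remains.
    out = health_update(2.0, 0.0, 1.0, base_params)
    assert out == pytest.approx((1 - base_params.mu) * 2.0, rel=1e-12)


def test_health_update_fixed_point(base_params):
    p = base_params
    g, P = 0.3, 1.2
    h_fix = (p.H / p.mu) * (g / P) ** p.sigma
    assert health_update(h_fix, g, P, p) == pytest.approx(h_fix, rel=1e-12)


def test_health_update_direct_arithmetic(base_params):
    # mu=0.85, H=3.7453, sigma=0.5, g/P=0.25 -> 0.15*h_prev + H*0.5
    p = base_params
    h_prev = 1.7
    expected = 0.15 * h_prev + p.H * 0.5
    assert health_update(h_prev, 0.25, 1.0, p) == pytest.approx(expected, rel=1e-12)


def test_health_update_rejects_nonpositive_pollution(base_params):
    with pytest.raises(DomainError):
        health_update(1.0, 0.1, 0.0, base_params)


# ---------------------------------------------------------------------------
# Production and factor prices
# ---------------------------------------------------------------------------

def test_factor_prices_symmetric_point(base_params):
    p = base_params.with_(A=1.0, alpha=0.5)
    R, w = factor_prices(1.0, p)
    assert (R, w) == (0.5, 0.5)


@given(A=st.floats(0.1, 10), alpha=st.floats(0.05, 0.95), k=st.floats(1e-3, 1e3))
@settings(max_examples=200, derandomize=True)
def test_factor_exhaustion(A, alpha, k, base_params):
    p = base_params.with_(A=A, alpha=alpha)
    R, w = factor_prices(k, p)
    assert R * k + w == pytest.approx(A * k ** alpha, rel=1e-12)


def test_factor_prices_rejects_nonpositive_capital(base_params):
    with pytest.raises(DomainError):
        factor_prices(0.0, base_params)


# ---------------------------------------------------------------------------
# Household problem
# ---------------------------------------------------------------------------

def test_household_no_survival_means_no_saving(base_params, base_policy):
    sol = household_solution(1.0, 0.0, 1.5, base_params, base_policy)
    assert sol.s == 0.0
    assert sol.c_old == 0.0
    disposable = (1 - base_params.nq) * (1 - base_policy.tau_p)
    assert sol.c_young == pytest.approx(disposable, rel=1e-12)


@given(w=st.floats(0.01, 100), pi=st.floats(0, 0.99), R=st.floats(0.1, 10))
@settings(max_examples=200, derandomize=True)
def test_household_budget_identity(w, pi, R, base_params, base_policy):
    sol = household_solution(w, pi, R, base_params, base_policy)
    disposable = w * (1 - base_params.nq) * (1 - base_policy.tau_p)
    assert sol.c_young + sol.s == pytest.approx(disposable, rel=1e-12)
    assert 0 <= sol.s_hat <= 1 - base_params.nq


def test_household_base_case_saving_rate(base_params, base_policy):
    """At the base-case survival probability the saving rate is 0.2857."""
    sol = household_solution(1.0, 0.59503, 1.5, base_params, base_policy)
    assert sol.s_hat == pytest.approx(0.2857, abs=1e-4)


# ---------------------------------------------------------------------------
# Fiscal split and pollution law
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi", [0.5, 0.86, 0.999])
def test_fiscal_split_balances(base_params, base_policy, phi):
    policy = base_policy.with_(phi=phi)
    g, m = fiscal_split(2.0, base_params, policy)
    revenue = policy.tau_p * 2.0 * (1 - base_params.nq)
    assert g + m == revenue  # exact split
    assert g == pytest.approx(phi * revenue, rel=1e-12)
    if phi == 0.5:
        assert g == pytest.approx(m, rel=1e-12)


def test_fiscal_split_direct_arithmetic(base_params, base_policy):
    g, _ = fiscal_split(1.0, base_params, base_policy)
    assert g == pytest.approx(0.86 * 0.046 * 0.935, rel=1e-12)


def test_pollution_full_absorption(base_params, base_policy):
    p = base_params.with_(delta=1 - 1e-15)
    out = pollution_transition(5.0, 1.0, p, base_policy)
    coeff = p.rho - p.chi * (1 - base_policy.phi) * base_policy.tau_p * (1 - p.nq) * (1 - p.alpha)
    assert out == pytest.approx(coeff * p.A, rel=1e-9)


def test_pollution_steady_state_is_fixed_point(base_params, base_policy):
    ss = steady_state_as_printed(base_params, base_policy)
    out = pollution_transition(ss.P_star, ss.k_star, base_params, base_policy)
    assert out == pytest.approx(ss.P_star, rel=1e-10)


def test_pollution_raises_when_abatement_exceeds_emissions(base_params):
    # Strong abatement with full absorption drives the stock negative.
    policy = PolicyParams(tau_p=0.5, phi=0.05)
    p = base_params.with_(delta=1 - 1e-15)
    with pytest.raises(InvalidRegimeError):
        pollution_transition(1e-12, 1.0, p, policy)


# ---------------------------------------------------------------------------
# Dependency ratio and annualization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pi, n, expected",
    [(0.0, 0.65, 0.0), (0.65, 0.65, 1.0), (0.5950, 0.65, pytest.approx(0.91538, abs=1e-5))],
)
def test_dependency_ratio(pi, n, expected):
    assert dependency_ratio(pi, n) == expected


def test_annualize_round_trip():
    assert annualize_gross_return(1.0, 30) == 0.0
    assert annualize_gross_return(1.02 ** 30, 30) == pytest.approx(0.02, rel=1e-12)
    with pytest.raises(DomainError):
        annualize_gross_return(0.0, 30)


# ---------------------------------------------------------------------------
# Assumption diagnostics
# ---------------------------------------------------------------------------

def test_assumptions_pass_at_base_case(base_params, base_policy):
    report = check_assumptions(base_params, base_policy)
    assert report.all_ok
    assert report.policy_threshold == pytest.approx(0.06 / (0.85 * 0.935 * 0.4), rel=1e-12)
    assert report.policy_threshold == pytest.approx(0.18874, abs=5e-6)
    assert report.policy_threshold < report.tau_p_bound


def test_assumption1_failure_reported(base_params, base_policy):
    bad = base_params.with_(rho=0.9)
    report = check_assumptions(bad, base_policy)
    assert not report.assumption1_ok
    with pytest.raises(InvalidRegimeError, match="Assumption 1"):
        steady_state_as_printed(bad, base_policy)


def test_assumption2_failure_reported(base_params):
    # Heavy abatement share at a high tax rate violates positivity of P*.
    policy = PolicyParams(tau_p=0.9, phi=0.05)
    report = check_assumptions(base_params, policy)
    assert not report.assumption2_ok
    with pytest.raises(InvalidRegimeError, match="Assumption 2"):
        steady_state_as_printed(base_params, policy)


# ---------------------------------------------------------------------------
# Closed-form steady state (as-printed mode)
# ---------------------------------------------------------------------------

def test_base_case_reproduces_published_values(base_params, base_policy):
    ss = steady_state_as_printed(base_params, base_policy)
    assert ss.pi_star == pytest.approx(0.5950, abs=5e-5)
    assert ss.s_hat_star == pytest.approx(0.2857, abs=5e-5)
    assert 100 * ss.r_annual == pytest.approx(4.45, abs=5e-3)
    assert ss.mode == "as_printed"


def test_steady_state_identities(base_params, base_policy):
    ss = steady_state_as_printed(base_params, base_policy)
    assert ss.R_period * ss.k_star + ss.w_star == pytest.approx(ss.y_star, rel=1e-10)
    revenue = base_policy.tau_p * ss.w_star * (1 - base_params.nq)
    assert ss.g_star + ss.m_star == pytest.approx(revenue, rel=1e-12)
    assert ss.P_star > 0
    assert 0 < ss.pi_star < base_params.b
    assert ss.dependency_ratio == pytest.approx(ss.pi_star / base_params.n, rel=1e-12)


def test_saving_rate_formula_consistent_with_survival(base_params, base_policy):
    """The printed saving-rate and survival closed forms are mutually
    consistent: s_hat = beta*pi*(1-nq)/(1+beta*pi)."""
    pi = pi_star_printed(base_params, base_policy)
    s_hat = s_hat_star_printed(base_params, base_policy)
    p = base_params
    assert s_hat == pytest.approx(p.beta * pi * (1 - p.nq) / (1 + p.beta * pi), rel=1e-10)


def test_capital_vanishes_as_tax_vanishes(base_params, base_policy):
    ss = steady_state_as_printed(base_params, base_policy.with_(tau_p=1e-8))
    assert ss.k_star < 1e-6


def test_closed_forms_deterministic(base_params, base_policy):
    a = steady_state_as_printed(base_params, base_policy)
    b = steady_state_as_printed(base_params, base_policy)
    assert a == b  # bit-identical dataclasses


# ---------------------------------------------------------------------------
# Self-consistent mode
# ---------------------------------------------------------------------------

def test_self_consistent_satisfies_primitive_fixed_points(base_params, base_policy):
    ss = steady_state_self_consistent(base_params, base_policy)
    p, pol = base_params, base_policy
    assert pollution_transition(ss.P_star, ss.k_star, p, pol) == pytest.approx(
        ss.P_star, rel=1e-10
    )
    assert health_update(ss.h_star, ss.g_star, ss.P_star, p) == pytest.approx(
        ss.h_star, rel=1e-10
    )
    R, w = factor_prices(ss.k_star, p)
    sol = household_solution(w, ss.pi_star, R, p, pol)
    assert sol.s / p.n == pytest.approx(ss.k_star, rel=1e-10)
    assert ss.pi_star == pytest.approx(
        survival_probability(ss.h_star, p.b), rel=1e-12
    )


def test_modes_differ_by_small_finite_gap(base_params, base_policy):
    """The printed closed forms and the primitive fixed point disagree by
    a small but nonzero amount (the absorption factor enters them
    differently)."""
    printed = steady_state_as_printed(base_params, base_policy)
    consistent = steady_state_self_consistent(base_params, base_policy)
    gap = abs(printed.pi_star - consistent.pi_star)
    assert 1e-4 < gap < 0.05
    assert printed.k_star != consistent.k_star
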