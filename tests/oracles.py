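"""Independent numeric oracles used to pin expected values.

These maximise the Poisson likelihoods directly by bounded 1-D numerical
optimisation; they never call the closed-form score implementations they
are used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def _xlogy(x, y):
    return 0.0 if x == 0 else x * np.log(y)


def _maximize_1d(neg_fun, lo, hi):
    res = minimize_scalar(
        neg_fun, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    return -res.fun


def kulldorff_numeric_llr(c, b, c_tot, b_tot):
    """log [max_{eta>=mu} L1(eta, mu) / max_mu L0(mu)] for Poisson counts.

    L1: inside events ~ Poisson(eta*b), outside ~ Poisson(mu*(B-b));
    L0: a single rate mu everywhere.  The H1 log likelihood separates in
    eta and mu, so each factor is maximised by bounded scalar search; if
    the unconstrained optimum violates eta >= mu the constrained optimum
    sits on the boundary eta = mu, where H1 collapses to H0.
    """
    c, b, c_tot, b_tot = float(c), float(b), float(c_tot), float(b_tot)
    c_out = c_tot - c
    b_out = b_tot - b
    hi = max(2.0 * c_tot / max(b - b_out + b_tot, 1e-9), 10.0 * (c + 1) / max(b, 1e-9), 1.0)

    def l_inside(eta):
        return _xlogy(c, eta * b) - eta * b

    def l_outside(mu):
        return _xlogy(c_out, mu * b_out) - mu * b_out

    # H0: counts Poisson(mu*base_i); aggregated log-lik (up to data-only
    # constants shared with H1, which cancel in the ratio)
    def l0_full(mu):
        return _xlogy(c, mu * b) - mu * b + _xlogy(c_out, mu * b_out) - mu * b_out

    l0_max = _maximize_1d(lambda m: -l0_full(m), 1e-12, hi)
    eta_hat = _maximize_1d_arg(l_inside, 1e-12, hi)
    mu_hat = _maximize_1d_arg(l_outside, 1e-12, hi)
    if eta_hat > mu_hat:
        l1_max = l_inside(eta_hat) + l_outside(mu_hat)
    else:
        l1_max = l0_max
    return max(l1_max - l0_max, 0.0)


def _maximize_1d_arg(fun, lo, hi):
    res = minimize_scalar(
        lambda x: -fun(x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    return res.x


def expectation_numeric_llr(c, b):
    """log [max_{mu>=1} Poisson(c; mu*b) / Poisson(c; b)]."""
    c, b = float(c), float(b)

    def ll(mu):
        return _xlogy(c, mu * b) - mu * b

    hi = max(10.0 * (c + 1) / b, 2.0)
    best = _maximize_1d(lambda m: -ll(m), 1.0, hi)
    return max(best - ll(1.0), 0.0)
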