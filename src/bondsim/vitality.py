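"""Quality, foraging, resource balance, mortality, and marginal analytics.

Each individual carries a fixed phenotypic quality ``q`` in [0, 1] drawn at
birth (Beta-distributed by default).  Quality sets the nightly foraging
success probability ``p_s(q) = ps0 + ps1 q`` and the start-of-day resource
balance ``zeta_0(q) = slope * q``; with the defaults an average-quality
individual fails to forage — and so needs help — about one day in ten.

Daily survival follows a declining logistic in foraging success ``z`` and
the end-of-day resource balance ``zeta``::

    mu(z, zeta) = (1 - mu_0) / (1 + exp(a + b z + c zeta)) + mu_0

with floor ``mu_0``.  Because the curve is convex over the relevant range,
a unit of food is worth far more to an unsuccessful, resource-poor forager
than it costs a successful one: the marginal benefit–cost machinery below
quantifies that asymmetry, which is what makes helping cheap to give and
valuable to receive in this model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "draw_quality",
    "draw_forage",
    "mortality_rate",
    "mortality_dzeta",
    "marginal_benefit_cost",
    "margin_curve",
]


def draw_quality(params, rng: np.random.Generator, size=None):
    """Draw phenotypic quality q ~ Beta(a, b); independent at every birth."""
    qa, qb = params.q_dist
    return rng.beta(qa, qb, size=size)


def draw_forage(q, params, rng: np.random.Generator):
    """Bernoulli foraging outcome z with success probability p_s(q)."""
    p = params.p_s(q)
    out = (rng.random(np.shape(p)) < p).astype(np.int8)
    return out if out.ndim else int(out)


def mortality_rate(z, zeta, params):
    """Daily death probability mu(z, zeta); vectorises elementwise.

    Strictly decreasing in both the foraging state and the resource
    balance, with limits mu_0 (zeta -> +inf) and 1 - ... < 1.
    """
    s = params.a + params.b * np.asarray(z, dtype=float) + params.c * np.asarray(zeta, dtype=float)
    return (1.0 - params.mu_0) / (1.0 + np.exp(s)) + params.mu_0


def mortality_dzeta(z, zeta, params):
    """Closed-form derivative d mu / d zeta (negative everywhere)."""
    s = params.a + params.b * np.asarray(z, dtype=float) + params.c * np.asarray(zeta, dtype=float)
    es = np.exp(s)
    return -(1.0 - params.mu_0) * params.c * es / (1.0 + es) ** 2


def marginal_benefit_cost(u: float, q_donor: float, q_recipient: float, params,
                          *, step: float = 1e-6, method: str = "fd") -> float:
    """Marginal benefit–cost ratio of transferring a little more food.

    The recipient is an unsuccessful forager (z = 0) at balance
    ``zeta_0(q_recipient) + u``; the donor is a successful forager (z = 1)
    at ``zeta_0(q_donor) - u``.  The ratio is
    ``|d mu/d zeta|`` at the recipient's state over ``|d mu/d zeta|`` at the
    donor's state — how much extra survival a marginal unit buys the
    recipient per unit of survival it costs the donor.

    ``method='fd'`` uses a central finite difference of
    :func:`mortality_rate` with the given step; ``method='exact'`` uses the
    closed form (the two agree to many significant digits and serve as
    mutual checks).
    """
    if u < 0:
        raise ValueError(f"transfer amount must be >= 0: {u}")
    zr = float(params.zeta_0(q_recipient)) + u
    zd = float(params.zeta_0(q_donor)) - u
    if method == "exact":
        benefit = abs(mortality_dzeta(0, zr, params))
        cost = abs(mortality_dzeta(1, zd, params))
    elif method == "fd":
        benefit = abs(mortality_rate(0, zr + step, params)
                      - mortality_rate(0, zr - step, params)) / (2 * step)
        cost = abs(mortality_rate(1, zd + step, params)
                   - mortality_rate(1, zd - step, params)) / (2 * step)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(benefit / cost)


def margin_curve(params, u_max: float = 0.5, n: int = 51,
                 q: float = 0.5) -> "np.ndarray":
    """Benefit–cost ratio as a function of the amount transferred.

    Returns an (n, 2) array of (u, ratio) for average-quality (or given q)
    donor and recipient; used by the ``bondsim margins`` CLI subcommand.
    """
    us = np.linspace(0.0, u_max, n)
    return np.column_stack([
        us, [marginal_benefit_cost(u, q, q, params) for u in us]])
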