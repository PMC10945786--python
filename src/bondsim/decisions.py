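"""Daily choices: whom to ask for help, and which subgroup to join.

Partner choice is a soft-max over effective bond strengths: a needy
individual asks partner ``j`` with probability proportional to
``exp(y_ij)``, restricted to subgroup-mates it perceives as successful
foragers (a success is detected with probability ``p_d``; a failed forager
is never mistaken for a success).  Up to ``n_ask_max`` distinct partners are
asked, re-drawing from the remaining candidates.

Subgroup choice mixes exploration with exploitation: with probability
``eps_p`` a uniformly random subgroup, otherwise a soft-max with
inverse-temperature ``beta`` over the individual's running estimates
``yhat`` of the average effective bond strength it has experienced in each
subgroup.  For two subgroups this reduces to

    P(better) = (1 - eps_p) / (1 + exp(-beta * dy)) + eps_p / 2.

An optional crowding penalty ``exp(-kappa * max(0, n_k - G) / G)`` can
down-weight over-occupied subgroups; it is off (``kappa = 0``) by default.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "perceive_success",
    "softmax_probs",
    "choose_partner",
    "subgroup_probs",
    "choose_subgroup",
    "update_subgroup_estimate",
    "select_ask_targets",
]


def perceive_success(z, p_d: float, rng: np.random.Generator):
    """Whether candidates are perceived as successful foragers.

    A true success (``z = 1``) is detected with probability ``p_d``; a
    failure (``z = 0``) is never perceived as a success.  Vectorised over
    ``z``.
    """
    z = np.asarray(z)
    hit = rng.random(z.shape) < p_d
    out = (z == 1) & hit
    return out if out.ndim else bool(out)


def softmax_probs(y: np.ndarray) -> np.ndarray:
    """Overflow-safe soft-max probabilities for value vector ``y``."""
    y = np.asarray(y, dtype=float)
    e = np.exp(y - y.max())
    return e / e.sum()


def choose_partner(y_values, rng: np.random.Generator) -> int:
    """Soft-max draw over effective bond strengths; returns the index.

    Raises ``ValueError`` on an empty candidate set (the caller must skip
    the ask instead).
    """
    y_values = np.asarray(y_values, dtype=float)
    if y_values.size == 0:
        raise ValueError("choose_partner requires at least one candidate")
    p = softmax_probs(y_values)
    # inverse-CDF draw (cheaper than rng.choice for tiny candidate sets)
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right").clip(0, p.size - 1))


def subgroup_probs(yhat_row, beta: float, eps_p: float,
                   occupancy=None, kappa: float = 0.0, G: float | None = None) -> np.ndarray:
    """Choice distribution over the K subgroups.

    Mixture of a uniform exploration component (weight ``eps_p``) and a
    soft-max over ``beta * yhat``; each probability lies in
    ``[eps_p/K, 1 - eps_p*(K-1)/K]``.
    """
    yhat_row = np.asarray(yhat_row, dtype=float)
    K = yhat_row.size
    logw = beta * yhat_row
    if kappa > 0.0 and occupancy is not None:
        if G is None:
            raise ValueError("crowding penalty requires the expected occupancy G")
        crowd = np.maximum(0.0, np.asarray(occupancy, dtype=float) - G) / G
        logw = logw - kappa * crowd
    p = softmax_probs(logw)
    return (1.0 - eps_p) * p + eps_p / K


def choose_subgroup(yhat_row, beta: float, eps_p: float, rng: np.random.Generator,
                    occupancy=None, kappa: float = 0.0, G: float | None = None) -> int:
    """Sample a subgroup index from :func:`subgroup_probs`."""
    p = subgroup_probs(yhat_row, beta, eps_p, occupancy=occupancy, kappa=kappa, G=G)
    return int(rng.choice(p.size, p=p))


def update_subgroup_estimate(yhat: float, observed_mean_y: float, rate: float) -> float:
    """EMA update of the per-subgroup average-bond estimate.

    Applied only for the subgroup visited today; an individual alone in its
    subgroup observes a mean of 0.  Estimates of unvisited subgroups are
    left untouched by the caller.
    """
    return yhat + rate * (observed_mean_y - yhat)


def select_ask_targets(candidate_ids, z, y_values, p_d: float, n_ask_max: int,
                       rng: np.random.Generator) -> list[int]:
    """Ordered list of up to ``n_ask_max`` distinct partners to ask.

    ``candidate_ids``, ``z`` and ``y_values`` describe the requester's
    subgroup-mates: identity, true foraging state, and the requester's
    effective bond strength toward each (including any new-partner
    increment).  Perception filters the candidates, then each target is a
    fresh soft-max draw over the perceived-successful candidates not yet
    chosen.  Returns fewer targets (possibly none) when candidates run out.
    """
    candidate_ids = np.asarray(candidate_ids)
    y_values = np.asarray(y_values, dtype=float)
    mask = perceive_success(np.asarray(z), p_d, rng)
    mask = np.atleast_1d(mask).copy()
    targets: list[int] = []
    while len(targets) < n_ask_max and mask.any():
        idx = np.flatnonzero(mask)
        j = idx[choose_partner(y_values[idx], rng)]
        targets.append(int(candidate_ids[j]))
        mask[j] = False
    return targets
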