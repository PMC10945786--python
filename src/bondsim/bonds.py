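"""Social-bond dynamics: bond strength, association estimate, effective bond.

A directed pair (focal -> partner) carries three coupled quantities:

* bond strength ``x`` — a saturating, Rescorla–Wagner-style learned value.
  Starting at ``x_s``, each helping exchange of amount ``u`` moves it toward
  the asymptote ``x_a``::

      x' = x + alpha * u * (x_a - x) / (x_a - x_s)

  Both members of the pair update after each donation, with the same ``u``
  but each with its own learning rate ``alpha`` — the bond is bidirectional
  even when help initially flows one way.

* association estimate ``rho`` in [0, 1] — an exponentially weighted
  frequency of sharing a subgroup, updated once per day.

* helping balance ``w`` — cumulative amount received from the partner minus
  amount donated to the partner; exactly antisymmetric within a pair.

The quantity that drives behaviour is the *effective* bond strength
``y = rho * x``: a strong bond to a partner one no longer associates with
decays toward zero.  A heritable increment ``dy_new`` is added to ``y`` for
never-helped partners, tilting individuals toward (positive values) or away
from (negative values) starting new relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BondMemory", "update_bond", "update_association", "effective_bond"]


@dataclass
class BondMemory:
    """State of one directed pair: focal's view of a partner."""

    x: float            # bond strength, in [x_s, x_a]
    rho: float = 0.0    # association estimate, in [0, 1]
    w: float = 0.0      # helping balance: received from partner - donated to partner
    ever_donated: bool = False   # focal has donated to partner at least once
    ever_received: bool = False  # focal has received from partner at least once
    total_donated: float = 0.0
    total_received: float = 0.0
    n_donated: int = 0
    n_received: int = 0


def update_bond(x, alpha, u, params):
    """One bond-strength update after a helping amount ``u``.

    Returns ``x + alpha * u * (x_a - x) / (x_a - x_s)``, clamped at ``x_a``
    (a large ``alpha * u`` would otherwise overshoot the asymptote).  Works
    elementwise on arrays.

    Raises ``ValueError`` if ``x`` lies outside ``[x_s, x_a]``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < params.x_s - 1e-12) or np.any(x > params.x_a + 1e-12):
        raise ValueError(
            f"bond strength outside [{params.x_s}, {params.x_a}]: {x!r}")
    x_new = x + np.asarray(alpha) * np.asarray(u) * (params.x_a - x) / (params.x_a - params.x_s)
    out = np.minimum(x_new, params.x_a)
    return out if out.ndim else float(out)


def update_association(rho, together, lam_rho):
    """Daily exponential tracking of subgroup co-membership.

    ``rho' = rho + lam_rho * (1{together} - rho)``; the estimate stays in
    [0, 1] and equals the exponentially weighted frequency with which the
    pair shared a subgroup.  Works elementwise on arrays.
    """
    rho = np.asarray(rho, dtype=float)
    ind = np.asarray(together, dtype=float)
    out = rho + lam_rho * (ind - rho)
    return out if out.ndim else float(out)


def effective_bond(mem: BondMemory, dy_new: float = 0.0, *, new_pair: bool | None = None) -> float:
    """Effective bond strength ``y = rho * x`` with the new-partner increment.

    ``dy_new`` is added iff the pair counts as new for the purpose at hand.
    By default "new" means the focal has neither donated to nor received from
    the partner; pass ``new_pair`` explicitly for the directional criteria
    the behaviour rules use (donor side: never donated; asker side: never
    received from the candidate).
    """
    if new_pair is None:
        new_pair = not (mem.ever_donated or mem.ever_received)
    y = mem.rho * mem.x
    if new_pair:
        y += dy_new
    return y
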