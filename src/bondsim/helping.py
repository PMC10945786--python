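"""Donation amounts and transfer bookkeeping.

The amount a donor ``i`` gives a requester ``j`` is the product of two
factors, ``u = H_y * H_w``:

* the bond gate ``H_y = 1 / (1 + exp(-d (y - y_0)))`` — a steep logistic in
  the donor's effective bond strength toward the requester, so help flows
  almost exclusively through sufficiently strong, recently maintained bonds
  (or to brand-new partners when the heritable increment ``dy_new`` is
  positive);

* the capacity/reciprocity scale
  ``H_w = h_a (g_0 + (1 - g_0) q) / (1 + exp(-h_s w - b z - c zeta))`` —
  bounded by the heritable asymptote ``h_a``, scaled by the donor's quality
  ``q``, and discounted through a logistic in the pairwise helping balance
  ``w`` (reciprocity enforcement via the heritable sensitivity ``h_s``), the
  donor's foraging success ``z`` and its current resource balance ``zeta``.
  A donor whose balance with a partner has gone far negative gives that
  partner almost nothing; a donor that has already given much today (low
  ``zeta``) gives less.

A transfer moves ``u`` from the donor's resource balance to the
recipient's, moves the pairwise helping balances antisymmetrically, and
strengthens both directed bond strengths with each individual's own
learning rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bonds import BondMemory, update_bond

__all__ = ["TransferEvent", "helping_gate", "helping_scale",
           "donation_amount", "apply_transfer"]


@dataclass(frozen=True)
class TransferEvent:
    """One ask and its (possibly zero) donation."""

    day: int
    donor: int
    recipient: int
    amount: float
    H_y: float
    H_w: float
    new_pair: bool  # donor had never donated to this recipient before


def _logistic(s):
    """1 / (1 + exp(-s)), overflow-safe for scalars and arrays."""
    if isinstance(s, float):  # fast scalar path (hot in the engine's ask loop)
        if s < -700.0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-s)) if s < 700.0 else 1.0
    s = np.asarray(s, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-s))


def helping_gate(y, d: float, y_0: float):
    """Bond gate ``H_y``: logistic in the effective bond strength."""
    if isinstance(y, float):
        return _logistic(d * (y - y_0))
    return _logistic(d * (np.asarray(y, dtype=float) - y_0))


def helping_scale(q, w, z, zeta, h_a, h_s, params):
    """Capacity/reciprocity scale ``H_w``; vectorises elementwise."""
    if isinstance(w, float) and isinstance(zeta, float):
        num = float(h_a) * (params.g_0 + (1.0 - params.g_0) * float(q))
        return num * _logistic(float(h_s) * w + params.b * float(z) + params.c * zeta)
    num = np.asarray(h_a, dtype=float) * (params.g_0 + (1.0 - params.g_0) * np.asarray(q, dtype=float))
    s = (np.asarray(h_s, dtype=float) * np.asarray(w, dtype=float)
         + params.b * np.asarray(z, dtype=float)
         + params.c * np.asarray(zeta, dtype=float))
    return num * _logistic(s)


def donation_amount(q, w, z, zeta, y, h_a, h_s, params, *,
                    dy_new: float = 0.0, new_pair: bool = False):
    """Amount donated: ``u = H_y * H_w``.

    ``y`` is the donor's plain effective bond ``rho * x`` toward the
    requester; ``dy_new`` is added inside the gate iff this would be the
    donor's first donation to the requester (``new_pair``).  ``u = 0`` is a
    valid outcome (no help given).  Returns ``(u, H_y, H_w)``.
    """
    y_eff = y + (dy_new if new_pair else 0.0)
    hy = helping_gate(y_eff, params.d, params.y_0)
    hw = helping_scale(q, w, z, zeta, h_a, h_s, params)
    return hy * hw, hy, hw


def apply_transfer(donor_mem: BondMemory, recipient_mem: BondMemory,
                   u: float, alpha_donor: float, alpha_recipient: float,
                   params) -> None:
    """Apply a donation of ``u`` to the pair's directed memories.

    ``donor_mem`` is the donor's memory of the recipient and vice versa.
    Helping balances move antisymmetrically (balance = received − donated),
    both bond strengths update with the same ``u`` under each individual's
    own learning rate, and cumulative totals, counts and first-donation
    flags are maintained.  The caller moves the resource balances
    (``zeta_donor -= u``, ``zeta_recipient += u``).

    A ``u = 0`` ask changes nothing (the bond increment is proportional to
    ``u`` and the flags only flip on a positive amount).
    """
    if u < 0:
        raise ValueError(f"negative transfer amount: {u}")
    donor_mem.w -= u        # donor: received - donated falls
    recipient_mem.w += u
    donor_mem.x = update_bond(donor_mem.x, alpha_donor, u, params)
    recipient_mem.x = update_bond(recipient_mem.x, alpha_recipient, u, params)
    if u > 0:
        donor_mem.total_donated += u
        recipient_mem.total_received += u
        donor_mem.n_donated += 1
        recipient_mem.n_received += 1
        donor_mem.ever_donated = True
        recipient_mem.ever_received = True
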