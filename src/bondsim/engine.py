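"""The daily scheduler: groups, subgroups, helping, survival, evolution.

A population of ``n_groups`` fixed-size groups of ``N`` individuals lives in
days.  Each day, in order:

1. every living individual picks one of its group's ``K`` subgroups
   (exploration-mixed soft-max over its per-subgroup bond estimates);
2. association estimates ``rho`` are updated for every living within-group
   ordered pair from today's co-membership;
3. resource balances reset to ``zeta_0(q)`` and nightly foraging outcomes
   ``z`` are drawn;
4. unsuccessful foragers, in uniformly random order, each ask up to
   ``n_ask_max`` perceived-successful subgroup-mates for help; donations
   ``u = H_y * H_w`` are computed and applied immediately (so a generous
   donor's falling balance throttles its later gifts);
5. per-subgroup bond estimates are updated from today's companions;
6. mortality is drawn from the end-of-day state and deaths applied;
7. every ``T`` days the dead are replaced by offspring of parents drawn
   uniformly from the global living population.

State is stored in group-blocked arrays (pairwise quantities as
``(n_groups, N, N)`` matrices), which keeps a full day at a few hundred
individuals in the sub-millisecond range.  Runs are bit-reproducible from
``(config, seed)``.

Experiment variants
-------------------
``baseline`` is the full model.  ``generalized_reciprocity`` removes
individual recognition: each individual keeps a single pooled bond strength
and pooled helping balance toward "anyone in the group" (association is
pinned at 1) and picks whom to ask uniformly among perceived successes.
Independent of the variant, any trait may be frozen at a fixed value via
the trait configuration (e.g. ``h_s = 0`` to switch reciprocity enforcement
off, or ``dy_new < 0`` to force initial caution toward strangers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics, vitality
from .decisions import select_ask_targets
from .genetics import ExtinctionError
from .helping import helping_gate, helping_scale
from .params import TRAIT_NAMES, ModelParams, SimConfig, dumps_config, validate_config

__all__ = ["WorldState", "SimOutput", "init_world", "run_day",
           "run_simulation", "write_outputs", "ExtinctionError"]

_IDX = {t: k for k, t in enumerate(TRAIT_NAMES)}

TRANSFER_COLUMNS = ["day", "donor", "recipient", "amount", "Hy", "Hw",
                    "new_pair", "rho", "established"]
LIFE_COLUMNS = ["id", "group", "born_day", "death_day", "lifespan", "q",
                "alpha", "beta", "dy_new", "h_a", "h_s",
                "total_donated", "total_received", "n_donated", "n_received",
                "n_partners", "top_bond", "top_total_help",
                "days_observed", "days_returned"]


@dataclass
class WorldState:
    """Complete mutable simulation state (group-blocked arrays)."""

    config: SimConfig
    params: ModelParams
    rng: np.random.Generator
    day: int = 0
    next_id: int = 0

    # per-individual, shape (n_groups, N)
    ids: np.ndarray = None
    born_day: np.ndarray = None
    q: np.ndarray = None
    z: np.ndarray = None
    zeta: np.ndarray = None
    alive: np.ndarray = None
    subgroup: np.ndarray = None
    prev_subgroup: np.ndarray = None
    traits: np.ndarray = None          # (n_groups, N, 5)
    yhat: np.ndarray = None            # (n_groups, N, K)

    # pairwise (focal, partner), shape (n_groups, N, N); baseline variant
    x: np.ndarray = None
    rho: np.ndarray = None
    w: np.ndarray = None
    donated: np.ndarray = None         # donated[g, i, j]: i has donated to j
    initiated: np.ndarray = None       # i made the pair's first donation
    tot_don: np.ndarray = None         # cumulative i -> j amounts
    n_don: np.ndarray = None

    # pooled memories; generalized-reciprocity variant
    pooled_x: np.ndarray = None
    pooled_w: np.ndarray = None
    pooled_donated: np.ndarray = None

    # lifetime accumulators, shape (n_groups, N)
    life_donated: np.ndarray = None
    life_received: np.ndarray = None
    life_n_don: np.ndarray = None
    life_n_rec: np.ndarray = None
    n_partners: np.ndarray = None
    top_x: np.ndarray = None
    top_help: np.ndarray = None
    ret_obs: np.ndarray = None
    ret_same: np.ndarray = None

    # logs
    recording: bool = False
    transfers: list = field(default_factory=list)
    life_records: list = field(default_factory=list)
    trait_rows: list = field(default_factory=list)
    rho_samples: list = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.config.n_groups

    @property
    def pooled(self) -> bool:
        return self.config.variant == "generalized_reciprocity"

    def alive_traits(self) -> np.ndarray:
        return self.traits[self.alive]

    def check_invariants(self) -> None:
        """Cheap structural assertions, mainly for tests."""
        p = self.params
        a = self.alive
        # newborns from a same-day replacement pick a subgroup next morning
        placed = a & (self.born_day < self.day)
        assert np.all((self.subgroup[placed] >= 0)
                      & (self.subgroup[placed] < self.config.n_subgroups)) \
            or self.day == 0
        if not self.pooled:
            assert np.all(self.x >= p.x_s - 1e-9) and np.all(self.x <= p.x_a + 1e-9)
            assert np.all((self.rho >= -1e-12) & (self.rho <= 1 + 1e-12))
            assert np.allclose(self.w, -np.swapaxes(self.w, 1, 2))
        assert self.ids[a].size == np.unique(self.ids[a]).size


def init_world(config: SimConfig) -> WorldState:
    """Build the founder population from a validated configuration."""
    config = validate_config(config)
    p = config.params
    Gn, N, K = config.n_groups, config.group_size, config.n_subgroups
    rng = np.random.default_rng(config.seed)
    w = WorldState(config=config, params=p, rng=rng)

    w.ids = np.arange(Gn * N, dtype=np.int64).reshape(Gn, N)
    w.next_id = Gn * N
    w.born_day = np.zeros((Gn, N), dtype=np.int64)
    w.q = vitality.draw_quality(p, rng, size=(Gn, N))
    w.z = np.zeros((Gn, N), dtype=np.int8)
    w.zeta = p.zeta_0(w.q)
    w.alive = np.ones((Gn, N), dtype=bool)
    w.subgroup = np.full((Gn, N), -1, dtype=np.int64)
    w.prev_subgroup = np.full((Gn, N), -1, dtype=np.int64)

    start = config.traits.start_array()
    scales = config.mutation.scale_array() * config.traits.jitter
    jit = rng.laplace(0.0, 1.0, size=(Gn, N, 5)) * scales
    w.traits = genetics.clip_traits(start + jit, config.traits)

    w.yhat = np.zeros((Gn, N, K))
    w.x = np.full((Gn, N, N), p.x_s)
    w.rho = np.zeros((Gn, N, N))
    w.w = np.zeros((Gn, N, N))
    w.donated = np.zeros((Gn, N, N), dtype=bool)
    w.initiated = np.zeros((Gn, N, N), dtype=bool)
    w.tot_don = np.zeros((Gn, N, N))
    w.n_don = np.zeros((Gn, N, N), dtype=np.int32)
    w.pooled_x = np.full((Gn, N), p.x_s)
    w.pooled_w = np.zeros((Gn, N))
    w.pooled_donated = np.zeros((Gn, N), dtype=bool)

    for name in ("life_donated", "life_received", "top_x", "top_help"):
        setattr(w, name, np.zeros((Gn, N)))
    for name in ("life_n_don", "life_n_rec", "n_partners", "ret_obs", "ret_same"):
        setattr(w, name, np.zeros((Gn, N), dtype=np.int64))
    w.top_x[:] = np.nan
    return w


# ---------------------------------------------------------------------------
# daily steps

def _choose_subgroups(w: WorldState) -> None:
    p, cfg = w.params, w.config
    K = cfg.n_subgroups
    beta = w.traits[..., _IDX["beta"]]
    logw = beta[..., None] * w.yhat
    if p.kappa > 0.0 and w.day > 1:
        # crowding penalty from yesterday's occupancy
        G = cfg.expected_subgroup_size
        occ = np.stack([(w.prev_subgroup == k) & w.alive for k in range(K)],
                       axis=-1).sum(axis=1, keepdims=True)
        logw = logw - p.kappa * np.maximum(0.0, occ - G) / G
    logw -= logw.max(axis=-1, keepdims=True)
    e = np.exp(logw)
    sm = e / e.sum(axis=-1, keepdims=True)
    probs = (1.0 - p.eps_p) * sm + p.eps_p / K
    u = w.rng.random(beta.shape)
    choice = (u[..., None] < np.cumsum(probs, axis=-1)).argmax(axis=-1)
    w.subgroup = np.where(w.alive, choice, -1)

    seen = w.alive & (w.prev_subgroup >= 0)
    w.ret_obs += seen
    w.ret_same += seen & (w.subgroup == w.prev_subgroup)
    w.prev_subgroup = w.subgroup.copy()


def _update_associations(w: WorldState) -> None:
    if w.pooled:
        return
    lam = w.params.lam_rho
    pair = w.alive[:, :, None] & w.alive[:, None, :]
    together = (w.subgroup[:, :, None] == w.subgroup[:, None, :]) & pair
    np.einsum("gii->gi", together)[:] = False
    upd = w.rho + lam * (together.astype(float) - w.rho)
    mask = pair.copy()
    np.einsum("gii->gi", mask)[:] = False
    w.rho = np.where(mask, upd, w.rho)


def _ask_round(w: WorldState) -> None:
    p = w.params
    Gn, N = w.q.shape
    dy_i = _IDX["dy_new"]
    al_i, ha_i, hs_i = _IDX["alpha"], _IDX["h_a"], _IDX["h_s"]
    flat = np.flatnonzero(w.alive.reshape(-1) & (w.z.reshape(-1) == 0))
    order = w.rng.permutation(flat.size)
    record = w.recording and w.config.record_transfers
    for f in flat[order]:
        g, i = divmod(int(f), N)
        if not w.alive[g, i]:  # pragma: no cover - deaths happen after asks
            continue
        mates = np.flatnonzero(w.alive[g] & (w.subgroup[g] == w.subgroup[g, i]))
        mates = mates[mates != i]
        if mates.size == 0:
            continue
        if w.pooled:
            y_ask = np.zeros(mates.size)  # uniform choice among perceived successes
        else:
            y_ask = w.rho[g, i, mates] * w.x[g, i, mates]
            never_received = ~w.donated[g, mates, i]
            y_ask = y_ask + never_received * w.traits[g, i, dy_i]
        targets = select_ask_targets(mates, w.z[g, mates], y_ask,
                                     p.p_d, p.n_ask_max, w.rng)
        for j in targets:
            if w.pooled:
                new_pair = not w.pooled_donated[g, j]
                y_d = w.pooled_x[g, j]
                w_d = w.pooled_w[g, j]
                rho_pair = 1.0
                established = bool(w.pooled_donated[g, j] and w.pooled_donated[g, i])
            else:
                new_pair = not w.donated[g, j, i]
                y_d = w.rho[g, j, i] * w.x[g, j, i]
                w_d = w.w[g, j, i]
                rho_pair = float(w.rho[g, j, i])
                # both directions exchanged before this transfer
                established = bool(w.donated[g, j, i] and w.donated[g, i, j])
            y_eff = y_d + (w.traits[g, j, dy_i] if new_pair else 0.0)
            hy = float(helping_gate(y_eff, p.d, p.y_0))
            hw = float(helping_scale(w.q[g, j], w_d, 1, w.zeta[g, j],
                                     w.traits[g, j, ha_i], w.traits[g, j, hs_i], p))
            u = hy * hw
            _apply(w, g, i, j, u)
            if record:
                w.transfers.append((w.day, int(w.ids[g, j]), int(w.ids[g, i]),
                                    u, hy, hw, new_pair, rho_pair, established))


def _apply(w: WorldState, g: int, i: int, j: int, u: float) -> None:
    """Apply donor j -> recipient i transfer of amount u (may be zero)."""
    p = w.params
    span = p.x_a - p.x_s
    w.zeta[g, j] -= u
    w.zeta[g, i] += u
    a_j = w.traits[g, j, _IDX["alpha"]]
    a_i = w.traits[g, i, _IDX["alpha"]]
    if w.pooled:
        w.pooled_w[g, j] -= u
        w.pooled_w[g, i] += u
        for k, a_k in ((j, a_j), (i, a_i)):
            xv = w.pooled_x[g, k]
            w.pooled_x[g, k] = min(p.x_a, xv + a_k * u * (p.x_a - xv) / span)
        if u > 0:
            w.pooled_donated[g, j] = True
    else:
        w.w[g, j, i] -= u
        w.w[g, i, j] += u
        xv = w.x[g, j, i]
        w.x[g, j, i] = min(p.x_a, xv + a_j * u * (p.x_a - xv) / span)
        xv = w.x[g, i, j]
        w.x[g, i, j] = min(p.x_a, xv + a_i * u * (p.x_a - xv) / span)
        if u > 0:
            if not (w.donated[g, j, i] or w.donated[g, i, j]):
                w.initiated[g, j, i] = True  # first donation of the pair
                w.n_partners[g, i] += 1
                w.n_partners[g, j] += 1
            w.donated[g, j, i] = True
            w.tot_don[g, j, i] += u
            w.n_don[g, j, i] += 1
    if u > 0:
        w.life_donated[g, j] += u
        w.life_received[g, i] += u
        w.life_n_don[g, j] += 1
        w.life_n_rec[g, i] += 1


def _update_yhat(w: WorldState) -> None:
    p, cfg = w.params, w.config
    rate = p.subgroup_rate
    if w.pooled:
        # a focal's effective bond is the same pooled value toward everyone
        counts = np.zeros_like(w.q)
        for k in range(cfg.n_subgroups):
            memb = (w.subgroup == k) & w.alive
            counts = np.where(memb, memb.sum(axis=1, keepdims=True) - 1, counts)
        obs = np.where(counts > 0, w.pooled_x, 0.0)
    else:
        pair = w.alive[:, :, None] & w.alive[:, None, :]
        same = (w.subgroup[:, :, None] == w.subgroup[:, None, :]) & pair
        np.einsum("gii->gi", same)[:] = False
        y = w.rho * w.x
        cnt = same.sum(axis=2)
        obs = np.where(cnt > 0, (y * same).sum(axis=2) / np.maximum(cnt, 1), 0.0)
    rows = np.nonzero(w.alive)
    ks = w.subgroup[rows]
    w.yhat[rows[0], rows[1], ks] += rate * (obs[rows] - w.yhat[rows[0], rows[1], ks])


def _fold_pair(w: WorldState, g: int, i: int, j: int) -> None:
    """Fold a dissolving partnership into i's top-bond lifetime summary."""
    if not w.initiated[g, i, j]:
        return
    if w.tot_don[g, i, j] == 0 and w.tot_don[g, j, i] == 0:  # pragma: no cover
        return
    xv = w.x[g, i, j]
    if np.isnan(w.top_x[g, i]) or xv > w.top_x[g, i]:
        w.top_x[g, i] = xv
        w.top_help[g, i] = w.tot_don[g, i, j] + w.tot_don[g, j, i]


def _record_death(w: WorldState, g: int, i: int) -> None:
    if w.pooled:
        w.top_x[g, i] = w.pooled_x[g, i]
        w.top_help[g, i] = w.life_donated[g, i] + w.life_received[g, i]
    else:
        for j in np.flatnonzero(w.alive[g]):
            if j == i:
                continue
            _fold_pair(w, g, i, int(j))   # i's own summary
            _fold_pair(w, g, int(j), i)   # surviving partner's summary
    t = w.traits[g, i]
    w.life_records.append((
        int(w.ids[g, i]), g, int(w.born_day[g, i]), w.day,
        w.day - int(w.born_day[g, i]), float(w.q[g, i]),
        *[float(t[k]) for k in range(5)],
        float(w.life_donated[g, i]), float(w.life_received[g, i]),
        int(w.life_n_don[g, i]), int(w.life_n_rec[g, i]),
        int(w.n_partners[g, i]), float(w.top_x[g, i]), float(w.top_help[g, i]),
        int(w.ret_obs[g, i]), int(w.ret_same[g, i])))


def _wipe_slot(w: WorldState, g: int, i: int) -> None:
    p = w.params
    for arr, val in ((w.x, p.x_s), (w.rho, 0.0), (w.w, 0.0),
                     (w.tot_don, 0.0), (w.n_don, 0), (w.donated, False),
                     (w.initiated, False)):
        arr[g, i, :] = val
        arr[g, :, i] = val
    w.pooled_x[g, i] = p.x_s
    w.pooled_w[g, i] = 0.0
    w.pooled_donated[g, i] = False


def _mortality(w: WorldState) -> None:
    mu = vitality.mortality_rate(w.z, w.zeta, w.params)
    die = w.alive & (w.rng.random(mu.shape) < mu)
    for g, i in zip(*np.nonzero(die)):
        g, i = int(g), int(i)
        _record_death(w, g, i)
        w.alive[g, i] = False
        _wipe_slot(w, g, i)
        w.subgroup[g, i] = -1
        w.prev_subgroup[g, i] = -1


def _replacement(w: WorldState) -> None:
    dead = np.nonzero(~w.alive)
    n_new = dead[0].size
    if n_new == 0:
        _log_traits(w)
        return
    pa, pb = genetics.draw_parent_pairs(w.alive.reshape(-1), n_new, w.rng)
    tr_flat = w.traits.reshape(-1, 5)
    children = genetics.make_offspring_batch(
        tr_flat[pa], tr_flat[pb], w.config.mutation, w.rng, w.config.traits)
    for k, (g, i) in enumerate(zip(*dead)):
        g, i = int(g), int(i)
        w.traits[g, i] = children[k]
        w.q[g, i] = vitality.draw_quality(w.params, w.rng)
        w.ids[g, i] = w.next_id
        w.next_id += 1
        w.born_day[g, i] = w.day
        w.zeta[g, i] = 0.0
        w.z[g, i] = 0
        w.yhat[g, i] = 0.0
        w.alive[g, i] = True
        for arr in (w.life_donated, w.life_received, w.top_help):
            arr[g, i] = 0.0
        for arr in (w.life_n_don, w.life_n_rec, w.n_partners,
                    w.ret_obs, w.ret_same):
            arr[g, i] = 0
        w.top_x[g, i] = np.nan
    _log_traits(w)


def _log_traits(w: WorldState) -> None:
    t = w.alive_traits()
    row = [w.day, int(w.alive.sum())]
    for k in range(5):
        row += [float(t[:, k].mean()), float(t[:, k].std())]
    w.trait_rows.append(tuple(row))


def _sample_rho(w: WorldState, max_per_group: int = 20) -> None:
    """Record rho for random same-subgroup living pairs (association survey)."""
    for g in range(w.n_groups):
        same = (w.subgroup[g][:, None] == w.subgroup[g][None, :])
        same &= w.alive[g][:, None] & w.alive[g][None, :]
        iu = np.triu_indices(w.config.group_size, k=1)
        cand = np.flatnonzero(same[iu])
        if cand.size == 0:
            continue
        take = w.rng.choice(cand, size=min(max_per_group, cand.size), replace=False)
        if w.pooled:
            vals = np.ones(take.size)
        else:
            vals = w.rho[g][iu][take]
        for v in vals:
            w.rho_samples.append((w.day, float(v)))


def run_day(w: WorldState) -> WorldState:
    """Advance the world by one day (steps 1–7 above)."""
    w.day += 1
    _choose_subgroups(w)
    _update_associations(w)
    w.zeta = np.where(w.alive, w.params.zeta_0(w.q), 0.0)
    w.z = np.where(w.alive, vitality.draw_forage(w.q, w.params, w.rng), 0).astype(np.int8)
    _ask_round(w)
    _update_yhat(w)
    _mortality(w)
    if w.day % w.params.T == 0:
        _replacement(w)
    if (w.recording and w.config.record_rho_snapshots
            and w.day % w.config.snapshot_every == 0):
        _sample_rho(w)
    return w


@dataclass
class SimOutput:
    """Tabular results of a run."""

    config: SimConfig
    life_records: pd.DataFrame
    trait_trajectory: pd.DataFrame
    transfers: pd.DataFrame
    rho_samples: pd.DataFrame
    return_probs: pd.DataFrame  # per individual alive at the end
    world: WorldState
    extinct: bool = False


def _final_return_probs(w: WorldState) -> pd.DataFrame:
    rows = []
    for g, i in zip(*np.nonzero(w.alive & (w.ret_obs > 0))):
        rows.append((int(w.ids[g, i]), int(w.ret_obs[g, i]),
                     int(w.ret_same[g, i]),
                     w.ret_same[g, i] / w.ret_obs[g, i]))
    return pd.DataFrame(rows, columns=["id", "days_observed", "days_returned",
                                       "return_prob"])


def run_simulation(config: SimConfig) -> SimOutput:
    """Run burn-in plus recorded days; fully reproducible from (config, seed)."""
    config = validate_config(config)
    w = init_world(config)
    total = config.burn_in + config.days
    extinct = False
    try:
        for _ in range(total):
            if w.day + 1 > config.burn_in:
                w.recording = True
            run_day(w)
    except ExtinctionError:
        extinct = True

    traj_cols = ["day", "n_alive"]
    for t in TRAIT_NAMES:
        traj_cols += [f"{t}_mean", f"{t}_sd"]
    out = SimOutput(
        config=config,
        life_records=pd.DataFrame(w.life_records, columns=LIFE_COLUMNS),
        trait_trajectory=pd.DataFrame(w.trait_rows, columns=traj_cols),
        transfers=pd.DataFrame(w.transfers, columns=TRANSFER_COLUMNS),
        rho_samples=pd.DataFrame(w.rho_samples, columns=["day", "rho"]),
        return_probs=_final_return_probs(w),
        world=w,
        extinct=extinct,
    )
    return out


def bonds_snapshot(w: WorldState) -> pd.DataFrame:
    """Final-state per-directed-pair table: day, focal, partner, x, rho, w."""
    rows = []
    for g in range(w.n_groups):
        for i in np.flatnonzero(w.alive[g]):
            for j in np.flatnonzero(w.alive[g]):
                if i == j:
                    continue
                rows.append((w.day, int(w.ids[g, i]), int(w.ids[g, j]),
                             float(w.x[g, i, j]), float(w.rho[g, i, j]),
                             float(w.w[g, i, j])))
    return pd.DataFrame(rows, columns=["day", "focal_id", "partner_id",
                                       "x", "rho", "w"])


def write_outputs(out: SimOutput, out_dir) -> None:
    """Write the run's TSV tables and a manifest echoing the resolved config."""
    import pathlib

    d = pathlib.Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    out.life_records.to_csv(d / "life_records.tsv", sep="\t", index=False)
    out.trait_trajectory.to_csv(d / "trait_trajectory.tsv", sep="\t", index=False)
    out.transfers.to_csv(d / "transfers.tsv", sep="\t", index=False)
    out.rho_samples.to_csv(d / "rho_samples.tsv", sep="\t", index=False)
    out.return_probs.to_csv(d / "return_probs.tsv", sep="\t", index=False)
    bonds_snapshot(out.world).to_csv(d / "bonds_snapshot.tsv", sep="\t", index=False)
    with open(d / "run_manifest.toml", "w") as fh:
        fh.write(dumps_config(out.config))
        fh.write(f"\n# final_day = {out.world.day}\n# extinct = {out.extinct}\n")
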