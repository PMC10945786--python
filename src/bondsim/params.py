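"""Model constants, heritable traits, and run configuration.

Every simulation run is specified by two objects:

* :class:`ModelParams` — the fixed (non-evolving) constants of the model:
  bond-strength range, helping-gate shape, mortality coefficients, detection
  and exploration probabilities, and the calibration functions for foraging
  success, quality, and the start-of-day resource balance.
* :class:`SimConfig` — population structure (groups, subgroups), duration,
  seed, trait start values, mutation settings, experiment variant, and
  output options.

Both carry validated defaults; :func:`validate_config` checks every invariant
before the engine starts and returns frozen copies.  Configurations round-trip
through a flat TOML dialect (:func:`load_config` / :func:`dumps_config`).
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_BOUNDS",
    "ModelParams",
    "MutationSettings",
    "TraitConfig",
    "SimConfig",
    "ConfigError",
    "validate_config",
    "load_config",
    "loads_config",
    "dumps_config",
    "save_config",
]

#: The five heritable traits, in canonical locus order.
#:
#: alpha  — bond learning rate (>= 0)
#: beta   — subgroup bond-strength sensitivity (sign free)
#: dy_new — temporary effective-bond increment for a never-helped partner
#: h_a    — asymptotic helping amount, the maximum donation of a top-quality
#:          individual (in [0, 1])
#: h_s    — sensitivity of donations to the pairwise helping balance
TRAIT_NAMES: tuple[str, ...] = ("alpha", "beta", "dy_new", "h_a", "h_s")

#: Hard clip bounds per trait, wide enough that observed evolved values
#: (alpha ~ 1.2, beta ~ 7.9, h_a ~ 0.5, h_s ~ 4.5) are interior points.
TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 5.0),
    "beta": (-20.0, 20.0),
    "dy_new": (-5.0, 5.0),
    "h_a": (0.0, 1.0),
    "h_s": (-20.0, 20.0),
}

VARIANTS: tuple[str, ...] = ("baseline", "generalized_reciprocity")


class ConfigError(ValueError):
    """A configuration invariant was violated.

    Carries ``errors``, a list of ``(field, message)`` pairs so a caller can
    report every problem at once.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        msg = "; ".join(f"{f}: {m}" for f, m in errors)
        super().__init__(f"invalid configuration: {msg}")


@dataclass(frozen=True)
class ModelParams:
    """Fixed model constants.

    The defaults are the model's standard parameterisation: bond strengths
    start at ``x_s = 1.25`` and saturate at ``x_a = 2.5``; the helping gate
    is a logistic in the effective bond strength with steepness ``d = 8`` and
    midpoint ``y_0 = 1.5``; daily mortality is a declining logistic in the
    resource balance with coefficients ``a = 2``, ``b = 4.5``, ``c = 3`` and
    floor ``mu_0 = 0.002``.  An average-quality individual (q = 0.5) fails to
    forage with probability 0.1, i.e. needs help about one day in ten.
    """

    x_s: float = 1.25    # starting bond strength
    x_a: float = 2.5     # asymptotic (maximum) bond strength
    d: float = 8.0       # helping-gate steepness
    y_0: float = 1.5     # helping-gate midpoint (effective bond strength)
    g_0: float = 0.75    # quality floor of the helping-scale numerator
    a: float = 2.0       # mortality logistic intercept
    b: float = 4.5       # mortality benefit of foraging success
    c: float = 3.0       # mortality benefit per unit resource balance
    mu_0: float = 0.002  # baseline daily mortality (floor)
    eps_p: float = 0.05  # probability of landing in a random subgroup
    p_d: float = 0.9     # probability of correctly detecting foraging success
    T: int = 20          # replacement interval, days
    lam_rho: float = 0.1     # association-estimate update rate per day
    n_ask_max: int = 2       # help requests per needy individual per day
    ps_coeffs: tuple[float, float] = (0.8, 0.2)  # p_s(q) = ps0 + ps1*q
    zeta0_slope: float = 0.6                     # zeta_0(q) = slope * q
    q_dist: tuple[float, float] = (4.0, 4.0)     # Beta(a, b) quality law
    yhat_rate: float | None = None  # subgroup-estimate EMA rate; None -> lam_rho
    kappa: float = 0.0  # crowding penalty on subgroup weights (0 = off)

    @property
    def subgroup_rate(self) -> float:
        """Effective EMA rate for the per-subgroup bond estimates."""
        return self.lam_rho if self.yhat_rate is None else self.yhat_rate

    def p_s(self, q):
        """Foraging success probability as a function of quality."""
        ps0, ps1 = self.ps_coeffs
        return np.clip(ps0 + ps1 * np.asarray(q, dtype=float), 0.0, 1.0)

    def zeta_0(self, q):
        """Start-of-day resource balance as a function of quality."""
        return self.zeta0_slope * np.asarray(q, dtype=float)

    def check(self) -> list[tuple[str, str]]:
        errs: list[tuple[str, str]] = []
        if not (self.x_a > self.x_s > 0):
            errs.append(("x_a/x_s", f"need x_a > x_s > 0, got x_a={self.x_a}, x_s={self.x_s}"))
        if not (0.0 <= self.eps_p <= 1.0):
            errs.append(("eps_p", f"probability out of [0,1]: {self.eps_p}"))
        if not (0.0 < self.mu_0 < 1.0):
            errs.append(("mu_0", f"need 0 < mu_0 < 1: {self.mu_0}"))
        if not (0.0 <= self.p_d <= 1.0):
            errs.append(("p_d", f"probability out of [0,1]: {self.p_d}"))
        if self.T < 1:
            errs.append(("T", f"replacement interval must be >= 1 day: {self.T}"))
        if self.n_ask_max < 1:
            errs.append(("n_ask_max", f"must allow at least one ask: {self.n_ask_max}"))
        if not (0.0 < self.lam_rho <= 1.0):
            errs.append(("lam_rho", f"rate must be in (0,1]: {self.lam_rho}"))
        if not (0.0 <= self.g_0 <= 1.0):
            errs.append(("g_0", f"fraction out of [0,1]: {self.g_0}"))
        if self.q_dist[0] <= 0 or self.q_dist[1] <= 0:
            errs.append(("q_dist", f"Beta shape parameters must be positive: {self.q_dist}"))
        return errs


@dataclass(frozen=True)
class MutationSettings:
    """Per-locus mutation law for the haploid genetics.

    Each locus mutates independently with probability ``m``; a mutation adds
    a long-tailed Laplace(0, scale) deviate and the result is clipped to the
    trait's bounds.  Default scales are 2% of each trait's bound width.
    """

    m: float = 0.02
    scales: dict[str, float] = field(
        default_factory=lambda: {
            t: 0.02 * (hi - lo) for t, (lo, hi) in TRAIT_BOUNDS.items()
        }
    )

    def check(self) -> list[tuple[str, str]]:
        errs = []
        if not (0.0 <= self.m <= 1.0):
            errs.append(("mutation.m", f"probability out of [0,1]: {self.m}"))
        for t in TRAIT_NAMES:
            s = self.scales.get(t)
            if s is None or s <= 0:
                errs.append((f"mutation.scales.{t}", f"Laplace scale must be > 0: {s}"))
        return errs

    def scale_array(self) -> np.ndarray:
        return np.array([self.scales[t] for t in TRAIT_NAMES])


@dataclass(frozen=True)
class TraitConfig:
    """Start values, initial jitter, and freeze map for the five traits.

    The default start is deliberately helping-naive (small h_a, zero beta,
    dy_new and h_s) so that evolved helping is an outcome rather than an
    initial condition.  ``frozen`` maps trait name -> value; a frozen locus
    is pinned at that value in the founders and in every offspring.
    """

    start: dict[str, float] = field(
        default_factory=lambda: {
            "alpha": 0.5, "beta": 0.0, "dy_new": 0.0, "h_a": 0.2, "h_s": 0.0,
        }
    )
    jitter: float = 1.0  # initial Laplace jitter, as a multiple of the mutation scale
    frozen: dict[str, float] = field(default_factory=dict)

    def check(self) -> list[tuple[str, str]]:
        errs = []
        for t in TRAIT_NAMES:
            if t not in self.start:
                errs.append((f"traits.start.{t}", "missing start value"))
                continue
            lo, hi = TRAIT_BOUNDS[t]
            if not (lo <= self.start[t] <= hi):
                errs.append((f"traits.start.{t}",
                             f"start {self.start[t]} outside bounds [{lo}, {hi}]"))
        for t, v in self.frozen.items():
            if t not in TRAIT_NAMES:
                errs.append((f"traits.frozen.{t}", "unknown trait"))
            else:
                lo, hi = TRAIT_BOUNDS[t]
                if not (lo <= v <= hi):
                    errs.append((f"traits.frozen.{t}",
                                 f"frozen value {v} outside bounds [{lo}, {hi}]"))
        if self.jitter < 0:
            errs.append(("traits.jitter", f"must be >= 0: {self.jitter}"))
        return errs

    def start_array(self) -> np.ndarray:
        vals = np.array([self.start[t] for t in TRAIT_NAMES])
        for t, v in self.frozen.items():
            vals[TRAIT_NAMES.index(t)] = v
        return vals

    def frozen_mask(self) -> np.ndarray:
        return np.array([t in self.frozen for t in TRAIT_NAMES])

    def frozen_values(self) -> np.ndarray:
        return np.array([self.frozen.get(t, np.nan) for t in TRAIT_NAMES])


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulation run."""

    population_size: int = 600
    group_size: int = 24       # N
    n_subgroups: int = 6       # K; expected subgroup occupancy G = N/K
    days: int = 2000           # recorded days after burn-in
    burn_in: int = 0           # unrecorded warm-up days
    seed: int = 0
    variant: str = "baseline"
    params: ModelParams = field(default_factory=ModelParams)
    traits: TraitConfig = field(default_factory=TraitConfig)
    mutation: MutationSettings = field(default_factory=MutationSettings)
    record_transfers: bool = True
    record_rho_snapshots: bool = True
    snapshot_every: int = 100  # days between same-subgroup rho samples
    out_dir: str | None = None
    verbose: bool = False

    @property
    def n_groups(self) -> int:
        return self.population_size // self.group_size

    @property
    def expected_subgroup_size(self) -> float:
        return self.group_size / self.n_subgroups


def validate_config(config: SimConfig) -> SimConfig:
    """Check every configuration invariant; return the validated config.

    Raises :class:`ConfigError` listing each violated field and constraint.
    """
    errs: list[tuple[str, str]] = []
    if config.population_size < 2:
        errs.append(("population_size", f"need at least 2 individuals: {config.population_size}"))
    if config.group_size < 1:
        errs.append(("group_size", f"must be >= 1: {config.group_size}"))
    elif config.population_size % config.group_size != 0:
        errs.append(("population_size",
                     f"{config.population_size} not divisible by group size {config.group_size}"))
    if config.n_subgroups < 1:
        errs.append(("n_subgroups", f"must be >= 1: {config.n_subgroups}"))
    if config.days < 0:
        errs.append(("days", f"must be >= 0: {config.days}"))
    if config.burn_in < 0:
        errs.append(("burn_in", f"must be >= 0: {config.burn_in}"))
    if config.variant not in VARIANTS:
        errs.append(("variant", f"unknown variant {config.variant!r}; one of {VARIANTS}"))
    if config.snapshot_every < 1:
        errs.append(("snapshot_every", f"must be >= 1: {config.snapshot_every}"))
    errs.extend(config.params.check())
    errs.extend(config.traits.check())
    errs.extend(config.mutation.check())
    if errs:
        raise ConfigError(errs)
    return config


# ---------------------------------------------------------------------------
# TOML round-trip

_SECTIONS = ("population", "params", "traits", "mutation", "experiment", "output")

_POPULATION_FIELDS = ("population_size", "group_size", "n_subgroups", "days",
                      "burn_in", "seed")
_OUTPUT_FIELDS = ("record_transfers", "record_rho_snapshots", "snapshot_every",
                  "out_dir", "verbose")


def loads_config(text: str) -> SimConfig:
    """Parse a TOML configuration string into a validated :class:`SimConfig`."""
    raw = tomllib.loads(text)
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError([(s, "unknown section") for s in sorted(unknown)])

    kwargs: dict[str, Any] = {}
    for k, v in raw.get("population", {}).items():
        if k not in _POPULATION_FIELDS:
            raise ConfigError([(f"population.{k}", "unknown field")])
        kwargs[k] = v

    pkw = dict(raw.get("params", {}))
    for key in ("ps_coeffs", "q_dist"):
        if key in pkw:
            pkw[key] = tuple(pkw[key])
    known = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(pkw) - known
    if bad:
        raise ConfigError([(f"params.{k}", "unknown field") for k in sorted(bad)])
    kwargs["params"] = ModelParams(**pkw)

    tsec = raw.get("traits", {})
    tkw: dict[str, Any] = {}
    if "start" in tsec:
        tkw["start"] = {**TraitConfig().start, **tsec["start"]}
    if "frozen" in tsec:
        tkw["frozen"] = dict(tsec["frozen"])
    if "jitter" in tsec:
        tkw["jitter"] = tsec["jitter"]
    kwargs["traits"] = TraitConfig(**tkw)

    msec = raw.get("mutation", {})
    mkw: dict[str, Any] = {}
    if "m" in msec:
        mkw["m"] = msec["m"]
    if "scales" in msec:
        mkw["scales"] = {**MutationSettings().scales, **msec["scales"]}
    kwargs["mutation"] = MutationSettings(**mkw)

    if "variant" in raw.get("experiment", {}):
        kwargs["variant"] = raw["experiment"]["variant"]

    for k, v in raw.get("output", {}).items():
        if k not in _OUTPUT_FIELDS:
            raise ConfigError([(f"output.{k}", "unknown field")])
        kwargs[k] = v

    return validate_config(SimConfig(**kwargs))


def load_config(path) -> SimConfig:
    with open(path, "rb") as fh:
        text = fh.read().decode()
    return loads_config(text)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if math.isinf(v) or math.isnan(v):
            raise ValueError(f"non-finite value not serialisable: {v}")
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def dumps_config(config: SimConfig) -> str:
    """Serialise a configuration to TOML; inverse of :func:`loads_config`."""
    lines: list[str] = []

    lines.append("[population]")
    for f in _POPULATION_FIELDS:
        lines.append(f"{f} = {_toml_value(getattr(config, f))}")

    lines.append("\n[params]")
    for f in dataclasses.fields(ModelParams):
        v = getattr(config.params, f.name)
        if v is None:
            continue  # optional field left at its sentinel default
        lines.append(f"{f.name} = {_toml_value(v)}")

    lines.append("\n[traits]")
    lines.append(f"jitter = {_toml_value(config.traits.jitter)}")
    lines.append("\n[traits.start]")
    for t in TRAIT_NAMES:
        lines.append(f"{t} = {_toml_value(config.traits.start[t])}")
    if config.traits.frozen:
        lines.append("\n[traits.frozen]")
        for t, v in config.traits.frozen.items():
            lines.append(f"{t} = {_toml_value(v)}")

    lines.append("\n[mutation]")
    lines.append(f"m = {_toml_value(config.mutation.m)}")
    lines.append("\n[mutation.scales]")
    for t in TRAIT_NAMES:
        lines.append(f"{t} = {_toml_value(config.mutation.scales[t])}")

    lines.append("\n[experiment]")
    lines.append(f"variant = {_toml_value(config.variant)}")

    lines.append("\n[output]")
    for f in _OUTPUT_FIELDS:
        v = getattr(config, f)
        if v is None:
            continue
        lines.append(f"{f} = {_toml_value(v)}")

    return "\n".join(lines) + "\n"


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_config(config))
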