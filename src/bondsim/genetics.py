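"""Haploid sexual genetics: recombination, Laplacian mutation, replacement.

Individuals are haploid with five heritable loci (see
:data:`bondsim.params.TRAIT_NAMES`).  Two parents form a transient diploid
from which a haploid offspring is drawn: each locus comes from either
parent with probability 1/2 (free recombination).  Each locus then mutates
independently with probability ``m`` by adding a long-tailed Laplace
deviate, and is clipped to its bounds.  Frozen loci bypass all of this and
are pinned at their configured value.

Dead individuals are replaced in batches every ``T`` days.  Parents are
drawn uniformly from the *global* pool of living individuals — newborns
land in whatever group has an empty slot, which deliberately destroys any
relatedness structure between group-mates, so helping cannot evolve through
kin selection here.
"""

from __future__ import annotations

import numpy as np

from .params import TRAIT_BOUNDS, TRAIT_NAMES

__all__ = ["trait_bounds_arrays", "clip_traits", "mutate", "make_offspring",
           "make_offspring_batch", "replacement_step", "ExtinctionError"]


class ExtinctionError(RuntimeError):
    """Fewer than two living individuals remain; reproduction is impossible."""


def trait_bounds_arrays() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([TRAIT_BOUNDS[t][0] for t in TRAIT_NAMES])
    hi = np.array([TRAIT_BOUNDS[t][1] for t in TRAIT_NAMES])
    return lo, hi


def clip_traits(traits: np.ndarray, trait_config=None) -> np.ndarray:
    """Clip trait values to bounds and re-pin frozen loci.  Works on any
    (..., 5) array."""
    lo, hi = trait_bounds_arrays()
    out = np.clip(traits, lo, hi)
    if trait_config is not None:
        mask = trait_config.frozen_mask()
        if mask.any():
            out[..., mask] = trait_config.frozen_values()[mask]
    return out


def mutate(traits: np.ndarray, settings, rng: np.random.Generator,
           trait_config=None) -> np.ndarray:
    """Per-locus Laplacian mutation with probability ``m``, then clip."""
    traits = np.array(traits, dtype=float, copy=True)
    scales = settings.scale_array()
    hit = rng.random(traits.shape) < settings.m
    dev = rng.laplace(0.0, scales, size=traits.shape)
    traits = traits + np.where(hit, dev, 0.0)
    return clip_traits(traits, trait_config)


def make_offspring(parent_a: np.ndarray, parent_b: np.ndarray, settings,
                   rng: np.random.Generator, trait_config=None,
                   parent_ids: tuple[int, int] | None = None) -> np.ndarray:
    """One haploid offspring trait vector from two distinct parents."""
    if parent_ids is not None and parent_ids[0] == parent_ids[1]:
        raise ValueError("offspring requires two distinct parents")
    parent_a = np.asarray(parent_a, dtype=float)
    parent_b = np.asarray(parent_b, dtype=float)
    pick = rng.random(parent_a.shape) < 0.5
    child = np.where(pick, parent_a, parent_b)
    return mutate(child, settings, rng, trait_config)


def make_offspring_batch(parents_a: np.ndarray, parents_b: np.ndarray,
                         settings, rng: np.random.Generator,
                         trait_config=None) -> np.ndarray:
    """Vectorised offspring production; inputs are (n, 5) parent arrays."""
    pick = rng.random(parents_a.shape) < 0.5
    children = np.where(pick, parents_a, parents_b)
    return mutate(children, settings, rng, trait_config)


def replacement_step(world) -> None:
    """Fill every dead slot in a world with a newborn (see the engine's
    daily schedule); parents are drawn uniformly from the global living
    population.  Raises :class:`ExtinctionError` if fewer than two
    individuals survive."""
    from .engine import _replacement

    _replacement(world)


def draw_parent_pairs(alive_flat: np.ndarray, n_pairs: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """For each newborn, two distinct parents uniform over living individuals.

    ``alive_flat`` is a boolean array over flat population slots.  Returns
    two arrays of flat parent indices.  Raises :class:`ExtinctionError`
    when fewer than two individuals live.
    """
    living = np.flatnonzero(alive_flat)
    if living.size < 2:
        raise ExtinctionError(
            f"only {living.size} living individual(s); population is extinct")
    pa = np.empty(n_pairs, dtype=np.int64)
    pb = np.empty(n_pairs, dtype=np.int64)
    for k in range(n_pairs):
        pair = rng.choice(living, size=2, replace=False)
        pa[k], pb[k] = pair
    return pa, pb
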