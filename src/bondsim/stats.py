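"""Summary statistics over run outputs.

These operations turn the engine's tabular logs into the analysis surfaces
of interest: the reciprocity correlation across partnerships, lifetime
helping summaries against lifespan, subgroup-fidelity (return-probability)
distributions, and the distribution of association estimates for different
samples of pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "spearman_correlation",
    "partnership_table",
    "reciprocity_correlation",
    "return_probability",
    "association_distributions",
    "lifetime_summaries",
]


def spearman_correlation(xs, ys) -> float:
    """Spearman rank correlation with average ranks for ties.

    Equals the Pearson correlation of the two rank vectors.  Raises
    ``ValueError`` for fewer than 3 pairs or a zero-variance input (the
    rank correlation is undefined there).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("paired inputs must have equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    return float(sps.spearmanr(xs, ys).statistic)


def partnership_table(transfers: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a transfer log into undirected partnership records.

    Returns one row per unordered pair with positive exchange, with columns
    ``a, b, donated_ab, donated_ba, n_ab, n_ba, bidirectional``.  From the
    perspective of member ``a``, ``donated_ab`` is its total donated and
    ``donated_ba`` its total received.
    """
    t = transfers[transfers["amount"] > 0]
    lo = np.minimum(t["donor"], t["recipient"])
    hi = np.maximum(t["donor"], t["recipient"])
    fwd = (t["donor"] == lo)  # a==lo donated
    df = pd.DataFrame({
        "a": lo, "b": hi,
        "donated_ab": np.where(fwd, t["amount"], 0.0),
        "donated_ba": np.where(fwd, 0.0, t["amount"]),
        "n_ab": fwd.astype(int), "n_ba": (~fwd).astype(int),
    })
    agg = df.groupby(["a", "b"], as_index=False).sum()
    agg["bidirectional"] = (agg["n_ab"] > 0) & (agg["n_ba"] > 0)
    return agg


def reciprocity_correlation(transfers: pd.DataFrame, *, sample: int | None = 1000,
                            rng: np.random.Generator | None = None) -> dict:
    """Spearman correlation of per-partnership totals donated vs received.

    Computed over partnerships with helping at least once in each
    direction, from both members' perspectives (each bidirectional pair
    contributes the points (d_ab, d_ba) and (d_ba, d_ab), so the statistic
    is symmetric in the pair ordering).  Returns the correlation over all
    bidirectional partnerships (``rs_all``) and over a uniform random
    sample capped at ``sample`` partnerships (``rs_sample``), together with
    the partnership count.
    """
    pt = partnership_table(transfers)
    bi = pt[pt["bidirectional"]]
    out = {"n_bidirectional": int(len(bi)), "rs_all": np.nan, "rs_sample": np.nan}
    if len(bi) < 3:
        return out

    def _rs(frame: pd.DataFrame) -> float:
        don = np.concatenate([frame["donated_ab"], frame["donated_ba"]])
        rec = np.concatenate([frame["donated_ba"], frame["donated_ab"]])
        return spearman_correlation(don, rec)

    out["rs_all"] = _rs(bi)
    if sample is not None and len(bi) > sample:
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.choice(len(bi), size=sample, replace=False)
        out["rs_sample"] = _rs(bi.iloc[idx])
    else:
        out["rs_sample"] = out["rs_all"]
    return out


def return_probability(history: np.ndarray) -> np.ndarray:
    """Per-individual probability of returning to yesterday's subgroup.

    ``history`` is a (days, individuals) integer array of subgroup indices
    (negative = absent/dead that day).  Returns, per individual, the
    fraction of valid consecutive day-pairs with identical subgroup; NaN if
    an individual has fewer than one valid pair of days.
    """
    h = np.asarray(history)
    if h.ndim == 1:
        h = h[:, None]
    if h.shape[0] < 2:
        raise ValueError("need at least 2 recorded days")
    valid = (h[:-1] >= 0) & (h[1:] >= 0)
    same = (h[:-1] == h[1:]) & valid
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, same.sum(axis=0) / np.maximum(n, 1), np.nan)
    return out


def association_distributions(rho_samples: pd.DataFrame,
                              transfers: pd.DataFrame,
                              bins: int = 20) -> dict[str, pd.DataFrame]:
    """Density histograms of the association estimate rho for three frames.

    * ``same_subgroup`` — random pairs sharing a subgroup (periodic survey
      samples from the engine);
    * ``helping`` — pairs at moments of actual helping (positive-amount
      transfers);
    * ``established`` — helping moments between established partners, i.e.
      pairs that had already exchanged help in both directions.

    Each value is a DataFrame with ``bin_left, bin_right, density``; the
    densities integrate to 1.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)

    def _hist(vals) -> pd.DataFrame:
        vals = np.asarray(vals, dtype=float)
        dens, _ = np.histogram(vals, bins=edges, density=True) if vals.size \
            else (np.zeros(bins), edges)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "density": dens})

    helped = transfers[transfers["amount"] > 0]
    return {
        "same_subgroup": _hist(rho_samples["rho"]),
        "helping": _hist(helped["rho"]),
        "established": _hist(helped.loc[helped["established"], "rho"]),
    }


def lifetime_summaries(life_records: pd.DataFrame, bins: int = 20) -> pd.DataFrame:
    """Binned means of lifetime helping totals and counts against lifespan.

    Equal-width lifespan bins; per bin the mean totals donated/received and
    mean event counts (the tabular counterpart of a smoothed
    lifespan-vs-help curve).
    """
    if len(life_records) == 0:
        raise ValueError("need at least one completed life")
    ls = life_records["lifespan"].to_numpy(dtype=float)
    lo, hi = ls.min(), ls.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.digitize(ls, edges) - 1, 0, bins - 1)
    df = life_records.assign(_bin=idx)
    agg = df.groupby("_bin").agg(
        n=("id", "size"),
        lifespan_mean=("lifespan", "mean"),
        donated_mean=("total_donated", "mean"),
        received_mean=("total_received", "mean"),
        n_donated_mean=("n_donated", "mean"),
        n_received_mean=("n_received", "mean"),
    ).reset_index()
    agg["bin_left"] = edges[agg["_bin"]]
    agg["bin_right"] = edges[agg["_bin"] + 1]
    return agg.drop(columns="_bin")
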