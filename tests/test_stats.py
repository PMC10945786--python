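"""Summary statistics: rank correlation, return probability, distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bondsim.stats import (association_distributions, lifetime_summaries,
                           partnership_table, reciprocity_correlation,
                           return_probability, spearman_correlation)


def _spearman_bruteforce(xs, ys):
    """Independent oracle: average ranks by hand, then Pearson of ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(v.size)
        for i, x in enumerate(v):
            less = np.sum(v < x)
            equal = np.sum(v == x)
            r[i] = less + (equal + 1) / 2.0
        return r
    rx, ry = avg_ranks(xs), avg_ranks(ys)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 5], [10, 20, 500]) == 1.0

    def test_hand_computed_tie_free_case(self):
        assert spearman_correlation([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_reversed_monotone(self):
        assert spearman_correlation([1, 2, 3, 4], [9, 7, 5, 1]) == -1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.integers(0, 5), min_size=3, max_size=8),
           st.lists(st.integers(0, 5), min_size=8, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle_on_small_inputs(self, xs, ys):
        ys = ys[:len(xs)]
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        assert spearman_correlation(xs, ys) == \
            pytest.approx(_spearman_bruteforce(xs, ys), abs=1e-12)


class TestReturnProbability:
    def test_faithful_individual(self):
        h = np.full((50, 1), 3)
        assert return_probability(h)[0] == 1.0

    def test_alternating_individual(self):
        h = np.array([[1], [2]] * 25)
        assert return_probability(h)[0] == 0.0

    def test_uniform_random_matches_one_over_k(self, rng):
        h = rng.integers(0, 6, size=(10_000, 20))
        p = return_probability(h)
        assert np.allclose(p, 1 / 6, atol=0.02)

    def test_absent_days_excluded(self):
        h = np.array([[2], [-1], [2], [2]])
        # only the (2,2) pair of days 2-3 is valid
        assert return_probability(h)[0] == 1.0


class TestPartnershipsAndReciprocity:
    def _toy_transfers(self):
        rows = [
            # day, donor, recipient, amount
            (1, 1, 2, 0.3), (2, 2, 1, 0.2), (3, 1, 2, 0.1),
            (1, 3, 4, 0.5),                      # one-way pair
            (2, 5, 6, 0.4), (3, 6, 5, 0.4),
            (4, 1, 3, 0.0),                      # refused ask: not a partnership
        ]
        df = pd.DataFrame(rows, columns=["day", "donor", "recipient", "amount"])
        df["Hy"] = df["Hw"] = 0.5
        df["new_pair"] = False
        df["rho"] = 0.5
        df["established"] = False
        return df

    def test_partnership_totals(self):
        pt = partnership_table(self._toy_transfers())
        assert len(pt) == 3
        p12 = pt[(pt.a == 1) & (pt.b == 2)].iloc[0]
        assert p12.donated_ab == pytest.approx(0.4)
        assert p12.donated_ba == pytest.approx(0.2)
        assert bool(p12.bidirectional)
        p34 = pt[(pt.a == 3) & (pt.b == 4)].iloc[0]
        assert not bool(p34.bidirectional)

    def test_reciprocity_uses_bidirectional_pairs_only(self):
        t = self._toy_transfers()
        extra = []
        for k in range(10, 40, 2):  # add reciprocal pairs with related totals
            extra.append((1, k, k + 1, 0.1 * k))
            extra.append((2, k + 1, k, 0.1 * k + 0.05))
        t2 = pd.concat([t, pd.DataFrame(
            [(d, a, b, u, 0.5, 0.5, False, 0.5, False) for d, a, b, u in extra],
            columns=t.columns)], ignore_index=True)
        rec = reciprocity_correlation(t2)
        assert rec["n_bidirectional"] == 17
        assert -1 <= rec["rs_all"] <= 1

    def test_reciprocal_run_shows_positive_rank_correlation(self, eco_run):
        rec = reciprocity_correlation(eco_run.transfers)
        assert rec["n_bidirectional"] > 100
        assert rec["rs_all"] > 0.3


class TestDistributions:
    def test_association_histograms_integrate_to_one(self, eco_run):
        hists = association_distributions(eco_run.rho_samples, eco_run.transfers)
        for name, h in hists.items():
            widths = h.bin_right - h.bin_left
            assert (h.density * widths).sum() == pytest.approx(1.0), name

    def test_established_partners_more_associated_than_random(self, eco_run):
        """Helping between established partners concentrates at higher
        association than random same-subgroup pairs."""
        t = eco_run.transfers
        helped = t[t.amount > 0]
        est = helped[helped.established].rho
        rand = eco_run.rho_samples.rho
        assert len(est) > 50 and len(rand) > 50
        assert est.mean() > rand.mean()

    def test_return_probability_concentrates_near_one_at_evolved_beta(self, eco_run):
        rp = eco_run.return_probs.return_prob
        assert len(rp) > 20
        assert np.median(rp) > 0.8


class TestLifetimeSummaries:
    def test_single_life(self):
        lr = pd.DataFrame([dict(id=1, lifespan=100, total_donated=3.0,
                                total_received=2.0, n_donated=10,
                                n_received=7)])
        out = lifetime_summaries(lr, bins=5)
        assert len(out) == 1
        assert out.donated_mean.iloc[0] == 3.0

    def test_no_lives_rejected(self):
        with pytest.raises(ValueError):
            lifetime_summaries(pd.DataFrame(columns=["id", "lifespan",
                                                     "total_donated",
                                                     "total_received",
                                                     "n_donated",
                                                     "n_received"]))

    def test_help_totals_grow_with_lifespan(self, eco_run):
        lr = eco_run.life_records
        done = lr[lr.born_day >= 200]  # born inside the recorded window
        assert len(done) > 50
        rs = spearman_correlation(done.lifespan, done.total_received)
        assert rs > 0.5
        binned = lifetime_summaries(done)
        big = binned[binned.n >= 5]
        # longer-lived bins accumulate more received help
        assert spearman_correlation(big.lifespan_mean, big.received_mean) > 0.5
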