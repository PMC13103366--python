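"""Focal splits, shuffle nulls, KS wrapper and the single-focal MAJIC run."""

import numpy as np
import pandas as pd
import pytest

from majic import (
    Majic,
    ks_two_sample,
    majic_single,
    shuffle_focal,
    split_by_focal,
)
from majic.tables import PresenceMatrix

from helpers import brute_force_mu, enum_ks_p, random_presence_frame


def _pa(frame: pd.DataFrame) -> PresenceMatrix:
    return PresenceMatrix(frame)


class TestSplitAndShuffle:
    def test_partition_sizes(self, rng):
        df = random_presence_frame(rng, 12, 6)
        split = split_by_focal(_pa(df), "sp0")
        assert split.n_plus + split.n_minus == 12
        assert set(split.sigma_plus).isdisjoint(split.sigma_minus)
        assert split.n_plus == int(df["sp0"].sum())

    def test_focal_everywhere_gives_empty_minus(self):
        df = pd.DataFrame({"f": [1, 1, 1], "x": [1, 0, 1]},
                          index=["a", "b", "c"])
        split = split_by_focal(_pa(df), "f")
        assert split.n_minus == 0

    def test_split_invariant_to_sample_order(self, rng):
        df = random_presence_frame(rng, 10, 4)
        s1 = split_by_focal(_pa(df), "sp0")
        s2 = split_by_focal(_pa(df.iloc[::-1]), "sp0")
        assert set(s1.sigma_plus) == set(s2.sigma_plus)

    def test_unknown_focal_raises(self, rng):
        with pytest.raises(KeyError):
            split_by_focal(_pa(random_presence_frame(rng, 8, 3)), "nope")

    def test_shuffle_preserves_prevalence(self, rng):
        df = random_presence_frame(rng, 20, 5)
        pa = _pa(df)
        k = int(df["sp0"].sum())
        for _ in range(200):
            split = shuffle_focal(pa, "sp0", rng)
            assert split.n_plus == k

    def test_shuffle_reproducible_under_seed(self, rng):
        df = random_presence_frame(rng, 15, 4)
        pa = _pa(df)
        a = shuffle_focal(pa, "sp0", np.random.default_rng(9))
        b = shuffle_focal(pa, "sp0", np.random.default_rng(9))
        assert a == b

    def test_shuffle_is_uniform_over_samples(self, rng):
        # 7/20 focal: every sample lands in sigma+ with frequency ~ 0.35
        bits = np.zeros((20, 3), dtype=int)
        bits[:, 1] = 1
        bits[:7, 0] = 1
        df = pd.DataFrame(bits, index=[f"s{i}" for i in range(20)],
                          columns=["f", "anchor", "x"])
        pa = _pa(df)
        counts = {s: 0 for s in pa.sample_ids}
        n = 4000
        for _ in range(n):
            for s in shuffle_focal(pa, "f", rng).sigma_plus:
                counts[s] += 1
        freqs = np.array([counts[s] / n for s in pa.sample_ids])
        # 4 sigma binomial band around 0.35
        band = 4 * np.sqrt(0.35 * 0.65 / n)
        assert np.all(np.abs(freqs - 0.35) < band)


class TestKsTwoSample:
    def test_identical_samples(self):
        D, p, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == 0.0
        assert p == 1.0

    def test_worked_exact_value(self):
        D, p, method = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert D == 1.0
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_matches_enumeration_oracle(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        D, p, _ = ks_two_sample(x, y)
        d_oracle, p_oracle = enum_ks_p(x, y)
        assert D == pytest.approx(d_oracle)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_asymptotic_near_exact_at_n50(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(0.3, 1.0, size=50)
        D_e, p_exact, _ = ks_two_sample(x[:25], y[:25])  # exact regime
        # same data through both scipy methods
        from scipy.stats import ks_2samp

        exact = ks_2samp(x, y, method="exact").pvalue
        asymp = ks_2samp(x, y, method="asymp").pvalue
        assert asymp == pytest.approx(exact, rel=0.10, abs=0.01)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMajicSingle:
    def test_identical_communities_give_zero_mu(self):
        bits = np.ones((8, 4), dtype=int)
        bits[:3, 0] = 1
        bits[3:, 0] = 0
        df = pd.DataFrame(bits, index=[f"s{i}" for i in range(8)],
                          columns=["f", "a", "b", "c"])
        res = majic_single(_pa(df), "f", n_shuffles=200,
                           ks_mode="permutation", rng=1)
        assert res.mu_plus == 0.0
        assert res.mu_minus == 0.0
        assert res.delta_mu == 0.0
        assert res.classification == "state_dissociated"

    def test_degenerate_split_not_computable(self):
        df = pd.DataFrame({"f": [1, 1, 1, 1, 1, 0], "a": [1] * 6},
                          index=[f"s{i}" for i in range(6)])
        res = majic_single(_pa(df), "f", n_shuffles=100, rng=0)
        assert res.classification == "not_computable"
        assert np.isnan(res.mu_plus)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            df = random_presence_frame(rng, 12, 8)
            res = majic_single(_pa(df), "sp0", n_shuffles=0, rng=0)
            mu_p, mu_m, delta = brute_force_mu(df, "sp0", include_focal=True)
            assert res.mu_plus == pytest.approx(mu_p, abs=1e-12)
            assert res.mu_minus == pytest.approx(mu_m, abs=1e-12)
            assert res.delta_mu == pytest.approx(delta, abs=1e-12)

    def test_exclude_focal_matches_oracle(self, rng):
        for _ in range(10):
            df = random_presence_frame(rng, 12, 8)
            res = majic_single(_pa(df), "sp0", n_shuffles=0,
                               include_focal=False, rng=0)
            mu_p, mu_m, delta = brute_force_mu(df, "sp0", include_focal=False)
            assert res.mu_plus == pytest.approx(mu_p, abs=1e-12)
            assert res.mu_minus == pytest.approx(mu_m, abs=1e-12)

    def test_delta_identity(self, rng):
        df = random_presence_frame(rng, 14, 6)
        res = majic_single(_pa(df), "sp0", n_shuffles=300, rng=5)
        assert res.delta_mu == res.mu_plus - res.mu_minus
        null = res.null
        np.testing.assert_array_equal(
            null.delta_mu_null, null.mu_plus_null - null.mu_minus_null
        )

    def test_null_vectors_have_requested_length(self, rng):
        df = random_presence_frame(rng, 12, 6)
        res = majic_single(_pa(df), "sp0", n_shuffles=321,
                           ks_mode="permutation", rng=2)
        assert len(res.null.mu_plus_null) == 321
        assert 0 < res.empirical_p <= 1

    def test_seeded_run_reproducible(self, rng):
        df = random_presence_frame(rng, 12, 6)
        r1 = majic_single(_pa(df), "sp0", n_shuffles=200, rng=77)
        r2 = majic_single(_pa(df), "sp0", n_shuffles=200, rng=77)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(
            r1.null.mu_plus_null, r2.null.mu_plus_null
        )

    def test_null_delta_centered_near_zero(self, rng):
        # under the frequency null, with the focal row excluded, µ⁺ and µ⁻
        # average the same exchangeable pair values, so ∆µ_null centers on 0
        from majic import synthetic, to_presence_absence

        t, _ = synthetic.simulate_neutral(40, 40, rng=rng)
        pa = to_presence_absence(t)
        res = majic_single(pa, "focal", n_shuffles=2000, include_focal=False,
                           ks_mode="permutation", rng=3)
        d = res.null.delta_mu_null
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 3 * se

    def test_include_focal_bias_cancels_in_null(self, rng):
        # with the focal row included, the shared-focal similarity shifts
        # µ⁺ below µ⁻ in observed AND null alike: the null ∆µ ensemble is
        # displaced by construction, centred near the observed neutral ∆µ
        from majic import synthetic, to_presence_absence

        t, _ = synthetic.simulate_neutral(40, 40, rng=rng)
        pa = to_presence_absence(t)
        res = majic_single(pa, "focal", n_shuffles=2000,
                          ks_mode="permutation", rng=3)
        d = res.null.delta_mu_null
        assert d.mean() < 0  # deterministic direction of the shared-bit bias
        spread = d.std(ddof=1)
        assert abs(res.delta_mu - d.mean()) < 4 * spread


class TestRunMajic:
    def test_two_group_report_shape(self, rng):
        from majic import AbundanceTable, SampleGroups, run_majic

        vals = rng.dirichlet(np.ones(6), size=16)
        table = AbundanceTable(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(16)],
                         columns=[f"sp{j}" for j in range(6)])
        )
        groups = SampleGroups(
            group=pd.Series(["A"] * 8 + ["B"] * 8, index=table.sample_ids)
        )
        res = run_majic(table, groups, seed=9, n_shuffles=100,
                        min_prevalence=0.0, min_abundance=0.0)
        df = res.to_frame()
        assert sorted(df["group"].unique()) == ["A", "B"]
        assert (df.groupby("group").size() == 6).all()

    def test_species_order_invariance(self, rng):
        from majic import AbundanceTable, run_majic

        vals = rng.dirichlet(np.ones(6), size=14)
        cols = [f"sp{j}" for j in range(6)]
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(14)], columns=cols)
        r1 = run_majic(AbundanceTable(df), seed=13, n_shuffles=200,
                       min_prevalence=0.0, min_abundance=0.0)
        shuffled_cols = list(np.random.default_rng(0).permutation(cols))
        r2 = run_majic(AbundanceTable(df[shuffled_cols]), seed=13,
                       n_shuffles=200, min_prevalence=0.0, min_abundance=0.0)
        pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())

    def test_summary_mentions_counts(self, rng):
        from majic import AbundanceTable, run_majic

        vals = rng.dirichlet(np.ones(4), size=10)
        table = AbundanceTable(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(10)],
                         columns=[f"sp{j}" for j in range(4)])
        )
        res = run_majic(table, seed=2, n_shuffles=50,
                        min_prevalence=0.0, min_abundance=0.0)
        text = res.summary()
        assert "focal species" in text
        assert "seed" in text
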