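"""Responsiveness classification, overlap vs chance, spatial distances."""

import numpy as np
import pytest
from scipy import stats

import fearcal as fc
from fearcal import responsiveness as resp
from fearcal import synth
from fearcal.protocol import AlignedTensor


def tensor_from_windows(baseline, evoked, bin_width=0.25):
    """Assemble an AlignedTensor from explicit (cells, trials, bins) windows."""
    data = np.concatenate([baseline, evoked], axis=2)
    nb = baseline.shape[2]
    return AlignedTensor("x", data, pre_window=nb * bin_width,
                         post_window=evoked.shape[2] * bin_width,
                         baseline_window=nb * bin_width, bin_width=bin_width)


class TestTrialResponseTest:
    def test_identical_windows_give_p_one(self):
        vals = np.tile(np.arange(120.0), (1, 1, 1))
        t = tensor_from_windows(vals, vals.copy())
        p, s = fc.trial_response_test(t)
        assert p[0, 0] > 0.99
        assert s[0, 0] == 0

    def test_strong_shift_is_overwhelming(self):
        base = np.zeros((1, 1, 120))
        evoked = np.full((1, 1, 120), 5.0)
        p, s = fc.trial_response_test(tensor_from_windows(base, evoked))
        assert p[0, 0] < 1e-10
        assert s[0, 0] == 1

    def test_negation_flips_sign_not_p(self, rng):
        base = rng.normal(size=(3, 5, 120))
        evoked = rng.normal(0.5, 1.0, size=(3, 5, 120))
        t_pos = tensor_from_windows(base, evoked)
        t_neg = tensor_from_windows(-base, -evoked)
        p1, s1 = fc.trial_response_test(t_pos)
        p2, s2 = fc.trial_response_test(t_neg)
        assert np.allclose(p1, p2)
        assert np.array_equal(s1, -s2)

    def test_too_few_bins_rejected(self):
        t = tensor_from_windows(np.zeros((1, 1, 1)), np.zeros((1, 1, 1)))
        with pytest.raises(ValueError, match="bins"):
            fc.trial_response_test(t)


class TestClassifyCells:
    def test_rule_forced_examples(self):
        p = np.array([[0.005, 0.2, 0.009, 0.003, 0.5]])
        s = np.ones((1, 5), int)
        c = fc.classify_cells(p, s)
        assert c.responsive[0] and c.direction[0] == "activated"

        p2 = np.array([[0.005, 0.2, 0.009, 0.2, 0.5]])
        c2 = fc.classify_cells(p2, s)
        assert not c2.responsive[0] and c2.direction[0] == "none"

    def test_majority_sign_wins(self):
        p = np.array([[0.005, 0.005, 0.005, 0.5, 0.5]])
        s = np.array([[1, 1, -1, 1, -1]])
        c = fc.classify_cells(p, s)
        assert c.direction[0] == "activated"

    def test_tie_uses_fallback(self):
        p = np.array([[0.005, 0.005, 0.005, 0.005, 0.5]])
        s = np.array([[1, 1, -1, -1, 1]])
        c = fc.classify_cells(p, s, tiebreak=np.array([-2.0]))
        assert c.direction[0] == "inhibited"

    def test_min_significant_above_trials_rejected(self):
        with pytest.raises(ValueError, match="min_significant"):
            fc.classify_cells(np.zeros((1, 2)), np.ones((1, 2)), min_significant=3)


class TestAcrossDayTrialSets:
    @pytest.mark.parametrize("day,stim,expected", [
        ("test_ext1", "CS_PLUS", [0, 1, 2, 3]),
        ("ext2", "CS_PLUS", [8, 9, 10, 11]),
        ("habituation", "CS_MINUS", [0, 1, 2, 3]),
        ("habituation", "CS_PLUS", [0, 1, 2, 3]),
        ("test_ext1", "CS_MINUS", [0, 1, 2, 3]),
    ])
    def test_trial_subsets(self, day, stim, expected):
        assert fc.across_day_trial_sets(day, stim) == expected

    def test_insufficient_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            fc.across_day_trial_sets("ext2", "CS_PLUS", n_trials=3)


class TestNullControl:
    def test_false_positive_rate_binomial_bound(self):
        """Independent-trial rule bound: P(>=3 of 5 at alpha) ~ 9.85e-6."""
        exact = sum(stats.binom.pmf(k, 5, 0.01) for k in (3, 4, 5))
        assert exact == pytest.approx(9.8506e-6, rel=1e-3)

    def test_null_cells_rarely_classified(self, conditioning):
        """1,000 pure-noise cells: responsive fraction well under 0.5%."""
        cfg = synth.null_config(1000, seed=17)
        pop, _ = synth.generate_population(cfg, {"conditioning": conditioning})
        t = fc.align_to_events(pop, conditioning, "CS_PLUS", 30, 30, 30)
        cls = fc.classify_tensor(t)
        assert cls.responsive.mean() <= 0.005

    def test_planted_direction_recovery(self, planted_population, conditioning):
        """>= 95% of stable activated cells recovered with direction.

        The CS windows (120 vs 120 bins) carry enough rank-sum power for the
        full recovery guarantee; the short US evoked window (8 vs 20 bins)
        has intrinsically lower power, checked at a correspondingly weaker
        bound.
        """
        pop, gt = planted_population
        cs = fc.align_to_events(pop, conditioning, "CS_PLUS", 30, 30, 30)
        cls = fc.classify_tensor(cs)
        planted = (gt.labels["cs_plus"] == "stable_activated").to_numpy()
        assert (cls.direction[planted] == "activated").mean() >= 0.95

        us = fc.align_to_events(pop, conditioning, "US", 5, 10, 5)
        cls_us = fc.classify_tensor(us, evoked_window=2.0)
        planted_us = (gt.labels["us"] == "activated_stable").to_numpy()
        assert (cls_us.direction[planted_us] == "activated").mean() >= 0.7


class TestFractionsAndOverlap:
    @staticmethod
    def classification_from_flags(flags, stim):
        n = len(flags)
        p = np.where(flags[:, None], 1e-4, 0.9) * np.ones((n, 5))
        return fc.classify_cells(p, np.ones((n, 5), int), stimulus=stim)

    def test_fraction_arithmetic(self):
        cls = self.classification_from_flags(np.array([True, True, False, False]), "US")
        out = fc.responsive_fractions(cls)
        assert out.loc[0, "responsive"] == pytest.approx(0.5)
        assert out.loc[0, "activated"] == pytest.approx(0.5)

    def test_per_animal_mean_equals_pooled_for_equal_n(self):
        flags = np.array([True, False, True, True])
        cls = self.classification_from_flags(flags, "US")
        animals = np.array(["a", "a", "b", "b"])
        per_animal = fc.responsive_fractions(cls, animals, group_by="animal")
        pooled = fc.responsive_fractions(cls)
        assert per_animal["responsive"].mean() == pytest.approx(
            pooled.loc[0, "responsive"])

    def test_overlap_examples(self):
        rng = np.random.default_rng(3)
        n = 4000
        flags = {s: rng.uniform(size=n) < 0.5 for s in ("CS_PLUS", "CS_MINUS", "US")}
        cls = {s: self.classification_from_flags(f, s) for s, f in flags.items()}
        summary = fc.overlap_with_chance(cls, np.full(n, "a"))
        triple = summary.pooled.set_index("combination")
        assert triple.loc["CS+/CS-/US", "chance"] == pytest.approx(0.125, abs=0.01)
        # planted independence: observed matches chance within binomial CI
        for _, row in summary.pooled.iterrows():
            se = np.sqrt(row["chance"] * (1 - row["chance"]) / n)
            assert abs(row["observed"] - row["chance"]) < 4 * se + 1e-12
        # fractions (7 combinations + none) partition the population
        assert summary.pooled["observed"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_responders_have_zero_triple_overlap(self):
        flags = {"CS_PLUS": np.array([True, False, False]),
                 "CS_MINUS": np.array([False, True, False]),
                 "US": np.array([False, False, True])}
        cls = {s: self.classification_from_flags(f, s) for s, f in flags.items()}
        out = fc.overlap_with_chance(cls, np.array(["a"] * 3)).pooled.set_index("combination")
        assert out.loc["CS+/CS-/US", "observed"] == 0

    def test_overlap_invariant_to_cell_order(self, rng):
        n = 60
        flags = {s: rng.uniform(size=n) < 0.4 for s in ("CS_PLUS", "CS_MINUS", "US")}
        animals = np.repeat(["a", "b"], n // 2)
        perm = rng.permutation(n)
        a = fc.overlap_with_chance(
            {s: self.classification_from_flags(f, s) for s, f in flags.items()}, animals)
        b = fc.overlap_with_chance(
            {s: self.classification_from_flags(f[perm], s) for s, f in flags.items()},
            animals[perm])
        merged = a.pooled.merge(b.pooled, on="combination")
        assert np.allclose(merged["observed_x"], merged["observed_y"])


class TestSpatialDistances:
    def test_three_four_five(self):
        cents = np.array([[0.0, 0.0], [3.0, 4.0]])
        out = fc.spatial_distance_distribution(cents, np.array(["g", "g"]))
        assert np.allclose(out["mean_distance"], 5.0)

    def test_colocated_cells(self):
        cents = np.zeros((3, 2))
        out = fc.spatial_distance_distribution(cents, np.array(["g"] * 3))
        assert np.allclose(out["mean_distance"], 0.0)

    def test_singleton_group_excluded(self):
        cents = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        out = fc.spatial_distance_distribution(cents, np.array(["a", "a", "b"]))
        assert set(out["group"]) == {"a"}

    def test_uniform_scatter_groups_indistinguishable(self):
        """Randomly placed groups: no separable within-group distance CDFs.

        Within-group mean distances share each group's geometry, so the
        plain two-sample KS p-value is anti-conservative no matter the cell
        count; the calibrated null is a label permutation, against which the
        KS statistic must be unremarkable in >= 90% of simulations.
        """
        rng = np.random.default_rng(12)
        hits, n_sims = 0, 20
        for _ in range(n_sims):
            cents = rng.uniform(0, 300, (80, 2))
            labels = rng.choice(["a", "b"], 80)

            def ks_stat(lab):
                d = fc.spatial_distance_distribution(cents, lab)
                return stats.ks_2samp(d.loc[d["group"] == "a", "mean_distance"],
                                      d.loc[d["group"] == "b", "mean_distance"]).statistic

            obs = ks_stat(labels)
            null = [ks_stat(rng.permutation(labels)) for _ in range(49)]
            hits += (1 + sum(s >= obs for s in null)) / 50 > 0.05
        assert hits >= int(0.9 * n_sims)
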