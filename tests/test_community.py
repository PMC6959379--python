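"""OTU-table processing, Bray-Curtis and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from meshbag import community
from meshbag.community import (
    BlastHit,
    OtuTable,
    assign_rank,
    average_replicates,
    bray_curtis,
    filter_rare_otus,
    guild_profile,
    permanova,
    process_counts,
    rarefy,
    relative_abundance,
)


class TestAssignRank:
    @pytest.mark.parametrize("identity,coverage,expected", [
        (97.2, 85.0, "species"),
        (96.0, 80.0, "species"),
        (94.5, 90.0, "genus"),
        (95.99, 80.0, "genus"),
        (97.2, 70.0, "unassigned"),   # coverage gate applies to both tiers
        (94.5, 70.0, "unassigned"),
        (93.9, 99.0, "unassigned"),
    ])
    def test_rule(self, identity, coverage, expected):
        hit = BlastHit("OTU1", identity, coverage, "Tylospora fibrillosa")
        assert assign_rank(hit) == expected

    def test_out_of_range_percentages_rejected(self):
        with pytest.raises(ValueError):
            BlastHit("OTU1", 101.0, 80.0)
        with pytest.raises(ValueError):
            BlastHit("OTU1", 96.0, -1.0)


class TestFilter:
    def test_default_either_mode(self, toy_table):
        out = filter_rare_otus(toy_table)
        # B: 9 reads/1 column; C: 9 reads/3 columns; D: 10 reads/1 column
        assert list(out.counts.index) == ["A"]
        assert sorted(out.meta["filter_log"]["removed"]) == ["B", "C", "D"]

    def test_literal_both_mode(self, toy_table):
        out = filter_rare_otus(toy_table, mode="both")
        # only B fails both conditions
        assert list(out.counts.index) == ["A", "C", "D"]
        assert out.meta["filter_log"]["removed"] == ["B"]

    def test_nine_reads_one_sample_removed_in_both_modes(self, toy_table):
        for mode in ("either", "both"):
            out = filter_rare_otus(toy_table, mode=mode)
            assert "B" not in out.counts.index

    def test_unknown_mode_rejected(self, toy_table):
        with pytest.raises(ValueError, match="mode"):
            filter_rare_otus(toy_table, mode="sometimes")


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        counts = pd.DataFrame({"S1_r1": [10, 0], "S1_r2": [20, 0],
                               "S1_r3": [30, 0]}, index=["A", "Z"])
        t = OtuTable(counts, replicate_groups={c: "S1" for c in counts})
        out = average_replicates(t)
        assert out.counts.loc["A", "S1"] == 20.0
        assert out.counts.loc["Z", "S1"] == 0.0

    def test_single_replicate_identity(self, toy_table):
        counts = toy_table.counts[["S1_r1"]]
        t = OtuTable(counts, replicate_groups={"S1_r1": "S1"})
        out = average_replicates(t)
        assert np.array_equal(out.counts["S1"], counts["S1_r1"])

    def test_missing_groups_rejected(self, toy_counts):
        t = OtuTable(toy_counts)
        with pytest.raises(ValueError, match="replicate"):
            average_replicates(t)


class TestRarefy:
    def make_table(self, cols):
        counts = pd.DataFrame(cols)
        counts.index = [f"O{i}" for i in range(len(counts))]
        return OtuTable(counts)

    def test_column_sums_equal_depth(self):
        t = self.make_table({"a": [500, 300, 200], "b": [100, 600, 400]})
        out = rarefy(t, depth=300, seed=0)
        assert (out.counts.sum(axis=0) == 300).all()

    def test_depth_equal_to_sum_is_identity(self):
        t = self.make_table({"a": [5, 3, 2], "b": [100, 600, 400]})
        out = rarefy(t, depth=10, seed=0)
        assert np.array_equal(out.counts["a"], [5, 3, 2])

    def test_default_depth_is_lower_median(self):
        t = self.make_table({"a": [10, 0], "b": [0, 30], "c": [20, 0], "d": [0, 40]})
        out = rarefy(t, seed=0, on_shallow="drop")
        assert out.meta["rarefaction"]["depth"] == 20
        assert out.meta["rarefaction"]["dropped"] == ["a"]

    def test_shallow_sample_error_names_it(self):
        t = self.make_table({"shallow": [1, 1, 1], "deep": [50, 50, 50]})
        with pytest.raises(ValueError, match="shallow"):
            rarefy(t, depth=100)

    def test_drop_policy_removes_shallow(self):
        t = self.make_table({"shallow": [1, 1, 1], "deep": [50, 50, 50]})
        out = rarefy(t, depth=100, on_shallow="drop", seed=0)
        assert list(out.counts.columns) == ["deep"]
        assert out.meta["rarefaction"]["dropped"] == ["shallow"]

    def test_seeded_determinism(self):
        t = self.make_table({"a": [500, 300, 200]})
        out1 = rarefy(t, depth=100, seed=9)
        out2 = rarefy(t, depth=100, seed=9)
        assert out1.counts.equals(out2.counts)

    def test_hypergeometric_expectation(self):
        """Mean rarefied proportion of an OTU at true proportion 0.25
        stays within [0.23, 0.27] over 200 seeds."""
        t = self.make_table({"a": [100, 150, 80, 70]})  # p = 0.25 for O0
        props = []
        for seed in range(200):
            out = rarefy(t, depth=100, seed=seed)
            props.append(out.counts.loc["O0", "a"] / 100.0)
        assert 0.23 <= np.mean(props) <= 0.27


class TestGuildProfile:
    def test_fractions_sum_to_one(self, toy_table):
        profile, _ = guild_profile(toy_table)
        assert np.allclose(profile.sum(axis=0), 1.0, atol=1e-9)

    def test_single_guild_table(self):
        counts = pd.DataFrame({"s": [30, 20]}, index=["A", "B"])
        t = OtuTable(counts, guild={"A": "ECM", "B": "ECM"})
        profile, _ = guild_profile(t)
        assert profile.loc["ECM", "s"] == 1.0

    def test_display_cutoff_is_strict(self):
        counts = pd.DataFrame({"s1": [50, 51, 200]}, index=["at", "above", "big"])
        t = OtuTable(counts, guild={"at": "ECM", "above": "ECM", "big": "ECM"})
        _, display = guild_profile(t)
        assert "at" not in display and "above" in display and "big" in display

    def test_zero_sum_sample_rejected(self):
        counts = pd.DataFrame({"ok": [5], "empty": [0]}, index=["A"])
        t = OtuTable(counts, guild={"A": "ECM"})
        with pytest.raises(ValueError, match="zero-sum"):
            guild_profile(t)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(np.array([[3, 3], [1, 1], [4, 4]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[5, 0], [0, 7]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_computed_value(self):
        x = np.array([[1, 0], [0, 1], [1, 1]])  # columns (1,0,1) and (0,1,1)
        d = bray_curtis(x)
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_two_all_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.zeros((3, 2)))

    @given(arrays(np.int64, (4, 3), elements=st.integers(0, 50)))
    def test_symmetry_and_identity(self, counts):
        counts[0, :] += 1  # avoid all-zero columns
        d = bray_curtis(counts).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert np.all((d >= 0.0) & (d <= 1.0))


def _brute_force_permanova(d2, labels):
    """Independent pseudo-F via explicit pairwise loops."""
    n = len(labels)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    a = len(set(labels))
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


class TestPermanova:
    def small_distance(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 5))
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(X, "braycurtis"))

    def test_matches_brute_force_on_toy(self):
        d = self.small_distance(seed=2, n=6)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, n_perm=99, seed=0)
        f_bf, r2_bf = _brute_force_permanova(d**2, labels)
        assert res.f_statistic == pytest.approx(f_bf, rel=1e-10)
        assert res.r_squared == pytest.approx(r2_bf, rel=1e-10)

    def test_exact_p_by_enumerating_four_samples(self):
        """With 4 samples the permutation null can be enumerated exactly."""
        d = self.small_distance(seed=3, n=4)
        labels = ["a", "a", "b", "b"]
        f_obs, _ = _brute_force_permanova(d**2, labels)
        fs = []
        for perm in itertools.permutations(range(4)):
            fs.append(_brute_force_permanova(
                d**2, [labels[i] for i in perm])[0])
        exact_p = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        res = permanova(d, labels, n_perm=9999, seed=0)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_matches_scikit_bio(self):
        """Cross-check the pseudo-F against the independent skbio code."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d = self.small_distance(seed=4, n=8)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(d, labels, n_perm=99, seed=0)
        dm = skbio_distance.DistanceMatrix(d)
        sk = skbio_distance.permanova(dm, grouping=labels, permutations=99)
        assert res.f_statistic == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_saturated_significance_for_separated_clouds(self):
        """Clouds separated far beyond their spread: only permutations that
        recover the original partition reach F_obs, so p bottoms out at
        1/(n_perm + 1)."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, size=(10, 3))
        b = rng.normal(10, 0.01, size=(10, 3))
        X = np.abs(np.vstack([a, b]))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(X, "braycurtis"))
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000.0, abs=1e-9)
        # R^2 = F/(F + (N - a)) for two groups; F ~ 94, N = 20 -> ~0.84
        assert res.r_squared > 0.8

    def test_r_squared_in_unit_interval(self):
        for seed in range(5):
            d = self.small_distance(seed=seed)
            res = permanova(d, ["a", "b", "a", "b", "a", "b"], n_perm=49, seed=seed)
            assert 0.0 <= res.r_squared <= 1.0

    def test_singleton_group_rejected(self):
        d = self.small_distance(n=4)
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["a", "b", "b", "b"])

    def test_seeded_determinism(self):
        d = self.small_distance(seed=6)
        labels = ["a", "a", "a", "b", "b", "b"]
        r1 = permanova(d, labels, n_perm=199, seed=5)
        r2 = permanova(d, labels, n_perm=199, seed=5)
        assert r1 == r2


class TestPipelineComposition:
    def test_canonical_order_on_synthetic_experiment(self, otu_experiment):
        """filter -> average -> rarefy -> relative abundance removes exactly
        the planted rare OTUs and yields unit column sums."""
        table, truth = otu_experiment
        out = process_counts(table, seed=0, on_shallow="drop")
        filtered = filter_rare_otus(table)
        assert sorted(filtered.meta["filter_log"]["removed"]) == sorted(
            truth["filter_targets"])
        assert not set(truth["filter_targets"]) & set(out.counts.index)
        assert np.allclose(out.counts.sum(axis=0), 1.0, atol=1e-9)

    def test_relative_abundance_tracks_truth(self, otu_experiment):
        table, truth = otu_experiment
        out = process_counts(table, seed=0, on_shallow="drop")
        comp = truth["composition"].loc[out.counts.index, out.counts.columns]
        comp = comp / comp.sum(axis=0)
        err = (out.counts - comp).abs().to_numpy().max()
        assert err < 0.02
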