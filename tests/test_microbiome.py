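"""Rarefaction, diversity, CST assignment, IndVal and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from vagicoda import microbiome as mb


@pytest.fixture
def counts4():
    return pd.DataFrame(
        [[100, 50, 25, 25], [10, 0, 5, 185], [60, 60, 60, 20], [0, 0, 0, 300]],
        index=list("abcd"),
        columns=["t1", "t2", "t3", "t4"],
    )


class TestRarefy:
    def test_exhaustive_draw_unchanged(self, counts4):
        out = mb.rarefy(counts4, 200, seed=0)
        assert (out.loc["a"] == counts4.loc["a"]).all()

    def test_rows_sum_to_depth(self, counts4):
        out = mb.rarefy(counts4, 150, seed=1)
        assert (out.sum(axis=1) == 150).all()

    def test_shallow_samples_dropped_with_warning(self, counts4):
        with pytest.warns(UserWarning, match="below depth"):
            out = mb.rarefy(counts4, 250, seed=0)
        assert "a" not in out.index  # sample a totals exactly 200

    def test_hypergeometric_mean(self):
        row = pd.DataFrame([[40, 60, 100]], columns=["x", "y", "z"])
        depth, total = 50, 200
        draws = np.array([mb.rarefy(row, depth, seed=s).iloc[0, 0] for s in range(500)])
        expected = depth * 40 / total
        var = depth * (40 / total) * (1 - 40 / total) * (total - depth) / (total - 1)
        assert abs(draws.mean() - expected) < 3 * np.sqrt(var / 500)

    def test_invalid_depth(self, counts4):
        with pytest.raises(ValueError):
            mb.rarefy(counts4, 0)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,metric,expected",
        [
            ([5] * 8, "shannon", 3.0),  # 8 equal taxa, log2
            ([7], "shannon", 0.0),
            ([7], "observed", 1),
            ([1, 1, 2, 5], "chao1", 4.5),  # S=4, F1=2, F2=1
            ([3, 0, 2, 1], "observed", 3),
        ],
    )
    def test_hand_computed_fixtures(self, counts, metric, expected):
        assert mb.alpha_diversity(np.array(counts), metric) == pytest.approx(expected)

    def test_chao1_at_least_observed(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 5, size=30)
            if counts.sum() == 0:
                continue
            assert mb.alpha_diversity(counts, "chao1") >= mb.alpha_diversity(counts, "observed")

    def test_shannon_maximal_at_uniform(self, rng):
        uniform = np.full(12, 10)
        h_max = mb.alpha_diversity(uniform, "shannon")
        for _ in range(20):
            counts = rng.integers(1, 50, size=12)
            assert mb.alpha_diversity(counts, "shannon") <= h_max + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mb.alpha_diversity(np.zeros(4), "shannon")


class TestAssignCST:
    def test_self_assignment_theta_one(self):
        cents = mb.synthetic_centroids()
        for label in cents.index:
            a = mb.assign_cst(cents.loc[label], cents)
            assert a.label == label
            assert a.similarity == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_theta_zero(self):
        cents = pd.DataFrame(
            {"t1": [1.0, 0.0], "t2": [0.0, 1.0]}, index=["A", "B"]
        )
        a = mb.assign_cst(pd.Series({"t1": 1.0}), cents)
        assert a.similarities["B"] == 0.0

    def test_mixture_oracle(self):
        """0.9 A + 0.1 B is assigned to A; theta verified by hand formula."""
        cents = pd.DataFrame(
            {"t1": [0.8, 0.1, 0.2], "t2": [0.1, 0.8, 0.2], "t3": [0.1, 0.1, 0.6]},
            index=["A", "B", "C"],
        )
        p = 0.9 * cents.loc["A"] + 0.1 * cents.loc["B"]
        a = mb.assign_cst(p, cents)
        q = cents.loc["A"]
        theta = (p * q).sum() / ((p**2).sum() + (q**2).sum() - (p * q).sum())
        assert a.label == "A"
        assert a.similarity == pytest.approx(theta, abs=1e-12)

    def test_scale_invariance(self):
        cents = mb.synthetic_centroids()
        profile = pd.Series(
            {"Lactobacillus crispatus": 7000, "Lactobacillus iners": 500, "Other": 2500}
        )
        a_counts = mb.assign_cst(profile, cents)
        a_rel = mb.assign_cst(profile / profile.sum(), cents)
        assert a_counts.label == a_rel.label
        assert a_counts.similarity == pytest.approx(a_rel.similarity, abs=1e-12)

    def test_off_simplex_profile_rejected(self):
        cents = mb.synthetic_centroids()
        with pytest.raises(ValueError):
            mb.assign_cst(pd.Series({"Lactobacillus crispatus": -1.0}), cents)


class TestGroupCST:
    @pytest.mark.parametrize(
        "label,expected",
        [("I", "I-II-V"), ("II", "I-II-V"), ("V", "I-II-V"), ("I-A", "I-II-V"),
         ("III", "III"), ("III-B", "III"), ("IV-A", "IV"), ("IV-B", "IV"), ("IV-C", "IV")],
    )
    def test_grouping_rule(self, label, expected):
        assert mb.group_cst(label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            mb.group_cst("VII")


def brute_force_indval(x, codes, levels):
    """Independent IndVal oracle: literal formula per taxon/group."""
    best = np.zeros(x.shape[1])
    for t in range(x.shape[1]):
        ivs = []
        means = [x[codes == g, t].mean() for g in range(levels)]
        for g in range(levels):
            a = means[g] / sum(means) if sum(means) > 0 else 0.0
            b = (x[codes == g, t] > 0).mean()
            ivs.append(100 * a * b)
        best[t] = max(ivs)
    return best


class TestIndicatorSpecies:
    def test_perfect_indicator_is_100(self):
        x = pd.DataFrame({"t": [1.0, 1.0, 0.0, 0.0, 0.0, 0.0]})
        res = mb.indicator_species(x, ["g1"] * 2 + ["g2"] * 2 + ["g3"] * 2, n_perm=9, seed=0)
        assert res.stats.loc["t", "indval"] == pytest.approx(100.0)
        assert res.stats.loc["t", "group"] == "g1"

    def test_omnipresent_equal_taxon(self):
        x = pd.DataFrame({"t": [0.5] * 9})
        res = mb.indicator_species(x, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, n_perm=9, seed=0)
        assert res.stats.loc["t", "indval"] == pytest.approx(100 / 3)

    def test_exhaustive_permutation_oracle(self):
        """On a 6-sample design, the exact p equals brute-force enumeration
        over all 90 distinct label assignments."""
        rng = np.random.default_rng(5)
        x = rng.random((6, 3))
        x[x < 0.3] = 0.0
        table = pd.DataFrame(x, columns=["t1", "t2", "t3"])
        groups = ["a", "a", "b", "b", "c", "c"]
        res = mb.indicator_species(table, groups, seed=0, exact=True)
        codes = np.array([0, 0, 1, 1, 2, 2])
        observed = brute_force_indval(x, codes, 3)
        perms = set(itertools.permutations(codes.tolist()))
        assert len(perms) == 90
        for j, taxon in enumerate(table.columns):
            hits = sum(
                brute_force_indval(x, np.array(p), 3)[j] >= observed[j] - 1e-12
                for p in perms
            )
            assert res.stats.loc[taxon, "p"] == pytest.approx(hits / 90)
            assert res.stats.loc[taxon, "indval"] == pytest.approx(observed[j])

    def test_a_b_component_ranges(self, cohort113):
        rel = mb.relative_abundance(cohort113.taxa_counts)
        res = mb.indicator_species(rel, cohort113.cst_group, n_perm=49, seed=0)
        assert ((res.A >= 0) & (res.A <= 1)).all().all()
        assert ((res.B >= 0) & (res.B <= 1)).all().all()
        assert ((res.stats["p"] > 0) & (res.stats["p"] <= 1)).all()

    def test_pvalues_superuniform_under_exchangeability(self):
        """Permutation p-values are (weakly) super-uniform when labels
        carry no signal."""
        rng = np.random.default_rng(6)
        rejections, total = 0, 0
        for rep in range(60):
            x = pd.DataFrame(rng.random((24, 4)))
            groups = rng.permutation(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
            res = mb.indicator_species(x, groups, n_perm=99, seed=rep)
            rejections += (res.stats["p"] <= 0.05).sum()
            total += 4
        assert rejections / total < 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / total)


class TestBrayCurtisPermanova:
    def test_identical_rows_zero(self):
        t = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]])
        assert mb.bray_curtis(t).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        t = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        assert mb.bray_curtis(t).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        t = pd.DataFrame([[0.7, 0.2, 0.1], [0.3, 0.3, 0.4], [0.0, 0.5, 0.5]])
        d = mb.bray_curtis(t)
        # 1 - sum(min): rows 0,1 -> 1-(0.3+0.2+0.1)=0.4
        assert d.iloc[0, 1] == pytest.approx(0.4, abs=1e-12)
        assert d.iloc[0, 2] == pytest.approx(1 - (0.0 + 0.2 + 0.1), abs=1e-12)
        assert d.iloc[1, 2] == pytest.approx(1 - (0.0 + 0.3 + 0.4), abs=1e-12)

    def test_two_separated_clusters_minimal_p(self, rng):
        # 15+15 so a random relabelling virtually never replicates the split
        a = rng.normal(0, 0.01, size=(15, 3)) + [5, 0, 0]
        b = rng.normal(0, 0.01, size=(15, 3)) + [0, 5, 0]
        d = pd.DataFrame(squareform(pdist(np.vstack([a, b]))))
        res = mb.permanova(d, ["a"] * 15 + ["b"] * 15, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_pseudo_f_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        x = rng.random((15, 4))
        d = squareform(pdist(x))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = mb.permanova(pd.DataFrame(d), groups, n_perm=49, seed=0)
        dm = skbio_stats.DistanceMatrix(d)
        ref = skbio_stats.permanova(dm, grouping=groups, permutations=49)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_singleton_groups_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="singleton"):
            mb.permanova(d, ["a", "b", "c"], n_perm=9)

    def test_synthetic_cohort_groups_separate(self, cohort113):
        """Bray-Curtis PERMANOVA separates the three CST groups of the
        default cohort decisively (p <= 0.005)."""
        rel = mb.relative_abundance(cohort113.taxa_counts)
        res = mb.permanova(mb.bray_curtis(rel), cohort113.cst_group, n_perm=999, seed=0)
        assert res.p <= 0.005


class TestAlphaGroupTest:
    def test_detects_large_shift(self, rng):
        values = pd.Series(np.r_[rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        groups = ["lo"] * 20 + ["hi"] * 20
        res = mb.alpha_group_test(values, groups, n_perm=199, seed=0)
        assert res["p"].iloc[0] <= 0.01
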