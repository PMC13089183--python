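"""Conformational-energetics tests: PIE sums, clustering recovery,
Tukey–Kramer statistics and letters, stable-cluster selection, dG_bind."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from tpmtools.conformers import (
    EnergyTriple,
    PIEMatrix,
    analyze_pie_matrix,
    cluster_conformations,
    compact_letter_display,
    delta_g_bind,
    dendrogram_newick,
    fragment_pie_profile,
    pairwise_q_statistics,
    select_stable_clusters,
    total_pie_per_conformation,
    tukey_kramer,
)
from tpmtools.synth import PIEClusterSpec, gen_pie_matrix


def _matrix(values, ids=None, frags=None) -> PIEMatrix:
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    frags = frags or [f"F{j}" for j in range(values.shape[1])]
    return PIEMatrix(pd.DataFrame(values, index=ids, columns=frags))


def _planted(k, sizes, totals, n_frag=12, within_sd=1.0, seed=0):
    rng = np.random.default_rng(seed + 77)
    profiles = []
    for t in totals:
        base = rng.uniform(-20.0, 20.0, size=n_frag)
        base += (t - base.sum()) / n_frag
        profiles.append(tuple(base))
    spec = PIEClusterSpec(
        n_fragments=n_frag, cluster_sizes=tuple(sizes),
        cluster_mean_profiles=tuple(profiles), within_sd=within_sd, seed=seed,
    )
    return gen_pie_matrix(spec)


class TestPIESums:
    def test_all_zero_matrix(self):
        m = _matrix(np.zeros((4, 3)))
        assert np.allclose(total_pie_per_conformation(m), 0.0)

    def test_single_conformation_arithmetic(self):
        m = _matrix([[-10.0, -5.0, 1.0]])
        assert total_pie_per_conformation(m).iloc[0] == pytest.approx(-14.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(-5, 10, size=(20, 15))
        m = _matrix(vals)
        totals = total_pie_per_conformation(m).to_numpy()
        oracle = np.array([sum(vals[i, j] for j in range(15)) for i in range(20)])
        assert np.allclose(totals, oracle, rtol=1e-12)

    def test_nonfinite_cells_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1.0, np.nan], [0.0, 2.0]])

    def test_duplicate_fragment_labels_rejected(self):
        with pytest.raises(ValueError):
            _matrix(np.zeros((2, 2)), frags=["A", "A"])


class TestFragmentProfile:
    def test_identity_like_matrix_gives_column_sums(self):
        vals = np.diag([-3.0, -7.0, -1.0])
        m = _matrix(vals)
        assert np.allclose(fragment_pie_profile(m), vals.sum(axis=0))

    def test_planted_cluster_mean_profile_recovered(self):
        m, labels = _planted(3, [5, 5, 5], [-300, -200, -100], within_sd=0.0)
        spec_profile = fragment_pie_profile(m, labels=labels, cluster=1) / 5.0
        # with zero within-cluster noise every row equals the mean profile
        assert np.allclose(spec_profile, m.values[labels == 1][0])

    def test_conservation_identity(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(-5, 8, size=(30, 10)))
        lhs = fragment_pie_profile(m).sum()
        rhs = total_pie_per_conformation(m).sum()
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_unknown_cluster_rejected(self):
        m, labels = _planted(2, [3, 3], [-100, -50])
        with pytest.raises(ValueError, match="unknown cluster"):
            fragment_pie_profile(m, labels=labels, cluster=99)


class TestClustering:
    def test_planted_partitions_recovered_exactly(self):
        for k, seed in [(3, 0), (5, 1), (9, 2)]:
            sizes = [10 + 2 * i for i in range(k)]
            totals = [-400 + 60 * i for i in range(k)]
            m, truth = _planted(k, sizes, totals, within_sd=1.0, seed=seed)
            res = cluster_conformations(m, n_clusters=k)
            assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_auto_gap_rule_finds_planted_count(self):
        m, truth = _planted(4, [12, 12, 12, 12], [-400, -300, -200, -100], within_sd=1.0)
        res = cluster_conformations(m)
        assert res.linkage_info["n_clusters"] == 4
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_rows_single_cluster(self):
        m = _matrix(np.tile([-5.0, -3.0], (6, 1)))
        res = cluster_conformations(m, n_clusters=1)
        assert np.all(res.labels == 0)

    def test_permutation_invariance(self):
        m, truth = _planted(3, [8, 8, 8], [-300, -200, -100], seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(m.n_conformations)
        mp = PIEMatrix(m.table.iloc[perm])
        a = cluster_conformations(m, n_clusters=3).labels
        b = cluster_conformations(mp, n_clusters=3).labels
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_too_many_clusters_rejected(self):
        m, _ = _planted(2, [3, 3], [-100, -50])
        with pytest.raises(ValueError):
            cluster_conformations(m, n_clusters=7)

    def test_scale_invariance_of_partition(self):
        m, _ = _planted(3, [8, 8, 8], [-300, -200, -100], seed=5)
        scaled = PIEMatrix(m.table * 7.5)
        a = cluster_conformations(m).labels
        b = cluster_conformations(scaled).labels
        assert np.array_equal(a, b)

    def test_matches_sklearn_agglomerative(self):
        """Independent route: scikit-learn's Ward agglomerative clustering
        yields the same partition on generic data."""
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(0, 5, size=(40, 6)))
        ours = cluster_conformations(m, n_clusters=4).labels
        sk = AgglomerativeClustering(n_clusters=4, linkage="ward").fit_predict(m.values)
        assert adjusted_rand_score(ours, sk) == 1.0

    def test_newick_export_parses(self):
        m, _ = _planted(2, [3, 3], [-100, -50])
        res = cluster_conformations(m, n_clusters=2)
        nwk = dendrogram_newick(res, leaf_names=list("abcdef"))
        assert nwk.endswith(";") and nwk.count("(") == 5


class TestTukeyKramer:
    def test_two_group_q_matches_hand_computation(self):
        a = np.array([-10.0, -12.0, -11.0, -9.0])
        b = np.array([-20.0, -18.0, -19.0, -21.0, -22.0])
        table, letters = tukey_kramer({0: a, 1: b}, alpha=0.05)
        # hand-computed pooled variance and Tukey–Kramer standard error
        s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (9 - 2)
        q_hand = abs(a.mean() - b.mean()) / np.sqrt(s2 / 2 * (1 / 4 + 1 / 5))
        row = table.iloc[0]
        assert row["q_statistic"] == pytest.approx(q_hand, rel=1e-12)
        # critical value from the studentized-range table: q(0.05; 2, 7) = 3.344
        assert row["reject"] == (q_hand > 3.344)
        assert letters[0] != letters[1]

    def test_tabulated_critical_values(self):
        # textbook studentized-range quantiles at alpha = 0.05
        assert studentized_range.ppf(0.95, 2, 10) == pytest.approx(3.151, abs=0.01)
        assert studentized_range.ppf(0.95, 3, 12) == pytest.approx(3.773, abs=0.01)

    def test_agrees_with_statsmodels_unequal_n(self):
        rng = np.random.default_rng(7)
        groups = {
            0: rng.normal(-30, 3, size=8),
            1: rng.normal(-28, 3, size=12),
            2: rng.normal(-10, 3, size=5),
        }
        table, _ = tukey_kramer(groups, alpha=0.05)
        endog = np.concatenate(list(groups.values()))
        labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
        sm = pairwise_tukeyhsd(endog, labels, alpha=0.05)
        assert np.allclose(table["mean_diff"].to_numpy(), sm.meandiffs, rtol=1e-9)
        assert np.allclose(table["p_adjusted"].to_numpy(), sm.pvalues, atol=1e-6)
        assert np.array_equal(table["reject"].to_numpy(), sm.reject)

    def test_identical_constant_groups_share_single_letter(self):
        groups = {g: np.full(4, -25.0) for g in range(3)}
        _, letters = tukey_kramer(groups)
        assert set(letters.values()) == {"a"}

    def test_extreme_separation_gives_distinct_letters(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(-100 * (g + 1), 1.0, size=6) for g in range(3)}
        _, letters = tukey_kramer(groups)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_kramer({0: np.array([1.0]), 1: np.array([1.0, 2.0])})

    def test_zero_pooled_variance_unequal_means_all_rejected(self):
        groups = {0: np.full(3, -10.0), 1: np.full(3, -20.0)}
        table, letters = tukey_kramer(groups)
        assert table["reject"].all()
        assert letters[0] != letters[1]

    def test_reduces_to_two_sample_q_test(self):
        # k=2 equal n: rejection agrees with the q-based two-group decision
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(rng.uniform(0, 2), 1, size=6)
            table, _ = tukey_kramer({0: a, 1: b}, alpha=0.05)
            qcrit = studentized_range.ppf(0.95, 2, 10)
            assert table["reject"].iloc[0] == (table["q_statistic"].iloc[0] > qcrit)

    def test_familywise_error_controlled_under_null(self):
        """With 5 identically distributed groups, the family-wise rejection
        rate over 1000 simulations stays within Monte-Carlo error of alpha."""
        rng = np.random.default_rng(10)
        k, n, reps, alpha = 5, 10, 1000, 0.05
        qcrit = studentized_range.ppf(1 - alpha, k, k * (n - 1))
        hits = 0
        for _ in range(reps):
            groups = {g: rng.normal(0.0, 1.0, size=n) for g in range(k)}
            table = pairwise_q_statistics(groups)
            hits += table["q_statistic"].max() > qcrit
        fwer = hits / reps
        assert fwer <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_letters_are_a_valid_cover(self):
        rng = np.random.default_rng(11)
        groups = {g: rng.normal(-5 * g, 4.0, size=7) for g in range(6)}
        table, letters = tukey_kramer(groups)
        for row in table.itertuples():
            share = bool(set(letters[row.cluster_a]) & set(letters[row.cluster_b]))
            assert share == (not row.reject)


class TestStableClusterSelection:
    def test_single_strongest_distinct(self):
        means = {0: -400.0, 1: -200.0, 2: -100.0}
        letters = {0: "a", 1: "b", 2: "c"}
        assert select_stable_clusters(means, letters) == [0]

    def test_tied_minimum_sharing_letter(self):
        means = {0: -400.0, 1: -399.0, 2: -100.0}
        letters = {0: "a", 1: "a", 2: "b"}
        assert select_stable_clusters(means, letters) == [0, 1]

    def test_planted_four_strong_five_weak(self):
        sizes = [20] * 9
        totals = [-400.0] * 4 + [-250.0, -210.0, -170.0, -130.0, -90.0]
        m, truth = _planted(9, sizes, totals, within_sd=1.5, seed=12)
        res, _ = analyze_pie_matrix(m, n_clusters=9)
        # map found labels back to planted clusters via majority vote
        found_stable = set(res.stable_ids)
        planted_strong = set()
        for c in res.cluster_ids:
            planted = np.bincount(truth[res.labels == c]).argmax()
            if planted < 4:
                planted_strong.add(c)
        assert found_stable == planted_strong
        assert len(found_stable) == 4


class TestDeltaG:
    def test_worked_example(self):
        assert delta_g_bind(EnergyTriple(-1000.0, -900.0, -6.0)) == pytest.approx(-94.0)

    def test_non_interacting_limit(self):
        assert delta_g_bind(EnergyTriple(-906.0, -900.0, -6.0)) == 0.0

    def test_random_triples_match_arithmetic_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            c, r, l = rng.normal(0, 500, size=3)
            assert delta_g_bind(EnergyTriple(c, r, l)) == pytest.approx(c - (r + l), abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            EnergyTriple(np.inf, -900.0, -6.0)


class TestCompactLetterDisplay:
    def test_non_transitive_chain(self):
        # 0 vs 2 differ; 0 vs 1 and 1 vs 2 do not: letters must overlap pairwise
        means = {0: -30.0, 1: -20.0, 2: -10.0}
        letters = compact_letter_display(means, {frozenset((0, 2))})
        assert set(letters[0]) & set(letters[1])
        assert set(letters[1]) & set(letters[2])
        assert not set(letters[0]) & set(letters[2])
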