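"""K-means fitting, validity indices against brute-force oracles, and voting."""

import itertools

import numpy as np
import pytest

from streamarch.kselect import (
    DEFAULT_INDEX_SET,
    INDEX_REGISTRY,
    RegistryError,
    SelectionError,
    kmeans_fit,
    tally_votes,
    total_ss,
    validity_index,
    vote_for_k,
    within_between,
)

FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])


# ---------------------------------------------------------------------------
# independent oracles (naive loops, no shared code with the implementation)


def oracle_calinski_harabasz(X, labels):
    n, k = len(X), len(set(labels))
    grand = X.mean(axis=0)
    b = w = 0.0
    for lab in set(labels):
        sub = X[labels == lab]
        c = sub.mean(axis=0)
        b += len(sub) * ((c - grand) ** 2).sum()
        for row in sub:
            w += ((row - c) ** 2).sum()
    return (b / (k - 1)) / (w / (n - k))


def oracle_silhouette(X, labels):
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:
            s.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != own
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


class TestKMeansFit:
    def test_separable_pairs(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        res = kmeans_fit(x, k=2, restarts=5, seed=0)
        assert res.within_ss == pytest.approx(1.0)
        assert sorted(res.centroids.ravel()) == pytest.approx([0.5, 10.5])
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]
        assert set(res.labels) == {1, 2}

    def test_k_equals_n_zero_within(self):
        res = kmeans_fit(FOUR_POINTS, k=4, restarts=3, seed=1)
        assert res.within_ss == pytest.approx(0.0, abs=1e-12)

    def test_best_of_restarts_no_worse_than_single(self):
        # with a shared seed the single-restart run uses the first of the
        # multi-restart initialisations, so best-of must be no worse
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        for seed in range(5):
            multi = kmeans_fit(X, k=5, restarts=20, seed=seed).within_ss
            single = kmeans_fit(X, k=5, restarts=1, seed=seed).within_ss
            assert multi <= single + 1e-9

    def test_inertia_conservation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        res = kmeans_fit(X, k=4, restarts=5, seed=0)
        w, b = within_between(X, res.labels)
        assert w + b == pytest.approx(total_ss(X), abs=1e-8)
        assert w == pytest.approx(res.within_ss, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            kmeans_fit(FOUR_POINTS, k=5)
        bad = FOUR_POINTS.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            kmeans_fit(bad, k=2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        a = kmeans_fit(X, k=3, restarts=10, seed=11)
        b = kmeans_fit(X, k=3, restarts=10, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert a.within_ss == b.within_ss


class TestValidityIndices:
    @pytest.fixture()
    def four_point_results(self):
        return {k: kmeans_fit(FOUR_POINTS, k, restarts=5, seed=0) for k in (2, 3)}

    def test_calinski_harabasz_hand_value(self, four_point_results):
        values, _ = validity_index(FOUR_POINTS, four_point_results, "calinski_harabasz")
        # between-SS 200, within-SS 1: (200/1) / (1/(4-2)) = 400
        assert values[2] == pytest.approx(400.0)

    def test_silhouette_hand_value(self, four_point_results):
        values, _ = validity_index(FOUR_POINTS, four_point_results, "silhouette")
        # corner points like (0,0): a = 1, b = mean(sqrt(200), sqrt(221)) ~ 14.504
        # inner points like (0,1): a = 1, b = mean(sqrt(181), sqrt(200)) ~ 13.798
        b_corner = (np.sqrt(200) + np.sqrt(221)) / 2
        b_inner = (np.sqrt(181) + np.sqrt(200)) / 2
        s_corner = (b_corner - 1) / b_corner  # ~ 0.931
        s_inner = (b_inner - 1) / b_inner
        assert s_corner == pytest.approx(0.931, abs=1e-3)
        assert values[2] == pytest.approx((s_corner + s_inner) / 2, abs=1e-9)

    def test_unregistered_index(self, four_point_results):
        with pytest.raises(RegistryError):
            validity_index(FOUR_POINTS, four_point_results, "nosuch")

    @pytest.mark.parametrize("index_name", ["calinski_harabasz", "silhouette"])
    def test_matches_brute_force_oracle_on_random_instances(self, index_name):
        oracle = {
            "calinski_harabasz": oracle_calinski_harabasz,
            "silhouette": oracle_silhouette,
        }[index_name]
        rng = np.random.default_rng(12)
        for _ in range(20):
            X = rng.normal(size=(10, 3))
            results = {k: kmeans_fit(X, k, restarts=5, seed=1) for k in (2, 3, 4)}
            values, _ = validity_index(X, results, index_name)
            for k, res in results.items():
                assert values[k] == pytest.approx(oracle(X, res.labels), rel=1e-9)

    def test_matches_sklearn_oracles(self):
        from sklearn.metrics import (
            calinski_harabasz_score,
            davies_bouldin_score,
            silhouette_score,
        )

        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 4))
        results = {k: kmeans_fit(X, k, restarts=5, seed=2) for k in (2, 3, 4, 5)}
        for name, fn in [
            ("calinski_harabasz", calinski_harabasz_score),
            ("silhouette", silhouette_score),
            ("davies_bouldin", davies_bouldin_score),
        ]:
            values, _ = validity_index(X, results, name)
            for k, res in results.items():
                assert values[k] == pytest.approx(fn(X, res.labels), rel=1e-9), name

    def test_winners_match_rule_reevaluation(self):
        """Each index's winner equals a brute-force application of its rule."""
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(loc, 0.5, size=(20, 2)) for loc in (0, 5, 10)])
        results = {k: kmeans_fit(X, k, restarts=10, seed=3) for k in range(2, 7)}
        for name in DEFAULT_INDEX_SET:
            values, winner = validity_index(X, results, name)
            rule = INDEX_REGISTRY[name].rule
            defined = {k: v for k, v in values.items() if np.isfinite(v)}
            if not defined:
                assert winner is None
                continue
            if rule == "max":
                expect = min(k for k, v in defined.items() if v == max(defined.values()))
            elif rule == "min":
                expect = min(k for k, v in defined.items() if v == min(defined.values()))
            else:  # max_drop
                drops = {
                    k: values[k - 1] - values[k]
                    for k in defined
                    if k - 1 in values and np.isfinite(values[k - 1])
                }
                expect = min(k for k, v in drops.items() if v == max(drops.values()))
            assert winner == expect, name

    def test_ch_winner_recovers_true_k(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(loc, 0.3, size=(15, 2)) for loc in (0, 6, 12)])
        results = {k: kmeans_fit(X, k, restarts=10, seed=4) for k in range(2, 7)}
        _, winner = validity_index(X, results, "calinski_harabasz")
        assert winner == 3

    def test_gap_statistic_recovers_two_blobs(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(8, 0.5, (20, 2))])
        results = {k: kmeans_fit(X, k, restarts=5, seed=5) for k in range(2, 6)}
        values, winner = validity_index(X, results, "gap", seed=5)
        assert winner == 2
        assert all(np.isfinite(v) for v in values.values())


class TestVoting:
    def test_parsimony_prefers_smaller_within_margin(self):
        winners = {f"i{j}": 9 for j in range(7)} | {f"j{j}": 2 for j in range(6)}
        votes, chosen, applied = tally_votes(winners, parsimony_margin=1)
        assert votes == {9: 7, 2: 6}
        assert chosen == 2 and applied

    def test_parsimony_margin_not_reached(self):
        winners = (
            {f"i{j}": 4 for j in range(7)}
            | {f"j{j}": 2 for j in range(5)}
            | {f"k{j}": 3 for j in range(5)}
        )
        votes, chosen, applied = tally_votes(winners, parsimony_margin=1)
        assert votes == {4: 7, 2: 5, 3: 5}
        assert chosen == 4 and not applied

    def test_tie_goes_to_smallest_k(self):
        winners = {"a": 5, "b": 3, "c": 5, "d": 3}
        _, chosen, _ = tally_votes(winners, parsimony_margin=0)
        assert chosen == 3

    def test_all_abstain_raises(self):
        with pytest.raises(SelectionError):
            tally_votes({"a": None, "b": None})

    def test_unanimous_two_blob_vote(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 0.4, (25, 2)), rng.normal(10, 0.4, (25, 2))])
        table, results = vote_for_k(X, k_range=(2, 6), restarts=10, seed=0)
        assert table.chosen_k == 2
        assert table.votes[2] == max(table.votes.values())
        assert table.votes[2] >= len(table.winners) / 2
        assert sum(table.votes.values()) == len(table.winners)
        assert set(results) == set(range(2, 7))

    def test_vote_deterministic(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(50, 3))
        a, _ = vote_for_k(X, k_range=(2, 5), restarts=5, seed=9)
        b, _ = vote_for_k(X, k_range=(2, 5), restarts=5, seed=9)
        assert a.chosen_k == b.chosen_k and a.votes == b.votes and a.grid == b.grid
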