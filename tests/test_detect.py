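"""kNN core: distances, neighbours, modified z-scores, RMS and ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from locshift.detect import (
    ChangeMatrix,
    change_matrix,
    euclidean_distance,
    find_neighbors,
    modified_zscores,
    rank_genes,
    rms_score,
)
from locshift.profiles import ProfileMatrix, localization_mask


def _pm(values, gene_ids=None, screen="s", labels=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(values.shape[0])]
    labels = labels or [f"f{j}" for j in range(values.shape[1])]
    return ProfileMatrix(screen_id=screen, gene_ids=list(gene_ids), values=values,
                         feature_labels=list(labels), aggregator="mean", rescaled=True)


def _labels60():
    from locshift.profiles import FEATURES
    return [f"{t}{b}_{f}" for t in ("bud", "mother") for b in range(1, 6) for f in FEATURES]


class TestEuclideanDistance:
    def test_identity(self):
        a = np.arange(60.0)
        assert euclidean_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = np.zeros(60)
        b = np.zeros(60)
        b[0], b[1] = 3.0, 4.0
        assert euclidean_distance(a, b) == pytest.approx(5.0)

    def test_matches_termwise_sum_oracle(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=(2, 60))
            oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert euclidean_distance(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestFindNeighbors:
    def test_self_is_excluded(self):
        pm = _pm([[0.0], [1.0], [2.0]])
        ns = find_neighbors(pm, "g000", k=1)
        assert ns.neighbor_ids == ["g001"]

    def test_duplicate_profile_is_first_neighbor_at_zero_distance(self):
        pm = _pm([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]])
        ns = find_neighbors(pm, "g000", k=2)
        assert ns.neighbor_ids[0] == "g002"
        assert ns.distances[0] == 0.0

    def test_distance_ties_break_lexicographically(self):
        pm = _pm([[0.0], [1.0], [-1.0]], gene_ids=["q", "b", "a"])
        ns = find_neighbors(pm, "q", k=2)
        assert ns.neighbor_ids == ["a", "b"]

    def test_matches_full_sort_oracle(self, rng):
        values = rng.normal(size=(200, 60))
        pm = _pm(values)
        ns = find_neighbors(pm, "g007", k=50)
        d = np.sqrt(((values - values[7]) ** 2).sum(axis=1))
        oracle = sorted((dist, g) for dist, g in zip(d, pm.gene_ids) if g != "g007")
        assert ns.neighbor_ids == [g for _, g in oracle[:50]]
        np.testing.assert_allclose(ns.distances, [dist for dist, _ in oracle[:50]])

    @pytest.mark.parametrize("k", [0, 3, 99])
    def test_invalid_k_raises(self, k):
        pm = _pm(np.arange(3.0)[:, None])
        with pytest.raises(ValueError):
            find_neighbors(pm, "g000", k=k)


class TestModifiedZscores:
    def test_query_at_median_scores_zero(self):
        nc = np.array([[1.0], [2.0], [3.0]])
        assert modified_zscores(np.array([2.0]), nc)[0] == 0.0

    def test_hand_computed_example(self):
        # neighbours {1..5}: median 3, MAD 1; query 5 -> 0.6745 * 2
        nc = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        M = modified_zscores(np.array([5.0]), nc)
        assert M[0] == pytest.approx(0.6745 * 2)

    def test_matches_per_feature_loop_oracle(self, rng):
        nc = rng.normal(size=(50, 60))
        x = rng.normal(size=60)
        M = modified_zscores(x, nc)
        for i in range(60):
            med = np.median(nc[:, i])
            mad = np.median(np.abs(nc[:, i] - med))
            assert M[i] == pytest.approx(0.6745 * (x[i] - med) / mad, rel=1e-12)

    def test_mad_zero_falls_back_to_mean_absolute_deviation(self):
        # {0,0,0,4}: median 0, MAD 0, meanAD 1 -> M = dev / 1.2533
        nc = np.array([[0.0], [0.0], [0.0], [4.0]])
        M = modified_zscores(np.array([2.0]), nc)
        assert M[0] == pytest.approx(2.0 / 1.2533)

    def test_fully_degenerate_feature_scores_zero_or_cap(self):
        nc = np.ones((5, 2))
        M = modified_zscores(np.array([1.0, 3.0]), nc, z_cap=10.0)
        assert M[0] == 0.0
        assert M[1] == 10.0

    def test_fewer_than_two_neighbors_raises(self):
        with pytest.raises(ValueError):
            modified_zscores(np.array([1.0]), np.array([[1.0]]))

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            modified_zscores(np.array([np.nan]), np.ones((3, 1)))


class TestRmsScore:
    def test_zero_vector_scores_zero(self):
        assert rms_score(np.zeros(60), np.ones(60, dtype=bool)) == 0.0

    def test_constant_masked_values_give_magnitude(self):
        M = np.full(60, -3.0)
        mask = np.zeros(60, dtype=bool)
        mask[10:] = True
        assert rms_score(M, mask) == pytest.approx(3.0)

    def test_matches_loop_oracle(self, rng):
        M = rng.normal(size=60)
        mask = rng.random(60) < 0.8
        expected = np.sqrt(sum(M[i] ** 2 for i in range(60) if mask[i]) / mask.sum())
        assert rms_score(M, mask) == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            rms_score(np.ones(60), np.zeros(60, dtype=bool))


class TestChangeMatrix:
    def test_wild_type_minus_perturbation(self):
        wt = _pm([[3.0, 1.0]], labels=["a", "b"])
        pert = _pm([[1.0, 2.0]], labels=["a", "b"])
        cm = change_matrix(wt, pert)
        np.testing.assert_array_equal(cm.values, [[2.0, -1.0]])

    def test_antisymmetric_under_screen_swap(self, small_profiles):
        wt, pert = small_profiles
        fwd = change_matrix(wt, pert)
        rev = change_matrix(pert, wt)
        np.testing.assert_array_equal(fwd.values, -rev.values)

    def test_restricted_to_shared_genes(self):
        wt = _pm([[1.0], [2.0]], gene_ids=["a", "b"])
        pert = _pm([[1.0], [5.0]], gene_ids=["b", "c"])
        cm = change_matrix(wt, pert)
        assert cm.gene_ids == ["b"]
        np.testing.assert_array_equal(cm.values, [[1.0]])


class TestRankGenes:
    def test_identical_screens_give_all_zero_scores(self, small_profiles):
        wt, _ = small_profiles
        results = rank_genes(wt, wt, k=10)
        assert all(r.rms == 0.0 for r in results)
        assert all(np.all(r.M == 0.0) for r in results)
        assert sorted(r.rank for r in results) == list(range(1, len(results) + 1))

    def test_single_large_change_ranks_first(self, rng):
        labels = _labels60()
        values = rng.normal(0, 1, size=(80, 60))
        wt = _pm(values, labels=labels)
        pert_values = values.copy()
        delta = np.zeros(60)
        delta[localization_mask(labels)] = rng.normal(0, 1, 50)
        delta *= 40.0 / np.linalg.norm(delta)
        pert_values[17] -= delta
        pert = _pm(pert_values, labels=labels)
        results = rank_genes(wt, pert, k=20)
        assert results[0].gene_id == wt.gene_ids[17]
        assert results[0].rank == 1

    def test_shift_invariance_is_bitwise(self, rng):
        """Adding one offset to the change vectors of a query and all its
        neighbours leaves the query's M untouched: the local median absorbs
        the shift and the MAD is unaffected. This is the mechanism by which
        the method cancels cluster-wide global effects.

        Values are dyadic rationals (multiples of 1/1024) so every addition
        is exact and the invariance can be asserted bit for bit."""
        labels = _labels60()
        values = rng.integers(-1024, 1024, size=(60, 60)) / 1024.0
        # two tight clusters so neighbourhoods are stable
        values[:30] += 32.0
        wt = _pm(values, labels=labels)
        pert_values = values + rng.integers(-256, 256, values.shape) / 1024.0
        pert = _pm(pert_values, labels=labels)
        base = rank_genes(wt, pert, k=15)
        # shift the change vector of every gene in the first cluster by delta
        # (equivalently: subtract delta from their perturbation profiles)
        delta = rng.integers(-4096, 4096, 60) / 1024.0
        shifted = pert_values.copy()
        shifted[:30] -= delta
        pert2 = _pm(shifted, labels=labels)
        res2 = rank_genes(wt, pert2, k=15)
        base_by_gene = {r.gene_id: r for r in base}
        for r in res2:
            i = wt.gene_ids.index(r.gene_id)
            if i < 30:  # query and all its neighbours received delta
                np.testing.assert_array_equal(r.M, base_by_gene[r.gene_id].M)

    def test_scale_invariance_of_zscores(self, rng):
        labels = _labels60()
        values = rng.normal(0, 1, size=(40, 60))
        wt = _pm(values, labels=labels)
        pert = _pm(values + rng.normal(0, 0.5, values.shape), labels=labels)
        base = rank_genes(wt, pert, k=10)
        # scaling all change vectors by c > 0 scales numerator and MAD alike;
        # scale the perturbation deviation from wild type by c
        c = 3.7
        pert2 = _pm(values + c * (pert.values - values), labels=labels)
        res2 = rank_genes(wt, pert2, k=10)
        # neighbourhoods are computed in wild-type space, hence unchanged
        for r0, r1 in zip(base, res2):
            assert r0.gene_id == r1.gene_id
            np.testing.assert_allclose(r1.M, r0.M, rtol=1e-9)

    def test_gene_set_mismatch_names_the_difference(self):
        wt = _pm([[1.0], [2.0]], gene_ids=["a", "b"])
        pert = _pm([[1.0], [2.0]], gene_ids=["a", "c"])
        with pytest.raises(ValueError, match=r"\['b', 'c'\]"):
            rank_genes(wt, pert, k=1)

    def test_matches_naive_quadratic_oracle(self, rng):
        """End-to-end agreement with a direct per-gene reimplementation."""
        labels = _labels60()
        values = rng.normal(0, 2, size=(100, 60))
        wt = _pm(values, labels=labels)
        pert = _pm(values + rng.normal(0, 0.5, values.shape), labels=labels)
        k = 12
        results = {r.gene_id: r for r in rank_genes(wt, pert, k=k)}
        change = wt.values - pert.values
        mask = localization_mask(labels)
        for i, gene in enumerate(wt.gene_ids):
            d = np.sqrt(((wt.values - wt.values[i]) ** 2).sum(axis=1))
            order = sorted((d[j], g, j) for j, g in enumerate(wt.gene_ids) if j != i)
            nb = [j for _, _, j in order[:k]]
            M = np.empty(60)
            for f in range(60):
                col = change[nb, f]
                med = np.median(col)
                mad = np.median(np.abs(col - med))
                M[f] = 0.6745 * (change[i, f] - med) / mad
            np.testing.assert_allclose(results[gene].M, M, rtol=1e-10)
            assert results[gene].rms == pytest.approx(
                np.sqrt(np.mean(M[mask] ** 2)), rel=1e-10
            )

    def test_deterministic_across_runs(self, small_profiles):
        wt, pert = small_profiles
        r1 = rank_genes(wt, pert, k=20)
        r2 = rank_genes(wt, pert, k=20)
        assert [x.gene_id for x in r1] == [x.gene_id for x in r2]
        np.testing.assert_array_equal(
            np.array([x.M for x in r1]), np.array([x.M for x in r2])
        )


@given(
    nc=hnp.arrays(np.float64, (12, 6), elements=st.integers(-100, 100).map(float)),
    x=hnp.arrays(np.float64, (6,), elements=st.integers(-100, 100).map(float)),
    delta=hnp.arrays(np.float64, (6,), elements=st.integers(-50, 50).map(float)),
    c=st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0]),
)
@settings(max_examples=100, deadline=None)
def test_zscore_shift_and_scale_invariance_property(nc, x, delta, c):
    """M(cx + d | {c x_m + d}) == M(x | {x_m}), exactly.

    Integer values and power-of-two scales keep every intermediate exact, so
    the translation/scale equivariance of the median and MAD carries through
    to bitwise equality of the z-scores (including the degenerate-MAD
    fallbacks, whose mean absolute deviation also scales exactly)."""
    base = modified_zscores(x, nc)
    moved = modified_zscores(c * x + delta, c * nc + delta)
    np.testing.assert_array_equal(moved, base)
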