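import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eigfusion import (
    ExpressionMatrix,
    RunConfig,
    SampleLabels,
    eigfusion_scores,
    loo_energy,
    median_summary,
    permutation_pvalues,
    rank1_energy,
    transform,
)
from eigfusion.core import pooled_empirical_pvalues


def _matrix(values, n_s1_last=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    samples = [f"s{j}" for j in range(n)]
    mat = ExpressionMatrix([f"g{i}" for i in range(m)], samples, values)
    return mat


class TestMedianSummary:
    def _summary(self, s1_values, s2_values=(0.0, 0.0)):
        x = np.concatenate([s1_values, s2_values])
        samples = [f"s{j}" for j in range(x.size)]
        labels = SampleLabels(samples[: len(s1_values)], samples[len(s1_values):])
        mat = ExpressionMatrix(["g"], samples, x[None, :])
        return median_summary(x, labels, samples)

    def test_symmetric_group_average_equals_median(self):
        s = self._summary([1, 2, 3, 4, 5])
        assert s.median_s1 == 3
        assert s.median_upper == 4.5
        assert s.median_lower == 1.5
        assert s.avg_median_s1 == 3

    def test_empty_strict_group_falls_back_to_median(self):
        s = self._summary([0, 0, 0, 10])
        assert s.median_s1 == 0
        assert s.median_upper == 10
        assert s.median_lower == 0  # no values strictly below the median
        assert s.avg_median_s1 == pytest.approx(10 / 3)

    def test_constant_cancer_group(self):
        s = self._summary([5, 5, 5, 5])
        assert s.median_s1 == s.median_upper == s.median_lower == 5
        assert s.avg_median_s1 == 5

    def test_average_identity_holds(self):
        s = self._summary([0.3, -2.0, 4.5, 1.1, 9.0, -3.2])
        assert s.avg_median_s1 == pytest.approx(
            (s.median_s1 + s.median_upper + s.median_lower) / 3, abs=0
        )


class TestTransform:
    def test_worked_example_row(self):
        mat = _matrix([np.arange(1, 9), [2, 1, 2, 3, 2, 1, 2, 3]])
        labels = SampleLabels(mat.sample_ids[4:], mat.sample_ids[:4])
        t = transform(mat, labels)
        np.testing.assert_array_equal(
            t.values[0], [-2.75, -2.25, -1.75, -1.25, -0.75, -0.25, 0.25, 0.75]
        )

    def test_constant_gene_dropped_with_reason(self):
        mat = _matrix([[3, 3, 3, 3, 3, 3], np.arange(6)])
        labels = SampleLabels(mat.sample_ids[:3], mat.sample_ids[3:])
        t = transform(mat, labels)
        assert t.gene_ids == ["g1"]
        assert t.dropped_genes == [("g0", "zero MAD")]

    def test_all_genes_dropped_is_error(self):
        mat = _matrix([[1, 1, 1, 1], [2, 2, 2, 2]])
        labels = SampleLabels(mat.sample_ids[:2], mat.sample_ids[2:])
        with pytest.raises(ValueError, match="no scorable genes"):
            transform(mat, labels)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-1e3, max_value=1e3),
    )
    def test_location_positive_scale_invariance(self, a, b):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(4, 10))
        mat = _matrix(base)
        labels = SampleLabels(mat.sample_ids[:5], mat.sample_ids[5:])
        scaled = base.copy()
        scaled[2] = a * scaled[2] + b
        t0 = transform(mat, labels)
        t1 = transform(_matrix(scaled), labels)
        np.testing.assert_allclose(t1.values[2], t0.values[2], rtol=1e-9, atol=1e-9)


class TestEnergies:
    def test_rank1_energy_is_squared_norm(self):
        assert rank1_energy([3, 4]) == 25
        assert rank1_energy(np.zeros(5)) == 0

    def test_rank1_energy_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            v = rng.normal(size=10)
            dense = np.linalg.eigvalsh(np.outer(v, v)).max()
            assert rank1_energy(v) == pytest.approx(dense, rel=1e-10)

    def test_loo_orthogonal_rows(self):
        # mutually orthogonal rows with norms 5, 3, 2: spectrum = squared norms
        rows = np.diag([5.0, 3.0, 2.0]) @ np.eye(3, 6)
        from eigfusion.core import TransformedMatrix

        t = TransformedMatrix(["a", "b", "c"], [f"s{j}" for j in range(6)], rows)
        assert loo_energy(t, 0) == pytest.approx(9.0, rel=1e-10)
        assert loo_energy(t, 1) == pytest.approx(25.0, rel=1e-10)

    def test_removing_zero_row_leaves_top_eigenvalue(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(4, 7))
        rows[1] = 0.0
        from eigfusion.core import TransformedMatrix

        t = TransformedMatrix(list("abcd"), [f"s{j}" for j in range(7)], rows)
        full_top = np.linalg.eigvalsh(rows @ rows.T).max()
        assert loo_energy(t, 1) == pytest.approx(full_top, rel=1e-10)

    def test_loo_matches_explicit_deletion_oracle(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(30, 12))
        from eigfusion.core import TransformedMatrix, _loo_top_eigenvalues

        t = TransformedMatrix(
            [f"g{i}" for i in range(30)], [f"s{j}" for j in range(12)], rows
        )
        loo = _loo_top_eigenvalues(rows)
        for i in range(30):
            deleted = np.delete(rows, i, axis=0)
            oracle = np.linalg.eigvalsh(deleted @ deleted.T).max()
            assert loo[i] == pytest.approx(oracle, rel=1e-8)

    def test_single_gene_loo_is_error(self):
        from eigfusion.core import TransformedMatrix, _loo_top_eigenvalues

        with pytest.raises(ValueError, match="at least 2"):
            _loo_top_eigenvalues(np.ones((1, 4)))


def _oracle_scores(values, s1_idx, s2_idx):
    """Direct evaluation of the score with explicit outer products, explicit
    row deletion and dense eigendecompositions."""
    rows = []
    for x in values:
        s1 = x[s1_idx]
        med1 = np.median(s1)
        up = s1[s1 > med1]
        lo = s1[s1 < med1]
        avg = (
            med1
            + (np.median(up) if up.size else med1)
            + (np.median(lo) if lo.size else med1)
        ) / 3.0
        mad = np.median(np.abs(x - np.median(x)))
        rows.append((x - avg) / mad)
    transformed = np.array(rows)
    scores = []
    for i, xh in enumerate(transformed):
        energy = np.linalg.eigvalsh(np.outer(xh, xh)).max()
        e1 = np.linalg.eigvalsh(np.outer(xh[s1_idx], xh[s1_idx])).max()
        e2 = np.linalg.eigvalsh(np.outer(xh[s2_idx], xh[s2_idx])).max()
        deleted = np.delete(transformed, i, axis=0)
        loo = np.linalg.eigvalsh(deleted @ deleted.T).max()
        scores.append(energy * (e1 / len(s1_idx) - e2 / len(s2_idx)) / loo)
    return np.array(scores)


class TestScores:
    def test_worked_fixture_matches_oracle_and_spiked_gene_ranks_first(
        self, worked_matrix, worked_labels
    ):
        table = eigfusion_scores(worked_matrix, worked_labels)
        oracle = _oracle_scores(worked_matrix.values, np.arange(4, 8), np.arange(4))
        by_gene = table.set_index("gene")
        for i, gid in enumerate(worked_matrix.gene_ids):
            assert by_gene.loc[gid, "score"] == pytest.approx(
                oracle[i], rel=1e-10, abs=1e-12
            )
        assert by_gene.loc["g5", "rank"] == 1

    def test_group_symmetric_gene_scores_zero(self, worked_matrix, worked_labels):
        # g2 and g4 repeat the same 4-sample pattern in both groups: equal
        # per-sample energy in S1 and S2, so the difference term vanishes
        by_gene = eigfusion_scores(worked_matrix, worked_labels).set_index("gene")
        assert by_gene.loc["g2", "score"] == 0.0
        assert by_gene.loc["g4", "score"] == 0.0

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(30, 12))
        mat = ExpressionMatrix(
            [f"g{i}" for i in range(30)], [f"s{j}" for j in range(12)], values
        )
        labels = SampleLabels(mat.sample_ids[:5], mat.sample_ids[5:])
        table = eigfusion_scores(mat, labels).set_index("gene")
        oracle = _oracle_scores(values, np.arange(5), np.arange(5, 12))
        for i in range(30):
            assert table.loc[f"g{i}", "score"] == pytest.approx(oracle[i], rel=1e-8)

    def test_scores_invariant_under_single_gene_affine(self, worked_matrix, worked_labels):
        scaled = worked_matrix.values.copy()
        scaled[0] = 3.5 * scaled[0] - 11.0
        mat2 = ExpressionMatrix(
            worked_matrix.gene_ids, worked_matrix.sample_ids, scaled
        )
        t1 = eigfusion_scores(worked_matrix, worked_labels).set_index("gene")["score"]
        t2 = eigfusion_scores(mat2, worked_labels).set_index("gene")["score"]
        np.testing.assert_allclose(t2, t1, rtol=1e-10)

    def test_ranks_are_stable_permutation(self, worked_matrix, worked_labels):
        table = eigfusion_scores(worked_matrix, worked_labels)
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))
        # scores non-increasing in rank; the two tied zero-score genes keep
        # input order (g2 before g4)
        ordered = table.sort_values("rank")
        assert (np.diff(ordered["score"]) <= 1e-15).all()
        tied = ordered[ordered["score"] == 0.0]["gene"].tolist()
        assert tied == ["g2", "g4"]


class TestPermutationPValues:
    def test_pooled_pvalue_extremes(self):
        null = np.arange(100, dtype=float)
        assert pooled_empirical_pvalues([1000.0], null)[0] == pytest.approx(1 / 101)
        assert pooled_empirical_pvalues([-5.0], null)[0] == 1.0

    def test_pvalues_bounded_and_monotone_in_score(self, random_matrix_factory):
        mat = random_matrix_factory(20, 16, seed=9)
        labels = SampleLabels(mat.sample_ids[:8], mat.sample_ids[8:])
        table = permutation_pvalues(
            mat, labels, RunConfig(n_permutations=25, seed=4)
        )
        n_pool = 20 * 25
        assert (table["p_value"] >= 1 / (1 + n_pool) - 1e-15).all()
        assert (table["p_value"] <= 1.0).all()
        ordered = table.sort_values("rank")
        assert (np.diff(ordered["p_value"]) >= -1e-15).all()

    def test_same_seed_reproduces_pvalues(self, random_matrix_factory):
        mat = random_matrix_factory(12, 12, seed=1)
        labels = SampleLabels(mat.sample_ids[:6], mat.sample_ids[6:])
        cfg = RunConfig(n_permutations=10, seed=33)
        t1 = permutation_pvalues(mat, labels, cfg)
        t2 = permutation_pvalues(mat, labels, cfg)
        np.testing.assert_array_equal(t1["p_value"], t2["p_value"])
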