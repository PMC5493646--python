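import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eigensig import (
    ExpressionBatch,
    eigengene_phenotype_pvalues,
    filter_eigengenes,
    merge,
    select_ell,
    svd_decompose,
    two_step_merge,
)
from eigensig.simulate import SimConfig, generate_batches


def _batch(values, statuses, batch="b1", prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {"batch": batch, "status": statuses},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionBatch(
        values=pd.DataFrame(values, index=genes, columns=samples), metadata=meta
    )


class TestSvdDecompose:
    def test_rank_one_matrix(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=8))
        E = svd_decompose(X)
        assert E.singular_values[0] > 1e-8
        assert np.all(E.singular_values[1:] < 1e-10 * E.singular_values[0])

    def test_diagonal_singular_values(self):
        E = svd_decompose(np.diag([3.0, 2.0, 1.0]))
        np.testing.assert_allclose(E.singular_values, [3.0, 2.0, 1.0])

    def test_frobenius_energy(self, rng):
        X = rng.normal(size=(50, 10))
        E = svd_decompose(X)
        np.testing.assert_allclose(
            (E.singular_values**2).sum(), (X**2).sum(), rtol=1e-12
        )

    def test_reconstruction_and_orthonormality(self, rng):
        X = rng.normal(size=(40, 12))
        E = svd_decompose(X)
        np.testing.assert_allclose(E.reconstruct(), X, atol=1e-10)
        np.testing.assert_allclose(
            E.eigengenes.T @ E.eigengenes, np.eye(E.L), atol=1e-10
        )
        np.testing.assert_allclose(
            E.eigenarrays @ E.eigenarrays.T, np.eye(E.L), atol=1e-10
        )

    def test_rejects_nonfinite(self):
        X = np.ones((3, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            svd_decompose(X)


def _exact_ks_tail_enumeration(a, b):
    """P(D >= observed) by exhaustive enumeration over all assignments of
    the pooled values to the two groups (tiny-n oracle)."""

    def ks_stat(x, y):
        pooled = np.sort(np.concatenate([x, y]))
        cx = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
        cy = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
        return np.abs(cx - cy).max()

    observed = ks_stat(a, b)
    pooled = np.concatenate([a, b])
    n = len(a)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        d = ks_stat(pooled[mask], pooled[~mask])
        hits += d >= observed - 1e-12
        total += 1
    return hits / total


class TestEigengenePvalues:
    def test_identical_groups_give_p_one(self):
        # one eigengene's sample expression identical across the groups
        row = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        X = np.vstack([row, np.zeros(6) + 1e-9])
        E = svd_decompose(X)
        p = eigengene_phenotype_pvalues(
            E, X, ["lean", "lean", "lean", "obese", "obese", "obese"]
        )
        assert p[0] > 0.95

    def test_fully_separated_groups_match_exact_enumeration(self):
        """All lean values below all obese values: D = 1 and the exact
        p-value equals the enumeration oracle."""
        lean = np.array([1.0, 2.0, 3.0, 4.0])
        obese = np.array([10.0, 11.0, 12.0, 13.0])
        row = np.concatenate([lean, obese])
        X = np.vstack([row, 1e-9 * np.arange(8)])
        E = svd_decompose(X)
        labels = ["lean"] * 4 + ["obese"] * 4
        # row 0 of U^T X is a monotone transform of `row` (up to sign),
        # so its KS statistic against the labels is also D = 1
        p_exact = eigengene_phenotype_pvalues(E, X, labels, method="exact")[0]
        oracle = _exact_ks_tail_enumeration(lean, obese)
        np.testing.assert_allclose(p_exact, oracle, rtol=1e-10)
        assert oracle == pytest.approx(2 / 70)  # 2 / C(8,4)

    def test_shuffled_labels_give_uniform_pvalues(self, rng):
        X = rng.normal(size=(20, 40))
        E = svd_decompose(X)
        pvals = []
        for _ in range(40):
            labels = np.array(["lean"] * 20 + ["obese"] * 20)
            rng.shuffle(labels)
            pvals.extend(eigengene_phenotype_pvalues(E, X, labels))
        pvals = np.asarray(pvals)
        # crude uniformity: mean near 1/2, mass spread over [0,1]
        assert abs(pvals.mean() - 0.5) < 0.05
        assert (pvals < 0.2).mean() < 0.3

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        E = svd_decompose(X)
        with pytest.raises(ValueError, match="at least two samples"):
            eigengene_phenotype_pvalues(E, X, ["lean", "obese", "obese", "obese"])


class TestSelectEll:
    @pytest.mark.parametrize(
        "pvalues, expected",
        [
            ((0.5, 0.001, 0.3), 2),
            ((0.001, 0.5, 0.3), 1),
            ((0.01, 0.01, 0.9), 1),  # tie: smallest index wins
        ],
    )
    def test_argmin_rule(self, pvalues, expected):
        assert select_ell(np.array(pvalues)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_ell(np.array([]))


class TestFilterEigengenes:
    def test_ell_one_is_identity(self, rng):
        X = rng.normal(size=(10, 6))
        E = svd_decompose(X)
        np.testing.assert_array_equal(filter_eigengenes(X, E, 1), X)

    def test_rank_one_fully_filtered(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=5))
        E = svd_decompose(X)
        np.testing.assert_allclose(filter_eigengenes(X, E, 2), 0, atol=1e-10)

    def test_out_of_range_ell(self, rng):
        X = rng.normal(size=(6, 4))
        E = svd_decompose(X)
        with pytest.raises(ValueError, match="out of range"):
            filter_eigengenes(X, E, 6)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_genes=st.integers(5, 60),
        n_samples=st.integers(3, 20),
        ell=st.integers(1, 3),
    )
    def test_orthogonality_and_energy_accounting(self, seed, n_genes, n_samples, ell):
        """Removed eigengenes have ~zero projection on the filtered matrix
        and the squared Frobenius norm splits exactly into kept plus
        removed eigenvalue energy."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_genes, n_samples))
        E = svd_decompose(X)
        ell = min(ell, E.L)
        Xhat = filter_eigengenes(X, E, ell)
        tol = 1e-8 * E.singular_values[0]
        for i in range(ell - 1):
            assert np.abs(E.eigengenes[:, i] @ Xhat).max() <= tol
        removed = (E.singular_values[: ell - 1] ** 2).sum()
        np.testing.assert_allclose(
            (X**2).sum(), (Xhat**2).sum() + removed, rtol=1e-10
        )


class TestMerge:
    def test_identical_gene_sets(self, rng):
        b1 = _batch(rng.normal(size=(5, 4)), ["lean"] * 2 + ["obese"] * 2, "b1", "a")
        b2 = _batch(rng.normal(size=(5, 3)), ["lean", "obese", "obese"], "b2", "b")
        m = merge([b1, b2])
        assert m.values.shape == (5, 7)

    def test_gene_intersection(self, rng):
        b1 = _batch(rng.normal(size=(3, 2)), ["lean", "obese"], "b1", "a")
        b1.values.index = ["A", "B", "C"]
        b2 = _batch(rng.normal(size=(3, 2)), ["lean", "obese"], "b2", "b")
        b2.values.index = ["B", "C", "D"]
        m = merge([b1, b2])
        assert list(m.gene_ids) == ["B", "C"]

    def test_sample_counts_add(self, rng):
        sizes = [10, 12, 15]
        batches = [
            _batch(
                rng.normal(size=(4, n)),
                ["lean"] * (n // 2) + ["obese"] * (n - n // 2),
                f"b{i}",
                f"p{i}",
            )
            for i, n in enumerate(sizes)
        ]
        assert merge(batches).values.shape[1] == 37

    def test_empty_intersection_rejected(self, rng):
        b1 = _batch(rng.normal(size=(2, 2)), ["lean", "obese"], "b1", "a")
        b1.values.index = ["A", "B"]
        b2 = _batch(rng.normal(size=(2, 2)), ["lean", "obese"], "b2", "b")
        b2.values.index = ["C", "D"]
        with pytest.raises(ValueError, match="intersection"):
            merge([b1, b2])

    def test_duplicate_sample_ids_rejected(self, rng):
        b1 = _batch(rng.normal(size=(3, 2)), ["lean", "obese"], "b1", "s")
        b2 = _batch(rng.normal(size=(3, 2)), ["lean", "obese"], "b2", "s")
        with pytest.raises(ValueError, match="duplicate sample ids"):
            merge([b1, b2])


class TestTwoStepMerge:
    def test_no_batch_effects_all_ell_one(self):
        """With zero batch offsets and a strong planted effect the
        phenotype is already the dominant eigengene in every batch."""
        config = SimConfig(batch_shift_scale=0.0, effect_size=3.0, seed=21)
        batches, _ = generate_batches(config)
        _, report = two_step_merge(batches)
        assert report.per_batch_ell == [1, 1, 1, 1]

    def test_reduces_between_batch_gap(self, small_cohort):
        """Two-step merging shrinks the within-vs-between batch
        correlation gap relative to the unfiltered merge."""
        _, batches, _ = small_cohort

        def gap(m):
            C = np.corrcoef(m.values.to_numpy().T)
            lab = m.provenance.to_numpy()
            iu = np.triu_indices(len(lab), 1)
            same = lab[iu[0]] == lab[iu[1]]
            return C[iu][same].mean() - C[iu][~same].mean()

        raw_gap = gap(merge(batches))
        merged, _ = two_step_merge(batches)
        assert gap(merged) < raw_gap
        assert abs(gap(merged)) < 0.2

    def test_single_batch_consistency(self, rng):
        """K=1 equals one per-batch filtering pass followed by the second
        filtering pass on the 'merged' (identical) matrix."""
        X = rng.normal(size=(30, 12))
        statuses = ["lean"] * 6 + ["obese"] * 6
        b = _batch(X, statuses)
        merged, report = two_step_merge([b])

        from eigensig.batch import _filter_matrix

        labels = np.array(statuses)
        step1, ell1, _ = _filter_matrix(X, labels, "asymp")
        step2, ell2, _ = _filter_matrix(step1, labels, "asymp")
        assert report.per_batch_ell == [ell1]
        assert report.merged_ell == ell2
        np.testing.assert_allclose(merged.values.to_numpy(), step2, atol=1e-10)

    def test_report_pvalues_in_unit_interval(self, merged_cohort):
        _, report, _ = merged_cohort
        for v in report.per_batch_ks_pvalues + [report.merged_ks_pvalues]:
            assert np.all((v >= 0) & (v <= 1))
        for ell, v in zip(report.per_batch_ell, report.per_batch_ks_pvalues):
            assert 1 <= ell <= len(v)
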