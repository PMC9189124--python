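"""CMS/MGCS statistics, the shuffle null and the lognormal tail."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cssig.anchor import unit_sum_average
from cssig.data_model import (
    DatasetCollection,
    ExpressionDataset,
    GeneModule,
    samples_in_class,
)
from cssig.module_score import (
    IntraCorrelationTable,
    cms,
    cms_for_module,
    evaluate_across_collection,
    intra_correlation_table,
    lognormal_p,
    mgcs,
    mgcs_all,
    permutation_null,
    random_module_null,
)
from cssig.synthetic_data import generate_collection, generate_null_collection

from conftest import small_config


def _dataset(matrix: np.ndarray, prefix: str = "G") -> ExpressionDataset:
    values = pd.DataFrame(matrix,
                          index=[f"{prefix}{i:02d}" for i in range(matrix.shape[0])],
                          columns=[f"S{j:02d}" for j in range(matrix.shape[1])])
    return ExpressionDataset("d", values)


def _table_from(matrix: np.ndarray) -> IntraCorrelationTable:
    genes = [f"G{i:02d}" for i in range(matrix.shape[0])]
    return IntraCorrelationTable(pd.DataFrame(matrix, index=genes, columns=genes),
                                 samples_used=10)


class TestIntraCorrelationTable:
    def test_full_square_table_with_diagonal(self, rng):
        ds = _dataset(rng.normal(size=(6, 8)))
        module = GeneModule("m", ds.genes)
        table = intra_correlation_table(ds, module)
        assert table.n_cells == 36
        arr = table.r.to_numpy()
        np.testing.assert_allclose(np.diag(arr), 1.0, atol=1e-12)
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        assert (np.abs(arr) <= 1 + 1e-12).all()

    def test_anti_correlated_pair(self):
        ds = _dataset(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        table = intra_correlation_table(ds, GeneModule("m", ds.genes))
        assert table.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        mat = rng.normal(size=(4, 6))
        mat[2] = 5.0
        ds = _dataset(mat)
        with pytest.warns(UserWarning, match="zero-variance"):
            table = intra_correlation_table(ds, GeneModule("m", ds.genes))
        assert table.dropped == ["G02"]
        assert len(table.genes) == 3

    def test_too_few_genes(self, rng):
        ds = _dataset(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match=">= 2"):
            intra_correlation_table(ds, GeneModule("m", ["G00"]))


class TestCmsMgcs:
    def test_hand_three_gene_cms(self):
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.1], [0.2, -0.1, 1.0]])
        assert cms(_table_from(r)) == pytest.approx(0.2)

    def test_identical_profiles_give_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        ds = _dataset(np.vstack([2 * base + 1, base, 0.5 * base + 4]))
        table = intra_correlation_table(ds, GeneModule("m", ds.genes))
        assert cms(table) == pytest.approx(1.0)
        np.testing.assert_allclose(mgcs_all(table).to_numpy(), 1.0, atol=1e-12)

    def test_single_gene_errors(self):
        table = _table_from(np.array([[1.0]]))
        with pytest.raises(ValueError):
            cms(table)
        with pytest.raises(ValueError):
            mgcs(table, "G00")

    def test_hand_mgcs(self):
        r = np.array([[1.0, 0.4, 0.6], [0.4, 1.0, 0.0], [0.6, 0.0, 1.0]])
        assert mgcs(_table_from(r), "G00") == pytest.approx(0.5)

    def test_absent_gene(self):
        with pytest.raises(KeyError):
            mgcs(_table_from(np.eye(2)), "nope")

    def test_bruteforce_oracle_and_identity(self, rng):
        """cms == double-loop mean of pairwise Pearson; mean(MGCS) == CMS."""
        for _ in range(100):
            mat = rng.normal(size=(10, 20))
            ds = _dataset(mat)
            table = intra_correlation_table(ds, GeneModule("m", ds.genes))
            vals = []
            for i in range(10):
                for j in range(10):
                    if i != j:
                        vals.append(stats.pearsonr(mat[i], mat[j]).statistic)
            assert cms(table) == pytest.approx(np.mean(vals), abs=1e-12)
            assert mgcs_all(table).mean() == pytest.approx(cms(table), abs=1e-12)

    def test_invariances(self, rng):
        """CMS unchanged by gene reordering and per-gene positive affine maps."""
        mat = rng.normal(size=(8, 12))
        ds = _dataset(mat)
        module = GeneModule("m", ds.genes)
        base = cms(intra_correlation_table(ds, module))
        shuffled = GeneModule("m2", list(reversed(ds.genes)))
        assert cms(intra_correlation_table(ds, shuffled)) == pytest.approx(
            base, abs=1e-12)
        scale = rng.uniform(0.5, 3.0, size=(8, 1))
        shift = rng.normal(size=(8, 1))
        affine = _dataset(mat * scale + shift)
        assert cms(intra_correlation_table(affine, module)) == pytest.approx(
            base, abs=1e-12)

    def test_150_gene_table_has_22500_cells(self, rng):
        ds = _dataset(rng.normal(size=(150, 10)))
        table = intra_correlation_table(ds, GeneModule("m", ds.genes))
        assert table.n_cells == 150 * 150 == 22500


class TestLognormalP:
    def test_closed_form_example(self):
        mu, sigma, p = lognormal_p([np.exp(-1), 1.0, np.exp(1)], np.exp(1))
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        # p = 1 - Phi(1 / sqrt(2/3)) = 1 - Phi(1.2247...)
        assert p == pytest.approx(1 - stats.norm.cdf(np.sqrt(1.5)), abs=1e-12)
        assert p == pytest.approx(0.110335, abs=1e-3)

    def test_limit_small_observation(self):
        _, _, p = lognormal_p([0.5, 1.0, 2.0], 1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_null_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            lognormal_p([0.0, 1.0], 1.0)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            lognormal_p([2.0, 2.0, 2.0], 1.0)


class TestPermutationNull:
    def test_deterministic_under_seed(self, small_study):
        collection, metabolites, _ = small_study
        anchor = collection.anchor
        profile = unit_sum_average(metabolites, ["citrate", "spermine"])
        cancer = samples_in_class(anchor, "cancer")
        a = permutation_null(anchor, profile, samples=cancer, k=30, n_perm=20,
                             seed=5)
        b = permutation_null(anchor, profile, samples=cancer, k=30, n_perm=20,
                             seed=5)
        np.testing.assert_array_equal(a.null_cms, b.null_cms)
        assert a.observed_cms == b.observed_cms
        assert a.observed_module.members == b.observed_module.members

    def test_observed_exceeds_null_on_planted_signal(self, small_study):
        collection, metabolites, _ = small_study
        anchor = collection.anchor
        profile = unit_sum_average(metabolites, ["citrate", "spermine"])
        cancer = samples_in_class(anchor, "cancer")
        null = permutation_null(anchor, profile, samples=cancer, k=40,
                                n_perm=50, seed=1)
        assert null.observed_cms > null.null_cms.max()
        assert null.p < 0.01

    def test_observed_within_null_range_under_null(self):
        """No metabolite-module coupling: observed CMS looks like a null draw."""
        config = small_config(n_datasets=1)
        inside = 0
        n_rep = 50
        for seed in range(n_rep):
            collection, metabolites, _ = generate_null_collection(config,
                                                                  seed=seed)
            anchor = collection.anchor
            profile = unit_sum_average(metabolites, ["citrate", "spermine"])
            cancer = samples_in_class(anchor, "cancer")
            null = permutation_null(anchor, profile, samples=cancer,
                                    k=config.planted_size, n_perm=50,
                                    seed=1000 + seed)
            lo, hi = null.null_cms.min(), null.null_cms.max()
            inside += int(lo <= null.observed_cms <= hi)
        assert inside >= 0.9 * n_rep

    def test_n_perm_lower_bound(self, small_study):
        collection, metabolites, _ = small_study
        profile = unit_sum_average(metabolites, ["citrate", "spermine"])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(collection.anchor, profile, k=10, n_perm=1)


class TestAcrossCollection:
    def test_single_dataset_matches_direct_cms(self, small_study):
        collection, _, truth = small_study
        module = truth.planted_module()
        single = DatasetCollection([collection.anchor],
                                   anchor_id=collection.anchor_id)
        res = evaluate_across_collection(single, module, class_filter="cancer")
        anchor = collection.anchor
        table = intra_correlation_table(anchor, module,
                                        samples=samples_in_class(anchor, "cancer"))
        assert res[anchor.dataset_id].cms == pytest.approx(cms(table), abs=1e-12)

    def test_missing_genes_reduce_table(self, small_study):
        collection, _, truth = small_study
        module = truth.planted_module()
        non_anchor = collection.datasets[1]
        res = cms_for_module(non_anchor, module,
                             samples=samples_in_class(non_anchor, "cancer"))
        assert set(res.missing) == set(module.members) - set(non_anchor.genes)
        reduced = GeneModule("r", [g for g in module.members
                                   if g in set(non_anchor.genes)])
        table = intra_correlation_table(
            non_anchor, reduced,
            samples=samples_in_class(non_anchor, "cancer"))
        assert res.cms == pytest.approx(cms(table), abs=1e-12)

    def test_planted_module_beats_random_modules_everywhere(self):
        """Planted CMS above the 95th percentile of random same-size modules."""
        for seed in (0, 1, 2):
            collection, _, truth = generate_collection(small_config(),
                                                       seed=seed)
            module = truth.planted_module()
            for ds in collection:
                cancer = samples_in_class(ds, "cancer")
                present = [g for g in module.members if g in set(ds.genes)]
                observed = cms(intra_correlation_table(
                    ds, GeneModule("p", present), samples=cancer))
                nulls = random_module_null(ds, size=len(present), n_modules=100,
                                           seed=seed * 100, samples=cancer)
                assert (observed > nulls).sum() >= 95

    def test_non_evaluable_dataset_reported_not_fatal(self, small_study):
        collection, _, _ = small_study
        foreign = GeneModule("foreign", ["ZZ1", "ZZ2", "ZZ3"])
        with pytest.warns(UserWarning, match="not evaluable"):
            res = evaluate_across_collection(collection, foreign)
        assert all(not r.evaluable for r in res.values())
        assert all(len(r.missing) == 3 for r in res.values())
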