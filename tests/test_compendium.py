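import numpy as np
import pandas as pd
import pytest

from cistronet.compendium import (ExpressionDataset, FilterThresholds,
                                  GeneFilterStats, compute_filter_stats,
                                  concat_datasets, impute_missing_knn,
                                  prepare_compendium, read_expression_table,
                                  select_genes, write_expression_table,
                                  z_standardize)
from conftest import make_dataset


class TestIO:
    def test_absent_sentinel_round_trip(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\ts1\ts2\nga\t1.5\tNA\ngb\t2.0\t0.5\ngc\t-1.0\t3.0\n")
        ds = read_expression_table(path, "cDNA_gDNA")
        assert ds.absent_mask.to_numpy().sum() == 1
        assert bool(ds.absent_mask.loc["ga", "s2"])
        assert np.isnan(ds.values.loc["ga", "s2"])
        out = tmp_path / "rt.tsv"
        write_expression_table(ds, out)
        again = read_expression_table(out, "cDNA_gDNA")
        pd.testing.assert_frame_equal(ds.values, again.values)
        pd.testing.assert_frame_equal(ds.absent_mask, again.absent_mask)

    def test_empty_and_duplicate_inputs_rejected(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("gene_id\ts1\ts2\n")
        with pytest.raises(ValueError):
            read_expression_table(empty, "cDNA_gDNA")
        dup = tmp_path / "dup.tsv"
        dup.write_text("gene_id\ts1\nga\t1\nga\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(dup, "cDNA_gDNA")


class TestFilterStats:
    def test_sd_and_absent_fraction(self):
        ds1 = make_dataset([[1, 2, 3]], ["ga"], ["s1", "s2", "s3"])
        ds2 = make_dataset([[0, 0, 0]], ["ga"], ["t1", "t2", "t3"], platform="cDNA_cDNA")
        (s,) = compute_filter_stats(ds1, ds2, {"ga"})
        assert s.a == 0.0
        assert s.b == pytest.approx(1.0)  # sample sd of (1,2,3)
        assert s.e is True

    def test_gene_absent_everywhere_and_probeset_lookup(self):
        ds1 = make_dataset(np.ones((1, 10)), ["ga"], [f"s{i}" for i in range(10)],
                           mask=np.ones((1, 10), dtype=bool))
        ds2 = make_dataset([[1.0, 2.0]], ["gb"], ["t1", "t2"], platform="cDNA_cDNA")
        stats = {s.gene_id: s for s in compute_filter_stats(ds1, ds2, {"ga"})}
        assert stats["ga"].a == 1.0
        assert stats["gb"].c == 0.0 and stats["gb"].a == 1.0  # not in ds1 at all
        assert stats["gb"].e is False


def _stats_population():
    """b-population {0,1,2,3,4} and d-population {0,0.4,0.8,1.2,1.6}.

    25th percentiles: b-cutoff 1.0, d-cutoff 0.4.
    """
    pop = []
    for i in range(5):
        pop.append(GeneFilterStats(f"bg{i}", a=0.0, b=float(i), c=0.0, d=0.4 * i, e=False))
    return pop


class TestSelectGenes:
    def test_first_disjunct(self):
        stats = _stats_population() + [
            GeneFilterStats("hit", a=0.10, b=3.5, c=0.30, d=0.0, e=True)
        ]
        assert "hit" in select_genes(stats)

    def test_e_false_never_selected(self):
        stats = _stats_population() + [
            GeneFilterStats("nohit", a=0.0, b=4.0, c=0.0, d=1.6, e=False)
        ]
        assert select_genes(stats) == set()

    def test_second_disjunct(self):
        # a exceeds the strict cutoff, so only the second disjunct can fire:
        # it needs few absent calls in dataset 2 and d above the d-cutoff
        stats = _stats_population() + [
            GeneFilterStats("hit2", a=0.25, b=0.0, c=0.15, d=1.5, e=True)
        ]
        assert "hit2" in select_genes(stats)
        # with too many dataset-2 absent calls the second disjunct fails too
        stats2 = _stats_population() + [
            GeneFilterStats("miss", a=0.25, b=0.0, c=0.25, d=1.5, e=True)
        ]
        assert "miss" not in select_genes(stats2)

    def test_empty_stats_error(self):
        with pytest.raises(ValueError):
            select_genes([])

    def test_monotone_in_absent_strict(self):
        rng = np.random.default_rng(42)
        stats = [
            GeneFilterStats(f"g{i}", a=rng.random(), b=rng.random() * 2,
                            c=rng.random(), d=rng.random() * 2, e=bool(rng.random() < 0.8))
            for i in range(200)
        ]
        tight = select_genes(stats, FilterThresholds(absent_strict=0.10))
        loose = select_genes(stats, FilterThresholds(absent_strict=0.30))
        assert tight <= loose


class TestImpute:
    def test_no_masked_cells_is_identity(self):
        ds = make_dataset([[1, 2], [3, 4]], ["ga", "gb"], ["s1", "s2"])
        out = impute_missing_knn(ds, k=1)
        pd.testing.assert_frame_equal(out.values, ds.values)
        assert not out.absent_mask.to_numpy().any()

    def test_mean_of_k_nearest(self):
        # gd masked at s3; nearest neighbors by profile are ga and gb
        vals = [[1, 1, 1.0], [1, 1, 3.0], [9, 9, 9.0], [1, 1, 0.0]]
        mask = np.zeros((4, 3), dtype=bool)
        mask[3, 2] = True
        ds = make_dataset(vals, ["ga", "gb", "gc", "gd"], ["s1", "s2", "s3"], mask)
        out = impute_missing_knn(ds, k=2)
        assert out.values.loc["gd", "s3"] == pytest.approx(2.0)  # mean(1.0, 3.0)
        # present cells are bit-identical
        keep = ~ds.absent_mask.to_numpy()
        assert np.array_equal(out.values.to_numpy()[keep], ds.values.to_numpy()[keep])

    def test_twin_gene_fills_with_twin_value(self):
        vals = [[1, 2, 5.0], [1, 2, 5.0], [8, 8, 8.0]]
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 2] = True
        ds = make_dataset(vals, ["ga", "gb", "gc"], ["s1", "s2", "s3"], mask)
        out = impute_missing_knn(ds, k=1)
        assert out.values.loc["ga", "s3"] == 5.0

    def test_all_absent_gene_rejected_by_name(self):
        mask = np.array([[True, True], [False, False]])
        ds = make_dataset([[1, 2], [3, 4]], ["dead", "gb"], ["s1", "s2"], mask)
        with pytest.raises(ValueError, match="dead"):
            impute_missing_knn(ds, k=1)

    def test_imputed_values_within_neighbor_range(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 8))
        mask = rng.random((20, 8)) < 0.15
        mask[:, 0] = False  # keep every gene partly present
        ds = make_dataset(vals, [f"g{i}" for i in range(20)],
                          [f"s{j}" for j in range(8)], mask)
        out = impute_missing_knn(ds, k=3)
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        assert out.values.to_numpy().min() >= lo - 1e-12
        assert out.values.to_numpy().max() <= hi + 1e-12


class TestStandardize:
    def test_basic_row(self):
        ds = make_dataset([[1, 2, 3]], ["ga"], ["s1", "s2", "s3"])
        out = z_standardize(ds)
        assert np.allclose(out.values.loc["ga"], [-1, 0, 1])

    def test_idempotent_and_row_moments(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(10, 30)), [f"g{i}" for i in range(10)],
                          [f"s{j}" for j in range(30)])
        out = z_standardize(ds)
        Z = out.values.to_numpy()
        assert np.all(np.abs(Z.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(Z.std(axis=1, ddof=1) - 1) < 1e-10)
        again = z_standardize(out)
        assert np.allclose(again.values.to_numpy(), Z, atol=1e-12)

    def test_constant_row_rejected_by_name(self):
        ds = make_dataset([[2, 2, 2]], ["flat"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="flat"):
            z_standardize(ds)


class TestConcat:
    def test_column_order_and_count(self):
        a = make_dataset([[1, 2, 3]], ["ga"], ["s1", "s2", "s3"])
        b = make_dataset([[4, 5]], ["ga"], ["t1", "t2"], platform="cDNA_cDNA")
        out = concat_datasets([a, b], ["ga"])
        assert list(out.values.columns) == ["s1", "s2", "s3", "t1", "t2"]
        assert out.n_samples == 5

    def test_single_part_identity(self):
        a = make_dataset([[1, 2]], ["ga"], ["s1", "s2"])
        out = concat_datasets([a], ["ga"])
        pd.testing.assert_frame_equal(out.values, a.values)

    def test_overlapping_samples_and_missing_genes_rejected(self):
        a = make_dataset([[1, 2]], ["ga"], ["s1", "s2"])
        b = make_dataset([[1, 2]], ["ga"], ["s1", "x2"], platform="cDNA_cDNA")
        with pytest.raises(ValueError, match="overlap"):
            concat_datasets([a, b], ["ga"])
        c = make_dataset([[1, 2]], ["gz"], ["t1", "t2"], platform="cDNA_cDNA")
        with pytest.raises(ValueError, match="absent"):
            concat_datasets([a, c], ["ga"])


def test_prepare_compendium_is_deterministic(default_synthetic):
    datasets = {k: v.copy() for k, v in default_synthetic["datasets"].items()}
    probeset = default_synthetic["datasets"]["oligo_chip"].gene_ids
    m1, s1 = prepare_compendium(datasets, probeset)
    m2, s2 = prepare_compendium(datasets, probeset)
    assert s1 == s2
    pd.testing.assert_frame_equal(m1.values, m2.values)
    # every selected gene row is standardized in each platform block
    assert m1.n_samples == sum(ds.n_samples for ds in datasets.values())
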