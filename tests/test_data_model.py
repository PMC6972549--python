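import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumenmark.data_model import (
    CountTable,
    GenotypeMatrix,
    PhenotypeTable,
    aggregate_taxon,
    clr,
    css_normalize,
    css_scaling_factors,
    filter_otus,
    genotype_qc,
    prepare_phenotypes,
    read_count_table,
    to_relative,
    write_count_table,
)


class TestCountTableIO:
    def test_round_trip_with_taxonomy(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_count_table(small_table, path)
        back = read_count_table(path)
        np.testing.assert_array_equal(back.counts, small_table.counts)
        assert back.feature_ids == small_table.feature_ids
        assert back.sample_ids == small_table.sample_ids
        assert back.taxonomy == small_table.taxonomy

    def test_non_integral_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\ts1\ts2\nA\t2.5\t1\n")
        with pytest.raises(ValueError, match="non-integral count"):
            read_count_table(path)

    def test_header_only_table_is_valid(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("feature_id\ts1\ts2\n")
        t = read_count_table(path)
        assert t.n_features == 0 and t.n_samples == 2

    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(["A", "A"], ["s1"], np.array([[1], [2]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CountTable(["A"], ["s1"], np.array([[-1]]))

    def test_samples_in_rows_orientation(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tA\tB\ns1\t1\t2\ns2\t3\t4\n")
        t = read_count_table(path, orientation_hint="samples_in_rows")
        assert t.feature_ids == ["A", "B"]
        np.testing.assert_array_equal(t.counts, [[1, 3], [2, 4]])


class TestFilterOtus:
    def test_doubletons_removed_and_fraction_floor(self):
        # one feature at the doubleton bound, one just under the 0.001% floor,
        # one just over it, plus a bulk feature carrying the grand total
        n_bulk = 10_000_000 - 2 - 99 - 101
        t = CountTable(
            ["double", "under", "over", "bulk"],
            ["s1"],
            np.array([[2], [99], [101], [n_bulk]]),
        )
        out = filter_otus(t)
        assert out.feature_ids == ["over", "bulk"]

    def test_identity_when_all_pass(self, small_table):
        out = filter_otus(small_table)
        assert out.feature_ids == small_table.feature_ids
        np.testing.assert_array_equal(out.counts, small_table.counts)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=1, max_size=40), st.integers(1, 4))
    def test_idempotent(self, totals, n_samples):
        rng = np.random.default_rng(0)
        counts = np.zeros((len(totals), n_samples), dtype=int)
        for i, tot in enumerate(totals):
            counts[i] = rng.multinomial(tot, np.ones(n_samples) / n_samples)
        t = CountTable([f"f{i}" for i in range(len(totals))], [f"s{j}" for j in range(n_samples)], counts)
        once = filter_otus(t)
        twice = filter_otus(once)
        assert once.feature_ids == twice.feature_ids


class TestAggregateTaxon:
    def test_same_genus_sums(self, small_table):
        g = aggregate_taxon(small_table, "genus")
        assert "Blautia" in g.feature_ids
        i = g.feature_ids.index("Blautia")
        np.testing.assert_array_equal(g.counts[i], [4, 6])

    def test_grand_total_conserved(self, small_table):
        g = aggregate_taxon(small_table, "genus")
        assert g.counts.sum() == small_table.counts.sum()

    def test_missing_rank_pooled_as_unclassified(self, small_table):
        g = aggregate_taxon(small_table, "genus")
        assert "unclassified_Ruminococcaceae" in g.feature_ids

    def test_single_feature_identity(self):
        t = CountTable(
            ["A"], ["s1", "s2"], np.array([[7, 8]]),
            {"A": "Bacteria;P;C;O;F;G"},
        )
        g = aggregate_taxon(t, "genus")
        assert g.feature_ids == ["G"]
        np.testing.assert_array_equal(g.counts, [[7, 8]])

    def test_unknown_rank_rejected(self, small_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxon(small_table, "strain")


def _geno(dosages):
    d = np.asarray(dosages)
    return GenotypeMatrix(
        [f"a{j}" for j in range(d.shape[1])], [f"snp{i}" for i in range(d.shape[0])], d
    )


class TestGenotypeQC:
    def test_maf_boundary_kept(self):
        # genotype counts 0:90, 1:8, 2:2 -> minor allele frequency 0.06 >= 0.05
        dos = np.array([[0] * 90 + [1] * 8 + [2] * 2])
        out, report = genotype_qc(_geno(dos), hwe_alpha=1e-12)
        assert report["removed_maf"] == 0 and out.n_snps == 1

    def test_missingness_above_threshold_removed(self):
        dos = np.array([[1, 0] * 45 + [-1] * 10])  # 10 of 100 missing: kept
        out, _ = genotype_qc(_geno(dos), hwe_alpha=0)
        assert out.n_snps == 1
        dos = np.array([[1, 0] * 44 + [1] + [-1] * 11])  # 11 of 100 missing: removed
        out, report = genotype_qc(_geno(dos), hwe_alpha=0)
        assert out.n_snps == 0 and report["removed_missing"] == 1

    def test_all_heterozygous_fails_hwe(self):
        dos = np.array([[1] * 100])
        out, report = genotype_qc(_geno(dos))
        assert report["removed_hwe"] == 1 and out.n_snps == 0

    def test_removal_sets_order_independent(self, rng):
        dos = rng.integers(0, 3, size=(50, 40))
        dos[rng.random(dos.shape) < 0.1] = -1
        g = _geno(dos)
        _, rep1 = genotype_qc(g)
        perm = rng.permutation(50)
        g2 = GenotypeMatrix(g.animal_ids, [g.snp_ids[i] for i in perm], dos[perm])
        _, rep2 = genotype_qc(g2)
        assert rep1 == rep2


class TestTransforms:
    def test_relative_column(self):
        t = CountTable(["a", "b", "c"], ["s"], np.array([[2], [2], [4]]))
        rel = to_relative(t)
        np.testing.assert_allclose(rel.values[:, 0], [0.25, 0.25, 0.5])

    def test_relative_rejects_abundance_input(self):
        t = CountTable(["a", "b"], ["s"], np.array([[1], [3]]))
        rel = to_relative(t)
        with pytest.raises(TypeError):
            to_relative(rel)

    def test_zero_library_rejected(self):
        t = CountTable(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="zero library"):
            to_relative(t)

    def test_clr_equal_parts_zero(self):
        t = CountTable(["a", "b", "c"], ["s"], np.array([[1], [1], [1]]))
        np.testing.assert_allclose(clr(t).values[:, 0], 0.0)

    def test_clr_hand_example(self):
        t = CountTable(["a", "b"], ["s"], np.array([[3], [0]]))
        # clr of counts (3, 0) with pseudocount 1: parts (4, 1), geometric
        # mean 2, hence (+ln 2, -ln 2)
        np.testing.assert_allclose(clr(t).values[:, 0], [np.log(2), -np.log(2)])

    def test_clr_columns_sum_to_zero(self, rng):
        t = CountTable(
            [f"f{i}" for i in range(30)], [f"s{j}" for j in range(10)],
            rng.integers(0, 50, size=(30, 10)),
        )
        np.testing.assert_allclose(clr(t).values.sum(axis=0), 0.0, atol=1e-9)

    def test_clr_bad_pseudocount(self, small_table):
        with pytest.raises(ValueError):
            clr(small_table, pseudocount=0)

    def test_clr_permutation_equivariant(self, rng):
        counts = rng.integers(0, 40, size=(20, 8))
        t = CountTable([f"f{i}" for i in range(20)], [f"s{j}" for j in range(8)], counts)
        perm = rng.permutation(8)
        tp = CountTable(t.feature_ids, [t.sample_ids[j] for j in perm], counts[:, perm])
        np.testing.assert_allclose(clr(tp).values, clr(t).values[:, perm])
        np.testing.assert_allclose(to_relative(tp).values, to_relative(t).values[:, perm])


class TestCss:
    def test_scale_invariance(self):
        col = np.array([5, 0, 12, 3, 0, 7])
        t = CountTable(
            [f"f{i}" for i in range(6)], ["s1", "s2"],
            np.column_stack([col, 3 * col]),
        )
        out = css_normalize(t)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_quantile_one_is_total_sum_scaling(self, rng):
        counts = rng.integers(0, 100, size=(40, 6))
        t = CountTable([f"f{i}" for i in range(40)], [f"s{j}" for j in range(6)], counts)
        np.testing.assert_allclose(
            css_scaling_factors(t, 1.0), counts.sum(axis=0).astype(float)
        )

    def test_factors_match_bruteforce(self, rng):
        counts = rng.integers(0, 60, size=(50, 5))
        counts[rng.random(counts.shape) < 0.4] = 0
        counts[0] = np.maximum(counts[0], 1)  # no empty samples
        t = CountTable([f"f{i}" for i in range(50)], [f"s{j}" for j in range(5)], counts)
        got = css_scaling_factors(t, 0.5)
        # independent recomputation of the rule, sample by sample
        expected = []
        for j in range(5):
            col = counts[:, j]
            nz = np.sort(col[col > 0])
            q = np.quantile(nz, 0.5)
            expected.append(col[col <= q].sum())
        np.testing.assert_allclose(got, expected)


class TestPreparePhenotypes:
    def _pheno(self, rows):
        return PhenotypeTable(pd.DataFrame(rows))

    def test_ch4y_definition(self):
        p = self._pheno(
            [{"animal_id": "a", "batch": "B1", "period": "P1", "CH4": 500.0, "DMI": 20.0},
             {"animal_id": "b", "batch": "B1", "period": "P1", "CH4": 400.0, "DMI": 20.0}]
        )
        out = prepare_phenotypes(p, "CH4y")
        assert out.data["CH4y"].iloc[0] == 25.0

    def test_residuals_sum_to_zero_per_cell(self, rng):
        rows = []
        for i in range(30):
            rows.append(
                {"animal_id": f"a{i}", "batch": f"B{i % 3}", "period": f"P{i % 2}",
                 "CH4": float(rng.normal(500, 50)), "DMI": float(rng.normal(21, 2))}
            )
        out = prepare_phenotypes(self._pheno(rows), "CH4y").data
        sums = out.groupby(["batch", "period"])["adj_CH4y"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_hand_adjustment(self):
        rows = [
            {"animal_id": "a", "batch": "B1", "period": "P1", "CH4y": 25.0},
            {"animal_id": "b", "batch": "B1", "period": "P1", "CH4y": 23.0},
            {"animal_id": "c", "batch": "B2", "period": "P1", "CH4y": 26.0},
            {"animal_id": "d", "batch": "B2", "period": "P1", "CH4y": 26.0},
        ]
        out = prepare_phenotypes(self._pheno(rows), "CH4y").data
        assert out["adj_CH4y"].iloc[0] == 1.0  # cell mean 24, animal at 25

    def test_singleton_cell_warns_with_zero_residual(self):
        rows = [
            {"animal_id": "a", "batch": "B1", "period": "P1", "CH4y": 25.0},
            {"animal_id": "b", "batch": "B2", "period": "P1", "CH4y": 20.0},
            {"animal_id": "c", "batch": "B2", "period": "P1", "CH4y": 22.0},
        ]
        with pytest.warns(UserWarning, match="single animal"):
            out = prepare_phenotypes(self._pheno(rows), "CH4y").data
        assert out["adj_CH4y"].iloc[0] == 0.0

    def test_inconsistent_ch4y_rejected(self):
        with pytest.raises(ValueError, match="CH4y"):
            self._pheno(
                [{"animal_id": "a", "batch": "B", "period": "P",
                  "CH4": 500.0, "DMI": 20.0, "CH4y": 30.0}]
            )
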