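import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psoilcycle.catalog import CATEGORIES, GeneCatalog, GeneEntry
from psoilcycle.profiling import (
    KoCountTable,
    ProfileMatrix,
    SampleMetadata,
    aggregate_systems,
    category_totals,
    median_normalize,
    relative_abundance,
    shift_statistic,
    taxon_shift,
)


def make_catalog(*entries):
    return GeneCatalog(entries=tuple(entries))


class TestMedianNormalize:
    def test_scale_factors_from_totals(self, tiny_counts):
        # totals [100, 200, 400] -> factors [2.0, 1.0, 0.5]
        out = median_normalize(tiny_counts)
        np.testing.assert_allclose(
            out.counts.loc["K00001"].to_numpy(), [10.0, 10.0, 10.0]
        )
        np.testing.assert_allclose(out.total_annotated.to_numpy(), [200.0] * 3)

    def test_single_sample_identity(self):
        t = KoCountTable(
            counts=pd.DataFrame({"s1": [4.0, 6.0]}, index=["K1", "K2"]),
            total_annotated=pd.Series({"s1": 50.0}),
        )
        out = median_normalize(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_equal_totals_identity(self):
        counts = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}, index=["K1", "K2"]
        )
        t = KoCountTable(counts=counts, total_annotated=pd.Series(
            {"a": 20.0, "b": 20.0, "c": 20.0}))
        pd.testing.assert_frame_equal(median_normalize(t).counts, counts)

    def test_zero_total_errors(self):
        t = KoCountTable(
            counts=pd.DataFrame({"s1": [0.0]}, index=["K1"]),
            total_annotated=pd.Series({"s1": 0.0}),
        )
        with pytest.raises(ValueError, match="zero annotated"):
            median_normalize(t)


class TestRelativeAbundance:
    def test_definition(self):
        cat = make_catalog(GeneEntry("phoD", ("K1",), "solubilization_mineralization"))
        t = KoCountTable(
            counts=pd.DataFrame({"s": [5.0]}, index=["K1"]),
            total_annotated=pd.Series({"s": 500.0}),
        )
        prof = relative_abundance(t, cat)
        assert prof.values.loc["phoD", "s"] == pytest.approx(1.0)

    def test_multi_ko_gene_sums(self):
        # two KOs with reads 3 and 7, total 1000 -> 1.0%
        cat = make_catalog(GeneEntry("gcd", ("K1", "K2"), "solubilization_mineralization"))
        t = KoCountTable(
            counts=pd.DataFrame({"s": [3.0, 7.0]}, index=["K1", "K2"]),
            total_annotated=pd.Series({"s": 1000.0}),
        )
        assert relative_abundance(t, cat).values.loc["gcd", "s"] == pytest.approx(1.0)

    def test_absent_gene_zero_with_warning(self, caplog):
        cat = make_catalog(GeneEntry("pit", ("K999",), "uptake_transport"))
        t = KoCountTable(
            counts=pd.DataFrame({"s": [3.0]}, index=["K1"]),
            total_annotated=pd.Series({"s": 100.0}),
        )
        with caplog.at_level("WARNING"):
            prof = relative_abundance(t, cat)
        assert prof.values.loc["pit", "s"] == 0.0
        assert any("pit" in r.message for r in caplog.records)

    def test_scale_invariance_under_normalization(self, tiny_counts):
        cat = make_catalog(
            GeneEntry("a", ("K00001",), "uptake_transport"),
            GeneEntry("b", ("K00002", "K00003"), "starvation_regulation"),
        )
        raw = relative_abundance(tiny_counts, cat)
        norm = relative_abundance(median_normalize(tiny_counts), cat)
        pd.testing.assert_frame_equal(raw.values, norm.values)


class TestAggregateSystems:
    def _profile_and_catalog(self, values):
        genes = ["pstB", "pstC", "pstA", "pstS"]
        cat = make_catalog(
            *(GeneEntry(g, (f"K{i}",), "uptake_transport", system_group="pst_transporter")
              for i, g in enumerate(genes)),
            GeneEntry("pit", ("K9",), "uptake_transport"),
        )
        prof = ProfileMatrix(values=pd.DataFrame(
            {"s": values + [0.7]}, index=genes + ["pit"]))
        return prof, cat

    def test_mean_of_members(self):
        prof, cat = self._profile_and_catalog([0.1, 0.2, 0.3, 0.4])
        out = aggregate_systems(prof, cat)
        assert out.values.loc["pst_transporter", "s"] == pytest.approx(0.25)
        assert out.values.loc["pit", "s"] == pytest.approx(0.7)  # pass-through

    def test_mean_with_zeros(self):
        prof, cat = self._profile_and_catalog([0.0, 0.0, 0.0, 0.4])
        out = aggregate_systems(prof, cat)
        assert out.values.loc["pst_transporter", "s"] == pytest.approx(0.1)

    def test_equal_members_preserved(self):
        prof, cat = self._profile_and_catalog([0.05] * 4)
        out = aggregate_systems(prof, cat)
        assert out.values.loc["pst_transporter", "s"] == pytest.approx(0.05)

    def test_missing_member_errors_with_name(self):
        prof, cat = self._profile_and_catalog([0.1, 0.2, 0.3, 0.4])
        prof = ProfileMatrix(values=prof.values.drop(index="pstA"))
        with pytest.raises(ValueError, match="pstA"):
            aggregate_systems(prof, cat)

    def test_linearity_mean_commutes(self, catalog, default_study):
        from psoilcycle.profiling import relative_abundance

        prof = relative_abundance(default_study.ko_table, catalog)
        aggregated = aggregate_systems(prof, catalog)
        # aggregate-then-average equals average-then-aggregate
        mean_then_agg = aggregate_systems(
            ProfileMatrix(values=prof.values.mean(axis=1).to_frame("m")), catalog
        )
        np.testing.assert_allclose(
            aggregated.values.mean(axis=1).to_numpy(),
            mean_then_agg.values["m"].to_numpy(),
        )


class TestCategoryTotals:
    def test_sum_within_category(self):
        cat = make_catalog(
            GeneEntry("a", ("K1",), "uptake_transport"),
            GeneEntry("b", ("K2",), "uptake_transport"),
        )
        prof = ProfileMatrix(values=pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"]))
        gp = category_totals(prof, cat)
        assert gp.totals.loc["uptake_transport", "s"] == pytest.approx(3.0)
        assert gp.totals.loc["starvation_regulation", "s"] == 0.0

    def test_partition_sums_to_total(self, catalog, default_study):
        prof = relative_abundance(default_study.ko_table, catalog)
        gp = category_totals(prof, catalog)
        np.testing.assert_allclose(
            gp.totals.sum(axis=0).to_numpy(), prof.values.sum(axis=0).to_numpy()
        )
        assert list(gp.totals.index) == list(CATEGORIES)


class TestShiftStatistic:
    def _series(self, meta, plus_val, minus_val):
        plus, minus = meta.contrast_groups("P")
        vals = pd.Series(index=meta.sample_ids, dtype=float)
        vals.loc[plus] = plus_val
        vals.loc[minus] = minus_val
        return vals

    def test_plus_five_percent(self, design_metadata):
        vals = self._series(design_metadata, 1.05, 1.00)
        assert shift_statistic(vals, design_metadata, "P") == pytest.approx(5.0)

    def test_zero_when_equal(self, design_metadata):
        vals = self._series(design_metadata, 1.0, 1.0)
        assert shift_statistic(vals, design_metadata, "P") == pytest.approx(0.0)

    def test_minus_11_5_percent(self, design_metadata):
        vals = self._series(design_metadata, 0.885, 1.000)
        assert shift_statistic(vals, design_metadata, "P") == pytest.approx(-11.5)

    def test_zero_minus_group_mean_errors(self, design_metadata):
        vals = self._series(design_metadata, 1.0, 0.0)
        with pytest.raises(ValueError):
            shift_statistic(vals, design_metadata, "P")

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, design_metadata, scale):
        rng = np.random.default_rng(3)
        vals = pd.Series(
            rng.uniform(0.5, 2.0, len(design_metadata.sample_ids)),
            index=design_metadata.sample_ids,
        )
        base = shift_statistic(vals, design_metadata, "N")
        scaled = shift_statistic(vals * scale, design_metadata, "N")
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unknown_contrast(self, design_metadata):
        with pytest.raises(ValueError):
            shift_statistic(
                pd.Series(1.0, index=design_metadata.sample_ids),
                design_metadata,
                "K",
            )


class TestTaxonShift:
    def _reads(self, meta, plus_vals, minus_vals, contrast="P"):
        plus, minus = meta.contrast_groups(contrast)
        row = pd.Series(index=meta.sample_ids, dtype=float)
        row.loc[plus] = plus_vals
        row.loc[minus] = minus_vals
        return pd.DataFrame({"taxon1": row}).T

    def test_simple_subtraction(self, design_metadata):
        reads = self._reads(design_metadata, 10.0, 4.0)
        out = taxon_shift(reads, design_metadata, "P")
        assert out["taxon1"] == pytest.approx(6.0)

    def test_identical_groups_zero(self, design_metadata):
        reads = self._reads(design_metadata, 7.0, 7.0)
        assert taxon_shift(reads, design_metadata, "P")["taxon1"] == pytest.approx(0.0)

    def test_hand_means(self, design_metadata):
        plus, minus = design_metadata.contrast_groups("N")
        row = pd.Series(index=design_metadata.sample_ids, dtype=float)
        row.loc[plus] = np.resize([5.0, 7.0], len(plus))
        row.loc[minus] = np.resize([10.0, 14.0], len(minus))
        out = taxon_shift(pd.DataFrame({"t": row}).T, design_metadata, "N")
        assert out["t"] == pytest.approx(6.0 - 12.0)

    def test_per_site(self, design_metadata):
        reads = self._reads(design_metadata, 10.0, 4.0)
        out = taxon_shift(reads, design_metadata, "P", per_site=True)
        assert set(out.columns) == {"GZ", "JX"}
        np.testing.assert_allclose(out.loc["taxon1"].to_numpy(), [6.0, 6.0])


class TestTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            KoCountTable(
                counts=pd.DataFrame({"s": [-1.0]}, index=["K1"]),
                total_annotated=pd.Series({"s": 10.0}),
            )

    def test_total_below_column_sum_rejected(self):
        with pytest.raises(ValueError, match="total_annotated"):
            KoCountTable(
                counts=pd.DataFrame({"s": [5.0, 6.0]}, index=["K1", "K2"]),
                total_annotated=pd.Series({"s": 10.0}),
            )

    def test_metadata_requires_columns(self):
        with pytest.raises(ValueError, match="required column"):
            SampleMetadata(table=pd.DataFrame({"site": ["GZ"]}, index=["s1"]))
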