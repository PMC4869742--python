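"""Table loading, standardization, group means, and built-in partitions."""

import numpy as np
import pandas as pd
import pytest

from diffcornet import (
    MetaboliteTable,
    builtin_partitions,
    get_partition,
    group_standardized_means,
    read_metabolite_table,
    standardize,
    write_metabolite_table,
)
from diffcornet.data_model import TableSchema
from diffcornet.errors import ConfigError, DataValidationError, ZeroVarianceError
from diffcornet.synthetic import simulate_table, study_spec

from conftest import make_table

HEADER = "sample_id,genotype,mulch,year,stage,replicate"


def _write(tmp_path, body, name="t.csv"):
    p = tmp_path / name
    p.write_text(body)
    return p


class TestRead:
    def test_toy_file_reports_missing_cells(self, tmp_path):
        rows = [
            f"{HEADER},GLU,CIT,FRU,ATP",
            "s1,2,BP,2006,red,1,1.0,2.0,3.0,4.0",
            "s2,8,HV,2006,red,1,1.1,,3.1,4.1",
            "s3,5,RY,2006,red,1,1.2,2.2,3.2,4.2",
            "s4,10,BS,2007,red,1,1.3,2.3,3.3,4.3",
            "s5,12,BP,2006,red,1,1.4,2.4,3.4,4.4",
            "s6,20,HV,2007,pink,2,1.5,2.5,3.5,4.5",
        ]
        table = read_metabolite_table(_write(tmp_path, "\n".join(rows)))
        assert table.n_samples == 6
        assert table.metabolites == ["ATP", "CIT", "FRU", "GLU"]
        assert table.n_missing() == 1
        assert np.isnan(table.values.loc["s2", "CIT"])

    def test_duplicate_metabolite_column_rejected(self, tmp_path):
        body = f"{HEADER},GLU,GLU\ns1,2,BP,2006,red,1,1,2\ns2,8,HV,2006,red,1,3,4\n"
        with pytest.raises(DataValidationError, match="duplicat"):
            read_metabolite_table(_write(tmp_path, body))

    def test_duplicate_sample_id_rejected(self, tmp_path):
        body = f"{HEADER},GLU\ns1,2,BP,2006,red,1,1\ns1,8,HV,2006,red,1,2\n"
        with pytest.raises(DataValidationError, match="sample id"):
            read_metabolite_table(_write(tmp_path, body))

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        body = f"{HEADER},GLU\ns1,2,BP,2006,red,1,oops\ns2,8,HV,2006,red,1,2\n"
        with pytest.raises(DataValidationError, match="s1.*GLU"):
            read_metabolite_table(_write(tmp_path, body))

    def test_unknown_factor_level_rejected(self, tmp_path):
        body = f"{HEADER},GLU\ns1,99,BP,2006,red,1,1\ns2,8,HV,2006,red,1,2\n"
        with pytest.raises(DataValidationError, match="genotype"):
            read_metabolite_table(_write(tmp_path, body))

    def test_tab_delimiter_autodetected(self, tmp_path):
        body = (
            HEADER.replace(",", "\t") + "\tGLU\n"
            "s1\t2\tBP\t2006\tred\t1\t1.5\n"
            "s2\t8\tHV\t2006\tred\t1\t2.5\n"
        )
        table = read_metabolite_table(_write(tmp_path, body, "t.tsv"))
        assert table.values.loc["s1", "GLU"] == 1.5

    def test_simulated_table_round_trips(self, tmp_path):
        table = simulate_table(study_spec(seed=3, replicates=1, missing_rate=0.05))
        path = tmp_path / "sim.csv"
        write_metabolite_table(table, path)
        back = read_metabolite_table(path)
        pd.testing.assert_frame_equal(back.values, table.values)
        pd.testing.assert_frame_equal(back.factors, table.factors)


class TestStandardize:
    def test_column_reaches_mean_zero_sd_one(self):
        t = make_table(np.array([[1.0], [2.0], [3.0]]), ["GLU"])
        s = standardize(t)
        assert s.values["GLU"].mean() == pytest.approx(0, abs=1e-12)
        assert s.values["GLU"].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_two_value_column_uses_sample_sd(self):
        # sample SD of [10, 20] is 10/sqrt(2): standardized to ±1/sqrt(2)
        t = make_table(np.array([[10.0], [20.0]]), ["GLU"])
        s = standardize(t)
        assert s.values["GLU"].tolist() == pytest.approx(
            [-0.70710678, +0.70710678], abs=1e-8
        )

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(5, 2, size=(12, 3)), ["A1", "A2", "A3"])
        once = standardize(t)
        twice = standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_missing_entries_stay_missing(self):
        vals = np.array([[1.0, 1.0], [2.0, np.nan], [3.0, 5.0]])
        s = standardize(make_table(vals, ["X1", "X2"]))
        assert np.isnan(s.values.iloc[1, 1])
        assert s.values["X2"].count() == 2

    def test_zero_variance_names_metabolite(self):
        t = make_table(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]), ["OK", "FLAT"])
        with pytest.raises(ZeroVarianceError, match="FLAT"):
            standardize(t)


class TestGroupMeans:
    def test_single_group_balanced_values_average_to_zero(self):
        t = make_table(np.array([[-1.0], [1.0]]), ["GLU"])
        reg = t.registry
        out = group_standardized_means(t, "year")
        assert out.loc["2006"].iloc[0] == pytest.approx(0)

    def test_sign_flipped_levels_give_opposite_means(self):
        vals = np.array([[1.0, 2.0], [-1.0, -2.0], [2.0, 1.0], [-2.0, -1.0]])
        t = make_table(vals, ["X1", "X2"], mulches=["BP", "HV", "BP", "HV"])
        out = group_standardized_means(t, "mulch")
        assert out.loc["BP"].iloc[0] == pytest.approx(-out.loc["HV"].iloc[0])

    def test_unknown_factor_rejected(self, study_table):
        with pytest.raises(ConfigError):
            group_standardized_means(study_table, "soil_ph")

    def test_count_weighted_means_sum_to_zero(self, study_table):
        s = standardize(study_table)
        out = group_standardized_means(s, "mulch")
        counts = s.factors["mulch"].value_counts()
        for g in out.columns:
            weighted = sum(out.loc[lv, g] * counts[lv] for lv in out.index)
            assert weighted / counts.sum() == pytest.approx(0, abs=1e-12)

    def test_planted_shift_recovered_after_standardization(self):
        # add 0.5·SD to every amino acid for HV samples; the standardized
        # HV group mean should be delta(1-f)/sqrt(1 + delta^2 f(1-f)) with
        # delta = 0.5 and f the HV sample fraction
        spec = study_spec(seed=41, replicates=6)
        table = simulate_table(spec)
        amino = [m for m, g in spec.groups.items() if g == "amino acid"]
        hv = table.factors["mulch"] == "HV"
        f = hv.mean()
        shifted = table.values.copy()
        for m in amino:
            shifted.loc[hv, m] += 0.5 * spec.sd_of(m)
        table = MetaboliteTable(shifted, table.factors, table.registry,
                                table.factor_registry)
        out = group_standardized_means(standardize(table), "mulch")
        expected = 0.5 * (1 - f) / np.sqrt(1 + 0.25 * f * (1 - f))
        assert out.loc["HV", "amino acid"] == pytest.approx(expected, abs=0.05)


class TestPartitions:
    def test_builtin_names_and_labels(self):
        schemes = {s.name: s for s in builtin_partitions()}
        assert set(schemes) == {
            "polyamine", "mejas", "mulch",
            "mulch_within_highPA", "mulch_within_lowPA",
        }
        assert schemes["polyamine"].subset_labels == ("low polyamine", "high polyamine")

    def test_genotype5_low_polyamine_and_hv_mulch_subsets(self):
        row = {"genotype": "5", "mulch": "HV"}
        assert get_partition("polyamine").assign(row) == "a"
        assert get_partition("mulch").assign(row) == "b"

    def test_genotype20_in_both_polyamine_and_mejas_groupings(self):
        row = {"genotype": "20", "mulch": "BP"}
        assert get_partition("polyamine").assign(row) == "b"   # high polyamine
        assert get_partition("mejas").assign(row) == "a"       # meJAS deficient

    def test_rye_excluded_from_nested_mulch_contrast(self):
        row = {"genotype": "8", "mulch": "RY"}
        assert get_partition("mulch_within_highPA").assign(row) is None
        low_pa = {"genotype": "8", "mulch": "BP"}
        assert get_partition("mulch_within_lowPA").assign(low_pa) is None

    def test_subsets_disjoint_and_counts_match_direct_filtering(self, study_table):
        factors = study_table.factors
        for scheme in builtin_partitions():
            ids_a, ids_b = scheme.apply(study_table)
            assert not set(ids_a) & set(ids_b)
            assert set(ids_a) | set(ids_b) <= set(study_table.sample_ids)
            direct = factors[
                factors[scheme.factor].isin(scheme.a_levels)
                & (
                    factors[scheme.stratum_factor].isin(scheme.stratum_levels)
                    if scheme.stratum_factor
                    else True
                )
            ]
            assert len(ids_a) == len(direct)

    def test_empty_subset_raises(self):
        t = make_table(
            np.arange(8, dtype=float).reshape(4, 2), ["X1", "X2"],
            genotypes=["2", "5", "12", "2"],  # low-polyamine only
        )
        with pytest.raises(DataValidationError, match="polyamine"):
            get_partition("polyamine").apply(t)

    def test_overlapping_subset_levels_rejected(self):
        from diffcornet import PartitionScheme

        with pytest.raises(ConfigError, match="both"):
            PartitionScheme(
                "bad", "genotype", frozenset({"2"}), frozenset({"2", "8"}), "a", "b"
            )
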