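import numpy as np
import pandas as pd
import pytest
from scipy import special

from specnet.io_tables import SpectralCountTable, TableValidationError
from specnet.quant import (
    NormalizedTable,
    abundance_index,
    ddct_fold_change,
    differential,
    normalize,
    volcano,
)

from conftest import random_count_table


def pooled_t_oracle(x, y):
    """Closed-form pooled-variance two-sided t-test.

    Independent of the implementation path: the p-value comes from the
    regularized incomplete beta evaluation of the t CDF.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


def _norm_from(values: dict, groups: dict) -> NormalizedTable:
    df = pd.DataFrame(values, dtype=float)
    return NormalizedTable(
        values=df, groups=groups,
        sample_totals=df.sum(axis=0), mean_total=float(df.sum(axis=0).mean()),
    )


GROUPS_2x3 = {
    "C1": "control", "C2": "control", "C3": "control",
    "I1": "injured", "I2": "injured", "I3": "injured",
}


class TestNormalize:
    def test_stated_formula_example(self):
        # totals (100, 200, 300), protein counts (10, 10, 30) -> (20, 10, 20)
        counts = pd.DataFrame(
            {"S1": [10, 90], "S2": [10, 190], "S3": [30, 270]}, index=["P1", "P2"]
        )
        groups = {"S1": "a", "S2": "a", "S3": "b"}
        norm = normalize(SpectralCountTable(counts=counts, groups=groups))
        assert norm.mean_total == 200
        assert list(norm.values.loc["P1"]) == [20.0, 10.0, 20.0]

    def test_equal_totals_identity(self):
        counts = pd.DataFrame({"S1": [5, 5], "S2": [7, 3]}, index=["P1", "P2"])
        norm = normalize(SpectralCountTable(counts=counts, groups={"S1": "a", "S2": "b"}))
        assert (norm.values.to_numpy() == counts.to_numpy()).all()

    def test_column_totals_equal_mean_total(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = random_count_table(rng, n_proteins=25)
            norm = normalize(table)
            totals = norm.values.sum(axis=0)
            assert np.allclose(totals, norm.mean_total, rtol=1e-9)

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"S1": [5], "S2": [0]}, index=["P1"])
        with pytest.raises(TableValidationError, match="S2"):
            normalize(SpectralCountTable(counts=counts, groups={"S1": "a", "S2": "b"}))


class TestDifferential:
    def test_identical_groups_degenerate(self):
        norm = _norm_from(
            {"C1": [5], "C2": [5], "C3": [5], "I1": [5], "I2": [5], "I3": [5]},
            GROUPS_2x3,
        )
        de = differential(norm, "injured", "control", epsilon=0.0)
        assert de["fold_change"].iloc[0] == 1.0
        assert de["p_value"].iloc[0] == 1.0
        assert bool(de["degenerate"].iloc[0])

    def test_hand_computed_pooled_t(self):
        norm = _norm_from(
            {"C1": [1], "C2": [2], "C3": [3], "I1": [7], "I2": [8], "I3": [9]},
            GROUPS_2x3,
        )
        de = differential(norm, "injured", "control")
        # hand arithmetic: means 8 vs 2, pooled var 1, t = 6 / sqrt(2/3)
        assert de["t_stat"].iloc[0] == pytest.approx(7.348, abs=1e-3)
        t, p = pooled_t_oracle([7, 8, 9], [1, 2, 3])
        assert de["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert de["p_value"].iloc[0] == pytest.approx(0.0018, abs=2e-4)

    def test_pseudocount_fold_change(self):
        norm = _norm_from(
            {"C1": [0], "C2": [0], "C3": [0], "I1": [4], "I2": [4], "I3": [4]},
            GROUPS_2x3,
        )
        de = differential(norm, "injured", "control", epsilon=0.5)
        assert de["fold_change"].iloc[0] == pytest.approx(9.0)

    def test_negative_epsilon_rejected(self):
        norm = _norm_from({"C1": [1], "C2": [1], "I1": [1], "I2": [1]},
                          {"C1": "control", "C2": "control", "I1": "injured", "I2": "injured"})
        with pytest.raises(ValueError, match="epsilon"):
            differential(norm, "injured", "control", epsilon=-0.1)

    def test_filter_blocks_p_value(self):
        norm = _norm_from(
            {"C1": [1, 1], "C2": [2, 2], "C3": [3, 3], "I1": [7, 7], "I2": [8, 8], "I3": [9, 9]},
            GROUPS_2x3,
        )
        unique = pd.DataFrame(
            {s: [1, 3] for s in norm.sample_ids}, index=norm.values.index
        )
        de = differential(norm, "injured", "control", unique_peptides=unique)
        assert not de["passed_filter"].iloc[0] and np.isnan(de["p_value"].iloc[0])
        assert de["passed_filter"].iloc[1] and np.isfinite(de["p_value"].iloc[1])

    def test_too_few_samples_rejected(self):
        norm = _norm_from({"C1": [1], "I1": [2], "I2": [3]},
                          {"C1": "control", "I1": "injured", "I2": "injured"})
        with pytest.raises(TableValidationError, match="2 samples"):
            differential(norm, "injured", "control")

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.poisson(10, size=(1, 6)).astype(float) + rng.uniform(0, 1, (1, 6))
            norm = _norm_from({s: vals[:, i] for i, s in enumerate(GROUPS_2x3)}, GROUPS_2x3)
            de = differential(norm, "injured", "control")
            _, p = pooled_t_oracle(vals[0, 3:], vals[0, :3])
            assert de["p_value"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_tiers_at_thresholds(self):
        rng = np.random.default_rng(2)
        table = random_count_table(rng, n_proteins=60)
        de = differential(normalize(table), "injured", "control")
        for _, row in de.iterrows():
            if np.isnan(row["p_value"]):
                assert row["tier"] == "ns"
            elif row["p_value"] <= 0.01:
                assert row["tier"] == "p01"
            elif row["p_value"] <= 0.05:
                assert row["tier"] == "p05"
            else:
                assert row["tier"] == "ns"


class TestVolcano:
    def _de(self, fc, p, passed=True):
        return pd.DataFrame(
            {
                "fold_change": [fc],
                "log2_fc": [np.log2(fc)],
                "p_value": [p],
                "passed_filter": [passed],
                "tier": ["p01" if p <= 0.01 else "p05" if p <= 0.05 else "ns"],
            },
            index=["P1"],
        )

    def test_origin_point(self):
        v = volcano(self._de(1.0, 1.0))
        assert v["log2_fc"].iloc[0] == 0.0
        assert v["neg_log10_p"].iloc[0] == 0.0
        assert v["tier"].iloc[0] == "ns"
        assert v["direction"].iloc[0] == "flat"

    def test_boundary_p05_inclusive(self):
        assert volcano(self._de(2.0, 0.05))["tier"].iloc[0] == "p05"

    def test_log_arithmetic(self):
        v = volcano(self._de(8.0, 0.001))
        assert v["log2_fc"].iloc[0] == pytest.approx(3.0)
        assert v["neg_log10_p"].iloc[0] == pytest.approx(3.0)
        assert v["tier"].iloc[0] == "p01"

    def test_filtered_rows_excluded(self):
        assert volcano(self._de(2.0, 0.01, passed=False)).empty


class TestAbundanceIndex:
    def _table(self, counts: dict, index) -> SpectralCountTable:
        df = pd.DataFrame(counts, index=index)
        groups = {s: "g" for s in df.columns}
        return SpectralCountTable(counts=df, groups=groups)

    def _meta(self, index, masses, genes=None):
        return pd.DataFrame(
            {
                "gene_symbol": genes or [f"G{i}" for i in range(len(index))],
                "mass_kda": masses,
            },
            index=pd.Index(index, name="accession"),
        )

    def test_ratio_definition(self):
        table = self._table({"S1": [22]}, ["P1"])
        ab = abundance_index(table, self._meta(["P1"], [10.0]), mode="mean_all")
        assert ab["ratio"].iloc[0] == pytest.approx(2.2)
        assert ab["rank"].iloc[0] == 1

    def test_equal_masses_preserve_count_ranking(self):
        table = self._table({"S1": [5, 50, 20]}, ["P1", "P2", "P3"])
        ab = abundance_index(table, self._meta(["P1", "P2", "P3"], [10.0] * 3))
        by_rank = ab.sort_values("rank").index.tolist()
        assert by_rank == ["P2", "P3", "P1"]

    def test_missing_mass_lists_accessions(self):
        table = self._table({"S1": [5, 5]}, ["P1", "P2"])
        with pytest.raises(TableValidationError, match="P2"):
            abundance_index(table, self._meta(["P1", "P2"], [10.0, np.nan]))

    def test_scale_consistency(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(9, size=(8, 3)) + 1
        idx = [f"P{i}" for i in range(8)]
        t1 = self._table({f"S{j}": counts[:, j] for j in range(3)}, idx)
        t3 = self._table({f"S{j}": 3 * counts[:, j] for j in range(3)}, idx)
        meta = self._meta(idx, rng.uniform(10, 200, 8))
        a1 = abundance_index(t1, meta)
        a3 = abundance_index(t3, meta)
        assert np.allclose(a3["ratio"], 3 * a1["ratio"])
        assert (a3["rank"] == a1["rank"]).all()

    def test_mode_validation(self):
        table = self._table({"S1": [1]}, ["P1"])
        with pytest.raises(ValueError, match="mode"):
            abundance_index(table, self._meta(["P1"], [1.0]), mode="median")
        with pytest.raises(ValueError, match="group"):
            abundance_index(table, self._meta(["P1"], [1.0]), mode="mean_group")

    def test_sum_vs_mean_modes(self):
        table = self._table({"S1": [10], "S2": [20]}, ["P1"])
        meta = self._meta(["P1"], [10.0])
        assert abundance_index(table, meta, mode="mean_all")["ratio"].iloc[0] == pytest.approx(1.5)
        assert abundance_index(table, meta, mode="sum_all")["ratio"].iloc[0] == pytest.approx(3.0)


class TestDdct:
    def test_zero_ddct_is_unity(self):
        assert ddct_fold_change(20, 15, 22, 17) == pytest.approx(1.0)

    def test_one_doubling(self):
        # ddCt = -1 -> FC = 2
        assert ddct_fold_change(20, 16, 23, 18) == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        assert ddct_fold_change(24, 18, 26, 18) == pytest.approx(4.0)
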