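"""Group comparisons, correlations and report assembly."""

import numpy as np
import pandas as pd
import pytest

from hippogamma.stats_report import (
    build_report,
    chi_squared_independence,
    compare_groups,
    correlate,
    stars,
)
from hippogamma.surrogates import gen_ad_like_dataset


def frame(groups):
    rows = []
    for name, vals in groups.items():
        rows.extend({"condition": name, "n_spikes": v} for v in vals)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        data = frame({"a": [1.0] * 10, "b": [1.0] * 10})
        res = compare_groups(data, "n_spikes")
        assert res.omnibus_p == 1.0
        assert not res.significant
        assert res.pairwise_p == {}

    def test_separated_groups_power(self, rng):
        """3-SD mean separation at n=30: rejection in >= 99% of replicates."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            data = frame({
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(3, 1, 30),
            })
            res = compare_groups(data, "n_spikes")
            rejections += res.omnibus_p < 0.001
        assert rejections / n_rep >= 0.99

    def test_posthoc_only_when_significant(self, rng):
        null = frame({"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
                      "c": rng.normal(0, 1, 20)})
        res = compare_groups(null, "n_spikes")
        if not res.significant:
            assert res.posthoc_test is None
        strong = frame({"a": rng.normal(0, 1, 20), "b": rng.normal(5, 1, 20),
                        "c": rng.normal(10, 1, 20)})
        res2 = compare_groups(strong, "n_spikes")
        assert res2.significant and res2.posthoc_test is not None
        assert len(res2.pairwise_p) == 3

    def test_nonnormal_data_uses_kruskal(self, rng):
        data = frame({
            "a": rng.exponential(1.0, 40),
            "b": rng.exponential(4.0, 40),
        })
        res = compare_groups(data, "n_spikes")
        assert res.omnibus_test == "kruskal-wallis"
        if res.significant:
            assert res.posthoc_test == "dunn-holm"

    def test_small_group_rejected(self):
        data = frame({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            compare_groups(data, "n_spikes")

    def test_nan_rows_dropped(self, rng):
        data = frame({"a": rng.normal(0, 1, 30), "b": rng.normal(4, 1, 30)})
        data.loc[0, "n_spikes"] = np.nan
        res = compare_groups(data, "n_spikes")
        assert res.significant


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)
        rho, _ = correlate(x, x**3, method="spearman")
        assert rho == pytest.approx(1.0)

    def test_permuted_pairs_null(self, rng):
        x = rng.normal(size=100)
        y = rng.permutation(x)
        r, p = correlate(x, y)
        assert abs(r) < 0.35

    def test_zero_variance_flagged(self):
        r, p = correlate(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3], method="kendall")


class TestSyntheticDataset:
    def test_row_counts(self):
        df = gen_ad_like_dataset(
            {"control": 500.0, "ad": 340.0}, {"control": 80.0, "ad": 80.0},
            n_per_group=30,
        )
        assert len(df) == 60
        assert set(df["condition"]) == {"control", "ad"}

    def test_zero_effect_type_one(self):
        """No significance in >= 94% of null replicates at alpha 0.05."""
        false_pos = 0
        n_rep = 100
        for seed in range(n_rep):
            df = gen_ad_like_dataset(
                {c: 100.0 for c in "abcde"}, {c: 10.0 for c in "abcde"},
                n_per_group=30, seed=seed,
            )
            false_pos += compare_groups(df, "n_spikes").significant
        assert (n_rep - false_pos) / n_rep >= 0.94

    def test_printed_effect_recovered(self):
        """Control/degeneration gap in SD units reaches omnibus significance."""
        hits = 0
        for seed in range(20):
            df = gen_ad_like_dataset(
                {"control": 505.0, "ad": 342.0},
                {"control": 86.4, "ad": 81.3},
                n_per_group=30, seed=seed,
            )
            hits += compare_groups(df, "n_spikes").omnibus_p < 0.001
        assert hits >= 19


class TestReport:
    def test_empty_inputs_yield_gaps(self, tmp_path):
        text = build_report(pd.DataFrame(), [], out_dir=tmp_path)
        assert "GAP" in text
        assert (tmp_path / "report.md").exists()

    def test_full_report_tables(self, rng, tmp_path):
        df = gen_ad_like_dataset(
            {"control": 500.0, "ad": 340.0}, {"control": 50.0, "ad": 50.0},
            n_per_group=10,
        )
        comp = compare_groups(df, "n_spikes")
        summary = df.groupby("condition", as_index=False)["n_spikes"].mean()
        text = build_report(summary, [comp], out_dir=tmp_path,
                            manifest={"seed": 1})
        assert "control" in text and "seed" in text
        assert (tmp_path / "comparisons.csv").exists()
        # star annotations consistent with adjusted p-values
        table = pd.read_csv(tmp_path / "comparisons.csv")
        for _, row in table.iterrows():
            if np.isfinite(row["p_adjusted"]):
                assert row["stars"] == stars(row["p_adjusted"])

    def test_regeneration_bit_identical(self, tmp_path):
        df = gen_ad_like_dataset(
            {"a": 1.0, "b": 5.0}, {"a": 1.0, "b": 1.0}, n_per_group=10
        )
        comp = compare_groups(df, "n_spikes")
        t1 = build_report(df.head(), [comp])
        t2 = build_report(df.head(), [comp])
        assert t1 == t2


def test_stars_thresholds():
    assert stars(0.2) == "ns"
    assert stars(0.04) == "*"
    assert stars(0.004) == "**"
    assert stars(0.0004) == "***"


def test_chi_squared_smoke():
    stat, p = chi_squared_independence([[30, 10], [10, 30]])
    assert p < 0.001
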