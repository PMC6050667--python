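import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonuse import (
    SimulationParams,
    correlation_suite,
    deviation_histogram,
    enc_plot_data,
    expression_stratification,
    gene_index_table,
    gene_set_compare,
    make_cds_record,
    neutrality_fit,
    pr2_analysis,
    simulate_cds_set,
)
from codonuse.evolution import bootstrap_deviation_histogram

from conftest import random_record


@pytest.fixture(scope="module")
def neutral_index():
    records, expr, _ = simulate_cds_set(SimulationParams(seed=11, n_genes=300))
    return gene_index_table(records, expr)


class TestEncPlot:
    def test_unbiased_genes_cluster_at_curve(self, neutral_index):
        scatter, curve = enc_plot_data(neutral_index)
        assert len(curve) == 1000
        # neutral genes straddle the curve with small deviations
        dev = neutral_index["deviation"].dropna()
        assert abs(dev.mean()) < 0.01
        assert dev.abs().quantile(0.9) < 0.05

    def test_selected_genes_fall_below_curve(self):
        """C-only selection concentrates usage beyond what GC3 alone
        predicts (selection toward both G and C endings would instead mimic
        compositional bias and stay on the curve)."""
        records, _, _ = simulate_cds_set(
            SimulationParams(seed=12, n_genes=150, selection_strength=1.5,
                             selection_endings=("C",))
        )
        scatter, _ = enc_plot_data(gene_index_table(records))
        assert scatter["below_curve"].mean() > 0.9

    def test_strong_bias_threshold_count(self, neutral_index):
        df = neutral_index.copy()
        df.loc[df.index[:3], "enc"] = 30.0  # plant exactly 3 strongly biased
        scatter, _ = enc_plot_data(df)
        assert int(scatter["strong_bias"].sum()) == 3

    def test_all_undefined_error(self, neutral_index):
        df = neutral_index.copy()
        df["enc"] = np.nan
        with pytest.raises(ValueError):
            enc_plot_data(df)


class TestDeviationHistogram:
    def test_single_bin(self):
        h = deviation_histogram([0.005] * 10)
        assert len(h) == 1
        assert h["frequency"].iloc[0] == 1.0
        assert (h["bin_left"].iloc[0], h["bin_right"].iloc[0]) == (0.0, 0.01)

    def test_negative_bin_present(self):
        h = deviation_histogram([-0.005, 0.005])
        assert h["frequency"].tolist() == [0.5, 0.5]
        assert h["bin_left"].iloc[0] == pytest.approx(-0.01)

    def test_matches_brute_force_binning(self, rng):
        d = rng.normal(0.08, 0.03, 500)
        h = deviation_histogram(d)
        assert h["frequency"].sum() == pytest.approx(1.0, abs=1e-12)
        modal = h.loc[h["frequency"].idxmax(), "bin_left"]
        brute = pd.Series(np.floor(d / 0.01)).value_counts().idxmax() * 0.01
        assert modal == pytest.approx(brute)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            deviation_histogram([])

    def test_bootstrap_bands_bracket_observed(self, rng):
        d = rng.normal(0.08, 0.02, 200)
        h = bootstrap_deviation_histogram(d, n_replicates=200, seed=1)
        inside = (h["freq_lo"] <= h["frequency"]) & (h["frequency"] <= h["freq_hi"])
        assert inside.mean() > 0.9


class TestPr2:
    def test_degenerate_denominator_undefined(self):
        rec = make_cds_record("a", "GCC" * 100)  # all third positions C
        points, tallies = pr2_analysis([rec])
        assert points["quadrant"].iloc[0] == "undefined"
        assert tallies["undefined"] == 1

    def test_quadrant_arithmetic(self):
        # third-position counts A=10, U=30, G=10, C=30
        seq = "GCA" * 10 + "GCT" * 30 + "GCG" * 10 + "GCC" * 30
        points, _ = pr2_analysis([make_cds_record("a", seq)])
        assert points["x"].iloc[0] == pytest.approx(0.25)
        assert points["y"].iloc[0] == pytest.approx(0.25)
        assert points["quadrant"].iloc[0] == "Q3"

    def test_boundary_excluded_from_quadrants(self):
        seq = "GCA" * 10 + "GCT" * 10 + "GCG" * 10 + "GCC" * 30
        points, tallies = pr2_analysis([make_cds_record("a", seq)])
        assert points["quadrant"].iloc[0] == "boundary"
        assert sum(tallies[q] for q in ("Q1", "Q2", "Q3", "Q4")) == 0

    def test_tallies_partition_records(self, rng):
        records = [random_record(rng, 100, f"g{i}") for i in range(40)]
        _, tallies = pr2_analysis(records)
        assert sum(tallies.values()) == 40

    def test_uc_bias_puts_plurality_in_q3(self):
        """U/C-favouring third-position selection drives points into Q3."""
        records, _, _ = simulate_cds_set(
            SimulationParams(seed=13, n_genes=200, selection_strength=0.8,
                             selection_endings=("U", "C"))
        )
        _, tallies = pr2_analysis(records)
        assert tallies["Q3"] > max(tallies["Q1"], tallies["Q2"], tallies["Q4"])

    def test_fourfold_only_mode_runs(self, rng):
        records = [random_record(rng, 150, f"g{i}") for i in range(5)]
        points, _ = pr2_analysis(records, fourfold_only=True)
        assert points["x"].between(0, 1).all()


class TestNeutralityFit:
    def test_identity_line(self):
        gc3 = np.linspace(0.2, 0.8, 50)
        fit = neutrality_fit(gc3, gc3)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.mutation_pct == pytest.approx(100.0)

    def test_flat_response(self):
        gc3 = np.linspace(0.2, 0.8, 50)
        fit = neutrality_fit(np.full(50, 0.40), gc3)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.selection_pct == pytest.approx(100.0)

    def test_decomposition_sums_to_100(self):
        rng = np.random.default_rng(3)
        gc3 = rng.uniform(0.2, 0.8, 100)
        fit = neutrality_fit(0.1 + 0.5 * gc3 + rng.normal(0, 0.02, 100), gc3)
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_slope_recovery_within_3se_across_seeds(self):
        """OLS recovers the generating slope within 3 SE, 20 seeds."""
        beta = 0.32
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gc3 = rng.uniform(0.25, 0.75, 400)
            gc12 = 0.2 + beta * gc3 + rng.normal(0, 0.01, 400)
            res = stats.linregress(gc3, gc12)
            fit = neutrality_fit(gc12, gc3)
            assert abs(fit.slope - beta) < 3 * res.stderr

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            neutrality_fit([0.4, 0.5], [0.3, 0.4])
        with pytest.raises(ValueError, match="variance"):
            neutrality_fit([0.4, 0.5, 0.6], [0.3, 0.3, 0.3])


class TestCorrelationSuite:
    def test_perfect_and_inverse_correlation(self):
        x = np.linspace(0, 1, 100)
        df = pd.DataFrame({"a": x, "b": x, "c": -2 * x + 1e-9 * np.sin(x)})
        out = correlation_suite(df, pairs=(("a", "b"), ("a", "c")))
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["pearson_r"].iloc[1] < -0.99

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = correlation_suite(df, pairs=(("a", "b"),))
        assert out["constant_column"].iloc[0]
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_null_correlation_replicates(self):
        """Independent x, y at n=1000: |r| < 0.08 and p > 0.01 in >=95/100."""
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(100):
            x, y = rng.normal(size=(2, 1000))
            r, p = stats.pearsonr(x, y)
            out = correlation_suite(
                pd.DataFrame({"x": x, "y": y}), pairs=(("x", "y"),)
            )
            assert out["pearson_r"].iloc[0] == pytest.approx(r)
            if abs(out["pearson_r"].iloc[0]) < 0.08 and out["p_value"].iloc[0] > 0.01:
                ok += 1
        assert ok >= 95


class TestExpressionStratification:
    def test_constructed_quartile_groups(self):
        n = 80
        gc = np.concatenate([
            np.linspace(0.30, 0.41, n // 4),
            np.linspace(0.42, 0.50, n // 2),
            np.linspace(0.51, 0.60, n // 4),
        ])
        df = pd.DataFrame({
            "id": [f"g{i}" for i in range(n)],
            "gc": gc, "enc": np.full(n, 50.0),
            "fpkm": np.full(n, 10.0), "log10_fpkm": np.full(n, 1.0),
        })
        table, summary = expression_stratification(
            df, gc_breaks=(0.418, 0.508))
        sizes = table["gc_group"].value_counts()
        assert abs(sizes["low_gc"] - n // 4) <= 1
        assert abs(sizes["mid_gc"] - n // 2) <= 1
        assert abs(sizes["high_gc"] - n // 4) <= 1

    def test_all_below_threshold_error(self):
        df = pd.DataFrame({"id": ["a", "b"], "gc": [0.4, 0.5],
                           "enc": [50.0, 51.0], "fpkm": [0.5, 0.5],
                           "log10_fpkm": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no rows above threshold"):
            expression_stratification(df)

    def test_coupled_selection_lowers_enc_in_high_gc_group(self):
        """GC-ending selection coupled to expression: the high-GC stratum
        carries the strongly selected genes and hence lower mean ENC."""
        records, expr, _ = simulate_cds_set(SimulationParams(
            seed=14, n_genes=400, selection_strength=1.0,
            selection_expression_coupling=1.0))
        idx = gene_index_table(records, expr)
        _, summary = expression_stratification(idx)
        s = summary.set_index("gc_group")["mean_enc"]
        assert s["high_gc"] < s["low_gc"]


class TestGeneSetCompare:
    def _index(self, rng, n=200):
        records, _, _ = simulate_cds_set(SimulationParams(seed=15, n_genes=n))
        return gene_index_table(records)

    def test_flags_vs_reference_means(self, rng):
        idx = self._index(rng)
        comp = gene_set_compare(idx, list(idx["id"].iloc[:5]))
        assert len(comp.table) == 5
        for _, row in comp.table.iterrows():
            assert row["enc_below_average"] == (row["enc"] < comp.mean_enc)

    def test_identity_ratio(self):
        df = pd.DataFrame({"id": ["a", "b", "c"],
                           "enc": [50.0, 52.0, 54.0],
                           "gc12": [0.45, 0.45, 0.50],
                           "gc3": [0.45, 0.50, 0.50]})
        comp = gene_set_compare(df, ["a"])
        assert comp.table["gc12_gc3_ratio"].iloc[0] == pytest.approx(1.0)

    def test_null_focal_set_splits_evenly(self, rng):
        """A focal set drawn from the background flags ~50% below average."""
        idx = self._index(rng)
        focal = list(idx["id"].sample(60, random_state=1))
        comp = gene_set_compare(idx, focal)
        frac = comp.n_enc_below_average / len(comp.table)
        assert 0.25 < frac < 0.75  # 3-sigma band around 1/2 at n=60

    def test_missing_and_empty(self, rng):
        idx = self._index(rng)
        comp = gene_set_compare(idx, [idx["id"].iloc[0], "nope"])
        assert comp.missing_ids == ("nope",)
        with pytest.raises(ValueError):
            gene_set_compare(idx, ["nope"])


def test_pure_mutation_mean_deviation_near_zero():
    """Without selection, observed ENC scatters around the expected curve:
    the mean deviation ratio is statistically indistinguishable from 0."""
    records, _, _ = simulate_cds_set(SimulationParams(seed=16, n_genes=400))
    idx = gene_index_table(records)
    d = idx["deviation"].dropna()
    se = d.std() / np.sqrt(len(d))
    assert abs(d.mean()) < 3 * se
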