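import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfarray import arrayio, simulate
from sulfarray.selection import (
    DEFAULT_COEFFS,
    SelectionCurve,
    classify_regulation,
    cross_line_ratios,
    median_stability_qc,
    passes_filter,
    reliable_intersection,
    selection_threshold,
    venn_partition,
)


def horner_threshold(log2_ratio, signed=False, clamp=True):
    """Independent Horner evaluation of the published quintic ceiling."""
    t = log2_ratio if signed else abs(log2_ratio)
    x = 20.0 * t + 1.0
    acc = 0.0
    for c in DEFAULT_COEFFS:
        acc = acc * x + c
    if clamp:
        acc = min(1.0, max(0.0, acc))
    return acc


class TestSelectionThreshold:
    def test_value_at_zero_ratio(self):
        assert selection_threshold(0.0) == pytest.approx(0.9893, abs=1e-12)

    def test_value_at_ratio_0_3(self):
        assert selection_threshold(0.3) == pytest.approx(0.0341, abs=1e-10)

    def test_clamped_to_zero_at_ratio_0_5(self):
        assert selection_threshold(0.5) == 0.0
        unclamped = SelectionCurve(clamp=False)
        assert selection_threshold(0.5, unclamped) < 0

    def test_matches_horner_oracle_on_grid(self):
        grid = np.linspace(-1.5, 1.5, 1000)
        ours = selection_threshold(grid)
        oracle = np.array([horner_threshold(r) for r in grid])
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_signed_transform_matches_signed_oracle(self):
        curve = SelectionCurve(x_transform="signed", clamp=False)
        for r in (-0.4, -0.1, 0.0, 0.2, 0.6):
            assert selection_threshold(r, curve) == pytest.approx(
                horner_threshold(r, signed=True, clamp=False), abs=1e-12
            )

    @settings(max_examples=300, deadline=None)
    @given(st.floats(min_value=-5, max_value=5))
    def test_absolute_curve_symmetric(self, r):
        assert selection_threshold(r) == selection_threshold(-r)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            SelectionCurve(x_transform="both")


class TestPassesFilter:
    def test_small_p_always_passes(self):
        assert passes_filter(0.04, 3.0)

    def test_large_p_near_zero_ratio_passes(self):
        assert passes_filter(0.5, 0.0)  # 0.5 <= 0.9893

    def test_large_p_large_ratio_fails(self):
        assert not passes_filter(0.5, 1.0)

    def test_nan_p_never_passes(self):
        assert not passes_filter(np.nan, 0.0)

    def test_exhaustive_grid_matches_brute_force(self):
        ps = np.linspace(0, 1, 101)
        ratios = np.linspace(-1.2, 1.2, 97)
        P, R = np.meshgrid(ps, ratios)
        ours = passes_filter(P.ravel(), R.ravel())
        brute = np.array(
            [
                p < 0.05 or p <= horner_threshold(r)
                for p, r in zip(P.ravel(), R.ravel())
            ]
        )
        np.testing.assert_array_equal(ours, brute)

    @settings(max_examples=300, deadline=None)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=-2, max_value=2),
    )
    def test_lowering_p_never_turns_pass_into_fail(self, p1, p2, r):
        lo, hi = min(p1, p2), max(p1, p2)
        if passes_filter(hi, r):
            assert passes_filter(lo, r)


def _stats(genes, ratios, ps, line="WT"):
    return pd.DataFrame(
        {
            "gene_id": genes,
            "line": line,
            "mean_log2_ratio": ratios,
            "p_value": ps,
            "n_arrays": 4,
        }
    )


class TestReliableIntersection:
    def test_gene_passing_one_line_only_excluded(self):
        s1 = _stats(["a", "b"], [0.0, 0.0], [0.5, 0.5])
        s2 = _stats(["a", "b"], [1.0, 0.0], [0.5, 0.5], line="AB3")
        got = reliable_intersection(s1, s2)
        assert set(got) == {"b"}

    def test_all_passing_gives_universe(self):
        s1 = _stats(["a", "b", "c"], [0.0] * 3, [0.01] * 3)
        s2 = _stats(["a", "b", "c"], [0.0] * 3, [0.01] * 3, line="AB3")
        assert set(reliable_intersection(s1, s2)) == {"a", "b", "c"}

    def test_disjoint_universes_rejected(self):
        s1 = _stats(["a"], [0.0], [0.5])
        s2 = _stats(["b"], [0.0], [0.5], line="AB3")
        with pytest.raises(ValueError, match="disjoint"):
            reliable_intersection(s1, s2)

    def test_null_experiment_retains_small_ratio_genes(self):
        """Direct application of the formula: in a no-signal experiment
        nearly all genes with tiny fold changes are kept."""
        rng = np.random.default_rng(17)
        n = 2000
        ratios = rng.normal(0, 0.05, n)
        ps = rng.uniform(0, 1, n)
        genes = [f"g{i}" for i in range(n)]
        s1 = _stats(genes, ratios, ps)
        s2 = _stats(genes, ratios, ps, line="AB3")
        kept = set(reliable_intersection(s1, s2))
        small = [g for g, r in zip(genes, ratios) if abs(r) < 0.05]
        frac = sum(g in kept for g in small) / len(small)
        assert frac >= 0.9


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "ratio,call",
        [(0.6, "up"), (-0.6, "down"), (0.5, "unchanged"), (-0.5, "unchanged"), (0.0, "unchanged")],
    )
    def test_strict_cutoffs(self, ratio, call):
        stats = _stats(["g"], [ratio], [0.01])
        got = classify_regulation(stats)
        assert got["call"].iloc[0] == call

    def test_restriction_to_reliable_set(self):
        stats = _stats(["a", "b"], [0.9, 0.9], [0.01, 0.01])
        got = classify_regulation(stats, reliable=pd.Index(["b"]))
        assert list(got["gene_id"]) == ["b"]


def _calls(up, down, line):
    genes = list(up) + list(down)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "line": line,
            "call": ["up"] * len(up) + ["down"] * len(down),
            "mean_log2_ratio": [1.0] * len(up) + [-1.0] * len(down),
        }
    )


class TestVennPartition:
    def test_worked_example(self):
        v = venn_partition(_calls("abc", "", "WT"), _calls("bcd", "", "AB3"))
        assert v.up_common == {"b", "c"}
        assert v.up_line1_only == {"a"}
        assert v.up_line2_only == {"d"}

    def test_empty_calls_give_empty_sets(self):
        v = venn_partition(_calls("", "", "WT"), _calls("", "", "AB3"))
        assert v.union == set()

    def test_opposite_direction_genes_tracked_in_both_line_sets(self):
        v = venn_partition(_calls("x", "", "WT"), _calls("", "x", "AB3"))
        assert v.opposite == {"x"}
        assert v.up_line1_only == {"x"}
        assert v.down_line2_only == {"x"}
        assert "x" in v.union

    def test_randomized_partition_matches_naive_set_operations(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(200)]
        for _ in range(10):
            up1 = {g for g in genes if rng.random() < 0.2}
            dn1 = {g for g in genes if g not in up1 and rng.random() < 0.2}
            up2 = {g for g in genes if rng.random() < 0.2}
            dn2 = {g for g in genes if g not in up2 and rng.random() < 0.2}
            v = venn_partition(_calls(up1, dn1, "WT"), _calls(up2, dn2, "AB3"))
            assert v.up_common == up1 & up2
            assert v.up_line1_only == up1 - up2
            assert v.down_line2_only == dn2 - dn1
            # conservation: |up1| = common + line1-only
            assert len(up1) == len(v.up_common) + len(v.up_line1_only)
            assert len(dn2) == len(v.down_common) + len(v.down_line2_only)
            assert v.union == up1 | dn1 | up2 | dn2


def _hset(line, arrays_spec):
    """arrays_spec: list of (orientation, ch_a array, ch_b array)."""
    arrays = []
    for i, (orient, a, b) in enumerate(arrays_spec):
        feats = pd.DataFrame(
            {
                "feature_id": [f"f{j}" for j in range(len(a))],
                "gene_id": [f"g{j}" for j in range(len(a))],
                "ch_a_median": a,
                "ch_b_median": b,
                "flag": 0,
            }
        )
        arrays.append(arrayio.ArrayData(f"{line}_r{i}", orient, feats))
    return arrayio.HybridizationSet(line, "-S_vs_nS", arrays)


class TestCrossLineRatios:
    def test_identical_lines_give_zero(self):
        vals = np.array([100.0, 200.0, 400.0])
        h1 = _hset("WT", [("fwd", vals, vals)])
        h2 = _hset("AB3", [("fwd", vals, vals)])
        for scale in ("median", "none"):
            out = cross_line_ratios(h1, h2, "-S", scale=scale)
            np.testing.assert_allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_doubled_intensities_give_ratio_one_unscaled(self):
        vals = np.array([100.0, 200.0, 400.0])
        h1 = _hset("WT", [("fwd", vals, vals)])
        h2 = _hset("AB3", [("fwd", 2 * vals, 2 * vals)])
        out = cross_line_ratios(h1, h2, "-S", scale="none")
        np.testing.assert_allclose(out["log2_ratio"], 1.0, atol=1e-12)
        # median scaling absorbs the global factor by design
        out_scaled = cross_line_ratios(h1, h2, "-S", scale="median")
        np.testing.assert_allclose(out_scaled["log2_ratio"], 0.0, atol=1e-12)

    def test_orientation_decides_condition_channel(self):
        a = np.array([100.0, 100.0])
        b = np.array([400.0, 400.0])
        h1 = _hset("WT", [("fwd", a, b)])  # -S in channel a
        h2 = _hset("AB3", [("rev", a, b)])  # -S in channel b
        out = cross_line_ratios(h1, h2, "-S", scale="none")
        np.testing.assert_allclose(out["log2_ratio"], 2.0)  # 400 vs 100

    def test_unknown_condition_rejected(self):
        vals = np.array([1.0, 2.0])
        h1 = _hset("WT", [("fwd", vals, vals)])
        h2 = _hset("AB3", [("fwd", vals, vals)])
        with pytest.raises(ValueError, match="absent"):
            cross_line_ratios(h1, h2, "+Fe")

    def test_missing_induction_detected_in_deficient_condition(self):
        """Genes induced by -S in WT but not in the second line show
        negative -S cross-line ratios (line2 / line1)."""
        cfg = simulate.SimulationConfig(
            n_genes=400,
            frac_up=0.1,
            frac_down=0.0,
            shared_fraction=0.0,  # AB3 regulates different genes than WT
            effect_size_log2=1.5,
            noise_sd_log2=0.05,
            dye_bias_coeffs=(0.0,),
            planted_enriched_terms=(),
            seed=31,
        )
        exp = simulate.generate_experiment(cfg)
        sets = {}
        for line in ("WT", "AB3"):
            arrays = [
                arrayio.ArrayData(r.array_id, r.dye_orientation, exp.arrays[r.array_id])
                for r in exp.design.query("line == @line").itertuples()
            ]
            sets[line] = arrayio.HybridizationSet(line, "-S_vs_nS", arrays)
        out = cross_line_ratios(sets["WT"], sets["AB3"], "-S").set_index("gene_id")
        wt_only_up = sorted(
            exp.truth.regulated_set("up:WT") - exp.truth.regulated_set("up:AB3")
        )
        assert out.loc[wt_only_up, "log2_ratio"].mean() < -0.5


class TestMedianStabilityQc:
    def test_identical_arrays_pass(self):
        vals = np.array([100.0, 200.0, 300.0])
        h = _hset("WT", [("fwd", vals, vals), ("rev", vals, vals)])
        table, report = median_stability_qc([h])
        assert report["max_min_ratio"] == pytest.approx(1.0)
        assert report["passed"]
        assert len(table) == 2

    def test_scaled_array_fails_default_tolerance(self):
        vals = np.array([100.0, 200.0, 300.0])
        h = _hset("WT", [("fwd", vals, vals), ("fwd", 2 * vals, 2 * vals)])
        _table, report = median_stability_qc([h])
        assert report["max_min_ratio"] == pytest.approx(2.0)
        assert not report["passed"]

    def test_infinite_tolerance_always_passes(self):
        vals = np.array([100.0, 200.0, 300.0])
        h = _hset("WT", [("fwd", vals, vals), ("fwd", 5 * vals, 5 * vals)])
        _table, report = median_stability_qc([h], tolerance=np.inf)
        assert report["passed"]

    def test_single_array_rejected(self):
        vals = np.array([1.0, 2.0])
        h = _hset("WT", [("fwd", vals, vals)])
        with pytest.raises(ValueError, match="2 arrays"):
            median_stability_qc([h])
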