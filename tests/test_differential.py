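import numpy as np
import pytest
from scipy import stats as sps

from glycolect.array_core import LectinAnnotation
from glycolect.datasets import (
    M16_CONTRAST,
    M48_CONTRAST,
    SAD_CONTRAST,
    mcao_ratio_tables,
    sad_ratio_table,
)
from glycolect.differential import (
    DifferentialCall,
    benjamini_hochberg,
    call_lectin,
    call_table,
    calls_from_ratios,
    classify_ratio,
    collapse_directions,
    compare_models,
    motif_summary,
    t_test,
)
from glycolect.errors import UndefinedRatioError
from glycolect.quantify import GroupProfile


def profile(group_id, block_nfis):
    """GroupProfile from lectin -> block vector."""
    mean = {l: float(np.mean(v)) for l, v in block_nfis.items()}
    sd = {l: float(np.std(v, ddof=1)) for l, v in block_nfis.items()}
    n = len(next(iter(block_nfis.values())))
    return GroupProfile(group_id, mean, sd, n,
                        {l: tuple(v) for l, v in block_nfis.items()})


class TestTTest:
    def test_identical_vectors(self):
        assert t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_textbook_example_vs_scipy(self):
        t, p = t_test([1, 2, 3], [2, 3, 4])
        ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t == pytest.approx(float(ref.statistic), abs=1e-10)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_antisymmetry(self):
        t1, p1 = t_test([1, 5, 2], [4, 4, 6])
        t2, p2 = t_test([4, 4, 6], [1, 5, 2])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_random_instances_match_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 8))
            t, p = t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = t_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and t < 0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0])

    def test_scale_invariance(self):
        x, y = [0.1, 0.2, 0.35], [0.15, 0.3, 0.4]
        t1, p1 = t_test(x, y)
        t2, p2 = t_test([v * 7.3 for v in x], [v * 7.3 for v in y])
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)


class TestClassifyRatio:
    @pytest.mark.parametrize("ratio,expected", [
        (2.35, "up"),          # published SAD PSA ratio
        (0.61, "down"),        # published SAD WFA ratio
        (1.39, "unchanged"),   # DBA at 16 h
        (1.58, "up"),          # DBA at 48 h
        (1.5, "up"),           # inclusive boundary
        (0.67, "down"),        # inclusive boundary
        (1.49, "unchanged"),
        (0.68, "unchanged"),
        (1.0, "unchanged"),
    ])
    def test_directions(self, ratio, expected):
        assert classify_ratio(ratio) == expected

    def test_invalid_ratio_is_na(self):
        assert classify_ratio(float("nan")) == "na"
        assert classify_ratio(0.0) == "na"

    def test_custom_thresholds(self):
        assert classify_ratio(1.4, up=1.3) == "up"
        assert classify_ratio(0.68, down=0.7) == "down"


class TestCallLectin:
    def test_up_call_with_p_gate(self):
        m = profile("M", {"A": [0.32, 0.33, 0.31, 0.32]})
        c = profile("C", {"A": [0.20, 0.19, 0.21, 0.20]})
        call = call_lectin(m, c, "A")
        assert call.direction == "up"
        assert call.ratio == pytest.approx(1.6)
        assert call.p_value < 0.05

    def test_p_gate_blocks_noisy_call(self):
        m = profile("M", {"A": [0.10, 0.50, 0.30]})
        c = profile("C", {"A": [0.05, 0.35, 0.20]})
        gated = call_lectin(m, c, "A", p_gate="lt")
        ungated = call_lectin(m, c, "A", p_gate="off")
        assert ungated.direction == "up"
        assert gated.direction == "unchanged"

    def test_p_gate_gt_reading(self):
        m = profile("M", {"A": [0.10, 0.50, 0.30]})
        c = profile("C", {"A": [0.05, 0.35, 0.20]})
        assert call_lectin(m, c, "A", p_gate="gt").direction == "up"

    def test_zero_control_mean_raises(self):
        m = profile("M", {"A": [0.5, 0.5]})
        c = profile("C", {"A": [0.0, 0.0]})
        with pytest.raises(UndefinedRatioError):
            call_lectin(m, c, "A")

    def test_common_scaling_preserves_call(self):
        m = profile("M", {"A": [0.30, 0.31, 0.29]})
        c = profile("C", {"A": [0.20, 0.19, 0.21]})
        base = call_lectin(m, c, "A")
        k = 0.37
        m2 = profile("M", {"A": [v * k for v in [0.30, 0.31, 0.29]]})
        c2 = profile("C", {"A": [v * k for v in [0.20, 0.19, 0.21]]})
        scaled = call_lectin(m2, c2, "A")
        assert scaled.direction == base.direction
        assert scaled.ratio == pytest.approx(base.ratio)
        assert scaled.p_value == pytest.approx(base.p_value)


class TestCallTable:
    def test_null_table_has_no_calls(self, tiny_panel):
        m = profile("M", {l: [0.33, 0.34, 0.33] for l in tiny_panel.names})
        c = profile("C", {l: [0.33, 0.34, 0.33] for l in tiny_panel.names})
        calls = call_table({"M": m, "C": c}, [("M", "C")], tiny_panel)
        assert all(c.direction == "unchanged" for c in calls)

    def test_panel_order_is_stable(self, tiny_panel):
        m = profile("M", {l: [0.3, 0.31] for l in tiny_panel.names})
        c = profile("C", {l: [0.3, 0.31] for l in tiny_panel.names})
        calls = call_table({"M": m, "C": c}, [("M", "C")], tiny_panel)
        assert [c.lectin for c in calls] == list(tiny_panel.names)

    def test_unknown_contrast_group(self, tiny_panel):
        m = profile("M", {l: [0.3, 0.31] for l in tiny_panel.names})
        with pytest.raises(KeyError):
            call_table({"M": m}, [("M", "C")], tiny_panel)

    def test_missing_lectin_becomes_na_row(self, tiny_panel):
        m = profile("M", {"A": [0.5, 0.5], "B": [0.5, 0.5]})
        c = profile("C", {l: [0.33, 0.34] for l in tiny_panel.names})
        calls = call_table({"M": m, "C": c}, [("M", "C")], tiny_panel)
        assert {x.lectin: x.direction for x in calls}["C"] == "na"

    def test_specificity_carried_from_panel(self, tiny_panel):
        m = profile("M", {l: [0.3, 0.31] for l in tiny_panel.names})
        calls = call_table({"M": m, "C": m}, [("M", "C")], tiny_panel)
        assert calls[0].specificity == "Gal"


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 30))
            mine = benjamini_hochberg(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_adjusted_never_smaller(self):
        p = [0.01, 0.04, 0.03, 0.5]
        assert all(a >= b for a, b in zip(benjamini_hochberg(p), p))


class TestPublishedRatioCalls:
    """Fold-change-only calls re-derived from the bundled ratio tables."""

    def test_sad_counts(self, panel):
        calls = calls_from_ratios(sad_ratio_table(), SAD_CONTRAST, panel)
        up = [c.lectin for c in calls if c.direction == "up"]
        down = [c.lectin for c in calls if c.direction == "down"]
        assert up == ["PSA"]
        assert len(down) == 8
        assert set(down) == {"WFA", "PTL-I", "AAL", "PTL-II", "SBA", "UEA-I",
                             "PHA-E + L", "SNA"}

    def test_mcao_counts(self, panel):
        tables = mcao_ratio_tables()
        calls = (calls_from_ratios(tables[M16_CONTRAST], M16_CONTRAST, panel)
                 + calls_from_ratios(tables[M48_CONTRAST], M48_CONTRAST, panel))
        directions = collapse_directions(calls)
        sig = {l for l, d in directions.items() if d in ("up", "down")}
        assert len(sig) == 18
        up = {l for l, d in directions.items() if d == "up"}
        assert len(up) == 11
        # up-regulated only at 48 h
        m16 = {c.lectin: c.direction for c in calls if c.contrast == M16_CONTRAST}
        for lec in ("DBA", "PTL-II", "NPA", "SNA"):
            assert m16[lec] == "unchanged" and lec in up


class TestCompareModels:
    def test_identical_lists_have_no_opposites(self, panel):
        calls = calls_from_ratios(sad_ratio_table(), SAD_CONTRAST, panel)
        result = compare_models(calls, calls, panel)
        assert result.opposite_lectins == ()
        assert set(result.shared_lectins) == {c.lectin for c in calls
                                              if c.significant}

    def test_up_only_in_b_excluded_from_shared(self):
        a = [DifferentialCall("X", ("M", "C"), 1.0, None, "unchanged")]
        b = [DifferentialCall("X", ("M2", "C2"), 2.0, None, "up")]
        result = compare_models(a, b)
        assert result.shared_lectins == ()

    def test_opposite_requires_strictly_opposite(self):
        a = [DifferentialCall("X", ("M", "C"), 2.0, None, "up"),
             DifferentialCall("Y", ("M", "C"), 2.0, None, "up")]
        b = [DifferentialCall("X", ("M2", "C2"), 0.4, None, "down"),
             DifferentialCall("Y", ("M2", "C2"), 2.0, None, "up")]
        result = compare_models(a, b)
        assert result.shared_lectins == ("X", "Y")
        assert result.opposite_lectins == ("X",)

    def test_membership_symmetric_direction_antisymmetric(self, panel):
        tables = mcao_ratio_tables()
        calls_a = calls_from_ratios(sad_ratio_table(), SAD_CONTRAST, panel)
        calls_b = (calls_from_ratios(tables[M16_CONTRAST], M16_CONTRAST, panel)
                   + calls_from_ratios(tables[M48_CONTRAST], M48_CONTRAST, panel))
        fwd = compare_models(calls_a, calls_b, panel)
        rev = compare_models(calls_b, calls_a, panel)
        assert set(fwd.shared_lectins) == set(rev.shared_lectins)
        assert set(fwd.opposite_lectins) == set(rev.opposite_lectins)
        for lec in fwd.opposite_lectins:
            assert fwd.direction_a[lec] == rev.direction_b[lec]
            assert fwd.direction_b[lec] == rev.direction_a[lec]

    def test_disjoint_panels_rejected(self):
        a = [DifferentialCall("X", ("M", "C"), 2.0, None, "up")]
        b = [DifferentialCall("Y", ("M2", "C2"), 0.4, None, "down")]
        with pytest.raises(ValueError):
            compare_models(a, b)

    def test_mixed_direction_counts_as_shared_not_opposite(self):
        a = [DifferentialCall("X", ("M", "C"), 0.4, None, "down")]
        b = [DifferentialCall("X", ("M2", "C2"), 2.0, None, "up"),
             DifferentialCall("X", ("M3", "C2"), 0.4, None, "down")]
        result = compare_models(a, b)
        assert result.shared_lectins == ("X",)
        assert result.opposite_lectins == ()


class TestMotifSummary:
    def test_single_annotation(self):
        out = dict(motif_summary([LectinAnnotation("SNA", "Sia2-6Gal/GalNAc")]))
        assert out == {"Sia": 1, "Gal": 1, "GalNAc": 1}

    def test_longest_match_never_splits_galnac(self):
        out = dict(motif_summary([LectinAnnotation("X", "GalNAc")]))
        assert out == {"GalNAc": 1}

    def test_five_opposite_lectins_frozen_counts(self, panel):
        # Hand-tokenized over the five opposite-pattern lectins' strings:
        # Gal in 4 (WFA, PTL-I, PTL-II, SNA), GalNAc in 3 (WFA, PTL-I, SNA),
        # GlcNAc/Glc/Sia in 1 each.
        lectins = [panel.get(n) for n in
                   ("WFA", "PTL-I", "PTL-II", "PHA-E + L", "SNA")]
        out = motif_summary(lectins)
        assert out[0] == ("Gal", 4)
        assert out[1] == ("GalNAc", 3)
        assert dict(out) == {"Gal": 4, "GalNAc": 3, "GlcNAc": 1, "Glc": 1, "Sia": 1}

    def test_empty_specificity_contributes_nothing(self):
        assert motif_summary([LectinAnnotation("X", "")]) == []

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            motif_summary([])

    def test_count_is_per_lectin_not_per_occurrence(self):
        out = dict(motif_summary([LectinAnnotation("X", "Gal, Galβ1-3Gal")]))
        assert out == {"Gal": 1}
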