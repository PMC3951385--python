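"""Unit tests for efficiency-corrected quantification."""

import decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as r
from refstab.quantify import (
    FlatTraceError,
    InsufficientExponentialPhaseError,
    NoAmplificationError,
    ThresholdBelowBaselineError,
    plate_threshold,
)


def make_trace(fluo, gene="g", sample="s", well="w"):
    fluo = np.asarray(fluo, dtype=float)
    return r.FluorescenceTrace(
        well_id=well, gene=gene, sample=sample,
        cycles=np.arange(1, len(fluo) + 1, dtype=float), fluorescence=fluo,
    )


def sigmoid_trace(r0=1e-8, eff=1.0, plateau=3.0, n=40):
    c = np.arange(1, n + 1, dtype=float)
    g = r0 * (1 + eff) ** c
    return make_trace(plateau * (1 - np.exp(-g / plateau)))


class TestDetermineCt:
    def test_exact_crossing(self):
        fluo = np.zeros(30)
        fluo[19:] = 1.0  # cycle 20 reaches the threshold exactly
        assert r.determine_ct(make_trace(fluo), 1.0) == 20.0

    def test_linear_interpolation_midpoint(self):
        fluo = np.zeros(30)
        fluo[18] = 0.5
        fluo[19:] = 1.5
        assert r.determine_ct(make_trace(fluo), 1.0) == pytest.approx(19.5)

    def test_matches_dense_grid_oracle(self):
        trace = sigmoid_trace()
        threshold = 0.3
        # oracle: brute-force fine-grid linear interpolation of the trace,
        # coarse pass to bracket the crossing then a dense pass inside it
        k = int(np.argmax(trace.fluorescence >= threshold))
        grid = np.linspace(trace.cycles[k - 1], trace.cycles[k], 4_000_001)
        interp = np.interp(grid, trace.cycles, trace.fluorescence)
        expected = grid[np.argmax(interp >= threshold)]
        assert r.determine_ct(trace, threshold) == pytest.approx(expected, abs=1e-6)

    def test_never_reaches_threshold(self):
        with pytest.raises(NoAmplificationError):
            r.determine_ct(make_trace(np.linspace(0, 0.1, 30)), 5.0)

    def test_threshold_below_baseline(self):
        with pytest.raises(ThresholdBelowBaselineError):
            r.determine_ct(make_trace(np.linspace(1.0, 3.0, 30)), 0.5)


class TestFitEfficiency:
    def test_perfect_doubling(self):
        fluo = 1e-8 * 2.0 ** np.arange(1, 41)
        eff, window, r2 = r.fit_efficiency(make_trace(fluo))
        assert eff == pytest.approx(1.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_recovers_generating_gain_with_plateau(self):
        trace = sigmoid_trace(r0=2e-9, eff=0.9)
        eff, _, _ = r.fit_efficiency(trace)
        assert eff == pytest.approx(0.9, abs=0.02)

    def test_flat_trace_raises(self):
        with pytest.raises(FlatTraceError):
            r.fit_efficiency(make_trace(np.full(40, 2.0)))

    def test_insufficient_exponential_phase(self):
        # monotone decreasing after baseline: no growing positive window
        fluo = np.concatenate([np.full(10, 1.0), np.linspace(1.0, 0.0, 30)])
        with pytest.raises(InsufficientExponentialPhaseError):
            r.fit_efficiency(make_trace(fluo))


class TestComputeR0:
    def test_closed_form(self):
        assert r.compute_r0(10, 1.0, 1.0) == pytest.approx(2.0**-10)

    def test_zero_cycle_identity(self):
        assert r.compute_r0(0, 0.73, 0.2) == 0.2

    def test_against_arbitrary_precision_oracle(self):
        # eEF-1a primer efficiency, high-precision decimal evaluation
        with decimal.localcontext() as ctx:
            ctx.prec = 50
            expected = decimal.Decimal("0.2") * decimal.Decimal("2.028") ** -20
        got = r.compute_r0(20, 1.028, 0.2)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_rejects_nonpositive_r_ct(self):
        with pytest.raises(ValueError):
            r.compute_r0(10, 1.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ct=st.floats(0.0, 40.0),
        eff=st.floats(0.5, 1.2),
        r_ct=st.floats(1e-3, 10.0),
    )
    def test_round_trip_with_solve_ct(self, ct, eff, r_ct):
        r0 = r.compute_r0(ct, eff, r_ct)
        assert r.solve_ct(r0, eff, r_ct) == pytest.approx(ct, rel=1e-9, abs=1e-9)


class TestScaleInvariance:
    def test_scaling_fluorescence_scales_r0_only(self):
        trace = sigmoid_trace(r0=1e-8, eff=1.0)
        scaled = make_trace(trace.fluorescence * 37.0)
        thr = plate_threshold([trace])
        fit = r.fit_well(trace, thr)
        fit_scaled = r.fit_well(scaled, 37.0 * thr)
        assert fit_scaled.ct == pytest.approx(fit.ct, rel=1e-9)
        assert fit_scaled.efficiency == pytest.approx(fit.efficiency, rel=1e-9)
        assert fit_scaled.r0 == pytest.approx(37.0 * fit.r0, rel=1e-9)


def _fit(eff):
    return r.AmplificationFit(
        ct=20.0, efficiency=eff, r_ct=1.0,
        r0=r.compute_r0(20.0, eff, 1.0), fit_window=(10, 13), fit_r2=0.999,
    )


class TestDetectOutliers:
    def test_identical_efficiencies_no_flags(self):
        sets = [
            r.ReplicateSet("g", f"s{i}", [_fit(1.0)] * 3) for i in range(5)
        ]
        sets, _ = r.detect_outliers(sets)
        assert not any(any(s.outlier_flags) for s in sets)

    def test_single_low_well_flagged(self):
        # 5 groups of 3 wells at 1.00 +/- 0.005, one well at 0.70
        offsets = [-0.005, 0.0, 0.005]
        effs = [[1.0 + o for o in offsets] for _ in range(5)]
        effs[2][1] = 0.70
        sets = [
            r.ReplicateSet("g", f"s{i}", [_fit(e) for e in es])
            for i, es in enumerate(effs)
        ]
        sets, _ = r.detect_outliers(sets, alpha=0.05)
        flags = {(i, j) for i, s in enumerate(sets) for j, b in enumerate(s.outlier_flags) if b}
        assert flags == {(2, 1)}
        # after exclusion the groups are equivalent again
        f_stat, p, ok = r.efficiency_equivalence(sets)
        assert ok and p > 0.05

    def test_equivalence_anova_matches_hand_computation(self):
        # textbook one-way ANOVA on 3 groups of 3 efficiencies
        effs = [[0.95, 1.00, 1.05], [1.00, 1.05, 1.10], [0.90, 0.95, 1.00]]
        sets = [
            r.ReplicateSet("g", f"s{i}", [_fit(e) for e in es])
            for i, es in enumerate(effs)
        ]
        flat = [e for es in effs for e in es]
        grand = np.mean(flat)
        ss_between = sum(3 * (np.mean(es) - grand) ** 2 for es in effs)
        ss_within = sum((e - np.mean(es)) ** 2 for es in effs for e in es)
        f_hand = (ss_between / 2) / (ss_within / 6)
        f_stat, p, _ = r.efficiency_equivalence(sets)
        assert f_stat == pytest.approx(f_hand, rel=1e-12)

    def test_two_equal_groups_not_flagged(self):
        a = [_fit(e) for e in (0.98, 1.00, 1.02)]
        b = [_fit(e) for e in (1.02, 1.00, 0.98)]
        sets, _ = r.detect_outliers(
            [r.ReplicateSet("g", "s1", a), r.ReplicateSet("g", "s2", b)]
        )
        assert not any(any(s.outlier_flags) for s in sets)

    def test_singleton_group_warned_not_flagged(self):
        sets = [
            r.ReplicateSet("g", "s1", [_fit(1.0)]),
            r.ReplicateSet("g", "s2", [_fit(1.0), _fit(1.01)]),
            r.ReplicateSet("g", "s3", [_fit(0.99), _fit(1.0)]),
        ]
        sets, warnings = r.detect_outliers(sets)
        assert len(warnings) == 1 and "s1" in warnings[0]
        assert not any(any(s.outlier_flags) for s in sets)


class TestRelativeQuantities:
    def test_ratio_to_max(self):
        m = pd.DataFrame({"a": [2e-8], "b": [1e-8], "c": [5e-9]}, index=["g"])
        out = r.relative_quantities(m)
        assert out.loc["g"].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_single_sample_self_calibrates(self):
        m = pd.DataFrame({"a": [3.7e-9]}, index=["g"])
        assert r.relative_quantities(m).loc["g", "a"] == 1.0

    def test_elementwise_oracle(self, rng):
        m = pd.DataFrame(rng.uniform(0.1, 5.0, size=(6, 10)))
        out = r.relative_quantities(m)
        expected = m.to_numpy() / m.to_numpy().max(axis=1, keepdims=True)
        np.testing.assert_allclose(out.to_numpy(), expected, rtol=1e-12)
        assert np.allclose(out.max(axis=1), 1.0)

    def test_all_missing_gene_dropped(self):
        m = pd.DataFrame(
            {"a": [1.0, np.nan], "b": [2.0, np.nan]}, index=["g1", "g2"]
        )
        out = r.relative_quantities(m)
        assert list(out.index) == ["g1"]


class TestCtTablePath:
    def test_unit_r_ct_cancels_in_ratios(self):
        ct = pd.DataFrame(
            {
                "gene": ["g"] * 4,
                "sample": ["a", "a", "b", "b"],
                "ct": [20.0, 20.2, 22.0, 22.2],
            }
        )
        out = r.quantify_ct_table(ct, {"g": 1.0})
        rq = out.set_index("sample")["relative_quantity"]
        # sample b trails a by 2 cycles of doubling
        assert rq["a"] == 1.0
        assert rq["b"] == pytest.approx(2.0**-2.0, rel=1e-9)
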