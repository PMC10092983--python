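"""FPR estimation, the positive/trace/negative cascade, and LoD logic."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmrd import (
    CALL_NEGATIVE,
    CALL_POSITIVE,
    CALL_TRACE,
    AssayFPR,
    assess_lod,
    call_sample,
    call_target,
    estimate_fpr,
    merge_replicates,
)
from ddmrd.calling import TargetCall
from tests.conftest import make_classified

VD = 0.00085


def nc_estimate(events_total=0, n_wells=12, n_droplets=16000):
    wells = [
        make_classified(events_total if i == 0 else 0, n_droplets,
                        well_id=f"N{i}", role="NC_cfDNA")
        for i in range(n_wells)
    ]
    return merge_replicates(wells, "t1", VD)


class TestEstimateFPR:
    def test_clean_wells_give_zero(self):
        wells = [make_classified(0, 16000, well_id=f"N{i}", role="NC_cfDNA")
                 for i in range(12)]
        fpr = estimate_fpr(wells, "t1")
        assert fpr.fpr_events_per_well == 0
        assert fpr.display == "0.00"

    @pytest.mark.parametrize("events,shown", [(1, "0.08"), (19, "1.58")])
    def test_event_rate_display(self, events, shown):
        wells = [make_classified(events if i == 0 else 0, 16000,
                                 well_id=f"N{i}", role="NC_cfDNA") for i in range(12)]
        fpr = estimate_fpr(wells, "t1")
        assert fpr.fpr_events_per_well == Fraction(events, 12)
        assert fpr.display == shown

    def test_zero_wells_rejected(self):
        with pytest.raises(ValueError):
            estimate_fpr([], "t1")

    def test_events_per_ml_uses_configurable_factor(self):
        fpr = AssayFPR("t1", 1, 12)
        assert fpr.events_per_ml(1.375) == pytest.approx(1.375 / 12)


class TestCallTarget:
    def test_four_droplets_zero_fpr_overlapping_ci_is_trace(self):
        # 4 droplets in one of three wells: between-well scatter makes the
        # total-error interval include zero, overlapping the NC interval
        sample = merge_replicates(
            [make_classified(0, 16000, well_id="A"),
             make_classified(0, 16000, well_id="B"),
             make_classified(4, 16000, well_id="C")],
            "t1", VD,
        )
        call = call_target(sample, nc_estimate(), AssayFPR("t1", 0, 12))
        assert call.call == CALL_TRACE
        assert call.fam_droplets == 4 and not call.ci_nonoverlap

    def test_two_droplets_is_negative_regardless_of_fpr(self):
        sample = merge_replicates(
            [make_classified(0, 16000, well_id="A"),
             make_classified(2, 16000, well_id="B"),
             make_classified(0, 16000, well_id="C")],
            "t1", VD,
        )
        call = call_target(sample, nc_estimate(), AssayFPR("t1", 0, 12))
        assert call.call == CALL_NEGATIVE

    def test_many_droplets_vs_clean_nc_is_positive(self):
        sample = merge_replicates(
            [make_classified(200, 16000, well_id=f"W{i}") for i in range(3)],
            "t1", VD,
        )
        call = call_target(sample, nc_estimate(), AssayFPR("t1", 0, 12))
        assert call.call == CALL_POSITIVE and call.ci_nonoverlap

    def test_nonzero_fpr_downgrades_borderline_to_negative(self):
        sample = merge_replicates(
            [make_classified(0, 16000, well_id="A"),
             make_classified(0, 16000, well_id="B"),
             make_classified(4, 16000, well_id="C")],
            "t1", VD,
        )
        call = call_target(sample, nc_estimate(), AssayFPR("t1", 2, 12))
        assert call.call == CALL_NEGATIVE

    def test_ci_separation_tested_before_fpr_rule(self):
        # unambiguous positives are never downgraded by a non-zero FPR
        sample = merge_replicates(
            [make_classified(200, 16000, well_id=f"W{i}") for i in range(3)],
            "t1", VD,
        )
        call = call_target(sample, nc_estimate(), AssayFPR("t1", 19, 12))
        assert call.call == CALL_POSITIVE

    def test_missing_nc_estimate_rejected(self):
        sample = merge_replicates([make_classified(5, 16000)], "t1", VD)
        with pytest.raises(ValueError):
            call_target(sample, None, AssayFPR("t1", 0, 12))

    @given(
        k=st.integers(min_value=0, max_value=500),
        fpr_events=st.integers(min_value=0, max_value=19),
    )
    @settings(max_examples=60, derandomize=True)
    def test_cascade_is_total(self, k, fpr_events):
        sample = merge_replicates([make_classified(k, 16000)], "t1", VD)
        call = call_target(sample, nc_estimate(1), AssayFPR("t1", fpr_events, 12))
        assert call.call in (CALL_POSITIVE, CALL_TRACE, CALL_NEGATIVE)


def _tc(call):
    return TargetCall("t", 0, (0, 0), (0, 0), False, Fraction(0), call)


class TestCallSample:
    def test_any_positive_wins(self):
        assert call_sample([_tc(CALL_NEGATIVE), _tc(CALL_POSITIVE)]) == CALL_POSITIVE

    def test_trace_counts_as_detected(self):
        assert call_sample([_tc(CALL_NEGATIVE), _tc(CALL_TRACE)]) == CALL_TRACE

    def test_all_negative(self):
        assert call_sample([_tc(CALL_NEGATIVE)]) == CALL_NEGATIVE

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            call_sample([])


class TestAssessLoD:
    @pytest.mark.parametrize(
        "calls,lod",
        [
            (("positive", "positive", "negative", "negative"), 100),
            (("positive", "positive", "positive", "negative"), 10),
        ],
    )
    def test_lod_is_lowest_uninterrupted_positive(self, calls, lod):
        series = list(zip((1000, 100, 10, 1), calls))
        res = assess_lod(series, "t")
        assert res.lod_mass_pg == lod
        assert res.monotone

    def test_no_positive_step_reports_above_max(self):
        series = [(1000, "negative"), (100, "negative"), (10, "negative"), (1, "negative")]
        res = assess_lod(series, "t")
        assert res.lod_mass_pg is None
        assert res.display == "> 1000 pg"

    def test_non_monotone_series_flagged(self):
        series = [(1000, "positive"), (100, "negative"), (10, "positive"), (1, "negative")]
        res = assess_lod(series, "t")
        assert not res.monotone
        assert res.lod_mass_pg == 1000

    def test_trace_positive_does_not_count_as_detected(self):
        series = [(1000, "positive"), (100, "trace_positive"), (10, "negative"),
                  (1, "negative")]
        assert assess_lod(series, "t").lod_mass_pg == 1000

    def test_increasing_masses_rejected(self):
        with pytest.raises(ValueError):
            assess_lod([(10, "positive"), (100, "positive")], "t")

    def test_single_step_rejected(self):
        with pytest.raises(ValueError):
            assess_lod([(100, "positive")], "t")


def test_no_false_calls_without_injected_false_positives(small_spec, model1):
    """Simulated target-free samples never call positive on a clean assay."""
    from ddmrd import classify_droplets, derive_gates, simulate_well
    from ddmrd.simulate import simulate_control_wells

    controls = simulate_control_wells(["t1"], model1, small_spec, seed=0)
    gates = derive_gates(controls, ["t1"])
    nc = nc_estimate(0, 12, small_spec.n_droplets)
    fpr = AssayFPR("t1", 0, 12)
    vd = small_spec.droplet_volume_ul
    for seed in range(100):
        wells = [
            classify_droplets(
                simulate_well({"t1": 0.0}, 50.0, model1, small_spec, 7000 + 3 * seed + j),
                gates,
            )
            for j in range(3)
        ]
        est = merge_replicates(wells, "t1", vd)
        assert call_target(est, nc, fpr).call == CALL_NEGATIVE
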