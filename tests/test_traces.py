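"""Trace analysis: phase detrending, segmentation, deltas, classification."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvscan import synth
from guvscan.errors import AnalysisError, InputError
from guvscan.traces import (
    ScanTrace,
    SegmentationResult,
    classify,
    classify_sections,
    cohort_stats,
    detrend_phase,
    primary_delta,
    section_delta,
    segment,
)


def make_trace(mag, frequency=2.7e9, rate=500.0, phase_deg=0.0):
    mag = np.asarray(mag, float)
    t = np.arange(mag.size) / rate
    return ScanTrace(
        time_s=t,
        s21=mag * np.exp(1j * np.deg2rad(phase_deg)),
        frequency_hz=frequency,
        sample_rate_hz=rate,
    )


def step_trace(n=1500, lo=700, hi=1100, base=0.5, amp=9e-4, **kw):
    mag = np.full(n, base)
    mag[lo:hi] = base - amp
    return make_trace(mag, **kw)


class TestDetrendPhase:
    def test_zero_reference_is_identity(self):
        tr = make_trace(np.full(100, 0.5), phase_deg=25.0)
        assert np.allclose(detrend_phase(tr, 0.0), 25.0)

    def test_published_first_mode_reference_nulls_phase(self):
        tr = make_trace(np.full(100, 0.5), phase_deg=103.9)
        assert np.allclose(detrend_phase(tr, 103.9), 0.0, atol=1e-9)

    def test_second_mode_preset_baseline_centred_near_zero(self, bundle):
        tr = synth.gen_trace(bundle.trace_preset("SM", 7.9e9), seed=11)
        phi = detrend_phase(tr, bundle.theta0(7.9e9))
        # 339.88 deg is stored modulo 360; accept either unwrap branch
        centred = (np.median(phi) + 180.0) % 360.0 - 180.0
        assert abs(centred) < 1.0


class TestSegmentation:
    def test_noiseless_step_edges_recovered_exactly(self):
        tr = step_trace()
        res = segment(tr)
        plateaus = res.plateaus()
        assert len(plateaus) == 1
        assert plateaus[0].start_index == 700
        assert plateaus[0].end_index == 1100
        assert plateaus[0].delta_magnitude == pytest.approx(9e-4, rel=1e-12)

    @given(
        lo=st.integers(400, 700),
        width=st.integers(200, 440),
        amp=st.floats(4e-4, 20e-4),
    )
    @settings(deadline=None, max_examples=30)
    def test_noiseless_planted_step_property(self, lo, width, amp):
        tr = step_trace(lo=lo, hi=lo + width, amp=amp)
        res = segment(tr)
        plateaus = res.plateaus()
        assert len(plateaus) == 1
        assert abs(plateaus[0].start_index - lo) <= 1
        assert abs(plateaus[0].end_index - (lo + width)) <= 1

    def test_pure_noise_has_no_plateaus(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            mag = 0.5 + rng.normal(0, 0.5e-4, 1500)
            res = segment(make_trace(mag))
            assert res.plateaus() == []

    def test_constant_trace_is_single_baseline(self):
        res = segment(make_trace(np.full(1500, 0.5)))
        assert len(res.segments) == 1
        assert res.segments[0].kind == "baseline"

    def test_short_event_labelled_transient(self):
        tr = step_trace(lo=700, hi=760, amp=9e-4)  # 0.12 s < 0.3 s
        res = segment(tr)
        kinds = [s.kind for s in res.segments]
        assert "transient" in kinds and "plateau" not in kinds

    def test_segments_tile_the_trace(self):
        res = segment(step_trace())
        edges = [(s.start_index, s.end_index) for s in res.segments]
        assert edges[0][0] == 0 and edges[-1][1] == 1500
        for (a, b), (c, d) in zip(edges, edges[1:]):
            assert b == c

    def test_too_short_trace_rejected(self):
        with pytest.raises(InputError):
            segment(make_trace(np.full(100, 0.5)))


class TestSectionDelta:
    def test_zero_for_section_at_baseline_level(self):
        res = segment(step_trace())
        assert res.segments[0].delta_magnitude == 0.0

    def test_invariant_under_global_phase(self):
        tr = step_trace()
        rotated = dataclasses.replace(tr, s21=tr.s21 * np.exp(1j * 1.234))
        assert segment(rotated).deltas == pytest.approx(segment(tr).deltas, abs=1e-12)

    def test_missing_baseline_raises(self):
        tr = step_trace()
        res = SegmentationResult(segments=[], baseline_mean=0.0, baseline_sd=0.0)
        with pytest.raises(AnalysisError):
            section_delta(tr, res)

    def test_noisy_recovery_within_clt_bound(self):
        # planted amplitude recovered within 4 sigma / sqrt(m) for >= 99% seeds
        amp, noise = 9e-4, 0.5e-4
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mag = np.full(1500, 0.5)
            mag[700:1100] -= amp
            mag = mag + rng.normal(0, noise, 1500)
            res = segment(make_trace(mag))
            if res.plateaus():
                delta = primary_delta(res)
                m = res.plateaus()[0].end_index - res.plateaus()[0].start_index
                ok += abs(delta - amp) <= 4 * noise / np.sqrt(m)
        assert ok >= 99


class TestClassification:
    @pytest.mark.parametrize(
        "delta,frequency,expected",
        [
            (10.64e-4, 2.7e9, "SM-rich"),
            (7.32e-4, 2.7e9, "SM-rich"),
            (9.29e-4, 2.7e9, "SM-rich"),
            (7.91e-4, 7.9e9, "SM-rich"),
            (4.55e-4, 2.7e9, "POPC-rich"),
            (2.92e-4, 2.7e9, "POPC-rich"),
            (4.74e-4, 2.7e9, "POPC-rich"),
            (2.71e-4, 7.9e9, "POPC-rich"),
        ],
    )
    def test_published_two_domain_rows_classified_as_printed(self, delta, frequency, expected):
        assert classify(delta, frequency) == expected

    def test_published_cohort_means_classify_as_themselves(self, bundle):
        for lipid in ("SM", "POPC"):
            for f in (2.7e9, 7.9e9):
                mean, _ = bundle.delta_stats(lipid, f)
                assert classify(mean, f) == f"{lipid}-rich"

    def test_equal_z_scores_are_ambiguous(self, bundle):
        (mu_s, sd_s) = bundle.delta_stats("SM", 2.7e9)
        (mu_p, sd_p) = bundle.delta_stats("POPC", 2.7e9)
        # point between the means with z_SM == z_POPC
        d = (mu_s * sd_p + mu_p * sd_s) / (sd_s + sd_p)
        assert classify(d, 2.7e9) == "ambiguous"

    def test_unknown_frequency_rejected(self):
        with pytest.raises(InputError):
            classify(5e-4, 1.0e9)

    def test_classify_sections_fills_result(self, bundle):
        p1, p2 = bundle.two_domain_presets(0)
        tr = synth.gen_two_domain(p1, p2, 5)
        res = segment(tr)
        labels = classify_sections(tr, res)
        assert res.classifications == labels
        assert labels == ["SM-rich", "POPC-rich"]


class TestCohortStats:
    def test_hand_computed_example(self):
        st_ = cohort_stats([1.0, 2.0, 3.0])
        assert st_.mean == 2.0
        assert st_.err_plus == 1.0
        assert st_.err_minus == 1.0

    def test_degenerate_cohort(self):
        st_ = cohort_stats([5.0, 5.0, 5.0])
        assert st_.sd == 0.0
        assert st_.err_plus == 0.0
        assert st_.err_minus == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            cohort_stats([])

    @given(st.lists(st.floats(0.0, 1e-2), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_range_identity(self, values):
        st_ = cohort_stats(values)
        assert st_.err_plus + st_.err_minus == pytest.approx(max(values) - min(values), abs=1e-15)
        assert st_.err_plus >= 0 and st_.err_minus >= 0
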