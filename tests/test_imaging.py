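"""The quantification chain: background, spillover, iFRET, dF/F0, maxima."""

import numpy as np
import pandas as pd
import pytest

from ipcquant import (
    AnalysisWindows,
    DegenerateTraceError,
    RoiTraceSet,
    TreatmentDesign,
    ValidationError,
    background_correct,
    compute_ifret,
    delta_f_over_f,
    max_response,
    normalize_to_baseline,
    quantify_fret,
    spillover_correct,
    summarize_treatment,
)
from ipcquant.imaging import DEFAULT_SPILLOVER, NormalizedResponse

from conftest import make_trace_frames

WINDOWS = AnalysisWindows(baseline=(0.0, 15.0), long=(15.0, 100.0), short=(15.0, 40.0))


class TestBackgroundCorrect:
    def test_scalar_background(self):
        np.testing.assert_allclose(background_correct([100.0, 110.0], 10.0), [90.0, 100.0])

    def test_trace_background(self):
        out = background_correct([120.0, 130.0, 125.0], [20.0, 20.0, 20.0])
        np.testing.assert_allclose(out, [100.0, 110.0, 105.0])

    def test_all_zero_corrected_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            background_correct([100.0], [100.0])

    def test_partial_flooring_keeps_trace(self):
        out = background_correct([100.0, 5.0], [10.0, 10.0], epsilon=1e-9)
        assert out[0] == 90.0 and out[1] == 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            background_correct([1.0, 2.0], [1.0])


class TestSpillover:
    def test_default_constant(self):
        assert DEFAULT_SPILLOVER == 0.357

    def test_zero_cfp_identity(self):
        np.testing.assert_allclose(spillover_correct([100.0], [0.0]), [100.0])

    def test_direct_arithmetic(self):
        np.testing.assert_allclose(
            spillover_correct([120.0], [50.0], k=0.357), [120.0 - 17.85]
        )

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            spillover_correct([1.0], [1.0], k=1.0)


class TestIfret:
    def test_zero_numerator(self):
        ifret, valid = compute_ifret([0.0], [100.0])
        assert ifret[0] == 0.0 and valid[0]

    def test_direct_arithmetic(self):
        ifret, valid = compute_ifret([50.0], [120.0], k=0.357)
        np.testing.assert_allclose(ifret, [50.0 / 102.15], rtol=1e-12)

    def test_singular_denominator_marked_invalid(self):
        ifret, valid = compute_ifret([100.0], [35.7], k=0.357)
        assert not valid[0] and np.isnan(ifret[0])


class TestNormalize:
    def test_constant_trace_is_zero_percent(self):
        t = np.arange(6) * 5.0
        trace, mean = normalize_to_baseline(t, np.full(6, 0.7), WINDOWS)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)
        assert mean == pytest.approx(0.7)

    def test_percent_change_arithmetic(self):
        t = np.arange(6) * 5.0  # baseline frames at t=0,5,10
        signal = np.array([0.5, 0.5, 0.5, 0.5, 0.6, 0.45])
        trace, mean = normalize_to_baseline(t, signal, WINDOWS)
        np.testing.assert_allclose(trace[3:], [0.0, 20.0, -10.0], rtol=1e-12)
        assert mean == 0.5

    def test_baseline_mean_zero_percent_at_baseline_frames(self):
        rng = np.random.default_rng(0)
        t = np.arange(20) * 5.0
        signal = rng.uniform(0.4, 0.6, 20)
        trace, _ = normalize_to_baseline(t, signal, WINDOWS)
        in_baseline = t < 15.0
        assert abs(np.mean(trace[in_baseline])) < 1e-10

    def test_too_few_baseline_frames_rejects(self):
        t = np.array([0.0, 5.0, 20.0, 25.0])
        with pytest.raises(ValidationError, match="baseline"):
            normalize_to_baseline(t, np.ones(4), WINDOWS)

    def test_nonpositive_baseline_rejects(self):
        t = np.arange(6) * 5.0
        with pytest.raises(ValidationError, match="non-positive"):
            normalize_to_baseline(t, np.zeros(6) - 1.0, WINDOWS)


class TestMaxResponse:
    def test_flat_trace(self):
        t = np.arange(10) * 5.0
        assert max_response(t, np.zeros(10), (15.0, 45.0)) == 0.0

    def test_peak_inside_window(self):
        t = np.arange(10) * 5.0
        trace = np.zeros(10)
        trace[5] = 12.5
        trace[9] = 99.0  # outside the window
        assert max_response(t, trace, (15.0, 40.0)) == 12.5

    def test_empty_window_errors(self):
        t = np.arange(10) * 5.0
        with pytest.raises(ValidationError, match="window"):
            max_response(t, np.zeros(10), (200.0, 300.0))

    def test_window_nesting_long_dominates_short(self, rng):
        t = np.arange(50) * 5.0
        for _ in range(25):
            trace = rng.normal(0, 5, 50)
            long = max_response(t, trace, (15.0, 240.0))
            short = max_response(t, trace, (15.0, 60.0))
            assert long >= short


class TestDeltaFOverF:
    def test_equal_to_baseline_is_zero(self):
        t = np.arange(6) * 5.0
        trace, f0 = delta_f_over_f(np.full(6, 100.0), t, WINDOWS)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_ten_percent_rise(self):
        t = np.arange(6) * 5.0
        gfp = np.array([100.0, 100.0, 100.0, 100.0, 110.0, 100.0])
        trace, _ = delta_f_over_f(gfp, t, WINDOWS)
        assert trace[4] == pytest.approx(10.0, rel=1e-12)

    def test_extinction_bound(self):
        t = np.arange(6) * 5.0
        gfp = np.array([100.0, 100.0, 100.0, 0.0, 100.0, 100.0])
        trace, _ = delta_f_over_f(gfp, t, WINDOWS)
        assert trace[3] == pytest.approx(-100.0)


class TestQuantifyChain:
    def test_scale_invariance(self, rng):
        """Multiplying CFP, YFP and backgrounds by any c > 0 leaves the
        normalized iFRET trace unchanged."""
        df = make_trace_frames(n_rois=2, n_frames=20, with_background=True)
        base = RoiTraceSet(frames=df.copy(), application_time=15.0, frame_rate=0.2)
        res0 = quantify_fret(base, windows=WINDOWS)
        for c in (0.25, 7.3):
            scaled = df.copy()
            for col in ("cfp", "yfp", "bg_cfp", "bg_yfp"):
                scaled[col] = scaled[col] * c
            res_c = quantify_fret(
                RoiTraceSet(frames=scaled, application_time=15.0, frame_rate=0.2),
                windows=WINDOWS,
            )
            for r0, rc in zip(res0.responses, res_c.responses):
                np.testing.assert_allclose(rc.trace, r0.trace, atol=1e-10)
                assert rc.max_long == pytest.approx(r0.max_long, abs=1e-10)

    def test_roi_rejected_above_invalid_fraction(self):
        df = make_trace_frames(n_rois=1, n_frames=20)
        # force non-positive denominator on 3/20 = 15% of frames
        df.loc[df.index[5:8], "yfp"] = 0.357 * df.loc[df.index[5:8], "cfp"] - 1.0
        df["yfp"] = df["yfp"].clip(lower=0.0)
        ts = RoiTraceSet(frames=df, application_time=15.0, frame_rate=0.2)
        result = quantify_fret(ts, windows=WINDOWS)
        assert result.n_accepted == 0
        assert "denominator" in result.rejected[0][1]


class TestSummarize:
    @staticmethod
    def _response(roi, trace, treatment="PDF"):
        t = np.arange(len(trace)) * 5.0
        trace = np.asarray(trace, dtype=float)
        return NormalizedResponse(
            brain_id="b1", roi_id=roi, treatment=treatment, kind="iFRET",
            t=t, trace=trace, valid=np.isfinite(trace), baseline_mean=1.0,
            max_long=float(np.nanmax(trace)), max_short=float(np.nanmax(trace[:3])),
        )

    def test_identical_neurons_have_zero_sem(self):
        design = TreatmentDesign.from_labels(["PDF"], "PDF")
        responses = [self._response(f"r{i}", [0.0, 1.0, 2.0, 3.0]) for i in range(2)]
        summ = summarize_treatment(responses, design)[0]
        np.testing.assert_allclose(summ.sem, 0.0, atol=1e-14)

    def test_score_vector_mean_and_sem(self):
        design = TreatmentDesign.from_labels(["PDF"], "PDF")
        responses = [self._response(f"r{i}", [0.0, 0.0, v])
                     for i, v in enumerate([8.0, 10.0, 12.0])]
        summ = summarize_treatment(responses, design)[0]
        scores = summ.scores["long"]
        assert np.mean(scores) == pytest.approx(10.0)
        assert np.std(scores, ddof=1) / np.sqrt(3) == pytest.approx(2.0 / np.sqrt(3))

    def test_unequal_lengths_truncated_to_common_grid(self):
        design = TreatmentDesign.from_labels(["PDF"], "PDF")
        responses = [self._response("r1", [0.0, 1.0, 2.0]),
                     self._response("r2", [0.0, 1.0, 2.0, 3.0, 4.0])]
        summ = summarize_treatment(responses, design)[0]
        assert len(summ.t) == 3

    def test_unknown_treatment_rejected(self):
        design = TreatmentDesign.from_labels(["HL3"], "HL3")
        with pytest.raises(ValidationError, match="not part of the design"):
            summarize_treatment([self._response("r1", [0.0, 1.0], treatment="PDF")],
                                design)

    def test_empty_treatment_excluded_with_warning(self, caplog):
        design = TreatmentDesign.from_labels(["PDF", "HL3"], "HL3")
        responses = [self._response("r1", [0.0, 1.0, 2.0])]
        with caplog.at_level("WARNING"):
            summaries = summarize_treatment(responses, design)
        assert [s.treatment for s in summaries] == ["PDF"]
        assert any("no accepted neurons" in m for m in caplog.messages)
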