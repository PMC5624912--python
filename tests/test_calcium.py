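import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gangliotype.calcium import (
    CalciumTrace,
    StimulusEvent,
    StimulusSchedule,
    baseline_stats,
    call_response,
    cluster_responses,
    gaba_inhibition,
    peak_dff,
    qc_trace,
    read_schedule,
    read_traces,
    summarize_cell,
    summarize_recording,
    write_schedule,
    write_traces,
)
from gangliotype.cluster import ClusterAssignment, adjusted_rand_index
from gangliotype.simulate import TRACE_ARCHETYPES, default_schedule, simulate_traces


def _trace(values, period=1.5, cell="cell"):
    return CalciumTrace(cell, np.asarray(values, dtype=float), period)


class TestBaseline:
    def test_constant_baseline(self):
        trace = _trace([100.0] * 20)
        assert baseline_stats(trace, 10) == (100.0, 0.0)

    def test_alternating_baseline_matches_direct_formula(self):
        values = [90.0, 110.0] * 10
        trace = _trace(values)
        mean, sd = baseline_stats(trace, 10)
        window = np.array(values[:10])
        assert mean == pytest.approx(window.mean()) == 100.0
        assert sd == pytest.approx(window.std())

    def test_insufficient_prestimulus_frames_rejected(self):
        with pytest.raises(ValueError):
            baseline_stats(_trace([100.0] * 20), 5)


class TestPeakDff:
    def test_half_amplitude_peak(self):
        values = [100.0] * 12 + [150.0] + [100.0] * 30
        assert peak_dff(_trace(values), 12) == pytest.approx(0.5)

    def test_flat_trace_scores_zero(self):
        assert peak_dff(_trace([100.0] * 60), 12) == 0.0

    def test_peak_outside_40s_window_ignored(self):
        # in-window max 100 (dF/F 0), large peak parked 45 s post-onset
        period = 1.5
        onset = 12
        late = onset + math.ceil(45.0 / period)
        values = [100.0] * 80
        values[late] = 200.0
        assert peak_dff(_trace(values, period), onset) == pytest.approx(0.0)

    def test_window_exceeding_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            peak_dff(_trace([100.0] * 20), 12)

    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_uniform_scaling(self, scale):
        values = np.array([100.0] * 12 + [137.0] + [100.0] * 30)
        base = peak_dff(_trace(values), 12)
        scaled = peak_dff(_trace(values * scale), 12)
        assert scaled == pytest.approx(base, rel=1e-12)


class TestCallResponse:
    @pytest.mark.parametrize(
        "peak,noise,expected",
        [(0.5, 0.05, True), (0.25, 0.05, False), (0.01, 0.0, True)],
    )
    def test_five_sd_rule_strict(self, peak, noise, expected):
        assert call_response(peak, noise) is expected


class TestGabaInhibition:
    def test_abolished_response_is_full_inhibition(self):
        assert gaba_inhibition(0.0, 0.5, 0.5) == pytest.approx(100.0)

    def test_doubled_response_is_minus_hundred(self):
        assert gaba_inhibition(1.0, 0.5, 0.5) == pytest.approx(-100.0)

    def test_unchanged_response_is_zero(self):
        assert gaba_inhibition(0.7, 0.7, 0.7) == pytest.approx(0.0)

    def test_nonpositive_flank_rejected(self):
        with pytest.raises(ValueError):
            gaba_inhibition(0.5, 0.0, 0.0)

    @given(g=st.floats(0.0, 5.0), flank=st.floats(0.05, 3.0))
    def test_affine_in_gaba_peak_and_bounded_above(self, g, flank):
        inh = gaba_inhibition(g, flank, flank)
        assert inh <= 100.0 + 1e-9
        assert inh == pytest.approx(100.0 * (1.0 - g / flank), rel=1e-12)


class TestQC:
    def test_compliant_synthetic_trace_passes(self, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        ok, reasons = qc_trace(traces[0], schedule)
        assert ok and reasons == []

    def test_weak_kcl_response_fails_with_reason(self):
        schedule = default_schedule()
        rng = np.random.default_rng(0)
        n = schedule.events[-1].onset_frame + 40
        values = 100.0 + rng.normal(0, 2.0, n)  # noisy baseline, no responses
        ok, reasons = qc_trace(_trace(values), schedule)
        assert not ok
        assert "kcl_below_5sd" in reasons

    def test_baseline_ramp_fails_drift_check(self, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        n = traces[0].n_frames
        ramp = traces[0].fluorescence * np.linspace(1.0, 1.2, n)
        ok, reasons = qc_trace(_trace(ramp), schedule, drift_tolerance=0.10)
        assert not ok
        assert "baseline_drift" in reasons

    def test_schedule_without_kcl_rejected(self):
        schedule = StimulusSchedule([StimulusEvent("ATP", 12)])
        with pytest.raises(ValueError, match="KCl"):
            qc_trace(_trace([100.0] * 100), schedule)


class TestSummaries:
    def test_identical_blocks_mean_equals_single_block(self, noiseless_traces):
        traces, schedule, truth = noiseless_traces
        row = summarize_cell(traces[0], schedule)
        assert row["dff_atp_1"] == pytest.approx(row["dff_atp_2"], abs=1e-12)
        assert row["dff_atp_mean"] == pytest.approx(row["dff_atp_1"], abs=1e-12)
        assert row["inhibition_mean"] == pytest.approx(row["inhibition_1"], abs=1e-9)

    def test_replicate_mean_is_arithmetic(self):
        # build a trace whose two ATP responses differ: 0.4 and 0.6
        schedule = default_schedule()
        n = schedule.events[-1].onset_frame + 40
        values = np.full(n, 100.0)
        for b, amp in zip(schedule.blocks(), [0.4, 0.6]):
            for e in b:
                a = amp if e.name == "ATP" else 1.0 if "KCl" in e.name else 0.2
                values[e.onset_frame + 1] = 100.0 * (1 + a)
        row = summarize_cell(_trace(values), schedule)
        assert row["dff_atp_mean"] == pytest.approx(0.5)

    def test_inconsistent_replicates_flagged_and_excluded(self):
        schedule = default_schedule()
        n = schedule.events[-1].onset_frame + 40
        values = np.full(n, 100.0)
        blocks = schedule.blocks()
        for b, atp_amp in zip(blocks, [0.5, 0.0]):  # responds once only
            for e in b:
                amp = atp_amp if e.name == "ATP" else 1.0 if "KCl" in e.name else 0.0
                if amp:
                    values[e.onset_frame + 1] = 100.0 * (1 + amp)
        row = summarize_cell(_trace(values), schedule)
        assert row["consistent"] is False
        assert row["responds_atp"] is None
        table = summarize_recording([_trace(values, cell="odd")] * 1, schedule)
        consistent_rows = [
            _trace(np.full(n, 100.0) + 0, cell=f"ok{i}") for i in range(4)
        ]
        # flat cells fail QC (no KCl response) so clustering over this single
        # inconsistent cell must refuse
        with pytest.raises(ValueError):
            cluster_responses(table, k=1)

    def test_incomplete_block_lists_missing_events(self):
        schedule = default_schedule()
        partial = StimulusSchedule(schedule.events[:7])
        with pytest.raises(ValueError, match="missing"):
            summarize_cell(_trace([100.0] * 700), partial)


class TestClusterResponses:
    def test_planted_archetypes_recovered_exactly(self, noisy_traces):
        traces, schedule, truth = noisy_traces
        table = summarize_recording(traces, schedule)
        assign, _ = cluster_responses(table, k=4)
        ari = adjusted_rand_index(assign, ClusterAssignment(truth.cell_labels))
        assert ari == pytest.approx(1.0)

    def test_duplicated_rows_keep_cluster_structure(self, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        table = summarize_recording(traces, schedule)
        assign_a, _ = cluster_responses(table, k=4)
        doubled = table.copy()
        doubled["cell_id"] = doubled["cell_id"] + "_dup"
        import pandas as pd

        both = pd.concat([table, doubled], ignore_index=True)
        assign_b, _ = cluster_responses(both, k=4)
        for cell in table["cell_id"]:
            same = assign_b.labels[cell] == assign_b.labels[cell + "_dup"]
            assert same

    def test_identical_rows_warn_and_split_deterministically(self, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        table = summarize_recording(traces[:3], schedule)  # one archetype
        with pytest.warns(UserWarning, match="identical"):
            assign_a, _ = cluster_responses(table, k=2)
        with pytest.warns(UserWarning):
            assign_b, _ = cluster_responses(table, k=2)
        assert assign_a.labels == assign_b.labels

    def test_fewer_rows_than_k_rejected(self, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        table = summarize_recording(traces[:2], schedule)
        with pytest.raises(ValueError):
            cluster_responses(table, k=5)


class TestSimulatedRecovery:
    def test_noiseless_scores_equal_planted_values(self, noiseless_traces):
        traces, schedule, truth = noiseless_traces
        table = summarize_recording(traces, schedule).set_index("cell_id")
        for cell, planted in truth.trace_truth.items():
            assert table.loc[cell, "dff_atp_mean"] == pytest.approx(
                planted["dff_ATP"], abs=1e-9
            )
            assert table.loc[cell, "dff_5ht_mean"] == pytest.approx(
                planted["dff_5HT"], abs=1e-9
            )
            assert table.loc[cell, "inhibition_mean"] == pytest.approx(
                planted["inhibition_percent"], abs=1e-6
            )

    def test_planted_inhibition_levels_recovered_under_noise(self, noisy_traces):
        traces, schedule, truth = noisy_traces
        table = summarize_recording(traces, schedule).set_index("cell_id")
        for arch in TRACE_ARCHETYPES:
            cells = [c for c, l in truth.cell_labels.items() if l == arch]
            planted = truth.trace_truth[cells[0]]["inhibition_percent"]
            recovered = table.loc[cells, "inhibition_mean"].mean()
            assert recovered == pytest.approx(planted, abs=3.0)

    def test_response_calls_sensitive_and_specific(self, noisy_traces):
        traces, schedule, truth = noisy_traces
        table = summarize_recording(traces, schedule).set_index("cell_id")
        for stim, key in [("ATP", "responds_atp"), ("5HT", "responds_5ht")]:
            truth_key = f"responds_{stim}"
            pos = [c for c, t in truth.trace_truth.items() if t[truth_key]]
            neg = [c for c, t in truth.trace_truth.items() if not t[truth_key]]
            sens = np.mean([bool(table.loc[c, key]) for c in pos])
            fpr = np.mean([bool(table.loc[c, key]) for c in neg])
            assert sens >= 0.95
            assert fpr <= 0.05

    def test_extreme_planted_inhibition_anchors(self):
        traces, schedule, truth = simulate_traces(
            n_cells_per_archetype=1,
            noise_sd_over_f=0.0,
            inhibition_levels=(100.0, -100.0, 0.0, 50.0),
            seed=2,
        )
        table = summarize_recording(traces, schedule).set_index("cell_id")
        by_arch = {truth.cell_labels[c]: c for c in table.index}
        assert table.loc[by_arch["ATP_only"], "inhibition_mean"] == pytest.approx(100.0)
        assert table.loc[by_arch["ATP_5HT"], "inhibition_mean"] == pytest.approx(-100.0)
        assert table.loc[by_arch["5HT_only"], "inhibition_mean"] == pytest.approx(0.0)


class TestTraceIO:
    def test_traces_and_schedule_round_trip(self, tmp_path, noiseless_traces):
        traces, schedule, _ = noiseless_traces
        tp = write_traces(traces, tmp_path / "traces.csv")
        sp = write_schedule(schedule, tmp_path / "schedule.csv")
        back = read_traces(tp)
        assert [t.cell_id for t in back] == [t.cell_id for t in traces]
        np.testing.assert_allclose(
            back[0].fluorescence, traces[0].fluorescence, rtol=1e-7
        )
        assert back[0].frame_period_s == traces[0].frame_period_s
        sched = read_schedule(sp)
        assert [e.name for e in sched] == [e.name for e in schedule]

    def test_schedule_json_round_trip(self, tmp_path):
        schedule = default_schedule()
        p = write_schedule(schedule, tmp_path / "schedule.json")
        back = read_schedule(p)
        assert [(e.name, e.onset_frame) for e in back] == [
            (e.name, e.onset_frame) for e in schedule
        ]
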