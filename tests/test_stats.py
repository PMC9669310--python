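"""Pause-statistics battery: summaries, correlations, backward regression,
population aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from pkjpause import (
    PauseModel,
    Protocol,
    Trial,
    aggregate_population,
    backward_isi_regression,
    detect_all,
    generate_cell_recording,
    pairwise_correlations,
    summarize_cell,
)
from pkjpause.detector import PauseEstimate


def estimates_frame(onsets, offsets, detected=None):
    onsets = np.asarray(onsets, float)
    offsets = np.asarray(offsets, float)
    return pd.DataFrame(
        {
            "cell_id": "c",
            "trial_index": np.arange(onsets.size),
            "onset_s": onsets,
            "offset_s": offsets,
            "width_s": offsets - onsets,
            "longest_isi_s": offsets - onsets + 0.002,
            "abruptness_s": 0.0,
            "detected": True if detected is None else detected,
            "longest_isi_censored": False,
        }
    )


class TestSummarizeCell:
    def test_constant_latencies_zero_cov(self, protocol):
        s = summarize_cell(estimates_frame([0.1] * 6, [0.3] * 6), protocol)
        assert s.row("onset")["cov"] == pytest.approx(0.0, abs=1e-12)
        assert s.row("onset")["mean"] == pytest.approx(0.1)
        assert s.n_detected == 6

    def test_scale_invariance_of_cov(self, protocol, rng):
        on = rng.normal(0.1, 0.02, 50)
        df1 = estimates_frame(on, on + 0.2)
        df2 = estimates_frame(3 * on, 3 * on + 0.6)
        s1, s2 = summarize_cell(df1, protocol), summarize_cell(df2, protocol)
        assert s1.row("onset")["cov"] == pytest.approx(s2.row("onset")["cov"])
        assert s2.row("onset")["mean"] == pytest.approx(3 * s1.row("onset")["mean"])

    def test_quartiles_ordered(self, protocol, rng):
        s = summarize_cell(
            estimates_frame(rng.normal(0.1, 0.02, 40), rng.normal(0.3, 0.04, 40)),
            protocol,
        )
        r = s.row("width")
        assert r["q1"] <= r["q2"] <= r["q3"]

    def test_too_few_detected_errors(self, protocol):
        df = estimates_frame([0.1, 0.11], [0.3, 0.31], detected=[True, False])
        with pytest.raises(ValueError, match="detected"):
            summarize_cell(df, protocol)

    def test_ground_truth_cov_recovery(self, protocol):
        # scalar-variability closure: the battery recovers the generative CoV
        _, truth = generate_cell_recording(protocol, n_trials=200, seed=31)
        df = estimates_frame(truth.true_onset_s, truth.true_offset_s)
        s = summarize_cell(df, protocol)
        assert s.row("onset")["cov"] == pytest.approx(0.2, abs=0.03)
        assert s.row("offset")["cov"] == pytest.approx(0.15, abs=0.03)


class TestPairwiseCorrelations:
    def test_affine_coupling_gives_unit_correlation(self, rng):
        on = rng.normal(0.1, 0.02, 30)
        cs = pairwise_correlations(estimates_frame(on, on + 0.2))
        assert cs.correlations[("onset", "offset")] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        cs = pairwise_correlations(estimates_frame([0.1] * 5, [0.3, 0.31, 0.29, 0.3, 0.32]))
        assert math.isnan(cs.correlations[("onset", "offset")])

    def test_independent_draws_structure(self, protocol, rng):
        on = rng.normal(0.1, 0.02, 200)
        off = rng.normal(0.3, 0.045, 200)
        cs = pairwise_correlations(estimates_frame(on, off))
        assert abs(cs.correlations[("onset", "offset")]) < 0.15
        assert cs.correlations[("onset", "width")] < 0
        assert cs.correlations[("offset", "width")] > 0
        assert cs.correlations[("width", "longest_isi")] > 0.95

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            pairwise_correlations(estimates_frame([0.1, 0.2], [0.3, 0.4]))


class TestBackwardRegression:
    def make_trial(self, isis_ms, onset):
        # spikes from CS onset accumulating the given ISIs (time order)
        t = 0.004 + np.cumsum([0.0] + list(np.asarray(isis_ms) / 1000.0))
        pre = np.arange(-0.5, -0.005, 0.02)
        spikes = np.concatenate([pre, t])
        return Trial(spike_times=spikes, record_start=-0.6, record_end=1.0)

    def estimate(self, onset):
        return PauseEstimate(onset_latency=onset, abruptness=0.0)

    def test_constant_isis_flat_fit(self):
        trial = self.make_trial([10] * 6, onset=0.08)
        res = backward_isi_regression(trial, self.estimate(0.08))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared <= 0.05
        assert res.slope_ci_lower <= 0 <= res.slope_ci_upper
        assert res.n_isis == 6

    def test_increasing_isis_toward_pause_give_negative_slope(self):
        trial = self.make_trial([10, 12, 14, 16, 18], onset=0.09)
        res = backward_isi_regression(trial, self.estimate(0.09))
        assert res.slope < 0

    def test_below_interval_threshold_returns_none(self):
        trial = self.make_trial([10, 12, 14], onset=0.05)
        assert backward_isi_regression(trial, self.estimate(0.05)) is None

    def test_step_model_cis_mostly_contain_zero(self, protocol):
        rng = np.random.default_rng(21)
        contain = total = 0
        for _ in range(8):
            rec, _ = generate_cell_recording(protocol, n_trials=20, seed=rng)
            tab = detect_all(rec)
            for _, row in tab[tab.detected].iterrows():
                est = PauseEstimate(
                    onset_latency=row.onset_s, abruptness=row.abruptness_s
                )
                r = backward_isi_regression(rec.trials[int(row.trial_index)], est)
                if r is not None:
                    total += 1
                    contain += r.slope_ci_lower <= 0 <= r.slope_ci_upper
        assert total >= 20
        assert contain / total >= 0.7


class TestBookkeepingInvariants:
    def test_width_identity_and_pause_is_single_isi(self, probe_recording):
        rec, _ = probe_recording
        tab = detect_all(rec)
        d = tab[tab.detected]
        np.testing.assert_allclose(d.width_s, d.offset_s - d.onset_s, atol=1e-12)
        # single-long-ISI structure: W and M nearly coincide
        assert (d.longest_isi_s - d.width_s).abs().median() <= 2 / 60.0


class TestAggregatePopulation:
    def build(self, intervals, n_trials=60, seed=41):
        out = []
        for i, T in enumerate(intervals):
            proto = Protocol(cs_us_interval=T, cs_duration=T, iti=15)
            _, truth = generate_cell_recording(proto, n_trials=n_trials, seed=seed + i)
            df = estimates_frame(truth.true_onset_s, truth.true_offset_s)
            out.append(summarize_cell(df, proto))
        return out

    def test_group_means_scale_with_interval(self):
        summaries = self.build([0.15, 0.3])
        tables = aggregate_population(summaries)
        g = tables["group_means"]
        on = g[g.parameter == "onset"].sort_values("cs_us_interval")
        ratio = on.mean_of_means.iloc[1] / on.mean_of_means.iloc[0]
        assert ratio == pytest.approx(2.0, abs=0.25)

    def test_flat_cov_across_intervals(self):
        summaries = self.build([0.15, 0.3], n_trials=200)
        g = aggregate_population(summaries)["group_means"]
        on = g[g.parameter == "onset"]
        assert abs(on.mean_cov.iloc[0] - on.mean_cov.iloc[1]) < 0.05

    def test_single_cell_group_well_formed(self):
        tables = aggregate_population(self.build([0.3]))
        q = tables["quartile_cdfs"]
        assert set(q.parameter) == {"width", "longest_isi"}
        assert (q.q1 <= q.q2).all() and (q.q2 <= q.q3).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_population([])
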