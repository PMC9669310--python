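"""Bayesian change-point detector: priors, marginals, onset/offset
estimation, and the detection rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pkjpause import (
    CellRecording,
    MomentaryProbHistogram,
    Protocol,
    Trial,
    bernoulli_nochange_logmarginal,
    build_priors,
    detect_all,
    detect_pause,
    estimate_offset,
    estimate_onset,
    generate_cell_recording,
    one_change_logmarginal,
)
from pkjpause.detector import ChangeModelResult, DetectorPriors


def seq_logmarginal_oracle(bits, a, b):
    """Sequential-predictive route to the Beta-Bernoulli marginal."""
    logp = 0.0
    k = 0
    for t, x in enumerate(bits):
        p1 = (a + k) / (a + b + t)
        logp += math.log(p1 if x else 1 - p1)
        k += x
    return logp


def brute_force_one_change(bits, prior_before, prior_after):
    n = len(bits)
    joints = []
    for c in range(1, n):
        joints.append(
            -math.log(n - 1)
            + seq_logmarginal_oracle(bits[:c], *prior_before)
            + seq_logmarginal_oracle(bits[c:], *prior_after)
        )
    m = max(joints)
    return m + math.log(sum(math.exp(j - m) for j in joints))


def flat_priors(anchor=(0.15, 0.165), onset_anchor=None, **kw):
    return DetectorPriors(
        anchor_bin=anchor,
        p_low=0.0,
        p_pre=0.06,
        onset_anchor_bin=onset_anchor,
        **kw,
    )


class TestBuildPriors:
    def test_hand_example(self):
        proto = Protocol(cs_us_interval=0.03, cs_duration=0.03, iti=15)
        h = MomentaryProbHistogram(
            bin_edges=np.array([-0.03, -0.015, 0.0, 0.015, 0.03]),
            probs=np.array([0.06, 0.05, 0.01, 0.04]),
            n_trials=10,
        )
        pri = build_priors(h, proto)
        assert pri.anchor_bin == (0.0, 0.015)
        assert pri.p_low == pytest.approx(0.01)
        assert pri.p_pre == pytest.approx(0.055)

    def test_flat_histogram_tiebreaks_per_direction(self):
        proto = Protocol(cs_us_interval=0.045, cs_duration=0.045, iti=15)
        h = MomentaryProbHistogram(
            bin_edges=np.array([-0.03, -0.015, 0.0, 0.015, 0.03, 0.045]),
            probs=np.array([0.05, 0.05, 0.05, 0.05, 0.05]),
            n_trials=10,
        )
        pri = build_priors(h, proto)
        assert pri.anchor_bin == (0.0, 0.015)  # earliest minimal: offset side
        assert pri.onset_anchor_bin == (0.03, 0.045)  # latest minimal: onset side
        assert pri.p_low == pri.p_pre

    def test_anchor_is_global_in_cs_minimum(self, probe_recording):
        from pkjpause import peri_cs_histogram

        rec, _ = probe_recording
        h = peri_cs_histogram(rec)
        pri = build_priors(h, rec.protocol)
        left = h.bin_edges[:-1]
        in_cs = (left >= -1e-9) & (h.bin_edges[1:] <= 0.3 + 1e-9)
        assert pri.p_low <= h.probs[in_cs].min() + 1e-12

    def test_silent_pre_cs_errors(self):
        proto = Protocol(cs_us_interval=0.03, cs_duration=0.03, iti=15)
        h = MomentaryProbHistogram(
            bin_edges=np.array([-0.015, 0.0, 0.015]),
            probs=np.array([0.0, 0.05]),
            n_trials=10,
        )
        with pytest.raises(ValueError, match="uninformative"):
            build_priors(h, proto)


class TestNoChangeMarginal:
    def test_single_one_uniform_prior(self):
        assert bernoulli_nochange_logmarginal([1], (1.0, 1.0)) == pytest.approx(
            math.log(0.5)
        )

    def test_one_zero_uniform_prior(self):
        # integral of p(1-p) over [0,1] = 1/6
        assert bernoulli_nochange_logmarginal([1, 0], (1.0, 1.0)) == pytest.approx(
            math.log(1 / 6)
        )

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=30),
        st.floats(0.2, 20.0),
        st.floats(0.2, 20.0),
    )
    def test_permutation_invariance_and_oracle(self, bits, a, b):
        lm = bernoulli_nochange_logmarginal(bits, (a, b))
        assert lm == pytest.approx(seq_logmarginal_oracle(bits, a, b), abs=1e-10)
        assert lm == pytest.approx(
            bernoulli_nochange_logmarginal(bits[::-1], (a, b)), abs=1e-12
        )


class TestOneChangeMarginal:
    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=12),
        st.floats(0.3, 5.0),
        st.floats(0.3, 5.0),
        st.floats(0.3, 5.0),
        st.floats(0.3, 5.0),
    )
    def test_matches_brute_force(self, bits, a1, b1, a2, b2):
        res = one_change_logmarginal(bits, (a1, b1), (a2, b2))
        expect = brute_force_one_change(bits, (a1, b1), (a2, b2))
        assert res.log_marginal_change == pytest.approx(expect, abs=1e-10)

    def test_clean_step_found_with_strong_evidence(self):
        bits = [0] * 30 + [1] * 30
        res = one_change_logmarginal(bits, (1.0, 1.0), (1.0, 1.0))
        assert res.map_location == 30
        assert res.weight_of_evidence > 1.0

    def test_iid_bits_give_no_evidence_in_median(self, rng):
        pri_low, pri_high = (0.5, 300.5), (18.5, 282.5)
        woes = []
        for _ in range(120):
            bits = (rng.random(300) < 0.06).astype(int)
            res = one_change_logmarginal(bits, pri_low, pri_high)
            woes.append(res.weight_of_evidence)
        assert np.median(woes) <= 0.0

    def test_weight_of_evidence_odds_semantics(self):
        res = ChangeModelResult(
            log_marginal_nochange=-5.0,
            log_marginal_change=-5.0 + math.log(10),
            map_location=1,
            posterior_over_locations=np.array([1.0]),
            rate_before=0.0,
            rate_after=0.0,
        )
        assert res.weight_of_evidence == pytest.approx(1.0)

    def test_map_tie_breaks_toward_anchor_end(self):
        # all-equal bits with identical priors: every split ties -> smallest c
        res = one_change_logmarginal([0, 0, 0, 0], (2.0, 2.0), (2.0, 2.0))
        assert res.map_location == 1

    def test_posterior_normalized(self):
        res = one_change_logmarginal([0, 1, 0, 1, 1], (1.0, 3.0), (3.0, 1.0))
        assert res.posterior_over_locations.sum() == pytest.approx(1.0)

    def test_degenerate_location_prior_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_change_logmarginal([0, 1], (1, 1), (1, 1), location_prior=np.array([0.0]))


def carved_trial(gap=(0.1, 0.3), isi=0.008, span=(-0.5, 1.0)):
    t = np.arange(span[0], span[1], isi)
    t = t[(t < gap[0]) | (t > gap[1])]
    return Trial(spike_times=t, record_start=span[0], record_end=span[1])


class TestOnsetOffset:
    def test_onset_lands_at_gap_start(self):
        pri = flat_priors(anchor=(0.18, 0.195))
        res, lat = estimate_onset(carved_trial(), pri)
        assert res is not None
        assert res.weight_of_evidence > 1
        assert abs(lat - 0.1) < 0.01

    def test_offset_lands_at_gap_end(self):
        pri = flat_priors(anchor=(0.15, 0.165))
        res, lat = estimate_offset(carved_trial(), pri, T=0.3)
        assert res is not None
        assert res.weight_of_evidence > 1
        assert abs(lat - 0.3) < 0.01

    def test_negative_onset_when_pause_supervenes(self):
        # spontaneous silence begins at -0.02; conditional gap continues it
        t = np.concatenate([np.arange(-0.5, -0.02, 0.012), np.arange(0.31, 1.0, 0.012)])
        trial = Trial(spike_times=t, record_start=-0.5, record_end=1.0)
        pri = flat_priors(anchor=(0.15, 0.165))
        res, lat = estimate_onset(trial, pri)
        assert lat < 0

    def test_no_spikes_means_undefined_evidence(self):
        trial = Trial(spike_times=np.array([]), record_start=-0.5, record_end=1.0)
        res, lat = estimate_onset(trial, flat_priors())
        assert res is None and math.isnan(lat)

    def test_silent_to_window_end_offset_undetected(self):
        t = np.arange(-0.5, 0.1, 0.012)
        trial = Trial(spike_times=t, record_start=-0.5, record_end=1.0)
        res, lat = estimate_offset(trial, flat_priors(), T=0.3)
        assert res is None and math.isnan(lat)

    def test_offset_recovery_at_short_interval(self):
        # offset_fraction 1.0 at T = 0.2: detected-offset median near 0.2
        proto = Protocol(cs_us_interval=0.2, cs_duration=0.2, iti=15)
        rng = np.random.default_rng(42)
        offs = []
        from pkjpause import peri_cs_histogram

        for _ in range(6):
            rec, _ = generate_cell_recording(proto, n_trials=20, seed=rng)
            pri = build_priors(peri_cs_histogram(rec), proto)
            for tr in rec.trials:
                r, lat = estimate_offset(tr, pri, T=0.2)
                if r is not None and r.weight_of_evidence > 1 and r.rate_after > r.rate_before:
                    offs.append(lat)
        assert len(offs) > 30
        assert 0.19 < np.median(offs) < 0.245


class TestDetectPause:
    def test_clean_pause_width_and_longest_isi(self):
        pri = flat_priors(anchor=(0.15, 0.165), onset_anchor=(0.18, 0.195))
        est = detect_pause(carved_trial(), pri, T=0.3)
        assert est.detected
        assert est.width == pytest.approx(0.2, abs=0.02)
        assert est.longest_isi == pytest.approx(est.width, abs=0.03)
        assert est.abruptness == pytest.approx(0.0, abs=0.02)

    def test_rate_increase_is_never_detected(self):
        # firing accelerates during the CS: strong change, wrong sign
        t = np.concatenate([np.arange(-0.5, 0.0, 0.025), np.arange(0.0, 1.0, 0.004)])
        trial = Trial(spike_times=t, record_start=-0.5, record_end=1.0)
        est = detect_pause(trial, flat_priors(), T=0.3)
        assert not est.detected

    def test_infinite_threshold_detects_nothing(self):
        pri = flat_priors(anchor=(0.15, 0.165), onset_anchor=(0.18, 0.195))
        est = detect_pause(carved_trial(), pri, evidence_threshold=math.inf, T=0.3)
        assert not est.detected


class TestDetectAll:
    def test_probe_recovery_rate_and_rows(self, probe_recording):
        rec, truth = probe_recording
        tab = detect_all(rec)
        assert len(tab) == 20
        assert tab["detected"].mean() >= 0.6  # single cell; population level ~0.8

    def test_determinism(self, probe_recording):
        rec, _ = probe_recording
        t1, t2 = detect_all(rec), detect_all(rec)
        assert t1.equals(t2)

    def test_width_monotone_in_injected_width(self, protocol):
        from pkjpause import PauseModel

        medians = []
        for frac in (0.85, 1.0):
            rng = np.random.default_rng(9)
            widths = []
            for _ in range(6):
                rec, _ = generate_cell_recording(
                    protocol, pause=PauseModel(offset_fraction=frac), n_trials=20, seed=rng
                )
                tab = detect_all(rec)
                widths += list(tab[tab.detected].width_s)
            medians.append(np.median(widths))
        assert medians[0] < medians[1]

    def test_negative_onsets_emerge_with_heavy_tails(self):
        from pkjpause import SpontaneousModel

        proto = Protocol(cs_us_interval=0.15, cs_duration=0.15, iti=15)
        spont = SpontaneousModel(tail_mix=0.12, tail_median=0.05, rate_cov_between_trials=0.0)
        rng = np.random.default_rng(42)
        neg = tot = 0
        for _ in range(10):
            rec, _ = generate_cell_recording(proto, spontaneous=spont, n_trials=20, seed=rng)
            d = detect_all(rec)
            d = d[d.detected]
            tot += len(d)
            neg += int((d.onset_s < 0).sum())
        assert tot > 0 and neg > 0
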