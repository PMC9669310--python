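"""Bayesian single-trial estimation of pause onset and offset.

The detector treats a trial's binarized spike train (one bit per 1-ms
moment) as a Bernoulli sequence and compares two conjugate models:

* **no-change** — the momentary spike probability is constant over the
  sequence, with a Beta prior on that probability;
* **one-change** — the probability steps once, from a "pause" level to the
  background level, with independent Beta priors on the two segment
  probabilities and a prior over the step location.

Both marginal likelihoods are exact Beta-Bernoulli integrals.  The weight
of evidence is the base-10 log of the Bayes factor (one-change vs
no-change): a weight of 1 corresponds to 10:1 odds in favor of a step, 2
to 100:1, and so on.

For the **onset**, the sequence is read *backward* (the retrospective
sequence) from the anchor — the midpoint of the 15-ms bin of the peri-CS
histogram where the momentary probability is minimal — so that the step is
an increase from the in-pause probability toward the pre-CS probability.
For the **offset**, the mirrored construction runs forward from the anchor.
A pause is scored as detected only when the evidence for the onset step
exceeds the threshold *and* the estimated pre-CS-side probability exceeds
the in-pause probability (on rare anomalous trials the rate rises during
the CS; no pause is detected there, however strong the evidence of a
change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from .core import (
    MOMENT_WIDTH,
    CellRecording,
    MomentaryProbHistogram,
    Protocol,
    Trial,
    binarize,
    interspike_intervals,
    peri_cs_histogram,
)

__all__ = [
    "DetectorPriors",
    "ChangeModelResult",
    "PauseEstimate",
    "build_priors",
    "bernoulli_nochange_logmarginal",
    "one_change_logmarginal",
    "estimate_onset",
    "estimate_offset",
    "detect_pause",
    "detect_all",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class DetectorPriors:
    """Histogram-derived quantities parameterizing the change-point priors.

    ``anchor_bin`` is the (start, end) of the minimum-probability 15-ms bin
    within the CS-US interval; ``p_low`` the momentary probability there;
    ``p_pre`` the mean pre-CS momentary probability.  ``pseudo_count`` is
    the strength (in pseudo-moments) of the Beta priors
    ``Beta(k*p + eps, k*(1-p) + eps)``.
    """

    anchor_bin: tuple[float, float]
    p_low: float
    p_pre: float
    pseudo_count: float = 300.0
    epsilon: float = 0.5
    lookback: float = 0.3
    lookahead: Optional[float] = None
    onset_anchor_bin: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if self.onset_anchor_bin is None:
            object.__setattr__(self, "onset_anchor_bin", self.anchor_bin)

    @property
    def anchor_mid(self) -> float:
        return 0.5 * (self.anchor_bin[0] + self.anchor_bin[1])

    @property
    def onset_anchor_mid(self) -> float:
        return 0.5 * (self.onset_anchor_bin[0] + self.onset_anchor_bin[1])

    def beta_params(self, p: float) -> tuple[float, float]:
        return (
            self.pseudo_count * p + self.epsilon,
            self.pseudo_count * (1.0 - p) + self.epsilon,
        )

    @property
    def low_prior(self) -> tuple[float, float]:
        return self.beta_params(self.p_low)

    @property
    def pre_prior(self) -> tuple[float, float]:
        return self.beta_params(self.p_pre)


@dataclass(frozen=True)
class ChangeModelResult:
    """Outcome of the one-change vs no-change comparison on one sequence."""

    log_marginal_nochange: float
    log_marginal_change: float
    map_location: int
    posterior_over_locations: np.ndarray
    rate_before: float
    rate_after: float

    @property
    def weight_of_evidence(self) -> float:
        """log10 Bayes factor, one-change over no-change."""
        return (self.log_marginal_change - self.log_marginal_nochange) / LN10


@dataclass
class PauseEstimate:
    """Per-trial pause parameters.

    ``onset_latency`` (up-arrow in the figures) may be negative when the
    conditional shutdown supervenes on a spontaneous long ISI that began
    before CS onset.  ``longest_isi`` (M, the pause depth) is the longest
    interspike interval intersecting ``[onset, offset]``; ``abruptness`` is
    the latency from pause onset to the start of that interval.
    """

    trial_index: int = -1
    onset_latency: float = math.nan
    offset_latency: float = math.nan
    width: float = math.nan
    longest_isi: float = math.nan
    abruptness: float = math.nan
    onset_evidence: float = math.nan
    offset_evidence: float = math.nan
    rate_pre: float = math.nan
    rate_pause: float = math.nan
    detected: bool = False
    onset_detected: bool = False
    offset_detected: bool = False
    longest_isi_censored: bool = False


def build_priors(
    histogram: MomentaryProbHistogram,
    protocol: Protocol,
    pseudo_count: float = 300.0,
    epsilon: float = 0.5,
    lookback: float = 0.3,
    lookahead: Optional[float] = None,
) -> DetectorPriors:
    """Derive detector priors from the peri-CS histogram.

    The anchor is the lowest bin whose span lies within ``(0, T]``;
    ``p_low`` is its height and ``p_pre`` the mean height of the bins left
    of CS onset.  With small trial counts the minimum is typically a
    plateau of equal (often zero-count) bins; ties are resolved
    per direction: the canonical ``anchor_bin`` (used by the forward,
    offset-side sequence) is the *earliest* minimal bin, while
    ``onset_anchor_bin`` (the retrospective sequence's origin) is the
    *latest* minimal bin, so that each sequence spans as much of the pause
    as the histogram can vouch for.  With a unique minimum the two
    coincide.
    """
    T = protocol.cs_us_interval
    left = histogram.bin_edges[:-1]
    right = histogram.bin_edges[1:]
    tol = MOMENT_WIDTH
    in_cs = (left >= -tol) & (right <= T + tol) & (right > 0)
    pre = right <= tol
    if not in_cs.any():
        raise ValueError("histogram has no bins within (0, T]")
    if not pre.any():
        raise ValueError("histogram has no pre-CS bins")
    p_pre = float(histogram.probs[pre].mean())
    if p_pre <= 0:
        raise ValueError("pre-CS region is silent; priors would be uninformative")
    cs_probs = histogram.probs[in_cs]
    cs_all = np.flatnonzero(in_cs)
    minimal = cs_all[cs_probs <= cs_probs.min() + 1e-12]
    first, last = int(minimal[0]), int(minimal[-1])
    return DetectorPriors(
        anchor_bin=(float(left[first]), float(right[first])),
        p_low=float(histogram.probs[first]),
        p_pre=p_pre,
        pseudo_count=pseudo_count,
        epsilon=epsilon,
        lookback=lookback,
        lookahead=lookahead,
        onset_anchor_bin=(float(left[last]), float(right[last])),
    )


def bernoulli_nochange_logmarginal(
    bits: Sequence[int], prior: tuple[float, float]
) -> float:
    """Exact log marginal of a Bernoulli sequence under a Beta prior.

    ``log B(a + k, b + n - k) - log B(a, b)`` with ``k`` ones in ``n``
    bits; exchangeable, so invariant to permutations of the sequence.
    """
    bits = np.asarray(bits)
    if bits.size == 0:
        raise ValueError("empty sequence")
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    k = int(bits.sum())
    n = int(bits.size)
    return float(betaln(a + k, b + n - k) - betaln(a, b))


def one_change_logmarginal(
    bits: Sequence[int],
    prior_before: tuple[float, float],
    prior_after: tuple[float, float],
    location_prior: Optional[np.ndarray] = None,
    nochange_prior: Optional[tuple[float, float]] = None,
) -> ChangeModelResult:
    """Exact one-change Beta-Bernoulli marginal with a prior over locations.

    A split at location ``c`` (``1 <= c <= n-1``) puts ``bits[:c]`` under
    ``prior_before`` and ``bits[c:]`` under ``prior_after``.  The change
    marginal sums the per-location joints over the location prior (default
    uniform); the MAP location is the argmax, ties broken toward the
    smallest ``c`` (the end of the sequence nearest the anchor, for the
    retrospective/forward constructions).  The no-change marginal uses
    ``nochange_prior`` (default: ``prior_after``, the background side).
    """
    bits = np.asarray(bits, dtype=np.int64)
    n = bits.size
    if n < 2:
        raise ValueError("need a sequence of length >= 2")
    a1, b1 = prior_before
    a2, b2 = prior_after
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("Beta parameters must be positive")
    if location_prior is None:
        log_loc = np.full(n - 1, -math.log(n - 1))
    else:
        location_prior = np.asarray(location_prior, dtype=float)
        if location_prior.shape != (n - 1,) or np.any(location_prior < 0):
            raise ValueError("location prior must be nonnegative with length n-1")
        tot = location_prior.sum()
        if tot <= 0:
            raise ValueError("location prior is degenerate (all zero)")
        with np.errstate(divide="ignore"):
            log_loc = np.log(location_prior / tot)

    cum = np.concatenate([[0], np.cumsum(bits)])
    k_tot = cum[-1]
    c = np.arange(1, n)
    k1 = cum[c]
    k2 = k_tot - k1
    seg1 = betaln(a1 + k1, b1 + c - k1) - betaln(a1, b1)
    seg2 = betaln(a2 + k2, b2 + (n - c) - k2) - betaln(a2, b2)
    joint = log_loc + seg1 + seg2
    log_marginal_change = float(logsumexp(joint))
    map_idx = int(np.argmax(joint))  # first max -> smallest c
    c_map = map_idx + 1
    with np.errstate(under="ignore"):
        posterior = np.exp(joint - log_marginal_change)
    posterior /= posterior.sum()
    if nochange_prior is None:
        nochange_prior = prior_after
    log_marginal_nochange = bernoulli_nochange_logmarginal(bits, nochange_prior)
    rate_before = (a1 + k1[map_idx]) / (a1 + b1 + c_map)
    rate_after = (a2 + k2[map_idx]) / (a2 + b2 + (n - c_map))
    return ChangeModelResult(
        log_marginal_nochange=log_marginal_nochange,
        log_marginal_change=log_marginal_change,
        map_location=c_map,
        posterior_over_locations=posterior,
        rate_before=float(rate_before),
        rate_after=float(rate_after),
    )


def _window_bits(
    trial: Trial, start: float, end: float
) -> tuple[np.ndarray, float, float]:
    start = max(start, trial.record_start)
    end = min(end, trial.record_end)
    return binarize(trial, start, end).bits, start, end


def estimate_onset(
    trial: Trial, priors: DetectorPriors
) -> tuple[Optional[ChangeModelResult], float]:
    """Estimate pause-onset latency on the retrospective sequence.

    Binarizes ``[-lookback, onset_anchor_mid)``, reverses it so that index 0 is
    the moment just before the anchor, and finds the step from the
    in-pause probability (``p_low`` prior) up to the pre-CS probability
    (``p_pre`` prior).  The MAP step at retrospective location ``c`` maps to
    trial time ``anchor_mid - c * 1 ms``; the latency may be negative.

    Returns ``(result, latency)``; ``(None, nan)`` when the window holds no
    spikes (evidence undefined).
    """
    bits, start, end = _window_bits(trial, -priors.lookback, priors.onset_anchor_mid)
    if bits.sum() == 0 or bits.size < 2:
        return None, math.nan
    retro = bits[::-1]
    res = one_change_logmarginal(
        retro,
        prior_before=priors.low_prior,
        prior_after=priors.pre_prior,
        nochange_prior=priors.pre_prior,
    )
    latency = end - res.map_location * MOMENT_WIDTH
    return res, float(latency)


def estimate_offset(
    trial: Trial, priors: DetectorPriors, T: Optional[float] = None
) -> tuple[Optional[ChangeModelResult], float]:
    """Mirror of :func:`estimate_onset` on the forward sequence.

    The forward window runs from the anchor midpoint to
    ``anchor_mid + lookahead`` (default: to ``min(record_end, T + 0.7 s)``
    when the CS-US interval ``T`` is given, else to the record end).  The
    step is from the in-pause probability up to the resumed background
    probability; the MAP step at forward location ``c`` maps to
    ``anchor_mid + c * 1 ms``.
    """
    if priors.lookahead is not None:
        end = priors.anchor_mid + priors.lookahead
    elif T is not None:
        end = min(trial.record_end, T + 0.7)
    else:
        end = trial.record_end
    bits, start, end = _window_bits(trial, priors.anchor_mid, end)
    if bits.sum() == 0 or bits.size < 2:
        return None, math.nan
    res = one_change_logmarginal(
        bits,
        prior_before=priors.low_prior,
        prior_after=priors.pre_prior,
        nochange_prior=priors.pre_prior,
    )
    latency = start + res.map_location * MOMENT_WIDTH
    return res, float(latency)


def _longest_isi_in(
    trial: Trial, onset: float, offset: float, win_start: float, win_end: float
) -> tuple[float, float, bool]:
    """Longest ISI intersecting [onset, offset]; window edges censor.

    Returns ``(duration, isi_start, censored)``.
    """
    t = trial.spike_times
    t = t[(t >= win_start) & (t < win_end)]
    censored = False
    if t.size == 0:
        return offset - onset, onset, True
    if t[0] > onset:
        t = np.concatenate([[win_start], t])
        censored = True
    if t[-1] < offset:
        t = np.concatenate([t, [win_end]])
        censored = True
    starts = t[:-1]
    durs = np.diff(t)
    ends = t[1:]
    overlap = (ends > onset) & (starts < offset)
    if not overlap.any():
        return math.nan, math.nan, True
    i = int(np.argmax(np.where(overlap, durs, -np.inf)))
    return float(durs[i]), float(starts[i]), censored


def detect_pause(
    trial: Trial,
    priors: DetectorPriors,
    evidence_threshold: float = 1.0,
    T: Optional[float] = None,
    require_offset: bool = True,
) -> PauseEstimate:
    """Full per-trial pause estimate with the detection rule applied.

    Detection requires the onset evidence to exceed ``evidence_threshold``
    *and* the estimated pre-CS-side momentary probability to exceed the
    in-pause probability (no detection when the rate increases during the
    CS).  When ``require_offset`` (probe trials), the mirrored conditions
    apply to the offset as well before width, longest ISI and abruptness
    are filled in.
    """
    est = PauseEstimate()
    on_res, on_lat = estimate_onset(trial, priors)
    if on_res is not None:
        est.onset_evidence = on_res.weight_of_evidence
        est.rate_pause = on_res.rate_before
        est.rate_pre = on_res.rate_after
        est.onset_detected = (
            on_res.weight_of_evidence > evidence_threshold
            and on_res.rate_after > on_res.rate_before
        )
        if est.onset_detected:
            est.onset_latency = on_lat
    off_res, off_lat = estimate_offset(trial, priors, T=T)
    if off_res is not None:
        est.offset_evidence = off_res.weight_of_evidence
        est.offset_detected = (
            off_res.weight_of_evidence > evidence_threshold
            and off_res.rate_after > off_res.rate_before
        )
        if est.offset_detected:
            est.offset_latency = off_lat
    est.detected = est.onset_detected and (est.offset_detected or not require_offset)
    if est.onset_detected and est.offset_detected and off_lat > on_lat:
        est.width = off_lat - on_lat
        if priors.lookahead is not None:
            win_end = priors.anchor_mid + priors.lookahead
        elif T is not None:
            win_end = min(trial.record_end, T + 0.7)
        else:
            win_end = trial.record_end
        m, m_start, censored = _longest_isi_in(
            trial, on_lat, off_lat, -priors.lookback, win_end
        )
        est.longest_isi = m
        est.longest_isi_censored = censored
        if math.isfinite(m_start):
            est.abruptness = max(0.0, m_start - on_lat)
    return est


def detect_all(
    recording: CellRecording,
    priors_from: str = "probe",
    evidence_threshold: float = 1.0,
    pseudo_count: float = 300.0,
    epsilon: float = 0.5,
    lookback: float = 0.3,
    lookahead: Optional[float] = None,
    require_offset: bool = True,
) -> pd.DataFrame:
    """Run the detector on every trial of a recording.

    Priors are built once per cell from the peri-CS histogram of the
    configured trial subset (``"probe"`` falls back to all trials when the
    recording has no probe trials).  Per-trial failures become undetected
    rows; the batch never aborts.
    """
    if priors_from == "probe" and "probe" in recording.phase_labels:
        filt = lambda i, phase: phase == "probe"  # noqa: E731
    elif priors_from in ("probe", "all"):
        filt = None
    else:
        raise ValueError(f"unknown priors_from: {priors_from!r}")
    hist = peri_cs_histogram(recording, trial_filter=filt)
    priors = build_priors(
        hist,
        recording.protocol,
        pseudo_count=pseudo_count,
        epsilon=epsilon,
        lookback=lookback,
        lookahead=lookahead,
    )
    T = recording.protocol.cs_us_interval
    rows = []
    for i, trial in enumerate(recording.trials):
        try:
            est = detect_pause(
                trial,
                priors,
                evidence_threshold=evidence_threshold,
                T=T,
                require_offset=require_offset,
            )
        except ValueError:
            est = PauseEstimate()
        est.trial_index = i
        rows.append(
            {
                "cell_id": recording.cell_id,
                "trial_index": i,
                "onset_s": est.onset_latency,
                "offset_s": est.offset_latency,
                "width_s": est.width,
                "longest_isi_s": est.longest_isi,
                "abruptness_s": est.abruptness,
                "onset_woe": est.onset_evidence,
                "offset_woe": est.offset_evidence,
                "detected": est.detected,
                "longest_isi_censored": est.longest_isi_censored,
            }
        )
    return pd.DataFrame(rows)
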