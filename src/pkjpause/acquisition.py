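"""Acquisition-trial estimation from cumulative rate-difference records.

For each trial the firing rate over the CS-US interval is subtracted from
the rate over the immediately preceding window of equal duration; the
cumulative record of these differences slopes upward once the conditional
pause has appeared.  The change rule is a reconstruction built from two
stages: a two-segment constant-mean least-squares split of the per-trial
differences locates the candidate change, and the candidate is accepted
when the mean difference from it onward exceeds the criterion (10 Hz by
default).  When even the pre-candidate mean exceeds the criterion the
pause was present from the first trial, and the estimate is reported as
trial 2 — the first trial on which prior experience can be expressed
(zero trials to acquisition is analytically impossible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CellRecording, count_spikes

__all__ = ["AcquisitionResult", "rate_difference_record", "estimate_acquisition_trial"]


@dataclass(frozen=True)
class AcquisitionResult:
    """Outcome of the acquisition analysis for one cell.

    ``acquisition_trial`` is 1-based (the first trial of the post-change
    regime), or ``None`` when no change satisfying the criterion exists.
    ``evidence`` is the fractional reduction in squared error achieved by
    the two-segment fit over a single mean.
    """

    diffs: np.ndarray
    cumulative: np.ndarray
    acquisition_trial: Optional[int]
    post_change_mean: float
    evidence: float


def rate_difference_record(
    recording: CellRecording,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial pre-CS minus within-CS rate differences and their cumsum.

    ``diff_i = count([-T, 0)) / T - count([0, T)) / T`` with T the CS-US
    interval; an upward-sloping cumulative record means the cell fires less
    during the CS-US interval than before CS onset.
    """
    T = recording.protocol.cs_us_interval
    diffs = []
    for t in recording.trials:
        pre = count_spikes(t, -T, 0.0)
        within = count_spikes(t, 0.0, T)
        diffs.append((pre - within) / T)
    diffs = np.asarray(diffs)
    return diffs, np.cumsum(diffs)


def _two_segment_split(diffs: np.ndarray) -> tuple[int, float]:
    """Least-squares constant-mean change point on the differences.

    Returns ``(k, evidence)`` where the post-change regime is
    ``diffs[k:]`` (0-based, ``1 <= k <= n-1``) and evidence is
    ``1 - SSE_2seg / SSE_1seg``.
    """
    n = diffs.size
    c = np.concatenate([[0.0], np.cumsum(diffs)])
    c2 = np.concatenate([[0.0], np.cumsum(diffs**2)])
    k = np.arange(1, n)
    sse_head = c2[k] - c[k] ** 2 / k
    sse_tail = (c2[n] - c2[k]) - (c[n] - c[k]) ** 2 / (n - k)
    sse = sse_head + sse_tail
    best = int(np.argmin(sse))
    sse0 = c2[n] - c[n] ** 2 / n
    evidence = float(1 - sse[best] / sse0) if sse0 > 0 else 0.0
    return int(k[best]), evidence


def estimate_acquisition_trial(
    diffs: Sequence[float], threshold: float = 10.0
) -> AcquisitionResult:
    """Estimate the trial at which the conditional pause appeared.

    ``threshold`` is the criterion on the mean post-change rate difference
    (Hz, default 10).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 3:
        raise ValueError("need at least 3 trials")
    if np.all(np.isnan(diffs)):
        raise ValueError("all rate differences are NaN")
    k, evidence = _two_segment_split(diffs)
    head_mean = float(diffs[:k].mean())
    tail_mean = float(diffs[k:].mean())
    cumulative = np.cumsum(diffs)
    if head_mean > threshold:
        # pause expressed from the very first trial: one-trial acquisition
        acq: Optional[int] = 2
        post_mean = float(diffs.mean())
    elif tail_mean > threshold:
        acq = k + 1  # first trial of the post-change regime, 1-based
        post_mean = tail_mean
    else:
        acq = None
        post_mean = tail_mean
    return AcquisitionResult(
        diffs=diffs,
        cumulative=cumulative,
        acquisition_trial=acq,
        post_change_mean=post_mean,
        evidence=evidence,
    )
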