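"""Trial-aligned spike-train data model and low-level transforms.

Conventions used throughout the package:

* times are in seconds, with zero at CS (conditional stimulus) onset;
  negative times are pre-CS,
* every window and every binarization moment is half-open, ``[start, end)``,
* a "moment" is a 1-ms bin of trial time; the spike trains analysed here
  never carry two spikes within one moment (Purkinje cells have an absolute
  refractory period of several milliseconds), and :class:`Trial` validates
  this at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Protocol",
    "Trial",
    "CellRecording",
    "BinarizedTrial",
    "MomentaryProbHistogram",
    "binarize",
    "interspike_intervals",
    "count_spikes",
    "peri_cs_histogram",
    "isi_empirical_pdf",
    "MOMENT_WIDTH",
]

#: default width of one binarization moment, seconds
MOMENT_WIDTH = 0.001


@dataclass(frozen=True)
class Protocol:
    """Conditioning protocol for one cell.

    Parameters
    ----------
    cs_us_interval : float
        The CS-US interval ``T`` in seconds, i.e. the duration the cell
        learns.  In the recordings this ranges from 0.15 to 0.45 s.
    cs_duration : float
        Duration of the CS in seconds.
    iti : float
        Inter-trial interval in seconds.
    cs_pulse_rate : float, optional
        Pulse rate of the CS stimulation train in Hz (e.g. 50 Hz forepaw
        stimulation); ``None`` when the CS is not a pulse train.
    label : str
        Free-text label.
    """

    cs_us_interval: float
    cs_duration: float
    iti: float
    cs_pulse_rate: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.cs_us_interval > 0:
            raise ValueError("cs_us_interval must be positive")
        if not self.cs_duration > 0:
            raise ValueError("cs_duration must be positive")
        if not self.iti > self.cs_duration:
            raise ValueError("iti must exceed cs_duration")


@dataclass(frozen=True)
class Trial:
    """One trial of spike times aligned to CS onset (CS onset = 0 s).

    ``spike_times`` must be strictly increasing with successive differences
    of at least one moment (1 ms) and lie within
    ``[record_start, record_end]``.
    """

    spike_times: np.ndarray
    record_start: float
    record_end: float

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if self.record_end <= self.record_start:
            raise ValueError("record_end must exceed record_start")
        if st.size:
            d = np.diff(st)
            if np.any(d <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(d < MOMENT_WIDTH - 1e-12):
                i = int(np.argmax(d < MOMENT_WIDTH - 1e-12))
                raise ValueError(
                    f"spikes {i} and {i + 1} are closer than one 1-ms moment "
                    f"({d[i] * 1e3:.3f} ms)"
                )
            if st[0] < self.record_start - 1e-12 or st[-1] > self.record_end + 1e-12:
                raise ValueError("spike times outside [record_start, record_end]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class CellRecording:
    """A cell's protocol plus its ordered trials.

    ``phase_labels`` tags each trial as ``"training"`` or ``"probe"``
    (a probe trial is a CS-alone trial with no US).
    """

    cell_id: str
    protocol: Protocol
    trials: list[Trial]
    phase_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("a recording needs at least one trial")
        if self.phase_labels is None:
            self.phase_labels = ["probe"] * len(self.trials)
        if len(self.phase_labels) != len(self.trials):
            raise ValueError("phase_labels must match trials in length")
        bad = set(self.phase_labels) - {"training", "probe"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class BinarizedTrial:
    """A trial rendered as one bit per 1-ms moment (1 = spike in moment)."""

    window_start: float
    moment_width: float
    bits: np.ndarray

    @property
    def n_moments(self) -> int:
        return int(self.bits.size)

    def moment_time(self, k: int) -> float:
        """Left edge of moment ``k`` in trial time."""
        return self.window_start + k * self.moment_width


@dataclass(frozen=True)
class MomentaryProbHistogram:
    """Peri-CS histogram of momentary spike probability.

    The momentary probability in a bin is the pooled spike count divided by
    ``n_trials * bin_width_in_ms``: the probability of observing a spike
    within any one 1-ms moment of that bin.
    """

    bin_edges: np.ndarray
    probs: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("momentary probabilities must lie in [0, 1]")


def _check_window(trial: Trial, window_start: float, window_end: float) -> None:
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    if window_start < trial.record_start - 1e-9 or window_end > trial.record_end + 1e-9:
        raise ValueError(
            f"window [{window_start}, {window_end}) outside recorded span "
            f"[{trial.record_start}, {trial.record_end}]"
        )


def binarize(
    trial: Trial,
    window_start: float,
    window_end: float,
    moment_width: float = MOMENT_WIDTH,
) -> BinarizedTrial:
    """Binarize a trial over ``[window_start, window_end)``.

    Bit ``k`` is 1 iff a spike lies in the half-open moment
    ``[window_start + k*w, window_start + (k+1)*w)``.  Spike count is
    conserved: ``bits.sum()`` equals the number of spikes in the window.
    """
    _check_window(trial, window_start, window_end)
    if moment_width <= 0:
        raise ValueError("moment_width must be positive")
    n = int(round((window_end - window_start) / moment_width))
    if n < 1:
        raise ValueError("window shorter than one moment")
    edges = window_start + moment_width * np.arange(n + 1)
    t = trial.spike_times
    sel = t[(t >= edges[0]) & (t < edges[-1])]
    idx = np.searchsorted(edges, sel, side="right") - 1
    bits = np.zeros(n, dtype=np.int8)
    if np.any(bits[idx]):
        raise ValueError("two spikes fell into one moment")  # excluded by Trial
    bits[idx] = 1
    return BinarizedTrial(window_start=window_start, moment_width=moment_width, bits=bits)


def interspike_intervals(
    trial: Trial,
    window_start: Optional[float] = None,
    window_end: Optional[float] = None,
) -> np.ndarray:
    """Interspike intervals between adjacent spikes inside a window.

    Returns a structured-free ``(n, 2)`` array of ``(isi_start_time,
    isi_duration)`` rows, one per adjacent spike pair whose both spikes lie in
    ``[window_start, window_end)``.  Empty array when fewer than two spikes.
    """
    t = trial.spike_times
    if window_start is not None or window_end is not None:
        ws = trial.record_start if window_start is None else window_start
        we = trial.record_end if window_end is None else window_end
        t = t[(t >= ws) & (t < we)]
    if t.size < 2:
        return np.empty((0, 2), dtype=float)
    return np.column_stack([t[:-1], np.diff(t)])


def count_spikes(trial: Trial, window_start: float, window_end: float) -> int:
    """Number of spikes in the half-open window ``[window_start, window_end)``."""
    _check_window(trial, window_start, window_end)
    t = trial.spike_times
    lo = np.searchsorted(t, window_start, side="left")
    hi = np.searchsorted(t, window_end, side="left")
    return int(hi - lo)


def peri_cs_histogram(
    recording: CellRecording,
    trial_filter: Optional[Callable[[int, str], bool]] = None,
    bin_width: float = 0.015,
    span: Optional[tuple[float, float]] = None,
) -> MomentaryProbHistogram:
    """Peri-CS momentary-probability histogram pooled over selected trials.

    Parameters
    ----------
    recording : CellRecording
    trial_filter : callable, optional
        ``f(trial_index, phase_label) -> bool``; default selects every trial.
    bin_width : float
        Bin width in seconds (default 15 ms).
    span : (float, float), optional
        Histogram span; default ``(-0.3, cs_us_interval)``.

    The height of a bin is ``pooled count / (n_trials * bin width in ms)``:
    the probability of a spike in any single 1-ms moment of that bin.
    """
    if span is None:
        # default span [-0.3, T], trimmed down to a whole number of bins
        start = -0.3
        n_bins = int(np.floor((recording.protocol.cs_us_interval - start) / bin_width + 1e-9))
        end = start + n_bins * bin_width
    else:
        start, end = span
        n_bins_f = (end - start) / bin_width
        n_bins = int(round(n_bins_f))
        if n_bins < 1 or abs(n_bins_f - n_bins) * bin_width > MOMENT_WIDTH:
            raise ValueError("bin_width must divide the span to within one moment")
    sel = [
        i
        for i in range(recording.n_trials)
        if trial_filter is None or trial_filter(i, recording.phase_labels[i])
    ]
    if not sel:
        raise ValueError("no trials selected for the peri-CS histogram")
    edges = start + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for i in sel:
        t = recording.trials[i].spike_times
        t = t[(t >= start) & (t < end)]
        counts += np.histogram(t, bins=edges)[0]
    probs = counts / (len(sel) * bin_width * 1000.0)
    return MomentaryProbHistogram(bin_edges=edges, probs=probs, n_trials=len(sel))


def isi_empirical_pdf(
    isis: Sequence[float], bin_width: float = 0.005
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ISI histogram (masses summing to 1).

    Returns ``(bin_edges, masses)`` with bins of ``bin_width`` seconds from 0
    to just past the longest interval.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("need at least one interspike interval")
    n_bins = int(np.floor(isis.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.histogram(isis, bins=edges)[0]
    return edges, counts / counts.sum()
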