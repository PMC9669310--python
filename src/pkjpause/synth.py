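"""Synthetic Purkinje-cell recordings with the statistical structure the
analysis assumes.

The generator emulates, per trial:

* spontaneous simple-spike firing at 40-80 Hz as a renewal process whose
  interspike-interval law has a hard refractory floor (3-8 ms), an abrupt
  rise (shifted-exponential body) and a fatter-than-exponential tail
  (log-normal mixture component),
* trial-to-trial drift of the basal rate (a log-normal rate multiplier per
  trial), which makes between-trial spike counts super-Poisson,
* a learned conditional pause: on trials at or after the acquisition trial,
  onset and offset latencies are drawn with constant coefficient of
  variation (scalar variability) and every spike in ``[L_on, L_off]`` is
  deleted, so the pause is realized as one unusually long interspike
  interval supervening on the spontaneous train,
* optionally, stimulation-locked spikes elicited by a pulse-train CS.

Ground-truth latencies are returned alongside each recording so that
detector recovery is a quantitative test surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import MOMENT_WIDTH, CellRecording, Protocol, Trial

__all__ = [
    "SpontaneousModel",
    "PauseModel",
    "StimulusModel",
    "sample_spontaneous_train",
    "generate_cell_recording",
    "generate_population",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpontaneousModel:
    """Renewal-process model of spontaneous simple-spike firing.

    Parameters
    ----------
    base_rate : float
        Mean firing rate in Hz.
    refractory : float
        Hard minimum ISI in seconds (the abrupt rise of the ISI density).
    tail_mix : float
        Probability that an ISI is drawn from the heavy-tail component.
    tail_median : float
        Median of the log-normal tail component, seconds.
    tail_shape : float
        Log-sd of the log-normal tail component (dimensionless).
    rate_cov_between_trials : float
        CoV of a per-trial log-normal multiplier on the basal rate;
        0 means a stationary basal rate.
    poisson_mode : bool
        Force a homogeneous Poisson train (no refractory beyond the 1-ms
        one-spike-per-moment floor, no tail, no rate drift).
    """

    base_rate: float = 60.0
    refractory: float = 0.005
    tail_mix: float = 0.02
    tail_median: float = 0.045
    tail_shape: float = 0.6
    rate_cov_between_trials: float = 0.15
    poisson_mode: bool = False

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0 <= self.tail_mix <= 1:
            raise ValueError("tail_mix must lie in [0, 1]")
        if self.refractory < 0 or self.rate_cov_between_trials < 0:
            raise ValueError("refractory and rate CoV must be nonnegative")
        if self.tail_shape <= 0 or self.tail_median <= 0:
            raise ValueError("tail parameters must be positive")
        if not self.poisson_mode and self.base_rate > self.max_rate:
            raise ValueError(
                f"base_rate {self.base_rate:.1f} Hz exceeds what the "
                f"refractory/tail configuration can sustain ({self.max_rate:.1f} Hz)"
            )

    @property
    def tail_mean(self) -> float:
        return self.tail_median * float(np.exp(self.tail_shape**2 / 2))

    @property
    def max_rate(self) -> float:
        """Highest mean rate the refractory/tail configuration can sustain."""
        return 0.999 / (self.refractory + self.tail_mix * self.tail_mean + 1e-4)

    def body_scale(self, rate: float) -> float:
        """Exponential-body scale that yields an overall mean ISI of 1/rate."""
        mean_isi = 1.0 / rate
        scale = (
            mean_isi - self.refractory - self.tail_mix * self.tail_mean
        ) / (1.0 - self.tail_mix)
        if scale <= 0:
            raise ValueError(
                "rate too high for the refractory/tail configuration "
                f"(rate={rate:.1f} Hz)"
            )
        return scale


@dataclass(frozen=True)
class PauseModel:
    """Scalar-variability model of the learned pause latencies.

    Mean onset latency is ``onset_fraction * T`` and mean offset latency
    ``offset_fraction * T`` (T = CS-US interval); each latency is drawn from
    a truncated-at-zero normal with sd = CoV x mean, independently unless
    ``coupling`` is nonzero.  No pause is injected before trial
    ``acquisition_trial`` (1-based; the default 1 means every trial).
    """

    onset_fraction: float = 1.0 / 3.0
    offset_fraction: float = 1.0
    onset_cov: float = 0.2
    offset_cov: float = 0.15
    coupling: float = 0.0
    acquisition_trial: int = 1

    def __post_init__(self) -> None:
        if self.onset_fraction <= 0 or self.offset_fraction <= 0:
            raise ValueError("latency fractions must be positive")
        if self.offset_fraction <= self.onset_fraction:
            raise ValueError("offset_fraction must exceed onset_fraction")
        if self.onset_cov < 0 or self.offset_cov < 0:
            raise ValueError("CoVs must be nonnegative")
        if not -1 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [-1, 1]")
        if self.acquisition_trial < 1:
            raise ValueError("acquisition_trial is a 1-based trial number")


@dataclass(frozen=True)
class StimulusModel:
    """Stimulation-locked spiking driven by a pulse-train CS."""

    pulse_rate: float = 50.0
    per_pulse_spike_prob: float = 0.5
    suppression_in_pause: float = 0.1
    pulse_latency: float = 0.002

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        for p in (self.per_pulse_spike_prob, self.suppression_in_pause):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_isis(model: SpontaneousModel, rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.poisson_mode:
        # 1-ms dead time keeps the one-spike-per-moment invariant; the
        # exponential rate is adjusted so the mean ISI stays 1/rate.
        if rate >= 1.0 / MOMENT_WIDTH:
            raise ValueError("poisson_mode rate must stay below 1000 Hz")
        scale = 1.0 / rate - MOMENT_WIDTH
        return MOMENT_WIDTH + rng.exponential(scale, size=n)
    scale = model.body_scale(rate)
    body = rng.exponential(scale, size=n)
    if model.tail_mix > 0:
        tail = rng.lognormal(np.log(model.tail_median), model.tail_shape, size=n)
        from_tail = rng.random(n) < model.tail_mix
        body = np.where(from_tail, tail, body)
    return model.refractory + body


def sample_spontaneous_train(
    model: SpontaneousModel,
    duration: float,
    seed: Union[int, np.random.Generator, None] = None,
    start: float = 0.0,
) -> np.ndarray:
    """One realization of the spontaneous train over ``[start, start+duration)``.

    The renewal process is burned in before ``start`` so that the train is
    (approximately) stationary at the window edge; deterministic for a fixed
    seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed)
    return _sample_spont_at_rate(model, model.base_rate, start, start + duration, rng)


def _draw_latencies(
    pause: PauseModel, T: float, rng: np.random.Generator, max_redraws: int = 1000
) -> tuple[float, float]:
    mu = np.array([pause.onset_fraction * T, pause.offset_fraction * T])
    sd = np.array([pause.onset_cov * mu[0], pause.offset_cov * mu[1]])
    rho = pause.coupling
    for attempt in range(max_redraws):
        z0, z1 = rng.standard_normal(2)
        on = mu[0] + sd[0] * z0
        off = mu[1] + sd[1] * (rho * z0 + math.sqrt(1.0 - rho**2) * z1)
        if on > 0 and off > on:
            return float(on), float(off)
    raise RuntimeError("could not draw a valid (onset, offset) pair")


def _merge_min_separation(times: np.ndarray, min_sep: float = MOMENT_WIDTH) -> np.ndarray:
    """Drop the later spike of any pair closer than ``min_sep``."""
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_sep:
            keep.append(t)
    return np.asarray(keep)


def generate_cell_recording(
    protocol: Protocol,
    spontaneous: SpontaneousModel = SpontaneousModel(),
    pause: Optional[PauseModel] = PauseModel(),
    stimulus: Optional[StimulusModel] = None,
    n_trials: int = 20,
    seed: Union[int, np.random.Generator, None] = None,
    cell_id: str = "cell",
    pre_window: float = 1.5,
    post_window: Optional[float] = None,
    phase: str = "probe",
) -> tuple[CellRecording, pd.DataFrame]:
    """Generate one cell's recording plus its ground-truth pause latencies.

    Returns ``(recording, truth)`` where ``truth`` has one row per trial with
    columns ``trial_index, true_onset_s, true_offset_s`` (NaN on trials
    without an injected pause).  Trials before ``pause.acquisition_trial``
    (1-based) carry no pause.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = _as_rng(seed)
    T = protocol.cs_us_interval
    if post_window is None:
        post_window = T + 0.8
    trials: list[Trial] = []
    truth_rows = []
    for i in range(n_trials):
        rate = spontaneous.base_rate
        if spontaneous.rate_cov_between_trials > 0 and not spontaneous.poisson_mode:
            cov = spontaneous.rate_cov_between_trials
            sigma = np.sqrt(np.log1p(cov**2))
            rate = rate * rng.lognormal(-sigma**2 / 2, sigma)
            # a drift draw cannot push the renewal process past saturation
            rate = min(rate, spontaneous.max_rate)
        trial_model = spontaneous
        spikes = _sample_spont_at_rate(trial_model, rate, -pre_window, post_window, rng)
        on = off = np.nan
        paused = pause is not None and (i + 1) >= pause.acquisition_trial
        if paused:
            on, off = _draw_latencies(pause, T, rng)
        if stimulus is not None:
            stim = _stimulus_spikes(stimulus, protocol, (on, off) if paused else None, rng)
            spikes = _merge_min_separation(np.sort(np.concatenate([spikes, stim])))
        if paused:
            spikes = spikes[(spikes < on) | (spikes > off)]
        trials.append(Trial(spike_times=spikes, record_start=-pre_window, record_end=post_window))
        truth_rows.append({"trial_index": i, "true_onset_s": on, "true_offset_s": off})
    rec = CellRecording(
        cell_id=cell_id,
        protocol=protocol,
        trials=trials,
        phase_labels=[phase] * n_trials,
    )
    return rec, pd.DataFrame(truth_rows)


def _sample_spont_at_rate(
    model: SpontaneousModel,
    rate: float,
    start: float,
    end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    burn = max(5.0 / rate, 0.25)
    t = start - burn
    out: list[float] = []
    block = max(16, int(np.ceil((end - t) * rate * 1.5)))
    while t < end:
        for isi in _sample_isis(model, rate, block, rng):
            t += isi
            if t >= end:
                break
            if t >= start:
                out.append(t)
    return np.asarray(out)


def _stimulus_spikes(
    stimulus: StimulusModel,
    protocol: Protocol,
    pause_bounds: Optional[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    pulse_times = np.arange(0.0, protocol.cs_duration, 1.0 / stimulus.pulse_rate)
    spike_times = pulse_times + stimulus.pulse_latency
    p = np.full(pulse_times.size, stimulus.per_pulse_spike_prob)
    if pause_bounds is not None:
        on, off = pause_bounds
        inside = (spike_times >= on) & (spike_times <= off)
        p[inside] *= stimulus.suppression_in_pause
    return spike_times[rng.random(pulse_times.size) < p]


def generate_population(
    spec_table: Union[pd.DataFrame, Sequence[dict]],
    seed: Union[int, None] = None,
    spontaneous: SpontaneousModel = SpontaneousModel(),
    pause: Optional[PauseModel] = PauseModel(),
    stimulus: Optional[StimulusModel] = None,
) -> tuple[list[CellRecording], pd.DataFrame]:
    """Generate a population of recordings from a per-cell spec table.

    ``spec_table`` rows need ``cell_id`` and ``cs_us_interval``; optional
    columns ``n_trials`` (default 20), ``cs_duration``, ``iti``.  Per-cell
    seeds are derived deterministically from the master seed, so a given
    master seed yields an identical population.  Returns the recordings and
    the concatenated ground-truth table (with a ``cell_id`` column).
    """
    table = pd.DataFrame(spec_table)
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id: {dup!r}")
    child_seeds = np.random.SeedSequence(seed).spawn(len(table))
    recordings: list[CellRecording] = []
    truths = []
    for (_, row), ss in zip(table.iterrows(), child_seeds):
        T = float(row["cs_us_interval"])
        proto = Protocol(
            cs_us_interval=T,
            cs_duration=float(row.get("cs_duration", T)),
            iti=float(row.get("iti", 15.0)),
            cs_pulse_rate=stimulus.pulse_rate if stimulus is not None else None,
        )
        rec, truth = generate_cell_recording(
            proto,
            spontaneous=spontaneous,
            pause=pause,
            stimulus=stimulus,
            n_trials=int(row.get("n_trials", 20)),
            seed=np.random.default_rng(ss),
            cell_id=str(row["cell_id"]),
        )
        truth.insert(0, "cell_id", rec.cell_id)
        recordings.append(rec)
        truths.append(truth)
    return recordings, pd.concat(truths, ignore_index=True)
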