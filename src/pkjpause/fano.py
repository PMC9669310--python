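"""Fano factors, stationary-Poisson plausibility limits, and the
exponential-vs-empirical ISI tail comparison.

The Fano factor of a set of spike counts is the ratio of their (unbiased)
sample variance to their sample mean; for counts from a stationary Poisson
process it is close to 1.  The plausibility limits answer: given the
observed mean count and the number of counts, how far from 1 can the Fano
factor plausibly stray if the process really is stationary and Poisson?
Two routes are offered: the chi-squared approximation
(``(n-1) * F ~ chi2(n-1)``, exact in the large-mean limit) and Monte-Carlo
quantiles of the statistic itself, which remain calibrated at small mean
counts where the approximation degrades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import CellRecording, count_spikes, interspike_intervals

__all__ = [
    "FanoResult",
    "IsiExponentialFit",
    "fano_factor",
    "poisson_fano_limits",
    "between_trial_fano",
    "within_trial_fano",
    "fit_exponential_isi",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FanoResult:
    fano: float
    n: int
    mean_count: float
    window: tuple[float, float]
    lower_limit: float
    upper_limit: float
    alpha: float

    @property
    def within_limits(self) -> bool:
        return self.lower_limit <= self.fano <= self.upper_limit


@dataclass(frozen=True)
class IsiExponentialFit:
    """Best-fitting exponential to ISIs after subtracting the minimum ISI."""

    minimum_isi: float
    rate: float
    tail_excess: float
    n: int


def fano_factor(counts: Sequence[int]) -> float:
    """Unbiased sample variance of the counts divided by their mean."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two counts")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    m = c.mean()
    if m == 0:
        raise ValueError("mean count is zero; Fano factor undefined")
    return float(c.var(ddof=1) / m)


def poisson_fano_limits(
    mean_count: float,
    n: int,
    alpha: float = 0.01,
    method: str = "chi2",
    seed: Union[int, np.random.Generator, None] = None,
    sided: str = "two",
    n_sim: int = 100_000,
) -> tuple[float, float]:
    """Plausibility limits on the Fano factor under a stationary Poisson process.

    ``sided="two"`` returns the ``alpha/2`` and ``1 - alpha/2`` quantiles;
    ``sided="upper"`` returns ``(0, q_{1-alpha})`` for the one-sided test of
    super-Poisson variability.  ``method="chi2"`` uses quantiles of
    ``chi2(n-1)/(n-1)``; ``method="montecarlo"`` uses empirical quantiles of
    the Fano factor over ``n_sim`` replicate sets of ``n`` Poisson counts
    (deterministic under a fixed seed).
    """
    if n < 2:
        raise ValueError("need n >= 2 counts")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    if sided == "two":
        q_lo, q_hi = alpha / 2, 1 - alpha / 2
    elif sided == "upper":
        q_lo, q_hi = None, 1 - alpha
    else:
        raise ValueError("sided must be 'two' or 'upper'")
    if method == "chi2":
        df = n - 1
        upper = stats.chi2.ppf(q_hi, df) / df
        lower = stats.chi2.ppf(q_lo, df) / df if q_lo is not None else 0.0
    elif method == "montecarlo":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        counts = rng.poisson(mean_count, size=(n_sim, n))
        means = counts.mean(axis=1)
        variances = counts.var(axis=1, ddof=1)
        ok = means > 0
        fanos = variances[ok] / means[ok]
        upper = float(np.quantile(fanos, q_hi))
        lower = float(np.quantile(fanos, q_lo)) if q_lo is not None else 0.0
    else:
        raise ValueError("method must be 'chi2' or 'montecarlo'")
    return float(lower), float(upper)


def between_trial_fano(
    recording: CellRecording,
    window: tuple[float, float] = (-1.0, 0.0),
    alpha: float = 0.01,
    method: str = "chi2",
    seed: Union[int, np.random.Generator, None] = None,
    sided: str = "upper",
) -> FanoResult:
    """Fano factor of per-trial spike counts in a fixed window.

    The default window is the 1 s immediately preceding CS onset with a
    one-sided upper limit, the construction used to demonstrate
    trial-to-trial non-stationarity of the basal rate.
    """
    if recording.n_trials < 2:
        raise ValueError("need at least two trials")
    for t in recording.trials:
        if window[0] < t.record_start - 1e-9 or window[1] > t.record_end + 1e-9:
            raise ValueError("count window not recorded on every trial")
    counts = [count_spikes(t, *window) for t in recording.trials]
    f = fano_factor(counts)
    mean_count = float(np.mean(counts))
    lo, hi = poisson_fano_limits(
        mean_count, len(counts), alpha=alpha, method=method, seed=seed, sided=sided
    )
    return FanoResult(
        fano=f,
        n=len(counts),
        mean_count=mean_count,
        window=window,
        lower_limit=lo,
        upper_limit=hi,
        alpha=alpha,
    )


def within_trial_fano(
    recording: CellRecording,
    subwindow_width: float = 0.1,
    alpha: float = 0.01,
    method: str = "chi2",
    seed: Union[int, np.random.Generator, None] = None,
    sided: str = "two",
) -> list[FanoResult]:
    """Per-trial Fano factors over successive pre-CS subwindows.

    Each trial's pre-CS span is tiled with windows of ``subwindow_width``
    ending at CS onset; the number of subwindows may differ between trials.
    Trials whose span holds fewer than two subwindows are skipped (logged).
    """
    out: list[FanoResult] = []
    for i, t in enumerate(recording.trials):
        span = 0.0 - t.record_start
        k = int(np.floor(span / subwindow_width + 1e-9))
        if k < 2:
            log.warning("trial %d: pre-CS span %.3f s too short, skipped", i, span)
            continue
        start = -k * subwindow_width
        counts = [
            count_spikes(t, start + j * subwindow_width, start + (j + 1) * subwindow_width)
            for j in range(k)
        ]
        mean_count = float(np.mean(counts))
        if mean_count == 0:
            log.warning("trial %d: no pre-CS spikes, skipped", i)
            continue
        f = fano_factor(counts)
        lo, hi = poisson_fano_limits(
            mean_count, k, alpha=alpha, method=method, seed=seed, sided=sided
        )
        out.append(
            FanoResult(
                fano=f,
                n=k,
                mean_count=mean_count,
                window=(start, 0.0),
                lower_limit=lo,
                upper_limit=hi,
                alpha=alpha,
            )
        )
    return out


def fit_exponential_isi(isis: Sequence[float], tail_quantile: float = 0.95) -> IsiExponentialFit:
    """Maximum-likelihood exponential fit to shifted ISIs, plus tail excess.

    The minimum ISI is subtracted before fitting (the refractory shift);
    the ML rate is the reciprocal mean of the shifted intervals.
    ``tail_excess`` is the ratio of the empirical to the fitted survival
    at the fitted distribution's ``tail_quantile`` point: values above 1
    mean the empirical tail is fatter than exponential.
    """
    x = np.sort(np.asarray(isis, dtype=float))
    if x.size < 10:
        raise ValueError("need at least 10 ISIs")
    shift = x[0]
    shifted = x - shift
    mean = shifted.mean()
    if mean <= 0:
        raise ValueError("degenerate (all-equal) ISIs")
    rate = 1.0 / mean
    t_q = -np.log(1 - tail_quantile) / rate
    empirical_survival = float(np.mean(shifted > t_q))
    tail_excess = empirical_survival / (1 - tail_quantile)
    return IsiExponentialFit(
        minimum_isi=float(shift), rate=float(rate), tail_excess=float(tail_excess), n=x.size
    )
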