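"""Descriptive battery over per-trial pause estimates.

Covers the per-cell summaries (means, quartiles, CoV = sd/mean of onset,
offset, width and longest within-pause ISI over detected trials), the
six pairwise Pearson correlations among those four parameters, the
backward interspike-interval regression used to test for graded (rather
than step-like) pause onsets, and the population-level grouping by CS-US
interval.  Constancy of the CoV across CS-US intervals is the scalar
variability (Weber's-law) signature of interval timing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Protocol, Trial
from .detector import PauseEstimate

__all__ = [
    "PAUSE_PARAMS",
    "CellSummary",
    "CorrelationStructure",
    "BackwardRegressionResult",
    "summarize_cell",
    "pairwise_correlations",
    "backward_isi_regression",
    "aggregate_population",
]

log = logging.getLogger(__name__)

#: column name -> short parameter label (onset, offset, width, longest ISI)
PAUSE_PARAMS = {
    "onset_s": "onset",
    "offset_s": "offset",
    "width_s": "width",
    "longest_isi_s": "longest_isi",
}


@dataclass(frozen=True)
class CellSummary:
    """Per-cell moments and quartiles of the pause parameters."""

    cell_id: str
    cs_us_interval: float
    n_detected: int
    stats: pd.DataFrame  # rows: parameters; cols: mean, median, q1, q2, q3, cov

    def row(self, param: str) -> pd.Series:
        return self.stats.loc[param]


@dataclass(frozen=True)
class CorrelationStructure:
    """Six pairwise Pearson correlations among the pause parameters."""

    cell_id: str
    cs_us_interval: float
    correlations: dict[tuple[str, str], float]
    n: int


@dataclass(frozen=True)
class BackwardRegressionResult:
    """OLS of ISI duration on backward interval index (1 = nearest the pause)."""

    slope: float
    slope_ci_lower: float
    slope_ci_upper: float
    r_squared: float
    n_isis: int


def _detected(estimates: pd.DataFrame) -> pd.DataFrame:
    return estimates[estimates["detected"].astype(bool)]


def summarize_cell(
    estimates: pd.DataFrame,
    protocol: Protocol,
    exclude_censored_longest_isi: bool = True,
) -> CellSummary:
    """Summary statistics over the detected trials of one cell.

    The CoV is the ratio of the (unbiased) standard deviation to the mean.
    Quartiles use linear interpolation of the empirical CDF.  Trials with a
    censored longest ISI are excluded from the longest-ISI row by default.
    """
    det = _detected(estimates)
    if len(det) < 2:
        raise ValueError(f"need >= 2 detected trials, got {len(det)}")
    rows = {}
    for col, name in PAUSE_PARAMS.items():
        vals = det[col]
        if (
            name == "longest_isi"
            and exclude_censored_longest_isi
            and "longest_isi_censored" in det
        ):
            vals = vals[~det["longest_isi_censored"].astype(bool)]
        vals = vals.dropna().to_numpy()
        if vals.size < 2:
            rows[name] = dict.fromkeys(["mean", "median", "q1", "q2", "q3", "cov"], math.nan)
            continue
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        mean = vals.mean()
        rows[name] = {
            "mean": mean,
            "median": q2,
            "q1": q1,
            "q2": q2,
            "q3": q3,
            "cov": vals.std(ddof=1) / mean if mean != 0 else math.nan,
        }
    cell_id = str(estimates["cell_id"].iloc[0]) if "cell_id" in estimates else ""
    return CellSummary(
        cell_id=cell_id,
        cs_us_interval=protocol.cs_us_interval,
        n_detected=len(det),
        stats=pd.DataFrame(rows).T,
    )


def pairwise_correlations(
    estimates: pd.DataFrame, cs_us_interval: float = math.nan
) -> CorrelationStructure:
    """Pearson correlations for the six pause-parameter pairs.

    Computed over detected trials; a zero-variance parameter yields NaN for
    its pairs (flagged by a warning).
    """
    det = _detected(estimates)
    if len(det) < 3:
        raise ValueError("need >= 3 detected trials for correlations")
    corrs: dict[tuple[str, str], float] = {}
    names = list(PAUSE_PARAMS)
    for a, b in itertools.combinations(names, 2):
        sub = det[[a, b]].dropna()
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        pair = (PAUSE_PARAMS[a], PAUSE_PARAMS[b])
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            log.warning("pair %s: degenerate, correlation undefined", pair)
            corrs[pair] = math.nan
        else:
            corrs[pair] = float(np.corrcoef(x, y)[0, 1])
    cell_id = str(estimates["cell_id"].iloc[0]) if "cell_id" in estimates else ""
    return CorrelationStructure(
        cell_id=cell_id,
        cs_us_interval=cs_us_interval,
        correlations=corrs,
        n=len(det),
    )


def backward_isi_regression(
    trial: Trial,
    estimate: PauseEstimate,
    anchor: str = "onset",
    min_isis: int = 5,
    conf_level: float = 0.95,
) -> Optional[BackwardRegressionResult]:
    """Regression of pre-pause ISIs on the backward interval index.

    The intervals lie between CS onset and the anchor (the estimated pause
    onset, or the start of the longest within-pause ISI when
    ``anchor="longest"``); index 1 is the interval nearest the pause.
    Returns ``None`` when fewer than ``min_isis`` interspike intervals
    qualify.  A positive slope means the intervals near CS onset tend to be
    longer than those near the pause.
    """
    if anchor == "onset":
        t_anchor = estimate.onset_latency
    elif anchor == "longest":
        t_anchor = estimate.onset_latency + (
            estimate.abruptness if math.isfinite(estimate.abruptness) else 0.0
        )
    else:
        raise ValueError("anchor must be 'onset' or 'longest'")
    if not math.isfinite(t_anchor):
        return None
    spikes = trial.spike_times
    spikes = spikes[(spikes >= 0.0) & (spikes <= t_anchor)]
    if spikes.size < min_isis + 1:
        return None
    isis = np.diff(spikes)
    n = isis.size
    # backward index: 1 = interval ending nearest the pause
    idx = np.arange(isis.size, 0, -1)
    if np.ptp(isis) == 0:  # constant intervals: flat fit, nothing explained
        return BackwardRegressionResult(
            slope=0.0, slope_ci_lower=0.0, slope_ci_upper=0.0, r_squared=0.0, n_isis=int(n)
        )
    res = sps.linregress(idx, isis)
    tcrit = sps.t.ppf(0.5 + conf_level / 2, n - 2)
    return BackwardRegressionResult(
        slope=float(res.slope),
        slope_ci_lower=float(res.slope - tcrit * res.stderr),
        slope_ci_upper=float(res.slope + tcrit * res.stderr),
        r_squared=float(res.rvalue**2),
        n_isis=int(n),
    )


def aggregate_population(
    summaries: Sequence[CellSummary],
    correlations: Sequence[CorrelationStructure] = (),
) -> dict[str, pd.DataFrame]:
    """Group per-cell results by CS-US interval.

    Returns a dict of tables:

    * ``"cell_stats"`` — one row per (cell, parameter) with mean/quartiles/CoV,
    * ``"group_means"`` — per (CS-US interval, parameter): group mean of the
      cell means and of the cell CoVs, with cell counts,
    * ``"quartile_cdfs"`` — per-cell quartiles of width and longest ISI,
      grouped by CS-US interval (the quartile-CDF raw material),
    * ``"correlations"`` — one row per (cell, parameter pair).
    """
    if not summaries:
        raise ValueError("no cell summaries to aggregate")
    cell_rows = []
    for s in summaries:
        for param, row in s.stats.iterrows():
            cell_rows.append(
                {
                    "cell_id": s.cell_id,
                    "cs_us_interval": s.cs_us_interval,
                    "parameter": param,
                    "n_detected": s.n_detected,
                    **row.to_dict(),
                }
            )
    cell_stats = pd.DataFrame(cell_rows)
    group_means = (
        cell_stats.groupby(["cs_us_interval", "parameter"])
        .agg(
            mean_of_means=("mean", "mean"),
            median_of_medians=("median", "median"),
            mean_cov=("cov", "mean"),
            median_cov=("cov", "median"),
            n_cells=("cell_id", "nunique"),
        )
        .reset_index()
    )
    quart = cell_stats[cell_stats["parameter"].isin(["width", "longest_isi"])][
        ["cs_us_interval", "cell_id", "parameter", "q1", "q2", "q3"]
    ].reset_index(drop=True)
    corr_rows = [
        {
            "cell_id": c.cell_id,
            "cs_us_interval": c.cs_us_interval,
            "pair": f"{a}~{b}",
            "correlation": r,
            "n": c.n,
        }
        for c in correlations
        for (a, b), r in c.correlations.items()
    ]
    out = {
        "cell_stats": cell_stats,
        "group_means": group_means,
        "quartile_cdfs": quart,
        "correlations": pd.DataFrame(corr_rows),
    }
    return out
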