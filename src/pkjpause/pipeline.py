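"""End-to-end pipeline driver: simulate -> detect -> fano -> acquisition -> stats.

Every stage writes plain-text tables under the configured output
directory; a manifest (config, seed, package version, input hashes,
per-stage row counts) makes deterministic stages bit-reproducible and
stochastic stages seed-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import estimate_acquisition_trial, rate_difference_record
from .detector import detect_all
from .fano import between_trial_fano, within_trial_fano
from .io import RunConfig, read_ground_truth, read_recordings, write_ground_truth, write_recordings
from .stats import (
    aggregate_population,
    pairwise_correlations,
    summarize_cell,
)
from .synth import PauseModel, SpontaneousModel, generate_population

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage", "detect_stage", "fano_stage", "acquisition_stage", "stats_stage"]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_stage(config: RunConfig, out_dir: Path) -> None:
    intervals = config.cs_us_intervals
    spec_rows = [
        {
            "cell_id": f"cell{i:03d}",
            "cs_us_interval": intervals[i % len(intervals)],
            "n_trials": config.n_trials,
        }
        for i in range(config.n_cells)
    ]
    recs, truth = generate_population(spec_rows, seed=config.seed)
    write_recordings(recs, out_dir)
    write_ground_truth(truth, out_dir)


def detect_stage(config: RunConfig, data_dir: Path, out_dir: Path) -> pd.DataFrame:
    recs = read_recordings(data_dir)
    tables = [
        detect_all(
            rec,
            priors_from=config.priors_from,
            evidence_threshold=config.evidence_threshold,
            pseudo_count=config.pseudo_count,
            lookback=config.lookback,
            lookahead=config.lookahead,
        )
        for rec in recs
    ]
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(out_dir / "pauses.csv", index=False)
    return out


def fano_stage(config: RunConfig, data_dir: Path, out_dir: Path) -> pd.DataFrame:
    recs = read_recordings(data_dir)
    rng = np.random.default_rng(config.seed)
    rows = []
    for rec in recs:
        bt = between_trial_fano(
            rec,
            window=config.fano_window,
            alpha=config.alpha,
            method=config.fano_method,
            seed=rng,
        )
        rows.append(
            {
                "cell_id": rec.cell_id,
                "kind": "between_trial",
                "fano": bt.fano,
                "n": bt.n,
                "mean_count": bt.mean_count,
                "lower_limit": bt.lower_limit,
                "upper_limit": bt.upper_limit,
                "alpha": bt.alpha,
            }
        )
        for wt in within_trial_fano(
            rec,
            subwindow_width=config.subwindow_width,
            alpha=config.alpha,
            method=config.fano_method,
            seed=rng,
        ):
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "kind": "within_trial",
                    "fano": wt.fano,
                    "n": wt.n,
                    "mean_count": wt.mean_count,
                    "lower_limit": wt.lower_limit,
                    "upper_limit": wt.upper_limit,
                    "alpha": wt.alpha,
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "fano.csv", index=False)
    return out


def acquisition_stage(config: RunConfig, data_dir: Path, out_dir: Path) -> pd.DataFrame:
    recs = read_recordings(data_dir)
    rows = []
    for rec in recs:
        diffs, _ = rate_difference_record(rec)
        res = estimate_acquisition_trial(diffs, threshold=config.acquisition_threshold)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "acquisition_trial": res.acquisition_trial,
                "post_change_mean_hz": res.post_change_mean,
                "evidence": res.evidence,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "acquisition.csv", index=False)
    return out


def stats_stage(
    config: RunConfig, data_dir: Path, pauses: pd.DataFrame, out_dir: Path
) -> dict[str, pd.DataFrame]:
    recs = {r.cell_id: r for r in read_recordings(data_dir)}
    summaries = []
    corrs = []
    for cid, sub in pauses.groupby("cell_id"):
        rec = recs[str(cid)]
        try:
            summaries.append(summarize_cell(sub, rec.protocol))
        except ValueError as e:
            log.warning("cell %s: %s", cid, e)
            continue
        try:
            corrs.append(pairwise_correlations(sub, rec.protocol.cs_us_interval))
        except ValueError as e:
            log.warning("cell %s: %s", cid, e)
    if not summaries:
        raise ValueError("no cell had enough detected trials to summarize")
    tables = aggregate_population(summaries, corrs)
    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False)
    return tables


def run_pipeline(config: RunConfig, data_dir: Optional[Union[str, Path]] = None) -> dict:
    """Run all stages and write a manifest; returns the manifest dict.

    When ``data_dir`` is None, the simulate stage generates the dataset
    under ``<out_dir>/data`` first; otherwise the existing dataset is used
    (it is validated before any stage writes results).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data_dir is None:
        data_dir = out_dir / "data"
        simulate_stage(config, data_dir)
    data_dir = Path(data_dir)
    read_recordings(data_dir)  # validate before any stage writes
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            p.name: _hash_file(p) for p in sorted(data_dir.glob("*.csv")) + sorted(data_dir.glob("*.json"))
        },
        "stages": {},
    }
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    stages = [
        ("detect", lambda: detect_stage(config, data_dir, out_dir)),
        ("fano", lambda: fano_stage(config, data_dir, out_dir)),
        ("acquisition", lambda: acquisition_stage(config, data_dir, out_dir)),
    ]
    pauses = None
    for name, fn in stages:
        t0 = time.perf_counter()
        result = fn()
        if name == "detect":
            pauses = result
            manifest["stages"][name] = {
                "rows": int(len(result)),
                "n_detected": int(result["detected"].sum()),
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            manifest["stages"][name] = {
                "rows": int(len(result)),
                "seconds": round(time.perf_counter() - t0, 3),
            }
    t0 = time.perf_counter()
    tables = stats_stage(config, data_dir, pauses, out_dir)
    manifest["stages"]["stats"] = {
        "tables": {k: int(len(v)) for k, v in tables.items()},
        "seconds": round(time.perf_counter() - t0, 3),
    }
    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(out_dir.glob("*.csv"))
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
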