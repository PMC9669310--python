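"""Plain-text formats for recordings, ground truth and run configuration.

A dataset directory holds:

* ``spikes.csv`` with header ``cell_id,trial_index,phase,spike_time_s``
  (one spike per row, times in seconds relative to CS onset),
* ``protocols.json`` mapping each cell id to its protocol
  (``cs_us_interval_s, cs_duration_s, iti_s, cs_pulse_rate_hz, n_trials``
  plus the recorded span ``record_start_s, record_end_s``),
* optionally ``ground_truth.csv`` with
  ``cell_id,trial_index,true_onset_s,true_offset_s``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import CellRecording, Protocol, Trial, MOMENT_WIDTH

__all__ = [
    "RunConfig",
    "read_recordings",
    "write_recordings",
    "read_ground_truth",
    "write_ground_truth",
]

log = logging.getLogger(__name__)

SPIKE_COLUMNS = ["cell_id", "trial_index", "phase", "spike_time_s"]
PROTOCOL_KEYS = ["cs_us_interval_s", "cs_duration_s", "iti_s", "n_trials"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    # simulate stage
    n_cells: int = 6
    n_trials: int = 20
    cs_us_intervals: list[float] = field(default_factory=lambda: [0.15, 0.2, 0.3])
    # detector stage
    lookback: float = 0.3
    lookahead: Optional[float] = None
    pseudo_count: float = 300.0
    evidence_threshold: float = 1.0
    priors_from: str = "probe"
    # fano stage
    alpha: float = 0.01
    fano_method: str = "chi2"
    fano_window: tuple[float, float] = (-1.0, 0.0)
    subwindow_width: float = 0.1
    # acquisition stage
    acquisition_threshold: float = 10.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fano_window"] = list(d["fano_window"])
        return d

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fano_window" in data:
            data["fano_window"] = tuple(data["fano_window"])
        return cls(**data)


def write_recordings(
    recordings: list[CellRecording], out_dir: Union[str, Path]
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    protocols = {}
    for rec in recordings:
        for i, trial in enumerate(rec.trials):
            phase = rec.phase_labels[i]
            for t in trial.spike_times:
                rows.append((rec.cell_id, i, phase, t))
        p = rec.protocol
        protocols[rec.cell_id] = {
            "cs_us_interval_s": p.cs_us_interval,
            "cs_duration_s": p.cs_duration,
            "iti_s": p.iti,
            "cs_pulse_rate_hz": p.cs_pulse_rate,
            "n_trials": rec.n_trials,
            "record_start_s": rec.trials[0].record_start,
            "record_end_s": rec.trials[0].record_end,
        }
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(out / "spikes.csv", index=False)
    (out / "protocols.json").write_text(json.dumps(protocols, indent=1))


def write_ground_truth(truth: pd.DataFrame, out_dir: Union[str, Path]) -> None:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    truth.to_csv(Path(out_dir) / "ground_truth.csv", index=False)


def read_ground_truth(in_dir: Union[str, Path]) -> Optional[pd.DataFrame]:
    p = Path(in_dir) / "ground_truth.csv"
    return pd.read_csv(p) if p.exists() else None


def read_recordings(
    in_dir: Union[str, Path], clip: bool = False
) -> list[CellRecording]:
    """Load and validate a dataset directory.

    Spike times must be sorted within each trial with successive
    differences of at least one 1-ms moment; violations are rejected with
    the offending row number, or merged (dropping the later spike) when
    ``clip`` is set.
    """
    in_dir = Path(in_dir)
    spikes_path = in_dir / "spikes.csv"
    proto_path = in_dir / "protocols.json"
    if not spikes_path.exists():
        raise FileNotFoundError(f"missing {spikes_path}")
    if not proto_path.exists():
        raise FileNotFoundError(f"missing {proto_path}")
    df = pd.read_csv(spikes_path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spikes.csv missing columns: {sorted(missing)}")
    protocols = json.loads(proto_path.read_text())
    for cid, p in protocols.items():
        for key in PROTOCOL_KEYS:
            if key not in p:
                raise ValueError(f"protocol for cell {cid!r} missing key {key!r}")
    df["_row"] = np.arange(2, len(df) + 2)  # header is line 1
    recordings = []
    for cid, p in protocols.items():
        sub = df[df["cell_id"].astype(str) == str(cid)]
        proto = Protocol(
            cs_us_interval=float(p["cs_us_interval_s"]),
            cs_duration=float(p["cs_duration_s"]),
            iti=float(p["iti_s"]),
            cs_pulse_rate=p.get("cs_pulse_rate_hz"),
        )
        rs = float(p.get("record_start_s", sub["spike_time_s"].min() if len(sub) else -1.0))
        re_ = float(p.get("record_end_s", sub["spike_time_s"].max() + 1e-3 if len(sub) else 1.0))
        n_trials = int(p["n_trials"])
        trials = []
        labels = []
        for i in range(n_trials):
            tsub = sub[sub["trial_index"] == i]
            times = tsub["spike_time_s"].to_numpy(dtype=float)
            rownums = tsub["_row"].to_numpy()
            if times.size:
                d = np.diff(times)
                if np.any(d <= -1e-12):
                    j = int(np.argmax(d <= -1e-12))
                    raise ValueError(
                        f"unsorted spike times for cell {cid!r} trial {i} "
                        f"at spikes.csv row {rownums[j + 1]}"
                    )
                if np.any(np.abs(d) < 1e-12):
                    j = int(np.argmax(np.abs(d) < 1e-12))
                    raise ValueError(
                        f"duplicate (cell, trial, time) at spikes.csv row {rownums[j + 1]}"
                    )
                close = d < MOMENT_WIDTH - 1e-12
                if np.any(close):
                    if not clip:
                        j = int(np.argmax(close))
                        raise ValueError(
                            f"ISI below 1 ms for cell {cid!r} trial {i} at "
                            f"spikes.csv row {rownums[j + 1]}; rerun with clip "
                            "to merge sub-moment spikes"
                        )
                    keep = np.concatenate([[True], ~close])
                    # iterate: merging can expose new sub-moment pairs
                    while True:
                        times = times[keep]
                        if times.size < 2:
                            break
                        close = np.diff(times) < MOMENT_WIDTH - 1e-12
                        if not close.any():
                            break
                        keep = np.concatenate([[True], ~close])
                    log.info("cell %s trial %d: merged sub-moment spikes", cid, i)
            trials.append(Trial(spike_times=times, record_start=rs, record_end=re_))
            phases = tsub["phase"].unique()
            labels.append(str(phases[0]) if len(phases) else "probe")
        recordings.append(
            CellRecording(cell_id=str(cid), protocol=proto, trials=trials, phase_labels=labels)
        )
    return recordings
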