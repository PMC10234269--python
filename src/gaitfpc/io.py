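"""Columnar trial files, pipeline configuration and serialization.

A trial file is plain CSV with a ``# key: value`` metadata header (sampling
rate, condition, participant id, leg length) followed by the required
time-series columns; units are fixed by the column names. Round-trips are
lossless (17 significant digits).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = (
    "time_s",
    "cop_ap_m",
    "cop_ml_m",
    "grf_ap_left_N",
    "grf_ap_right_N",
    "ankle_moment_left_Nm",
    "ankle_moment_right_Nm",
    "com_pos_ap_m",
    "com_vel_ap_mps",
    "heel_ap_left_m",
    "heel_ap_right_m",
)

CONDITIONS = ("normal", "slow")


class TrialFormatError(ValueError):
    """Malformed trial file."""


@dataclass
class Trial:
    """In-memory trial: time-series frame plus header metadata."""

    signals: pd.DataFrame
    fs: float
    condition: str
    participant: str
    leg_length: float


def write_trial(trial, path) -> None:
    """Write a trial (or SyntheticTrial) to a headered CSV file."""
    path = Path(path)
    meta = {
        "fs": trial.fs,
        "condition": trial.condition,
        "participant": getattr(trial, "participant", "unknown"),
        "leg_length": trial.leg_length,
    }
    df = trial.signals
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required columns: {missing}")
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trial(path) -> Trial:
    """Read and validate a trial file; diagnostics name the offending
    column or header line."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        try:
            key, value = line[1:].split(":", 1)
        except ValueError:
            raise TrialFormatError(f"{path}:{i + 1}: malformed header line {line!r}")
        meta[key.strip()] = value.strip()
    for key in ("fs", "condition", "participant", "leg_length"):
        if key not in meta:
            raise TrialFormatError(f"{path}: missing header field '{key}'")
    if meta["condition"] not in CONDITIONS:
        raise TrialFormatError(f"{path}: condition must be one of {CONDITIONS}")
    fs = float(meta["fs"])
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])),
                     float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"{path}: missing required column '{col}'")
        if not np.issubdtype(df[col].dtype, np.number):
            raise TrialFormatError(f"{path}: column '{col}' is not numeric")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise TrialFormatError(f"{path}: time_s not strictly increasing at row {bad}")
    if np.max(np.abs(dt - 1.0 / fs)) > 1e-6:
        raise TrialFormatError(
            f"{path}: time_s spacing disagrees with header fs={fs} by more than 1e-6 s"
        )
    return Trial(signals=df, fs=fs, condition=meta["condition"],
                 participant=meta["participant"], leg_length=float(meta["leg_length"]))


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters."""

    j_ds: int = 20
    j_ss: int = 80
    min_step_time: float = 0.3       # s, event-detection merge window
    smooth_window: float = 0.025     # s, CoP pre-smoothing
    interp_method: str = "linear"
    alpha: float = 0.05
    n_permutations: int = 10_000
    k_extreme: int = 10
    seed: int = 0
    out_dir: str = "results"
    use_truth_events: bool = False   # synthetic trials only: skip detection

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_extreme < 1:
            raise ValueError("k_extreme must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(path, config: PipelineConfig, inputs: list[str],
                   outputs: list[str], dropped: list[str]) -> None:
    from . import __version__

    payload = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "dropped_steps": dropped,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
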