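"""Trial-log I/O and construction of 5 Hz movement-fluctuation series.

Two fluctuation series summarize how a player structures its search:

* the **displacement angle** — the angle of the position displacement
  vector between adjacent timepoints, ``atan2(dy, dx)``; and
* the **head-orientation change** — the smallest signed angular
  difference of the head-orientation channel between adjacent timepoints.

Both are built from tracks decimated from the logging rate to 5 Hz with
the first second of samples removed to discard transients, matching the
preprocessing applied before DFA and before search-area construction.

Trial logs round-trip through a flat CSV (one row per sample) plus a JSON
sidecar manifest carrying configuration, seed, outcome, duration, and
condition labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import STATUS_LABELS, TrialLog

__all__ = [
    "AngleSeries",
    "TrialLogSchemaError",
    "write_trial_log",
    "read_trial_log",
    "downsample",
    "displacement_angle_series",
    "head_orientation_change_series",
    "wrap_angle",
    "prepared_player_tracks",
    "write_angle_series",
]

ANALYSIS_HZ = 5.0

_STATUS_CODE = {label: code for code, label in enumerate(STATUS_LABELS)}


class TrialLogSchemaError(ValueError):
    """A trial-log file violates the expected column schema."""


@dataclass
class AngleSeries:
    """A 5 Hz angular fluctuation series with construction metadata."""

    values: np.ndarray
    kind: str  # "displacement_angle" | "head_orientation_change"
    sample_rate: float = ANALYSIS_HZ
    source_player: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle series contains non-finite values")
        if self.kind not in ("displacement_angle", "head_orientation_change"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)


def wrap_angle(angles: np.ndarray) -> np.ndarray:
    """Map angles to the half-open interval (-pi, pi]."""
    out = np.mod(np.asarray(angles, dtype=float), 2.0 * np.pi)
    return np.where(out > np.pi, out - 2.0 * np.pi, out)


# ---------------------------------------------------------------------------
# Trial-log CSV + manifest I/O
# ---------------------------------------------------------------------------


def _column_names(n_players: int, n_targets: int) -> list[str]:
    cols = ["time_s"]
    for i in range(n_players):
        cols += [f"p{i}_x", f"p{i}_y", f"p{i}_heading"]
    for j in range(n_targets):
        cols += [f"ta{j}_x", f"ta{j}_y", f"ta{j}_status"]
    return cols


def write_trial_log(log: TrialLog, path: str | Path) -> Path:
    """Write a trial log as CSV with a JSON manifest alongside.

    The manifest lives at the same path with a ``.json`` suffix and holds
    the world/policy configuration, seed, outcome, duration, condition
    labels, and sample rate.
    """
    log.validate()
    path = Path(path)
    n, p, k = log.n_samples, log.n_players, log.n_targets
    data: dict[str, np.ndarray | list] = {"time_s": log.time}
    for i in range(p):
        data[f"p{i}_x"] = log.player_pos[:, i, 0]
        data[f"p{i}_y"] = log.player_pos[:, i, 1]
        data[f"p{i}_heading"] = log.player_heading[:, i]
    for j in range(k):
        data[f"ta{j}_x"] = log.ta_pos[:, j, 0]
        data[f"ta{j}_y"] = log.ta_pos[:, j, 1]
        data[f"ta{j}_status"] = [STATUS_LABELS[c] for c in log.ta_status[:, j]]
    frame = pd.DataFrame(data, columns=_column_names(p, k))
    frame.to_csv(path, index=False, float_format="%.17g")

    manifest = {
        "sample_rate": log.sample_rate,
        "n_players": p,
        "n_targets": k,
        "outcome": log.outcome,
        "duration": log.duration,
        "seed": log.seed,
        "condition": log.condition,
        "config": log.config,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path


def read_trial_log(path: str | Path) -> TrialLog:
    """Read a trial log written by :func:`write_trial_log`.

    Raises
    ------
    TrialLogSchemaError
        On missing columns, non-finite numeric entries, or unknown status
        labels; the message names the offending column (and row where
        applicable).
    """
    path = Path(path)
    manifest_path = path.with_suffix(".json")
    if not manifest_path.exists():
        raise TrialLogSchemaError(f"missing manifest sidecar {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    frame = pd.read_csv(path, float_precision="round_trip")

    p = int(manifest["n_players"])
    k = int(manifest["n_targets"])
    expected = _column_names(p, k)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise TrialLogSchemaError(f"missing column(s): {', '.join(missing)}")

    n = len(frame)
    numeric_cols = [c for c in expected if not c.endswith("_status")]
    for col in numeric_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy()))
        if bad.size:
            raise TrialLogSchemaError(
                f"non-finite or non-numeric value in column {col!r} at row {bad[0]}"
            )

    status = np.empty((n, k), dtype=np.int8)
    for j in range(k):
        col = f"ta{j}_status"
        labels = frame[col].astype(str)
        unknown = ~labels.isin(STATUS_LABELS)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise TrialLogSchemaError(
                f"unknown status label {labels.iloc[row]!r} in column {col!r} at row {row}"
            )
        status[:, j] = [_STATUS_CODE[s] for s in labels]

    player_pos = np.stack(
        [frame[[f"p{i}_x", f"p{i}_y"]].to_numpy(float) for i in range(p)], axis=1
    )
    player_heading = np.column_stack([frame[f"p{i}_heading"].to_numpy(float) for i in range(p)])
    ta_pos = np.stack(
        [frame[[f"ta{j}_x", f"ta{j}_y"]].to_numpy(float) for j in range(k)], axis=1
    )

    log = TrialLog(
        sample_rate=float(manifest["sample_rate"]),
        time=frame["time_s"].to_numpy(float),
        player_pos=player_pos,
        player_heading=player_heading,
        ta_pos=ta_pos,
        ta_status=status,
        outcome=str(manifest["outcome"]),
        duration=float(manifest["duration"]),
        seed=manifest.get("seed"),
        condition=manifest.get("condition", {}),
        config=manifest.get("config", {}),
    )
    log.validate()
    return log


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------


def downsample(track: np.ndarray, from_hz: float, to_hz: float = ANALYSIS_HZ) -> np.ndarray:
    """Decimate a track and delete the first second of retained samples.

    Keeps every ``from_hz / to_hz``-th sample starting at index 0 (no
    filtering or interpolation), then removes the first ``to_hz`` samples
    (one second) to discard transients.  The rate ratio must be an exact
    integer.
    """
    track = np.asarray(track)
    ratio = from_hz / to_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"from_hz ({from_hz}) must be an integer multiple of to_hz ({to_hz})"
        )
    kept = track[::factor]
    return kept[int(round(to_hz)):]


def displacement_angle_series(
    positions: np.ndarray,
    source_player: str | None = None,
    hold_last: bool = True,
) -> AngleSeries:
    """Angle of the displacement vector between adjacent 5 Hz positions.

    ``value_t = atan2(y_{t+1} - y_t, x_{t+1} - x_t)`` in (-pi, pi]; the
    output has one fewer sample than the input.  A zero-displacement frame
    has no defined angle: by default the previous angle is carried forward
    (0 before any motion); with ``hold_last=False`` such frames emit 0.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
        raise ValueError("positions must be an (n >= 2, 2) array")
    d = np.diff(pos, axis=0)
    stationary = (d[:, 0] == 0.0) & (d[:, 1] == 0.0)
    angles = np.arctan2(d[:, 1], d[:, 0])
    angles = np.asarray(wrap_angle(angles))
    if hold_last:
        idx = np.where(~stationary, np.arange(angles.size), -1)
        idx = np.maximum.accumulate(idx)
        angles = np.where(idx >= 0, angles[np.maximum(idx, 0)], 0.0)
    else:
        angles = np.where(stationary, 0.0, angles)
    return AngleSeries(values=angles, kind="displacement_angle",
                       source_player=source_player)


def head_orientation_change_series(
    headings: np.ndarray, source_player: str | None = None
) -> AngleSeries:
    """Wrap-aware change in head orientation between adjacent 5 Hz samples.

    Differences are mapped to the smallest signed angle in (-pi, pi], so
    a rotation from 179 degrees to -179 degrees counts as +2 degrees, not
    -358.
    """
    h = np.asarray(headings, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("headings must be a 1-D array of length >= 2")
    return AngleSeries(
        values=np.asarray(wrap_angle(np.diff(h))),
        kind="head_orientation_change",
        source_player=source_player,
    )


def prepared_player_tracks(
    log: TrialLog, player: int
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, headings) of one player at 5 Hz with transient removed."""
    positions = downsample(log.player_pos[:, player, :], log.sample_rate, ANALYSIS_HZ)
    headings = downsample(log.player_heading[:, player], log.sample_rate, ANALYSIS_HZ)
    return positions, headings


def write_angle_series(series: AngleSeries, path: str | Path) -> Path:
    """Write an angle series as a two-column CSV (time_s, value_rad)."""
    path = Path(path)
    t = np.arange(series.n) / series.sample_rate
    pd.DataFrame({"time_s": t, "value_rad": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path
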