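"""On-disk formats, probe geometry and session loading.

Conventions used throughout the package: time is in seconds (float, zero at
paradigm start), sample indices are 0-based, channel and electrode ids are
1-based to match the montage figures.  The canonical interchange format is a
UTF-8 tab-separated table with ``#``-prefixed ``key: value`` metadata lines
before the header row; the paradigm is a 3-column onset/duration/condition
table in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hrf import ParadigmSchedule

__all__ = [
    "ProbeGeometry",
    "default_geometry",
    "validate_geometry",
    "Session",
    "load_session",
    "write_timeseries",
    "read_timeseries",
    "write_paradigm",
    "read_paradigm",
    "fnirs_to_eeg_index",
]

N_EMITTERS = 12
N_DETECTORS = 3
N_CHANNELS = 36


@dataclass
class ProbeGeometry:
    """Optode/electrode layout of the hybrid patch over the left motor cortex.

    Twelve emitters and three detectors form 36 channels under the pairing
    ``channel = emitter + 12 * (detector - 1)`` (so emitter 1 + detector 1 is
    channel 1 and emitter 1 + detector 2 is channel 13).  Five EEG electrodes
    sit on the same patch: #1-2 horizontally above the grid, #3-5 vertically
    along its left edge.
    """

    emitters: dict[int, tuple[float, float]]
    detectors: dict[int, tuple[float, float]]
    channels: pd.DataFrame  # channel_id, emitter_id, detector_id, x, y, distance_cm
    electrodes: pd.DataFrame  # electrode_id, x, y, group


def default_geometry(spacing_cm: float = 1.4, row_gap_cm: float = 1.0) -> ProbeGeometry:
    """Reference montage: 4 x 3 emitter grid with one detector per row."""
    emitters: dict[int, tuple[float, float]] = {}
    for e in range(1, N_EMITTERS + 1):
        col = (e - 1) % 4
        row = (e - 1) // 4
        emitters[e] = (col * spacing_cm, -row * row_gap_cm)
    detectors = {
        d: (1.5 * spacing_cm, -(d - 1) * row_gap_cm) for d in range(1, N_DETECTORS + 1)
    }
    rows = []
    for d in range(1, N_DETECTORS + 1):
        for e in range(1, N_EMITTERS + 1):
            ch = e + N_EMITTERS * (d - 1)
            ex, ey = emitters[e]
            dx, dy = detectors[d]
            dist = float(np.hypot(ex - dx, ey - dy))
            rows.append((ch, e, d, (ex + dx) / 2, (ey + dy) / 2, max(dist, spacing_cm / 2)))
    channels = pd.DataFrame(
        rows, columns=["channel_id", "emitter_id", "detector_id", "x", "y", "distance_cm"]
    ).sort_values("channel_id", ignore_index=True)
    electrodes = pd.DataFrame(
        {
            "electrode_id": [1, 2, 3, 4, 5],
            "x": [0.5 * spacing_cm, 2.5 * spacing_cm, -0.7, -0.7, -0.7],
            "y": [0.8, 0.8, 0.0, -1.0, -2.0],
            "group": ["horizontal", "horizontal", "vertical", "vertical", "vertical"],
        }
    )
    return ProbeGeometry(emitters, detectors, channels, electrodes)


def validate_geometry(g: ProbeGeometry) -> list[str]:
    """Check the montage against the pairing and grouping rules.

    Returns a list of human-readable violations (empty = valid).
    """
    report: list[str] = []
    if len(g.emitters) != N_EMITTERS:
        report.append(f"expected {N_EMITTERS} emitters, found {len(g.emitters)}")
    if len(g.detectors) != N_DETECTORS:
        report.append(f"expected {N_DETECTORS} detectors, found {len(g.detectors)}")
    ids = g.channels["channel_id"].to_numpy()
    if len(ids) != N_CHANNELS or len(np.unique(ids)) != len(ids):
        report.append(f"expected {N_CHANNELS} unique channel ids, found {len(ids)} rows")
    for _, row in g.channels.iterrows():
        want = row["emitter_id"] + N_EMITTERS * (row["detector_id"] - 1)
        if row["channel_id"] != want:
            report.append(
                f"channel {row['channel_id']}: pairing rule gives {want} for "
                f"emitter {row['emitter_id']} / detector {row['detector_id']}"
            )
    if (g.channels["distance_cm"] <= 0).any():
        report.append("non-positive emitter-detector distance")
    groups = dict(zip(g.electrodes["electrode_id"], g.electrodes["group"]))
    for e in (1, 2):
        if groups.get(e) != "horizontal":
            report.append(f"electrode {e} must be in the horizontal group")
    for e in (3, 4, 5):
        if groups.get(e) != "vertical":
            report.append(f"electrode {e} must be in the vertical group")
    return report


# ---------------------------------------------------------------------------
# delimited time-series tables


def write_timeseries(
    path, df: pd.DataFrame, meta: dict | None = None, float_format: str = "%.17g"
) -> None:
    """Write a wide time-series table with '#'-prefixed metadata lines.

    The default float format preserves full double precision so writer and
    reader round-trip losslessly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format=float_format)


def read_timeseries(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_timeseries`; returns (df, meta)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return df, meta


def write_paradigm(path, schedule: ParadigmSchedule) -> None:
    table = schedule.to_table()
    write_timeseries(
        path,
        table,
        meta={
            "format": "paradigm onset/duration/condition (seconds, 0-based onsets)",
            "fnirs_rate_hz": schedule.rate,
            "n_trials": schedule.n_trials,
        },
    )


def read_paradigm(path) -> ParadigmSchedule:
    table, meta = read_timeseries(path)
    if "fnirs_rate_hz" not in meta:
        raise ValueError(f"{path}: paradigm file lacks the fnirs_rate_hz metadata line")
    rate = float(meta["fnirs_rate_hz"])
    task = table[table["condition"] == "task"].reset_index(drop=True)
    if task.empty:
        raise ValueError(f"{path}: paradigm contains no task blocks")
    task_s = float(task["duration"].iloc[0])
    pre_rest_s = float(task["onset"].iloc[0])
    if len(task) > 1:
        rest_s = float(task["onset"].iloc[1] - task["onset"].iloc[0] - task_s)
    else:
        rest_s = float(table["duration"].iloc[-2]) if len(table) > 2 else 0.0
    total = float((table["onset"] + table["duration"]).max())
    post_rest_s = total - (pre_rest_s + len(task) * (task_s + rest_s))
    return ParadigmSchedule.block_design(
        n_trials=len(task),
        task_s=task_s,
        rest_s=rest_s,
        pre_rest_s=pre_rest_s,
        post_rest_s=max(post_rest_s, 0.0),
        rate=rate,
    )


# ---------------------------------------------------------------------------
# sessions


@dataclass
class Session:
    """Aligned dual-modality session on a shared zero at paradigm start.

    fNIRS intensity tables are wide (time + ch1..chN columns, one table per
    wavelength); EEG is wide (time + e1..eM).  Each modality keeps its native
    rate; :func:`fnirs_to_eeg_index` maps between the two clocks.
    """

    intensity_690: pd.DataFrame
    intensity_830: pd.DataFrame
    eeg: pd.DataFrame
    schedule: ParadigmSchedule
    fnirs_rate: float
    eeg_rate: float
    truth: dict | None = None
    spec: object | None = None

    @property
    def fnirs_channels(self) -> list[int]:
        return [int(c[2:]) for c in self.intensity_690.columns if c.startswith("ch")]

    @property
    def electrodes(self) -> list[int]:
        return [int(c[1:]) for c in self.eeg.columns if c.startswith("e")]

    def intensity_pair(self, channel_id: int) -> tuple[np.ndarray, np.ndarray]:
        col = f"ch{channel_id}"
        return (
            self.intensity_690[col].to_numpy(),
            self.intensity_830[col].to_numpy(),
        )


def fnirs_to_eeg_index(i, fnirs_rate: float = 9.19, eeg_rate: float = 256.0):
    """Nearest EEG sample index for fNIRS sample index ``i``."""
    return np.round(np.asarray(i) * eeg_rate / fnirs_rate).astype(int)


def load_session(directory) -> Session:
    """Load a session written by the fixture writer from a directory.

    Expects intensity_690.tsv, intensity_830.tsv, eeg.tsv, paradigm.tsv and
    manifest.json; raises a structured error naming any missing file.
    """
    directory = Path(directory)
    paths = {
        name: directory / f"{name}.tsv"
        for name in ("intensity_690", "intensity_830", "eeg", "paradigm")
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"session is missing its {name} file: {p}")
    i690, meta690 = read_timeseries(paths["intensity_690"])
    i830, _ = read_timeseries(paths["intensity_830"])
    eeg, meta_eeg = read_timeseries(paths["eeg"])
    schedule = read_paradigm(paths["paradigm"])
    if len(i690) != len(i830):
        raise ValueError("intensity_690 and intensity_830 differ in length")
    spec = None
    manifest = directory / "manifest.json"
    if manifest.exists():
        with manifest.open() as fh:
            spec = json.load(fh)
    return Session(
        intensity_690=i690,
        intensity_830=i830,
        eeg=eeg,
        schedule=schedule,
        fnirs_rate=float(meta690.get("rate_hz", schedule.rate)),
        eeg_rate=float(meta_eeg.get("rate_hz", 256.0)),
        spec=spec,
    )
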