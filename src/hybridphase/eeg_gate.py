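"""EEG band-power gating and the electrode -> fNIRS-channel cross-check.

Beta-band power in a 1-s moving window is compared against the maximum
window power of the resting baseline; an exceedance by more than the
configured fraction (15% by default) is a *gate event* and triggers the
placement of the inner threshold circle in the vector-phase diagram.  The
cross-check map translates the best-responding horizontal/vertical electrode
pair into the set of nearby fNIRS channels worth monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GateConfig",
    "CrossCheckMap",
    "window_power",
    "sliding_power",
    "baseline_max_power",
    "gate",
    "select_electrodes",
    "candidate_channels",
]

#: Electrode grouping on the hybrid patch: #1-2 run horizontally above the
#: optode grid, #3-5 vertically along its left edge.
HORIZONTAL_ELECTRODES = (1, 2)
VERTICAL_ELECTRODES = (3, 4, 5)

#: fNIRS sampling rate of the reference acquisition (Hz); the default window
#: hop so gate events and trajectory samples share a clock.
FNIRS_RATE_HZ = 9.19


@dataclass(frozen=True)
class GateConfig:
    """Configuration of the EEG activation gate.

    ``threshold_frac`` is the fractional margin over the baseline maximum
    window power (0.15 = 15%).  ``baseline_t`` delimits the resting baseline
    in seconds.  ``joint`` demands that *both* selected electrodes exceed
    the threshold (set False to gate on the best electrode alone).
    """

    threshold_frac: float = 0.15
    baseline_t: tuple[float, float] = (0.0, 60.0)
    band: str = "beta"
    window_s: float = 1.0
    hop_s: float = 1.0 / FNIRS_RATE_HZ
    joint: bool = True

    def __post_init__(self) -> None:
        if self.threshold_frac < 0:
            raise ValueError("threshold_frac must be >= 0")
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be > 0")


def window_power(
    band_series: np.ndarray, rate: float, t_start: float, duration: float = 1.0
) -> float:
    """Mean squared amplitude of a band-limited series over one window."""
    x = np.asarray(band_series, dtype=float)
    i0 = int(round(t_start * rate))
    i1 = int(round((t_start + duration) * rate))
    if i0 < 0 or i1 > len(x) or i1 <= i0:
        raise ValueError(
            f"window [{t_start}, {t_start + duration}] s outside series of "
            f"{len(x) / rate:.2f} s"
        )
    w = x[i0:i1]
    return float(np.mean(w * w))


def sliding_power(
    band_series: np.ndarray,
    rate: float,
    window_s: float = 1.0,
    hop_s: float = 1.0 / FNIRS_RATE_HZ,
) -> pd.DataFrame:
    """Power of every complete sliding window.

    Returns a table (window_id, t_start, t_end, power); window k starts at
    ``k * hop_s``.  Implemented with a cumulative sum so the full-session
    sweep is O(n).
    """
    x = np.asarray(band_series, dtype=float)
    n = len(x)
    wlen = int(round(window_s * rate))
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    starts_t = []
    k = 0
    idx0 = []
    while True:
        i0 = int(round(k * hop_s * rate))
        if i0 + wlen > n:
            break
        idx0.append(i0)
        starts_t.append(k * hop_s)
        k += 1
    idx0 = np.asarray(idx0, dtype=int)
    power = (csum[idx0 + wlen] - csum[idx0]) / wlen
    t0 = np.asarray(starts_t)
    return pd.DataFrame(
        {
            "window_id": np.arange(len(idx0)),
            "t_start": t0,
            "t_end": t0 + window_s,
            "power": power,
        }
    )


def baseline_max_power(
    powers: pd.DataFrame, baseline_t: tuple[float, float], window_s: float = 1.0
) -> float:
    """Maximum baseline window power over non-overlapping 1-s windows.

    The threshold reference is the maximum over all complete, *tiling*
    windows of the baseline span; using every sliding window would take the
    maximum of hundreds of heavily correlated estimates and systematically
    overshoot it.
    """
    sel = (powers["t_start"] >= baseline_t[0]) & (powers["t_end"] <= baseline_t[1])
    if not sel.any():
        raise ValueError(f"no complete windows inside baseline {baseline_t}")
    tbl = powers.loc[sel]
    # keep windows on the non-overlapping grid anchored at the baseline start
    k = np.round((tbl["t_start"] - baseline_t[0]) / window_s)
    on_grid = np.abs(tbl["t_start"] - baseline_t[0] - k * window_s) < window_s / 4
    if on_grid.any():
        tbl = tbl.loc[on_grid]
    return float(tbl["power"].max())


def gate(
    powers_by_electrode: dict[int, pd.DataFrame],
    cfg: GateConfig,
    electrodes: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Gate events: windows whose power strictly exceeds the threshold.

    ``powers_by_electrode`` maps electrode id -> sliding-power table (as
    produced by :func:`sliding_power`, identical window grids).  The
    threshold per electrode is ``(1 + threshold_frac) * max`` baseline window
    power of that electrode.  With ``cfg.joint`` both monitored electrodes
    must exceed their thresholds in the same window.  Returns a table
    (window_id, t_start, t_end, power, threshold) where power/threshold refer
    to the first monitored electrode.
    """
    if electrodes is None:
        electrodes = tuple(sorted(powers_by_electrode))[:1]
    masks = []
    ref = None
    for e in electrodes:
        tbl = powers_by_electrode[e]
        thr = (1.0 + cfg.threshold_frac) * baseline_max_power(tbl, cfg.baseline_t)
        masks.append(tbl["power"].to_numpy() > thr)
        if ref is None:
            ref = tbl.assign(power=tbl["power"], threshold=thr)
    fire = np.logical_and.reduce(masks) if cfg.joint else np.logical_or.reduce(masks)
    events = ref.loc[fire, ["window_id", "t_start", "t_end", "power", "threshold"]]
    return events.reset_index(drop=True)


def select_electrodes(
    epoch_powers: dict[int, float],
    horizontal: tuple[int, ...] = HORIZONTAL_ELECTRODES,
    vertical: tuple[int, ...] = VERTICAL_ELECTRODES,
) -> tuple[int, int]:
    """Best-responding (horizontal, vertical) electrode pair.

    Argmax of task-epoch power within each group; ties break to the lowest
    electrode id.
    """
    def best(group: tuple[int, ...]) -> int:
        if not group:
            raise ValueError("electrode group is empty")
        return min(group, key=lambda e: (-epoch_powers[e], e))

    return best(horizontal), best(vertical)


def _replicate_rows(base: tuple[int, ...]) -> frozenset[int]:
    """4 base channels replicated across the 3 detector rows (+0/+12/+24)."""
    return frozenset(b + off for b in base for off in (0, 12, 24))


@dataclass(frozen=True)
class CrossCheckMap:
    """Lookup from a (horizontal, vertical) electrode pair to fNIRS channels.

    Each mapped set holds exactly 12 channels: the 4 first-row channels
    nearest the electrode pair, replicated across the three detector rows.
    The default ships the pairs recoverable from the reference montage;
    further pairs can be supplied in configuration.
    """

    lookup: dict[tuple[int, int], frozenset[int]] = field(
        default_factory=lambda: {
            (1, 4): _replicate_rows((5, 6, 8, 9)),
            (1, 3): _replicate_rows((8, 9, 11, 12)),
        }
    )

    def __post_init__(self) -> None:
        for pair, chans in self.lookup.items():
            if len(chans) != 12:
                raise ValueError(f"pair {pair}: mapped set must have exactly 12 channels")
            base = sorted(c for c in chans if c <= 12)
            if frozenset(chans) != _replicate_rows(tuple(base)):
                raise ValueError(
                    f"pair {pair}: channels must be 4 base channels replicated "
                    "across detector rows (+0, +12, +24)"
                )


def candidate_channels(pair: tuple[int, int], cmap: CrossCheckMap | None = None) -> frozenset[int]:
    """fNIRS channels to monitor for a selected electrode pair."""
    cmap = cmap or CrossCheckMap()
    try:
        return cmap.lookup[tuple(pair)]
    except KeyError:
        raise KeyError(
            f"electrode pair {tuple(pair)} has no cross-check entry; supply one in "
            "the CrossCheckMap configuration"
        ) from None
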