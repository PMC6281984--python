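"""Raw-signal conversion and band filtering.

Continuous-wave fNIRS intensities at 690 and 830 nm are converted to
optical-density changes and then, through the modified Beer-Lambert law
(MBLL), to oxy-/deoxy-hemoglobin concentration changes.  Hemodynamic series
are band-pass filtered (4th-order Butterworth, 0.01-0.15 Hz) to suppress
cardiac, respiratory and drift components; EEG is split into the delta,
theta, alpha and beta bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ExtinctionTable",
    "HemoSeries",
    "FilterSpec",
    "EEG_BANDS_HZ",
    "intensity_to_od",
    "od_to_hemo",
    "hemo_to_od",
    "bandpass_hemo",
    "bandpass",
    "eeg_band_decompose",
]

#: EEG band edges in Hz.
EEG_BANDS_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 28.0),
}


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (mM^-1 cm^-1) at the two wavelengths.

    Defaults are the values used for the ISS Imagent wavelength pair:
    at 690 nm deoxyhemoglobin dominates absorption, at 830 nm
    oxyhemoglobin does.
    """

    eps_hbo_690: float = 0.95
    eps_hbr_690: float = 4.93
    eps_hbo_830: float = 2.135
    eps_hbr_830: float = 1.791

    @property
    def matrix(self) -> np.ndarray:
        """Rows = wavelengths (690, 830); columns = chromophores (HbO, HbR)."""
        return np.array(
            [
                [self.eps_hbo_690, self.eps_hbr_690],
                [self.eps_hbo_830, self.eps_hbr_830],
            ]
        )

    @property
    def inverse(self) -> np.ndarray:
        m = self.matrix
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) < 1e-12:
            raise ValueError(
                "extinction matrix for wavelengths (690, 830) is singular; "
                "the chromophore spectra must differ between wavelengths"
            )
        return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


@dataclass
class HemoSeries:
    """Paired oxy/deoxy-hemoglobin concentration-change series for a channel.

    Units are mM when pathlength and DPF were applied during conversion
    (mM*cm otherwise, i.e. molar-absorbance scale).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    rate: float
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")

    def __len__(self) -> int:
        return len(self.hbo)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.hbo)) / self.rate

    def slice_seconds(self, t_start: float, t_end: float) -> "HemoSeries":
        i0 = int(np.ceil(t_start * self.rate - 1e-9))
        i1 = int(np.floor(t_end * self.rate + 1e-9)) + 1
        i0, i1 = max(i0, 0), min(i1, len(self.hbo))
        return HemoSeries(self.hbo[i0:i1], self.hbr[i0:i1], self.rate, self.channel_id)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for hemodynamic series."""

    order: int = 4
    low_cut: float = 0.01
    high_cut: float = 0.15
    mode: str = "causal"  # or "zero-phase"

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError("mode must be 'causal' or 'zero-phase'")

    def validate_rate(self, rate: float) -> None:
        if self.high_cut >= rate / 2:
            raise ValueError(
                f"high_cut={self.high_cut} Hz is at or above Nyquist ({rate / 2} Hz)"
            )


def intensity_to_od(raw_intensity: np.ndarray, baseline_window: slice | tuple) -> np.ndarray:
    """Optical-density change relative to the mean baseline intensity.

    ``dOD(t) = -log10(I(t) / mean(I_baseline))`` per wavelength.  Raises on
    non-positive intensities, naming the first offending sample.
    """
    x = np.asarray(raw_intensity, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"non-positive intensity at sample index {bad[0]}")
    if isinstance(baseline_window, tuple):
        baseline_window = slice(*baseline_window)
    base = x[baseline_window]
    if base.size == 0:
        raise ValueError("baseline window is empty")
    return -np.log10(x / base.mean())


def od_to_hemo(
    od_690: np.ndarray,
    od_830: np.ndarray,
    ext: ExtinctionTable | None = None,
    pathlength_cm: float = 3.0,
    dpf: float = 6.0,
    rate: float = 9.19,
    channel_id: int = 0,
) -> HemoSeries:
    """Invert the MBLL: optical densities at the two wavelengths -> (dHbO, dHbR).

    ``(dHbO, dHbR) = E^-1 (dOD_690, dOD_830) / (pathlength_cm * dpf)`` per
    sample, with E the 2x2 extinction matrix.  With ``pathlength_cm = dpf = 1``
    the output stays on the molar-absorbance (mM*cm) scale.
    """
    if pathlength_cm <= 0 or dpf <= 0:
        raise ValueError("pathlength_cm and dpf must be > 0")
    ext = ext or ExtinctionTable()
    od = np.vstack([np.asarray(od_690, float), np.asarray(od_830, float)])
    conc = ext.inverse @ od / (pathlength_cm * dpf)
    return HemoSeries(conc[0], conc[1], rate=rate, channel_id=channel_id)


def hemo_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    ext: ExtinctionTable | None = None,
    pathlength_cm: float = 3.0,
    dpf: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL model: concentration changes -> optical-density changes.

    Exact inverse of :func:`od_to_hemo`; used by the synthetic generator to
    fold ground-truth concentrations into two-wavelength intensities.
    """
    ext = ext or ExtinctionTable()
    od = ext.matrix @ np.vstack([hbo, hbr]) * (pathlength_cm * dpf)
    return od[0], od[1]


def _butter_sos(order: int, low: float, high: float, rate: float):
    return signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass(x: np.ndarray, rate: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the Butterworth band-pass to one series (causal by default).

    The causal filter is initialised at steady state with respect to the
    first sample; without this the slow high-pass pole rings for tens of
    seconds at session start and the startup transient would dominate the
    resting baseline.
    """
    spec = spec or FilterSpec()
    spec.validate_rate(rate)
    x = np.asarray(x, float)
    sos = _butter_sos(spec.order, spec.low_cut, spec.high_cut, rate)
    if spec.mode == "zero-phase":
        return signal.sosfiltfilt(sos, x)
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def bandpass_hemo(h: HemoSeries, spec: FilterSpec | None = None) -> HemoSeries:
    """Band-pass both chromophore series of a channel, preserving length."""
    spec = spec or FilterSpec()
    return HemoSeries(
        bandpass(h.hbo, h.rate, spec),
        bandpass(h.hbr, h.rate, spec),
        rate=h.rate,
        channel_id=h.channel_id,
    )


def eeg_band_decompose(
    eeg: np.ndarray, rate: float = 256.0, order: int = 4
) -> dict[str, np.ndarray]:
    """Split an EEG series into delta/theta/alpha/beta band series.

    Each band is a 4th-order Butterworth band-pass (the delta band is the
    cascade of a 0.5 Hz high-pass and a 4 Hz low-pass of the same order).
    Requires the sampling rate to resolve the beta band (rate > 56 Hz).
    """
    if rate <= 2 * EEG_BANDS_HZ["beta"][1]:
        raise ValueError(f"rate={rate} Hz too low to resolve the beta band (needs > 56 Hz)")
    x = np.asarray(eeg, dtype=float)
    out: dict[str, np.ndarray] = {}
    for band, (lo, hi) in EEG_BANDS_HZ.items():
        if band == "delta":
            hp = signal.butter(order, lo, btype="highpass", fs=rate, output="sos")
            lp = signal.butter(order, hi, btype="lowpass", fs=rate, output="sos")
            out[band] = signal.sosfilt(lp, signal.sosfilt(hp, x))
        else:
            out[band] = signal.sosfilt(_butter_sos(order, lo, hi, rate), x)
    return out
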