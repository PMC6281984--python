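"""Seeded synthetic dual-modality sessions with ground truth.

A session emulates the block paradigm of the reference acquisition: 60 s
pre-rest, twelve 30-s trials (10 s thumb-tapping task + 20 s rest) and 10 s
post-rest, recorded by a 36-channel fNIRS patch at 9.19 Hz and five EEG
electrodes at 256 Hz.  Task-active fNIRS channels carry a two-gamma-HRF
shaped oxyhemoglobin rise with a mirrored deoxyhemoglobin fall; the
concentration ground truth is folded through the forward modified
Beer-Lambert model into two-wavelength intensities so the conversion stage
can be validated by round-trip recovery.  Physiological noise (cardiac,
respiratory, slow drift, white) is added in concentration space.  EEG is
synthesised as band-limited noise whose beta-band amplitude rises during
task blocks on the responsive electrodes, with occasional spontaneous beta
bursts during the rest periods — the false-positive pressure the hybrid
detector exists to reject.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preproc
from .hrf import GammaParams, ParadigmSchedule, canonical_hrf, designed_hrf
from .io import Session, write_paradigm, write_timeseries

__all__ = ["NoiseSpec", "SessionSpec", "generate_session", "generate_study", "write_fixtures"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise structure of one synthetic session.

    fNIRS noise (concentration space, mM): sinusoidal cardiac (~1 Hz),
    respiratory (~0.3 Hz) and low-frequency drift components with
    channel-specific random phases, plus white noise.  Amplitudes are typical
    of band-limited motor-cortex recordings relative to a ~2 uM evoked
    response.  EEG: per-band noise amplitudes (arbitrary uV-scale units),
    task modulation of the beta band by ``eeg_beta_gain_task`` on fully
    responsive electrodes (``electrode_response`` scales the gain per
    electrode), and spontaneous rest-period beta bursts
    (``burst_*`` fields) that mimic transient sensorimotor beta events.
    Bursts are injected only after the pre-rest calibration baseline, which
    the gate assumes to be clean.
    """

    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    drift_hz: float = 0.005
    cardiac_amp: float = 1.0e-4
    resp_amp: float = 2.0e-4
    drift_amp: float = 3.0e-4
    # per-channel spread of the cardiac/respiratory rates; without it the
    # oscillations phase-lock to the 30-s trial grid (0.3 and 1.0 Hz are
    # integer multiples of 1/30 Hz), an artificial coherence real
    # physiology does not have
    cardiac_hz_sd: float = 0.03
    resp_hz_sd: float = 0.02
    # broadband Mayer-wave/vasomotion noise inside the 0.01-0.15 Hz analysis
    # band, the dominant residual after filtering
    vasomotion_band_hz: tuple[float, float] = (0.04, 0.15)
    vasomotion_sd: float = 1.5e-4
    white_sd: float = 3.0e-5
    hbr_noise_scale: float = 0.5
    eeg_beta_gain_task: float = 2.0
    eeg_band_amps: tuple[tuple[str, float], ...] = (
        ("delta", 20.0),
        ("theta", 10.0),
        ("alpha", 10.0),
        ("beta", 5.0),
    )
    eeg_white_sd: float = 2.0
    electrode_response: tuple[float, ...] = (1.0, 0.4, 0.3, 1.0, 0.4)
    # rest-period bursts carry task-level beta power: in scalp EEG a
    # spontaneous sensorimotor beta event is not separable from a voluntary
    # one by band power alone, which is why the fNIRS confirmation exists
    burst_gain: float = 2.0
    burst_rate_hz: float = 0.15
    burst_duration_range_s: tuple[float, float] = (0.3, 1.5)

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "resp_amp", "drift_amp", "vasomotion_sd",
                 "white_sd", "eeg_white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.burst_duration_range_s
        if self.burst_rate_hz < 0 or not 0 < lo <= hi:
            raise ValueError("burst rate must be >= 0 and duration range positive")


@dataclass(frozen=True)
class SessionSpec:
    """Everything needed to deterministically regenerate one session."""

    n_trials: int = 12
    task_s: float = 10.0
    rest_s: float = 20.0
    pre_rest_s: float = 60.0
    post_rest_s: float = 10.0
    fnirs_rate: float = 9.19
    eeg_rate: float = 256.0
    n_fnirs_channels: int = 36
    n_eeg_electrodes: int = 5
    active_channel_ids: tuple[int, ...] = (17, 18, 29, 33)
    response_peak_mM: float = 1.0e-3
    hbr_ratio: float = 1.0 / 3.0
    # neurovascular onset latency: hemodynamics start rising ~1 s after
    # neural activity begins
    response_onset_delay_s: float = 1.0
    # trial-to-trial variability: reaction delay between cue and response
    # (applies to both modalities), lognormal hemodynamic amplitude scatter
    # and lognormal scatter of the beta-band ERS magnitude
    reaction_delay_range_s: tuple[float, float] = (0.2, 1.2)
    trial_amp_sigma: float = 0.3
    trial_beta_sigma: float = 0.4
    pathlength_cm: float = 3.0
    dpf: float = 6.0
    # fast-onset two-gamma response (peak ~2 s): the injected dynamics mirror
    # the early threshold-circle crossings observed in real motor recordings,
    # which rise far faster than the canonical slow HRF used for regression
    hrf_params: GammaParams = field(default_factory=lambda: GammaParams(phi1=3))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fnirs_rate, self.eeg_rate) <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if min(self.task_s, self.rest_s) <= 0 or min(self.pre_rest_s, self.post_rest_s) < 0:
            raise ValueError("durations must be positive")
        if not set(self.active_channel_ids) <= set(range(1, self.n_fnirs_channels + 1)):
            raise ValueError("active_channel_ids must be a subset of the channel ids")
        if not 0 < self.hbr_ratio <= 1:
            raise ValueError("hbr_ratio must lie in (0, 1]")

    def schedule(self) -> ParadigmSchedule:
        return ParadigmSchedule.block_design(
            self.n_trials, self.task_s, self.rest_s, self.pre_rest_s,
            self.post_rest_s, self.fnirs_rate,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hrf_params"] = dataclasses.asdict(self.hrf_params)
        d["noise"] = dataclasses.asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSpec":
        d = dict(d)
        d["hrf_params"] = GammaParams(**d["hrf_params"])
        noise = dict(d["noise"])
        noise["eeg_band_amps"] = tuple(tuple(x) for x in noise["eeg_band_amps"])
        noise["electrode_response"] = tuple(noise["electrode_response"])
        d["noise"] = NoiseSpec(**noise)
        d["active_channel_ids"] = tuple(d["active_channel_ids"])
        d["reaction_delay_range_s"] = tuple(d["reaction_delay_range_s"])
        return cls(**d)


def _band_noise(rng: np.random.Generator, n: int, rate: float, band: str) -> np.ndarray:
    lo, hi = preproc.EEG_BANDS_HZ[band]
    from scipy import signal

    white = rng.standard_normal(n)
    if band == "delta":
        hp = signal.butter(4, lo, btype="highpass", fs=rate, output="sos")
        lp = signal.butter(4, hi, btype="lowpass", fs=rate, output="sos")
        x = signal.sosfilt(lp, signal.sosfilt(hp, white))
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        x = signal.sosfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _beta_gain_profile(
    spec: SessionSpec,
    rng: np.random.Generator,
    delays: np.ndarray,
    beta_scales: np.ndarray,
) -> tuple[np.ndarray, list]:
    """Shared beta modulation envelope on the EEG clock (gain 1 baseline).

    The task-active span of trial i runs from cue onset plus that trial's
    reaction delay to the end of the cue block, carrying that trial's ERS
    scale.  Returns (task_scale array — 0 at rest, the trial's beta scale
    during task — and burst intervals in seconds); bursts are drawn inside
    inter-trial rest segments only, keeping the pre-rest calibration
    baseline clean.
    """
    sched = spec.schedule()
    n_e = int(round(sched.duration_s * spec.eeg_rate))
    t = np.arange(n_e) / spec.eeg_rate
    task = np.zeros(n_e)
    for onset, d, sc in zip(sched.trial_onsets_s, delays, beta_scales):
        task[(t >= onset + d) & (t < onset + spec.task_s)] = sc
    bursts: list[tuple[float, float]] = []
    noise = spec.noise
    if noise.burst_rate_hz > 0:
        lo, hi = noise.burst_duration_range_s
        for onset in sched.trial_onsets_s:
            r0, r1 = onset + spec.task_s, onset + spec.task_s + spec.rest_s
            n_bursts = rng.poisson(noise.burst_rate_hz * (r1 - r0))
            durs = rng.uniform(lo, hi, size=n_bursts)
            starts = np.sort(rng.uniform(r0, r1 - hi, size=n_bursts))
            bursts.extend(
                (float(s), float(s + d)) for s, d in zip(starts, durs)
            )
    return task, bursts


def generate_session(spec: SessionSpec) -> Session:
    """Generate one ground-truth-labelled synthetic session.

    Identical ``spec`` (including seed) gives bit-identical output.  The
    returned :class:`~hybridphase.io.Session` carries a ``truth`` dict with
    the injected concentration series, segment labels, burst intervals and
    the active channel set.
    """
    rng = np.random.default_rng(spec.seed)
    sched = spec.schedule()
    n_f = sched.n_samples
    t_f = sched.times_s

    # fixed rng order: trial delays/scales, per-channel amplitude jitter,
    # per-channel noise streams, then EEG streams
    d0, d1 = spec.reaction_delay_range_s
    delays = rng.uniform(d0, d1, size=spec.n_trials)
    trial_scales = np.exp(spec.trial_amp_sigma * rng.standard_normal(spec.n_trials))
    beta_scales = np.exp(spec.trial_beta_sigma * rng.standard_normal(spec.n_trials))
    amp_jitter = 1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=spec.n_fnirs_channels)

    # jittered, per-trial-scaled stimulus convolved with the response kernel
    # (shifted by the neurovascular onset latency); normalised so a
    # unit-scale trial peaks at response_peak_mM
    h_kernel = canonical_hrf(spec.hrf_params, t_f - spec.response_onset_delay_s)
    stim = np.zeros(n_f)
    for onset, d, sc in zip(sched.trial_onsets_s, delays, trial_scales):
        stim[(t_f >= onset + d) & (t_f < onset + spec.task_s)] = sc
    single = ParadigmSchedule.block_design(
        1, spec.task_s, spec.rest_s, 0.0, 0.0, spec.fnirs_rate
    )
    unit_peak = designed_hrf(spec.hrf_params, single).max()
    u = spec.hrf_params.k1 * np.convolve(h_kernel, stim)[:n_f] / unit_peak

    n_ch = spec.n_fnirs_channels
    hbo_true = np.zeros((n_f, n_ch))
    hbr_true = np.zeros((n_f, n_ch))
    for ch in spec.active_channel_ids:
        a = spec.response_peak_mM * amp_jitter[ch - 1]
        hbo_true[:, ch - 1] = a * u
        hbr_true[:, ch - 1] = -spec.hbr_ratio * a * u

    noise = spec.noise
    i690 = np.empty((n_f, n_ch))
    i830 = np.empty((n_f, n_ch))
    ext = preproc.ExtinctionTable()
    from scipy import signal as _signal

    vaso_sos = None
    if noise.vasomotion_sd > 0:
        vaso_sos = _signal.butter(
            2, noise.vasomotion_band_hz, btype="bandpass", fs=spec.fnirs_rate,
            output="sos",
        )
    for c in range(n_ch):
        parts = []
        for comp in ("hbo", "hbr"):
            ph = rng.uniform(0, 2 * np.pi, size=3)
            f_card = rng.normal(noise.cardiac_hz, noise.cardiac_hz_sd)
            f_resp = rng.normal(noise.resp_hz, noise.resp_hz_sd)
            osc = (
                noise.cardiac_amp * np.sin(2 * np.pi * f_card * t_f + ph[0])
                + noise.resp_amp * np.sin(2 * np.pi * f_resp * t_f + ph[1])
                + noise.drift_amp * np.sin(2 * np.pi * noise.drift_hz * t_f + ph[2])
            )
            if vaso_sos is not None:
                v = _signal.sosfilt(vaso_sos, rng.standard_normal(n_f))
                sd = v.std()
                if sd > 0:
                    osc = osc + noise.vasomotion_sd * v / sd
            white = noise.white_sd * rng.standard_normal(n_f)
            parts.append(osc + white)
        hbo_c = hbo_true[:, c] + parts[0]
        hbr_c = hbr_true[:, c] + noise.hbr_noise_scale * parts[1]
        od690, od830 = preproc.hemo_to_od(
            hbo_c, hbr_c, ext, spec.pathlength_cm, spec.dpf
        )
        i690[:, c] = 10.0 ** (-od690)
        i830[:, c] = 10.0 ** (-od830)

    # EEG ------------------------------------------------------------------
    n_e = int(round(sched.duration_s * spec.eeg_rate))
    t_e = np.arange(n_e) / spec.eeg_rate
    task_scale, bursts = _beta_gain_profile(spec, rng, delays, beta_scales)
    burst_mask = np.zeros(n_e, dtype=bool)
    for b0, b1 in bursts:
        burst_mask |= (t_e >= b0) & (t_e < b1)
    amps = dict(noise.eeg_band_amps)
    eeg = np.empty((n_e, spec.n_eeg_electrodes))
    for e in range(spec.n_eeg_electrodes):
        resp = noise.electrode_response[e] if e < len(noise.electrode_response) else 0.0
        x = np.zeros(n_e)
        for band, amp in amps.items():
            comp = amp * _band_noise(rng, n_e, spec.eeg_rate, band)
            if band == "beta":
                gain = 1.0 + (noise.eeg_beta_gain_task - 1.0) * resp * task_scale
                gain[burst_mask] = np.maximum(gain[burst_mask], noise.burst_gain)
                comp = comp * gain
            x += comp
        if noise.eeg_white_sd > 0:
            x += noise.eeg_white_sd * rng.standard_normal(n_e)
        eeg[:, e] = x

    fnirs_cols = [f"ch{c}" for c in range(1, n_ch + 1)]
    eeg_cols = [f"e{e}" for e in range(1, spec.n_eeg_electrodes + 1)]
    truth = {
        "hbo_mM": hbo_true,
        "hbr_mM": hbr_true,
        "active_channel_ids": tuple(spec.active_channel_ids),
        "segment_labels": sched.segment_labels(),
        "beta_bursts_s": bursts,
        "eeg_task_scale": task_scale,
        "reaction_delays_s": delays,
        "trial_amp_scales": trial_scales,
        "trial_beta_scales": beta_scales,
    }
    return Session(
        intensity_690=pd.DataFrame(i690, columns=fnirs_cols).assign(time=t_f)[
            ["time"] + fnirs_cols
        ],
        intensity_830=pd.DataFrame(i830, columns=fnirs_cols).assign(time=t_f)[
            ["time"] + fnirs_cols
        ],
        eeg=pd.DataFrame(eeg, columns=eeg_cols).assign(time=t_e)[["time"] + eeg_cols],
        schedule=sched,
        fnirs_rate=spec.fnirs_rate,
        eeg_rate=spec.eeg_rate,
        truth=truth,
        spec=spec,
    )


def generate_study(
    n_subjects: int = 3, base_spec: SessionSpec | None = None, base_seed: int = 0
) -> list[Session]:
    """One session per subject with subject-specific seeds.

    The default 3-subject study yields 36 channels x 12 trials x 3 subjects
    = 1,296 channel-trial series.
    """
    base_spec = base_spec or SessionSpec()
    sessions = []
    for s in range(n_subjects):
        spec = dataclasses.replace(base_spec, seed=base_seed + 1000 * s)
        sessions.append(generate_session(spec))
    return sessions


def n_channel_trial_series(sessions: list[Session]) -> int:
    """Total number of channel-trial series across sessions."""
    return sum(
        len(s.fnirs_channels) * s.schedule.n_trials for s in sessions
    )


def write_fixtures(session: Session, dir_path) -> dict[str, Path]:
    """Write a session as delimited tables + paradigm + JSON manifest.

    Round-trips losslessly through :func:`hybridphase.io.load_session` (to
    the precision of the decimal text representation, which is full double
    precision here).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for name, df, rate in (
        ("intensity_690", session.intensity_690, session.fnirs_rate),
        ("intensity_830", session.intensity_830, session.fnirs_rate),
        ("eeg", session.eeg, session.eeg_rate),
    ):
        p = dir_path / f"{name}.tsv"
        write_timeseries(
            p,
            df,
            meta={"rate_hz": rate, "units": "intensity (a.u.)" if "intensity" in name else "uV"},
        )
        files[name] = p
    p = dir_path / "paradigm.tsv"
    write_paradigm(p, session.schedule)
    files["paradigm"] = p
    manifest = dir_path / "manifest.json"
    payload = {"seed": getattr(session.spec, "seed", None)}
    if isinstance(session.spec, SessionSpec):
        payload["spec"] = session.spec.to_dict()
    with manifest.open("w") as fh:
        json.dump(payload, fh, indent=1)
    files["manifest"] = manifest
    return files


def regenerate_from_manifest(manifest_path) -> Session:
    """Rebuild a session from its manifest (seed + spec)."""
    with Path(manifest_path).open() as fh:
        payload = json.load(fh)
    return generate_session(SessionSpec.from_dict(payload["spec"]))
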