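"""Trajectory-crossing detection, trial scoring and the LDA baseline.

A command is issued only when the two modalities agree: an EEG gate event
places the inner circle (radius R2, from the hemoglobin excursions inside
the active 1-s window) and the vector-phase trajectory must then cross R2
and subsequently the resting-state circle R1 while in the fourth quadrant
(dHbO > 0 > dHbR) within a timeout.  EEG-only bursts die at the R1 test;
hemodynamic drifts without EEG support never open a gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eeg_gate as gate_mod
from . import phase, preproc

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionRecord",
    "TrialOutcome",
    "detect_events",
    "detect",
    "classify_trials",
    "accuracy_pct",
    "lda_baseline",
    "extract_lda_features",
    "run_hybrid_session",
]


@dataclass(frozen=True)
class DetectionRecord:
    """Outcome of monitoring one channel after one gate event (or trial)."""

    channel_id: int
    trial_id: int
    gate_time: float
    r2: float
    r2_cross_time: float | None
    r1_cross_time: float | None
    decision: str  # "detected" | "not-detected"

    @property
    def latency(self) -> float | None:
        """Seconds from the R2 crossing to the R1 crossing."""
        if self.r1_cross_time is None or self.r2_cross_time is None:
            return None
        return self.r1_cross_time - self.r2_cross_time

    @property
    def command_time(self) -> float | None:
        """Time at which the command is issued (the R1 crossing)."""
        return self.r1_cross_time


@dataclass(frozen=True)
class TrialOutcome:
    trial_id: int
    truth: str
    predicted: str

    @property
    def correct(self) -> bool:
        return self.truth == self.predicted


def detect_events(
    h: preproc.HemoSeries,
    gates: pd.DataFrame,
    r1: float,
    timeout_s: float = 3.0,
    trial_id: int = -1,
) -> list[DetectionRecord]:
    """Evaluate every gate event against one channel's trajectory.

    For each gate event the inner radius R2 is computed from the hemoglobin
    excursions inside the gating window; the trajectory (monitored from the
    window end) must cross R2 and then R1, both in the fourth quadrant, with
    the R1 crossing within ``timeout_s`` of the gate.  Crossing times are
    linearly interpolated between samples.  A degenerate flat baseline
    (r1 == 0) is rejected.
    """
    if r1 <= 0:
        raise ValueError(
            "resting radius r1 is zero; the resting baseline must be nonempty "
            "and nonconstant"
        )
    times = h.times_s
    mags = phase.magnitude(h.hbo, h.hbr)
    q4 = (h.hbo > 0) & (h.hbr < 0)
    records: list[DetectionRecord] = []
    for ev in gates.itertuples(index=False):
        window = h.slice_seconds(ev.t_start, ev.t_end)
        if len(window) == 0:
            continue
        r2 = phase.eeg_window_radius(window)
        gate_t = float(ev.t_end)
        # monitor only the gating window plus the timeout span
        i0 = max(int(np.searchsorted(times, ev.t_start)) - 1, 0)
        i1 = min(int(np.searchsorted(times, gate_t + timeout_s)) + 2, len(times))
        tw, mw, qw = times[i0:i1], mags[i0:i1], q4[i0:i1]
        r2_cross = phase.crossing_time(tw, mw, r2, t_from=gate_t, in_q4=qw)
        r1_cross = None
        decision = "not-detected"
        if r2_cross is not None:
            # normally R1 > R2 and the outer crossing must follow the inner
            # one; if the EEG-window circle exceeds the resting circle the
            # ordering inverts: crossing R2 already proves R1 was passed, so
            # any post-gate Q4 crossing of R1 counts and, failing that, the
            # R2 crossing itself completes the detection
            t_after = r2_cross if r1 >= r2 else gate_t
            r1_cross = phase.crossing_time(tw, mw, r1, t_from=t_after, in_q4=qw)
            if r1_cross is None and r2 > r1:
                r1_cross = r2_cross
            if r1_cross is not None and r1_cross - gate_t <= timeout_s:
                decision = "detected"
            elif r1_cross is not None:
                logger.debug(
                    "channel %d: R1 crossing at %.2f s missed the %.1f s timeout "
                    "after the gate at %.2f s",
                    h.channel_id, r1_cross, timeout_s, gate_t,
                )
                r1_cross = None
        records.append(
            DetectionRecord(
                channel_id=h.channel_id,
                trial_id=trial_id,
                gate_time=gate_t,
                r2=r2,
                r2_cross_time=r2_cross,
                r1_cross_time=r1_cross if decision == "detected" else None,
                decision=decision,
            )
        )
    return records


def detect(
    h: preproc.HemoSeries,
    gates: pd.DataFrame,
    r1: float,
    schedule=None,
    timeout_s: float = 3.0,
) -> list[DetectionRecord]:
    """Per-trial detection records for one channel.

    With a schedule, gate events are grouped by trial (the trial whose
    [onset, onset + task + rest) span contains the gating-window end) and the
    first successful detection per trial is reported; trials without one get
    a not-detected record.  Without a schedule this is :func:`detect_events`.
    """
    if schedule is None:
        return detect_events(h, gates, r1, timeout_s)
    onsets = schedule.trial_onsets_s
    span = schedule.task_s + schedule.rest_s
    per_trial: list[DetectionRecord] = []
    for i, onset in enumerate(onsets):
        sel = gates[(gates["t_end"] >= onset) & (gates["t_end"] < onset + span)]
        hit = None
        for k in range(len(sel)):  # stop at the first successful gate
            recs = detect_events(h, sel.iloc[k : k + 1], r1, timeout_s, trial_id=i)
            if recs and recs[0].decision == "detected":
                hit = recs[0]
                break
        if hit is not None:
            per_trial.append(hit)
        else:
            per_trial.append(
                DetectionRecord(h.channel_id, i, float("nan"), float("nan"), None, None,
                                "not-detected")
            )
    return per_trial


def accuracy_pct(n_correct: int, n_total: int) -> float:
    """Accuracy in percent, reported to one decimal (10/12 -> 83.3)."""
    if n_total <= 0:
        raise ValueError("empty outcome set")
    return round(100.0 * n_correct / n_total, 1)


def classify_trials(
    records: list[DetectionRecord],
    schedule,
    rest_offset_s: float = 20.0,
) -> tuple[list[TrialOutcome], float]:
    """Score per-trial task/rest decisions against the paradigm.

    ``records`` pools the detection records of every monitored channel;
    channel fusion is a logical OR.  A trial is predicted *task* iff any
    channel completed a detection (gate event plus Q4 crossings within its
    timeout) whose gate fired inside the trial's task block.  Matched
    negatives are equally long segments time-locked ``rest_offset_s`` after
    each onset — by default the last 10 s of each rest period, i.e. the
    pre-cue baseline of the next trial, where the hemodynamic response has
    returned toward baseline — predicted *task* (incorrectly) iff a
    completed detection's gate fired inside them, giving one balanced
    negative per trial.  Returns (outcomes, accuracy %).
    """
    if not records:
        raise ValueError("no detection records to score")
    gate_times = np.array(
        [r.gate_time for r in records if r.decision == "detected"], dtype=float
    )

    def any_detection(t0: float, t1: float) -> bool:
        return bool(((gate_times >= t0) & (gate_times <= t1)).any()) if gate_times.size else False

    span = schedule.task_s
    outcomes: list[TrialOutcome] = []
    for i, onset in enumerate(schedule.trial_onsets_s):
        hit = any_detection(onset, onset + span)
        outcomes.append(TrialOutcome(i, "task", "task" if hit else "rest"))
        neg0 = onset + rest_offset_s
        hit = any_detection(neg0, neg0 + span)
        outcomes.append(TrialOutcome(i, "rest", "task" if hit else "rest"))
    acc = accuracy_pct(sum(o.correct for o in outcomes), len(outcomes))
    return outcomes, acc


# ---------------------------------------------------------------------------
# LDA baseline


def extract_lda_features(
    hemo_by_channel: dict[int, preproc.HemoSeries],
    beta_by_electrode: dict[int, np.ndarray],
    eeg_rate: float,
    schedule,
    channels: tuple[int, ...],
    electrodes: tuple[int, int],
    window_s: float = 1.5,
    rest_offset_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for the windowed LDA comparison.

    One row per scoring window: 12 task windows at the cue onsets and 12
    matched negatives at the end of each rest period (the pre-cue baseline
    of the following trial; ``rest_offset_s`` overrides the anchor).
    Features: per monitored channel the mean and slope of dHbO over the
    0..window_s span, plus the beta-band window power of each selected
    electrode.  Labels: 1 = task, 0 = rest.
    """
    if rest_offset_s is None:
        rest_offset_s = schedule.task_s + schedule.rest_s - window_s
    rows, labels = [], []
    for onset in schedule.trial_onsets_s:
        for t0, y in ((onset, 1), (onset + rest_offset_s, 0)):
            feats = []
            for ch in channels:
                h = hemo_by_channel[ch]
                seg = h.slice_seconds(t0, t0 + window_s)
                tt = np.arange(len(seg)) / h.rate
                feats.append(seg.hbo.mean())
                feats.append(np.polyfit(tt, seg.hbo, 1)[0] if len(seg) > 1 else 0.0)
            for e in electrodes:
                feats.append(
                    gate_mod.window_power(beta_by_electrode[e], eeg_rate, t0, window_s)
                )
            rows.append(feats)
            labels.append(y)
    return np.asarray(rows), np.asarray(labels)


def lda_baseline(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated LDA accuracy in percent.

    When the within-class scatter is (near-)singular — fewer training
    samples than features — a ridge-regularised (Ledoit-Wolf shrinkage)
    solver is used instead of plain LDA, and the fallback is logged.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import LeaveOneOut, cross_val_score

    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("LDA needs at least two classes")
    n, p = X.shape
    if p >= n - 1:
        logger.info(
            "within-class scatter singular (%d features, %d samples): using "
            "shrinkage-regularised LDA", p, n,
        )
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        clf = LinearDiscriminantAnalysis()
    scores = cross_val_score(clf, X, y, cv=LeaveOneOut())
    return accuracy_pct(int(scores.sum()), len(scores))


# ---------------------------------------------------------------------------
# full-session pipeline


def run_hybrid_session(
    session,
    gate_cfg: gate_mod.GateConfig | None = None,
    cross_map: gate_mod.CrossCheckMap | None = None,
    filter_spec: preproc.FilterSpec | None = None,
    rest_offset_s: float = 20.0,
    timeout_s: float = 3.0,
    with_lda: bool = True,
) -> dict:
    """Run the full hybrid pipeline on one (synthetic or loaded) session.

    Converts intensities to band-passed hemodynamics, decomposes EEG,
    selects the electrode pair on the first-trial calibration epoch, gates
    on joint beta-power exceedance, monitors the cross-check candidate
    channels and scores trials; optionally also computes the windowed LDA
    baseline on the same session.  Returns a summary dict.

    Hemodynamics are filtered causally by default — the detector is an
    online method and both it and the LDA baseline see only past samples.
    Pass a zero-phase :class:`~hybridphase.preproc.FilterSpec` for offline
    re-analysis.
    """
    sched = session.schedule
    cfg = gate_cfg or gate_mod.GateConfig(baseline_t=(0.0, sched.pre_rest_s))
    fspec = filter_spec or preproc.FilterSpec()

    # fNIRS conversion + band-pass
    spec = session.spec
    pathlength = getattr(spec, "pathlength_cm", 3.0)
    dpf = getattr(spec, "dpf", 6.0)
    baseline = (0, int(sched.pre_rest_s * session.fnirs_rate))
    hemo: dict[int, preproc.HemoSeries] = {}
    for ch in session.fnirs_channels:
        raw690, raw830 = session.intensity_pair(ch)
        od690 = preproc.intensity_to_od(raw690, baseline)
        od830 = preproc.intensity_to_od(raw830, baseline)
        h = preproc.od_to_hemo(
            od690, od830, pathlength_cm=pathlength, dpf=dpf,
            rate=session.fnirs_rate, channel_id=ch,
        )
        hemo[ch] = preproc.bandpass_hemo(h, fspec)

    # EEG band power
    beta: dict[int, np.ndarray] = {}
    powers: dict[int, pd.DataFrame] = {}
    for e in session.electrodes:
        bands = preproc.eeg_band_decompose(
            session.eeg[f"e{e}"].to_numpy(), session.eeg_rate
        )
        beta[e] = bands[cfg.band]
        powers[e] = gate_mod.sliding_power(
            beta[e], session.eeg_rate, cfg.window_s, cfg.hop_s
        )

    # electrode selection on the first-trial calibration epoch
    onset0 = float(sched.trial_onsets_s[0])
    epoch_power = {
        e: gate_mod.window_power(beta[e], session.eeg_rate, onset0, sched.task_s)
        for e in session.electrodes
    }
    electrodes = gate_mod.select_electrodes(epoch_power)
    channels = tuple(sorted(gate_mod.candidate_channels(electrodes, cross_map)))

    events = gate_mod.gate(powers, cfg, electrodes)

    # monitor candidate channels against every gate event; R1 from each
    # channel's own pre-rest baseline
    records: list[DetectionRecord] = []
    for ch in channels:
        h = hemo[ch]
        r1 = phase.resting_radius(h.slice_seconds(0.0, sched.pre_rest_s))
        records.extend(detect_events(h, events, r1, timeout_s=timeout_s))

    if records:
        outcomes, accuracy = classify_trials(records, sched, rest_offset_s=rest_offset_s)
    else:
        # no gate events at all (e.g. silent EEG): every decision is "rest"
        outcomes = [
            o
            for i in range(sched.n_trials)
            for o in (TrialOutcome(i, "task", "rest"), TrialOutcome(i, "rest", "rest"))
        ]
        accuracy = accuracy_pct(sum(o.correct for o in outcomes), len(outcomes))
    # latency statistics from the first completed detection of each trial
    latencies = []
    detected = sorted(
        (r for r in records if r.decision == "detected"), key=lambda r: r.gate_time
    )
    for onset in sched.trial_onsets_s:
        first = next(
            (r for r in detected if onset <= r.gate_time <= onset + sched.task_s), None
        )
        if first is not None and first.latency is not None:
            latencies.append(first.latency)
    result = {
        "electrodes": electrodes,
        "channels": channels,
        "n_gate_events": len(events),
        "records": records,
        "outcomes": outcomes,
        "accuracy_pct": accuracy,
        "mean_latency_s": float(np.mean(latencies)) if latencies else float("nan"),
        "hemo": hemo,
    }
    if with_lda:
        X, y = extract_lda_features(
            hemo, beta, session.eeg_rate, sched, channels, electrodes
        )
        result["lda_accuracy_pct"] = lda_baseline(X, y)
    return result
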