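"""Two-gamma hemodynamic response model and the block-design paradigm.

The canonical HRF (cHRF) is a difference of two gamma-variant kernels: a
positive response lobe followed by a delayed undershoot.  Convolving it with
the task boxcar ``s(k)`` on the fNIRS sample clock gives the *designed* HRF
(dHRF) ``u(k)``, the regressor used both to inject ground truth into
synthetic sessions and to fit measured oxyhemoglobin in the activation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.special import gamma as gamma_fn

__all__ = [
    "GammaParams",
    "ParadigmSchedule",
    "canonical_hrf",
    "designed_hrf",
    "ideal_trajectory",
]


@dataclass(frozen=True)
class GammaParams:
    """Parameters of the two-gamma canonical HRF.

    ``alpha1`` scales the whole kernel; when ``None`` it is chosen so the
    positive peak equals 1.  ``alpha2`` is the undershoot-to-response ratio.
    ``tau1``/``tau2`` (seconds) set the time scale and ``phi1``/``phi2`` the
    shape of the response and undershoot lobes.  With integer shapes the
    normalising constant is ``(phi - 1)!``; ``generalized=True`` replaces the
    factorial with ``Gamma(phi)`` and then accepts non-integer shapes.
    ``k1`` scales the designed HRF after convolution.
    """

    alpha1: float | None = None
    alpha2: float = 1.0 / 6.0
    tau1: float = 1.0
    tau2: float = 1.0
    phi1: float = 6
    phi2: float = 16
    k1: float = 10.0
    generalized: bool = False

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time-scaling constants tau1, tau2 must be > 0")
        if not 0 <= self.alpha2 < 1:
            raise ValueError("undershoot ratio alpha2 must lie in [0, 1)")
        if not self.generalized:
            for name, phi in (("phi1", self.phi1), ("phi2", self.phi2)):
                if phi != int(phi) or phi < 1:
                    raise ValueError(
                        f"{name}={phi!r}: the factorial form requires a positive "
                        "integer shape; pass generalized=True to use Gamma(phi) "
                        "with non-integer shapes"
                    )


def _gamma_variant(t: np.ndarray, tau: float, phi: float, generalized: bool) -> np.ndarray:
    """Single gamma-variant lobe ``(t/tau)^(phi-1) e^(-t/tau) / (tau (phi-1)!)``."""
    norm = gamma_fn(phi) if generalized else float(factorial(int(phi) - 1))
    x = t / tau
    with np.errstate(invalid="ignore"):
        out = np.where(t >= 0, x ** (phi - 1) * np.exp(-x) / (tau * norm), 0.0)
    return out


def canonical_hrf(params: GammaParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the two-gamma canonical HRF on a time grid ``t`` (seconds).

    Returns ``alpha1 * [g1(t) - alpha2 * g2(t)]``.  If ``params.alpha1`` is
    None the kernel is peak-normalised to 1 on the supplied grid.
    """
    t = np.asarray(t, dtype=float)
    g1 = _gamma_variant(t, params.tau1, params.phi1, params.generalized)
    g2 = _gamma_variant(t, params.tau2, params.phi2, params.generalized)
    h = g1 - params.alpha2 * g2
    if params.alpha1 is None:
        peak = h.max()
        if peak > 0:
            h = h / peak
        return h
    return params.alpha1 * h


@dataclass(frozen=True)
class ParadigmSchedule:
    """Block paradigm on the fNIRS sample clock.

    ``boxcar`` is the binary stimulus sequence s(k) (1 during task), ``rate``
    the fNIRS sampling rate in Hz, and ``trial_onsets_s`` the task-onset
    times in seconds (one per trial).
    """

    boxcar: np.ndarray
    rate: float
    task_s: float
    rest_s: float
    pre_rest_s: float
    post_rest_s: float
    n_trials: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boxcar)
        if not np.isin(b, (0, 1)).all():
            raise ValueError("boxcar must be binary")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @classmethod
    def block_design(
        cls,
        n_trials: int = 12,
        task_s: float = 10.0,
        rest_s: float = 20.0,
        pre_rest_s: float = 60.0,
        post_rest_s: float = 10.0,
        rate: float = 9.19,
    ) -> "ParadigmSchedule":
        if min(task_s, rest_s) <= 0 or min(pre_rest_s, post_rest_s) < 0:
            raise ValueError("durations must be positive (rests may be zero)")
        if n_trials < 1:
            raise ValueError("need at least one trial")
        total = pre_rest_s + n_trials * (task_s + rest_s) + post_rest_s
        n = int(round(total * rate))
        t = np.arange(n) / rate
        s = np.zeros(n, dtype=int)
        for i in range(n_trials):
            onset = pre_rest_s + i * (task_s + rest_s)
            s[(t >= onset) & (t < onset + task_s)] = 1
        return cls(
            boxcar=s,
            rate=rate,
            task_s=task_s,
            rest_s=rest_s,
            pre_rest_s=pre_rest_s,
            post_rest_s=post_rest_s,
            n_trials=n_trials,
        )

    @property
    def n_samples(self) -> int:
        return len(self.boxcar)

    @property
    def duration_s(self) -> float:
        return self.pre_rest_s + self.n_trials * (self.task_s + self.rest_s) + self.post_rest_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    @property
    def trial_onsets_s(self) -> np.ndarray:
        return self.pre_rest_s + np.arange(self.n_trials) * (self.task_s + self.rest_s)

    def segment_labels(self) -> np.ndarray:
        """Per-sample labels partitioning the timeline.

        Returns an array of {'pre_rest','task','rest','post_rest'} with no
        gaps or overlaps.
        """
        t = self.times_s
        labels = np.full(self.n_samples, "rest", dtype=object)
        labels[t < self.pre_rest_s] = "pre_rest"
        labels[t >= self.pre_rest_s + self.n_trials * (self.task_s + self.rest_s)] = "post_rest"
        labels[self.boxcar.astype(bool)] = "task"
        return labels

    def to_table(self):
        """Onset/duration/condition table (seconds, 0-based onsets)."""
        import pandas as pd

        rows = [(0.0, self.pre_rest_s, "rest")]
        for onset in self.trial_onsets_s:
            rows.append((float(onset), self.task_s, "task"))
            rows.append((float(onset + self.task_s), self.rest_s, "rest"))
        rows.append((self.duration_s - self.post_rest_s, self.post_rest_s, "rest"))
        return pd.DataFrame(rows, columns=["onset", "duration", "condition"])

    def with_rate(self, rate: float) -> "ParadigmSchedule":
        return self.block_design(
            self.n_trials, self.task_s, self.rest_s, self.pre_rest_s, self.post_rest_s, rate
        )


def designed_hrf(params: GammaParams, schedule: ParadigmSchedule) -> np.ndarray:
    """Designed HRF: causal convolution of the cHRF with the task boxcar.

    ``u(k) = k1 * sum_n h(n) s(k - n)`` evaluated on the schedule's sample
    clock; u is identically zero before the first task onset.
    """
    n = schedule.n_samples
    h = canonical_hrf(params, np.arange(n) / schedule.rate)
    u = params.k1 * np.convolve(h, schedule.boxcar.astype(float))[:n]
    return u


def ideal_trajectory(
    params: GammaParams, schedule: ParadigmSchedule, hbr_ratio: float = 1.0 / 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free vector-diagram trajectory implied by the two-gamma model.

    The oxy component follows the designed HRF and the deoxy component mirrors
    it with opposite sign, ``hbr = -hbr_ratio * hbo``, so every nonzero point
    lies on a straight line through the origin; while u > 0 the trajectory is
    confined to the hemodynamic octants of the phase diagram.
    """
    if not 0 < hbr_ratio <= 1:
        raise ValueError("hbr_ratio must lie in (0, 1]")
    u = designed_hrf(params, schedule)
    return u, -hbr_ratio * u


def _normalized_dhrf(params: GammaParams, schedule: ParadigmSchedule) -> np.ndarray:
    """Designed HRF rescaled to unit positive peak (helper for synthesis)."""
    u = designed_hrf(params, schedule)
    peak = u.max()
    return u / peak if peak > 0 else u
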