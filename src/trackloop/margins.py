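"""Stability margins, tracking-error metrics, and the gain-swap counterfactual.

The loop transfer used for margins is the open-loop feedback pathway PB.
The gain margin is 1/|L| at the phase crossover (unwrapped phase = -180 deg)
and the phase margin is 180 deg + angle(L) at the gain crossover (|L| = 1);
both crossovers are located by linear interpolation — in log-magnitude and
unwrapped phase versus log-frequency — after optional smoothing of
nonparametric FRFs.  When a crossing is absent the margin is reported as a
sentinel (infinite gain margin / undefined phase margin), not an error.

The counterfactual replays identical stimuli through a subject whose
feedback gain alone is changed, answering whether "restoring" a reduced
gain would actually improve tracking or merely erode the stability margin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .frf import FrequencyResponseSet
from .simulate import (PathwayModel, SyntheticSubject, TrialRecord,
                       simulate_session)
from .stimulus import SessionPlan, SumOfSinesSpec

DEFAULT_BAND_HZ = (0.08, 2.84)
DEFAULT_N_POINTS = 1000
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_POLE_SWEEP = (0.1, 0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class StabilityMargins:
    """Gain/phase margins of a loop transfer.

    ``gain_margin`` is a ratio (inf when the phase never reaches -180 deg);
    ``phase_margin_deg`` is NaN when there is no gain crossover, and the
    corresponding crossover frequencies are NaN likewise.
    """

    gain_margin: float
    phase_margin_deg: float
    gain_crossover_hz: float
    phase_crossover_hz: float

    @property
    def has_gain_crossover(self) -> bool:
        return math.isfinite(self.gain_crossover_hz)

    @property
    def has_phase_crossover(self) -> bool:
        return math.isfinite(self.phase_crossover_hz)


def smooth_frf(frf: FrequencyResponseSet, window: int = DEFAULT_SMOOTH_WINDOW,
               ) -> FrequencyResponseSet:
    """Moving-average smoothing of magnitude and unwrapped phase.

    Interior points are replaced by the mean of magnitude and of unwrapped
    phase over a centered window (clipped at the record edges); the first
    and last frequencies are left untouched.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(frf):
        raise ValueError("window longer than the grid")
    if window == 1 or len(frf) < 3:
        return frf.with_values(frf.values.copy())
    mag = np.abs(frf.values)
    ph = np.unwrap(np.angle(frf.values))
    h = window // 2
    out = frf.values.copy()
    for i in range(1, len(frf) - 1):
        lo, hi = max(0, i - h), min(len(frf), i + h + 1)
        out[i] = mag[lo:hi].mean() * np.exp(1j * ph[lo:hi].mean())
    return frf.with_values(out)


def _loop_samples(loop, band: tuple[float, float] | None,
                  n_points: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(loop, FrequencyResponseSet):
        return loop.frequencies, loop.values
    band = DEFAULT_BAND_HZ if band is None else band
    f = np.logspace(np.log10(band[0]), np.log10(band[1]), n_points)
    if isinstance(loop, PathwayModel):
        return f, loop.frequency_response(f)
    if callable(loop):
        return f, np.asarray(loop(f), dtype=complex)
    raise TypeError(f"unsupported loop type {type(loop)!r}")


def _interp_crossing(x: np.ndarray, g: np.ndarray, other: np.ndarray,
                     ) -> tuple[float, float] | None:
    """First sign change of g along x; returns (x, other) linearly
    interpolated at the crossing, or None."""
    sign = np.sign(g)
    for i in range(len(g) - 1):
        if g[i] == 0.0:
            return float(x[i]), float(other[i])
        if sign[i] * sign[i + 1] < 0:
            t = g[i] / (g[i] - g[i + 1])
            return (float(x[i] + t * (x[i + 1] - x[i])),
                    float(other[i] + t * (other[i + 1] - other[i])))
    if g[-1] == 0.0:
        return float(x[-1]), float(other[-1])
    return None


def stability_margins(loop, band: tuple[float, float] | None = None,
                      n_points: int = DEFAULT_N_POINTS) -> StabilityMargins:
    """Gain and phase margins of a loop transfer function.

    ``loop`` may be a :class:`FrequencyResponseSet` (its own grid is used —
    smooth first if desired), a :class:`PathwayModel`, or any callable
    ``f_hz -> complex``; models and callables are sampled on an
    ``n_points``-point log grid over ``band`` (default: the stimulus band).
    """
    f, L = _loop_samples(loop, band, n_points)
    x = np.log10(f)
    with np.errstate(divide="ignore"):
        logmag = np.log10(np.abs(L))
    phase_deg = np.degrees(np.unwrap(np.angle(L)))

    gc = _interp_crossing(x, logmag, phase_deg)
    if gc is None:
        pm, gc_hz = float("nan"), float("nan")
    else:
        gc_hz = 10.0 ** gc[0]
        pm = 180.0 + gc[1]

    pc = _interp_crossing(x, phase_deg + 180.0, logmag)
    if pc is None:
        gm, pc_hz = float("inf"), float("nan")
    else:
        pc_hz = 10.0 ** pc[0]
        gm = 1.0 / 10.0 ** pc[1]
    return StabilityMargins(gain_margin=gm, phase_margin_deg=pm,
                            gain_crossover_hz=gc_hz, phase_crossover_hz=pc_hz)


def tracking_error(trial: TrialRecord, discard_s: float = 0.0) -> float:
    """Mean squared tracking error (cm^2): mean over samples of the squared
    cursor-target distance, both axes summed."""
    n0 = int(round(discard_s * trial.sample_rate))
    if n0 >= len(trial.t):
        raise ValueError("discard window longer than the record")
    err = trial.y[n0:] - trial.r[n0:]
    if err.shape[0] == 0:
        raise ValueError("empty record after discard")
    return float(np.mean(np.sum(err**2, axis=1)))


@dataclass(frozen=True)
class GainSwapResult:
    """Outcome of replaying identical stimuli with only the feedback gain
    changed."""

    mse_original: float
    mse_swapped: float
    margins_original: StabilityMargins
    margins_swapped: StabilityMargins
    original_gain: float
    swapped_gain: float


def gain_swap_experiment(subject: SyntheticSubject, new_feedback_gain: float,
                         plan: SessionPlan,
                         ref_groups: dict[str, SumOfSinesSpec],
                         dist_groups: dict[str, SumOfSinesSpec],
                         duration: float, sample_rate: float,
                         band: tuple[float, float] | None = None,
                         ) -> GainSwapResult:
    """Re-simulate a session with the feedback gain replaced.

    Tracking error is the mean MSE across the session's trials (noise-free
    path); margins are computed on the parametric feedback pathway of each
    variant.  Raises the loop-instability error if the swap destabilizes.
    """
    swapped_pb = replace(subject.feedback, k=float(new_feedback_gain))
    swapped = replace(subject, feedback=swapped_pb,
                      subject_id=subject.subject_id + "_gainswap")

    def session_mse(subj: SyntheticSubject) -> float:
        records = simulate_session(subj, plan, ref_groups, dist_groups,
                                   duration, sample_rate, seed=None)
        return float(np.mean([tracking_error(tr) for tr in records]))

    return GainSwapResult(
        mse_original=session_mse(subject),
        mse_swapped=session_mse(swapped),
        margins_original=stability_margins(subject.feedback, band=band),
        margins_swapped=stability_margins(swapped.feedback, band=band),
        original_gain=float(subject.feedback.k),
        swapped_gain=float(new_feedback_gain),
    )
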