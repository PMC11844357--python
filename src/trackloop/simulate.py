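"""Synthetic closed-loop tracking subjects.

A subject is defined by two open-loop pathway transfer functions evaluated at
s = j*2*pi*f:

* the feedforward pathway PF — the cascade of the feedforward controller and
  the motor plant, driven purely by the reference, and
* the feedback pathway PB — the cascade of the error-driven controller and
  the plant, driven by the perceived cursor-minus-target error,

plus, optionally, a per-frequency complex preview filter M that pre-processes
the reference when a lookahead of the target trajectory is displayed.  The
closed-loop cursor response is

    Y = H_yr R + H_yd D,   H_yr = (PF + PB) M / (1 + PB),   H_yd = 1 / (1 + PB)

(with M = 1 in the no-preview condition).  The preview filter is assumed not
to act on the disturbance loop, mirroring the empirical finding that preview
leaves the feedback pathway unchanged.

Because the stimuli are finite sums of sinusoids, trials are synthesized as
exact steady-state superpositions of the per-component responses — there is
no numerical integration and no transient in the noise-free path.  An
optional "remnant" (white Gaussian noise on the displayed cursor) models the
operator output power that is not linearly correlated with the stimuli.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .exceptions import LoopInstabilityError
from .stimulus import SessionPlan, SumOfSinesSpec, TrialSlot, generate_signal

STABILITY_TOL = 1e-6

#: free parameters per model structure, in fitting order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "gain_delay": ("k", "tau"),
    "leaky_integrator_delay": ("k", "tau", "a"),
    "first_order_delay": ("k", "tau", "a"),
    "second_order_delay": ("k", "tau", "a", "b"),
}


@dataclass(frozen=True)
class PathwayModel:
    """A parametric transfer function with delay, evaluable at any frequency.

    Structures (s = j*2*pi*f):

    * ``gain_delay``:              k * exp(-s*tau)
    * ``leaky_integrator_delay``:  k * exp(-s*tau) / (s + a)   (McRuer-style
      crossover model: a delayed, scaled integrator with leak rate ``a``)
    * ``first_order_delay``:       k * exp(-s*tau) / (1 + s/a)  (DC gain k,
      pole at a rad/s)
    * ``second_order_delay``:      k * exp(-s*tau) / ((1 + s/a)(1 + s/b))
    * ``tabulated``:               nonparametric values on a fixed grid

    Units: k dimensionless (cm/cm), tau seconds, poles a, b in rad/s.
    """

    structure: str
    k: float = 0.0
    tau: float = 0.0
    a: float | None = None
    b: float | None = None
    table: tuple[tuple[float, ...], tuple[complex, ...]] | None = None

    def __post_init__(self) -> None:
        if self.structure not in PARAM_NAMES and self.structure != "tabulated":
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "tabulated":
            if self.table is None:
                raise ValueError("tabulated structure requires a table")
            return
        if self.k < 0 or self.tau < 0:
            raise ValueError("k and tau must be non-negative")
        names = PARAM_NAMES[self.structure]
        if "a" in names and (self.a is None or self.a <= 0):
            raise ValueError(f"{self.structure} requires pole a > 0")
        if "b" in names and (self.b is None or self.b <= 0):
            raise ValueError(f"{self.structure} requires pole b > 0")

    @property
    def params(self) -> dict[str, float]:
        if self.structure == "tabulated":
            return {}
        return {n: float(getattr(self, n)) for n in PARAM_NAMES[self.structure]}

    def frequency_response(self, f) -> np.ndarray:
        """Complex response at frequency ``f`` (Hz; scalar or array)."""
        f = np.asarray(f, dtype=float)
        s = 1j * 2.0 * np.pi * f
        if self.structure == "gain_delay":
            h = self.k * np.exp(-s * self.tau)
        elif self.structure == "leaky_integrator_delay":
            h = self.k * np.exp(-s * self.tau) / (s + self.a)
        elif self.structure == "first_order_delay":
            h = self.k * np.exp(-s * self.tau) / (1.0 + s / self.a)
        elif self.structure == "second_order_delay":
            h = self.k * np.exp(-s * self.tau) / ((1.0 + s / self.a) * (1.0 + s / self.b))
        else:  # tabulated
            tf, tv = (np.asarray(self.table[0]), np.asarray(self.table[1]))
            idx = np.searchsorted(tf, f)
            idx = np.clip(idx, 0, len(tf) - 1)
            if not np.allclose(tf[idx], f, rtol=0, atol=1e-9):
                raise ValueError("tabulated model queried off its grid")
            h = tv[idx]
        return h

    __call__ = frequency_response

    def with_params(self, **kwargs) -> "PathwayModel":
        return replace(self, **kwargs)


def make_pathway(structure: str, values: Sequence[float]) -> PathwayModel:
    """Build a ``PathwayModel`` from an ordered parameter vector."""
    names = PARAM_NAMES[structure]
    if len(values) != len(names):
        raise ValueError(f"{structure} takes {len(names)} parameters")
    return PathwayModel(structure=structure, **dict(zip(names, map(float, values))))


@dataclass(frozen=True)
class SyntheticSubject:
    """A simulated operator: pathway cascades, optional preview filter,
    optional remnant noise.

    ``preview_filter`` maps frequency (Hz, scalar or array) to a complex
    value; ``None`` means the subject does not exploit preview (M = 1).
    ``remnant_sd`` is the standard deviation (cm) of white Gaussian noise
    added to the displayed cursor per sample.
    """

    subject_id: str
    feedforward: PathwayModel
    feedback: PathwayModel
    preview_filter: Callable[[np.ndarray], np.ndarray] | None = None
    remnant_sd: float = 0.0

    def check_stable(self, frequencies: np.ndarray) -> None:
        pb = self.feedback.frequency_response(frequencies)
        bad = np.abs(1.0 + pb) <= STABILITY_TOL
        if np.any(bad):
            f_bad = np.asarray(frequencies)[bad]
            raise LoopInstabilityError(
                f"|1 + PB| <= {STABILITY_TOL} at f = {f_bad} Hz "
                f"for subject {self.subject_id}")


def closed_loop_response(subject: SyntheticSubject, f,
                         preview: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Closed-loop transfer values (H_yr, H_yd) at frequency ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    pf = subject.feedforward.frequency_response(f)
    pb = subject.feedback.frequency_response(f)
    denom = 1.0 + pb
    if np.any(np.abs(denom) <= STABILITY_TOL):
        f_bad = f[np.abs(denom) <= STABILITY_TOL]
        raise LoopInstabilityError(
            f"|1 + PB| <= {STABILITY_TOL} at f = {f_bad} Hz")
    h_yr = (pf + pb) / denom
    if preview and subject.preview_filter is not None:
        h_yr = h_yr * np.asarray(subject.preview_filter(f))
    h_yd = 1.0 / denom
    return h_yr, h_yd


@dataclass
class TrialRecord:
    """One trial's sampled time series and its stimulus bookkeeping.

    ``r``, ``d``, ``y`` are (n_samples, 2) arrays, columns x then y axis, cm.
    ``frequencies`` maps each role ('rx', 'dx', 'ry', 'dy') to the component
    frequencies assigned to it in this trial.
    """

    t: np.ndarray
    r: np.ndarray
    d: np.ndarray
    y: np.ndarray
    composition: dict[str, str]
    frequencies: dict[str, tuple[float, ...]]
    preview_ms: int
    subject_id: str
    sample_rate: float
    trial: int = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("r", "d", "y"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2)")

    def axis_series(self, axis: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r, d, y) 1-D series for axis 'x' or 'y'."""
        col = {"x": 0, "y": 1}[axis]
        return self.r[:, col], self.d[:, col], self.y[:, col]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t,
            "rx_cm": self.r[:, 0], "ry_cm": self.r[:, 1],
            "dx_cm": self.d[:, 0], "dy_cm": self.d[:, 1],
            "yx_cm": self.y[:, 0], "yy_cm": self.y[:, 1],
        })

    def write_csv(self, path: str | Path) -> None:
        """Write the time series as CSV with a JSON sidecar of metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "composition": self.composition,
            "frequencies": {k: list(v) for k, v in self.frequencies.items()},
            "preview_ms": self.preview_ms,
            "subject_id": self.subject_id,
            "sample_rate_hz": self.sample_rate,
            "trial": self.trial,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _axis_response(subject: SyntheticSubject, ref: SumOfSinesSpec,
                   dist: SumOfSinesSpec, t: np.ndarray,
                   preview: bool) -> np.ndarray:
    """Exact steady-state cursor response for one axis."""
    y = np.zeros_like(t)
    for f, m, phi in zip(ref.frequencies, ref.magnitudes, ref.phases):
        h_yr, _ = closed_loop_response(subject, f, preview=preview)
        y += np.abs(h_yr) * m * np.sin(2 * np.pi * f * t + phi + np.angle(h_yr))
    for f, m, phi in zip(dist.frequencies, dist.magnitudes, dist.phases):
        _, h_yd = closed_loop_response(subject, f, preview=preview)
        y += np.abs(h_yd) * m * np.sin(2 * np.pi * f * t + phi + np.angle(h_yd))
    return y


def simulate_trial(subject: SyntheticSubject,
                   specs: dict[str, SumOfSinesSpec],
                   preview_ms: int,
                   duration: float,
                   sample_rate: float,
                   rng: np.random.Generator | None = None,
                   trial: int = 0) -> TrialRecord:
    """Simulate one trial given the four role specs {'rx','dx','ry','dy'}.

    The cursor is the exact steady-state closed-loop response to each
    sinusoidal component (superposition), plus optional white remnant noise
    when ``subject.remnant_sd > 0`` (an ``rng`` is then required).
    """
    for key in ("rx", "dx", "ry", "dy"):
        if key not in specs:
            raise ValueError(f"missing spec for role {key!r}")
    all_freqs = np.concatenate([np.asarray(specs[k].frequencies)
                                for k in ("rx", "dx", "ry", "dy")])
    subject.check_stable(all_freqs)
    preview = preview_ms > 0
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    r = np.column_stack([generate_signal(specs["rx"], duration, sample_rate),
                         generate_signal(specs["ry"], duration, sample_rate)])
    d = np.column_stack([generate_signal(specs["dx"], duration, sample_rate),
                         generate_signal(specs["dy"], duration, sample_rate)])
    y = np.column_stack([
        _axis_response(subject, specs["rx"], specs["dx"], t, preview),
        _axis_response(subject, specs["ry"], specs["dy"], t, preview),
    ])
    if subject.remnant_sd > 0:
        if rng is None:
            raise ValueError("remnant_sd > 0 requires an rng")
        y = y + rng.normal(0.0, subject.remnant_sd, size=y.shape)
    return TrialRecord(
        t=t, r=r, d=d, y=y,
        composition={k: specs[k].group_id for k in ("rx", "dx", "ry", "dy")},
        frequencies={k: specs[k].frequencies for k in ("rx", "dx", "ry", "dy")},
        preview_ms=preview_ms, subject_id=subject.subject_id,
        sample_rate=sample_rate, trial=trial,
    )


def slot_specs(slot: TrialSlot, ref_groups: dict[str, SumOfSinesSpec],
               dist_groups: dict[str, SumOfSinesSpec]) -> dict[str, SumOfSinesSpec]:
    """Resolve a session-plan slot to its four role specs."""
    return {
        "rx": ref_groups[slot.rx], "ry": ref_groups[slot.ry],
        "dx": dist_groups[slot.dx], "dy": dist_groups[slot.dy],
    }


def simulate_session(subject: SyntheticSubject, plan: SessionPlan,
                     ref_groups: dict[str, SumOfSinesSpec],
                     dist_groups: dict[str, SumOfSinesSpec],
                     duration: float, sample_rate: float,
                     seed: int | None = None) -> list[TrialRecord]:
    """Simulate every trial of a session plan for one subject."""
    rng = np.random.default_rng(seed) if seed is not None else None
    records = []
    for slot in plan.trials:
        records.append(simulate_trial(
            subject, slot_specs(slot, ref_groups, dist_groups),
            slot.preview_ms, duration, sample_rate, rng=rng, trial=slot.trial))
    return records


def simulate_cohort(subjects: Sequence[SyntheticSubject], plan: SessionPlan,
                    ref_groups: dict[str, SumOfSinesSpec],
                    dist_groups: dict[str, SumOfSinesSpec],
                    duration: float, sample_rate: float,
                    seed: int | None = None) -> dict[str, list[TrialRecord]]:
    """Simulate the session plan for every subject; returns records keyed by
    subject id.  Each subject gets an independent noise stream spawned from
    ``seed``."""
    out: dict[str, list[TrialRecord]] = {}
    ss = np.random.SeedSequence(seed) if seed is not None else None
    children = ss.spawn(len(subjects)) if ss is not None else [None] * len(subjects)
    for subject, child in zip(subjects, children):
        sub_seed = None if child is None else int(child.generate_state(1)[0] % (2**31))
        out[subject.subject_id] = simulate_session(
            subject, plan, ref_groups, dist_groups, duration, sample_rate,
            seed=sub_seed)
    return out
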