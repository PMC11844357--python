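"""Sum-of-sines stimulus design for closed-loop tracking experiments.

The tracking task probes a human operator with two concurrent pseudo-random
inputs — a visual target ("reference") and a cursor perturbation
("disturbance") — each built as a sum of five sinusoids.  The component
frequencies are prime multiples of a common base frequency (0.04 Hz by
default), which guarantees that no stimulus frequency is an integer multiple
of another: the operator cannot exploit harmonic structure, and the response
at each probed frequency is attributable to exactly one input component.

Component amplitudes follow a two-branch profile that caps both the peak
position and the peak velocity of each sinusoid, so low-frequency components
are position-limited and high-frequency components are velocity-limited.

A session consists of 16 experimental trials.  Four signal groups (five
frequencies each) rotate across the four stimulus roles (reference x/y,
disturbance x/y) so that, pooled over the session, every grid frequency is
probed in every role on every axis, in both the preview and no-preview
conditions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sympy import nextprime

from .exceptions import LeakageError

# Amplitude-profile constants: velocity coefficient (cm/s) and position cap (cm).
REFERENCE_VELOCITY_COEFF = 1.3
REFERENCE_POSITION_CAP = 2.3
DISTURBANCE_VELOCITY_COEFF = 0.7
DISTURBANCE_POSITION_CAP = 1.5

DEFAULT_BASE_HZ = 0.04
DEFAULT_GRID_SIZE = 20
N_SIGNAL_GROUPS = 4
COMPONENTS_PER_GROUP = 5
DEFAULT_SAMPLE_RATE_HZ = 80.0
DEFAULT_TRIAL_DURATION_S = 75.0
DEFAULT_DISCARD_S = 25.0
PREVIEW_MS = 500

# Rotation of signal groups over the stimulus roles (rx, dx, ry, dy).  Each row
# is run twice per preview condition, giving 4 rows x 2 conditions x 2 = 16
# experimental trials; pooled, every group serves every role on every axis.
ROTATION: tuple[tuple[str, str, str, str], ...] = (
    ("r1", "d2", "r3", "d4"),
    ("r2", "d1", "r4", "d3"),
    ("r3", "d4", "r1", "d2"),
    ("r4", "d3", "r2", "d1"),
)


@dataclass(frozen=True)
class FrequencyGrid:
    """Stimulus frequency grid: prime multiples of a base frequency.

    Attributes
    ----------
    base_hz
        Base frequency in Hz; its reciprocal is the fundamental period that
        every record length must be a multiple of.
    multipliers
        The prime integers, ascending.
    """

    base_hz: float
    multipliers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.base_hz <= 0:
            raise ValueError(f"base_hz must be positive, got {self.base_hz}")
        if len(self.multipliers) == 0:
            raise ValueError("grid needs at least one frequency")
        if list(self.multipliers) != sorted(set(self.multipliers)):
            raise ValueError("multipliers must be strictly increasing")

    @property
    def frequencies(self) -> np.ndarray:
        """Grid frequencies in Hz, ascending."""
        return self.base_hz * np.asarray(self.multipliers, dtype=float)

    @property
    def base_period_s(self) -> float:
        return 1.0 / self.base_hz

    def __len__(self) -> int:
        return len(self.multipliers)


def build_frequency_grid(base_hz: float = DEFAULT_BASE_HZ,
                         count: int = DEFAULT_GRID_SIZE) -> FrequencyGrid:
    """First ``count`` primes, each multiplied by ``base_hz``.

    With the defaults this spans 0.08 Hz (2 x 0.04) to 2.84 Hz (71 x 0.04).
    """
    if base_hz <= 0:
        raise ValueError(f"base_hz must be positive, got {base_hz}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    primes: list[int] = []
    p = 1
    for _ in range(count):
        p = int(nextprime(p))
        primes.append(p)
    return FrequencyGrid(base_hz=base_hz, multipliers=tuple(primes))


def amplitude_profile(f: float, velocity_coeff: float, position_cap: float) -> float:
    """Component amplitude (cm) at frequency ``f`` (Hz).

    The lesser of the velocity-limited branch ``velocity_coeff / f`` and the
    positional cap, so that every component satisfies both
    ``M <= position_cap`` and peak velocity ``2*pi*f*M <= 2*pi*velocity_coeff``.
    """
    if np.any(np.asarray(f) <= 0):
        raise ValueError(f"frequency must be positive, got {f}")
    return np.minimum(velocity_coeff / np.asarray(f, dtype=float), position_cap)


@dataclass(frozen=True)
class SumOfSinesSpec:
    """One signal group: five (frequency, magnitude, phase) sinusoid components.

    ``group_id`` is one of r1..r4 (reference groups) or d1..d4 (disturbance
    groups).  Units: Hz, cm, radians.
    """

    group_id: str
    frequencies: tuple[float, ...]
    magnitudes: tuple[float, ...]
    phases: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.frequencies)
        if not (len(self.magnitudes) == len(self.phases) == n):
            raise ValueError("component arrays must have equal length")
        if any(m <= 0 for m in self.magnitudes):
            raise ValueError("magnitudes must be strictly positive")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be strictly positive")

    def __len__(self) -> int:
        return len(self.frequencies)


def generate_signal(spec: SumOfSinesSpec, duration: float,
                    sample_rate: float) -> np.ndarray:
    """Sample ``sum_i M_i sin(2 pi f_i t + phi_i)`` on a uniform time base.

    The record must hold an integer number of cycles of every component
    (duration an integer multiple of the grid base period); otherwise the
    single-frequency DFTs used downstream would leak and the call errors out.
    """
    freqs = np.asarray(spec.frequencies)
    if sample_rate < 2.0 * freqs.max():
        raise ValueError("sample_rate below Nyquist for the highest component")
    cycles = freqs * duration
    if not np.allclose(cycles, np.round(cycles), atol=1e-9):
        raise LeakageError(
            f"duration {duration} s does not hold integer cycles of all "
            f"components of group {spec.group_id}")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for f, m, phi in zip(spec.frequencies, spec.magnitudes, spec.phases):
        out += m * np.sin(2.0 * np.pi * f * t + phi)
    return out


def make_signal_groups(grid: FrequencyGrid, role: str,
                       rng: np.random.Generator) -> dict[str, SumOfSinesSpec]:
    """Partition the grid into four 5-frequency groups for one stimulus role.

    ``role`` is ``"reference"`` or ``"disturbance"`` and selects the amplitude
    profile.  The partition is round-robin by ascending frequency (grid index
    mod 4), so each group spans the low-to-high band.  Phases are drawn
    uniformly on [0, 2 pi) from ``rng``.
    """
    if role == "reference":
        prefix, vcoeff, cap = "r", REFERENCE_VELOCITY_COEFF, REFERENCE_POSITION_CAP
    elif role == "disturbance":
        prefix, vcoeff, cap = "d", DISTURBANCE_VELOCITY_COEFF, DISTURBANCE_POSITION_CAP
    else:
        raise ValueError(f"role must be 'reference' or 'disturbance', got {role!r}")
    if len(grid) % N_SIGNAL_GROUPS != 0:
        raise ValueError("grid size must be divisible by the number of groups")
    freqs = grid.frequencies
    groups: dict[str, SumOfSinesSpec] = {}
    for g in range(N_SIGNAL_GROUPS):
        fsel = freqs[g::N_SIGNAL_GROUPS]
        mags = tuple(float(amplitude_profile(f, vcoeff, cap)) for f in fsel)
        phases = tuple(float(p) for p in rng.uniform(0.0, 2.0 * np.pi, len(fsel)))
        groups[f"{prefix}{g + 1}"] = SumOfSinesSpec(
            group_id=f"{prefix}{g + 1}",
            frequencies=tuple(float(f) for f in fsel),
            magnitudes=mags,
            phases=phases,
        )
    return groups


@dataclass(frozen=True)
class TrialSlot:
    """One session trial: the group-to-role assignment and preview condition."""

    trial: int
    rx: str
    dx: str
    ry: str
    dy: str
    preview_ms: int

    @property
    def composition(self) -> dict[str, str]:
        return {"rx": self.rx, "dx": self.dx, "ry": self.ry, "dy": self.dy}


@dataclass(frozen=True)
class SessionPlan:
    """16 experimental trials realizing the group rotation in both preview
    conditions, in a seeded pseudo-random order."""

    trials: tuple[TrialSlot, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != len(ROTATION) * 2 * 2:
            raise ValueError(f"expected {len(ROTATION) * 4} trials, "
                             f"got {len(self.trials)}")
        for preview in (0, PREVIEW_MS):
            rows = {(t.rx, t.dx, t.ry, t.dy)
                    for t in self.trials if t.preview_ms == preview}
            if rows != set(ROTATION):
                raise ValueError(
                    f"rotation rows incomplete for preview={preview} ms")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(t.trial, t.rx, t.dx, t.ry, t.dy, t.preview_ms) for t in self.trials],
            columns=["trial", "rx", "dx", "ry", "dy", "preview_ms"],
        )


def build_session_plan(grid: FrequencyGrid, rng_seed: int) -> SessionPlan:
    """Build the 16-trial plan: rotation rows x {0, 500} ms preview x 2
    repetitions, shuffled by ``rng_seed`` and numbered 1..16."""
    if len(grid) != DEFAULT_GRID_SIZE:
        raise ValueError(f"session plan requires a {DEFAULT_GRID_SIZE}-frequency "
                         f"grid, got {len(grid)}")
    cells = [(row, preview)
             for row in ROTATION
             for preview in (0, PREVIEW_MS)
             for _ in range(2)]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(cells))
    trials = tuple(
        TrialSlot(trial=i + 1, rx=cells[j][0][0], dx=cells[j][0][1],
                  ry=cells[j][0][2], dy=cells[j][0][3], preview_ms=cells[j][1])
        for i, j in enumerate(order)
    )
    return SessionPlan(trials=trials, seed=rng_seed)
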