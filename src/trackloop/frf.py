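"""Frequency-response-function (FRF) estimation from trial records.

Each stimulus component is a sine ``M sin(2 pi f t + phi)``.  We represent it
by the complex phasor ``c = M exp(j phi)`` so that an LTI pathway with
response H maps ``c`` to ``H c``: the output component is
``|H c| sin(2 pi f t + angle(H c))``.  Because record lengths are integer
multiples of the grid base period and the grid frequencies are distinct
prime multiples of the base, single-frequency DFTs over the full record are
exactly orthogonal across components — each phasor is recovered to machine
precision with no window or leakage correction.

The closed-loop FRFs are estimated per axis:

    H_YR(f) = DFT_f(y) / DFT_f(r)   at frequencies assigned to the reference
    H_YD(f) = DFT_f(y) / DFT_f(d)   at frequencies assigned to the disturbance

and pooled across trials by the complex mean (phasor averaging), which is
unbiased for the linear response under additive remnant noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CoverageError, LeakageError
from .simulate import TrialRecord
from .stimulus import DEFAULT_DISCARD_S, FrequencyGrid

AXES = ("x", "y")
INPUT_FLOOR = 1e-12  # minimum input phasor magnitude to form a ratio


@dataclass
class FrequencyResponseSet:
    """Complex frequency-response values on a fixed frequency grid.

    ``channel`` names what the values are (e.g. 'H_YR', 'H_YD', 'PF', 'PB',
    'PH_R', 'PH_B', 'PH_P', 'PH_BP', 'M'); ``n_pooled`` counts the trials
    averaged at each frequency (all-ones when not applicable).
    """

    frequencies: np.ndarray
    values: np.ndarray
    channel: str
    axis: str = ""
    subject_id: str = ""
    n_pooled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite FRF values in channel {self.channel}")
        if self.n_pooled is None:
            self.n_pooled = np.ones(len(self.frequencies), dtype=int)

    def __len__(self) -> int:
        return len(self.frequencies)

    def value_at(self, f: float) -> complex:
        idx = np.argmin(np.abs(self.frequencies - f))
        if abs(self.frequencies[idx] - f) > 1e-9:
            raise KeyError(f"frequency {f} Hz not on the grid")
        return complex(self.values[idx])

    def with_values(self, values: np.ndarray,
                    channel: str | None = None) -> "FrequencyResponseSet":
        return replace(self, values=np.asarray(values, dtype=complex),
                       channel=channel if channel is not None else self.channel)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "freq_hz": self.frequencies,
            "re": self.values.real,
            "im": self.values.imag,
            "channel": self.channel,
            "axis": self.axis,
            "subject": self.subject_id,
            "n_pooled": self.n_pooled,
        })


def complex_mean(sets: list[FrequencyResponseSet]) -> FrequencyResponseSet:
    """Element-wise complex mean of FRF sets sharing a grid and channel."""
    if not sets:
        raise ValueError("need at least one FRF set")
    base = sets[0]
    for s in sets[1:]:
        if not np.allclose(s.frequencies, base.frequencies, atol=1e-12):
            raise ValueError("FRF sets are on different grids")
    mean = np.mean([s.values for s in sets], axis=0)
    return replace(base, values=mean, subject_id="group_mean")


def single_frequency_dft(series: np.ndarray, f: float,
                         sample_rate: float) -> complex:
    """Sine-convention phasor of ``series`` at frequency ``f``.

    Returns c such that the component equals ``|c| sin(2 pi f t + angle(c))``.
    Requires the record to hold an integer number of cycles of ``f``.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    cycles = f * n / sample_rate
    if abs(cycles - round(cycles)) > 1e-6:
        raise LeakageError(
            f"record of {n} samples holds {cycles:.6f} cycles of {f} Hz")
    t = np.arange(n) / sample_rate
    # For x = M sin(wt + phi): (2/N) sum x exp(-jwt) = -j M exp(j phi)
    return complex(1j * (2.0 / n) * np.sum(series * np.exp(-2j * np.pi * f * t)))


def _discarded(series: np.ndarray, sample_rate: float, discard_s: float) -> np.ndarray:
    n0 = int(round(discard_s * sample_rate))
    if n0 >= len(series):
        raise ValueError("discard window longer than the record")
    return series[n0:]


def estimate_frfs(trials: list[TrialRecord], grid: FrequencyGrid,
                  preview_ms: int | None = None,
                  discard_s: float = DEFAULT_DISCARD_S,
                  subject_id: str = "",
                  ) -> dict[str, dict[str, FrequencyResponseSet]]:
    """Estimate H_YR and H_YD per axis by pooling trials.

    Parameters
    ----------
    trials
        Records for one subject.
    preview_ms
        Keep only trials of this preview condition; ``None`` pools all
        (appropriate when the subject's response is condition-independent).
    discard_s
        Initial transient window dropped before the DFT; the remaining record
        must still hold integer cycles of every grid frequency.

    Returns ``{'x': {'H_YR': set, 'H_YD': set}, 'y': {...}}``.

    Raises :class:`CoverageError` if any grid frequency is never probed in a
    required role on some axis (including the degenerate case of an input
    with no power at its own assigned frequency).
    """
    if preview_ms is not None:
        trials = [tr for tr in trials if tr.preview_ms == preview_ms]
    if not trials:
        raise CoverageError("no trials in the requested condition")
    freqs = grid.frequencies
    out: dict[str, dict[str, FrequencyResponseSet]] = {}
    for axis in AXES:
        per_channel: dict[str, FrequencyResponseSet] = {}
        for channel, role_key, input_idx in (("H_YR", "r" + axis, 0),
                                             ("H_YD", "d" + axis, 1)):
            samples: list[list[complex]] = [[] for _ in freqs]
            for tr in trials:
                r, d, y = tr.axis_series(axis)
                u = (r, d)[input_idx]
                u = _discarded(u, tr.sample_rate, discard_s)
                yw = _discarded(y, tr.sample_rate, discard_s)
                for f in tr.frequencies[role_key]:
                    idx = int(np.argmin(np.abs(freqs - f)))
                    if abs(freqs[idx] - f) > 1e-9:
                        continue  # off-grid component: not pooled
                    cu = single_frequency_dft(u, f, tr.sample_rate)
                    if abs(cu) < INPUT_FLOOR:
                        raise CoverageError(
                            f"input power absent at {f} Hz in role {role_key} "
                            f"(trial {tr.trial})")
                    cy = single_frequency_dft(yw, f, tr.sample_rate)
                    samples[idx].append(cy / cu)
            missing = [float(freqs[i]) for i, s in enumerate(samples) if not s]
            if missing:
                raise CoverageError(
                    f"axis {axis} channel {channel}: no trials probe "
                    f"frequencies {missing}")
            values = np.array([np.mean(s) for s in samples])
            per_channel[channel] = FrequencyResponseSet(
                frequencies=freqs.copy(), values=values, channel=channel,
                axis=axis, subject_id=subject_id,
                n_pooled=np.array([len(s) for s in samples]))
        out[axis] = per_channel
    return out


def off_axis_magnitude(trial: TrialRecord, grid: FrequencyGrid,
                       discard_s: float = DEFAULT_DISCARD_S) -> dict[str, float]:
    """Diagnostic: cursor power leaking onto the axis orthogonal to a
    stimulus component.  Returns, per role, the maximum off-axis |DFT(y)| /
    input magnitude across that role's components.  Near zero for an
    axis-separable subject."""
    out: dict[str, float] = {}
    for role, on_axis in (("rx", "x"), ("dx", "x"), ("ry", "y"), ("dy", "y")):
        off_axis = "y" if on_axis == "x" else "x"
        _, _, y_off = trial.axis_series(off_axis)
        y_off = _discarded(y_off, trial.sample_rate, discard_s)
        ratios = []
        spec_freqs = trial.frequencies[role]
        u = trial.r if role.startswith("r") else trial.d
        u_series = u[:, 0 if on_axis == "x" else 1]
        u_series = _discarded(u_series, trial.sample_rate, discard_s)
        for f in spec_freqs:
            cu = single_frequency_dft(u_series, f, trial.sample_rate)
            cy = single_frequency_dft(y_off, f, trial.sample_rate)
            ratios.append(abs(cy) / max(abs(cu), INPUT_FLOOR))
        out[role] = float(max(ratios))
    return out
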