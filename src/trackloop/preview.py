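"""Preview-filter extraction from preview vs. no-preview FRFs.

In the two-channel ("reference controller") view of the loop, a reference
controller H_R processes the target and a feedback controller H_B processes
the displayed cursor; both cascade with the plant.  From the closed-loop
FRFs,

    PH_B = 1/H_YD - 1        (identically the feedback pathway PB)
    PH_R = H_YR / H_YD       (identically PF + PB)

When a lookahead of the target trajectory is displayed, the reference
controller may change (PH_P) while the feedback channel should not (PH_BP):
the preview filter is the per-frequency ratio

    M(f) = PH_P(f) / PH_R(f)

i.e. the complex filter that, applied to the reference before the unchanged
no-preview controllers, reproduces the preview-condition behavior.  The
feedback-invariance assumption is *checked* — the ratio PH_BP/PH_B is
stored and a warning raised when it strays from 1 — never enforced.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import NearSingularError
from .frf import FrequencyResponseSet
from .isolate import EPS
from .stimulus import SumOfSinesSpec

RATIO_WARN_TOL = 0.2


@dataclass
class PreviewFilterEstimate:
    """Nonparametric preview filter M and the feedback-invariance diagnostic.

    ``feedback_ratio`` is PH_BP / PH_B per frequency; values near 1 support
    the assumption that preview leaves the feedback channel unchanged.
    """

    frequencies: np.ndarray
    values: np.ndarray
    feedback_ratio: np.ndarray
    axis: str = ""
    subject_id: str = ""

    def value_at(self, f: float) -> complex:
        idx = np.argmin(np.abs(self.frequencies - f))
        if abs(self.frequencies[idx] - f) > 1e-9:
            raise KeyError(f"frequency {f} Hz not on the preview-filter grid")
        return complex(self.values[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "freq_hz": self.frequencies,
            "re": self.values.real,
            "im": self.values.imag,
            "fb_ratio_re": self.feedback_ratio.real,
            "fb_ratio_im": self.feedback_ratio.imag,
            "axis": self.axis,
            "subject": self.subject_id,
        })


def reference_controller_frfs(h_yr: FrequencyResponseSet,
                              h_yd: FrequencyResponseSet,
                              ) -> tuple[FrequencyResponseSet, FrequencyResponseSet]:
    """Two-channel FRFs: PH_R = H_YR/H_YD, PH_B = 1/H_YD - 1."""
    if not np.allclose(h_yr.frequencies, h_yd.frequencies, atol=1e-12):
        raise ValueError("H_YR and H_YD are on different grids")
    bad = np.abs(h_yd.values) <= EPS
    if np.any(bad):
        raise NearSingularError(
            f"|H_YD| <= {EPS} at f = {h_yd.frequencies[bad]} Hz")
    ph_r = h_yd.with_values(h_yr.values / h_yd.values, channel="PH_R")
    ph_b = h_yd.with_values(1.0 / h_yd.values - 1.0, channel="PH_B")
    return ph_r, ph_b


def _smooth_complex(values: np.ndarray, window: int) -> np.ndarray:
    """Centered complex moving average; endpoints use the available span."""
    if window == 1:
        return values
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    h = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - h), min(len(values), i + h + 1)
        out[i] = values[lo:hi].mean()
    return out


def extract_preview_filter(no_preview: tuple[FrequencyResponseSet, FrequencyResponseSet],
                           preview: tuple[FrequencyResponseSet, FrequencyResponseSet],
                           ratio_warn_tol: float = RATIO_WARN_TOL,
                           smooth_window: int = 1) -> PreviewFilterEstimate:
    """Estimate M = PH_P / PH_R per frequency.

    Parameters
    ----------
    no_preview, preview
        (PH_R, PH_B)-style pairs from :func:`reference_controller_frfs`,
        estimated in the no-preview and preview conditions respectively.
    ratio_warn_tol
        Warn when |PH_BP/PH_B - 1| exceeds this at any frequency.
    smooth_window
        Optional odd-width complex moving average applied to M (1 = off).
    """
    ph_r, ph_b = no_preview
    ph_p, ph_bp = preview
    if not np.allclose(ph_r.frequencies, ph_p.frequencies, atol=1e-12):
        raise ValueError("conditions estimated on different grids")
    small = np.abs(ph_r.values) <= EPS
    if np.any(small):
        raise NearSingularError(
            f"|PH_R| <= {EPS} at f = {ph_r.frequencies[small]} Hz")
    m = ph_p.values / ph_r.values
    fb_ratio = ph_bp.values / ph_b.values
    worst = float(np.max(np.abs(fb_ratio - 1.0)))
    if worst > ratio_warn_tol:
        warnings.warn(
            f"feedback channel changed between conditions: "
            f"max |PH_BP/PH_B - 1| = {worst:.3f} > {ratio_warn_tol}",
            stacklevel=2)
    m = _smooth_complex(m, smooth_window)
    return PreviewFilterEstimate(
        frequencies=ph_r.frequencies.copy(), values=m,
        feedback_ratio=fb_ratio, axis=ph_r.axis, subject_id=ph_r.subject_id)


def filtered_reference(estimate: PreviewFilterEstimate, spec: SumOfSinesSpec,
                       duration: float, sample_rate: float) -> np.ndarray:
    """Reconstruct the effective ("filtered") reference the subject tracks.

    Each stimulus component is scaled by |M(f)| and phase-shifted by
    angle(M(f)); a phase-leading M yields a trajectory whose peaks and
    reversals occur earlier than the raw reference.
    """
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for f, mag, phi in zip(spec.frequencies, spec.magnitudes, spec.phases):
        m = estimate.value_at(f)  # KeyError if off-grid
        out += np.abs(m) * mag * np.sin(2 * np.pi * f * t + phi + np.angle(m))
    return out
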