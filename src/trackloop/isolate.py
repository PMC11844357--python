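"""Open-loop pathway isolation from closed-loop FRFs.

With scalar per-axis dynamics the closed loop gives
``H_YR = (PF + PB) / (1 + PB)`` and ``H_YD = 1 / (1 + PB)``, which invert to

    PB = 1 / H_YD - 1
    PF = H_YR / H_YD - 1 / H_YD + 1

These are exact algebraic identities, so isolation introduces no modeling
assumptions beyond linearity and per-axis separability.  Near-zero H_YD is a
hard error rather than a regularized division: the synthetic noise-free path
never approaches the threshold, and silently damping the inverse would bias
every downstream fit.
"""
from __future__ import annotations

import numpy as np

from .exceptions import NearSingularError
from .frf import FrequencyResponseSet

EPS = 1e-8


def _check_invertible(h_yd: FrequencyResponseSet) -> None:
    bad = np.abs(h_yd.values) <= EPS
    if np.any(bad):
        f_bad = h_yd.frequencies[bad]
        raise NearSingularError(
            f"|H_YD| <= {EPS} at f = {f_bad} Hz (axis {h_yd.axis!r})")


def isolate_feedback(h_yd: FrequencyResponseSet) -> FrequencyResponseSet:
    """Feedback pathway PB = 1/H_YD - 1."""
    _check_invertible(h_yd)
    return h_yd.with_values(1.0 / h_yd.values - 1.0, channel="PB")


def isolate_feedforward(h_yr: FrequencyResponseSet,
                        h_yd: FrequencyResponseSet) -> FrequencyResponseSet:
    """Feedforward pathway PF = H_YR/H_YD - 1/H_YD + 1."""
    if not np.allclose(h_yr.frequencies, h_yd.frequencies, atol=1e-12):
        raise ValueError("H_YR and H_YD are on different grids")
    _check_invertible(h_yd)
    pf = h_yr.values / h_yd.values - 1.0 / h_yd.values + 1.0
    return h_yd.with_values(pf, channel="PF")
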