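"""Stability margins, tracking error, and the gain-swap counterfactual."""
import numpy as np
import pytest
from scipy.optimize import brentq

import trackloop as tl
from trackloop.margins import DEFAULT_BAND_HZ


def margins_oracle(k, tau, a, band=DEFAULT_BAND_HZ):
    """Independent dense root-finding on L = k e^{-s tau}/(s + a).

    Returns (gain_margin, phase_margin_deg); NaN components when the
    corresponding crossover lies outside the band.
    """
    w_lo, w_hi = 2 * np.pi * band[0], 2 * np.pi * band[1]
    mag = lambda w: k / np.hypot(w, a)
    phase = lambda w: -w * tau - np.arctan2(w, a)  # radians, monotone down
    gm = pm = float("nan")
    if (mag(w_lo) - 1) * (mag(w_hi) - 1) < 0:
        w_gc = brentq(lambda w: mag(w) - 1.0, w_lo, w_hi, xtol=1e-12)
        pm = 180.0 + np.degrees(phase(w_gc))
    if (phase(w_lo) + np.pi) * (phase(w_hi) + np.pi) < 0:
        w_pc = brentq(lambda w: phase(w) + np.pi, w_lo, w_hi, xtol=1e-12)
        gm = 1.0 / mag(w_pc)
    return gm, pm


class TestSmoothFrf:
    def _frf(self, values):
        freqs = np.array([0.08, 0.2, 0.52, 1.0, 2.84])
        return tl.FrequencyResponseSet(freqs, np.asarray(values, complex),
                                       channel="PB")

    def test_window_one_is_identity(self):
        frf = self._frf([1 + 1j, 2, 3 - 1j, 0.5j, 1])
        out = tl.smooth_frf(frf, window=1)
        assert np.array_equal(out.values, frf.values)

    def test_constant_frf_unchanged(self):
        frf = self._frf([0.5 - 0.5j] * 5)
        out = tl.smooth_frf(frf, window=3)
        assert np.allclose(out.values, frf.values, atol=1e-12)

    def test_three_point_window_hand_computed(self):
        """Interior points: mean magnitude and mean unwrapped phase over the
        3-point neighbourhood; endpoints untouched."""
        mags = np.array([1.0, 2.0, 4.0, 2.0, 1.0])
        phs = np.array([0.0, -0.4, -0.9, -1.5, -2.0])
        frf = self._frf(mags * np.exp(1j * phs))
        out = tl.smooth_frf(frf, window=3)
        for i in (1, 2, 3):
            expected = (mags[i - 1:i + 2].mean()
                        * np.exp(1j * phs[i - 1:i + 2].mean()))
            assert out.values[i] == pytest.approx(expected, abs=1e-12)
        assert out.values[0] == pytest.approx(frf.values[0])
        assert out.values[-1] == pytest.approx(frf.values[-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            tl.smooth_frf(self._frf([1] * 5), window=2)


class TestStabilityMargins:
    def test_pure_gain_has_no_crossovers(self):
        m = tl.stability_margins(lambda f: 0.5 * np.ones_like(np.asarray(f),
                                                              dtype=complex))
        assert np.isinf(m.gain_margin)
        assert np.isnan(m.phase_margin_deg)

    def test_delayed_integrator_closed_form(self):
        """L = e^{-0.3 s}/s: gain crossover at 1 rad/s with PM = 90 -
        0.3*180/pi ~ 72.81 deg; phase crossover gives GM = pi/0.6."""
        L = lambda f: (np.exp(-0.3j * 2 * np.pi * np.asarray(f))
                       / (2j * np.pi * np.asarray(f)))
        m = tl.stability_margins(L)
        assert m.phase_margin_deg == pytest.approx(90 - 0.3 * 180 / np.pi,
                                                   abs=0.1)
        assert m.gain_margin == pytest.approx(np.pi / 0.6, abs=0.01)
        assert m.gain_crossover_hz == pytest.approx(1 / (2 * np.pi), rel=1e-3)

    def test_leaky_integrator_against_root_finding_oracle(self):
        k, tau, a = 1.3, 0.123, 0.5
        loop = tl.PathwayModel("leaky_integrator_delay", k=k, tau=tau, a=a)
        m = tl.stability_margins(loop)
        gm, pm = margins_oracle(k, tau, a)
        assert m.phase_margin_deg == pytest.approx(pm, abs=0.1)
        assert m.gain_margin == pytest.approx(gm, abs=0.01)

    def test_oracle_equivalence_over_random_loops(self):
        """100 random (k, tau, a) loops: interpolation path within 0.1 deg /
        0.01 of the dense root-finding oracle."""
        rng = np.random.default_rng(11)
        n_checked = 0
        for _ in range(100):
            k = rng.uniform(0.5, 3.0)
            tau = rng.uniform(0.05, 0.3)
            a = rng.uniform(0.1, 2.0)
            loop = tl.PathwayModel("leaky_integrator_delay", k=k, tau=tau, a=a)
            m = tl.stability_margins(loop)
            gm, pm = margins_oracle(k, tau, a)
            if np.isfinite(pm):
                assert m.phase_margin_deg == pytest.approx(pm, abs=0.1)
                n_checked += 1
            if np.isfinite(gm):
                assert m.gain_margin == pytest.approx(gm, abs=0.01)
        assert n_checked > 50  # the sweep must actually exercise the check

    def test_margins_from_estimated_frf(self, ataxia_analysis,
                                        ataxia_subject):
        """Nonparametric path: margins from the smoothed 20-point PB FRF are
        close to the parametric-model margins."""
        model_m = tl.stability_margins(ataxia_subject.feedback)
        frf_m = tl.stability_margins(
            tl.smooth_frf(ataxia_analysis.pb["x"], window=3))
        assert frf_m.phase_margin_deg == pytest.approx(
            model_m.phase_margin_deg, abs=5.0)

    def test_phase_margin_decreases_with_delay(self):
        pms = []
        for tau in np.linspace(0.05, 0.3, 6):
            loop = tl.PathwayModel("leaky_integrator_delay",
                                   k=1.3, tau=tau, a=0.5)
            pms.append(tl.stability_margins(loop).phase_margin_deg)
        assert np.all(np.diff(pms) < 0)

    def test_gain_margin_decreases_with_gain(self):
        gms = []
        for k in np.linspace(0.8, 2.0, 6):
            loop = tl.PathwayModel("leaky_integrator_delay",
                                   k=k, tau=0.144, a=0.5)
            gms.append(tl.stability_margins(loop).gain_margin)
        assert np.all(np.diff(gms) < 0)


class TestTrackingError:
    def test_perfect_tracking_zero_error(self, control_records):
        import copy

        tr = copy.copy(control_records[0])
        tr.y = tr.r.copy()
        assert tl.tracking_error(tr) == 0.0

    def test_single_sinusoid_error_power(self, signal_groups):
        """y - r a single sinusoid of amplitude A on one axis -> MSE A^2/2."""
        ref, dist = signal_groups
        specs = {"rx": ref["r1"], "dx": dist["d2"],
                 "ry": ref["r3"], "dy": dist["d4"]}
        subj = tl.SyntheticSubject(
            "t", tl.PathwayModel("gain_delay", k=0.0, tau=0.0),
            tl.PathwayModel("gain_delay", k=0.0, tau=0.0))
        tr = tl.simulate_trial(subj, specs, 0, 75.0, 80.0)
        tr.y = tr.r.copy()
        A = 0.8
        t = tr.t
        tr.y[:, 0] += A * np.sin(2 * np.pi * 0.2 * t)  # 5 cycles in 25 s
        assert tl.tracking_error(tr) == pytest.approx(A**2 / 2, abs=1e-9)

    def test_matches_parseval_closed_form(self, control_subject,
                                          control_records, signal_groups):
        """MSE equals the frequency-domain sum of |H_yr - 1|^2 M^2/2 over
        reference components plus |H_yd|^2 M^2/2 over disturbance
        components, both axes."""
        tr = control_records[0]
        assert tr.preview_ms in (0, 500)
        expected = 0.0
        for role in ("rx", "ry", "dx", "dy"):
            gid = tr.composition[role]
            ref, dist = signal_groups
            spec = (ref if role.startswith("r") else dist)[gid]
            for f, m in zip(spec.frequencies, spec.magnitudes):
                h_yr, h_yd = tl.closed_loop_response(
                    control_subject, f, preview=tr.preview_ms > 0)
                if role.startswith("r"):
                    expected += abs(h_yr - 1.0)**2 * m**2 / 2
                else:
                    expected += abs(h_yd)**2 * m**2 / 2
        assert tl.tracking_error(tr) == pytest.approx(expected, abs=1e-9)

    def test_discard_longer_than_record_rejected(self, control_records):
        with pytest.raises(ValueError):
            tl.tracking_error(control_records[0], discard_s=1e6)


def phase_margin_eroded(orig, swapped):
    """True when the swap moved the phase margin toward instability.

    The phase margin exists only when the loop magnitude crosses 1 (NaN
    sentinel otherwise, e.g. k = 1 with pole a >= 1 keeps |L| < 1 at all
    frequencies).  A crossover appearing only after a gain increase is
    itself erosion — the loop went from never reaching unit gain to having
    a finite margin.
    """
    o, s = orig.phase_margin_deg, swapped.phase_margin_deg
    if np.isnan(o) and np.isnan(s):
        return True  # undefined on both sides: vacuous, GM carries the claim
    if np.isnan(o):
        return True  # unit-gain crossover appeared after the swap
    if np.isnan(s):
        return False  # crossover vanished: margin improved
    return s < o


class TestGainSwap:
    POLE_SWEEP = (0.1, 0.25, 0.5, 1.0, 2.0)

    def _ataxia_subject(self, a):
        return tl.SyntheticSubject(
            "ax", tl.PathwayModel("gain_delay", k=0.6, tau=0.245),
            tl.PathwayModel("leaky_integrator_delay", k=1.0, tau=0.144, a=a))

    def test_same_gain_identical_outputs(self, plan, signal_groups):
        ref, dist = signal_groups
        subj = self._ataxia_subject(0.5)
        res = tl.gain_swap_experiment(subj, 1.0, plan, ref, dist, 75.0, 80.0)
        assert res.mse_swapped == pytest.approx(res.mse_original)
        assert (res.margins_swapped.gain_margin
                == pytest.approx(res.margins_original.gain_margin))

    @pytest.mark.parametrize("a", POLE_SWEEP)
    def test_raising_gain_to_control_level_erodes_margins(
            self, a, plan, signal_groups):
        """Counterfactual: replacing the ataxia-level feedback gain (1.0)
        with the control level (1.3) strictly decreases the gain margin for
        every integrator pole on the default sweep, and erodes the phase
        margin wherever it is defined."""
        ref, dist = signal_groups
        subj = self._ataxia_subject(a)
        res = tl.gain_swap_experiment(subj, 1.3, plan, ref, dist, 75.0, 80.0)
        assert (res.margins_swapped.gain_margin
                < res.margins_original.gain_margin)
        assert phase_margin_eroded(res.margins_original, res.margins_swapped)
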