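"""Model fitting: FD error, multi-start optimisation, leave-one-subject-out
cross-validation, and parsimony-aware selection."""
import numpy as np
import pytest

import trackloop as tl
from trackloop.fitting import fd_error

GRID = tl.build_frequency_grid().frequencies


def _tabulate(values, freqs=None):
    freqs = GRID if freqs is None else freqs
    return tl.FrequencyResponseSet(freqs, values, channel="PF")


def _sampled(model, freqs=None):
    freqs = GRID if freqs is None else freqs
    return _tabulate(model.frequency_response(freqs), freqs)


class TestFDError:
    def test_exact_model_zero_error(self):
        model = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        assert fd_error(model, _sampled(model)) == 0.0

    def test_gain_perturbation_closed_form(self):
        """For data k e^{-jwt}, perturbing the gain by delta adds n*delta^2
        because the phase factors have unit modulus."""
        model = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        data = _sampled(model)
        delta = 0.07
        perturbed = model.with_params(k=0.62 + delta)
        assert fd_error(perturbed, data) == pytest.approx(20 * delta**2,
                                                          rel=1e-12)

    def test_empty_grid(self):
        model = tl.PathwayModel("gain_delay", k=1.0, tau=0.1)
        empty = tl.FrequencyResponseSet(np.array([]), np.array([]), "PF")
        assert fd_error(model, empty) == 0.0

    def test_tabulated_model_reproduces_itself(self):
        vals = (0.3 + 0.1j) * np.ones(len(GRID))
        model = tl.PathwayModel("tabulated",
                                table=(tuple(GRID), tuple(vals)))
        assert fd_error(model, _tabulate(vals)) == 0.0


class TestFitModel:
    def test_gain_delay_recovery(self):
        truth = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        rep = tl.fit_model(_sampled(truth), "gain_delay",
                           rng=np.random.default_rng(0))
        assert rep.params["k"] == pytest.approx(0.62, abs=1e-6)
        assert rep.params["tau"] == pytest.approx(0.185, abs=1e-6)
        assert rep.fd_error < 1e-10

    def test_beats_brute_force_grid_search(self):
        """The optimiser never returns a worse error than a dense 2-D grid
        search over (k, tau)."""
        truth = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        data = _sampled(truth)
        ks = np.arange(0.0, 2.0 + 1e-9, 1e-3)
        taus = np.arange(0.0, 0.6 + 1e-9, 1e-3)
        # vectorised residual: |k e^{-jwt} - data|^2 summed over frequencies
        w = 2 * np.pi * GRID
        phase = np.exp(-1j * np.outer(taus, w))          # (n_tau, n_f)
        d = data.values[None, None, :]
        resid = (ks[:, None, None] * phase[None, :, :] - d)
        errors = np.sum(np.abs(resid) ** 2, axis=2)
        grid_min = errors.min()
        rep = tl.fit_model(data, "gain_delay", rng=np.random.default_rng(1))
        assert rep.fd_error <= grid_min + 1e-12

    def test_leaky_integrator_recovery(self):
        truth = tl.PathwayModel("leaky_integrator_delay",
                                k=1.3, tau=0.123, a=0.5)
        rep = tl.fit_model(_sampled(truth), "leaky_integrator_delay",
                           rng=np.random.default_rng(2))
        assert rep.params["k"] == pytest.approx(1.3, abs=1e-4)
        assert rep.params["tau"] == pytest.approx(0.123, abs=1e-4)
        assert rep.params["a"] == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("structure,truth_params", [
        ("first_order_delay", {"k": 0.8, "tau": 0.2, "a": 3.0}),
        ("second_order_delay", {"k": 0.7, "tau": 0.1, "a": 3.0, "b": 8.0}),
    ])
    def test_parameter_recovery_other_structures(self, structure,
                                                 truth_params):
        truth = tl.PathwayModel(structure, **truth_params)
        rep = tl.fit_model(_sampled(truth), structure,
                           rng=np.random.default_rng(3))
        assert rep.fd_error < 1e-8
        for name, val in truth_params.items():
            assert rep.params[name] == pytest.approx(val, abs=1e-3)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            tl.fit_model(_sampled(tl.PathwayModel("gain_delay", k=1, tau=0)),
                         "cubic_spline")


class TestCrossValidate:
    def test_homogeneous_group_zero_cve(self):
        truth = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        sets = [_sampled(truth) for _ in range(4)]
        rep = tl.cross_validate(sets, "gain_delay", n_restarts=30,
                                rng=np.random.default_rng(4))
        assert rep.cve < 1e-10
        assert rep.cve == pytest.approx(np.mean(rep.ve))

    def test_two_subject_hand_computation(self):
        """With 2 subjects, each fold fits the *other* subject exactly, so
        VE_i = sum_f |model_j(f) - data_i(f)|^2 with model_j the generator
        of subject j."""
        m1 = tl.PathwayModel("gain_delay", k=0.6, tau=0.18)
        m2 = tl.PathwayModel("gain_delay", k=0.7, tau=0.22)
        sets = [_sampled(m1), _sampled(m2)]
        rep = tl.cross_validate(sets, "gain_delay", n_restarts=40,
                                rng=np.random.default_rng(5))
        ve1 = np.sum(np.abs(m2.frequency_response(GRID)
                            - m1.frequency_response(GRID))**2)
        assert rep.ve[0] == pytest.approx(ve1, rel=1e-6)
        assert rep.ve[1] == pytest.approx(ve1, rel=1e-6)  # symmetric here
        assert rep.cve == pytest.approx(ve1, rel=1e-6)

    def test_outlier_subject_has_largest_ve(self):
        base = tl.PathwayModel("gain_delay", k=0.6, tau=0.18)
        outlier = tl.PathwayModel("gain_delay", k=1.4, tau=0.4)
        sets = [_sampled(base)] * 3 + [_sampled(outlier)]
        rep = tl.cross_validate(sets, "gain_delay", n_restarts=30,
                                rng=np.random.default_rng(6))
        assert np.argmax(rep.ve) == 3

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            tl.cross_validate([_sampled(tl.PathwayModel("gain_delay",
                                                        k=1, tau=0))],
                              "gain_delay")


class TestSelectModel:
    def _cv(self, sets, structures, seed=7, n_restarts=40):
        rng = np.random.default_rng(seed)
        return [tl.cross_validate(sets, s, n_restarts=n_restarts, rng=rng)
                for s in structures]

    def test_parsimony_prefers_gain_delay(self):
        """Gain+delay data: the richer first-order structure fits equally
        well (CVE tie within tolerance), so the simpler model is chosen."""
        truth = tl.PathwayModel("gain_delay", k=0.62, tau=0.185)
        sets = [_sampled(truth) for _ in range(3)]
        reports = self._cv(sets, ["gain_delay", "first_order_delay"])
        assert tl.select_model(reports).structure == "gain_delay"

    def test_leaky_integrator_beats_gain_delay(self):
        """Leaky-integrator data cannot be zero-fitted by a pure gain+delay;
        the CVE gap exceeds the parsimony tolerance."""
        truth = tl.PathwayModel("leaky_integrator_delay",
                                k=1.3, tau=0.123, a=0.5)
        sets = [_sampled(truth) for _ in range(3)]
        reports = self._cv(sets, ["leaky_integrator_delay", "gain_delay"])
        assert tl.select_model(reports).structure == "leaky_integrator_delay"

    def test_single_candidate_returned_unconditionally(self):
        rep = tl.FitReport("gain_delay", {"k": 1.0, "tau": 0.1},
                           fd_error=5.0, n_restarts=1)
        assert tl.select_model([rep]) is rep


class TestRobustnessToRemnant:
    def test_delay_bias_small_under_remnant(self, grid, plan, signal_groups):
        """Monte-Carlo: remnant_sd = 0.1 cm, 8 pooled trials; the fitted
        feedforward delay is biased by well under 2 ms over seeds."""
        from conftest import make_subject

        ref, dist = signal_groups
        taus = []
        for seed in range(10):
            subject = make_subject("mc", "control", remnant_sd=0.1)
            records = tl.simulate_session(subject, plan, ref, dist,
                                          75.0, 80.0, seed=seed)
            no_preview = [tr for tr in records if tr.preview_ms == 0]
            sa = tl.identify_subject(no_preview, grid, preview_ms=0,
                                     discard_s=25.0)
            rep = tl.fit_model(sa.pf["x"], "gain_delay", n_restarts=40,
                               rng=np.random.default_rng(seed))
            taus.append(rep.params["tau"])
        bias = abs(np.mean(taus) - 0.185)
        assert bias < 0.002
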