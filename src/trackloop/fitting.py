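"""Parametric model fitting of pathway FRFs with cross-validated selection.

A candidate structure (gain + delay, McRuer-style leaky integrator + delay,
first- or second-order lag + delay) is fitted to a complex-valued FRF by
minimizing the frequency-domain squared error

    FD_error = sum_f | model(f) - data(f) |^2

with multi-start Nelder-Mead simplex search (delays enter the complex
residual directly, so no phase unwrapping is involved).  Structure selection
uses leave-one-subject-out cross-validation: for each held-out subject the
structure is fitted to the complex mean of the remaining subjects' FRFs and
scored against the held-out data; the cross-validation error (CVE) is the
mean of these validation errors.  Among structures whose CVE is within a
parsimony tolerance of the best, the one with the fewest parameters wins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import OptimizationError
from .frf import FrequencyResponseSet, complex_mean
from .simulate import PARAM_NAMES, PathwayModel, make_pathway

#: restart-sampling bounds per parameter (also soft constraints during search)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (1e-6, 5.0),
    "tau": (0.0, 0.6),
    "a": (1e-3, 20.0),
    "b": (1e-3, 20.0),
}
DEFAULT_N_RESTARTS = 100
PARSIMONY_TOL = 0.05


@dataclass
class FitReport:
    """Result of fitting one candidate structure.

    ``ve`` and ``cve`` are present only after cross-validation; ``params``
    always refers to the fit on the full (group-mean) data.
    """

    structure: str
    params: dict[str, float]
    fd_error: float
    n_restarts: int
    ve: list[float] | None = None
    cve: float | None = None
    fold_params: list[dict[str, float]] | None = None
    subject_params: dict[str, dict[str, float]] | None = None

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.structure])

    @property
    def model(self) -> PathwayModel:
        return PathwayModel(structure=self.structure, **self.params)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "params": self.params,
            "fd_error": self.fd_error,
            "n_restarts": self.n_restarts,
            "ve": self.ve,
            "cve": self.cve,
        }


def fd_error(model: PathwayModel, data: FrequencyResponseSet) -> float:
    """Squared complex-residual norm of the model over the data grid."""
    if len(data) == 0:
        return 0.0
    resid = model.frequency_response(data.frequencies) - data.values
    return float(np.sum(np.abs(resid) ** 2))


def _bounds_arrays(structure: str,
                   bounds: dict[str, tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    names = PARAM_NAMES[structure]
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    return lo, hi


def fit_model(data: FrequencyResponseSet, structure: str,
              n_restarts: int = DEFAULT_N_RESTARTS,
              bounds: dict[str, tuple[float, float]] | None = None,
              rng: np.random.Generator | None = None) -> FitReport:
    """Multi-start derivative-free fit of one structure to one FRF set.

    Each restart draws a uniform start within ``bounds`` and runs Nelder-Mead
    on FD_error (values outside the bounds are penalized); the best restart
    wins.  Tight simplex tolerances let zero-residual problems converge to
    ~1e-8 parameter accuracy.
    """
    if structure not in PARAM_NAMES:
        raise ValueError(f"unknown structure {structure!r}")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    rng = np.random.default_rng(0) if rng is None else rng
    lo, hi = _bounds_arrays(structure, bounds)

    def objective(x: np.ndarray) -> float:
        below = np.maximum(lo - x, 0.0)
        above = np.maximum(x - hi, 0.0)
        violation = float(np.sum(below**2 + above**2))
        if violation > 0:
            return 1e9 * (1.0 + violation)
        return fd_error(make_pathway(structure, x), data)

    best = None
    n_converged = 0
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 4000, "maxfev": 8000})
        if np.isfinite(res.fun):
            n_converged += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.all((best.x >= lo - 1e-12) & (best.x <= hi + 1e-12)):
        raise OptimizationError(
            f"no restart of {structure} converged inside bounds "
            f"({n_converged}/{n_restarts} finite)")
    params = dict(zip(PARAM_NAMES[structure], map(float, best.x)))
    return FitReport(structure=structure, params=params,
                     fd_error=float(best.fun), n_restarts=n_restarts)


def cross_validate(subject_sets: list[FrequencyResponseSet], structure: str,
                   n_restarts: int = DEFAULT_N_RESTARTS,
                   bounds: dict[str, tuple[float, float]] | None = None,
                   rng: np.random.Generator | None = None) -> FitReport:
    """Leave-one-subject-out cross-validation of one structure.

    For each held-out subject the structure is fitted to the complex mean of
    the remaining subjects' FRFs; the validation error is the FD error of
    that fit on the held-out subject's data.  The returned report carries the
    fit on the all-subject mean (``params``, ``fd_error``), per-fold
    parameters, the VE list, and CVE = mean(VE).
    """
    if len(subject_sets) < 2:
        raise ValueError("cross-validation needs at least 2 subjects")
    rng = np.random.default_rng(0) if rng is None else rng
    full = fit_model(complex_mean(subject_sets), structure,
                     n_restarts=n_restarts, bounds=bounds, rng=rng)
    ve: list[float] = []
    fold_params: list[dict[str, float]] = []
    for i, held_out in enumerate(subject_sets):
        rest = subject_sets[:i] + subject_sets[i + 1:]
        fold = fit_model(complex_mean(rest), structure,
                         n_restarts=n_restarts, bounds=bounds, rng=rng)
        ve.append(fd_error(fold.model, held_out))
        fold_params.append(fold.params)
    full.ve = ve
    full.cve = float(np.mean(ve))
    full.fold_params = fold_params
    return full


def select_model(reports: list[FitReport],
                 parsimony_tol: float = PARSIMONY_TOL) -> FitReport:
    """Choose the simplest adequately cross-validating structure.

    Among reports whose CVE is within ``(1 + parsimony_tol)`` of the minimum
    CVE, return the one with the fewest parameters; ties break by lower FD
    error, then by position in ``reports``.  Reports without a CVE (plain
    fits) are compared on FD error instead.
    """
    if not reports:
        raise ValueError("need at least one report")
    if len(reports) == 1:
        return reports[0]
    scores = [r.cve if r.cve is not None else r.fd_error for r in reports]
    best_score = min(scores)
    # Absolute floor avoids 0 * (1 + tol) == 0 rejecting exact-fit ties.
    threshold = best_score * (1.0 + parsimony_tol) + 1e-12
    admissible = [(i, r) for i, r in enumerate(reports)
                  if scores[i] <= threshold]
    fewest = min(r.n_params for _, r in admissible)
    simplest = [(i, r) for i, r in admissible if r.n_params == fewest]
    # FD-error tie-break with the same tolerance, so that structures that
    # both fit to numerical noise fall through to the declared order.
    best_fd = min(r.fd_error for _, r in simplest)
    fd_threshold = best_fd * (1.0 + parsimony_tol) + 1e-12
    finalists = [(i, r) for i, r in simplest if r.fd_error <= fd_threshold]
    return min(finalists, key=lambda item: item[0])[1]
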