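"""End-to-end identification pipeline and tabular reporting.

`run_pipeline` executes the full study on synthetic cohorts: stimulus design,
closed-loop simulation, FRF estimation, pathway isolation, cross-validated
model fitting, preview-filter extraction, stability margins, and the
feedback-gain-swap counterfactual.  Every artifact is a CSV/JSON file
stamped with the resolved configuration hash and seed, and every number is
reproducible from (config, seed) alone.

`summarize` turns a completed run directory into the per-subject tables the
study's group comparisons consume: pathway parameters, the feedforward-minus-
feedback delay difference, tracking error by preview condition, and margins.
Group-level inferential statistics (t-tests, ANOVA, correlations) are
standard and deliberately not reimplemented here.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stimulus as stim
from .fitting import (DEFAULT_N_RESTARTS, PARSIMONY_TOL, FitReport,
                      cross_validate, fit_model, select_model)
from .frf import FrequencyResponseSet, estimate_frfs
from .isolate import isolate_feedback, isolate_feedforward
from .margins import (DEFAULT_SMOOTH_WINDOW, gain_swap_experiment,
                      smooth_frf, stability_margins, tracking_error)
from .preview import extract_preview_filter, reference_controller_frfs
from .simulate import (PathwayModel, SyntheticSubject, simulate_session)
from .stimulus import PREVIEW_MS

#: published group-level best-fit parameters used as simulator ground truth.
#: Feedforward: pure gain with delay; feedback: leaky integrator with delay
#: (delays in seconds).  The feedforward gain and the integrator pole are
#: not reported at group level; 0.6 and 0.5 rad/s are the package defaults.
GROUP_PARAMS = {
    "control": {
        "feedforward": {"structure": "gain_delay", "k": 0.6, "tau": 0.185},
        "feedback": {"structure": "leaky_integrator_delay",
                     "k": 1.3, "tau": 0.123, "a": 0.5},
    },
    "ataxia": {
        "feedforward": {"structure": "gain_delay", "k": 0.6, "tau": 0.245},
        "feedback": {"structure": "leaky_integrator_delay",
                     "k": 1.0, "tau": 0.144, "a": 0.5},
    },
}

FEEDFORWARD_CANDIDATES = ("gain_delay", "first_order_delay", "second_order_delay")
FEEDBACK_CANDIDATES = ("leaky_integrator_delay", "gain_delay", "first_order_delay")


def make_preview_filter(advance_s: float, cutoff_hz: float):
    """Lookahead filter: a pure time advance cascaded with a first-order
    low-pass — phase lead across the band with high-frequency roll-off."""
    def m(f):
        f = np.asarray(f, dtype=float)
        return np.exp(2j * np.pi * f * advance_s) / (1.0 + 1j * f / cutoff_hz)
    return m


@dataclass
class GroupConfig:
    """One synthetic cohort: generating pathway models and noise settings."""

    name: str
    feedforward: dict = field(default_factory=dict)
    feedback: dict = field(default_factory=dict)
    n_subjects: int = 6
    remnant_sd: float = 0.0
    param_jitter: float = 0.0         # fractional between-subject spread
    preview_advance_s: float | None = None
    preview_cutoff_hz: float | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    base_hz: float = stim.DEFAULT_BASE_HZ
    n_freqs: int = stim.DEFAULT_GRID_SIZE
    duration_s: float = stim.DEFAULT_TRIAL_DURATION_S
    sample_rate_hz: float = stim.DEFAULT_SAMPLE_RATE_HZ
    discard_s: float = stim.DEFAULT_DISCARD_S
    groups: list[GroupConfig] = field(default_factory=list)
    candidates_feedforward: tuple[str, ...] = FEEDFORWARD_CANDIDATES
    candidates_feedback: tuple[str, ...] = FEEDBACK_CANDIDATES
    n_restarts: int = DEFAULT_N_RESTARTS
    parsimony_tol: float = PARSIMONY_TOL
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    enable_preview: bool = True
    enable_margins: bool = True
    enable_gain_swap: bool = True
    gain_swap_group: str = "ataxia"   # whose gain is replaced ...
    gain_donor_group: str = "control"  # ... by this group's feedback gain
    write_trials: bool = False

    def __post_init__(self) -> None:
        self.groups = [g if isinstance(g, GroupConfig) else GroupConfig(**g)
                       for g in self.groups]
        self.candidates_feedforward = tuple(self.candidates_feedforward)
        self.candidates_feedback = tuple(self.candidates_feedback)

    @classmethod
    def demo(cls, seed: int = 0, n_subjects: int = 6,
             n_restarts: int = DEFAULT_N_RESTARTS) -> "RunConfig":
        """Two-group noise-free demo cohort with the published parameters."""
        groups = [
            GroupConfig(name="control", n_subjects=n_subjects,
                        preview_advance_s=0.25, preview_cutoff_hz=1.5,
                        **GROUP_PARAMS["control"]),
            GroupConfig(name="ataxia", n_subjects=n_subjects,
                        preview_advance_s=0.15, preview_cutoff_hz=1.0,
                        **GROUP_PARAMS["ataxia"]),
        ]
        return cls(seed=seed, groups=groups, n_restarts=n_restarts)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["candidates_feedforward"] = list(self.candidates_feedforward)
        d["candidates_feedback"] = list(self.candidates_feedback)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _jittered(params: dict, jitter: float, rng: np.random.Generator) -> dict:
    out = dict(params)
    if jitter > 0:
        for key, val in out.items():
            if key == "structure":
                continue
            out[key] = float(max(val * (1.0 + jitter * rng.standard_normal()),
                                 1e-4))
    return out


def build_group_subjects(group: GroupConfig, seed: int) -> list[SyntheticSubject]:
    """Instantiate a cohort from a group config (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    preview = None
    if group.preview_advance_s is not None:
        preview = make_preview_filter(group.preview_advance_s,
                                      group.preview_cutoff_hz or 1.5)
    subjects = []
    for i in range(group.n_subjects):
        ff = _jittered(group.feedforward, group.param_jitter, rng)
        fb = _jittered(group.feedback, group.param_jitter, rng)
        subjects.append(SyntheticSubject(
            subject_id=f"{group.name}_{i + 1:02d}",
            feedforward=PathwayModel(**ff),
            feedback=PathwayModel(**fb),
            preview_filter=preview,
            remnant_sd=group.remnant_sd))
    return subjects


@dataclass
class SubjectAnalysis:
    """Per-subject identification products for one preview condition."""

    subject_id: str
    group: str
    frfs: dict                       # axis -> {'H_YR','H_YD'}
    pf: dict[str, FrequencyResponseSet]   # axis -> PF set
    pb: dict[str, FrequencyResponseSet]   # axis -> PB set


def identify_subject(trials, grid, preview_ms, discard_s, subject_id="",
                     group="") -> SubjectAnalysis:
    """FRF estimation + pathway isolation for one subject/condition."""
    frfs = estimate_frfs(trials, grid, preview_ms=preview_ms,
                         discard_s=discard_s, subject_id=subject_id)
    pf = {ax: isolate_feedforward(frfs[ax]["H_YR"], frfs[ax]["H_YD"])
          for ax in frfs}
    pb = {ax: isolate_feedback(frfs[ax]["H_YD"]) for ax in frfs}
    return SubjectAnalysis(subject_id=subject_id, group=group,
                           frfs=frfs, pf=pf, pb=pb)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns a dict of artifact paths and
    in-memory results.  Aborts with the offending stage's exception."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(config.to_yaml())
    meta = {"seed": config.seed, "config_hash": config.config_hash,
            "stages": []}
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(child.generate_state(1)[0] % (2**31))
             for name, child in zip(
                 ("phases", "plan", "subjects", "remnant", "fitting"),
                 ss.spawn(5))}

    # --- design ---------------------------------------------------------
    grid = stim.build_frequency_grid(config.base_hz, config.n_freqs)
    phase_rng = np.random.default_rng(seeds["phases"])
    ref_groups = stim.make_signal_groups(grid, "reference", phase_rng)
    dist_groups = stim.make_signal_groups(grid, "disturbance", phase_rng)
    plan = stim.build_session_plan(grid, seeds["plan"])
    plan.to_frame().to_csv(out / "session_plan.csv", index=False)
    comp_rows = []
    for role, groups in (("reference", ref_groups), ("disturbance", dist_groups)):
        for gid, spec in groups.items():
            for f, m, p in zip(spec.frequencies, spec.magnitudes, spec.phases):
                comp_rows.append((role, gid, f, m, p))
    pd.DataFrame(comp_rows, columns=["role", "group_id", "freq_hz",
                                     "magnitude_cm", "phase_rad"]
                 ).to_csv(out / "stimulus_components.csv", index=False)
    meta["stages"].append("design")

    # --- simulate -------------------------------------------------------
    cohorts: dict[str, list[SyntheticSubject]] = {}
    records: dict[str, list] = {}
    subj_rng = np.random.default_rng(seeds["subjects"])
    for group in config.groups:
        cohorts[group.name] = build_group_subjects(
            group, int(subj_rng.integers(2**31)))
        for subject in cohorts[group.name]:
            noise_seed = (None if subject.remnant_sd == 0
                          else int(subj_rng.integers(2**31)))
            records[subject.subject_id] = simulate_session(
                subject, plan, ref_groups, dist_groups,
                config.duration_s, config.sample_rate_hz, seed=noise_seed)
    if config.write_trials:
        tdir = out / "trials"
        tdir.mkdir(exist_ok=True)
        for sid, trs in records.items():
            for tr in trs:
                tr.write_csv(tdir / f"{sid}_trial{tr.trial:02d}.csv")
    meta["stages"].append("simulate")

    # --- estimate + isolate --------------------------------------------
    analyses: dict[str, dict[int | None, SubjectAnalysis]] = {}
    frf_frames = []
    for group in config.groups:
        for subject in cohorts[group.name]:
            per_cond: dict[int | None, SubjectAnalysis] = {}
            conditions = [0, PREVIEW_MS] if config.enable_preview else [0]
            for cond in conditions:
                sa = identify_subject(records[subject.subject_id], grid,
                                      cond, config.discard_s,
                                      subject_id=subject.subject_id,
                                      group=group.name)
                per_cond[cond] = sa
                for ax in sa.frfs:
                    for ch_set in (sa.frfs[ax]["H_YR"], sa.frfs[ax]["H_YD"],
                                   sa.pf[ax], sa.pb[ax]):
                        frame = ch_set.to_frame()
                        frame["preview_ms"] = cond
                        frame["group"] = group.name
                        frf_frames.append(frame)
            analyses[subject.subject_id] = per_cond
    pd.concat(frf_frames, ignore_index=True).to_csv(out / "frf.csv", index=False)
    meta["stages"].append("estimate")

    # --- fit + cross-validate ------------------------------------------
    fit_rng = np.random.default_rng(seeds["fitting"])
    group_fits: dict = {}
    subject_rows = []
    for group in config.groups:
        sids = [s.subject_id for s in cohorts[group.name]]
        group_fits[group.name] = {}
        for pathway, candidates in (("feedforward", config.candidates_feedforward),
                                    ("feedback", config.candidates_feedback)):
            group_fits[group.name][pathway] = {}
            for axis in ("x", "y"):
                sets = [getattr(analyses[sid][0],
                                "pf" if pathway == "feedforward" else "pb")[axis]
                        for sid in sids]
                reports = [cross_validate(sets, s, n_restarts=config.n_restarts,
                                          rng=fit_rng)
                           for s in candidates]
                chosen = select_model(reports, config.parsimony_tol)
                group_fits[group.name][pathway][axis] = {
                    "reports": [r.to_dict() for r in reports],
                    "selected": chosen.to_dict(),
                }
                for sid, frf_set in zip(sids, sets):
                    rep = fit_model(frf_set, chosen.structure,
                                    n_restarts=config.n_restarts, rng=fit_rng)
                    subject_rows.append({
                        "group": group.name, "subject": sid,
                        "pathway": pathway, "axis": axis,
                        "structure": rep.structure,
                        "fd_error": rep.fd_error, **rep.params})
    (out / "group_fits.json").write_text(json.dumps(
        {"config_hash": config.config_hash, "seed": config.seed,
         "fits": group_fits}, indent=1))
    subject_fits = pd.DataFrame(subject_rows)
    subject_fits.to_csv(out / "subject_fits.csv", index=False)
    meta["stages"].append("fit")

    # --- tracking error -------------------------------------------------
    err_rows = []
    for group in config.groups:
        for subject in cohorts[group.name]:
            for tr in records[subject.subject_id]:
                err_rows.append({
                    "group": group.name, "subject": subject.subject_id,
                    "trial": tr.trial, "preview_ms": tr.preview_ms,
                    "mse_cm2": tracking_error(tr, discard_s=config.discard_s)})
    pd.DataFrame(err_rows).to_csv(out / "tracking_error.csv", index=False)
    meta["stages"].append("tracking_error")

    # --- preview filter -------------------------------------------------
    if config.enable_preview:
        pv_frames = []
        for group in config.groups:
            for subject in cohorts[group.name]:
                for axis in ("x", "y"):
                    np_frf = analyses[subject.subject_id][0].frfs[axis]
                    pv_frf = analyses[subject.subject_id][PREVIEW_MS].frfs[axis]
                    est = extract_preview_filter(
                        reference_controller_frfs(np_frf["H_YR"], np_frf["H_YD"]),
                        reference_controller_frfs(pv_frf["H_YR"], pv_frf["H_YD"]))
                    frame = est.to_frame()
                    frame["group"] = group.name
                    pv_frames.append(frame)
        pd.concat(pv_frames, ignore_index=True).to_csv(
            out / "preview_filter.csv", index=False)
        meta["stages"].append("preview")

    # --- stability margins ----------------------------------------------
    if config.enable_margins:
        margin_rows = []
        fits_by_key = {(r["subject"], r["pathway"], r["axis"]): r
                       for r in subject_rows}
        for group in config.groups:
            for subject in cohorts[group.name]:
                for axis in ("x", "y"):
                    row = fits_by_key[(subject.subject_id, "feedback", axis)]
                    model = PathwayModel(
                        structure=row["structure"],
                        **{k: row[k] for k in ("k", "tau", "a", "b")
                           if k in row and pd.notna(row.get(k))})
                    for path_name, loop in (
                            ("model", model),
                            ("frf", smooth_frf(
                                analyses[subject.subject_id][0].pb[axis],
                                config.smooth_window))):
                        m = stability_margins(loop)
                        margin_rows.append({
                            "group": group.name, "subject": subject.subject_id,
                            "axis": axis, "path": path_name,
                            "gain_margin": m.gain_margin,
                            "phase_margin_deg": m.phase_margin_deg,
                            "gc_hz": m.gain_crossover_hz,
                            "pc_hz": m.phase_crossover_hz,
                            "window": config.smooth_window})
        pd.DataFrame(margin_rows).to_csv(out / "margins.csv", index=False)
        meta["stages"].append("margins")

    # --- gain-swap counterfactual ---------------------------------------
    if config.enable_gain_swap:
        names = [g.name for g in config.groups]
        if config.gain_swap_group in names and config.gain_donor_group in names:
            target = cohorts[config.gain_swap_group][0]
            donor_gain = cohorts[config.gain_donor_group][0].feedback.k
            res = gain_swap_experiment(
                dataclasses.replace(target, remnant_sd=0.0),
                donor_gain, plan, ref_groups, dist_groups,
                config.duration_s, config.sample_rate_hz)
            (out / "gain_swap.json").write_text(json.dumps({
                "config_hash": config.config_hash,
                "swap_group": config.gain_swap_group,
                "donor_group": config.gain_donor_group,
                "original_gain": res.original_gain,
                "swapped_gain": res.swapped_gain,
                "mse_original_cm2": res.mse_original,
                "mse_swapped_cm2": res.mse_swapped,
                "gain_margin_original": res.margins_original.gain_margin,
                "gain_margin_swapped": res.margins_swapped.gain_margin,
                "phase_margin_original_deg": res.margins_original.phase_margin_deg,
                "phase_margin_swapped_deg": res.margins_swapped.phase_margin_deg,
            }, indent=1))
            meta["stages"].append("gain_swap")

    (out / "run_meta.json").write_text(json.dumps(meta, indent=1))
    summarize(out)
    return {"out_dir": out, "meta": meta, "grid": grid, "plan": plan,
            "cohorts": cohorts, "analyses": analyses,
            "group_fits": group_fits, "subject_fits": subject_fits}


def summarize(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Build summary tables from a completed run directory.

    Writes (and returns) the per-subject pathway-parameter table, the
    feedforward-minus-feedback delay-difference table, tracking error by
    preview condition, and the margins table.  Raises FileNotFoundError
    listing any missing prerequisite artifacts.
    """
    run_dir = Path(run_dir)
    required = ["subject_fits.csv", "tracking_error.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete, missing: {missing}")
    sdir = run_dir / "summary"
    sdir.mkdir(exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    fits = pd.read_csv(run_dir / "subject_fits.csv")
    tables["parameters"] = fits
    fits.to_csv(sdir / "parameters.csv", index=False)

    wide = fits.pivot_table(index=["group", "subject", "axis"],
                            columns="pathway", values="tau").reset_index()
    wide["delay_difference_s"] = wide["feedforward"] - wide["feedback"]
    tables["delay_difference"] = wide
    wide.to_csv(sdir / "delay_difference.csv", index=False)

    err = pd.read_csv(run_dir / "tracking_error.csv")
    by_cond = (err.groupby(["group", "subject", "preview_ms"])["mse_cm2"]
               .mean().reset_index())
    tables["tracking_error"] = by_cond
    by_cond.to_csv(sdir / "tracking_error.csv", index=False)

    if (run_dir / "margins.csv").exists():
        margins = pd.read_csv(run_dir / "margins.csv")
        tables["margins"] = margins
        margins.to_csv(sdir / "margins.csv", index=False)
    return tables
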