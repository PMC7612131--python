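"""End-to-end orchestration: simulate → screen → score → phenotype →
regress → two-step analysis, from a single validated config, with
provenance logging.  Every stage writes its intermediate table to the run
directory; runs are idempotent given identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, erp, inference, phenotype, screening, synth_cohort
from . import synth_eeg, synth_flanker, synth_twostep, twostep_analysis


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration with the published analysis constants as
    named defaults."""

    seed: int = 0
    n_subjects: int = 196
    #: ERP quantification method and regression outcome variant
    method: str = "adaptive_mean"
    outcome: str = "ern"  # ern | delta_ern | ern_resid
    #: analysis constants
    reject_threshold_uv: float = 50.0
    baseline_window_ms: tuple[float, float] = (-400.0, -200.0)
    search_window_ms: tuple[float, float] = (-20.0, 120.0)
    halfwidth_ms: float = 40.0
    missed_trial_limit: int = 96
    accuracy_floor: float = 0.55
    family_alpha: float = 0.05
    reported_threshold: float = 0.005
    #: generator blocks (field overrides for the dataclass defaults)
    behaviour: dict = field(default_factory=dict)
    eeg: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    twostep: dict = field(default_factory=dict)
    #: optional planted effect {"target", "dimension", "beta"}
    plant: dict | None = None
    twostep_coupling: dict | None = None
    write_epochs: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        if self.method not in erp.METHODS:
            raise ConfigError(f"method must be one of {erp.METHODS}")
        if self.outcome not in ("ern", "delta_ern", "ern_resid"):
            raise ConfigError("outcome must be ern | delta_ern | ern_resid")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def scoring_config(self) -> erp.ScoringConfig:
        return erp.ScoringConfig(
            baseline_window_ms=tuple(self.baseline_window_ms),
            reject_threshold_uv=self.reject_threshold_uv,
            search_window_ms=tuple(self.search_window_ms),
            halfwidth_ms=self.halfwidth_ms,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages and write every intermediate table plus a
    provenance log and a final association report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.scoring_config()
    (s_beh, s_eeg, s_items, s_demo, s_two) = _child_seeds(config.seed, 5)
    n = config.n_subjects
    subjects = [f"s{i + 1:03d}" for i in range(n)]

    # --- behaviour ------------------------------------------------------
    beh_frames = {}
    for i, sid in enumerate(subjects):
        params = synth_flanker.BehaviourParams(**{**config.behaviour, "seed": s_beh + i})
        df = synth_flanker.simulate_behaviour(synth_flanker.generate_schedule(s_beh + i), params)
        df.insert(0, "subject", sid)
        beh_frames[sid] = df
    behaviour = pd.concat(beh_frames.values(), ignore_index=True)
    behaviour.to_csv(out / "behaviour.csv", index=False)

    # --- EEG ------------------------------------------------------------
    eeg_params = synth_eeg.EEGGenParams(**{**config.eeg, "n_subjects": n, "seed": s_eeg})
    epoch_sets = synth_eeg.simulate_epochs(eeg_params)
    by_subject: dict[str, dict[str, synth_eeg.EpochSet]] = {}
    for e in epoch_sets:
        by_subject.setdefault(e.subject_id, {})[e.condition] = e
    if config.write_epochs:
        synth_eeg.write_epochs_h5(out / "epochs.h5", epoch_sets)

    # --- questionnaire items -------------------------------------------
    model = synth_cohort.LatentModel(**{**config.cohort, "seed": s_items})
    items = synth_cohort.simulate_items(model, n)
    responses = items["responses"]
    responses.index = subjects
    truth = items["truth"]
    truth.index = subjects
    demo = synth_cohort.simulate_demographics(n, seed=s_demo)
    responses.to_csv(out / "responses.csv")
    truth.to_csv(out / "factor_truth.csv")

    # --- screening ------------------------------------------------------
    reports = []
    for sid in subjects:
        reports.append(
            screening.apply_exclusions(
                beh_frames[sid],
                by_subject[sid]["error"],
                str(responses.loc[sid, "catch_response"]),
                cfg=cfg,
            )
        )
    screening.write_exclusion_log(reports, out / "exclusions.json")
    retained = [r.subject_id for r in reports if not r.excluded]
    retained = [sid for sid in subjects if sid in set(retained)]
    if len(retained) < 3:
        raise RuntimeError("screening retained fewer than 3 subjects")

    summaries = pd.DataFrame(
        {sid: screening.behaviour_summary(beh_frames[sid]) for sid in retained}
    ).T
    summaries.index.name = "subject"

    # --- ERP scoring ----------------------------------------------------
    cohort_erp: list[erp.SubjectERP] = []
    score_rows = []
    for sid in retained:
        ern_est = erp.score_epochs(by_subject[sid]["error"], cfg, config.method)
        crn_est = erp.score_epochs(by_subject[sid]["correct"], cfg, config.method)
        cohort_erp.append(erp.SubjectERP(subject_id=sid, ern=ern_est, crn=crn_est))
        score_rows.append((sid, "error", ern_est))
        score_rows.append((sid, "correct", crn_est))
    erp.residualise_ern(cohort_erp)
    erp.scores_to_csv(score_rows, out / "erp_scores.csv")

    rel_epochs = {
        sid: erp.baseline_correct(by_subject[sid]["error"], cfg) for sid in retained
    }
    reliability = erp.split_half_reliability(rel_epochs, cfg, config.method)
    with open(out / "reliability.json", "w") as f:
        json.dump(reliability, f, indent=2)

    summaries["ern_uv"] = [s.ern.value_uv for s in cohort_erp]
    summaries["crn_uv"] = [s.crn.value_uv for s in cohort_erp]
    summaries.to_csv(out / "behaviour_summaries.csv")
    contrasts = screening.paired_contrasts(summaries)
    contrasts.to_csv(out / "contrasts.csv", index=False)

    # --- phenotype ------------------------------------------------------
    resp_retained = responses.loc[retained]
    scales = phenotype.score_scales(resp_retained, items["manifest"])
    dims = phenotype.project_dimensions(resp_retained)
    scales.to_csv(out / "scale_scores.csv")
    dims.to_csv(out / "dimension_scores.csv")

    # --- cohort table and regressions ----------------------------------
    cohort = pd.DataFrame(index=pd.Index(retained, name="subject"))
    cohort["ern"] = [s.ern.value_uv for s in cohort_erp]
    cohort["crn"] = [s.crn.value_uv for s in cohort_erp]
    cohort["delta_ern"] = [s.delta_ern_uv for s in cohort_erp]
    cohort["ern_resid"] = [s.ern_resid_uv for s in cohort_erp]
    cohort["error_rate"] = summaries["error_rate"]
    for scale in synth_cohort.SCALE_ITEMS:
        cohort[scale] = scales[scale]
    for dim in synth_cohort.DIMENSIONS:
        cohort[dim] = dims[dim]
        cohort[f"{dim}_truth"] = truth.loc[retained, dim]
    cohort = cohort.join(demo.loc[retained])
    if config.plant:
        cohort = synth_cohort.plant_association(
            cohort,
            config.plant["target"],
            config.plant["dimension"],
            float(config.plant["beta"]),
        )
    cohort.to_csv(out / "cohort.csv")

    scale_names = tuple(synth_cohort.SCALE_ITEMS)
    specs = inference.questionnaire_battery_specs(scale_names, outcome=config.outcome)
    specs.append(inference.dimension_model_spec(outcome=config.outcome))
    results = inference.fit_battery(cohort, specs)
    results.to_csv(out / "regressions.csv", index=False)
    thresholds = {
        "bonferroni": inference.bonferroni_threshold(len(scale_names), config.family_alpha),
        "reported": config.reported_threshold,
    }
    with open(out / "thresholds.json", "w") as f:
        json.dump(thresholds, f, indent=2)

    # --- two-step -------------------------------------------------------
    two_cfg = synth_twostep.TwoStepConfig(**config.twostep)
    dim_scores = dims[[f"{d}_z" for d in synth_cohort.DIMENSIONS]].copy()
    dim_scores.columns = list(synth_cohort.DIMENSIONS)
    coupling = config.twostep_coupling
    two = synth_twostep.simulate_cohort(
        two_cfg, len(retained), coupling=coupling, seed=s_two, dimension_scores=dim_scores
    )
    two["trials"].to_csv(out / "twostep_trials.csv", index=False)
    records = twostep_analysis.code_stays(two["trials"], dimension_scores=dim_scores)
    stay = twostep_analysis.fit_stay_model(records, with_dimensions=True)
    stay.coefficients.to_csv(out / "stay_model.csv", index=False)

    # --- provenance and report -----------------------------------------
    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {
            "behaviour": s_beh, "eeg": s_eeg, "items": s_items,
            "demographics": s_demo, "twostep": s_two,
        },
        "n_retained": len(retained),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2)

    report = results[["model", "predictor", "beta", "se", "t", "p"]].copy()
    report.insert(0, "outcome", config.outcome)
    report.to_csv(out / "report.csv", index=False)
    return out


def make_fixtures(size: str, out_dir, seed: int = 0) -> Path:
    """Generate a fixture run: ``tiny`` (8 subjects, ~20 epochs, fast) or
    ``paper_scale`` (196 subjects at the published design values)."""
    if size == "tiny":
        config = RunConfig(
            seed=seed,
            n_subjects=8,
            eeg={
                "epochs_error_mean": 20.0, "epochs_error_sd": 4.0,
                "epochs_correct_mean": 20.0, "epochs_correct_sd": 4.0,
            },
        )
    elif size == "paper_scale":
        config = RunConfig(seed=seed, n_subjects=196)
    else:
        raise ValueError("size must be 'tiny' or 'paper_scale'")
    return run_pipeline(config, out_dir)
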