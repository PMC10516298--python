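"""End-to-end orchestration: simulate -> extract -> associate -> model."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import metrics
from .clinical import CLINICAL_OUTCOMES, compute_composites
from .io import PipelineConfig, write_cohort_csv, write_profiles_csv
from .pls import PLSResult, SearchSettings, exhaustive_feature_selection
from .preprocess import (EmptyRecordingError, TooShortRecordingError,
                         estimate_velocity, remove_artifacts)
from .saccades import DetectionSettings, detect_saccades, fit_events
from .stats import compare_edss_subgroups, spearman_with_fdr
from .synth import SyntheticCohort, SyntheticCohortConfig, simulate_cohort

log = logging.getLogger(__name__)


def extract_profile(recordings: dict,
                    detection: DetectionSettings = DetectionSettings(),
                    include_time_to_target: bool = True,
                    fit: bool = True) -> pd.Series:
    """One participant's 20(+1)-parameter profile from task recordings.

    ``recordings`` maps task kind to ``(TaskSpec, GazeRecording)``;
    absent or unusable tasks leave their slots structurally missing.
    """
    parts: dict[str, object] = {}
    for kind, (spec, rec) in recordings.items():
        try:
            rec = remove_artifacts(rec)
            vel_det = estimate_velocity(rec, window=detection.velocity_window,
                                        method=detection.velocity_method)
            vel = estimate_velocity(rec)  # polynomial filter for pursuit gain
        except (EmptyRecordingError, TooShortRecordingError):
            continue
        events = detect_saccades(vel_det, detection, rec=rec)
        if fit and kind in ("fixation", "prosaccade", "antisaccade"):
            events = fit_events(rec, events)
        if kind == "fixation":
            parts["fixation"] = metrics.compute_fixation_params(
                rec, events, spec)
        elif kind == "prosaccade":
            parts["prosaccade"] = metrics.compute_prosaccade_params(
                rec, events, spec)
        elif kind == "antisaccade":
            scored = [metrics.classify_antisaccade_trial(rec, events, tr)
                      for tr in spec.trials]
            parts["antisaccade"] = metrics.compute_antisaccade_params(scored)
        elif kind == "pursuit":
            parts["pursuit"] = metrics.compute_pursuit_params(
                rec, vel, events, spec)
    return metrics.assemble_profile(
        fixation=parts.get("fixation"), prosaccade=parts.get("prosaccade"),
        antisaccade=parts.get("antisaccade"), pursuit=parts.get("pursuit"),
        include_time_to_target=include_time_to_target)


def extract_cohort_profiles(cohort: SyntheticCohort,
                            detection: DetectionSettings = DetectionSettings(),
                            include_time_to_target: bool = True) -> pd.DataFrame:
    """Profile table (one row per participant, canonical columns)."""
    rows = {}
    for pid, per_task in cohort.recordings.items():
        recordings = {kind: (spec, rec) for kind, (spec, rec, _log)
                      in per_task.items()}
        rows[pid] = extract_profile(recordings, detection,
                                    include_time_to_target)
    profiles = pd.DataFrame(rows).T
    profiles.index.name = "participant_id"
    return profiles


def associate(profiles: pd.DataFrame, clinical: pd.DataFrame,
              alpha: float = 0.05, bh_family: str = "per_outcome"):
    """Correlation grid and EDSS-subgroup radar table.

    ``clinical`` must carry the composites (see compute_composites);
    rows are aligned on participant_id.
    """
    clin = clinical.set_index("participant_id") \
        if "participant_id" in clinical.columns else clinical
    clin = clin.loc[profiles.index]
    outcomes = clin[list(CLINICAL_OUTCOMES)]
    correlations = spearman_with_fdr(profiles, outcomes, alpha=alpha,
                                     family=bh_family)
    radar = compare_edss_subgroups(profiles, clin["edss"], alpha=alpha)
    return correlations, radar


def model_outcomes(profiles: pd.DataFrame, clinical: pd.DataFrame,
                   settings: SearchSettings = SearchSettings(),
                   outcomes=CLINICAL_OUTCOMES) -> dict[str, PLSResult]:
    """One PLS model per clinical outcome, age always as covariate."""
    clin = clinical.set_index("participant_id") \
        if "participant_id" in clinical.columns else clinical
    clin = clin.loc[profiles.index]
    age = clin[["age"]].astype(float)
    results = {}
    for outcome in outcomes:
        results[outcome] = exhaustive_feature_selection(
            profiles, clin[outcome].values, outcome, settings=settings,
            covariates=age)
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on a seeded synthetic cohort; write result tables.

    Writes, under ``config.output_dir``: the cohort table with
    composites, the profile table, the correlation grid, the radar
    table, one model report JSON per outcome, predictions and the
    contribution matrix, plus a run-metadata log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    detection = DetectionSettings(**config.detection)
    search = SearchSettings(**config.search)

    cohort_cfg = SyntheticCohortConfig(
        n_participants=config.n_participants, seed=config.seed,
        **config.cohort)
    log.info("simulating cohort n=%d seed=%d", config.n_participants,
             config.seed)
    cohort = simulate_cohort(cohort_cfg)
    clinical = compute_composites(cohort.clinical)
    write_cohort_csv(clinical, out / "cohort.csv")

    log.info("extracting oculomotor profiles")
    profiles = extract_cohort_profiles(
        cohort, detection, include_time_to_target=config.include_time_to_target)
    write_profiles_csv(profiles, out / "profiles.csv")

    log.info("association statistics")
    correlations, radar = associate(profiles, clinical, alpha=config.alpha,
                                    bh_family=config.bh_family)
    correlations.to_csv(out / "correlations.csv", index=False)
    radar.to_csv(out / "radar.csv", index=False)

    log.info("PLS models")
    models = model_outcomes(profiles, clinical, settings=search)
    contrib = pd.DataFrame({o: pd.Series(m.contributions)
                            for o, m in models.items()})
    contrib.to_csv(out / "contributions.csv", index_label="parameter")
    for outcome, m in models.items():
        (out / f"model_{outcome}.json").write_text(
            json.dumps(m.to_report(), indent=2))
        m.predictions.to_csv(out / f"predictions_{outcome}.csv",
                             index_label="participant_id")

    meta = {
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "n_profiles": int(len(profiles)),
        "warnings": [f"search for {o} not exhaustive"
                     for o, m in models.items() if not m.exhaustive],
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return {"cohort": clinical, "profiles": profiles,
            "correlations": correlations, "radar": radar, "models": models,
            "metadata": meta}
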