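"""End-to-end orchestration: simulation -> SMP extraction -> (optional) deep
stabilization -> replicate-ensemble diagnosis -> MK surface, in a single
seeded, manifest-tracked run.

Both modes share the binned spectrum domain so that the only difference
between a ``no_stabilization`` ("N") and a ``deep_stabilized`` ("D") run is
whether replicate spectra pass through the trained stabilizer before feature
extraction.  Stage seeds derive from the global seed by fixed offsets
(recorded in the manifest) so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import io as ldio
from .diagnosis import ElasticNetDiagnosis, OPLSDA, \
    cross_validate, replicate_ensemble, screen_biomarkers
from .mk import build_surface, select_threshold, vus
from .preprocessing import extract_smp
from .simulate import AcquisitionConfig, make_panel, sample_cohort, \
    simulate_spectrum
from .stabilizer import DeepStabilizer, bin_spectrum, unbin_vector

log = logging.getLogger(__name__)

MODES = ("no_stabilization", "deep_stabilized")

# fixed per-stage seed offsets (mod 2**31), recorded in the manifest
STAGE_OFFSETS = {"panel": 11, "cohort": 23, "spectra": 37, "stabilizer": 53,
                 "ensemble": 71, "metrics": 89}


class InsufficientReplicatesError(ValueError):
    pass


class SimulationSection(BaseModel):
    n_features: int = 35
    n_biomarkers: int = 6
    effect_log2fc: float = 0.25
    n_up: int = 5
    n_control: int = 14
    n_case: int = 14
    between_subject_cv: float = 0.15
    replicates: int = 10
    shots_per_replicate: int = 1000
    n_points: int = 4096
    mz_min: float = 100.0
    mz_max: float = 1000.0
    min_spacing: float = 12.0


class StabilizerSection(BaseModel):
    input_length: int = 512
    n_dense_blocks: int = 2
    layers_per_block: int = 2
    growth_channels: int = 8
    base_channels: int = 8
    kernel_size: int = 5
    epochs: int = 12
    batch_size: int = 16
    learning_rate: float = 3e-3
    adversarial_weight: float = 0.01
    reconstruction_weight: float = 1.0


class DiagnosisSection(BaseModel):
    n_models: int = 30
    ensemble_C: float = 0.5
    ensemble_l1_ratio: float = 0.3
    cv_folds: int = 5
    cv_folds_pred: int = 3


class MKSection(BaseModel):
    cv_max: float = 0.10
    cv_mode: str = "patient_labels"

    @field_validator("cv_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("patient_labels", "model_sensitivity"):
            raise ValueError("invalid cv_mode")
        return v


class PipelineConfig(BaseModel):
    seed: int = 0
    output_dir: str | None = None
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    stabilizer: StabilizerSection = Field(default_factory=StabilizerSection)
    diagnosis: DiagnosisSection = Field(default_factory=DiagnosisSection)
    mk: MKSection = Field(default_factory=MKSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_OFFSETS[stage]) % 2**31


def _simulate_replicates(config: PipelineConfig):
    """Panel, cohort and binned replicate spectra shared by both modes."""
    sim = config.simulation
    panel = make_panel(sim.n_features, sim.n_biomarkers, sim.effect_log2fc,
                       sim.n_up, seed=config.stage_seed("panel"),
                       mz_min=sim.mz_min, mz_max=sim.mz_max,
                       min_spacing=sim.min_spacing)
    cohort = sample_cohort(panel, sim.n_control, sim.n_case,
                           sim.between_subject_cv,
                           seed=config.stage_seed("cohort"))
    acq = AcquisitionConfig(mz_min=sim.mz_min, mz_max=sim.mz_max,
                            n_points=sim.n_points)
    L = config.stabilizer.input_length
    base = config.stage_seed("spectra")
    binned = {}  # sample_id -> (replicates x L)
    for i, s in enumerate(cohort.samples):
        reps = [bin_spectrum(
            simulate_spectrum(s, panel, acq, sim.shots_per_replicate,
                              seed=(base + 1009 * i + j) % 2**31,
                              replicate_id=f"r{j}"), L)
            for j in range(sim.replicates)]
        binned[s.sample_id] = np.stack(reps)
    return panel, cohort, acq, binned


def _feature_matrix_from_binned(binned, cohort, mz_range, mz_tolerance,
                                raw_binned=None, min_fraction=0.85):
    spectra, labels, refs = [], [], []
    for s in cohort.samples:
        for j, vec in enumerate(binned[s.sample_id]):
            spectra.append(unbin_vector(vec, mz_range, sample_id=s.sample_id,
                                        replicate_id=f"r{j}"))
            labels.append(s.label)
            if raw_binned is not None:
                refs.append(unbin_vector(raw_binned[s.sample_id][j], mz_range))
    return extract_smp(spectra, mz_tolerance=mz_tolerance,
                       min_fraction=min_fraction, labels=np.array(labels),
                       noise_references=refs if raw_binned is not None else None)


def run_pipeline(config: PipelineConfig, mode: str = "no_stabilization",
                 _shared=None) -> dict:
    """Execute the full pipeline in one mode and return the run report."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    sim = config.simulation
    if sim.replicates < 2:
        raise InsufficientReplicatesError(
            "the MK-surface stage needs >= 2 technical replicates")
    panel, cohort, acq, binned = _shared or _simulate_replicates(config)
    L = config.stabilizer.input_length
    mz_range = (sim.mz_min, sim.mz_max)
    bin_width = (sim.mz_max - sim.mz_min) / L

    stabilizer = None
    if mode == "deep_stabilized":
        log.info("training deep stabilizer (%d pairs)", len(cohort) * sim.replicates)
        lows, highs = [], []
        for s in cohort.samples:
            reps = binned[s.sample_id]
            ref = reps.mean(axis=0)  # high-shot-equivalent reference
            for r in reps:
                lows.append(r)
                highs.append(ref)
        stabilizer = DeepStabilizer(
            input_length=L, seed=config.stage_seed("stabilizer"),
            **config.stabilizer.model_dump(exclude={"input_length"}))
        stabilizer.fit(np.stack(lows), np.stack(highs))
        used = {sid: stabilizer.transform(reps) for sid, reps in binned.items()}
    else:
        used = binned

    fm = _feature_matrix_from_binned(
        used, cohort, mz_range, mz_tolerance=1.5 * bin_width,
        raw_binned=binned if mode == "deep_stabilized" else None)
    log.info("mode %s: %d features x %d rows", mode, fm.n_features,
             len(fm.sample_ids))

    diag = config.diagnosis
    ens = replicate_ensemble(
        fm.values, fm.labels, fm.sample_ids, n_models=diag.n_models,
        seed=config.stage_seed("ensemble"), cv_folds_pred=diag.cv_folds_pred,
        estimator=ElasticNetDiagnosis(cv_folds=None, C=diag.ensemble_C,
                                      l1_ratio=diag.ensemble_l1_ratio,
                                      seed=config.stage_seed("ensemble")))

    # per-individual aggregate profile (replicate mean) for AUC comparison
    uniq = list(dict.fromkeys(fm.sample_ids))
    sample_arr = np.asarray(fm.sample_ids)
    Xagg = np.stack([fm.values[sample_arr == s].mean(axis=0) for s in uniq])
    yagg = np.array([int(fm.labels[sample_arr == s][0]) for s in uniq])
    cv_enet = cross_validate(Xagg, yagg, k=diag.cv_folds,
                             seed=config.stage_seed("metrics"),
                             estimator=ElasticNetDiagnosis(
                                 cv_folds=None, C=diag.ensemble_C,
                                 l1_ratio=diag.ensemble_l1_ratio))
    cv_oplsda = cross_validate(Xagg, yagg, k=diag.cv_folds,
                               seed=config.stage_seed("metrics"),
                               estimator=OPLSDA(n_orthogonal=1))

    screen = screen_biomarkers(Xagg, yagg, fm.feature_mz, ens["hit_counts"],
                               n_models=diag.n_models)

    surface = build_surface(ens["probabilities"], cv_mode=config.mk.cv_mode)
    volume = vus(surface)
    selected = select_threshold(surface, cv_max=config.mk.cv_max)

    def _cv(a):
        a = np.asarray(a, float)
        return float(a.std(ddof=1) / a.mean()) if a.mean() != 0 else 0.0

    _cv_vec = _cv

    rp = ens["probabilities"]
    prob_cv = float(np.mean([_cv_vec(row) for row in
                             np.vstack([rp.control_probs, rp.patient_probs])]))
    report = {
        "mode": mode,
        "n_features": fm.n_features,
        "probability_cv": prob_cv,
        "auc": cv_enet["pooled"].auc,
        "auc_oplsda": cv_oplsda["pooled"].auc,
        "sensitivity": cv_enet["pooled"].sensitivity,
        "specificity": cv_enet["pooled"].specificity,
        "auc_mean_models": float(ens["auc_per_model"].mean()),
        "auc_cv": _cv(ens["auc_per_model"]),
        "sensitivity_cv": _cv(ens["sensitivity_per_model"]),
        "specificity_cv": _cv(ens["specificity_per_model"]),
        "vus": volume,
        "selected_percentile": selected[0] if selected else None,
        "selected_threshold": selected[1] if selected else None,
        "selected_sensitivity": selected[2] if selected else None,
        "n_biomarkers_screened": int(screen["passes_screen"].sum()),
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = "D" if mode == "deep_stabilized" else "N"
        ldio.write_feature_matrix(fm, out / f"features_{tag}.csv")
        surface.to_frame().to_csv(out / f"mk_surface_{tag}.csv", index=False)
        screen.to_csv(out / f"biomarker_screen_{tag}.csv", index=False)
        (out / f"report_{tag}.json").write_text(json.dumps(report, indent=2))
        if stabilizer is not None:
            stabilizer.save(out / "stabilizer.ckpt")
        ldio.write_manifest(out / "manifest.json", f"pipeline[{tag}]",
                            config.model_dump(), seed=config.seed,
                            extra={"stage_offsets": STAGE_OFFSETS})
    return report


def compare_modes(config: PipelineConfig) -> dict:
    """Run both modes on the same simulated cohort; paired N-vs-D report."""
    shared = _simulate_replicates(config)
    reports = {m: run_pipeline(config, m, _shared=shared) for m in MODES}
    paired = {"no_stabilization": reports["no_stabilization"],
              "deep_stabilized": reports["deep_stabilized"]}
    if config.output_dir:
        (Path(config.output_dir) / "comparison.json").write_text(
            json.dumps(paired, indent=2))
    return paired
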