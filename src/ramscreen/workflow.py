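"""End-to-end seeded experiments: simulate → screen → train → classify
→ evaluate, with YAML configuration and reproducible manifests.

A single root seed fans out into named sub-seeds (panel, case set,
CV shuffle) so stages can be re-run independently; every run manifest
records the config, its hash, the seed and the package version, which
is sufficient to reproduce all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .decision import DecisionThresholds, batch_classify
from .errors import ValidationError
from .evaluation import (confusion_table, fn_rate_curve, lod_estimate,
                         lod_frame, row_rates)
from .outliers import OutlierReport, flag_outliers
from .pls import (CVResult, PLSModel, cross_validate_grouped,
                  fit_plsda_cocaine, fit_plsr_cocaine)
from .preprocess import PLSDA_CHAIN, PLSR_CHAIN, PreprocessChain, \
    apply_chain_matrix
from .spectra_io import SpectrumSet, concat_sets, default_grid
from .synthetic import (DEFAULT_AGENTS, DEFAULT_LEVELS, InstrumentModel,
                        builtin_compound_library, derive_seed,
                        generate_binary_panel, generate_case_like_set)

log = logging.getLogger("ramscreen")

REPORT_FILES = ("confusion.csv", "rates.csv", "fn_curves.csv", "lods.csv",
                "predictions.csv")


class PanelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    agents: list[str] = Field(default_factory=lambda: list(DEFAULT_AGENTS))
    levels: list[float] = Field(default_factory=lambda: list(DEFAULT_LEVELS))
    replicates: int = 10


class CaseSetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_hcl: int = 58
    n_base: int = 32
    n_negative: int = 52
    replicates: int = 3


class InstrumentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gain_sigma: float = 0.3
    baseline_offset_range: tuple[float, float] = (20.0, 150.0)
    baseline_slope_range: tuple[float, float] = (-0.01, 0.01)
    noise_sd: float = 25.0
    weak_scan_prob: float = 0.0

    def build(self, seed: int = 0) -> InstrumentModel:
        return InstrumentModel(gain_sigma=self.gain_sigma,
                               baseline_offset_range=self.baseline_offset_range,
                               baseline_slope_range=self.baseline_slope_range,
                               noise_sd=self.noise_sd,
                               weak_scan_prob=self.weak_scan_prob, seed=seed)


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    roi_lo: float = 1700.0
    roi_hi: float = 1728.0
    sg_window: int = 9
    sg_order: int = 2

    def chain(self, chain_id: str) -> PreprocessChain:
        return PreprocessChain(chain_id, self.roi_lo, self.roi_hi,
                               self.sg_window, self.sg_order)


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plsr_ncomp: int = 4
    plsda_ncomp: int = 2
    cv_segments: int = 10


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    da_positive: float = 0.8
    da_ambiguous_low: float = 0.65
    r_cut_wt_pct: float = 30.0

    def build(self) -> DecisionThresholds:
        return DecisionThresholds(self.da_positive, self.da_ambiguous_low,
                                  self.r_cut_wt_pct)


class OutlierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    ncomp: int = 3
    coverage: float = 0.99
    mode: str = "per_sample"


class ExperimentConfig(BaseModel):
    """Full experiment description; defaults are the study conditions."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    panel: PanelConfig = Field(default_factory=PanelConfig)
    case_set: CaseSetConfig = Field(default_factory=CaseSetConfig)
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    outlier: OutlierConfig = Field(default_factory=OutlierConfig)
    inconclusive_snr: float | None = None
    outdir: str = "results"

    @model_validator(mode="after")
    def _check(self):
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(data)


@dataclass
class TrainingBundle:
    plsr: PLSModel
    plsda: PLSModel
    cv_plsr: CVResult
    cv_plsda: CVResult
    outlier_report: OutlierReport | None
    trainset: SpectrumSet
    n_generated: int
    n_fit: int

    def to_json(self) -> str:
        return json.dumps({
            "format_version": 1,
            "plsr": json.loads(self.plsr.to_json()),
            "plsda": json.loads(self.plsda.to_json()),
            "n_generated": self.n_generated,
            "n_fit": self.n_fit,
        }, sort_keys=True)


def build_training_set(config: ExperimentConfig) -> SpectrumSet:
    """Training spectra: the binary panel plus the case-like sets."""
    library = builtin_compound_library()
    grid = default_grid()
    panel = generate_binary_panel(
        library=library, agents=config.panel.agents,
        levels=config.panel.levels, replicates=config.panel.replicates,
        instrument=config.instrument.build(), grid=grid,
        seed=derive_seed(config.seed, "panel"))
    cs = config.case_set
    if cs.n_hcl + cs.n_base + cs.n_negative > 0:
        cases = generate_case_like_set(
            n_hcl=cs.n_hcl, n_base=cs.n_base, n_negative=cs.n_negative,
            replicates=cs.replicates, instrument=config.instrument.build(),
            grid=grid, seed=derive_seed(config.seed, "case-set"),
            library=library)
        return concat_sets([panel, cases])
    return panel


def train_models(config: ExperimentConfig) -> TrainingBundle:
    """Simulate training spectra, screen outliers, fit both PLS models.

    Flagged outlier scans are excluded before fitting. Cross-validation
    keeps replicate scans (grouped by sample_id) in one segment.
    """
    trainset = build_training_set(config)
    n_generated = len(trainset)
    log.info("training set: %d spectra", n_generated)

    report = None
    if config.outlier.enabled:
        report = flag_outliers(trainset, ncomp=config.outlier.ncomp,
                               coverage=config.outlier.coverage,
                               mode=config.outlier.mode)
        log.info("outlier screen: %d/%d flagged and excluded",
                 report.n_flagged, n_generated)
        trainset = trainset.subset(~report.flags)

    plsr = fit_plsr_cocaine(trainset, ncomp=config.model.plsr_ncomp,
                            chain=config.preprocess.chain("plsr"))
    plsda = fit_plsda_cocaine(trainset, ncomp=config.model.plsda_ncomp,
                              chain=config.preprocess.chain("plsda"))
    log.info("PLS-R explained X-variance (%d comps): %.4f",
             plsr.ncomp, plsr.cumulative_explained_x_variance)

    y_wt = np.array([m.cocaine_wt_pct for m in trainset.metas])
    y_cls = (y_wt > 0).astype(float)
    groups = [m.sample_id for m in trainset.metas]
    cv_seed = derive_seed(config.seed, "cv-shuffle")
    Xr = apply_chain_matrix(trainset, config.preprocess.chain("plsr"))
    Xd = apply_chain_matrix(trainset, config.preprocess.chain("plsda"))
    cv_plsr = cross_validate_grouped(Xr, y_wt, groups,
                                     nseg=config.model.cv_segments,
                                     max_ncomp=config.model.plsr_ncomp,
                                     seed=cv_seed)
    cv_plsda = cross_validate_grouped(Xd, y_cls, groups,
                                      nseg=config.model.cv_segments,
                                      max_ncomp=config.model.plsda_ncomp,
                                      seed=cv_seed)
    log.info("RMSEP_cv (PLS-R, %d comps): %.3f wt%%",
             plsr.ncomp, cv_plsr.rmsep_cv[-1])
    return TrainingBundle(plsr=plsr, plsda=plsda, cv_plsr=cv_plsr,
                          cv_plsda=cv_plsda, outlier_report=report,
                          trainset=trainset, n_generated=n_generated,
                          n_fit=len(trainset))


@dataclass
class PanelReport:
    bundle: TrainingBundle
    panel: SpectrumSet
    results: list
    fn_include: "object"
    fn_exclude: "object"
    lods: dict
    table: "object"
    rates: np.ndarray
    manifest: dict


def run_panel_experiment(config: ExperimentConfig,
                         outdir=None) -> PanelReport:
    """Full pipeline on a fresh evaluation panel; writes the report CSVs.

    Report files: confusion.csv, rates.csv, fn_curves.csv (both
    inconclusive policies, long format), lods.csv, predictions.csv,
    plus manifest.json.
    """
    bundle = train_models(config)
    library = builtin_compound_library()
    eval_panel = generate_binary_panel(
        library=library, agents=config.panel.agents,
        levels=config.panel.levels, replicates=config.panel.replicates,
        instrument=config.instrument.build(), grid=default_grid(),
        seed=derive_seed(config.seed, "eval-panel"))
    results = batch_classify(eval_panel, bundle.plsr, bundle.plsda,
                             thresholds=config.thresholds.build(),
                             inconclusive_snr=config.inconclusive_snr)
    fn_inc = fn_rate_curve(eval_panel, results, policy="include")
    fn_exc = fn_rate_curve(eval_panel, results, policy="exclude")
    lods = lod_estimate(fn_exc)
    truth = [m.cocaine_wt_pct > 0 for m in eval_panel.metas]
    table = confusion_table(truth, [r.outcome for r in results])
    rates = row_rates(table)

    n_unique = len({m.sample_id for m in eval_panel.metas})
    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "panel_unique_samples": n_unique,
        "panel_spectra": len(eval_panel),
        "train_spectra_generated": bundle.n_generated,
        "train_spectra_fit": bundle.n_fit,
        "outliers_removed": bundle.n_generated - bundle.n_fit,
        "plsr_explained_x_variance":
            bundle.plsr.cumulative_explained_x_variance,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(out / "confusion.csv")
        import pandas as pd
        pd.DataFrame(rates, index=["cocaine", "non_cocaine"],
                     columns=["positive", "negative", "inconclusive"]
                     ).to_csv(out / "rates.csv")
        pd.concat([fn_inc.to_frame(), fn_exc.to_frame()],
                  ignore_index=True).to_csv(out / "fn_curves.csv", index=False)
        lod_frame(lods).to_csv(out / "lods.csv", index=False)
        pd.DataFrame([{
            "sample_id": m.sample_id, "replicate": m.replicate_index,
            "adulterant": m.source_tag, "cocaine_wt_pct": m.cocaine_wt_pct,
            "da_score": r.da_score, "r_pred": r.r_pred,
            "outcome": r.outcome, "rule_fired": r.rule_fired,
        } for m, r in zip(eval_panel.metas, results)]
        ).to_csv(out / "predictions.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("reports written to %s", out)

    return PanelReport(bundle=bundle, panel=eval_panel, results=results,
                       fn_include=fn_inc, fn_exclude=fn_exc, lods=lods,
                       table=table, rates=rates, manifest=manifest)
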