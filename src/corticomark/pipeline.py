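"""End-to-end nested control-test pipeline with locking discipline.

Stages run strictly in order: feature extraction (PAF + corticomotor
class), growth-mixture labelling with locked thresholds, internal
cross-validation and model selection, model locking, and a single blinded
prediction of the permuted test set. Every stage appends to an audit log;
the locked model's integrity hash is verified before the test stage, and
test-set truth is un-shuffled only at scoring time.

All randomness flows from one master seed through named substreams, so a
rerun with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import dataclasses
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import cme as cme_mod
from . import models as models_mod
from . import paf as paf_mod
from . import trajectory as traj
from .reliability import class_agreement, icc
from .synthetic import CohortConfig, Participant, SyntheticCohort, generate_cohort

PAF_QC_BAND = (6.0, 14.0)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = CohortConfig()
    paf_source: str = "sensor_roi"          # "component" | "sensor_roi"
    paf_window: tuple[float, float] = paf_mod.DEFAULT_WINDOW
    paf_method: str = "cog"                 # "cog" | "peak"
    roi: tuple[str, ...] | None = None      # None -> default central ROI
    cme_metric: str = "volume"              # "volume" | "area"
    active_fraction: float = cme_mod.DEFAULT_ACTIVE_FRACTION
    label_span_days: int = 7                # 7 or 30
    imputation: str = "linear_interpolate"  # or "none"
    n_extreme: int = 40
    gmm_n_starts: int = 50
    families: tuple[str, ...] = models_mod.FAMILIES
    seed: int = 0
    compute_reliability: bool = False
    compare_covariates: bool = False

    def __post_init__(self) -> None:
        if self.paf_source not in ("component", "sensor_roi"):
            raise ValueError(f"invalid paf_source {self.paf_source!r}")
        if self.paf_method not in ("cog", "peak"):
            raise ValueError(f"invalid paf_method {self.paf_method!r}")
        if self.cme_metric not in ("volume", "area"):
            raise ValueError(f"invalid cme_metric {self.cme_metric!r}")
        if self.imputation not in ("linear_interpolate", "none"):
            raise ValueError(f"invalid imputation {self.imputation!r}")
        if self.label_span_days < 3:
            raise ValueError("label_span_days must be >= 3")

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        import yaml
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return yaml.safe_dump(enc(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        import yaml
        from .synthetic import EEGSimParams, MapSimParams, TrajectoryParams
        raw = yaml.safe_load(text) or {}
        cohort_raw = raw.pop("cohort", {})
        for key, sub in (("eeg", EEGSimParams), ("map", MapSimParams),
                         ("diary_high", TrajectoryParams),
                         ("diary_low", TrajectoryParams)):
            if key in cohort_raw and isinstance(cohort_raw[key], dict):
                d = cohort_raw[key]
                d = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()}
                cohort_raw[key] = sub(**d)
        for k, v in list(cohort_raw.items()):
            if isinstance(v, list):
                cohort_raw[k] = tuple(v)
        for k, v in list(raw.items()):
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(cohort=CohortConfig(**cohort_raw), **raw)


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("gmm", "cv", "lock", "shuffle", "bootstrap", "covariates")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31))
            for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# cached per-participant feature extraction

class FeatureExtractor:
    """Computes PAF and corticomotor features, caching the expensive EEG
    spectra and ICA decompositions so that a robustness grid can re-derive
    features under different windows/methods without re-simulating."""

    def __init__(self, cohort: SyntheticCohort):
        self.cohort = cohort
        self._sensor_spectra: dict[tuple[str, int], paf_mod.PowerSpectrum] = {}
        self._component_spectra: dict[tuple[str, int], tuple] = {}

    def sensor_spectrum(self, p: Participant, day: int) -> paf_mod.PowerSpectrum:
        key = (p.pid, day)
        if key not in self._sensor_spectra:
            rec = paf_mod.preprocess(p.eeg(day))
            self._sensor_spectra[key] = paf_mod.compute_spectrum(rec)
        return self._sensor_spectra[key]

    def component_state(self, p: Participant, day: int):
        key = (p.pid, day)
        if key not in self._component_spectra:
            rec = paf_mod.preprocess(p.eeg(day))
            decomp = paf_mod.decompose(rec, seed=p.eeg_seeds[day] % (2**31))
            spectra = paf_mod.compute_spectrum(decomp.sources,
                                               sfreq=rec.sfreq)
            self._component_spectra[key] = (decomp, spectra)
        return self._component_spectra[key]

    def paf(self, p: Participant, day: int, source: str,
            window, method: str, roi=None) -> paf_mod.PAFEstimate:
        if source == "sensor_roi":
            spectrum = self.sensor_spectrum(p, day)
            roi_labels = list(roi) if roi else None
            return paf_mod.sensor_roi_paf(spectrum, roi_labels,
                                          window=window, method=method)
        decomp, spectra = self.component_state(p, day)
        comp, flags = paf_mod.select_sensorimotor_component(
            decomp, spectra, window=window)
        if comp is None:
            return paf_mod.PAFEstimate(np.nan, method, tuple(window),
                                       "component", qc_flags=flags)
        est = paf_mod.estimate_paf(spectra.pick(comp), window=window,
                                   method=method, source="component")
        est.component_id = comp
        return est

    def cme(self, p: Participant, metric: str, active_fraction: float,
            day_pair=(0, 5)) -> cme_mod.CMEMetrics:
        return cme_mod.classify_cme(p.maps[day_pair[0]], p.maps[day_pair[1]],
                                    metric=metric,
                                    threshold_fraction=active_fraction)

    def feature_table(self, config: PipelineConfig) -> pd.DataFrame:
        rows = []
        for p in self.cohort:
            est = self.paf(p, 0, config.paf_source, config.paf_window,
                           config.paf_method, config.roi)
            metrics = self.cme(p, config.cme_metric, config.active_fraction)
            qc = list(est.qc_flags)
            if est.valid and not (PAF_QC_BAND[0] <= est.paf <= PAF_QC_BAND[1]):
                qc.append("paf_outside_plausible_band")
            rows.append({
                "participant": p.pid,
                "paf_hz": est.paf,
                "cme_class": 1.0 if metrics.is_facilitator else 0.0,
                "delta_cme": metrics.delta,
                "sex": 1.0 if p.sex == "F" else 0.0,
                "pcs_total": float(p.pcs_total),
                "pcs_helplessness": float(p.pcs_helplessness),
                "qc_flags": ";".join(qc),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run report

@dataclass
class RunReport:
    config_hash: str
    seed: int
    n_train: int
    n_test: int
    n_train_labeled: int
    n_test_labeled: int
    test_label_counts: dict
    cv_table: pd.DataFrame
    locked_family: str
    validation_auc: float
    test_auc: float
    test_auc_ci: tuple[float, float]
    test_band: str
    threshold: float
    sensitivity: float
    specificity: float
    paf_cutoffs: dict
    features: pd.DataFrame
    train_labels: pd.Series
    test_labels: pd.Series
    locked_model: models_mod.LockedModel
    blinded: models_mod.BlindedResult
    audit_log: list
    reliability: dict | None = None
    covariates: dict | None = None
    gmm_loglik: float = float("nan")

    def summary(self) -> dict:
        out = {
            "config_hash": self.config_hash, "seed": self.seed,
            "n_train": self.n_train, "n_test": self.n_test,
            "n_train_labeled": self.n_train_labeled,
            "n_test_labeled": self.n_test_labeled,
            "test_label_counts": self.test_label_counts,
            "locked_family": self.locked_family,
            "validation_auc": self.validation_auc,
            "test_auc": self.test_auc,
            "test_auc_ci": list(self.test_auc_ci),
            "test_band": self.test_band,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "paf_cutoffs": self.paf_cutoffs,
        }
        if self.reliability is not None:
            out["reliability"] = self.reliability
        if self.covariates is not None:
            out["covariates"] = {
                k: v for k, v in self.covariates.items()
                if k in ("selected_features", "test_auc", "validation_auc")}
        return out

    def to_markdown(self) -> str:
        s = self.summary()
        lines = [
            "# Biomarker validation run",
            f"- config `{s['config_hash']}`, master seed {s['seed']}",
            f"- split: {s['n_train']} training / {s['n_test']} test "
            f"participants; {s['n_train_labeled']} training and "
            f"{s['n_test_labeled']} test participants labelled "
            f"({s['test_label_counts']})",
            "",
            "## Model selection (validation AUC per family)",
            self.cv_table.to_markdown(index=False),
            "",
            f"Locked family: **{s['locked_family']}** "
            f"(validation AUC {s['validation_auc']:.2f})",
            "",
            "## Blinded test performance",
            f"- test AUC {s['test_auc']:.2f} "
            f"(95% CI {s['test_auc_ci'][0]:.2f}-{s['test_auc_ci'][1]:.2f}), "
            f"band: {s['test_band']}",
            f"- probability threshold {s['threshold']:.2f}: "
            f"sensitivity {s['sensitivity']:.3f}, "
            f"specificity {s['specificity']:.3f}",
            f"- raw-Hz PAF cutoffs: {s['paf_cutoffs']}",
        ]
        return "\n".join(lines)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class LabelState:
    """Output of the growth-mixture labelling stage (cacheable across
    robustness-grid cells that share span/imputation settings)."""

    fit: traj.GrowthMixtureFit
    rule: traj.LabelRule
    train_labels: pd.Series
    test_labels: pd.Series


def compute_labels(cohort: SyntheticCohort, config: PipelineConfig,
                   seed: int) -> LabelState:
    """Growth-mixture labelling: fit on training diaries, lock thresholds,
    label the test set with the locked model."""
    diaries = cohort.diaries()
    matrix = traj.build_trajectory_matrix(diaries,
                                          span_days=config.label_span_days)
    matrix = traj.impute_trajectories(matrix, mode=config.imputation)
    train_ids = [p.pid for p in cohort.train]
    test_ids = [p.pid for p in cohort.test]
    train_matrix = matrix.loc[[i for i in train_ids if i in matrix.index]]
    test_matrix = matrix.loc[[i for i in test_ids if i in matrix.index]]
    fit = traj.fit_gmm(train_matrix, n_starts=config.gmm_n_starts, seed=seed)
    train_labels, rule = traj.assign_training_labels(
        fit, n_extreme=config.n_extreme)
    rule.lock()
    test_posteriors = traj.posterior_for(fit, test_matrix)
    test_labels = traj.apply_locked_labels(test_posteriors, rule)
    return LabelState(fit=fit, rule=rule, train_labels=train_labels,
                      test_labels=test_labels)


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None,
                 extractor: FeatureExtractor | None = None,
                 label_state: LabelState | None = None) -> RunReport:
    """Execute the full nested control-test workflow on one cohort.

    A pre-generated cohort/extractor/label state may be passed to reuse
    cached spectra and growth-mixture fits (the robustness grid does this);
    otherwise everything is derived from the config.
    """
    seeds = _stage_seeds(config.seed)
    chash = config.config_hash()
    audit: list[dict] = []

    def log(stage: str, **info):
        audit.append({"stage": stage, "order": len(audit),
                      "time": time.time(), **info})

    if cohort is None:
        cohort = generate_cohort(config.cohort)
    if extractor is None:
        extractor = FeatureExtractor(cohort)

    stage = "features"
    try:
        features = extractor.feature_table(config)
        log(stage, n=len(features))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "gmm_labels"
    try:
        if label_state is None:
            label_state = compute_labels(cohort, config, seeds["gmm"])
        fit, rule = label_state.fit, label_state.rule
        train_labels = label_state.train_labels
        test_labels = label_state.test_labels
        log(stage, loglik=fit.loglik, tau_high=rule.tau_high,
            tau_low=rule.tau_low,
            n_train_labeled=int(train_labels.notna().sum()),
            n_test_labeled=int(test_labels.notna().sum()))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "internal_cv"
    try:
        feat = features.set_index("participant")
        train_feat = feat.loc[train_labels.index].copy()
        train_feat["label"] = train_labels
        train_feat = train_feat.dropna(subset=["paf_hz"])
        cv_results = models_mod.internal_cv(
            train_feat.reset_index(), families=config.families,
            seed=seeds["cv"])
        cv_table = pd.DataFrame(
            [{"family": r.family, "validation_auc": r.validation_auc,
              "best_params": json.dumps(r.best_params)}
             for r in cv_results])
        log(stage, families=list(config.families),
            best=cv_table.loc[cv_table["validation_auc"].idxmax(), "family"])
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "lock"
    try:
        locked = models_mod.select_and_lock(
            cv_results, train_feat.reset_index(), seed=seeds["lock"])
        log(stage, family=locked.family, params_hash=locked.params_hash,
            threshold=locked.probability_threshold)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "blinded_test"
    try:
        labeled_test = test_labels.dropna()
        test_feat = feat.loc[labeled_test.index].copy()
        keep = test_feat["paf_hz"].notna()
        test_feat, labeled_test = test_feat[keep], labeled_test[keep]
        rng = np.random.default_rng(seeds["shuffle"])
        perm = rng.permutation(len(labeled_test))
        shuffled_truth = labeled_test.to_numpy()[perm]
        log(stage + ":shuffle_recorded", n=len(labeled_test))
        blinded = models_mod.predict_blinded(
            locked, test_feat.reset_index(), shuffled_truth, perm,
            seed=seeds["bootstrap"])
        cutoffs = (models_mod.paf_cutoffs(locked)
                   if locked.family == "logistic_regression" else {})
        log(stage, auc=blinded.roc.auc)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    reliability = None
    if config.compute_reliability:
        reliability = compute_reliability(cohort, extractor, config)
        log("reliability", **{k: v for k, v in reliability.items()
                              if isinstance(v, (int, float))})

    covariates = None
    if config.compare_covariates:
        stage = "covariates"
        try:
            cov_model, cov_table = models_mod.covariate_model(
                train_feat.reset_index(), seed=seeds["covariates"])
            cov_feat = test_feat.reset_index()
            cov_blinded = models_mod.predict_blinded(
                cov_model, cov_feat, shuffled_truth, perm,
                seed=seeds["bootstrap"])
            covariates = {
                "selected_features": cov_model.feature_names,
                "p_values": cov_table,
                "validation_auc": cov_model.validation_auc,
                "test_auc": cov_blinded.roc.auc,
                "model": cov_model,
            }
            log(stage, test_auc=cov_blinded.roc.auc)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    counts = labeled_test.value_counts().to_dict()
    return RunReport(
        config_hash=chash, seed=config.seed,
        n_train=len(cohort.train), n_test=len(cohort.test),
        n_train_labeled=int(train_labels.notna().sum()),
        n_test_labeled=int(len(labeled_test)),
        test_label_counts={str(k): int(v) for k, v in counts.items()},
        cv_table=cv_table, locked_family=locked.family,
        validation_auc=locked.validation_auc,
        test_auc=blinded.roc.auc,
        test_auc_ci=(blinded.roc.ci_low, blinded.roc.ci_high),
        test_band=blinded.roc.band,
        threshold=blinded.threshold,
        sensitivity=blinded.sensitivity, specificity=blinded.specificity,
        paf_cutoffs=cutoffs, features=features,
        train_labels=train_labels, test_labels=test_labels,
        locked_model=locked, blinded=blinded, audit_log=audit,
        reliability=reliability, covariates=covariates,
        gmm_loglik=fit.loglik)


def compute_reliability(cohort: SyntheticCohort,
                        extractor: FeatureExtractor,
                        config: PipelineConfig,
                        session_days: tuple[int, ...] | None = None) -> dict:
    """PAF test-retest ICC across sessions and day-2/day-5 agreement of the
    facilitator/depressor classification."""
    days = session_days or cohort.config.eeg_session_days
    paf_cols = []
    for day in days:
        col = [extractor.paf(p, day, config.paf_source, config.paf_window,
                             config.paf_method, config.roi).paf
               for p in cohort]
        paf_cols.append(col)
    paf_matrix = np.array(paf_cols).T
    report = icc(paf_matrix)
    day2 = [extractor.cme(p, config.cme_metric, config.active_fraction,
                          day_pair=(0, 2)).cme_class for p in cohort]
    day5 = [extractor.cme(p, config.cme_metric, config.active_fraction,
                          day_pair=(0, 5)).cme_class for p in cohort]
    agree = class_agreement(day2, day5)
    return {
        "paf_icc": report.icc,
        "paf_icc_ci": (report.ci_low, report.ci_high),
        "paf_icc_band": report.band,
        "cme_day2_day5_kappa": agree.kappa,
        "cme_day2_day5_agreement": agree.percent_agreement,
        "n_subjects": report.n_subjects,
        "n_sessions": report.n_sessions,
    }


# ---------------------------------------------------------------------------
# robustness grid

GRID_AXES = {
    "paf_source": ("component", "sensor_roi"),
    "paf_window": ((8.0, 12.0), (9.0, 11.0)),
    "paf_method": ("cog", "peak"),
    "cme_metric": ("volume", "area"),
    "label_span_days": (7, 30),
    "imputation": ("linear_interpolate", "none"),
}


def robustness_grid(config: PipelineConfig,
                    grid: dict | None = None,
                    cohort: SyntheticCohort | None = None) -> pd.DataFrame:
    """Re-run the pipeline over a grid of methodological choices.

    The cohort is generated once and EEG spectra are cached across cells;
    only the stated options vary, with the same stage seeds throughout.
    A failed cell is recorded (``error`` column) and the grid continues.
    """
    from itertools import product

    grid = grid if grid is not None else GRID_AXES
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    extractor = FeatureExtractor(cohort)
    label_cache: dict[tuple, LabelState] = {}
    keys = list(grid)
    rows = []
    for values in product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        cfg = dataclasses.replace(config, **cell)
        row = {k: (str(v) if isinstance(v, tuple) else v)
               for k, v in cell.items()}
        label_key = (cfg.label_span_days, cfg.imputation, cfg.n_extreme,
                     cfg.gmm_n_starts)
        try:
            if label_key not in label_cache:
                label_cache[label_key] = compute_labels(
                    cohort, cfg, _stage_seeds(cfg.seed)["gmm"])
            report = run_pipeline(cfg, cohort=cohort, extractor=extractor,
                                  label_state=label_cache[label_key])
            row.update(validation_auc=report.validation_auc,
                       test_auc=report.test_auc,
                       locked_family=report.locked_family, error=None)
        except Exception as e:  # noqa: BLE001
            row.update(validation_auc=np.nan, test_auc=np.nan,
                       locked_family=None, error=str(e))
        rows.append(row)
    return pd.DataFrame(rows)
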