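"""End-to-end orchestration: simulate -> extract -> delta -> test -> classify.

A single :class:`PipelineConfig` holds every study condition (acquisition
geometry, phantom, window spec, quantization, classifier settings, cohort
size and seed); :func:`run_pipeline` turns it into a :class:`RunReport`
holding the per-time-point group-test tables, the wrapper classification
results for 1..3 features x {K-NN, naive Bayes}, and the Kaplan-Meier /
log-rank survival summary. A report is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import features as ft
from .spectral import ParametricMapSet, WindowSpec, build_parametric_maps
from .synthetic import (
    TIMEPOINTS,
    AcquisitionGeometry,
    CohortDataset,
    EffectSpec,
    ReferencePhantom,
    RFFrame,
    SurvivalSpec,
    default_cohort_geometry,
    generate_cohort,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "extract_cohort_features", "export_parametric_overlay"]

log = logging.getLogger("qusdr")


@dataclass
class PipelineConfig:
    """All tunable study conditions of one end-to-end run."""

    n_patients: int = 36
    cr_fraction: float = 14.0 / 36.0
    seed: int = 0
    # acquisition / simulation
    use_full_geometry: bool = False      # full 5 cm / 256-line sector
    scatterer_density: float = 20000.0   # per cm^2
    noise_floor_db: float = 30.0
    phantom_attenuation: float = 0.576   # dB/MHz/cm
    # analysis
    window_axial_mm: float = 2.0
    window_lateral_mm: float = 2.0
    window_overlap: float = 0.94
    n_levels: int = 16
    ar_order: int = 14
    # classification
    models: tuple = ("nb", "knn")
    max_features: int | None = None      # default: floor(n/10)
    knn_k: int = 3
    positive_class: str = "CR"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["models"] = list(data["models"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_axial_mm, self.window_lateral_mm,
                          self.window_overlap)

    def config_hash(self) -> str:
        data = asdict(self)
        data["models"] = list(data["models"])
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run computed, regenerable bit-identically from config."""

    group_tests: dict                   # timepoint -> DataFrame
    classifier_reports: list            # ClassifierReport, Table-3 shape
    survival: dict                      # curves, statistic, p, RFS summaries
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "group_tests": {
                tp: df.to_dict(orient="records")
                for tp, df in self.group_tests.items()
            },
            "classification": [r.as_dict() for r in self.classifier_reports],
            "survival": self.survival,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(_round_floats(self.to_dict()), indent=indent,
                          sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def report_hash(self) -> str:
        """Digest of the scientific content (wall-clock timings excluded)."""
        data = _round_floats(self.to_dict())
        data["provenance"] = {k: v for k, v in data["provenance"].items()
                              if k != "stage_seconds"}
        blob = json.dumps(data, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def classification_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.classifier_reports])


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _simulate(config: PipelineConfig) -> CohortDataset:
    geometry = (AcquisitionGeometry() if config.use_full_geometry
                else default_cohort_geometry())
    phantom = ReferencePhantom(attenuation=config.phantom_attenuation)
    return generate_cohort(
        n_patients=config.n_patients, cr_fraction=config.cr_fraction,
        effect_spec=EffectSpec(), survival_spec=SurvivalSpec(),
        seed=config.seed, geometry=geometry, phantom=phantom,
        density=config.scatterer_density, noise_floor=config.noise_floor_db,
    )


def extract_cohort_features(cohort: CohortDataset,
                            config: PipelineConfig | None = None) -> list:
    """Parametric maps + 31 features for every scan of a cohort."""
    config = config or PipelineConfig()
    vectors = []
    for patient in cohort.patients:
        for tp, frame in patient.frames.items():
            t0 = time.perf_counter()
            maps = build_parametric_maps(
                frame, cohort.reference_frame, patient.roi_mask,
                window_spec=config.window_spec, phantom=cohort.phantom,
                ar_order=config.ar_order,
            )
            vec = ft.assemble_features(maps, patient_id=patient.id,
                                       timepoint=tp,
                                       n_levels=config.n_levels)
            vectors.append(vec)
            log.debug("extracted %s/%s in %.2fs", patient.id, tp,
                      time.perf_counter() - t0)
    return vectors


def _deltas(vectors) -> list:
    by_patient: dict = {}
    for v in vectors:
        by_patient.setdefault(v.patient_id, {})[v.timepoint] = v
    deltas = []
    for pid, scans in by_patient.items():
        base = scans.get("baseline")
        if base is None:
            raise ValueError(f"patient {pid} lacks a baseline scan")
        for tp, v in scans.items():
            if tp != "baseline":
                deltas.append(ft.delta_features(v, base))
    return deltas


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Run the full study: returns the report, optionally writing artifacts.

    Stages log to the ``qusdr`` logger with timing; any stage failure
    propagates with its stage named. When ``out_dir`` is given, the feature
    table is cached there keyed by the config hash and reused on re-runs.
    """
    stages: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages[name] = time.perf_counter() - t0
        log.info("stage %s done in %.1fs", name, stages[name])
        return result

    out_dir = Path(out_dir) if out_dir is not None else None
    chash = config.config_hash()
    cache = out_dir / f"features_{chash}.csv" if out_dir else None

    if cache is not None and cache.exists():
        tidy = pd.read_csv(cache)
        cohort = _stage("simulate", lambda: _simulate(config))
        vectors = _tidy_to_vectors(tidy)
        log.info("reusing cached features from %s", cache)
    else:
        cohort = _stage("simulate", lambda: _simulate(config))
        vectors = _stage("extract",
                         lambda: extract_cohort_features(cohort, config))
        if cache is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            ft.features_to_tidy(vectors).to_csv(cache, index=False)

    deltas = _stage("delta", lambda: _deltas(vectors))
    labels_by_pid = {p.id: p.label for p in cohort.patients}
    on_treatment = [tp for tp in TIMEPOINTS if tp != "baseline"]

    def _group_tests():
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for tp in on_treatment:
                wide = ft.delta_wide_table(deltas, tp)
                labels = [labels_by_pid[pid] for pid in wide.index]
                out[tp] = ft.group_test_table(wide, labels)
        return out

    group_tests = _stage("compare-groups", _group_tests)

    def _survival():
        times = [p.followup_months for p in cohort.patients]
        events = [p.event for p in cohort.patients]
        labels = [p.label for p in cohort.patients]
        res = ft.km_estimate(times, events, labels)
        stat, p = ft.logrank_test(times, events, labels)
        out = {"logrank_statistic": stat, "logrank_p": p}
        for g, (t, s) in res.curves.items():
            out[f"rfs_36mo_{g}"] = float(np.interp(36.0, t, s))
            out[f"n_{g}"] = int(sum(1 for x in labels if x == g))
        return out

    survival = _stage("survival", _survival)

    def _classify():
        reports = []
        for tp in on_treatment:
            wide = ft.delta_wide_table(deltas, tp)
            labels = np.array([labels_by_pid[pid] for pid in wide.index])
            ds = cls.Dataset(X=wide, y=labels,
                             positive_class=config.positive_class)
            for model in config.models:
                reports.extend(cls.sequential_forward_select(
                    ds, model, max_features=config.max_features,
                    k=config.knn_k, timepoint=tp))
        return reports

    reports = _stage("classify", _classify)

    provenance = {
        "config": {**asdict(config), "models": list(config.models)},
        "config_hash": chash,
        "seed": config.seed,
        "stage_seconds": {k: round(v, 2) for k, v in stages.items()},
    }
    report = RunReport(group_tests=group_tests, classifier_reports=reports,
                       survival=survival, provenance=provenance)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        for tp, df in group_tests.items():
            df.to_csv(out_dir / f"group_tests_{tp}.csv", index=False)
        report.classification_table().to_csv(out_dir / "classification.csv",
                                             index=False)
    return report


def _tidy_to_vectors(tidy: pd.DataFrame) -> list:
    vectors = []
    for (pid, tp), grp in tidy.groupby(["patient_id", "timepoint"],
                                       sort=False):
        values = dict(zip(grp["feature"], grp["value"]))
        vectors.append(ft.FeatureVector(values={k: values[k]
                                                for k in ft.FEATURE_NAMES},
                                        patient_id=pid, timepoint=tp))
    return vectors


def export_parametric_overlay(frame: RFFrame, map_set: ParametricMapSet,
                              path, param: str = "SI",
                              dynamic_range_db: float = 50.0) -> None:
    """B-mode image with a parametric-map overlay inside the ROI (PNG).

    The B-mode background is the log-compressed Hilbert envelope of the RF
    (display only). The overlay shows the selected parameter on its window
    grid, registered to frame coordinates.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.signal import hilbert

    if param not in map_set.maps:
        raise ValueError(f"unknown parametric map {param!r}")
    geom = frame.geometry
    zc, xc = map_set.axial_centers, map_set.lateral_centers
    if zc.max() > geom.depth + 1e-9 or xc.max() > geom.lateral_width + 1e-9:
        raise ValueError("map grid does not register to the frame")

    env = np.abs(hilbert(np.asarray(frame.samples, dtype=float), axis=0))
    env = 20.0 * np.log10(np.maximum(env / env.max(), 1e-12))
    fig, ax = plt.subplots(figsize=(5, 5 * geom.depth / geom.lateral_width))
    ax.imshow(env, cmap="gray", vmin=-dynamic_range_db, vmax=0,
              extent=(0, geom.lateral_width, geom.depth, 0), aspect="auto")
    overlay = map_set.maps[param]
    if np.any(map_set.roi_mask):
        ax.imshow(np.ma.masked_invalid(overlay), cmap="jet", alpha=0.6,
                  extent=(xc[0], xc[-1], zc[-1], zc[0]), aspect="auto")
    else:
        warnings.warn("empty ROI: exporting B-mode only", RuntimeWarning,
                      stacklevel=2)
    ax.set_xlabel("lateral (cm)")
    ax.set_ylabel("depth (cm)")
    ax.set_title(param)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
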