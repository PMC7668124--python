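"""Per-scan feature vectors, delta features, and group/survival statistics.

Each scan yields exactly 31 features: the 7 QUS spectral means (MBF, SS,
SI, ACE, SAS, ASD, AAC) plus 24 GLCM texture values (6 maps x CON, COR,
ENE, HOM — no texture for the constant-valued ACE map). Delta features are
the on-treatment values minus baseline; those deltas feed the CR-vs-PR
group tests (Shapiro-Wilk routed t-test / Mann-Whitney U) and the
classifiers, and follow-up feeds Kaplan-Meier / log-rank survival analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .spectral import MAP_NAMES, ParametricMapSet, mean_map_value
from .texture import texture_summary

__all__ = [
    "FEATURE_NAMES",
    "TEXTURE_MAPS",
    "FeatureVector",
    "DeltaFeatureVector",
    "GroupTestResult",
    "SurvivalResult",
    "assemble_features",
    "delta_features",
    "compare_groups",
    "group_test_table",
    "km_estimate",
    "logrank_test",
    "features_to_tidy",
    "delta_wide_table",
]

#: Maps that get texture analysis (all but the constant ACE map).
TEXTURE_MAPS = tuple(m for m in MAP_NAMES if m != "ACE")
_TEXTURE_FEATS = ("CON", "COR", "ENE", "HOM")

#: The 31 feature names: 7 spectral means + 24 texture values.
FEATURE_NAMES = tuple(MAP_NAMES) + tuple(
    f"{m}-{t}" for m in TEXTURE_MAPS for t in _TEXTURE_FEATS
)


@dataclass
class FeatureVector:
    """The 31 named features of one patient scan."""

    values: dict
    patient_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must hold exactly the {len(FEATURE_NAMES)} "
                f"canonical features (missing={sorted(missing)}, "
                f"unexpected={sorted(extra)})"
            )


@dataclass
class DeltaFeatureVector:
    """Changes from baseline; names carry a 'd' prefix in tabular output."""

    values: dict
    patient_id: str | None = None
    timepoint: str | None = None

    def named(self) -> dict:
        return {f"d{k}": v for k, v in self.values.items()}


@dataclass(frozen=True)
class GroupTestResult:
    feature: str
    test_used: str                  # "t" or "mann_whitney"
    p_value: float
    group_stats: dict               # label -> (mean, sem)


@dataclass
class SurvivalResult:
    curves: dict                    # label -> (times, survival probability)
    statistic: float | None = None
    p_value: float | None = None


def assemble_features(map_set: ParametricMapSet, patient_id: str | None = None,
                      timepoint: str | None = None,
                      n_levels: int = 16) -> FeatureVector:
    """Spectral means + texture summaries of one parametric map set."""
    for name in MAP_NAMES:
        if name not in map_set.maps:
            raise ValueError(f"missing parametric map: {name}")
    values = {}
    for name in MAP_NAMES:
        values[name] = mean_map_value(map_set.maps[name], map_set.roi_mask)
    for name in TEXTURE_MAPS:
        tex = texture_summary(map_set.maps[name], map_set.roi_mask, n_levels)
        for feat, v in tex.as_dict().items():
            values[f"{name}-{feat}"] = v
    return FeatureVector(values=values, patient_id=patient_id,
                         timepoint=timepoint)


def delta_features(current: FeatureVector,
                   baseline: FeatureVector) -> DeltaFeatureVector:
    """Elementwise current - baseline for one patient."""
    if current.values.keys() != baseline.values.keys():
        raise ValueError("feature name mismatch between scans")
    if (current.patient_id is not None and baseline.patient_id is not None
            and current.patient_id != baseline.patient_id):
        raise ValueError("delta features must compare scans of one patient")
    values = {k: current.values[k] - baseline.values[k]
              for k in current.values}
    return DeltaFeatureVector(values=values, patient_id=current.patient_id,
                              timepoint=current.timepoint)


def compare_groups(values, labels, feature: str = "",
                   alpha_normality: float = 0.05) -> GroupTestResult:
    """CR-vs-PR test of one delta feature with normality routing.

    Shapiro-Wilk is run per group; only if neither group rejects at
    ``alpha_normality`` is a two-sided Welch t-test used, otherwise the
    two-sided Mann-Whitney U-test. Group summaries are mean +/- SEM.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    xs = [values[labels == g] for g in groups]
    if min(len(x) for x in xs) < 3:
        raise ValueError("each group needs >= 3 observations")
    stats_by_group = {
        g: (float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x))))
        for g, x in zip(groups, xs)
    }

    degenerate = any(np.ptp(x) == 0 for x in xs)
    normal = False
    if not degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = all(stats.shapiro(x).pvalue > alpha_normality for x in xs)
    if normal:
        res = stats.ttest_ind(xs[0], xs[1], equal_var=False)
        return GroupTestResult(feature=feature, test_used="t",
                               p_value=float(res.pvalue),
                               group_stats=stats_by_group)
    if degenerate:
        warnings.warn("zero-variance group; falling back to Mann-Whitney",
                      RuntimeWarning, stacklevel=2)
    res = stats.mannwhitneyu(xs[0], xs[1], alternative="two-sided")
    return GroupTestResult(feature=feature, test_used="mann_whitney",
                           p_value=float(res.pvalue),
                           group_stats=stats_by_group)


def group_test_table(delta_wide: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-feature group tests in the shape of a published results table:
    feature, test, p-value, and mean +/- SEM per group."""
    rows = []
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    for col in delta_wide.columns:
        r = compare_groups(delta_wide[col].to_numpy(), labels, feature=col)
        row = {"feature": col, "test": r.test_used, "p_value": r.p_value}
        for g in groups:
            m, s = r.group_stats[g]
            row[f"{g}_mean"] = m
            row[f"{g}_sem"] = s
        rows.append(row)
    return pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)


def km_estimate(times, events, group_labels) -> SurvivalResult:
    """Kaplan-Meier product-limit curves per group (censoring-aware)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    curves = {}
    for g in sorted(set(group_labels.tolist())):
        sel = group_labels == g
        if not np.any(sel):
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = (sf.index.to_numpy(dtype=float),
                     sf.iloc[:, 0].to_numpy(dtype=float))
    return SurvivalResult(curves=curves)


def logrank_test(times, events, group_labels):
    """Two-group log-rank chi-square (1 df); returns (statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    groups = sorted(set(group_labels.tolist()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    sel = group_labels == groups[0]
    if sel.all() or not sel.any():
        raise ValueError("one group is empty")
    res = _ll_logrank(times[sel], times[~sel], events[sel], events[~sel])
    return float(res.test_statistic), float(res.p_value)


def features_to_tidy(vectors) -> pd.DataFrame:
    """Tidy table (patient_id, timepoint, feature, value) of feature vectors."""
    rows = []
    for v in vectors:
        vals = v.named() if isinstance(v, DeltaFeatureVector) else v.values
        for name, val in vals.items():
            rows.append({"patient_id": v.patient_id, "timepoint": v.timepoint,
                         "feature": name, "value": val})
    return pd.DataFrame(rows)


def delta_wide_table(delta_vectors, timepoint: str) -> pd.DataFrame:
    """Patients x delta-features matrix for one time point."""
    sel = [v for v in delta_vectors if v.timepoint == timepoint]
    if not sel:
        raise ValueError(f"no delta vectors at timepoint {timepoint!r}")
    return pd.DataFrame([v.named() for v in sel],
                        index=[v.patient_id for v in sel])
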