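"""Two-threshold speed classification and its validation protocols.

A single scalar feature (typically the hand's mean instantaneous velocity)
separates the three speed classes with two decision boundaries: THR1 splits
slow from {normal, fast}, THR2 splits {slow, normal} from fast.  Thresholds
are learned either from the valleys of a kernel-density estimate of the
pooled training values (interclass protocol) or by averaging per-subject
midpoint thresholds (intraclass protocol).  Validation is leave-one-subject-
out: every subject in turn is classified with thresholds learned from the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import (FEATURE_NAMES, MotionSlice, SliceTooShortError,
                       canonical_windows, feature_table)
from .motion_io import CLASS_LABELS, Dataset

__all__ = [
    "ThresholdPair",
    "CrossValReport",
    "SeparationTestResult",
    "fit_thresholds",
    "fit_thresholds_intraclass",
    "classify",
    "classify_many",
    "loo_cross_validate",
    "loo_from_table",
    "partial_motion_analysis",
    "group_separation_tests",
]

_VALLEY_GRID = 512


@dataclass(frozen=True)
class ThresholdPair:
    """The two decision boundaries, in feature units; thr1 < thr2."""

    thr1: float
    thr2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.thr1) and np.isfinite(self.thr2)):
            raise ValueError("thresholds must be finite")
        if not self.thr1 < self.thr2:
            raise ValueError(f"thr1 ({self.thr1}) must be < thr2 ({self.thr2})")


@dataclass
class CrossValReport:
    """Per-fold thresholds and error rates of a leave-one-subject-out run.

    ``overall_error_pct`` pools misclassifications over all motions;
    ``mean_fold_error_pct`` averages the per-fold percentages instead (the
    two coincide when every subject contributes the same number of motions).
    """

    protocol: str
    feature: str
    joint: str
    filtered: bool
    steps: list[dict] = field(default_factory=list)
    overall_error_pct: float = 0.0
    mean_fold_error_pct: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per fold plus a final ``overall`` row."""
        rows = [
            {"step": i + 1, "subject": s["held_out_subject"],
             "thr1": s["thr1"], "thr2": s["thr2"],
             "error_pct": s["error_pct"]}
            for i, s in enumerate(self.steps)
        ]
        rows.append({"step": "overall", "subject": "",
                     "thr1": np.nan, "thr2": np.nan,
                     "error_pct": self.overall_error_pct})
        return pd.DataFrame(rows)


@dataclass
class SeparationTestResult:
    """p-values of one-way ANOVA and Kruskal-Wallis across the classes."""

    anova_p: float
    kruskal_p: float
    n_per_class: dict[str, int]


def _class_arrays(values: np.ndarray, labels: np.ndarray
                  ) -> dict[str, np.ndarray]:
    groups = {}
    for cls in CLASS_LABELS:
        grp = values[labels == cls]
        if grp.size == 0:
            raise ValueError(f"class {cls!r} has no values")
        groups[cls] = grp
    return groups


def _midpoint(lower: np.ndarray, upper: np.ndarray) -> float:
    """Midpoint between the adjacent classes' boundary order statistics."""
    return float((lower.max() + upper.min()) / 2.0)


def fit_thresholds(values, labels, method: str = "valley") -> ThresholdPair:
    """Learn THR1/THR2 from labeled feature values.

    ``method="valley"`` places each threshold at the interior minimum of a
    Gaussian kernel-density estimate (Silverman bandwidth, 512-point grid
    over the pooled data range) between the adjacent class means — the
    valley of the pooled distribution.  When no interior minimum exists the
    midpoint rule is used for that boundary.  ``method="midpoint"`` uses the
    midpoint between the lower class's maximum and the upper class's minimum
    directly (robust for very small per-class counts).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    groups = _class_arrays(values, labels)
    for cls, grp in groups.items():
        if grp.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 values, has {grp.size}")
    means = {cls: float(grp.mean()) for cls, grp in groups.items()}
    if not means["slow"] < means["normal"] < means["fast"]:
        raise ValueError(
            f"class means not ordered slow < normal < fast: {means}"
        )
    if method == "midpoint":
        thr1 = _midpoint(groups["slow"], groups["normal"])
        thr2 = _midpoint(groups["normal"], groups["fast"])
    elif method == "valley":
        kde = stats.gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(values.min(), values.max(), _VALLEY_GRID)
        thr1 = _valley_between(kde, grid, means["slow"], means["normal"]) \
            or _midpoint(groups["slow"], groups["normal"])
        thr2 = _valley_between(kde, grid, means["normal"], means["fast"]) \
            or _midpoint(groups["normal"], groups["fast"])
    else:
        raise ValueError(f"method must be valley|midpoint, got {method!r}")
    return ThresholdPair(thr1=thr1, thr2=thr2)


def _valley_between(kde, grid: np.ndarray, lo: float, hi: float) -> float | None:
    """Density argmin strictly inside (lo, hi); None if it sits on the edge."""
    inside = grid[(grid > lo) & (grid < hi)]
    if inside.size < 3:
        return None
    dens = kde(inside)
    i = int(np.argmin(dens))
    if i == 0 or i == inside.size - 1:
        return None
    return float(inside[i])


def fit_thresholds_intraclass(values, labels, subjects) -> ThresholdPair:
    """Average of per-subject midpoint thresholds.

    Each subject's own values yield a ThresholdPair via the midpoint rule
    (a kernel-density valley is ill-posed on ~5 values per class); the
    subject thresholds are then averaged componentwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    thr1s, thr2s = [], []
    for subj in np.unique(subjects):
        mask = subjects == subj
        groups = _class_arrays(values[mask], labels[mask])
        means = {cls: grp.mean() for cls, grp in groups.items()}
        if not means["slow"] < means["normal"] < means["fast"]:
            raise ValueError(
                f"subject {subj!r}: class means not ordered slow < normal < fast"
            )
        thr1s.append(_midpoint(groups["slow"], groups["normal"]))
        thr2s.append(_midpoint(groups["normal"], groups["fast"]))
    return ThresholdPair(thr1=float(np.mean(thr1s)), thr2=float(np.mean(thr2s)))


def classify(value: float, thr: ThresholdPair) -> str:
    """Assign a speed class; ties at a boundary go to the slower class."""
    if not np.isfinite(value):
        raise ValueError("feature value must be finite")
    if value <= thr.thr1:
        return "slow"
    if value <= thr.thr2:
        return "normal"
    return "fast"


def classify_many(values, thr: ThresholdPair) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    out = np.where(values <= thr.thr1, "slow",
                   np.where(values <= thr.thr2, "normal", "fast"))
    return out.astype(object)


def _fit(train: pd.DataFrame, feature: str, protocol: str,
         method: str) -> ThresholdPair:
    if protocol == "inter":
        return fit_thresholds(train[feature].to_numpy(),
                              train["label"].to_numpy(), method=method)
    if protocol == "intra":
        return fit_thresholds_intraclass(train[feature].to_numpy(),
                                         train["label"].to_numpy(),
                                         train["subject_id"].to_numpy())
    raise ValueError(f"protocol must be intra|inter, got {protocol!r}")


def loo_from_table(table: pd.DataFrame, feature: str = "f1",
                   protocol: str = "inter", method: str = "valley",
                   joint: str = "", filtered: bool = False,
                   on_degenerate: str = "raise") -> CrossValReport:
    """Leave-one-subject-out cross-validation over a feature table.

    The table needs columns ``subject_id``, ``label`` and the feature.
    A training fold whose class means cannot be ordered slow < normal <
    fast (a feature with no monotone relation to speed, e.g. the mean
    acceleration of a rest-to-rest movement) admits no thresholds; with
    ``on_degenerate="raise"`` (default) this propagates as an error, with
    ``on_degenerate="chance"`` the fold predicts the central class for
    every motion — chance-level performance — and its thresholds are
    reported as NaN.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"feature must be one of {FEATURE_NAMES}")
    if on_degenerate not in ("raise", "chance"):
        raise ValueError("on_degenerate must be raise|chance")
    if table[feature].isna().any():
        raise ValueError(f"feature {feature} unavailable for some recordings")
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects, have {len(subjects)}")
    report = CrossValReport(protocol=protocol, feature=feature,
                            joint=joint, filtered=filtered)
    total, wrong = 0, 0
    for subj in subjects:
        test = table[table["subject_id"] == subj]
        train = table[table["subject_id"] != subj]
        try:
            thr = _fit(train, feature, protocol, method)
            predicted = classify_many(test[feature].to_numpy(), thr)
            thr1, thr2 = thr.thr1, thr.thr2
        except ValueError:
            if on_degenerate == "raise":
                raise
            predicted = np.full(len(test), "normal", dtype=object)
            thr1 = thr2 = float("nan")
        mis = int(np.sum(predicted != test["label"].to_numpy()))
        n = len(test)
        report.steps.append({
            "held_out_subject": subj,
            "thr1": thr1,
            "thr2": thr2,
            "error_pct": 100.0 * mis / n,
        })
        total += n
        wrong += mis
    report.overall_error_pct = 100.0 * wrong / total
    report.mean_fold_error_pct = float(
        np.mean([s["error_pct"] for s in report.steps]))
    return report


def loo_cross_validate(dataset: Dataset, joint: str = "HAND",
                       feature: str = "f1", filtered: bool = False,
                       protocol: str = "inter", method: str = "valley",
                       timing: str = "nominal",
                       on_degenerate: str = "raise") -> CrossValReport:
    """Leave-one-subject-out validation of the two-threshold classifier."""
    table = feature_table(dataset, joint, filtered, timing=timing)
    return loo_from_table(table, feature=feature, protocol=protocol,
                          method=method, joint=joint, filtered=filtered,
                          on_degenerate=on_degenerate)


def partial_motion_analysis(dataset: Dataset, joint: str = "HAND",
                            feature: str = "f1", filtered: bool = False,
                            protocol: str = "inter", mode: str = "window",
                            method: str = "valley", timing: str = "nominal",
                            refilter: bool = False,
                            on_degenerate: str = "chance") -> pd.DataFrame:
    """Repeat the LOO protocol on partial motions.

    ``mode="prefix"`` uses growing prefixes (10%, 20%, ..., 100% of each
    motion); ``mode="window"`` uses the ten canonical sequential 10%
    windows.  Thresholds are refit per slice on the training folds.  A slice
    too short for some recording (or leaving the feature undefined) is
    reported with ``available=False`` and a NaN error.

    Uninformative portions of the motion (the stationary holds framing the
    raise) give training folds whose class means cannot be ordered; by
    default such folds score chance-level error rather than aborting the
    slice, so the error-versus-portion curve keeps the high shoulders seen
    at the edges of a motion.

    Returns a table with columns slice_start, slice_end, available,
    overall_error_pct.
    """
    if mode == "prefix":
        slices = [(0.0, k / 10) for k in range(1, 11)]
        kwargs_list = [{"prefix": end} for _, end in slices]
    elif mode == "window":
        windows = canonical_windows()
        slices = [(w.start_fraction, w.end_fraction) for w in windows]
        kwargs_list = [{"slice_": w} for w in windows]
    else:
        raise ValueError(f"mode must be prefix|window, got {mode!r}")
    rows = []
    for (start, end), kwargs in zip(slices, kwargs_list):
        try:
            table = feature_table(dataset, joint, filtered, timing=timing,
                                  refilter=refilter, **kwargs)
            report = loo_from_table(table, feature=feature, protocol=protocol,
                                    method=method, joint=joint,
                                    filtered=filtered,
                                    on_degenerate=on_degenerate)
            rows.append({"slice_start": start, "slice_end": end,
                         "available": True,
                         "overall_error_pct": report.overall_error_pct})
        except (SliceTooShortError, ValueError):
            rows.append({"slice_start": start, "slice_end": end,
                         "available": False,
                         "overall_error_pct": np.nan})
    return pd.DataFrame(rows)


def group_separation_tests(values, labels) -> SeparationTestResult:
    """One-way ANOVA and Kruskal-Wallis across the three speed classes.

    Degenerate input (all values identical) yields NaN p-values with an
    explicit warning instead of an exception.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = _class_arrays(values, labels)
    for cls, grp in groups.items():
        if grp.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 values, has {grp.size}")
    samples = [groups[cls] for cls in CLASS_LABELS]
    n_per_class = {cls: int(groups[cls].size) for cls in CLASS_LABELS}
    if np.ptp(values) == 0:
        warnings.warn("all feature values identical; separation tests are "
                      "degenerate", RuntimeWarning, stacklevel=2)
        return SeparationTestResult(anova_p=float("nan"),
                                    kruskal_p=float("nan"),
                                    n_per_class=n_per_class)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        anova = stats.f_oneway(*samples)
        kruskal = stats.kruskal(*samples)
    return SeparationTestResult(anova_p=float(anova.pvalue),
                                kruskal_p=float(kruskal.pvalue),
                                n_per_class=n_per_class)
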