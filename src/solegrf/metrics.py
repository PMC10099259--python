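"""Agreement metrics between estimated and force-plate-measured GRF.

Implements the validation suite used to score the estimator:

* per-axis Pearson correlation and RMSE, pooled over all test samples,
* the mid-stance timing error -- the difference between estimated and
  measured AP zero-crossing times (braking -> propulsion), also
  expressed as a percentage of the stance phase and of the full gait
  cycle (stance is ~60% of the cycle in level walking),
* per-axis peak (maximum force) extraction,
* Bland-Altman agreement on the peaks: bias, 1.96-SD limits of
  agreement, and 95% confidence intervals for the bias and for each
  limit (classical approximation, LoA standard error = sd * sqrt(3/n)),
* a subgroup breakdown by metatarsal timing group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import StanceSegment

__all__ = [
    "AxisMetrics",
    "TimingReport",
    "BlandAltmanResult",
    "EvalReport",
    "AXES",
    "pearson_per_axis",
    "rmse_per_axis",
    "midstance_crossing_time",
    "midstance_timing_error",
    "timing_error_percent",
    "peak_values",
    "bland_altman",
    "evaluate_testset",
]

AXES = ("vertical", "ap", "ml")


class CrossingError(ValueError):
    """The AP series has no braking-to-propulsion sign change."""


@dataclass(frozen=True)
class AxisMetrics:
    axis: str
    pearson_r: float
    rmse: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass(frozen=True)
class TimingReport:
    """Mid-stance timing errors across test trials.

    ``signed_errors`` holds estimated minus measured crossing times (s)
    per scored trial; trials whose estimate has no crossing are counted
    in ``n_excluded``. Percentages use the cohort mean stance duration
    and the stance fraction of the gait cycle.
    """

    signed_errors: tuple[float, ...]
    mean_abs_error: float
    pct_of_cycle: float
    pct_of_stance: float
    n_earlier: int
    n_later: int
    n_equal: int
    n_excluded: int = 0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, limits of agreement and their 95% confidence intervals (N)."""

    n: int
    bias: float
    sd_diff: float
    lloa: float
    uloa: float
    bias_ci: tuple[float, float]
    lloa_ci: tuple[float, float]
    uloa_ci: tuple[float, float]
    means: tuple[float, ...] = ()
    diffs: tuple[float, ...] = ()


@dataclass(frozen=True)
class EvalReport:
    """Full evaluation: axis metrics, timing, peak agreement, subgroups."""

    axis_metrics: tuple[AxisMetrics, AxisMetrics, AxisMetrics]
    timing: TimingReport
    bland_altman_peaks: dict[str, BlandAltmanResult]
    n_trials: int
    subgroups: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def ba_dict(b: BlandAltmanResult) -> dict:
            return {
                "n": b.n,
                "bias": b.bias,
                "sd_diff": b.sd_diff,
                "lloa": b.lloa,
                "uloa": b.uloa,
                "bias_ci": list(b.bias_ci),
                "lloa_ci": list(b.lloa_ci),
                "uloa_ci": list(b.uloa_ci),
            }

        return {
            "n_trials": self.n_trials,
            "axes": {
                m.axis: {"pearson_r": m.pearson_r, "rmse": m.rmse}
                for m in self.axis_metrics
            },
            "timing": {
                "signed_errors_s": list(self.timing.signed_errors),
                "mean_abs_error_s": self.timing.mean_abs_error,
                "pct_of_cycle": self.timing.pct_of_cycle,
                "pct_of_stance": self.timing.pct_of_stance,
                "n_earlier": self.timing.n_earlier,
                "n_later": self.timing.n_later,
                "n_equal": self.timing.n_equal,
                "n_excluded": self.timing.n_excluded,
            },
            "bland_altman_peaks": {k: ba_dict(v) for k, v in self.bland_altman_peaks.items()},
            "subgroups": {k: v.to_dict() for k, v in self.subgroups.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _pooled(pred: Sequence[np.ndarray], meas: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if len(pred) != len(meas):
        raise ValueError("prediction and measurement counts differ")
    for p, m in zip(pred, meas):
        if np.shape(p) != np.shape(m):
            raise ValueError("paired series must have equal shapes")
    p = np.concatenate([np.asarray(x, dtype=float) for x in pred], axis=-1)
    m = np.concatenate([np.asarray(x, dtype=float) for x in meas], axis=-1)
    return p, m


def pearson_per_axis(pred: Sequence[np.ndarray], meas: Sequence[np.ndarray]) -> np.ndarray:
    """Pooled Pearson r per axis over all concatenated test samples.

    ``pred`` and ``meas`` are sequences of (3, T_i) arrays. Zero
    variance in either pooled series is an error (correlation
    undefined), not a silent NaN.
    """
    p, m = _pooled(pred, meas)
    rs = []
    for axis in range(p.shape[0]):
        if np.std(p[axis]) == 0 or np.std(m[axis]) == 0:
            raise ValueError(f"zero variance on axis {AXES[axis]}: correlation undefined")
        rs.append(float(np.corrcoef(p[axis], m[axis])[0, 1]))
    return np.array(rs)


def rmse_per_axis(pred: Sequence[np.ndarray], meas: Sequence[np.ndarray]) -> np.ndarray:
    """Pooled root-mean-square error per axis, newtons."""
    p, m = _pooled(pred, meas)
    return np.sqrt(np.mean((p - m) ** 2, axis=-1))


def midstance_crossing_time(ap: np.ndarray, sample_rate: float) -> float:
    """Time (s) of the braking-to-propulsion sign change of the AP GRF.

    The search starts at the global minimum of the series (the deepest
    braking point) so spurious near-zero flips around foot contact are
    ignored; the crossing is located with linear sub-sample
    interpolation between the bracketing samples.
    """
    ap = np.asarray(ap, dtype=float)
    if ap.size < 2:
        raise CrossingError("series too short for a crossing")
    start = int(np.argmin(ap))
    for i in range(start, ap.size - 1):
        if ap[i] < 0 and ap[i + 1] >= 0:
            frac = -ap[i] / (ap[i + 1] - ap[i])
            return float((i + frac) / sample_rate)
    raise CrossingError("no negative-to-positive crossing after the global minimum")


def midstance_timing_error(
    pred_ap: np.ndarray, meas_ap: np.ndarray, sample_rate: float
) -> tuple[float, float, str]:
    """Signed and absolute crossing-time error, plus an earlier/later class.

    Signed error is estimated minus measured; |error| below half a
    sample period counts as "equal".
    """
    signed = midstance_crossing_time(pred_ap, sample_rate) - midstance_crossing_time(
        meas_ap, sample_rate
    )
    half_period = 0.5 / sample_rate
    if abs(signed) < half_period:
        label = "equal"
    elif signed < 0:
        label = "earlier"
    else:
        label = "later"
    return signed, abs(signed), label


def timing_error_percent(
    mean_abs_error: float, mean_stance: float, stance_fraction: float = 0.6
) -> tuple[float, float]:
    """(percent of gait cycle, percent of stance) for a timing error.

    The gait-cycle duration is reconstructed as
    ``mean_stance / stance_fraction`` (stance is ~60% of a cycle).
    """
    if mean_stance <= 0:
        raise ValueError("mean_stance must be positive")
    if not 0 < stance_fraction <= 1:
        raise ValueError("stance_fraction must lie in (0, 1]")
    pct_of_stance = 100.0 * mean_abs_error / mean_stance
    pct_of_cycle = pct_of_stance * stance_fraction
    return pct_of_cycle, pct_of_stance


def peak_values(targets: np.ndarray) -> tuple[float, float, float]:
    """(max vertical, max propulsive AP, max ML) of a (3, T) array, N.

    The AP peak is the maximum of the propulsive (positive) phase; an
    all-negative AP series has no propulsive peak and is an error.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[0] != 3 or targets.shape[1] == 0:
        raise ValueError("expected a non-empty (3, T) array")
    ap_max = float(targets[1].max())
    if ap_max <= 0:
        raise ValueError("no propulsive peak: AP series never positive")
    return float(targets[0].max()), ap_max, float(targets[2].max())


def bland_altman(estimated: Sequence[float], measured: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement between paired scalar measurements.

    Differences are estimated minus measured. Limits of agreement are
    bias +- 1.96 sd; the bias CI uses the t(n-1) standard error
    sd/sqrt(n); each LoA CI uses the classical approximation
    sd*sqrt(3/n) with the same t multiplier.
    """
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.ndim != 1:
        raise ValueError("estimated and measured must be equal-length 1-D sequences")
    n = est.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = est - mea
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lloa = bias - 1.96 * sd
    uloa = bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        lloa=lloa,
        uloa=uloa,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        lloa_ci=(lloa - tcrit * se_loa, lloa + tcrit * se_loa),
        uloa_ci=(uloa - tcrit * se_loa, uloa + tcrit * se_loa),
        means=tuple((est + mea) / 2.0),
        diffs=tuple(d),
    )


def _evaluate_pairs(
    preds: list[np.ndarray],
    segments: Sequence[StanceSegment],
    stance_fraction: float,
) -> EvalReport:
    meas = [s.targets for s in segments]
    rs = pearson_per_axis(preds, meas)
    rmses = rmse_per_axis(preds, meas)
    axis_metrics = tuple(
        AxisMetrics(axis=a, pearson_r=float(r), rmse=float(e))
        for a, r, e in zip(AXES, rs, rmses)
    )

    signed: list[float] = []
    labels: list[str] = []
    excluded = 0
    for p, s in zip(preds, segments):
        try:
            se, _, label = midstance_timing_error(p[1], s.targets[1], s.sample_rate)
        except CrossingError:
            excluded += 1
            continue
        signed.append(se)
        labels.append(label)
    mean_stance = float(np.mean([s.duration for s in segments]))
    mean_abs = float(np.mean(np.abs(signed))) if signed else 0.0
    pct_cycle, pct_stance = timing_error_percent(mean_abs, mean_stance, stance_fraction)
    timing = TimingReport(
        signed_errors=tuple(signed),
        mean_abs_error=mean_abs,
        pct_of_cycle=pct_cycle,
        pct_of_stance=pct_stance,
        n_earlier=labels.count("earlier"),
        n_later=labels.count("later"),
        n_equal=labels.count("equal"),
        n_excluded=excluded,
    )

    ba: dict[str, BlandAltmanResult] = {}
    if len(segments) >= 2:
        est_peaks = np.array([peak_values(p) for p in preds])
        mea_peaks = np.array([peak_values(s.targets) for s in segments])
        for i, axis in enumerate(AXES):
            ba[f"max_{axis}"] = bland_altman(est_peaks[:, i], mea_peaks[:, i])

    return EvalReport(
        axis_metrics=axis_metrics,  # type: ignore[arg-type]
        timing=timing,
        bland_altman_peaks=ba,
        n_trials=len(segments),
    )


def evaluate_testset(
    model, test: Sequence[StanceSegment], stance_fraction: float = 0.6
) -> EvalReport:
    """Score ``model`` on held-out segments; subgroup by timing group.

    ``model`` is anything with a ``predict((4, T)) -> (3, T)`` method
    (a :class:`solegrf.grfnet.TrainedEstimator`). When segments carry
    ``timing_group`` labels the same metrics are recomputed per group.
    """
    if not test:
        raise ValueError("test set is empty")
    preds = [np.asarray(model.predict(s.inputs), dtype=float) for s in test]
    report = _evaluate_pairs(preds, test, stance_fraction)

    groups = sorted({s.timing_group for s in test if s.timing_group is not None})
    subgroups: dict[str, EvalReport] = {}
    for g in groups:
        idx = [i for i, s in enumerate(test) if s.timing_group == g]
        if len(idx) >= 2:
            subgroups[g] = _evaluate_pairs(
                [preds[i] for i in idx], [test[i] for i in idx], stance_fraction
            )
    return EvalReport(
        axis_metrics=report.axis_metrics,
        timing=report.timing,
        bland_altman_peaks=report.bland_altman_peaks,
        n_trials=report.n_trials,
        subgroups=subgroups,
    )
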