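"""End-to-end experiment orchestration and file I/O.

Wires the stages together: generate (or load) paired recordings,
preprocess every trial into stance segments, split subject-wise into
train/validation/test (the splits share no subjects, so the test score
measures generalization to new people), train the estimator, evaluate
on the held-out subjects, and archive everything needed to reproduce
the run (config, seeds, versions, model checkpoint, report).

CSV dialects (UTF-8, header row, '.' decimal separator):

* load-cell recording:   time_s,heel_n,met1_n,met5_n
* force-plate recording: time_s,fz_n,fap_n,fml_n
* subject table:         subject_id,body_weight_n,stance_s,timing_group
* trial truth:           heel_strike_s,toe_off_s,ap_crossing_s,
                         peak_vertical_n,peak_ap_n,peak_ml_n
* stance segment:        heel_n,met1_n,met5_n,sum_n,fz_n,fap_n,fml_n
                         (+ JSON sidecar with ids, rate, timing group)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grfnet import ModelConfig, build_estimator, save_estimator, train_estimator
from .metrics import EvalReport, evaluate_testset
from .preprocess import FilterSpec, OnsetThresholds, StanceSegment, synchronize_pair
from .synthgait import (
    ForcePlateRecording,
    LoadCellRecording,
    SyntheticConfig,
    SyntheticDataset,
    TrialTruth,
    generate_dataset,
)

__all__ = [
    "SplitSpec",
    "RunConfig",
    "split_subjects",
    "run_experiment",
    "read_loadcell_csv",
    "read_forceplate_csv",
    "write_loadcell_csv",
    "write_forceplate_csv",
    "write_dataset",
    "write_report",
    "preprocess_dataset",
]

logger = logging.getLogger("solegrf")


@dataclass(frozen=True)
class SplitSpec:
    """Subject-wise split counts (train/validation/test) and shuffle seed."""

    train: int = 37
    val: int = 12
    test: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split counts must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs; serializable for reproducibility."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    thresholds: OnsetThresholds = field(default_factory=OnsetThresholds)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    stance_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction <= 1:
            raise ValueError("stance_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            synthetic=SyntheticConfig(**d.get("synthetic", {})),
            filter=FilterSpec(**d.get("filter", {})),
            thresholds=OnsetThresholds(**d.get("thresholds", {})),
            model=ModelConfig(**d.get("model", {})),
            split=SplitSpec(**d.get("split", {})),
            stance_fraction=d.get("stance_fraction", 0.6),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def split_subjects(subject_ids, spec: SplitSpec) -> tuple[list, list, list]:
    """Seeded shuffle of subjects into disjoint train/val/test id lists."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    total = spec.train + spec.val + spec.test
    if total > len(ids):
        raise ValueError(f"split needs {total} subjects but only {len(ids)} are available")
    rng = np.random.default_rng(spec.seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    train = order[: spec.train]
    val = order[spec.train : spec.train + spec.val]
    test = order[spec.train + spec.val : total]
    return train, val, test


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_LC_COLUMNS = ["time_s", "heel_n", "met1_n", "met5_n"]
_FP_COLUMNS = ["time_s", "fz_n", "fap_n", "fml_n"]
_SEG_COLUMNS = ["heel_n", "met1_n", "met5_n", "sum_n", "fz_n", "fap_n", "fml_n"]


class RecordingParseError(ValueError):
    """A recording CSV does not conform to the expected dialect."""


def _check_time_column(t: np.ndarray, path) -> float:
    """Validate monotone, uniform sampling; return the sample rate."""
    if t.size < 2:
        raise RecordingParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise RecordingParseError(f"{path}: time column is not strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise RecordingParseError(f"{path}: sampling jitter exceeds 1% of the sample period")
    return 1.0 / med


def _read_recording(path, columns: list[str]) -> tuple[pd.DataFrame, float]:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing column(s) {', '.join(missing)}")
    rate = _check_time_column(df["time_s"].to_numpy(dtype=float), path)
    return df, rate


def _ids_from_path(path) -> tuple[str, str]:
    # file stem convention: <subject>_<trial>_<kind>.csv
    parts = Path(path).stem.split("_")
    if len(parts) >= 3:
        return parts[0], parts[1]
    return Path(path).stem, "t0"


def read_loadcell_csv(path) -> LoadCellRecording:
    df, rate = _read_recording(path, _LC_COLUMNS)
    subject_id, trial_id = _ids_from_path(path)
    return LoadCellRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        sample_rate=rate,
        heel=df["heel_n"].to_numpy(dtype=float),
        met1=df["met1_n"].to_numpy(dtype=float),
        met5=df["met5_n"].to_numpy(dtype=float),
    )


def read_forceplate_csv(path) -> ForcePlateRecording:
    df, rate = _read_recording(path, _FP_COLUMNS)
    subject_id, trial_id = _ids_from_path(path)
    return ForcePlateRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        sample_rate=rate,
        vertical=df["fz_n"].to_numpy(dtype=float),
        ap=df["fap_n"].to_numpy(dtype=float),
        ml=df["fml_n"].to_numpy(dtype=float),
    )


def write_loadcell_csv(rec: LoadCellRecording, path) -> None:
    pd.DataFrame(
        {"time_s": rec.times, "heel_n": rec.heel, "met1_n": rec.met1, "met5_n": rec.met5}
    ).to_csv(path, index=False, float_format="%.10g")


def write_forceplate_csv(rec: ForcePlateRecording, path) -> None:
    pd.DataFrame(
        {"time_s": rec.times, "fz_n": rec.vertical, "fap_n": rec.ap, "fml_n": rec.ml}
    ).to_csv(path, index=False, float_format="%.10g")


def write_segment_csv(seg: StanceSegment, path) -> None:
    data = np.vstack([seg.inputs, seg.targets]).T
    pd.DataFrame(data, columns=_SEG_COLUMNS).to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "subject_id": seg.subject_id,
        "trial_id": seg.trial_id,
        "sample_rate": seg.sample_rate,
        "timing_group": seg.timing_group,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_segment_csv(path) -> StanceSegment:
    df = pd.read_csv(path)
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing column(s) {', '.join(missing)}")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    arr = df.to_numpy(dtype=float).T
    return StanceSegment(
        subject_id=sidecar["subject_id"],
        trial_id=sidecar["trial_id"],
        sample_rate=sidecar["sample_rate"],
        inputs=np.vstack([arr[:3], arr[:3].sum(axis=0, keepdims=True)]),
        targets=arr[4:],
        timing_group=sidecar.get("timing_group"),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """One CSV per recording plus subject table and per-trial truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in dataset.subjects],
            "body_weight_n": [s.body_weight for s in dataset.subjects],
            "stance_s": [s.stance_duration for s in dataset.subjects],
            "timing_group": [s.timing_group for s in dataset.subjects],
        }
    ).to_csv(out / "subjects.csv", index=False, float_format="%.10g")
    for lc, fp, truth in dataset.trials:
        stem = f"{lc.subject_id}_{lc.trial_id}"
        write_loadcell_csv(lc, out / f"{stem}_loadcell.csv")
        write_forceplate_csv(fp, out / f"{stem}_forceplate.csv")
        pd.DataFrame([dataclasses.asdict(truth)]).rename(
            columns={
                "heel_strike_time": "heel_strike_s",
                "toe_off_time": "toe_off_s",
                "ap_crossing_time": "ap_crossing_s",
                "peak_vertical": "peak_vertical_n",
                "peak_ap": "peak_ap_n",
                "peak_ml": "peak_ml_n",
            }
        ).to_csv(out / f"{stem}_truth.csv", index=False, float_format="%.10g")


def preprocess_dataset(dataset: SyntheticDataset, config: RunConfig) -> list[StanceSegment]:
    """Synchronize every trial pair; log and drop trials that fail."""
    groups = {s.subject_id: s.timing_group for s in dataset.subjects}
    segments = []
    dropped = 0
    for lc, fp, _truth in dataset.trials:
        try:
            segments.append(
                synchronize_pair(
                    lc,
                    fp,
                    spec=config.filter,
                    thresholds=config.thresholds,
                    timing_group=groups.get(lc.subject_id),
                )
            )
        except ValueError as exc:
            dropped += 1
            logger.warning("dropped trial %s/%s: %s", lc.subject_id, lc.trial_id, exc)
    logger.info("preprocessed %d trials (%d dropped)", len(segments), dropped)
    return segments


def write_report(report: EvalReport, out_dir) -> None:
    """EvalReport as full-precision JSON plus a flat CSV summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(indent=2))
    rows = []
    for m in report.axis_metrics:
        rows.append({"group": "all", "axis": m.axis, "statistic": "pearson_r", "value": m.pearson_r})
        rows.append({"group": "all", "axis": m.axis, "statistic": "rmse_n", "value": m.rmse})
    rows.append(
        {"group": "all", "axis": "ap", "statistic": "timing_mae_s", "value": report.timing.mean_abs_error}
    )
    for g, sub in report.subgroups.items():
        for m in sub.axis_metrics:
            rows.append({"group": g, "axis": m.axis, "statistic": "pearson_r", "value": m.pearson_r})
            rows.append({"group": g, "axis": m.axis, "statistic": "rmse_n", "value": m.rmse})
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False, float_format="%.10g")
    # Bland-Altman point sets for plotting
    for name, ba in report.bland_altman_peaks.items():
        pd.DataFrame({"mean_n": ba.means, "diff_n": ba.diffs}).to_csv(
            out / f"bland_altman_{name}.csv", index=False, float_format="%.10g"
        )


def run_experiment(config: RunConfig, out_dir=None) -> EvalReport:
    """Generate -> preprocess -> split -> train -> evaluate -> archive.

    Fails fast (before training) if any split would be empty of
    segments. When ``out_dir`` is given, writes the archived config,
    the model checkpoint, the evaluation report and a run log there, so
    the run can be reproduced from the directory alone.
    """
    logger.info("generating %d subjects x %d trials (seed %d)",
                config.synthetic.n_subjects, config.synthetic.trials_per_subject,
                config.synthetic.seed)
    dataset = generate_dataset(config.synthetic)
    segments = preprocess_dataset(dataset, config)
    if not segments:
        raise RuntimeError("preprocessing produced no usable segments")

    subject_ids = [s.subject_id for s in dataset.subjects]
    train_ids, val_ids, test_ids = split_subjects(subject_ids, config.split)
    by_split = {
        "train": [s for s in segments if s.subject_id in set(train_ids)],
        "val": [s for s in segments if s.subject_id in set(val_ids)],
        "test": [s for s in segments if s.subject_id in set(test_ids)],
    }
    for name in ("train", "test"):
        if not by_split[name]:
            raise RuntimeError(f"{name} split contains no segments")
    logger.info(
        "split sizes (segments): train=%d val=%d test=%d",
        *(len(by_split[k]) for k in ("train", "val", "test")),
    )

    estimator = build_estimator(config.model)
    model = train_estimator(estimator, by_split["train"], by_split["val"], config.model)
    report = evaluate_testset(model, by_split["test"], config.stance_fraction)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
        save_estimator(model, out / "model.npz")
        write_report(report, out)
        run_log = {
            "solegrf_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "seeds": {
                "synthetic": config.synthetic.seed,
                "split": config.split.seed,
                "model": config.model.seed,
            },
            "n_subjects": config.synthetic.n_subjects,
            "n_segments": len(segments),
            "split_segments": {k: len(v) for k, v in by_split.items()},
            "test_subjects": test_ids,
        }
        (out / "run.json").write_text(json.dumps(run_log, indent=2))
    return report
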