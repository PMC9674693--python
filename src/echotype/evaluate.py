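"""Metrics, fold aggregation and the cross-validated experiment suite.

Metrics follow the set formulation: with T the predicted-positive set, T*
the actual-positive set and U the whole evaluation set,

    A = (|T* ∩ T| + |(T* ∪ T)^c|) / |U|,   P = |T* ∩ T| / |T|,
    R = |T* ∩ T| / |T*|,                    F1 = 2PR / (P + R),

with the conventions P := 0 (R := 0) for an empty denominator and F1 := 0
when P + R = 0.  Fold aggregates are the arithmetic mean and the sample
standard deviation (n-1 denominator) of the unrounded per-fold values.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify import (
    BaselineSpec,
    ClassifierTrainSpec,
    Conv1DClassifierSpec,
    Conv2DClassifierSpec,
    predict_labels,
    train_1d_classifier,
    train_2d_classifier,
    train_baseline,
)
from .denoise import (
    AETrainSpec,
    AutoencoderSpec,
    NoiseSpec,
    augment_training_set,
    denoise_batch,
    normalize_signal,
    train_autoencoder,
)
from .features import ResolutionSpec, STFTSpec, fft_spectrum, reduce_resolution, stft_spectrogram
from .io import FoldAssignment, LabeledSignalSet, SignalRecord, stratified_kfold
from .util import derive_seed

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("waveform", "spectrum", "spectrogram")
MODEL_FAMILIES = ("cnn1d", "cnn2d", "svm", "logit", "mlp")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
        recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        return cls(accuracy=(c.tp + c.tn) / c.total, precision=precision, recall=recall, f1=f1)

    def as_tuple(self):
        return (self.accuracy, self.precision, self.recall, self.f1)


def confusion_counts(true_labels, predicted_labels, positive_label=1) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label sequences differ in length: {t.shape} vs {p.shape}")
    tpos = t == positive_label
    ppos = p == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def compute_metrics(true_labels, predicted_labels, positive_label=1) -> MetricsReport:
    return MetricsReport.from_counts(confusion_counts(true_labels, predicted_labels, positive_label))


def aggregate_folds(reports: list[MetricsReport]) -> tuple[MetricsReport, MetricsReport]:
    """Per-metric mean and sample standard deviation across folds."""
    if len(reports) < 2:
        raise ValueError("need >= 2 fold reports to aggregate (sample SD undefined)")
    values = np.array([r.as_tuple() for r in reports])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return MetricsReport(*mean), MetricsReport(*sd)


@dataclass
class ExperimentReport:
    per_fold: list[MetricsReport]
    mean: MetricsReport
    sd: MetricsReport
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_fold": [asdict(r) for r in self.per_fold],
            "mean": asdict(self.mean),
            "sd": asdict(self.sd),
            "config": self.config,
        }


class AblationMode(enum.Enum):
    RAW = "Raw"  # no denoiser, no injection
    DN = "DN"  # denoising autoencoder only
    DN_PLUS = "DN+"  # autoencoder + Gaussian-noise augmentation


@dataclass
class PipelineConfig:
    """Everything an experiment needs beyond the dataset itself."""

    noise: NoiseSpec = field(default_factory=NoiseSpec)
    ae_spec: AutoencoderSpec | None = None  # None -> latent derived from N
    ae_train: AETrainSpec = field(default_factory=AETrainSpec)
    cnn1d_spec: Conv1DClassifierSpec = field(default_factory=Conv1DClassifierSpec)
    cnn2d_spec: Conv2DClassifierSpec = field(default_factory=Conv2DClassifierSpec)
    cnn_train: ClassifierTrainSpec = field(default_factory=ClassifierTrainSpec)
    stft: STFTSpec = field(default_factory=STFTSpec)
    resolution: ResolutionSpec | None = None
    threshold: float = 0.5


def _featurize(signals: np.ndarray, representation: str, pipeline: PipelineConfig) -> np.ndarray:
    """Per-example max-normalized features for one representation."""
    feats = []
    for x in signals:
        if representation == "waveform":
            f = x
        elif representation == "spectrum":
            rep = fft_spectrum(x)
            if pipeline.resolution is not None:
                rep = reduce_resolution(rep, pipeline.resolution)
            f = rep.magnitudes
        elif representation == "spectrogram":
            rep = stft_spectrogram(x, pipeline.stft)
            if pipeline.resolution is not None:
                rep = reduce_resolution(rep, pipeline.resolution)
            f = rep.values
        else:
            raise ValueError(f"unknown representation {representation!r}")
        feats.append(normalize_signal(f))
    return np.stack(feats)


def _train_model(representation, model_family, features, labels, pipeline):
    if model_family == "cnn1d":
        if representation == "spectrogram":
            raise ValueError("cnn1d consumes 1D representations; use cnn2d for spectrograms")
        return train_1d_classifier(features, labels, pipeline.cnn1d_spec, pipeline.cnn_train)
    if model_family == "cnn2d":
        if representation != "spectrogram":
            raise ValueError("cnn2d consumes spectrograms")
        return train_2d_classifier(features, labels, pipeline.cnn2d_spec, pipeline.cnn_train)
    return train_baseline(features, labels, BaselineSpec(model_family), seed=pipeline.cnn_train.seed)


def _prepare_fold(sset, folds, fold, mode, pipeline, seed):
    """Normalize, denoise (train-fit only) and augment one fold's data.

    Returns the augmented training set, the processed test signals and the
    test subset.  Any overlap of train and test ids is a hard error.
    """
    train_ids, test_ids = folds.train_test_ids(fold)
    if set(train_ids) & set(test_ids):
        raise AssertionError("leakage: train and test folds overlap")
    train = sset.subset(train_ids, role="train")
    test = sset.subset(test_ids, role="test")
    train_sig = np.stack([normalize_signal(r.samples) for r in train.records])
    test_sig = np.stack([normalize_signal(r.samples) for r in test.records])

    if mode is not AblationMode.RAW:
        norm_train = LabeledSignalSet(
            [SignalRecord(r.id, s, r.label, r.metadata) for r, s in zip(train.records, train_sig)],
            positive_label=train.positive_label,
            role="train",
        )
        ae = train_autoencoder(
            norm_train,
            pipeline.ae_spec,
            pipeline.ae_train,
            pipeline.noise,
            seed=derive_seed(seed, f"ae-fold{fold}"),
        )
        train_sig = denoise_batch(ae, train_sig)
        test_sig = denoise_batch(ae, test_sig)

    train_work = LabeledSignalSet(
        [SignalRecord(r.id, s, r.label, r.metadata) for r, s in zip(train.records, train_sig)],
        positive_label=train.positive_label,
        role="train",
    )
    if mode is AblationMode.DN_PLUS:
        aug_noise = NoiseSpec(
            sigma_n=pipeline.noise.sigma_n,
            copies_per_signal=pipeline.noise.copies_per_signal,
            seed=derive_seed(seed, f"augment-fold{fold}"),
        )
        train_work = augment_training_set(train_work, aug_noise)
    if set(test.ids) & set(train_work.ids):
        raise AssertionError("leakage: test ids entered the training set")
    return train_work, test_sig, test


def _fold_report(train_work, test_sig, test, representation, model_family, pipeline):
    x_train = _featurize(train_work.signal_matrix(), representation, pipeline)
    x_test = _featurize(test_sig, representation, pipeline)
    model = _train_model(representation, model_family, x_train, train_work.binary_labels(), pipeline)
    preds = predict_labels(model, x_test, threshold=pipeline.threshold)
    return compute_metrics(test.binary_labels(), [p.label for p in preds], positive_label=1)


def _experiment_config(sset, folds, representation, model_family, mode, seed, pipeline):
    return {
        "representation": representation,
        "model_family": model_family,
        "mode": mode.value,
        "k": folds.k,
        "seed": seed,
        "positive_label": sset.positive_label,
        "n_signals": len(sset),
        "sigma_n": pipeline.noise.sigma_n,
        "copies_per_signal": pipeline.noise.copies_per_signal,
        "resolution": pipeline.resolution.target_bins if pipeline.resolution else None,
    }


def run_cv_experiment(
    sset: LabeledSignalSet,
    representation: str = "spectrum",
    model_family: str = "cnn1d",
    mode: AblationMode = AblationMode.DN_PLUS,
    k: int = 3,
    seed: int = 0,
    pipeline: PipelineConfig | None = None,
    folds: FoldAssignment | None = None,
) -> ExperimentReport:
    """Stratified k-fold evaluation of one pipeline configuration.

    Per fold: the denoiser (if any) and the noise augmentation are fitted /
    applied on the training folds only; the test fold is featurized and
    scored untouched.
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"representation must be one of {REPRESENTATIONS}")
    if model_family not in MODEL_FAMILIES:
        raise ValueError(f"model_family must be one of {MODEL_FAMILIES}")
    pipeline = pipeline or PipelineConfig()
    folds = folds or stratified_kfold(sset, k, seed=derive_seed(seed, "folds"))
    if set(folds.fold_of) != set(sset.ids):
        raise AssertionError("fold assignment does not match the dataset ids")
    per_fold = []
    for fold in range(folds.k):
        train_work, test_sig, test = _prepare_fold(sset, folds, fold, mode, pipeline, seed)
        per_fold.append(_fold_report(train_work, test_sig, test, representation, model_family, pipeline))
    mean, sd = aggregate_folds(per_fold)
    config = _experiment_config(sset, folds, representation, model_family, mode, seed, pipeline)
    return ExperimentReport(per_fold=per_fold, mean=mean, sd=sd, config=config)


def default_model_for(representation: str) -> str:
    return "cnn2d" if representation == "spectrogram" else "cnn1d"


def run_representation_suite(
    sset: LabeledSignalSet,
    representations=REPRESENTATIONS,
    mode: AblationMode = AblationMode.DN_PLUS,
    k: int = 3,
    seed: int = 0,
    pipeline: PipelineConfig | None = None,
    model_for: dict[str, str] | None = None,
) -> dict[str, ExperimentReport]:
    """Waveform/spectrum/spectrogram comparison on shared folds.

    The fold split and the per-fold denoiser are computed once and shared
    by every representation (they act on the raw signals, upstream of
    featurization), so the comparison isolates the representation itself.
    """
    pipeline = pipeline or PipelineConfig()
    folds = stratified_kfold(sset, k, seed=derive_seed(seed, "folds"))
    per_rep: dict[str, list[MetricsReport]] = {r: [] for r in representations}
    for fold in range(folds.k):
        train_work, test_sig, test = _prepare_fold(sset, folds, fold, mode, pipeline, seed)
        for representation in representations:
            family = (model_for or {}).get(representation, default_model_for(representation))
            per_rep[representation].append(
                _fold_report(train_work, test_sig, test, representation, family, pipeline)
            )
    out = {}
    for representation, reports in per_rep.items():
        family = (model_for or {}).get(representation, default_model_for(representation))
        mean, sd = aggregate_folds(reports)
        config = _experiment_config(sset, folds, representation, family, mode, seed, pipeline)
        out[representation] = ExperimentReport(per_fold=reports, mean=mean, sd=sd, config=config)
    return out


def run_ablation(
    sset: LabeledSignalSet,
    representation: str = "spectrum",
    model_family: str = "cnn1d",
    k: int = 3,
    seed: int = 0,
    pipeline: PipelineConfig | None = None,
) -> dict[str, ExperimentReport]:
    """Raw vs DN vs DN+ with shared fold assignments and seeds."""
    folds = stratified_kfold(sset, k, seed=derive_seed(seed, "folds"))
    return {
        mode.value: run_cv_experiment(
            sset, representation, model_family, mode, k=k, seed=seed, pipeline=pipeline, folds=folds
        )
        for mode in (AblationMode.RAW, AblationMode.DN, AblationMode.DN_PLUS)
    }


def run_resolution_sweep(
    sset: LabeledSignalSet,
    model_family: str = "cnn",
    resolutions=None,
    k: int = 3,
    seed: int = 0,
    pipeline: PipelineConfig | None = None,
    mode: AblationMode = AblationMode.DN_PLUS,
    method: str = "decimate",
) -> list[dict]:
    """Paired spectrum/spectrogram accuracy as a function of frequency
    resolution (default sweep 125..2000 in steps of 125).

    ``model_family="cnn"`` pairs cnn1d with the spectrum and cnn2d with the
    spectrogram; a baseline family is used for both.  Resolutions exceeding
    the available bin count are skipped with a warning.  Returns long-format
    rows (resolution, representation, metric, value).
    """
    resolutions = list(resolutions) if resolutions is not None else list(range(125, 2001, 125))
    pipeline = pipeline or PipelineConfig()
    n = len(sset.records[0].samples)
    bins = {"spectrum": n // 2 + 1, "spectrogram": pipeline.stft.window_length // 2 + 1}
    folds = stratified_kfold(sset, k, seed=derive_seed(seed, "folds"))
    rows = []
    for res in resolutions:
        for representation in ("spectrum", "spectrogram"):
            if res > bins[representation]:
                logger.warning(
                    "skipping resolution %d for %s (only %d bins)", res, representation, bins[representation]
                )
                continue
            family = model_family
            if model_family == "cnn":
                family = default_model_for(representation)
            pl = dataclasses.replace(pipeline, resolution=ResolutionSpec(res, method=method))
            report = run_cv_experiment(
                sset, representation, family, mode, k=k, seed=seed, pipeline=pl, folds=folds
            )
            for metric in METRIC_NAMES:
                rows.append(
                    {
                        "resolution": res,
                        "representation": representation,
                        "metric": metric,
                        "value": getattr(report.mean, metric),
                    }
                )
    return rows


def report_to_csv(report: ExperimentReport, path) -> None:
    """Fold rows plus Avg./S.D. rows, 2 decimal places (display only)."""
    lines = ["fold,accuracy,precision,recall,f1"]
    for i, r in enumerate(report.per_fold, start=1):
        lines.append(f"{i}-Fold," + ",".join(f"{v:.2f}" for v in r.as_tuple()))
    lines.append("Avg.," + ",".join(f"{v:.2f}" for v in report.mean.as_tuple()))
    lines.append("S.D.," + ",".join(f"{v:.2f}" for v in report.sd.as_tuple()))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def report_to_json(report: ExperimentReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
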