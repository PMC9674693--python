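import dataclasses

import numpy as np
import pytest
from sklearn import metrics as skm

from conftest import toy_set
from echotype.classify import ClassifierTrainSpec, Conv1DClassifierSpec, Conv2DClassifierSpec
from echotype.denoise import AETrainSpec, AutoencoderSpec, NoiseSpec, latent_for_length
from echotype.evaluate import (
    AblationMode,
    MetricsReport,
    PipelineConfig,
    aggregate_folds,
    compute_metrics,
    confusion_counts,
    report_to_csv,
    run_ablation,
    run_cv_experiment,
    run_resolution_sweep,
)
from echotype.features import STFTSpec


def tiny_pipeline(n_samples=512):
    return PipelineConfig(
        noise=NoiseSpec(sigma_n=0.1, copies_per_signal=1),
        ae_spec=AutoencoderSpec(
            latent_dim=latent_for_length(n_samples),
            encoder_filters=(4, 4, 8, 8, 4, 2),
            decoder_filters=(4, 4, 8, 8, 4, 4),
        ),
        ae_train=AETrainSpec(epochs=2, learning_rate=0.003, loss="mse"),
        cnn1d_spec=Conv1DClassifierSpec(filters=(4, 4, 8, 8, 8, 8, 16), fc_widths=(32, 16)),
        cnn2d_spec=Conv2DClassifierSpec(filters=(4, 4, 8, 8, 8, 8, 16), fc_widths=(32, 16)),
        cnn_train=ClassifierTrainSpec(epochs=2),
    )


class TestMetrics:
    def test_printed_fold_f1_rounds_to_064(self):
        # tp=67, fp=33, fn=43 gives P = 0.67, R = 0.61 at 2 d.p.
        report = compute_metrics([1] * 67 + [0] * 33 + [1] * 43, [1] * 67 + [1] * 33 + [0] * 43)
        assert round(report.precision, 2) == 0.67
        assert round(report.recall, 2) == 0.61
        assert round(report.f1, 2) == 0.64

    def test_perfect_prediction(self):
        report = compute_metrics([1, 0, 1], [1, 0, 1])
        assert report.as_tuple() == (1.0, 1.0, 1.0, 1.0)

    def test_small_table_against_direct_counting(self):
        true_ = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        c = confusion_counts(true_, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 6)
        report = compute_metrics(true_, pred)
        assert report.accuracy == pytest.approx(0.8)
        assert report.precision == pytest.approx(2 / 3)
        assert report.recall == pytest.approx(2 / 3)
        assert report.f1 == pytest.approx(2 / 3)

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 40)
            t = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            r = compute_metrics(t, p)
            assert r.accuracy == pytest.approx(skm.accuracy_score(t, p))
            assert r.precision == pytest.approx(skm.precision_score(t, p, zero_division=0))
            assert r.recall == pytest.approx(skm.recall_score(t, p, zero_division=0))
            assert r.f1 == pytest.approx(skm.f1_score(t, p, zero_division=0))
            assert r.f1 <= max(r.precision, r.recall) + 1e-12
            if r.precision + r.recall > 0:
                assert min(r.precision, r.recall) - 1e-12 <= r.f1 <= (r.precision + r.recall) / 2 + 1e-12

    def test_zero_denominator_conventions(self):
        report = compute_metrics([0, 0], [0, 0])
        assert (report.precision, report.recall, report.f1) == (0.0, 0.0, 0.0)
        assert report.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [1])


class TestAggregation:
    def test_printed_f1_triple_gives_088_and_021(self):
        reports = [MetricsReport(1, 1, 1, f) for f in (0.64, 1.00, 1.00)]
        mean, sd = aggregate_folds(reports)
        assert round(mean.f1, 2) == 0.88
        assert round(sd.f1, 2) == 0.21  # sample SD; population SD would print 0.17

    def test_identical_folds_zero_sd(self):
        reports = [MetricsReport(0.9, 0.8, 0.7, 0.6)] * 3
        _, sd = aggregate_folds(reports)
        assert sd.as_tuple() == pytest.approx((0.0, 0.0, 0.0, 0.0), abs=1e-12)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([MetricsReport(1, 1, 1, 1)])


class TestExperiments:
    def test_raw_logit_on_separable_beads(self, small_dataset):
        report = run_cv_experiment(
            small_dataset, "spectrum", "logit", AblationMode.RAW, k=3, seed=0, pipeline=tiny_pipeline()
        )
        assert report.mean.accuracy >= 0.9
        assert len(report.per_fold) == 3

    def test_metrics_reproducible_exactly(self, small_dataset):
        kw = dict(representation="spectrum", model_family="logit", mode=AblationMode.RAW,
                  k=3, seed=7, pipeline=tiny_pipeline())
        r1 = run_cv_experiment(small_dataset, **kw)
        r2 = run_cv_experiment(small_dataset, **kw)
        assert [f.as_tuple() for f in r1.per_fold] == [f.as_tuple() for f in r2.per_fold]

    def test_dn_plus_pipeline_runs_and_reports(self, small_dataset):
        report = run_cv_experiment(
            small_dataset, "spectrum", "logit", AblationMode.DN_PLUS, k=3, seed=0,
            pipeline=tiny_pipeline(),
        )
        for fold in report.per_fold:
            for v in fold.as_tuple():
                assert 0.0 <= v <= 1.0
        assert report.config["mode"] == "DN+"

    def test_invalid_representation_model_pairing(self, small_dataset):
        with pytest.raises(ValueError, match="cnn2d"):
            run_cv_experiment(small_dataset, "spectrum", "cnn2d", AblationMode.RAW,
                              pipeline=tiny_pipeline())

    def test_ablation_produces_three_modes(self, small_dataset):
        reports = run_ablation(small_dataset, "spectrum", "logit", k=3, seed=1,
                               pipeline=tiny_pipeline())
        assert set(reports) == {"Raw", "DN", "DN+"}
        for mode, rep in reports.items():
            assert rep.config["mode"] == mode
            assert rep.config["k"] == 3

    def test_sweep_rows_and_skipping(self, small_dataset):
        pipeline = dataclasses.replace(tiny_pipeline(), stft=STFTSpec(32, 16))
        rows = run_resolution_sweep(
            small_dataset, model_family="logit", resolutions=[8, 1000], k=3, seed=0,
            pipeline=pipeline,
        )
        # 1000 exceeds both bin counts (257 spectrum bins, 17 spectrogram bins)
        assert {r["resolution"] for r in rows} == {8}
        assert {r["representation"] for r in rows} == {"spectrum", "spectrogram"}
        assert all(0 <= r["value"] <= 1 for r in rows)

    @pytest.mark.parametrize("family", ["logit", "svm", "mlp"])
    def test_permuted_labels_give_chance_for_baselines(self, small_dataset, family):
        import numpy as np

        from echotype.io import LabeledSignalSet, SignalRecord

        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(small_dataset.labels))
        null_set = LabeledSignalSet(
            [SignalRecord(r.id, r.samples, lab, {}) for r, lab in zip(small_dataset.records, shuffled)],
            positive_label=small_dataset.positive_label,
        )
        report = run_cv_experiment(null_set, "spectrum", family, AblationMode.RAW,
                                   k=3, seed=2, pipeline=tiny_pipeline())
        assert 0.3 <= report.mean.accuracy <= 0.7

    def test_report_csv_layout(self, small_dataset, tmp_path):
        report = run_cv_experiment(small_dataset, "spectrum", "logit", AblationMode.RAW,
                                   k=3, seed=0, pipeline=tiny_pipeline())
        out = tmp_path / "report.csv"
        report_to_csv(report, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "fold,accuracy,precision,recall,f1"
        assert len(lines) == 6  # 3 folds + Avg. + S.D.
        assert lines[-2].startswith("Avg.")
        assert lines[-1].startswith("S.D.")
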