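"""Cross-validation protocol: fold algebra, best-on-test tracking, training
reproducibility and the experiment matrices."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mducnn import (OptimizerConfig, ScheduleConfig, build_model,
                    count_parameters, cross_validate, kfold_split, train_model)
from mducnn.evaluation import (EpochRecord, FoldResult, run_augmentation_study,
                               run_variants)
from mducnn.metrics import aggregate_folds
from mducnn.models import mdu_config, unet_config


class TestKFold:
    def test_even_split(self):
        a = kfold_split(10, 5, seed=0)
        assert all(len(f) == 2 for f in a.folds)
        assert sorted(i for f in a.folds for i in f) == list(range(10))

    def test_remainder_to_earliest_folds(self):
        a = kfold_split(11, 5, seed=0)
        assert [len(f) for f in a.folds] == [3, 2, 2, 2, 2]

    def test_seeded_determinism(self):
        assert kfold_split(20, 4, seed=3) == kfold_split(20, 4, seed=3)

    @pytest.mark.parametrize("n,k", [(5, 6), (5, 1), (3, 0)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            kfold_split(n, k, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(n=st.integers(2, 200), k=st.integers(2, 20), seed=st.integers(0, 10 ** 6))
    def test_partition_properties(self, n, k, seed):
        if k > n:
            return
        a = kfold_split(n, k, seed)
        flat = [i for f in a.folds for i in f]
        assert sorted(flat) == list(range(n))            # coverage, disjointness
        sizes = [len(f) for f in a.folds]
        assert max(sizes) - min(sizes) <= 1              # balance
        for j in range(k):
            assert not set(a.folds[j]) & set(a.train_indices(j))


class TestBestTracking:
    def test_max_over_records(self):
        records = [EpochRecord(1, 1.0, 0.3), EpochRecord(2, 0.8, 0.6),
                   EpochRecord(3, 0.7, 0.5)]
        r = FoldResult.from_records(1, records)
        assert r.best_jaccard == pytest.approx(60.0)
        assert r.best_epoch == 2

    def test_best_never_decreases_with_more_epochs(self):
        rng = np.random.default_rng(0)
        records = [EpochRecord(i + 1, 1.0, float(v))
                   for i, v in enumerate(rng.random(20))]
        bests = [FoldResult.from_records(1, records[:n]).best_jaccard
                 for n in range(1, 21)]
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))


def tiny_cfg():
    return mdu_config(2, depth=2,
                      schedule=ScheduleConfig(mode="formula", base_filters=(4, 8, 16)))


class TestTraining:
    def test_reproducible_epoch_records(self, easy_samples_32):
        opt = OptimizerConfig(epochs=2, batch_size=4, seed=3)
        runs = []
        for _ in range(2):
            model = build_model(tiny_cfg())
            runs.append(train_model(model, easy_samples_32[:6],
                                    easy_samples_32[6:8], opt))
        assert runs[0].records == runs[1].records

    def test_empty_sets_rejected(self, easy_samples_32):
        model = build_model(tiny_cfg())
        opt = OptimizerConfig(epochs=1)
        with pytest.raises(ValueError):
            train_model(model, [], easy_samples_32[:2], opt)

    def test_optimizer_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(alpha1=1.0)
        with pytest.raises(ValueError):
            OptimizerConfig(epochs=0)


class TestCrossValidate:
    def test_partition_and_internal_consistency(self, easy_samples_32):
        opt = OptimizerConfig(epochs=1, batch_size=4, seed=1)
        report = cross_validate(tiny_cfg(), easy_samples_32, k=4, opt=opt, seed=2)
        assert len(report.fold_results) == 4
        mean, std = aggregate_folds(report.per_fold)
        assert report.mean == pytest.approx(mean)
        assert report.std == pytest.approx(std)

    def test_too_few_samples(self, easy_samples_32):
        with pytest.raises(ValueError):
            cross_validate(tiny_cfg(), easy_samples_32[:3], k=4,
                           opt=OptimizerConfig(epochs=1), seed=0)


class TestExperimentMatrices:
    def test_variant_table_layout(self, easy_samples_32):
        opt = OptimizerConfig(epochs=1, batch_size=4, seed=1)
        base = tiny_cfg()
        unet = unet_config(2, depth=2, unet_widths=(4, 8, 16))
        table, reports = run_variants(easy_samples_32[:8], k=2, opt=opt,
                                      base_config=base, unet_config=unet, seed=5)
        assert list(table.columns) == ["Type", "F = 1", "F = 2", "Avg"]
        assert len(table) == 4
        for _, row in table.iterrows():
            assert row["Avg"] == pytest.approx(
                np.mean([row["F = 1"], row["F = 2"]]), abs=1e-3)

    def test_paths_only_has_more_parameters_than_baseline(self, easy_samples_32):
        unet = unet_config(2, depth=2, unet_widths=(4, 8, 16))
        paths_only = replace(unet, skips="respath")
        assert (count_parameters(build_model(paths_only)).total_trainable
                > count_parameters(build_model(unet)).total_trainable)

    def test_augmentation_study_shapes(self, easy_samples_32):
        opt = OptimizerConfig(epochs=1, batch_size=4, seed=1)
        table, reports = run_augmentation_study(
            easy_samples_32[:6], k=2, opt=opt, mdu_cfg=tiny_cfg(),
            unet_cfg=unet_config(2, depth=2, unet_widths=(4, 8, 16)),
            factor=3, seed=4)
        assert len(table) == 4
        assert {"Without DA Traditional U-Net", "With DA MDU-CNN"} <= set(table["Type"])
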