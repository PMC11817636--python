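"""Cross-validated training: trace bookkeeping, determinism, continued vs
fresh strategies, hyperparameter search, and learning sanity."""

import numpy as np
import pytest

from mslesion.dataset import FoldPlan, make_fold_plan
from mslesion.models import spec_cnn2d
from mslesion.training import (PAPER_BATCH_RANGE, PAPER_LR_RANGE, TrainConfig,
                               TrainingDivergence, random_grid_search,
                               train_cross_validated)
from tests.conftest import make_random_cubes


@pytest.fixture(scope="module")
def small_data():
    return make_random_cubes({"nevus": 8, "melanoma": 8, "bcc": 8},
                             side=16, bands=2, seed=0)


@pytest.fixture(scope="module")
def small_plan(small_data):
    return make_fold_plan(small_data, test_fraction=0.25, folds=2, seed=0)


SPEC16 = spec_cnn2d((16, 16, 2), 3)


def quick_config(**over):
    base = dict(batch_size=4, learning_rate=1e-3, epochs_per_fold=2, seed=0)
    base.update(over)
    return TrainConfig(**base)


class TestProtocol:
    def test_trace_has_one_record_per_fold_epoch(self, small_data, small_plan):
        _, trace = train_cross_validated(SPEC16, small_data, small_plan,
                                         quick_config(epochs_per_fold=3))
        keys = [(r.fold, r.epoch) for r in trace.records]
        assert len(keys) == small_plan.fold_count * 3
        assert len(set(keys)) == len(keys)
        assert all(r.train_loss >= 0 and 0 <= r.val_accuracy <= 1
                   for r in trace.records)

    def test_same_seed_reproduces_validation_sequence(self, small_data,
                                                      small_plan):
        cfg = quick_config()
        _, t1 = train_cross_validated(SPEC16, small_data, small_plan, cfg)
        _, t2 = train_cross_validated(SPEC16, small_data, small_plan, cfg)
        assert t1.validation_accuracies() == t2.validation_accuracies()
        assert [r.train_loss for r in t1.records] == \
            [r.train_loss for r in t2.records]

    def test_single_fold_fresh_equals_continued(self, small_data, small_plan):
        """With one fold there is nothing to continue: both strategies are a
        plain train/validation run and give identical traces."""
        plan1 = FoldPlan(test_indices=small_plan.test_indices,
                         folds=small_plan.folds[:1], seed=0, test_fraction=0.25)
        _, t_cont = train_cross_validated(SPEC16, small_data, plan1,
                                          quick_config(strategy="continued"))
        _, t_fresh = train_cross_validated(SPEC16, small_data, plan1,
                                           quick_config(strategy="fresh_per_fold"))
        assert t_cont.validation_accuracies() == t_fresh.validation_accuracies()

    def test_strategies_diverge_after_first_fold(self, small_data, small_plan):
        """Continued training carries fold-0 learning into fold 1; a fresh
        model does not, so the fold-1 records differ."""
        _, t_cont = train_cross_validated(SPEC16, small_data, small_plan,
                                          quick_config(strategy="continued"))
        _, t_fresh = train_cross_validated(SPEC16, small_data, small_plan,
                                           quick_config(strategy="fresh_per_fold"))
        fold0_c = [r.val_loss for r in t_cont.records if r.fold == 0]
        fold0_f = [r.val_loss for r in t_fresh.records if r.fold == 0]
        assert fold0_c == fold0_f
        fold1_c = [r.val_loss for r in t_cont.records if r.fold == 1]
        fold1_f = [r.val_loss for r in t_fresh.records if r.fold == 1]
        assert fold1_c != fold1_f

    def test_class_weights_are_neutral_on_balanced_data(self, small_data,
                                                        small_plan):
        _, t_off = train_cross_validated(SPEC16, small_data, small_plan,
                                         quick_config(use_class_weights=False))
        _, t_on = train_cross_validated(SPEC16, small_data, small_plan,
                                        quick_config(use_class_weights=True))
        off = np.array([r.train_loss for r in t_off.records])
        on = np.array([r.train_loss for r in t_on.records])
        assert np.allclose(off, on, atol=1e-9)

    def test_divergence_reports_fold_and_epoch(self, small_data, small_plan):
        """A learning rate large enough to overflow the weights must abort
        with the offending fold and epoch, not return silently."""
        with np.errstate(all="ignore"), pytest.raises(TrainingDivergence) as err:
            train_cross_validated(SPEC16, small_data, small_plan,
                                  quick_config(learning_rate=1e300,
                                               epochs_per_fold=5))
        assert err.value.fold >= 0 and err.value.epoch >= 0

    def test_learning_sanity_on_separable_phantoms(self):
        """Capacity check: with wide class gaps in every band and the
        protocol's materialized augmentation, the small CNN fits the
        validation set within 20 epochs at a relaxed 1e-4 rate."""
        from mslesion.calibration import calibrate
        from mslesion.dataset import AugmentationPolicy, LabeledDataset
        from mslesion.phantom import (CLASS_NAMES, SimulationConfig,
                                      simulate_dataset)
        sim = SimulationConfig(frame_shape=(24, 24),
                               separability_mode="all_bands",
                               class_counts={c: 35 for c in CLASS_NAMES},
                               seed=5)
        data = LabeledDataset([calibrate(c) for c in simulate_dataset(sim)])
        plan = make_fold_plan(data, test_fraction=0.2, folds=2, seed=1)
        spec = spec_cnn2d((24, 24, 8), 3)
        cfg = TrainConfig(batch_size=2, learning_rate=1e-4,
                          epochs_per_fold=10, seed=1,
                          augmentation=AugmentationPolicy(factor=25),
                          materialize_augmentation=True)
        _, trace = train_cross_validated(spec, data, plan, cfg)
        assert trace.final_validation_accuracy >= 0.95

    def test_vgg3d_two_epoch_smoke_train(self):
        """The 3D VGG trains end to end (dropout active, He init) for a
        short smoke run with a complete, finite trace."""
        from mslesion.models import spec_vgg16_3d
        data = make_random_cubes({"nevus": 4, "melanoma": 4, "bcc": 4},
                                 side=16, bands=4, seed=1)
        plan = make_fold_plan(data, test_fraction=0.25, folds=2, seed=0)
        plan = FoldPlan(test_indices=plan.test_indices, folds=plan.folds[:1],
                        seed=0, test_fraction=0.25)
        spec = spec_vgg16_3d((16, 16, 4, 1), 3, dense_units=(16, 16))
        _, trace = train_cross_validated(
            spec, data, plan,
            TrainConfig(batch_size=3, learning_rate=1e-4, epochs_per_fold=2,
                        seed=0))
        assert len(trace.records) == 2
        assert all(np.isfinite(r.train_loss) and np.isfinite(r.val_loss)
                   for r in trace.records)

    def test_trace_csv(self, tmp_path, small_data, small_plan):
        _, trace = train_cross_validated(SPEC16, small_data, small_plan,
                                         quick_config())
        path = trace.to_csv(tmp_path / "trace.csv")
        df = trace.to_dataframe()
        assert path.exists()
        assert set(df.columns) >= {"fold", "epoch", "train_loss",
                                   "val_accuracy"}


class TestRandomGridSearch:
    def test_configs_within_printed_ranges_and_distinct(self):
        configs = random_grid_search(trials=5, seed=0)
        assert len(configs) == 5
        keys = {(c.batch_size, c.learning_rate) for c in configs}
        assert len(keys) == 5
        for c in configs:
            assert PAPER_BATCH_RANGE[0] <= c.batch_size <= PAPER_BATCH_RANGE[1]
            assert PAPER_LR_RANGE[0] <= c.learning_rate <= PAPER_LR_RANGE[1]

    def test_single_trial(self):
        assert len(random_grid_search(trials=1, seed=3)) == 1

    def test_seeded_reproducibility(self):
        a = random_grid_search(trials=8, seed=11)
        b = random_grid_search(trials=8, seed=11)
        assert [(c.batch_size, c.learning_rate) for c in a] == \
            [(c.batch_size, c.learning_rate) for c in b]

    def test_invalid_trials(self):
        with pytest.raises(ValueError):
            random_grid_search(trials=0)


class TestTrainConfigValidation:
    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(strategy="warm")
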