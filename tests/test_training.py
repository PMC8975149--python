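import numpy as np
import pandas as pd
import pytest

from canet import models, training
from canet.training import (
    AugmentConfig,
    TrainConfig,
    augment,
    average_precision,
    build_samples,
    evaluate,
    make_folds,
    nll,
    roc_auc,
    train,
)

from conftest import preprocess_series


# ---------------------------------------------------------------------------
# metrics


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_random_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.1

    def test_constant_scores_give_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                     for p in pos for q in neg]
            assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_is_undefined(self):
        assert np.isnan(roc_auc([0.1, 0.9], [1, 1]))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(a, abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_alternating_example(self):
        # thresholds: P=(1, 1/2, 2/3, 1/2), recall steps at n=1 and n=3
        ap = average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)

    def test_single_positive_ranked_last(self):
        assert average_precision([0.9, 0.1], [0, 1]) == pytest.approx(0.5)

    def test_no_positives_is_undefined(self):
        assert np.isnan(average_precision([0.9, 0.1], [0, 0]))

    def test_matches_sklearn_and_threshold_enumeration(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(50):
            n = int(rng.integers(3, 25))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, size=n)
            labels[int(rng.integers(n))] = 1
            # exhaustive enumeration of descending unique thresholds
            ap_ref, r_prev = 0.0, 0.0
            n_pos = labels.sum()
            for t in sorted(set(scores), reverse=True):
                sel = scores >= t
                p = labels[sel].sum() / sel.sum()
                r = labels[sel].sum() / n_pos
                ap_ref += (r - r_prev) * p
                r_prev = r
            ap = average_precision(scores, labels)
            assert ap == pytest.approx(ap_ref, abs=1e-12)
            assert ap == pytest.approx(
                sklearn_metrics.average_precision_score(labels, scores), abs=1e-9)

    def test_roc_auc_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores = np.round(rng.random(30), 1)
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            assert roc_auc(scores, labels) == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-9)


class TestNll:
    def test_certain_correct_is_zero(self):
        assert nll([1.0, 1.0, 1.0]) == 0.0

    def test_coin_flip_is_ln2(self):
        assert nll([0.5] * 4) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_fixture(self):
        p = [0.9, 0.8, 0.6, 0.3, 0.5]
        expected = -np.mean(np.log(p))
        assert nll(p) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_is_clipped(self):
        assert np.isfinite(nll([0.0, 1.0]))


# ---------------------------------------------------------------------------
# folds


def _fake_series(n_benign, n_malignant):
    from canet.volumes import LongitudinalSeries, NoduleVolume

    out = []
    for i in range(n_benign + n_malignant):
        label = "benign" if i < n_benign else "malignant"
        pid = f"p{i:03d}"
        vol = NoduleVolume(voxels=np.zeros((2, 2, 2)), spacing=(1, 1, 1),
                           patient_id=pid, interval=0, label=label,
                           bbox_center=(1, 1, 1))
        out.append(LongitudinalSeries(volumes=[vol], patient_id=pid, label=label))
    return out


class TestFolds:
    def test_one_patient_per_fold_when_k_equals_n(self):
        plan = make_folds(_fake_series(3, 2), k=5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [1, 1, 1, 1, 1]

    def test_balanced_assignment_100_patients(self):
        series = _fake_series(50, 50)
        plan = make_folds(series, k=5, seed=1)
        label = {s.patient_id: s.label for s in series}
        for fold in plan.folds:
            n_b = sum(label[p] == "benign" for p in fold)
            n_m = len(fold) - n_b
            assert abs(n_b - 10) <= 2 and abs(n_m - 10) <= 2

    def test_disjoint_and_covering_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            nb, nm = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            k = int(rng.integers(2, min(6, nb + nm)))
            series = _fake_series(nb, nm)
            plan = make_folds(series, k=k, seed=int(rng.integers(1000)))
            everyone = [p for f in plan.folds for p in f]
            assert len(everyone) == len(set(everyone)) == nb + nm

    def test_roles_partition_the_folds(self):
        plan = make_folds(_fake_series(10, 10), k=5, seed=0)
        tr, va, te = plan.roles(2)
        assert not (tr & va) and not (tr & te) and not (va & te)
        assert len(tr | va | te) == 20

    def test_fewer_patients_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_fake_series(2, 1), k=5, seed=0)

    def test_deterministic_under_seed(self):
        series = _fake_series(12, 8)
        assert make_folds(series, 4, seed=3).folds == make_folds(series, 4, seed=3).folds
        assert make_folds(series, 4, seed=3).folds != make_folds(series, 4, seed=4).folds


# ---------------------------------------------------------------------------
# augmentation


class TestAugment:
    def test_zero_magnitudes_are_exact_identity(self, rng):
        cfg = AugmentConfig(flip_prob=0, max_shift_frac=0, max_rotate_deg=0,
                            noise_sigma=0)
        vols = [rng.random((4, 8, 8)) for _ in range(2)]
        out = augment(vols, rng, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(vols, out))

    def test_unison_geometry_for_identical_volumes(self, rng):
        # same geometric transform on identical inputs: outputs differ only
        # by the independent per-volume noise
        cfg = AugmentConfig(noise_sigma=0.01)
        v = rng.random((4, 16, 16))
        out = augment([v, v.copy()], rng, cfg)
        diff = out[0] - out[1]
        assert abs(diff.mean()) < 0.005
        assert diff.std() == pytest.approx(np.sqrt(2) * 0.01, rel=0.2)

    def test_unison_geometry_is_exact_without_noise(self, rng):
        cfg = AugmentConfig(noise_sigma=0.0)
        v = rng.random((4, 16, 16))
        out = augment([v, v.copy()], rng, cfg)
        assert np.array_equal(out[0], out[1])

    def test_fixed_seed_reproducible(self, rng):
        v = rng.random((4, 8, 8))
        a = augment([v], np.random.default_rng(3), AugmentConfig())
        b = augment([v], np.random.default_rng(3), AugmentConfig())
        assert np.array_equal(a[0], b[0])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            augment([rng.random((4, 8, 8)), rng.random((4, 9, 8))], rng)


# ---------------------------------------------------------------------------
# training + evaluation on a small phantom set


def _tiny_can(m=1, seed=0):
    cfg = models.ModelConfig(variant="CAN", M_branches=m,
                             backbone=models.BackboneSpec(name="tiny_test"))
    return models.build_can(cfg, rng=seed)


@pytest.fixture(scope="module")
def quick_config():
    return TrainConfig(batch_size=16, learning_rate=1e-3, max_epochs=3,
                       patience=3, seed=0, augment=None)


class TestTrainLoop:
    def test_loss_decreases_and_history_shape(self, small_cohort_tiny, quick_config):
        plan = make_folds(small_cohort_tiny, k=4, seed=0)
        model = _tiny_can()
        hist = train(model, small_cohort_tiny, plan, 0, quick_config)
        assert list(hist.columns) == ["epoch", "train_loss", "val_loss"]
        assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]

    def test_same_seed_gives_identical_history(self, small_cohort_tiny, quick_config):
        plan = make_folds(small_cohort_tiny, k=4, seed=0)
        hists = [train(_tiny_can(), small_cohort_tiny, plan, 0, quick_config)
                 for _ in range(2)]
        pd.testing.assert_frame_equal(hists[0], hists[1])

    def test_empty_split_rejected(self, small_cohort_tiny, quick_config):
        plan = make_folds(small_cohort_tiny, k=4, seed=0)
        benign_only = [s for s in small_cohort_tiny if s.label == "benign"]
        empty_plan = type(plan)(folds=[[s.patient_id for s in benign_only], [], [], []])
        with pytest.raises(ValueError, match="empty"):
            train(_tiny_can(), benign_only, empty_plan, 0, quick_config)


class TestBuildSamples:
    def test_single_branch_uses_every_volume(self, small_cohort_tiny):
        X, y, table = build_samples(small_cohort_tiny, 1)
        n_vols = sum(len(s) for s in small_cohort_tiny)
        assert X.shape[0] == n_vols == len(y) == len(table)

    def test_two_branch_uses_consecutive_pairs_only(self, small_cohort_tiny):
        X, y, table = build_samples(small_cohort_tiny, 2)
        assert X.shape[1] == 2
        expected = sum(max(0, len(s) - 1) for s in small_cohort_tiny
                       if s.intervals == list(range(s.intervals[0],
                                                    s.intervals[0] + len(s))))
        assert X.shape[0] == expected

    def test_triplet_requires_three_consecutive(self, small_cohort_tiny):
        X, y, _ = build_samples(small_cohort_tiny, 3)
        n3 = sum(1 for s in small_cohort_tiny if s.intervals == [0, 1, 2])
        assert X.shape[0] == n3


class TestEvaluate:
    def test_interval_filter_restricts_samples(self, small_cohort_tiny):
        model = _tiny_can()
        rep_all = evaluate(model, small_cohort_tiny, "all")
        rep_t1 = evaluate(model, small_cohort_tiny, 1)
        n_t1 = sum(1 for s in small_cohort_tiny for v in s.volumes if v.interval == 1)
        assert rep_t1.n_samples == n_t1 < rep_all.n_samples
        assert set(rep_t1.predictions.intervals) == {"1"}

    def test_perfect_and_coin_flip_metrics(self):
        rep_auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert rep_auc == 1.0
        assert average_precision([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert nll([0.5] * 6) == pytest.approx(np.log(2))

    def test_single_class_set_flagged_with_nll_still_computed(self, small_cohort_tiny):
        model = _tiny_can()
        benign_only = [s for s in small_cohort_tiny if s.label == "benign"]
        rep = evaluate(model, benign_only, "all")
        assert np.isnan(rep.auc) and np.isnan(rep.ap)
        assert np.isfinite(rep.nll)
        assert "single-class" in rep.note
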