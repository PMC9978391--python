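import numpy as np
import pytest

from dwisr.io import DWIVolume
from dwisr.metrics import MetricReport
from dwisr.network import SRCNNSpec, init_model
from dwisr.phantom import PhantomSpec, generate_phantom
from dwisr.resample import ResampleSpec
from dwisr.training import (
    AdaGrad,
    BValueGroup,
    ConfigError,
    SuperResolution3D,
    TrainingLog,
    TrainingPair,
    TrainingSpec,
    build_pairs,
    group_by_bvalue,
    select_best_checkpoint,
    train,
)


def _report(psnr, ssim=1.0, cosine=1.0):
    return MetricReport(psnr=psnr, ssim=ssim, cosine=cosine, mse=0.1, imax=1.0)


class TestBuildPairs:
    def test_one_pair_per_gradient_same_dims(self):
        vol = generate_phantom(PhantomSpec(grid_shape=(12, 12, 9), noise_sigma=0.0))
        pairs = build_pairs(vol, ResampleSpec())
        assert len(pairs) == vol.n_gradients
        for p in pairs:
            assert p.source.shape == p.target.shape == (12, 12, 9)

    def test_non_divisible_volume_zero_padded(self):
        data = np.random.default_rng(0).random((10, 11, 7, 2))
        vol = DWIVolume(data=data, voxel_size=(1, 1, 1), bvals=[0.0, 1000.0],
                        bvecs=[[0, 0, 0], [1, 0, 0]])
        pairs = build_pairs(vol, ResampleSpec())
        assert pairs[0].target.shape == (12, 12, 9)
        np.testing.assert_array_equal(pairs[0].target[:10, :11, :7], data[..., 0])
        assert np.all(pairs[0].target[10:] == 0)

    def test_constant_target_gives_identical_source(self):
        data = np.full((6, 6, 6, 1), 4.0)
        vol = DWIVolume(data=data, voxel_size=(1, 1, 1), bvals=[0.0],
                        bvecs=[[0, 0, 0]])
        pairs = build_pairs(vol, ResampleSpec())
        np.testing.assert_allclose(pairs[0].source, pairs[0].target, atol=1e-12)


class TestGrouping:
    def test_canonical_three_groups(self):
        pairs = [
            TrainingPair(None, None, b) for b in (0.0, 1000.0, 1500.0, 2000.0, 0.0)
        ]
        groups = group_by_bvalue(pairs)
        assert [g.label for g in groups] == ["b0b1000", "b1500", "b2000"]
        assert len(groups[0].pairs) == 3  # b=0 merged with b=1000
        assert len(groups[1].pairs) == 1
        assert len(groups[2].pairs) == 1

    def test_all_pairs_one_shell(self):
        groups = group_by_bvalue([TrainingPair(None, None, 1500.0)] * 4)
        sizes = {g.label: len(g.pairs) for g in groups}
        assert sizes == {"b0b1000": 0, "b1500": 4, "b2000": 0}

    def test_unknown_bvalue_named_in_error(self):
        with pytest.raises(ConfigError, match="700"):
            group_by_bvalue([TrainingPair(None, None, 700.0)])


class TestAdaGrad:
    def test_matches_hand_rolled_scalar_quadratic(self):
        # minimize (theta - 1)^2 from theta = 0; oracle recursion:
        # g = 2(theta-1); acc += g^2; theta -= lr*g/sqrt(acc+eps)
        lr, eps = 0.1, 1e-8
        theta_oracle, acc = 0.0, 0.0
        expected = []
        for _ in range(10):
            g = 2.0 * (theta_oracle - 1.0)
            acc += g * g
            theta_oracle -= lr * g / np.sqrt(acc + eps)
            expected.append(theta_oracle)

        p = np.array(0.0)
        opt = AdaGrad([p], learning_rate=lr, epsilon=eps)
        got = []
        for _ in range(10):
            g = np.array(2.0 * (p - 1.0))
            opt.step([g])
            got.append(float(p))
        np.testing.assert_allclose(got, expected, atol=1e-12, rtol=0)


def _tiny_group(n_pairs=3, size=9, seed=0, subjects=None):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        t = rng.random((size, size, size))
        s = t + rng.normal(0, 0.05, t.shape)
        subj = subjects[i] if subjects else i
        pairs.append(TrainingPair(source=s, target=t, bval=1500.0, subject=subj))
    return BValueGroup("b1500", frozenset({1500.0}), pairs)


class TestTrainLoop:
    def test_loss_decreases_on_fixed_pair(self):
        group = _tiny_group(n_pairs=1)
        model = init_model(SRCNNSpec(seed=0))
        spec = TrainingSpec(epochs=100, max_iterations=100, checkpoint_interval=10**6)
        _, log = train(group, model, spec)
        assert log.losses[-1] < log.losses[0]

    def test_determinism(self):
        group = _tiny_group(n_pairs=2)
        spec = TrainingSpec(epochs=5, seed=3, checkpoint_interval=10**6)
        m1, log1 = train(group, init_model(SRCNNSpec(seed=0)), spec)
        m2, log2 = train(group, init_model(SRCNNSpec(seed=0)), spec)
        assert log1.losses == log2.losses
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_cadence_and_final_checkpoint(self):
        group = _tiny_group(n_pairs=3)
        spec = TrainingSpec(epochs=3, checkpoint_interval=4)
        _, log = train(group, init_model(SRCNNSpec(seed=0)), spec)
        assert log.checkpoint_ids() == [4, 8, 9]  # 9 iterations total

    def test_subject_loss_is_mean_of_member_iterations(self):
        group = _tiny_group(n_pairs=4, subjects=["a", "a", "b", "b"])
        spec = TrainingSpec(epochs=1, checkpoint_interval=10**6)
        _, log = train(group, init_model(SRCNNSpec(seed=0)), spec)
        for subject, _epoch, agg in log.subject_losses:
            member = [l for _, s, l in log.iterations if s == subject]
            assert agg == pytest.approx(np.mean(member), rel=1e-12)

    def test_empty_group_rejected(self):
        group = BValueGroup("b2000", frozenset({2000.0}), [])
        with pytest.raises(ValueError):
            train(group, init_model(SRCNNSpec()), TrainingSpec())


class TestCheckpointSelection:
    def _log(self, ids):
        log = TrainingLog()
        log.checkpoints = [(i, None) for i in ids]
        return log

    def test_single_checkpoint(self):
        assert select_best_checkpoint(self._log([5]), [_report(30.0)]) == 5

    def test_argmax_of_product(self):
        reports = [_report(30, 0.90, 1.0), _report(30, 0.95, 1.0), _report(30, 0.93, 1.0)]
        assert select_best_checkpoint(self._log([1, 2, 3]), reports) == 2

    def test_tie_breaks_to_earlier(self):
        reports = [_report(30, 0.9, 1.0), _report(30, 0.9, 1.0)]
        assert select_best_checkpoint(self._log([10, 20]), reports) == 10

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint(self._log([1]), [])


class TestModelResultsFrontEnd:
    def test_fit_returns_results_with_summary(self):
        vols = [
            generate_phantom(PhantomSpec(grid_shape=(12, 12, 9), noise_sigma=1.0, seed=s))
            for s in (0, 1)
        ]
        model = SuperResolution3D(
            vols,
            srcnn_spec=SRCNNSpec(seed=0),
            training_spec=TrainingSpec(epochs=1, checkpoint_interval=10**6),
        )
        res = model.fit()
        assert set(res.group_labels) == {"b0b1000", "b1500", "b2000"}
        assert all(l >= 0 for l in res.final_losses().values())
        assert all(len(log.losses) > 0 for log in res.logs.values())
        text = res.summary()
        assert "b1500" in text and "AdaGrad" in text

    def test_missing_shell_warns_and_trains_fewer_models(self):
        data = np.random.default_rng(0).random((6, 6, 6, 2))
        vol = DWIVolume(data=data, voxel_size=(1, 1, 1),
                        bvals=[0.0, 1000.0], bvecs=[[0, 0, 0], [1, 0, 0]])
        with pytest.warns(UserWarning, match="b2000"):
            model = SuperResolution3D(
                [vol], training_spec=TrainingSpec(epochs=1, checkpoint_interval=10**6)
            )
        res = model.fit()
        assert res.group_labels == ["b0b1000"]
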