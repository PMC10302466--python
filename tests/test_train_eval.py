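"""Tests for condition splitting, dataset assembly, training and evaluation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pointrdf.datatypes import Condition
from pointrdf.pointcloud_model import ModelSpec, PointNetRDF, build_model
from pointrdf.rdf_core import RadialGrid, average_rdf, snapshot_rdf
from pointrdf.train_eval import (
    ConditionSplit,
    TrainConfig,
    TrainingSample,
    build_dataset,
    evaluate,
    split_conditions,
    train,
)


class TestSplitConditions:
    @pytest.mark.parametrize(
        "n,expected",
        [(400, (320, 40, 40)), (200, (160, 20, 20)), (5, (3, 1, 1))],
    )
    def test_published_split_sizes(self, n, expected):
        split = split_conditions([f"c{i}" for i in range(n)], seed=0)
        assert (
            len(split.train), len(split.validation), len(split.test)
        ) == expected

    @given(st.integers(5, 80), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_properties(self, n, seed):
        ids = [f"c{i}" for i in range(n)]
        split = split_conditions(ids, seed=seed)
        subsets = [set(split.train), set(split.validation), set(split.test)]
        assert all(subsets)
        assert not (subsets[0] & subsets[1] or subsets[0] & subsets[2]
                    or subsets[1] & subsets[2])
        assert subsets[0] | subsets[1] | subsets[2] == set(ids)

    def test_deterministic_given_seed(self):
        ids = [f"c{i}" for i in range(20)]
        assert split_conditions(ids, seed=3) == split_conditions(ids, seed=3)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_conditions([f"c{i}" for i in range(10)], (0.5, 0.2, 0.2))

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            split_conditions(["a", "b", "c"])

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError):
            ConditionSplit(train=("a", "b"), validation=("b",), test=("c",))


class TestBuildDataset:
    def test_window_counting_and_shared_targets(self, liquid_trajectory):
        trajs = {"liq-T1.0": liquid_trajectory}
        grid = RadialGrid.for_box(liquid_trajectory[0].box, r_max=3.0)
        samples, truths, _ = build_dataset(trajs, grid, input_window=0.2)
        # 20% of 50 frames -> 10 samples, all sharing one target
        assert len(samples) == 10
        targets = {tuple(s.target) for s in samples}
        assert len(targets) == 1

    def test_stride_halves_sample_count(self, liquid_trajectory):
        trajs = {"liq-T1.0": liquid_trajectory}
        grid = RadialGrid.for_box(liquid_trajectory[0].box, r_max=3.0)
        samples, _, _ = build_dataset(trajs, grid, input_window=0.2, stride=2)
        assert len(samples) == 5

    def test_target_equals_full_trajectory_average(self, liquid_trajectory):
        trajs = {"liq-T1.0": liquid_trajectory}
        grid = RadialGrid.for_box(liquid_trajectory[0].box, r_max=3.0)
        samples, truths, _ = build_dataset(trajs, grid)
        independent = average_rdf(
            [snapshot_rdf(s, (0, 0), grid) for s in liquid_trajectory]
        )
        assert np.allclose(samples[0].target, independent.g, atol=1e-12)
        assert truths["liq-T1.0"].curves[(0, 0)].n_frames_averaged == 50

    def test_normalizer_fit_on_training_conditions_only(
        self, liquid_trajectory
    ):
        # five pseudo-conditions sharing one trajectory but different labels
        trajs = {}
        for i, t in enumerate((0.9, 1.0, 1.1, 1.2, 1.3)):
            traj = liquid_trajectory
            cond = Condition(t, 0.8, f"c{i}")
            from pointrdf.datatypes import Trajectory

            trajs[f"c{i}"] = Trajectory(
                condition=cond,
                snapshots=[
                    s.copy() for s in liquid_trajectory[:5]
                ],
                sample_interval=traj.sample_interval,
            )
            for s in trajs[f"c{i}"].snapshots:
                s.condition = cond
        grid = RadialGrid.for_box(liquid_trajectory[0].box, r_max=3.0)
        split = split_conditions(sorted(trajs), seed=1)
        _, _, normalizer = build_dataset(trajs, grid, split=split)
        fit_temps = [
            trajs[cid].condition.temperature for cid in split.train
        ]
        assert normalizer.state_mean[1] == pytest.approx(np.mean(fit_temps))


def _synthetic_samples(n_conditions=6, frames_per=4, n_points=8, seed=0):
    """Tiny dataset whose target curve is a smooth function of the state
    scalars, learnable by a small head in a few epochs."""
    rng = np.random.default_rng(seed)
    bins = np.linspace(0, 1, 20)
    samples = []
    for c in range(n_conditions):
        t = 0.8 + 0.1 * c
        target = np.exp(-((bins - 0.3 - 0.2 * t) ** 2) / 0.02)
        for _ in range(frames_per):
            samples.append(
                TrainingSample(
                    point_features=rng.normal(size=(n_points, 6)),
                    state_scalars=np.array([0.0, t]),
                    target=target,
                    condition_id=f"c{c}",
                )
            )
    return samples


TOY_SPEC = ModelSpec(
    n_point_features=6,
    n_output_pairs=1,
    n_bins_per_pair=20,
    pointwise_layer_widths=(8, 16),
    head_layer_widths=(16,),
)


def _toy_split():
    return ConditionSplit(
        train=("c0", "c1", "c2", "c3"), validation=("c4",), test=("c5",)
    )


class TestTrain:
    def test_early_stopping_and_best_restore(self):
        samples = _synthetic_samples()
        config = TrainConfig(max_epochs=300, patience=5, batch_size=4, seed=1)
        model, history = train(build_model(TOY_SPEC, 0), samples, _toy_split(), config)
        best_epoch = int(history["val_mse"].idxmin())
        assert len(history) <= best_epoch + 1 + config.patience
        # restored parameters reproduce the best recorded validation MSE
        val = [s for s in samples if s.condition_id == "c4"]
        X = np.stack([s.point_features for s in val])
        S = np.stack([s.state_scalars for s in val])
        Y = np.stack([s.target for s in val])
        mse = float(np.mean((model.forward_batch(X, S) - Y) ** 2))
        assert mse == pytest.approx(history["val_mse"].min(), rel=1e-9)

    def test_best_validation_monotone_non_increasing(self):
        samples = _synthetic_samples()
        config = TrainConfig(max_epochs=40, patience=40, batch_size=4, seed=1)
        _, history = train(build_model(TOY_SPEC, 0), samples, _toy_split(), config)
        best = history["best_val_mse"].to_numpy()
        assert np.all(np.diff(best) <= 0)

    def test_deterministic_given_seeds(self):
        samples = _synthetic_samples()
        config = TrainConfig(max_epochs=15, patience=15, batch_size=4, seed=7)
        _, h1 = train(build_model(TOY_SPEC, 3), samples, _toy_split(), config)
        _, h2 = train(build_model(TOY_SPEC, 3), samples, _toy_split(), config)
        assert h1["val_mse"].iloc[-1] == h2["val_mse"].iloc[-1]

    def test_empty_subsets_rejected(self):
        samples = [s for s in _synthetic_samples() if s.condition_id != "c4"]
        config = TrainConfig(max_epochs=5)
        with pytest.raises(ValueError):
            train(build_model(TOY_SPEC, 0), samples, _toy_split(), config)


class _OracleModel(PointNetRDF):
    """Returns the exact target regardless of input — the upper bound."""

    def __init__(self, spec, target):
        super().__init__(spec, [], [])
        self._target = target

    def forward_batch(self, X, S, cache=False):
        out = np.tile(self._target, (X.shape[0], 1))
        return (out, None) if cache else out


class TestEvaluate:
    def test_oracle_model_scores_perfectly(self, liquid_trajectory):
        from pointrdf.pointcloud_model import FeatureNormalizer

        trajs = {"liq-T1.0": liquid_trajectory}
        grid = RadialGrid.for_box(liquid_trajectory[0].box, r_max=3.0)
        samples, truths, normalizer = build_dataset(trajs, grid)
        spec = ModelSpec(
            n_point_features=normalizer.n_point_features,
            n_output_pairs=1,
            n_bins_per_pair=grid.n_bins,
        )
        oracle = _OracleModel(spec, truths["liq-T1.0"].concatenated())
        report = evaluate(oracle, samples, truths, normalizer)
        assert report.summary["mean_r2"] == pytest.approx(1.0)
        assert report.summary["mean_eps_model"] == pytest.approx(0.0, abs=1e-30)
        assert report.summary["mu_re"] == pytest.approx(0.0, abs=1e-15)
        # the MD baseline on the same frames is strictly worse
        assert report.summary["mean_eps_md"] > 0.0

    def test_no_samples_rejected(self, liquid_trajectory):
        from pointrdf.pointcloud_model import FeatureNormalizer

        nz = FeatureNormalizer(n_species=1, grid=RadialGrid(3.0, 50))
        with pytest.raises(ValueError):
            evaluate(build_model(TOY_SPEC, 0), [], {}, nz)
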