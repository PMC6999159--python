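import numpy as np
import pandas as pd
import pytest

from cfnet import (
    Schedule,
    SyntheticConfig,
    build_network,
    generate_synthetic,
    normalize_rates,
    run_baseline,
    run_schedule,
    sweep,
    trigger_statistics,
)
from cfnet.protocols import (
    UNASSIGNED,
    assign_labels,
    classify,
    labels_from_counts,
    reports_to_frame,
    save_reports,
    synthetic_study_config,
)


@pytest.fixture(scope="module")
def small_config():
    return synthetic_study_config(n_neurons=8)


@pytest.fixture(scope="module")
def trained_small(small_config):
    """A CFN trained on the cheap two-class dataset, plus its splits."""
    ds = generate_synthetic(
        SyntheticConfig(n_classes=2, clusters_per_class=2, samples_per_class=16, seed=7)
    )
    net = build_network(small_config, np.random.default_rng(0))
    reports = run_schedule(net, ds, Schedule("disjoint", 1), seed=0)
    return net, ds, reports


class TestLabelDecision:
    def test_majority_and_tie_rules(self):
        counts = np.array(
            [
                [0.0, 0.0, 12.0, 0.0],  # clear class 2
                [10.0, 0.0, 0.0, 10.0],  # tie -> lowest class index
                [0.0, 0.0, 0.0, 0.0],  # silent -> unassigned
            ]
        )
        np.testing.assert_array_equal(labels_from_counts(counts), [2, 0, UNASSIGNED])

    def test_requires_frozen_network(self, trained_small):
        net, ds, _ = trained_small
        assert not net.frozen
        with pytest.raises(ValueError, match="frozen"):
            assign_labels(net, ds.samples[:2], ds.labels[:2])

    def test_assignment_deterministic_on_frozen_net(self, trained_small):
        net, ds, _ = trained_small
        net.freeze()
        try:
            a = assign_labels(net, ds.samples[:16], ds.labels[:16])
            b = assign_labels(net, ds.samples[:16], ds.labels[:16])
        finally:
            net.unfreeze()
        np.testing.assert_array_equal(a, b)


class TestClassify:
    def test_matched_sample_gets_its_class(self, trained_small):
        net, ds, _ = trained_small
        net.freeze()
        try:
            label_map = assign_labels(net, ds.samples, ds.labels)
            for cls in (0, 1):
                i = int(ds.class_indices(cls)[0])
                pred, fallback = classify(net, label_map, ds.samples[i])
                assert pred == cls
        finally:
            net.unfreeze()

    def test_predictions_deterministic(self, trained_small):
        net, ds, _ = trained_small
        net.freeze()
        try:
            label_map = assign_labels(net, ds.samples[:8], ds.labels[:8])
            preds = [classify(net, label_map, ds.samples[3]) for _ in range(2)]
        finally:
            net.unfreeze()
        assert preds[0] == preds[1]


class TestRunSchedule:
    def test_disjoint_stage_shapes(self, trained_small):
        _, ds, reports = trained_small
        assert len(reports) == 2
        for k, rep in enumerate(reports):
            assert rep.seen_classes == list(range(k + 1))
            # evaluation covers exactly the classes seen so far
            assert sorted(rep.per_class_accuracy) == list(range(k + 1))
            assert sorted(rep.per_class_false_positives) == list(range(k + 1))
            assert 0.0 <= rep.combined_accuracy <= 1.0
            assert len(rep.dopamine_triggers) > 0

    def test_combined_is_weighted_mean_of_per_class(self, trained_small):
        _, ds, reports = trained_small
        rep = reports[-1]
        # equal class sizes in the test split -> plain mean
        expected = np.mean([rep.per_class_accuracy[c] for c in rep.seen_classes])
        assert rep.combined_accuracy == pytest.approx(expected)

    def test_random_weights_training_is_noop(self, small_config):
        ds = generate_synthetic(
            SyntheticConfig(
                n_classes=2, clusters_per_class=2, samples_per_class=16, seed=7
            )
        )
        cfg = small_config.replace(variant="random_weights")
        net = build_network(cfg, np.random.default_rng(1))
        before = net.W.copy()
        run_schedule(net, ds, Schedule("disjoint", 1), seed=1)
        assert net.W.tobytes() == before.tobytes()

    def test_missing_class_in_schedule_rejected(self, small_config, small_dataset):
        net = build_network(small_config, np.random.default_rng(0))
        sched = Schedule("disjoint", 1, class_order=[0, 1, 5])
        with pytest.raises(ValueError, match="absent"):
            run_schedule(net, small_dataset, sched, seed=0)

    def test_report_serialization(self, trained_small, tmp_path):
        _, _, reports = trained_small
        frame = reports_to_frame(reports, "cfn")
        assert {"stage", "seed", "variant", "combined_acc"} <= set(frame.columns)
        save_reports(reports, tmp_path / "reports.json")
        assert (tmp_path / "reports.json").stat().st_size > 100

    def test_run_baseline_validates_variant(self, small_config, small_dataset):
        with pytest.raises(ValueError, match="baseline"):
            run_baseline("cfn", small_dataset, Schedule("disjoint", 1), small_config)


class TestSweep:
    def test_grid_shape_best_flag_and_reproducibility(self, small_config):
        ds = generate_synthetic(
            SyntheticConfig(
                n_classes=2, clusters_per_class=2, samples_per_class=12, seed=7
            )
        )
        sched = Schedule("disjoint", 1)
        tables = [
            sweep(small_config, ds, sched, [13.5, 13.75], [1, 2], seed=3)
            for _ in range(2)
        ]
        table = tables[0]
        assert len(table) == 4
        assert table["best"].sum() == 1
        assert table.loc[table["best"], "train_accuracy"].iloc[0] == pytest.approx(
            table["train_accuracy"].max()
        )
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_empty_grid_rejected(self, small_config, small_dataset):
        with pytest.raises(ValueError):
            sweep(small_config, small_dataset, Schedule("disjoint", 1), [], [1])

    def test_threshold_above_steady_state_forces_escalation(self, small_config):
        """With v_th >= tau_mem no neuron can reach threshold at base rates
        (steady-state mean <= tau_mem for unit vectors): every inference
        needs rate escalation, while a tuned threshold rarely does."""
        from cfnet.simulator import present_sample

        ds = generate_synthetic(
            SyntheticConfig(
                n_classes=2, clusters_per_class=2, samples_per_class=12, seed=7
            )
        )
        counts = {}
        for v_th in (20.0, 13.5):
            cfg = small_config.replace(v_th=v_th, max_escalation_steps=4)
            net = build_network(cfg, np.random.default_rng(0))
            run_schedule(net, ds, Schedule("disjoint", 1), seed=0)
            net.freeze()
            steps = []
            for x in ds.samples[::4]:
                r = present_sample(net, normalize_rates(x), "infer")
                steps.append(r.escalation_steps)
            net.unfreeze()
            counts[v_th] = steps
        assert all(s >= 1 for s in counts[20.0])
        assert np.mean([s == 0 for s in counts[13.5]]) > 0.8


class TestTriggerStatistics:
    def test_empty_log_gives_empty_curve(self):
        assert trigger_statistics([]).empty

    def test_disjoint_novelty_declines_within_tasks(self, trained_small):
        _, _, reports = trained_small
        stats = trigger_statistics(reports)
        assert len(stats) == 2
        # the first task always starts from an untrained network: novelty
        # triggers concentrate at the start
        first = stats.iloc[0]
        assert first.first_decile_mean >= first.last_decile_mean
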