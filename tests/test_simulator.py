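import numpy as np
import pytest

from cfnet import (
    EventStream,
    RunConfig,
    build_network,
    normalize_rates,
    present_sample,
    run_spike_train,
)
from cfnet.plasticity import cap_and_normalize
from cfnet.protocols import synthetic_study_config


def planted_network(cfg, directions, rng_seed=0):
    """Network whose first rows are cap-normalized copies of ``directions``."""
    net = build_network(cfg, np.random.default_rng(rng_seed))
    for j, direction in enumerate(directions):
        net.W[j] = cap_and_normalize(np.asarray(direction, dtype=float), cfg.w_cap)
    return net


class TestBuildNetwork:
    def test_rows_unit_norm(self, study_config):
        net = build_network(study_config, 3)
        np.testing.assert_allclose(np.linalg.norm(net.W, axis=1), 1.0, atol=1e-12)
        assert net.W.shape == (32, 64)
        assert abs(np.linalg.norm(net.d) - 1.0) < 1e-12

    def test_deterministic_under_seed(self, study_config):
        a = build_network(study_config, 9)
        b = build_network(study_config, 9)
        assert a.W.tobytes() == b.W.tobytes()
        assert a.d.tobytes() == b.d.tobytes()

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            RunConfig(variant="nope")

    def test_baselines_have_no_dopamine_unit(self, study_config):
        net = build_network(study_config.replace(variant="no_dopamine"), 0)
        assert net.d is None and net.dopamine is None
        net = build_network(
            study_config.replace(variant="no_dopamine_homeostasis"), 0
        )
        assert net.homeostasis is not None


class TestLateralInhibition:
    def test_hard_winner_take_all(self, study_config):
        net = build_network(study_config, 0)
        net.v[:2] = [13.9, 13.8]
        net.v[0] = 0.0  # winner reset happens before inhibition in _handle_fire
        net.apply_lateral_inhibition(0, plastic=False)
        assert np.all(net.v == 0.0)

    def test_subtractive_mode(self, study_config):
        cfg = study_config.replace(inhibition="subtractive", inhibition_amount=5.0)
        net = build_network(cfg, 0)
        net.v[:2] = [13.9, 13.8]
        net.apply_lateral_inhibition(0, plastic=False)
        assert net.v[1] == pytest.approx(8.8)
        assert net.v[0] == 0.0

    def test_inhibition_resets_boosted_alpha(self, study_config):
        net = build_network(study_config, 0)
        net.alphas.boost_all()
        net.alphas.values[0] = net.cfg.alpha_base  # the winner, already reset
        net.apply_lateral_inhibition(0, plastic=True)
        assert np.all(net.alphas.values == net.cfg.alpha_base)


class TestDopamineStimulation:
    def test_max_d_neuron_fires_at_kappa_one(self, study_config):
        net = build_network(study_config, 4)
        target = int(np.argmax(net.d))
        winner = net.fire_dopamine(plastic=False)
        assert winner == target

    def test_kappa_below_one_gives_no_immediate_fire(self, study_config):
        net = build_network(study_config.replace(kappa=0.5), 4)
        assert net.fire_dopamine(plastic=False) is None
        assert np.all(net.alphas.values == 1.0)

    def test_frozen_inference_never_fires_dopamine(self, study_config, synth_dataset):
        net = build_network(study_config, 0)
        net.freeze()
        r = present_sample(net, normalize_rates(synth_dataset.samples[0]), "infer")
        assert r.dopamine_fires == 0


class TestPresentSample:
    def test_matched_neuron_recognizes_quickly(self, study_config, synth_dataset):
        lam = normalize_rates(synth_dataset.samples[0])
        net = planted_network(study_config, [lam.rates])
        r = present_sample(net, lam, "train")
        assert r.total_spikes == study_config.recognize_spikes
        assert set(r.winners) == {0}
        assert r.dopamine_fires == 0
        assert 0 < r.duration < 1000

    def test_orthogonal_input_triggers_isolated_adoption(self, study_config):
        # all weights on the first 32 channels, input on the last 16
        rng = np.random.default_rng(3)
        dirs = np.zeros((8, 64))
        dirs[:, :32] = rng.uniform(0.1, 1.0, size=(8, 32))
        cfg = study_config.replace(n_neurons=8)
        net = planted_network(cfg, dirs)
        before = net.W.copy()
        lam = np.zeros(64)
        lam[48:] = 1.0
        r = present_sample(net, normalize_rates(lam), "train")
        assert r.dopamine_fires >= 1
        changed = np.flatnonzero(np.abs(net.W - before).max(axis=1) > 1e-12)
        assert len(changed) == 1
        lam_unit = normalize_rates(lam).rates
        assert net.W[changed[0]] @ lam_unit >= 0.95

    def test_frozen_network_is_untouched(self, study_config, synth_dataset):
        net = build_network(study_config, 0)
        net.freeze()
        before = (net.W.copy(), net.d.copy())
        r = present_sample(net, normalize_rates(synth_dataset.samples[5]), "infer")
        assert net.W.tobytes() == before[0].tobytes()
        assert net.d.tobytes() == before[1].tobytes()

    def test_progress_guarantee_in_cfn_training(self, study_config):
        # even a hostile input (uniform across channels) terminates: the
        # dopaminergic unit fires by t=200 and kappa=1 forces an output spike
        net = build_network(study_config, 0)
        r = present_sample(net, normalize_rates(np.ones(64)), "train")
        assert r.total_spikes >= study_config.recognize_spikes

    def test_infer_escalates_then_falls_back(self, study_config):
        # weights orthogonal to the input and frozen: escalation runs out
        cfg = study_config.replace(max_escalation_steps=2)
        dirs = np.zeros((4, 64))
        dirs[:, :16] = 1.0
        net = planted_network(cfg.replace(n_neurons=4), dirs)
        net.freeze()
        lam = np.zeros(64)
        lam[32:] = 1.0
        r = present_sample(net, normalize_rates(lam), "infer")
        assert r.fallback
        assert r.escalation_steps == 2
        assert r.final_potentials is not None

    def test_deterministic_trajectories(self, study_config, synth_dataset):
        results = []
        for _ in range(2):
            net = build_network(study_config, 11)
            seq = [
                present_sample(net, normalize_rates(x), "train")
                for x in synth_dataset.samples[:10]
            ]
            results.append(
                (
                    net.W.tobytes(),
                    [tuple(r.spike_counts) for r in seq],
                    [r.duration for r in seq],
                )
            )
        assert results[0] == results[1]


class TestEventStream:
    def test_capture_times_strictly_increasing(self, study_config, synth_dataset):
        net = build_network(study_config, 0)
        cap = EventStream()
        present_sample(net, normalize_rates(synth_dataset.samples[0]), "train", cap)
        times = cap.times()
        assert len(cap) > 0
        assert np.all(np.diff(times) > 0)

    def test_capture_off_is_empty(self):
        stream = EventStream()
        assert len(stream) == 0 and stream.to_rows() == []

    def test_raster_export(self, tmp_path, study_config, synth_dataset):
        from cfnet.io import raster_to_csv

        net = build_network(study_config, 0)
        cap = EventStream()
        present_sample(net, normalize_rates(synth_dataset.samples[0]), "train", cap)
        raster_to_csv(cap, tmp_path / "raster.csv")
        lines = (tmp_path / "raster.csv").read_text().strip().splitlines()
        assert lines[0] == "time,unit_id,kind"
        assert len(lines) == len(cap) + 1


class TestRunSpikeTrain:
    def test_known_fire_sequence(self, study_config):
        # one neuron, all weight on channel 0; four rapid spikes cross v_th
        cfg = study_config.replace(n_neurons=1, input_dim=2, v_th=2.5, w_cap=1.0)
        net = planted_network(cfg, [[1.0, 0.0]])
        times = np.array([0.1, 0.2, 0.3, 0.4])
        channels = np.zeros(4, dtype=int)
        r = run_spike_train(net, times, channels, mode="infer")
        # potential ~ 1 per spike with negligible decay: fires on 3rd spike
        assert r.total_spikes == 1
        assert r.winners == [0]
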