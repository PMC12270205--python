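"""Architecture bookkeeping, parameter counting, and the training protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurobag import net, nn


class TestCountParameters:
    def test_stem_only_hand_count(self):
        """5^3 conv (125*4 + 4) + norm (2*4) + head (4 + 1) = 517."""
        cfg = net.NetConfig(stem_width=4, block_layers=(), final_conv_width=None)
        assert net.count_parameters(cfg) == 517
        assert net.build_model(cfg, seed=0).num_parameters() == 517

    def test_reference_config_count(self):
        assert net.count_parameters(net.REFERENCE_CONFIG) == 251_098_737

    def test_channels_entering_block2(self):
        """After block 1 (3 layers) the transition compresses C0 + 3k."""
        cfg = net.NetConfig(stem_width=10, growth_rate=4, block_layers=(3, 2),
                            compression=0.5, final_conv_width=None)
        trace = dict(cfg.channel_trace())
        assert trace["block1"] == 10 + 3 * 4
        assert trace["transition1"] == math.floor(0.5 * 22)

    @given(
        c0=st.integers(1, 12), k=st.integers(1, 6), s=st.integers(1, 3),
        comp=st.sampled_from([0.5, 0.75, 1.0]),
        blocks=st.lists(st.integers(0, 3), min_size=1, max_size=3),
        final=st.sampled_from([None, 5]),
        bb=st.booleans(), gb=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_closed_form_matches_instantiation(self, c0, k, s, comp, blocks,
                                               final, bb, gb):
        cfg = net.NetConfig(stem_width=c0, growth_rate=k, bottleneck_scale=s,
                            compression=comp, block_layers=tuple(blocks),
                            final_conv_width=final, bottleneck_bias=bb,
                            growth_bias=gb)
        try:
            expected = net.count_parameters(cfg)
        except ValueError:
            return  # degenerate channel widths are rejected consistently
        assert net.build_model(cfg, seed=0).num_parameters() == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            net.count_parameters(net.NetConfig(stem_width=0))
        with pytest.raises(ValueError):
            net.count_parameters(net.NetConfig(compression=0.0))


class TestResolveReferenceConfig:
    def test_grid_containing_reference_returns_it(self):
        grid = {"stem_width": [net.REFERENCE_CONFIG.stem_width, 8],
                "growth_rate": [net.REFERENCE_CONFIG.growth_rate, 4],
                "bottleneck_scale": [1],
                "compression": [0.5],
                "final_conv_width": [net.REFERENCE_CONFIG.final_conv_width]}
        matches, _ = net.resolve_reference_config(search_grid=grid)
        assert net.REFERENCE_CONFIG in matches

    def test_middle_of_three_known_counts(self):
        cfgs = [net.NetConfig(stem_width=c, block_layers=(1,), growth_rate=2,
                              final_conv_width=None) for c in (2, 4, 6)]
        target = net.count_parameters(cfgs[1])
        matches, _ = net.resolve_reference_config(
            block_layers=(1,),
            search_grid={"stem_width": [2, 4, 6], "growth_rate": [2],
                         "bottleneck_scale": [1], "compression": [0.5],
                         "final_conv_width": [None]},
            target=target)
        assert [m.stem_width for m in matches] == [4]

    def test_empty_grid_reports_no_match(self):
        matches, nearest = net.resolve_reference_config(
            search_grid={"stem_width": []}, target=123)
        assert matches == [] and nearest == []


class TestForwardPass:
    def test_degenerate_architecture_scalar_output(self):
        cfg = net.NetConfig(stem_width=3, block_layers=(0, 0), growth_rate=1,
                            final_conv_width=4, compression=1.0)
        model = net.build_model(cfg, seed=0)
        out = model.forward(np.random.default_rng(0).normal(size=(2, 16, 16, 16)))
        assert out.shape == (2, 1) and np.isfinite(out).all()

    def test_scalar_output_for_larger_grids(self, tiny_model):
        out = tiny_model.forward(np.zeros((1, 20, 24, 18)))
        assert out.shape == (1, 1)

    def test_prediction_determinism_and_batch_invariance(self, tiny_model, rng):
        vols = rng.normal(size=(8, 16, 16, 16))
        batch = net.predict_brain_age(tiny_model, vols, batch_size=8)
        single = np.array([net.predict_brain_age(tiny_model, v[None])[0] for v in vols])
        np.testing.assert_allclose(batch, single, rtol=1e-10)
        again = net.predict_brain_age(tiny_model, vols, batch_size=3)
        np.testing.assert_allclose(batch, again, rtol=1e-10)


class TestStagedSchedule:
    def _run(self, losses, tc):
        sched = net.StagedSchedule(tc)
        events = [sched.observe(e, l) for e, l in enumerate(losses)]
        return sched, events

    def test_strictly_improving_never_stops_or_decays(self):
        tc = net.TrainConfig(cycles=5, epochs_per_cycle=15)
        losses = [10.0 - 0.1 * e for e in range(75)]
        sched, events = self._run(losses, tc)
        assert not any(ev["stop"] or ev["decayed"] for ev in events)
        assert sched.lr == tc.lr0

    def test_frozen_loss_stops_after_patience(self):
        """Validation loss frozen from epoch e=3 onward: six consecutive
        non-improvements stop training at epoch 9."""
        tc = net.TrainConfig(patience=6)
        losses = [5.0, 4.0, 3.0, 2.0] + [2.0] * 20
        sched, events = self._run(losses, tc)
        stops = [e for e, ev in enumerate(events) if ev["stop"]]
        assert stops[0] == 3 + 6

    def test_decay_applied_when_cycle_has_no_improvement(self):
        tc = net.TrainConfig(epochs_per_cycle=3, patience=100, lr_decay=0.7)
        losses = [3.0, 2.0, 1.0] + [1.0, 1.0, 1.0]
        sched, events = self._run(losses, tc)
        assert not events[2]["decayed"]        # cycle 1 improved
        assert events[5]["decayed"]            # cycle 2 plateaued
        assert sched.lr == pytest.approx(tc.lr0 * 0.7)

    def test_counter_is_epoch_global_across_cycles(self):
        tc = net.TrainConfig(epochs_per_cycle=4, patience=6)
        losses = [2.0] + [2.0] * 10  # first epoch improves over inf, then flat
        sched, events = self._run(losses, tc)
        stops = [e for e, ev in enumerate(events) if ev["stop"]]
        assert stops[0] == 6  # not reset at the epoch-4 cycle boundary


class TestStagedTrain:
    def _data(self, n=24, shape=(16, 16, 16), seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n,) + shape)
        y = rng.uniform(30, 90, n)
        return x, y

    def test_empty_sets_rejected(self, tiny_net_config):
        model = net.build_model(tiny_net_config, seed=0)
        x, y = self._data()
        with pytest.raises(ValueError):
            net.staged_train(model, (x[:0], y[:0]), (x, y), net.TrainConfig())

    def test_checkpoint_is_min_of_history(self, tiny_net_config):
        model = net.build_model(tiny_net_config, seed=0)
        x, y = self._data()
        tc = net.TrainConfig(cycles=1, epochs_per_cycle=3, lr0=1e-3, seed=1)
        state = net.staged_train(model, (x[:16], y[:16]), (x[16:], y[16:]), tc)
        assert state.best_val == pytest.approx(min(state.val_history))
        assert state.val_history[state.best_epoch] == state.best_val

    def test_reproducible_loss_curves(self, tiny_net_config):
        x, y = self._data()
        histories = []
        for _ in range(2):
            model = net.build_model(tiny_net_config, seed=3)
            tc = net.TrainConfig(cycles=1, epochs_per_cycle=2, lr0=1e-3, seed=3)
            st_ = net.staged_train(model, (x[:16], y[:16]), (x[16:], y[16:]), tc)
            histories.append((st_.train_history, st_.val_history))
        assert histories[0] == histories[1]

    def test_restores_best_state(self, tiny_net_config):
        model = net.build_model(tiny_net_config, seed=0)
        x, y = self._data()
        tc = net.TrainConfig(cycles=1, epochs_per_cycle=3, lr0=1e-2, seed=1)
        state = net.staged_train(model, (x[:16], y[:16]), (x[16:], y[16:]), tc)
        val = float(np.mean(np.abs(net.predict_brain_age(model, x[16:]) - y[16:])))
        assert val == pytest.approx(state.best_val, rel=1e-6)


class TestAdamAndLoss:
    def test_mae_loss_gradient_signs(self):
        pred = np.array([1.0, -2.0, 3.0])
        target = np.array([0.0, 0.0, 4.0])
        loss, grad = nn.mae_loss(pred, target)
        assert loss == pytest.approx(4.0 / 3.0)
        np.testing.assert_allclose(grad, np.array([1, -1, -1]) / 3)

    def test_adam_reduces_quadratic(self):
        p = nn.Param(np.array([5.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            p.zero_grad()
            p.add_grad(2 * p.value)
            opt.step()
        assert abs(p.value[0]) < 0.1
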