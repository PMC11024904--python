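import json

import numpy as np
import pytest

from dnaturbo import (
    CodecConfig,
    default_finetune_constraints,
    generate_bit_blocks,
    reconstruction_accuracy,
    smooth_l1_loss,
)
from dnaturbo.autodiff import Tensor
from dnaturbo.channel import ChannelConfig, ErrorSource
from dnaturbo.constraints import ConstraintConfig, ProbabilityGraph
from dnaturbo.models import build_model
from dnaturbo.training import (
    CheckpointError,
    LossSpec,
    TrainHyper,
    Trainer,
    encoder_loss,
    evaluate_model,
    fine_tune_constraints,
    graph_affine_eval,
    soft_constraint_penalty,
    train,
)


def tiny_config(**kw) -> CodecConfig:
    defaults = dict(block_bits=8, rate_mode="third", decoder_iterations=1,
                    units=6, layers=1, encoder_arch="cnn",
                    transcoder_arch="cnn", decoder_arch="cnn")
    defaults.update(kw)
    return CodecConfig(**defaults)


TINY_HYPER = TrainHyper(batch_size=16, enc_batches=2, dec_batches=2,
                        lr=1e-3, eval_blocks=16)


def tiny_channel(total=0.02) -> ChannelConfig:
    return ChannelConfig(sources=[
        ErrorSource("s", substitution=total * 0.6, insertion=total * 0.2,
                    deletion=total * 0.2)
    ])


class TestSmoothL1:
    def test_identical_is_zero(self):
        assert smooth_l1_loss([1, 0, 1], [1, 0, 1]) == 0.0

    def test_quadratic_branch(self):
        # 0.5 * 0.5^2 / 1
        assert smooth_l1_loss([0.0], [0.5], beta=1.0) == pytest.approx(0.125)

    def test_linear_branch(self):
        # 2 - 0.5
        assert smooth_l1_loss([0.0], [2.0], beta=1.0) == pytest.approx(1.5)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_continuity_at_beta(self, beta):
        eps = 1e-7
        below = smooth_l1_loss([0.0], [beta - eps], beta=beta)
        at = smooth_l1_loss([0.0], [beta], beta=beta)
        above = smooth_l1_loss([0.0], [beta + eps], beta=beta)
        assert below == pytest.approx(at, abs=1e-6)
        assert above == pytest.approx(at, abs=1e-6)
        assert at == pytest.approx(0.5 * beta)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_closed_forms_both_sides(self, beta, rng):
        d = rng.normal(size=50) * 2 * beta
        expected = np.where(np.abs(d) < beta, 0.5 * d * d / beta,
                            np.abs(d) - 0.5 * beta).mean()
        assert smooth_l1_loss(np.zeros(50), d, beta=beta) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            smooth_l1_loss([0, 1], [0, 1, 1])

    def test_bad_beta(self):
        with pytest.raises(ValueError):
            smooth_l1_loss([0], [0], beta=0.0)


class TestReconstructionAccuracy:
    def test_identical(self):
        u = generate_bit_blocks(1, 24, 0)[0]
        assert reconstruction_accuracy(u, u) == 1.0

    def test_complement(self):
        u = generate_bit_blocks(1, 24, 0)[0]
        assert reconstruction_accuracy(u, 1 - u) == 0.0

    def test_partial(self):
        u = np.zeros(24, dtype=int)
        u_hat = u.copy()
        u_hat[:6] = 1
        assert reconstruction_accuracy(u, u_hat) == pytest.approx(0.75)

    def test_complement_identity_property(self, rng):
        for _ in range(20):
            u = rng.integers(0, 2, size=32)
            v = rng.integers(0, 2, size=32)
            total = reconstruction_accuracy(u, v) + reconstruction_accuracy(u, 1 - v)
            assert total == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_accuracy([0, 1], [0])


class TestBitBlocks:
    def test_reproducible(self):
        a = generate_bit_blocks(10, 24, 42)
        b = generate_bit_blocks(10, 24, 42)
        assert np.array_equal(a, b)

    def test_frequency_within_3_sigma(self):
        bits = generate_bit_blocks(1000, 100, 7)
        p = bits.mean()
        sigma = np.sqrt(0.25 / bits.size)
        assert abs(p - 0.5) < 3 * sigma

    def test_empty(self):
        assert generate_bit_blocks(0, 24, 0).shape == (0, 24)

    def test_invalid(self):
        with pytest.raises(ValueError):
            generate_bit_blocks(2, 0, 0)


class TestGraphAffineEval:
    def test_values_match_graph(self):
        g = ProbabilityGraph([(0, 100), (40, 100), (41, 0), (59, 0),
                              (60, 100), (100, 100)])
        xs = np.array([0.0, 30.0, 40.5, 50.0, 75.0, 120.0])
        out = graph_affine_eval(g, Tensor(xs))
        expected = [g.evaluate(x) for x in xs]
        assert np.allclose(out.data, expected, atol=1e-4)

    def test_gradient_is_segment_slope(self):
        g = ProbabilityGraph([(40, 100), (41, 0)])
        x = Tensor(np.array([40.5]), requires_grad=True)
        out = graph_affine_eval(g, x)
        out.backward()
        assert x.grad[0] == pytest.approx(-100.0)

    def test_gradient_zero_outside_range(self):
        g = ProbabilityGraph([(40, 100), (41, 0)])
        x = Tensor(np.array([10.0]), requires_grad=True)
        graph_affine_eval(g, x).backward()
        assert x.grad[0] == 0.0


class TestConstraintSurrogate:
    def test_penalty_orders_violating_batches(self):
        cfg = default_finetune_constraints()
        # strand with a long homopolymer vs an alternating strand
        from dnaturbo.models import bits_from_strand

        good = "ACGTACGTACGT"
        bad = "AAAAAAGTACGT"
        xg = Tensor(2.0 * bits_from_strand(good)[None, :].astype(float) - 1.0)
        xb = Tensor(2.0 * bits_from_strand(bad)[None, :].astype(float) - 1.0)
        assert float(soft_constraint_penalty(xb, cfg).data) > \
            float(soft_constraint_penalty(xg, cfg).data)

    def test_penalty_has_gradient(self):
        cfg = default_finetune_constraints()
        x = Tensor(np.random.default_rng(0).normal(size=(4, 24)),
                   requires_grad=True)
        from dnaturbo import autodiff as ad

        pen = soft_constraint_penalty(ad.binarize_ste(x), cfg)
        pen.backward()
        assert x.grad is not None
        assert np.abs(x.grad).sum() > 0


class TestEncoderLoss:
    def test_zero_weight_equals_reconstruction_term(self):
        model = build_model(tiny_config(), seed=0)
        u = generate_bit_blocks(8, 8, 0)
        rng = np.random.default_rng(0)
        loss0, _ = encoder_loss(u, model, None, None,
                                LossSpec(stability_weight=0.0), rng)
        # all-violating constraint (constant 100% graph): adds exactly weight*1
        cfg = ConstraintConfig(gc_graph=ProbabilityGraph([(0, 100)]))
        loss1, info = encoder_loss(u, model, None, cfg,
                                   LossSpec(stability_weight=1.0),
                                   np.random.default_rng(0))
        assert info["stability"] == 0.0
        assert float(loss1.data) == pytest.approx(float(loss0.data) + 1.0,
                                                  abs=1e-5)

    def test_all_adhering_adds_nothing(self):
        model = build_model(tiny_config(), seed=0)
        u = generate_bit_blocks(8, 8, 0)
        cfg = ConstraintConfig(gc_graph=ProbabilityGraph([(0, 0)]))
        loss0, _ = encoder_loss(u, model, None, None,
                                LossSpec(stability_weight=0.0),
                                np.random.default_rng(0))
        loss1, info = encoder_loss(u, model, None, cfg,
                                   LossSpec(stability_weight=1.0),
                                   np.random.default_rng(0))
        assert info["stability"] == 1.0
        assert float(loss1.data) == pytest.approx(float(loss0.data), abs=1e-6)


class TestTrainLoop:
    def test_zero_epochs_checkpoint_and_empty_log(self, tmp_path):
        log, ckpt = train(tiny_config(), epochs=0, seed=0,
                          workdir=str(tmp_path / "w"), hyper=TINY_HYPER)
        assert log == []
        assert (tmp_path / "w" / "checkpoint" / "weights.npz").exists()

    def test_epoch_log_records(self, tmp_path):
        log, _ = train(tiny_config(), epochs=2, seed=0,
                       workdir=str(tmp_path / "w"),
                       channel=tiny_channel(), hyper=TINY_HYPER)
        assert [r["epoch"] for r in log] == [1, 2]
        for r in log:
            for key in ("encoder_loss", "decoder_loss", "accuracy",
                        "stability", "noise_level", "perfect_fraction"):
                assert key in r
        lines = (tmp_path / "w" / "log.jsonl").read_text().splitlines()
        assert len(lines) == 2
        assert json.loads(lines[0])["epoch"] == 1

    def test_resume_is_bit_identical(self, tmp_path):
        cfg = tiny_config()
        log_a, _ = train(cfg, epochs=6, seed=3, workdir=str(tmp_path / "a"),
                         channel=tiny_channel(), hyper=TINY_HYPER)
        log_b, _ = train(cfg, epochs=3, seed=3, workdir=str(tmp_path / "b"),
                         channel=tiny_channel(), hyper=TINY_HYPER)
        log_b2, _ = train(cfg, epochs=6, seed=3, workdir=str(tmp_path / "b"),
                          resume=True)
        assert [r["epoch"] for r in log_b2] == [1, 2, 3, 4, 5, 6]
        for ra, rb in zip(log_a, log_b2):
            assert ra["encoder_loss"] == pytest.approx(rb["encoder_loss"],
                                                       rel=1e-6)
            assert ra["decoder_loss"] == pytest.approx(rb["decoder_loss"],
                                                       rel=1e-6)
            assert ra["accuracy"] == rb["accuracy"]

    def test_resume_config_mismatch_refused(self, tmp_path):
        train(tiny_config(), epochs=1, seed=0, workdir=str(tmp_path / "w"),
              hyper=TINY_HYPER)
        with pytest.raises(CheckpointError, match="mismatch"):
            train(tiny_config(block_bits=16), epochs=2, seed=0,
                  workdir=str(tmp_path / "w"), resume=True)

    def test_online_hyperparameter_refresh(self, tmp_path):
        cfg_path = tmp_path / "hyper.json"
        cfg_path.write_text(json.dumps({"lr": 5e-4, "stability_weight": 0.25}))
        trainer = Trainer(tiny_config(), str(tmp_path / "w"), seed=0,
                          hyper=TINY_HYPER, config_path=str(cfg_path))
        trainer.train(1)
        assert trainer.opt.lr == pytest.approx(5e-4)
        assert trainer.loss_spec.stability_weight == pytest.approx(0.25)


class TestFineTune:
    def test_zero_epochs_unchanged_weights(self, tmp_path):
        train(tiny_config(), epochs=1, seed=0, workdir=str(tmp_path / "w"),
              hyper=TINY_HYPER)
        before, *_ = __import__("dnaturbo.training", fromlist=["load_checkpoint"]) \
            .load_checkpoint(str(tmp_path / "w" / "checkpoint"))
        state_before = before.state_dict()
        log, _ = fine_tune_constraints(str(tmp_path / "w"),
                                       default_finetune_constraints(),
                                       epochs=0)
        after, *_ = __import__("dnaturbo.training", fromlist=["load_checkpoint"]) \
            .load_checkpoint(str(tmp_path / "w" / "checkpoint"))
        for k, v in after.state_dict().items():
            assert np.array_equal(v, state_before[k])

    def test_fine_tune_logs_stability(self, tmp_path):
        train(tiny_config(), epochs=1, seed=0, workdir=str(tmp_path / "w"),
              channel=tiny_channel(), hyper=TINY_HYPER)
        log, _ = fine_tune_constraints(str(tmp_path / "w"),
                                       default_finetune_constraints(),
                                       epochs=1)
        assert log[-1]["epoch"] == 2
        assert log[-1]["stability"] is not None


class TestEvaluate:
    def test_empty_report(self):
        model = build_model(tiny_config(), seed=0)
        assert evaluate_model(model, None, None, 0, 0) == {"n_blocks": 0}

    def test_fixed_seed_identical(self):
        model = build_model(tiny_config(), seed=0)
        ch = tiny_channel()
        a = evaluate_model(model, ch, None, 32, 5)
        b = evaluate_model(model, ch, None, 32, 5)
        assert a == b

    def test_report_fields(self):
        model = build_model(tiny_config(), seed=0)
        rep = evaluate_model(model, tiny_channel(),
                             default_finetune_constraints(), 32, 5)
        assert set(rep) >= {"accuracy", "perfect_fraction", "stability",
                            "noise_level", "n_blocks"}
        assert rep["noise_level"] == pytest.approx(0.02)


class TestTrainingSmokeInvariant:
    def test_rate_third_smoke_reaches_095(self, smoke_trainer_third):
        # block 24, rate 1/3, CNN/ResNet/CNN, <=2% error, 50 epochs
        assert smoke_trainer_third.log[-1]["accuracy"] > 0.95
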