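import numpy as np
import pytest

from dnaturbo import CodecConfig, InterleaverSpec
from dnaturbo.channel import NoisyRead
from dnaturbo.models import (
    ModelConfigError,
    bits_from_strand,
    build_model,
    strands_from_bits,
)
from dnaturbo.training import generate_bit_blocks


def tiny_config(**kw) -> CodecConfig:
    defaults = dict(block_bits=8, rate_mode="third", latent_redundancy=0,
                    decoder_iterations=1, units=6, layers=1,
                    encoder_arch="cnn", transcoder_arch="cnn",
                    decoder_arch="cnn")
    defaults.update(kw)
    return CodecConfig(**defaults)


class TestBuildModel:
    @pytest.mark.parametrize("enc", ["cnn", "rnn", "vae", "transformer"])
    def test_encoder_architectures_construct_and_run(self, enc):
        model = build_model(tiny_config(encoder_arch=enc), seed=0)
        u = generate_bit_blocks(2, 8, 0)
        x, _ = model.encode(u)
        assert x.shape == (2, 24)

    @pytest.mark.parametrize("trans", ["cnn", "rnn", "resnet"])
    def test_transcoder_architectures(self, trans):
        model = build_model(tiny_config(transcoder_arch=trans), seed=0)
        _, y = model.transcode(["ACGT" * 3])
        assert y.shape == (1, 24)

    @pytest.mark.parametrize("dec", ["cnn", "rnn", "resnet", "transformer"])
    def test_decoder_architectures(self, dec):
        model = build_model(tiny_config(decoder_arch=dec), seed=0)
        logits = model.decode(np.zeros((2, 24)))
        assert logits.shape == (2, 8)

    def test_paper_focus_combination_constructs(self):
        model = build_model(tiny_config(encoder_arch="vae",
                                        transcoder_arch="resnet",
                                        decoder_arch="cnn"), seed=0)
        assert model.parameters()

    def test_transformer_transcoder_rejected(self):
        with pytest.raises(ModelConfigError) as exc:
            build_model(tiny_config(transcoder_arch="transformer"), seed=0)
        assert "valid options" in str(exc.value)
        assert "resnet" in str(exc.value)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ModelConfigError, match="valid options"):
            build_model(tiny_config(encoder_arch="perceptron"), seed=0)


class TestEncoder:
    def test_output_length_rate_third(self):
        model = build_model(tiny_config(), seed=0)
        x, _ = model.encode(generate_bit_blocks(4, 8, 1))
        assert x.shape == (4, 24)

    def test_output_length_with_latent_redundancy(self):
        model = build_model(tiny_config(latent_redundancy=8), seed=0)
        x, _ = model.encode(generate_bit_blocks(4, 8, 1))
        assert x.shape == (4, 48)

    def test_output_length_rate_half(self):
        model = build_model(tiny_config(rate_mode="half"), seed=0)
        x, _ = model.encode(generate_bit_blocks(4, 8, 1))
        assert x.shape == (4, 16)

    def test_output_is_bipolar(self):
        model = build_model(tiny_config(), seed=0)
        x, _ = model.encode(generate_bit_blocks(16, 8, 2))
        assert set(np.unique(x.data)) <= {-1.0, 1.0}

    def test_deterministic(self):
        u = generate_bit_blocks(4, 8, 3)
        a = build_model(tiny_config(), seed=7).encode_bits(u)
        b = build_model(tiny_config(), seed=7).encode_bits(u)
        assert np.array_equal(a, b)

    def test_systematic_encoder_reproduces_message(self):
        model = build_model(tiny_config(encoder_arch="systematic"), seed=0)
        u = generate_bit_blocks(8, 8, 4)
        x = model.encode_bits(u)
        assert np.array_equal(x[:, :8], u)
        assert np.array_equal(x[:, 8:16], u)
        assert np.array_equal(x[:, 16:], u[:, model.perm_n.perm])

    def test_degenerate_constant_blocks_invertible(self):
        model = build_model(tiny_config(encoder_arch="systematic"), seed=0)
        u = np.vstack([np.zeros(8, dtype=int), np.ones(8, dtype=int)])
        x = model.encode_bits(u)
        assert np.array_equal(x[:, :8], u)

    def test_systematic_requires_no_redundancy(self):
        with pytest.raises(ModelConfigError):
            build_model(tiny_config(encoder_arch="systematic",
                                    latent_redundancy=4), seed=0)


class TestTranscoder:
    def test_nominal_length_read_shape(self):
        model = build_model(tiny_config(), seed=0)
        _, y = model.transcode(["ACGT" * 3])  # 12 bases == nominal
        assert y.shape == (1, 24)

    def test_empty_read_valid_shape(self):
        model = build_model(tiny_config(), seed=0)
        _, y = model.transcode([""])
        assert y.shape == (1, 24)
        assert np.isfinite(y.data).all()

    def test_read_longer_than_window_truncated(self):
        model = build_model(tiny_config(), seed=0)
        window = model.cfg.window
        long_read = "ACGT" * (window // 2 + 10)
        inp = model.transcoder.inputs_from_reads([long_read])
        assert inp.shape[-1] == window  # right-truncated to the window
        _, y = model.transcode([long_read])
        assert y.shape == (1, 24)

    def test_binarized_mode_output_is_bipolar(self):
        model = build_model(tiny_config(), seed=0)
        _, y = model.transcode(["ACGT" * 3])
        assert set(np.unique(y.data)) <= {-1.0, 1.0}

    def test_continuous_mode(self):
        model = build_model(tiny_config(transcoder_binarize=False), seed=0)
        _, y = model.transcode(["ACGT" * 3])
        assert not set(np.unique(y.data)) <= {-1.0, 1.0}

    def test_bits_input_mode(self):
        model = build_model(tiny_config(transcoder_input="bits"), seed=0)
        _, y = model.transcode(["ACGT" * 3])
        assert y.shape == (1, 24)

    def test_accepts_noisy_read_objects(self):
        model = build_model(tiny_config(), seed=0)
        _, y = model.transcode([NoisyRead(sequence="ACGT" * 3)])
        assert y.shape == (1, 24)

    def test_bypass_transcoder_demaps(self):
        model = build_model(tiny_config(transcoder_arch="bypass"), seed=0)
        u = generate_bit_blocks(3, 8, 5)
        strands = model.strands(u)
        _, y = model.transcode(strands)
        expected = 2.0 * model.encode_bits(u) - 1.0
        assert np.array_equal(y.data, expected)


class TestTurboDecoder:
    def test_single_iteration_defined(self):
        model = build_model(tiny_config(decoder_iterations=1), seed=0)
        u_hat = model.decode_bits(np.zeros((2, 24)))
        assert u_hat.shape == (2, 8)

    def test_wrong_length_raises(self):
        model = build_model(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="decoder input length"):
            model.decode(np.zeros((2, 23)))

    def test_deterministic(self):
        model = build_model(tiny_config(decoder_iterations=3), seed=1)
        y = np.random.default_rng(0).normal(size=(4, 24))
        a = model.decode_bits(y)
        b = model.decode_bits(y)
        assert np.array_equal(a, b)

    def test_batch_order_invariance(self):
        model = build_model(tiny_config(decoder_iterations=2), seed=1)
        y = np.random.default_rng(0).normal(size=(6, 24)).astype(np.float32)
        out = model.decode_bits(y)
        perm = np.array([3, 0, 5, 1, 4, 2])
        out_perm = model.decode_bits(y[perm])
        assert np.array_equal(out_perm, out[perm])

    def test_majority_decoder_round_trip(self):
        cfg = tiny_config(encoder_arch="systematic", decoder_arch="majority",
                          transcoder_arch="bypass")
        model = build_model(cfg, seed=0)
        u = generate_bit_blocks(32, 8, 6)
        y = model.decoder_input(model.strands(u))
        assert np.array_equal(model.decode_bits(y), u)

    def test_rate_half_decodes(self):
        model = build_model(tiny_config(rate_mode="half"), seed=0)
        u_hat = model.decode_bits(np.zeros((2, 16)))
        assert u_hat.shape == (2, 8)


class TestPipelineShapes:
    def test_shape_conservation(self):
        cfg = tiny_config(latent_redundancy=2)
        model = build_model(cfg, seed=0)
        u = generate_bit_blocks(5, 8, 7)
        x, _ = model.encode(u)
        assert x.shape[1] == cfg.total_bits == 30
        strands = model.strands(u)
        assert all(len(s) == cfg.strand_bases == 15 for s in strands)
        y = model.decoder_input(strands, mode="model")
        assert y.shape == (5, 30)
        u_hat = model.decode_bits(y)
        assert u_hat.shape == u.shape

    def test_auto_mode_mixes_bypass_and_transcoder(self):
        model = build_model(tiny_config(), seed=0)
        u = generate_bit_blocks(2, 8, 8)
        strands = model.strands(u)
        short = strands[1][:-1]  # simulate a deletion
        y = model.decoder_input([strands[0], short], mode="auto")
        y_bypass = model.decoder_input([strands[0]], mode="bypass")
        assert np.array_equal(y[0], y_bypass[0])

    def test_interleaver_shared_and_stored(self):
        spec = InterleaverSpec("deterministic", k=3, u=1)
        model = build_model(tiny_config(interleaver=spec), seed=0)
        assert model.perm_n.perm.tolist() == [1, 4, 7, 2, 5, 0, 3, 6]
        # decoder uses the same spec at stream length
        assert len(model.perm_s) == model.cfg.stream_bits


class TestStrandHelpers:
    def test_roundtrip(self, rng):
        bits = rng.integers(0, 2, size=(10, 24))
        strands = strands_from_bits(bits)
        back = np.stack([bits_from_strand(s) for s in strands])
        assert np.array_equal(back, bits)

    def test_invalid_strand(self):
        with pytest.raises(ValueError):
            bits_from_strand("ACGU")
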