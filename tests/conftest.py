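import numpy as np
import pytest

from dnaturbo import (
    CodecConfig,
    amplify,
    default_channel_config,
)
from dnaturbo.training import TrainHyper, Trainer

# Smoke-scale training setup shared by the training/acceptance tests.
# Epoch count, batch size, block geometry and noise level follow the
# acceptance setup; the per-epoch batch schedule is deliberately small so a
# full run stays on a single-CPU budget.
SMOKE_EPOCHS = 50
SMOKE_TOTAL_ERROR = 0.015
SMOKE_HYPER = dict(batch_size=256, enc_batches=6, dec_batches=18, lr=2e-4)
SMOKE_SEEDS = (1, 2, 3)


def smoke_config(latent_redundancy: int = 0,
                 rate_mode: str = "half") -> CodecConfig:
    return CodecConfig(
        block_bits=24,
        rate_mode=rate_mode,
        latent_redundancy=latent_redundancy,
        decoder_iterations=2,
        encoder_arch="cnn",
        transcoder_arch="resnet",
        decoder_arch="cnn",
        units=16,
    )


def smoke_channel(total: float = SMOKE_TOTAL_ERROR):
    return amplify(default_channel_config(), total)


def train_smoke(workdir, seed: int, latent_redundancy: int = 0,
                rate_mode: str = "half",
                epochs: int = SMOKE_EPOCHS) -> Trainer:
    trainer = Trainer(
        smoke_config(latent_redundancy, rate_mode),
        str(workdir),
        seed=seed,
        channel=smoke_channel(),
        hyper=TrainHyper(**SMOKE_HYPER),
    )
    trainer.train(epochs)
    return trainer


@pytest.fixture(scope="session")
def smoke_trainers_red0(tmp_path_factory):
    """Three seeds of the trained smoke model (rate 1/2, redundancy 0)."""
    root = tmp_path_factory.mktemp("smoke_red0")
    return {
        seed: train_smoke(root / f"seed{seed}", seed) for seed in SMOKE_SEEDS
    }


@pytest.fixture(scope="session")
def smoke_trainers_red8(tmp_path_factory):
    """Three seeds with 8 bits of latent redundancy (rate 1/2)."""
    root = tmp_path_factory.mktemp("smoke_red8")
    return {
        seed: train_smoke(root / f"seed{seed}", seed, latent_redundancy=8)
        for seed in SMOKE_SEEDS
    }


@pytest.fixture(scope="session")
def smoke_trainer_third(tmp_path_factory):
    """One rate-1/3 smoke model (training invariant + file round trip)."""
    root = tmp_path_factory.mktemp("smoke_third")
    return train_smoke(root / "seed2", seed=2, rate_mode="third")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
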