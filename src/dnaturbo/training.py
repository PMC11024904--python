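"""Losses, metrics, the alternating-phase training schedule, constraint
fine-tuning, checkpoint/resume and the synthetic bit-block generator."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .channel import ChannelConfig, channel_config_from_dict, transmit_batch
from .codec import CodecConfig
from .constraints import (
    ConstraintConfig,
    ProbabilityGraph,
    batch_stability,
    constraint_config_from_dict,
)
from .models import BypassTranscoder, TurboCodec, build_model, strands_from_bits
from .nn import Adam

logger = logging.getLogger(__name__)


# -- losses and metrics ---------------------------------------------------

def smooth_l1_loss(u, u_hat, beta: float = 1.0) -> float:
    """Mean smooth-L1 between two equal-length vectors (numeric contract)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    u = np.asarray(u, dtype=np.float64).ravel()
    u_hat = np.asarray(u_hat, dtype=np.float64).ravel()
    if u.shape != u_hat.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {u_hat.shape}")
    d = np.abs(u - u_hat)
    elems = np.where(d < beta, 0.5 * d * d / beta, d - 0.5 * beta)
    return float(elems.mean())


def reconstruction_accuracy(u, u_hat) -> float:
    """Fraction of positions where the reconstruction matches the input."""
    u = np.asarray(u).ravel()
    u_hat = np.asarray(u_hat).ravel()
    if u.shape != u_hat.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {u_hat.shape}")
    return float((u == u_hat).mean())


def generate_bit_blocks(n: int, block_bits: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. uniform message blocks as an (n, block_bits) 0/1 array."""
    if n == 0:
        return np.zeros((0, block_bits), dtype=np.int64)
    if n < 0 or block_bits <= 0:
        raise ValueError("n must be >= 0 and block_bits positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(n, block_bits), dtype=np.int64)


@dataclass
class LossSpec:
    beta: float = 1.0
    stability_weight: float = 0.0
    transcoder_target: str = "encoder_output"  # or "input_bits"

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.stability_weight < 0:
            raise ValueError("stability_weight must be >= 0")
        if self.transcoder_target not in ("encoder_output", "input_bits"):
            raise ValueError("unknown transcoder_target")


@dataclass
class TrainHyper:
    batch_size: int = 256
    enc_batches: int = 100
    dec_batches: int = 500
    lr: float = 1e-4
    eval_blocks: int = 256
    # per-batch channel noise scaling factors ("noise sampled per batch");
    # mixing clean and amplified batches keeps the codec exact on clean
    # reads while still training it on the nominal error rate
    noise_factors: tuple = (0.0, 0.5, 1.0, 1.5)


# -- differentiable constraint surrogate ----------------------------------

def graph_affine_eval(graph: ProbabilityGraph, x: Tensor) -> Tensor:
    """Evaluate a probability graph on a tensor of constraint values.

    The forward value matches :meth:`ProbabilityGraph.evaluate` exactly; the
    gradient is the local segment slope (zero outside the x-range and in
    step mode), which is what the piecewise-linear curve defines a.e.
    """
    xs, ys = graph._x, graph._y
    xd = np.asarray(x.data, dtype=np.float64)
    xc = np.clip(xd, xs[0], xs[-1])
    yv = np.interp(xc, xs, ys)
    if graph.interpolation == "step" or len(xs) == 1:
        slopes = np.zeros_like(xd)
        i = np.clip(np.searchsorted(xs, xc, side="right") - 1, 0, len(xs) - 1)
        yv = ys[i]
    else:
        seg = np.clip(np.searchsorted(xs, xc, side="right") - 1, 0, len(xs) - 2)
        slopes = (ys[seg + 1] - ys[seg]) / (xs[seg + 1] - xs[seg])
        slopes = np.where((xd < xs[0]) | (xd > xs[-1]), 0.0, slopes)
    return x * slopes.astype(np.float32) + (yv - xd * slopes).astype(np.float32)


def _homopolymer_threshold(graph: ProbabilityGraph, cap: int = 12):
    """Smallest run length >= 2 the graph penalizes, or None."""
    for r in range(2, cap + 1):
        if graph.evaluate(r) > 0:
            return r
    return None


def soft_constraint_penalty(x: Tensor, cfg: ConstraintConfig) -> Tensor:
    """Differentiable surrogate for the batch constraint-violation level.

    Operates on the bipolar encoder output (gradients reach the encoder
    through the straight-through binarizer): the GC term evaluates the GC
    graph at the soft GC percentage; the homopolymer term counts windows of
    identical consecutive bases at the graph's penalized run length.
    Motif and k-mer constraints contribute no surrogate gradient.
    """
    B, T = x.shape
    L = T // 2
    terms = []
    if cfg.gc_graph is not None:
        # base is G or C iff the second bit of its pair is 1
        b1 = ad.take(x, np.arange(1, T, 2), axis=-1)
        gc_pct = ad.tmean((b1 + 1.0) * 0.5, axis=-1) * 100.0  # (B,)
        terms.append(ad.tmean(graph_affine_eval(cfg.gc_graph, gc_pct)) * 0.01)
    if cfg.homopolymer_graph is not None and L >= 2:
        r = _homopolymer_threshold(cfg.homopolymer_graph)
        if r is not None and L >= r:
            x0 = ad.take(x, np.arange(0, T, 2), axis=-1)
            x1 = ad.take(x, np.arange(1, T, 2), axis=-1)
            lead = np.arange(L - 1)
            same = (
                ((ad.take(x0, lead + 1, -1) * ad.take(x0, lead, -1)) + 1.0)
                * 0.5
                * (((ad.take(x1, lead + 1, -1) * ad.take(x1, lead, -1)) + 1.0)
                   * 0.5)
            )  # (B, L-1), 1 where consecutive bases identical
            win = np.arange(L - r + 1)
            w = ad.take(same, win, -1)
            for m in range(1, r - 1):
                w = w * ad.take(same, win + m, -1)
            terms.append(ad.tmean(w))
    if not terms:
        return Tensor(np.zeros(()))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def stability_term(x: Tensor, strands, constraints: ConstraintConfig):
    """Exact ``1 - w`` batch violation with surrogate gradients attached."""
    batch = batch_stability(strands, constraints)
    surrogate = soft_constraint_penalty(x, constraints)
    return ad.surrogate_value(1.0 - batch.w, surrogate), batch.w


def encoder_loss(u01: np.ndarray, model: TurboCodec,
                 channel: ChannelConfig | None,
                 constraints: ConstraintConfig | None,
                 spec: LossSpec, rng: np.random.Generator):
    """Reconstruction loss plus the weighted constraint-stability term.

    Returns ``(loss, info)`` where ``loss`` is a scalar tensor ready for
    ``backward`` and ``info`` carries the exact stability score.
    """
    x, kl = model.encode(u01, train=True, rng=rng)
    holder = {}

    def through_channel(x_data: np.ndarray) -> np.ndarray:
        bits = (x_data > 0).astype(np.int64)
        strands = strands_from_bits(bits)
        holder["strands"] = strands
        if channel is None or channel.total == 0:
            reads = strands
        else:
            reads = transmit_batch(strands, channel, rng)
        return model.decoder_input(reads, mode="auto")

    y = ad.passthrough(x, through_channel)
    u_hat = ad.sigmoid(model.decode(y))
    loss = ad.smooth_l1(u_hat, np.asarray(u01, dtype=np.float32), spec.beta)
    info = {"stability": 1.0}
    if constraints is not None and spec.stability_weight > 0:
        term, w = stability_term(x, holder["strands"], constraints)
        loss = loss + spec.stability_weight * term
        info["stability"] = w
    if kl is not None and model.cfg.kl_weight > 0:
        loss = loss + model.cfg.kl_weight * kl
    info["u_hat"] = (u_hat.data > 0.5).astype(np.int64)
    return loss, info


def _decoder_loss(u01, model, channel, spec: LossSpec,
                  rng: np.random.Generator):
    x, _ = model.encode(u01)  # encoder frozen: plain forward
    strands = strands_from_bits((x.data > 0).astype(np.int64))
    if channel is None or channel.total == 0:
        reads = strands
    else:
        reads = transmit_batch(strands, channel, rng)
    if isinstance(model.transcoder, BypassTranscoder):
        raw, y = None, Tensor(model.transcoder.decoder_input(reads))
    else:
        raw, y = model.transcode(reads, with_grad=True)
    u_hat = ad.sigmoid(model.decode(y))
    loss = ad.smooth_l1(u_hat, np.asarray(u01, dtype=np.float32), spec.beta)
    trans_loss = 0.0
    if raw is not None and spec.transcoder_target == "encoder_output":
        tl = ad.smooth_l1(raw, x.data, spec.beta)
        trans_loss = float(tl.data)
        loss = loss + tl
    return loss, trans_loss


# -- evaluation -----------------------------------------------------------

def evaluate_model(model: TurboCodec, channel: ChannelConfig | None,
                   constraints: ConstraintConfig | None, n_blocks: int,
                   seed: int, transcoder_mode: str = "auto") -> dict:
    """Full-pipeline metrics over fresh random blocks."""
    if n_blocks == 0:
        return {"n_blocks": 0}
    u = generate_bit_blocks(n_blocks, model.cfg.block_bits, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7A1]))
    strands = model.strands(u)
    if channel is None or channel.total == 0:
        reads = strands
    else:
        reads = transmit_batch(strands, channel, rng)
    y = model.decoder_input(reads, mode=transcoder_mode)
    u_hat = model.decode_bits(y)
    report = {
        "n_blocks": int(n_blocks),
        "accuracy": reconstruction_accuracy(u, u_hat),
        "perfect_fraction": float((u == u_hat).all(axis=1).mean()),
        "noise_level": float(channel.total) if channel is not None else 0.0,
    }
    if constraints is not None:
        report["stability"] = batch_stability(strands, constraints).w
    return report


# -- checkpointing --------------------------------------------------------

class CheckpointError(RuntimeError):
    pass


def save_checkpoint(ckpt_dir: str, model: TurboCodec, opt: Adam, epoch: int,
                    rng: np.random.Generator, meta: dict):
    os.makedirs(ckpt_dir, exist_ok=True)
    np.savez(os.path.join(ckpt_dir, "weights.npz"), **model.state_dict())
    np.savez(os.path.join(ckpt_dir, "optim.npz"), **opt.state_dict())
    state = {
        "epoch": epoch,
        "rng_state": rng.bit_generator.state,
        "codec": model.cfg.to_dict(),
        "meta": meta,
    }
    with open(os.path.join(ckpt_dir, "state.json"), "w") as fh:
        json.dump(state, fh, indent=1, default=str)


def load_checkpoint(ckpt_dir: str):
    """Rebuild (model, optimizer-state, epoch, rng_state, meta) from disk."""
    state_path = os.path.join(ckpt_dir, "state.json")
    if not os.path.exists(state_path):
        raise CheckpointError(f"no checkpoint found at {ckpt_dir}")
    with open(state_path) as fh:
        state = json.load(fh)
    cfg = CodecConfig.from_dict(state["codec"])
    model = build_model(cfg, seed=state["meta"].get("seed", 0))
    weights = dict(np.load(os.path.join(ckpt_dir, "weights.npz")))
    model.load_state_dict(weights)
    optim_state = dict(np.load(os.path.join(ckpt_dir, "optim.npz")))
    rng_state = state["rng_state"]
    # JSON round-trips the 128-bit PCG64 integers as strings
    if isinstance(rng_state.get("state"), dict):
        rng_state["state"] = {k: int(v) for k, v in rng_state["state"].items()}
    for key in ("has_uint32", "uinteger"):
        if key in rng_state:
            rng_state[key] = int(rng_state[key])
    return model, optim_state, int(state["epoch"]), rng_state, state["meta"]


# -- training loop --------------------------------------------------------

_TUNABLE_KEYS = ("lr", "beta", "stability_weight", "enc_batches",
                 "dec_batches", "batch_size")


class Trainer:
    """Alternating-phase trainer with per-epoch checkpoint + JSONL log."""

    def __init__(self, cfg: CodecConfig, workdir: str, seed: int = 0,
                 channel: ChannelConfig | None = None,
                 constraints: ConstraintConfig | None = None,
                 loss_spec: LossSpec | None = None,
                 hyper: TrainHyper | None = None,
                 config_path: str | None = None):
        self.cfg = cfg
        self.workdir = workdir
        self.seed = seed
        self.channel = channel
        self.constraints = constraints
        self.loss_spec = loss_spec or LossSpec(beta=cfg.beta)
        self.hyper = hyper or TrainHyper()
        self.config_path = config_path
        self.model = build_model(cfg, seed=seed)
        self.opt = Adam(self.model.parameters(), lr=self.hyper.lr)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E4]))
        self.epoch = 0
        self.log: list = []
        os.makedirs(workdir, exist_ok=True)

    # -- persistence ------------------------------------------------------
    @property
    def ckpt_dir(self) -> str:
        return os.path.join(self.workdir, "checkpoint")

    @property
    def log_path(self) -> str:
        return os.path.join(self.workdir, "log.jsonl")

    def _meta(self) -> dict:
        return {
            "seed": self.seed,
            "loss_spec": asdict(self.loss_spec),
            "hyper": asdict(self.hyper),
            "channel": self.channel.to_dict() if self.channel else None,
            "constraints": (
                constraint_config_to_dict(self.constraints)
                if self.constraints else None
            ),
        }

    def save(self):
        save_checkpoint(self.ckpt_dir, self.model, self.opt, self.epoch,
                        self.rng, self._meta())

    @classmethod
    def from_checkpoint(cls, workdir: str,
                        expected_cfg: CodecConfig | None = None) -> "Trainer":
        ckpt_dir = os.path.join(workdir, "checkpoint")
        model, optim_state, epoch, rng_state, meta = load_checkpoint(ckpt_dir)
        if expected_cfg is not None and expected_cfg.to_dict() != model.cfg.to_dict():
            raise CheckpointError(
                "checkpoint/config mismatch: stored codec config "
                f"{model.cfg.to_dict()} differs from requested "
                f"{expected_cfg.to_dict()}; refusing to resume"
            )
        channel = (channel_config_from_dict(meta["channel"])
                   if meta.get("channel") else None)
        constraints = (constraint_config_from_dict(meta["constraints"])
                       if meta.get("constraints") else None)
        self = cls.__new__(cls)
        self.cfg = model.cfg
        self.workdir = workdir
        self.seed = meta.get("seed", 0)
        self.channel = channel
        self.constraints = constraints
        self.loss_spec = LossSpec(**meta["loss_spec"])
        self.hyper = TrainHyper(**meta["hyper"])
        self.config_path = None
        self.model = model
        self.opt = Adam(self.model.parameters(), lr=self.hyper.lr)
        self.opt.load_state_dict(optim_state)
        self.rng = np.random.default_rng()
        self.rng.bit_generator.state = rng_state
        self.epoch = epoch
        self.log = []
        if os.path.exists(self.log_path):
            with open(self.log_path) as fh:
                self.log = [json.loads(line) for line in fh if line.strip()]
        return self

    # -- online hyperparameter refresh ------------------------------------
    def _refresh_hypers(self):
        if not self.config_path or not os.path.exists(self.config_path):
            return
        try:
            with open(self.config_path) as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError):
            return
        for key in _TUNABLE_KEYS:
            if key not in raw:
                continue
            val = raw[key]
            if key == "lr":
                self.hyper.lr = float(val)
                self.opt.lr = float(val)
            elif key == "beta":
                self.loss_spec.beta = float(val)
            elif key == "stability_weight":
                self.loss_spec.stability_weight = float(val)
            elif key in ("enc_batches", "dec_batches", "batch_size"):
                setattr(self.hyper, key, int(val))

    # -- phases -----------------------------------------------------------
    def _rand_blocks(self, n: int) -> np.ndarray:
        return self.rng.integers(0, 2, size=(n, self.cfg.block_bits),
                                 dtype=np.int64)

    def _batch_channel(self) -> ChannelConfig | None:
        if self.channel is None or self.channel.total == 0:
            return self.channel
        factors = self.hyper.noise_factors
        factor = factors[int(self.rng.integers(len(factors)))]
        if factor == 0:
            return None
        if factor == 1:
            return self.channel
        from .channel import amplify

        return amplify(self.channel, min(factor * self.channel.total, 1.0))

    def _run_epoch(self) -> dict:
        enc_names = self.model.encoder_param_names()
        dec_names = self.model.decoder_param_names()
        h = self.hyper
        enc_losses, stabilities = [], []
        # encoder phase (decoder + transcoder frozen)
        self.model.set_trainable(dec_names, False)
        self.model.set_trainable(enc_names, True)
        for _ in range(h.enc_batches):
            if not enc_names:
                break  # systematic encoder has nothing to train
            u = self._rand_blocks(h.batch_size)
            self.opt.zero_grad()
            loss, info = encoder_loss(u, self.model, self._batch_channel(),
                                      self.constraints, self.loss_spec,
                                      self.rng)
            loss.backward()
            self.opt.step(only=enc_names)
            enc_losses.append(float(loss.data))
            stabilities.append(info["stability"])
        # decoder + transcoder phase (encoder frozen)
        self.model.set_trainable(enc_names, False)
        self.model.set_trainable(dec_names, True)
        dec_losses, trans_losses = [], []
        for _ in range(h.dec_batches):
            if not dec_names:
                break
            u = self._rand_blocks(h.batch_size)
            self.opt.zero_grad()
            loss, tl = _decoder_loss(u, self.model, self._batch_channel(),
                                     self.loss_spec, self.rng)
            loss.backward()
            self.opt.step(only=dec_names)
            dec_losses.append(float(loss.data))
            trans_losses.append(tl)
        self.model.set_trainable(enc_names, True)
        eval_seed = int(self.rng.integers(1 << 31))
        report = evaluate_model(self.model, self.channel, self.constraints,
                                h.eval_blocks, eval_seed)
        record = {
            "epoch": self.epoch + 1,
            "encoder_loss": float(np.mean(enc_losses)) if enc_losses else None,
            "decoder_loss": float(np.mean(dec_losses)) if dec_losses else None,
            "transcoder_loss": (
                float(np.mean(trans_losses)) if trans_losses else None
            ),
            "accuracy": report.get("accuracy"),
            "stability": report.get(
                "stability",
                float(np.mean(stabilities)) if stabilities else None,
            ),
            "noise_level": report.get("noise_level", 0.0),
            "perfect_fraction": report.get("perfect_fraction"),
        }
        return record

    def train(self, epochs: int) -> list:
        """Train until ``epochs`` total epochs are complete (resumable)."""
        if self.epoch == 0 and not os.path.exists(self.ckpt_dir):
            self.save()  # epoch-0 checkpoint of the initialized model
        while self.epoch < epochs:
            self._refresh_hypers()
            record = self._run_epoch()
            self.epoch += 1
            self.log.append(record)
            with open(self.log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
            self.save()
            logger.info(
                "epoch %d: acc=%s stability=%s", self.epoch,
                record["accuracy"], record["stability"],
            )
        return self.log


def constraint_config_to_dict(cfg: ConstraintConfig) -> dict:
    out = {}
    for name, graph in (("gc", cfg.gc_graph),
                        ("homopolymer", cfg.homopolymer_graph),
                        ("kmer", cfg.kmer_graph)):
        if graph is not None:
            entry = {
                "points": [{"x": float(x), "y": float(y)}
                           for x, y in zip(graph._x, graph._y)],
                "interpolation": graph.interpolation,
            }
            if name == "kmer":
                entry["k"] = cfg.kmer_k
            out[name] = entry
    if cfg.motifs:
        out["motifs"] = [
            {"motif": m.motif, "error_probability": m.error_probability,
             "description": m.description}
            for m in cfg.motifs
        ]
    if cfg.match_reverse_complement:
        out["match_reverse_complement"] = True
    return out


def train(cfg: CodecConfig, epochs: int, seed: int, workdir: str,
          channel: ChannelConfig | None = None,
          constraints: ConstraintConfig | None = None,
          loss_spec: LossSpec | None = None,
          hyper: TrainHyper | None = None,
          resume: bool = False, config_path: str | None = None):
    """Train a model; returns ``(log, checkpoint_dir)``."""
    if resume:
        trainer = Trainer.from_checkpoint(workdir, expected_cfg=cfg)
    else:
        trainer = Trainer(cfg, workdir, seed=seed, channel=channel,
                          constraints=constraints, loss_spec=loss_spec,
                          hyper=hyper, config_path=config_path)
    log = trainer.train(epochs)
    return log, trainer.ckpt_dir


def fine_tune_constraints(workdir: str, constraints: ConstraintConfig,
                          epochs: int, stability_weight: float = 1.0,
                          hyper: TrainHyper | None = None,
                          reseed: int | None = None):
    """Continue training from a checkpoint with the stability term enabled.

    ``epochs`` counts additional fine-tuning epochs on top of the
    checkpointed epoch counter.  ``reseed`` replaces the restored RNG
    stream (the default continues the checkpointed stream bit-exactly).
    """
    trainer = Trainer.from_checkpoint(workdir)
    trainer.constraints = constraints
    trainer.loss_spec.stability_weight = stability_weight
    if hyper is not None:
        trainer.hyper = hyper
        trainer.opt.lr = hyper.lr
    if reseed is not None:
        trainer.rng = np.random.default_rng(
            np.random.SeedSequence([reseed, 0xF17E])
        )
    log = trainer.train(trainer.epoch + epochs)
    return log, trainer.ckpt_dir
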