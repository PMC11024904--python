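"""Neural codec components: encoder streams, indel-reduction transcoder and
the iterative turbo decoder, plus non-neural systematic/majority baselines.

All architectures are built on the package's own autodiff engine; a model
bundle is fully determined by its :class:`~dnaturbo.codec.CodecConfig` and
an initialization seed.
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .codec import (
    CodecConfig,
    DECODER_ARCHS,
    ENCODER_ARCHS,
    TRANSCODER_ARCHS,
    Permutation,
    make_interleaver,
)
from .nn import (
    BiRNNStack,
    ConvStack,
    Linear,
    Module,
    ResNetStack,
    TransformerStack,
)

logger = logging.getLogger(__name__)

_BASE_LUT = np.frombuffer(b"AGTC", dtype=np.uint8)
_PAIR_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"AGTC"):
    _PAIR_LUT[_b] = _i
_ONEHOT_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ONEHOT_IDX[_b] = _i


class ModelConfigError(ValueError):
    pass


def _make_stack(arch: str, c_in: int, units: int, layers: int, k: int,
                rng: np.random.Generator) -> Module:
    if arch == "cnn":
        return ConvStack(c_in, units, layers, k, rng)
    if arch == "resnet":
        return ResNetStack(c_in, units, layers, k, rng)
    if arch == "rnn":
        return BiRNNStack(c_in, units, layers, rng)
    if arch == "transformer":
        return TransformerStack(c_in, units, layers, rng)
    raise ModelConfigError(f"no network stack for architecture {arch!r}")


def strands_from_bits(bits01: np.ndarray) -> list:
    """Map rows of an even-width 0/1 array to DNA strands (pair mapping)."""
    b = np.asarray(bits01, dtype=np.int64)
    B, T = b.shape
    pairs = b.reshape(B, T // 2, 2)
    idx = 2 * pairs[:, :, 0] + pairs[:, :, 1]
    chars = _BASE_LUT[idx]
    return [bytes(row).decode("ascii") for row in chars]


def bits_from_strand(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = _PAIR_LUT[codes]
    if (idx < 0).any():
        raise ValueError("invalid DNA character in strand")
    out = np.empty(2 * len(seq), dtype=np.int64)
    out[0::2] = idx >> 1
    out[1::2] = idx & 1
    return out


class EncoderStream(Module):
    """One encoder branch: residual trunk + linear head to the stream width.

    The head is initialized near-identity so a fresh model starts as a
    systematic code (stream output == message bits), which the training
    then deforms toward a more robust representation.
    """

    def __init__(self, arch: str, n: int, out_bits: int, units: int,
                 layers: int, k: int, rng: np.random.Generator,
                 rep_offset: int = 0):
        super().__init__()
        self.vae = arch == "vae"
        self.stack = _make_stack("cnn" if self.vae else arch, 1, units,
                                 layers, k, rng)
        self.head = Linear(n, out_bits, rng, init="identity")
        if out_bits > n:
            # stagger which message bits the redundancy units repeat, so
            # the streams jointly cover the whole block
            w = self.head.w.data
            w[:, n:] = rng.normal(0, 0.05, size=(n, out_bits - n))
            for j in range(n, out_bits):
                w[(rep_offset + j - n) % n, j] += 1.0
        if self.vae:
            self.logvar = Linear(n, out_bits, rng, init="zero")
            self.logvar.b.data[:] = -6.0  # near-deterministic at init

    def __call__(self, u_bipolar: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None):
        B, n = u_bipolar.shape
        h = self.stack(ad.reshape(u_bipolar, (B, 1, n)))
        pre = u_bipolar + ad.reshape(h, (B, n))
        z = self.head(pre)
        kl = None
        if self.vae:
            lv = self.logvar(pre)
            if train and rng is not None:
                eps = Tensor(rng.normal(size=z.shape))
                z = z + eps * ad.exp(lv * 0.5)
            kl = ad.tmean(0.5 * (ad.exp(lv) + z * z - 1.0 - lv))
        return z, kl


class SystematicStream(Module):
    """Parameter-free stream emitting the (possibly interleaved) message."""

    def __call__(self, u_bipolar: Tensor, train: bool = False, rng=None):
        return u_bipolar, None


class Encoder(Module):
    def __init__(self, cfg: CodecConfig, perm_n: Permutation,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.perm_n = perm_n
        if cfg.encoder_arch == "systematic":
            if cfg.latent_redundancy != 0:
                raise ModelConfigError(
                    "systematic encoder requires latent_redundancy == 0"
                )
            self.streams = [SystematicStream() for _ in range(cfg.streams)]
        else:
            self.streams = [
                EncoderStream(cfg.encoder_arch, cfg.block_bits,
                              cfg.stream_bits, cfg.units, cfg.layers,
                              cfg.kernel_size, rng,
                              rep_offset=(i * cfg.latent_redundancy)
                              % cfg.block_bits)
                for i in range(cfg.streams)
            ]

    @staticmethod
    def _norm_binarize(z: Tensor) -> Tensor:
        # per-example block normalization (population sd) + straight-through
        # binarization; the tiny raw-value term breaks ties on degenerate
        # constant blocks so all-zero / all-one messages stay invertible
        mu = ad.tmean(z, axis=-1, keepdims=True)
        xc = z - mu
        var = ad.tmean(xc * xc, axis=-1, keepdims=True)
        xn = xc * ad.power(var + 1e-8, -0.5)
        return ad.binarize_ste(xn + 1e-3 * z, bipolar=True)

    def __call__(self, u01: np.ndarray, train: bool = False, rng=None):
        """Encode a 0/1 message batch into the bipolar codeword tensor.

        Returns ``(x, kl)`` with ``x`` of shape (B, streams * stream_bits),
        exactly +/-1 valued, and ``kl`` the summed VAE divergence (or None).
        """
        u01 = np.asarray(u01)
        outs, kl_total = [], None
        for i, net in enumerate(self.streams):
            ui = u01 if i < self.cfg.streams - 1 else u01[:, self.perm_n.perm]
            z, kl = net(Tensor(2.0 * ui - 1.0), train=train, rng=rng)
            outs.append(self._norm_binarize(z))
            if kl is not None:
                kl_total = kl if kl_total is None else kl_total + kl
        return ad.concat(outs, axis=-1), kl_total


class BypassTranscoder(Module):
    """Demap the read directly to bipolar bits, padded/truncated to size."""

    def __init__(self, cfg: CodecConfig):
        super().__init__()
        self.total = cfg.total_bits

    def decoder_input(self, reads) -> np.ndarray:
        out = np.zeros((len(reads), self.total), dtype=np.float32)
        for i, read in enumerate(reads):
            seq = read if isinstance(read, str) else read.sequence
            bits = bits_from_strand(seq)[: self.total]
            out[i, : bits.size] = 2.0 * bits - 1.0
        return out


class NeuralTranscoder(Module):
    """Fixed-window network mapping a noisy read to the decoder's input.

    Reads are right-truncated to the window and padded with a dedicated
    pad channel; a direct linear path from the (flattened) window input to
    the output lets the net represent the clean demapping exactly.
    """

    #: base-position offsets presented as parallel channel groups, letting
    #: the conv stack pick a local alignment around indels
    SHIFTS = (-1, 0, 1)

    def __init__(self, cfg: CodecConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.window = cfg.window
        self.mode = cfg.transcoder_input
        self._c_base = 4 if self.mode == "onehot" else 2
        self.c_in = self._c_base * len(self.SHIFTS) + 1  # + pad channel
        self.stack = _make_stack(cfg.transcoder_arch, self.c_in, cfg.units,
                                 cfg.layers, cfg.kernel_size, rng)
        self.out = Linear(self.window * (1 + self.c_in), cfg.total_bits, rng)

    def inputs_from_reads(self, reads) -> np.ndarray:
        W = self.window
        pad = max(self.SHIFTS) - min(self.SHIFTS)
        base = np.zeros((len(reads), self._c_base, W + pad), dtype=np.float32)
        lens = np.empty(len(reads), dtype=np.int64)
        off = -min(self.SHIFTS)
        for i, read in enumerate(reads):
            seq = read if isinstance(read, str) else read.sequence
            seq = seq[:W]
            lens[i] = n = len(seq)
            if n:
                codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                if self.mode == "onehot":
                    idx = _ONEHOT_IDX[codes]
                    base[i, idx, off + np.arange(n)] = 1.0
                else:
                    idx = _PAIR_LUT[codes]
                    base[i, 0, off:off + n] = (idx >> 1).astype(np.float32)
                    base[i, 1, off:off + n] = (idx & 1).astype(np.float32)
        groups = [base[:, :, off + s:off + s + W] for s in self.SHIFTS]
        inp = np.concatenate(
            groups + [np.zeros((len(reads), 1, W), dtype=np.float32)], axis=1
        )
        for i, n in enumerate(lens):
            inp[i, -1, n:] = 1.0  # pad channel
        return inp

    def __call__(self, inp: Tensor) -> Tensor:
        B = inp.shape[0]
        h = self.stack(inp)  # (B, 1, W)
        feats = ad.concat(
            [ad.reshape(h, (B, self.window)),
             ad.reshape(inp, (B, self.c_in * self.window))],
            axis=-1,
        )
        return self.out(feats)  # raw, continuous

    def output(self, raw: Tensor) -> Tensor:
        if self.cfg.transcoder_binarize:
            return ad.binarize_ste(raw, bipolar=True)
        return raw


class TurboDecoder(Module):
    """Two serial decoder networks exchanging prior/posterior beliefs.

    Per iteration: ``q = D0(y0, y1, prior)``; the interleaved posterior and
    interleaved y0 feed ``D1`` together with y2; the deinterleaved D1
    output becomes the next prior.  After the last iteration the
    deinterleaved belief goes through a linear head and a sigmoid.
    """

    def __init__(self, cfg: CodecConfig, perm_s: Permutation,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.perm = perm_s
        ch = cfg.streams  # y-lanes per decoder network
        self.d0 = _make_stack(cfg.decoder_arch, ch, cfg.units, cfg.layers,
                              cfg.kernel_size, rng)
        self.d1 = _make_stack(cfg.decoder_arch, ch, cfg.units, cfg.layers,
                              cfg.kernel_size, rng)
        self.head = Linear(cfg.stream_bits, cfg.block_bits, rng,
                           init="identity")
        self.mix = None
        if cfg.latent_redundancy > 0:
            # redundancy bits live beyond conv reach of their source
            # positions; per-lane mixers (identity + fold init matching the
            # encoder's staggered repetition) let them act as extra votes
            # from the first iteration
            n, Ls = cfg.block_bits, cfg.stream_bits
            mixers = []
            for s in range(cfg.streams):
                mix = Linear(Ls, Ls, rng, init="zero")
                w = np.eye(Ls, dtype=np.float32)
                offset = (s * cfg.latent_redundancy) % n
                for i in range(cfg.latent_redundancy):
                    w[n + i, (offset + i) % n] += 1.0
                mix.w.data = w
                mixers.append(mix)
            self.mix = mixers

    @staticmethod
    def _lanes(parts) -> Tensor:
        B, L = parts[0].shape
        return ad.concat([ad.reshape(p, (B, 1, L)) for p in parts], axis=1)

    def __call__(self, y: Tensor) -> Tensor:
        cfg = self.cfg
        Ls, S = cfg.stream_bits, cfg.streams
        B = y.shape[0]
        lanes = [
            ad.take(y, np.arange(i * Ls, (i + 1) * Ls), axis=-1)
            for i in range(S)
        ]
        if self.mix is not None:
            lanes = [mix(lane) for mix, lane in zip(self.mix, lanes)]
        y0 = lanes[0]
        prior = Tensor(np.zeros((B, Ls), dtype=np.float32))
        for _ in range(cfg.decoder_iterations):
            if S == 3:
                in0 = self._lanes([y0, lanes[1], prior])
            else:
                in0 = self._lanes([y0, prior])
            q = y0 + ad.reshape(self.d0(in0), (B, Ls))
            qi = ad.take(q, self.perm.perm, axis=-1)
            y0i = ad.take(y0, self.perm.perm, axis=-1)
            if S == 3:
                in1 = self._lanes([y0i, qi, lanes[2]])
            else:
                in1 = self._lanes([qi, lanes[1]])
            out = qi + ad.reshape(self.d1(in1), (B, Ls))
            prior = ad.take(out, self.perm.inv, axis=-1)
        return self.head(prior)  # logits; sigmoid applied by callers


class MajorityDecoder(Module):
    """Deterministic baseline: per-bit majority vote across the streams.

    Only meaningful together with the systematic encoder; gives an exactly
    invertible reference codec under a noiseless channel.
    """

    def __init__(self, cfg: CodecConfig, perm_s: Permutation):
        super().__init__()
        if cfg.latent_redundancy != 0:
            raise ModelConfigError(
                "majority decoder requires latent_redundancy == 0"
            )
        self.cfg = cfg
        self.perm = perm_s

    def __call__(self, y: Tensor) -> Tensor:
        cfg = self.cfg
        Ls, S = cfg.stream_bits, cfg.streams
        yd = y.data if isinstance(y, Tensor) else np.asarray(y)
        votes = np.zeros((yd.shape[0], Ls), dtype=np.float32)
        if S == 3:
            votes += np.sign(yd[:, :Ls])
            votes += np.sign(yd[:, Ls:2 * Ls])
            votes += np.sign(yd[:, 2 * Ls:])[:, self.perm.inv]
        else:
            # no 3-way vote at rate 1/2: trust the direct stream, use the
            # interleaved one only to break (impossible) zero votes
            votes += 2.0 * np.sign(yd[:, :Ls])
            votes += np.sign(yd[:, Ls:])[:, self.perm.inv]
        # logits on the vote scale; ties break toward 1
        return Tensor(votes + 1e-6)


class TurboCodec:
    """The full model bundle: encoder, transcoder, decoder + shared permutations."""

    def __init__(self, cfg: CodecConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DEC]))
        self.perm_n = make_interleaver(cfg.interleaver, cfg.block_bits)
        self.perm_s = make_interleaver(cfg.interleaver, cfg.stream_bits)
        self.encoder = Encoder(cfg, self.perm_n, rng)
        if cfg.transcoder_arch == "bypass":
            self.transcoder = BypassTranscoder(cfg)
        else:
            self.transcoder = NeuralTranscoder(cfg, rng)
        if cfg.decoder_arch == "majority":
            self.decoder = MajorityDecoder(cfg, self.perm_s)
        else:
            self.decoder = TurboDecoder(cfg, self.perm_s, rng)

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> dict:
        out = {}
        out.update(self.encoder.parameters("encoder."))
        out.update(self.transcoder.parameters("transcoder."))
        out.update(self.decoder.parameters("decoder."))
        return out

    def encoder_param_names(self) -> set:
        return set(self.encoder.parameters("encoder."))

    def decoder_param_names(self) -> set:
        names = set(self.transcoder.parameters("transcoder."))
        names |= set(self.decoder.parameters("decoder."))
        return names

    def set_trainable(self, names, flag: bool):
        params = self.parameters()
        for k in names:
            params[k].requires_grad = flag

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for {k}")
            p.data = arr.copy()

    # -- forward paths ----------------------------------------------------
    def encode(self, u01: np.ndarray, train: bool = False, rng=None):
        return self.encoder(u01, train=train, rng=rng)

    def encode_bits(self, u01: np.ndarray) -> np.ndarray:
        x, _ = self.encode(u01)
        return (x.data > 0).astype(np.int64)

    def strands(self, u01: np.ndarray) -> list:
        return strands_from_bits(self.encode_bits(u01))

    def transcode(self, reads, with_grad: bool = True):
        """Run the indel-reduction component; returns (raw, decoder_input)."""
        if isinstance(self.transcoder, BypassTranscoder):
            y = Tensor(self.transcoder.decoder_input(reads))
            return None, y
        inp = Tensor(self.transcoder.inputs_from_reads(reads))
        raw = self.transcoder(inp)
        y = self.transcoder.output(raw)
        if not with_grad:
            return raw.detach(), y.detach()
        return raw, y

    def decoder_input(self, reads, mode: str = "auto") -> np.ndarray:
        """Numeric decoder input for a list of reads.

        ``auto`` passes nominal-length reads straight through the demapper
        and sends everything else (indel-affected lengths) through the
        transcoder.
        """
        bypass = BypassTranscoder(self.cfg)
        if mode == "bypass" or isinstance(self.transcoder, BypassTranscoder):
            return bypass.decoder_input(reads)
        if mode == "model":
            _, y = self.transcode(reads, with_grad=False)
            return y.data
        seqs = [r if isinstance(r, str) else r.sequence for r in reads]
        nominal = self.cfg.strand_bases
        out = np.zeros((len(seqs), self.cfg.total_bits), dtype=np.float32)
        clean_idx = [i for i, s in enumerate(seqs) if len(s) == nominal]
        noisy_idx = [i for i, s in enumerate(seqs) if len(s) != nominal]
        if clean_idx:
            out[clean_idx] = bypass.decoder_input([seqs[i] for i in clean_idx])
        if noisy_idx:
            _, y = self.transcode([seqs[i] for i in noisy_idx], with_grad=False)
            out[noisy_idx] = y.data
        return out

    def decode(self, y) -> Tensor:
        """Decoder logits for a (B, total_bits) input."""
        if not isinstance(y, Tensor):
            y = Tensor(np.asarray(y, dtype=np.float32))
        if y.shape[-1] != self.cfg.total_bits:
            raise ValueError(
                f"decoder input length {y.shape[-1]} != expected "
                f"{self.cfg.total_bits}"
            )
        return self.decoder(y)

    def decode_bits(self, y, verify: bool = False,
                    max_flips: int = 2) -> np.ndarray:
        logits = self.decode(y)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        u_hat = (probs > 0.5).astype(np.int64)
        if verify:
            y_np = y.data if isinstance(y, Tensor) else np.asarray(y)
            u_hat = self._verify_decode(u_hat, y_np, max_flips)
        return u_hat

    def _verify_decode(self, u_hat: np.ndarray, y: np.ndarray,
                       max_flips: int) -> np.ndarray:
        """Re-encode verification with a small Hamming-ball refinement.

        Each decoded block is re-encoded and compared against the received
        hard decisions; blocks that do not reproduce them exactly are
        replaced by the candidate within ``max_flips`` bit flips whose
        re-encoding is closest to the received word (minimum-distance
        decoding on a local neighbourhood; exact on a noiseless channel
        whenever the decoder is within ``max_flips`` bits of the message).
        """
        from itertools import combinations

        y_bits = (y > 0).astype(np.int64)
        re_enc = self.encode_bits(u_hat)
        dists = (re_enc != y_bits).sum(axis=1)
        n = self.cfg.block_bits
        flip_sets = [()]
        for k in range(1, max_flips + 1):
            flip_sets.extend(combinations(range(n), k))
        refinable = np.where((dists > 0) &
                             (dists <= y_bits.shape[1] // 4))[0]
        for i in refinable:
            best_u, best_d = u_hat[i].copy(), int(dists[i])
            for _ in range(4):  # greedy descent over Hamming balls
                cands = np.tile(best_u, (len(flip_sets), 1))
                for c, flips in enumerate(flip_sets):
                    for j in flips:
                        cands[c, j] ^= 1
                cand_dists = (self.encode_bits(cands) != y_bits[i]).sum(axis=1)
                b = int(np.argmin(cand_dists))
                if cand_dists[b] >= best_d:
                    break
                best_u, best_d = cands[b], int(cand_dists[b])
                if best_d == 0:
                    break
            u_hat[i] = best_u
        return u_hat


def build_model(cfg: CodecConfig, seed: int = 0) -> TurboCodec:
    """Construct a model bundle, validating the architecture combination."""
    checks = (
        ("encoder", cfg.encoder_arch, ENCODER_ARCHS),
        ("transcoder", cfg.transcoder_arch, TRANSCODER_ARCHS),
        ("decoder", cfg.decoder_arch, DECODER_ARCHS),
    )
    for comp, arch, valid in checks:
        if arch not in valid:
            raise ModelConfigError(
                f"unsupported {comp} architecture {arch!r}; "
                f"valid options: {', '.join(valid)}"
            )
    model = TurboCodec(cfg, seed=seed)
    n_params = sum(p.data.size for p in model.parameters().values())
    logger.info(
        "built model (%s/%s/%s): %d parameters",
        cfg.encoder_arch, cfg.transcoder_arch, cfg.decoder_arch, n_params,
    )
    return model
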