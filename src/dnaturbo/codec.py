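"""Deterministic codec machinery.

Interleaver construction, block normalization, binarization, the bit-pair
to nucleotide mapping and its inverse, code-rate accounting and payload
segmentation.  Everything in this module is non-neural and exactly
reproducible; the neural components build on these primitives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "InterleaverSpec",
    "Permutation",
    "CodecConfig",
    "make_interleaver",
    "normalize_block",
    "binarize",
    "bits_to_dna",
    "dna_to_bits",
    "code_rate",
    "segment_payload",
    "reassemble_payload",
    "PayloadHeader",
]

# bit pair (b0, b1) -> base, indexed by 2*b0 + b1
_PAIR_TO_BASE = "AGTC"
_BASE_TO_PAIR = {"A": (0, 0), "G": (0, 1), "T": (1, 0), "C": (1, 1)}


class InvalidSpecError(ValueError):
    """Raised for interleaver specs that do not define a bijection."""


@dataclass(frozen=True)
class InterleaverSpec:
    """How the shared message permutation is generated.

    ``pseudo_random`` derives a permutation of any requested length from
    ``seed``; ``deterministic`` uses the affine rule ``pi(n) = k*n + u mod N``
    which is a bijection iff ``gcd(k, N) == 1``.
    """

    mode: str = "pseudo_random"
    seed: int = 0
    k: int = 1
    u: int = 0

    def __post_init__(self):
        if self.mode not in ("pseudo_random", "deterministic"):
            raise InvalidSpecError(f"unknown interleaver mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InterleaverSpec":
        return cls(**d)


class Permutation:
    """A bijection on ``[0, N)`` with a cached inverse."""

    def __init__(self, perm: np.ndarray):
        perm = np.asarray(perm, dtype=np.int64)
        n = perm.size
        if sorted(perm.tolist()) != list(range(n)):
            raise InvalidSpecError("array is not a permutation of [0, N)")
        self.perm = perm
        self.inv = np.empty(n, dtype=np.int64)
        self.inv[perm] = np.arange(n)

    def __len__(self) -> int:
        return self.perm.size

    def apply(self, x: np.ndarray, axis: int = -1) -> np.ndarray:
        """Return ``x`` re-ordered so entry ``i`` holds ``x[pi(i)]``."""
        return np.take(x, self.perm, axis=axis)

    def invert(self, x: np.ndarray, axis: int = -1) -> np.ndarray:
        return np.take(x, self.inv, axis=axis)


def make_interleaver(spec: InterleaverSpec, length: int) -> Permutation:
    """Build the shared permutation of ``length`` elements from ``spec``.

    Raises :class:`InvalidSpecError` in deterministic mode when
    ``gcd(k, length) != 1`` (the affine map would not be bijective).
    """
    if length <= 0:
        raise InvalidSpecError("interleaver length must be positive")
    if spec.mode == "deterministic":
        if math.gcd(spec.k, length) != 1:
            raise InvalidSpecError(
                f"k={spec.k} is not coprime to N={length}; pi(n)=k*n+u mod N "
                "is not a bijection"
            )
        n = np.arange(length, dtype=np.int64)
        return Permutation((spec.k * n + spec.u) % length)
    # pseudo-random: fold the length into the seed so one spec yields an
    # independent, reproducible permutation per requested length
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, length]))
    return Permutation(rng.permutation(length))


def normalize_block(values: np.ndarray) -> np.ndarray:
    """Center and scale one encoder-stream block to mean 0, population sd 1.

    A degenerate (constant) block cannot be scaled; it is returned as zeros
    with a warning rather than raising, so a pathological batch does not
    abort training.
    """
    values = np.asarray(values, dtype=np.float64)
    mu = values.mean()
    sigma = values.std()  # population sd
    if sigma == 0:
        warnings.warn("constant block passed to normalize_block; returning zeros")
        return np.zeros_like(values)
    return (values - mu) / sigma


def binarize(x: np.ndarray, bipolar: bool = False) -> np.ndarray:
    """Sign-threshold at 0 (ties map to 1).

    This is the forward pass only; the straight-through gradient contract
    lives in :mod:`dnaturbo.autodiff`.
    """
    b = (np.asarray(x) >= 0).astype(np.float64)
    if bipolar:
        return 2.0 * b - 1.0
    return b


def bits_to_dna(bits: Iterable[int]) -> str:
    """Map an even-length bit vector to DNA, two bits per base.

    The pair mapping is 00->A, 01->G, 10->T, 11->C.
    """
    arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits)
    arr = arr.astype(np.int64).ravel()
    if arr.size % 2 != 0:
        raise ValueError("bit vector length must be even to map to bases")
    if arr.size == 0:
        return ""
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bit vector must contain only 0/1")
    idx = 2 * arr[0::2] + arr[1::2]
    return "".join(_PAIR_TO_BASE[i] for i in idx)


def dna_to_bits(seq: str) -> np.ndarray:
    """Exact inverse of :func:`bits_to_dna`."""
    out = np.empty(2 * len(seq), dtype=np.int64)
    for i, base in enumerate(seq):
        try:
            b0, b1 = _BASE_TO_PAIR[base]
        except KeyError:
            raise ValueError(f"invalid DNA character {base!r} at position {i}")
        out[2 * i] = b0
        out[2 * i + 1] = b1
    return out


ENCODER_ARCHS = ("cnn", "rnn", "vae", "transformer", "systematic")
TRANSCODER_ARCHS = ("cnn", "rnn", "resnet", "bypass")
DECODER_ARCHS = ("cnn", "rnn", "resnet", "transformer", "majority")


@dataclass
class CodecConfig:
    """Full configuration of a codec instance.

    ``rate_mode`` selects two ("half") or three ("third") encoder streams;
    ``latent_redundancy`` adds that many output units per stream beyond the
    block length, fractionally lowering the code rate.
    """

    block_bits: int = 24
    rate_mode: str = "third"
    latent_redundancy: int = 0
    decoder_iterations: int = 6
    beta: float = 1.0
    interleaver: InterleaverSpec = field(default_factory=InterleaverSpec)
    encoder_arch: str = "cnn"
    transcoder_arch: str = "resnet"
    decoder_arch: str = "cnn"
    units: int = 24
    layers: int = 2
    kernel_size: int = 5
    window_margin: int = 8
    transcoder_input: str = "onehot"  # "onehot" quaternary or "bits"
    transcoder_binarize: bool = True
    kl_weight: float = 0.0

    def __post_init__(self):
        if self.block_bits <= 0:
            raise ValueError("block_bits must be positive")
        if self.rate_mode not in ("half", "third"):
            raise ValueError("rate_mode must be 'half' or 'third'")
        if self.latent_redundancy < 0:
            raise ValueError("latent_redundancy must be >= 0")
        if self.decoder_iterations < 1:
            raise ValueError("decoder_iterations must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if (self.streams * self.stream_bits) % 2 != 0:
            raise ValueError("total encoded bits must be even to map to bases")

    @property
    def streams(self) -> int:
        return 2 if self.rate_mode == "half" else 3

    @property
    def stream_bits(self) -> int:
        return self.block_bits + self.latent_redundancy

    @property
    def total_bits(self) -> int:
        return self.streams * self.stream_bits

    @property
    def strand_bases(self) -> int:
        return self.total_bits // 2

    @property
    def window(self) -> int:
        """Transcoder input window: nominal strand length plus an indel margin."""
        return self.strand_bases + self.window_margin

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interleaver"] = self.interleaver.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CodecConfig":
        d = dict(d)
        if isinstance(d.get("interleaver"), dict):
            d["interleaver"] = InterleaverSpec.from_dict(d["interleaver"])
        return cls(**d)


def code_rate(cfg: CodecConfig) -> float:
    """Data bits per transmitted bit: ``block / (streams * (block + redundancy))``."""
    return cfg.block_bits / (cfg.streams * (cfg.block_bits + cfg.latent_redundancy))


@dataclass
class PayloadHeader:
    """Reassembly metadata for a segmented payload."""

    payload_bits: int
    block_bits: int

    @property
    def n_blocks(self) -> int:
        return -(-self.payload_bits // self.block_bits) if self.payload_bits else 0

    @property
    def pad_bits(self) -> int:
        if self.payload_bits == 0:
            return 0
        return self.n_blocks * self.block_bits - self.payload_bits

    def to_block(self) -> np.ndarray:
        """Encode the payload bit-length as one big-endian block of bits."""
        if self.payload_bits >= 1 << self.block_bits:
            raise ValueError(
                f"payload of {self.payload_bits} bits does not fit a "
                f"{self.block_bits}-bit header block"
            )
        s = format(self.payload_bits, f"0{self.block_bits}b")
        return np.array([int(c) for c in s], dtype=np.int64)

    @classmethod
    def from_block(cls, block: np.ndarray) -> "PayloadHeader":
        bits = "".join(str(int(b)) for b in np.asarray(block).ravel())
        return cls(payload_bits=int(bits, 2) if bits else 0,
                   block_bits=len(bits))


def segment_payload(data: bytes, block_bits: int):
    """Split a byte payload into fixed-size bit blocks plus a header.

    The final block is zero-padded; the header records the true payload bit
    length so :func:`reassemble_payload` inverts exactly.
    """
    if block_bits <= 0:
        raise ValueError("block_bits must be positive")
    header = PayloadHeader(payload_bits=8 * len(data), block_bits=block_bits)
    if not data:
        return [], header
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8)).astype(np.int64)
    padded = np.zeros(header.n_blocks * block_bits, dtype=np.int64)
    padded[: bits.size] = bits
    blocks = [padded[i * block_bits:(i + 1) * block_bits]
              for i in range(header.n_blocks)]
    return blocks, header


def reassemble_payload(blocks, header: PayloadHeader) -> bytes:
    """Invert :func:`segment_payload`, stripping the recorded padding."""
    if header.payload_bits == 0:
        return b""
    if len(blocks) != header.n_blocks:
        missing = sorted(set(range(header.n_blocks)) -
                         set(range(len(blocks))))
        raise ValueError(
            f"expected {header.n_blocks} blocks, got {len(blocks)} "
            f"(missing indices {missing})"
        )
    bits = np.concatenate([np.asarray(b).ravel() for b in blocks])
    bits = bits[: header.payload_bits].astype(np.uint8)
    return np.packbits(bits).tobytes()
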