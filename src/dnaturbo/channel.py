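"""DNA data storage channel simulation.

Injects substitutions, insertions and deletions into DNA sequences
according to a configurable, amplifiable error profile.  Profiles are
loaded from JSON; both a native layout and the MESA-style export layout
(per-component ``err_rate`` plus ``err_data`` proportions) are accepted
and normalized on load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

EVENT_TYPES = ("substitution", "insertion", "deletion")


class ChannelConfigError(ValueError):
    """Malformed or out-of-range channel configuration."""


@dataclass
class ErrorSource:
    """One channel component (synthesis, sequencing, PCR, storage, ...).

    Rates are per-base event probabilities in [0, 1].  ``substitution_bias``
    optionally maps an original base to a probability distribution over the
    three replacement bases; absent entries fall back to uniform.
    """

    name: str
    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    substitution_bias: Optional[dict] = None

    def __post_init__(self):
        for attr in ("substitution", "insertion", "deletion"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ChannelConfigError(
                    f"source {self.name!r}: {attr} rate {v} outside [0, 1]"
                )

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion

    def scaled(self, factor: float) -> "ErrorSource":
        return ErrorSource(
            name=self.name,
            substitution=self.substitution * factor,
            insertion=self.insertion * factor,
            deletion=self.deletion * factor,
            substitution_bias=self.substitution_bias,
        )


@dataclass
class ChannelConfig:
    """A set of error sources making up the full storage channel."""

    sources: list = field(default_factory=list)
    amplifier_total: Optional[float] = None

    @property
    def substitution(self) -> float:
        return sum(s.substitution for s in self.sources)

    @property
    def insertion(self) -> float:
        return sum(s.insertion for s in self.sources)

    @property
    def deletion(self) -> float:
        return sum(s.deletion for s in self.sources)

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion

    @property
    def proportions(self) -> tuple:
        """Relative sub:ins:del proportions (nan-free; zero total -> zeros)."""
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.substitution / t, self.insertion / t, self.deletion / t)

    def substitution_matrix(self) -> np.ndarray:
        """4x3 replacement distribution per original base.

        Row i: distribution over the three bases != BASES[i], ordered by
        base index.  Sources with a bias contribute proportionally to their
        substitution rate; unbiased mass is uniform.
        """
        mat = np.zeros((4, 4))
        total_sub = self.substitution
        if total_sub == 0:
            mat[:] = 1.0
        else:
            for src in self.sources:
                if src.substitution == 0:
                    continue
                w = src.substitution / total_sub
                for i, orig in enumerate(BASES):
                    bias = (src.substitution_bias or {}).get(orig)
                    if bias:
                        for repl, p in bias.items():
                            mat[i, _BASE_IDX[repl]] += w * float(p)
                    else:
                        for j in range(4):
                            if j != i:
                                mat[i, j] += w / 3.0
        np.fill_diagonal(mat, 0.0)
        rows = mat.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return mat / rows

    def to_dict(self) -> dict:
        return {
            "error_sources": [
                {
                    "name": s.name,
                    "substitution": s.substitution,
                    "insertion": s.insertion,
                    "deletion": s.deletion,
                    **(
                        {"substitution_bias": s.substitution_bias}
                        if s.substitution_bias
                        else {}
                    ),
                }
                for s in self.sources
            ],
            "amplifier_total": self.amplifier_total,
        }


def amplify(config: ChannelConfig, target_total: float) -> ChannelConfig:
    """Scale every rate so the summed per-base rate equals ``target_total``.

    Relative error-type proportions and per-source contributions are
    preserved exactly (one multiplication per rate).
    """
    if config.total == 0:
        raise ChannelConfigError("cannot amplify a zero-rate channel config")
    if not (0.0 < target_total <= 1.0):
        raise ChannelConfigError(f"target total {target_total} outside (0, 1]")
    factor = target_total / config.total
    return ChannelConfig(
        sources=[s.scaled(factor) for s in config.sources],
        amplifier_total=target_total,
    )


_NATIVE_SOURCE_KEYS = {"name", "substitution", "insertion", "deletion",
                       "substitution_bias"}


def _source_from_native(entry: dict) -> ErrorSource:
    unknown = set(entry) - _NATIVE_SOURCE_KEYS
    if unknown:
        logger.warning("ignoring unknown error-source keys: %s", sorted(unknown))
    return ErrorSource(
        name=str(entry.get("name", "unnamed")),
        substitution=float(entry.get("substitution", 0.0)),
        insertion=float(entry.get("insertion", 0.0)),
        deletion=float(entry.get("deletion", 0.0)),
        substitution_bias=entry.get("substitution_bias"),
    )


def _source_from_mesa(name: str, entry: dict) -> ErrorSource:
    # MESA exports a per-component total error rate plus err_data proportions
    # for mismatch/insertion/deletion.  Positional/pattern conditioning beyond
    # flat rates ("err_attributes") is collapsed to flat per-base rates.
    rate = float(entry.get("err_rate", entry.get("error_rate", 0.0)))
    data = entry.get("err_data", {})
    sub_p = float(data.get("mismatch", data.get("substitution", 0.0)))
    ins_p = float(data.get("insertion", 0.0))
    del_p = float(data.get("deletion", 0.0))
    if "err_attributes" in entry:
        logger.warning(
            "source %r: err_attributes pattern conditioning collapsed to "
            "flat per-base rates", name,
        )
    psum = sub_p + ins_p + del_p
    if psum > 0:
        sub_p, ins_p, del_p = sub_p / psum, ins_p / psum, del_p / psum
    return ErrorSource(
        name=name,
        substitution=rate * sub_p,
        insertion=rate * ins_p,
        deletion=rate * del_p,
    )


def channel_config_from_dict(raw: dict) -> ChannelConfig:
    """Normalize either JSON dialect into a :class:`ChannelConfig`."""
    if not isinstance(raw, dict):
        raise ChannelConfigError("channel config must be a JSON object")
    sources = []
    if "error_sources" in raw:
        if not isinstance(raw["error_sources"], list):
            raise ChannelConfigError("'error_sources' must be a list")
        sources = [_source_from_native(e) for e in raw["error_sources"]]
        extra = set(raw) - {"error_sources", "amplifier_total"}
        if extra:
            logger.warning("ignoring unknown channel-config keys: %s",
                           sorted(extra))
    else:
        for key, val in raw.items():
            if key == "amplifier_total":
                continue
            if isinstance(val, dict) and (
                "err_rate" in val or "error_rate" in val
            ):
                sources.append(_source_from_mesa(key, val))
            else:
                logger.warning("ignoring unknown channel-config key %r", key)
        if not sources:
            raise ChannelConfigError(
                "no error sources found (expected 'error_sources' or "
                "MESA-style component entries)"
            )
    cfg = ChannelConfig(sources=sources,
                        amplifier_total=raw.get("amplifier_total"))
    if cfg.amplifier_total is not None:
        cfg = amplify(cfg, float(cfg.amplifier_total))
    return cfg


def load_channel_config(path) -> ChannelConfig:
    """Load and validate a channel configuration JSON file."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as e:
            raise ChannelConfigError(
                f"malformed channel config JSON at {path}: {e}"
            ) from e
    return channel_config_from_dict(raw)


@dataclass
class NoisyRead:
    """Channel output for one strand plus its complete event log.

    Event positions refer to the clean input coordinates; replaying the log
    on the clean input reproduces ``sequence`` exactly.
    """

    sequence: str
    event_log: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def replay_events(clean: str, event_log) -> str:
    """Apply an event log to the clean input, reproducing the noisy read."""
    by_pos = {}
    for pos, etype, orig, repl in event_log:
        by_pos.setdefault(pos, []).append((etype, orig, repl))
    out = []
    for i, base in enumerate(clean):
        events = by_pos.get(i, [])
        emitted = base
        inserted = None
        for etype, orig, repl in events:
            if etype == "substitution":
                emitted = repl
            elif etype == "deletion":
                emitted = None
            elif etype == "insertion":
                inserted = repl
        if emitted is not None:
            out.append(emitted)
        if inserted is not None:
            out.append(inserted)
    return "".join(out)


def transmit(seq: str, config: ChannelConfig,
             rng: np.random.Generator) -> NoisyRead:
    """Pass one strand through the channel.

    Each position independently suffers at most one event, drawn from a
    categorical over {none, substitution, insertion, deletion} with the
    configured summed per-type rates.  Insertions place one uniform-random
    base after the position; substitutions draw a different base from the
    (possibly biased) replacement distribution.
    """
    if not seq:
        raise ValueError("cannot transmit an empty sequence")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.size, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        idx[arr == ord(b)] = i
    if (idx < 0).any():
        bad = seq[int(np.argmax(idx < 0))]
        raise ValueError(f"invalid DNA character {bad!r} in input sequence")

    p_sub, p_ins, p_del = config.substitution, config.insertion, config.deletion
    n = len(seq)
    u = rng.random(n)
    # categorical thresholds: [0,sub) sub, [sub,sub+ins) ins, [..,+del) del
    ev = np.zeros(n, dtype=np.int64)  # 0 none, 1 sub, 2 ins, 3 del
    ev[u < p_sub + p_ins + p_del] = 3
    ev[u < p_sub + p_ins] = 2
    ev[u < p_sub] = 1

    submat = config.substitution_matrix() if (ev == 1).any() else None
    out = []
    log = []
    for i in range(n):
        base = seq[i]
        e = ev[i]
        if e == 0:
            out.append(base)
        elif e == 1:
            repl = BASES[rng.choice(4, p=submat[idx[i]])]
            out.append(repl)
            log.append((i, "substitution", base, repl))
        elif e == 2:
            ins = BASES[rng.integers(4)]
            out.append(base)
            out.append(ins)
            log.append((i, "insertion", base, ins))
        else:
            log.append((i, "deletion", base, None))
    return NoisyRead(sequence="".join(out), event_log=log)


def transmit_batch(seqs: Sequence[str], config: ChannelConfig,
                   rng: np.random.Generator) -> list:
    """Vectorized-draw transmission of many strands (training hot path).

    Equivalent in distribution to calling :func:`transmit` per strand but
    draws all event categories in one shot; strands that received no indel
    are handled without per-base Python loops.
    """
    if not seqs:
        return []
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64)
    total = int(lens.sum())
    p_sub, p_ins, p_del = config.substitution, config.insertion, config.deletion
    u = rng.random(total)
    ev = np.zeros(total, dtype=np.int64)
    ev[u < p_sub + p_ins + p_del] = 3
    ev[u < p_sub + p_ins] = 2
    ev[u < p_sub] = 1
    submat = config.substitution_matrix() if (ev == 1).any() else None

    reads = []
    off = 0
    for s, ln in zip(seqs, lens):
        e = ev[off:off + ln]
        off += ln
        if not e.any():
            reads.append(NoisyRead(sequence=s, event_log=[]))
            continue
        out = []
        log = []
        for i, base in enumerate(s):
            ei = e[i]
            if ei == 0:
                out.append(base)
            elif ei == 1:
                repl = BASES[rng.choice(4, p=submat[_BASE_IDX[base]])]
                out.append(repl)
                log.append((i, "substitution", base, repl))
            elif ei == 2:
                ins = BASES[rng.integers(4)]
                out.append(base)
                out.append(ins)
                log.append((i, "insertion", base, ins))
            else:
                log.append((i, "deletion", base, None))
        reads.append(NoisyRead(sequence="".join(out), event_log=log))
    return reads


def random_strands(n: int, length: int, rng: np.random.Generator) -> list:
    """Uniform-random DNA strands (calibration / test helper)."""
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[j] for j in row) for row in draws]


def empirical_error_rate(config: ChannelConfig, n_seqs: int, seq_len: int,
                         seed: int) -> float:
    """Transmit random strands and return total events / total bases."""
    if n_seqs <= 0 or seq_len <= 0:
        raise ValueError("n_seqs and seq_len must be positive")
    rng = np.random.default_rng(seed)
    strands = random_strands(n_seqs, seq_len, rng)
    reads = transmit_batch(strands, config, rng)
    events = sum(len(r.event_log) for r in reads)
    return events / (n_seqs * seq_len)
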