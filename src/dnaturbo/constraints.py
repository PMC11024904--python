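"""Constraint evaluation for encoded DNA strands.

Each constraint (GC content, homopolymer run length, k-mer repeat count,
undesired motifs) maps a sequence feature to an error probability in
percent via a user-defined probability graph; per-sequence probabilities
combine under an independent-failure product and batches are summarized by
the stability score ``w = 1 - mean(p)`` on the [0, 1] scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


class ConstraintConfigError(ValueError):
    pass


@dataclass
class ProbabilityGraph:
    """Piecewise curve mapping a constraint value to an error probability (%).

    ``points`` are (x, y) pairs with strictly increasing x and y in
    [0, 100].  Evaluation clamps x to the covered range; between points the
    curve is either linearly interpolated (default) or stepwise (y of the
    greatest point with point.x <= x).
    """

    points: list
    interpolation: str = "linear"

    def __post_init__(self):
        if not self.points:
            raise ConstraintConfigError("probability graph needs >= 1 point")
        xs = [float(p[0]) for p in self.points]
        ys = [float(p[1]) for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConstraintConfigError("graph x values must strictly increase")
        if any(not (0.0 <= y <= 100.0) for y in ys):
            raise ConstraintConfigError("graph y values must lie in [0, 100]")
        if self.interpolation not in ("linear", "step"):
            raise ConstraintConfigError(
                f"unknown interpolation {self.interpolation!r}"
            )
        self._x = np.array(xs)
        self._y = np.array(ys)

    def evaluate(self, x: float) -> float:
        """Error probability (%) at constraint value ``x`` (clamped)."""
        xv = float(np.clip(x, self._x[0], self._x[-1]))
        if self.interpolation == "step":
            i = int(np.searchsorted(self._x, xv, side="right")) - 1
            return float(self._y[max(i, 0)])
        return float(np.interp(xv, self._x, self._y))


def evaluate_graph(graph: ProbabilityGraph, x: float) -> float:
    return graph.evaluate(x)


@dataclass
class MotifEntry:
    motif: str
    error_probability: float
    description: str = ""

    def __post_init__(self):
        if not self.motif or set(self.motif) - _VALID:
            raise ConstraintConfigError(
                f"motif {self.motif!r} must be nonempty over ACGT"
            )
        if not (0.0 <= self.error_probability <= 100.0):
            raise ConstraintConfigError(
                f"motif probability {self.error_probability} outside [0, 100]"
            )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConstraintConfig:
    """The full constraint set; any absent part contributes probability 0."""

    gc_graph: Optional[ProbabilityGraph] = None
    homopolymer_graph: Optional[ProbabilityGraph] = None
    kmer_graph: Optional[ProbabilityGraph] = None
    kmer_k: int = 10
    motifs: list = field(default_factory=list)
    match_reverse_complement: bool = False


def gc_percent(seq: str) -> float:
    """GC content in percent: 100 * (#G + #C) / length."""
    if not seq:
        raise ValueError("gc_percent of empty sequence")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest run of one identical base."""
    if not seq:
        raise ValueError("max_homopolymer of empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def max_kmer_count(seq: str, k: int) -> int:
    """Maximum overlapping occurrence count over all k-mers of ``seq``."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(seq) < k:
        return 0
    counts = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        counts[km] = counts.get(km, 0) + 1
    return max(counts.values())


def sequence_error_probability(seq: str, cfg: ConstraintConfig) -> float:
    """Combined error probability (%) of one strand under ``cfg``.

    Individual constraint probabilities combine as independent failure
    modes: ``p = 100 * (1 - prod(1 - p_c/100))``.
    """
    if set(seq) - _VALID:
        raise ValueError("sequence contains non-ACGT characters")
    probs = []
    if cfg.gc_graph is not None:
        probs.append(cfg.gc_graph.evaluate(gc_percent(seq)))
    if cfg.homopolymer_graph is not None:
        probs.append(cfg.homopolymer_graph.evaluate(max_homopolymer(seq)))
    if cfg.kmer_graph is not None:
        probs.append(cfg.kmer_graph.evaluate(max_kmer_count(seq, cfg.kmer_k)))
    for m in cfg.motifs:
        hit = m.motif in seq
        if not hit and cfg.match_reverse_complement:
            hit = reverse_complement(m.motif) in seq
        if hit:
            probs.append(m.error_probability)
    surv = 1.0
    for p in probs:
        surv *= 1.0 - p / 100.0
    return 100.0 * (1.0 - surv)


@dataclass
class StabilityBatch:
    """Per-block error probabilities on [0, 1] plus their stability score.

    Construction is the single place percent-scale probabilities are
    normalized to [0, 1].
    """

    probabilities: np.ndarray
    w: float

    @classmethod
    def from_percent(cls, percents: Sequence[float]) -> "StabilityBatch":
        probs = np.asarray(percents, dtype=np.float64) / 100.0
        return cls(probabilities=probs, w=stability_score(probs))

    @property
    def n(self) -> int:
        return self.probabilities.size


def stability_score(probabilities: Sequence[float]) -> float:
    """``1 - mean(x_i)`` over per-block error probabilities on [0, 1]."""
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("stability score of an empty batch is undefined")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - probs.mean())


def batch_stability(seqs: Sequence[str], cfg: ConstraintConfig) -> StabilityBatch:
    """Evaluate every strand and build the batch stability summary."""
    return StabilityBatch.from_percent(
        [sequence_error_probability(s, cfg) for s in seqs]
    )


def _graph_from_json(obj) -> ProbabilityGraph:
    if isinstance(obj, dict):
        pts = obj.get("points", obj.get("data"))
        interp = obj.get("interpolation", "linear")
    else:
        pts, interp = obj, "linear"
    if pts is None:
        raise ConstraintConfigError("graph entry lacks 'points'/'data'")
    points = []
    for p in pts:
        if isinstance(p, dict):
            points.append((float(p["x"]), float(p["y"])))
        else:
            points.append((float(p[0]), float(p[1])))
    return ProbabilityGraph(points=points, interpolation=interp)


_GRAPH_KEYS = {
    "gc_graph": ("gc", "gc_graph", "gc_error_prob"),
    "homopolymer_graph": ("homopolymer", "homopolymer_graph",
                          "homopolymer_error_prob"),
    "kmer_graph": ("kmer", "kmer_graph", "kmer_error_prob"),
}


def constraint_config_from_dict(raw: dict) -> ConstraintConfig:
    """Accept the native layout or MESA-style key names."""
    if not isinstance(raw, dict):
        raise ConstraintConfigError("constraint config must be a JSON object")
    kwargs = {}
    used = set()
    for attr, aliases in _GRAPH_KEYS.items():
        for key in aliases:
            if key in raw:
                entry = raw[key]
                kwargs[attr] = _graph_from_json(entry)
                if attr == "kmer_graph" and isinstance(entry, dict):
                    kwargs["kmer_k"] = int(entry.get("k", 10))
                used.add(key)
                break
    motifs_raw = None
    for key in ("motifs", "undesired_motifs"):
        if key in raw:
            motifs_raw = raw[key]
            used.add(key)
            break
    if motifs_raw:
        kwargs["motifs"] = [
            MotifEntry(
                motif=str(m["motif"]).upper(),
                error_probability=float(
                    m.get("error_probability", m.get("errorprob", 100.0))
                ),
                description=str(m.get("description", "")),
            )
            for m in motifs_raw
        ]
    if "match_reverse_complement" in raw:
        kwargs["match_reverse_complement"] = bool(raw["match_reverse_complement"])
        used.add("match_reverse_complement")
    unknown = set(raw) - used
    if unknown:
        logger.warning("ignoring unknown constraint-config keys: %s",
                       sorted(unknown))
    return ConstraintConfig(**kwargs)


def load_constraint_config(path) -> ConstraintConfig:
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as e:
            raise ConstraintConfigError(
                f"malformed constraint config JSON at {path}: {e}"
            ) from e
    return constraint_config_from_dict(raw)
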