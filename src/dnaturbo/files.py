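"""FASTA strand interchange and whole-file encode/decode.

Strand sets are exchanged as FASTA with record IDs ``strand_<zero-padded
index>``; strand 0 is a header strand carrying the payload bit-length so
reassembly is order-independent and exact.
"""

from __future__ import annotations

import logging
import re

import numpy as np

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import PayloadHeader, reassemble_payload, segment_payload
from .models import TurboCodec

logger = logging.getLogger(__name__)

_ID_RE = re.compile(r"(?:strand_)?0*(\d+)$")


class DecodeError(RuntimeError):
    pass


def write_strands_fasta(path, strands, ids=None):
    """Write strands to FASTA (wrapped at 80 columns, IDs zero-padded)."""
    strands = list(strands)
    width = max(4, len(str(max(len(strands) - 1, 0))))
    records = []
    for i, seq in enumerate(strands):
        rid = ids[i] if ids is not None else f"strand_{i:0{width}d}"
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(records, path, "fasta")


def read_strands_fasta(path) -> dict:
    """Read strands keyed by integer index parsed from the record ID."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("skipping length-0 record %s", rec.id)
            continue
        m = _ID_RE.match(rec.id)
        if not m:
            raise DecodeError(f"cannot parse strand index from ID {rec.id!r}")
        out[int(m.group(1))] = seq
    return out


def read_fasta_sequences(path) -> list:
    """Plain ordered (id, sequence) pairs — used by corrupt/score."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta_sequences(path, pairs):
    records = [SeqRecord(Seq(seq), id=rid, description="")
               for rid, seq in pairs]
    SeqIO.write(records, path, "fasta")


def _scramble_mask(index: int, block_bits: int) -> np.ndarray:
    """Deterministic per-strand whitening mask.

    Structured blocks (the header, zero padding, repetitive payloads) sit
    far from the uniform-random blocks the codec is trained on; XOR-ing
    each block with an index-seeded pseudorandom mask makes every encoded
    block look random.  The mask depends only on the strand index, so
    decoding inverts it exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x5C4A, index]))
    return rng.integers(0, 2, size=block_bits, dtype=np.int64)


def encode_file(model: TurboCodec, data: bytes) -> list:
    """Encode a byte payload into strands; strand 0 is the header."""
    blocks, header = segment_payload(data, model.cfg.block_bits)
    all_blocks = np.stack([header.to_block()] + list(blocks)) \
        if blocks else header.to_block()[None, :]
    masks = np.stack([_scramble_mask(i, model.cfg.block_bits)
                      for i in range(all_blocks.shape[0])])
    all_blocks = all_blocks ^ masks
    strands = []
    for start in range(0, all_blocks.shape[0], 1024):
        strands.extend(model.strands(all_blocks[start:start + 1024]))
    return strands


def decode_file(model: TurboCodec, strands_by_index: dict,
                transcoder_mode: str = "auto") -> bytes:
    """Decode strands back into the original byte payload.

    Reassembly is driven by the indices, so record order is irrelevant;
    missing strands raise a :class:`DecodeError` naming the gaps.
    """
    if 0 not in strands_by_index:
        raise DecodeError("missing header strand (index 0)")
    header_y = model.decoder_input([strands_by_index[0]],
                                   mode=transcoder_mode)
    header_bits = model.decode_bits(header_y, verify=True, max_flips=3)[0]
    header_bits = header_bits ^ _scramble_mask(0, model.cfg.block_bits)
    header = PayloadHeader.from_block(header_bits)
    n_blocks = header.n_blocks
    missing = [i for i in range(1, n_blocks + 1) if i not in strands_by_index]
    if missing:
        raise DecodeError(f"missing strand indices: {missing}")
    blocks = []
    order = list(range(1, n_blocks + 1))
    for start in range(0, n_blocks, 1024):
        chunk = [strands_by_index[i] for i in order[start:start + 1024]]
        if not chunk:
            break
        y = model.decoder_input(chunk, mode=transcoder_mode)
        bits = model.decode_bits(y, verify=True, max_flips=3)
        for offset, row in enumerate(bits):
            idx = order[start + offset]
            blocks.append(row ^ _scramble_mask(idx, model.cfg.block_bits))
    return reassemble_payload(blocks, header)
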