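# dnaturbo

A trainable turbo-autoencoder codec for the DNA data storage channel,
implemented in pure scientific Python (NumPy + a small built-in reverse-mode
autodiff engine — no deep-learning framework required).

The pipeline mirrors the classic turbo-autoencoder layout adapted to DNA
storage:

```
bits u ──► encoder E (2-3 stream nets, one on the interleaved input)
       ──► normalize ──► binarize (straight-through) ──► λ: bit pairs → bases
       ──► channel simulator C (substitutions / insertions / deletions)
       ──► indel-reduction transcoder Q (variable-length read → fixed input)
       ──► iterative turbo decoder D (two nets exchanging prior/posterior)
       ──► bits û
```

plus a constraint evaluator `f(·)` (GC content, homopolymer runs, k-mer
repeats, undesired motifs) whose batch **stability score**
`w = 1 − mean(error probability)` can be weighted into the encoder loss to
fine-tune models toward constraint-adhering DNA.

## Features

- **Channel simulator** — multi-source per-base error profiles
  (synthesis / sequencing / PCR / storage), JSON-configurable in both a
  native layout and a MESA-style layout (`err_rate` + `err_data`
  proportions), with an *amplifier* that rescales every rate to a target
  total while preserving error-type proportions exactly. Each transmitted
  read carries a complete, replayable event log.
- **Constraint evaluator** — piecewise probability graphs (linear or step
  interpolation) over GC %, homopolymer run length and k-mer repeat counts,
  plus motif lists; per-sequence probabilities combine as independent
  failure modes.
- **Codec core** — affine (`π(n) = k·n + u mod N`) and seeded pseudo-random
  interleavers, block normalization (population sd), tie-broken sign
  binarization with a straight-through gradient contract, the bit-pair
  mapping `00→A, 01→G, 10→T, 11→C`, code-rate accounting with latent
  redundancy, and payload segmentation with an index/header scheme.
- **Neural components** — encoder architectures `cnn | rnn | vae |
  transformer` (+ a parameter-free `systematic` baseline), transcoders
  `cnn | rnn | resnet` (+ `bypass`), decoders `cnn | rnn | resnet |
  transformer` (+ `majority` baseline); any supported combination is
  constructible from config.
- **Training** — alternating encoder / decoder+transcoder phases, smooth-L1
  losses, per-batch channel noise sampling, per-epoch JSONL logging and
  checkpointing, bit-identical pause/resume, online (epoch-boundary)
  hyperparameter refresh, and constraint fine-tuning via an exact-value /
  surrogate-gradient stability term.

## CLI

```bash
dnaturbo train    --workdir run/ --epochs 50 --seed 1 \
                  --channel channel.json --block-bits 24
dnaturbo finetune --checkpoint run/ --constraints constraints.json --epochs 20
dnaturbo encode   --checkpoint run/ --in payload.bin --out strands.fasta
dnaturbo corrupt  --config channel.json --seed 7 --in strands.fasta --out noisy.fasta
dnaturbo decode   --checkpoint run/ --in noisy.fasta --out restored.bin
dnaturbo score    --constraints constraints.json --in strands.fasta
dnaturbo evaluate --checkpoint run/ --channel channel.json --n-blocks 1000 --seed 0
```

Strand files are FASTA with IDs `strand_<zero-padded index>`; strand 0 is a
header strand recording the payload bit length, so decoding is
order-independent. Blocks are whitened with an index-seeded scrambling mask
before encoding, and file decoding applies re-encode verification (greedy
minimum-distance refinement over small Hamming balls) on top of the turbo
decoder. Every run writes its effective configuration to JSON for
reproducibility.

### Channel config dialects

Native:

```json
{"error_sources": [
   {"name": "synthesis", "substitution": 6e-4, "insertion": 4e-4,
    "deletion": 8e-4}],
 "amplifier_total": null}
```

MESA-style (component entries with a total `err_rate` and `err_data`
proportions; pattern conditioning beyond flat rates is collapsed with a
logged notice):

```json
{"synthesis": {"err_rate": 0.0018,
               "err_data": {"mismatch": 0.33, "insertion": 0.22,
                            "deletion": 0.45}}}
```

The bundled default profile (column synthesis + ErrASE, Illumina single-end,
TAQ 30 cycles, E. coli 24 months) totals 0.33% per base; only the total is
calibrated — the per-component split is this package's documented choice
(`dnaturbo.profiles`).

## Notes on scale

The built-in autodiff engine is single-threaded NumPy; the test suite's
smoke trainings therefore use a reduced per-epoch batch schedule (6 encoder
+ 18 decoder batches of 256) rather than the heavyweight default schedule
(100 + 500). Schedules, architectures, widths and iteration counts are all
configurable.
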