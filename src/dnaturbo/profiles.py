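"""Bundled default channel and constraint profiles.

The default channel profile models column synthesis with ErrASE error
correction, Illumina single-end sequencing, 30 PCR cycles with TAQ
polymerase and 24 months of storage in E. coli.  Only the summed per-base
rate of 0.33% is calibrated against published channel characterizations;
the per-component split below is this package's own documented choice.
"""

from __future__ import annotations

from .channel import ChannelConfig, channel_config_from_dict
from .constraints import ConstraintConfig, constraint_config_from_dict

DEFAULT_CHANNEL_DICT = {
    "error_sources": [
        {
            "name": "synthesis_column_errase",
            "substitution": 0.0006,
            "insertion": 0.0004,
            "deletion": 0.0008,
        },
        {
            "name": "sequencing_illumina_single_end",
            "substitution": 0.0008,
            "insertion": 0.00005,
            "deletion": 0.00005,
        },
        {
            "name": "pcr_taq_30_cycles",
            "substitution": 0.0003,
            "insertion": 0.0,
            "deletion": 0.0,
        },
        {
            "name": "storage_ecoli_24_months",
            "substitution": 0.0003,
            "insertion": 0.0,
            "deletion": 0.0,
        },
    ],
    "amplifier_total": None,
}

# GC-content graph: full penalty outside the 41-59% band.
FINETUNE_CONSTRAINT_DICT = {
    "gc": {
        "points": [
            {"x": 0, "y": 100},
            {"x": 40, "y": 100},
            {"x": 41, "y": 0},
            {"x": 59, "y": 0},
            {"x": 60, "y": 100},
            {"x": 100, "y": 100},
        ],
        "interpolation": "linear",
    },
    # runs longer than three bases are fully penalized
    "homopolymer": {
        "points": [
            {"x": 0, "y": 0},
            {"x": 3, "y": 0},
            {"x": 4, "y": 100},
            {"x": 100, "y": 100},
        ],
        "interpolation": "linear",
    },
}


def default_channel_config() -> ChannelConfig:
    """The bundled 0.33%-total channel profile."""
    return channel_config_from_dict(DEFAULT_CHANNEL_DICT)


def default_finetune_constraints() -> ConstraintConfig:
    """GC 40-60% band plus homopolymer-run-length <= 3 constraint set."""
    return constraint_config_from_dict(FINETUNE_CONSTRAINT_DICT)
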