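"""Factorial structure of the two TOJ experiments.

Both experiments present a pair of lateral visual targets separated by a
signed SOA (negative = left target first) shortly after a nociceptive cue
on the hand(s).  Experiment 1 crosses target position (near/far from the
trunk) with response modality ("which first" / "which second") into 4
blocks, each containing three interleaved 20-trial adaptive series (cue
left / cue right / cue bilateral).  Experiment 2 drops the bilateral cue,
adds hand congruency (hands beside the judged pair or beside the other
pair), yielding 8 blocks of two interleaved 20-trial series.

Schedules fix the block order and the per-trial cue-condition sequence;
the SOA of each trial is left unassigned and is chosen online by the PSI
engine, one independent engine per (block x cue condition) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentConfig",
    "Block",
    "build_exp1_config",
    "build_exp2_config",
    "schedule_session",
    "EXP1_SOAS",
    "EXP2_SOAS",
]

EXP1_SOAS = sorted(s * sign for s in (200, 90, 55, 30, 10) for sign in (1, -1))
EXP2_SOAS = sorted(
    s * sign
    for s in (200, 145, 90, 75, 60, 45, 30, 15, 10, 5)
    for sign in (1, -1)
)

UNILATERAL_LEFT = "unilateral_left"
UNILATERAL_RIGHT = "unilateral_right"
BILATERAL = "bilateral"


@dataclass(frozen=True)
class Block:
    block_id: str
    visual_position: str  # 'near' | 'far'
    response_modality: str  # 'first' | 'second'
    hand_congruency: str | None = None  # 'congruent' | 'incongruent' | None


@dataclass
class ExperimentConfig:
    """Full design of one experiment.

    Timing fields (fixation lead, cue-to-target interval, inter-trial
    interval) are carried as metadata; the simulator is not a real-time
    engine.
    """

    name: str
    soa_set: list[float]
    cue_conditions: list[str]
    positions: list[str] = field(default_factory=lambda: ["near", "far"])
    modalities: list[str] = field(default_factory=lambda: ["first", "second"])
    congruencies: list[str] | None = None
    trials_per_series: int = 20
    cue_to_target_interval_ms: float = 200.0
    fixation_lead_ms: float = 500.0
    inter_trial_ms: float = 2000.0

    def __post_init__(self) -> None:
        soas = sorted(float(s) for s in self.soa_set)
        if 0.0 in soas:
            raise ValueError("soa_set must exclude 0")
        if any(-s not in soas for s in soas):
            raise ValueError("soa_set must be symmetric about 0")
        if self.trials_per_series <= 0:
            raise ValueError("trials_per_series must be positive")
        self.soa_set = soas

    @property
    def blocks(self) -> list[Block]:
        if self.congruencies is None:
            return [
                Block(f"{pos}_{mod}", pos, mod)
                for pos, mod in product(self.positions, self.modalities)
            ]
        return [
            Block(f"{pos}_{cong}_{mod}", pos, mod, cong)
            for pos, cong, mod in product(
                self.positions, self.congruencies, self.modalities
            )
        ]

    @property
    def n_trials(self) -> int:
        return len(self.blocks) * len(self.cue_conditions) * self.trials_per_series

    def cells(self) -> list[tuple]:
        """Analysis cells: (position,) or (position, congruency)."""
        if self.congruencies is None:
            return [(p,) for p in self.positions]
        return list(product(self.positions, self.congruencies))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "soa_set": list(self.soa_set),
            "cue_conditions": list(self.cue_conditions),
            "positions": list(self.positions),
            "modalities": list(self.modalities),
            "congruencies": list(self.congruencies) if self.congruencies else None,
            "trials_per_series": self.trials_per_series,
            "cue_to_target_interval_ms": self.cue_to_target_interval_ms,
            "fixation_lead_ms": self.fixation_lead_ms,
            "inter_trial_ms": self.inter_trial_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def build_exp1_config() -> ExperimentConfig:
    """Experiment 1: 4 blocks (position x modality), 3 cue conditions,
    10 SOAs (+/-200, 90, 55, 30, 10 ms), 20 trials per series (240 total)."""
    return ExperimentConfig(
        name="exp1",
        soa_set=EXP1_SOAS,
        cue_conditions=[UNILATERAL_LEFT, UNILATERAL_RIGHT, BILATERAL],
    )


def build_exp2_config() -> ExperimentConfig:
    """Experiment 2: 8 blocks (position x congruency x modality), 2 cue
    conditions, 20 SOAs, 20 trials per series (320 total)."""
    return ExperimentConfig(
        name="exp2",
        soa_set=EXP2_SOAS,
        cue_conditions=[UNILATERAL_LEFT, UNILATERAL_RIGHT],
        congruencies=["congruent", "incongruent"],
    )


def schedule_session(config: ExperimentConfig, rng_seed) -> pd.DataFrame:
    """Seeded trial schedule: randomized block order, and within each block
    an equiprobable random interleave of the cue-condition series.

    SOA fields are left unassigned (NaN); the PSI engine fills them at
    run time, one independent engine per (block x cue condition) series.
    """
    rng = np.random.default_rng(rng_seed)
    blocks = list(config.blocks)
    order = rng.permutation(len(blocks))
    rows = []
    trial_index = 0
    for block_pos, bi in enumerate(order):
        block = blocks[bi]
        cues = np.repeat(config.cue_conditions, config.trials_per_series)
        cues = rng.permutation(cues)
        for cue in cues:
            rows.append(
                {
                    "trial_index": trial_index,
                    "block_order": block_pos,
                    "block_id": block.block_id,
                    "visual_position": block.visual_position,
                    "response_modality": block.response_modality,
                    "hand_congruency": block.hand_congruency,
                    "cue_condition": cue,
                    "soa_ms": np.nan,
                    "response": None,
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)
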