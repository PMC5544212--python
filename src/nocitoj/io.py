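"""Session-log and results file schemas.

Trial logs are plain CSV (UTF-8, comma-separated, '.' decimal, one trial
per row) with a commented header carrying the provenance needed to
reproduce the session: experiment name, participant id, RNG seed and the
PSI grid settings.  SOAs are stored in the left/right frame only
(negative = left target first); every other frame is derived at analysis
time, which prevents double sign-flip bugs.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import ExperimentConfig

__all__ = ["SessionLog", "write_session_csv", "read_session_csv", "RunManifest"]

TRIAL_COLUMNS = [
    "trial_index",
    "block_order",
    "block_id",
    "visual_position",
    "response_modality",
    "hand_congruency",
    "cue_condition",
    "soa_ms",
    "response",
]


@dataclass
class SessionLog:
    """One participant's full session: trials plus per-series estimates."""

    participant_id: str
    config: ExperimentConfig
    seed: int
    trials: pd.DataFrame
    estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)


def write_session_csv(log: SessionLog, path) -> None:
    path = Path(path)
    header = {
        "experiment": log.config.name,
        "participant_id": log.participant_id,
        "seed": log.seed,
        "config": log.config.to_dict(),
        **log.meta,
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        log.trials[TRIAL_COLUMNS].to_csv(fh, index=False)


def read_session_csv(path) -> SessionLog:
    path = Path(path)
    meta: dict = {}
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = json.loads(value.strip())
            else:
                body_lines.append(line)
    if "config" not in meta:
        raise ValueError(f"{path}: missing '# config:' header line")
    trials = pd.read_csv(_io.StringIO("".join(body_lines)))
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    config = ExperimentConfig.from_dict(meta.pop("config"))
    return SessionLog(
        participant_id=str(meta.pop("participant_id", path.stem)),
        config=config,
        seed=int(meta.pop("seed", -1)),
        trials=trials,
        meta={k: v for k, v in meta.items() if k != "experiment"},
    )


@dataclass
class RunManifest:
    """Provenance record written next to every batch of outputs."""

    command: str
    seed: int
    config: dict
    outputs: list
    package_version: str
    timestamp: str
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
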