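"""Sleep-stage sequences scored in 30-s epochs.

A hypnogram is the per-epoch sequence of manually scored sleep stages
(W, N1, N2, N3, R) that anchors every stage-aware computation in the
package: epoching, stage-restricted detection, and macro-architecture
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30.0

STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = ("N1", "N2", "N3", "R")
NREM_STAGES = ("N1", "N2", "N3")

#: Mapping from common annotation spellings to canonical stage tokens.
STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "WK": "W", "0": "W", "SLEEP STAGE W": "W",
    "N1": "N1", "S1": "N1", "1": "N1", "NREM1": "N1", "SLEEP STAGE N1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2", "NREM2": "N2", "SLEEP STAGE N2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3", "NREM3": "N3",
    "SWS": "N3", "SLEEP STAGE N3": "N3", "SLEEP STAGE N4": "N3",
    "R": "R", "REM": "R", "5": "R", "SLEEP STAGE R": "R",
}


def normalize_stage(label: str) -> str:
    """Map an annotation label to one of W/N1/N2/N3/R.

    Raises
    ------
    ValueError
        If the label is not in the documented alias table.
    """
    key = str(label).strip().upper()
    if key not in STAGE_ALIASES:
        raise ValueError(f"unrecognized stage label {label!r}")
    return STAGE_ALIASES[key]


@dataclass
class Hypnogram:
    """Per-epoch stage labels on a fixed 30-s grid.

    Epochs are 0-based and half-open in time: epoch k covers
    [30k, 30k + 30) seconds from record start.
    """

    stages: np.ndarray  # array of str, one per 30-s epoch
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"invalid stage labels: {sorted(set(map(str, bad)))}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_seconds

    def epochs_of(self, stage: str | tuple[str, ...]) -> np.ndarray:
        """Indices of epochs scored with the given stage(s)."""
        wanted = (stage,) if isinstance(stage, str) else tuple(stage)
        return np.flatnonzero(np.isin(self.stages, wanted))

    def is_sleep(self) -> np.ndarray:
        return np.isin(self.stages, SLEEP_STAGES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "onset_s": np.arange(self.n_epochs) * self.epoch_seconds,
                "stage": self.stages,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("epoch_index")
        stages = [normalize_stage(s) for s in df["stage"]]
        return cls(np.asarray(stages, dtype=object))

    @classmethod
    def from_labels(cls, labels) -> "Hypnogram":
        return cls(np.asarray([normalize_stage(s) for s in labels], dtype=object))
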