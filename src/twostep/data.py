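"""Trial-level dataset container and its CSV dialect.

A :class:`SubjectDataset` holds one subject x one task variant as parallel
numpy arrays (one entry per trial).  Integer sentinel -1 encodes a missing
value in memory; the CSV dialect writes missing values as empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import VARIANTS, DEFAULT_TRANSITIONS

MISSING = -1

#: CSV column order, one row per trial.
CSV_COLUMNS = [
    "trial_index", "practice", "stakes", "state", "left_dwelling",
    "choice", "response_key", "creature", "outcome_units", "final_result",
    "certainty", "outcome_estimate",
]


@dataclass
class SubjectDataset:
    """Ordered trials for one subject on one task variant."""

    subject_id: str
    variant: str
    trial_index: np.ndarray       # 0-based
    practice: np.ndarray          # bool
    stakes: np.ndarray            # int, one of stakes_values
    state: np.ndarray             # first-stage state 0/1
    left_dwelling: np.ndarray     # which dwelling (0/1) is shown on the left
    choice: np.ndarray            # chosen dwelling 0/1, MISSING if no response
    response_key: np.ndarray      # 0=left, 1=right, MISSING
    creature: np.ndarray          # visited creature 0/1, MISSING
    outcome_units: np.ndarray     # 0-9, MISSING
    final_result: np.ndarray      # result magnitude (flames/points), MISSING;
                                  # direction given by task.result_sign(variant)
    certainty: np.ndarray         # 0-9 probe rating, MISSING
    outcome_estimate: np.ndarray  # 0-9 probe rating, MISSING
    transition_map: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        n = len(self.trial_index)
        for name in CSV_COLUMNS:
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"column {name} has wrong length")
            setattr(self, name, arr)
        self.practice = self.practice.astype(bool)
        if not np.all(np.diff(self.trial_index) > 0):
            raise ValueError("trials must be ordered by trial_index")
        both = (self.certainty != MISSING) & (self.outcome_estimate != MISSING)
        if both.any():
            raise ValueError("certainty and outcome_estimate probed on same trial")
        responded = self.choice != MISSING
        out = self.outcome_units[responded]
        if out.size and (out.min() < 0 or out.max() > 9):
            raise ValueError("outcome_units outside [0, 9]")

    def __len__(self) -> int:
        return len(self.trial_index)

    @property
    def analyzable(self) -> np.ndarray:
        """Mask of non-practice trials."""
        return ~self.practice

    @property
    def missed_fraction(self) -> float:
        keep = self.analyzable
        return float(np.mean(self.choice[keep] == MISSING))

    def subset(self, mask: np.ndarray) -> "SubjectDataset":
        kw = {name: getattr(self, name)[mask] for name in CSV_COLUMNS}
        return SubjectDataset(subject_id=self.subject_id, variant=self.variant,
                              transition_map=self.transition_map, **kw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in CSV_COLUMNS})
        df["practice"] = df["practice"].astype(int)
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        # empty cells for missing values, everything else integer
        df = df.astype(object).mask(df.eq(MISSING), "")
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str, variant: str,
                   transition_map: np.ndarray | None = None) -> "SubjectDataset":
        missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"dataset missing columns {missing_cols}")
        kw = {}
        for c in CSV_COLUMNS:
            col = pd.to_numeric(df[c], errors="coerce")
            bad = col.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(f"non-numeric value in column {c!r} at row {row}")
            kw[c] = col.fillna(MISSING).to_numpy().astype(np.int64)
        tm = DEFAULT_TRANSITIONS.copy() if transition_map is None else transition_map
        return cls(subject_id=subject_id, variant=variant, transition_map=tm, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str, variant: str,
                 transition_map: np.ndarray | None = None) -> "SubjectDataset":
        df = pd.read_csv(path, dtype=str)
        try:
            return cls.from_frame(df, subject_id, variant, transition_map)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
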