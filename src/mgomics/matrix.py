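"""Feature-by-sample expression container with an explicit processing stage.

The cleaning pipeline moves a matrix through a fixed sequence of stages
(``raw`` → ``scaled`` → ``s_over_s`` → ``log2`` → ``zscore``); each operation
checks that its input is at the stage it expects, so a half-normalized matrix
cannot silently enter a downstream screen.  Missing values are ``NaN``;
an intensity of zero in the raw tables means "not observed" and is converted
to ``NaN`` at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "scaled", "s_over_s", "log2", "zscore")


class StageError(ValueError):
    """Raised when an operation receives a matrix at the wrong stage."""


@dataclass
class ExpressionMatrix:
    """Features x samples abundance grid.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample-id columns.  ``NaN``
        marks a missing (unobserved) entry.
    stage
        One of :data:`STAGES`.
    batch_map
        Mapping sample id -> batch id for every column.
    note
        Free-text provenance note appended to by pipeline steps.
    """

    values: pd.DataFrame
    stage: str
    batch_map: dict[str, str] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        missing = [c for c in self.values.columns if c not in self.batch_map]
        if self.batch_map and missing:
            raise ValueError(f"samples absent from batch map: {missing[:5]}")

    # -- stage machinery ---------------------------------------------------

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, got {self.stage!r}"
            )

    def advance(self, new_stage: str, values: pd.DataFrame, note: str = "") -> "ExpressionMatrix":
        """Return a copy at ``new_stage``; transitions must move forward."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move back from {self.stage!r} to {new_stage!r}")
        joined = self.note if not note else (self.note + "; " + note if self.note else note)
        return replace(self, values=values, stage=new_stage, note=joined)

    # -- convenience -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing entries."""
        return self.values.isna().mean(axis=1)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return replace(
            self,
            values=self.values[samples],
            batch_map={s: self.batch_map[s] for s in samples} if self.batch_map else {},
        )


def as_float_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce to float64, mapping non-numeric cells to an informative error."""
    try:
        return df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"malformed numeric value at row {row!r}, column {col!r}"
                ) from exc
        raise
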