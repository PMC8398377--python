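"""Core data containers: abundance matrices and sample metadata.

An :class:`AbundanceMatrix` is a samples × metabolites grid of non-negative
intensities (``NaN`` marks a value below the detection limit) tagged with a
processing *stage*.  Stages advance only in the fixed order

    raw → normalized → logged → imputed

which mirrors the preprocessing order of a volume-normalised untargeted
LC-MS workflow; functions in :mod:`radmetab.preprocess` enforce the order.

Sample metadata is kept as a plain :class:`pandas.DataFrame` with the
columns listed in :data:`METADATA_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("raw", "normalized", "logged", "imputed")

#: canonical metadata columns (one row per plasma sample)
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "sex",
    "dose_gy",
    "day",
    "cohort",
    "timepoint",
    "volume_ml",
)


class StageError(ValueError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass
class AbundanceMatrix:
    """Samples × metabolites intensity table with a processing-stage tag.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per metabolite id.
        ``NaN`` entries are missing (below detection limit).
    stage
        One of ``raw``, ``normalized``, ``logged``, ``imputed``.
    """

    data: pd.DataFrame
    stage: str = "raw"
    log_base: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids in abundance matrix")
        self.data = self.data.astype(float)
        if self.stage == "imputed" and self.data.isna().any().any():
            raise StageError("imputed matrix must contain no missing values")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing entries."""
        return self.data.isna().mean(axis=0)

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is at {self.stage!r}"
            )

    def with_data(self, data: pd.DataFrame, stage: str,
                  log_base: float | None = None) -> "AbundanceMatrix":
        """Return a new matrix at ``stage``; transitions must follow stage order."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move from {self.stage!r} back to {stage!r}")
        return AbundanceMatrix(data, stage=stage,
                               log_base=log_base if log_base is not None else self.log_base)

    # -- IO --------------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV: first column ``sample_id``, then metabolite columns.

        Missing entries are written as empty cells.
        """
        self.data.rename_axis("sample_id").to_csv(path, na_rep="")

    @classmethod
    def read_csv(cls, path, stage: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(df, stage=stage)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a metadata frame has the canonical columns and unique sample ids."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


def read_annotation(path) -> pd.DataFrame:
    """Read a metabolite → subpathway → superpathway annotation CSV."""
    ann = pd.read_csv(path)
    required = {"metabolite_id", "subpathway", "superpathway"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return ann
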