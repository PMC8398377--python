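"""Preprocessing of raw abundance matrices.

The pipeline follows a fixed order, enforced through the matrix stage tag:

1. :func:`normalize_volume` — divide each sample by its plasma volume;
2. :func:`filter_missingness` — drop metabolites not detected in more than
   20 % of samples (strictly greater than the threshold);
3. :func:`log_transform` — natural log of the observed intensities;
4. :func:`impute_minimum` — replace each remaining missing entry by that
   metabolite's minimum observed (logged) value, the standard treatment of
   detection-limit censoring in untargeted LC-MS panels.

The missing-fraction denominator is all samples in the matrix (the filter
runs once, before any sex or arm subsetting), and imputation uses the
per-metabolite minimum over all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix

__all__ = [
    "FilterReport",
    "normalize_volume",
    "filter_missingness",
    "log_transform",
    "impute_minimum",
    "preprocess_pipeline",
]


@dataclass
class FilterReport:
    """Outcome of the missingness filter."""

    excluded_metabolites: list[tuple[str, float]]
    retained_count: int
    max_missing_fraction: float

    @property
    def excluded_count(self) -> int:
        return len(self.excluded_metabolites)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metabolite_id": m, "missing_fraction": f, "excluded": True}
                for m, f in self.excluded_metabolites]
        return pd.DataFrame(rows, columns=["metabolite_id", "missing_fraction", "excluded"])


def normalize_volume(matrix: AbundanceMatrix, volumes: pd.Series) -> AbundanceMatrix:
    """Divide each sample's intensities by its plasma volume.

    ``volumes`` is indexed by sample id (or a metadata frame's
    ``volume_ml`` column reindexed by ``sample_id``).  Missing entries stay
    missing; a zero, negative or absent volume is an error naming the sample.
    """
    matrix.require_stage("raw")
    vols = volumes.reindex(matrix.sample_ids)
    bad = vols.index[vols.isna() | (vols <= 0)]
    if len(bad):
        raise ValueError(f"non-positive or missing plasma volume for sample(s): "
                         f"{list(bad[:5])}")
    data = matrix.data.div(vols, axis=0)
    return matrix.with_data(data, "normalized")


def filter_missingness(matrix: AbundanceMatrix,
                       max_missing_fraction: float = 0.20,
                       ) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop metabolites whose missing fraction is strictly above the threshold.

    "Not detected in more than 20 % of samples" is read as a strict
    inequality: a metabolite missing in exactly 20 % of samples is retained.
    """
    matrix.require_stage("normalized")
    frac = matrix.missing_fraction()
    excluded = frac[frac > max_missing_fraction]
    kept = matrix.data.loc[:, frac.index[frac <= max_missing_fraction]]
    report = FilterReport(
        excluded_metabolites=[(m, float(f)) for m, f in excluded.items()],
        retained_count=kept.shape[1],
        max_missing_fraction=max_missing_fraction,
    )
    return matrix.with_data(kept, "normalized"), report


def log_transform(matrix: AbundanceMatrix, base: float | None = None) -> AbundanceMatrix:
    """Log-transform observed values (natural log by default).

    The base only shifts log-scale statistics by a constant factor and does
    not change t-test p-values or VIP ranks.  Non-positive observed values
    are an error naming the offending cell.
    """
    matrix.require_stage("normalized")
    vals = matrix.data
    bad = (vals <= 0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-positive intensity at sample {row!r}, metabolite {col!r}")
    logged = np.log(vals) if base is None else np.log(vals) / np.log(base)
    return matrix.with_data(logged, "logged", log_base=base or float(np.e))


def impute_minimum(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries by the metabolite's minimum observed value.

    Requires every metabolite to have at least one observed value (an
    all-missing column should have been removed by the missingness filter).
    """
    matrix.require_stage("logged")
    all_missing = matrix.data.columns[matrix.data.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"all-missing metabolite(s) cannot be imputed: "
                         f"{list(all_missing[:5])}")
    data = matrix.data.fillna(matrix.data.min(axis=0))
    return matrix.with_data(data, "imputed")


def preprocess_pipeline(matrix: AbundanceMatrix, meta: pd.DataFrame,
                        max_missing_fraction: float = 0.20,
                        log_base: float | None = None,
                        ) -> tuple[AbundanceMatrix, AbundanceMatrix, FilterReport]:
    """Run the full preprocessing chain on a raw matrix.

    Returns ``(imputed, normalized_filtered, report)``; the normalized
    (unlogged, still-censored) matrix is kept because fold changes are
    computed on that scale.
    """
    vols = meta.set_index("sample_id")["volume_ml"]
    normalized = normalize_volume(matrix, vols)
    filtered, report = filter_missingness(normalized, max_missing_fraction)
    imputed = impute_minimum(log_transform(filtered, base=log_base))
    return imputed, filtered, report
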