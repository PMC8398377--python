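"""Per-metabolite differential abundance: fold change, Welch's t, BH.

For each pairwise contrast (two timepoint groups at a fixed dose, or two
doses at a fixed timepoint group) every metabolite gets:

* a fold change — the ratio of the two group means, computed by default on
  the volume-normalised, unlogged scale (arithmetic means; imputed values
  participate);
* a two-sided Welch two-sample t-test on the logged, imputed scale, with
  Welch–Satterthwaite degrees of freedom;
* a Benjamini–Hochberg adjusted q-value across metabolites within the
  contrast.

The fold-change cutoff of 2 is applied symmetrically downstream
(fc > 2 or fc < 0.5, i.e. |log2 FC| > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = [
    "ContrastSpec",
    "fold_change",
    "welch_test",
    "bh_adjust",
    "run_contrast",
    "anova_timepoints",
    "significance_counts",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise group comparison.

    ``axis='time_within_dose'``: group_a/group_b are timepoint labels and
    ``fixed`` is the dose in Gy.  ``axis='dose_within_time'``: groups are
    doses and ``fixed`` is the timepoint label.  Only samples whose sex is
    in ``sex_filter`` participate (default: males only, matching a design
    whose female arms are underpowered).
    """

    axis: str
    fixed: float | str
    group_a: float | str
    group_b: float | str
    sex_filter: tuple[str, ...] = ("M",)

    def __post_init__(self):
        if self.axis not in ("time_within_dose", "dose_within_time"):
            raise ValueError(f"unknown contrast axis {self.axis!r}")
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")

    def label(self) -> str:
        if self.axis == "time_within_dose":
            return f"{self.fixed:g}Gy_{self.group_a}_vs_{self.group_b}"
        return f"{self.fixed}_{self.group_a:g}Gy_vs_{self.group_b:g}Gy"

    def select(self, meta: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        """Sample ids of group_a and group_b after the sex filter."""
        sub = meta[meta["sex"].isin(self.sex_filter)]
        if self.axis == "time_within_dose":
            sub = sub[sub["dose_gy"] == self.fixed]
            a = sub.loc[sub["timepoint"] == self.group_a, "sample_id"]
            b = sub.loc[sub["timepoint"] == self.group_b, "sample_id"]
        else:
            sub = sub[sub["timepoint"] == self.fixed]
            a = sub.loc[sub["dose_gy"] == self.group_a, "sample_id"]
            b = sub.loc[sub["dose_gy"] == self.group_b, "sample_id"]
        if a.empty or b.empty:
            raise ValueError(f"contrast {self.label()}: empty group after sex filter")
        return pd.Index(a), pd.Index(b)


def fold_change(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, str]:
    """Ratio of group means, mean(b)/mean(a), with an up/down call for b vs a."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValueError("fold change requires non-empty groups")
    ma = values_a.mean()
    if ma == 0:
        raise ValueError("zero mean in fold-change denominator")
    fc = values_b.mean() / ma
    return float(fc), ("up" if fc > 1 else "down")


def welch_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t-test: ``(t, df, p)``.

    Degenerate zero-variance cases: equal constants give (0, n−2, 1);
    different constants give (±inf, n−2, 0) and are flagged by callers.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's test requires at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(b.mean() - a.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(imputed: AbundanceMatrix, meta: pd.DataFrame, spec: ContrastSpec,
                 normalized: AbundanceMatrix | None = None,
                 fc_scale: str = "unlogged") -> pd.DataFrame:
    """Full univariate table for one contrast.

    Welch tests run on the logged, imputed matrix.  Fold changes use
    arithmetic means on the unlogged scale by default: from ``normalized``
    if given (imputed cells then use the metabolite's minimum, matching the
    logged imputation) or from ``exp`` of the imputed matrix otherwise.
    ``fc_scale='logged'`` instead uses the ratio of geometric means.

    Returns a frame indexed by metabolite with columns ``fold_change,
    log2_fc, t_stat, df, p_value, q_value, direction, degenerate``.
    """
    imputed.require_stage("imputed")
    ids_a, ids_b = spec.select(meta)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"contrast {spec.label()}: needs >=2 samples per group")

    logged_a = imputed.data.loc[ids_a]
    logged_b = imputed.data.loc[ids_b]

    base = imputed.log_base or float(np.e)
    if fc_scale == "unlogged":
        if normalized is not None:
            raw = normalized.data[imputed.metabolite_ids]
            raw = raw.fillna(raw.min(axis=0))
            raw_a, raw_b = raw.loc[ids_a], raw.loc[ids_b]
        else:
            raw_a, raw_b = base ** logged_a, base ** logged_b
        fc = raw_b.mean(axis=0) / raw_a.mean(axis=0)
    elif fc_scale == "logged":
        fc = base ** (logged_b.mean(axis=0) - logged_a.mean(axis=0))
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")

    rows = {}
    for met in imputed.metabolite_ids:
        t, df, p = welch_test(logged_a[met].to_numpy(), logged_b[met].to_numpy())
        rows[met] = (t, df, p, not np.isfinite(t))
    stats_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["t_stat", "df", "p_value", "degenerate"])

    out = pd.DataFrame(index=imputed.metabolite_ids)
    out["fold_change"] = fc
    out["log2_fc"] = np.log2(fc)
    out[["t_stat", "df", "p_value", "degenerate"]] = stats_df
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.where(out["fold_change"] > 1, "up", "down")
    out.index.name = "metabolite_id"
    return out


def anova_timepoints(imputed: AbundanceMatrix, meta: pd.DataFrame, dose: float,
                     sex_filter: tuple[str, ...] = ("M",)) -> pd.DataFrame:
    """One-way ANOVA across all timepoint groups at a fixed dose, BH-adjusted.

    Secondary analysis: the pairwise Welch contrasts are the primary path.
    """
    sub = meta[(meta["sex"].isin(sex_filter)) & (meta["dose_gy"] == dose)]
    groups = [g["sample_id"] for _, g in sub.groupby("timepoint") if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError(f"dose {dose}: fewer than two timepoint groups with >=2 samples")
    arrays = [imputed.data.loc[pd.Index(g)] for g in groups]
    f, p = stats.f_oneway(*[a.to_numpy() for a in arrays], axis=0)
    out = pd.DataFrame({"F_stat": f, "p_value": p}, index=imputed.metabolite_ids)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out.index.name = "metabolite_id"
    return out


def passes_thresholds(result: pd.DataFrame, fc_threshold: float = 2.0,
                      alpha: float = 0.05, use_q: bool = False) -> pd.Series:
    """Boolean mask: |log2 FC| above the symmetric cutoff and p (or q) < alpha."""
    pcol = "q_value" if use_q else "p_value"
    return (result["log2_fc"].abs() > np.log2(fc_threshold)) & (result[pcol] < alpha)


def significance_counts(results: Mapping[str, pd.DataFrame],
                        fc_threshold: float = 2.0,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-contrast counts of significant metabolites, raw-p and BH-adjusted.

    ``results`` maps contrast labels to :func:`run_contrast` tables.  Each
    row reports ``n_signif`` (fc cutoff & p < alpha) and ``n_signif_bh``
    (fc cutoff & q < alpha), the two numbers a dose × timepoint summary
    table prints.
    """
    rows = []
    for label, res in results.items():
        rows.append({
            "contrast": label,
            "n_signif": int(passes_thresholds(res, fc_threshold, alpha).sum()),
            "n_signif_bh": int(passes_thresholds(res, fc_threshold, alpha, use_q=True).sum()),
        })
    return pd.DataFrame(rows, columns=["contrast", "n_signif", "n_signif_bh"])
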