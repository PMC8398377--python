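"""Composite biomarker selection, confounder filtering and set reporting.

A metabolite is selected for one contrast when it jointly satisfies:

* fold change above the symmetric cutoff (|log2 FC| > log2 2);
* Welch t-test p-value below 0.05;
* VIP > 1.0 from that contrast's OPLS-DA model, with the model itself
  validated (permutation p < 0.05 and Q² > 0) when required;
* membership in a subpathway of at least 5 background metabolites whose
  hypergeometric enrichment p is below 0.05.

Metabolites and subpathways that also pass the same rule in the sham-arm
(0 Gy) version of a TP1-vs-TPk contrast are time-varying confounders, not
radiation markers, and are removed by :func:`confounder_filter`.  Every
rejection records the first criterion that failed, so a selection table is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix

__all__ = [
    "SelectionThresholds",
    "SelectionResult",
    "composite_select",
    "confounder_filter",
    "venn_partition",
    "dose_response_profile",
]


@dataclass(frozen=True)
class SelectionThresholds:
    """Cutoffs of the composite biomarker rule."""

    fc_min: float = 2.0
    p_max: float = 0.05
    vip_min: float = 1.0
    subpathway_min_size: int = 5
    subpathway_p_max: float = 0.05
    require_validated_model: bool = True
    model_perm_p_max: float = 0.05
    model_q2_min: float = 0.0

    def __post_init__(self):
        if self.fc_min <= 0 or self.vip_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.p_max <= 1 and 0 < self.subpathway_p_max <= 1):
            raise ValueError("p-type thresholds must lie in (0, 1]")


@dataclass
class SelectionResult:
    """Per-contrast outcome of the composite rule.

    ``table`` has one row per background metabolite with the evidence and a
    ``selected`` flag plus ``rejection_reason`` (empty when selected).
    ``selected_subpathways`` are the enriched subpathways that contributed.
    ``removed_as_confounder`` is filled by :func:`confounder_filter`.
    """

    contrast: str
    table: pd.DataFrame
    selected_subpathways: set = field(default_factory=set)
    model_validated: bool = True
    removed_as_confounder: set = field(default_factory=set)
    removed_subpathways: set = field(default_factory=set)

    @property
    def selected_metabolites(self) -> dict[str, str]:
        sel = self.table[self.table["selected"]]
        return dict(zip(sel.index, sel["direction"]))

    def copy(self) -> "SelectionResult":
        return replace(self, table=self.table.copy(),
                       selected_subpathways=set(self.selected_subpathways),
                       removed_as_confounder=set(self.removed_as_confounder),
                       removed_subpathways=set(self.removed_subpathways))


def composite_select(univariate: pd.DataFrame, vip: pd.Series,
                     model_validated: bool, enrichment: pd.DataFrame,
                     annotation: pd.DataFrame,
                     thresholds: SelectionThresholds = SelectionThresholds(),
                     contrast: str = "") -> SelectionResult:
    """Apply the composite biomarker rule to one contrast's evidence.

    ``univariate`` is a :func:`radmetab.univariate.run_contrast` table,
    ``vip`` the per-metabolite VIP of the contrast's OPLS-DA model,
    ``enrichment`` the tested-subpathway table for this contrast's
    significant set.  All three must cover the same metabolite background.
    """
    background = set(univariate.index)
    if set(vip.index) != background:
        raise ValueError("VIP table does not cover the univariate background")

    ann = annotation.set_index("metabolite_id")
    sub_of = ann["subpathway"].reindex(univariate.index)
    sup_of = ann["superpathway"].reindex(univariate.index)
    enr = enrichment.set_index("subpathway") if len(enrichment) else pd.DataFrame(
        columns=["K", "p_over", "p_under"]).rename_axis("subpathway")
    enriched = {s for s, row in enr.iterrows()
                if row["K"] >= thresholds.subpathway_min_size
                and min(row["p_over"], row["p_under"]) < thresholds.subpathway_p_max}

    lfc_min = np.log2(thresholds.fc_min)
    reasons = []
    selected = []
    for met in univariate.index:
        row = univariate.loc[met]
        reason = ""
        if thresholds.require_validated_model and not model_validated:
            reason = "OPLS-DA model not validated"
        elif abs(row["log2_fc"]) <= lfc_min:
            reason = "fold change below threshold"
        elif row["p_value"] >= thresholds.p_max:
            reason = "p-value above threshold"
        elif vip[met] <= thresholds.vip_min:
            reason = "VIP below threshold"
        elif pd.isna(sub_of[met]):
            reason = "unannotated metabolite"
        elif sub_of[met] in enr.index and \
                enr.loc[sub_of[met], "K"] < thresholds.subpathway_min_size:
            reason = "subpathway below min size"
        elif sub_of[met] not in enriched:
            reason = "subpathway not enriched"
        reasons.append(reason)
        selected.append(reason == "")

    table = univariate.copy()
    table["vip"] = vip
    table["subpathway"] = sub_of
    table["superpathway"] = sup_of
    table["selected"] = selected
    table["rejection_reason"] = reasons
    sel_subs = {sub_of[m] for m, s in zip(univariate.index, selected) if s}
    return SelectionResult(contrast=contrast, table=table,
                           selected_subpathways=sel_subs,
                           model_validated=model_validated)


def confounder_filter(candidate: SelectionResult, sham: SelectionResult,
                      ) -> SelectionResult:
    """Remove sham-arm (0 Gy) markers from an irradiated arm's selection.

    Both results must refer to the same timepoint contrast (label suffix
    after the dose prefix).  Metabolites and subpathways selected in the
    sham arm are time-varying confounders: they are deselected with reason
    "sham time drift".  Idempotent.
    """
    def _suffix(label: str) -> str:
        return label.split("_", 1)[1] if "_" in label else label

    if _suffix(candidate.contrast) != _suffix(sham.contrast):
        raise ValueError(f"mismatched contrasts: {candidate.contrast!r} vs "
                         f"{sham.contrast!r}")
    sham_mets = set(sham.selected_metabolites)
    sham_subs = set(sham.selected_subpathways)

    out = candidate.copy()
    hit = out.table.index.isin(sham_mets) & out.table["selected"]
    out.table.loc[hit, "selected"] = False
    out.table.loc[hit, "rejection_reason"] = "sham time drift"
    out.removed_as_confounder = set(out.table.index[hit])
    out.removed_subpathways = out.selected_subpathways & sham_subs
    out.selected_subpathways = {
        s for s in pd.unique(out.table.loc[out.table["selected"], "subpathway"])
        if pd.notna(s)} - sham_subs
    return out


def venn_partition(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty intersection region of 2–4 named sets.

    The key is the tuple of set names a region belongs to (and implicitly
    not to the others); counts over all 2^k − 1 regions sum to the size of
    the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition handles 2 to 4 sets; report a table instead")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(set(sets[n]) for n in inside))
            for n in names:
                if n not in inside:
                    region -= set(sets[n])
            regions[inside] = len(region)
    return regions


def dose_response_profile(imputed: AbundanceMatrix, meta: pd.DataFrame,
                          metabolite_ids, timepoint: str,
                          sex_filter: tuple[str, ...] = ("M",)) -> pd.DataFrame:
    """Per-dose mean and SD of logged abundance at a fixed timepoint.

    Triage-marker reporting: shows whether a candidate's level orders with
    dose.  Rows are (metabolite, dose); columns ``mean_log, sd_log, n``.
    """
    unknown = [m for m in metabolite_ids if m not in imputed.metabolite_ids]
    if unknown:
        raise ValueError(f"unknown metabolite(s): {unknown[:5]}")
    sub = meta[(meta["timepoint"] == timepoint) & meta["sex"].isin(sex_filter)]
    rows = []
    for dose, g in sub.groupby("dose_gy"):
        vals = imputed.data.loc[pd.Index(g["sample_id"]), list(metabolite_ids)]
        for met in metabolite_ids:
            rows.append({"metabolite_id": met, "dose_gy": float(dose),
                         "mean_log": float(vals[met].mean()),
                         "sd_log": float(vals[met].std(ddof=1)) if len(vals) > 1 else 0.0,
                         "n": int(len(vals))})
    return pd.DataFrame(rows, columns=["metabolite_id", "dose_gy", "mean_log",
                                       "sd_log", "n"])
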