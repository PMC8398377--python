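"""End-to-end orchestration: simulate/load → preprocess → statistics → selection.

:func:`run_full_pipeline` executes the whole workflow over the contrast
grid the study design supports: for every dose, the pre-exposure group
(TP1) against each post-exposure group (TP2–TP4); and for every timepoint
group, sham (0 Gy) against each irradiated dose.  Contrasts with fewer
than 3 usable samples in either group (after the sex filter) are skipped
and listed.  Every source of randomness descends from one master seed, so
two runs with the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import AbundanceMatrix
from .preprocess import FilterReport, preprocess_pipeline
from .univariate import ContrastSpec, passes_thresholds, run_contrast, significance_counts
from .latent import PcaModel, OplsDaModel, fit_pca, validate_oplsda
from .enrichment import enrich_subpathways
from .selection import (SelectionResult, SelectionThresholds, composite_select,
                        confounder_filter, venn_partition)
from .simulate import DesignConfig, EffectSpec, GroundTruth, simulate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_full_pipeline"]

_TIME_ORDER = ("TP1", "TP2", "TP3", "TP4")


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (defaults match the study conditions)."""

    design: DesignConfig | None = None
    effect_spec: EffectSpec | None = None
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    sex_filter: tuple[str, ...] = ("M",)
    max_missing_fraction: float = 0.20
    n_permutations: int = 100
    n_orthogonal: int | str = "auto"
    k_max: int = 2
    folds: int | str = "auto"
    min_group: int = 3
    pca_components: int = 2


@dataclass
class PipelineResult:
    meta: pd.DataFrame
    annotation: pd.DataFrame
    imputed: AbundanceMatrix
    normalized: AbundanceMatrix
    filter_report: FilterReport
    truth: GroundTruth | None
    univariate: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    pca: PcaModel
    models: dict[str, OplsDaModel]
    enrichment: dict[str, pd.DataFrame]
    selections_pre: dict[str, SelectionResult]
    selections_post: dict[str, SelectionResult]
    venns: dict[str, dict]
    skipped_contrasts: list[str]
    manifest: dict


def _contrast_grid(meta: pd.DataFrame, sex_filter, min_group) -> tuple[list, list]:
    """All supportable TP1-vs-TPk and sham-vs-dose contrasts."""
    sub = meta[meta["sex"].isin(sex_filter)]
    sizes = sub.groupby(["dose_gy", "timepoint"]).size()
    doses = sorted(sub["dose_gy"].unique())
    tps = [t for t in _TIME_ORDER if t in set(sub["timepoint"])]

    def cell(d, t):
        return int(sizes.get((d, t), 0))

    specs, skipped = [], []
    for d in doses:
        for t in tps:
            if t == "TP1":
                continue
            spec = ContrastSpec("time_within_dose", d, "TP1", t, tuple(sex_filter))
            if cell(d, "TP1") >= min_group and cell(d, t) >= min_group:
                specs.append(spec)
            else:
                skipped.append(spec.label())
    for t in tps:
        for d in doses:
            if d == 0.0:
                continue
            spec = ContrastSpec("dose_within_time", t, 0.0, d, tuple(sex_filter))
            if cell(0.0, t) >= min_group and cell(d, t) >= min_group:
                specs.append(spec)
            else:
                skipped.append(spec.label())
    return specs, skipped


def run_full_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                      matrix: AbundanceMatrix | None = None,
                      meta: pd.DataFrame | None = None,
                      annotation: pd.DataFrame | None = None,
                      outdir: str | Path | None = None) -> PipelineResult:
    """Run the complete analysis; simulate a cohort when no data is given.

    Stage errors propagate annotated with the stage and contrast label.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    s_sim, s_models = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]

    truth = None
    if matrix is None:
        matrix, meta, annotation, truth = simulate_cohort(
            config.design, config.effect_spec, seed=s_sim)
    elif meta is None or annotation is None:
        raise ValueError("loading data requires matrix, meta and annotation together")

    imputed, normalized, report = preprocess_pipeline(
        matrix, meta, config.max_missing_fraction)

    specs, skipped = _contrast_grid(meta, config.sex_filter, config.min_group)

    male_ids = meta.loc[meta["sex"].isin(config.sex_filter), "sample_id"]
    pca = fit_pca(imputed.data.loc[pd.Index(male_ids)],
                  n_components=config.pca_components)

    univariate: dict[str, pd.DataFrame] = {}
    models: dict[str, OplsDaModel] = {}
    enrichment: dict[str, pd.DataFrame] = {}
    selections_pre: dict[str, SelectionResult] = {}
    background = list(imputed.metabolite_ids)

    for spec in specs:
        label = spec.label()
        try:
            uni = run_contrast(imputed, meta, spec, normalized=normalized)
            ids_a, ids_b = spec.select(meta)
            rows = imputed.data.loc[ids_a.append(ids_b)]
            labels = np.array(["a"] * len(ids_a) + ["b"] * len(ids_b))
            model_seed = int(np.random.SeedSequence(
                [s_models, zlib.crc32(label.encode())]).generate_state(1)[0] % (2 ** 31))
            model = validate_oplsda(rows, labels, n_orthogonal=config.n_orthogonal,
                                    folds=config.folds, k_max=config.k_max,
                                    n_permutations=config.n_permutations,
                                    seed=model_seed)
            sig = set(uni.index[passes_thresholds(uni, config.thresholds.fc_min,
                                                  config.thresholds.p_max)])
            enr, _small = enrich_subpathways(sig, background, annotation,
                                             min_size=config.thresholds.subpathway_min_size,
                                             alpha=config.thresholds.subpathway_p_max)
            validated = model.is_validated(config.thresholds.model_perm_p_max,
                                           config.thresholds.model_q2_min)
            sel = composite_select(uni, model.vip, validated, enr, annotation,
                                   config.thresholds, contrast=label)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for contrast {label}: {exc}") from exc
        univariate[label] = uni
        models[label] = model
        enrichment[label] = enr
        selections_pre[label] = sel

    counts = significance_counts(univariate, config.thresholds.fc_min,
                                 config.thresholds.p_max)

    # sham time-drift confounder filter on TP1-vs-TPk contrasts at dose > 0
    selections_post: dict[str, SelectionResult] = {}
    for spec in specs:
        label = spec.label()
        sel = selections_pre[label]
        if spec.axis == "time_within_dose" and spec.fixed != 0.0:
            sham_label = ContrastSpec("time_within_dose", 0.0, spec.group_a,
                                      spec.group_b, tuple(config.sex_filter)).label()
            if sham_label in selections_pre:
                sel = confounder_filter(sel, selections_pre[sham_label])
        selections_post[label] = sel

    venns = _venn_summaries(specs, selections_post)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "sex_filter": list(config.sex_filter),
        "max_missing_fraction": config.max_missing_fraction,
        "n_permutations": config.n_permutations,
        "n_orthogonal": config.n_orthogonal,
        "folds": config.folds,
        "thresholds": {k: v for k, v in vars(config.thresholds).items()},
        "contrasts": [s.label() for s in specs],
        "skipped_contrasts": skipped,
        "n_samples": int(len(meta)),
        "n_metabolites_input": int(matrix.data.shape[1]),
        "n_metabolites_retained": int(report.retained_count),
        "n_metabolites_excluded": int(report.excluded_count),
        "selected_counts_post_filter": {
            label: len(sel.selected_metabolites)
            for label, sel in sorted(selections_post.items())},
    }

    result = PipelineResult(
        meta=meta, annotation=annotation, imputed=imputed, normalized=normalized,
        filter_report=report, truth=truth, univariate=univariate, counts=counts,
        pca=pca, models=models, enrichment=enrichment,
        selections_pre=selections_pre, selections_post=selections_post,
        venns=venns, skipped_contrasts=skipped, manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _venn_summaries(specs, selections_post) -> dict[str, dict]:
    """Venn partitions across time contrasts per dose, and across doses."""
    venns: dict[str, dict] = {}
    time_specs = [s for s in specs if s.axis == "time_within_dose" and s.fixed != 0.0]

    by_dose: dict[float, dict[str, set]] = {}
    for s in time_specs:
        sel = selections_post[s.label()]
        by_dose.setdefault(s.fixed, {})[f"TP1_vs_{s.group_b}"] = set(
            sel.selected_metabolites)
    for dose, sets in by_dose.items():
        if 2 <= len(sets) <= 4:
            venns[f"time_contrasts_{dose:g}Gy"] = {
                "+".join(k): v for k, v in venn_partition(sets).items()}

    dose_union = {f"{d:g}Gy": set().union(*sets.values())
                  for d, sets in by_dose.items() if sets}
    if 2 <= len(dose_union) <= 4:
        venns["doses_union_over_time"] = {
            "+".join(k): v for k, v in venn_partition(dose_union).items()}
    return venns


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.counts.to_csv(outdir / "significance_counts.tsv", sep="\t", index=False)
    result.filter_report.to_frame().to_csv(outdir / "filter_report.tsv",
                                           sep="\t", index=False)
    for label, sel in sorted(result.selections_post.items()):
        sel.table.to_csv(outdir / f"selection_{label}.tsv", sep="\t")
    with open(outdir / "venn_partitions.json", "w") as fh:
        json.dump(result.venns, fh, indent=1, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
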