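"""Design-faithful synthetic NHP plasma-metabolomics cohorts.

The generator reproduces the sampling layout of a partial-body irradiation
study in nonhuman primates: five radiation doses (0, 8, 11, 12.5, 14 Gy),
eight sampling days pooled into four timepoint groups (TP1 = days −5/−1
pre-exposure, TP2 = days 9/10, TP3 = days 28/29, TP4 = days 59/60), both
sexes, and two collection cohorts (2016 males only, 2017 both sexes).  The
default design (:func:`default_design`) reproduces the published per-cell
sample counts exactly — 200 plasma samples in total.

Abundances follow a log-normal model: per-metabolite baseline log-means,
subject-level random intercepts (the real design is repeated-measures),
i.i.d. within-group biological noise, and two kinds of planted structure —

* *radiation effects*: a per-metabolite log2 fold change scaled by a
  dose–response curve and a timepoint profile that peaks at TP2 and decays
  afterwards;
* *sham time drift*: a dose-independent log2 shift that grows over the
  study, applied to a disjoint metabolite subset, so that a downstream
  time-varying-confounder filter has a known truth to remove.

Missingness is left-censoring at a per-metabolite detection-limit quantile
(values below the limit become ``NaN``), the mechanism implied by
minimum-value imputation; an MCAR option exists behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import METADATA_COLUMNS, AbundanceMatrix

__all__ = [
    "DesignConfig",
    "EffectSpec",
    "GroundTruth",
    "default_design",
    "generate_design",
    "generate_abundances",
    "apply_missingness",
    "generate_annotation",
    "simulate_cohort",
    "write_cohort",
]

TIMEPOINT_MAP = {-5: "TP1", -1: "TP1", 9: "TP2", 10: "TP2",
                 28: "TP3", 29: "TP3", 59: "TP4", 60: "TP4"}

#: published per-cell sample counts: (dose_gy, day, sex, cohort) -> n.
#: 2016 cohort collected on days −5/9/29/59 (males only); 2017 on days
#: −1/10/28/60 (males and females).  Cells sum to 200.
_TABLE_COUNTS: dict[tuple[float, int, str, int], int] = {}


def _fill_counts() -> None:
    day_cohort = {-5: 2016, -1: 2017, 9: 2016, 10: 2017,
                  28: 2017, 29: 2016, 59: 2016, 60: 2017}
    # per dose: {day: (n_male, n_female)}; 2016 days have no female column
    rows: dict[float, dict[int, tuple[int, int]]] = {
        0.0: {-5: (4, 0), -1: (1, 2), 9: (4, 0), 10: (2, 2),
              28: (1, 2), 29: (4, 0), 59: (4, 0), 60: (2, 2)},
        8.0: {-5: (0, 0), -1: (6, 6), 9: (0, 0), 10: (5, 5),
              28: (4, 3), 29: (0, 0), 59: (0, 0), 60: (2, 2)},
        11.0: {-5: (12, 0), -1: (6, 6), 9: (12, 0), 10: (6, 5),
               28: (4, 3), 29: (11, 0), 59: (10, 0), 60: (1, 1)},
        12.5: {-5: (12, 0), -1: (0, 0), 9: (11, 0), 10: (0, 0),
               28: (0, 0), 29: (7, 0), 59: (6, 0), 60: (0, 0)},
        14.0: {-5: (0, 0), -1: (6, 6), 9: (0, 0), 10: (3, 4),
               28: (2, 1), 29: (0, 0), 59: (0, 0), 60: (2, 0)},
    }
    for dose, days in rows.items():
        for day, (n_m, n_f) in days.items():
            cohort = day_cohort[day]
            if n_m:
                _TABLE_COUNTS[(dose, day, "M", cohort)] = n_m
            if n_f:
                _TABLE_COUNTS[(dose, day, "F", cohort)] = n_f


_fill_counts()


@dataclass
class DesignConfig:
    """Sampling design: which (dose, day, sex, cohort) cells exist and how big.

    ``counts`` maps ``(dose_gy, day, sex, cohort) -> number of samples``;
    ``timepoint_map`` pools study days into timepoint-group labels.
    """

    dose_levels: Sequence[float]
    day_schedule: Sequence[int]
    counts: Mapping[tuple[float, int, str, int], int]
    timepoint_map: Mapping[int, str] = field(default_factory=lambda: dict(TIMEPOINT_MAP))
    seed: int = 0

    def validate(self) -> None:
        for key, n in self.counts.items():
            dose, day, sex, _cohort = key
            if n < 0:
                raise ValueError(f"negative count for cell {key}")
            if dose < 0:
                raise ValueError(f"negative dose in cell {key}")
            if sex not in ("M", "F"):
                raise ValueError(f"sex must be M or F in cell {key}")
            if day not in self.timepoint_map:
                raise ValueError(f"day {day} missing from timepoint_map (cell {key})")

    @property
    def total_samples(self) -> int:
        return int(sum(self.counts.values()))


def default_design(seed: int = 0) -> DesignConfig:
    """The published study layout: 200 samples over 5 doses × 8 days × 2 sexes."""
    return DesignConfig(
        dose_levels=(0.0, 8.0, 11.0, 12.5, 14.0),
        day_schedule=(-5, -1, 9, 10, 28, 29, 59, 60),
        counts=dict(_TABLE_COUNTS),
        seed=seed,
    )


def balanced_design(doses: Sequence[float] = (0.0, 12.5),
                    days: Sequence[int] = (-1, 9),
                    n_per_cell: int = 12,
                    sexes: Sequence[str] = ("M",),
                    cohort: int = 2016,
                    seed: int = 0) -> DesignConfig:
    """A small balanced layout (equal cell sizes), handy for power studies."""
    counts = {(d, day, s, cohort): n_per_cell
              for d in doses for day in days for s in sexes}
    return DesignConfig(dose_levels=tuple(doses), day_schedule=tuple(days),
                        counts=counts, seed=seed)


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Expand a :class:`DesignConfig` into one metadata row per sample.

    Subjects are repeated-measures units: within each (dose, sex, cohort)
    stratum a pool of animals is created, sized by the largest single-day
    cell, and each day's samples are drawn from that pool with a seeded RNG
    so that subject identity is stable across days and reproducible.
    Plasma volumes are drawn uniformly in 0.4–0.6 mL.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # subject pools per stratum
    pool_size: dict[tuple[float, str, int], int] = {}
    for (dose, _day, sex, cohort), n in config.counts.items():
        key = (dose, sex, cohort)
        pool_size[key] = max(pool_size.get(key, 0), n)

    subject_pool = {
        key: [f"S{key[2]}_{key[0]:g}Gy_{key[1]}{i:02d}" for i in range(n)]
        for key, n in sorted(pool_size.items())
    }

    records = []
    for (dose, day, sex, cohort), n in sorted(config.counts.items()):
        if n == 0:
            continue
        pool = subject_pool[(dose, sex, cohort)]
        chosen = sorted(rng.choice(len(pool), size=n, replace=False))
        for i in chosen:
            records.append({
                "subject_id": pool[i],
                "sex": sex,
                "dose_gy": dose,
                "day": day,
                "cohort": cohort,
                "timepoint": config.timepoint_map[day],
                "volume_ml": round(float(rng.uniform(0.4, 0.6)), 4),
            })
    meta = pd.DataFrame(records, columns=[c for c in METADATA_COLUMNS if c != "sample_id"])
    if meta.empty:
        return pd.DataFrame(columns=list(METADATA_COLUMNS))
    meta.insert(0, "sample_id", [f"P{i:04d}" for i in range(len(meta))])
    return meta


@dataclass
class EffectSpec:
    """Parameters of the planted-effect abundance model.

    Defaults emulate the study conditions: 696 named metabolites, ~15 % of
    them radiation-responsive with |log2 FC| in 1.0–2.5, a dose–response
    curve with 8 Gy weakest and ≥11 Gy near-saturating, a time profile
    peaking at TP2 with partial restoration by TP3/TP4, and a sham drift on
    a disjoint 3 % of metabolites that grows over the study (the sham arm
    shows more change at TP4 than TP2).
    """

    n_metabolites: int = 696
    fraction_affected: float = 0.15
    effect_log2fc_range: tuple[float, float] = (1.0, 2.5)
    dose_response: Mapping[float, float] = field(default_factory=lambda: {
        0.0: 0.0, 8.0: 0.4, 11.0: 0.85, 12.5: 1.0, 14.0: 1.1})
    time_profile: Mapping[str, float] = field(default_factory=lambda: {
        "TP1": 0.0, "TP2": 1.0, "TP3": 0.5, "TP4": 0.35})
    sham_drift_log2fc: float = 2.0
    sham_drift_fraction: float = 0.03
    drift_profile: Mapping[str, float] = field(default_factory=lambda: {
        "TP1": 0.0, "TP2": 0.8, "TP3": 0.9, "TP4": 1.0})
    baseline_log_mean_sd: tuple[float, float] = (14.0, 1.5)
    noise_log_sd: float = 0.4
    subject_log_sd: float = 0.2
    missing_lod_quantile: float = 0.08
    high_missing_fraction: float = 0.17
    high_missing_lod_quantile: float = 0.30
    allow_overlap: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValueError("fraction_affected must be in [0, 1]")
        if self.noise_log_sd <= 0:
            raise ValueError("noise_log_sd must be > 0")
        if not 0.0 <= self.missing_lod_quantile < 1.0:
            raise ValueError("missing_lod_quantile must be in [0, 1)")
        if self.n_metabolites <= 0:
            raise ValueError("n_metabolites must be positive")


@dataclass
class GroundTruth:
    """Which metabolites carry planted effects, and how large they are.

    ``effect_log2fc`` holds the signed per-metabolite base effect; the
    realised group-mean shift at (dose d, timepoint t) is
    ``effect_log2fc * dose_response[d] * time_profile[t]`` log2 units.
    Sham-drift metabolites shift by ``drift_log2fc * drift_profile[t]``
    at every dose.  The two sets are disjoint unless overlap was allowed.
    """

    affected_metabolites: dict[str, float]
    sham_drift_metabolites: dict[str, float]
    dose_response: dict[float, float]
    time_profile: dict[str, float]
    drift_profile: dict[str, float]

    def effect_at(self, metabolite: str, dose: float, timepoint: str) -> float:
        """Total planted log2 shift of a metabolite's mean at (dose, timepoint)."""
        shift = 0.0
        if metabolite in self.affected_metabolites:
            shift += (self.affected_metabolites[metabolite]
                      * self.dose_response.get(dose, 0.0)
                      * self.time_profile.get(timepoint, 0.0))
        if metabolite in self.sham_drift_metabolites:
            shift += (self.sham_drift_metabolites[metabolite]
                      * self.drift_profile.get(timepoint, 0.0))
        return shift

    def to_json(self, path) -> None:
        payload = {
            "affected_metabolites": self.affected_metabolites,
            "sham_drift_metabolites": self.sham_drift_metabolites,
            "dose_response": {str(k): v for k, v in self.dose_response.items()},
            "time_profile": dict(self.time_profile),
            "drift_profile": dict(self.drift_profile),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _metabolite_ids(n: int) -> list[str]:
    return [f"met{j:04d}" for j in range(n)]


def generate_abundances(design: pd.DataFrame, spec: EffectSpec, seed: int,
                        affected_ids: Sequence[str] | None = None,
                        drift_ids: Sequence[str] | None = None,
                        ) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw a raw (uncensored) abundance matrix with planted ground truth.

    ``affected_ids`` / ``drift_ids`` override the random choice of which
    metabolites carry effects (used to cluster effects within subpathways);
    when omitted they are drawn disjointly at the EffectSpec fractions.
    Intensities are strictly positive; the same seed gives bit-identical
    output.
    """
    if design.empty:
        raise ValueError("design must contain at least one sample")
    spec.validate()
    rng = np.random.default_rng(seed)
    m = spec.n_metabolites
    met_ids = _metabolite_ids(m)

    if affected_ids is None:
        n_aff = int(round(spec.fraction_affected * m))
        perm = rng.permutation(m)
        affected_idx = perm[:n_aff]
        if drift_ids is None:
            n_drift = int(round(spec.sham_drift_fraction * m))
            start = 0 if spec.allow_overlap else n_aff
            drift_idx = perm[start:start + n_drift]
        else:
            drift_idx = np.array([met_ids.index(i) for i in drift_ids])
    else:
        affected_idx = np.array([met_ids.index(i) for i in affected_ids], dtype=int)
        if drift_ids is None:
            rest = np.setdiff1d(np.arange(m), affected_idx)
            n_drift = int(round(spec.sham_drift_fraction * m))
            drift_idx = rng.permutation(rest)[:n_drift]
        else:
            drift_idx = np.array([met_ids.index(i) for i in drift_ids], dtype=int)
    if not spec.allow_overlap and np.intersect1d(affected_idx, drift_idx).size:
        raise ValueError("affected and sham-drift sets overlap; set allow_overlap=True")

    lo, hi = spec.effect_log2fc_range
    eff = rng.uniform(lo, hi, size=len(affected_idx)) * rng.choice([-1.0, 1.0],
                                                                  size=len(affected_idx))
    drift = spec.sham_drift_log2fc * rng.choice([-1.0, 1.0], size=len(drift_idx))

    base_mu, base_sd = spec.baseline_log_mean_sd
    baseline = rng.normal(base_mu, base_sd, size=m)

    subjects = design["subject_id"].to_numpy()
    uniq_subj = pd.unique(subjects)
    subj_int = {s: rng.normal(0.0, spec.subject_log_sd, size=m) for s in uniq_subj}

    ln2 = np.log(2.0)
    n = len(design)
    logx = np.tile(baseline, (n, 1))
    eff_col = np.zeros(m)
    drift_col = np.zeros(m)
    eff_col[affected_idx] = eff * ln2
    drift_col[drift_idx] = drift * ln2

    for i, row in enumerate(design.itertuples(index=False)):
        d_mult = spec.dose_response.get(row.dose_gy, 0.0)
        t_mult = spec.time_profile.get(row.timepoint, 0.0)
        dr_mult = spec.drift_profile.get(row.timepoint, 0.0)
        logx[i] += subj_int[row.subject_id]
        logx[i] += eff_col * (d_mult * t_mult) + drift_col * dr_mult
        # measured signal scales with the plasma volume loaded, which is
        # exactly what downstream volume normalization removes
        logx[i] += np.log(row.volume_ml)
    logx += rng.normal(0.0, spec.noise_log_sd, size=(n, m))

    data = pd.DataFrame(np.exp(logx), index=pd.Index(design["sample_id"], name="sample_id"),
                        columns=met_ids)
    truth = GroundTruth(
        affected_metabolites={met_ids[j]: float(e) for j, e in zip(affected_idx, eff)},
        sham_drift_metabolites={met_ids[j]: float(d) for j, d in zip(drift_idx, drift)},
        dose_response=dict(spec.dose_response),
        time_profile=dict(spec.time_profile),
        drift_profile=dict(spec.drift_profile),
    )
    return AbundanceMatrix(data, stage="raw"), truth


def apply_missingness(matrix: AbundanceMatrix, lod_quantile,
                      seed: int | None = None,
                      mechanism: str = "lod") -> AbundanceMatrix:
    """Censor low intensities to missing.

    With ``mechanism='lod'`` (default) each metabolite's entries below its
    own ``lod_quantile`` empirical quantile are set to ``NaN`` — the
    detection-limit mechanism implied by minimum-value imputation.  With
    ``mechanism='mcar'`` the same expected fraction is removed completely
    at random (requires ``seed``).  ``lod_quantile`` may be a scalar or a
    per-metabolite mapping/Series; raising it never un-censors an entry.
    """
    matrix.require_stage("raw")
    q = pd.Series(lod_quantile, index=matrix.metabolite_ids, dtype=float) \
        if np.isscalar(lod_quantile) else pd.Series(lod_quantile).reindex(
            matrix.metabolite_ids).fillna(0.0).astype(float)
    if (q >= 1.0).any():
        raise ValueError("lod_quantile must be < 1")
    if (q < 0.0).any():
        raise ValueError("lod_quantile must be >= 0")

    data = matrix.data.copy()
    if mechanism == "lod":
        for col in data.columns:
            qc = q[col]
            if qc <= 0.0:
                continue
            thr = np.nanquantile(data[col].to_numpy(), qc)
            data.loc[data[col] < thr, col] = np.nan
    elif mechanism == "mcar":
        if seed is None:
            raise ValueError("mechanism='mcar' requires a seed")
        rng = np.random.default_rng(seed)
        mask = rng.random(data.shape) < q.to_numpy()[None, :]
        data = data.mask(mask)
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    return AbundanceMatrix(data, stage="raw")


def generate_annotation(n_metabolites: int, seed: int = 0,
                        subpathway_size_mean: float = 8.0,
                        subpathways_per_superpathway: int = 10) -> pd.DataFrame:
    """Assign metabolites to a two-level subpathway/superpathway hierarchy.

    Subpathway sizes are drawn 3 + Poisson(mean − 3) so most sets clear the
    minimum-size-5 enrichment filter while some fall below it, as in real
    Metabolon-style annotations.
    """
    rng = np.random.default_rng(seed)
    met_ids = _metabolite_ids(n_metabolites)
    rows = []
    j = 0
    sub = 0
    while j < n_metabolites:
        size = 3 + rng.poisson(max(subpathway_size_mean - 3.0, 0.0))
        size = min(size, n_metabolites - j)
        sup = sub // subpathways_per_superpathway
        for _ in range(size):
            rows.append({"metabolite_id": met_ids[j],
                         "subpathway": f"subpath{sub:03d}",
                         "superpathway": f"superpath{sup:02d}"})
            j += 1
        sub += 1
    return pd.DataFrame(rows)


def _pick_by_subpathway(annotation: pd.DataFrame, n_wanted: int,
                        rng: np.random.Generator,
                        exclude: set[str] = frozenset()) -> list[str]:
    """Pick ~n_wanted metabolites as whole subpathway blocks (clustered effects)."""
    chosen: list[str] = []
    groups = [g for _, g in annotation.groupby("subpathway")]
    rng.shuffle(groups)
    for g in groups:
        ids = [i for i in g["metabolite_id"] if i not in exclude]
        if not ids:
            continue
        take = min(len(ids), n_wanted - len(chosen))
        chosen.extend(ids[:take])
        if len(chosen) >= n_wanted:
            break
    return chosen


def simulate_cohort(config: DesignConfig | None = None,
                    spec: EffectSpec | None = None,
                    seed: int = 0,
                    cluster_by_subpathway: bool = True,
                    n_affected: int | None = None,
                    n_drift: int | None = None,
                    ) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """One-call cohort simulation: design, abundances, censoring, annotation.

    Returns ``(matrix_raw_with_missing, metadata, annotation, truth)``.
    With ``cluster_by_subpathway`` (default) planted effects fill whole
    subpathways, emulating coordinated pathway-level dysregulation, so that
    hypergeometric enrichment has signal to find; drift metabolites occupy
    different subpathways from radiation-affected ones.
    """
    config = config or default_design(seed=seed)
    spec = spec or EffectSpec()
    ss = np.random.SeedSequence(seed)
    s_design, s_ann, s_pick, s_abund, s_miss = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    config.seed = s_design
    meta = generate_design(config)
    annotation = generate_annotation(spec.n_metabolites, seed=s_ann)

    affected_ids = drift_ids = None
    if cluster_by_subpathway:
        rng = np.random.default_rng(s_pick)
        n_aff = n_affected if n_affected is not None else int(
            round(spec.fraction_affected * spec.n_metabolites))
        n_dr = n_drift if n_drift is not None else int(
            round(spec.sham_drift_fraction * spec.n_metabolites))
        affected_ids = _pick_by_subpathway(annotation, n_aff, rng)
        # drift lives in entirely different subpathways so the confounder
        # filter has a clean pathway-level truth as well
        sub_of = annotation.set_index("metabolite_id")["subpathway"]
        affected_subs = {sub_of[m] for m in affected_ids}
        exclude = set(annotation.loc[annotation["subpathway"].isin(affected_subs),
                                     "metabolite_id"])
        drift_ids = _pick_by_subpathway(annotation, n_dr, rng, exclude=exclude)

    matrix, truth = generate_abundances(meta, spec, seed=s_abund,
                                        affected_ids=affected_ids, drift_ids=drift_ids)

    # a subset of null metabolites sits near the detection limit and will be
    # dropped by the downstream >20%-missing filter, as in real cohorts
    lod = pd.Series(spec.missing_lod_quantile, index=matrix.metabolite_ids)
    n_high = int(round(spec.high_missing_fraction * spec.n_metabolites))
    if n_high > 0:
        planted = set(truth.affected_metabolites) | set(truth.sham_drift_metabolites)
        nulls = [m for m in matrix.metabolite_ids if m not in planted]
        rng_miss = np.random.default_rng(s_miss)
        high = rng_miss.choice(len(nulls), size=min(n_high, len(nulls)), replace=False)
        lod.loc[[nulls[i] for i in high]] = spec.high_missing_lod_quantile
    matrix = apply_missingness(matrix, lod, seed=s_miss)
    return matrix, meta, annotation, truth


def write_cohort(outdir, matrix: AbundanceMatrix, meta: pd.DataFrame,
                 annotation: pd.DataFrame, truth: GroundTruth) -> None:
    """Write matrix/metadata/annotation CSVs and the ground-truth JSON."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "abundance.csv")
    meta.to_csv(out / "metadata.csv", index=False)
    annotation.to_csv(out / "annotation.csv", index=False)
    truth.to_json(out / "ground_truth.json")
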