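"""Composite biomarker rule, confounder filter, Venn partitions, profiles."""

import numpy as np
import pandas as pd
import pytest

import radmetab as rm


def evidence(n=8, sub_sizes=(6, 2)):
    """Hand-built evidence tables: metabolites b0.. in 'big' (enriched),
    s0.. in 'small' (below min size)."""
    big = [f"b{i}" for i in range(sub_sizes[0])]
    small = [f"s{i}" for i in range(sub_sizes[1])]
    idx = big + small
    uni = pd.DataFrame({
        "fold_change": 3.0, "log2_fc": np.log2(3.0),
        "t_stat": 5.0, "df": 10.0, "p_value": 0.01, "q_value": 0.02,
        "direction": "up", "degenerate": False,
    }, index=pd.Index(idx, name="metabolite_id"))
    vip = pd.Series(1.5, index=idx)
    ann = pd.DataFrame(
        [{"metabolite_id": m, "subpathway": "big", "superpathway": "SP"} for m in big]
        + [{"metabolite_id": m, "subpathway": "small", "superpathway": "SP"} for m in small])
    enr = pd.DataFrame([{"subpathway": "big", "superpathway": "SP",
                         "N": n, "K": len(big), "n": 4, "k": 4,
                         "p_over": 0.01, "p_under": 1.0,
                         "direction": "over", "significant": True}])
    return uni, vip, ann, enr


class TestCompositeSelect:
    def test_all_criteria_met_selects(self):
        uni, vip, ann, enr = evidence()
        sel = rm.composite_select(uni, vip, True, enr, ann, contrast="c")
        assert "b0" in sel.selected_metabolites
        assert sel.selected_subpathways == {"big"}

    def test_single_criterion_failures_record_reason(self):
        uni, vip, ann, enr = evidence()
        vip_low = vip.copy(); vip_low["b0"] = 0.9
        sel = rm.composite_select(uni, vip_low, True, enr, ann)
        assert sel.table.loc["b0", "rejection_reason"] == "VIP below threshold"

        sel = rm.composite_select(uni, vip, True, enr, ann)
        assert sel.table.loc["s0", "rejection_reason"] == "subpathway not enriched"

        enr_small = enr.copy(); enr_small.loc[0, "K"] = 4
        sel = rm.composite_select(uni, vip, True, enr_small, ann)
        assert sel.table.loc["b0", "rejection_reason"] == "subpathway below min size"

        uni_p = uni.copy(); uni_p.loc["b0", "p_value"] = 0.2
        sel = rm.composite_select(uni_p, vip, True, enr, ann)
        assert sel.table.loc["b0", "rejection_reason"] == "p-value above threshold"

        uni_fc = uni.copy()
        uni_fc.loc["b0", ["fold_change", "log2_fc"]] = (1.5, np.log2(1.5))
        sel = rm.composite_select(uni_fc, vip, True, enr, ann)
        assert sel.table.loc["b0", "rejection_reason"] == "fold change below threshold"

    def test_unvalidated_model_blocks_everything(self):
        uni, vip, ann, enr = evidence()
        sel = rm.composite_select(uni, vip, False, enr, ann)
        assert not sel.selected_metabolites
        assert (sel.table["rejection_reason"] == "OPLS-DA model not validated").all()
        relaxed = rm.SelectionThresholds(require_validated_model=False)
        sel2 = rm.composite_select(uni, vip, False, enr, ann, thresholds=relaxed)
        assert "b0" in sel2.selected_metabolites

    def test_selection_is_intersection_of_criteria(self, small_imputed):
        imputed, normalized, meta, ann, _ = small_imputed
        spec = rm.ContrastSpec("time_within_dose", 12.5, "TP1", "TP2")
        uni = rm.run_contrast(imputed, meta, spec, normalized=normalized)
        ids_a, ids_b = spec.select(meta)
        model = rm.fit_oplsda(imputed.data.loc[ids_a.append(ids_b)],
                              ["a"] * len(ids_a) + ["b"] * len(ids_b))
        sig = set(uni.index[(uni.log2_fc.abs() > 1) & (uni.p_value < 0.05)])
        enr, _ = rm.enrich_subpathways(sig, set(uni.index), ann)
        sel = rm.composite_select(uni, model.vip, True, enr, ann)
        chosen = set(sel.selected_metabolites)
        assert chosen  # planted effects exist at this contrast
        assert chosen <= sig
        assert all(model.vip[m] > 1.0 for m in chosen)
        enriched = set(enr.loc[enr.significant & (enr.K >= 5), "subpathway"])
        sub_of = ann.set_index("metabolite_id")["subpathway"]
        assert all(sub_of[m] in enriched for m in chosen)

    def test_coverage_mismatch_rejected(self):
        uni, vip, ann, enr = evidence()
        with pytest.raises(ValueError, match="background"):
            rm.composite_select(uni, vip.drop("b0"), True, enr, ann)


class TestConfounderFilter:
    def _result(self, contrast, selected):
        uni, vip, ann, enr = evidence()
        sel = rm.composite_select(uni, vip, True, enr, ann, contrast=contrast)
        keep = sel.table.index.isin(selected)
        sel.table.loc[~keep, "selected"] = False
        sel.table.loc[~keep & (sel.table.rejection_reason == ""),
                      "rejection_reason"] = "p-value above threshold"
        sel.selected_subpathways = {
            s for s in sel.table.loc[sel.table.selected, "subpathway"].unique()}
        return sel

    def test_sham_markers_removed_with_reason(self):
        cand = self._result("12.5Gy_TP1_vs_TP2", ["b0", "b1"])
        sham = self._result("0Gy_TP1_vs_TP2", ["b0"])
        out = rm.confounder_filter(cand, sham)
        assert set(out.selected_metabolites) == {"b1"}
        assert out.table.loc["b0", "rejection_reason"] == "sham time drift"
        assert out.removed_as_confounder == {"b0"}

    def test_empty_or_disjoint_sham_leaves_candidate(self):
        cand = self._result("11Gy_TP1_vs_TP3", ["b0", "b1"])
        for sham_sel in ([], ["b3"]):
            out = rm.confounder_filter(cand, self._result("0Gy_TP1_vs_TP3", sham_sel))
            assert set(out.selected_metabolites) == {"b0", "b1"}

    def test_idempotent(self):
        cand = self._result("12.5Gy_TP1_vs_TP2", ["b0", "b1"])
        sham = self._result("0Gy_TP1_vs_TP2", ["b0"])
        once = rm.confounder_filter(cand, sham)
        twice = rm.confounder_filter(once, sham)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_mismatched_contrasts_rejected(self):
        cand = self._result("12.5Gy_TP1_vs_TP2", ["b0"])
        sham = self._result("0Gy_TP1_vs_TP3", ["b0"])
        with pytest.raises(ValueError, match="mismatched"):
            rm.confounder_filter(cand, sham)

    def test_subpathway_filtering_mirrors_metabolites(self):
        cand = self._result("12.5Gy_TP1_vs_TP2", ["b0", "b1"])
        sham = self._result("0Gy_TP1_vs_TP2", ["b0"])
        out = rm.confounder_filter(cand, sham)
        assert out.selected_subpathways == set()  # "big" was a sham subpathway too
        assert out.removed_subpathways == {"big"}


class TestVennPartition:
    def test_hand_enumeration(self):
        parts = rm.venn_partition({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        assert parts[("A",)] == 1 and parts[("B",)] == 1
        assert parts[("A", "B", "C")] == 1
        assert parts[("A", "B")] == 0 and parts[("A", "C")] == 0
        assert sum(parts.values()) == 3  # union size

    def test_identical_and_disjoint(self):
        same = rm.venn_partition({"A": {1, 2}, "B": {1, 2}})
        assert same[("A", "B")] == 2 and same[("A",)] == 0
        disj = rm.venn_partition({"A": {1}, "B": {2}})
        assert disj[("A",)] == 1 and disj[("B",)] == 1 and disj[("A", "B")] == 0

    def test_union_conserved_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sets = {n: set(rng.choice(30, size=rng.integers(0, 15), replace=False))
                    for n in "ABCD"}
            parts = rm.venn_partition(sets)
            assert sum(parts.values()) == len(set().union(*sets.values()))
            assert all(v >= 0 for v in parts.values())

    def test_set_count_limits(self):
        with pytest.raises(ValueError):
            rm.venn_partition({"A": set()})
        with pytest.raises(ValueError):
            rm.venn_partition({n: set() for n in "ABCDE"})


class TestDoseResponseProfile:
    def test_planted_monotone_dose_effect(self):
        spec = rm.EffectSpec(n_metabolites=40, fraction_affected=0.2,
                             sham_drift_fraction=0.0, noise_log_sd=0.2,
                             missing_lod_quantile=0.0, high_missing_fraction=0.0)
        cfg = rm.balanced_design(doses=(0.0, 8.0, 11.0, 12.5), days=(-1, 9),
                                 n_per_cell=10)
        mat, meta, ann, truth = rm.simulate_cohort(cfg, spec, seed=21)
        imputed, _, _ = rm.preprocess_pipeline(mat, meta)
        up = [m for m, e in truth.affected_metabolites.items() if e > 1.5][:3]
        prof = rm.dose_response_profile(imputed, meta, up, "TP2")
        for m in up:
            sub = prof[prof.metabolite_id == m].sort_values("dose_gy")
            assert sub["mean_log"].is_monotonic_increasing

    def test_flat_profile_for_null_metabolite(self, small_imputed):
        imputed, _, meta, _, truth = small_imputed
        planted = set(truth.affected_metabolites) | set(truth.sham_drift_metabolites)
        null = next(m for m in imputed.metabolite_ids if m not in planted)
        prof = rm.dose_response_profile(imputed, meta, [null], "TP2")
        spread = prof["mean_log"].max() - prof["mean_log"].min()
        assert spread < 3 * prof["sd_log"].max()

    def test_unknown_metabolite_rejected(self, small_imputed):
        imputed, _, meta, _, _ = small_imputed
        with pytest.raises(ValueError, match="nope"):
            rm.dose_response_profile(imputed, meta, ["nope"], "TP1")
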