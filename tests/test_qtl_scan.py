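"""Likelihood-ratio marker model, genome scan, permutation threshold, co-location."""

import numpy as np
import pandas as pd
import pytest

import leafqtl as lq
from leafqtl.qtl_scan import (
    MarkerSkipped,
    fit_marker_model,
    threshold_from_maxima,
)


class TestFitMarkerModel:
    def test_hand_computed_ml_oracle(self):
        # classes A: (1,2,1,2), B: (3,4,3,4): RSS0 = 10, RSS1 = 2
        y = [1, 2, 1, 2, 3, 4, 3, 4]
        cls = list("AAAABBBB")
        fit = fit_marker_model(y, cls, min_class_n=2)
        assert fit.mu_j == (1.5, 3.5)
        assert fit.rss0 == pytest.approx(10.0)
        assert fit.rss1 == pytest.approx(2.0)
        assert fit.lr == pytest.approx(8 * np.log(5))
        assert fit.pve_percent == pytest.approx(80.0)
        assert fit.effects["delta"] == pytest.approx(2.0)

    def test_equal_class_means_give_null_identity(self):
        y = [1, 2, 3, 0, 2, 4]
        cls = list("AAABBB")
        fit = fit_marker_model(y, cls, min_class_n=2)
        assert fit.lr == pytest.approx(0.0, abs=1e-12)
        assert fit.pve_percent == pytest.approx(0.0, abs=1e-9)

    def test_intercross_effect_definitions(self):
        # class means exactly (0, 1, 2) in AA/Aa/aa order: a = 1, d = 0
        y = [0.0] * 5 + [1.0] * 5 + [2.0] * 5 + [0.5, -0.5, 1.5, 0.5, 2.5]
        cls = ["AA"] * 5 + ["Aa"] * 5 + ["aa"] * 5 + ["AA", "AA", "Aa", "Aa", "aa"]
        # keep means exact: rebuild without the noise tail
        fit = fit_marker_model(y[:15], cls[:15], min_class_n=2,
                               class_labels=("AA", "Aa", "aa"))
        assert fit.effects["additive"] == pytest.approx(1.0)
        assert fit.effects["dominance"] == pytest.approx(0.0)

    def test_sparse_class_skipped(self):
        with pytest.raises(MarkerSkipped) as exc:
            fit_marker_model([1, 2, 3, 4, 5, 9], list("AAAAAB"), min_class_n=2)
        assert exc.value.reason == "sparse_class"

    def test_monomorphic_skipped(self):
        with pytest.raises(MarkerSkipped) as exc:
            fit_marker_model([1, 2, 3], list("AAA"), min_class_n=1)
        assert exc.value.reason == "monomorphic"

    def test_zero_residual_variance_flagged_infinite(self):
        fit = fit_marker_model([1, 1, 1, 2, 2, 2], list("AAABBB"), min_class_n=2)
        assert fit.zero_residual
        assert np.isinf(fit.lr)

    def test_missing_values_dropped(self):
        y = [1, 2, 1, 2, 3, 4, 3, 4, np.nan]
        cls = list("AAAABBBB") + [None]
        fit = fit_marker_model(y, cls, min_class_n=2)
        assert fit.n == 8

    @pytest.mark.parametrize("instance_seed", range(8))
    def test_lr_equals_group_means_r2_identity_and_affine_invariance(self, instance_seed):
        # brute-force oracle: LR = n ln(1 / (1 - R^2)) with one-way between-class R^2
        rng = np.random.default_rng(instance_seed)
        n = int(rng.integers(20, 60))
        cls = rng.choice(["A", "B", "C"], size=n, p=[0.4, 0.35, 0.25])
        y = rng.normal(size=n) + (cls == "B") * rng.normal(0, 1)
        fit = fit_marker_model(y, cls, min_class_n=2)
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        ss_between = sum(
            (cls == g).sum() * (y[cls == g].mean() - grand) ** 2 for g in set(cls)
        )
        r2 = ss_between / ss_tot
        assert fit.lr == pytest.approx(n * np.log(1.0 / (1.0 - r2)))
        # affine invariance of LR and PVE
        fit2 = fit_marker_model(3.7 * y - 11.0, cls, min_class_n=2)
        assert fit2.lr == pytest.approx(fit.lr)
        assert fit2.pve_percent == pytest.approx(fit.pve_percent)

    def test_lr_monotone_in_pooled_t_squared_for_testcross(self):
        rng = np.random.default_rng(3)
        n = 40
        t2s, lrs = [], []
        for _ in range(12):
            cls = np.array(["aa"] * 20 + ["ab"] * 20)
            y = rng.normal(size=n) + (cls == "ab") * rng.uniform(0, 2)
            fit = fit_marker_model(y, cls, min_class_n=2)
            a, b = y[:20], y[20:]
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n - 2)
            t2 = (b.mean() - a.mean()) ** 2 / (sp2 * (1 / 20 + 1 / 20))
            t2s.append(t2)
            lrs.append(fit.lr)
        order = np.argsort(t2s)
        assert (np.diff(np.array(lrs)[order]) > 0).all()


class TestGenomeScan:
    def test_planted_qtl_is_scan_maximum(self, planted_scan):
        lmap, geno, pheno, truth, marker = planted_scan
        res = lq.genome_scan(pheno, geno, lmap, "LA")
        best = res.table.loc[res.table["lr"].idxmax()]
        markers = res.table["marker_id"].tolist()
        hit_zone = {marker}
        idx = markers.index(marker)
        hit_zone.update(markers[max(0, idx - 1):idx + 2])
        assert best["marker_id"] in hit_zone

    def test_markers_ordered_along_map(self, planted_scan):
        lmap, geno, pheno, _, _ = planted_scan
        res = lq.genome_scan(pheno, geno, lmap, "LA")
        tab = res.table
        for _, sub in tab.groupby("linkage_group"):
            assert sub["position"].is_monotonic_increasing

    def test_duplicate_markers_at_zero_distance_identical_lr(self):
        spec = lq.CrossSpec(n_progeny=100, linkage_groups=1, markers_per_group=3,
                            marker_spacing=0.0, testcross_fraction=1.0,
                            maternal_testcross_fraction=1.0, seed=13)
        lmap, geno = lq.simulate_cross(spec)
        rng = np.random.default_rng(0)
        pheno = lq.PhenotypeTable(
            pd.DataFrame({"LA": rng.normal(size=100)}, index=geno.individuals))
        res = lq.genome_scan(pheno, geno, lmap, "LA")
        assert res.table["lr"].nunique() == 1

    def test_no_overlapping_individuals_rejected(self, small_cross):
        lmap, geno = small_cross
        pheno = lq.PhenotypeTable(pd.DataFrame({"LA": [1.0, 2.0, 3.0]},
                                               index=["x1", "x2", "x3"]))
        with pytest.raises(lq.ValidationError, match="overlapping"):
            lq.genome_scan(pheno, geno, lmap, "LA")

    def test_unmapped_markers_reported_as_skipped(self, planted_scan):
        lmap, geno, pheno, _, _ = planted_scan
        half_map = lq.LinkageMap(lmap.table.iloc[: len(lmap.table) // 2])
        res = lq.genome_scan(pheno, geno, half_map, "LA")
        assert (res.skipped["reason"] == "not_in_map").sum() == len(lmap.table) - len(
            half_map.table
        )


class TestPermutationThreshold:
    def test_order_statistic_convention(self):
        maxima = np.arange(1.0, 101.0)
        assert threshold_from_maxima(maxima, alpha=0.05) == 95.0

    def test_alpha_one_gives_minimum(self):
        maxima = np.arange(1.0, 101.0)
        assert threshold_from_maxima(maxima, alpha=1.0) == 1.0

    def test_brute_force_sort_oracle(self, rng):
        maxima = rng.exponential(size=137)
        alpha = 0.1
        k = int(np.ceil((1 - alpha) * 137))
        assert threshold_from_maxima(maxima, alpha) == sorted(maxima)[k - 1]

    def test_threshold_reproducible_from_stored_maxima(self, planted_scan):
        lmap, geno, pheno, _, _ = planted_scan
        res = lq.scan_trait(pheno, geno, lmap, "LA", n_perm=120, alpha=0.05, seed=31)
        assert res.threshold == threshold_from_maxima(res.permutation_max_lrs, 0.05)
        assert (res.qtl_calls()["lr"] >= res.threshold).all()

    def test_seed_reproducibility(self, planted_scan):
        lmap, geno, pheno, _, _ = planted_scan
        t1, m1 = lq.permutation_threshold(pheno, geno, lmap, "LA", n_perm=100, seed=5)
        t2, m2 = lq.permutation_threshold(pheno, geno, lmap, "LA", n_perm=100, seed=5)
        assert t1 == t2 and np.array_equal(m1, m2)

    def test_small_permutation_count_rejected(self, planted_scan):
        lmap, geno, pheno, _, _ = planted_scan
        with pytest.raises(lq.ValidationError, match="n_perm"):
            lq.permutation_threshold(pheno, geno, lmap, "LA", n_perm=50)


def _fake_scan(trait, rows, threshold):
    table = pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position", "lr",
                                        "pve_percent"])
    return lq.ScanResult(trait=trait, table=table, skipped=pd.DataFrame(),
                         n_individuals=100, alpha=0.05, threshold=threshold)


class TestCallAndColocate:
    def test_shared_marker_counts_once_in_intersection(self):
        s1 = _fake_scan("LA", [("mX", "LG1", 5.0, 20.0, 10.0)], 10.0)
        s2 = _fake_scan("Cir", [("mX", "LG1", 5.0, 18.0, 9.0)], 10.0)
        table, venn = lq.call_and_colocate({"LA": s1, "Cir": s2},
                                           {"LA": "size", "Cir": "shape"})
        assert venn["per_module"] == {"shape": 1, "size": 1}
        assert venn["intersections"]["shape&size"] == 1

    def test_disjoint_calls_have_empty_intersections(self):
        s1 = _fake_scan("LA", [("mX", "LG1", 5.0, 20.0, 10.0)], 10.0)
        s2 = _fake_scan("Cir", [("mY", "LG2", 9.0, 18.0, 9.0)], 10.0)
        _, venn = lq.call_and_colocate({"LA": s1, "Cir": s2},
                                       {"LA": "size", "Cir": "shape"})
        assert venn["intersections"]["shape&size"] == 0

    def test_window_merges_nearby_markers(self):
        s1 = _fake_scan("LA", [("mX", "LG1", 5.0, 20.0, 10.0)], 10.0)
        s2 = _fake_scan("Cir", [("mZ", "LG1", 6.5, 18.0, 9.0)], 10.0)
        _, venn0 = lq.call_and_colocate({"LA": s1, "Cir": s2},
                                        {"LA": "size", "Cir": "shape"}, coloc_window_cm=0.0)
        _, venn2 = lq.call_and_colocate({"LA": s1, "Cir": s2},
                                        {"LA": "size", "Cir": "shape"}, coloc_window_cm=2.0)
        assert venn0["intersections"]["shape&size"] == 0
        assert venn2["intersections"]["shape&size"] == 1

    def test_missing_module_tag_rejected(self):
        s1 = _fake_scan("LA", [("mX", "LG1", 5.0, 20.0, 10.0)], 10.0)
        with pytest.raises(lq.ValidationError, match="module"):
            lq.call_and_colocate({"LA": s1}, {})

    def test_unthresholded_scan_rejected(self):
        s1 = _fake_scan("LA", [("mX", "LG1", 5.0, 20.0, 10.0)], None)
        with pytest.raises(lq.ValidationError, match="threshold"):
            lq.call_and_colocate({"LA": s1}, {"LA": "size"})

    def test_planted_pleiotropic_qtl_recovered_as_colocated(self):
        hits = 0
        reps = 25
        for seed in range(reps):
            spec = lq.CrossSpec(n_progeny=179, linkage_groups=2, markers_per_group=15,
                                marker_spacing=5.0, seed=600 + seed)
            lmap, geno = lq.simulate_cross(spec)
            marker = next(m for m in geno.marker_ids
                          if geno.marker_info.loc[m, "seg_type"] == "testcross2")
            qtls = lq.QTLSpec(
                effects=[lq.QTLEffect("LA", marker, (0.0, 2.0)),
                         lq.QTLEffect("Cir", marker, (0.0, 2.0))],
                residual_sd=2.0,
            )
            pheno, _ = lq.simulate_phenotypes(geno, qtls, seed=700 + seed)
            scans = {
                t: lq.scan_trait(pheno, geno, lmap, t, n_perm=120, alpha=0.05,
                                 seed=800 + seed)
                for t in ["LA", "Cir"]
            }
            _, venn = lq.call_and_colocate(scans, {"LA": "size", "Cir": "shape"},
                                           coloc_window_cm=5.0)
            if venn["intersections"].get("shape&size", 0) >= 1:
                hits += 1
        assert hits >= 0.9 * reps
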