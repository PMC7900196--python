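import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromstate.pipeline as pipeline
from chromstate.bivalency import extract_bivalent_regions, union_bivalent_regions
from chromstate.context import (
    ConservationTrack,
    SilencerSet,
    bivalent_silencer_overlap_z,
    distance_matched_tss_control,
    interval_bin_mask,
    nearest_silencer_distance,
    silencer_center_state,
    silencer_footprint_enrichment,
    state_mean_conservation,
    target_tss_state_enrichment,
    tissue_mean_conservation,
    transposon_overlap_fraction,
    tss_conservation_by_bivalency,
)
from chromstate.genome import BinnedGenome
from chromstate.segstats import genome_coverage
from conftest import make_segmentation


def silencer_set(rows, links=None):
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "group", "silencer_id"]
    )
    return SilencerSet(df, links or {})


def cons_track(seg, values):
    return ConservationTrack(seg.genome, {"c": np.asarray(values, dtype=float)})


class TestConservation:
    def test_constant_score_every_state(self):
        seg = make_segmentation({"c": np.array([0, 1, 1, 0])}, ["A", "B"])
        out = state_mean_conservation(seg, cons_track(seg, [0.3] * 4))
        assert np.allclose(out, 0.3)

    def test_state_mean_and_missing_bins_ignored(self):
        seg = make_segmentation({"c": np.array([0, 0, 1, 0])}, ["A", "B"])
        out = state_mean_conservation(
            seg, cons_track(seg, [0.2, 0.6, 0.9, np.nan])
        )
        assert np.isclose(out["A"], 0.4)
        assert np.isclose(out["B"], 0.9)

    def test_absent_state_is_nan_and_tissue_average(self):
        seg = make_segmentation({"c": np.array([0, 0])}, ["A", "B"])
        out = state_mean_conservation(seg, cons_track(seg, [0.1, 0.3]))
        assert np.isnan(out["B"])
        merged = tissue_mean_conservation([out, out + 0.2])
        assert np.isclose(merged["A"], 0.3)

    def test_bivalent_state_ranks_first_on_synthetic_data(self, small_dataset,
                                                          decoded):
        ds = small_dataset
        track = ConservationTrack(ds.genome, ds.conservation)
        per = [state_mean_conservation(seg, track) for seg in decoded.values()]
        means = tissue_mean_conservation(per)
        assert means.idxmax() == "TssBiv"


class TestTssConservationByBivalency:
    def test_constructed_separation(self):
        rng = np.random.default_rng(8)
        n = 400
        labels = np.zeros(n, dtype=int)
        labels[:200] = 1  # TssBiv bins first
        seg = make_segmentation({"c": labels}, ["Other", "TssBiv"])
        scores = np.where(labels == 1, rng.normal(0.8, 0.1, n),
                          rng.normal(0.5, 0.1, n))
        track = cons_track(seg, scores)
        tss = [("c", int(b) * 200 + 50) for b in range(n)]
        a, b, p, skipped = tss_conservation_by_bivalency(tss, seg, track)
        assert a.mean() > b.mean()
        assert p < 0.01 and skipped == 0

    def test_single_group_p_undefined(self):
        seg = make_segmentation({"c": np.array([1, 1])}, ["Other", "TssBiv"])
        track = cons_track(seg, [0.5, 0.6])
        a, b, p, _ = tss_conservation_by_bivalency(
            [("c", 10), ("c", 210)], seg, track
        )
        assert len(b) == 0 and np.isnan(p)

    def test_missing_score_skipped(self):
        seg = make_segmentation({"c": np.array([1, 0])}, ["Other", "TssBiv"])
        track = cons_track(seg, [np.nan, 0.2])
        a, b, p, skipped = tss_conservation_by_bivalency(
            [("c", 10), ("c", 210)], seg, track
        )
        assert skipped == 1 and len(a) == 0 and len(b) == 1


class TestTransposonOverlap:
    def test_full_coverage(self):
        seg = make_segmentation({"c": np.array([0, 1, 0, 1])}, ["A", "Enh"])
        tp = pd.DataFrame([("c", 0, 800)], columns=["chrom", "start", "end"])
        frac, control = transposon_overlap_fraction(seg, "Enh", tp)
        assert frac == 1.0 and control == 1.0

    def test_single_bp_overlap_counts(self):
        seg = make_segmentation({"c": np.array([0, 1])}, ["Enh", "B"])
        tp = pd.DataFrame([("c", 199, 205)], columns=["chrom", "start", "end"])
        frac, control = transposon_overlap_fraction(seg, "Enh", tp)
        assert frac == 1.0  # bin [0,200) overlaps by exactly 1 bp
        assert control == 1.0

    def test_counting_oracle_toy(self):
        labels = np.array([1, 0, 1, 0, 1, 1, 0, 0, 0, 0])
        seg = make_segmentation({"c": labels}, ["A", "Enh"])
        tp = pd.DataFrame(
            [("c", 0, 100), ("c", 450, 460), ("c", 900, 1100)],
            columns=["chrom", "start", "end"],
        )
        mask = interval_bin_mask(seg.genome, tp)
        # brute force: bins 0, 2, 4, 5 hold Enh; transposon bins 0, 2, 4, 5?
        brute = np.zeros(10, dtype=bool)
        for s, e in [(0, 100), (450, 460), (900, 1100)]:
            for b in range(10):
                if max(s, b * 200) < min(e, (b + 1) * 200):
                    brute[b] = True
        assert (mask == brute).all()
        frac, control = transposon_overlap_fraction(seg, "Enh", tp)
        assert frac == mask[labels == 1].mean()
        assert control == mask.mean()


class TestSilencerCenterState:
    def test_fold_is_center_fraction_over_footprint(self):
        labels = np.zeros(20, dtype=int)
        labels[:2] = 1  # TssBiv covers 10%
        seg = make_segmentation({"c": labels}, ["Quies", "TssBiv"])
        sils = silencer_set(
            [("c", 0, 300, 3, "s1"), ("c", 150, 450, 3, "s2")]
        )  # centers 150, 300 -> bins 0, 1 (both TssBiv)
        per_sil, table = silencer_center_state(sils, seg)
        assert (per_sil == "TssBiv").all()
        assert np.isclose(table.loc["TssBiv", "fold"], 1.0 / 0.1)

    def test_fraction_conservation_with_unassigned(self):
        labels = np.array([0, -1, 1, 1])
        seg = make_segmentation({"c": labels}, ["A", "B"])
        sils = silencer_set(
            [("c", 0, 200, 1, "a"), ("c", 200, 400, 2, "b"),
             ("c", 400, 600, 3, "x"), ("c", 600, 800, 4, "y")]
        )
        per_sil, table = silencer_center_state(sils, seg)
        assert np.isclose(table["center_fraction"].sum(), 1.0)
        assert per_sil["b"] == "unassigned"

    def test_empty_set_gives_missing(self):
        seg = make_segmentation({"c": np.array([0])}, ["A"])
        per_sil, table = silencer_center_state(silencer_set([]), seg)
        assert table["center_fraction"].isna().all()

    def test_paper_scale_fold_arithmetic(self):
        # center fraction 0.24 over footprint 0.0028 -> 85.7-fold
        assert np.isclose(0.24 / 0.0028, 85.7, atol=0.05)


class TestFootprintEnrichment:
    def test_centers_only_in_reference_state(self):
        labels = np.zeros(200, dtype=int)
        labels[:20] = 1
        seg = make_segmentation({"c": labels}, ["Quies", "TssBiv"])
        rows = [("c", b * 200, b * 200 + 100, 3, f"s{b}") for b in range(10)]
        out = silencer_footprint_enrichment(
            seg, silencer_set(rows), "TssBiv", n_draws=50, seed=1
        )
        assert out.loc["TssBiv", "percent"] == 50.0  # 10 of 20 bins
        assert out.loc["Quies", "percent"] == 0.0
        assert out.loc["Quies", "sd"] == 0.0

    def test_resampling_stability(self, decoded, small_dataset):
        seg = next(iter(decoded.values()))
        sils = small_dataset.silencers
        a = silencer_footprint_enrichment(seg, sils, "TssBiv", n_draws=1, seed=5)
        b = silencer_footprint_enrichment(seg, sils, "TssBiv", n_draws=100, seed=5)
        for state in ("ReprPC", "Quies"):
            sd = b.loc[state, "sd"]
            assert abs(a.loc[state, "percent"] - b.loc[state, "percent"]) <= \
                max(3 * sd, 1e-9)

    def test_small_state_sampled_with_replacement_flagged(self):
        labels = np.zeros(50, dtype=int)
        labels[:10] = 1
        labels[10:12] = 2  # tiny state
        seg = make_segmentation({"c": labels}, ["Quies", "TssBiv", "Tiny"])
        with pytest.warns(UserWarning, match="replacement"):
            out = silencer_footprint_enrichment(
                seg, silencer_set([("c", 0, 100, 1, "s")]), "TssBiv",
                n_draws=10, seed=2,
            )
        assert out.loc["Tiny", "with_replacement"]


class TestOverlapZ:
    def test_identical_sets_all_observed(self):
        genome = BinnedGenome([("c", 1_000_000)])
        regions = pd.DataFrame(
            [("c", i * 10_000, i * 10_000 + 600, "s") for i in range(20)],
            columns=["chrom", "start", "end", "biosample"],
        )
        sils = silencer_set(
            [("c", r.start, r.end, 3, f"x{i}")
             for i, r in enumerate(regions.itertuples())]
        )
        res = bivalent_silencer_overlap_z(regions, sils, genome, n_random=20,
                                          seed=1)
        assert res.observed == 20

    def test_constructed_enrichment_gives_large_z(self):
        rng = np.random.default_rng(4)
        genome = BinnedGenome([("c", 2_000_000)])
        starts = rng.choice(9_000, size=100, replace=False) * 200
        regions = pd.DataFrame(
            [("c", int(s), int(s) + 200, "s") for s in starts],
            columns=["chrom", "start", "end", "biosample"],
        )  # ~1% genome coverage
        sils = silencer_set(
            [("c", int(s) + 20, int(s) + 170, 3, f"s{i}")
             for i, s in enumerate(starts[:60])]
        )
        res = bivalent_silencer_overlap_z(regions, sils, genome, n_random=100,
                                          seed=9)
        assert res.observed == 60
        assert res.z > 10

    def test_null_is_calibrated_over_seeds(self):
        genome = BinnedGenome([("c", 1_000_000)])
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rs = rng.integers(0, 4_950, size=50) * 200
            regions = pd.DataFrame(
                [("c", int(s), int(s) + int(rng.integers(1, 4)) * 200, "b")
                 for s in rs],
                columns=["chrom", "start", "end", "biosample"],
            )
            ss = rng.integers(0, 999_400, size=80)
            sils = silencer_set(
                [("c", int(s), int(s) + 400, 1 + i % 4, f"s{i}")
                 for i, s in enumerate(ss)]
            )
            res = bivalent_silencer_overlap_z(
                regions, sils, genome, n_random=30, seed=seed + 1000
            )
            if not np.isfinite(res.z) or abs(res.z) < 3:
                inside += 1
        assert inside >= 95

    def test_zero_sd_reports_nan_z(self):
        genome = BinnedGenome([("c", 2000)])
        regions = pd.DataFrame(
            [("c", 0, 2000, "s")], columns=["chrom", "start", "end", "biosample"]
        )  # covers the whole chromosome: every placement identical
        sils = silencer_set([("c", 100, 300, 1, "s1")])
        res = bivalent_silencer_overlap_z(regions, sils, genome, n_random=10,
                                          seed=0)
        assert np.isnan(res.z) and res.observed == 1


class TestDistanceMatchedControl:
    def test_single_target_gets_control_from_stratum(self):
        sils = silencer_set([("c", 10_000, 11_000, 1, "s")])
        target = [("c", 12_000)]  # distance ~1000
        pool = [("c", 12_100), ("c", 500_000), ("c", 13_000)]
        controls, unmatched = distance_matched_tss_control(
            target, target + pool, sils, seed=3
        )
        assert unmatched == 0 and len(controls) == 1
        d = nearest_silencer_distance(controls, sils)[0]
        assert 10 ** (np.floor(10 * np.log10(1000)) / 10) <= d < 10 ** (
            (np.floor(10 * np.log10(1000)) + 2) / 10
        )

    def test_distribution_matched_ks(self):
        rng = np.random.default_rng(6)
        sils = silencer_set([("c", 5_000_000, 5_001_000, 2, "s")])
        # bimodal distances: ~10 kb and ~1 Mb
        d1 = 10 ** rng.normal(4, 0.15, size=400)
        d2 = 10 ** rng.normal(6, 0.1, size=400)
        targets = [("c", int(5_001_000 + d)) for d in np.concatenate([d1, d2])]
        pool = [
            ("c", int(5_001_000 + 10 ** rng.uniform(3, 6.5))) for _ in range(8000)
        ]
        controls, unmatched = distance_matched_tss_control(
            targets, targets + pool, sils, seed=7
        )
        assert unmatched < 0.05 * len(targets)
        dt = np.log10(nearest_silencer_distance(targets, sils))
        dc = np.log10(nearest_silencer_distance(controls, sils))
        ks = stats.ks_2samp(dt, dc).statistic
        assert ks < 0.1

    def test_no_pool_rejected(self):
        sils = silencer_set([("c", 0, 100, 1, "s")])
        with pytest.raises(ValueError):
            distance_matched_tss_control([("c", 500)], [("c", 500)], sils)


class TestTargetTssEnrichment:
    def test_fully_separated_placement(self):
        labels = np.array([1, 1, 0, 0])
        seg = make_segmentation({"c": labels}, ["Quies", "TssBiv"])
        out = target_tss_state_enrichment(
            [("c", 10), ("c", 210)], [("c", 410), ("c", 610)], seg
        )
        assert out.loc["TssBiv", "target"] == 100.0
        assert out.loc["TssBiv", "control"] == 0.0

    def test_identical_distributions_equal_percentages(self):
        labels = np.array([1, 0, 1, 0])
        seg = make_segmentation({"c": labels}, ["Quies", "TssBiv"])
        out = target_tss_state_enrichment(
            [("c", 10), ("c", 210)], [("c", 410), ("c", 610)], seg
        )
        assert (out["target"] == out["control"]).all()

    def test_group_linked_silencers_enrich_bivalent_targets(
        self, small_dataset, decoded
    ):
        # Group-3 silencers sit in TssBiv/ReprPC context and link nearby
        # TSSs; their targets should hit TssBiv more often than distance-
        # matched controls in the placement biosample.
        ds = small_dataset
        b = ds.biosample_names[0]
        seg = decoded[b]
        g3 = set(ds.silencers.group(3)["silencer_id"])
        targets = sorted(
            {t for sid in g3 for t in ds.silencers.links.get(sid, [])}
        )
        all_tss = [g.tss[0] for g in ds.genes]
        controls, _ = distance_matched_tss_control(
            targets, all_tss, ds.silencers, seed=11
        )
        controls = [c for c in controls if c not in set(targets)]
        out = target_tss_state_enrichment(targets, controls, seg)
        assert out.loc["TssBiv", "target"] > out.loc["TssBiv", "control"]

    def test_overlapping_sets_rejected(self):
        seg = make_segmentation({"c": np.array([0])}, ["A"])
        with pytest.raises(ValueError):
            target_tss_state_enrichment([("c", 1)], [("c", 1)], seg)
        with pytest.raises(ValueError):
            target_tss_state_enrichment([("c", 1)], [], seg)


class TestPipelineRegionStatistics:
    def test_union_regions_enrich_silencers_on_synthetic_study(
        self, small_dataset, decoded
    ):
        ds = small_dataset
        regions = union_bivalent_regions(
            [extract_bivalent_regions(seg) for seg in decoded.values()]
        )
        assert len(regions) > 20
        res = bivalent_silencer_overlap_z(
            regions.assign(biosample="union"), ds.silencers, ds.genome,
            n_random=50, seed=21,
        )
        # groups 3/4 (dominant) sit in TssBiv/ReprPC context by construction
        assert res.observed > res.random_mean
        assert res.z > 5
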