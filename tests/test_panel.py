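"""Probe tiling, consensus masking, GC boosting and in-silico coverage."""

import numpy as np
import pytest

import methpanel as mp
from methpanel.intervals import GenomicInterval, MaskTrack
from methpanel.panel import (
    DEFAULT_BOOST_SCHEDULE,
    Probe,
    boost_probes,
    consensus_mask,
    filter_masked_probes,
    in_silico_coverage,
    panel_summary,
    tile_probes,
)

REF = {"chrT": "ACGT" * 300}  # 1200 bp, GC 0.5, no Ns


def probe_depth(probes, length):
    depth = np.zeros(length, dtype=int)
    for p in probes:
        depth[p.interval.start : p.interval.end] += 1
    return depth


class TestTiling:
    def test_region_equal_to_probe_gives_one_probe(self):
        probes = tile_probes(
            [GenomicInterval("chrT", 0, 120)], REF, probe_len=120, tiling_density=1
        )
        assert len(probes) == 1
        assert (probes[0].interval.start, probes[0].interval.end) == (0, 120)

    def test_density3_steps_40_and_covers_every_base(self):
        probes = tile_probes(
            [GenomicInterval("chrT", 0, 200)], REF, probe_len=120, tiling_density=3
        )
        assert [p.interval.start for p in probes] == [0, 40, 80]
        assert (probe_depth(probes, 200)[:200] > 0).all()

    def test_short_region_gets_one_centered_flanked_probe(self):
        probes = tile_probes(
            [GenomicInterval("chrT", 500, 560)], REF, probe_len=120, tiling_density=3
        )
        assert len(probes) == 1
        iv = probes[0].interval
        assert iv.length == 120
        assert iv.start <= 500 and iv.end >= 560

    def test_probes_with_ambiguous_bases_dropped(self):
        ref = {"chrT": "ACGT" * 50 + "N" * 10 + "ACGT" * 50}
        probes = tile_probes(
            [GenomicInterval("chrT", 0, 410)], ref, probe_len=120, tiling_density=3
        )
        for p in probes:
            assert "N" not in ref["chrT"][p.interval.start : p.interval.end]

    def test_out_of_bounds_target_raises_naming_interval(self):
        with pytest.raises(ValueError, match="chrT:900-2000"):
            tile_probes([GenomicInterval("chrT", 900, 2000)], REF)
        with pytest.raises(ValueError):
            tile_probes([GenomicInterval("chrT", 0, 200)], REF, tiling_density=0)

    def test_tiling_matches_brute_force_enumeration(self, rng):
        """Oracle: per-base depth equals brute-force enumeration; mean ~ k."""
        for _ in range(30):
            L = int(rng.integers(60, 121))
            k = int(rng.integers(1, 6))
            start = int(rng.integers(0, 200))
            length = int(rng.integers(L, 900))
            region = GenomicInterval("chrT", start, start + length)
            probes = tile_probes([region], REF, probe_len=L, tiling_density=k)
            step = max(1, round(L / k))
            # independent brute-force placement
            if length >= L:
                starts = list(range(start, start + length - L + 1, step))
                if starts[-1] != start + length - L:
                    starts.append(start + length - L)
                assert sorted(p.interval.start for p in probes) == sorted(starts)
            depth = probe_depth(probes, 1200)
            assert (depth[start : start + length] > 0).all()
            if length >= 10 * L:
                mean = depth[start : start + length].mean()
                assert k - 0.5 <= mean <= k + 0.5


class TestConsensusMask:
    TRACKS = [
        MaskTrack("a", [GenomicInterval("c", 0, 100)]),
        MaskTrack("b", [GenomicInterval("c", 50, 150)]),
        MaskTrack("d", [GenomicInterval("c", 60, 80)]),
    ]

    def test_least_stringent_is_intersection(self):
        out = consensus_mask(self.TRACKS, "least_stringent")
        assert [(iv.start, iv.end) for iv in out.intervals] == [(60, 80)]

    def test_most_stringent_is_union(self):
        out = consensus_mask(self.TRACKS, "most_stringent")
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 150)]

    def test_single_track_identity_and_empty_error(self):
        single = consensus_mask([self.TRACKS[0]], "least_stringent")
        assert single.intervals == self.TRACKS[0].intervals
        assert (
            consensus_mask([self.TRACKS[0]], "most_stringent").intervals
            == self.TRACKS[0].intervals
        )
        with pytest.raises(ValueError):
            consensus_mask([], "least_stringent")

    def test_subset_superset_invariants(self):
        least = consensus_mask(self.TRACKS, "least_stringent")
        most = consensus_mask(self.TRACKS, "most_stringent")
        for track in self.TRACKS:
            assert track.contains(least)
            assert most.contains(track)


def _probe(start, end, gc=0.5):
    return Probe(
        id=f"p{start}", interval=GenomicInterval("c", start, end), gc_fraction=gc
    )


class TestMaskFilter:
    MASK = MaskTrack("m", [GenomicInterval("c", 100, 200)])

    def test_fully_masked_probe_removed(self):
        assert filter_masked_probes([_probe(110, 230)], self.MASK, 0.5) == []

    def test_unmasked_probe_retained_with_zero(self):
        kept = filter_masked_probes([_probe(300, 420)], self.MASK, 0.0)
        assert len(kept) == 1 and kept[0].masked_bases == 0

    def test_threshold_is_strict_greater(self):
        # 30 of 120 masked = 0.25 exactly: retained
        kept = filter_masked_probes([_probe(170, 290)], self.MASK, 0.25)
        assert len(kept) == 1 and kept[0].masked_bases == 30
        assert filter_masked_probes([_probe(169, 289)], self.MASK, 0.25) == []


class TestBoost:
    def test_default_schedule_examples(self):
        probes = boost_probes([_probe(0, 120, gc=0.40), _probe(0, 120, gc=1.0)])
        assert probes[0].copy_number == 1
        assert probes[1].copy_number == 16

    def test_monotone_in_gc_and_capped(self, rng):
        gcs = rng.random(200)
        probes = boost_probes([_probe(0, 120, gc=g) for g in gcs])
        copies = np.array([p.copy_number for p in probes])
        order = np.argsort(gcs)
        assert (np.diff(copies[order]) >= 0).all()
        assert copies.max() <= 16 and copies.min() >= 1

    def test_non_monotone_schedule_rejected(self):
        with pytest.raises(ValueError):
            boost_probes([_probe(0, 120)], schedule=[(0.5, 4), (0.7, 2)])


class TestCoverageAndSummary:
    def test_exact_tiling_gives_full_coverage(self):
        target = GenomicInterval("chrT", 0, 240)
        probes = [_probe2(0, 120), _probe2(120, 240)]
        design = mp.PanelDesign(probes=probes, target_groups={"t": [target]})
        assert in_silico_coverage(design)["overall"] == 1.0

    def test_no_probes_is_zero(self):
        design = mp.PanelDesign(
            probes=[], target_groups={"t": [GenomicInterval("chrT", 0, 1000)]}
        )
        assert in_silico_coverage(design)["t"] == 0.0

    def test_single_probe_on_1kb_target(self):
        design = mp.PanelDesign(
            probes=[_probe2(100, 220)],
            target_groups={"t": [GenomicInterval("chrT", 0, 1000)]},
        )
        assert in_silico_coverage(design)["t"] == pytest.approx(0.12)

    def test_coverage_invariant_under_boosting(self):
        design = mp.PanelDesign(
            probes=[_probe2(0, 120), _probe2(40, 160)],
            target_groups={"t": [GenomicInterval("chrT", 0, 500)]},
        )
        before = in_silico_coverage(design)
        for p in design.probes:
            p.copy_number = 16
        assert in_silico_coverage(design) == before

    def test_summary_footprint_dedup(self):
        disjoint = [_probe2(0, 120), _probe2(200, 320), _probe2(400, 520)]
        design = mp.PanelDesign(
            probes=disjoint, target_groups={"t": [GenomicInterval("chrT", 0, 600)]}
        )
        total = panel_summary(design).set_index("group").loc["total"]
        assert total["capture_kb"] == pytest.approx(0.36)
        overlapping = [_probe2(0, 120), _probe2(40, 160)]
        design2 = mp.PanelDesign(
            probes=overlapping, target_groups={"t": [GenomicInterval("chrT", 0, 600)]}
        )
        total2 = panel_summary(design2).set_index("group").loc["total"]
        assert total2["capture_kb"] == pytest.approx(0.16)
        assert total2["n_probes"] == 2

    def test_empty_design_summary_all_zero(self):
        design = mp.PanelDesign(probes=[], target_groups={})
        total = panel_summary(design).set_index("group").loc["total"]
        assert total["n_probes"] == 0 and total["capture_kb"] == 0.0


def _probe2(start, end, gc=0.5):
    return Probe(
        id=f"q{start}", interval=GenomicInterval("chrT", start, end), gc_fraction=gc
    )
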