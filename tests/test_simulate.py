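"""Simulator contracts: composition targets, determinism, truth conservation."""

import numpy as np
import pytest

import methpanel as mp
from methpanel.simulate import ConversionModel


class TestReference:
    def test_gc_and_cpg_targets_hit(self, toy_reference):
        seq = toy_reference["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.43 <= gc <= 0.47
        cpg = seq.count("CG") / (len(seq) - 1)
        assert 0.8 * 0.02 <= cpg <= 1.2 * 0.02

    def test_same_seed_is_byte_identical(self):
        a = mp.simulate_reference(length=5_000, seed=7)
        b = mp.simulate_reference(length=5_000, seed=7)
        assert a.sequences == b.sequences

    def test_no_repeat_spec_gives_empty_track(self):
        ref = mp.simulate_reference(length=2_000, seed=1)
        assert ref.repeats.intervals == []

    def test_planted_repeats_recorded_and_present(self, toy_reference):
        assert len(toy_reference.repeats.intervals) == 4
        for iv in toy_reference.repeats.intervals:
            assert iv.end <= len(toy_reference["chr1"])

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            mp.simulate_reference(length=5_000, gc_target=0.3, cpg_rate=0.2)
        with pytest.raises(ValueError):
            mp.simulate_reference(length=500)


class TestDiploid:
    def test_zero_rate_gives_identical_haplotypes(self):
        ref = mp.simulate_reference(length=5_000, seed=3)
        truth = mp.simulate_diploid(ref, snv_rate=0.0, seed=4)
        assert truth.haplotypes["chr1"] == (ref["chr1"], ref["chr1"])
        assert truth.variants == []

    def test_variant_count_poisson_consistent(self):
        ref = mp.simulate_reference(length=100_000, seed=5)
        truth = mp.simulate_diploid(ref, snv_rate=1e-3, seed=6)
        n = len(truth.variants)
        assert abs(n - 100) <= 3 * np.sqrt(100)

    def test_het_fraction_one_makes_all_het(self):
        ref = mp.simulate_reference(length=20_000, seed=7)
        truth = mp.simulate_diploid(ref, snv_rate=1e-3, het_fraction=1.0, seed=8)
        assert truth.variants and all(v.genotype == "het" for v in truth.variants)

    def test_haplotypes_differ_exactly_at_variants(self, toy_truth):
        ref = toy_truth.reference["chr1"]
        h0, h1 = toy_truth.haplotypes["chr1"]
        diff = {i for i in range(len(ref)) if h0[i] != ref[i] or h1[i] != ref[i]}
        assert diff == {v.pos for v in toy_truth.variants}
        for v in toy_truth.variants:
            hap = (h0, h1)
            if v.genotype == "hom_alt":
                assert h0[v.pos] == h1[v.pos] == v.alt
            else:
                assert hap[v.haplotype][v.pos] == v.alt
                assert hap[1 - v.haplotype][v.pos] == v.ref


class TestMethylationTruth:
    def test_empty_dmr_spec_gives_identical_conditions(self):
        ref = mp.simulate_reference(length=10_000, seed=9)
        truth = mp.simulate_diploid(ref, snv_rate=0, seed=9)
        truth = mp.assign_methylation(truth, seed=9)
        np.testing.assert_array_equal(
            truth.beta["A"]["chr1"], truth.beta["B"]["chr1"]
        )

    def test_delta_shifts_condition_b(self):
        ref = mp.simulate_reference(length=10_000, seed=10)
        truth = mp.simulate_diploid(ref, snv_rate=0, seed=10)
        iv = mp.GenomicInterval("chr1", 2_000, 4_000)
        truth = mp.assign_methylation(
            truth, dmr_spec=[(iv, 0.3)], dmr_baseline_shape=None, seed=10
        )
        pos = truth.cpg_positions["chr1"]
        inside = (pos >= 2_000) & (pos < 4_000)
        a, b = truth.beta["A"]["chr1"], truth.beta["B"]["chr1"]
        np.testing.assert_allclose(
            b[inside], np.clip(a[inside] + 0.3, 0, 1), atol=1e-12
        )
        np.testing.assert_array_equal(b[~inside], a[~inside])

    def test_pure_high_component_is_hypermethylated(self):
        ref = mp.simulate_reference(length=50_000, seed=11)
        truth = mp.simulate_diploid(ref, snv_rate=0, seed=11)
        truth = mp.assign_methylation(
            truth, mix_weight=1.0, high_shape=(10.0, 0.5), seed=11
        )
        assert truth.beta["A"]["chr1"].mean() > 0.9

    def test_cpg_free_interval_warns(self):
        ref = mp.simulate_reference(length=10_000, seed=12)
        truth = mp.simulate_diploid(ref, snv_rate=0, seed=12)
        seq = ref["chr1"]
        # find a CpG-free stretch
        start = next(
            i for i in range(0, 9_000) if "CG" not in seq[i : i + 40]
        )
        with pytest.warns(UserWarning, match="no CpGs"):
            mp.assign_methylation(
                truth,
                dmr_spec=[(mp.GenomicInterval("chr1", start, start + 39), 0.2)],
                seed=12,
            )


class TestCaptureReads:
    def test_determinism(self, toy_truth, toy_panel):
        a = mp.simulate_capture_reads(toy_truth, toy_panel, 2_000, seed=42)
        b = mp.simulate_capture_reads(toy_truth, toy_panel, 2_000, seed=42)
        assert a == b

    def test_unconverted_errorfree_reads_match_haplotype(self, toy_truth, toy_panel):
        obs = mp.simulate_capture_reads(
            toy_truth, toy_panel, 3_000, conversion=ConversionModel.none(),
            seq_error=0.0, seed=13,
        )
        assert obs
        for o in obs[:200]:
            hap = toy_truth.haplotypes[o.chrom][o.haplotype]
            assert o.bases == hap[o.start : o.end]

    def test_complete_conversion_removes_all_cs_on_ot(self, toy_reference, toy_panel):
        truth = mp.simulate_diploid(toy_reference, snv_rate=0.0, seed=14)
        truth = mp.assign_methylation(
            truth, mix_weight=0.0, low_shape=(1e-3, 1e3), seed=14
        )  # beta ~ 0 everywhere
        obs = mp.simulate_capture_reads(
            truth, toy_panel, 2_000,
            conversion=ConversionModel("BS", failure_rate=0.0), seq_error=0.0,
            seed=14,
        )
        for o in obs[:300]:
            if o.strand == "OT":
                assert "C" not in o.bases
            else:
                assert "G" not in o.bases

    def test_insert_length_distribution(self, toy_truth, toy_panel):
        # off_target_rate=1 makes retention length-independent so the
        # sampled insert distribution itself is measured
        obs = mp.simulate_capture_reads(
            toy_truth, toy_panel, 10_000, insert_mean=250, insert_sd=30,
            off_target_rate=1.0, capture_coefficient=100.0, seed=15,
        )
        lengths = {}
        for o in obs:
            lo, hi = lengths.get(o.fragment_id, (o.start, o.end))
            lengths[o.fragment_id] = (min(lo, o.start), max(hi, o.end))
        sizes = np.array([hi - lo for lo, hi in lengths.values()])
        assert abs(sizes.mean() - 250) < 1.0

    def test_capture_enrichment_on_footprint(self, toy_truth, toy_panel, dna_obs):
        depth = mp.depth_track(dna_obs, toy_truth.reference)["chr1"]
        mask = np.zeros(len(depth), dtype=bool)
        for iv in toy_panel.footprint():
            mask[iv.start : iv.end] = True
        assert depth[mask].mean() / max(depth[~mask].mean(), 1e-9) >= 10

    def test_truth_betas_recoverable_at_depth(self, toy_truth, toy_panel):
        """Binomial convergence: deep coverage recovers per-CpG truth."""
        obs = mp.simulate_capture_reads(
            toy_truth, toy_panel, 120_000,
            conversion=ConversionModel("BS", 0.0, 0.0), seq_error=0.0,
            condition="A", seed=16,
        )
        table = mp.quantify(obs, toy_truth.reference, min_cov=200)
        pos = toy_truth.cpg_positions["chr1"]
        beta = dict(zip(pos.tolist(), toy_truth.beta["A"]["chr1"]))
        rec = table.records
        # a C/T variant inside a CpG legitimately shifts the apparent beta;
        # the binomial recovery bound applies away from planted variants
        var_pos = {v.pos for v in toy_truth.variants}
        rec = rec[
            ~rec["pos"].isin(var_pos) & ~(rec["pos"] + 1).isin(var_pos)
        ]
        assert len(rec) > 50
        resid = rec["beta"].to_numpy() - np.array(
            [beta[p] for p in rec["pos"]]
        )
        depth = (rec["meth"] + rec["unmeth"]).to_numpy()
        bound = np.sqrt(np.mean(rec["beta"] * (1 - rec["beta"]) / depth))
        assert np.sqrt(np.mean(resid**2)) <= 1.5 * bound

    def test_zero_retention_raises(self, toy_truth):
        empty_panel = mp.PanelDesign(
            probes=[
                mp.Probe(
                    id="p",
                    interval=mp.GenomicInterval("chr1", 0, 120),
                    gc_fraction=0.5,
                )
            ],
            target_groups={},
        )
        with pytest.raises(RuntimeError, match="n_fragments"):
            mp.simulate_capture_reads(
                toy_truth, empty_panel, 1, off_target_rate=0.0,
                capture_coefficient=0.0, seed=1,
            )
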