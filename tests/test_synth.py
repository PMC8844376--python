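"""Synthetic cohort generator: determinism, realized frequencies, truth
bookkeeping, and end-to-end consistency of emitted files."""

import json

import numpy as np
import pytest

from mmindel.io_formats import Panel, read_annotations, read_genetic_map, \
    read_fasta, read_phased_vcf
from mmindel.synth import (
    ScenarioSpec, SynthesisError, _sample_codes, generate_dataset,
)
from conftest import tiny_spec


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        spec = tiny_spec(n_snp=30, n_biallelic_indel=20, n_ma_qualifying=5,
                         n_cluster_pair=3)
        a = generate_dataset(spec, tmp_path / "a", seed=123)
        b = generate_dataset(spec, tmp_path / "b", seed=123)
        for attr in ("reference_fa", "vcf", "panel_tsv", "genetic_map",
                     "repeats_bed", "genes_gff"):
            assert getattr(a, attr).read_bytes() == \
                getattr(b, attr).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        spec = tiny_spec(n_snp=30)
        a = generate_dataset(spec, tmp_path / "a", seed=1)
        b = generate_dataset(spec, tmp_path / "b", seed=2)
        assert a.vcf.read_bytes() != b.vcf.read_bytes()


class TestReference:
    def test_gc_tracks_block_levels(self, tmp_path):
        spec = tiny_spec(chrom_lengths={"chr1": 600_000},
                         gc_block_len=200_000, gc_levels=(0.3, 0.7))
        ds = generate_dataset(spec, tmp_path, seed=5)
        seq = read_fasta(ds.reference_fa)["chr1"]
        for start, level in ((0, 0.3), (200_000, 0.7), (400_000, 0.3)):
            block = seq[start:start + 200_000]
            gc = (block.count("G") + block.count("C")) / len(block)
            se = (level * (1 - level) / len(block)) ** 0.5
            assert abs(gc - level) < 3 * se

    def test_n_blocks_masked(self, tmp_path):
        spec = tiny_spec(n_blocks=(("chr1", 100_000, 110_000),))
        ds = generate_dataset(spec, tmp_path, seed=5)
        seq = read_fasta(ds.reference_fa)["chr1"]
        assert set(seq[100_000:110_000]) == {"N"}


class TestSampling:
    def test_realized_frequencies_converge_with_n(self):
        target = np.array([0.7, 0.2, 0.1])
        for n_dip, tol_factor in ((50, 3.0), (500, 3.0)):
            rng = np.random.default_rng(77)
            sizes = {p: n_dip for p in
                     ("AFR", "AMR", "EUR", "EAS", "SAS")}
            codes = _sample_codes(rng, sizes,
                                  {p: target for p in sizes})
            n_h = 2 * 5 * n_dip
            freq = np.bincount(codes.ravel(), minlength=3) / n_h
            for f, t in zip(freq, target):
                se = (t * (1 - t) / n_h) ** 0.5
                assert abs(f - t) < tol_factor * se

    def test_infeasible_frequencies_rejected(self, tmp_path):
        from mmindel.synth import _check_targets
        with pytest.raises(SynthesisError):
            _check_targets(np.array([0.8, 0.3]))
        with pytest.raises(SynthesisError):
            _check_targets(np.array([1.1, -0.1]))


@pytest.fixture(scope="module")
def small(tmp_path_factory):
    spec = tiny_spec(n_snp=40, n_biallelic_indel=30, n_ma_qualifying=8,
                     n_ma_lowfreq=4, n_cluster_pair=6,
                     n_cluster_linked=2, n_repeats=10, n_genes=3)
    out = tmp_path_factory.mktemp("small")
    return spec, generate_dataset(spec, out, seed=9)


class TestManifestConsistency:
    def test_manifest_round_trips_to_disk(self, small):
        _, ds = small
        on_disk = json.loads(ds.manifest_json.read_text())
        assert on_disk["seed"] == ds.manifest["seed"]
        assert len(on_disk["variants"]) == len(ds.manifest["variants"])

    def test_realized_frequencies_recounted_from_vcf(self, small):
        """Re-parsing the emitted VCF reproduces the manifest's realized
        haplotype frequencies exactly."""
        _, ds = small
        panel = Panel.read(ds.panel_tsv)
        ref = read_fasta(ds.reference_fa)
        sites = {(s.chrom, s.pos): s
                 for s in read_phased_vcf(ds.vcf, panel, reference=ref)}
        n_checked = 0
        for v in ds.manifest["variants"]:
            if v["chrom"] == "chrX" or v["cluster_id"]:
                continue
            s = sites[(v["chrom"], v["pos"])]
            assert s.ref == v["ref"] and s.alts == v["alts"]
            gt = s.genotypes
            counts = np.bincount(gt[gt >= 0].ravel(),
                                 minlength=1 + len(v["alts"]))
            freq = counts / counts.sum()
            assert np.allclose(freq, v["realized_global_freq"], atol=1e-12)
            n_checked += 1
        assert n_checked >= 80

    def test_planted_cluster_gaps_match_positions(self, small):
        _, ds = small
        by_id = {v["id"]: v for v in ds.manifest["variants"]}
        for cl in ds.manifest["clusters"]:
            members = [by_id[m] for m in cl["member_ids"]]
            for up, down, gap in zip(members, members[1:], cl["gaps"]):
                end_up = up["pos"] + len(up["ref"]) - 1
                assert down["pos"] - end_up - 1 == gap

    def test_expected_verdicts_follow_thresholds(self, small):
        _, ds = small
        af_min = ds.manifest["af_min"]
        for v in ds.manifest["variants"]:
            if not v["type"].startswith("ma"):
                continue
            indel_idx = [i for i, k in enumerate(v["kinds"])
                         if k in ("INS", "DEL")]
            n_valid = int(v["realized_global_freq"][0] > af_min) + sum(
                v["realized_global_freq"][i + 1] > af_min for i in indel_idx)
            all_random = all(v["classes"][i] == "RANDOM" for i in indel_idx)
            expect = (len(indel_idx) >= 2 and all_random and v["flank_ok"]
                      and n_valid >= 3)
            assert v["expected_multiallelic"] == expect

    def test_map_and_annotations_parse_back(self, small):
        _, ds = small
        segs = read_genetic_map(ds.genetic_map)
        assert segs and all(s.rate >= 0 for s in segs)
        manifest_segs = ds.manifest["map_segments"]
        assert len(segs) == len(manifest_segs)
        assert segs[0].rate == pytest.approx(manifest_segs[0]["rate"])
        repeats = read_annotations(ds.repeats_bed)
        assert len(repeats) == len(ds.manifest["annotations"]["repeats"])
        genes = read_annotations(ds.genes_gff)
        n_feat = sum(1 + len(g["exons"]) + len(g["cds"])
                     for g in ds.manifest["annotations"]["genes"])
        assert len(genes) == n_feat

    def test_linked_clusters_never_expected(self, small):
        _, ds = small
        for cl in ds.manifest["clusters"]:
            if cl["type"] == "cluster_linked":
                assert cl["expected_multi_indels"] == []

    def test_bin_counts_conserve_markers(self, small):
        _, ds = small
        total_mm = sum(sum(c["mm"]) for c in ds.manifest["bin_counts"].values())
        assert total_mm == (len(ds.manifest["expected_multiallelic"])
                            + len(ds.manifest["expected_multi_indels"]))
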