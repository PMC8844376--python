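import numpy as np
import pytest

from mmindel.io_formats import IndelSite, Panel, SampleInfo, POPULATIONS
from mmindel.pipeline import PipelineConfig, run_all
from mmindel.synth import ScenarioSpec, desk_preset, generate_dataset

DESK_SEED = 7


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """The default desk-scale synthetic cohort (generated once per session)."""
    outdir = tmp_path_factory.mktemp("desk")
    return generate_dataset(desk_preset(), outdir, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_result(desk_dataset):
    """Full pipeline run over the desk cohort."""
    cfg = PipelineConfig(
        vcf=str(desk_dataset.vcf),
        panel=str(desk_dataset.panel_tsv),
        reference=str(desk_dataset.reference_fa),
        genetic_map=str(desk_dataset.genetic_map),
        repeats_bed=str(desk_dataset.repeats_bed),
        genes_gff=str(desk_dataset.genes_gff),
        outdir=str(desk_dataset.outdir / "pipeline_out"),
    )
    return run_all(cfg, write=True), cfg


def tiny_spec(**overrides) -> ScenarioSpec:
    """A minimal scenario for fast targeted tests: everything zeroed unless
    overridden."""
    base = dict(
        chrom_lengths={"chr1": 400_000}, chrx_length=0,
        n_blocks=(), n_snp=0, n_biallelic_indel=0, n_expansion_indel=0,
        n_ma_qualifying=0, n_ma_lowfreq=0, n_ma_expansion_allele=0,
        n_ma_flank_repeat=0, n_ma_with_snp_alt=0, n_ma_pop_specific=0,
        n_cluster_pair=0, n_cluster_triple=0, n_cluster_four_combo=0,
        n_cluster_linked=0, n_cluster_wide=0, n_cluster_ma_member=0,
        n_chrx_records=0, n_repeats=0, n_genes=0,
        map_segment_len=100_000,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


@pytest.fixture
def four_sample_panel():
    return Panel([SampleInfo("S1", "AFR"), SampleInfo("S2", "AMR"),
                  SampleInfo("S3", "EUR"), SampleInfo("S4", "EAS")])


@pytest.fixture
def five_pop_panel():
    samples = [SampleInfo(f"{p}{i}", p) for p in POPULATIONS for i in range(4)]
    return Panel(samples)


def make_site(chrom="chr1", pos=100, ref="A", alts=("AT",), gt=None,
              n_samples=4):
    """Hand-built IndelSite; ``gt`` is a flat list of 2*n_samples codes."""
    if gt is None:
        gt = [0] * (2 * n_samples)
    g = np.asarray(gt, dtype=np.int16).reshape(n_samples, 2)
    return IndelSite(chrom, pos, ref, list(alts), g)
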