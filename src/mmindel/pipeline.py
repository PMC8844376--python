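"""End-to-end pipeline: configuration, stage drivers, and table emission.

Every stage is a thin orchestration over the analysis modules; the numbered
scripts under ``analysis/`` and the CLI subcommands both call in here.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann_mod
from . import genome_scan as gs
from . import mai_filter as mai
from . import multi_indel as mind
from . import popgen
from .io_formats import (
    Panel, VariantKind, read_annotations, read_fasta, read_genetic_map,
    read_phased_vcf, FeatureKind,
)
from .seq_class import ClassParams, site_is_random_context


@dataclass
class PipelineConfig:
    """All thresholds of the marker filter and scan, plus input paths."""

    vcf: str = ""
    panel: str = ""
    reference: str = ""
    genetic_map: str = ""
    repeats_bed: str = ""
    genes_gff: str = ""
    outdir: str = "results"
    seed: int = 0

    af_min: float = 0.01
    min_valid_alleles: int = 3
    max_gap: int = 20
    cluster_mode: str = "consecutive_gap"
    flank_len: int = 12
    min_unit: int = 1
    max_unit: int = 15
    flank_homopolymer_max: int = 5
    flank_array_min_len: int = 8
    flank_array_min_copies: int = 2
    bin_width: int = 100_000
    mdv_cutoff: float = 25.0
    empty_bin_denominator: str = "all"

    def __post_init__(self) -> None:
        for name in ("af_min", "min_valid_alleles", "max_gap", "flank_len",
                     "min_unit", "max_unit", "bin_width", "mdv_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")

    def class_params(self) -> ClassParams:
        return ClassParams(
            min_unit=self.min_unit, max_unit=self.max_unit,
            flank_len=self.flank_len,
            flank_homopolymer_max=self.flank_homopolymer_max,
            flank_array_min_len=self.flank_array_min_len,
            flank_array_min_copies=self.flank_array_min_copies)

    def filter_params(self) -> mai.FilterParams:
        return mai.FilterParams(af_min=self.af_min,
                                min_valid_alleles=self.min_valid_alleles)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _freq_str(values) -> str:
    return ",".join(f"{v:.6g}" for v in values)


@dataclass
class PipelineResult:
    sites: list
    ma_markers: list
    mi_markers: list
    clusters: list
    hist: mind.DistanceHistogram
    mdv: dict
    gap_threshold: int
    bins: list
    correlations: list
    annotations_ma: list
    annotations_mi: list
    presences_ma: list
    presences_mi: list
    summary: dict


def run_all(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis and (optionally) write all output tables."""
    t0 = time.time()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "effective_config.yaml")

    panel = Panel.read(config.panel)
    reference = read_fasta(config.reference)
    sites = list(read_phased_vcf(config.vcf, panel, reference=reference))
    cparams = config.class_params()
    fparams = config.filter_params()

    # criterion cascade: multi-allelic markers
    funnel_ma: dict = {}
    ma_markers = mai.filter_multi_allelic(
        sites, reference, panel, fparams, cparams, funnel=funnel_ma)

    # random-context indel stream for adjacency/clustering
    random_indels = [
        s for s in sites
        if s.n_indel_alts >= 1 and site_is_random_context(s, reference, cparams)
    ]
    hist = mind.adjacent_distance_histogram(random_indels)
    mdv = mind.mean_difference_series(hist, s_max=max(100, config.max_gap * 3))
    gap_thr = mind.suggest_gap_threshold(mdv, cutoff=config.mdv_cutoff)

    clusters = mind.cluster_indels(random_indels, max_gap=config.max_gap,
                                   mode=config.cluster_mode)
    funnel_mi: dict = {}
    mi_markers = mind.filter_multi_indels(clusters, panel, fparams,
                                          funnel=funnel_mi)

    # genome scan
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    bins = gs.make_bins(chrom_lengths, width=config.bin_width)
    snp_sites = [s for s in sites
                 if all(k == VariantKind.SNP for k in s.kinds)]
    indel_sites = [s for s in sites if s.n_indel_alts >= 1]
    mm_positions = ([(m.site.chrom, m.site.pos) for m in ma_markers]
                    + [(m.chrom, m.pos) for m in mi_markers])
    gs.assign_counts(mm_positions, bins, "n_mm", config.bin_width)
    gs.assign_counts([(s.chrom, s.pos) for s in snp_sites], bins, "n_snp",
                     config.bin_width)
    gs.assign_counts([(s.chrom, s.pos) for s in indel_sites], bins, "n_indel",
                     config.bin_width)
    map_segments = (read_genetic_map(config.genetic_map)
                    if config.genetic_map else None)
    gs.annotate_bins(bins, reference=reference, map_segments=map_segments)
    correlations = []
    for factor in gs.Factor:
        try:
            correlations.append(gs.correlate(bins, factor))
        except ValueError:
            pass

    # genomic context
    annotations_ma: list = []
    annotations_mi: list = []
    if config.repeats_bed or config.genes_gff:
        repeats = (read_annotations(config.repeats_bed)
                   if config.repeats_bed else [])
        genes = (read_annotations(config.genes_gff)
                 if config.genes_gff else [])
        index = ann_mod.AnnotationIndex(repeats, genes)
        annotations_ma = [ann_mod.annotate_marker(m, index) for m in ma_markers]
        annotations_mi = [ann_mod.annotate_marker(m, index) for m in mi_markers]

    # populations
    presences_ma = [popgen.population_presence(m, fparams) for m in ma_markers]
    presences_mi = [popgen.population_presence(m, fparams) for m in mi_markers]

    summary = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "runtime_s": round(time.time() - t0, 2),
        "n_sites": len(sites),
        "funnel_multiallelic": funnel_ma,
        "funnel_multi_indel": funnel_mi,
        "n_multiallelic_markers": len(ma_markers),
        "n_multi_indel_markers": len(mi_markers),
        "n_random_indel_sites": len(random_indels),
        "suggested_gap_threshold": gap_thr,
        "allele_count_histogram_ma": mai.allele_count_histogram(ma_markers),
        "allele_count_histogram_mi": mai.allele_count_histogram(mi_markers),
        "fraction_empty_bins": gs.fraction_empty(
            bins, config.empty_bin_denominator),
        "correlations": {c.factor.value: {"r": c.r, "p": c.p, "n": c.n_bins}
                         for c in correlations},
        "popgen_ma": popgen.presence_summary(presences_ma),
        "popgen_mi": popgen.presence_summary(presences_mi),
    }

    result = PipelineResult(sites, ma_markers, mi_markers, clusters, hist,
                            mdv, gap_thr, bins, correlations, annotations_ma,
                            annotations_mi, presences_ma, presences_mi,
                            summary)
    if write:
        write_outputs(result, config, outdir)
    return result


def write_outputs(res: PipelineResult, config: PipelineConfig,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ann_ma = {a.marker_id: a for a in res.annotations_ma}
    ann_mi = {a.marker_id: a for a in res.annotations_mi}

    rows = []
    for m in res.ma_markers:
        s, spec = m.site, m.spectrum
        a = ann_ma.get(m.marker_id)
        rows.append({
            "marker_id": m.marker_id, "chrom": s.chrom, "start": s.pos,
            "end": s.ref_end, "type": "multi_allelic",
            "n_alleles": m.n_valid_alleles,
            "allele_seqs": ",".join(spec.alleles),
            "global_freqs": _freq_str(spec.global_freq),
            "pop_freqs": ";".join(
                f"{p}:{_freq_str(spec.pop_freq[p])}" for p in spec.pop_freq),
            "annotation_class": (f"{a.repeat_class.value}|{a.gene_context.value}"
                                 if a else ""),
            "max_allele_len": m.max_allele_len,
        })
    pd.DataFrame(rows).to_csv(outdir / "multiallelic_markers.tsv",
                              sep="\t", index=False)

    rows = []
    for m in res.mi_markers:
        spec = m.spectrum
        a = ann_mi.get(m.marker_id)
        rows.append({
            "marker_id": m.marker_id, "chrom": m.chrom,
            "start": m.pos, "end": m.member_sites[-1].ref_end,
            "type": "multi_indel", "n_members": len(m.member_sites),
            "member_pos": ",".join(str(s.pos) for s in m.member_sites),
            "gaps": ",".join(map(str, m.gaps)), "span": m.span,
            "n_alleles": m.n_valid_alleles,
            "allele_seqs": ",".join(spec.alleles),
            "global_freqs": _freq_str(spec.global_freq),
            "pop_freqs": ";".join(
                f"{p}:{_freq_str(spec.pop_freq[p])}" for p in spec.pop_freq),
            "annotation_class": (f"{a.repeat_class.value}|{a.gene_context.value}"
                                 if a else ""),
        })
    pd.DataFrame(rows).to_csv(outdir / "multi_indel_markers.tsv",
                              sep="\t", index=False)

    pd.DataFrame(
        sorted(res.hist.counts.items()),
        columns=["distance_bp", "n_pairs"],
    ).to_csv(outdir / "adjacent_distance_hist.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(res.mdv.items()), columns=["distance_bp", "mdv"],
    ).to_csv(outdir / "mdv_series.tsv", sep="\t", index=False)

    gs.bins_to_frame(res.bins).to_csv(outdir / "genome_bins.tsv",
                                      sep="\t", index=False)
    gs.density_group_summary(res.bins).to_csv(
        outdir / "density_group_summary.tsv", sep="\t", index=False)
    with open(outdir / "correlations.json", "w") as fh:
        json.dump(res.summary["correlations"], fh, indent=1)

    for label, markers, presences in (
            ("multiallelic", res.ma_markers, res.presences_ma),
            ("multi_indel", res.mi_markers, res.presences_mi)):
        popgen.rank_frequency_by_population(markers).to_csv(
            outdir / f"rank_freq_by_pop_{label}.tsv", sep="\t", index=False)
        cells = popgen.intersection_counts(presences)
        with open(outdir / f"venn_cells_{label}.json", "w") as fh:
            json.dump(popgen.venn_cells_json(cells), fh, indent=1)
        pd.DataFrame([{
            "marker_id": p.marker_id,
            "present_in": "+".join(sorted(p.present_in)),
            "category": p.category.value if p.category else "",
            "specific_alleles": ";".join(
                f"{a}:{pop}" for a, pop in p.specific_alleles.items()),
        } for p in presences]).to_csv(
            outdir / f"population_presence_{label}.tsv", sep="\t", index=False)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=1, default=_default)
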