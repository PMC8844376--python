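#!/usr/bin/env python
"""Genomic-context summary: how many markers fall inside repeat elements
(SINE/LINE/LTR/other) and inside genes (CDS / non-coding exon / intron)."""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd


def summarize(table: Path, label: str) -> None:
    df = pd.read_csv(table, sep="\t")
    ann = df["annotation_class"].fillna("")
    rep = Counter(a.split("|")[0] for a in ann if a)
    gene = Counter(a.split("|")[1] for a in ann if a)
    n = len(df)
    in_rep = sum(v for k, v in rep.items() if k != "NONE")
    in_gene = sum(v for k, v in gene.items() if k != "INTERGENIC")
    print(f"{label}: {n} markers")
    print(f"  in repeat elements: {in_rep} ({in_rep / n:.1%})  {dict(rep)}")
    print(f"  in genes:           {in_gene} ({in_gene / n:.1%})  "
          f"{dict(gene)}")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipedir", default="results/pipeline")
    args = ap.parse_args()
    pipedir = Path(args.pipedir)
    summarize(pipedir / "multiallelic_markers.tsv", "multi-allelic InDels")
    summarize(pipedir / "multi_indel_markers.tsv", "multi-InDels")


if __name__ == "__main__":
    main()
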