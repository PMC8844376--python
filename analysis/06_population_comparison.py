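#!/usr/bin/env python
"""Cross-population comparison: per-rank allele frequencies by
superpopulation, five-way presence (Venn cells), entire-allele versus
loss/birth shares, and population-specific alleles."""

import argparse
import json
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipedir", default="results/pipeline")
    args = ap.parse_args()
    pipedir = Path(args.pipedir)

    for label in ("multiallelic", "multi_indel"):
        print(f"== {label} markers ==")
        ranks = pd.read_csv(pipedir / f"rank_freq_by_pop_{label}.tsv",
                            sep="\t")
        cols = ["rank", "AFR", "AMR", "EUR", "EAS", "SAS"]
        print(ranks[cols].round(3).to_string(index=False))

        cells = json.loads(
            (pipedir / f"venn_cells_{label}.json").read_text())
        shared = cells.get("AFR+AMR+EAS+EUR+SAS", 0)
        total = sum(cells.values())
        print(f"present in >=1 population: {total}; in all five: {shared}")
        top = sorted(((v, k) for k, v in cells.items() if v), reverse=True)
        print("largest cells:", [f"{k}={v}" for v, k in top[:4]])

        pres = pd.read_csv(pipedir / f"population_presence_{label}.tsv",
                           sep="\t")
        cat = pres["category"].fillna("")
        entire = (cat == "ENTIRE_ALLELES").sum()
        loss = (cat == "LOSS_OR_BIRTH").sum()
        if entire + loss:
            print(f"entire alleles in all five populations: {entire} "
                  f"({entire / (entire + loss):.1%} of shared); "
                  f"loss/birth: {loss}")
        spec = pres["specific_alleles"].fillna("")
        n_spec = (spec != "").sum()
        afr = spec.str.contains("AFR").sum()
        print(f"markers with a single-population-specific allele: {n_spec} "
              f"({n_spec / len(pres):.1%} of markers; {afr} AFR-specific)")
        print()


if __name__ == "__main__":
    main()
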