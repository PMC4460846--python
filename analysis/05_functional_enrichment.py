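#!/usr/bin/env python
"""Functional annotation clustering of differentially expressed genes.

For each direction of the FC30' and RT30' call sets (fdr<0.1), tests every
annotation term for EASE enrichment against the array universe, groups
redundant enriched terms by Cohen's kappa agreement, and scores each fuzzy
cluster as -log10 of the geometric mean of its member term p-values
(enriched if >= 1.3).

Reads results/{data,de}/, writes results/enrichment/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from uvdex import call_de, read_gmt, read_matrix
from uvdex.enrich import cluster_enrichment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--fdr", type=float, default=0.1)
    args = ap.parse_args()

    collection = read_gmt(args.datadir / "annotation.gmt")
    X = read_matrix(args.datadir / "matrix.tsv",
                    args.datadir / "annotations.tsv")
    universe = set(X.gene_ids)
    args.outdir.mkdir(parents=True, exist_ok=True)

    for treatment, control in (("FC30", "CC30"), ("RT30", "CC30")):
        res = pd.read_csv(args.dedir / f"de_{treatment}_vs_{control}.tsv",
                          sep="\t", index_col="gene")
        for direction in ("up", "down"):
            up, down = call_de(res, args.fdr)
            genes = up if direction == "up" else down
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clusters = cluster_enrichment(genes, collection, universe)
            out = args.outdir / f"clusters_{treatment}_{direction}.tsv"
            pd.DataFrame(
                [(i + 1, c.ease_score, c.enriched, ";".join(c.members))
                 for i, c in enumerate(clusters)],
                columns=["cluster", "ease_score", "enriched", "terms"],
            ).to_csv(out, sep="\t", index=False, float_format="%.4g")
            label = (f"{treatment} {direction} ({len(genes)} genes): ")
            if clusters:
                top = clusters[0]
                print(label + f"top cluster EASE={top.ease_score:.2f} "
                      f"({len(top.members)} terms"
                      f"{', enriched' if top.enriched else ''}): "
                      + ";".join(top.members[:4]) + ("..." if len(top.members) > 4 else ""))
            else:
                print(label + "no term clusters")


if __name__ == "__main__":
    main()
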