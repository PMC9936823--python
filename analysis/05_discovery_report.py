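#!/usr/bin/env python
"""PIP-based SNP discovery report.

Ranks SNPs by posterior inclusion probability from a fitted SNP-effect
table (analysis/03), writes the Manhattan data (chrom, pos, PIP per SNP),
the top-20 table, and — when a gene annotation (BED or GFF3) is supplied —
the genes within 1 Mb of each top SNP.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from beefq.evaluate import nearest_genes, top_snps
from beefq.io import read_gene_annotation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fit-dir", type=Path, default=Path("results/fit"))
    ap.add_argument("--trait", default="tender")
    ap.add_argument("--out-dir", type=Path, default=Path("results/discovery"))
    ap.add_argument("--annotation", type=Path, default=None,
                    help="gene intervals as BED or GFF3")
    ap.add_argument("--window", type=int, default=1_000_000)
    args = ap.parse_args()

    effects = pd.read_csv(args.fit_dir / f"snp_effects_{args.trait}.csv")
    table = effects.rename(columns={"pip": "pip"})[
        ["snp_id", "chrom", "pos", "pip"]
    ]
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"manhattan_{args.trait}.csv", index=False)
    top = top_snps(table, n=20)

    if args.annotation is not None:
        ann = read_gene_annotation(args.annotation)
        genes = nearest_genes(top, ann, window=args.window)
        top = top.assign(
            genes_within_1mb=[";".join(genes[s]) for s in top["snp_id"]]
        )
        with open(out / f"genes_{args.trait}.json", "w") as fh:
            json.dump(genes, fh, indent=2)
    top.to_csv(out / f"top20_{args.trait}.csv", index=False)
    print(top.head(10).to_string(index=False))
    print(f"wrote top-20 and Manhattan tables for {args.trait} -> {out}")


if __name__ == "__main__":
    main()
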