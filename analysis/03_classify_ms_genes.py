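#!/usr/bin/env python
"""Classify susceptibility genes as pathogenic or protective from eQTL direction.

With the table harmonized to the risk allele (OR > 1), a gene whose risk
allele associates with higher expression (NES < 0) is pathogenic; lower
expression (NES > 0) is protective. Pairs with missing NES are excluded and
genes with conflicting pairs quarantined.
"""

import argparse
from pathlib import Path

import pandas as pd

from foxsplice import synthetic
from foxsplice.ms_catalog import build_pairs, collapse_to_genes, label_counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = synthetic.read_tsv(args.indir / "ms_pairs.tsv")
    pairs = build_pairs(table)
    sets = collapse_to_genes(pairs)
    counts = label_counts(pairs)

    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "ms_gene_sets.tsv"
    rows = ([{"gene_id": g, "set": "pathogenic"} for g in sorted(sets.pathogenic)]
            + [{"gene_id": g, "set": "protective"} for g in sorted(sets.protective)]
            + [{"gene_id": g, "set": "conflicted"} for g in sorted(sets.conflicted)])
    synthetic.write_tsv(pd.DataFrame(rows), out)

    print(f"{len(pairs)} SNP-gene pairs: {counts['pathogenic']} pathogenic, "
          f"{counts['protective']} protective, "
          f"{counts['excluded_missing']} excluded (missing NES)")
    print(f"gene level: {len(sets.pathogenic)} pathogenic, "
          f"{len(sets.protective)} protective, {len(sets.conflicted)} conflicted "
          f"of {len(sets.susceptibility)} susceptibility genes")
    print(f"gene sets written to {out}")


if __name__ == "__main__":
    main()
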