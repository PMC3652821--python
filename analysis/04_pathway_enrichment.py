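"""Pathway-level comparison of the studies: hypergeometric enrichment of each
study's DE genes against the synthetic GMT collection, merged into one
enrichment-map network.

Writes per-study enrichment tables and the node/edge tables of the merged
term network under results/enrichment/.
"""

import argparse
from pathlib import Path

import pandas as pd

from endosig import io
from endosig.enrichment import hypergeom_enrich, merge_top_terms
from endosig.pipeline import load_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--dge", type=Path, default=Path("results/dge"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--top-n", type=int, default=20)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    meta = io.read_metadata(args.data / "metadata.tsv")
    gmt = io.read_gmt(args.data / "pathways.gmt")

    tables, universes = {}, {}
    for sid in ("study1", "study2", "study3"):
        table = pd.read_csv(args.dge / f"dge_{sid}.tsv", sep="\t", index_col=0)
        de = set(table.index[table["called"].astype(bool)])
        study = load_study(
            sid, args.data / f"expr_{sid}.tsv", args.data / f"probemap_{sid}.tsv", meta
        )
        universes[sid] = study.gene_universe()
        enr = hypergeom_enrich(de, universes[sid], gmt)
        enr.to_csv(args.out / f"enrichment_{sid}.tsv", sep="\t", index=False)
        tables[sid] = enr
        top = enr.iloc[0]
        print(
            f"{sid}: {int((enr['p_value'] <= args.alpha).sum())}/{len(enr)} pathways "
            f"at p<={args.alpha}; top hit {top['pathway']} "
            f"(k={top['k']}/K={top['K']}, p={top['p_value']:.2e})"
        )

    emap = merge_top_terms(
        tables, gmt, set.union(*universes.values()),
        top_n=args.top_n, alpha=args.alpha,
    )
    emap.nodes.to_csv(args.out / "emap_nodes.tsv", sep="\t")
    emap.edges.to_csv(args.out / "emap_edges.tsv", sep="\t", index=False)
    print(
        f"enrichment map: {len(emap.nodes)} terms significant in >=1 study, "
        f"{len(emap.edges)} Jaccard edges (threshold 0.25)"
    )


if __name__ == "__main__":
    main()
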