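"""Generate the synthetic study collection the downstream analyses consume.

Emulates the real integration design: three independent two-group endotoxin
exposure studies on partially overlapping platforms (8 / 6 / 4 mice per
group), a fourth study with four exposure conditions
(air / LPS / smoke / LPS+smoke; 6/5/6/5 mice), and a synthetic pathway
collection containing one pathway fully overlapping the planted signature.

Writes expression, metadata, probe-map, GMT and ground-truth files under
results/data/.
"""

import argparse
from pathlib import Path

import pandas as pd

from endosig import io
from endosig.pipeline import stage_seed, write_study
from endosig.simulate import (
    SimulationConfig,
    generate_multicondition,
    generate_multistudy,
    generate_pathway_db,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=stage_seed(args.seed, "simulate"))
    studies, truth = generate_multistudy(cfg)
    effects_out: dict = {}
    multi = generate_multicondition(
        signature=truth.signature_genes,
        groups=[("air", 6), ("lps", 5), ("smoke", 6), ("lps_smoke", 5)],
        effects={"air": 0.0, "lps": 2.0, "smoke": 4.0, "lps_smoke": 2.0},
        seed=stage_seed(args.seed, "multicondition"),
        effects_out=effects_out,
    )
    truth.condition_effects = effects_out

    meta_rows = []
    for st in studies + [multi]:
        write_study(st, args.out)
        meta_rows += [(s, st.study_id, st.groups[s]) for s in st.samples]
    io.write_metadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "study_id", "group"]),
        args.out / "metadata.tsv",
    )
    io.write_json(truth.to_dict(), args.out / "ground_truth.json")

    gmt = generate_pathway_db(
        universe=truth.per_study_universe["study1"],
        n_pathways=50,
        size_range=(10, 60),
        planted=[("PLANTED_SIGNATURE", truth.signature_genes, 1.0)],
        seed=stage_seed(args.seed, "pathways"),
    )
    io.write_gmt(gmt, args.out / "pathways.gmt")

    for st in studies:
        labels = st.group_labels()
        print(
            f"{st.study_id}: {st.matrix.shape[0]} probes x {len(st.samples)} samples "
            f"({labels.count('control')} control vs {labels.count('exposed')} exposed), "
            f"universe {len(st.gene_universe())} genes"
        )
    print(
        f"{multi.study_id}: {len(multi.samples)} samples across 4 exposure conditions; "
        f"planted signature {len(truth.signature_genes)} genes "
        f"(forced onto every platform); {len(gmt)} pathways written"
    )


if __name__ == "__main__":
    main()
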