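"""End-to-end orchestration: simulate -> normalize -> collapse -> SAM ->
signature + overlap tests -> enrichment -> consensus validation.

One structured config drives every stage; a single global seed is fanned out
to stage-specific derived seeds (fixed offsets, so adding a stage never
perturbs the randomness of earlier ones). Every intermediate is persisted as
TSV/JSON and the run ends with a machine-readable summary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from endosig import io
from endosig.consensus import consensus_cluster, fold_change_heatmap_table, random_signature_baseline
from endosig.enrichment import hypergeom_enrich, merge_top_terms
from endosig.overlap import build_common_background, intersect_signature, pairwise_overlap_report
from endosig.preprocess import ExpressionStudy, collapse_probes, quantile_normalize
from endosig.sam import DEResult, SAMConfig, sam_permutation_fdr
from endosig.simulate import (
    CONTROL_GROUP,
    EXPOSED_GROUP,
    SimulationConfig,
    generate_multicondition,
    generate_multistudy,
    generate_pathway_db,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (all derived seeds stay below 2**31)
STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "multicondition": 23,
    "pathways": 37,
    "sam": 53,
    "consensus": 71,
    "baseline": 89,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


DEFAULT_CONFIG: dict = {
    "simulation": {},  # SimulationConfig field overrides
    "multicondition": {
        "groups": [["air", 6], ["lps", 5], ["smoke", 6], ["lps_smoke", 5]],
        "effects": {"air": 0.0, "lps": 2.0, "smoke": 4.0, "lps_smoke": 2.0},
        "noise_sd": 0.5,
        "sign_mode": "random",
    },
    "pathways": {"n_pathways": 50, "size_range": [10, 60], "planted_overlap_frac": 1.0},
    "sam": {"n_permutations": 200, "target_fdr": 0.05, "delta_grid_step": 0.05, "pi0_mode": "one"},
    "enrichment": {"alpha": 0.05, "top_n": 20, "similarity_threshold": 0.25},
    "consensus": {"frac": 0.8, "reps": 200, "k": None, "n_random": 100, "reps_per_signature": 20},
}


def merged_config(user: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, block in (user or {}).items():
        if isinstance(block, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(block)
        else:
            cfg[key] = block
    return cfg


def write_study(study: ExpressionStudy, out_dir: Path) -> None:
    io.write_expression(study.matrix, out_dir / f"expr_{study.study_id}.tsv")
    pm = pd.DataFrame(
        [(p, sym, ez if ez is not None else "NA") for p, (sym, ez) in study.probe_map.items()],
        columns=["probe_id", "gene_symbol", "entrez_id"],
    )
    io.write_probe_map(pm, out_dir / f"probemap_{study.study_id}.tsv")


def load_study(study_id: str, expr_path, map_path, meta: pd.DataFrame) -> ExpressionStudy:
    matrix = io.read_expression(expr_path)
    pm = io.read_probe_map(map_path)
    probe_map = {
        r.probe_id: (r.gene_symbol, None if r.entrez_id in ("NA", "") else r.entrez_id)
        for r in pm.itertuples()
    }
    rows = meta[meta["study_id"] == study_id]
    groups = dict(zip(rows["sample_id"], rows["group"]))
    return ExpressionStudy(study_id=study_id, matrix=matrix, groups=groups, probe_map=probe_map)


def preprocess_study(study: ExpressionStudy, collapse_method: str = "max_mean") -> pd.DataFrame:
    """Quantile-normalize then collapse to a gene x sample matrix."""
    normalized = quantile_normalize(study.matrix)
    norm_study = ExpressionStudy(
        study_id=study.study_id,
        matrix=normalized,
        groups=study.groups,
        probe_map=study.probe_map,
    )
    return collapse_probes(norm_study, method=collapse_method)


def run_sam_for_study(
    study: ExpressionStudy, sam_cfg: SAMConfig, collapse_method: str = "max_mean"
) -> tuple[pd.DataFrame, DEResult]:
    gene_matrix = preprocess_study(study, collapse_method)
    result = sam_permutation_fdr(
        gene_matrix, [study.groups[s] for s in gene_matrix.columns], sam_cfg
    )
    return gene_matrix, result


def run_all(config: dict | None, out_dir: str | Path, seed: int) -> dict:
    """Execute the whole pipeline from a config; returns the summary dict.

    Stage failure raises with the failing stage named; outputs written before
    the failure are retained.
    """
    cfg = merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "stages": []}

    stage = "simulate"
    try:
        sim_cfg = SimulationConfig(**cfg["simulation"], seed=stage_seed(seed, "simulate"))
        studies, truth = generate_multistudy(sim_cfg)
        mc_cfg = cfg["multicondition"]
        effects_out: dict = {}
        multi = generate_multicondition(
            signature=truth.signature_genes,
            groups=[tuple(g) for g in mc_cfg["groups"]],
            effects=mc_cfg["effects"],
            seed=stage_seed(seed, "multicondition"),
            noise_sd=mc_cfg.get("noise_sd", 0.5),
            sign_mode=mc_cfg.get("sign_mode", "random"),
            effects_out=effects_out,
        )
        truth.condition_effects = effects_out
        for st in studies + [multi]:
            write_study(st, out)
        meta_rows = [
            (s, st.study_id, st.groups[s])
            for st in studies + [multi]
            for s in st.samples
        ]
        io.write_metadata(
            pd.DataFrame(meta_rows, columns=["sample_id", "study_id", "group"]),
            out / "metadata.tsv",
        )
        io.write_json(truth.to_dict(), out / "ground_truth.json")
        pw_cfg = cfg["pathways"]
        gmt = generate_pathway_db(
            universe=truth.per_study_universe["study1"],
            n_pathways=pw_cfg["n_pathways"],
            size_range=tuple(pw_cfg["size_range"]),
            planted=[("PLANTED_SIGNATURE", truth.signature_genes, pw_cfg["planted_overlap_frac"])],
            seed=stage_seed(seed, "pathways"),
        )
        io.write_gmt(gmt, out / "pathways.gmt")
        summary["stages"].append(stage)

        stage = "dge_sam"
        sam_cfg = SAMConfig(**cfg["sam"], seed=stage_seed(seed, "sam"))
        per_study_called: dict[str, set[str]] = {}
        per_study_universe: dict[str, set[str]] = {}
        gene_matrices: dict[str, pd.DataFrame] = {}
        de_results: dict[str, DEResult] = {}
        de_counts = {}
        for st in studies:
            gm, res = run_sam_for_study(st, sam_cfg)
            gene_matrices[st.study_id] = gm
            de_results[st.study_id] = res
            per_study_called[st.study_id] = res.called_genes
            per_study_universe[st.study_id] = st.gene_universe()
            res.table.to_csv(out / f"dge_{st.study_id}.tsv", sep="\t")
            de_counts[st.study_id] = int(res.table["called"].sum())
            io.write_json(
                {
                    "s0": res.s0,
                    "delta_selected": res.delta_selected,
                    "fdr_estimate": res.fdr_estimate,
                    "pi0": res.pi0,
                    "n_called": de_counts[st.study_id],
                    "n_permutations": res.n_permutations_used,
                },
                out / f"dge_summary_{st.study_id}.json",
            )
        summary["de_counts"] = de_counts
        summary["stages"].append(stage)

        stage = "integrate"
        background = build_common_background(per_study_universe)
        signature = intersect_signature(
            per_study_called,
            background,
            provenance={
                s: {"target_fdr": sam_cfg.target_fdr, "delta": de_results[s].delta_selected}
                for s in per_study_called
            },
        )
        io.write_gene_list(signature.genes, out / "signature.txt")
        io.write_gene_list(background, out / "background.txt")
        tests = pairwise_overlap_report(signature, per_study_universe)
        io.write_json([t.to_dict() for t in tests], out / "overlap_tests.json")
        summary["signature_size"] = len(signature.genes)
        summary["background_size"] = len(background)
        summary["overlap_tests"] = [t.to_dict() for t in tests]
        summary["stages"].append(stage)

        stage = "enrichment"
        en_cfg = cfg["enrichment"]
        tables = {}
        for st in studies:
            table = hypergeom_enrich(
                per_study_called[st.study_id], per_study_universe[st.study_id], gmt
            )
            table.to_csv(out / f"enrichment_{st.study_id}.tsv", sep="\t", index=False)
            tables[st.study_id] = table
        emap = merge_top_terms(
            tables,
            {k: set(v) for k, v in gmt.items()},
            set.union(*per_study_universe.values()),
            top_n=en_cfg["top_n"],
            alpha=en_cfg["alpha"],
            similarity_threshold=en_cfg["similarity_threshold"],
        )
        emap.nodes.to_csv(out / "emap_nodes.tsv", sep="\t")
        emap.edges.to_csv(out / "emap_edges.tsv", sep="\t", index=False)
        summary["top_pathways"] = {
            s: tables[s].head(5)["pathway"].tolist() for s in tables
        }
        summary["emap_nodes"] = int(len(emap.nodes))
        summary["emap_edges"] = int(len(emap.edges))
        summary["stages"].append(stage)

        stage = "evaluate"
        co_cfg = cfg["consensus"]
        multi_gm = preprocess_study(multi)
        labels = [multi.groups[s] for s in multi_gm.columns]
        n_present = len(set(signature.genes) & set(multi_gm.index))
        if n_present < 5:
            logger.warning(
                "signature has only %d genes on the multi-condition platform; "
                "skipping consensus validation",
                n_present,
            )
            summary["consensus"] = {"skipped": f"only {n_present} signature genes present"}
            summary["stages"].append(stage)
            io.write_json(summary, out / "run_summary.json")
            return summary
        res = consensus_cluster(
            multi_gm,
            labels,
            signature.genes,
            frac=co_cfg["frac"],
            reps=co_cfg["reps"],
            k=co_cfg.get("k"),
            seed=stage_seed(seed, "consensus"),
        )
        accs, mean_baseline = random_signature_baseline(
            multi_gm,
            labels,
            size=res.config["n_signature_genes"],
            n_signatures=co_cfg["n_random"],
            reps_per_signature=co_cfg["reps_per_signature"],
            k=co_cfg.get("k"),
            seed=stage_seed(seed, "baseline"),
            frac=co_cfg["frac"],
        )
        res.baseline_accuracies = accs
        res.mean_baseline = mean_baseline
        res.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
        fc = fold_change_heatmap_table(multi_gm, labels, signature.genes, reference_group="air")
        fc.to_csv(out / "fold_change_table.tsv", sep="\t")
        io.write_json(
            {
                "signature_accuracy": res.signature_accuracy,
                "mean_baseline": mean_baseline,
                "mean_within_group_consensus": res.mean_within_group_consensus,
                "mean_between_group_consensus": res.mean_between_group_consensus,
                "config": res.config,
            },
            out / "consensus_summary.json",
        )
        summary["consensus"] = {
            "signature_accuracy": res.signature_accuracy,
            "mean_baseline": mean_baseline,
        }
        summary["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io.write_json(summary, out / "run_summary.json")
    return summary
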