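"""Hypergeometric pathway enrichment and enrichment-map merging.

Each study's differentially expressed genes are tested against a GMT gene-set
collection restricted to that study's platform universe; the upper-tail
hypergeometric p is reported raw (the historical significance rule is raw
p <= 0.05) alongside a Benjamini-Hochberg q-value. The top terms of several
studies can be merged into an enrichment map: nodes are terms significant in
at least one study, edges connect terms whose universe-restricted gene sets
have Jaccard similarity above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_JACCARD_THRESHOLD = 0.25


@dataclass
class EnrichmentMap:
    """Term-similarity network over merged per-study enrichment results."""

    nodes: pd.DataFrame  # index term; p_<study>, q_<study>, sig_<study> columns
    edges: pd.DataFrame  # columns: source, target, jaccard


def _tail_p(N: int, K: int, n: int, k: int) -> float:
    if k <= max(0, K + n - N):
        return 1.0  # at least k overlapping genes is certain
    ks = np.arange(k, min(K, n) + 1)
    if ks.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n)))))


def hypergeom_enrich(
    de_genes: set[str], universe: set[str], gmt: dict[str, set[str]]
) -> pd.DataFrame:
    """Test every pathway for over-representation of ``de_genes``.

    Pathway gene sets are intersected with the universe before testing; a row
    is emitted for each pathway retaining K >= 1 genes. Columns: pathway,
    K (pathway size in universe), n (DE set size), k (overlap), p_value,
    bh_q, overlap_genes. Sorted by ascending p, ties by pathway name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes) & universe
    N, n = len(universe), len(de)
    rows = []
    for name in sorted(gmt):
        members = set(gmt[name]) & universe
        K = len(members)
        if K < 1:
            continue
        hit = de & members
        k = len(hit)
        rows.append(
            {
                "pathway": name,
                "K": K,
                "n": n,
                "k": k,
                "p_value": _tail_p(N, K, n, k),
                "overlap_genes": ",".join(sorted(hit)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "K", "n", "k", "p_value", "overlap_genes"]
    )
    if len(table):
        table["bh_q"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p_value", "pathway"], kind="stable").reset_index(drop=True)
    else:
        table["bh_q"] = pd.Series(dtype=float)
    return table[["pathway", "K", "n", "k", "p_value", "bh_q", "overlap_genes"]]


def merge_top_terms(
    per_study_tables: dict[str, pd.DataFrame],
    gmt: dict[str, set[str]],
    universe: set[str],
    top_n: int = 20,
    alpha: float = 0.05,
    similarity_threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> EnrichmentMap:
    """Merge each study's ``top_n`` most significant terms into one network.

    A candidate term is retained iff its raw p <= ``alpha`` in at least one
    study. Edges connect retained terms whose universe-restricted gene sets
    have Jaccard similarity >= ``similarity_threshold``.
    """
    if not per_study_tables:
        raise ValueError("need >= 1 study table")
    universe = set(universe)
    candidates: set[str] = set()
    for table in per_study_tables.values():
        top = table.nsmallest(top_n, "p_value", keep="first")
        candidates |= set(top["pathway"])

    studies = sorted(per_study_tables)
    records = {}
    for term in sorted(candidates):
        rec: dict[str, float | bool] = {}
        keep = False
        for study in studies:
            table = per_study_tables[study].set_index("pathway")
            if term in table.index:
                p = float(table.loc[term, "p_value"])
                q = float(table.loc[term, "bh_q"])
            else:
                p, q = np.nan, np.nan
            sig = bool(p <= alpha) if np.isfinite(p) else False
            rec[f"p_{study}"] = p
            rec[f"q_{study}"] = q
            rec[f"sig_{study}"] = sig
            keep = keep or sig
        if keep:
            records[term] = rec
    nodes = pd.DataFrame.from_dict(records, orient="index").sort_index()
    nodes.index.name = "term"

    edge_rows = []
    retained = list(nodes.index)
    restricted = {t: set(gmt.get(t, set())) & universe for t in retained}
    for t1, t2 in combinations(retained, 2):
        s1, s2 = restricted[t1], restricted[t2]
        union = s1 | s2
        jac = len(s1 & s2) / len(union) if union else 0.0
        if jac >= similarity_threshold:
            edge_rows.append({"source": t1, "target": t2, "jaccard": jac})
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "jaccard"])
    return EnrichmentMap(nodes=nodes, edges=edges)
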