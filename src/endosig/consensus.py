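"""Signature validation: correlation clustering of samples and subsampled
consensus clustering against a random-signature null.

A candidate gene signature is judged by how stably it groups samples into
their exposure conditions. Each replicate subsamples a fraction of the
signature genes, centers every gene to mean zero, and clusters the samples by
average-linkage on 1 - Pearson correlation; a replicate is "accurate" when
its k-cluster partition reproduces the exposure labels exactly (adjusted Rand
index 1). The consensus matrix records how often each sample pair
co-clusters. The same procedure applied to random gene sets of equal size
gives the null distribution against which the signature's accuracy is
compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Consensus clustering output for one candidate signature."""

    consensus_matrix: pd.DataFrame
    per_rep_partitions: np.ndarray  # reps x samples cluster labels
    signature_accuracy: float
    mean_within_group_consensus: float
    mean_between_group_consensus: float
    baseline_accuracies: list[float] = field(default_factory=list)
    mean_baseline: float = float("nan")
    config: dict = field(default_factory=dict)


def center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center every gene (row) to mean zero across samples."""
    if matrix.shape[1] < 1:
        raise ValueError("need >= 1 sample")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def _correlation_condensed(X: np.ndarray, sample_ids) -> np.ndarray:
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [str(sample_ids[i]) for i in dead]
        raise ValueError(f"zero-variance sample profile(s): {', '.join(names)}")
    corr = np.corrcoef(X, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_samples(
    matrix: pd.DataFrame,
    k: int,
    gene_set: set[str] | None = None,
    method: str = "average",
    metric: str = "correlation",
) -> np.ndarray:
    """Hierarchical clustering of sample profiles cut at k clusters.

    Distance is 1 - Pearson correlation between sample columns (or Euclidean
    with ``metric="euclidean"``); linkage is average by default. Returns one
    integer cluster label per sample, deterministic for fixed input.
    """
    if gene_set is not None:
        rows = [g for g in matrix.index if g in gene_set]
        if not rows:
            raise ValueError("gene set does not intersect matrix rows")
        matrix = matrix.loc[rows]
    n = matrix.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n} samples]")
    X = matrix.to_numpy(dtype=float)
    if metric == "correlation":
        condensed = _correlation_condensed(X, list(matrix.columns))
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(X.T, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(condensed, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def _partition_matches(labels_pred: np.ndarray, labels_true) -> bool:
    return adjusted_rand_score(list(labels_true), list(labels_pred)) > 1 - 1e-9


def consensus_cluster(
    matrix: pd.DataFrame,
    labels,
    signature: set[str],
    frac: float = 0.8,
    reps: int = 1000,
    k: int | None = None,
    seed: int = 0,
    method: str = "average",
    metric: str = "correlation",
) -> ConsensusResult:
    """Feature-subsampled consensus clustering of samples on a gene signature.

    Every replicate draws ``ceil(frac x |signature ∩ rows|)`` signature genes
    without replacement, centers them, and clusters all samples at k (default:
    the number of distinct exposure labels). Because subsampling is over
    genes, every sample pair co-occurs in every replicate, so the consensus
    denominator is ``reps``. ``signature_accuracy`` is the fraction of
    replicates whose partition matches the exposure labels up to relabeling.
    """
    labels = list(labels)
    if len(labels) != matrix.shape[1]:
        raise ValueError("one exposure label per sample required")
    present = [g for g in matrix.index if g in set(signature)]
    if len(present) < 5:
        raise ValueError(f"only {len(present)} signature genes in matrix; >= 5 required")
    if k is None:
        k = len(set(labels))
    n = matrix.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    sub_matrix = matrix.loc[present]
    X_full = sub_matrix.to_numpy(dtype=float)
    m = int(np.ceil(frac * len(present)))
    co = np.zeros((n, n))
    partitions = np.empty((reps, n), dtype=int)
    hits = 0
    for r in range(reps):
        pick = rng.choice(len(present), size=m, replace=False)
        X = X_full[pick]
        X = X - X.mean(axis=1, keepdims=True)
        condensed = _correlation_condensed(X, list(matrix.columns))
        part = fcluster(linkage(condensed, method=method), t=k, criterion="maxclust")
        partitions[r] = part
        co += (part[:, None] == part[None, :]).astype(float)
        if _partition_matches(part, labels):
            hits += 1
    consensus = co / reps
    np.fill_diagonal(consensus, 1.0)

    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    off = ~np.eye(n, dtype=bool)
    within = float(consensus[same & off].mean()) if (same & off).any() else float("nan")
    between = float(consensus[~same].mean()) if (~same).any() else float("nan")

    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=matrix.columns, columns=matrix.columns),
        per_rep_partitions=partitions,
        signature_accuracy=hits / reps,
        mean_within_group_consensus=within,
        mean_between_group_consensus=between,
        config={
            "frac": frac,
            "reps": reps,
            "k": k,
            "seed": seed,
            "n_signature_genes": len(present),
        },
    )


def random_signature_baseline(
    matrix: pd.DataFrame,
    labels,
    size: int,
    n_signatures: int = 1000,
    reps_per_signature: int = 50,
    k: int | None = None,
    seed: int = 0,
    frac: float = 0.8,
    method: str = "average",
    metric: str = "correlation",
) -> tuple[list[float], float]:
    """Null accuracies of random gene sets of a given size.

    Draws ``n_signatures`` gene sets uniformly from the matrix rows and pushes
    each through the same subsampled-consensus procedure (with
    ``reps_per_signature`` replicates). Returns the per-signature accuracies
    and their mean.
    """
    if size > matrix.shape[0]:
        raise ValueError("size exceeds number of genes in matrix")
    rng = np.random.default_rng(seed)
    genes = np.asarray(matrix.index)
    accuracies = []
    for i in range(n_signatures):
        draw = set(rng.choice(genes, size=size, replace=False).tolist())
        res = consensus_cluster(
            matrix,
            labels,
            draw,
            frac=frac,
            reps=reps_per_signature,
            k=k,
            seed=int(rng.integers(0, 2**31 - 1)),
            method=method,
            metric=metric,
        )
        accuracies.append(res.signature_accuracy)
    return accuracies, float(np.mean(accuracies)) if accuracies else float("nan")


def fold_change_heatmap_table(
    matrix: pd.DataFrame,
    labels,
    signature: set[str],
    reference_group: str,
) -> pd.DataFrame:
    """Per-signature-gene mean log2 fold change of each condition vs. reference.

    Signature genes absent from the platform are dropped with a logged
    warning, never imputed. Columns are the non-reference conditions in
    sorted order.
    """
    labels = list(labels)
    groups = sorted(set(labels))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not among {groups}")
    missing = set(signature) - set(matrix.index)
    if missing:
        logger.warning(
            "%d signature genes absent from platform; dropped: %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    present = [g for g in matrix.index if g in set(signature)]
    sub = matrix.loc[present]
    lab = np.asarray(labels)
    ref_mean = sub.loc[:, lab == reference_group].mean(axis=1)
    out = {}
    for g in groups:
        if g == reference_group:
            continue
        out[g] = sub.loc[:, lab == g].mean(axis=1) - ref_mean
    table = pd.DataFrame(out, index=present)
    table.index.name = "gene"
    return table
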