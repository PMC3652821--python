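"""Per-study preprocessing: quantile normalization and probe-to-gene collapse.

Input matrices are probe-level log2 intensities, assumed already
background-adjusted (synthetic data is generated on that scale directly).
Normalization forces every sample onto a common intensity distribution; the
collapse step maps probes to harmonized gene identifiers so studies run on
different platforms become comparable.

Gene identity key: the Entrez ID when one is present, otherwise the exact
(case-sensitive) MGI symbol. Entrez IDs are unambiguous; symbols drift across
annotation releases, so they serve only as the fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "NA", "NaN", "nan", "None"}


def harmonized_gene_key(symbol: str, entrez: str | None) -> str:
    """Stable cross-platform gene identifier: Entrez if present, else symbol."""
    if entrez is not None and str(entrez) not in NA_TOKENS:
        return f"entrez:{entrez}"
    return f"sym:{symbol}"


@dataclass
class ExpressionStudy:
    """One study's probe x sample matrix with group labels and probe map.

    ``matrix`` rows are probe IDs; ``probe_map`` maps probe -> (MGI symbol,
    Entrez ID or None). The study's gene universe is the image of its probes
    under the harmonized gene key.
    """

    study_id: str
    matrix: pd.DataFrame
    groups: dict[str, str]
    probe_map: dict[str, tuple[str, str | None]]
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = list(self.matrix.columns)
        if list(self.matrix.columns) != self.samples:
            raise ValueError("matrix columns do not match sample order")
        unmapped = set(self.matrix.index) - set(self.probe_map)
        if unmapped:
            raise ValueError(
                f"{self.study_id}: {len(unmapped)} matrix rows missing from probe map"
            )
        if self.matrix.isna().any().any():
            raise ValueError(f"{self.study_id}: missing values in expression matrix")

    def gene_universe(self) -> set[str]:
        """Harmonized gene IDs interrogated by this platform."""
        return {
            harmonized_gene_key(sym, ez)
            for sym, ez in (self.probe_map[p] for p in self.probe_map)
        }

    def group_labels(self) -> list[str]:
        return [self.groups[s] for s in self.samples]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference distribution is the vector of row means of the column-sorted
    input. Each column's values are replaced by the reference value at their
    rank; ties within a column receive the mean of the reference values at
    their tied ranks. Row and column order are preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 columns")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in expression matrix")
    n_rows, n_cols = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_cols):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n_rows)
        ranked[order] = reference
        # average reference values over runs of tied input values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_rows]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(study: ExpressionStudy, method: str = "max_mean") -> pd.DataFrame:
    """Collapse the probe-level matrix to one row per harmonized gene.

    ``max_mean`` keeps, per gene, the probe with the highest mean intensity
    (ties broken by lexicographically smallest probe ID); ``mean`` averages all
    of a gene's probes. Probes with no gene mapping are dropped and counted in
    the log.
    """
    if method not in {"max_mean", "mean"}:
        raise ValueError(f"unknown collapse method {method!r}")
    gene_of: dict[str, str] = {}
    n_unmapped = 0
    for probe in study.matrix.index:
        sym, ez = study.probe_map[probe]
        if (sym is None or str(sym) in NA_TOKENS) and (ez is None or str(ez) in NA_TOKENS):
            n_unmapped += 1
            continue
        gene_of[probe] = harmonized_gene_key(sym, ez)
    if n_unmapped:
        logger.info("%s: dropped %d unmapped probes", study.study_id, n_unmapped)
    if not gene_of:
        raise ValueError(f"{study.study_id}: no probe mapped to any gene")

    mapped = study.matrix.loc[list(gene_of)]
    genes = pd.Series({p: gene_of[p] for p in mapped.index}, name="gene")
    if method == "mean":
        collapsed = mapped.groupby(genes, sort=True).mean()
    else:
        means = mapped.mean(axis=1)
        frame = pd.DataFrame({"gene": genes, "mean": means, "probe": mapped.index})
        # highest mean wins; ties -> smallest probe ID
        frame = frame.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        keep = frame.drop_duplicates("gene", keep="first")
        collapsed = mapped.loc[keep["probe"]]
        collapsed.index = keep["gene"].to_numpy()
        collapsed = collapsed.sort_index()
    collapsed.index.name = "feature_id"
    return collapsed
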