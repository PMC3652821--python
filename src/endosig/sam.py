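"""Two-class SAM: modified t-statistic, fudge-factor search, permutation FDR.

The per-gene statistic is d = (mean1 - mean2) / (s + s0), where s is the
pooled standard error and s0 a small "fudge factor" that damps the inflated
statistics of low-variance genes. s0 is chosen among the 21 percentiles
{0, 5, ..., 100} of the s distribution to minimize the coefficient of
variation of the median absolute deviation of d across 100 equal-count
windows of s.

Significance is calibrated by permuting group labels: the observed order
statistics d_(i) are compared with their permutation means, and a gap
threshold delta defines symmetric call cutoffs. The FDR at a given delta is
pi0 times the median (over permutations) count of permuted statistics beyond
the cutoffs, divided by the number of called genes. The selected delta is the
smallest on the grid whose FDR estimate does not exceed the target.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_S0_CANDIDATE_PERCENTILES = 21  # 0, 5, ..., 100
N_S0_WINDOWS = 100


@dataclass
class SAMConfig:
    """Knobs of the permutation analysis.

    ``n_permutations`` caps the number of label permutations (exhaustive when
    fewer distinct assignments exist). ``pi0_mode`` is ``"one"`` (conservative
    pi0 = 1, the default) or ``"quantile"`` (estimate pi0 from the central
    quartile band of the permuted statistics).
    """

    n_permutations: int = 200
    target_fdr: float = 0.05
    delta_grid_step: float = 0.05
    pi0_mode: str = "one"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.target_fdr < 1):
            raise ValueError("target_fdr must be in (0, 1)")
        if self.delta_grid_step <= 0:
            raise ValueError("delta_grid_step must be positive")
        if self.pi0_mode not in {"one", "quantile"}:
            raise ValueError(f"unknown pi0_mode {self.pi0_mode!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class DEResult:
    """Per-gene SAM output plus the study-level calibration quantities."""

    table: pd.DataFrame  # columns: d, s, log2fc, called, direction
    s0: float
    delta_selected: float
    fdr_estimate: float
    pi0: float
    cut_up: float
    cut_low: float
    expected_order_stats: np.ndarray
    no_delta_found: bool = False
    n_permutations_used: int = 0
    config: SAMConfig | None = None

    @property
    def called_genes(self) -> set[str]:
        return set(self.table.index[self.table["called"]])


def _group_stats(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    n1, n2 = idx1.size, idx2.size
    x1, x2 = X[:, idx1], X[:, idx2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = ss / (n1 + n2 - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
    return m1 - m2, s


def sam_statistic(
    group1: np.ndarray, group2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (d, s, log2fc) for two groups of log2 expression values.

    ``group1``/``group2`` are gene x sample arrays; log2fc = mean1 - mean2.
    """
    group1 = np.atleast_2d(np.asarray(group1, dtype=float))
    group2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if group1.shape[1] < 2 or group2.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    X = np.hstack([group1, group2])
    diff, s = _group_stats(
        X, np.arange(group1.shape[1]), np.arange(group1.shape[1], X.shape[1])
    )
    d = diff / (s + s0)
    return d, s, diff


def estimate_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimizing the CV of window-wise MAD(d) over s windows.

    Candidates are the 21 percentiles {0, 5, ..., 100} of s. Genes are split
    into 100 equal-count windows by s; for each candidate the MAD of
    d = diff/(s + cand) is computed per window and the candidate minimizing
    the coefficient of variation of those MADs wins (ties -> smallest
    candidate). Degenerate inputs (all s equal) return 0 with a warning.
    """
    diff = np.asarray(diff, dtype=float)
    s = np.asarray(s, dtype=float)
    n = s.size
    if n < 100:
        warnings.warn(f"estimate_s0: only {n} genes; >=100 recommended", stacklevel=2)
    if np.allclose(s, s[0]):
        warnings.warn("estimate_s0: all s equal; returning s0 = 0", stacklevel=2)
        return 0.0
    candidates = np.percentile(s, np.linspace(0, 100, N_S0_CANDIDATE_PERCENTILES))
    order = np.argsort(s, kind="stable")
    n_win = min(N_S0_WINDOWS, n)
    windows = np.array_split(order, n_win)
    best_s0, best_cv = 0.0, math.inf
    for cand in candidates:
        d = diff / (s + cand)
        mads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]
        )
        mean = mads.mean()
        if mean == 0:
            cv = 0.0
        else:
            cv = mads.std(ddof=1) / mean
        if cv < best_cv - 1e-15 or (abs(cv - best_cv) <= 1e-15 and cand < best_s0):
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _label_permutations(
    labels: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets assigned to class 1, observed assignment first.

    All distinct assignments when there are at most ``n_permutations`` of
    them; otherwise a seeded sample without replacement (observed included).
    """
    classes = np.unique(labels)
    idx1 = np.flatnonzero(labels == classes[0])
    n, n1 = labels.size, idx1.size
    total = math.comb(n, n1)
    observed = tuple(idx1.tolist())
    if total <= n_permutations:
        perms = [np.array(c) for c in combinations(range(n), n1)]
        # observed assignment first for reporting clarity
        perms.sort(key=lambda c: tuple(c.tolist()) != observed)
        return perms
    seen = {observed}
    perms = [np.array(observed)]
    while len(perms) < n_permutations:
        pick = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if pick not in seen:
            seen.add(pick)
            perms.append(np.array(pick))
    return perms


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """Symmetric call cutoffs for one delta.

    cut_up is the smallest observed order statistic exceeding its permutation
    expectation by more than delta; cut_low the mirror image below.
    """
    above = d_sorted - dbar > delta
    cut_up = d_sorted[above].min() if above.any() else math.inf
    below = dbar - d_sorted > delta
    cut_low = d_sorted[below].max() if below.any() else -math.inf
    return cut_up, cut_low


def sam_permutation_fdr(
    matrix: pd.DataFrame,
    labels,
    config: SAMConfig | None = None,
    class1: str | None = None,
) -> DEResult:
    """Full SAM analysis of a gene x sample matrix with two-class labels.

    ``class1`` names the class whose mean enters the statistic positively
    (default: the lexicographically larger label, so "exposed" vs "control"
    gives positive d for up-regulation under exposure). Deterministic given
    ``config.seed``.
    """
    config = config or SAMConfig()
    config.validate()
    labels = np.asarray(list(labels))
    if labels.size != matrix.shape[1]:
        raise ValueError("one label per sample column required")
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 label classes required, got {classes}")
    if class1 is None:
        class1 = classes[1]
    class2 = [c for c in classes if c != class1][0]
    idx1 = np.flatnonzero(labels == class1)
    idx2 = np.flatnonzero(labels == class2)
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs >= 2 samples")

    # order columns class1-first so permutation indexing is uniform
    col_order = np.concatenate([idx1, idx2])
    X = matrix.to_numpy(dtype=float)[:, col_order]
    n1 = idx1.size
    n = X.shape[1]

    diff, s = _group_stats(X, np.arange(n1), np.arange(n1, n))
    s0 = estimate_s0(diff, s)
    d = diff / (s + s0)

    rng = np.random.default_rng(config.seed)
    perm_labels = np.array([class1] * n1 + [class2] * (n - n1))
    perms = _label_permutations(perm_labels, config.n_permutations, rng)
    n_genes = X.shape[0]
    all_idx = np.arange(n)
    perm_d_sorted = np.empty((len(perms), n_genes))
    for b, p1 in enumerate(perms):
        p2 = np.setdiff1d(all_idx, p1, assume_unique=True)
        pdiff, ps = _group_stats(X, p1, p2)
        perm_d_sorted[b] = np.sort(pdiff / (ps + s0))
    dbar = perm_d_sorted.mean(axis=0)
    d_sorted = np.sort(d)

    pi0 = 1.0
    if config.pi0_mode == "quantile":
        q25, q75 = np.percentile(perm_d_sorted.ravel(), [25, 75])
        in_band = np.count_nonzero((d >= q25) & (d <= q75))
        pi0 = min(1.0, in_band / (0.5 * n_genes))

    max_gap = float(np.max(np.abs(d_sorted - dbar)))
    grid = np.arange(0.0, max_gap + config.delta_grid_step, config.delta_grid_step)

    def fdr_at(delta: float) -> tuple[float, float, float, int]:
        cu, cl = _cutoffs(d_sorted, dbar, delta)
        n_called = int(np.count_nonzero((d >= cu) | (d <= cl)))
        false_counts = np.count_nonzero(
            (perm_d_sorted >= cu) | (perm_d_sorted <= cl), axis=1
        )
        if n_called == 0:
            fdr = 0.0
        else:
            fdr = pi0 * float(np.median(false_counts)) / max(1, n_called)
        return fdr, cu, cl, n_called

    delta_selected = None
    for delta in grid:
        fdr, cu, cl, n_called = fdr_at(float(delta))
        if fdr <= config.target_fdr:
            delta_selected = float(delta)
            break
    no_delta = delta_selected is None
    if no_delta:
        logger.warning("no delta reaches target FDR %.3g; calling no genes", config.target_fdr)
        delta_selected = math.inf
        fdr, cu, cl, n_called = 0.0, math.inf, -math.inf, 0

    called = (d >= cu) | (d <= cl)
    direction = np.where(d > 0, "up", "down")
    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "log2fc": diff,
            "called": called,
            "direction": direction,
        },
        index=matrix.index,
    )
    table.index.name = "gene"
    return DEResult(
        table=table,
        s0=s0,
        delta_selected=delta_selected,
        fdr_estimate=fdr,
        pi0=pi0,
        cut_up=cu,
        cut_low=cl,
        expected_order_stats=dbar,
        no_delta_found=no_delta,
        n_permutations_used=len(perms),
        config=config,
    )
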