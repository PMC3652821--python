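"""Cross-study integration: common background, intersection signature, and
exact k-way hypergeometric overlap tests.

The null model treats each study's called gene set as an independent uniform
fixed-size subset of the common background universe. For two sets this is the
classical hypergeometric overlap test; for three sets the tail of
|A ∩ B ∩ C| is computed exactly by conditioning on |A ∩ B|:

    P(X3 = x) = sum_m h(m; N, a, b) * h(x; N, m, c)

where h is the hypergeometric mass. All tail sums run in log space so the
astronomically small p-values typical of conserved signatures do not
underflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    """Result of one k-way overlap significance test."""

    universe_N: int
    set_sizes: list[int]
    observed_t: int
    p_value: float
    log10_p: float
    arity: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "universe_N": self.universe_N,
            "set_sizes": list(self.set_sizes),
            "observed_t": self.observed_t,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
            "arity": self.arity,
        }


@dataclass
class GeneSignature:
    """Harmonized cross-study signature with its provenance."""

    genes: set[str]
    per_study_called: dict[str, set[str]]
    background: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for study, called in self.per_study_called.items():
            if not called <= self.background:
                raise ValueError(f"called set of {study} not within background")
        expected = set.intersection(*self.per_study_called.values()) if self.per_study_called else set()
        if self.genes != expected:
            raise ValueError("signature genes are not the intersection of called sets")


def build_common_background(universes: dict[str, set[str]] | list[set[str]]) -> set[str]:
    """Exact intersection of the studies' harmonized gene universes."""
    sets = list(universes.values()) if isinstance(universes, dict) else list(universes)
    if len(sets) < 2:
        raise ValueError("need >= 2 universes")
    background = set.intersection(*map(set, sets))
    if not background:
        raise ValueError("empty common background across platforms")
    return background


def intersect_signature(
    per_study_called: dict[str, set[str]],
    background: set[str],
    provenance: dict | None = None,
) -> GeneSignature:
    """Signature = intersection of the background-restricted called sets."""
    restricted = {s: set(c) & background for s, c in per_study_called.items()}
    genes = set.intersection(*restricted.values()) if restricted else set()
    if not genes:
        logger.warning("empty intersection signature")
    return GeneSignature(
        genes=genes,
        per_study_called=restricted,
        background=set(background),
        provenance=provenance or {},
    )


def _check_sets(N: int, sizes: tuple[int, ...], t: int) -> None:
    if N < 0 or t < 0:
        raise ValueError("N and t must be non-negative")
    for a in sizes:
        if not (0 <= a <= N):
            raise ValueError(f"set size {a} outside [0, {N}]")


def hypergeom_overlap_p(N: int, a: int, b: int, t: int) -> float:
    """Exact upper tail P(|A ∩ B| >= t) for independent uniform subsets.

    Equivalently the hypergeometric survival probability of drawing at least
    t marked elements when b of N elements are drawn and a are marked.
    Computed by log-space summation of the mass function for stability at
    extreme tails.
    """
    _check_sets(N, (a, b), t)
    if t <= max(0, a + b - N):
        return 1.0  # overlap of at least t is certain
    if t > min(a, b):
        warnings.warn(
            f"impossible overlap t={t} > min(a={a}, b={b}); p = 0", stacklevel=2
        )
        return 0.0
    ks = np.arange(t, min(a, b) + 1)
    logp = hypergeom.logpmf(ks, N, a, b)
    return float(min(1.0, np.exp(logsumexp(logp))))


def _log_hypergeom_sf_terms(N: int, m: np.ndarray, c: int, t: int) -> np.ndarray:
    """log P(Hypergeom(N, m, c) >= t) for a vector of marked counts m."""
    out = np.full(m.shape, -np.inf)
    for i, mi in enumerate(m):
        hi = min(mi, c)
        if t > hi:
            continue
        ks = np.arange(t, hi + 1)
        out[i] = logsumexp(hypergeom.logpmf(ks, N, mi, c))
    return out


def threeway_overlap_p(N: int, a: int, b: int, c: int, t: int) -> float:
    """Exact upper tail P(|A ∩ B ∩ C| >= t), three independent subsets.

    Conditions on m = |A ∩ B| (hypergeometric in N, a, b); given m, the triple
    overlap is hypergeometric in (N, m, c). With c = N this collapses to the
    two-way test.
    """
    _check_sets(N, (a, b, c), t)
    if t <= max(0, a + b + c - 2 * N):
        return 1.0  # minimum possible triple overlap is a + b + c - 2N
    if t > min(a, b, c):
        warnings.warn(
            f"impossible overlap t={t} > min({a}, {b}, {c}); p = 0", stacklevel=2
        )
        return 0.0
    m = np.arange(0, min(a, b) + 1)
    log_pm = hypergeom.logpmf(m, N, a, b)
    log_tail = _log_hypergeom_sf_terms(N, m, c, t)
    finite = np.isfinite(log_pm) & np.isfinite(log_tail)
    if not finite.any():
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_pm[finite] + log_tail[finite]))))


def _log10(p: float) -> float:
    return float(np.log10(p)) if p > 0 else -np.inf


def pairwise_overlap_report(
    signature: GeneSignature,
    per_study_universe: dict[str, set[str]] | None = None,
    pair_background: str = "per_pair",
) -> list[OverlapTest]:
    """Two-way tests for every study pair plus a 3-way test for 3 studies.

    ``pair_background`` selects the sampling frame for the pairwise tests:
    ``"per_pair"`` (default) uses the intersection of the two studies'
    platform universes when ``per_study_universe`` is given, ``"common"``
    uses the all-study background for every pair. The 3-way test always uses
    the all-study background.
    """
    if pair_background not in {"per_pair", "common"}:
        raise ValueError(f"unknown pair_background {pair_background!r}")
    studies = sorted(signature.per_study_called)
    if len(studies) < 2:
        raise ValueError("need >= 2 studies")
    tests: list[OverlapTest] = []
    for s1, s2 in combinations(studies, 2):
        if pair_background == "per_pair" and per_study_universe is not None:
            frame = set(per_study_universe[s1]) & set(per_study_universe[s2])
        else:
            frame = signature.background
        set1 = signature.per_study_called[s1] & frame
        set2 = signature.per_study_called[s2] & frame
        t = len(set1 & set2)
        p = hypergeom_overlap_p(len(frame), len(set1), len(set2), t)
        tests.append(
            OverlapTest(
                universe_N=len(frame),
                set_sizes=[len(set1), len(set2)],
                observed_t=t,
                p_value=p,
                log10_p=_log10(p),
                arity=2,
                label=f"{s1} vs {s2}",
            )
        )
    if len(studies) == 3:
        N = len(signature.background)
        sizes = [len(signature.per_study_called[s]) for s in studies]
        t = len(signature.genes)
        p = threeway_overlap_p(N, *sizes, t)
        tests.append(
            OverlapTest(
                universe_N=N,
                set_sizes=sizes,
                observed_t=t,
                p_value=p,
                log10_p=_log10(p),
                arity=3,
                label=" vs ".join(studies),
            )
        )
    return tests


def monte_carlo_overlap_p(
    N: int, sizes: tuple[int, ...], t: int, n_draws: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo k-way overlap tail with its standard error.

    Experimental fallback for k > 3 and independent cross-check for the
    exact routines.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    universe = np.arange(N)
    for _ in range(n_draws):
        inter: set[int] | None = None
        for size in sizes:
            draw = set(rng.choice(universe, size=size, replace=False).tolist())
            inter = draw if inter is None else inter & draw
            if len(inter) < t:
                break
        if inter is not None and len(inter) >= t:
            hits += 1
    p = hits / n_draws
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return p, se
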