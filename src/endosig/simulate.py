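"""Synthetic multi-study expression data with a planted shared signature.

The generator emulates the design of the real integration analysis: several
independent two-group (control vs. endotoxin-exposed) murine studies run on
distinct platforms whose gene universes only partially overlap, plus a
four-condition exposure study (air / LPS / smoke / LPS+smoke). A configurable
set of "signature" genes is differentially expressed in every study; each
study additionally carries private differentially expressed genes that the
cross-study intersection should reject.

All simulation is on the log2 scale, matching post-normalization microarray
intensities. Signature genes are forced onto every platform so that a planted
intersection is recoverable by construction; effect directions are split
50% up / 50% down, fixed by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from endosig.preprocess import ExpressionStudy, harmonized_gene_key

CONTROL_GROUP = "control"
EXPOSED_GROUP = "exposed"


@dataclass
class SimulationConfig:
    """Parameters of the multi-study simulation.

    ``n_per_group`` may be one count for all studies or one count per study;
    the default (8, 6, 4) mirrors the group sizes of the three real studies.
    ``effect_size`` is the standardized mean shift in units of the
    within-group SD ``noise_sd``; ``probes_per_gene`` is an inclusive uniform
    range so multi-probe genes exercise the collapse step.
    """

    n_studies: int = 3
    genes_master: int = 2000
    universe_frac: float = 0.7
    probes_per_gene: tuple[int, int] = (1, 3)
    n_per_group: int | Sequence[int] = (8, 6, 4)
    signature_size: int = 100
    private_de_per_study: int = 150
    effect_size: float = 3.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    entrez_na_frac: float = 0.05
    seed: int = 0

    def per_study_n(self) -> list[int]:
        if isinstance(self.n_per_group, int):
            return [self.n_per_group] * self.n_studies
        ns = list(self.n_per_group)
        if len(ns) != self.n_studies:
            raise ValueError(
                f"n_per_group has {len(ns)} entries for {self.n_studies} studies"
            )
        return ns

    def validate(self) -> None:
        if self.n_studies < 1 or self.genes_master < 1 or self.signature_size < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 < self.universe_frac <= 1):
            raise ValueError("universe_frac must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 2 for n in self.per_study_n()):
            raise ValueError("each group needs >= 2 samples")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a positive inclusive range")
        universe_size = round(self.universe_frac * self.genes_master)
        if self.signature_size > universe_size:
            raise ValueError(
                f"infeasible config: signature_size={self.signature_size} exceeds the "
                f"per-study universe size round(universe_frac x genes_master)={universe_size}"
            )
        expected_intersection = self.genes_master * self.universe_frac**self.n_studies
        if self.signature_size > expected_intersection:
            raise ValueError(
                f"infeasible config: signature_size={self.signature_size} exceeds the "
                f"expected universe intersection genes_master x universe_frac^n_studies="
                f"{expected_intersection:.1f}"
            )
        if self.signature_size + self.private_de_per_study > universe_size:
            raise ValueError(
                "infeasible config: signature_size + private_de_per_study exceeds the "
                f"per-study universe size {universe_size}"
            )


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic studies."""

    signature_genes: set[str]
    per_study_private_de: dict[str, set[str]]
    per_study_universe: dict[str, set[str]]
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "signature_genes": sorted(self.signature_genes),
            "per_study_private_de": {
                k: sorted(v) for k, v in self.per_study_private_de.items()
            },
            "per_study_universe": {
                k: sorted(v) for k, v in self.per_study_universe.items()
            },
            "condition_effects": {
                g: dict(sorted(c.items())) for g, c in sorted(self.condition_effects.items())
            },
        }


def _master_gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    idx = np.arange(config.genes_master)
    symbols = [f"Gene{i:05d}" for i in idx]
    entrez = [str(100001 + i) for i in idx]
    na_mask = rng.random(config.genes_master) < config.entrez_na_frac
    entrez = ["NA" if na else e for e, na in zip(entrez, na_mask)]
    keys = [harmonized_gene_key(s, e) for s, e in zip(symbols, entrez)]
    return pd.DataFrame({"symbol": symbols, "entrez": entrez, "key": keys})


def generate_multistudy(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate ``n_studies`` two-group studies with a planted shared signature.

    Each study's gene universe is a seeded random subset of the master
    universe, forced to include every signature gene. Exposed-group samples of
    signature and study-private DE genes are shifted by
    ``effect_size x noise_sd`` on the log2 scale (direction fixed per gene by
    the seed); controls are unshifted. Identical seed and config reproduce the
    output exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    master = _master_gene_table(config, rng)
    universe_size = round(config.universe_frac * config.genes_master)

    sig_idx = rng.choice(config.genes_master, size=config.signature_size, replace=False)
    sig_set = set(sig_idx.tolist())
    # one direction per master gene, shared across studies (half up, half down)
    directions = np.where(rng.random(config.genes_master) < 0.5, 1.0, -1.0)

    studies: list[ExpressionStudy] = []
    per_study_private: dict[str, set[str]] = {}
    per_study_universe: dict[str, set[str]] = {}
    used_private: set[int] = set()
    group_ns = config.per_study_n()
    lo_p, hi_p = config.probes_per_gene

    for s in range(config.n_studies):
        study_id = f"study{s + 1}"
        n = group_ns[s]
        non_sig = np.array(sorted(set(range(config.genes_master)) - sig_set))
        extra = rng.choice(non_sig, size=universe_size - config.signature_size, replace=False)
        universe_idx = np.concatenate([sig_idx, extra])
        universe_idx.sort()

        # study-private DE genes: in this universe, outside the signature,
        # never reused by another study (keeps the planted intersection clean)
        candidates = np.array(
            sorted(set(extra.tolist()) - used_private), dtype=int
        )
        private = rng.choice(candidates, size=config.private_de_per_study, replace=False)
        used_private.update(private.tolist())
        private_set = set(private.tolist())

        n_probes = rng.integers(lo_p, hi_p + 1, size=universe_idx.size)
        probe_gene = np.repeat(universe_idx, n_probes)
        probe_rep = np.concatenate([np.arange(k) for k in n_probes])
        probe_ids = [
            f"{study_id}:{master['symbol'][g]}:p{r + 1}"
            for g, r in zip(probe_gene, probe_rep)
        ]

        samples = [f"{study_id}_s{i + 1:02d}" for i in range(2 * n)]
        groups = {
            smp: (CONTROL_GROUP if i < n else EXPOSED_GROUP)
            for i, smp in enumerate(samples)
        }
        shift = config.effect_size * config.noise_sd
        is_de = np.isin(probe_gene, list(sig_set | private_set))
        gene_base = config.baseline_mean + rng.normal(0.0, 1.0, size=universe_idx.size)
        base_of = dict(zip(universe_idx.tolist(), gene_base))
        probe_base = np.array([base_of[g] for g in probe_gene]) + rng.normal(
            0.0, 0.25, size=len(probe_gene)
        )
        X = probe_base[:, None] + rng.normal(
            0.0, config.noise_sd, size=(len(probe_gene), 2 * n)
        )
        de_shift = np.where(is_de, shift * directions[probe_gene], 0.0)
        X[:, n:] += de_shift[:, None]

        matrix = pd.DataFrame(X, index=probe_ids, columns=samples)
        matrix.index.name = "feature_id"
        probe_map = {
            pid: (master["symbol"][g], master["entrez"][g])
            for pid, g in zip(probe_ids, probe_gene)
        }
        studies.append(
            ExpressionStudy(study_id=study_id, matrix=matrix, groups=groups, probe_map=probe_map)
        )
        per_study_private[study_id] = {master["key"][g] for g in private_set}
        per_study_universe[study_id] = {master["key"][g] for g in universe_idx}

    truth = GroundTruth(
        signature_genes={master["key"][g] for g in sig_set},
        per_study_private_de=per_study_private,
        per_study_universe=per_study_universe,
    )
    return studies, truth


def _gene_symbol_entrez(gene_id: str) -> tuple[str, str]:
    """Invert a harmonized key (or accept a bare symbol) for probe-map output."""
    if gene_id.startswith("entrez:"):
        return f"E{gene_id[7:]}", gene_id[7:]
    if gene_id.startswith("sym:"):
        return gene_id[4:], "NA"
    return gene_id, "NA"


def generate_multicondition(
    signature: Iterable[str],
    groups: Sequence[tuple[str, int]],
    effects: Mapping[str, float] | Mapping[str, Mapping[str, float]],
    seed: int,
    n_background: int = 1900,
    noise_sd: float = 0.5,
    baseline_mean: float = 8.0,
    sign_mode: str = "random",
    study_id: str = "multi",
    effects_out: dict | None = None,
) -> ExpressionStudy:
    """Generate one multi-group exposure study (e.g. air/LPS/smoke/LPS+smoke).

    Signature genes carry condition-specific log2 shifts; non-signature
    background genes have no group structure. ``effects`` maps each condition
    label either to a scalar shift magnitude or to an explicit per-gene shift
    table. With the default ``sign_mode="random"`` a scalar magnitude gets an
    independent +/- sign per (gene, condition), so conditions sharing a
    magnitude still have distinct expression centroids (distinct per-gene
    fold-change patterns per exposure); ``sign_mode="fixed"`` applies the
    scalar uniformly. ``effects_out``, if given, is filled with the realized
    gene -> condition -> shift map.
    """
    signature = sorted(set(signature))
    if not signature:
        raise ValueError("signature must be non-empty")
    labels = [g for g, _ in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels in {labels}")
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if sign_mode not in {"random", "fixed"}:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")

    rng = np.random.default_rng(seed)
    background = [f"sym:Bg{i:05d}" for i in range(n_background)]
    genes = signature + background
    n_sig = len(signature)

    # realized per-gene, per-condition shifts on signature genes
    realized: dict[str, dict[str, float]] = {g: {} for g in signature}
    for label in labels:
        spec = effects.get(label, 0.0)
        if isinstance(spec, Mapping):
            for g in signature:
                realized[g][label] = float(spec.get(g, 0.0))
        else:
            mag = float(spec)
            if sign_mode == "random":
                signs = np.where(rng.random(n_sig) < 0.5, 1.0, -1.0)
            else:
                signs = np.ones(n_sig)
            for g, sgn in zip(signature, signs):
                realized[g][label] = mag * sgn

    samples: list[str] = []
    sample_groups: dict[str, str] = {}
    for label, n in groups:
        for i in range(n):
            sid = f"{study_id}_s{len(samples) + 1:02d}"
            samples.append(sid)
            sample_groups[sid] = label

    gene_base = baseline_mean + rng.normal(0.0, 1.0, size=len(genes))
    X = gene_base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    for j, sid in enumerate(samples):
        label = sample_groups[sid]
        for i, g in enumerate(signature):
            X[i, j] += realized[g][label]

    probe_ids = [f"{study_id}:{g}:p1" for g in genes]
    matrix = pd.DataFrame(X, index=probe_ids, columns=samples)
    matrix.index.name = "feature_id"
    probe_map = {
        pid: _gene_symbol_entrez(g) for pid, g in zip(probe_ids, genes)
    }
    if effects_out is not None:
        effects_out.update(realized)
    return ExpressionStudy(
        study_id=study_id, matrix=matrix, groups=sample_groups, probe_map=probe_map
    )


def generate_pathway_db(
    universe: Iterable[str],
    n_pathways: int,
    size_range: tuple[int, int],
    planted: Sequence[tuple[str, Iterable[str], float]] = (),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Build a synthetic GMT collection over ``universe``.

    ``n_pathways`` random gene sets with sizes uniform in the inclusive
    ``size_range`` are drawn from the universe; each ``planted`` entry
    ``(name, source_genes, overlap_frac)`` adds a pathway of the source set's
    size sharing ``overlap_frac`` of its members with the source set, the
    remainder drawn outside it.
    """
    universe = sorted(set(universe))
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must be a positive inclusive range")
    if hi > len(universe):
        raise ValueError("pathway sizes exceed universe size")
    rng = np.random.default_rng(seed)
    collection: dict[str, list[str]] = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection[f"RAND_{i + 1:03d}"] = sorted(members.tolist())
    for name, source, frac in planted:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"overlap_frac must be in [0, 1], got {frac}")
        source = sorted(set(source) & set(universe))
        if not source:
            raise ValueError(f"planted pathway {name!r}: source set disjoint from universe")
        size = len(source)
        k_in = round(frac * size)
        inside = rng.choice(source, size=k_in, replace=False).tolist()
        outside_pool = sorted(set(universe) - set(source))
        if size - k_in > len(outside_pool):
            raise ValueError(f"planted pathway {name!r}: not enough genes outside source")
        outside = rng.choice(outside_pool, size=size - k_in, replace=False).tolist()
        collection[name] = sorted(inside + outside)
    return collection
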