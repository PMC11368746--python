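"""Synthetic two-sample GWAS summary statistics with a known causal DAG.

The generator emulates the inputs of a summary-statistics Mendelian
randomization study: a universe of traits partitioned into immune-cell,
immune-protein and sarcopenia (outcome) classes, a sparse directed acyclic
graph of true causal effects among them, and per-trait GWAS summary tables.

The simulation is purely at summary level.  Each trait owns ``m_snps``
instruments with direct per-SNP effects drawn ``N(0, h2/m_snps)`` and
oriented so the effect allele is the trait-increasing allele.  The true
marginal effect of a SNP on any trait follows path algebra over the DAG: for
direct-effect matrix ``A`` (``A[i, j]`` = effect of trait i on trait j), the
total-effect matrix is ``(I - A)^{-1}``, i.e. the sum over all directed
paths of the products of edge effects.  Observed effects add independent
noise per trait (the two-sample regime), with standard errors from the
standard GWAS approximation ``se = 1 / sqrt(2 * eaf * (1 - eaf) * n)``.

Horizontal pleiotropy (balanced or directional), gross outlier instruments,
and deliberately shared cross-trait instruments are all configurable, so
every downstream filtering and sensitivity stage can be exercised against
ground truth.

Reproducibility: every random quantity is drawn from a stream keyed by the
master seed plus stable indices (one stream per trait for its instrument
definitions, one stream per ordered trait pair for observation noise), so
the same seed yields byte-identical output and adding a trait at the end of
the registry never perturbs the draws of existing traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml
from scipy import stats

from .sumstats_io import (
    SummaryRecord,
    TraitMeta,
    write_registry,
    write_sumstats,
)

__all__ = [
    "TrueCausalGraph",
    "GenArchitecture",
    "simulate_universe",
    "default_scenario",
    "true_effect_pairs",
    "write_universe",
    "scenario_from_yaml",
    "scenario_to_yaml",
    "DEFAULT_EDGE_CLASS_CENSUS",
]

_PMIN = 1e-300  # keep p-values strictly inside (0, 1]

_ALLELE_PAIRS = [  # non-palindromic pairs preferred; a few palindromes kept in
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
    ("A", "T"), ("C", "G"),  # palindromic, exercised by harmonization
]


@dataclass(frozen=True)
class TrueCausalGraph:
    """Ground-truth causal structure: traits plus signed direct effects."""

    traits: list[TraitMeta]
    edges: list[tuple[str, str, float]]  # (source, target, true effect)

    def __post_init__(self) -> None:
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trait_id in graph")
        known = set(ids)
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for s, t, theta in self.edges:
            if s == t:
                raise ValueError(f"self-loop on {s!r}")
            if s not in known or t not in known:
                raise ValueError(f"edge ({s}, {t}) references unknown trait")
            g.add_edge(s, t, theta=theta)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("causal graph must be acyclic")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t in self.traits:
            g.add_node(t.trait_id, trait_class=t.trait_class)
        for s, t, theta in self.edges:
            g.add_edge(s, t, theta=theta)
        return g

    def direct_effect_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        idx = {t.trait_id: i for i, t in enumerate(self.traits)}
        A = np.zeros((len(idx), len(idx)))
        for s, t, theta in self.edges:
            A[idx[s], idx[t]] = theta
        return A, idx

    def total_effect_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        """Sum over directed paths of edge-effect products; diagonal = 1."""
        A, idx = self.direct_effect_matrix()
        T = np.linalg.inv(np.eye(len(idx)) - A)
        return T, idx


@dataclass(frozen=True)
class GenArchitecture:
    """Simulation controls for one universe.

    ``h2`` is the variance explained jointly by a trait's own instruments;
    individual instrument effects have second moment ``h2 / m_snps``.
    ``pleiotropy_frac`` of each trait's instruments gain a direct effect on
    one randomly chosen other trait (a descendant when one exists), drawn
    with mean zero (``balanced``) or positive mean (``directional``); the
    pleiotropic effects have scale ``pleiotropy_scale`` relative to the
    typical instrument effect ``sqrt(h2 / m_snps)`` (0.3 by default —
    moderate contamination, the regime where pleiotropy-robust estimators
    are expected to help).  ``outlier_frac`` gain a direct effect ten times
    the typical instrument scale.  ``n_shared_snps`` variants instrument two
    traits at once, the device that exercises the more-than-one-trait filter.
    """

    m_snps: int = 40
    h2: float = 0.25
    n_gwas: int = 200_000
    pleiotropy_frac: float = 0.0
    pleiotropy_mode: str = "balanced"  # balanced | directional
    pleiotropy_scale: float = 0.3
    outlier_frac: float = 0.0
    n_shared_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if not 0.0 <= self.outlier_frac <= 1.0:
            raise ValueError("outlier_frac must lie in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError("pleiotropy_mode must be 'balanced' or 'directional'")


def _choose_target(
    rng: np.random.Generator, host: str, descendants: Sequence[str], others: Sequence[str]
) -> str | None:
    """Pleiotropy/outlier target: a random descendant if any, else any other trait."""
    pool = list(descendants) if len(descendants) else list(others)
    if not pool:
        return None
    return pool[int(rng.integers(len(pool)))]


def simulate_universe(
    graph: TrueCausalGraph, arch: GenArchitecture
) -> tuple[dict[str, TraitMeta], dict[str, list[SummaryRecord]]]:
    """Generate per-trait summary statistics for every variant in the universe.

    Returns ``(registry, sumstats)`` where ``sumstats[trait_id]`` holds one
    :class:`SummaryRecord` per panel variant (all traits report the full
    panel, as real GWAS do), in a deterministic panel order.
    """
    traits = graph.traits
    n_traits = len(traits)
    if n_traits == 0:
        raise ValueError("graph has no traits")
    Ttot, idx = graph.total_effect_matrix()
    gnx = graph.to_networkx()
    scale = float(np.sqrt(arch.h2 / arch.m_snps))

    # --- variant panel with direct-effect vectors --------------------------
    vids: list[str] = []
    eafs: list[float] = []
    alleles: list[tuple[str, str]] = []
    direct: list[np.ndarray] = []

    for t_i, trait in enumerate(traits):
        rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 11, t_i]))
        gamma = np.abs(rng.normal(0.0, scale, arch.m_snps))
        eaf_t = rng.uniform(0.05, 0.95, arch.m_snps)
        pair_ix = rng.integers(0, len(_ALLELE_PAIRS), arch.m_snps)
        n_pleio = int(round(arch.pleiotropy_frac * arch.m_snps))
        n_out = int(round(arch.outlier_frac * arch.m_snps))
        special = rng.choice(arch.m_snps, size=min(arch.m_snps, n_pleio + n_out), replace=False)
        pleio_ix = set(special[:n_pleio].tolist())
        out_ix = set(special[n_pleio:n_pleio + n_out].tolist())
        desc = sorted(nx.descendants(gnx, trait.trait_id))
        others = sorted(set(idx) - {trait.trait_id})
        p_scale = arch.pleiotropy_scale * scale
        mu = p_scale if arch.pleiotropy_mode == "directional" else 0.0
        for j in range(arch.m_snps):
            d = np.zeros(n_traits)
            d[t_i] = gamma[j]
            if j in pleio_ix:
                target = _choose_target(rng, trait.trait_id, desc, others)
                if target is not None:
                    d[idx[target]] += rng.normal(mu, p_scale)
            if j in out_ix:
                target = _choose_target(rng, trait.trait_id, desc, others)
                if target is not None:
                    d[idx[target]] += float(rng.choice([-1.0, 1.0])) * 10.0 * scale
            vids.append(f"rs_{trait.trait_id}_{j:04d}")
            eafs.append(float(eaf_t[j]))
            alleles.append(_ALLELE_PAIRS[int(pair_ix[j])])
            direct.append(d)

    if arch.n_shared_snps > 0 and n_traits >= 2:
        rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 13]))
        for k in range(arch.n_shared_snps):
            hosts = rng.choice(n_traits, size=2, replace=False)
            d = np.zeros(n_traits)
            for h in hosts:
                d[h] = abs(rng.normal(0.0, scale)) + 2.0 * scale  # strong in both
            vids.append(f"rs_shared_{k:04d}")
            eafs.append(float(rng.uniform(0.05, 0.95)))
            alleles.append(_ALLELE_PAIRS[int(rng.integers(0, 8))])  # non-palindromic
            direct.append(d)

    n_var = len(vids)
    D = np.vstack(direct)                       # (variants, traits) direct effects
    B_true = D @ Ttot                           # marginal effects via path algebra
    eaf_arr = np.asarray(eafs)
    se = 1.0 / np.sqrt(2.0 * eaf_arr * (1.0 - eaf_arr) * arch.n_gwas)

    # panel coordinates: consecutive panel variants 25 Mb apart, cycling chroms
    chroms = [str(k % 22 + 1) for k in range(n_var)]
    poss = [1 + (k // 22) * 25_000_000 for k in range(n_var)]

    # block boundaries of each source trait's variants, for per-(u, t) noise
    blocks = [(t_i * arch.m_snps, (t_i + 1) * arch.m_snps) for t_i in range(n_traits)]
    shared_lo = n_traits * arch.m_snps

    registry = {t.trait_id: t for t in traits}
    sumstats: dict[str, list[SummaryRecord]] = {}
    for u_i, trait in enumerate(traits):
        noise = np.empty(n_var)
        for t_i, (lo, hi) in enumerate(blocks):
            rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 17, u_i, t_i]))
            noise[lo:hi] = rng.normal(0.0, 1.0, hi - lo)
        if n_var > shared_lo:
            rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 17, u_i, n_traits]))
            noise[shared_lo:] = rng.normal(0.0, 1.0, n_var - shared_lo)
        beta_obs = B_true[:, u_i] + noise * se
        z = beta_obs / se
        pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), _PMIN, 1.0)
        sumstats[trait.trait_id] = [
            SummaryRecord(
                variant_id=vids[k],
                chrom=chroms[k],
                pos=poss[k],
                effect_allele=alleles[k][0],
                other_allele=alleles[k][1],
                eaf=float(eaf_arr[k]),
                beta=float(beta_obs[k]),
                se=float(se[k]),
                pval=float(pval[k]),
                n=arch.n_gwas,
            )
            for k in range(n_var)
        ]
    return registry, sumstats


# --------------------------------------------------------------------------
# Default scenario: a three-layer universe (cells -> proteins -> outcomes,
# with reverse-causation edges) at a desk-scale analogue of the study design.
# --------------------------------------------------------------------------

#: Edge-class census of :func:`default_scenario`, mirrored in docs/methods.md.
DEFAULT_EDGE_CLASS_CENSUS = {
    "cell->sarcopenia": 3,
    "protein->sarcopenia": 3,
    "cell->protein": 4,
    "sarcopenia->cell": 2,
}

_DEFAULT_EDGES: list[tuple[str, str, float]] = [
    # immune cell -> sarcopenia outcome
    ("cell_01", "grip_strength", 0.30),
    ("cell_02", "walk_pace", 0.25),
    ("cell_03", "grip_strength", -0.35),
    # immune protein -> sarcopenia outcome
    ("prot_01", "grip_strength", 0.35),
    ("prot_02", "walk_pace", -0.30),
    ("prot_03", "walk_pace", 0.20),
    # immune cell -> immune protein
    ("cell_04", "prot_01", 0.30),
    ("cell_05", "prot_02", -0.25),
    ("cell_06", "prot_03", 0.30),
    ("cell_07", "prot_04", 0.20),
    # reverse causation: sarcopenia outcome -> immune cell
    ("grip_strength", "cell_08", 0.25),
    ("walk_pace", "cell_09", -0.20),
]


def default_scenario(seed: int = 0) -> tuple[TrueCausalGraph, GenArchitecture]:
    """The documented desk-scale study scenario.

    20 immune-cell traits, 8 immune-protein traits and 2 sarcopenia outcome
    traits, connected by 12 true edges spanning all four edge classes
    (:data:`DEFAULT_EDGE_CLASS_CENSUS`), with effect magnitudes in
    [0.15, 0.4].  Architecture: 40 instruments per trait, h2 = 0.25,
    n = 200,000 per GWAS, 5% balanced pleiotropy, 2% gross outliers, and
    five deliberately shared cross-trait instruments.
    """
    traits = (
        [TraitMeta(f"cell_{i:02d}", "cell", label=f"immune cell phenotype {i}") for i in range(1, 21)]
        + [TraitMeta(f"prot_{i:02d}", "protein", label=f"immune protein {i}") for i in range(1, 9)]
        + [
            TraitMeta("grip_strength", "sarcopenia", label="hand grip strength"),
            TraitMeta("walk_pace", "sarcopenia", label="usual walking pace"),
        ]
    )
    graph = TrueCausalGraph(traits=traits, edges=list(_DEFAULT_EDGES))
    arch = GenArchitecture(
        m_snps=40,
        h2=0.25,
        n_gwas=200_000,
        pleiotropy_frac=0.05,
        pleiotropy_mode="balanced",
        outlier_frac=0.02,
        n_shared_snps=5,
        seed=seed,
    )
    return graph, arch


def true_effect_pairs(
    graph: TrueCausalGraph, tol: float = 1e-12
) -> dict[tuple[str, str], float]:
    """All ordered trait pairs with a nonzero *total* causal effect.

    MR estimates total (path-summed) effects, so an exposure upstream of a
    mediator truly causes the downstream trait even without a direct edge;
    evaluation against the generator must use this set, not the direct edges.
    """
    T, idx = graph.total_effect_matrix()
    rev = {i: t for t, i in idx.items()}
    out: dict[tuple[str, str], float] = {}
    for i in range(len(idx)):
        for j in range(len(idx)):
            if i != j and abs(T[i, j]) > tol:
                out[(rev[i], rev[j])] = float(T[i, j])
    return out


def write_universe(
    registry: Mapping[str, TraitMeta],
    sumstats: Mapping[str, Sequence[SummaryRecord]],
    out_dir: str | Path,
) -> Path:
    """Write per-trait TSVs plus the YAML registry; returns the registry path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    located = {}
    for trait_id, meta in registry.items():
        rel = f"{trait_id}.tsv"
        write_sumstats(sumstats[trait_id], out_dir / rel)
        located[trait_id] = TraitMeta(
            trait_id=meta.trait_id,
            trait_class=meta.trait_class,
            label=meta.label,
            binary=meta.binary,
            path=rel,
        )
    return write_registry(located, out_dir / "registry.yaml")


def scenario_from_yaml(path: str | Path) -> tuple[TrueCausalGraph, GenArchitecture]:
    """Load a scenario spec (traits, edges, architecture) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = [
        TraitMeta(
            trait_id=t["trait_id"],
            trait_class=t["trait_class"],
            label=t.get("label", t["trait_id"]),
            binary=bool(t.get("binary", False)),
        )
        for t in raw["traits"]
    ]
    edges = [(e["source"], e["target"], float(e["effect"])) for e in raw.get("edges", [])]
    arch = GenArchitecture(**raw.get("architecture", {}))
    return TrueCausalGraph(traits=traits, edges=edges), arch


def scenario_to_yaml(
    graph: TrueCausalGraph, arch: GenArchitecture, path: str | Path
) -> Path:
    path = Path(path)
    payload = {
        "traits": [
            {
                "trait_id": t.trait_id,
                "trait_class": t.trait_class,
                "label": t.label,
                "binary": t.binary,
            }
            for t in graph.traits
        ],
        "edges": [
            {"source": s, "target": t, "effect": theta} for s, t, theta in graph.edges
        ],
        "architecture": {
            "m_snps": arch.m_snps,
            "h2": arch.h2,
            "n_gwas": arch.n_gwas,
            "pleiotropy_frac": arch.pleiotropy_frac,
            "pleiotropy_mode": arch.pleiotropy_mode,
            "pleiotropy_scale": arch.pleiotropy_scale,
            "outlier_frac": arch.outlier_frac,
            "n_shared_snps": arch.n_shared_snps,
            "seed": arch.seed,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path
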