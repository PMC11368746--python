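"""Orchestration of the analysis groups, FDR adjustment and edge extraction.

The study design runs five analysis groups over a registry of immune-cell,
immune-protein and sarcopenia traits:

* ``A_forward``  — exposures: cells,     outcomes: sarcopenia traits;
* ``A_reverse``  — exposures: sarcopenia, outcomes: cells;
* ``B_forward``  — exposures: proteins,  outcomes: sarcopenia traits;
* ``B_reverse``  — exposures: sarcopenia, outcomes: proteins;
* ``C``          — cell/protein couples, both directions, restricted to
  couples whose two members are each significantly associated (main model,
  raw p) with the same sarcopenia trait.

For every exposure-outcome pair the six-step instrument filtration runs,
MR-PRESSO prunes outlier instruments, and all seven MR models plus the
sensitivity suite are fitted; pairs with too few surviving instruments are
recorded as skips with a reason code.  Benjamini-Hochberg adjustment is
applied per family (by default: all main-model p-values of one analysis
group for one outcome trait), and significant results become signed directed
edge candidates for the network stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .iv_selection import (
    FilterConfig,
    build_instrument_set,
    cross_trait_banned,
    pval_lookup,
    select_by_pvalue,
)
from .mr_estimators import METHODS, EstimatorConfig, fit_all_models
from .sensitivity import SensitivityResult, mr_presso, sensitivity_suite
from .sumstats_io import SummaryRecord, TraitMeta

__all__ = [
    "AnalysisGroupSpec",
    "GROUP_ORDER",
    "standard_groups",
    "enumerate_pairs",
    "group_c_pairs",
    "run_group",
    "bh_adjust",
    "apply_fdr",
    "extract_edges",
    "run_study",
    "StudyResult",
    "total_model_count",
]

logger = logging.getLogger(__name__)

GROUP_ORDER = ("A_forward", "A_reverse", "B_forward", "B_reverse", "C")

RESULT_COLUMNS = (
    "exposure", "outcome", "group", "method", "nsnp",
    "beta", "se", "ci_low", "ci_high", "pval", "fdr",
)


@dataclass(frozen=True)
class AnalysisGroupSpec:
    """One analysis group: which trait classes face each other, and thresholds."""

    group_id: str
    exposure_class: str
    outcome_class: str
    main_model: str = "RE_IVW"
    alpha: float = 0.05
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.group_id != "C" and self.exposure_class == self.outcome_class:
            raise ValueError("exposure and outcome class must differ outside group C")
        if self.main_model not in METHODS:
            raise ValueError(f"unknown main_model {self.main_model!r}")


def standard_groups(main_model: str = "RE_IVW") -> dict[str, AnalysisGroupSpec]:
    """The five analysis groups of the study design, in running order."""
    defs = {
        "A_forward": ("cell", "sarcopenia"),
        "A_reverse": ("sarcopenia", "cell"),
        "B_forward": ("protein", "sarcopenia"),
        "B_reverse": ("sarcopenia", "protein"),
        "C": ("cell", "protein"),
    }
    return {
        gid: AnalysisGroupSpec(gid, exp, out, main_model=main_model)
        for gid, (exp, out) in defs.items()
    }


def _by_class(registry: Mapping[str, TraitMeta], cls: str) -> list[str]:
    return [tid for tid, t in registry.items() if t.trait_class == cls]


def enumerate_pairs(
    registry: Mapping[str, TraitMeta],
    spec: AnalysisGroupSpec,
    couples: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Exposure-outcome pairs for one group.

    Groups A/B take the full cross product of their classes (registry
    order).  Group C takes the supplied cell/protein couples and runs each
    in both directions; see :func:`group_c_pairs`.
    """
    if spec.group_id == "C":
        if couples is None:
            raise ValueError("group C requires the significant cell/protein couples")
        pairs: list[tuple[str, str]] = []
        for cell, prot in couples:
            pairs.append((cell, prot))
            pairs.append((prot, cell))
        return pairs
    exposures = _by_class(registry, spec.exposure_class)
    outcomes = _by_class(registry, spec.outcome_class)
    if not exposures:
        raise ValueError(f"no traits of class {spec.exposure_class!r} in registry")
    if not outcomes:
        raise ValueError(f"no traits of class {spec.outcome_class!r} in registry")
    return [(e, o) for e in exposures for o in outcomes]


def group_c_pairs(
    registry: Mapping[str, TraitMeta],
    results: pd.DataFrame,
    alpha: float = 0.05,
    main_model: str = "RE_IVW",
) -> list[tuple[str, str]]:
    """Cell/protein couples eligible for group C.

    A couple (cell, protein) qualifies when both members hold a main-model
    significant association (raw p < alpha, either direction) with the same
    sarcopenia trait in the group A/B results.
    """
    main = results[(results["method"] == main_model) & (results["pval"] < alpha)]
    sarco = set(_by_class(registry, "sarcopenia"))
    hits: dict[str, set[str]] = {}  # sarcopenia trait -> significant immune traits
    for row in main.itertuples(index=False):
        if row.outcome in sarco and row.exposure not in sarco:
            hits.setdefault(row.outcome, set()).add(row.exposure)
        elif row.exposure in sarco and row.outcome not in sarco:
            hits.setdefault(row.exposure, set()).add(row.outcome)
    cells = set(_by_class(registry, "cell"))
    prots = set(_by_class(registry, "protein"))
    couples: set[tuple[str, str]] = set()
    for immune in hits.values():
        for c in immune & cells:
            for p in immune & prots:
                couples.add((c, p))
    return sorted(couples)


def _derived_seed(master: int, *idx: int) -> int:
    return int(np.random.SeedSequence([master, *idx]).generate_state(1)[0] & 0x7FFFFFFF)


def run_group(
    spec: AnalysisGroupSpec,
    registry: Mapping[str, TraitMeta],
    sumstats: Mapping[str, Sequence[SummaryRecord]],
    filter_config: FilterConfig = FilterConfig(),
    estimator_config: EstimatorConfig = EstimatorConfig(),
    presso_sims: int = 1000,
    presso_alpha: float = 0.05,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict], pd.DataFrame]:
    """Run every pair of one analysis group.

    Returns ``(results, sensitivity, skips, provenance)``: a long-format
    MR-result table (one row per pair and model), the sensitivity table, the
    skip records (reason-coded), and per-step instrument counts per pair.
    """
    if pairs is None:
        pairs = enumerate_pairs(registry, spec)
    g_i = GROUP_ORDER.index(spec.group_id) if spec.group_id in GROUP_ORDER else 99
    logger.info("group %s: %d pairs", spec.group_id, len(pairs))

    # Group-level precomputation: cross-trait ban set over this group's
    # exposures, confounder lookups over the registry's confounder traits.
    exposure_ids = sorted({e for e, _ in pairs})
    selected = {
        e: select_by_pvalue(sumstats[e], filter_config.p_instrument)
        for e in exposure_ids
    }
    exposure_pv = {e: pval_lookup(sumstats[e]) for e in exposure_ids}
    banned = (
        cross_trait_banned(selected, exposure_pv, filter_config.cross_trait_threshold)
        if len(exposure_ids) > 1
        else set()
    )
    confounder_pv = [
        pval_lookup(sumstats[tid]) for tid in _by_class(registry, "confounder")
        if tid in sumstats
    ]

    res_rows: list[dict] = []
    sens_rows: list[dict] = []
    skips: list[dict] = []
    prov_rows: list[dict] = []

    for p_i, (exp_id, out_id) in enumerate(pairs):
        iset = build_instrument_set(
            exp_id,
            out_id,
            sumstats[exp_id],
            sumstats[out_id],
            filter_config,
            banned_cross_trait=banned,
            confounder_pvals=confounder_pv,
        )
        presso_res: SensitivityResult | None = None
        if iset.n_snp >= 4:
            presso_res, iset = mr_presso(
                iset,
                sims=presso_sims,
                outlier_alpha=presso_alpha,
                seed=_derived_seed(seed, g_i, p_i, 1),
            )
        prov_rows.append(
            {"exposure": exp_id, "outcome": out_id, "group": spec.group_id,
             **iset.provenance}
        )
        if iset.n_snp < filter_config.min_ivs:
            logger.debug("%s -> %s: skipped (%d IVs)", exp_id, out_id, iset.n_snp)
            skips.append(
                {"exposure": exp_id, "outcome": out_id, "group": spec.group_id,
                 "reason": "insufficient_ivs", "n_snp": iset.n_snp}
            )
            continue
        logger.debug("%s -> %s: %d IVs", exp_id, out_id, iset.n_snp)

        cfg = replace(estimator_config, seed=_derived_seed(seed, g_i, p_i, 2))
        models = fit_all_models(iset, cfg)
        egger_res = next(m for m in models if m.method == "EGGER")
        re_res = next(m for m in models if m.method == "RE_IVW")
        sens = sensitivity_suite(iset, egger_res, re_res.beta, presso_res)

        for m in models:
            res_rows.append(
                {"exposure": exp_id, "outcome": out_id, "group": spec.group_id,
                 "method": m.method, "nsnp": m.n_snp, "beta": m.beta, "se": m.se,
                 "ci_low": m.ci_low, "ci_high": m.ci_high, "pval": m.pval,
                 "fdr": np.nan}
            )
        sens_rows.append(
            {"exposure": exp_id, "outcome": out_id, "group": spec.group_id,
             "Q": sens.Q, "Q_df": sens.Q_df, "Q_pval": sens.Q_pval,
             "egger_intercept": sens.egger_intercept,
             "intercept_se": sens.intercept_se,
             "intercept_pval": sens.intercept_pval,
             "presso_global_pval": sens.presso_global_pval,
             "n_outliers": len(sens.presso_outliers),
             "outlier_ids": ";".join(sens.presso_outliers),
             "presso_sims": sens.presso_sims}
        )

    results = pd.DataFrame(res_rows, columns=list(RESULT_COLUMNS))
    sensitivity = pd.DataFrame(sens_rows)
    provenance = pd.DataFrame(prov_rows)
    return results, sensitivity, skips, provenance


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    ``adj_i = min_{k >= i} p_(k) * m / k`` on the sorted p-values, capped at
    1.  Inputs must lie in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(
    results: pd.DataFrame, family: str = "per_outcome"
) -> pd.DataFrame:
    """Fill the ``fdr`` column, adjusting within the chosen family.

    ``per_outcome`` (default): one family per (group, method, outcome);
    ``per_group``: per (group, method); ``global``: per method across all
    groups.  Adjusting within method keeps the seven models' corrections
    independent, as each model's result set is reported separately.
    """
    keymap = {
        "per_outcome": ["group", "method", "outcome"],
        "per_group": ["group", "method"],
        "global": ["method"],
    }
    if family not in keymap:
        raise ValueError(f"unknown FDR family {family!r}")
    out = results.copy()
    if not len(out):
        return out
    for _, idx in out.groupby(keymap[family], sort=False).groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "pval"])
    return out


def extract_edges(
    results: pd.DataFrame,
    threshold_kind: str = "pval",
    main_model: str = "RE_IVW",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant main-model results as signed directed edge candidates."""
    if threshold_kind not in ("pval", "fdr"):
        raise ValueError("threshold_kind must be 'pval' or 'fdr'")
    main = results[results["method"] == main_model]
    if threshold_kind == "fdr" and main["fdr"].isna().any():
        raise ValueError("FDR not computed; call apply_fdr first")
    sig = main[main[threshold_kind] < alpha]
    edges = pd.DataFrame(
        {
            "source": sig["exposure"].to_numpy(),
            "target": sig["outcome"].to_numpy(),
            "group": sig["group"].to_numpy(),
            "beta": sig["beta"].to_numpy(),
            "se": sig["se"].to_numpy(),
            "pval": sig["pval"].to_numpy(),
            "fdr": sig["fdr"].to_numpy(),
            "nsnp": sig["nsnp"].to_numpy(),
        }
    )
    edges["sign"] = np.where(edges["beta"] >= 0, "+", "-")
    return edges.reset_index(drop=True)


@dataclass
class StudyResult:
    """Everything one full study run produces, prior to network assembly."""

    results: pd.DataFrame
    sensitivity: pd.DataFrame
    skips: list[dict] = field(default_factory=list)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    couples: list[tuple[str, str]] = field(default_factory=list)

    def edges(self, threshold_kind: str = "pval", main_model: str = "RE_IVW",
              alpha: float = 0.05) -> pd.DataFrame:
        return extract_edges(self.results, threshold_kind, main_model, alpha)


def run_study(
    registry: Mapping[str, TraitMeta],
    sumstats: Mapping[str, Sequence[SummaryRecord]],
    filter_config: FilterConfig = FilterConfig(),
    estimator_config: EstimatorConfig = EstimatorConfig(),
    main_model: str = "RE_IVW",
    fdr_family: str = "per_outcome",
    presso_sims: int = 1000,
    presso_alpha: float = 0.05,
    seed: int = 0,
) -> StudyResult:
    """Run the full five-group design and apply the B-H correction.

    Groups run in the design order; group C's pair list is derived from the
    main-model raw-p significant results of groups A and B.
    """
    groups = standard_groups(main_model)
    all_results: list[pd.DataFrame] = []
    all_sens: list[pd.DataFrame] = []
    all_skips: list[dict] = []
    all_prov: list[pd.DataFrame] = []

    for gid in ("A_forward", "A_reverse", "B_forward", "B_reverse"):
        res, sens, skips, prov = run_group(
            groups[gid], registry, sumstats, filter_config, estimator_config,
            presso_sims, presso_alpha, seed,
        )
        all_results.append(res)
        all_sens.append(sens)
        all_skips.extend(skips)
        all_prov.append(prov)

    ab_results = pd.concat(all_results, ignore_index=True)
    couples = group_c_pairs(registry, ab_results, groups["C"].alpha, main_model)
    if couples:
        pairs = enumerate_pairs(registry, groups["C"], couples)
        res, sens, skips, prov = run_group(
            groups["C"], registry, sumstats, filter_config, estimator_config,
            presso_sims, presso_alpha, seed, pairs=pairs,
        )
        all_results.append(res)
        all_sens.append(sens)
        all_skips.extend(skips)
        all_prov.append(prov)

    results = pd.concat(all_results, ignore_index=True)
    results = apply_fdr(results, fdr_family)
    sensitivity = pd.concat([s for s in all_sens if len(s)], ignore_index=True) \
        if any(len(s) for s in all_sens) else pd.DataFrame()
    provenance = pd.concat(all_prov, ignore_index=True) if all_prov else pd.DataFrame()
    return StudyResult(
        results=results,
        sensitivity=sensitivity,
        skips=all_skips,
        provenance=provenance,
        couples=couples,
    )


def total_model_count(
    analysis_counts: Iterable[int], models_per_analysis: int = 7
) -> int:
    """Total fitted models implied by per-group analysis counts (design arithmetic)."""
    return sum(int(c) for c in analysis_counts) * models_per_analysis
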