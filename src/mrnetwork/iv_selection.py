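"""Six-step instrument filtration, harmonization, and instrument strength.

The filtration pipeline mirrors strict instrumental-variable selection for
two-sample MR:

1. keep variants associated with the exposure at ``p < p_instrument``
   (default 5e-6);
2. clump to approximate independence (greedy by ascending p within an LD or
   distance window);
3. drop variants instrumenting more than one exposure trait of the same
   analysis group;
4. drop variants associated with any screened confounder trait;
5. drop variants associated with the outcome at genome-wide significance;
6. harmonize exposure and outcome records (allele swaps, strand flips,
   frequency-orientation of palindromes), dropping what cannot be aligned.

MR-PRESSO outlier exclusion (the sensitivity module) runs downstream of
these six steps.  Every step counts its removals into the instrument set's
provenance, so initial = final + sum of per-step drops always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import SummaryRecord

__all__ = [
    "FilterConfig",
    "InstrumentSet",
    "select_by_pvalue",
    "clump",
    "cross_trait_banned",
    "drop_cross_trait",
    "drop_confounder_associated",
    "drop_outcome_associated",
    "harmonize",
    "instrument_strength",
    "build_instrument_set",
    "pval_lookup",
    "read_ld_table",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ROW_COLUMNS = (
    "variant_id", "b_X", "se_X", "pval_X", "b_Y", "se_Y", "pval_Y",
    "eaf", "n_X", "n_Y",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the six filtration steps.

    Only ``p_instrument`` is dictated by the study design (5e-6); the
    remaining thresholds follow common MR practice and are configurable.
    ``palindromic_eaf_window`` w drops palindromes with an allele frequency
    in [0.5 - w, 0.5 + w] on either side, where strand cannot be inferred.
    """

    p_instrument: float = 5e-6
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    p_cross_trait: float | None = None  # default: same as p_instrument
    p_confounder: float = 1e-5
    p_outcome: float = 5e-8
    palindromic_eaf_window: float = 0.08
    min_ivs: int = 3

    def __post_init__(self) -> None:
        for name in ("p_instrument", "clump_r2", "p_confounder", "p_outcome"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p_cross_trait is not None and not 0.0 < self.p_cross_trait < 1.0:
            raise ValueError("p_cross_trait must lie in (0, 1)")
        if self.min_ivs < 2:
            raise ValueError("min_ivs must be >= 2")

    @property
    def cross_trait_threshold(self) -> float:
        return self.p_instrument if self.p_cross_trait is None else self.p_cross_trait


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome instrument rows plus filtration provenance.

    ``rows`` carries one harmonized variant per row with exposure effect
    ``b_X`` (se ``se_X``), outcome effect ``b_Y`` oriented to the exposure's
    effect allele (se ``se_Y``), the exposure effect-allele frequency, and
    per-IV variance explained ``R2`` and strength ``F``.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows):
            if self.rows["variant_id"].duplicated().any():
                raise ValueError("duplicate variant_id in instrument set")
            if (self.rows["se_X"] <= 0).any() or (self.rows["se_Y"] <= 0).any():
                raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.rows)

    def check_provenance(self) -> bool:
        """initial count == final count + sum of per-step drops."""
        p = self.provenance
        drops = sum(v for k, v in p.items() if k not in ("initial", "final"))
        return p.get("initial", 0) == p.get("final", self.n_snp) + drops


def pval_lookup(records: Iterable[SummaryRecord]) -> dict[str, float]:
    """variant_id -> pval map (first occurrence wins)."""
    out: dict[str, float] = {}
    for r in records:
        out.setdefault(r.variant_id, r.pval)
    return out


def select_by_pvalue(
    records: Sequence[SummaryRecord], p_instrument: float = 5e-6
) -> list[SummaryRecord]:
    """Step 1: keep variants with exposure p < p_instrument, order preserved."""
    return [r for r in records if r.pval < p_instrument]


def read_ld_table(path: str | Path) -> dict[frozenset, float]:
    """Load a 3-column TSV (variant_a, variant_b, r2) into a pair lookup."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return {
        frozenset((str(a), str(b))): float(r)
        for a, b, r in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    }


def clump(
    records: Sequence[SummaryRecord],
    ld: Mapping[frozenset, float] | None = None,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
) -> list[SummaryRecord]:
    """Step 2: greedy p-value clumping within ``clump_kb`` kilobase windows.

    Variants are visited by ascending p-value (stable in input order); a
    variant is kept iff its r² with every already-kept variant within the
    window on the same chromosome is below ``clump_r2``.  Without an LD
    lookup, same-window variants are treated as r² = 1 (pure distance
    clumping) and distant pairs as r² = 0.
    """
    if not records:
        return []
    if any(r.chrom is None or r.pos is None for r in records):
        raise ValueError("clumping requires chrom and pos on every record")
    window = clump_kb * 1000
    order = sorted(range(len(records)), key=lambda i: (records[i].pval, i))
    kept: list[int] = []
    for i in order:
        ri = records[i]
        ok = True
        for j in kept:
            rj = records[j]
            if ri.chrom != rj.chrom or abs(ri.pos - rj.pos) > window:
                continue
            if ld is None:
                r2 = 1.0
            else:
                r2 = ld.get(frozenset((ri.variant_id, rj.variant_id)), 0.0)
            if r2 >= clump_r2:
                ok = False
                break
        if ok:
            kept.append(i)
    kept.sort()  # restore input order
    return [records[i] for i in kept]


def cross_trait_banned(
    selected: Mapping[str, Sequence[SummaryRecord]],
    exposure_pvals: Mapping[str, Mapping[str, float]],
    p_cross_trait: float = 5e-6,
) -> set[str]:
    """Variants instrumenting more than one exposure trait of one group.

    A variant present in any exposure's selected set is banned when it is
    associated (p < threshold) with two or more of the group's exposure
    traits, whether or not it was independently selected for both.
    """
    candidates = {r.variant_id for recs in selected.values() for r in recs}
    banned: set[str] = set()
    for vid in candidates:
        hits = 0
        for lookup in exposure_pvals.values():
            p = lookup.get(vid)
            if p is not None and p < p_cross_trait:
                hits += 1
                if hits >= 2:
                    banned.add(vid)
                    break
    return banned


def drop_cross_trait(
    selected: Mapping[str, Sequence[SummaryRecord]],
    exposure_pvals: Mapping[str, Mapping[str, float]],
    p_cross_trait: float = 5e-6,
) -> tuple[dict[str, list[SummaryRecord]], dict[str, int]]:
    """Step 3 applied across a whole analysis group's exposures at once."""
    banned = cross_trait_banned(selected, exposure_pvals, p_cross_trait)
    filtered: dict[str, list[SummaryRecord]] = {}
    removed: dict[str, int] = {}
    for exp_id, recs in selected.items():
        keep = [r for r in recs if r.variant_id not in banned]
        filtered[exp_id] = keep
        removed[exp_id] = len(recs) - len(keep)
    return filtered, removed


def drop_confounder_associated(
    records: Sequence[SummaryRecord],
    confounder_pvals: Sequence[Mapping[str, float]] = (),
    p_confounder: float = 1e-5,
) -> list[SummaryRecord]:
    """Step 4: drop variants associated with any screened confounder trait."""
    if not confounder_pvals:
        return list(records)
    out = []
    for r in records:
        hit = any(
            (p := lk.get(r.variant_id)) is not None and p < p_confounder
            for lk in confounder_pvals
        )
        if not hit:
            out.append(r)
    return out


def drop_outcome_associated(
    records: Sequence[SummaryRecord],
    outcome_pvals: Mapping[str, float],
    p_outcome: float = 5e-8,
) -> list[SummaryRecord]:
    """Step 5: drop variants genome-wide associated with the outcome."""
    out = []
    for r in records:
        p = outcome_pvals.get(r.variant_id)
        if p is None or p >= p_outcome:
            out.append(r)
    return out


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure_records: Sequence[SummaryRecord],
    outcome_records: Iterable[SummaryRecord],
    palindromic_eaf_window: float = 0.08,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Step 6: orient outcome effects onto the exposure's effect allele.

    Alignment rules, per variant joined on ``variant_id``:

    - absent from the outcome -> dropped (``not_in_outcome``);
    - identical allele pair -> keep outcome beta as-is;
    - swapped alleles -> negate outcome beta, complement outcome eaf;
    - alleles matching only after strand complement (A<->T, C<->G) ->
      complement, then align as above;
    - palindromic pairs (A/T, C/G) -> align by allele labels, then use
      allele frequencies to detect a strand mismatch (frequencies on
      opposite sides of 0.5 imply the outcome is reporting the complementary
      strand: flip again); dropped as ambiguous when either frequency falls
      within ``0.5 +/- palindromic_eaf_window`` or is missing;
    - anything else -> dropped as incompatible.

    Returns the harmonized rows (exposure order) and per-reason drop counts.
    Exposure betas are never altered.
    """
    out_by_id = {}
    for r in outcome_records:
        out_by_id.setdefault(r.variant_id, r)

    drops = {
        "not_in_outcome": 0,
        "palindromic_ambiguous": 0,
        "incompatible_alleles": 0,
        "duplicate": 0,
    }
    rows = []
    seen: set[str] = set()
    w = palindromic_eaf_window
    for ex in exposure_records:
        if ex.variant_id in seen:
            drops["duplicate"] += 1
            continue
        seen.add(ex.variant_id)
        oc = out_by_id.get(ex.variant_id)
        if oc is None:
            drops["not_in_outcome"] += 1
            continue
        ea_x, oa_x = ex.effect_allele, ex.other_allele
        ea_y, oa_y = oc.effect_allele, oc.other_allele
        b_y, eaf_y = oc.beta, oc.eaf

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                drops["incompatible_alleles"] += 1
                continue
            if (ea_y, oa_y) == (oa_x, ea_x):  # label swap first
                b_y = -b_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            if (
                ex.eaf is None
                or eaf_y is None
                or abs(ex.eaf - 0.5) <= w
                or abs(eaf_y - 0.5) <= w
            ):
                drops["palindromic_ambiguous"] += 1
                continue
            if (ex.eaf < 0.5) != (eaf_y < 0.5):  # strand mismatch inferred
                b_y = -b_y
                eaf_y = 1.0 - eaf_y
        else:
            cea_y, coa_y = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                b_y = -b_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            elif (cea_y, coa_y) == (ea_x, oa_x):
                pass
            elif (cea_y, coa_y) == (oa_x, ea_x):
                b_y = -b_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            else:
                drops["incompatible_alleles"] += 1
                continue

        rows.append(
            (
                ex.variant_id,
                ex.beta,
                ex.se,
                ex.pval,
                b_y,
                oc.se,
                oc.pval,
                ex.eaf,
                ex.n,
                oc.n,
            )
        )
    df = pd.DataFrame(rows, columns=list(ROW_COLUMNS))
    return df, drops


def instrument_strength(rows: pd.DataFrame, n_X: int | None = None) -> pd.DataFrame:
    """Per-IV variance explained and F statistic (appended as R2, F columns).

    Under the standardized-trait approximation, ``R2 = 2 * b_X^2 * eaf *
    (1 - eaf)`` and ``F = (n - 2) * R2 / (1 - R2)``.  Missing allele
    frequencies or sample sizes yield NaN (reported unavailable, never
    fabricated).
    """
    rows = rows.copy()
    eaf = pd.to_numeric(rows["eaf"], errors="coerce").to_numpy(dtype=float)
    b = rows["b_X"].to_numpy(dtype=float)
    if n_X is not None:
        n = np.full(len(rows), float(n_X))
    else:
        n = pd.to_numeric(rows["n_X"], errors="coerce").to_numpy(dtype=float)
    r2 = 2.0 * b**2 * eaf * (1.0 - eaf)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (n - 2.0) * r2 / (1.0 - r2)
    rows["R2"] = r2
    rows["F"] = f
    return rows


def build_instrument_set(
    exposure_id: str,
    outcome_id: str,
    exposure_records: Sequence[SummaryRecord],
    outcome_records: Sequence[SummaryRecord],
    config: FilterConfig = FilterConfig(),
    banned_cross_trait: frozenset[str] | set[str] = frozenset(),
    confounder_pvals: Sequence[Mapping[str, float]] = (),
    ld: Mapping[frozenset, float] | None = None,
) -> InstrumentSet:
    """Run the six filtration steps for one exposure-outcome pair.

    The cross-trait ban set is computed once per analysis group (it needs
    every exposure of the group) and passed in; see :func:`cross_trait_banned`.
    """
    prov: dict[str, int] = {"initial": len(exposure_records)}

    step1 = select_by_pvalue(exposure_records, config.p_instrument)
    prov["p_threshold"] = len(exposure_records) - len(step1)

    step2 = clump(step1, ld=ld, clump_r2=config.clump_r2, clump_kb=config.clump_kb)
    prov["clump"] = len(step1) - len(step2)

    step3 = [r for r in step2 if r.variant_id not in banned_cross_trait]
    prov["cross_trait"] = len(step2) - len(step3)

    step4 = drop_confounder_associated(step3, confounder_pvals, config.p_confounder)
    prov["confounder"] = len(step3) - len(step4)

    outcome_pv = pval_lookup(outcome_records)
    step5 = drop_outcome_associated(step4, outcome_pv, config.p_outcome)
    prov["outcome_associated"] = len(step4) - len(step5)

    rows, drops = harmonize(step5, outcome_records, config.palindromic_eaf_window)
    prov.update(drops)

    rows = instrument_strength(rows)
    prov["final"] = len(rows)
    return InstrumentSet(
        exposure_id=exposure_id, outcome_id=outcome_id, rows=rows, provenance=prov
    )
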