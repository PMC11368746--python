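"""Reading and writing GWAS summary-statistics tables and trait registries.

Every downstream stage consumes the canonical tab-separated dialect defined
here: one row per variant with columns ``variant_id, chrom, pos,
effect_allele, other_allele, eaf, beta, se, pval, n``.  A *dialect* maps the
canonical names onto whatever headers a source file uses (TwoSampleMR-style,
GWAS-Catalog-style, ...), so files from heterogeneous providers can be read
without rewriting them.

Trait registries are YAML files mapping ``trait_id`` to the trait's summary
file, its class (``cell``, ``protein``, ``sarcopenia`` or ``confounder``),
a human-readable label, and whether the effect is a log-odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SummaryRecord",
    "TraitMeta",
    "ParsedSumstats",
    "CANONICAL_COLUMNS",
    "DIALECTS",
    "SumstatsError",
    "DialectError",
    "read_sumstats",
    "write_sumstats",
    "records_to_frame",
    "frame_to_records",
    "read_registry",
    "write_registry",
]

CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Columns a file may omit entirely (parsed as missing when absent).
_OPTIONAL = frozenset({"chrom", "pos", "eaf", "n"})

#: Ready-made dialects for common provider schemas.  A dialect maps the
#: canonical column name to the header used in the file.
DIALECTS: Mapping[str, Mapping[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "twosamplemr": {
        "variant_id": "SNP",
        "chrom": "chr",
        "pos": "position",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "pval",
        "n": "samplesize",
    },
    "gwas_catalog": {
        "variant_id": "variant_id",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pval": "p_value",
        "n": "n",
    },
}

_VALID_ALLELES = frozenset("ACGT")


class SumstatsError(ValueError):
    """Malformed summary-statistics content (bad numeric, bad allele...)."""


class DialectError(KeyError):
    """A mandatory column could not be resolved through the dialect map."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (trait units, or log-odds for binary traits); ``se`` its standard error;
    ``pval`` the association p-value; ``eaf`` the effect-allele frequency;
    ``n`` the GWAS sample size.  ``chrom``/``pos`` (1-based) are only needed
    for distance clumping.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise SumstatsError(
                f"{self.variant_id}: se must be a positive finite float, got {self.se}"
            )
        if not 0.0 < self.pval <= 1.0:
            raise SumstatsError(
                f"{self.variant_id}: pval must lie in (0, 1], got {self.pval}"
            )
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise SumstatsError(
                f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _VALID_ALLELES:
                raise SumstatsError(
                    f"{self.variant_id}: allele {allele!r} is not one of A/C/G/T"
                )


@dataclass(frozen=True)
class TraitMeta:
    """Registry entry for one trait: identity, class and file location."""

    trait_id: str
    trait_class: str  # cell | protein | sarcopenia | confounder
    label: str = ""
    binary: bool = False
    path: str | None = None

    _CLASSES = ("cell", "protein", "sarcopenia", "confounder")

    def __post_init__(self) -> None:
        if self.trait_class not in self._CLASSES:
            raise ValueError(
                f"trait_class must be one of {self._CLASSES}, got {self.trait_class!r}"
            )


@dataclass
class ParsedSumstats:
    """Records surviving the parse plus the count of dropped rows.

    Rows lacking beta, se or p (``NA``/empty) are dropped and counted rather
    than failing the whole file; iteration yields the surviving records in
    input order.
    """

    records: list[SummaryRecord]
    n_dropped: int = 0
    source: str | None = None

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _resolve_dialect(
    header: Sequence[str], dialect: Mapping[str, str] | str | None
) -> dict[str, str]:
    """Map canonical column names to the file's headers, validating presence."""
    if dialect is None:
        dialect = "canonical"
    if isinstance(dialect, str):
        try:
            mapping = dict(DIALECTS[dialect])
        except KeyError:
            raise DialectError(f"unknown dialect {dialect!r}") from None
    else:
        # Partial maps fall back to canonical names for unmapped columns.
        mapping = {c: c for c in CANONICAL_COLUMNS}
        mapping.update(dialect)
    present = set(header)
    resolved: dict[str, str] = {}
    for canon, col in mapping.items():
        if col in present:
            resolved[canon] = col
        elif canon not in _OPTIONAL:
            raise DialectError(
                f"mandatory column {canon!r} (file header {col!r}) not found; "
                f"available columns: {sorted(present)}"
            )
    return resolved


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | str | None = None,
) -> ParsedSumstats:
    """Read a tab-separated summary-statistics file into records.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        Either the name of a built-in dialect (``"canonical"``,
        ``"twosamplemr"``, ``"gwas_catalog"``) or a mapping from canonical
        column names to the file's headers.  Unmapped columns default to
        their canonical names.

    Rows with missing beta, se or p-value are dropped and counted in
    ``ParsedSumstats.n_dropped``; any other unparseable value raises
    :class:`SumstatsError` naming the line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_dialect(df.columns, dialect)

    records: list[SummaryRecord] = []
    n_dropped = 0
    missing_tokens = {"", "NA", "NaN", "nan", "na", "."}
    col_idx = {canon: df.columns.get_loc(col) for canon, col in cols.items()}
    for i, row in enumerate(df.itertuples(index=False, name=None), start=2):
        raw = {canon: row[j] for canon, j in col_idx.items()}
        if any(raw.get(k, "") in missing_tokens for k in ("beta", "se", "pval")):
            n_dropped += 1
            continue
        try:
            records.append(
                SummaryRecord(
                    variant_id=str(raw["variant_id"]),
                    chrom=str(raw["chrom"]) if raw.get("chrom") not in (None, "") else None,
                    pos=int(raw["pos"]) if raw.get("pos") not in (None, "") else None,
                    effect_allele=str(raw["effect_allele"]).upper(),
                    other_allele=str(raw["other_allele"]).upper(),
                    eaf=float(raw["eaf"]) if raw.get("eaf") not in (None, "", "NA") else None,
                    beta=float(raw["beta"]),
                    se=float(raw["se"]),
                    pval=float(raw["pval"]),
                    n=int(float(raw["n"])) if raw.get("n") not in (None, "", "NA") else None,
                )
            )
        except (ValueError, SumstatsError) as exc:
            raise SumstatsError(f"{path}, line {i}: {exc}") from exc
    return ParsedSumstats(records=records, n_dropped=n_dropped, source=str(path))


def write_sumstats(records: Iterable[SummaryRecord], path: str | Path) -> Path:
    """Write records as a canonical TSV; round-trips at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr() of a float round-trips exactly in Python 3.
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.variant_id,
                        "" if rec.chrom is None else str(rec.chrom),
                        "" if rec.pos is None else str(int(rec.pos)),
                        rec.effect_allele,
                        rec.other_allele,
                        "" if rec.eaf is None else repr(float(rec.eaf)),
                        repr(float(rec.beta)),
                        repr(float(rec.se)),
                        repr(float(rec.pval)),
                        "" if rec.n is None else str(int(rec.n)),
                    ]
                )
                + "\n"
            )
    return path


def records_to_frame(records: Iterable[SummaryRecord]) -> pd.DataFrame:
    """Records -> DataFrame with canonical columns (object dtype for optionals)."""
    rows = [
        (
            r.variant_id,
            r.chrom,
            r.pos,
            r.effect_allele,
            r.other_allele,
            r.eaf,
            r.beta,
            r.se,
            r.pval,
            r.n,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[SummaryRecord]:
    """DataFrame with canonical columns -> list of records (input order)."""
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SummaryRecord(
                variant_id=str(r.variant_id),
                chrom=None if pd.isna(r.chrom) or r.chrom is None else str(r.chrom),
                pos=None if pd.isna(r.pos) or r.pos is None else int(r.pos),
                effect_allele=str(r.effect_allele),
                other_allele=str(r.other_allele),
                eaf=None if pd.isna(r.eaf) or r.eaf is None else float(r.eaf),
                beta=float(r.beta),
                se=float(r.se),
                pval=float(r.pval),
                n=None if pd.isna(r.n) or r.n is None else int(r.n),
            )
        )
    return out


def read_registry(path: str | Path) -> dict[str, TraitMeta]:
    """Load a YAML trait registry: trait_id -> {path, trait_class, label, binary}."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry: dict[str, TraitMeta] = {}
    for trait_id, entry in raw.items():
        if trait_id in registry:
            raise ValueError(f"duplicate trait_id {trait_id!r} in registry")
        registry[trait_id] = TraitMeta(
            trait_id=trait_id,
            trait_class=entry["trait_class"],
            label=entry.get("label", trait_id),
            binary=bool(entry.get("binary", False)),
            path=entry.get("path"),
        )
    return registry


def write_registry(registry: Mapping[str, TraitMeta], path: str | Path) -> Path:
    """Write a trait registry as YAML (inverse of :func:`read_registry`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        t.trait_id: {
            "trait_class": t.trait_class,
            "label": t.label,
            "binary": t.binary,
            **({"path": t.path} if t.path else {}),
        }
        for t in registry.values()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
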