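"""GWAS summary-statistic tables and LD matrices.

The package works entirely from per-variant summary associations: one row
per genetic variant with its alleles, effect-allele frequency (EAF), effect
size, standard error, p-value and sample size.  This module defines the
in-memory model (:class:`VariantAssociation`, :class:`SummaryTable`,
:class:`LDMatrix`) and delimited-text readers/writers with explicit column
mapping.  Column mapping is deliberately explicit — the upstream GWAS
sources each use a different header layout, and silently misreading a beta
column is the classic way an MR analysis goes wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryTable",
    "LDMatrix",
    "RowIssue",
    "SummaryFormatError",
    "SummaryValidationError",
    "read_summary_table",
    "write_summary_table",
    "read_ld_matrix",
    "write_ld_matrix",
]

MISSING_TOKEN = "NA"

SEX_STRATA = ("men", "women", "overall")
SCALES = ("sd", "martingale", "log_odds", "other")

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


class SummaryFormatError(ValueError):
    """File-level problem: missing mapped column, unreadable layout."""


class SummaryValidationError(ValueError):
    """Table-level invariant violation, e.g. duplicate variant identifiers."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is on the trait's analysis scale: SD units for the exposure,
    rank-normalized martingale residuals or log odds for outcomes.  ``eaf``
    is the effect-allele frequency and may be missing (``None``); it is
    never imputed because it drives the palindromic-variant rule during
    harmonization.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())

    def problems(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        issues: list[str] = []
        if not self.variant_id:
            issues.append("empty variant_id")
        if not self.effect_allele or not self.other_allele:
            issues.append("empty allele")
        elif self.effect_allele == self.other_allele:
            issues.append("effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            issues.append("non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            issues.append("se must be > 0")
        if not (math.isfinite(self.pvalue) and 0 < self.pvalue <= 1):
            issues.append("pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            issues.append("eaf must be in [0, 1] or missing")
        return issues

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class RowIssue:
    """Per-row rejection record produced by :func:`read_summary_table`."""

    row: int
    variant_id: str
    reasons: tuple[str, ...]


@dataclass
class SummaryTable:
    """Ordered collection of :class:`VariantAssociation` for one trait.

    ``sex_stratum`` and ``scale`` are set explicitly by the caller, never
    inferred from file contents.
    """

    trait_label: str
    sex_stratum: str
    scale: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex_stratum not in SEX_STRATA:
            raise SummaryValidationError(
                f"sex_stratum must be one of {SEX_STRATA}, got {self.sex_stratum!r}"
            )
        if self.scale not in SCALES:
            raise SummaryValidationError(
                f"scale must be one of {SCALES}, got {self.scale!r}"
            )
        dupes = self.duplicate_ids()
        if dupes:
            raise SummaryValidationError(
                f"duplicate variant_id in table {self.trait_label!r}: "
                + ", ".join(sorted(dupes))
            )

    def duplicate_ids(self) -> set[str]:
        seen: set[str] = set()
        dupes: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                dupes.add(rec.variant_id)
            seen.add(rec.variant_id)
        return dupes

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [rec.variant_id for rec in self.records]

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {rec.variant_id: rec for rec in self.records}

    def subset(self, variant_ids: Iterable[str]) -> "SummaryTable":
        """New table with only the given variants, in current order."""
        keep = set(variant_ids)
        return replace(
            self, records=[rec for rec in self.records if rec.variant_id in keep]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LDMatrix:
    """Square symmetric matrix of squared correlations (r^2) between variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise SummaryValidationError(
                f"LD matrix shape {self.r2.shape} does not match {k} variant ids"
            )
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise SummaryValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise SummaryValidationError("LD matrix diagonal must be exactly 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise SummaryValidationError("LD r2 values must lie in [0, 1]")
        self._pos = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._pos) != k:
            raise SummaryValidationError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    def pairwise(self, a: str, b: str) -> float:
        return float(self.r2[self._pos[a], self._pos[b]])


def _parse_float(value, *, allow_missing: bool = False) -> float | None:
    if value is None:
        if allow_missing:
            return None
        raise ValueError("missing value")
    s = str(value).strip()
    if s in ("", MISSING_TOKEN, "nan", "NaN", "."):
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(s)


def read_summary_table(
    path,
    column_map: Mapping[str, str],
    *,
    scale: str,
    sex: str,
    trait_label: str = "",
    delimiter: str = "\t",
) -> tuple[SummaryTable, list[RowIssue]]:
    """Read a delimited summary-statistics file with an explicit column map.

    ``column_map`` maps canonical field names (``variant_id``,
    ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pvalue`` and
    optionally ``eaf``, ``n``) to the file's header names.  Rows that
    violate the :class:`VariantAssociation` invariants are rejected, and
    every rejection is reported with its row number and reasons; the
    retained plus rejected row counts always equal the input row count.

    Raises :class:`SummaryFormatError` if a mapped column is absent and
    :class:`SummaryValidationError` if a variant appears twice.
    """
    required = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
    for fieldname in required:
        if fieldname not in column_map:
            raise SummaryFormatError(f"column_map must map {fieldname!r}")

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in column_map.values() if c not in df.columns]
    if missing_cols:
        raise SummaryFormatError(
            f"mapped columns absent from {path}: {', '.join(missing_cols)}"
        )

    records: list[VariantAssociation] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        vid = str(rowd[column_map["variant_id"]]).strip()
        reasons: list[str] = []
        parsed: dict[str, float | None] = {}
        for fieldname, allow_missing in (
            ("beta", False),
            ("se", False),
            ("pvalue", False),
            ("eaf", True),
            ("n", True),
        ):
            col = column_map.get(fieldname)
            if col is None:
                parsed[fieldname] = None
                continue
            try:
                parsed[fieldname] = _parse_float(
                    rowd[col], allow_missing=allow_missing
                )
            except ValueError:
                reasons.append(f"non-numeric {fieldname}")
                parsed[fieldname] = None
        if reasons:
            issues.append(RowIssue(row=i, variant_id=vid, reasons=tuple(reasons)))
            continue
        rec = VariantAssociation(
            variant_id=vid,
            effect_allele=str(rowd[column_map["effect_allele"]]).strip(),
            other_allele=str(rowd[column_map["other_allele"]]).strip(),
            beta=parsed["beta"],
            se=parsed["se"],
            pvalue=parsed["pvalue"],
            eaf=parsed["eaf"],
            n=parsed["n"],
        )
        problems = rec.problems()
        if problems:
            issues.append(RowIssue(row=i, variant_id=vid, reasons=tuple(problems)))
        else:
            records.append(rec)

    table = SummaryTable(
        trait_label=trait_label, sex_stratum=sex, scale=scale, records=records
    )
    return table, issues


def _fmt(value: float | None) -> str:
    if value is None:
        return MISSING_TOKEN
    return repr(float(value))


def write_summary_table(table: SummaryTable, path, *, delimiter: str = "\t") -> None:
    """Write a table in the canonical column layout.

    Floats are written at full precision (``repr``) so a write-then-read
    round trip is the identity on every field; missing ``eaf``/``n`` are
    written as the designated missing token.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(CANONICAL_COLUMNS) + "\n")
        for rec in table.records:
            fh.write(
                delimiter.join(
                    (
                        rec.variant_id,
                        rec.effect_allele,
                        rec.other_allele,
                        _fmt(rec.eaf),
                        _fmt(rec.beta),
                        _fmt(rec.se),
                        _fmt(rec.pvalue),
                        _fmt(rec.n),
                    )
                )
                + "\n"
            )


def canonical_column_map() -> dict[str, str]:
    """Identity column map for files written by :func:`write_summary_table`."""
    return {c: c for c in CANONICAL_COLUMNS}


def read_ld_matrix(path, *, delimiter: str = "\t") -> LDMatrix:
    """Read an LD r^2 matrix stored as TSV with ids in first row and column."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    ids = [str(v) for v in df.columns]
    if [str(v) for v in df.index] != ids:
        raise SummaryFormatError("LD matrix row and column ids differ")
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, *, delimiter: str = "\t") -> None:
    df = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep=delimiter)
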