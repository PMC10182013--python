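"""Instrument selection: variant filters, LD clumping, confounder screen.

Instruments for the exposure are chosen in a fixed stage order — biallelic
status, minor-allele frequency, Hardy–Weinberg equilibrium, genome-wide
significance, then greedy LD clumping — with a report that accounts for
every removal exactly once.  A Bonferroni-corrected screen against
confounder-trait associations flags (but never silently removes)
potentially confounded instruments; excluding them is a sensitivity
analysis performed by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_stats_io import LDMatrix, SummaryTable

__all__ = [
    "SelectionThresholds",
    "SelectionReport",
    "SelectionError",
    "hwe_chi2_test",
    "filter_variants",
    "ld_clump",
    "confounder_screen",
]

log = logging.getLogger(__name__)

STAGES = (
    "non_biallelic",
    "rare",
    "hwe_fail",
    "non_significant",
    "clumped",
    "unavailable_in_outcome",
)


class SelectionError(ValueError):
    """Configuration or input problem during instrument selection."""


@dataclass(frozen=True)
class SelectionThresholds:
    """Filter cutoffs.

    Defaults: genome-wide significance ``p < 5e-8`` (strict inequality — a
    variant exactly at the boundary is removed), MAF >= 0.01, HWE
    chi-squared p >= 0.05, clumping ceiling r^2 < 0.001.
    """

    pvalue_max: float = 5e-8
    maf_min: float = 0.01
    hwe_p_min: float = 0.05
    clump_r2_max: float = 0.001

    def __post_init__(self) -> None:
        for name in ("pvalue_max", "maf_min", "hwe_p_min", "clump_r2_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise SelectionError(f"{name} must be in (0, 1), got {v}")


@dataclass
class SelectionReport:
    """Per-stage removal counts plus the retained variant ids.

    Invariant: the stage counts sum with the retained count to the input
    count, so no variant is ever dropped unaccounted.
    """

    input_count: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {stage: 0 for stage in STAGES}
    )
    removed_ids: dict[str, list[str]] = field(
        default_factory=lambda: {stage: [] for stage in STAGES}
    )
    retained_ids: list[str] = field(default_factory=list)

    def record_removal(self, stage: str, variant_id: str) -> None:
        self.removed[stage] += 1
        self.removed_ids[stage].append(variant_id)

    @property
    def removed_total(self) -> int:
        return sum(self.removed.values())

    def check_conservation(self) -> bool:
        return self.removed_total + len(self.retained_ids) == self.input_count

    def merged_with(self, later: "SelectionReport") -> "SelectionReport":
        """Combine with a report from a downstream stage on this stage's output."""
        out = SelectionReport(input_count=self.input_count)
        for stage in STAGES:
            out.removed[stage] = self.removed[stage] + later.removed[stage]
            out.removed_ids[stage] = self.removed_ids[stage] + later.removed_ids[stage]
        out.retained_ids = list(later.retained_ids)
        return out


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy–Weinberg equilibrium chi-squared test p-value (1 df).

    Compares observed genotype counts to the counts expected at the
    observed allele frequency.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0):
        raise SelectionError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise SelectionError("all genotype counts are zero")
    p_hat = (2 * n_hom_alt + n_het) / (2 * n)
    expected = n * np.array(
        [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
    )
    # monomorphic: observed matches expectation exactly, chi2 = 0
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return float(stats.chi2.sf(chi2, df=1))


def filter_variants(
    table: SummaryTable,
    thresholds: SelectionThresholds | None = None,
    *,
    biallelic_flags: dict[str, bool] | None = None,
    hwe_pvalues: dict[str, float] | None = None,
) -> tuple[SummaryTable, SelectionReport]:
    """Apply the biallelic / MAF / HWE / significance filters in order.

    Each variant is counted against the first stage it fails, so stage
    counts plus retained equal the input count.  Biallelic flags and HWE
    p-values come from genotype-level QC and are caller-supplied; when
    absent those stages pass with a logged warning (summary statistics
    alone cannot determine them).  MAF is ``min(eaf, 1 - eaf)``; a missing
    EAF also passes the MAF stage with a warning.
    """
    thresholds = thresholds or SelectionThresholds()
    report = SelectionReport(input_count=len(table))
    if biallelic_flags is None:
        log.warning("no biallelic flags supplied; biallelic filter passes all")
    if hwe_pvalues is None:
        log.warning("no HWE p-values supplied; HWE filter passes all")

    kept = []
    for rec in table:
        if biallelic_flags is not None and not biallelic_flags.get(
            rec.variant_id, True
        ):
            report.record_removal("non_biallelic", rec.variant_id)
            continue
        maf = rec.maf
        if maf is not None and maf < thresholds.maf_min:
            report.record_removal("rare", rec.variant_id)
            continue
        if hwe_pvalues is not None:
            hwe_p = hwe_pvalues.get(rec.variant_id)
            if hwe_p is not None and hwe_p < thresholds.hwe_p_min:
                report.record_removal("hwe_fail", rec.variant_id)
                continue
        if not (rec.pvalue < thresholds.pvalue_max):
            report.record_removal("non_significant", rec.variant_id)
            continue
        kept.append(rec.variant_id)

    report.retained_ids = kept
    return table.subset(kept), report


def ld_clump(
    table: SummaryTable,
    ld: LDMatrix,
    r2_max: float = 0.001,
) -> tuple[SummaryTable, SelectionReport]:
    """Greedy LD clumping by ascending p-value.

    Repeatedly retain the remaining variant with the smallest p-value
    (ties broken by lexicographic variant id) and discard every remaining
    variant correlated with it at ``r^2 >= r2_max``.  The retained set is
    pairwise ``r^2 < r2_max`` and depends only on the p-value order and
    the LD matrix, never on input row order.
    """
    if not (0 < r2_max < 1):
        raise SelectionError(f"r2_max must be in (0, 1), got {r2_max}")
    missing = [rec.variant_id for rec in table if rec.variant_id not in ld]
    if missing:
        raise SelectionError(
            "variants absent from LD matrix: " + ", ".join(sorted(missing))
        )

    report = SelectionReport(input_count=len(table))
    remaining = sorted(table.records, key=lambda r: (r.pvalue, r.variant_id))
    retained: list[str] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index.variant_id)
        still = []
        for rec in remaining:
            if ld.pairwise(index.variant_id, rec.variant_id) >= r2_max:
                report.record_removal("clumped", rec.variant_id)
            else:
                still.append(rec)
        remaining = still
    report.retained_ids = retained
    return table.subset(retained), report


def confounder_screen(
    instruments: SummaryTable,
    confounder_tables: list[SummaryTable],
    alpha: float = 0.05,
) -> tuple[dict[str, list[str]], float]:
    """Bonferroni screen of instruments against confounder traits.

    The threshold is ``alpha / (J * T)`` with J the instrument count and T
    the number of confounder traits.  Returns ``(flags, threshold)`` where
    ``flags`` maps each flagged variant id to the confounder trait labels
    implicating it.  The instrument table is not mutated: exclusion of
    flagged instruments is the caller's sensitivity analysis.
    """
    if not confounder_tables:
        raise SelectionError("confounder_tables must be non-empty")
    if not (0 < alpha < 1):
        raise SelectionError(f"alpha must be in (0, 1), got {alpha}")
    j = len(instruments)
    t = len(confounder_tables)
    if j == 0:
        raise SelectionError("instrument table is empty")
    threshold = alpha / (j * t)

    flags: dict[str, list[str]] = {}
    for conf in confounder_tables:
        idx = conf._index()
        for rec in instruments:
            assoc = idx.get(rec.variant_id)
            if assoc is not None and assoc.pvalue < threshold:
                flags.setdefault(rec.variant_id, []).append(conf.trait_label)
    return flags, threshold
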