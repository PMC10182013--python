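"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires the exposure and outcome effect sizes of each
variant to refer to the same effect allele.  The exposure table is the
reference orientation (its source reports alleles on the forward strand);
the outcome association is reflected (beta sign and EAF flipped) when its
allele labels are swapped, and complement-matched when the two sources
reported opposite strands.

Palindromic variants (allele pair A/T or C/G) cannot be oriented from the
letters at all.  They are retained only when the exposure effect-allele
frequency is informative — at most 0.45 or at least 0.55, i.e. not close
to 0.50 — and, when the outcome reports a frequency, only when that
frequency falls on the side of 0.5 consistent with the exposure allele;
otherwise they are dropped as ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .summary_stats_io import SummaryTable, VariantAssociation

__all__ = [
    "Action",
    "HarmonizedInstrument",
    "HarmonizationReport",
    "HarmonizationError",
    "harmonize_pair",
    "harmonize_tables",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(ValueError):
    pass


class Action:
    """Outcome of harmonizing one exposure/outcome pair."""

    UNCHANGED = "unchanged"
    FLIPPED = "outcome_sign_flipped"
    COMPLEMENT = "complement_matched"
    DROPPED_PALINDROMIC = "dropped_palindromic_ambiguous"
    DROPPED_MISMATCH = "dropped_allele_mismatch"

    RETAINED = (UNCHANGED, FLIPPED, COMPLEMENT)
    DROPPED = (DROPPED_PALINDROMIC, DROPPED_MISMATCH)
    ALL = RETAINED + DROPPED


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome pair aligned to a shared effect allele.

    For dropped pairs the effect sizes are withheld (``None``) so they can
    never leak into downstream estimation.
    """

    variant_id: str
    effect_allele: str
    action: str
    bx: float | None = None
    se_x: float | None = None
    by: float | None = None
    se_y: float | None = None
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False

    @property
    def retained(self) -> bool:
        return self.action in Action.RETAINED


@dataclass
class HarmonizationReport:
    """Counts by action plus variants unavailable in one of the tables."""

    counts: dict[str, int] = field(
        default_factory=lambda: {a: 0 for a in Action.ALL}
    )
    unavailable: int = 0
    unavailable_ids: list[str] = field(default_factory=list)

    @property
    def retained(self) -> int:
        return sum(self.counts[a] for a in Action.RETAINED)

    @property
    def dropped(self) -> int:
        return sum(self.counts[a] for a in Action.DROPPED)


def _complement_allele(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def _dropped(exposure: VariantAssociation, outcome, action: str, palindromic: bool):
    return HarmonizedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        action=action,
        eaf_exposure=exposure.eaf,
        eaf_outcome=None if outcome is None else outcome.eaf,
        palindromic=palindromic,
    )


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    *,
    palindromic_eaf_low: float = 0.45,
    palindromic_eaf_high: float = 0.55,
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome pair to the exposure's effect allele.

    The exposure association is never altered.  Actions:

    - ``unchanged``: outcome alleles match in the same orientation;
    - ``outcome_sign_flipped``: labels swapped, so ``by := -by`` and
      ``eaf := 1 - eaf``;
    - ``complement_matched``: labels match only after A<->T / C<->G
      complementation (opposite reported strands); the sign flip is still
      applied when the complemented labels are also swapped;
    - ``dropped_palindromic_ambiguous`` / ``dropped_allele_mismatch``.

    For palindromic variants the exposure EAF governs retention (it must
    lie outside the open interval (low, high)); the outcome EAF, when
    present, is only checked for orientation consistency.
    """
    if exposure.variant_id != outcome.variant_id:
        raise HarmonizationError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )

    ea, oa = exposure.effect_allele, exposure.other_allele
    palindromic = exposure.is_palindromic

    def build(by: float, eaf_out: float | None, action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            variant_id=exposure.variant_id,
            effect_allele=ea,
            action=action,
            bx=exposure.beta,
            se_x=exposure.se,
            by=by,
            se_y=outcome.se,
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_out,
            palindromic=palindromic,
        )

    if palindromic:
        # letters cannot resolve strand; the EAF window is the only handle
        eaf_x = exposure.eaf
        if eaf_x is None or palindromic_eaf_low < eaf_x < palindromic_eaf_high:
            return _dropped(exposure, outcome, Action.DROPPED_PALINDROMIC, True)
        same_labels = outcome.effect_allele == ea and outcome.other_allele == oa
        swapped_labels = outcome.effect_allele == oa and outcome.other_allele == ea
        if not (same_labels or swapped_labels):
            return _dropped(exposure, outcome, Action.DROPPED_MISMATCH, True)
        if outcome.eaf is None:
            log.warning(
                "palindromic variant %s has no outcome EAF; orienting by labels",
                exposure.variant_id,
            )
            if same_labels:
                return build(outcome.beta, None, Action.UNCHANGED)
            return build(-outcome.beta, None, Action.FLIPPED)
        # outcome EAF must sit on the side of 0.5 implied by its label
        exp_side = eaf_x >= 0.5
        out_side = outcome.eaf >= 0.5
        if same_labels:
            if out_side == exp_side:
                return build(outcome.beta, outcome.eaf, Action.UNCHANGED)
            return _dropped(exposure, outcome, Action.DROPPED_PALINDROMIC, True)
        if out_side != exp_side:
            return build(-outcome.beta, 1 - outcome.eaf, Action.FLIPPED)
        return _dropped(exposure, outcome, Action.DROPPED_PALINDROMIC, True)

    # non-palindromic: letters are decisive
    if outcome.effect_allele == ea and outcome.other_allele == oa:
        return build(outcome.beta, outcome.eaf, Action.UNCHANGED)
    if outcome.effect_allele == oa and outcome.other_allele == ea:
        eaf_out = None if outcome.eaf is None else 1 - outcome.eaf
        return build(-outcome.beta, eaf_out, Action.FLIPPED)
    cea = _complement_allele(outcome.effect_allele)
    coa = _complement_allele(outcome.other_allele)
    if cea is not None and coa is not None:
        if cea == ea and coa == oa:
            return build(outcome.beta, outcome.eaf, Action.COMPLEMENT)
        if cea == oa and coa == ea:
            eaf_out = None if outcome.eaf is None else 1 - outcome.eaf
            return build(-outcome.beta, eaf_out, Action.FLIPPED)
    return _dropped(exposure, outcome, Action.DROPPED_MISMATCH, False)


def harmonize_tables(
    exposure: SummaryTable,
    outcome: SummaryTable,
    *,
    palindromic_eaf_low: float = 0.45,
    palindromic_eaf_high: float = 0.55,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Harmonize every variant present in both tables.

    Variants present in only one table are counted as unavailable (the
    analysis discards instruments unavailable for the outcome).  The
    report satisfies retained + dropped + unavailable = union count.
    """
    out_idx = {rec.variant_id: rec for rec in outcome}
    exp_ids = set(exposure.variant_ids)
    report = HarmonizationReport()
    retained: list[HarmonizedInstrument] = []
    for rec in exposure:
        out_rec = out_idx.get(rec.variant_id)
        if out_rec is None:
            report.unavailable += 1
            report.unavailable_ids.append(rec.variant_id)
            continue
        harm = harmonize_pair(
            rec,
            out_rec,
            palindromic_eaf_low=palindromic_eaf_low,
            palindromic_eaf_high=palindromic_eaf_high,
        )
        report.counts[harm.action] += 1
        if harm.retained:
            retained.append(harm)
    for vid in outcome.variant_ids:
        if vid not in exp_ids:
            report.unavailable += 1
            report.unavailable_ids.append(vid)
    return retained, report
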