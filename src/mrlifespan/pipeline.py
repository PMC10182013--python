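"""End-to-end study orchestration: select, harmonize, estimate, report.

`run_study` executes the full analysis plan for a two-stratum (men /
women) design: harmonize each sex's exposure instruments against each
outcome, screen instruments against confounder traits, run every
requested estimator twice (all instruments, and excluding
confounder-flagged ones), convert martingale-scale estimates to years of
life lost and log-odds estimates to odds ratios, test for a sex
difference per method, and pool the sex-specific years-of-life-lost
estimates with a fixed-effect meta-analysis.  Outputs are a
machine-readable results TSV, a human-readable report and a log carrying
the seeds; identical configs and seeds produce byte-identical outputs.

Any stage error aborts the run — partial study outputs are never written
silently, because a missing estimator row would fabricate a different
results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mr_estimators as est
from .harmonization import HarmonizedInstrument, harmonize_tables
from .instrument_selection import confounder_screen
from .lifespan_reporting import (
    LifespanEffect,
    PooledEffect,
    SexComparison,
    logodds_to_or,
    martingale_to_years,
    meta_fixed_effect,
    sex_difference_test,
)
from .summary_stats_io import SummaryTable

__all__ = [
    "OutcomeSpec",
    "StratumSpec",
    "StudyConfig",
    "StudyResult",
    "PipelineError",
    "run_study",
    "estimate_all",
    "harmonized_to_dataframe",
    "dataframe_to_harmonized",
]

log = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_mre", "weighted_median", "egger", "raps", "presso")

RESULT_COLUMNS = (
    "exposure",
    "sex",
    "outcome",
    "scale",
    "selection",
    "method",
    "n_instruments",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "cochran_q",
    "q_pvalue",
    "egger_intercept",
    "egger_intercept_p",
    "i2_gx",
    "outliers",
    "years_lost",
    "se_years",
    "ci_low_years",
    "ci_high_years",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class OutcomeSpec:
    table: SummaryTable
    parent: str | None = None  # father/mother for martingale outcomes


@dataclass
class StratumSpec:
    exposure: SummaryTable
    outcomes: list[OutcomeSpec]
    confounders: list[SummaryTable] = field(default_factory=list)


@dataclass
class StudyConfig:
    strata: dict[str, StratumSpec]
    output_dir: Path
    methods: tuple[str, ...] = DEFAULT_METHODS
    seed: int = 0
    presso_sims: int = 10_000
    n_boot: int = 1000
    palindromic_eaf_low: float = 0.45
    palindromic_eaf_high: float = 0.55
    alpha_confounder: float = 0.05


@dataclass
class StudyResult:
    results: pd.DataFrame
    sex_comparisons: pd.DataFrame
    meta: pd.DataFrame
    flags: dict[str, dict[str, list[str]]]
    output_files: list[Path]


def estimate_all(
    instruments: Sequence[HarmonizedInstrument],
    methods: Sequence[str],
    *,
    seed: int,
    presso_sims: int = 10_000,
    n_boot: int = 1000,
) -> dict[str, est.MREstimate]:
    """Run the requested estimators on one instrument set.

    Returns a mapping from method name to estimate; ``egger`` also yields
    an ``egger_intercept`` entry and ``presso`` yields the corrected
    estimate under ``presso``.
    """
    out: dict[str, est.MREstimate] = {}
    for method in methods:
        if method == "ivw_mre":
            out[method] = est.ivw_multiplicative_random(instruments)
        elif method == "weighted_median":
            out[method] = est.weighted_median(instruments, n_boot=n_boot, seed=seed)
        elif method == "egger":
            res = est.egger(instruments)
            out["egger"] = res.slope
            out["egger_intercept"] = res.intercept
        elif method == "raps":
            out[method] = est.mr_raps(instruments)
        elif method == "presso":
            res = est.mr_presso(
                instruments, n_sim=presso_sims, seed=seed
            )
            out["presso"] = res.corrected
        else:
            raise PipelineError(f"unknown method {method!r}")
    return out


def _result_row(
    exposure: str,
    sex: str,
    outcome: SummaryTable,
    selection: str,
    method: str,
    e: est.MREstimate,
    parent: str | None,
    intercept: est.MREstimate | None = None,
) -> dict:
    row = {c: "" for c in RESULT_COLUMNS}
    row.update(
        exposure=exposure,
        sex=sex,
        outcome=outcome.trait_label,
        scale=outcome.scale,
        selection=selection,
        method=method,
        n_instruments=e.n_instruments,
        estimate=e.estimate,
        se=e.se,
        ci_low=e.ci_low,
        ci_high=e.ci_high,
        pvalue=e.pvalue,
    )
    if e.cochran_q is not None:
        row["cochran_q"] = e.cochran_q
        row["q_pvalue"] = e.q_pvalue
    if intercept is not None:
        row["egger_intercept"] = intercept.estimate
        row["egger_intercept_p"] = intercept.pvalue
    if e.i2_gx is not None:
        row["i2_gx"] = e.i2_gx
    if e.outliers:
        row["outliers"] = ",".join(e.outliers)
    if outcome.scale == "martingale" and parent is not None:
        years = martingale_to_years(e, parent)
        row.update(
            years_lost=years.years_lost,
            se_years=years.se_years,
            ci_low_years=years.ci_low_years,
            ci_high_years=years.ci_high_years,
        )
    elif outcome.scale == "log_odds":
        orr = logodds_to_or(e)
        row.update(
            odds_ratio=orr.or_, or_ci_low=orr.ci_low, or_ci_high=orr.ci_high
        )
    return row


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full analysis plan and write the results bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    years_by_key: dict[tuple, LifespanEffect] = {}
    all_flags: dict[str, dict[str, list[str]]] = {}

    for sex, stratum in config.strata.items():
        flags: dict[str, list[str]] = {}
        if stratum.confounders:
            flags, _ = confounder_screen(
                stratum.exposure, stratum.confounders, config.alpha_confounder
            )
        all_flags[sex] = flags

        for spec in stratum.outcomes:
            instruments, _ = harmonize_tables(
                stratum.exposure,
                spec.table,
                palindromic_eaf_low=config.palindromic_eaf_low,
                palindromic_eaf_high=config.palindromic_eaf_high,
            )
            subsets = {"all": instruments}
            if stratum.confounders:
                subsets["excluding_confounded"] = [
                    h for h in instruments if h.variant_id not in flags
                ]
            for selection, subset in subsets.items():
                try:
                    estimates = estimate_all(
                        subset,
                        config.methods,
                        seed=config.seed,
                        presso_sims=config.presso_sims,
                        n_boot=config.n_boot,
                    )
                except Exception as exc:  # abort with context, never skip
                    raise PipelineError(
                        f"estimation failed for sex={sex}, "
                        f"outcome={spec.table.trait_label}, selection={selection}: {exc}"
                    ) from exc
                intercept = estimates.pop("egger_intercept", None)
                for method, e in estimates.items():
                    rows.append(
                        _result_row(
                            stratum.exposure.trait_label,
                            sex,
                            spec.table,
                            selection,
                            method,
                            e,
                            spec.parent,
                            intercept=intercept if method == "egger" else None,
                        )
                    )
                    if spec.table.scale == "martingale" and spec.parent:
                        years_by_key[(sex, selection, method)] = martingale_to_years(
                            e, spec.parent
                        )

    results = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))

    # sex-difference z-tests and overall meta-analysis on years of life lost
    comp_rows, meta_rows = [], []
    selections = sorted({k[1] for k in years_by_key})
    methods = sorted({k[2] for k in years_by_key})
    for selection in selections:
        for method in methods:
            men = years_by_key.get(("men", selection, method))
            women = years_by_key.get(("women", selection, method))
            if men is None or women is None:
                continue
            comp = sex_difference_test(men, women)
            comp_rows.append(
                {
                    "selection": selection,
                    "method": method,
                    "years_lost_men": comp.estimate_men,
                    "years_lost_women": comp.estimate_women,
                    "z": comp.z,
                    "pvalue": comp.pvalue,
                }
            )
            pooled = meta_fixed_effect([men, women])
            meta_rows.append(
                {
                    "selection": selection,
                    "method": method,
                    "years_lost_overall": pooled.estimate,
                    "se": pooled.se,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "pvalue": pooled.pvalue,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    meta = pd.DataFrame(meta_rows)

    written = []
    results_path = outdir / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False, float_format="%.10g")
    written.append(results_path)
    comp_path = outdir / "sex_comparison.tsv"
    comparisons.to_csv(comp_path, sep="\t", index=False, float_format="%.10g")
    written.append(comp_path)
    meta_path = outdir / "meta_overall.tsv"
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.10g")
    written.append(meta_path)

    report_path = outdir / "report.txt"
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write(_human_report(results, comparisons, meta, all_flags, config))
    written.append(report_path)

    log_path = outdir / "run.log"
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"methods\t{','.join(config.methods)}\n")
        fh.write(f"presso_sims\t{config.presso_sims}\n")
        fh.write(f"n_boot\t{config.n_boot}\n")
        for sex, flags in all_flags.items():
            fh.write(f"confounder_flags_{sex}\t{len(flags)}\n")
    written.append(log_path)

    return StudyResult(
        results=results,
        sex_comparisons=comparisons,
        meta=meta,
        flags=all_flags,
        output_files=written,
    )


def _human_report(results, comparisons, meta, flags, config) -> str:
    lines = ["MR study results", "================", ""]
    for _, r in results.iterrows():
        desc = (
            f"{r['sex']}: {r['exposure']} -> {r['outcome']} "
            f"[{r['selection']}, {r['method']}, J={r['n_instruments']}] "
            f"beta={r['estimate']:.4g} (SE {r['se']:.4g}, p={r['pvalue']:.3g})"
        )
        if r["years_lost"] != "":
            desc += (
                f"; years of life lost {r['years_lost']:.3g} "
                f"({r['ci_low_years']:.3g} to {r['ci_high_years']:.3g})"
            )
        if r["odds_ratio"] != "":
            desc += (
                f"; OR {r['odds_ratio']:.3g} "
                f"({r['or_ci_low']:.3g} to {r['or_ci_high']:.3g})"
            )
        lines.append(desc)
    if len(comparisons):
        lines += ["", "Sex differences (women - men, years of life lost):"]
        for _, r in comparisons.iterrows():
            lines.append(
                f"  {r['selection']}/{r['method']}: z={r['z']:.3f}, "
                f"p={r['pvalue']:.3g}"
            )
    if len(meta):
        lines += ["", "Overall (fixed-effect pool of sex-specific years lost):"]
        for _, r in meta.iterrows():
            lines.append(
                f"  {r['selection']}/{r['method']}: "
                f"{r['years_lost_overall']:.3g} "
                f"({r['ci_low']:.3g} to {r['ci_high']:.3g}), p={r['pvalue']:.3g}"
            )
    for sex, fl in flags.items():
        lines.append("")
        lines.append(f"Confounder-flagged instruments ({sex}): {len(fl)}")
    return "\n".join(lines) + "\n"


HARMONIZED_COLUMNS = (
    "variant_id",
    "effect_allele",
    "action",
    "bx",
    "se_x",
    "by",
    "se_y",
    "eaf_exposure",
    "eaf_outcome",
    "palindromic",
)


def harmonized_to_dataframe(
    instruments: Sequence[HarmonizedInstrument],
) -> pd.DataFrame:
    rows = []
    for h in instruments:
        rows.append(
            {
                "variant_id": h.variant_id,
                "effect_allele": h.effect_allele,
                "action": h.action,
                "bx": np.nan if h.bx is None else h.bx,
                "se_x": np.nan if h.se_x is None else h.se_x,
                "by": np.nan if h.by is None else h.by,
                "se_y": np.nan if h.se_y is None else h.se_y,
                "eaf_exposure": np.nan if h.eaf_exposure is None else h.eaf_exposure,
                "eaf_outcome": np.nan if h.eaf_outcome is None else h.eaf_outcome,
                "palindromic": h.palindromic,
            }
        )
    return pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))


def dataframe_to_harmonized(df: pd.DataFrame) -> list[HarmonizedInstrument]:
    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        HarmonizedInstrument(
            variant_id=str(r["variant_id"]),
            effect_allele=str(r["effect_allele"]),
            action=str(r["action"]),
            bx=opt(r["bx"]),
            se_x=opt(r["se_x"]),
            by=opt(r["by"]),
            se_y=opt(r["se_y"]),
            eaf_exposure=opt(r["eaf_exposure"]),
            eaf_outcome=opt(r["eaf_outcome"]),
            palindromic=bool(r["palindromic"]),
        )
        for _, r in df.iterrows()
    ]
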