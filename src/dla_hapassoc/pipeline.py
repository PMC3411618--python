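"""End-to-end orchestration: genotypes → phasing → tables → tests → report.

`run_pipeline` reads an unphased genotype TSV, phases the cohort,
builds the three per-locus allele tables and the haplotype table, runs
the Monte-Carlo T1/T2 tests on each, computes odds ratios with Woolf
intervals for every category (chromosome level for alleles; both
chromosome and carrier level for haplotypes), applies the configured
significance thresholds (per-locus Bonferroni for alleles, unadjusted
alpha for haplotypes) and writes CSV tables, a machine-readable
``summary.json`` and a short text report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    ClumpVariant,
    FilterScope,
    FrequencyTable,
    build_allele_table,
    build_haplotype_table,
    bonferroni_threshold,
    carrier_table,
    chromosome_table,
    clump_test,
    filter_by_frequency,
    odds_ratio,
)
from .errors import ValidationError
from .genotypes import LOCI, Haplotype, read_genotypes, write_diplotypes
from .phasing import assign_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: Path
    output_dir: Path
    trials: int = 100_000
    seed: int = 0
    min_freq: float = 0.01
    or_level: str = "both"          # chromosome | carrier | both
    alpha: float = 0.05
    n_tests_per_locus: int = 3
    allow_unresolved: bool = False
    log_phasing: bool = False

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.output_dir = Path(self.output_dir)
        if self.trials < 1 or self.alpha <= 0 or self.alpha >= 1 \
                or self.n_tests_per_locus < 1 or not (0 <= self.min_freq < 1):
            raise ValidationError("invalid numeric configuration")
        if self.or_level not in ("chromosome", "carrier", "both"):
            raise ValidationError(f"unknown or_level {self.or_level!r}")


def _or_columns(table: FrequencyTable, category: str, alpha: float) -> dict:
    res = odds_ratio(chromosome_table(table, category), alpha=alpha)
    return {
        "OR": res.point,
        "CI_low": res.ci_low,
        "CI_high": res.ci_high,
        "haldane_corrected": res.haldane_corrected,
    }


def _table_frame(table: FrequencyTable, alpha: float) -> pd.DataFrame:
    rows = []
    for i, cat in enumerate(table.categories):
        row = {
            "category": cat,
            "case_n": table.case_counts[i],
            "case_freq": table.case_frequencies[i],
            "control_n": table.control_counts[i],
            "control_freq": table.control_frequencies[i],
        }
        row.update(_or_columns(table, cat, alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def _clump_entry(result) -> dict:
    return {
        "variant": result.variant.value,
        "statistic": result.statistic_observed,
        "p": result.p_empirical,
        "trials": result.n_trials,
        "seed": result.seed,
        "clumped_categories": sorted(
            c for c, g in result.clumping_map.items() if g == "clumped"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the summary dict it also writes."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_genotypes(config.input_path)
    logger.info("read %d dogs (%d cases / %d controls) from %s",
                len(cohort), cohort.n_case, cohort.n_control,
                config.input_path)

    phasing = assign_all(cohort)
    write_diplotypes(cohort, phasing.assignments,
                     config.output_dir / "diplotypes.tsv")
    if config.log_phasing:
        with (config.output_dir / "phasing_log.json").open("w") as fh:
            json.dump([asdict(e) for e in phasing.pass_log], fh, indent=1)

    summary: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "cohort": {
            "n_case": cohort.n_case,
            "n_control": cohort.n_control,
            "case_chromosomes": cohort.case_chromosomes,
            "control_chromosomes": cohort.control_chromosomes,
            "unresolved_dogs": sorted(phasing.unresolved_ids),
        },
        "alleles": {},
        "haplotypes": {},
    }

    allele_alpha = bonferroni_threshold(config.alpha, config.n_tests_per_locus)
    seed = config.seed
    for locus in LOCI:
        table = build_allele_table(cohort, locus)
        frame = _table_frame(table, config.alpha)
        frame.to_csv(config.output_dir / f"alleles_{locus.value}.csv",
                     index=False)
        t1 = clump_test(table, ClumpVariant.T1_ALL, config.trials, seed)
        t2 = clump_test(table, ClumpVariant.T2_CLUMPED, config.trials,
                        seed + 1)
        seed += 2
        summary["alleles"][locus.value] = {
            "categories": list(table.categories),
            "tests": {"T1": _clump_entry(t1), "T2": _clump_entry(t2)},
            "significance_threshold": allele_alpha,
            "significant": min(t1.p_empirical, t2.p_empirical) < allele_alpha,
        }

    hap_table = build_haplotype_table(
        phasing, cohort, allow_unresolved=config.allow_unresolved)
    filtered = filter_by_frequency(hap_table, config.min_freq,
                                   FilterScope.EITHER_GROUP)
    frame = _table_frame(hap_table, config.alpha)
    clumped = clump_test(hap_table, ClumpVariant.T2_CLUMPED, config.trials,
                         seed + 1).clumping_map
    frame["clumped"] = [clumped[c] == "clumped" for c in hap_table.categories]
    frame["passes_min_freq"] = [c in filtered.categories
                                for c in hap_table.categories]

    carrier_rows = []
    for cat in hap_table.categories:
        res = odds_ratio(
            carrier_table(phasing, cohort, Haplotype.from_label(cat),
                          allow_unresolved=config.allow_unresolved),
            alpha=config.alpha)
        carrier_rows.append(res)
    if config.or_level in ("carrier", "both"):
        frame["carrier_OR"] = [r.point for r in carrier_rows]
        frame["carrier_CI_low"] = [r.ci_low for r in carrier_rows]
        frame["carrier_CI_high"] = [r.ci_high for r in carrier_rows]
    if config.or_level == "carrier":
        frame = frame.drop(columns=["OR", "CI_low", "CI_high"])
    frame.to_csv(config.output_dir / "haplotypes.csv", index=False)

    t1 = clump_test(hap_table, ClumpVariant.T1_ALL, config.trials, seed)
    t2 = clump_test(hap_table, ClumpVariant.T2_CLUMPED, config.trials,
                    seed + 1)

    calls = {}
    for cat in hap_table.categories:
        # flagged only if the chromosome-level Woolf CI excludes 1
        chrom = odds_ratio(chromosome_table(hap_table, cat),
                           alpha=config.alpha)
        if chrom.ci_low is not None and chrom.ci_low > 1:
            calls[cat] = "risk"
        elif chrom.ci_high is not None and chrom.ci_high < 1:
            calls[cat] = "protective"
    summary["haplotypes"] = {
        "categories": list(hap_table.categories),
        "n_passing_min_freq": len(filtered.categories),
        "tests": {"T1": _clump_entry(t1), "T2": _clump_entry(t2)},
        "significance_threshold": config.alpha,
        "significant": min(t1.p_empirical, t2.p_empirical) < config.alpha,
        "direction_calls": calls,
    }

    with (config.output_dir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_text_report(summary, config.output_dir / "report.txt")
    return summary


def _write_text_report(summary: dict, path: Path) -> None:
    lines = [
        "DLA class II case-control association report",
        f"package version {summary['version']}",
        "",
        "cohort: {n_case} cases ({case_chromosomes} chromosomes), "
        "{n_control} controls ({control_chromosomes} chromosomes)".format(
            **summary["cohort"]),
    ]
    if summary["cohort"]["unresolved_dogs"]:
        lines.append("unresolved dogs: "
                     + ", ".join(summary["cohort"]["unresolved_dogs"]))
    lines.append("")
    for locus, entry in summary["alleles"].items():
        t = entry["tests"]
        lines.append(
            f"{locus}: T1 p={t['T1']['p']:.4g}, T2 p={t['T2']['p']:.4g} "
            f"(threshold {entry['significance_threshold']:.4g}, "
            f"{'significant' if entry['significant'] else 'not significant'})")
    h = summary["haplotypes"]
    t = h["tests"]
    lines.append(
        f"haplotypes: T1 p={t['T1']['p']:.4g}, T2 p={t['T2']['p']:.4g} "
        f"(threshold {h['significance_threshold']:.4g}, "
        f"{'significant' if h['significant'] else 'not significant'})")
    for cat, call in h["direction_calls"].items():
        lines.append(f"  {cat}: {call}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
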