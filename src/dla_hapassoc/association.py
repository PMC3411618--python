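"""Case-control association statistics on chromosome-count tables.

The analysis surface is a 2×n contingency table of chromosome counts
(cases vs controls over n alleles or haplotypes).  Significance is
assessed the way the CLUMP program does for sparse MHC tables:

* **T1** — Pearson's chi-squared on the full table, with significance
  taken not from the asymptotic distribution (invalid with sparse
  cells) but from Monte-Carlo resampling of tables with both margins
  fixed (sequential multivariate hypergeometric sampling, which is the
  uniform conditional null under independence).
* **T2** — the same Monte-Carlo test after *clumping*: every category
  whose expected count in either group falls below 5 is pooled, and the
  pooled clump keeps absorbing the smallest remaining category until
  its own expected counts reach 5 in both groups.  The partition is
  fixed by the observed table and reused for every simulated table, so
  observed and simulated statistics are computed on the same cells.

Empirical p-values carry the +1/+1 correction,
``p = (1 + #{sim >= obs}) / (1 + n_trials)``, so they are valid
p-values and never exactly zero.

Effect sizes are odds ratios from 2×2 collapses of the table, at
either the chromosome level (each dog contributes two observations) or
the carrier level (a dog either carries the haplotype or not), with
Woolf confidence intervals and the Haldane–Anscombe +0.5 correction
when a cell is empty.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, PhasingError, ValidationError
from .genotypes import Cohort, Haplotype, Locus, Status
from .phasing import PhasingResult

# frequencies are compared against thresholds like "1%" inclusively,
# with a tiny slack so 3/300 passes a 0.01 threshold despite float round-off
_FREQ_EPS = 1e-12
# float slack when counting simulated statistics >= the observed one
_TIE_EPS = 1e-9

OTHER_LABEL = "other"


class ClumpVariant(enum.Enum):
    T1_ALL = "T1_all"
    T2_CLUMPED = "T2_clumped"


class ExposureLevel(enum.Enum):
    CHROMOSOME = "chromosome"
    CARRIER = "carrier"


@dataclass(frozen=True)
class FrequencyTable:
    """Per-category chromosome counts split by cohort.

    ``case_total``/``control_total`` are the chromosome denominators
    (2 × dogs per group); after frequency filtering the column sums may
    fall below them, but frequencies are always counts over the full
    denominator, as in the source tables.
    """

    categories: tuple[str, ...]
    case_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    case_total: int
    control_total: int

    def __post_init__(self) -> None:
        k = len(self.categories)
        if len(self.case_counts) != k or len(self.control_counts) != k:
            raise ValidationError("count vectors must match category list")
        if len(set(self.categories)) != k:
            raise ValidationError("duplicate category labels")
        for c in (*self.case_counts, *self.control_counts):
            if int(c) != c or c < 0:
                raise ValidationError("counts must be nonnegative integers")
        if sum(self.case_counts) > self.case_total \
                or sum(self.control_counts) > self.control_total:
            raise ValidationError("column sums exceed stated totals")

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[tuple[str, int, int]],
        case_total: Optional[int] = None,
        control_total: Optional[int] = None,
    ) -> "FrequencyTable":
        labels = [c[0] for c in counts]
        case = [c[1] for c in counts]
        ctrl = [c[2] for c in counts]
        return cls(tuple(labels), tuple(case), tuple(ctrl),
                   case_total if case_total is not None else sum(case),
                   control_total if control_total is not None else sum(ctrl))

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def pooled_counts(self) -> tuple[int, ...]:
        return tuple(a + b for a, b in
                     zip(self.case_counts, self.control_counts))

    @property
    def case_frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.case_total for c in self.case_counts)

    @property
    def control_frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.control_total for c in self.control_counts)

    @property
    def pooled_frequencies(self) -> tuple[float, ...]:
        n = self.case_total + self.control_total
        return tuple(c / n for c in self.pooled_counts)

    def count_pair(self, category: str) -> tuple[int, int]:
        i = self.categories.index(category)
        return self.case_counts[i], self.control_counts[i]

    def to_arrays(self) -> np.ndarray:
        """2×n integer array, cases on the first row."""
        return np.array([self.case_counts, self.control_counts], dtype=np.int64)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed/unexposed counts: a,b are cases, c,d are controls."""

    a: int
    b: int
    c: int
    d: int
    level: ExposureLevel = ExposureLevel.CHROMOSOME

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 counts must be nonnegative")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def swapped(self) -> "TwoByTwo":
        """Cases and controls exchanged (OR reciprocity check)."""
        return TwoByTwo(self.c, self.d, self.a, self.b, self.level)


@dataclass(frozen=True)
class OddsRatioResult:
    point: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    alpha: float
    level: ExposureLevel
    haldane_corrected: bool


@dataclass(frozen=True)
class ClumpResult:
    statistic_observed: float
    p_empirical: float
    n_trials: int
    variant: ClumpVariant
    clumping_map: dict[str, str] = field(hash=False, default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_empirical <= 1.0):
            raise ValidationError("empirical p must lie in (0, 1]")


def build_allele_table(cohort: Cohort, locus: Locus) -> FrequencyTable:
    """Chromosome counts of every allele at one locus, cases vs controls.

    Categories are sorted by descending pooled count, ties by label.
    """
    case: dict[str, int] = {}
    ctrl: dict[str, int] = {}
    for r in cohort:
        bucket = case if r.status is Status.CASE else ctrl
        for a in r.genotype(locus).alleles:
            bucket[a] = bucket.get(a, 0) + 1
    labels = sorted(set(case) | set(ctrl),
                    key=lambda a: (-(case.get(a, 0) + ctrl.get(a, 0)), a))
    table = FrequencyTable(
        tuple(labels),
        tuple(case.get(a, 0) for a in labels),
        tuple(ctrl.get(a, 0) for a in labels),
        cohort.case_chromosomes,
        cohort.control_chromosomes,
    )
    assert sum(table.case_counts) == table.case_total
    assert sum(table.control_counts) == table.control_total
    return table


def build_haplotype_table(
    phasing: PhasingResult,
    cohort: Cohort,
    *,
    allow_unresolved: bool = False,
) -> FrequencyTable:
    """Chromosome counts of every assigned haplotype, cases vs controls."""
    unresolved = phasing.unresolved_ids
    if unresolved and not allow_unresolved:
        raise PhasingError(
            f"{len(unresolved)} unresolved dog(s): {sorted(unresolved)[:5]}; "
            "rerun with allow_unresolved to drop them")
    case: dict[Haplotype, int] = {}
    ctrl: dict[Haplotype, int] = {}
    n_case = n_control = 0
    for r in cohort:
        d = phasing.assignments.get(r.dog_id)
        if d is None:
            continue
        if r.status is Status.CASE:
            bucket, n_case = case, n_case + 1
        else:
            bucket, n_control = ctrl, n_control + 1
        for h in d.haplotypes:
            bucket[h] = bucket.get(h, 0) + 1
    haps = sorted(set(case) | set(ctrl),
                  key=lambda h: (-(case.get(h, 0) + ctrl.get(h, 0)), h))
    return FrequencyTable(
        tuple(h.label for h in haps),
        tuple(case.get(h, 0) for h in haps),
        tuple(ctrl.get(h, 0) for h in haps),
        2 * n_case,
        2 * n_control,
    )


class FilterScope(enum.Enum):
    EITHER_GROUP = "either_group"
    POOLED = "pooled"


def filter_by_frequency(
    table: FrequencyTable,
    min_freq: float,
    scope: FilterScope = FilterScope.EITHER_GROUP,
    *,
    pool_other: bool = False,
) -> FrequencyTable:
    """Keep categories reaching ``min_freq`` under the chosen scope.

    The threshold is inclusive (a category at exactly ``min_freq`` is
    kept).  With ``pool_other`` the removed categories are collapsed
    into a single ``"other"`` row instead of being dropped, preserving
    the column sums.
    """
    if not (0 <= min_freq < 1):
        raise ValidationError("min_freq must lie in [0, 1)")
    keep = []
    for i in range(len(table)):
        if scope is FilterScope.EITHER_GROUP:
            ok = (table.case_frequencies[i] >= min_freq - _FREQ_EPS
                  or table.control_frequencies[i] >= min_freq - _FREQ_EPS)
        else:
            ok = table.pooled_frequencies[i] >= min_freq - _FREQ_EPS
        keep.append(ok)
    labels = [c for c, k in zip(table.categories, keep) if k]
    case = [c for c, k in zip(table.case_counts, keep) if k]
    ctrl = [c for c, k in zip(table.control_counts, keep) if k]
    if pool_other and not all(keep):
        label = OTHER_LABEL
        while label in labels:  # avoid clashing with a real category
            label += "_"
        labels.append(label)
        case.append(sum(c for c, k in zip(table.case_counts, keep) if not k))
        ctrl.append(sum(c for c, k in zip(table.control_counts, keep) if not k))
    return FrequencyTable(tuple(labels), tuple(case), tuple(ctrl),
                          table.case_total, table.control_total)


def _nonempty(table: FrequencyTable) -> np.ndarray:
    obs = table.to_arrays()
    return obs[:, obs.sum(axis=0) > 0]


def chi_squared_statistic(table: FrequencyTable) -> float:
    """Pearson's statistic on the 2×n table, empty categories excluded."""
    obs = _nonempty(table)
    if obs.shape[1] < 2:
        raise DegenerateTableError(
            "chi-squared needs at least two non-empty categories")
    if obs.sum(axis=1).min() == 0:
        raise DegenerateTableError("a group has zero total count")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def clump_partition(table: FrequencyTable) -> dict[str, str]:
    """The T2 category partition: which labels fall into the clump.

    Every category whose expected count under the margins is below 5 in
    either group joins the clump; the clump then absorbs the smallest
    remaining category (by pooled count, ties by label) until its own
    expected counts reach 5 in both groups.  Returns a map
    ``category -> category-or-"clumped"``.
    """
    obs = table.to_arrays().astype(float)
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError("empty table")
    row_frac = obs.sum(axis=1) / n
    pooled = obs.sum(axis=0)
    expected_min = pooled * row_frac.min()

    clump = {table.categories[i] for i in range(len(table))
             if expected_min[i] < 5}
    if clump:
        order = sorted(
            (c for c in table.categories if c not in clump),
            key=lambda c: (sum(table.count_pair(c)), c))
        clump_total = sum(sum(table.count_pair(c)) for c in clump)
        for c in order:
            if clump_total * row_frac.min() >= 5:
                break
            clump.add(c)
            clump_total += sum(table.count_pair(c))
    if clump and len(table) - len(clump) < 1:
        raise DegenerateTableError(
            "clumping would pool the entire table into one category")
    return {c: ("clumped" if c in clump else c) for c in table.categories}


def clump_test(
    table: FrequencyTable,
    variant: ClumpVariant = ClumpVariant.T1_ALL,
    n_trials: int = 100_000,
    seed: int = 0,
) -> ClumpResult:
    """Monte-Carlo chi-squared emulation on a 2×n table (CLUMP T1/T2).

    Null tables are drawn uniformly from all tables sharing both
    margins with the observed one, by multivariate hypergeometric
    allocation of the case row.  Fixed seed gives a bit-identical
    result.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if len(table) < 2:
        raise DegenerateTableError("need at least two categories")

    if variant is ClumpVariant.T2_CLUMPED:
        mapping = clump_partition(table)
    else:
        mapping = {c: c for c in table.categories}

    group_labels: list[str] = []
    groups: list[list[int]] = []
    for i, c in enumerate(table.categories):
        g = mapping[c]
        if g not in group_labels:
            group_labels.append(g)
            groups.append([])
        groups[group_labels.index(g)].append(i)
    if len(groups) < 2:
        raise DegenerateTableError("fewer than two categories after clumping")

    obs = table.to_arrays()
    pooled = obs.sum(axis=0)
    nonzero = pooled > 0
    n_case, n_control = obs.sum(axis=1)
    if n_case == 0 or n_control == 0:
        raise DegenerateTableError("a group has zero total count")
    n = n_case + n_control

    obs_g = np.stack([obs[:, g].sum(axis=1) for g in groups], axis=-1)
    keep = obs_g.sum(axis=0) > 0
    obs_g = obs_g[:, keep]
    if obs_g.shape[1] < 2:
        raise DegenerateTableError("fewer than two non-empty categories")
    exp_case = obs_g.sum(axis=0) * (n_case / n)
    exp_ctrl = obs_g.sum(axis=0) * (n_control / n)
    stat_obs = float((((obs_g[0] - exp_case) ** 2) / exp_case).sum()
                     + (((obs_g[1] - exp_ctrl) ** 2) / exp_ctrl).sum())

    rng = np.random.default_rng(seed)
    # resample only over non-empty original categories (empty ones can
    # never receive a count when both margins are fixed)
    colors = pooled[nonzero]
    idx_map = np.flatnonzero(nonzero)
    sim_case_full = np.zeros((n_trials, len(table)), dtype=np.int64)
    sim_case_full[:, idx_map] = rng.multivariate_hypergeometric(
        colors, int(n_case), size=n_trials)
    sim_g = np.stack(
        [sim_case_full[:, g].sum(axis=1) for g in groups], axis=-1)[:, keep]
    sim_ctrl_g = obs_g.sum(axis=0)[np.newaxis, :] - sim_g
    sim_stat = (((sim_g - exp_case) ** 2 / exp_case).sum(axis=1)
                + ((sim_ctrl_g - exp_ctrl) ** 2 / exp_ctrl).sum(axis=1))
    exceed = int((sim_stat >= stat_obs - _TIE_EPS).sum())
    p = (1 + exceed) / (1 + n_trials)
    return ClumpResult(stat_obs, p, n_trials, variant, mapping, seed)


def odds_ratio(
    t: TwoByTwo,
    ci_method: str = "woolf",
    alpha: float = 0.05,
) -> OddsRatioResult:
    """Odds ratio ``ad/bc`` with an optional Woolf (log) interval.

    Empty cells get the Haldane–Anscombe +0.5 added to *all four*
    cells, flagged in the result.
    """
    if ci_method not in ("woolf", "none"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    corrected = t.has_zero_cell
    a, b, c, d = (x + 0.5 if corrected else float(x)
                  for x in (t.a, t.b, t.c, t.d))
    point = (a * d) / (b * c)
    if ci_method == "none":
        return OddsRatioResult(point, None, None, alpha, t.level, corrected)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = (math.exp(math.log(point) - z * se),
              math.exp(math.log(point) + z * se))
    return OddsRatioResult(point, lo, hi, alpha, t.level, corrected)


def chromosome_table(table: FrequencyTable, category: str) -> TwoByTwo:
    """2×2 chromosome-level collapse of one category of a frequency table."""
    a, c = table.count_pair(category)
    return TwoByTwo(a, table.case_total - a, c, table.control_total - c,
                    ExposureLevel.CHROMOSOME)


def carrier_table(
    phasing: PhasingResult,
    cohort: Cohort,
    h: Haplotype,
    *,
    allow_unresolved: bool = False,
) -> TwoByTwo:
    """Dog-level exposure: carries at least one copy of ``h`` or none."""
    unresolved = phasing.unresolved_ids
    if unresolved and not allow_unresolved:
        raise PhasingError(
            f"{len(unresolved)} unresolved dog(s) present")
    a = b = c = d = 0
    for r in cohort:
        dip = phasing.assignments.get(r.dog_id)
        if dip is None:
            continue
        carries = dip.count_of(h) > 0
        if r.status is Status.CASE:
            a, b = a + carries, b + (not carries)
        else:
            c, d = c + carries, d + (not carries)
    return TwoByTwo(a, b, c, d, ExposureLevel.CARRIER)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha/n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    return alpha / n_tests
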