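"""Synthetic case-control cohorts with known phase.

Two generators:

* :func:`simulate` draws a cohort from a :class:`PopulationModel`:
  diplotypes form by Hardy–Weinberg random mating over a haplotype
  pool, and disease status is Bernoulli with odds multiplicative over
  the dog's two haplotypes.  Sampling rejects until exactly the
  requested numbers of cases and controls are collected, mimicking a
  case-control ascertainment design.  The ground-truth phase of every
  dog is retained, so phasing accuracy is directly measurable.

* :func:`fixture_from_tables` deterministically expands the published
  ESS chromosome counts into 66 case and 84 control diplotypes whose
  margins equal the published table exactly and which contain exactly
  the stated homozygotes (one case and two controls for the risk
  haplotype, none for the protective one).  The pairing of the
  remaining chromosomes is not knowable from printed margins; the rule
  used here (homozygote-constrained haplotypes paired against the most
  abundant partner, then homozygote pairs, then leftovers in table
  order) is one admissible choice, and every statistic the analysis
  reports depends only on the margins and the stated homozygote facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import reference_data as ref
from .errors import SimulationError, ValidationError
from .genotypes import (
    Cohort,
    Diplotype,
    Haplotype,
    Provenance,
    Status,
    cohort_from_diplotypes,
)

_MAX_DRAW_BATCHES = 1000


@dataclass
class PopulationModel:
    """A haplotype pool plus a multiplicative disease-odds model.

    ``effects[h]`` multiplies a dog's disease odds once per copy of
    ``h`` carried (1.0 = no effect), on top of ``baseline_odds`` —
    the simplest model producing haplotype-level odds ratios on the
    scale case-control studies report.
    """

    haplotypes: Sequence[Haplotype]
    frequencies: Sequence[float]
    effects: dict[Haplotype, float] = field(default_factory=dict)
    baseline_odds: float = 0.25
    n_case: int = 66
    n_control: int = 84
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if len(f) != len(self.haplotypes) or len(f) == 0:
            raise ValidationError("need one frequency per haplotype")
        if (f <= 0).any() or f.max() > 1:
            raise ValidationError("frequencies must lie in (0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("frequencies must sum to 1")
        if any(e <= 0 for e in self.effects.values()):
            raise ValidationError("effects must be positive odds multipliers")
        if self.baseline_odds <= 0:
            raise ValidationError("baseline_odds must be positive")
        if self.n_case < 0 or self.n_control < 0:
            raise ValidationError("cohort sizes must be nonnegative")

    @classmethod
    def from_reference_controls(
        cls,
        effects: Optional[dict[Haplotype, float]] = None,
        **kwargs,
    ) -> "PopulationModel":
        """Pool = the published ESS control haplotype frequencies."""
        pool = ref.control_haplotype_frequencies()
        return cls(
            haplotypes=[h for h, _ in pool],
            frequencies=[f for _, f in pool],
            effects=effects or {},
            **kwargs,
        )


@dataclass
class SimulatedCohort:
    """An unphased cohort plus the ground-truth phase of every dog."""

    cohort: Cohort
    truth: dict[str, Diplotype]

    def accuracy_of(self, assignments: dict[str, Optional[Diplotype]]) -> float:
        """Per-chromosome share of correctly assigned haplotypes.

        Unresolved dogs count as two wrong chromosomes.
        """
        total = correct = 0
        for dog_id, true_d in self.truth.items():
            total += 2
            got = assignments.get(dog_id)
            if got is None:
                continue
            true_haps = list(true_d.haplotypes)
            for h in got.haplotypes:
                if h in true_haps:
                    true_haps.remove(h)
                    correct += 1
        return correct / total if total else 1.0


def simulate(model: PopulationModel) -> SimulatedCohort:
    """Draw a case-control cohort from the population model."""
    rng = np.random.default_rng(model.seed)
    k = len(model.haplotypes)
    freqs = np.asarray(model.frequencies, dtype=float)
    freqs = freqs / freqs.sum()
    eff = np.array([model.effects.get(h, 1.0) for h in model.haplotypes])

    cases: list[Diplotype] = []
    controls: list[Diplotype] = []
    batch = max(64, 2 * (model.n_case + model.n_control))
    for _ in range(_MAX_DRAW_BATCHES):
        if len(cases) >= model.n_case and len(controls) >= model.n_control:
            break
        i1 = rng.choice(k, size=batch, p=freqs)
        i2 = rng.choice(k, size=batch, p=freqs)
        odds = model.baseline_odds * eff[i1] * eff[i2]
        is_case = rng.random(batch) < odds / (1.0 + odds)
        for a, b, c in zip(i1, i2, is_case):
            bucket = cases if c else controls
            need = model.n_case if c else model.n_control
            if len(bucket) < need:
                bucket.append(Diplotype(model.haplotypes[a],
                                        model.haplotypes[b],
                                        Provenance.SIMULATED))
    else:
        raise SimulationError(
            "could not fill the requested case/control counts; "
            "check baseline_odds and effects")

    width = len(str(max(model.n_case, model.n_control, 1)))
    pairs = [(f"case{i + 1:0{width}d}", Status.CASE, d)
             for i, d in enumerate(cases)]
    pairs += [(f"ctrl{i + 1:0{width}d}", Status.CONTROL, d)
              for i, d in enumerate(controls)]
    cohort, truth = cohort_from_diplotypes(pairs)
    return SimulatedCohort(cohort, truth)


def _expand_group(
    counts: list[tuple[Haplotype, int]],
    homozygotes: dict[Haplotype, int],
) -> list[Diplotype]:
    """Pair one group's chromosomes into diplotypes, deterministically.

    ``homozygotes`` states exactly how many homozygous dogs each listed
    haplotype has; those haplotypes form no further homozygotes.  All
    remaining chromosomes of a constrained haplotype are paired against
    the currently most abundant unconstrained haplotype (ties broken by
    table order); unconstrained haplotypes then pair with themselves,
    and the odd leftovers pair up in table order.
    """
    order = [h for h, _ in counts]
    remaining = {h: c for h, c in counts}
    pairs: list[Diplotype] = []

    for h, n_hom in homozygotes.items():
        if remaining.get(h, 0) < 2 * n_hom:
            raise ValidationError(
                f"{h.label}: {n_hom} homozygotes need {2 * n_hom} chromosomes")
        pairs.extend(Diplotype(h, h, Provenance.SIMULATED)
                     for _ in range(n_hom))
        remaining[h] -= 2 * n_hom

    constrained = [h for h in order if h in homozygotes]
    for h in constrained:
        while remaining[h] > 0:
            partners = [p for p in order
                        if p not in homozygotes and remaining[p] > 0]
            if not partners:
                raise ValidationError(
                    f"cannot pair {h.label} without creating an extra "
                    "homozygote")
            partner = max(partners, key=lambda p: remaining[p])
            pairs.append(Diplotype(h, partner, Provenance.SIMULATED))
            remaining[h] -= 1
            remaining[partner] -= 1

    for h in order:
        if h in homozygotes:
            continue
        n_hom, remaining[h] = divmod(remaining[h], 2)
        pairs.extend(Diplotype(h, h, Provenance.SIMULATED)
                     for _ in range(n_hom))

    leftovers = [h for h in order if remaining[h] == 1]
    if len(leftovers) % 2:
        raise ValidationError("odd chromosome total cannot be paired")
    for a, b in zip(leftovers[::2], leftovers[1::2]):
        pairs.append(Diplotype(a, b, Provenance.SIMULATED))
    return pairs


def fixture_from_tables() -> SimulatedCohort:
    """The published ESS cohort, reconstructed from its printed counts.

    Deterministic: repeated calls give identical cohorts.  Margins per
    haplotype equal the published chromosome counts in both groups, and
    the homozygote facts stated in the study text hold exactly.
    """
    case_counts = [(h, ca) for _, h, ca, _ in ref.HAPLOTYPE_COUNTS]
    case_counts.append((ref.OTHER_CASE_HAPLOTYPE, 1))
    ctrl_counts = [(h, co) for _, h, _, co in ref.HAPLOTYPE_COUNTS]
    ctrl_counts.append((ref.OTHER_CONTROL_HAPLOTYPE, 1))

    case_hom = {h: n[0] for h, n in ref.HOMOZYGOTE_COUNTS.items()}
    ctrl_hom = {h: n[1] for h, n in ref.HOMOZYGOTE_COUNTS.items()}

    case_pairs = _expand_group([(h, c) for h, c in case_counts if c > 0],
                               case_hom)
    ctrl_pairs = _expand_group([(h, c) for h, c in ctrl_counts if c > 0],
                               ctrl_hom)
    assert len(case_pairs) == ref.N_CASE_DOGS
    assert len(ctrl_pairs) == ref.N_CONTROL_DOGS

    pairs = [(f"case{i + 1:03d}", Status.CASE, d)
             for i, d in enumerate(case_pairs)]
    pairs += [(f"ctrl{i + 1:03d}", Status.CONTROL, d)
              for i, d in enumerate(ctrl_pairs)]
    cohort, truth = cohort_from_diplotypes(pairs)
    return SimulatedCohort(cohort, truth)
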