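"""Homozygote-anchored sequential phasing of three-locus genotypes.

Because DLA class II alleles travel in tightly linked DRB1/DQA1/DQB1
blocks, a breed cohort typically segregates only a handful of haplotypes
and phase can be recovered combinatorially rather than statistically:

1. **Triple homozygotes** carry two copies of one haplotype; each one
   anchors that haplotype with certainty.
2. **Double homozygotes** (homozygous at exactly two loci) split their
   single heterozygous locus across two otherwise-identical haplotypes —
   the decomposition is forced, confirming known haplotypes or adding
   new ones.
3. **Remaining dogs** are resolved against the accumulated known set:
   among the at most four phase configurations of a three-locus
   genotype, a dog is assigned the configuration whose two haplotypes
   are both already known.  If no such pair exists but exactly one
   configuration pairs one known haplotype with one new one, that new
   haplotype is proposed; dogs whose genotypes would require inventing
   two haplotypes at once stay unresolved.  The pass is repeated (the
   known set only grows) until nothing changes.

The module also provides :func:`oracle_enumerate`, a brute-force
enumeration of every phase-consistent diplotype, used as the
independent oracle in tests.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .genotypes import (
    LOCI,
    Cohort,
    Diplotype,
    DogRecord,
    Haplotype,
    Provenance,
)

MAX_PASSES = 10


class KnownHaplotypeSet:
    """Haplotypes established so far, with observation tallies.

    The tally (number of chromosomes on which a haplotype has been
    seen) is the tie-breaking weight when a genotype admits more than
    one known-pair decomposition.
    """

    def __init__(self, seed: Optional[Iterable[Haplotype]] = None) -> None:
        self._counts: Counter[Haplotype] = Counter()
        self._seeded: set[Haplotype] = set(seed or ())

    def add(self, h: Haplotype, n: int = 1) -> None:
        if n < 0:
            raise ValueError("haplotype tally increments must be >= 0")
        self._counts[h] += n

    def count(self, h: Haplotype) -> int:
        return self._counts[h]

    def __contains__(self, h: Haplotype) -> bool:
        return self._counts[h] > 0 or h in self._seeded

    def __len__(self) -> int:
        return len(set(self._counts) | self._seeded)

    def __iter__(self):
        return iter(sorted(set(self._counts) | self._seeded))

    def copy(self) -> "KnownHaplotypeSet":
        new = KnownHaplotypeSet(self._seeded)
        new._counts = self._counts.copy()
        return new


@dataclass
class PassLogEntry:
    pass_name: str
    dog_id: str
    detail: str = ""


@dataclass
class PhasingResult:
    """Outcome of phasing: per-dog assignments, novelties and a pass log."""

    assignments: dict[str, Optional[Diplotype]] = field(default_factory=dict)
    novel_haplotypes: set[Haplotype] = field(default_factory=set)
    pass_log: list[PassLogEntry] = field(default_factory=list)
    known: KnownHaplotypeSet = field(default_factory=KnownHaplotypeSet)

    @property
    def unresolved_ids(self) -> list[str]:
        return [d for d, a in self.assignments.items() if a is None]

    @property
    def n_resolved(self) -> int:
        return sum(a is not None for a in self.assignments.values())

    def haplotype_counts(self, cohort: Cohort) -> dict[Haplotype, Counter]:
        """Chromosome tallies per haplotype, keyed then split by status."""
        out: dict[Haplotype, Counter] = {}
        for r in cohort:
            d = self.assignments.get(r.dog_id)
            if d is None:
                continue
            for h in d.haplotypes:
                out.setdefault(h, Counter())[r.status] += 1
        return out


def oracle_enumerate(record: DogRecord) -> list[Diplotype]:
    """Enumerate every diplotype consistent with a dog's genotypes.

    A genotype heterozygous at ``h`` loci has ``2**(h-1)`` distinct phase
    configurations (``1`` for a triple homozygote): fixing the first
    heterozygous locus's orientation and flipping the rest.  Brute force
    over all ``2**3`` orientations with deduplication — small enough to
    serve as the exhaustive oracle.
    """
    allele_pairs = [record.genotype(l).alleles for l in LOCI]
    seen: set[Diplotype] = set()
    out: list[Diplotype] = []
    for flips in itertools.product((0, 1), repeat=3):
        h1 = Haplotype(*(pair[f] for pair, f in zip(allele_pairs, flips)))
        h2 = Haplotype(*(pair[1 - f] for pair, f in zip(allele_pairs, flips)))
        d = Diplotype(h1, h2)
        if d not in seen:
            seen.add(d)
            out.append(d)
    return sorted(out, key=lambda d: (d.h1, d.h2))


def phase_triple_homozygotes(
    cohort: Cohort,
    result: Optional[PhasingResult] = None,
) -> PhasingResult:
    """Pass 1: assign every dog homozygous at all three loci."""
    result = result or PhasingResult()
    for r in cohort:
        if r.n_homozygous_loci != 3 or r.dog_id in result.assignments:
            continue
        h = Haplotype(*(r.genotype(l).alleles[0] for l in LOCI))
        if h not in result.known:
            result.novel_haplotypes.add(h)
        result.known.add(h, 2)
        result.assignments[r.dog_id] = Diplotype(
            h, h, Provenance.TRIPLE_HOMOZYGOTE)
        result.pass_log.append(
            PassLogEntry("triple_homozygote", r.dog_id, h.label))
    return result


def phase_double_homozygotes(
    cohort: Cohort,
    result: Optional[PhasingResult] = None,
) -> PhasingResult:
    """Pass 2: dogs homozygous at exactly two loci have a forced split."""
    result = result or PhasingResult()
    for r in cohort:
        if r.n_homozygous_loci != 2 or r.dog_id in result.assignments:
            continue
        (het,) = r.heterozygous_loci()
        a1, a2 = r.genotype(het).alleles
        shared = {l: r.genotype(l).alleles[0] for l in LOCI if l is not het}

        def build(a: str) -> Haplotype:
            return Haplotype(*(a if l is het else shared[l] for l in LOCI))

        h1, h2 = build(a1), build(a2)
        for h in (h1, h2):
            if h not in result.known:
                result.novel_haplotypes.add(h)
            result.known.add(h, 1)
        result.assignments[r.dog_id] = Diplotype(
            h1, h2, Provenance.DOUBLE_HOMOZYGOTE)
        result.pass_log.append(
            PassLogEntry("double_homozygote", r.dog_id,
                         f"{h1.label} + {h2.label}"))
    return result


def resolve_from_known(
    record: DogRecord,
    known: KnownHaplotypeSet,
) -> list[Diplotype]:
    """All phase configurations whose two haplotypes are both known.

    Sorted by descending combined observation tally, ties broken
    lexicographically, so the head of the list is the preferred
    (most frequently observed) decomposition.
    """
    candidates = [
        d for d in oracle_enumerate(record)
        if d.h1 in known and d.h2 in known
    ]
    candidates.sort(key=lambda d: (-(known.count(d.h1) + known.count(d.h2)),
                                   d.h1, d.h2))
    return candidates


def _novel_proposals(
    record: DogRecord,
    known: KnownHaplotypeSet,
) -> list[Diplotype]:
    """Configurations pairing exactly one known with one new haplotype."""
    return [
        d for d in oracle_enumerate(record)
        if (d.h1 in known) != (d.h2 in known)
    ]


def assign_all(
    cohort: Cohort,
    seed_known: Optional[KnownHaplotypeSet] = None,
) -> PhasingResult:
    """Run the full sequential phasing process over a cohort.

    Deterministic given input order: within every pass dogs are
    processed in cohort order, and ambiguity is broken by observation
    tally then lexicographic order.  Unresolved dogs are reported in
    the result, never dropped.
    """
    result = PhasingResult(known=seed_known.copy() if seed_known
                           else KnownHaplotypeSet())
    phase_triple_homozygotes(cohort, result)
    phase_double_homozygotes(cohort, result)

    for pass_no in range(MAX_PASSES):
        changed = False
        for r in cohort:
            if r.dog_id in result.assignments:
                continue
            candidates = resolve_from_known(r, result.known)
            if candidates:
                best = candidates[0]
                d = Diplotype(best.h1, best.h2, Provenance.RESOLVED_FROM_KNOWN)
                detail = f"{d.h1.label} + {d.h2.label}"
                if len(candidates) > 1:
                    detail += f" (ambiguous among {len(candidates)}, " \
                              "highest-tally pair chosen)"
                for h in d.haplotypes:
                    result.known.add(h, 1)
                result.assignments[r.dog_id] = d
                result.pass_log.append(PassLogEntry(
                    f"resolve_from_known[{pass_no + 1}]", r.dog_id, detail))
                changed = True
                continue
            proposals = _novel_proposals(r, result.known)
            if len(proposals) == 1:
                best = proposals[0]
                d = Diplotype(best.h1, best.h2, Provenance.NOVEL_PROPOSED)
                new = d.h1 if d.h1 not in result.known else d.h2
                result.novel_haplotypes.add(new)
                for h in d.haplotypes:
                    result.known.add(h, 1)
                result.assignments[r.dog_id] = d
                result.pass_log.append(PassLogEntry(
                    f"novel_proposed[{pass_no + 1}]", r.dog_id,
                    f"{d.h1.label} + {d.h2.label} (new: {new.label})"))
                changed = True
        if not changed:
            break

    for r in cohort:
        if r.dog_id not in result.assignments:
            result.assignments[r.dog_id] = None
            result.pass_log.append(PassLogEntry("unresolved", r.dog_id))

    # conservation is a hard invariant: every assignment must re-emit
    # exactly the genotype it was derived from
    for r in cohort:
        d = result.assignments[r.dog_id]
        if d is not None:
            assert d.matches(r), f"conservation violated for {r.dog_id}"
    return result
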