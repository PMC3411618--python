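"""Domain types and file I/O for unphased three-locus DLA class II genotypes.

The unit of observation is a dog typed at the three polymorphic class II
loci DRB1, DQA1 and DQB1.  Allele labels are the bare digit strings of
standard DLA nomenclature (e.g. ``"00501"``, ``"013017"``, ``"012v"``)
and are preserved byte-for-byte — ``"00501"`` and ``"501"`` are distinct
alleles.  Frequencies throughout the package are chromosome-level: every
dog contributes two chromosomes, so a cohort of ``n`` dogs has ``2n``
chromosomes per group.

Genotype files are plain TSV with the fixed header::

    dog_id  status  DRB1_1  DRB1_2  DQA1_1  DQA1_2  DQB1_1  DQB1_2

where ``status`` is ``case`` or ``control``.  Phased output files carry
one row per dog with the two haplotypes slash-joined as
``DRB1/DQA1/DQB1`` plus the provenance of the assignment.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "-"

GENOTYPE_HEADER = [
    "dog_id", "status",
    "DRB1_1", "DRB1_2", "DQA1_1", "DQA1_2", "DQB1_1", "DQB1_2",
]

DIPLOTYPE_HEADER = ["dog_id", "status", "hap1", "hap2", "provenance"]


class Locus(enum.Enum):
    """The three polymorphic DLA class II loci, in chromosomal order."""

    DRB1 = "DRB1"
    DQA1 = "DQA1"
    DQB1 = "DQB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LOCI: tuple[Locus, Locus, Locus] = (Locus.DRB1, Locus.DQA1, Locus.DQB1)


class Status(enum.Enum):
    CASE = "case"
    CONTROL = "control"

    @classmethod
    def parse(cls, token: str) -> "Status":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValidationError(f"unknown status token {token!r}") from None


class Provenance(enum.Enum):
    """How a diplotype assignment was obtained during phasing."""

    TRIPLE_HOMOZYGOTE = "triple_homozygote"
    DOUBLE_HOMOZYGOTE = "double_homozygote"
    RESOLVED_FROM_KNOWN = "resolved_from_known"
    NOVEL_PROPOSED = "novel_proposed"
    SIMULATED = "simulated"


@dataclass(frozen=True)
class AlleleCall:
    """A locus-qualified allele label."""

    locus: Locus
    allele: str

    def __post_init__(self) -> None:
        if not self.allele:
            raise ValidationError("allele label must be a nonempty string")


class Haplotype(NamedTuple):
    """An ordered DRB1/DQA1/DQB1 allele triple — one chromosome's worth."""

    drb1: str
    dqa1: str
    dqb1: str

    def allele(self, locus: Locus) -> str:
        return {Locus.DRB1: self.drb1, Locus.DQA1: self.dqa1,
                Locus.DQB1: self.dqb1}[locus]

    @property
    def label(self) -> str:
        return f"{self.drb1}/{self.dqa1}/{self.dqb1}"

    @classmethod
    def from_label(cls, label: str) -> "Haplotype":
        parts = label.split("/")
        if len(parts) != 3 or not all(parts):
            raise ParseError(f"malformed haplotype label {label!r}")
        return cls(*parts)


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered pair of allele labels at one locus (may be equal)."""

    locus: Locus
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or not all(self.alleles):
            raise ValidationError(
                f"{self.locus}: genotype needs exactly two allele labels")
        # canonical order so that unordered pairs compare equal
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def multiset(self) -> Counter:
        return Counter(self.alleles)


@dataclass(frozen=True)
class DogRecord:
    """One animal: identifier, cohort label and its three locus genotypes."""

    dog_id: str
    status: Status
    genotypes: Mapping[Locus, LocusGenotype]

    def __post_init__(self) -> None:
        if set(self.genotypes) != set(LOCI):
            raise ValidationError(
                f"dog {self.dog_id!r}: need exactly one genotype per locus")
        object.__setattr__(self, "genotypes", dict(self.genotypes))

    def genotype(self, locus: Locus) -> LocusGenotype:
        return self.genotypes[locus]

    @property
    def n_homozygous_loci(self) -> int:
        return sum(self.genotypes[l].is_homozygous for l in LOCI)

    def heterozygous_loci(self) -> list[Locus]:
        return [l for l in LOCI if not self.genotypes[l].is_homozygous]


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of haplotypes carried by one dog."""

    h1: Haplotype
    h2: Haplotype
    provenance: Provenance = Provenance.RESOLVED_FROM_KNOWN

    def __post_init__(self) -> None:
        # canonical order; provenance is annotation, not identity
        if self.h2 < self.h1:
            lo, hi = self.h2, self.h1
            object.__setattr__(self, "h1", lo)
            object.__setattr__(self, "h2", hi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return {self.h1, self.h2} == {other.h1, other.h2}

    def __hash__(self) -> int:
        return hash(frozenset((self.h1, self.h2)))

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.h1, self.h2)

    @property
    def is_homozygous(self) -> bool:
        return self.h1 == self.h2

    def count_of(self, h: Haplotype) -> int:
        return (self.h1 == h) + (self.h2 == h)

    def matches(self, record: DogRecord) -> bool:
        """Conservation: per-locus allele multisets equal the genotype's."""
        return all(
            Counter((self.h1.allele(l), self.h2.allele(l)))
            == record.genotype(l).multiset()
            for l in LOCI
        )

    def to_genotypes(self, status: Status, dog_id: str) -> DogRecord:
        """Strip phase: re-emit the unphased genotypes this pair implies."""
        return DogRecord(
            dog_id=dog_id,
            status=status,
            genotypes={
                l: LocusGenotype(l, (self.h1.allele(l), self.h2.allele(l)))
                for l in LOCI
            },
        )


@dataclass
class Cohort:
    """A case-control collection of dog records.

    Chromosome totals are exactly twice the dog totals in each group;
    that identity is the denominator of every frequency in the package.
    """

    records: list[DogRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.dog_id in seen:
                raise ValidationError(f"duplicate dog_id {r.dog_id!r}")
            seen.add(r.dog_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_case(self) -> int:
        return sum(r.status is Status.CASE for r in self.records)

    @property
    def n_control(self) -> int:
        return sum(r.status is Status.CONTROL for r in self.records)

    @property
    def case_chromosomes(self) -> int:
        return 2 * self.n_case

    @property
    def control_chromosomes(self) -> int:
        return 2 * self.n_control

    def by_status(self, status: Status) -> list[DogRecord]:
        return [r for r in self.records if r.status is status]

    def record(self, dog_id: str) -> DogRecord:
        for r in self.records:
            if r.dog_id == dog_id:
                return r
        raise ValidationError(f"unknown dog_id {dog_id!r}")


def read_genotypes(
    path: str | Path,
    *,
    missing_policy: str = "error",
    known_alleles: Optional[Mapping[Locus, Iterable[str]]] = None,
) -> Cohort:
    """Read a genotype TSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        TSV file with the documented 8-column header.
    missing_policy
        ``"error"`` (default) rejects a row containing the missing token
        ``"-"`` with a hard error; ``"drop"`` skips it with a warning.
    known_alleles
        Optional per-locus allele lists.  Labels outside the list are
        accepted with a warning — published breed panels are incomplete
        and variant labels (e.g. ``"012v"``) are legitimate calls.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    known = {l: set(v) for l, v in (known_alleles or {}).items()}
    records: list[DogRecord] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENOTYPE_HEADER:
            raise ParseError(
                f"{path}:1: bad header {header!r}; expected {GENOTYPE_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(GENOTYPE_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(GENOTYPE_HEADER)} "
                    f"columns, got {len(fields)}")
            dog_id, status_tok, *alleles = fields
            if MISSING_TOKEN in alleles:
                if missing_policy == "drop":
                    logger.warning("%s:%d: dropping %s (missing genotype)",
                                   path, lineno, dog_id)
                    continue
                raise ParseError(
                    f"{path}:{lineno}: missing allele token for {dog_id!r}")
            status = Status.parse(status_tok)
            genotypes = {}
            for i, locus in enumerate(LOCI):
                a1, a2 = alleles[2 * i], alleles[2 * i + 1]
                for a in (a1, a2):
                    if locus in known and a not in known[locus]:
                        logger.warning(
                            "%s:%d: allele %s*%s not in known-allele list",
                            path, lineno, locus.value, a)
                genotypes[locus] = LocusGenotype(locus, (a1, a2))
            records.append(DogRecord(dog_id, status, genotypes))
    return Cohort(records)


def write_genotypes(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the genotype TSV dialect (input row order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GENOTYPE_HEADER) + "\n")
        for r in cohort:
            row = [r.dog_id, r.status.value]
            for locus in LOCI:
                row.extend(r.genotype(locus).alleles)
            fh.write("\t".join(row) + "\n")


def write_diplotypes(
    cohort: Cohort,
    assignments: Mapping[str, Optional[Diplotype]],
    path: str | Path,
) -> None:
    """Write phased diplotypes, one row per dog, sorted by dog_id.

    Unresolved dogs (``None`` assignment) are written with the marker
    ``"-"`` in the haplotype columns so they are never silently dropped.
    """
    ids = {r.dog_id for r in cohort}
    unknown = set(assignments) - ids
    if unknown:
        raise ValidationError(
            f"assignments for unknown dog_ids: {sorted(unknown)}")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(DIPLOTYPE_HEADER) + "\n")
        for r in sorted(cohort, key=lambda r: r.dog_id):
            d = assignments.get(r.dog_id)
            if d is None:
                row = [r.dog_id, r.status.value,
                       MISSING_TOKEN, MISSING_TOKEN, "unresolved"]
            else:
                if not d.matches(r):
                    raise ValidationError(
                        f"diplotype for {r.dog_id!r} does not conserve "
                        "its genotype alleles")
                row = [r.dog_id, r.status.value,
                       d.h1.label, d.h2.label, d.provenance.value]
            fh.write("\t".join(row) + "\n")


def read_diplotypes(
    path: str | Path,
) -> tuple[Cohort, dict[str, Optional[Diplotype]]]:
    """Read a phased TSV back into an (unphased cohort, assignments) pair.

    Inverse of :func:`write_diplotypes` up to row order (sorted by dog_id).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records: list[DogRecord] = []
    assignments: dict[str, Optional[Diplotype]] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DIPLOTYPE_HEADER:
            raise ParseError(
                f"{path}:1: bad header {header!r}; expected {DIPLOTYPE_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(DIPLOTYPE_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(DIPLOTYPE_HEADER)} "
                    f"columns, got {len(fields)}")
            dog_id, status_tok, hap1, hap2, prov = fields
            status = Status.parse(status_tok)
            if hap1 == MISSING_TOKEN or hap2 == MISSING_TOKEN:
                raise ParseError(
                    f"{path}:{lineno}: unresolved dog {dog_id!r} cannot be "
                    "re-imported as a phased record")
            d = Diplotype(Haplotype.from_label(hap1), Haplotype.from_label(hap2),
                          Provenance(prov))
            records.append(d.to_genotypes(status, dog_id))
            assignments[dog_id] = d
    return Cohort(records), assignments


def cohort_from_diplotypes(
    pairs: Sequence[tuple[str, Status, Diplotype]],
) -> tuple[Cohort, dict[str, Diplotype]]:
    """Build an unphased cohort plus truth map from (id, status, diplotype)."""
    records = [d.to_genotypes(status, dog_id) for dog_id, status, d in pairs]
    truth = {dog_id: d for dog_id, _, d in pairs}
    return Cohort(records), truth
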