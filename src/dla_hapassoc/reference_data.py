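"""Published DLA class II counts for the English Springer Spaniel
chronic-hepatitis case-control cohort (66 cases, 84 controls).

These are the chromosome-count tables from the sequence-based typing
study of DRB1/DQA1/DQB1 in ESSs with chronic hepatitis: the DRB1 allele
table, the three-locus haplotype table, and the homozygote facts stated
alongside them.  They are the real inputs of the analysis — no raw
genotypes were deposited — and everything downstream (fixture cohort,
Monte-Carlo tests, odds ratios) is derived from them.

Haplotype numbering follows the published table: haplotype 4
(00601/005011/00701) is the risk haplotype, haplotype 8
(00501/00301/00501) the protective one.
"""

from __future__ import annotations

from .genotypes import Haplotype

N_CASE_DOGS = 66
N_CONTROL_DOGS = 84
CASE_CHROMOSOMES = 2 * N_CASE_DOGS      # 132
CONTROL_CHROMOSOMES = 2 * N_CONTROL_DOGS  # 168

# DRB1 allele chromosome counts: label -> (cases, controls)
DRB1_ALLELE_COUNTS: list[tuple[str, int, int]] = [
    ("00101", 11, 11),
    ("00501", 4, 20),
    ("00601", 19, 11),
    ("00901", 1, 3),
    ("01201", 30, 43),
    ("01501", 50, 68),
    ("01502", 2, 0),
    ("02001", 14, 11),
    ("02301", 1, 0),
    ("012v", 0, 1),
]

# Three-locus haplotypes, in published numbering, with chromosome counts
HAPLOTYPE_COUNTS: list[tuple[int, Haplotype, int, int]] = [
    (1, Haplotype("01501", "00601", "00301"), 26, 42),
    (2, Haplotype("01201", "00401", "01303"), 24, 43),
    (3, Haplotype("01501", "00601", "02002"), 23, 24),
    (4, Haplotype("00601", "005011", "00701"), 19, 11),
    (5, Haplotype("02001", "00401", "01303"), 14, 11),
    (6, Haplotype("00101", "00201", "01303"), 11, 11),
    (7, Haplotype("01201", "00401", "013017"), 6, 0),
    (8, Haplotype("00501", "00301", "00501"), 4, 20),
    (9, Haplotype("01502", "00601", "02301"), 2, 0),
    (10, Haplotype("00901", "00101", "008011"), 1, 3),
    (11, Haplotype("01501", "00601", "02301"), 1, 2),
]

RISK_HAPLOTYPE = HAPLOTYPE_COUNTS[3][1]        # number 4
PROTECTIVE_HAPLOTYPE = HAPLOTYPE_COUNTS[7][1]  # number 8

# The published table closes with an "other single haplotypes" row of
# one case and one control chromosome.  The exact triples are not
# printed; the fixture represents them as one distinct singleton
# haplotype per group, with allele composition chosen to be consistent
# with every allele count the study text does print: the case singleton
# carries DRB1*02301 (completing the DRB1 margin), DQA1*00401 (33.0%)
# and DQB1*00501 (5 case chromosomes, 3.8%); the control singleton
# carries DRB1*012v, DQA1*00201 and DQB1*01303 (38.3% overall).
OTHER_CASE_HAPLOTYPE = Haplotype("02301", "00401", "00501")
OTHER_CONTROL_HAPLOTYPE = Haplotype("012v", "00201", "01303")

# Homozygote facts stated in the study text: one affected and two
# control dogs were homozygous for the risk haplotype; no dog in either
# group was homozygous for the protective haplotype.
HOMOZYGOTE_COUNTS: dict[Haplotype, tuple[int, int]] = {
    RISK_HAPLOTYPE: (1, 2),
    PROTECTIVE_HAPLOTYPE: (0, 0),
}


def haplotype_table_rows(*, merge_other: bool = True
                         ) -> list[tuple[str, int, int]]:
    """The published 2×12 haplotype table as (label, cases, controls).

    With ``merge_other`` (default) the two singletons are pooled into a
    single ``"other"`` row, exactly as printed; otherwise each singleton
    appears under its own haplotype label.
    """
    rows = [(h.label, ca, co) for _, h, ca, co in HAPLOTYPE_COUNTS]
    if merge_other:
        rows.append(("other", 1, 1))
    else:
        rows.append((OTHER_CASE_HAPLOTYPE.label, 1, 0))
        rows.append((OTHER_CONTROL_HAPLOTYPE.label, 0, 1))
    return rows


def control_haplotype_frequencies() -> list[tuple[Haplotype, float]]:
    """Control-group haplotype frequencies, the default simulation pool."""
    out = [(h, co / CONTROL_CHROMOSOMES)
           for _, h, ca, co in HAPLOTYPE_COUNTS if co > 0]
    out.append((OTHER_CONTROL_HAPLOTYPE, 1 / CONTROL_CHROMOSOMES))
    return out
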