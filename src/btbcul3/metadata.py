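"""Curated KCTD-family metadata.

Binder / non-binder status against Cullin 3, structure-based cluster
labels, BTB construct boundaries, and the stoichiometry used when each
complex is predicted.  These labels come from the experimental-interaction
literature (BioGRID plus targeted in-vitro studies) and are carried as
data, not computed: the pipeline's job is to see whether confidence-based
classification of the predicted complexes reproduces them.

Notes carried as flags:

* KCTD11 — its predicted complex is known to be low-reliability, and it is
  excluded from conservation tallies by default downstream;
* KCNRG — its unliganded pentamer is loose, so inter-subunit confidence is
  also poor;
* the three KCTD19 BTB domains are treated as independent 1:1 jobs; in the
  full-length protein their weak predicted complexes clash sterically with
  the rest of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FamilyEntry", "FAMILY_TABLE", "binders", "non_binders"]


@dataclass(frozen=True)
class FamilyEntry:
    cluster: str
    protein: str
    domain_label: str  # BTB, BTBa, BTBb, BTBc
    start_res: int
    end_res: int
    stoichiometry: tuple[int, int]
    binds_cul3: bool  # curated experimental label
    flags: tuple[str, ...] = ()

    @property
    def complex_name(self) -> str:
        return f"{self.protein}^{self.domain_label}-Cul3"


FAMILY_TABLE: tuple[FamilyEntry, ...] = (
    FamilyEntry("1A", "KCTD8", "BTB", 44, 145, (5, 5), False),
    FamilyEntry("1A", "KCTD12", "BTB", 33, 131, (5, 5), False),
    FamilyEntry("1A", "KCTD16", "BTB", 25, 123, (5, 5), False),
    FamilyEntry("1B", "KCTD1", "BTB", 30, 133, (5, 5), False),
    FamilyEntry("1B", "KCTD15", "BTB", 56, 162, (5, 5), False),
    FamilyEntry("2A", "KCTD6", "BTB", 12, 107, (5, 5), True),
    FamilyEntry("2A", "KCNRG", "BTB", 5, 104, (5, 5), False, ("loose_pentamer",)),
    FamilyEntry("2B", "KCTD11", "BTB", 14, 123, (5, 5), True, ("low_reliability",)),
    FamilyEntry("2B", "KCTD21", "BTB", 4, 108, (5, 5), True),
    FamilyEntry("3", "KCTD2", "BTB", 72, 178, (5, 5), True),
    FamilyEntry("3", "KCTD5", "BTB", 42, 149, (5, 5), True),
    FamilyEntry("3", "KCTD17", "BTB", 30, 135, (5, 5), True),
    FamilyEntry("-", "KCTD18", "BTB", 12, 118, (1, 1), True),
    FamilyEntry("4", "KCTD4", "BTB", 33, 135, (5, 5), False),
    FamilyEntry("4", "KCTD19", "BTBa", 13, 107, (1, 1), False, ("steric_clash_fl",)),
    FamilyEntry("4", "KCTD19", "BTBb", 172, 258, (1, 1), False, ("steric_clash_fl",)),
    FamilyEntry("4", "KCTD19", "BTBc", 396, 487, (1, 1), False, ("steric_clash_fl",)),
    FamilyEntry("5A", "BTBD10", "BTB", 149, 266, (1, 1), True),
    FamilyEntry("5A", "KCTD20", "BTB", 117, 216, (1, 1), True),
    FamilyEntry("5B", "KCTD7", "BTB", 50, 143, (5, 5), True),
    FamilyEntry("5B", "KCTD14", "BTB", 33, 124, (5, 5), False),
    FamilyEntry("6", "KCTD10", "BTB", 33, 129, (5, 5), True),
    FamilyEntry("6", "KCTD13", "BTB", 41, 142, (5, 5), True),
    FamilyEntry("6", "TNFAIP1", "BTB", 28, 130, (5, 5), True),
    FamilyEntry("7", "KCTD3", "BTB", 18, 115, (5, 5), True),
    FamilyEntry("7", "SHKBP1", "BTB", 19, 118, (5, 5), True),
    FamilyEntry("-", "KCTD9", "BTB", 89, 191, (5, 5), True),
)


def binders() -> list[FamilyEntry]:
    return [e for e in FAMILY_TABLE if e.binds_cul3]


def non_binders() -> list[FamilyEntry]:
    return [e for e in FAMILY_TABLE if not e.binds_cul3]
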