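"""The study family: two parents, dizygotic twins discordant for specific
reading disability (SRD), and an affected older sibling.

The cohort object is deliberately rigid: every downstream stage (the
co-segregation filter, the pairwise ICCs, the Q-Q comparisons) is defined
in terms of exactly this five-member nuclear family, with imaging available
for the three siblings only and genotypes for all five members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CohortError

ROLE_PARENT = "parent"
ROLE_TWIN = "twin"
ROLE_OLDER_SIBLING = "older_sibling"

#: Canonical labels for the three sibling pairs.
PAIR_TWINS = "twin-twin"      # proband (affected twin) vs typically developing twin
PAIR_SRD = "SRD"              # the two affected siblings (proband + older sibling)
PAIR_TD_OS = "TD-OS"          # typically developing twin vs affected older sibling

PAIR_LABELS = (PAIR_TWINS, PAIR_SRD, PAIR_TD_OS)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    role: str
    affected: bool
    sex: str = "F"

    def __post_init__(self):
        if self.role not in (ROLE_PARENT, ROLE_TWIN, ROLE_OLDER_SIBLING):
            raise CohortError(f"unknown role {self.role!r} for {self.subject_id}")


@dataclass
class FamilyCohort:
    """Validated five-member nuclear family.

    Invariants enforced at construction: exactly 2 parents, 2 twins and
    1 older sibling; exactly one twin affected; the older sibling affected.
    """

    subjects: list[Subject] = field(default_factory=list)
    family_id: str = "FAM1"

    def __post_init__(self):
        roles = [s.role for s in self.subjects]
        if len(self.subjects) != 5:
            raise CohortError(f"expected 5 subjects, got {len(self.subjects)}")
        if roles.count(ROLE_PARENT) != 2:
            raise CohortError("expected exactly 2 parents")
        if roles.count(ROLE_TWIN) != 2:
            raise CohortError("expected exactly 2 twins")
        if roles.count(ROLE_OLDER_SIBLING) != 1:
            raise CohortError("expected exactly 1 older sibling")
        twins = self.twins
        if sum(t.affected for t in twins) != 1:
            raise CohortError("exactly one twin must be affected")
        if not self.older_sibling.affected:
            raise CohortError("the older sibling must be affected")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != 5:
            raise CohortError("subject ids must be unique")

    # -- convenience views -------------------------------------------------
    @property
    def parents(self) -> list[Subject]:
        return [s for s in self.subjects if s.role == ROLE_PARENT]

    @property
    def twins(self) -> list[Subject]:
        return [s for s in self.subjects if s.role == ROLE_TWIN]

    @property
    def older_sibling(self) -> Subject:
        return next(s for s in self.subjects if s.role == ROLE_OLDER_SIBLING)

    @property
    def siblings(self) -> list[Subject]:
        """The three imaged siblings (twins + older sibling)."""
        return self.twins + [self.older_sibling]

    @property
    def proband(self) -> Subject:
        """The affected (SRD) twin."""
        return next(t for t in self.twins if t.affected)

    @property
    def td_twin(self) -> Subject:
        """The typically developing (unaffected) twin."""
        return next(t for t in self.twins if not t.affected)

    @property
    def discordant_id(self) -> str:
        return self.td_twin.subject_id

    @property
    def affected_sibling_ids(self) -> tuple[str, str]:
        """(proband, older sibling) — the two affected siblings."""
        return (self.proband.subject_id, self.older_sibling.subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def sibling_pairs(self) -> dict[str, tuple[str, str]]:
        """The three labelled sibling pairs used throughout the analyses."""
        p, t, o = self.proband.subject_id, self.td_twin.subject_id, self.older_sibling.subject_id
        return {PAIR_TWINS: (p, t), PAIR_SRD: (p, o), PAIR_TD_OS: (t, o)}

    @classmethod
    def default(cls) -> "FamilyCohort":
        """The canonical study family.

        All three siblings are female; the proband is the affected twin and
        the older sibling has a reported history of reading difficulty.
        """
        return cls(
            subjects=[
                Subject("mother", ROLE_PARENT, affected=False, sex="F"),
                Subject("father", ROLE_PARENT, affected=False, sex="M"),
                Subject("proband", ROLE_TWIN, affected=True, sex="F"),
                Subject("td_twin", ROLE_TWIN, affected=False, sex="F"),
                Subject("older_sibling", ROLE_OLDER_SIBLING, affected=True, sex="F"),
            ]
        )
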