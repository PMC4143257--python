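"""Typed data model for egocentric roster surveys.

One :class:`EgoRecord` per respondent, one :class:`AlterTie` per nominated
ego--alter relation (closeness position 1 = closest), and one
:class:`NetworkNominations` per respondent for the three network-level
items that point back at roster positions.  A :class:`SurveyDataset`
bundles them with the :class:`~egonet.codebook.Codebook` in force.

Field-level constraints (value ranges, category membership) are enforced at
construction by pydantic; cross-record invariants (position contiguity,
referential integrity, the nomination cap) are the business of
:func:`egonet.validate.validate`.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field

from .codebook import Codebook, default_codebook


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Residence(str, enum.Enum):
    """Where the alter lives relative to the ego."""

    SAME_HOUSEHOLD = "same_household"
    SAME_CITY = "same_city"
    OTHER = "other"


class BodyweightVsEgo(str, enum.Enum):
    """Ego-perceived alter bodyweight relative to the ego's own."""

    LESS = "less"
    SIMILAR = "similar"
    MORE = "more"


class EgoRecord(BaseModel):
    """One survey respondent.

    ``covariates`` is a free key-value bag (age, marital status, income
    band, ...) carried over from a host survey; values are kept as strings
    so file round-trips are lossless.
    """

    ego_id: str
    sex: Sex
    tobacco_use: Optional[bool] = None
    bodyweight_class: Optional[str] = None
    city: Optional[str] = None
    covariates: dict[str, str] = Field(default_factory=dict)


class AlterTie(BaseModel):
    """One nominated ego--alter tie with its name-interpretation items.

    ``position`` is the closeness rank from the name generator (1 =
    closest).  ``None`` in any attribute field means the item is missing or
    was answered "don't know"; proportions over alters exclude unknowns
    from both numerator and denominator.
    """

    ego_id: str
    position: int = Field(ge=1)
    alter_label: Optional[str] = None
    alter_sex: Optional[Sex] = None
    relationship: str
    residence: Optional[Residence] = None
    talk_own_health_freq: Optional[str] = None
    talk_alter_health_freq: Optional[str] = None
    contacted_14d: Optional[bool] = None
    snack_days_14d: Optional[int] = Field(default=None, ge=0, le=14)
    meal_days_14d: Optional[int] = Field(default=None, ge=0, le=14)
    exercised_14d: Optional[bool] = None
    walked_tasks_14d: Optional[bool] = None
    meal_prep_shop_14d: Optional[bool] = None
    tobacco_co_use_14d: Optional[bool] = None
    alter_tobacco_use: Optional[bool] = None
    alter_bodyweight_vs_ego: Optional[BodyweightVsEgo] = None


class NetworkNominations(BaseModel):
    """The three network-level choices, each a roster position or absent."""

    ego_id: str
    emergency_contact_pos: Optional[int] = Field(default=None, ge=1)
    health_problem_pos: Optional[int] = Field(default=None, ge=1)
    overwhelmed_contact_pos: Optional[int] = Field(default=None, ge=1)


class SurveyDataset(BaseModel):
    """A full egocentric survey: egos, ties, nominations, codebook."""

    egos: list[EgoRecord] = Field(default_factory=list)
    ties: list[AlterTie] = Field(default_factory=list)
    nominations: list[NetworkNominations] = Field(default_factory=list)
    codebook: Codebook = Field(default_factory=default_codebook)

    # -- lookups ---------------------------------------------------------

    def ego(self, ego_id: str) -> EgoRecord:
        for e in self.egos:
            if e.ego_id == ego_id:
                return e
        raise KeyError(f"unknown ego_id: {ego_id!r}")

    def ties_for(self, ego_id: str) -> list[AlterTie]:
        """Ties of one ego, sorted by closeness position."""
        return sorted(
            (t for t in self.ties if t.ego_id == ego_id), key=lambda t: t.position
        )

    def nominations_for(self, ego_id: str) -> Optional[NetworkNominations]:
        for n in self.nominations:
            if n.ego_id == ego_id:
                return n
        return None

    def ties_by_ego(self) -> dict[str, list[AlterTie]]:
        """All rosters at once (position-sorted); one pass over the ties."""
        grouped: dict[str, list[AlterTie]] = {e.ego_id: [] for e in self.egos}
        for t in self.ties:
            grouped.setdefault(t.ego_id, []).append(t)
        for ties in grouped.values():
            ties.sort(key=lambda t: t.position)
        return grouped

    def nominations_by_ego(self) -> dict[str, NetworkNominations]:
        return {n.ego_id: n for n in self.nominations}

    def network_sizes(self) -> dict[str, int]:
        sizes = {e.ego_id: 0 for e in self.egos}
        for t in self.ties:
            if t.ego_id in sizes:
                sizes[t.ego_id] += 1
        return sizes

    @property
    def n_egos(self) -> int:
        return len(self.egos)

    @property
    def n_ties(self) -> int:
        return len(self.ties)
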