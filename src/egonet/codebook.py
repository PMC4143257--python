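"""Code lists and classification policy for roster instruments.

The codebook declares everything about a survey that is convention rather
than data: the recognised relationship codes and their grouping into broad
tie classes, the response scale for the health-talk frequency items, the
residence code list, the nomination cap of the name generator, and the
activity domains that enter tie multiplexity.  All of it can be overridden
from a YAML/JSON document so the same pipeline serves adapted instruments.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, model_validator


class TieClass(str, enum.Enum):
    """Broad grouping of a relationship code (three classes plus 'other')."""

    MALE_RELATIVE = "male-relative"
    FEMALE_RELATIVE = "female-relative"
    NON_RELATIVE = "non-relative"
    OTHER = "other"


#: Default relationship code list.  Kin codes that imply the alter's sex map
#: to a sexed relative class; friend/workmate/neighbor are non-relatives.
DEFAULT_RELATIONSHIP_CLASSES: dict[str, TieClass] = {
    "husband": TieClass.MALE_RELATIVE,
    "son": TieClass.MALE_RELATIVE,
    "son-in-law": TieClass.MALE_RELATIVE,
    "father": TieClass.MALE_RELATIVE,
    "brother": TieClass.MALE_RELATIVE,
    "father-in-law": TieClass.MALE_RELATIVE,
    "brother-in-law": TieClass.MALE_RELATIVE,
    "cousin-male": TieClass.MALE_RELATIVE,
    "uncle": TieClass.MALE_RELATIVE,
    "nephew": TieClass.MALE_RELATIVE,
    "wife": TieClass.FEMALE_RELATIVE,
    "daughter": TieClass.FEMALE_RELATIVE,
    "daughter-in-law": TieClass.FEMALE_RELATIVE,
    "mother": TieClass.FEMALE_RELATIVE,
    "sister": TieClass.FEMALE_RELATIVE,
    "sister-in-law": TieClass.FEMALE_RELATIVE,
    "mother-in-law": TieClass.FEMALE_RELATIVE,
    "cousin-female": TieClass.FEMALE_RELATIVE,
    "aunt": TieClass.FEMALE_RELATIVE,
    "niece": TieClass.FEMALE_RELATIVE,
    "friend": TieClass.NON_RELATIVE,
    "workmate": TieClass.NON_RELATIVE,
    "neighbor": TieClass.NON_RELATIVE,
    "other": TieClass.OTHER,
}

#: Relationship codes whose label fixes the alter's sex.
SEXED_RELATIONSHIPS: dict[str, str] = {
    "husband": "male",
    "son": "male",
    "son-in-law": "male",
    "father": "male",
    "brother": "male",
    "father-in-law": "male",
    "brother-in-law": "male",
    "cousin-male": "male",
    "uncle": "male",
    "nephew": "male",
    "wife": "female",
    "daughter": "female",
    "daughter-in-law": "female",
    "mother": "female",
    "sister": "female",
    "sister-in-law": "female",
    "mother-in-law": "female",
    "cousin-female": "female",
    "aunt": "female",
    "niece": "female",
}

DEFAULT_HEALTH_TALK_LEVELS = ["never", "rarely", "sometimes", "often"]
DEFAULT_RESIDENCE_CODES = ["same_household", "same_city", "other"]

#: The shared-activity domains counted by tie multiplexity.
DEFAULT_ACTIVITY_DOMAINS = [
    "communication",
    "snacks",
    "meals",
    "exercise",
    "walking_tasks",
    "meal_prep_shop",
    "tobacco_co_use",
    "health_talk",
]


class Codebook(BaseModel):
    """Code lists and the classification policy in force for a dataset.

    Parameters
    ----------
    relationship_classes
        Map from relationship code to its :class:`TieClass`.
    other_is_relative
        Whether ties coded ``other`` count as relatives in the binary
        relative / non-relative classification.  Default ``True``.
    nomination_cap
        Maximum number of alters the name generator accepts per ego.
    health_talk_levels
        Ordered response scale for the two health-talk frequency items,
        weakest first; any level above the first counts as engagement for
        the health-talk multiplexity domain.
    residence_codes
        Allowed residence codes; the first two are treated as "same city"
        for the residence homogeneity measure.
    activity_domains
        Names of the shared-activity domains counted by multiplexity.
    """

    relationship_classes: dict[str, TieClass] = Field(
        default_factory=lambda: dict(DEFAULT_RELATIONSHIP_CLASSES)
    )
    other_is_relative: bool = True
    nomination_cap: int = Field(default=5, ge=1)
    health_talk_levels: list[str] = Field(
        default_factory=lambda: list(DEFAULT_HEALTH_TALK_LEVELS)
    )
    residence_codes: list[str] = Field(
        default_factory=lambda: list(DEFAULT_RESIDENCE_CODES)
    )
    activity_domains: list[str] = Field(
        default_factory=lambda: list(DEFAULT_ACTIVITY_DOMAINS)
    )

    @model_validator(mode="after")
    def _check(self) -> "Codebook":
        if len(self.health_talk_levels) < 2:
            raise ValueError("health_talk_levels needs at least 2 ordered levels")
        if len(set(self.health_talk_levels)) != len(self.health_talk_levels):
            raise ValueError("health_talk_levels must be distinct")
        return self

    # -- classification -------------------------------------------------

    def tie_class(self, relationship: str) -> TieClass:
        """Broad class of a relationship code; KeyError on unknown codes."""
        try:
            return self.relationship_classes[relationship]
        except KeyError:
            raise KeyError(f"unknown relationship code: {relationship!r}") from None

    def is_relative(self, relationship: str) -> bool:
        """Binary relative / non-relative classification under the policy."""
        cls = self.tie_class(relationship)
        if cls is TieClass.OTHER:
            return self.other_is_relative
        return cls in (TieClass.MALE_RELATIVE, TieClass.FEMALE_RELATIVE)

    def implied_alter_sex(self, relationship: str) -> str | None:
        return SEXED_RELATIONSHIPS.get(relationship)

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = self.model_dump()
        d["relationship_classes"] = {
            k: v.value for k, v in self.relationship_classes.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Codebook":
        return cls.model_validate(d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        """Load a codebook from YAML or JSON (sniffed by suffix)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


def default_codebook() -> Codebook:
    return Codebook()
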