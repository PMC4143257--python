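"""Per-ego and per-tie network measures.

The measures follow the standard egocentric vocabulary:

* **network size** -- number of nominated alters (0 up to the cap);
* **network exposure** -- proportion of alters exhibiting an attribute,
  among alters whose value is known;
* **network homogeneity** -- proportion of alters sharing the ego's own
  value of an attribute (same sex, same city, similar bodyweight);
* **network diversity** -- share of relative ties and the number of
  distinct broad tie classes present;
* **tie strength** -- closeness rank (nomination order), intimacy
  nominations, and 14-day contact frequency;
* **tie multiplexity** -- number of distinct shared-activity domains a
  dyad spans in the past 14 days.

Proportions are undefined (``None``) exactly when their denominator is
zero; alters with unknown values are excluded from numerator and
denominator alike, never imputed.
"""

from __future__ import annotations

from typing import Callable, Optional

import pandas as pd
from pydantic import BaseModel

from .codebook import Codebook
from .model import (
    AlterTie,
    BodyweightVsEgo,
    EgoRecord,
    NetworkNominations,
    Residence,
    SurveyDataset,
)

TiePredicate = Callable[[AlterTie], Optional[bool]]


class MissingEgoValueError(ValueError):
    """Homogeneity asked for an attribute the ego's own record lacks."""


class EgoMeasures(BaseModel):
    ego_id: str
    network_size: int
    exposure: dict[str, Optional[float]]
    homogeneity: dict[str, Optional[float]]
    pct_family: Optional[float]
    n_tie_types: int
    first_named_relative: Optional[bool]
    health_contact_relative: Optional[bool]
    top_snack_partner_relative: Optional[bool]


class TieMeasures(BaseModel):
    ego_id: str
    position: int
    strength_rank: int
    multiplexity: int
    contact_days_14d: int
    contacted_14d: Optional[bool]
    is_emergency_contact: bool
    is_health_contact: bool
    is_overwhelmed_contact: bool


# ---------------------------------------------------------------------------
# attribute predicates

def tobacco_attribute(tie: AlterTie) -> Optional[bool]:
    return tie.alter_tobacco_use


#: Exposure attributes addressable by name.
EXPOSURE_ATTRIBUTES: dict[str, TiePredicate] = {"tobacco": tobacco_attribute}


def _proportion(flags: list[Optional[bool]]) -> Optional[float]:
    known = [f for f in flags if f is not None]
    if not known:
        return None
    return sum(known) / len(known)


# ---------------------------------------------------------------------------
# operations

def network_size(ties: list[AlterTie]) -> int:
    """Number of reported relations out of the possible nominations."""
    return len(ties)


def network_exposure(
    ties: list[AlterTie], attribute: str | TiePredicate
) -> Optional[float]:
    """Proportion of alters exhibiting ``attribute``, among known values.

    ``attribute`` is a registered name (``"tobacco"``) or any callable
    mapping a tie to True / False / None (None = unknown, excluded).
    Returns None when no alter has a known value.
    """
    pred = EXPOSURE_ATTRIBUTES[attribute] if isinstance(attribute, str) else attribute
    return _proportion([pred(t) for t in ties])


def network_homogeneity(
    ego: EgoRecord, ties: list[AlterTie], attribute: str
) -> Optional[float]:
    """Proportion of alters sharing the ego's own value of ``attribute``.

    Supported attributes: ``sex`` (alter sex equals ego sex), ``city``
    (alter resides in the ego's household or city), ``bodyweight`` (alter
    perceived as of similar weight to the ego; the item is already
    ego-referent), ``tobacco`` (alter's use equals the ego's own use).
    Raises :class:`MissingEgoValueError` if the ego's value is missing.
    """
    if attribute == "sex":
        if ego.sex is None:
            raise MissingEgoValueError("ego sex is missing")
        flags = [None if t.alter_sex is None else t.alter_sex == ego.sex for t in ties]
    elif attribute == "city":
        flags = [
            None
            if t.residence is None
            else t.residence in (Residence.SAME_HOUSEHOLD, Residence.SAME_CITY)
            for t in ties
        ]
    elif attribute == "bodyweight":
        flags = [
            None
            if t.alter_bodyweight_vs_ego is None
            else t.alter_bodyweight_vs_ego is BodyweightVsEgo.SIMILAR
            for t in ties
        ]
    elif attribute == "tobacco":
        if ego.tobacco_use is None:
            raise MissingEgoValueError("ego tobacco_use is missing")
        flags = [
            None if t.alter_tobacco_use is None else t.alter_tobacco_use == ego.tobacco_use
            for t in ties
        ]
    else:
        raise KeyError(f"unknown homogeneity attribute: {attribute!r}")
    return _proportion(flags)


def network_diversity(
    ties: list[AlterTie], codebook: Codebook
) -> tuple[Optional[float], int]:
    """(share of relative ties, number of distinct broad tie classes).

    The relative share is undefined for an empty roster; the class count
    uses the codebook's broad grouping (male relative / female relative /
    non-relative / other), so it is at most 4 and never exceeds the
    roster size.
    """
    if not ties:
        return None, 0
    pct_family = sum(codebook.is_relative(t.relationship) for t in ties) / len(ties)
    n_types = len({codebook.tie_class(t.relationship) for t in ties})
    return pct_family, n_types


def tie_multiplexity(tie: AlterTie, codebook: Codebook) -> int:
    """Count of distinct activity domains engaged with this alter.

    Unknown (missing) responses count as not engaged.  Health talk counts
    as engaged when either talk item is above the scale's lowest level.
    """
    above_never = set(codebook.health_talk_levels[1:])
    engaged = {
        "communication": bool(tie.contacted_14d),
        "snacks": bool(tie.snack_days_14d),
        "meals": bool(tie.meal_days_14d),
        "exercise": bool(tie.exercised_14d),
        "walking_tasks": bool(tie.walked_tasks_14d),
        "meal_prep_shop": bool(tie.meal_prep_shop_14d),
        "tobacco_co_use": bool(tie.tobacco_co_use_14d),
        "health_talk": tie.talk_own_health_freq in above_never
        or tie.talk_alter_health_freq in above_never,
    }
    return sum(engaged[d] for d in codebook.activity_domains if d in engaged)


def tie_strength(
    ties: list[AlterTie],
    nominations: Optional[NetworkNominations],
    codebook: Codebook,
) -> list[TieMeasures]:
    """Per-tie strength summary for one ego's roster.

    Rank equals the closeness position (1 = strongest); the three intimacy
    flags record whether the alter was chosen for the emergency, health
    problem, or overwhelmed item; contact frequency is the shared snack
    plus meal day count.
    """
    out = []
    for t in sorted(ties, key=lambda t: t.position):
        out.append(
            TieMeasures(
                ego_id=t.ego_id,
                position=t.position,
                strength_rank=t.position,
                multiplexity=tie_multiplexity(t, codebook),
                contact_days_14d=(t.snack_days_14d or 0) + (t.meal_days_14d or 0),
                contacted_14d=t.contacted_14d,
                is_emergency_contact=bool(
                    nominations and nominations.emergency_contact_pos == t.position
                ),
                is_health_contact=bool(
                    nominations and nominations.health_problem_pos == t.position
                ),
                is_overwhelmed_contact=bool(
                    nominations and nominations.overwhelmed_contact_pos == t.position
                ),
            )
        )
    return out


def top_snack_partner(ties: list[AlterTie]) -> Optional[AlterTie]:
    """The alter with the most shared snack days; closeness breaks ties.

    Undefined (None) when no alter shared any snack in the recall window.
    """
    candidates = [t for t in ties if (t.snack_days_14d or 0) > 0]
    if not candidates:
        return None
    return max(candidates, key=lambda t: (t.snack_days_14d, -t.position))


def ego_measures(
    dataset: SurveyDataset,
    ego_id: str,
    health_contact_item: str = "health_problem",
    exposure_attributes: Optional[dict[str, TiePredicate]] = None,
) -> EgoMeasures:
    """All per-ego measures for one respondent.

    ``health_contact_item`` selects which network-level nomination defines
    the "primary contact for a health concern" flag: ``"health_problem"``
    (default) or ``"emergency"``.
    """
    return _compute_ego_measures(
        dataset.ego(ego_id),  # KeyError on unknown ego
        dataset.ties_for(ego_id),
        dataset.nominations_for(ego_id),
        dataset.codebook,
        health_contact_item,
        exposure_attributes,
    )


def _compute_ego_measures(
    ego: EgoRecord,
    ties: list[AlterTie],
    noms: Optional[NetworkNominations],
    cb: Codebook,
    health_contact_item: str = "health_problem",
    exposure_attributes: Optional[dict[str, TiePredicate]] = None,
) -> EgoMeasures:
    ego_id = ego.ego_id
    attrs = exposure_attributes if exposure_attributes is not None else EXPOSURE_ATTRIBUTES
    exposure = {name: network_exposure(ties, pred) for name, pred in attrs.items()}
    homogeneity = {
        a: network_homogeneity(ego, ties, a) for a in ("sex", "city", "bodyweight")
    }
    pct_family, n_types = network_diversity(ties, cb)

    first_named = None
    if ties:
        first_named = cb.is_relative(ties[0].relationship)

    if health_contact_item == "health_problem":
        pos = noms.health_problem_pos if noms else None
    elif health_contact_item == "emergency":
        pos = noms.emergency_contact_pos if noms else None
    else:
        raise ValueError(f"unknown health_contact_item: {health_contact_item!r}")
    health_contact = None
    if pos is not None:
        by_pos = {t.position: t for t in ties}
        if pos not in by_pos:
            raise ValueError(
                f"ego {ego_id}: nomination refers to position {pos} with no tie"
            )
        health_contact = cb.is_relative(by_pos[pos].relationship)

    snack = top_snack_partner(ties)
    return EgoMeasures(
        ego_id=ego_id,
        network_size=network_size(ties),
        exposure=exposure,
        homogeneity=homogeneity,
        pct_family=pct_family,
        n_tie_types=n_types,
        first_named_relative=first_named,
        health_contact_relative=health_contact,
        top_snack_partner_relative=None if snack is None else cb.is_relative(snack.relationship),
    )


# ---------------------------------------------------------------------------
# tabular exports

EGO_MEASURE_COLUMNS = [
    "ego_id",
    "sex",
    "network_size",
    "exposure_tobacco",
    "homogeneity_sex",
    "homogeneity_city",
    "homogeneity_bodyweight",
    "pct_family",
    "n_tie_types",
    "first_named_relative",
    "health_contact_relative",
    "top_snack_partner_relative",
]


def ego_measures_table(
    dataset: SurveyDataset, health_contact_item: str = "health_problem"
) -> pd.DataFrame:
    """One row per ego with every measure; None becomes NaN."""
    rosters = dataset.ties_by_ego()
    noms = dataset.nominations_by_ego()
    cb = dataset.codebook
    rows = []
    for e in dataset.egos:
        m = _compute_ego_measures(
            e, rosters.get(e.ego_id, []), noms.get(e.ego_id), cb,
            health_contact_item=health_contact_item,
        )
        rows.append(
            {
                "ego_id": m.ego_id,
                "sex": e.sex.value,
                "network_size": m.network_size,
                "exposure_tobacco": m.exposure.get("tobacco"),
                "homogeneity_sex": m.homogeneity["sex"],
                "homogeneity_city": m.homogeneity["city"],
                "homogeneity_bodyweight": m.homogeneity["bodyweight"],
                "pct_family": m.pct_family,
                "n_tie_types": m.n_tie_types,
                "first_named_relative": m.first_named_relative,
                "health_contact_relative": m.health_contact_relative,
                "top_snack_partner_relative": m.top_snack_partner_relative,
            }
        )
    return pd.DataFrame(rows, columns=EGO_MEASURE_COLUMNS)


def tie_measures_table(dataset: SurveyDataset) -> pd.DataFrame:
    """One row per tie: strength, multiplexity, class, activity flags."""
    cb = dataset.codebook
    rosters = dataset.ties_by_ego()
    all_noms = dataset.nominations_by_ego()
    rows = []
    for e in dataset.egos:
        ties = rosters.get(e.ego_id, [])
        noms = all_noms.get(e.ego_id)
        for t, s in zip(ties, tie_strength(ties, noms, cb)):
            rows.append(
                {
                    "ego_id": t.ego_id,
                    "position": t.position,
                    "relationship": t.relationship,
                    "tie_class": cb.tie_class(t.relationship).value,
                    "is_relative": cb.is_relative(t.relationship),
                    "strength_rank": s.strength_rank,
                    "multiplexity": s.multiplexity,
                    "contact_days_14d": s.contact_days_14d,
                    "exercised_14d": t.exercised_14d,
                    "is_emergency_contact": s.is_emergency_contact,
                    "is_health_contact": s.is_health_contact,
                    "is_overwhelmed_contact": s.is_overwhelmed_contact,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ego_id",
            "position",
            "relationship",
            "tie_class",
            "is_relative",
            "strength_rank",
            "multiplexity",
            "contact_days_14d",
            "exercised_14d",
            "is_emergency_contact",
            "is_health_contact",
            "is_overwhelmed_contact",
        ],
    )
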