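"""Dataset-level validation: cross-record invariants as a violation report.

``validate`` never raises and never mutates; it returns the complete list
of violations (empty list = valid dataset).  Readers raise
:class:`SchemaError` on the subset of violations considered hard errors at
ingest time.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel

from .model import SurveyDataset


class Violation(BaseModel):
    """One invariant violation: which ego, which rule, human detail."""

    ego_id: str
    rule: str
    detail: str


class SchemaError(ValueError):
    """Hard ingest failure; carries the full list of violations found."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "; ".join(f"[{v.rule}] ego {v.ego_id}: {v.detail}" for v in violations)
        super().__init__(f"{len(violations)} schema violation(s): {lines}")


DAY_COUNT_FIELDS = ("snack_days_14d", "meal_days_14d")

NOMINATION_FIELDS = (
    "emergency_contact_pos",
    "health_problem_pos",
    "overwhelmed_contact_pos",
)


def validate(dataset: SurveyDataset) -> list[Violation]:
    """Check every cross-record invariant; return all violations found.

    Checks, per ego: unique ego_id, non-missing sex; per roster: unique
    contiguous positions starting at 1, nomination cap; per tie: ego
    exists, relationship code known to the codebook, day counts in
    [0, 14]; per nomination record: ego exists, each nominated position
    refers to an existing tie of that ego.
    """
    out: list[Violation] = []
    cb = dataset.codebook

    ego_ids: set[str] = set()
    for e in dataset.egos:
        if e.ego_id in ego_ids:
            out.append(
                Violation(ego_id=e.ego_id, rule="duplicate-ego", detail="ego_id repeated")
            )
        ego_ids.add(e.ego_id)
        if e.sex is None:
            out.append(
                Violation(ego_id=e.ego_id, rule="missing-sex", detail="ego sex is required")
            )

    positions: dict[str, list[int]] = {}
    for t in dataset.ties:
        positions.setdefault(t.ego_id, []).append(t.position)
        if t.ego_id not in ego_ids:
            out.append(
                Violation(
                    ego_id=t.ego_id,
                    rule="orphan-tie",
                    detail=f"tie at position {t.position} has no matching ego record",
                )
            )
        if t.relationship not in cb.relationship_classes:
            out.append(
                Violation(
                    ego_id=t.ego_id,
                    rule="unknown-relationship",
                    detail=f"position {t.position}: code {t.relationship!r} not in codebook",
                )
            )
        for f in DAY_COUNT_FIELDS:
            v = getattr(t, f)
            if v is not None and not (0 <= v <= 14):
                out.append(
                    Violation(
                        ego_id=t.ego_id,
                        rule="day-count-range",
                        detail=f"position {t.position}: {f}={v} outside [0, 14]",
                    )
                )

    for ego_id, pos in positions.items():
        seen: set[int] = set()
        for p in pos:
            if p in seen:
                out.append(
                    Violation(
                        ego_id=ego_id,
                        rule="duplicate-position",
                        detail=f"position {p} nominated twice",
                    )
                )
            seen.add(p)
        expected = set(range(1, len(seen) + 1))
        if seen != expected:
            out.append(
                Violation(
                    ego_id=ego_id,
                    rule="position-gap",
                    detail=(
                        f"positions {sorted(seen)} are not a contiguous run starting at 1"
                    ),
                )
            )
        if len(pos) > cb.nomination_cap:
            out.append(
                Violation(
                    ego_id=ego_id,
                    rule="cap-exceeded",
                    detail=f"{len(pos)} ties exceed the cap of {cb.nomination_cap}",
                )
            )

    nom_seen: set[str] = set()
    for n in dataset.nominations:
        if n.ego_id in nom_seen:
            out.append(
                Violation(
                    ego_id=n.ego_id,
                    rule="duplicate-nomination-record",
                    detail="more than one nomination record for this ego",
                )
            )
        nom_seen.add(n.ego_id)
        if n.ego_id not in ego_ids:
            out.append(
                Violation(
                    ego_id=n.ego_id,
                    rule="orphan-nomination",
                    detail="nomination record has no matching ego record",
                )
            )
            continue
        have = set(positions.get(n.ego_id, []))
        for f in NOMINATION_FIELDS:
            p = getattr(n, f)
            if p is not None and p not in have:
                out.append(
                    Violation(
                        ego_id=n.ego_id,
                        rule="nomination-position-missing",
                        detail=f"{f} refers to position {p} but roster has positions {sorted(have)}",
                    )
                )

    return out


def write_report(violations: list[Violation], path: str | Path) -> None:
    """Write a validation report as JSON lines, one violation per line."""
    with open(path, "w") as fh:
        for v in violations:
            fh.write(json.dumps(v.model_dump()) + "\n")
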