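"""Shared fixtures: tiny hand-built datasets and roster helpers."""

from __future__ import annotations

import pytest

from egonet import (
    AlterTie,
    EgoRecord,
    NetworkNominations,
    SurveyDataset,
    default_codebook,
)


def make_tie(ego_id: str, position: int, relationship: str = "brother", **kwargs) -> AlterTie:
    """A tie with sensible defaults; override any field via kwargs."""
    base = dict(
        ego_id=ego_id,
        position=position,
        alter_label=f"{ego_id}-a{position}",
        alter_sex="male" if relationship in ("husband", "son", "brother", "father") else None,
        relationship=relationship,
        residence="same_city",
        contacted_14d=True,
        snack_days_14d=0,
        meal_days_14d=0,
    )
    base.update(kwargs)
    return AlterTie(**base)


def make_dataset(egos, ties, nominations=(), codebook=None) -> SurveyDataset:
    return SurveyDataset(
        egos=list(egos),
        ties=list(ties),
        nominations=list(nominations),
        codebook=codebook or default_codebook(),
    )


@pytest.fixture
def codebook():
    return default_codebook()


@pytest.fixture
def tiny_dataset():
    """2 egos, 3 ties, 1 nomination record: the smallest interesting survey."""
    egos = [
        EgoRecord(ego_id="e1", sex="female", tobacco_use=False),
        EgoRecord(ego_id="e2", sex="male", tobacco_use=True),
    ]
    ties = [
        make_tie("e1", 1, "husband", alter_tobacco_use=True, snack_days_14d=3),
        make_tie("e1", 2, "friend", alter_sex="female", alter_tobacco_use=False),
        make_tie("e2", 1, "wife", alter_sex="female", meal_days_14d=7),
    ]
    noms = [NetworkNominations(ego_id="e1", health_problem_pos=1, emergency_contact_pos=2)]
    return make_dataset(egos, ties, noms)
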