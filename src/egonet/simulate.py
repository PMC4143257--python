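"""Seeded synthetic roster-survey generator and parameter-recovery harness.

The generator emulates the statistical structure of an urban Indian adult
sample interviewed with a 5-nomination closeness roster: the network-size
frequency distribution, the relationship-type mix at each nomination
position (spouses dominate position 1, friends and siblings appear later),
kin-skewed shared-activity rates, and alter attributes (sex, residence,
tobacco use, perceived relative bodyweight).  Defaults encode the published
sample-level distributions; every rate is exposed in
:class:`GeneratorConfig` so adapted instruments can re-parameterise.

Reproducibility: one pseudo-random child stream per ego, derived from the
master seed with ``numpy``'s ``SeedSequence.spawn``, so the same
seed+config always yields the identical dataset, independent of generation
order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .aggregate import dyadic_features, summarize_measures, tie_composition
from .codebook import Codebook, default_codebook
from .model import (
    AlterTie,
    BodyweightVsEgo,
    EgoRecord,
    NetworkNominations,
    Residence,
    Sex,
    SurveyDataset,
)

#: Default network-size distribution over 0-5 nominations (counts observed
#: in a 208-respondent sample: 7, 8, 12, 56, 45, 80).
DEFAULT_SIZE_COUNTS = [7, 8, 12, 56, 45, 80]

#: Default tie-type percentage by nomination position (columns of the
#: published composition table); normalised to a pmf at load time.
DEFAULT_TIE_TYPE_PCT_BY_POSITION: dict[int, dict[str, float]] = {
    1: {
        "husband": 28.4, "son": 4.0, "son-in-law": 0.0, "father": 2.0,
        "brother": 3.0, "father-in-law": 0.5, "brother-in-law": 2.0,
        "cousin-male": 1.0, "uncle": 1.5, "nephew": 0.0,
        "wife": 30.4, "daughter": 5.0, "daughter-in-law": 0.0, "mother": 5.0,
        "sister": 4.5, "sister-in-law": 2.0, "mother-in-law": 0.0,
        "cousin-female": 0.0, "aunt": 0.0, "niece": 0.0,
        "friend": 8.0, "workmate": 0.5, "neighbor": 2.0, "other": 0.5,
    },
    2: {
        "husband": 1.6, "son": 17.6, "son-in-law": 0.0, "father": 2.1,
        "brother": 10.4, "father-in-law": 0.5, "brother-in-law": 2.6,
        "cousin-male": 0.5, "uncle": 0.5, "nephew": 0.5,
        "wife": 4.2, "daughter": 9.8, "daughter-in-law": 1.0, "mother": 8.8,
        "sister": 8.3, "sister-in-law": 4.2, "mother-in-law": 2.6,
        "cousin-female": 0.5, "aunt": 0.0, "niece": 0.5,
        "friend": 14.5, "workmate": 1.0, "neighbor": 6.7, "other": 1.6,
    },
    3: {
        "husband": 6.1, "son": 12.2, "son-in-law": 0.0, "father": 2.8,
        "brother": 13.3, "father-in-law": 0.0, "brother-in-law": 4.4,
        "cousin-male": 1.7, "uncle": 1.1, "nephew": 0.6,
        "wife": 5.5, "daughter": 9.9, "daughter-in-law": 2.8, "mother": 7.2,
        "sister": 6.6, "sister-in-law": 3.9, "mother-in-law": 0.0,
        "cousin-female": 1.7, "aunt": 0.0, "niece": 0.6,
        "friend": 13.4, "workmate": 0.6, "neighbor": 5.0, "other": 1.1,
    },
    4: {
        "husband": 4.8, "son": 9.6, "son-in-law": 0.8, "father": 0.8,
        "brother": 10.4, "father-in-law": 0.0, "brother-in-law": 3.2,
        "cousin-male": 0.0, "uncle": 0.0, "nephew": 0.8,
        "wife": 1.6, "daughter": 9.6, "daughter-in-law": 4.0, "mother": 3.2,
        "sister": 8.8, "sister-in-law": 11.2, "mother-in-law": 0.0,
        "cousin-female": 2.4, "aunt": 0.0, "niece": 0.8,
        "friend": 18.4, "workmate": 1.6, "neighbor": 3.2, "other": 4.8,
    },
    5: {
        "husband": 2.5, "son": 13.8, "son-in-law": 1.3, "father": 2.5,
        "brother": 8.8, "father-in-law": 0.0, "brother-in-law": 0.0,
        "cousin-male": 2.5, "uncle": 0.0, "nephew": 0.0,
        "wife": 2.5, "daughter": 8.8, "daughter-in-law": 6.3, "mother": 3.8,
        "sister": 7.5, "sister-in-law": 10.0, "mother-in-law": 2.5,
        "cousin-female": 0.0, "aunt": 2.5, "niece": 1.3,
        "friend": 10.0, "workmate": 2.5, "neighbor": 7.5, "other": 3.8,
    },
}

DEFAULT_ACTIVITY_RATES: dict[str, float] = {
    # day-count items: binomial success rate per day over the 14-day window
    "snack_rate_relative": 0.25,
    "snack_rate_nonrelative": 0.08,
    "meal_rate_relative": 0.50,
    "meal_rate_nonrelative": 0.05,
    # binary items: engagement probability in the window
    "contacted": 0.90,
    "walked_relative": 0.35,
    "walked_nonrelative": 0.15,
    "meal_prep_relative": 0.30,
    "meal_prep_nonrelative": 0.05,
    "tobacco_co_use_given_alter_use": 0.30,
    "tobacco_co_use_otherwise": 0.01,
}

#: weights pushing the three network-level nominations toward close ranks
_NOMINATION_WEIGHTS = np.array([0.5, 0.2, 0.15, 0.1, 0.05])


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic survey, with published-sample defaults."""

    n_egos: int = Field(default=208, ge=1)
    p_female: float = Field(default=105 / 208, ge=0.0, le=1.0)
    size_pmf: list[float] = Field(
        default_factory=lambda: [c / sum(DEFAULT_SIZE_COUNTS) for c in DEFAULT_SIZE_COUNTS]
    )
    tie_type_pmf_by_position: dict[int, dict[str, float]] = Field(
        default_factory=lambda: {
            pos: {k: v / sum(col.values()) for k, v in col.items()}
            for pos, col in DEFAULT_TIE_TYPE_PCT_BY_POSITION.items()
        }
    )
    p_exercise_given_relative: float = Field(default=0.08, ge=0, le=1)
    p_exercise_given_nonrelative: float = Field(default=0.17, ge=0, le=1)
    p_alter_tobacco_by_sex: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.03, "male": 0.39}
    )
    p_same_city: float = Field(default=0.9, ge=0, le=1)
    p_household_given_same_city_relative: float = Field(default=0.65, ge=0, le=1)
    p_household_given_same_city_nonrelative: float = Field(default=0.05, ge=0, le=1)
    p_unknown_tobacco: float = Field(default=0.05, ge=0, le=1)
    p_unknown_bodyweight: float = Field(default=0.05, ge=0, le=1)
    bodyweight_pmf: dict[str, float] = Field(
        default_factory=lambda: {"less": 0.35, "similar": 0.31, "more": 0.34}
    )
    health_talk_pmf: list[float] = Field(
        default_factory=lambda: [0.2, 0.3, 0.3, 0.2]
    )
    p_alter_female_unsexed: float = Field(default=0.5, ge=0, le=1)
    p_no_nomination: float = Field(default=0.02, ge=0, le=1)
    activity_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_RATES)
    )
    pmf_tolerance: float = 1e-6
    seed: int = 0

    @model_validator(mode="after")
    def _check_pmfs(self) -> "GeneratorConfig":
        def chk(name: str, vals) -> None:
            arr = np.asarray(list(vals), dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > self.pmf_tolerance:
                raise ValueError(f"{name} is not a probability vector (sum={arr.sum()})")

        chk("size_pmf", self.size_pmf)
        chk("bodyweight_pmf", self.bodyweight_pmf.values())
        chk("health_talk_pmf", self.health_talk_pmf)
        for pos, col in self.tie_type_pmf_by_position.items():
            chk(f"tie_type_pmf_by_position[{pos}]", col.values())
        if len(self.size_pmf) < 2:
            raise ValueError("size_pmf must cover at least sizes 0 and 1")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data)


def _position_pmf(
    config: GeneratorConfig, position: int, ego_sex: Sex
) -> tuple[list[str], np.ndarray]:
    """Tie-type pmf for a position, spouse codes made consistent with ego sex.

    The probability mass of the impossible spouse code (husband for male
    egos, wife for female egos) is moved onto the possible one, so the
    combined spouse share is preserved for any sex mix.
    """
    pmfs = config.tie_type_pmf_by_position
    col = pmfs.get(position) or pmfs[max(pmfs)]
    codes = list(col)
    probs = np.array([col[c] for c in codes], dtype=float)
    drop, keep = ("husband", "wife") if ego_sex is Sex.MALE else ("wife", "husband")
    if drop in col and keep in col:
        i, j = codes.index(drop), codes.index(keep)
        probs[j] += probs[i]
        probs[i] = 0.0
    return codes, _normalize(probs)


def _draw_tie(
    rng: np.random.Generator,
    config: GeneratorConfig,
    codebook: Codebook,
    ego: EgoRecord,
    position: int,
) -> AlterTie:
    codes, probs = _position_pmf(config, position, ego.sex)
    rel = codes[rng.choice(len(codes), p=probs)]
    relative = codebook.is_relative(rel)
    rates = config.activity_rates

    implied = codebook.implied_alter_sex(rel)
    if implied is not None:
        alter_sex = Sex(implied)
    else:
        alter_sex = Sex.FEMALE if rng.random() < config.p_alter_female_unsexed else Sex.MALE

    if rng.random() < config.p_same_city:
        p_hh = (
            config.p_household_given_same_city_relative
            if relative
            else config.p_household_given_same_city_nonrelative
        )
        residence = Residence.SAME_HOUSEHOLD if rng.random() < p_hh else Residence.SAME_CITY
    else:
        residence = Residence.OTHER

    if rng.random() < config.p_unknown_tobacco:
        alter_tobacco: Optional[bool] = None
    else:
        alter_tobacco = rng.random() < config.p_alter_tobacco_by_sex[alter_sex.value]

    if rng.random() < config.p_unknown_bodyweight:
        bodyweight: Optional[BodyweightVsEgo] = None
    else:
        bw_codes = list(config.bodyweight_pmf)
        bw_probs = _normalize(np.array([config.bodyweight_pmf[c] for c in bw_codes]))
        bodyweight = BodyweightVsEgo(bw_codes[rng.choice(len(bw_codes), p=bw_probs)])

    suffix = "relative" if relative else "nonrelative"
    levels = codebook.health_talk_levels
    talk_probs = _normalize(np.asarray(config.health_talk_pmf, dtype=float))
    p_ex = (
        config.p_exercise_given_relative if relative else config.p_exercise_given_nonrelative
    )
    if alter_tobacco:
        p_co_use = rates["tobacco_co_use_given_alter_use"]
    else:
        p_co_use = rates["tobacco_co_use_otherwise"]

    return AlterTie(
        ego_id=ego.ego_id,
        position=position,
        alter_label=f"{ego.ego_id}-a{position}",
        alter_sex=alter_sex,
        relationship=rel,
        residence=residence,
        talk_own_health_freq=levels[rng.choice(len(levels), p=talk_probs)],
        talk_alter_health_freq=levels[rng.choice(len(levels), p=talk_probs)],
        contacted_14d=bool(rng.random() < rates["contacted"]),
        snack_days_14d=int(rng.binomial(14, rates[f"snack_rate_{suffix}"])),
        meal_days_14d=int(rng.binomial(14, rates[f"meal_rate_{suffix}"])),
        exercised_14d=bool(rng.random() < p_ex),
        walked_tasks_14d=bool(rng.random() < rates[f"walked_{suffix}"]),
        meal_prep_shop_14d=bool(rng.random() < rates[f"meal_prep_{suffix}"]),
        tobacco_co_use_14d=bool(rng.random() < p_co_use),
        alter_tobacco_use=alter_tobacco,
        alter_bodyweight_vs_ego=bodyweight,
    )


def generate(
    config: Optional[GeneratorConfig] = None, codebook: Optional[Codebook] = None
) -> SurveyDataset:
    """Generate a valid synthetic :class:`SurveyDataset`.

    Deterministic for a fixed (config, codebook): ego ``i`` consumes only
    its own child stream of the master seed.
    """
    config = config or GeneratorConfig()
    codebook = codebook or default_codebook()

    egos: list[EgoRecord] = []
    ties: list[AlterTie] = []
    noms: list[NetworkNominations] = []

    width = len(str(config.n_egos))
    children = np.random.SeedSequence(config.seed).spawn(config.n_egos)
    size_pmf = _normalize(np.asarray(config.size_pmf, dtype=float))
    max_size = min(len(size_pmf) - 1, codebook.nomination_cap)

    for i in range(config.n_egos):
        rng = np.random.default_rng(children[i])
        sex = Sex.FEMALE if rng.random() < config.p_female else Sex.MALE
        ego = EgoRecord(
            ego_id=f"ego{i:0{width}d}",
            sex=sex,
            tobacco_use=bool(rng.random() < config.p_alter_tobacco_by_sex[sex.value]),
            city="Delhi",
        )
        egos.append(ego)

        size = int(rng.choice(len(size_pmf), p=size_pmf))
        size = min(size, max_size)
        for pos in range(1, size + 1):
            ties.append(_draw_tie(rng, config, codebook, ego, pos))

        if size > 0:
            w = _normalize(_NOMINATION_WEIGHTS[:size])
            picks = {}
            for item in ("emergency_contact_pos", "health_problem_pos", "overwhelmed_contact_pos"):
                if rng.random() < config.p_no_nomination:
                    picks[item] = None
                else:
                    picks[item] = int(rng.choice(size, p=w)) + 1
            if any(v is not None for v in picks.values()):
                noms.append(NetworkNominations(ego_id=ego.ego_id, **picks))

    return SurveyDataset(egos=egos, ties=ties, nominations=noms, codebook=codebook)


def dataset_from_size_counts(
    counts_by_sex: dict[str, list[int]],
    relationship: str = "brother",
    codebook: Optional[Codebook] = None,
) -> SurveyDataset:
    """Expand a network-size frequency table into a minimal valid dataset.

    ``counts_by_sex`` maps an ego sex ('female'/'male') to the number of
    egos with size 0, 1, ..., k.  Rosters are filled with a single
    relationship code.  This turns a printed frequency column back into
    respondent-level data, so size summaries can be recomputed exactly.
    """
    codebook = codebook or default_codebook()
    egos: list[EgoRecord] = []
    ties: list[AlterTie] = []
    i = 0
    for sex, counts in counts_by_sex.items():
        for size, count in enumerate(counts):
            for _ in range(count):
                ego_id = f"ego{i:05d}"
                egos.append(EgoRecord(ego_id=ego_id, sex=Sex(sex)))
                ties.extend(
                    AlterTie(ego_id=ego_id, position=p, relationship=relationship)
                    for p in range(1, size + 1)
                )
                i += 1
    return SurveyDataset(egos=egos, ties=ties, codebook=codebook)


# ---------------------------------------------------------------------------
# parameter recovery


def recover_parameters(dataset: SurveyDataset) -> dict:
    """Estimate generator parameters back from a dataset.

    Runs the measurement pipeline (sample summary, tie composition, dyadic
    features) and returns the estimable subset of
    :class:`GeneratorConfig`: the network-size pmf, full-network tie-type
    shares (plus the pooled spouse share, which is invariant to the
    spouse/ego-sex consistency rule), conditional exercise probabilities,
    and alter tobacco prevalence by alter sex.
    """
    n = dataset.n_egos
    summary = summarize_measures(dataset, group_by="sex")
    cap = dataset.codebook.nomination_cap
    size_pmf = [summary.frequency_cell(s, "full")[0] / n for s in range(cap + 1)]

    comp = tie_composition(dataset)
    total = comp.total_ties
    shares = {
        code: comp.counts.loc[code, "full"] / total if total else float("nan")
        for code in comp.counts.index
    }

    dyad = dyadic_features(dataset)
    ex = dyad.exercise.set_index("tie_class")
    p_ex_rel = float(ex.loc["relative", "pct_exercised"]) / 100.0
    p_ex_nonrel = float(ex.loc["non_relative", "pct_exercised"]) / 100.0

    tobacco: dict[str, float] = {}
    for sex in ("female", "male"):
        known = [
            t.alter_tobacco_use
            for t in dataset.ties
            if t.alter_sex is not None
            and t.alter_sex.value == sex
            and t.alter_tobacco_use is not None
        ]
        tobacco[sex] = sum(known) / len(known) if known else float("nan")

    mean_size = summary.measure_cell("network_size", "full")[0]
    return {
        "n_egos": n,
        "p_female": sum(e.sex.value == "female" for e in dataset.egos) / n,
        "size_pmf": size_pmf,
        "mean_network_size": mean_size,
        "tie_type_shares": shares,
        "spouse_share": shares.get("husband", 0.0) + shares.get("wife", 0.0),
        "p_exercise_given_relative": p_ex_rel,
        "p_exercise_given_nonrelative": p_ex_nonrel,
        "p_alter_tobacco_by_sex": tobacco,
    }
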