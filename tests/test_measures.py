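"""Per-ego and per-tie measure semantics, with brute-force oracles."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egonet import (
    EgoRecord,
    GeneratorConfig,
    ego_measures,
    generate,
    network_diversity,
    network_exposure,
    network_homogeneity,
    network_size,
    tie_multiplexity,
    tie_strength,
    top_snack_partner,
)
from egonet.measures import MissingEgoValueError

from conftest import make_dataset, make_tie

FLAGS = st.lists(st.sampled_from([True, False, None]), max_size=8)


def roster_with_tobacco(flags):
    return [
        make_tie("e", i + 1, "friend", alter_tobacco_use=f)
        for i, f in enumerate(flags)
    ]


# ---------------------------------------------------------------------------
# size and exposure


def test_network_size_counts_positions():
    assert network_size(roster_with_tobacco([True, False, None])) == 3
    assert network_size([]) == 0


def test_exposure_simple_fractions():
    assert network_exposure(roster_with_tobacco([True, False, False, False, False]), "tobacco") == 0.2
    assert network_exposure(roster_with_tobacco([True, True, True]), "tobacco") == 1.0


def test_exposure_undefined_without_known_values():
    assert network_exposure([], "tobacco") is None
    assert network_exposure(roster_with_tobacco([None, None]), "tobacco") is None


@settings(max_examples=200, derandomize=True)
@given(FLAGS)
def test_exposure_matches_counting_oracle(flags):
    """Exposure equals (#true / #known) computed by direct enumeration."""
    got = network_exposure(roster_with_tobacco(flags), "tobacco")
    n_true = sum(1 for f in flags if f is True)
    n_known = sum(1 for f in flags if f is not None)
    assert got == (n_true / n_known if n_known else None)


@settings(max_examples=100, derandomize=True)
@given(FLAGS)
def test_exposure_complement_sums_to_one_when_all_known(flags):
    ties = roster_with_tobacco(flags)
    p = network_exposure(ties, "tobacco")
    q = network_exposure(ties, lambda t: None if t.alter_tobacco_use is None
                         else not t.alter_tobacco_use)
    if all(f is not None for f in flags) and flags:
        assert p + q == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# homogeneity


def _ego(sex="female", tobacco=None):
    return EgoRecord(ego_id="e", sex=sex, tobacco_use=tobacco)


def sex_roster(sexes):
    return [
        make_tie("e", i + 1, "friend", alter_sex=s) for i, s in enumerate(sexes)
    ]


def test_homogeneity_sex_half_and_full():
    assert network_homogeneity(_ego(), sex_roster(["female", "female", "male", "male"]), "sex") == 0.5
    assert network_homogeneity(_ego(), sex_roster(["female"]), "sex") == 1.0


def test_homogeneity_missing_ego_value_names_attribute():
    with pytest.raises(MissingEgoValueError, match="tobacco"):
        network_homogeneity(_ego(tobacco=None), sex_roster(["male"]), "tobacco")


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.sampled_from(["female", "male", None]), max_size=6),
       st.sampled_from(["female", "male"]))
def test_homogeneity_invariant_under_joint_relabeling(sexes, ego_sex):
    """Swapping the sex labels of ego and alters together changes nothing."""
    flip = {"female": "male", "male": "female", None: None}
    before = network_homogeneity(_ego(ego_sex), sex_roster(sexes), "sex")
    after = network_homogeneity(
        _ego(flip[ego_sex]), sex_roster([flip[s] for s in sexes]), "sex"
    )
    assert before == after


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.sampled_from(["female", "male", None]), max_size=6))
def test_homogeneity_equals_exposure_to_shared_value(sexes):
    ego = _ego("female")
    ties = sex_roster(sexes)
    shared = lambda t: None if t.alter_sex is None else t.alter_sex == ego.sex
    assert network_homogeneity(ego, ties, "sex") == network_exposure(ties, shared)


def test_homogeneity_bodyweight_uses_similar():
    ties = [
        make_tie("e", 1, "son", alter_bodyweight_vs_ego="similar"),
        make_tie("e", 2, "son", alter_bodyweight_vs_ego="more"),
        make_tie("e", 3, "son", alter_bodyweight_vs_ego=None),
    ]
    assert network_homogeneity(_ego(), ties, "bodyweight") == 0.5


def test_homogeneity_city_counts_household_and_city():
    ties = [
        make_tie("e", 1, "son", residence="same_household"),
        make_tie("e", 2, "son", residence="same_city"),
        make_tie("e", 3, "son", residence="other"),
    ]
    assert network_homogeneity(_ego(), ties, "city") == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# diversity and multiplexity


def test_diversity_mixed_roster(codebook):
    ties = [make_tie("e", i + 1, r) for i, r in
            enumerate(["husband", "son", "friend", "neighbor"])]
    pct, n_types = network_diversity(ties, codebook)
    assert pct == 0.5
    assert n_types == 2  # male-relative and non-relative
    ties = [make_tie("e", i + 1, r) for i, r in
            enumerate(["husband", "daughter", "friend"])]
    assert network_diversity(ties, codebook) == (pytest.approx(2 / 3), 3)


def test_diversity_all_kin_and_empty(codebook):
    ties = [make_tie("e", i + 1, r) for i, r in enumerate(["wife", "son", "mother"])]
    assert network_diversity(ties, codebook)[0] == 1.0
    assert network_diversity([], codebook) == (None, 0)


def test_diversity_invariant_to_position_permutation(codebook):
    rels = ["husband", "son", "friend", "neighbor", "other"]
    a = [make_tie("e", i + 1, r) for i, r in enumerate(rels)]
    b = [make_tie("e", i + 1, r) for i, r in enumerate(reversed(rels))]
    assert network_diversity(a, codebook) == network_diversity(b, codebook)


def test_multiplexity_counts_distinct_domains(codebook):
    tie = make_tie("e", 1, "son", snack_days_14d=3, meal_days_14d=5,
                   exercised_14d=True, contacted_14d=False)
    assert tie_multiplexity(tie, codebook) == 3
    silent = make_tie("e", 1, "son", contacted_14d=False)
    assert tie_multiplexity(silent, codebook) == 0
    everything = make_tie(
        "e", 1, "son", contacted_14d=True, snack_days_14d=1, meal_days_14d=1,
        exercised_14d=True, walked_tasks_14d=True, meal_prep_shop_14d=True,
        tobacco_co_use_14d=True, talk_own_health_freq="often",
    )
    assert tie_multiplexity(everything, codebook) == 8


def test_multiplexity_health_talk_above_never(codebook):
    never = make_tie("e", 1, "son", contacted_14d=False,
                     talk_own_health_freq="never", talk_alter_health_freq="never")
    rarely = make_tie("e", 1, "son", contacted_14d=False,
                      talk_alter_health_freq="rarely")
    assert tie_multiplexity(never, codebook) == 0
    assert tie_multiplexity(rarely, codebook) == 1


# ---------------------------------------------------------------------------
# tie strength


def test_tie_strength_rank_and_flags(tiny_dataset):
    cb = tiny_dataset.codebook
    ties = tiny_dataset.ties_for("e1")
    noms = tiny_dataset.nominations_for("e1")
    s = tie_strength(ties, noms, cb)
    assert [x.strength_rank for x in s] == [1, 2]
    assert s[0].is_health_contact and not s[0].is_emergency_contact
    assert s[1].is_emergency_contact and not s[1].is_health_contact


@pytest.mark.parametrize("seed", [0, 5])
def test_ranks_are_a_strict_total_order_per_ego(seed):
    ds = generate(GeneratorConfig(n_egos=40, seed=seed))
    for e in ds.egos:
        ties = ds.ties_for(e.ego_id)
        ranks = [x.strength_rank for x in
                 tie_strength(ties, ds.nominations_for(e.ego_id), ds.codebook)]
        assert ranks == list(range(1, len(ties) + 1))


def test_tie_nominated_everywhere_has_all_flags(tiny_dataset):
    from egonet import NetworkNominations
    noms = NetworkNominations(ego_id="e1", emergency_contact_pos=1,
                              health_problem_pos=1, overwhelmed_contact_pos=1)
    s = tie_strength(tiny_dataset.ties_for("e1"), noms, tiny_dataset.codebook)
    assert s[0].is_emergency_contact and s[0].is_health_contact and s[0].is_overwhelmed_contact


# ---------------------------------------------------------------------------
# ego_measures composition


def test_ego_with_empty_roster_is_all_undefined():
    ds = make_dataset([EgoRecord(ego_id="e0", sex="male")], [])
    m = ego_measures(ds, "e0")
    assert m.network_size == 0
    assert m.pct_family is None and m.n_tie_types == 0
    assert m.exposure["tobacco"] is None
    assert all(v is None for v in m.homogeneity.values())
    assert m.first_named_relative is None
    assert m.top_snack_partner_relative is None


def test_unknown_ego_raises():
    ds = make_dataset([EgoRecord(ego_id="e0", sex="male")], [])
    with pytest.raises(KeyError):
        ego_measures(ds, "nope")


def test_top_snack_partner_friend_means_false():
    ego = EgoRecord(ego_id="e", sex="female")
    ties = [
        make_tie("e", 1, "husband", snack_days_14d=0),
        make_tie("e", 2, "friend", snack_days_14d=2),
    ]
    ds = make_dataset([ego], ties)
    assert ego_measures(ds, "e").top_snack_partner_relative is False


def test_top_snack_partner_tie_breaks_by_closeness():
    ties = [
        make_tie("e", 1, "husband", snack_days_14d=4),
        make_tie("e", 2, "friend", snack_days_14d=4),
        make_tie("e", 3, "sister", snack_days_14d=6),
    ]
    assert top_snack_partner(ties).relationship == "sister"
    ties[2].snack_days_14d = 4
    assert top_snack_partner(ties).relationship == "husband"
    for t in ties:
        t.snack_days_14d = 0
    assert top_snack_partner(ties) is None


@pytest.mark.parametrize("seed", [1, 11])
def test_ego_measures_agrees_with_measure_by_measure_recomputation(seed):
    """The composed record equals each measure computed independently."""
    ds = generate(GeneratorConfig(n_egos=30, seed=seed))
    for e in ds.egos:
        ties = ds.ties_for(e.ego_id)
        m = ego_measures(ds, e.ego_id)
        assert m.network_size == network_size(ties)
        assert m.exposure["tobacco"] == network_exposure(ties, "tobacco")
        for attr in ("sex", "city", "bodyweight"):
            assert m.homogeneity[attr] == network_homogeneity(e, ties, attr)
        assert (m.pct_family, m.n_tie_types) == network_diversity(ties, ds.codebook)
        if ties:
            assert m.first_named_relative == ds.codebook.is_relative(ties[0].relationship)


def test_all_proportions_lie_in_unit_interval():
    ds = generate(GeneratorConfig(n_egos=60, seed=9))
    for e in ds.egos:
        m = ego_measures(ds, e.ego_id)
        vals = [m.pct_family, *m.exposure.values(), *m.homogeneity.values()]
        assert all(v is None or 0.0 <= v <= 1.0 for v in vals)
        assert m.n_tie_types <= m.network_size
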