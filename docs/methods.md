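# Methods

## Data model

A survey is a triple of record types joined on `ego_id`:

* `EgoRecord` — one respondent: sex (required, because the same-sex
  homogeneity measure and the grouped summaries need it), optional own
  tobacco use, city, a self-referent bodyweight class, and a free
  key–value covariate bag for fields carried from a host survey. Covariate
  values are kept as strings so CSV round-trips are lossless.
* `AlterTie` — one nominated ego–alter relation: the closeness position
  (1 = closest; positions within an ego must be a contiguous run starting
  at 1, at most the nomination cap, default 5), the relationship code,
  alter sex and residence, two ordered health-talk frequency items, and
  the 14-day shared-activity recall (binary items plus snack/meal day
  counts in [0, 14]).
* `NetworkNominations` — the three network-level choices (emergency
  contact, health-problem confidant, overwhelmed contact), each a roster
  position; a nomination may only reference an existing tie of the same
  ego.

Field-level constraints are enforced at construction (pydantic);
cross-record invariants are checked by `validate`, which returns the full
list of violations and never mutates. File readers collect *all* problems
found — malformed cells, duplicate or gapped positions, unknown codes,
out-of-range day counts, dangling nominations — and raise them together,
so nothing is silently dropped. Missing alter attributes are represented
as `None` and excluded from both numerator and denominator of any
proportion; they are never imputed.

## Codebook and classification policy

The codebook declares the 24 recognised relationship codes and their
grouping into four broad classes (male relative, female relative,
non-relative, other). Friend, workmate and neighbor are non-relatives; all
kin codes are relatives. Two genuinely open conventions are explicit
config, not hard-coded:

* **"Other" ties** default to the *relative* side of the binary
  relative/non-relative classification. This is the only convention under
  which the published tie-pooled counts are mutually consistent (the
  four-class composition shares and the 637/143 relative/non-relative
  split over 780 ties agree only when "other" pools with relatives). It
  can be flipped via `Codebook.other_is_relative` or `--policy`.
* **Health-talk response scale**: the instrument's exact scale is not
  printed in the source material we work from, so the codebook ships a
  4-level ordered default (never/rarely/sometimes/often), overridable.
  Any level above the lowest counts as engagement for the health-talk
  multiplexity domain.

## Measures

Definitions follow the standard egocentric vocabulary (see README).
Numerical conventions worth stating:

* **Exposure** is the unconditional proportion over alters with known
  values. A stricter reading would restrict the measure to egos lacking
  the attribute themselves; we follow the convention used in published
  sample summaries (means reported over all egos), and the predicate
  interface lets a caller impose the restriction externally.
* **Homogeneity** raises an error (naming the attribute) when the ego's
  own value is missing, rather than silently returning undefined — a
  missing ego value is a data problem, not an empty denominator. For the
  bodyweight item "match" means the alter was perceived as of *similar*
  weight; the item is already ego-referent. For residence, household and
  same-city codes both count as "same city".
* **Top snack partner** is the alter with the maximal snack-day count,
  ties broken by closeness rank (lower position wins) — deterministic and
  closeness-respecting; undefined when no alter shared a snack.
* **Primary health contact** defaults to the health-problem nomination
  and can be switched to the emergency item (`health_contact_item`).
* **Multiplexity** counts engaged domains among the configured list (8 by
  default); unknown responses count as not engaged, so the count is a
  lower bound under item non-response.

## Aggregation

Network-size mean/SD and the size frequency distribution are computed over
all egos, including empty rosters; composition measures (exposure,
homogeneity, diversity) over egos with ≥ 1 alter. Egos with a non-empty
roster can still have an undefined measure when every alter's value is
unknown; `undefined="drop"` (default) averages over defined values only,
`undefined="zero"` substitutes 0. Both modes are exposed because sample
summaries in the literature rarely state which convention they used.

SDs are sample SDs (n − 1). Tabulated percentages and means are rounded
half-up at the precision of the corresponding output (one decimal for
summary and composition tables, integers for the dyadic table); raw
unrounded values are always retained in the objects and CSVs, rounding is
display-only. p-values print with two decimals and a "<0.01" floor.
Group comparisons use Pearson chi-square without continuity correction
(categorical rows; unobserved categories are dropped from the table since
they carry no information) and the classical one-way ANOVA F-test
(continuous rows), both delegated to scipy behind the module interface.
All aggregate outputs are invariant to the row order of the input files.

## Synthetic data generator

The generator emulates a ~200-respondent urban-Indian adult sample
interviewed with a 5-nomination closeness roster. Defaults are the
published sample-level distributions, and they define the test conditions:

* network-size pmf ∝ the observed frequency column (7, 8, 12, 56, 45, 80
  egos naming 0–5 members; mean 3.75);
* tie-type distribution *per nomination position* ∝ the observed
  composition columns — spouses dominate position 1, children, siblings
  and friends appear at later positions;
* conditional exercise-partner probabilities 0.08 (relative ties) and
  0.17 (non-relative ties); alter tobacco prevalence 0.39 for male and
  0.03 for female alters (the published ego-level rates, applied to
  alters); 90% of alters in the ego's city.

Where the source tables report no value, rates are one-time modelling
choices: snack/meal day counts are Binomial(14, rate) with kin-skewed
rates (meals strongly so, reflecting co-residence), walking and
meal-preparation partners are likelier among relatives, and the three
network-level nominations are drawn with weights decaying in position.
Alter sex is implied by sexed kin codes and Bernoulli(0.5) for unsexed
codes. Spouse codes are made consistent with ego sex by moving the
impossible code's probability mass onto the possible one (husband→wife for
male egos and vice versa), which preserves the pooled spouse share for any
sex mix; a roster can therefore (rarely) contain two spouse-coded ties,
which we accept to keep the per-position type law exactly multinomial.

Each ego consumes its own child stream of the master seed
(`SeedSequence.spawn`), so output is reproducible and independent of
generation order.

**What the generator does not emulate:** within-household correlation of
the sampling design (one man + one woman per household), any joint
distribution of alter tobacco use with relationship type (independence
given alter sex), item non-response beyond the unknown-rate parameters,
and the correlation between network size and composition. Passing tests
therefore demonstrate correctness of the measurement pipeline and
calibration of the marginal structure, not behaviour on the full
dependence structure of real survey data.

## Parameter recovery

`recover_parameters` re-estimates the estimable config subset (size pmf,
tie-type shares, conditional exercise probabilities, tobacco prevalence by
alter sex) by running the measurement pipeline on a generated dataset. The
acceptance check generates 20,000 egos (~75,000 ties) and requires each
estimate within 3 binomial standard errors of its target; tie-type shares
are compared position-weighted, with husband+wife pooled because the pooled
share is invariant to the spouse/ego-sex consistency rule. Consistency is
additionally checked across 500 / 5,000 / 50,000 egos (L1 error of the
recovered size pmf must decrease). These problem sizes keep the full suite
at roughly two minutes on one core while leaving Monte-Carlo error well
below the tolerances.

## Known limitations

* Published *respondent-level* means of exposure/homogeneity (and their
  p-values) cannot be recomputed from sample-level tables alone; the
  acceptance surface deliberately covers only quantities that are
  functions of printed counts, plus generator-based self-consistency.
* The long/wide readers expect the package's own column naming; mapping
  arbitrary field exports onto the schema is left to the caller.
* The wide format allocates one column block per slot up to the cap, so
  very large caps produce wide files; the long format is preferred there.
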