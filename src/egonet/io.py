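"""Readers and writers for roster survey tables.

Two tabular layouts are supported, both CSV (UTF-8, header row):

* **long** -- one row per ego--alter tie, plus a companion ego table that
  carries the respondent fields and the three network-level nominations;
* **wide** -- one row per ego mirroring the instrument layout, with one
  positional column block per nomination slot (``a1_``, ``a2_``, ...);
  an all-empty block is an un-nominated slot.

Reading validates: field-level problems and cross-record invariant
violations are collected and raised together as a
:class:`~egonet.validate.SchemaError`; nothing is silently dropped.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import pandas as pd
from pydantic import ValidationError

from .codebook import Codebook, default_codebook
from .model import AlterTie, EgoRecord, NetworkNominations, SurveyDataset
from .validate import SchemaError, Violation, validate

TIE_COLUMNS = [
    "ego_id",
    "position",
    "alter_label",
    "alter_sex",
    "relationship",
    "residence",
    "talk_own_health_freq",
    "talk_alter_health_freq",
    "contacted_14d",
    "snack_days_14d",
    "meal_days_14d",
    "exercised_14d",
    "walked_tasks_14d",
    "meal_prep_shop_14d",
    "tobacco_co_use_14d",
    "alter_tobacco_use",
    "alter_bodyweight_vs_ego",
]

EGO_COLUMNS = [
    "ego_id",
    "sex",
    "tobacco_use",
    "bodyweight_class",
    "city",
    "emergency_contact_pos",
    "health_problem_pos",
    "overwhelmed_contact_pos",
]

_BOOL_FIELDS = {
    "contacted_14d",
    "exercised_14d",
    "walked_tasks_14d",
    "meal_prep_shop_14d",
    "tobacco_co_use_14d",
    "alter_tobacco_use",
    "tobacco_use",
}
_INT_FIELDS = {
    "position",
    "snack_days_14d",
    "meal_days_14d",
    "emergency_contact_pos",
    "health_problem_pos",
    "overwhelmed_contact_pos",
}


def _parse_cell(field: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if field in _BOOL_FIELDS:
        if raw in ("1", "true", "True", "yes"):
            return True
        if raw in ("0", "false", "False", "no"):
            return False
        raise ValueError(f"{field}: cannot parse {raw!r} as binary (use 1/0)")
    if field in _INT_FIELDS:
        return int(raw)
    return raw


def _fmt_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if hasattr(value, "value"):  # enums
        return str(value.value)
    return str(value)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# long format


def _parse_ego_rows(df: pd.DataFrame, errors: list[Violation]):
    egos: list[EgoRecord] = []
    noms: list[NetworkNominations] = []
    extra = [c for c in df.columns if c not in EGO_COLUMNS]
    for _, row in df.iterrows():
        ego_id = str(row.get("ego_id", "")).strip()
        try:
            kwargs = {
                f: _parse_cell(f, str(row[f]))
                for f in ("ego_id", "sex", "tobacco_use", "bodyweight_class", "city")
                if f in df.columns
            }
            covariates = {
                c: str(row[c]).strip() for c in extra if str(row[c]).strip() != ""
            }
            egos.append(EgoRecord(**kwargs, covariates=covariates))
            nom_kwargs = {
                f: _parse_cell(f, str(row[f]))
                for f in (
                    "emergency_contact_pos",
                    "health_problem_pos",
                    "overwhelmed_contact_pos",
                )
                if f in df.columns
            }
            if any(v is not None for v in nom_kwargs.values()):
                noms.append(NetworkNominations(ego_id=ego_id, **nom_kwargs))
        except (ValueError, ValidationError) as exc:
            errors.append(
                Violation(ego_id=ego_id or "?", rule="bad-ego-row", detail=str(exc))
            )
    return egos, noms


def _parse_tie_kwargs(kwargs: dict, errors: list[Violation]) -> AlterTie | None:
    ego_id = str(kwargs.get("ego_id") or "?")
    try:
        return AlterTie(**kwargs)
    except (ValueError, ValidationError) as exc:
        errors.append(Violation(ego_id=ego_id, rule="bad-tie-row", detail=str(exc)))
        return None


def read_long(
    ties_path: str | Path,
    egos_path: str | Path,
    codebook: Codebook | None = None,
) -> SurveyDataset:
    """Read a long-format tie table plus its ego table into a valid dataset.

    Raises :class:`SchemaError` carrying every problem found (malformed
    cells, duplicate or gapped positions, out-of-range day counts, unknown
    relationship codes, dangling nominations).
    """
    codebook = codebook or default_codebook()
    errors: list[Violation] = []

    egos, noms = _parse_ego_rows(_read_csv(egos_path), errors)

    tie_df = _read_csv(ties_path)
    ties: list[AlterTie] = []
    for _, row in tie_df.iterrows():
        try:
            kwargs = {
                f: _parse_cell(f, str(row[f])) for f in TIE_COLUMNS if f in tie_df.columns
            }
        except ValueError as exc:
            errors.append(
                Violation(
                    ego_id=str(row.get("ego_id", "?")),
                    rule="bad-tie-row",
                    detail=str(exc),
                )
            )
            continue
        tie = _parse_tie_kwargs(kwargs, errors)
        if tie is not None:
            ties.append(tie)

    dataset = SurveyDataset(egos=egos, ties=ties, nominations=noms, codebook=codebook)
    errors.extend(validate(dataset))
    if errors:
        raise SchemaError(errors)
    return dataset


def write_long(
    dataset: SurveyDataset, ties_path: str | Path, egos_path: str | Path
) -> None:
    """Write the long tie table and the ego table as CSV."""
    tie_rows = [
        {c: _fmt_cell(getattr(t, c)) for c in TIE_COLUMNS}
        for t in sorted(dataset.ties, key=lambda t: (t.ego_id, t.position))
    ]
    pd.DataFrame(tie_rows, columns=TIE_COLUMNS).to_csv(ties_path, index=False)

    cov_keys = sorted({k for e in dataset.egos for k in e.covariates})
    noms = dataset.nominations_by_ego()
    ego_rows = []
    for e in dataset.egos:
        n = noms.get(e.ego_id)
        row = {
            "ego_id": e.ego_id,
            "sex": _fmt_cell(e.sex),
            "tobacco_use": _fmt_cell(e.tobacco_use),
            "bodyweight_class": _fmt_cell(e.bodyweight_class),
            "city": _fmt_cell(e.city),
            "emergency_contact_pos": _fmt_cell(n.emergency_contact_pos if n else None),
            "health_problem_pos": _fmt_cell(n.health_problem_pos if n else None),
            "overwhelmed_contact_pos": _fmt_cell(
                n.overwhelmed_contact_pos if n else None
            ),
        }
        for k in cov_keys:
            row[k] = e.covariates.get(k, "")
        ego_rows.append(row)
    pd.DataFrame(ego_rows, columns=EGO_COLUMNS + cov_keys).to_csv(egos_path, index=False)


# ---------------------------------------------------------------------------
# wide format

_WIDE_TIE_FIELDS = [c for c in TIE_COLUMNS if c not in ("ego_id", "position")]


def read_wide(path: str | Path, codebook: Codebook | None = None) -> SurveyDataset:
    """Read a wide-format table (one row per ego, ``a<k>_`` column blocks).

    A block counts as filled when any of its cells is non-empty; filled
    slots must be contiguous from slot 1 (a gap is a hard error).
    """
    codebook = codebook or default_codebook()
    df = _read_csv(path)
    errors: list[Violation] = []

    slots = []
    k = 1
    while any(f"a{k}_{f}" in df.columns for f in _WIDE_TIE_FIELDS):
        slots.append(k)
        k += 1

    ego_cols = [c for c in df.columns if not any(c.startswith(f"a{k}_") for k in slots)]
    egos, noms = _parse_ego_rows(df[ego_cols], errors)

    ties: list[AlterTie] = []
    for _, row in df.iterrows():
        ego_id = str(row.get("ego_id", "")).strip()
        for k in slots:
            block = {
                f: str(row[f"a{k}_{f}"])
                for f in _WIDE_TIE_FIELDS
                if f"a{k}_{f}" in df.columns
            }
            if all(v.strip() == "" for v in block.values()):
                continue
            try:
                kwargs = {f: _parse_cell(f, v) for f, v in block.items()}
            except ValueError as exc:
                errors.append(
                    Violation(ego_id=ego_id or "?", rule="bad-tie-row", detail=str(exc))
                )
                continue
            tie = _parse_tie_kwargs({"ego_id": ego_id, "position": k, **kwargs}, errors)
            if tie is not None:
                ties.append(tie)

    dataset = SurveyDataset(egos=egos, ties=ties, nominations=noms, codebook=codebook)
    errors.extend(validate(dataset))
    if errors:
        raise SchemaError(errors)
    return dataset


def write_wide(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the dataset as one row per ego with positional column blocks."""
    cap = dataset.codebook.nomination_cap
    cov_keys = sorted({k for e in dataset.egos for k in e.covariates})
    cols = EGO_COLUMNS + cov_keys + [
        f"a{k}_{f}" for k in range(1, cap + 1) for f in _WIDE_TIE_FIELDS
    ]
    noms = dataset.nominations_by_ego()
    rosters = dataset.ties_by_ego()
    rows = []
    for e in dataset.egos:
        n = noms.get(e.ego_id)
        row = dict.fromkeys(cols, "")
        row.update(
            ego_id=e.ego_id,
            sex=_fmt_cell(e.sex),
            tobacco_use=_fmt_cell(e.tobacco_use),
            bodyweight_class=_fmt_cell(e.bodyweight_class),
            city=_fmt_cell(e.city),
            emergency_contact_pos=_fmt_cell(n.emergency_contact_pos if n else None),
            health_problem_pos=_fmt_cell(n.health_problem_pos if n else None),
            overwhelmed_contact_pos=_fmt_cell(n.overwhelmed_contact_pos if n else None),
        )
        for k in cov_keys:
            row[k] = e.covariates.get(k, "")
        for t in rosters.get(e.ego_id, []):
            for f in _WIDE_TIE_FIELDS:
                row[f"a{t.position}_{f}"] = _fmt_cell(getattr(t, f))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# utilities


def pseudonymize(dataset: SurveyDataset, salt: str = "") -> SurveyDataset:
    """Return a copy with alter labels replaced by one-way hashed tokens.

    Alter names are collected only to anchor follow-up items during the
    interview; no measure needs them, so rosters can be scrubbed before
    storage.  The same (salt, label) pair always yields the same token.
    """
    out = dataset.model_copy(deep=True)
    for t in out.ties:
        if t.alter_label is not None:
            digest = hashlib.sha256((salt + t.alter_label).encode()).hexdigest()[:12]
            t.alter_label = f"p{digest}"
    return out


def to_networkx(dataset: SurveyDataset) -> dict[str, nx.Graph]:
    """Each ego's roster as a star graph (ego at the hub), keyed by ego_id.

    Edges carry position, relationship and the tie-class label; handy for
    plotting or for feeding dyad lists into graph tooling.
    """
    graphs: dict[str, nx.Graph] = {}
    for e in dataset.egos:
        g = nx.Graph()
        g.add_node(e.ego_id, kind="ego", sex=e.sex.value)
        for t in dataset.ties_for(e.ego_id):
            alter = t.alter_label or f"{e.ego_id}:a{t.position}"
            g.add_node(alter, kind="alter")
            g.add_edge(
                e.ego_id,
                alter,
                position=t.position,
                relationship=t.relationship,
                tie_class=dataset.codebook.tie_class(t.relationship).value,
            )
        graphs[e.ego_id] = g
    return graphs
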