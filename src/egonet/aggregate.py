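"""Sample-level summaries of a roster survey.

Three grouped outputs mirror how egocentric health-survey results are
conventionally reported:

* a **sample summary** -- mean/SD of each network measure and the network
  size frequency distribution, for the full sample and by a grouping
  variable (default: ego sex), with chi-square / one-way ANOVA group
  comparisons;
* a **tie composition table** -- the share of each relationship type among
  all ties and within each nomination position;
* a **dyadic features table** -- relative vs non-relative splits of the
  first-named alter, the primary health contact and the most frequent
  snack partner, plus exercise-partner shares within relative and
  non-relative ties.

Denominator conventions: mean/SD and the frequency distribution of network
size are computed over *all* egos (including empty rosters); composition
measures (exposure, homogeneity, diversity) are computed over egos with at
least one alter, since they are undefined on empty rosters.  Every output
row carries its denominator explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import json
import numpy as np
import pandas as pd
from scipy import stats

from .measures import ego_measures_table, tie_measures_table
from .model import SurveyDataset

#: ego-level measures reported as percentages over egos with >= 1 alter
COMPOSITION_MEASURES = [
    "exposure_tobacco",
    "homogeneity_sex",
    "homogeneity_bodyweight",
    "homogeneity_city",
    "pct_family",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Two-decimal p-value with '<0.01' flooring, NaN-safe."""
    if p != p:  # NaN
        return ""
    if p < 0.01:
        return "<0.01"
    return f"{round_half_up(p, 2):.2f}"


# ---------------------------------------------------------------------------
# group-comparison statistics


def chi_square_2xk(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (statistic, degrees of freedom, p-value).  Raises ValueError
    on a malformed table or a zero row/column marginal.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row or column marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA F-test.

    ``groups`` is a sequence of value sequences, one per group.  Returns
    (F, df between, df within, p).  Raises ValueError with fewer than two
    groups or a group with fewer than two observations.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    k = len(arrs)
    n = sum(a.size for a in arrs)
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:  # all observations identical: no variance to test
        return 0.0, k - 1, n - k, 1.0
    f, p = stats.f_oneway(*arrs)
    return float(f), k - 1, n - k, float(p)


# ---------------------------------------------------------------------------
# sample summary (measure means, SDs, size frequencies, comparisons)


@dataclass
class SampleSummary:
    """Grouped measure means/SDs and the size frequency distribution."""

    group_by: str
    group_ns: dict[str, int]  # all egos per group ('full' included)
    measures: pd.DataFrame  # measure, group, n, mean, sd
    frequency: pd.DataFrame  # size, group, count, pct
    comparisons: pd.DataFrame  # row, test, statistic, df, p, p_display

    def measure_cell(self, measure: str, group: str = "full") -> tuple[float, float]:
        """(mean, sd) for one measure in one group."""
        m = self.measures
        row = m[(m["measure"] == measure) & (m["group"] == group)]
        if row.empty:
            raise KeyError((measure, group))
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def frequency_cell(self, size: int, group: str = "full") -> tuple[int, float]:
        f = self.frequency
        row = f[(f["size"] == size) & (f["group"] == group)]
        if row.empty:
            raise KeyError((size, group))
        return int(row["count"].iloc[0]), float(row["pct"].iloc[0])

    def rounded(self, ndigits: int = 1) -> "SampleSummary":
        """Copy with means/SDs/percentages rounded half-up for display."""
        meas = self.measures.copy()
        for c in ("mean", "sd"):
            meas[c] = meas[c].map(lambda v: round_half_up(v, ndigits) if v == v else v)
        freq = self.frequency.copy()
        freq["pct"] = freq["pct"].map(lambda v: round_half_up(v, ndigits))
        return SampleSummary(
            self.group_by, dict(self.group_ns), meas, freq, self.comparisons.copy()
        )

    def to_text(self) -> str:
        r = self.rounded()
        parts = [
            f"Egos per group: {self.group_ns}",
            "",
            "Measures (mean, SD, n):",
            r.measures.to_string(index=False),
            "",
            "Network size frequency:",
            r.frequency.to_string(index=False),
            "",
            "Group comparisons:",
            r.comparisons.to_string(index=False),
        ]
        return "\n".join(parts) + "\n"


def _group_values(df: pd.DataFrame, group_by: str) -> list[str]:
    if df[group_by].isna().any() or (df[group_by] == "").any():
        missing = df.loc[df[group_by].isna() | (df[group_by] == ""), "ego_id"]
        raise ValueError(
            f"grouping field {group_by!r} missing for egos: {sorted(missing)[:5]}"
        )
    return sorted(df[group_by].unique())


def summarize_measures(
    dataset: SurveyDataset,
    group_by: str = "sex",
    undefined: str = "drop",
    health_contact_item: str = "health_problem",
) -> SampleSummary:
    """Build the grouped sample summary.

    ``undefined`` controls how undefined composition measures on non-empty
    rosters are averaged: ``"drop"`` (default) averages over egos with a
    defined value only; ``"zero"`` substitutes 0.  (Undefined can occur
    when every alter's value for an attribute is unknown.)
    """
    if undefined not in ("drop", "zero"):
        raise ValueError("undefined must be 'drop' or 'zero'")
    table = ego_measures_table(dataset, health_contact_item=health_contact_item)
    if group_by != "sex":
        table = table.assign(
            **{group_by: [e.covariates.get(group_by, "") for e in dataset.egos]}
        )
    levels = _group_values(table, group_by)
    groups = {"full": table} | {g: table[table[group_by] == g] for g in levels}
    cap = dataset.codebook.nomination_cap

    meas_rows, freq_rows = [], []
    for gname, gdf in groups.items():
        sizes = gdf["network_size"].to_numpy(dtype=float)
        meas_rows.append(
            {
                "measure": "network_size",
                "group": gname,
                "n": len(gdf),
                "mean": sizes.mean() if len(gdf) else float("nan"),
                "sd": sizes.std(ddof=1) if len(gdf) > 1 else float("nan"),
            }
        )
        nonempty = gdf[gdf["network_size"] > 0]
        for m in COMPOSITION_MEASURES:
            vals = nonempty[m].astype(float) * 100.0
            vals = vals.fillna(0.0) if undefined == "zero" else vals.dropna()
            meas_rows.append(
                {
                    "measure": m,
                    "group": gname,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else float("nan"),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                }
            )
        counts = gdf["network_size"].value_counts()
        for s in range(cap + 1):
            c = int(counts.get(s, 0))
            freq_rows.append(
                {
                    "size": s,
                    "group": gname,
                    "count": c,
                    "pct": 100.0 * c / len(gdf) if len(gdf) else float("nan"),
                }
            )

    comp_rows = []
    if len(levels) >= 2:
        def _try(row, test, fn):
            try:
                comp_rows.append({"row": row, "test": test} | fn())
            except ValueError:
                comp_rows.append(
                    {"row": row, "test": test, "statistic": float("nan"),
                     "df": "", "p": float("nan")}
                )

        def _anova_row(m, all_egos=False):
            def fn():
                vals = []
                for g in levels:
                    gdf = groups[g]
                    if not all_egos:
                        gdf = gdf[gdf["network_size"] > 0]
                    v = gdf[m].astype(float)
                    v = v.fillna(0.0) if undefined == "zero" else v.dropna()
                    vals.append(v.to_numpy())
                f, df1, df2, p = anova_oneway(vals)
                return {"statistic": f, "df": f"{df1},{df2}", "p": p}
            _try(m, "anova", fn)

        _anova_row("network_size", all_egos=True)

        def freq_fn():
            tab = np.array(
                [
                    [
                        int((groups[g]["network_size"] == s).sum())
                        for s in range(cap + 1)
                    ]
                    for g in levels
                ]
            )
            tab = tab[:, tab.sum(axis=0) > 0]  # unobserved sizes carry no information
            stat, df, p = chi_square_2xk(tab)
            return {"statistic": stat, "df": str(df), "p": p}

        _try("size_frequency", "chi-square", freq_fn)
        for m in COMPOSITION_MEASURES:
            _anova_row(m)

    comparisons = pd.DataFrame(
        comp_rows, columns=["row", "test", "statistic", "df", "p"]
    )
    if len(comparisons):
        comparisons["p_display"] = comparisons["p"].map(format_p)
    else:
        comparisons["p_display"] = pd.Series(dtype=str)

    return SampleSummary(
        group_by=group_by,
        group_ns={g: len(df_) for g, df_ in groups.items()},
        measures=pd.DataFrame(meas_rows),
        frequency=pd.DataFrame(freq_rows),
        comparisons=comparisons,
    )


# ---------------------------------------------------------------------------
# tie composition by nomination position


@dataclass
class TieCompositionTable:
    """Counts and shares of each tie type, overall and per position."""

    counts: pd.DataFrame  # index: relationship code; columns: 'full', 1..cap
    class_counts: pd.DataFrame  # index: tie class; same columns
    position_denominators: dict[int, int]
    total_ties: int

    def percentages(self, ndigits: Optional[int] = None) -> pd.DataFrame:
        return self._pct(self.counts, ndigits)

    def class_percentages(self, ndigits: Optional[int] = None) -> pd.DataFrame:
        return self._pct(self.class_counts, ndigits)

    def _pct(self, counts: pd.DataFrame, ndigits: Optional[int]) -> pd.DataFrame:
        denom = {"full": self.total_ties} | self.position_denominators
        out = counts.astype(float)
        for col in out.columns:
            d = denom[col]
            out[col] = out[col] * 100.0 / d if d else float("nan")
        if ndigits is not None:
            out = out.map(lambda v: round_half_up(v, ndigits) if v == v else v)
        return out

    def to_text(self) -> str:
        pct = self.percentages(1)
        head = ["Position denominators: "
                + ", ".join(f"{k}: n={v}" for k, v in self.position_denominators.items())
                + f"; total ties {self.total_ties}"]
        return "\n".join(head + ["", pct.to_string()]) + "\n"


def tie_composition(dataset: SurveyDataset) -> TieCompositionTable:
    """Tabulate tie types over all ties and within each position.

    Full-network shares use the total tie count as denominator; positional
    shares use the number of ties at that position (which is non-increasing
    in position because rosters are contiguous from position 1).
    """
    cb = dataset.codebook
    cap = cb.nomination_cap
    codes = list(cb.relationship_classes)
    cols = ["full"] + list(range(1, cap + 1))
    counts = pd.DataFrame(0, index=codes, columns=cols, dtype=int)
    for t in dataset.ties:
        counts.loc[t.relationship, "full"] += 1
        counts.loc[t.relationship, t.position] += 1
    class_counts = counts.groupby(
        [cb.tie_class(c).value for c in codes], sort=False
    ).sum()
    pos_denoms = {p: int(counts[p].sum()) for p in range(1, cap + 1)}
    return TieCompositionTable(
        counts=counts,
        class_counts=class_counts,
        position_denominators=pos_denoms,
        total_ties=int(counts["full"].sum()),
    )


# ---------------------------------------------------------------------------
# dyadic features (strongest ties, exercise partners)


@dataclass
class DyadicFeaturesTable:
    """Relative / non-relative splits of strongest-tie features.

    ``strongest``: one row per feature (first_named, health_contact,
    snack_partner) with relative and non-relative counts, percentages and
    the row's denominator (egos with that feature defined).

    ``exercise``: one row per tie class (relative, non_relative) with the
    number and share of ties the ego exercised with, over all ties of the
    class.
    """

    strongest: pd.DataFrame
    exercise: pd.DataFrame

    def to_text(self) -> str:
        s = self.strongest.copy()
        e = self.exercise.copy()
        for df_, col in ((s, "pct_relative"), (s, "pct_nonrelative"), (e, "pct_exercised")):
            df_[col] = df_[col].map(lambda v: round_half_up(v, 0) if v == v else v)
        return (
            "Strongest ties (relative vs non-relative):\n"
            + s.to_string(index=False)
            + "\n\nExercise partners by tie class:\n"
            + e.to_string(index=False)
            + "\n"
        )


def dyadic_features(
    dataset: SurveyDataset, health_contact_item: str = "health_problem"
) -> DyadicFeaturesTable:
    """Build the dyadic features table.

    Row denominators: first-named over egos with >= 1 alter; health
    contact over egos with the nomination answered; snack partner over
    egos with at least one positive snack-day count.  Exercise rows are
    tie-pooled within each class.
    """
    etab = ego_measures_table(dataset, health_contact_item=health_contact_item)
    rows = []
    for feature, col in (
        ("first_named", "first_named_relative"),
        ("health_contact", "health_contact_relative"),
        ("snack_partner", "top_snack_partner_relative"),
    ):
        defined = etab[col].dropna()
        n = len(defined)
        n_rel = int(defined.sum())
        rows.append(
            {
                "feature": feature,
                "n_relative": n_rel,
                "pct_relative": 100.0 * n_rel / n if n else float("nan"),
                "n_nonrelative": n - n_rel,
                "pct_nonrelative": 100.0 * (n - n_rel) / n if n else float("nan"),
                "denominator": n,
            }
        )

    ttab = tie_measures_table(dataset)
    ex_rows = []
    for cls, flag in (("relative", True), ("non_relative", False)):
        sub = ttab[ttab["is_relative"] == flag]
        n = len(sub)
        n_ex = int((sub["exercised_14d"] == True).sum())  # noqa: E712 (None-safe)
        ex_rows.append(
            {
                "tie_class": cls,
                "n_exercised": n_ex,
                "pct_exercised": 100.0 * n_ex / n if n else float("nan"),
                "n_ties": n,
            }
        )
    return DyadicFeaturesTable(
        strongest=pd.DataFrame(rows), exercise=pd.DataFrame(ex_rows)
    )


# ---------------------------------------------------------------------------
# file output


def write_tables(
    dataset: SurveyDataset,
    outdir: str | Path,
    group_by: str = "sex",
    undefined: str = "drop",
    health_contact_item: str = "health_problem",
    rounding_digits: int = 1,
) -> dict:
    """Write the three summary tables (CSV + aligned text) and a manifest.

    Returns the manifest dict (denominators, classification policy,
    rounding mode) that is also written as ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary = summarize_measures(
        dataset, group_by=group_by, undefined=undefined,
        health_contact_item=health_contact_item,
    )
    comp = tie_composition(dataset)
    dyad = dyadic_features(dataset, health_contact_item=health_contact_item)

    summary.measures.to_csv(outdir / "network_summary_measures.csv", index=False)
    summary.frequency.to_csv(outdir / "network_summary_frequency.csv", index=False)
    summary.comparisons.to_csv(outdir / "network_summary_comparisons.csv", index=False)
    (outdir / "network_summary.txt").write_text(summary.to_text())

    comp.counts.to_csv(outdir / "tie_composition_counts.csv")
    comp.percentages().to_csv(outdir / "tie_composition_pct.csv")
    (outdir / "tie_composition.txt").write_text(comp.to_text())

    dyad.strongest.to_csv(outdir / "dyadic_strongest.csv", index=False)
    dyad.exercise.to_csv(outdir / "dyadic_exercise.csv", index=False)
    (outdir / "dyadic_features.txt").write_text(dyad.to_text())

    manifest = {
        "n_egos": dataset.n_egos,
        "n_ties": dataset.n_ties,
        "group_by": group_by,
        "group_ns": summary.group_ns,
        "position_denominators": comp.position_denominators,
        "undefined_policy": undefined,
        "health_contact_item": health_contact_item,
        "other_is_relative": dataset.codebook.other_is_relative,
        "nomination_cap": dataset.codebook.nomination_cap,
        "rounding": {"mode": "half-up", "digits": rounding_digits},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
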