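"""Descriptive tabulations and assembly of the monthly model dataset.

Covers the study's reporting layer: dyad-category tables of interactions
(with the play / other-affiliation / aggression split) and of silverback
nearest-neighbour associations, per-group descriptives, and the assembly
of the filtered monthly per-individual table exported for mixed-model
fitting (the fit itself is delegated to standard mixed-model software).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from apesoc.obs_data import (
    AGE_CLASSES,
    InteractionEvent,
    Node,
    ScanRecord,
    StudyRegistry,
    ValidationError,
    behavior_class,
    classify_dyad,
    dyad_category_name,
    node_for,
)

__all__ = [
    "DyadCategoryTable",
    "tabulate_interactions",
    "tabulate_nn",
    "group_descriptives",
    "assemble_monthly_records",
    "eligibility_filter",
    "assemble_model_dataset",
    "round_half_up",
]

#: Continuous predictors z-scored for the model export.
CONTINUOUS_PREDICTORS = (
    "age_years",
    "group_size",
    "proportion_immatures",
    "fruit_availability",
    "rainfall_mm",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table presentation style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DyadCategoryTable:
    """Per-(context, category) tabulation with conserved subtotals.

    ``rows`` has one line per dyad category and context; ``subtotals``
    maps context to its record count; ``grand_total`` is the overall
    count.  Percentages are kept unrounded; rounding is presentational.
    """

    rows: pd.DataFrame
    subtotals: dict[str, int]
    grand_total: int

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        df = self.rows.copy()
        for col in df.columns:
            if col.startswith("pct_"):
                df[col] = df[col].map(lambda v: round_half_up(v, ndigits))
        return df


def _category_sort_key(category: str) -> tuple:
    display_order = ["Immature", "Adult Female", "Blackback", "Silverback"]

    def rank(name: str) -> int:
        return display_order.index(name)

    if category.endswith(" dyads"):
        base = category[: -len(" dyads")]
        return (rank(base), rank(base))
    # categories are rendered "A-B" with display names that may contain spaces
    for first in display_order:
        if category.startswith(first + "-"):
            return (rank(first), rank(category[len(first) + 1 :]))
    raise ValueError(f"unrecognised category {category!r}")


def tabulate_interactions(
    events: Sequence[InteractionEvent],
    nodes: Sequence[Node],
    behavior_mapping: Mapping[str, str] | None = None,
) -> DyadCategoryTable:
    """Interaction counts and behaviour-mix percentages per dyad category.

    Every event is classified by the static node classes of its
    participants (routed to the tenure active on the event date) and its
    behaviour class; row percentages are of that row's N.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for ev in events:
        a = node_for(nodes, ev.actor_id, ev.event_date)
        b = node_for(nodes, ev.receiver_id, ev.event_date)
        context, category = classify_dyad(a, b)
        bclass = behavior_class(ev.behavior, behavior_mapping)
        row = counts.setdefault((context, category), {"play": 0, "other_affiliation": 0, "aggression": 0})
        row[bclass] += 1

    records = []
    for (context, category), row in counts.items():
        n = sum(row.values())
        records.append(
            {
                "context": context,
                "category": category,
                "n_interactions": n,
                "pct_play": 100.0 * row["play"] / n,
                "pct_other_affiliation": 100.0 * row["other_affiliation"] / n,
                "pct_aggression": 100.0 * row["aggression"] / n,
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "context",
            "category",
            "n_interactions",
            "pct_play",
            "pct_other_affiliation",
            "pct_aggression",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["context", "category"],
            key=lambda s: s.map(
                (lambda c: {"intragroup": 0, "intergroup": 1}[c])
                if s.name == "context"
                else _category_sort_key
            ),
        ).reset_index(drop=True)
    subtotals = df.groupby("context")["n_interactions"].sum().to_dict() if len(df) else {}
    return DyadCategoryTable(
        rows=df,
        subtotals={k: int(v) for k, v in subtotals.items()},
        grand_total=int(df["n_interactions"].sum()) if len(df) else 0,
    )


def tabulate_nn(scans: Sequence[ScanRecord], nodes: Sequence[Node]) -> DyadCategoryTable:
    """Silverback nearest-neighbour association counts per dyad category.

    Each scan with a recorded nearest neighbour contributes one dyadic
    association (the partner's class paired with Silverback); percentages
    are of the grand total of associations, not per row.
    """
    counts: dict[tuple[str, str], int] = {}
    for scan in scans:
        if scan.nearest_neighbor_id is None:
            continue
        date = scan.scan_datetime.date()
        sb = node_for(nodes, scan.silverback_id, date)
        nn = node_for(nodes, scan.nearest_neighbor_id, date)
        context, category = classify_dyad(sb, nn)
        counts[(context, category)] = counts.get((context, category), 0) + 1

    grand = sum(counts.values())
    records = [
        {
            "context": context,
            "category": category,
            "n_associations": n,
            "pct_of_total": 100.0 * n / grand,
        }
        for (context, category), n in counts.items()
    ]
    df = pd.DataFrame.from_records(
        records, columns=["context", "category", "n_associations", "pct_of_total"]
    )
    if len(df):
        df = df.sort_values(
            ["context", "category"],
            key=lambda s: s.map(
                (lambda c: {"intragroup": 0, "intergroup": 1}[c])
                if s.name == "context"
                else _category_sort_key
            ),
        ).reset_index(drop=True)
    subtotals = df.groupby("context")["n_associations"].sum().to_dict() if len(df) else {}
    return DyadCategoryTable(
        rows=df,
        subtotals={k: int(v) for k, v in subtotals.items()},
        grand_total=grand,
    )


def group_descriptives(
    events: Sequence[InteractionEvent],
    scans: Sequence[ScanRecord],
    nodes: Sequence[Node],
) -> pd.DataFrame:
    """Per-group totals of interactions and nearest-neighbour associations.

    Whether an intergroup record counts toward one group or both is a
    reporting convention, so totals are given under both: ``credit_both``
    (an intergroup record counts once for each group involved) and
    ``intragroup_only`` (intergroup records excluded).  Means and sample
    SDs across groups are appended as summary rows (SD absent with a
    single group).
    """
    groups = sorted({n.group_id for n in nodes})
    inter_tot = {g: {"credit_both": 0, "intragroup_only": 0} for g in groups}
    nn_tot = {g: {"credit_both": 0, "intragroup_only": 0} for g in groups}

    for ev in events:
        a = node_for(nodes, ev.actor_id, ev.event_date)
        b = node_for(nodes, ev.receiver_id, ev.event_date)
        for g in {a.group_id, b.group_id}:
            inter_tot[g]["credit_both"] += 1
        if a.group_id == b.group_id:
            inter_tot[a.group_id]["intragroup_only"] += 1

    for scan in scans:
        if scan.nearest_neighbor_id is None:
            continue
        date = scan.scan_datetime.date()
        sb = node_for(nodes, scan.silverback_id, date)
        nn = node_for(nodes, scan.nearest_neighbor_id, date)
        for g in {sb.group_id, nn.group_id}:
            nn_tot[g]["credit_both"] += 1
        if sb.group_id == nn.group_id:
            nn_tot[sb.group_id]["intragroup_only"] += 1

    rows = [
        {
            "group_id": g,
            "interactions_credit_both": inter_tot[g]["credit_both"],
            "interactions_intragroup_only": inter_tot[g]["intragroup_only"],
            "nn_credit_both": nn_tot[g]["credit_both"],
            "nn_intragroup_only": nn_tot[g]["intragroup_only"],
        }
        for g in groups
    ]
    df = pd.DataFrame(rows)
    summary = {"group_id": "MEAN"}
    sd_row = {"group_id": "SD"}
    for col in df.columns[1:]:
        summary[col] = float(df[col].mean())
        sd_row[col] = float(df[col].std(ddof=1)) if len(df) > 1 else np.nan
    return pd.concat([df, pd.DataFrame([summary, sd_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# monthly model dataset


def assemble_monthly_records(
    scans: Sequence[ScanRecord],
    registry: StudyRegistry,
    nodes: Sequence[Node],
) -> pd.DataFrame:
    """Monthly per-individual scan tallies with demographic covariates.

    For every individual and calendar month: the number of scans in which
    the individual was observed and the number in which its scanned
    activity was social, plus sex, age at the month midpoint, group,
    group size and proportion of immatures among co-residents that month.
    """
    rows: dict[tuple[str, str], dict] = {}
    for scan in scans:
        ym = scan.scan_datetime.strftime("%Y-%m")
        for pid in scan.observed_ids:
            key = (pid, ym)
            rec = rows.setdefault(key, {"n_scans_total": 0, "n_scans_social": 0})
            rec["n_scans_total"] += 1
            if pid in scan.social_ids:
                rec["n_scans_social"] += 1

    by_id = {ind.individual_id: ind for ind in registry.individuals}
    node_class = {}
    out = []
    for (pid, ym), rec in sorted(rows.items()):
        year, month = int(ym[:4]), int(ym[5:])
        mid = dt.date(year, month, 15)
        group = registry.group_at(pid, mid)
        if group is None:
            continue
        residents = [
            i for i in by_id if registry.group_at(i, mid) == group
        ]
        classes = []
        for i in residents:
            try:
                classes.append(node_for(nodes, i, mid).age_class)
            except ValidationError:
                continue
        ind = by_id[pid]
        age = (mid - ind.birth_date).days / 365.25 if ind.birth_date else np.nan
        out.append(
            {
                "individual_id": pid,
                "year_month": ym,
                "n_scans_total": rec["n_scans_total"],
                "n_scans_social": rec["n_scans_social"],
                "sex": ind.sex,
                "age_years": age,
                "group_id": group,
                "group_size": len(residents),
                "proportion_immatures": (
                    classes.count("immature") / len(classes) if classes else np.nan
                ),
            }
        )
    return pd.DataFrame(out)


def eligibility_filter(
    records: pd.DataFrame,
    min_months: int = 5,
    min_scans: int = 20,
    order: str = "months_first",
) -> pd.DataFrame:
    """Inclusion filter for the monthly model dataset.

    Default order: drop individual-months with fewer than ``min_scans``
    total scans, then drop individuals left with fewer than ``min_months``
    months.  ``order='individuals_first'`` applies the individual filter
    on raw months before the month filter.  Idempotent either way.
    """
    df = records.copy()
    if order not in {"months_first", "individuals_first"}:
        raise ValidationError(f"unknown filter order {order!r}")
    if order == "individuals_first":
        keep = df.groupby("individual_id")["year_month"].transform("nunique") >= min_months
        df = df[keep]
        df = df[df["n_scans_total"] >= min_scans]
    else:
        df = df[df["n_scans_total"] >= min_scans]
        keep = df.groupby("individual_id")["year_month"].transform("nunique") >= min_months
        df = df[keep]
    return df.reset_index(drop=True)


def assemble_model_dataset(
    records: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join covariates, z-score continuous predictors, add the log offset.

    Returns the model-ready table plus transform metadata (each
    predictor's mean and SD) sufficient to reconstruct the raw columns
    exactly.  A constant predictor z-scores to all zeros and is flagged.
    Missing covariate months are an error listing the months.
    """
    df = records.merge(covariates, on=["year_month", "group_id"], how="left")
    missing = df.loc[df["fruit_availability"].isna(), "year_month"].unique().tolist()
    if missing:
        raise ValidationError(f"covariates missing for months: {sorted(missing)}")
    metadata: dict[str, dict] = {}
    for col in CONTINUOUS_PREDICTORS:
        mean = float(df[col].mean())
        # population SD: the transformed column has SD exactly 1
        sd = float(df[col].std(ddof=0))
        metadata[col] = {"mean": mean, "sd": sd, "constant": bool(sd == 0.0)}
        df[f"z_{col}"] = 0.0 if sd == 0.0 else (df[col] - mean) / sd
    df["offset_log_scans"] = np.log(df["n_scans_total"].astype(float))
    return df, metadata
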