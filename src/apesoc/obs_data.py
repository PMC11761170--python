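"""Observational data model: registry, events, scans, nodes and dyads.

The study design is a multi-group primate field study: a registry of
individually identified animals with group-membership intervals and maternal
pedigree, an all-occurrence stream of dyadic social interactions, and an
instantaneous group-scan stream recording the silverback's nearest
neighbour together with every individual visible in the scan.

Networks are static over the study window, so each individual is
represented by one node per *group tenure*: an animal that transfers
between groups contributes one node per group it resided in, each with its
own age-sex class computed from the average age during that tenure.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "AgeThresholds",
    "IndividualRecord",
    "GroupMembership",
    "InteractionEvent",
    "ScanRecord",
    "Node",
    "StudyRegistry",
    "BEHAVIOR_VOCABULARY",
    "DEFAULT_BEHAVIOR_CLASSES",
    "AGE_CLASSES",
    "load_registry",
    "load_interactions",
    "load_scans",
    "load_covariates",
    "assign_age_class",
    "derive_node_set",
    "classify_dyad",
    "dyad_category_name",
    "behavior_class",
    "node_for",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data model; names the row."""


#: Closed vocabulary of recordable social behaviours.
BEHAVIOR_VOCABULARY = frozenset(
    {
        "play",
        "groom",
        "aggression",
        "submission",
        "reproductive",
        "food_share",
        "beg",
        "nurse",
        "approach",
        "follow",
    }
)

#: Default collapse of the behaviour vocabulary into reporting classes.
DEFAULT_BEHAVIOR_CLASSES: Mapping[str, str] = {
    "play": "play",
    "aggression": "aggression",
    "submission": "aggression",
    "groom": "other_affiliation",
    "reproductive": "other_affiliation",
    "food_share": "other_affiliation",
    "beg": "other_affiliation",
    "nurse": "other_affiliation",
    "approach": "other_affiliation",
    "follow": "other_affiliation",
}

#: Age-sex classes in canonical (naming) order.
AGE_CLASSES = ("immature", "adult_female", "blackback", "silverback")

_DISPLAY = {
    "immature": "Immature",
    "adult_female": "Adult Female",
    "blackback": "Blackback",
    "silverback": "Silverback",
}


@dataclass(frozen=True)
class AgeThresholds:
    """Age-class boundaries in years.

    Females are adult above ``female_adult``; males are immature below
    ``male_blackback``, blackback from there on, and silverback only when
    the registry flags the date the male was recognised as one — silverback
    status is observational, not an age cut-off.
    """

    female_adult: float = 10.0
    male_blackback: float = 8.0
    male_adult: float = 11.0


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    name: str
    sex: str  # female | male | unknown
    birth_date: dt.date | None
    mother_id: str | None = None
    silverback_from: dt.date | None = None
    age_class_override: str | None = None


@dataclass(frozen=True)
class GroupMembership:
    individual_id: str
    group_id: str
    start_date: dt.date
    end_date: dt.date | None  # open interval when None; [start, end)


@dataclass(frozen=True)
class InteractionEvent:
    event_date: dt.date
    group_context: str
    actor_id: str
    receiver_id: str
    behavior: str


@dataclass(frozen=True)
class ScanRecord:
    scan_id: str
    scan_datetime: dt.datetime
    group_id: str
    silverback_id: str
    nearest_neighbor_id: str | None
    observed_ids: frozenset[str]
    social_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Node:
    """One analysis node: an individual within one group tenure."""

    node_id: str
    individual_id: str
    group_id: str
    age_class: str
    sex: str
    tenure_start: dt.date = dt.date.min
    tenure_end: dt.date = dt.date.max  # closed-open


@dataclass
class StudyRegistry:
    individuals: list[IndividualRecord]
    memberships: list[GroupMembership]
    study_window: tuple[dt.date, dt.date]
    _by_id: dict[str, IndividualRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {ind.individual_id: ind for ind in self.individuals}

    def individual(self, individual_id: str) -> IndividualRecord:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise ValidationError(f"unknown individual_id {individual_id!r}") from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def memberships_of(self, individual_id: str) -> list[GroupMembership]:
        return sorted(
            (m for m in self.memberships if m.individual_id == individual_id),
            key=lambda m: m.start_date,
        )

    def group_at(self, individual_id: str, date: dt.date) -> str | None:
        for m in self.memberships_of(individual_id):
            end = m.end_date or dt.date.max
            if m.start_date <= date < end:
                return m.group_id
        return None

    @property
    def group_ids(self) -> list[str]:
        return sorted({m.group_id for m in self.memberships})


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_date(value, *, where: str) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return pd.Timestamp(value).date()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{where}: unparseable date {value!r}") from exc


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def load_registry(
    individuals_path: str | Path,
    memberships_path: str | Path,
    window: tuple[dt.date, dt.date],
) -> StudyRegistry:
    """Read and cross-validate the individual registry and membership table.

    Raises :class:`ValidationError` naming the offending row for duplicate
    ids, dangling maternal references, silverback dates on non-males,
    overlapping membership intervals, or individuals without membership.
    """
    ind_df = pd.read_csv(individuals_path, dtype=str)
    mem_df = pd.read_csv(memberships_path, dtype=str)

    individuals: list[IndividualRecord] = []
    seen: set[str] = set()
    for row in ind_df.itertuples(index=False):
        iid = str(row.individual_id)
        if iid in seen:
            raise ValidationError(f"individuals: duplicate individual_id {iid!r}")
        seen.add(iid)
        sex = str(row.sex)
        if sex not in {"female", "male", "unknown"}:
            raise ValidationError(f"individuals row {iid!r}: bad sex {sex!r}")
        sb_from = _parse_date(getattr(row, "silverback_from", None), where=f"individuals row {iid!r}")
        if sb_from is not None and sex != "male":
            raise ValidationError(f"individuals row {iid!r}: silverback_from on non-male")
        override = _opt(getattr(row, "age_class_override", None))
        if override is not None and override not in AGE_CLASSES:
            raise ValidationError(f"individuals row {iid!r}: bad age_class_override {override!r}")
        individuals.append(
            IndividualRecord(
                individual_id=iid,
                name=_opt(getattr(row, "name", None)) or iid,
                sex=sex,
                birth_date=_parse_date(row.birth_date, where=f"individuals row {iid!r}"),
                mother_id=_opt(getattr(row, "mother_id", None)),
                silverback_from=sb_from,
                age_class_override=override,
            )
        )
    by_id = {i.individual_id: i for i in individuals}
    for ind in individuals:
        if ind.mother_id is not None:
            mother = by_id.get(ind.mother_id)
            if mother is None:
                raise ValidationError(
                    f"individuals row {ind.individual_id!r}: mother_id {ind.mother_id!r} not in registry"
                )
            if mother.sex == "male":
                raise ValidationError(
                    f"individuals row {ind.individual_id!r}: mother_id {ind.mother_id!r} is male"
                )

    memberships: list[GroupMembership] = []
    for i, row in enumerate(mem_df.itertuples(index=False)):
        iid = str(row.individual_id)
        if iid not in by_id:
            raise ValidationError(f"memberships row {i}: unknown individual_id {iid!r}")
        start = _parse_date(row.start_date, where=f"memberships row {i}")
        if start is None:
            raise ValidationError(f"memberships row {i} ({iid!r}): missing start_date")
        memberships.append(
            GroupMembership(
                individual_id=iid,
                group_id=str(row.group_id),
                start_date=start,
                end_date=_parse_date(row.end_date, where=f"memberships row {i}"),
            )
        )
    for iid in by_id:
        ivals = sorted(
            ((m.start_date, m.end_date or dt.date.max) for m in memberships if m.individual_id == iid)
        )
        if not ivals:
            raise ValidationError(f"individual {iid!r} has no membership interval")
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValidationError(f"individual {iid!r}: overlapping membership intervals")

    if window[0] >= window[1]:
        raise ValidationError("study window is empty")
    return StudyRegistry(individuals=individuals, memberships=memberships, study_window=window)


def load_interactions(path: str | Path, registry: StudyRegistry) -> list[InteractionEvent]:
    """Read and validate the all-occurrence interaction event table."""
    df = pd.read_csv(path, dtype=str)
    start, end = registry.study_window
    events: list[InteractionEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        date = _parse_date(row.event_date, where=f"interactions row {i}")
        if date is None or not (start <= date < end):
            raise ValidationError(f"interactions row {i}: date {row.event_date!r} outside study window")
        actor, receiver = str(row.actor_id), str(row.receiver_id)
        if actor == receiver:
            raise ValidationError(f"interactions row {i}: actor equals receiver ({actor!r})")
        for pid in (actor, receiver):
            if pid not in registry:
                raise ValidationError(f"interactions row {i}: unknown participant {pid!r}")
            if registry.group_at(pid, date) is None:
                raise ValidationError(
                    f"interactions row {i}: {pid!r} has no group membership on {date}"
                )
        behavior = str(row.behavior)
        if behavior not in BEHAVIOR_VOCABULARY:
            raise ValidationError(f"interactions row {i}: unknown behavior {behavior!r}")
        events.append(
            InteractionEvent(
                event_date=date,
                group_context=str(row.group_context),
                actor_id=actor,
                receiver_id=receiver,
                behavior=behavior,
            )
        )
    return events


def _split_ids(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(s for s in str(cell).split(";") if s)


def load_scans(path: str | Path, registry: StudyRegistry) -> list[ScanRecord]:
    """Read and validate the instantaneous group-scan table.

    Enforces: the silverback and the nearest neighbour (when recorded) are
    among the observed individuals, the nearest neighbour is not the
    silverback itself, and every id resolves in the registry.
    """
    df = pd.read_csv(path, dtype=str)
    start, end = registry.study_window
    scans: list[ScanRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        sid = str(row.scan_id)
        if sid in seen_ids:
            raise ValidationError(f"scans row {i}: duplicate scan_id {sid!r}")
        seen_ids.add(sid)
        try:
            when = pd.Timestamp(row.scan_datetime).to_pydatetime()
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"scans row {i}: unparseable datetime {row.scan_datetime!r}") from exc
        if not (start <= when.date() < end):
            raise ValidationError(f"scans row {i}: datetime outside study window")
        observed = _split_ids(row.observed_ids)
        social = _split_ids(getattr(row, "scan_social_ids", None))
        sb = str(row.silverback_id)
        nn = _opt(row.nearest_neighbor_id)
        for pid in observed | {sb} | ({nn} if nn else set()):
            if pid not in registry:
                raise ValidationError(f"scans row {i}: unknown individual {pid!r}")
        if nn is not None:
            if sb not in observed:
                raise ValidationError(f"scans row {i}: silverback {sb!r} not in observed_ids")
            if nn == sb:
                raise ValidationError(f"scans row {i}: nearest neighbor equals silverback {sb!r}")
            if nn not in observed:
                raise ValidationError(f"scans row {i}: nearest neighbor {nn!r} not in observed_ids")
        if not social <= observed:
            raise ValidationError(f"scans row {i}: scan_social_ids not a subset of observed_ids")
        scans.append(
            ScanRecord(
                scan_id=sid,
                scan_datetime=when,
                group_id=str(row.group_id),
                silverback_id=sb,
                nearest_neighbor_id=nn,
                observed_ids=observed,
                social_ids=social,
            )
        )
    return scans


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Read the monthly covariate table (fruit availability, rainfall)."""
    df = pd.read_csv(path, dtype={"year_month": str, "group_id": str})
    required = {"year_month", "group_id", "fruit_availability", "rainfall_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"covariates: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# age classes, nodes, dyads


def _midpoint(start: dt.date, end: dt.date) -> dt.date:
    return start + (end - start) / 2


def _age_years(birth: dt.date, on: dt.date) -> float:
    return (on - birth).days / 365.25


def assign_age_class(
    individual: IndividualRecord,
    window: tuple[dt.date, dt.date],
    thresholds: AgeThresholds = AgeThresholds(),
) -> str:
    """Age-sex class from the average age over ``window``.

    The average age over a residence window equals the age at its midpoint,
    so individuals observed across two age bands are classed by where their
    mean age falls.  A male is silverback only if his recorded
    silverback-recognition date precedes the window midpoint; an explicit
    registry override always wins.
    """
    if individual.age_class_override is not None:
        return individual.age_class_override
    if individual.birth_date is None:
        raise ValidationError(
            f"{individual.individual_id!r}: missing birth_date and no age_class_override"
        )
    mid = _midpoint(*window)
    age = _age_years(individual.birth_date, mid)
    if individual.sex == "male":
        if individual.silverback_from is not None and individual.silverback_from <= mid:
            return "silverback"
        return "immature" if age < thresholds.male_blackback else "blackback"
    if individual.sex == "female":
        return "immature" if age < thresholds.female_adult else "adult_female"
    # unknown sex: only the immature class is sex-neutral
    if age < thresholds.female_adult:
        return "immature"
    raise ValidationError(
        f"{individual.individual_id!r}: adult with unknown sex needs age_class_override"
    )


def _tenures(registry: StudyRegistry, individual_id: str) -> list[tuple[str, dt.date, dt.date]]:
    """Merge consecutive same-group membership intervals into group tenures."""
    out: list[tuple[str, dt.date, dt.date]] = []
    for m in registry.memberships_of(individual_id):
        end = m.end_date or registry.study_window[1]
        if out and out[-1][0] == m.group_id:
            out[-1] = (m.group_id, out[-1][1], end)
        else:
            out.append((m.group_id, m.start_date, end))
    return out


def derive_node_set(
    registry: StudyRegistry, thresholds: AgeThresholds = AgeThresholds()
) -> list[Node]:
    """One node per individual per group tenure.

    Transfer individuals get one node per tenure; the second and later
    tenures carry a numeric suffix on the node id (id, id2, id3, ...), and
    each tenure is age-classed independently over its overlap with the
    study window — so a female who dispersed at adulthood appears as an
    immature in her natal group and an adult female in the group she
    joined.  Deterministic and idempotent; node count equals individuals
    plus between-group transfers.
    """
    w0, w1 = registry.study_window
    nodes: list[Node] = []
    for ind in registry.individuals:
        tenures = _tenures(registry, ind.individual_id)
        for k, (group_id, start, end) in enumerate(tenures):
            o0, o1 = max(start, w0), min(end, w1)
            if o0 >= o1:
                o0, o1 = start, end  # tenure outside the window: class on the tenure itself
            node_id = ind.individual_id if k == 0 else f"{ind.individual_id}{k + 1}"
            nodes.append(
                Node(
                    node_id=node_id,
                    individual_id=ind.individual_id,
                    group_id=group_id,
                    age_class=assign_age_class(ind, (o0, o1), thresholds),
                    sex=ind.sex,
                    tenure_start=start,
                    tenure_end=end,
                )
            )
    return nodes


def node_for(nodes: Sequence[Node], individual_id: str, date: dt.date) -> Node:
    """Route a dated record to the tenure node active on that date."""
    candidates = [n for n in nodes if n.individual_id == individual_id]
    if not candidates:
        raise ValidationError(f"no node for individual {individual_id!r}")
    if len(candidates) == 1:
        return candidates[0]
    for n in candidates:
        if n.tenure_start <= date < n.tenure_end:
            return n
    raise ValidationError(f"no tenure of {individual_id!r} active on {date}")


def dyad_category_name(class_a: str, class_b: str) -> str:
    """Canonical dyad-category label, e.g. 'Immature-Blackback' or 'Silverback dyads'."""
    order = {c: i for i, c in enumerate(AGE_CLASSES)}
    a, b = sorted((class_a, class_b), key=order.__getitem__)
    if a == b:
        return f"{_DISPLAY[a]} dyads"
    return f"{_DISPLAY[a]}-{_DISPLAY[b]}"


def classify_dyad(node_a: Node, node_b: Node) -> tuple[str, str]:
    """(context, category) of a dyad: intragroup iff the tenures share a group.

    Symmetric in its arguments; identical nodes are an error.
    """
    if node_a.node_id == node_b.node_id:
        raise ValidationError(f"dyad of a node with itself: {node_a.node_id!r}")
    context = "intragroup" if node_a.group_id == node_b.group_id else "intergroup"
    return context, dyad_category_name(node_a.age_class, node_b.age_class)


def behavior_class(behavior: str, mapping: Mapping[str, str] | None = None) -> str:
    """Collapse a vocabulary term to play / other_affiliation / aggression."""
    mapping = DEFAULT_BEHAVIOR_CLASSES if mapping is None else mapping
    try:
        return mapping[behavior]
    except KeyError:
        raise ValidationError(f"unknown behavior term {behavior!r}") from None


def validate_dataset(
    data_dir: str | Path, window: tuple[dt.date, dt.date] | None = None
) -> tuple[StudyRegistry, list[InteractionEvent], list[ScanRecord], pd.DataFrame]:
    """Load and validate a full data directory (the five-CSV layout)."""
    data_dir = Path(data_dir)
    if window is None:
        window = infer_window(data_dir)
    registry = load_registry(data_dir / "individuals.csv", data_dir / "memberships.csv", window)
    events = load_interactions(data_dir / "interactions.csv", registry)
    scans = load_scans(data_dir / "scans.csv", registry)
    cov_path = data_dir / "covariates.csv"
    covariates = load_covariates(cov_path) if cov_path.exists() else pd.DataFrame()
    return registry, events, scans, covariates


def infer_window(data_dir: str | Path) -> tuple[dt.date, dt.date]:
    """Study window from a window.csv sidecar, else the membership span."""
    data_dir = Path(data_dir)
    sidecar = data_dir / "window.csv"
    if sidecar.exists():
        df = pd.read_csv(sidecar, dtype=str)
        return (
            pd.Timestamp(df["start_date"].iloc[0]).date(),
            pd.Timestamp(df["end_date"].iloc[0]).date(),
        )
    mem = pd.read_csv(data_dir / "memberships.csv", dtype=str)
    starts = pd.to_datetime(mem["start_date"])
    ends = pd.to_datetime(mem["end_date"].dropna()) if mem["end_date"].notna().any() else starts
    return (starts.min().date(), (ends.max() + pd.Timedelta(days=1)).date())
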