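"""Network construction: counts, simple-ratio associations, binary, expected.

Four matrices over the same node set drive the analysis:

* the interaction-count matrix — bidirectional totals of all-occurrence
  dyadic interactions;
* the silverback nearest-neighbour association matrix — simple ratio
  index (SRI) per dyad, with tiny between-group associations floored to
  0.001 so that rare intergroup ties are not lost to rounding;
* the binarized observed network — an edge wherever a dyad interacted
  more than once;
* the expected network — a prior-knowledge null with edges between every
  group member and the group's silverback(s), mother-offspring pairs, and
  maternal siblings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from apesoc.obs_data import (
    InteractionEvent,
    Node,
    ScanRecord,
    StudyRegistry,
    ValidationError,
    node_for,
)

__all__ = [
    "SocialMatrix",
    "SriComponents",
    "sri",
    "build_interaction_matrix",
    "build_nn_association_matrix",
    "binarize",
    "build_expected_network",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_edge_list",
    "write_nodes_csv",
    "read_nodes_csv",
]

logger = logging.getLogger(__name__)

#: Intergroup associations at or below this are floored (to FLOOR_VALUE).
FLOOR_THRESHOLD = 0.0009
FLOOR_VALUE = 0.001


@dataclass
class SocialMatrix:
    """Square symmetric matrix over an ordered node set.

    ``flavor`` is one of ``count`` (non-negative integers), ``sri``
    (values in [0, 1]) or ``binary`` ({0, 1}); the diagonal is zero.
    """

    nodes: list[Node]
    values: np.ndarray
    flavor: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValidationError("matrix diagonal is not zero")
        if self.flavor == "count":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValidationError("count matrix must hold non-negative integers")
        elif self.flavor == "sri":
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValidationError("sri matrix values must lie in [0, 1]")
        elif self.flavor == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValidationError("binary matrix values must be 0 or 1")
        else:
            raise ValidationError(f"unknown matrix flavor {self.flavor!r}")

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def copy(self) -> "SocialMatrix":
        return SocialMatrix(list(self.nodes), self.values.copy(), self.flavor)

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.node_ids
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class SriComponents:
    """Scan tallies for one dyad.

    ``n_together``: scans where the dyad was the recorded
    silverback-nearest-neighbour pair; ``n_only_a``/``n_only_b``: scans
    where exactly one member was observed; ``n_both_apart``: scans where
    both were observed but not as the pair.
    """

    n_together: int
    n_only_a: int
    n_only_b: int
    n_both_apart: int

    def __post_init__(self) -> None:
        if min(self.n_together, self.n_only_a, self.n_only_b, self.n_both_apart) < 0:
            raise ValidationError("SRI components must be non-negative")


def sri(components: SriComponents) -> float:
    """Simple ratio association index: together / (together + apart).

    A never-observed dyad (zero denominator) returns 0 with a warning
    rather than NaN.
    """
    c = components
    denom = c.n_together + c.n_only_a + c.n_only_b + c.n_both_apart
    if denom == 0:
        logger.warning("SRI of a never-observed dyad requested; returning 0")
        return 0.0
    return c.n_together / denom


def _node_index(nodes: Sequence[Node]) -> dict[str, int]:
    idx = {n.node_id: i for i, n in enumerate(nodes)}
    if len(idx) != len(nodes):
        raise ValidationError("duplicate node_ids in node set")
    return idx


def build_interaction_matrix(
    events: Sequence[InteractionEvent], nodes: Sequence[Node]
) -> SocialMatrix:
    """Bidirectional total interaction counts per dyad.

    Direction is discarded: A→B and B→A both increment the same cell.
    Records of transfer individuals are routed to the tenure node active
    on the event date.  The upper-triangle sum equals the event count.
    """
    idx = _node_index(nodes)
    m = np.zeros((len(nodes), len(nodes)))
    for ev in events:
        i = idx[node_for(nodes, ev.actor_id, ev.event_date).node_id]
        j = idx[node_for(nodes, ev.receiver_id, ev.event_date).node_id]
        if i == j:
            raise ValidationError(
                f"event on {ev.event_date} maps both participants to node "
                f"{nodes[i].node_id!r}"
            )
        m[i, j] += 1
        m[j, i] += 1
    return SocialMatrix(list(nodes), m, "count")


def nn_components(
    scans: Sequence[ScanRecord], nodes: Sequence[Node]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dyad scan tallies: together counts, observation counts, co-observation.

    Returns (together[n,n], observed[n], co_observed[n,n]) over the node
    order.  A scan contributes one "together" to its recorded
    silverback-nearest-neighbour pair and one observation to every node in
    its observed set (scans with no recorded neighbour still contribute
    observations).
    """
    idx = _node_index(nodes)
    n = len(nodes)
    together = np.zeros((n, n))
    obs_rows = np.zeros((len(scans), n), dtype=bool)
    for r, scan in enumerate(scans):
        date = scan.scan_datetime.date()
        for pid in scan.observed_ids:
            obs_rows[r, idx[node_for(nodes, pid, date).node_id]] = True
        if scan.nearest_neighbor_id is not None:
            i = idx[node_for(nodes, scan.silverback_id, date).node_id]
            j = idx[node_for(nodes, scan.nearest_neighbor_id, date).node_id]
            together[i, j] += 1
            together[j, i] += 1
    co = (obs_rows.astype(np.float64).T @ obs_rows.astype(np.float64))
    observed = np.diagonal(co).copy()
    return together, observed, co


def build_nn_association_matrix(
    scans: Sequence[ScanRecord],
    nodes: Sequence[Node],
    floor: float = FLOOR_VALUE,
    floor_threshold: float = FLOOR_THRESHOLD,
) -> SocialMatrix:
    """Silverback nearest-neighbour SRI matrix with intergroup flooring.

    The sampling design is anchored on silverbacks: only dyads with at
    least one silverback member have sampling occasions, so all other
    dyads are fixed at 0.  For a sampled dyad the SRI denominator is the
    number of scans in which either member was observed.  Intergroup
    dyads with a positive SRI at or below ``floor_threshold`` are raised
    to ``floor`` so that rare between-group associations survive
    rounding; intragroup cells are never floored.
    """
    together, observed, co = nn_components(scans, nodes)
    n = len(nodes)
    denom = observed[:, None] + observed[None, :] - co
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, together / np.where(denom > 0, denom, 1.0), 0.0)

    is_sb = np.array([nd.age_class == "silverback" for nd in nodes])
    has_sb = is_sb[:, None] | is_sb[None, :]
    values = np.where(has_sb, values, 0.0)

    groups = np.array([nd.group_id for nd in nodes])
    intergroup = groups[:, None] != groups[None, :]
    tiny = (values > 0) & (values <= floor_threshold + 1e-15) & intergroup
    values = np.where(tiny, floor, values)

    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2  # numerically symmetric
    return SocialMatrix(list(nodes), values, "sri")


def binarize(observed: SocialMatrix, threshold_exclusive: int = 1) -> SocialMatrix:
    """Edge wherever the dyad count strictly exceeds the threshold.

    With the default threshold of 1, a pair must interact more than once
    over the study to earn an edge.  Idempotent on binary input only when
    the threshold is 0, so the flavor is checked.
    """
    if observed.flavor != "count":
        raise ValidationError(f"binarize expects a count matrix, got {observed.flavor!r}")
    values = (observed.values > threshold_exclusive).astype(float)
    return SocialMatrix(list(observed.nodes), values, "binary")


def build_expected_network(nodes: Sequence[Node], registry: StudyRegistry) -> SocialMatrix:
    """Rule-built expected network used as the comparison null.

    Within each group: every member is linked to the group's
    silverback(s) (all of them, in a multi-male group), every mother to
    her co-resident offspring, and maternal siblings to each other.
    Rules are within-group only, so the expected network has no
    intergroup edges; a dispersed female's second-tenure node is linked
    only through her new group's silverback.
    """
    n = len(nodes)
    m = np.zeros((n, n))
    mother_of = {
        ind.individual_id: ind.mother_id
        for ind in registry.individuals
        if ind.mother_id is not None
    }
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            if a.group_id != b.group_id:
                continue
            edge = (
                a.age_class == "silverback"
                or b.age_class == "silverback"
                or mother_of.get(a.individual_id) == b.individual_id
                or mother_of.get(b.individual_id) == a.individual_id
                or (
                    a.individual_id in mother_of
                    and b.individual_id in mother_of
                    and mother_of[a.individual_id] == mother_of[b.individual_id]
                )
            )
            if edge:
                m[i, j] = m[j, i] = 1.0
    return SocialMatrix(list(nodes), m, "binary")


# ---------------------------------------------------------------------------
# serialization


def write_matrix_csv(m: SocialMatrix, path: str | Path) -> None:
    """Labelled CSV: first row/column are node ids; SRI at 12 significant digits."""
    df = m.to_dataframe()
    fmt = "%.12g" if m.flavor == "sri" else "%g"
    df.to_csv(path, float_format=fmt, index_label="node_id")


def read_matrix_csv(
    path: str | Path, flavor: str, nodes: Sequence[Node] | None = None
) -> SocialMatrix:
    """Read a labelled matrix CSV back; exact for counts and binary.

    Without an explicit node set, stub nodes carrying only ids are built
    (sufficient for density comparisons; knockouts need real nodes).
    """
    df = pd.read_csv(path, index_col=0)
    if nodes is None:
        nodes = [
            Node(node_id=str(c), individual_id=str(c), group_id="", age_class="immature", sex="unknown")
            for c in df.columns
        ]
    else:
        ids = [n.node_id for n in nodes]
        df = df.loc[ids, ids]
    return SocialMatrix(list(nodes), df.to_numpy(dtype=float), flavor)


def write_edge_list(m: SocialMatrix, path: str | Path, include_zeros: bool = False) -> None:
    ids = m.node_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = m.values[i, j]
            if v != 0 or include_zeros:
                rows.append((ids[i], ids[j], v))
    pd.DataFrame(rows, columns=["node_a", "node_b", "value"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_nodes_csv(nodes: Sequence[Node], path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_id": [n.node_id for n in nodes],
            "individual_id": [n.individual_id for n in nodes],
            "group_id": [n.group_id for n in nodes],
            "age_class": [n.age_class for n in nodes],
            "sex": [n.sex for n in nodes],
            "tenure_start": [n.tenure_start.isoformat() for n in nodes],
            "tenure_end": [n.tenure_end.isoformat() for n in nodes],
        }
    ).to_csv(path, index=False)


def read_nodes_csv(path: str | Path) -> list[Node]:
    import datetime as dt

    df = pd.read_csv(path, dtype=str)
    return [
        Node(
            node_id=r.node_id,
            individual_id=r.individual_id,
            group_id=r.group_id,
            age_class=r.age_class,
            sex=r.sex,
            tenure_start=dt.date.fromisoformat(r.tenure_start),
            tenure_end=dt.date.fromisoformat(r.tenure_end),
        )
        for r in df.itertuples(index=False)
    ]
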