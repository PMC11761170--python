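"""Seeded generator of synthetic multi-group ape observational studies.

Emulates the sampling design of a long-term multi-group field study: four
neighbouring groups of 5–17 gorillas (1–2 silverbacks, 2–5 blackbacks,
1–8 adult females, 1–3 immatures), an interaction stream dominated by
play involving immatures with rare aggression and rare intergroup events,
a silverback nearest-neighbour scan stream whose partner-class shares
approximate the field proportions (immatures ~48%, adult females ~31%,
blackbacks ~20%), one between-group female transfer, and sinusoidal
monthly covariates.  Every draw flows from a single seed, output is
byte-stable, and an exact :class:`GroundTruth` accompanies each dataset
so pipeline tabulations can be checked record-for-record, not just
statistically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from apesoc.obs_data import AGE_CLASSES, ValidationError

__all__ = ["SimConfig", "GroundTruth", "generate_study", "plant_removal_effect", "fixture_small"]

_CLASS_RANK = {c: i for i, c in enumerate(AGE_CLASSES)}


def rate_key(class_a: str, class_b: str) -> str:
    """Canonical dyad-class key for rate tables, e.g. 'immature:blackback'."""
    a, b = sorted((class_a, class_b), key=_CLASS_RANK.__getitem__)
    return f"{a}:{b}"


def _default_intragroup_rates() -> dict[str, float]:
    # expected events per dyad per month; tuned so the default study's
    # category totals approximate the field frequencies
    return {
        "immature:immature": 6.3,
        "immature:adult_female": 0.063,
        "immature:blackback": 0.64,
        "immature:silverback": 0.043,
        "adult_female:adult_female": 0.0035,
        "adult_female:blackback": 0.0093,
        "adult_female:silverback": 0.027,
        "blackback:blackback": 0.21,
        "blackback:silverback": 0.004,
        "silverback:silverback": 0.026,
    }


def _default_intergroup_rates() -> dict[str, float]:
    return {
        "immature:immature": 0.011,
        "immature:adult_female": 0.001,
        "immature:blackback": 0.0076,
        "immature:silverback": 0.0,
        "adult_female:adult_female": 0.0,
        "adult_female:blackback": 0.00055,
        "adult_female:silverback": 0.0,
        "blackback:blackback": 0.0041,
        "blackback:silverback": 0.00017,
        "silverback:silverback": 0.0015,
    }


def _default_behavior_mix() -> dict[str, dict[str, tuple[float, float, float]]]:
    # (play, other_affiliation, aggression) probabilities per dyad class pair
    intra = {
        "immature:immature": (0.99, 0.01, 0.0),
        "immature:adult_female": (0.64, 0.34, 0.02),
        "immature:blackback": (0.99, 0.01, 0.0),
        "immature:silverback": (0.51, 0.39, 0.10),
        "adult_female:adult_female": (0.36, 0.28, 0.36),
        "adult_female:blackback": (0.70, 0.21, 0.09),
        "adult_female:silverback": (0.0, 0.90, 0.10),
        "blackback:blackback": (0.97, 0.02, 0.01),
        "blackback:silverback": (0.25, 0.375, 0.375),
        "silverback:silverback": (0.20, 0.20, 0.60),
    }
    inter = {
        "immature:immature": (1.0, 0.0, 0.0),
        "immature:adult_female": (0.5, 0.4, 0.1),
        "immature:blackback": (0.97, 0.02, 0.01),
        "immature:silverback": (1.0, 0.0, 0.0),
        "adult_female:adult_female": (1.0, 0.0, 0.0),
        "adult_female:blackback": (0.6, 0.2, 0.2),
        "adult_female:silverback": (1.0, 0.0, 0.0),
        "blackback:blackback": (0.97, 0.0, 0.03),
        "blackback:silverback": (0.0, 0.0, 1.0),
        "silverback:silverback": (0.0, 0.0, 1.0),
    }
    return {"intragroup": intra, "intergroup": inter}


#: concrete vocabulary terms drawn within each behaviour class
_TERMS = {
    "play": (("play",), (1.0,)),
    "aggression": (("aggression", "submission"), (0.5, 0.5)),
    "other_affiliation": (
        ("groom", "approach", "follow", "beg", "nurse", "food_share", "reproductive"),
        (0.40, 0.25, 0.15, 0.08, 0.05, 0.04, 0.03),
    ),
}


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults reproduce the field study's scale and mix: 4 groups over 96
    months, ~140 nearest-neighbour scan records per group-month (matching
    the association volume, not the number of scan sessions), dyadic
    interaction rates per class pair tuned to the observed category
    frequencies, and nearest-neighbour class propensities of 0.48 / 0.31 /
    0.20 / 0.01 for immatures / adult females / blackbacks / others.
    """

    seed: int = 0
    n_groups: int = 4
    months: int = 96
    start: dt.date = dt.date(2014, 1, 1)
    scans_per_month: int = 140
    composition: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "silverback": (1, 2),
            "blackback": (2, 5),
            "adult_female": (1, 8),
            "immature": (1, 3),
        }
    )
    group_size_range: tuple[int, int] = (5, 17)
    intragroup_rates: Mapping[str, float] = field(default_factory=_default_intragroup_rates)
    intergroup_rates: Mapping[str, float] = field(default_factory=_default_intergroup_rates)
    behavior_mix: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=_default_behavior_mix
    )
    nn_propensity: Mapping[str, float] = field(
        default_factory=lambda: {
            "immature": 0.48,
            "adult_female": 0.31,
            "blackback": 0.20,
            "silverback": 0.01,
        }
    )
    intergroup_nn_rate: float = 0.002
    observation_prob: float = 0.9
    social_scan_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "immature": 0.30,
            "blackback": 0.15,
            "adult_female": 0.06,
            "silverback": 0.05,
        }
    )
    n_transfers: int = 1
    overdispersion: float | None = None  # negative-binomial shape; None = Poisson
    fruit_mean: float = 0.36
    fruit_amplitude: float = 0.11
    rainfall_log_mean: float = 4.6
    rainfall_log_amplitude: float = 0.8
    rainfall_log_sd: float = 0.4

    def validate(self) -> None:
        if self.n_groups < 1 or self.months < 1:
            raise ValidationError("need at least one group and one month")
        if self.composition["silverback"][0] < 1:
            raise ValidationError("every group needs at least one silverback")
        for mix_ctx in self.behavior_mix.values():
            for key, mix in mix_ctx.items():
                if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                    raise ValidationError(f"behavior mix for {key!r} must sum to 1")
        for rates in (self.intragroup_rates, self.intergroup_rates):
            if any(r < 0 for r in rates.values()):
                raise ValidationError("interaction rates must be non-negative")
        if not all(0 <= p <= 1 for p in self.nn_propensity.values()):
            raise ValidationError("nn propensities must lie in [0, 1]")
        if self.n_transfers == 1 and self.n_groups < 2:
            raise ValidationError("a transfer needs at least two groups")
        if self.n_transfers not in (0, 1):
            raise ValidationError("only 0 or 1 scripted transfers supported")


@dataclass
class GroundTruth:
    """Exact record-level truth accompanying a generated dataset."""

    event_counts: dict  # "context|category" -> {behavior_class: n}
    dyad_counts: dict  # "node_a|node_b" -> n (canonical node order)
    nn_counts: dict  # "context|category" -> n
    nn_assignments: dict  # scan_id -> nearest-neighbour node_id
    nn_propensity: dict
    expected_edges: list  # [node_a, node_b] canonical order
    n_individuals: int
    n_nodes: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# helpers


def _month_start(start: dt.date, m: int) -> dt.date:
    total = start.month - 1 + m
    return dt.date(start.year + total // 12, total % 12 + 1, 1)


@dataclass(frozen=True)
class _SimNode:
    node_id: str
    individual_id: str
    group: int
    age_class: str
    sex: str
    start_month: int
    end_month: int  # exclusive

    def active(self, m: int) -> bool:
        return self.start_month <= m < self.end_month


def _draw_composition(cfg: SimConfig, rng: np.random.Generator) -> list[dict[str, int]]:
    comps = []
    for _ in range(cfg.n_groups):
        for _try in range(1000):
            comp = {
                c: int(rng.integers(lo, hi + 1)) for c, (lo, hi) in cfg.composition.items()
            }
            if cfg.group_size_range[0] <= sum(comp.values()) <= cfg.group_size_range[1]:
                comps.append(comp)
                break
        else:
            raise ValidationError("infeasible composition ranges")
    return comps


def _birth_for(age_class: str, sex: str, midpoint: dt.date, rng: np.random.Generator) -> float:
    """Age in years at ``midpoint`` appropriate to the class."""
    if age_class == "immature":
        hi = 9.5 if sex == "female" else 7.5
        return float(rng.uniform(1.5, hi))
    if age_class == "blackback":
        return float(rng.uniform(8.2, 10.8))
    if age_class == "adult_female":
        return float(rng.uniform(10.5, 30.0))
    return float(rng.uniform(13.0, 30.0))  # silverback


def generate_study(config: SimConfig, out_dir: str | Path) -> tuple[Path, GroundTruth]:
    """Generate one study directory (the five CSVs + window sidecar).

    Fully deterministic in ``config.seed``; returns the directory and the
    exact ground truth of what was written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = (config.start, _month_start(config.start, config.months))
    mid_all = config.start + (window[1] - config.start) / 2

    comps = _draw_composition(config, rng)
    class_initial = {"silverback": "SB", "blackback": "BB", "adult_female": "AF", "immature": "IM"}

    individuals: list[dict] = []
    memberships: list[dict] = []
    nodes: list[_SimNode] = []

    for g, comp in enumerate(comps):
        gid = f"G{g + 1}"
        females = []
        # adult females are created before immatures so mothers exist
        for cls in ("silverback", "blackback", "adult_female", "immature"):
            for k in range(comp[cls]):
                iid = f"{gid}{class_initial[cls]}{k + 1}"
                sex = (
                    "female"
                    if cls == "adult_female"
                    else "male"
                    if cls in ("blackback", "silverback")
                    else ("female" if rng.random() < 0.5 else "male")
                )
                age_mid = _birth_for(cls, sex, mid_all, rng)
                birth = mid_all - dt.timedelta(days=int(age_mid * 365.25))
                mother = None
                if cls == "immature" and females:
                    mother = str(rng.choice(females))
                sb_from = (
                    (config.start - dt.timedelta(days=365)).isoformat()
                    if cls == "silverback"
                    else ""
                )
                individuals.append(
                    {
                        "individual_id": iid,
                        "name": iid,
                        "sex": sex,
                        "birth_date": birth.isoformat(),
                        "mother_id": mother or "",
                        "silverback_from": sb_from,
                        "age_class_override": "",
                    }
                )
                memberships.append(
                    {
                        "individual_id": iid,
                        "group_id": gid,
                        "start_date": window[0].isoformat(),
                        "end_date": window[1].isoformat(),
                    }
                )
                nodes.append(
                    _SimNode(iid, iid, g, cls, sex, 0, config.months)
                )
                if cls == "adult_female":
                    females.append(iid)

    if config.n_transfers == 1:
        # one natal female dispersing to a neighbouring group at adulthood,
        # at a month boundary; immature in her natal tenure, adult in the next
        m_t = max(1, min(config.months - 1, round(config.months * 0.625)))
        t_date = _month_start(config.start, m_t)
        birth = t_date - dt.timedelta(days=int(10.05 * 365.25))
        src, dst = 0, 1
        iid = "TRF1"
        individuals.append(
            {
                "individual_id": iid,
                "name": iid,
                "sex": "female",
                "birth_date": birth.isoformat(),
                "mother_id": "",
                "silverback_from": "",
                "age_class_override": "",
            }
        )
        memberships.append(
            {
                "individual_id": iid,
                "group_id": "G1",
                "start_date": window[0].isoformat(),
                "end_date": t_date.isoformat(),
            }
        )
        memberships.append(
            {
                "individual_id": iid,
                "group_id": "G2",
                "start_date": t_date.isoformat(),
                "end_date": window[1].isoformat(),
            }
        )
        nodes.append(_SimNode(iid, iid, src, "immature", "female", 0, m_t))
        nodes.append(_SimNode(f"{iid}2", iid, dst, "adult_female", "female", m_t, config.months))

    # ---------------- interactions ----------------
    dyads: list[tuple[int, int, str, str, float]] = []  # i, j, context, key, rate
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            if a.individual_id == b.individual_id:
                continue
            key = rate_key(a.age_class, b.age_class)
            if a.group == b.group:
                dyads.append((i, j, "intragroup", key, float(config.intragroup_rates.get(key, 0.0))))
            else:
                dyads.append((i, j, "intergroup", key, float(config.intergroup_rates.get(key, 0.0))))

    rates = np.array([d[4] for d in dyads])
    event_rows: list[dict] = []
    event_counts: dict[str, dict[str, int]] = {}
    dyad_counts: dict[str, int] = {}
    group_ids = [f"G{g + 1}" for g in range(config.n_groups)]

    for m in range(config.months):
        m0 = _month_start(config.start, m)
        m1 = _month_start(config.start, m + 1)
        ndays = (m1 - m0).days
        active = np.array(
            [nodes[i].active(m) and nodes[j].active(m) for i, j, *_ in dyads]
        )
        lam = np.where(active, rates, 0.0)
        if config.overdispersion is not None:
            shape = config.overdispersion
            lam = np.where(lam > 0, rng.gamma(shape, lam / shape), 0.0)
        counts = rng.poisson(lam)
        for d_idx in np.nonzero(counts)[0]:
            i, j, context, key, _ = dyads[d_idx]
            k = int(counts[d_idx])
            mix = config.behavior_mix[context][key]
            per_class = rng.multinomial(k, mix)
            a, b = nodes[i], nodes[j]
            pair = "|".join(sorted((a.node_id, b.node_id)))
            dyad_counts[pair] = dyad_counts.get(pair, 0) + k
            cat = _category_label(context, key)
            tally = event_counts.setdefault(
                cat, {"play": 0, "other_affiliation": 0, "aggression": 0}
            )
            for bclass, n_b in zip(("play", "other_affiliation", "aggression"), per_class):
                if n_b == 0:
                    continue
                tally[bclass] += int(n_b)
                terms, probs = _TERMS[bclass]
                term_draws = rng.choice(len(terms), size=n_b, p=probs)
                days = rng.integers(0, ndays, size=n_b)
                flips = rng.random(n_b) < 0.5
                for t_ix, day, flip in zip(term_draws, days, flips):
                    actor, receiver = (a, b) if flip else (b, a)
                    ctx_group = (
                        group_ids[a.group]
                        if a.group == b.group
                        else group_ids[a.group if rng.random() < 0.5 else b.group]
                    )
                    event_rows.append(
                        {
                            "event_date": (m0 + dt.timedelta(days=int(day))).isoformat(),
                            "group_context": ctx_group,
                            "actor_id": actor.individual_id,
                            "receiver_id": receiver.individual_id,
                            "behavior": terms[t_ix],
                        }
                    )

    # ---------------- scans ----------------
    scan_rows: list[dict] = []
    nn_counts: dict[str, int] = {}
    nn_assignments: dict[str, str] = {}
    prop = dict(config.nn_propensity)
    classes = list(AGE_CLASSES)

    members_by_group: dict[int, list[_SimNode]] = {g: [] for g in range(config.n_groups)}
    for nd in nodes:
        members_by_group[nd.group].append(nd)

    for m in range(config.months):
        m0 = _month_start(config.start, m)
        m1 = _month_start(config.start, m + 1)
        ndays = (m1 - m0).days
        active_by_group = {
            g: [nd for nd in mem if nd.active(m)] for g, mem in members_by_group.items()
        }
        for g in range(config.n_groups):
            members = active_by_group[g]
            sbs = [nd for nd in members if nd.age_class == "silverback"]
            others = [nd for nd in members if nd.age_class != "silverback"]
            for s in range(config.scans_per_month):
                sb = sbs[int(rng.integers(len(sbs)))] if len(sbs) > 1 else sbs[0]
                in_scan = [
                    nd
                    for nd, keep in zip(others, rng.random(len(others)) < config.observation_prob)
                    if keep
                ] + [nd for nd in sbs if nd is not sb and rng.random() < config.observation_prob]
                observed = [sb] + in_scan
                nn: _SimNode | None = None
                if rng.random() < config.intergroup_nn_rate and config.n_groups > 1:
                    other_groups = [h for h in range(config.n_groups) if h != g]
                    h = other_groups[int(rng.integers(len(other_groups)))]
                    pool = active_by_group[h]
                    if pool:
                        nn = _weighted_class_choice(pool, prop, classes, rng)
                        observed = observed + [nn]
                if nn is None and in_scan:
                    nn = _weighted_class_choice(in_scan, prop, classes, rng)
                day = int(rng.integers(0, ndays))
                slot = int(rng.integers(0, 30))
                when = dt.datetime.combine(
                    m0 + dt.timedelta(days=day), dt.time(hour=6 + slot // 3, minute=20 * (slot % 3))
                )
                social = [
                    nd.individual_id
                    for nd in observed
                    if rng.random() < config.social_scan_prob.get(nd.age_class, 0.05)
                ]
                scan_id = f"S{g + 1}_{m:03d}_{s:04d}"
                scan_rows.append(
                    {
                        "scan_id": scan_id,
                        "scan_datetime": when.isoformat(sep=" "),
                        "group_id": group_ids[g],
                        "silverback_id": sb.individual_id,
                        "nearest_neighbor_id": nn.individual_id if nn else "",
                        "observed_ids": ";".join(nd.individual_id for nd in observed),
                        "scan_social_ids": ";".join(social),
                    }
                )
                if nn is not None:
                    context = "intragroup" if nn.group == sb.group else "intergroup"
                    cat = _category_label(context, rate_key("silverback", nn.age_class))
                    nn_counts[cat] = nn_counts.get(cat, 0) + 1
                    nn_assignments[scan_id] = nn.node_id

    # ---------------- covariates ----------------
    cov_rows = []
    for m in range(config.months):
        ym = _month_start(config.start, m).strftime("%Y-%m")
        season = np.sin(2 * np.pi * (m % 12) / 12.0)
        for g in range(config.n_groups):
            fruit = float(
                np.clip(
                    config.fruit_mean + config.fruit_amplitude * season + rng.normal(0, 0.03),
                    0.01,
                    1.0,
                )
            )
            rain = float(
                np.exp(
                    config.rainfall_log_mean
                    + config.rainfall_log_amplitude * season
                    + rng.normal(0, config.rainfall_log_sd)
                )
            )
            cov_rows.append(
                {
                    "year_month": ym,
                    "group_id": group_ids[g],
                    "fruit_availability": round(fruit, 4),
                    "rainfall_mm": round(rain, 1),
                }
            )

    # ---------------- expected network (independent rule enumeration) -------
    mother = {r["individual_id"]: r["mother_id"] for r in individuals if r["mother_id"]}
    expected_edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            if a.group != b.group:
                continue
            is_edge = (
                "silverback" in (a.age_class, b.age_class)
                or mother.get(a.individual_id) == b.individual_id
                or mother.get(b.individual_id) == a.individual_id
                or (
                    mother.get(a.individual_id) is not None
                    and mother.get(a.individual_id) == mother.get(b.individual_id)
                )
            )
            if is_edge:
                expected_edges.append(sorted((a.node_id, b.node_id)))

    # ---------------- write ----------------
    pd.DataFrame(individuals).to_csv(out_dir / "individuals.csv", index=False)
    pd.DataFrame(memberships).to_csv(out_dir / "memberships.csv", index=False)
    pd.DataFrame(
        event_rows,
        columns=["event_date", "group_context", "actor_id", "receiver_id", "behavior"],
    ).to_csv(out_dir / "interactions.csv", index=False)
    pd.DataFrame(
        scan_rows,
        columns=[
            "scan_id",
            "scan_datetime",
            "group_id",
            "silverback_id",
            "nearest_neighbor_id",
            "observed_ids",
            "scan_social_ids",
        ],
    ).to_csv(out_dir / "scans.csv", index=False)
    pd.DataFrame(cov_rows).to_csv(out_dir / "covariates.csv", index=False)
    pd.DataFrame(
        [{"start_date": window[0].isoformat(), "end_date": window[1].isoformat()}]
    ).to_csv(out_dir / "window.csv", index=False)

    truth = GroundTruth(
        event_counts=event_counts,
        dyad_counts=dyad_counts,
        nn_counts=nn_counts,
        nn_assignments=nn_assignments,
        nn_propensity=dict(config.nn_propensity),
        expected_edges=sorted(expected_edges),
        n_individuals=len(individuals),
        n_nodes=len(nodes),
    )
    truth.to_json(out_dir / "ground_truth.json")
    return out_dir, truth


def _weighted_class_choice(
    pool: list[_SimNode],
    propensity: Mapping[str, float],
    classes: list[str],
    rng: np.random.Generator,
) -> _SimNode:
    """Pick a class by propensity among classes present, then a member uniformly.

    Class-first sampling makes the aggregate partner-class shares converge
    to the configured propensities regardless of group composition.
    """
    present = [c for c in classes if any(nd.age_class == c for nd in pool)]
    weights = np.array([propensity.get(c, 0.0) for c in present])
    if weights.sum() <= 0:
        weights = np.ones(len(present))
    weights = weights / weights.sum()
    cls = present[int(rng.choice(len(present), p=weights))]
    members = [nd for nd in pool if nd.age_class == cls]
    return members[int(rng.integers(len(members)))]


_DISPLAY = {
    "immature": "Immature",
    "adult_female": "Adult Female",
    "blackback": "Blackback",
    "silverback": "Silverback",
}


def _category_label(context: str, key: str) -> str:
    a, b = key.split(":")
    if a == b:
        name = f"{_DISPLAY[a]} dyads"
    else:
        name = f"{_DISPLAY[a]}-{_DISPLAY[b]}"
    return f"{context}|{name}"


# ---------------------------------------------------------------------------
# planted removal effects


def _expected_dyad_counts(
    config: SimConfig, target_class: str, context: str, n_draws: int = 2000
) -> tuple[float, float]:
    """Monte-Carlo expectation of dyads incident / not incident to a class.

    Composition is random per seed, so the expected counts of dyads in
    the requested context containing at least one member of the target
    class are estimated over the composition distribution with a fixed
    internal stream (independent of the study seed).
    """
    rng = np.random.default_rng(987654321)
    inc = non = 0.0
    for _ in range(n_draws):
        comps = _draw_composition(config, rng)
        totals = [sum(c.values()) for c in comps]
        tgt = [c[target_class] for c in comps]
        if context == "intragroup":
            for n, t in zip(totals, tgt):
                all_d = n * (n - 1) / 2
                non_t = (n - t) * (n - t - 1) / 2
                inc += all_d - non_t
                non += non_t
        else:
            g = len(comps)
            for a in range(g):
                for b in range(a + 1, g):
                    all_d = totals[a] * totals[b]
                    non_t = (totals[a] - tgt[a]) * (totals[b] - tgt[b])
                    inc += all_d - non_t
                    non += non_t
    return inc / n_draws, non / n_draws


def plant_removal_effect(
    config: SimConfig,
    target_class: str,
    target_loss_pct: float,
    context: str = "intragroup",
) -> SimConfig:
    """Rescale dyad rates so removing ``target_class`` loses ~``target_loss_pct``%
    of the edges in ``context``.

    Dyads incident to the target class are given a rate making an edge
    (at least one interaction) near-certain; the remaining dyads' shared
    edge probability is solved so that the expected fraction of edges
    incident to the class equals the target.  Raises when the target is
    infeasible for the composition (required non-incident edge
    probability above 1).
    """
    if not 0 < target_loss_pct <= 100:
        raise ValidationError("target_loss_pct must lie in (0, 100]")
    if target_class not in AGE_CLASSES:
        raise ValidationError(f"unknown age class {target_class!r}")
    if context not in ("intragroup", "intergroup"):
        raise ValidationError(f"unknown context {context!r}")

    d_inc, d_non = _expected_dyad_counts(config, target_class, context)
    if d_inc == 0:
        raise ValidationError(f"no {context} dyads involve {target_class!r}")
    t = target_loss_pct / 100.0
    p_inc = 0.95
    e_inc = p_inc * d_inc
    p_non = 0.0 if t == 1.0 else e_inc * (1 - t) / (t * d_non) if d_non > 0 else 0.0
    if p_non > 1.0:
        raise ValidationError(
            f"target loss {target_loss_pct}% infeasible: would need non-incident "
            f"edge probability {p_non:.2f}"
        )
    rate_inc = -np.log(1 - p_inc) / config.months
    rate_non = 0.0 if p_non == 0 else -np.log(1 - p_non) / config.months

    new_rates = {}
    for key in _default_intragroup_rates():
        a, b = key.split(":")
        new_rates[key] = rate_inc if target_class in (a, b) else rate_non
    if context == "intragroup":
        return dataclasses.replace(config, intragroup_rates=new_rates)
    return dataclasses.replace(config, intergroup_rates=new_rates)


# ---------------------------------------------------------------------------
# hand-checkable micro fixture


def fixture_small(out_dir: str | Path) -> tuple[Path, GroundTruth]:
    """Deterministic 2-group, 10-individual, 3-month micro dataset.

    Every record is authored by hand so each tabulation can be verified
    by enumeration; the accompanying ground truth holds the hand tallies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    individuals = [
        # id, sex, birth, mother, silverback_from
        ("KSB", "male", "2000-01-01", "", "2015-01-01"),
        ("KBB", "male", "2011-01-01", "", ""),
        ("KAF1", "female", "1995-06-01", "", ""),
        ("KAF2", "female", "1998-03-01", "", ""),
        ("KIM1", "male", "2016-05-01", "KAF1", ""),
        ("KIM2", "female", "2017-02-01", "KAF1", ""),
        ("BSB", "male", "1998-07-01", "", "2012-01-01"),
        ("BAF", "female", "2002-04-01", "", ""),
        ("BIM", "female", "2015-09-01", "BAF", ""),
        ("BBB", "male", "2010-02-01", "", ""),
    ]
    pd.DataFrame(
        [
            {
                "individual_id": i,
                "name": i,
                "sex": s,
                "birth_date": b,
                "mother_id": mo,
                "silverback_from": sb,
                "age_class_override": "",
            }
            for i, s, b, mo, sb in individuals
        ]
    ).to_csv(out_dir / "individuals.csv", index=False)

    group_of = {i[0]: ("K" if i[0].startswith("K") else "B") for i in individuals}
    pd.DataFrame(
        [
            {
                "individual_id": i,
                "group_id": g,
                "start_date": "2020-01-01",
                "end_date": "2020-04-01",
            }
            for i, g in group_of.items()
        ]
    ).to_csv(out_dir / "memberships.csv", index=False)

    events = [
        ("2020-01-05", "K", "KIM1", "KIM2", "play"),
        ("2020-01-06", "K", "KIM2", "KIM1", "play"),
        ("2020-01-10", "K", "KIM1", "KBB", "play"),
        ("2020-02-02", "K", "KIM1", "KBB", "play"),
        ("2020-02-03", "K", "KBB", "KIM1", "play"),
        ("2020-01-15", "K", "KAF1", "KIM1", "nurse"),
        ("2020-02-20", "K", "KAF2", "KSB", "groom"),
        ("2020-03-01", "K", "KSB", "KAF2", "aggression"),
        ("2020-03-05", "B", "BIM", "BSB", "play"),
        ("2020-03-06", "B", "BSB", "BIM", "play"),
        ("2020-02-10", "K", "KIM1", "BIM", "play"),
        ("2020-03-15", "B", "BBB", "KBB", "aggression"),
    ]
    pd.DataFrame(
        events, columns=["event_date", "group_context", "actor_id", "receiver_id", "behavior"]
    ).to_csv(out_dir / "interactions.csv", index=False)

    # scan layout: group K silverback KSB, group B silverback BSB
    scans = [
        # scan_id, datetime, group, sb, nn, observed, social
        ("K01", "2020-01-02 08:00", "K", "KSB", "KIM1", "KSB;KIM1;KIM2;KAF1", "KIM1"),
        ("K02", "2020-01-05 08:20", "K", "KSB", "KIM1", "KSB;KIM1;KBB", "KIM1;KBB"),
        ("K03", "2020-01-09 09:00", "K", "KSB", "KIM2", "KSB;KIM2;KAF1;KAF2", ""),
        ("K04", "2020-01-20 10:00", "K", "KSB", "KAF1", "KSB;KAF1;KIM1", ""),
        ("K05", "2020-02-03 08:00", "K", "KSB", "KIM1", "KSB;KIM1;KIM2;KBB", "KIM1;KIM2"),
        ("K06", "2020-02-07 08:40", "K", "KSB", "KBB", "KSB;KBB;KIM1", ""),
        ("K07", "2020-02-11 11:00", "K", "KSB", "KIM1", "KSB;KIM1;KAF2", "KIM1"),
        ("K08", "2020-02-21 09:20", "K", "KSB", "KAF1", "KSB;KAF1;KAF2;KIM2", ""),
        ("K09", "2020-03-02 08:00", "K", "KSB", "KIM2", "KSB;KIM2;KBB", "KIM2"),
        ("K10", "2020-03-06 10:20", "K", "KSB", "KIM1", "KSB;KIM1;KIM2;KAF1;KBB", "KIM1"),
        ("K11", "2020-03-14 09:40", "K", "KSB", "KBB", "KSB;KBB;KAF1", ""),
        ("K12", "2020-03-20 08:00", "K", "KSB", "", "KSB;KAF2", ""),
        ("B01", "2020-01-03 08:00", "B", "BSB", "BIM", "BSB;BIM;BAF", "BIM"),
        ("B02", "2020-01-12 08:20", "B", "BSB", "BIM", "BSB;BIM;BBB", ""),
        ("B03", "2020-01-25 09:00", "B", "BSB", "BAF", "BSB;BAF;BIM", ""),
        ("B04", "2020-02-06 08:00", "B", "BSB", "BIM", "BSB;BIM;BAF;BBB", "BIM;BBB"),
        ("B05", "2020-02-15 10:00", "B", "BSB", "BBB", "BSB;BBB", ""),
        ("B06", "2020-03-04 08:20", "B", "BSB", "BAF", "BSB;BAF", ""),
        ("B07", "2020-03-11 09:00", "B", "BSB", "BIM", "BSB;BIM", "BIM"),
        ("B08", "2020-03-22 08:40", "B", "BSB", "KSB", "BSB;BAF;KSB", ""),
    ]
    pd.DataFrame(
        scans,
        columns=[
            "scan_id",
            "scan_datetime",
            "group_id",
            "silverback_id",
            "nearest_neighbor_id",
            "observed_ids",
            "scan_social_ids",
        ],
    ).to_csv(out_dir / "scans.csv", index=False)

    cov = []
    for ym, fruit, rain in (("2020-01", 0.42, 120.0), ("2020-02", 0.35, 95.5), ("2020-03", 0.28, 60.2)):
        for g in ("K", "B"):
            cov.append(
                {"year_month": ym, "group_id": g, "fruit_availability": fruit, "rainfall_mm": rain}
            )
    pd.DataFrame(cov).to_csv(out_dir / "covariates.csv", index=False)
    pd.DataFrame([{"start_date": "2020-01-01", "end_date": "2020-04-01"}]).to_csv(
        out_dir / "window.csv", index=False
    )

    truth = GroundTruth(
        event_counts={
            "intragroup|Immature dyads": {"play": 2, "other_affiliation": 0, "aggression": 0},
            "intragroup|Immature-Blackback": {"play": 3, "other_affiliation": 0, "aggression": 0},
            "intragroup|Immature-Adult Female": {"play": 0, "other_affiliation": 1, "aggression": 0},
            "intragroup|Adult Female-Silverback": {"play": 0, "other_affiliation": 1, "aggression": 1},
            "intragroup|Immature-Silverback": {"play": 2, "other_affiliation": 0, "aggression": 0},
            "intergroup|Immature dyads": {"play": 1, "other_affiliation": 0, "aggression": 0},
            "intergroup|Blackback dyads": {"play": 0, "other_affiliation": 0, "aggression": 1},
        },
        dyad_counts={
            "KIM1|KIM2": 2,
            "KBB|KIM1": 3,
            "KAF1|KIM1": 1,
            "KAF2|KSB": 2,
            "BIM|BSB": 2,
            "BIM|KIM1": 1,
            "BBB|KBB": 1,
        },
        nn_counts={
            # K: KIM1 x5, KIM2 x2; B: BIM x4 -> 11 immature nearest neighbours
            "intragroup|Immature-Silverback": 11,
            "intragroup|Adult Female-Silverback": 4,  # KAF1 x2, BAF x2
            "intragroup|Blackback-Silverback": 3,  # KBB x2, BBB x1
            "intergroup|Silverback dyads": 1,  # B08: KSB nearest to BSB
        },
        nn_assignments={
            s[0]: s[4] for s in scans if s[4]
        },
        nn_propensity={},
        expected_edges=sorted(
            [
                sorted(e)
                for e in [
                    ("KSB", "KBB"),
                    ("KSB", "KAF1"),
                    ("KSB", "KAF2"),
                    ("KSB", "KIM1"),
                    ("KSB", "KIM2"),
                    ("KAF1", "KIM1"),
                    ("KAF1", "KIM2"),
                    ("KIM1", "KIM2"),
                    ("BSB", "BAF"),
                    ("BSB", "BIM"),
                    ("BSB", "BBB"),
                    ("BAF", "BIM"),
                ]
            ]
        ),
        n_individuals=10,
        n_nodes=10,
    )
    truth.to_json(out_dir / "ground_truth.json")
    return out_dir, truth
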