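"""Matrix construction: counts, SRI, flooring, binarization, expected rules."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from apesoc import net_build, obs_data
from apesoc.net_build import (
    SocialMatrix,
    SriComponents,
    binarize,
    build_expected_network,
    build_interaction_matrix,
    build_nn_association_matrix,
    read_matrix_csv,
    sri,
    write_matrix_csv,
)
from apesoc.obs_data import InteractionEvent, Node, ValidationError


def _node(node_id, group, age_class, sex="female"):
    return Node(node_id=node_id, individual_id=node_id, group_id=group, age_class=age_class, sex=sex)


FOUR_NODES = [
    _node("A", "K", "silverback", "male"),
    _node("B", "K", "immature"),
    _node("C", "K", "adult_female"),
    _node("D", "B", "blackback", "male"),
]


def _ev(actor, receiver, behavior="play", date=dt.date(2020, 1, 15)):
    return InteractionEvent(
        event_date=date, group_context="K", actor_id=actor, receiver_id=receiver, behavior=behavior
    )


class TestInteractionMatrix:
    def test_bidirectional_sum(self):
        events = [_ev("A", "B")] * 3 + [_ev("B", "A")] * 2
        m = build_interaction_matrix(events, FOUR_NODES)
        assert m.values[0, 1] == 5 and m.values[1, 0] == 5

    def test_empty_events_zero_matrix(self):
        m = build_interaction_matrix([], FOUR_NODES)
        assert not m.values.any() and m.flavor == "count"

    def test_matches_brute_force_oracle(self, fixture_pipeline):
        _, events, _, _, nodes, _ = fixture_pipeline
        m = build_interaction_matrix(events, nodes)
        assert np.array_equal(m.values, oracles.count_matrix(events, nodes))

    def test_upper_triangle_sum_equals_event_count(self, fixture_pipeline):
        _, events, _, _, nodes, _ = fixture_pipeline
        m = build_interaction_matrix(events, nodes)
        assert m.values[np.triu_indices(len(nodes), 1)].sum() == len(events)


class TestSri:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ((3, 2, 5, 0), 0.3),
            ((7, 0, 0, 0), 1.0),
            ((1, 0, 0, 0), 1.0),
            ((0, 4, 6, 2), 0.0),
            ((2, 1, 1, 4), 0.25),
        ],
    )
    def test_formula(self, components, expected):
        assert sri(SriComponents(*components)) == pytest.approx(expected)

    def test_zero_denominator_returns_zero(self, caplog):
        assert sri(SriComponents(0, 0, 0, 0)) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            SriComponents(-1, 0, 0, 0)

    @given(
        x=st.integers(0, 50), ya=st.integers(0, 50), yb=st.integers(0, 50), yab=st.integers(0, 50)
    )
    def test_bounded_in_unit_interval(self, x, ya, yb, yab):
        v = sri(SriComponents(x, ya, yb, yab))
        assert 0.0 <= v <= 1.0


class TestNnAssociationMatrix:
    def test_matches_brute_force_oracle_before_flooring(self, fixture_pipeline):
        _, _, scans, _, nodes, _ = fixture_pipeline
        # disable flooring to compare raw SRI values with the oracle
        m = build_nn_association_matrix(scans, nodes, floor_threshold=-1.0)
        assert np.allclose(m.values, oracles.sri_matrix(scans, nodes))

    def test_together_total_equals_scans_with_nn(self, fixture_pipeline):
        _, _, scans, _, nodes, _ = fixture_pipeline
        together, _, _ = net_build.nn_components(scans, nodes)
        n_with_nn = sum(1 for s in scans if s.nearest_neighbor_id is not None)
        assert together[np.triu_indices(len(nodes), 1)].sum() == n_with_nn

    def test_non_silverback_dyads_zero(self, fixture_pipeline):
        _, _, scans, _, nodes, _ = fixture_pipeline
        m = build_nn_association_matrix(scans, nodes)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if i != j and "silverback" not in (a.age_class, b.age_class):
                    assert m.values[i, j] == 0.0

    def _scan(self, sid, sb, nn, observed, group, day):
        from apesoc.obs_data import ScanRecord

        return ScanRecord(
            scan_id=sid,
            scan_datetime=dt.datetime(2020, 1, day, 8, 0),
            group_id=group,
            silverback_id=sb,
            nearest_neighbor_id=nn,
            observed_ids=frozenset(observed),
        )

    def test_intergroup_flooring_applied(self):
        # A (silverback, K) and D (blackback, B) nearest neighbours once in
        # many joint observations: raw SRI far below the flooring threshold
        nodes = FOUR_NODES
        scans = [self._scan("s0", "A", "D", {"A", "B", "D"}, "K", 1)]
        scans += [self._scan(f"s{k}", "A", "B", {"A", "B", "D"}, "K", 2) for k in range(1, 28)]
        m = build_nn_association_matrix(scans, nodes)
        i, j = m.index_of("A"), m.index_of("D")
        raw = 1 / 28
        assert raw > net_build.FLOOR_THRESHOLD  # sanity: this dyad is NOT floored
        assert m.values[i, j] == pytest.approx(raw)
        # now dilute to push the intergroup SRI under the threshold
        scans += [self._scan(f"t{k}", "A", "B", {"A", "B", "D"}, "K", 3) for k in range(28, 1200)]
        m2 = build_nn_association_matrix(scans, nodes)
        assert 0 < 1 / len(scans) <= net_build.FLOOR_THRESHOLD
        assert m2.values[i, j] == net_build.FLOOR_VALUE

    def test_intragroup_never_floored(self):
        nodes = FOUR_NODES
        scans = [self._scan("s0", "A", "B", {"A", "B"}, "K", 1)]
        scans += [self._scan(f"s{k}", "A", "C", {"A", "B", "C"}, "K", 2) for k in range(1, 1200)]
        m = build_nn_association_matrix(scans, nodes)
        i, j = m.index_of("A"), m.index_of("B")
        assert 0 < m.values[i, j] <= net_build.FLOOR_THRESHOLD  # tiny but intact

    def test_never_co_observed_dyad_zero(self):
        m = build_nn_association_matrix([], FOUR_NODES)
        assert not m.values.any()

    @given(raw=st.floats(1e-6, 1.0))
    def test_flooring_never_decreases_any_value(self, raw):
        floored = net_build.FLOOR_VALUE if raw <= net_build.FLOOR_THRESHOLD else raw
        assert floored >= raw


class TestBinarize:
    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 0), (2, 1), (5, 1)])
    def test_edge_requires_more_than_one_interaction(self, count, expected):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = count
        m = SocialMatrix(FOUR_NODES[:3], values, "count")
        assert binarize(m).values[0, 1] == expected

    def test_idempotent_through_counts(self):
        values = np.array([[0, 3, 0], [3, 0, 2], [0, 2, 0]], dtype=float)
        m = SocialMatrix(FOUR_NODES[:3], values, "count")
        b1 = binarize(m)
        b2 = binarize(SocialMatrix(FOUR_NODES[:3], b1.values, "count"), threshold_exclusive=0)
        assert np.array_equal(b1.values, b2.values)

    def test_rejects_non_count_input(self):
        m = SocialMatrix(FOUR_NODES[:3], np.zeros((3, 3)), "sri")
        with pytest.raises(ValidationError):
            binarize(m)


def _toy_registry(tmp_path, individuals, memberships, window=(dt.date(2014, 1, 1), dt.date(2022, 1, 1))):
    import pandas as pd

    pd.DataFrame(
        individuals,
        columns=[
            "individual_id",
            "name",
            "sex",
            "birth_date",
            "mother_id",
            "silverback_from",
            "age_class_override",
        ],
    ).to_csv(tmp_path / "individuals.csv", index=False)
    pd.DataFrame(
        memberships, columns=["individual_id", "group_id", "start_date", "end_date"]
    ).to_csv(tmp_path / "memberships.csv", index=False)
    return obs_data.load_registry(tmp_path / "individuals.csv", tmp_path / "memberships.csv", window)


class TestExpectedNetwork:
    def test_five_node_group_enumeration(self, tmp_path):
        # 1 silverback, 2 adult females, 2 immatures (both offspring of AF1):
        # 4 silverback edges + 2 mother-offspring + 1 sibling = 7 of 10 dyads
        individuals = [
            ("SB1", "SB1", "male", "2000-01-01", "", "2013-01-01", ""),
            ("AF1", "AF1", "female", "2003-01-01", "", "", ""),
            ("AF2", "AF2", "female", "2004-01-01", "", "", ""),
            ("IM1", "IM1", "male", "2015-01-01", "AF1", "", ""),
            ("IM2", "IM2", "female", "2016-01-01", "AF1", "", ""),
        ]
        memberships = [(i[0], "G1", "2014-01-01", "") for i in individuals]
        reg = _toy_registry(tmp_path, individuals, memberships)
        nodes = obs_data.derive_node_set(reg)
        m = build_expected_network(nodes, reg)
        assert m.values[np.triu_indices(5, 1)].sum() == 7
        from apesoc.net_stats import density

        assert density(m) == pytest.approx(0.7)

    def test_no_pedigree_gives_silverback_star(self, tmp_path):
        individuals = [
            ("SB1", "SB1", "male", "2000-01-01", "", "2013-01-01", ""),
            ("AF1", "AF1", "female", "2003-01-01", "", "", ""),
            ("AF2", "AF2", "female", "2004-01-01", "", "", ""),
            ("BB1", "BB1", "male", "2012-01-01", "", "", ""),
        ]
        memberships = [(i[0], "G1", "2014-01-01", "") for i in individuals]
        reg = _toy_registry(tmp_path, individuals, memberships)
        nodes = obs_data.derive_node_set(reg)
        m = build_expected_network(nodes, reg)
        i_sb = m.index_of("SB1")
        for j in range(4):
            assert m.values[i_sb, j] == (0 if j == i_sb else 1)
        off = [j for j in range(4) if j != i_sb]
        assert not m.values[np.ix_(off, off)].any()

    def test_multimale_group_links_both_silverbacks(self, fixture_pipeline):
        registry, _, _, _, nodes, _ = fixture_pipeline
        m = build_expected_network(nodes, registry)
        # every within-group dyad touching a silverback has an edge
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if i < j and a.group_id == b.group_id and "silverback" in (a.age_class, b.age_class):
                    assert m.values[i, j] == 1

    def test_rules_are_within_group_only(self, tmp_path):
        individuals = [
            ("SB1", "SB1", "male", "2000-01-01", "", "2013-01-01", ""),
            ("SB2", "SB2", "male", "1999-01-01", "", "2013-01-01", ""),
            ("AF1", "AF1", "female", "2003-01-01", "", "", ""),
            ("IM1", "IM1", "female", "2015-01-01", "AF1", "", ""),
        ]
        memberships = [
            ("SB1", "G1", "2014-01-01", ""),
            ("AF1", "G1", "2014-01-01", ""),
            ("SB2", "G2", "2014-01-01", ""),
            ("IM1", "G2", "2014-01-01", ""),  # daughter lives apart from mother
        ]
        reg = _toy_registry(tmp_path, individuals, memberships)
        nodes = obs_data.derive_node_set(reg)
        m = build_expected_network(nodes, reg)
        groups = np.array([n.group_id for n in nodes])
        inter = groups[:, None] != groups[None, :]
        assert not m.values[inter].any()

    def test_fixture_matches_ground_truth_edges(self, fixture_pipeline):
        registry, _, _, _, nodes, truth = fixture_pipeline
        m = build_expected_network(nodes, registry)
        ids = m.node_ids
        edges = {
            tuple(sorted((ids[i], ids[j])))
            for i, j in zip(*np.triu_indices(len(ids), 1))
            if m.values[i, j]
        }
        assert edges == {tuple(e) for e in truth.expected_edges}


class TestMatrixInvariantsAndIO:
    def test_constructor_rejects_asymmetry(self):
        values = np.zeros((3, 3))
        values[0, 1] = 1
        with pytest.raises(ValidationError):
            SocialMatrix(FOUR_NODES[:3], values, "count")

    def test_constructor_rejects_nonzero_diagonal(self):
        values = np.eye(3)
        with pytest.raises(ValidationError):
            SocialMatrix(FOUR_NODES[:3], values, "count")

    @pytest.mark.parametrize("flavor", ["count", "binary", "sri"])
    def test_csv_round_trip(self, tmp_path, fixture_pipeline, flavor):
        registry, events, scans, _, nodes, _ = fixture_pipeline
        if flavor == "count":
            m = build_interaction_matrix(events, nodes)
        elif flavor == "binary":
            m = binarize(build_interaction_matrix(events, nodes))
        else:
            m = build_nn_association_matrix(scans, nodes)
        path = tmp_path / "m.csv"
        write_matrix_csv(m, path)
        back = read_matrix_csv(path, flavor, nodes=nodes)
        if flavor == "sri":
            assert np.allclose(back.values, m.values, rtol=1e-11, atol=0)
        else:
            assert np.array_equal(back.values, m.values)

    def test_all_built_matrices_symmetric_zero_diag(self, fixture_pipeline):
        registry, events, scans, _, nodes, _ = fixture_pipeline
        for m in (
            build_interaction_matrix(events, nodes),
            build_nn_association_matrix(scans, nodes),
            binarize(build_interaction_matrix(events, nodes)),
            build_expected_network(nodes, registry),
        ):
            assert np.allclose(m.values, m.values.T)
            assert not np.diagonal(m.values).any()
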