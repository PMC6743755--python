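"""Net data model, firing semantics and structural checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bernet import Arc, PetriNet
from bernet.net import FiringError, NetStructureError
from bernet.synth import generate_random_net


@st.composite
def small_nets(draw):
    n = draw(st.integers(1, 4))
    m = draw(st.integers(1, 4))
    places = [f"p{i}" for i in range(n)]
    trans = [f"t{j}" for j in range(m)]
    arcs = []
    for p in places:
        for t in trans:
            if draw(st.booleans()):
                arcs.append(Arc(p, t, draw(st.integers(1, 3))))
            if draw(st.booleans()):
                arcs.append(Arc(t, p, draw(st.integers(1, 3))))
    marking = {p: draw(st.integers(0, 3)) for p in places}
    return PetriNet(places, trans, arcs, initial_marking=marking)


def chain_net():
    return PetriNet(["p"], ["t_in", "t_out"], [Arc("t_in", "p"), Arc("p", "t_out")])


class TestIncidence:
    def test_single_consuming_arc(self):
        net = PetriNet(["p"], ["t"], [Arc("p", "t")])
        assert net.incidence_matrix().tolist() == [[-1]]

    def test_single_producing_arc(self):
        net = PetriNet(["p"], ["t"], [Arc("t", "p")])
        assert net.incidence_matrix().tolist() == [[1]]

    @pytest.mark.parametrize("seed", range(10))
    def test_column_equals_firing_delta(self, seed):
        """A[:, j] must equal the marking change of firing t_j once,
        measured by actually firing from a saturated marking."""
        net = generate_random_net(6, 8, 0.35, seed=seed, max_weight=3)
        A = net.incidence_matrix()
        big = np.full(net.n_places, 50, dtype=np.int64)
        for t in net.transitions:
            delta = net.fire(big, t.id) - big
            assert delta.tolist() == A[:, t.index].tolist()


class TestEnabledFire:
    def test_source_always_enabled(self):
        net = chain_net()
        assert "t_in" in net.enabled([0])

    def test_empty_preplace_disables(self):
        net = chain_net()
        assert "t_out" not in net.enabled([0])
        with pytest.raises(FiringError):
            net.fire([0], "t_out")

    def test_cycle_restores_marking(self):
        net = PetriNet(
            ["p1", "p2"], ["t1", "t2"],
            [Arc("p1", "t1"), Arc("t1", "p2"), Arc("p2", "t2"), Arc("t2", "p1")],
            initial_marking={"p1": 1},
        )
        m = net.fire(net.initial_marking, "t1")
        m = net.fire(m, "t2")
        assert m.tolist() == net.initial_marking.tolist()

    @pytest.mark.parametrize("seed", range(10))
    def test_enabled_matches_arc_scan(self, seed):
        net = generate_random_net(5, 6, 0.4, seed=seed, max_weight=2)
        rng = np.random.Generator(np.random.PCG64(seed))
        marking = rng.integers(0, 3, net.n_places)
        pre = net.pre_matrix()
        expected = {
            t.id
            for t in net.transitions
            if all(marking[i] >= pre[i, t.index] for i in range(net.n_places))
        }
        assert net.enabled(marking) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_fire_restores(self, seed):
        net = generate_random_net(5, 6, 0.4, seed=seed)
        big = np.full(net.n_places, 20, dtype=np.int64)
        pre, post = net.pre_matrix(), net.post_matrix()
        for t in net.transitions:
            after = net.fire(big, t.id)
            restored = after + pre[:, t.index] - post[:, t.index]
            assert restored.tolist() == big.tolist()


class TestStructuralReport:
    def test_cycle_is_conservative_and_strongly_connected(self):
        net = PetriNet(
            ["p1", "p2"], ["t1", "t2"],
            [Arc("p1", "t1"), Arc("t1", "p2"), Arc("p2", "t2"), Arc("t2", "p1")],
        )
        rep = net.structural_report()
        assert rep.strongly_connected and rep.conservative
        assert not rep.static_conflicts
        assert rep.pure and rep.ordinary and rep.homogeneous

    def test_read_arc_pair_breaks_purity(self):
        net = PetriNet(["p"], ["t"], [Arc("p", "t"), Arc("t", "p")])
        assert not net.structural_report().pure

    def test_shared_preplace_is_static_conflict(self):
        net = PetriNet(["p"], ["a", "b"], [Arc("p", "a"), Arc("p", "b")])
        assert net.structural_report().static_conflicts == [("a", "b")]

    @pytest.mark.parametrize("seed", range(20))
    def test_flags_match_definitions(self, seed):
        """Each structural flag recomputed from its bare definition."""
        net = generate_random_net(5, 5, 0.3, seed=seed, max_weight=2)
        rep = net.structural_report()
        pre, post = net.pre_matrix(), net.post_matrix()
        assert rep.pure == (not ((pre > 0) & (post > 0)).any())
        assert rep.ordinary == all(a.weight == 1 for a in net.arcs)
        assert rep.conservative == all(
            pre[:, j].sum() == post[:, j].sum() for j in range(net.n_transitions)
        )
        assert set(rep.input_transitions) == {
            t.id for t in net.transitions if pre[:, t.index].sum() == 0
        }
        assert set(rep.output_transitions) == {
            t.id for t in net.transitions if post[:, t.index].sum() == 0
        }
        if rep.ordinary:
            assert rep.homogeneous

    def test_conservative_iff_zero_column_sums_on_ordinary_nets(self):
        for seed in range(200):
            net = generate_random_net(4, 5, 0.4, seed=seed)  # weight 1 -> ordinary
            rep = net.structural_report()
            A = net.incidence_matrix()
            assert rep.conservative == bool((A.sum(axis=0) == 0).all()), seed


class TestValidationAndIO:
    def test_duplicate_place_rejected(self):
        with pytest.raises(NetStructureError):
            PetriNet(["p", "p"], ["t"], [])

    def test_dangling_arc_rejected(self):
        with pytest.raises(NetStructureError, match="ghost"):
            PetriNet(["p"], ["t"], [Arc("ghost", "t")])

    def test_place_place_arc_rejected(self):
        with pytest.raises(NetStructureError):
            PetriNet(["p", "q"], ["t"], [Arc("p", "q")])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(NetStructureError):
            PetriNet(["p"], ["t"], [Arc("p", "t", 0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_json_round_trip(self, seed, tmp_path):
        net = generate_random_net(6, 7, 0.3, seed=seed, max_weight=3)
        path = tmp_path / "net.json"
        net.to_json(path)
        assert PetriNet.from_json(str(path)) == net

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_nets())
    def test_json_round_trip_property(self, net):
        assert PetriNet.from_json(net.to_json()) == net

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_nets())
    def test_firing_never_goes_negative(self, net):
        marking = net.initial_marking
        for tid in sorted(net.enabled(marking)):
            after = net.fire(marking, tid)
            assert (after >= 0).all()

    def test_matrix_round_trip_on_pure_net(self):
        """For pure nets the arc multiset is recoverable from pre/post."""
        net = chain_net()
        pre, post = net.pre_matrix(), net.post_matrix()
        rebuilt = []
        for i, p in enumerate(net.places):
            for j, t in enumerate(net.transitions):
                if pre[i, j]:
                    rebuilt.append((p.id, t.id, int(pre[i, j])))
                if post[i, j]:
                    rebuilt.append((t.id, p.id, int(post[i, j])))
        assert sorted(rebuilt) == sorted((a.source, a.target, a.weight) for a in net.arcs)
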