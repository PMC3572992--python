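"""Network builders: topology counts, groups, protocols, composition."""

import numpy as np
import pytest

from clionesim.circuits import (
    SRC_IDS,
    NetworkSpec,
    StimulusProtocol,
    apply_protocol,
    build_cerebral_interface,
    build_full_model,
    build_statocyst,
    build_wing_cpg,
    compose,
)


class TestStatocyst:
    def test_counts_without_hunting(self):
        net = build_statocyst(hunting=False)
        assert len(net.cells) == 6
        assert len(net.edges) == 12
        assert all(e.kind == "inhibitory" for e in net.edges)

    def test_counts_with_hunting(self):
        net = build_statocyst(hunting=True)
        assert len(net.cells) == 7
        assert len(net.edges) == 18
        exc = [e for e in net.edges if e.kind == "excitatory"]
        assert len(exc) == 6
        assert all(e.pre == "H" for e in exc)
        # H receives nothing
        assert not any(e.post == "H" for e in net.edges)

    def test_plus2_edges_form_triangles(self):
        net = build_statocyst(hunting=False)
        for tri in (("SRC1", "SRC3", "SRC5"), ("SRC2", "SRC4", "SRC6")):
            sub = {(e.pre, e.post) for e in net.edges
                   if e.pre in tri and e.post in tri}
            # a directed 3-cycle among the triangle cells
            assert len(sub) == 3
            succ = dict(sub)
            node = tri[0]
            seen = []
            for _ in range(3):
                seen.append(node)
                node = succ[node]
            assert node == tri[0] and len(set(seen)) == 3

    def test_each_src_projects_to_next_two(self):
        net = build_statocyst(hunting=False)
        for i in range(6):
            pre = SRC_IDS[i]
            posts = {e.post for e in net.edges if e.pre == pre}
            assert posts == {SRC_IDS[(i + 1) % 6], SRC_IDS[(i + 2) % 6]}

    def test_symmetric_weights_warn(self):
        with pytest.warns(UserWarning, match="non-symmetrical"):
            build_statocyst(weights=np.full(12, 0.1))

    def test_bad_weight_vector_rejected(self):
        with pytest.raises(ValueError):
            build_statocyst(weights=np.ones(5))
        with pytest.raises(ValueError):
            build_statocyst(weights=-np.ones(12))


class TestCerebralInterface:
    def test_group_wiring(self):
        net = build_cerebral_interface()
        src_cg = [(e.pre, e.post) for e in net.edges
                  if e.pre.startswith("SRC") and e.kind == "excitatory"]
        assert len(src_cg) == 6
        assert {p for s, p in src_cg if s in ("SRC1", "SRC2", "SRC3")} == {"CG1"}
        assert {p for s, p in src_cg if s in ("SRC4", "SRC5", "SRC6")} == {"CG2"}

    def test_mutual_inhibition_and_integration(self):
        net = build_cerebral_interface()
        inh = {(e.pre, e.post) for e in net.edges if e.kind == "inhibitory"}
        assert inh == {("CG1", "CG2"), ("CG2", "CG1")}
        cg3_in = {e.pre for e in net.edges if e.post == "CG3"}
        assert cg3_in == {"CG1", "CG2"}
        cg3_out = {e.post for e in net.edges if e.pre == "CG3"}
        assert cg3_out == {"7", "8"}


class TestWingCpg:
    def test_half_center_structure(self):
        net = build_wing_cpg()
        assert set(net.groups["dorsal"]) == {"7", "1A", "3"}
        assert set(net.groups["ventral"]) == {"8", "2A", "4"}
        inh = {(e.pre, e.post) for e in net.edges if e.kind == "inhibitory"}
        assert ("7", "8") in inh and ("8", "7") in inh
        # interneurons excite their own motoneurons
        exc = {(e.pre, e.post) for e in net.edges if e.kind == "excitatory"}
        assert {("7", "1A"), ("7", "3"), ("8", "2A"), ("8", "4")} <= exc

    def test_intra_group_electrical_coupling(self):
        net = build_wing_cpg()
        gaps = [{e.pre, e.post} for e in net.edges if e.kind == "gap"]
        for group in (("7", "1A", "3"), ("8", "2A", "4")):
            pairs = [set(p) for p in
                     [(group[0], group[1]), (group[0], group[2]), (group[1], group[2])]]
            for p in pairs:
                assert p in gaps


class TestComposition:
    def test_full_model_cell_count(self):
        net = build_full_model(hunting=True)
        assert len(net.cells) == 16    # 6 SRC + H + 3 CG + 6 CPG

    def test_overlapping_ids_rejected(self):
        a = build_statocyst(hunting=False)
        with pytest.raises(ValueError, match="overlap"):
            compose(a, build_statocyst(hunting=False))

    def test_dangling_edges_resolve_only_at_composition(self):
        cer = build_cerebral_interface()
        with pytest.raises(ValueError, match="unknown cell"):
            cer.validate(strict=True)
        full = build_full_model()
        full.validate(strict=True)


class TestProtocol:
    def test_pressed_current_routing(self):
        net = build_statocyst(hunting=False)
        proto = StimulusProtocol(duration=1000.0, pressed_src="SRC2",
                                 I_statolith=2.5)
        I = apply_protocol(net, proto, t=10.0)
        assert I[net.index("SRC2")] == 2.5
        assert np.count_nonzero(I) == 1

    def test_switch_moves_pressed_identity(self):
        net = build_statocyst(hunting=False)
        proto = StimulusProtocol(duration=60000.0, pressed_src="SRC1",
                                 I_statolith=3.0,
                                 switch_events=((30000.0, "SRC6"),))
        before = apply_protocol(net, proto, t=29999.0)
        after = apply_protocol(net, proto, t=30001.0)
        assert before[net.index("SRC1")] == 3.0 and after[net.index("SRC1")] == 0.0
        assert after[net.index("SRC6")] == 3.0

    def test_switch_to_unknown_cell_rejected(self):
        net = build_statocyst(hunting=False)
        proto = StimulusProtocol(duration=1000.0, pressed_src="SRC1",
                                 switch_events=((500.0, "SRC9"),))
        with pytest.raises(ValueError, match="SRC9"):
            proto.schedule(net)

    def test_hunting_drive_targets_h(self):
        net = build_statocyst(hunting=True)
        proto = StimulusProtocol(duration=1000.0, hunting_on=True, I_hunting=3.0)
        I = apply_protocol(net, proto, t=0.0)
        assert I[net.index("H")] == 3.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(duration=-1.0)
        with pytest.raises(ValueError):
            StimulusProtocol(duration=100.0, I_statolith=-2.0)
        with pytest.raises(ValueError):
            StimulusProtocol(duration=100.0,
                             switch_events=((50.0, "SRC2"), (20.0, "SRC3")))
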