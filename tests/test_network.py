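"""Structural and dynamical unit tests for the circuit definition."""

import json
import math

import pytest

from hemigait.network import (
    CONDITIONS,
    Connection,
    NetworkSpec,
    PopulationSpec,
    PopulationState,
    build_network,
    h_inf,
    output_function,
    population_rhs,
    synaptic_inputs,
)


def _mirror(name: str) -> str:
    if name.endswith("-L"):
        return name[:-2] + "-R"
    if name.endswith("-R"):
        return name[:-2] + "-L"
    return name


class TestBuildNetwork:
    def test_intact_is_mirror_symmetric(self):
        net = build_network("intact")
        conns = {(c.source, c.target): (c.weight, c.sign, c.crossed) for c in net.connections}
        mirrored = {
            (_mirror(s), _mirror(t)): v for (s, t), v in conns.items()
        }
        assert conns == mirrored
        pops = {p.id: p for p in net.populations}
        for pid, p in pops.items():
            q = pops[_mirror(pid)]
            assert (p.kind, p.gNaP, p.gL, p.tau0) == (q.kind, q.gNaP, q.gL, q.tau0)

    def test_hemisection_touches_only_right_drive_weights(self):
        intact = build_network("intact")
        hemi = build_network("hemisected")
        assert len(intact.connections) == len(hemi.connections)
        for ci, ch in zip(intact.connections, hemi.connections):
            assert (ci.source, ci.target, ci.sign, ci.crossed) == (
                ch.source, ch.target, ch.sign, ch.crossed)
            if ci.source in ("drive-alpha-R", "drive-gamma-R"):
                assert ch.weight == 0.0
            else:
                assert ch.weight == ci.weight

    def test_transection_zeroes_all_drives_keeps_feedback(self):
        intact = build_network("intact")
        tx = build_network("transected")
        for ci, ct in zip(intact.connections, tx.connections):
            if ci.source.startswith("drive-"):
                assert ct.weight == 0.0
            else:
                assert ct.weight == ci.weight
        fb = [c for c in tx.connections if c.source.startswith("SF-")]
        assert fb and all(c.weight > 0 for c in fb)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            build_network("lesioned")

    def test_crossed_flag_matches_sides(self):
        for cond in CONDITIONS:
            for c in build_network(cond).connections:
                if c.source.startswith(("drive-", "SF-")):
                    src_side = "left" if c.source.endswith("-L") else "right"
                else:
                    src_side = "left" if c.source.endswith("-L") else "right"
                tgt_side = "left" if c.target.endswith("-L") else "right"
                assert c.crossed == (src_side != tgt_side)


class TestOutputFunction:
    @pytest.mark.parametrize("frac,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5), (0.25, 0.25)])
    def test_piecewise_linear(self, frac, expected):
        spec = PopulationSpec(id="x", side="left", kind="relay")
        V = spec.Vout_min + frac * (spec.Vout_max - spec.Vout_min)
        assert output_function(V, spec) == pytest.approx(expected)

    def test_saturation(self):
        spec = PopulationSpec(id="x", side="left", kind="relay")
        assert output_function(spec.Vout_min - 30.0, spec) == 0.0
        assert output_function(spec.Vout_max + 30.0, spec) == 1.0

    def test_monotone(self):
        spec = PopulationSpec(id="x", side="left", kind="relay")
        vals = [output_function(v, spec) for v in range(-90, 30, 2)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPopulationRhs:
    def test_relay_leak_equilibrium(self):
        spec = PopulationSpec(id="x", side="left", kind="relay")
        dV, dh = population_rhs(PopulationState(V=spec.EL), spec, 0.0, 0.0)
        assert dV == pytest.approx(0.0)
        assert dh == 0.0

    def test_inactivation_sigmoid_midpoint(self):
        spec = PopulationSpec(id="x", side="left", kind="burster", gNaP=5.0)
        assert h_inf(spec.Vh_half, spec) == pytest.approx(0.5)

    def test_burster_with_h_zero_reduces_to_leak(self):
        spec = PopulationSpec(id="x", side="left", kind="burster", gNaP=5.0)
        V = -55.0
        dV, _ = population_rhs(PopulationState(V=V, h=0.0), spec, 0.0, 0.0)
        assert dV == pytest.approx(-spec.gL * (V - spec.EL) / spec.C)

    def test_corrupt_h_rejected(self):
        spec = PopulationSpec(id="x", side="left", kind="burster", gNaP=5.0)
        with pytest.raises(ValueError):
            PopulationState(V=-60.0, h=1.2)
        state = PopulationState(V=-60.0, h=1.0)
        state.h = -0.1  # corrupt after construction
        with pytest.raises(ValueError, match="corrupt"):
            population_rhs(state, spec, 0.0, 0.0)

    def test_negative_conductance_rejected(self):
        spec = PopulationSpec(id="x", side="left", kind="relay")
        with pytest.raises(ValueError):
            population_rhs(PopulationState(V=-60.0), spec, -1.0, 0.0)


class TestSynapticInputs:
    def test_all_zero_inputs(self):
        net = build_network("intact")
        outputs = {pid: 0.0 for pid in net.population_ids}
        g = synaptic_inputs(net, outputs, {}, {})
        assert all(v == (0.0, 0.0) for v in g.values())

    def test_single_connection_linearity(self):
        net = build_network("intact")
        outputs = {pid: 0.0 for pid in net.population_ids}
        outputs["RG-F-L"] = 0.5
        g = synaptic_inputs(net, outputs, {}, {})
        w = next(c.weight for c in net.connections
                 if c.source == "RG-F-L" and c.target == "InF-L")
        assert g["InF-L"][0] == pytest.approx(w * 0.5)

    def test_hemisected_crossed_drive_persists(self):
        net = build_network("hemisected")
        outputs = {pid: 0.0 for pid in net.population_ids}
        drives = {"drive-alpha-L": 0.5, "drive-alpha-R": 0.0,
                  "drive-gamma-L": 0.5, "drive-gamma-R": 0.0}
        g = synaptic_inputs(net, outputs, drives, {})
        # right flexor half-center still receives the crossed left drive
        assert g["RG-F-R"][0] > 0.0
        # no right-drive contribution anywhere: zeroing alphaR/gammaR weights
        # means right-side-only targets like RG-E-R receive nothing
        assert g["RG-E-R"][0] == 0.0

    def test_missing_outputs_rejected(self):
        net = build_network("intact")
        with pytest.raises(ValueError, match="missing"):
            synaptic_inputs(net, {"RG-F-L": 0.1}, {}, {})

    def test_unknown_target_rejected(self):
        net = build_network("intact")
        with pytest.raises(ValueError):
            NetworkSpec(
                populations=net.populations,
                connections=list(net.connections)
                + [Connection("RG-F-L", "ghost", 1.0, "excitatory")],
                condition="intact",
            )


class TestSerialization:
    def test_json_round_trip_exact(self):
        net = build_network("hemisected")
        clone = NetworkSpec.from_json(net.to_json())
        assert clone.condition == net.condition
        assert clone.populations == net.populations
        assert clone.connections == net.connections
        assert clone.params == net.params

    def test_json_is_valid_document(self):
        doc = json.loads(build_network("intact").to_json())
        assert set(doc) == {"condition", "params", "populations", "connections"}


class TestSpecValidation:
    def test_relay_with_nap_rejected(self):
        with pytest.raises(ValueError, match="gNaP"):
            PopulationSpec(id="x", side="left", kind="relay", gNaP=1.0)

    def test_bad_output_bounds_rejected(self):
        with pytest.raises(ValueError, match="Vout"):
            PopulationSpec(id="x", side="left", kind="relay",
                           Vout_min=0.0, Vout_max=-50.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Connection("a", "b", -0.5, "excitatory")
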