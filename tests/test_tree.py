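"""Poiseuille tree surrogate: network solve, dilation, coupling and FFR."""

import dataclasses

import numpy as np
import pytest

from coroperf import (
    CoronaryTree,
    DarcyGrid,
    DarcyParams,
    PerfusionContext,
    Segment,
    Stenosis,
    TreeSupply,
    ValidationError,
    assign_territories,
    build_aortic_waveform,
    build_effective_waveform,
    compute_ffr,
    default_tree,
    derive_all,
    dilate,
    find_peak_diastolic_time,
    run_beat,
    scale_to_stress,
    segment_resistance,
    solve_network,
)
from coroperf.perfusion import MMHG_TO_PA
from coroperf.tree import TERRITORIES, landmark_nodes


def dense_network_oracle(tree, inlet_pressure, terminal_pressure):
    """Independent nodal-conductance-matrix solve (numpy dense).

    Node per segment distal end; leaf distal nodes and inlet nodes carry
    known pressures.  Returns nodal pressures [mmHg] keyed like the
    implementation.
    """
    by_id, children = tree.by_id, tree.children
    unknown = [s.id for s in tree.segments if children[s.id]]  # internal distal nodes
    pos = {sid: i for i, sid in enumerate(unknown)}
    n = len(unknown)
    A = np.zeros((n, n))
    b = np.zeros(n)

    def known_pressure(sid):
        # distal node of a leaf is the territory sink
        return terminal_pressure[by_id[sid].territory] * MMHG_TO_PA

    def proximal_pressure_term(sid):
        seg = by_id[sid]
        if seg.parent is None:
            name = tree.inlet_name(sid)
            p = inlet_pressure[name] if isinstance(inlet_pressure, dict) else inlet_pressure
            return None, p * MMHG_TO_PA
        return seg.parent, None

    for sid in unknown:
        i = pos[sid]
        # edge to the proximal side through this segment's resistance
        g = 1.0 / tree.resistance(sid)
        parent, fixed = proximal_pressure_term(sid)
        A[i, i] += g
        if parent is None:
            b[i] += g * fixed
        elif parent in pos:
            A[i, pos[parent]] -= g
        else:  # parent is a leaf? impossible: parents always have children
            raise AssertionError
        # edges to each child through the child's resistance
        for c in children[sid]:
            gc = 1.0 / tree.resistance(c)
            A[i, i] += gc
            if c in pos:
                A[i, pos[c]] -= gc
            else:
                b[i] += gc * known_pressure(c)
    x = np.linalg.solve(A, b)
    out = {sid: x[pos[sid]] / MMHG_TO_PA for sid in unknown}
    for leaf in tree.leaves:
        out[leaf] = terminal_pressure[by_id[leaf].territory]
    return out


def random_tree(rng, n_segments):
    segs = [Segment("s0", None, rng.uniform(0.01, 0.05), rng.uniform(1e-3, 2.5e-3), "LAD")]
    for i in range(1, n_segments):
        parent = segs[rng.integers(0, len(segs))].id
        terr = TERRITORIES[rng.integers(0, 3)]
        segs.append(
            Segment(f"s{i}", parent, rng.uniform(0.01, 0.05), rng.uniform(1e-3, 2.5e-3), terr)
        )
    return CoronaryTree(segments=tuple(segs))


class TestSegmentResistance:
    def test_reference_value(self):
        assert segment_resistance(0.03, 1.5e-3, 3.5e-3) == pytest.approx(5.28e7, rel=1e-2)

    def test_radius_fourth_power(self):
        assert segment_resistance(0.03, 0.75e-3) == pytest.approx(
            16 * segment_resistance(0.03, 1.5e-3)
        )

    def test_linear_in_length(self):
        assert segment_resistance(0.06, 1.5e-3) == pytest.approx(
            2 * segment_resistance(0.03, 1.5e-3)
        )

    def test_stenosis_series_resistance(self, healthy_tree):
        sten = Stenosis("LAD_mid", 0.5, 0.4)
        tree = dataclasses.replace(healthy_tree, stenoses=(sten,))
        seg = tree.by_id["LAD_mid"]
        expected = segment_resistance(seg.length * 0.6, seg.radius) + segment_resistance(
            seg.length * 0.4, seg.radius * 0.5
        )
        assert tree.resistance("LAD_mid") == pytest.approx(expected, rel=1e-12)


class TestDilation:
    def test_radius_ratio(self, healthy_tree):
        big = dilate(healthy_tree)
        for a, b in zip(healthy_tree.segments, big.segments):
            assert b.radius / a.radius == pytest.approx(1.225, rel=1e-12)
            assert b.length == a.length

    def test_identity_factor(self, healthy_tree):
        assert dilate(healthy_tree, 1.0) == healthy_tree

    def test_resistance_ratio_fourth_power(self, healthy_tree):
        big = dilate(healthy_tree)
        for seg in healthy_tree.segments:
            assert big.resistance(seg.id) / healthy_tree.resistance(seg.id) == pytest.approx(
                1.225**-4, rel=1e-12
            )

    def test_nonpositive_factor_rejected(self, healthy_tree):
        with pytest.raises(ValidationError):
            dilate(healthy_tree, 0.0)


class TestSolveNetwork:
    def test_equal_pressures_zero_flow(self, healthy_tree):
        term = dict.fromkeys(TERRITORIES, 90.0)
        state = solve_network(healthy_tree, 90.0, term)
        for q in state.segment_flow.values():
            assert q == pytest.approx(0.0, abs=1e-18)

    def test_single_segment_ohm(self):
        tree = CoronaryTree(segments=(Segment("a", None, 0.03, 1.5e-3, "LAD"),))
        state = solve_network(tree, 100.0, {"LAD": 90.0})
        expected = 10.0 * MMHG_TO_PA / tree.resistance("a")
        assert state.segment_flow["a"] == pytest.approx(expected, rel=1e-12)

    def test_seven_segment_tree_matches_dense_oracle(self):
        rng = np.random.default_rng(23)
        tree = random_tree(rng, 7)
        term = {t: rng.uniform(20.0, 60.0) for t in TERRITORIES}
        state = solve_network(tree, 95.0, term)
        oracle = dense_network_oracle(tree, 95.0, term)
        for sid, p in oracle.items():
            assert state.node_pressure[sid] == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_trees_match_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(5, 16)))
        term = {t: rng.uniform(10.0, 70.0) for t in TERRITORIES}
        state = solve_network(tree, rng.uniform(80.0, 120.0), term)
        oracle = dense_network_oracle(tree, state.node_pressure["left_inlet"], term)
        for sid, p in oracle.items():
            assert state.node_pressure[sid] == pytest.approx(p, rel=1e-12)

    def test_kirchhoff_balance(self, healthy_tree):
        term = {"LAD": 30.0, "LCX": 35.0, "RCA": 25.0}
        state = solve_network(healthy_tree, 90.0, term)
        scale = max(abs(q) for q in state.segment_flow.values())
        for sid, ch in healthy_tree.children.items():
            if ch:
                imbalance = state.segment_flow[sid] - sum(state.segment_flow[c] for c in ch)
                assert abs(imbalance) <= 1e-10 * scale + 1e-22

    def test_reverse_flow_reported(self, healthy_tree):
        state = solve_network(healthy_tree, 10.0, dict.fromkeys(TERRITORIES, 50.0))
        assert all(q < 0 for q in state.inlet_flow.values())


class TestTreeValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValidationError):
            CoronaryTree(
                segments=(
                    Segment("a", "b", 0.01, 1e-3, "LAD"),
                    Segment("b", "a", 0.01, 1e-3, "LAD"),
                    Segment("r", None, 0.01, 1e-3, "RCA"),
                )
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValidationError):
            CoronaryTree(segments=(Segment("a", "ghost", 0.01, 1e-3, "LAD"),))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            CoronaryTree(
                segments=(Segment("a", None, 0.01, 1e-3, "LAD"), Segment("a", None, 0.01, 1e-3, "RCA"))
            )

    def test_stenosis_bounds(self):
        with pytest.raises(ValidationError):
            Stenosis("a", 1.0, 0.5)
        with pytest.raises(ValidationError):
            Stenosis("a", 0.5, 0.0)


@pytest.fixture(scope="module")
def beat_setup(healthy_tree):
    patient = __import__("coroperf").PatientRecord(
        age=60, sex="male", height=175, weight=75, HR=70, P_sys=120, P_dia=80, LV_mass=160
    )
    from coroperf import calibrate_rest, rest_to_stress

    grid = DarcyGrid(8, 8, 5, 2e-3)
    territories = assign_territories(grid)
    timings_r, pressures_r = derive_all(patient)
    peff_r = build_effective_waveform(build_aortic_waveform(timings_r, pressures_r), timings_r)
    cal = calibrate_rest(
        grid, DarcyParams(), TreeSupply(healthy_tree, peff_r.mean(), territories), target_inflow=1.0
    )
    stress = rest_to_stress(patient)
    timings_s, pressures_s = derive_all(stress)
    peff_s = build_effective_waveform(build_aortic_waveform(timings_s, pressures_s), timings_s)
    ctx = PerfusionContext(
        grid=grid, params=scale_to_stress(cal.params), territory_field=territories
    )
    return dict(
        grid=grid, ctx=ctx, peff=peff_s, timings=timings_s,
        stress_tree=dilate(healthy_tree), cal=cal,
    )


class TestRunBeat:
    def test_beat_conserves_mass(self, beat_setup):
        sol = run_beat(beat_setup["stress_tree"], beat_setup["peff"], beat_setup["ctx"], dt=1e-3)
        inflow, drain = sol.per_beat_inflow_ml(), sol.per_beat_drain_ml()
        assert abs(inflow - drain) / inflow < 0.005

    def test_flow_is_mostly_diastolic(self, beat_setup):
        sol = run_beat(beat_setup["stress_tree"], beat_setup["peff"], beat_setup["ctx"], dt=1e-3)
        assert sol.diastolic_flow_fraction("left") > 0.5

    def test_dilation_increases_per_beat_inflow(self, beat_setup, healthy_tree):
        sol_small = run_beat(healthy_tree, beat_setup["peff"], beat_setup["ctx"], dt=1e-3)
        sol_big = run_beat(beat_setup["stress_tree"], beat_setup["peff"], beat_setup["ctx"], dt=1e-3)
        assert sol_big.per_beat_inflow_ml() > sol_small.per_beat_inflow_ml()

    def test_coarse_dt_rejected(self, beat_setup, healthy_tree):
        with pytest.raises(ValidationError):
            run_beat(healthy_tree, beat_setup["peff"], beat_setup["ctx"], dt=5e-3)


@pytest.fixture(scope="module")
def solution(beat_setup):
    return run_beat(beat_setup["stress_tree"], beat_setup["peff"], beat_setup["ctx"], dt=1e-3)


@pytest.fixture(scope="module")
def ffr(solution, beat_setup):
    t_star = find_peak_diastolic_time(beat_setup["peff"], beat_setup["timings"])
    return compute_ffr(solution, t_star)


class TestFfr:
    def test_inlet_ffr_is_one(self, ffr):
        assert ffr.node_ffr["left_inlet"] == 1.0
        assert ffr.node_ffr["right_inlet"] == 1.0

    def test_ffr_in_unit_interval(self, ffr):
        for v in ffr.node_ffr.values():
            assert 0.0 < v <= 1.0

    def test_monotone_along_root_to_leaf_paths(self, ffr, beat_setup):
        tree = beat_setup["stress_tree"]
        for seg in tree.segments:
            if seg.parent is not None:
                assert ffr.node_ffr[seg.id] <= ffr.node_ffr[seg.parent] + 1e-12

    def test_landmarks_are_deepest_distal_nodes(self, healthy_tree):
        assert landmark_nodes(healthy_tree) == {
            "LAD": "LAD_dist",
            "LCX": "LCX_dist",
            "RCA": "RCA_dist",
        }

    def test_stenosis_strictly_lowers_distal_ffr(self, beat_setup, ffr):
        sten_tree = dataclasses.replace(
            beat_setup["stress_tree"], stenoses=(Stenosis("LAD_mid", 0.7, 0.5),)
        )
        sol = run_beat(sten_tree, beat_setup["peff"], beat_setup["ctx"], dt=1e-3)
        t_star = find_peak_diastolic_time(beat_setup["peff"], beat_setup["timings"])
        sten_ffr = compute_ffr(sol, t_star)
        for node in ("LAD_mid", "LAD_dist"):  # strictly distal to the stenosis
            assert sten_ffr.node_ffr[node] < ffr.node_ffr[node]

    def test_healthy_landmarks_above_threshold(self, ffr):
        for v in ffr.landmarks.values():
            assert v > 0.95
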