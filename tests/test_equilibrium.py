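import math

import pytest
from hypothesis import given, settings, strategies as st

from retequil import (BindingNetwork, Reaction, build_network,
                      load_parameters, oracle_bisection, solve_binary,
                      solve_equilibrium)
from retequil.network import P1, P2, RT

conc = st.floats(min_value=0.01, max_value=10.0,
                 allow_nan=False, allow_infinity=False)
kd = st.floats(min_value=1e-2, max_value=1e2,
               allow_nan=False, allow_infinity=False)


def binary_bisection_oracle(l_total, p_total, kd_value, iters=200):
    """Independent scalar bisection on kd*b - (l-b)(p-b) = 0."""
    lo, hi = 0.0, min(l_total, p_total)

    def h(b):
        return kd_value * b - (l_total - b) * (p_total - b)

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSolveBinary:
    def test_infinite_affinity_binds_min(self):
        assert solve_binary(1.73, 3.23, 0.0) == pytest.approx(1.73)
        assert solve_binary(3.23, 1.73, 0.0) == pytest.approx(1.73)

    def test_default_kd_vs_independent_bisection(self):
        bound = solve_binary(1.73, 3.23, 0.664)
        assert bound == pytest.approx(
            binary_bisection_oracle(1.73, 3.23, 0.664), abs=1e-12)
        assert bound == pytest.approx(1.2890, abs=5e-5)

    def test_zero_ligand(self):
        assert solve_binary(0.0, 3.23, 0.5) == 0.0
        assert solve_binary(1.0, 0.0, 0.5) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            solve_binary(-1.0, 1.0, 0.1)

    @given(l=conc, p=conc, k=kd)
    def test_bounds_symmetry_and_oracle(self, l, p, k):
        bound = solve_binary(l, p, k)
        assert 0.0 <= bound <= min(l, p) + 1e-12
        assert bound == pytest.approx(solve_binary(p, l, k), rel=1e-12)
        assert bound == pytest.approx(binary_bisection_oracle(l, p, k),
                                      abs=1e-9)


def single_reaction_network(l, p, k):
    return BindingNetwork(species=(("L", l), ("P", p)),
                          reactions=(Reaction("L", "P", "LP", k),))


class TestSolveEquilibrium:
    def test_single_reaction_matches_closed_form(self):
        state = solve_equilibrium(single_reaction_network(1.73, 3.23, 0.664))
        assert state.converged
        assert state.complexes["LP"] == pytest.approx(
            solve_binary(1.73, 3.23, 0.664), abs=1e-9)

    def test_default_network_conservation(self, default_params):
        net = build_network(default_params)
        state = solve_equilibrium(net)
        assert state.converged
        assert state.max_residual < 1e-10
        comp = net.composition()
        for species, total in net.species:
            bound = sum(n * state.complexes[c]
                        for c, counts in comp.items()
                        for s, n in counts.items() if s == species)
            assert state.free[species] + bound == pytest.approx(total,
                                                                abs=1e-9)

    def test_default_network_mass_action(self, default_params):
        net = build_network(default_params)
        state = solve_equilibrium(net)
        free = dict(state.free)
        free.update(state.complexes)
        for rxn in net.reactions:
            lhs = state.complexes[rxn.product] * rxn.kd
            rhs = free[rxn.side_a] * free[rxn.side_b]
            assert abs(lhs - rhs) / max(1.0, lhs) < 1e-9

    def test_ternary_sink_lowers_free_retinol(self, default_params):
        state = solve_equilibrium(build_network(default_params))
        binary_free = 1.73 - solve_binary(1.73, 3.23, 0.664)
        assert state.free[RT] < binary_free

    def test_default_network_regression_snapshot(self, default_params):
        # solver output, frozen as a regression guard (not a published value)
        state = solve_equilibrium(build_network(default_params))
        assert state.free[RT] == pytest.approx(0.16040046016330956, abs=1e-9)
        assert state.free[P1] == pytest.approx(0.23770192947369780, abs=1e-9)
        assert state.free[P2] == pytest.approx(1.97512286150569660, abs=1e-9)

    def test_no_binding_limit(self, default_params):
        weak = default_params.with_updates(kd1=1e9, kd2=1e9, kd3=1e9)
        state = solve_equilibrium(build_network(weak))
        for name, total in build_network(weak).species:
            assert state.free[name] == pytest.approx(total, rel=1e-6)
        assert all(c < 1e-6 for c in state.complexes.values())

    def test_binary_limit_as_ttr_kds_diverge(self, default_params):
        loose = default_params.with_updates(kd2=1e6, kd3=1e6)
        state = solve_equilibrium(build_network(loose))
        binary_free = 1.73 - solve_binary(1.73, 3.23, 0.664)
        assert state.free[RT] == pytest.approx(binary_free, abs=1e-4)

    def test_deterministic_bit_identical(self, default_params):
        net = build_network(default_params)
        a = solve_equilibrium(net)
        b = solve_equilibrium(net)
        assert a.free == b.free
        assert a.complexes == b.complexes

    def test_tolerance_validation(self, default_params):
        with pytest.raises(ValueError):
            solve_equilibrium(build_network(default_params), tolerance=0)


class TestMonotonicity:
    def test_free_retinol_nonincreasing_in_p1(self, default_params):
        frees = [solve_equilibrium(
            build_network(default_params.with_updates(p1_total=p1))).free[RT]
            for p1 in (0.5, 1.62, 2.26, 3.23, 4.2, 4.85, 8.0)]
        assert all(a >= b for a, b in zip(frees, frees[1:]))

    def test_free_retinol_nonincreasing_in_p2(self, default_params):
        frees = [solve_equilibrium(
            build_network(default_params.with_updates(p2_total=p2))).free[RT]
            for p2 in (0.5, 2.0, 4.91, 8.0, 20.0)]
        assert all(a >= b for a, b in zip(frees, frees[1:]))

    def test_free_retinol_nondecreasing_in_kd1(self, default_params):
        frees = [solve_equilibrium(
            build_network(default_params.with_updates(kd1=k))).free[RT]
            for k in (0.05, 0.2, 0.664, 2.0, 10.0)]
        assert all(a <= b for a, b in zip(frees, frees[1:]))


class TestOracleBisection:
    def test_single_reaction_agrees_with_closed_form(self):
        state = oracle_bisection(single_reaction_network(1.73, 3.23, 0.664))
        assert state.complexes["LP"] == pytest.approx(
            solve_binary(1.73, 3.23, 0.664), abs=1e-9)

    def test_default_network_cross_oracle(self, default_params):
        net = build_network(default_params)
        newton = solve_equilibrium(net)
        oracle = oracle_bisection(net)
        for name in newton.free:
            assert newton.free[name] == pytest.approx(oracle.free[name],
                                                      abs=1e-9)

    def test_degenerate_network(self):
        state = oracle_bisection(BindingNetwork(species=(("A", 2.0),)))
        assert state.free == {"A": 2.0}


def cascade_network(totals, kds):
    """Acyclic test cascades of 1..3 reactions over up to 3 base species."""
    species = tuple((name, t) for name, t in zip(("A", "B", "C"), totals))
    reactions = [Reaction("A", "B", "AB", kds[0])]
    if len(kds) > 1:
        reactions.append(Reaction("AB", "C", "ABC", kds[1]))
    if len(kds) > 2:
        reactions.append(Reaction("B", "C", "BC", kds[2]))
    return BindingNetwork(species, tuple(reactions))


@st.composite
def random_networks(draw):
    n_reactions = draw(st.integers(min_value=1, max_value=3))
    totals = [draw(conc) for _ in range(3)]
    kds = [draw(kd) for _ in range(n_reactions)]
    return cascade_network(totals, kds)


class TestRandomNetworkProperties:
    @settings(max_examples=60, deadline=None)
    @given(network=random_networks())
    def test_conservation_and_oracle_equivalence(self, network):
        newton = solve_equilibrium(network)
        assert newton.converged
        assert newton.max_residual < 1e-10
        oracle = oracle_bisection(network)
        for name in newton.free:
            assert newton.free[name] == pytest.approx(oracle.free[name],
                                                      abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(l=conc, p=conc, k=kd)
    def test_single_reaction_three_routes_agree(self, l, p, k):
        net = single_reaction_network(l, p, k)
        closed = solve_binary(l, p, k)
        assert solve_equilibrium(net).complexes["LP"] == pytest.approx(
            closed, abs=1e-9)
        assert oracle_bisection(net).complexes["LP"] == pytest.approx(
            closed, abs=1e-9)
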