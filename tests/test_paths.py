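"""Minimum-action path machinery: action, target, optimizer, profiling."""

import numpy as np
import pytest

from bindfold import (
    DiscretePath,
    PathSpec,
    action,
    analytic_surface,
    detect_backtracking,
    init_path_linear,
    optimize_sdp,
    profile_path,
    target,
    validate_potential,
)


class FlatPotential:
    def __init__(self, value=1.0, dim=2):
        self.value = value
        self.dim = dim

    def energy_gradient(self, x):
        return self.value, np.zeros_like(np.asarray(x, dtype=float))


def arc_path(n=40, height=1.0):
    """Crooked initial path from (-1, 0) to (1, 0) bulging to y = height."""
    t = np.linspace(0, 1, n)
    return DiscretePath(np.column_stack([
        -1 + 2 * t, height * np.sin(np.pi * t)
    ]))


class TestInitPathLinear:
    def test_midpoint(self):
        p = init_path_linear(np.array([0.0, 0.0]), np.array([2.0, 0.0]), 3)
        np.testing.assert_allclose(p.grids[1], [1.0, 0.0])

    def test_endpoints_exact(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        p = init_path_linear(a, b, 7)
        np.testing.assert_array_equal(p.grids[0], a)
        np.testing.assert_array_equal(p.grids[-1], b)

    def test_uniform_spacing(self, rng):
        p = init_path_linear(rng.standard_normal(3), rng.standard_normal(3), 5)
        dl = p.segment_lengths
        assert np.abs(dl - dl.mean()).max() < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            init_path_linear(np.zeros(2), np.zeros(3), 5)


class TestAction:
    def test_flat_potential_straight_is_optimal(self):
        flat = FlatPotential()
        straight = init_path_linear(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), 40)
        assert action(straight, flat, 1.0) < action(arc_path(40, 0.5), flat, 1.0)

    def test_additivity_over_concatenation(self, rng):
        dw = analytic_surface("double_well")
        grids = np.column_stack([np.linspace(-1, 1, 21),
                                 0.3 * rng.standard_normal(21)])
        full = DiscretePath(grids)
        k = 8
        left = DiscretePath(grids[: k + 1])
        right = DiscretePath(grids[k:])
        s = action(full, dw, 0.7)
        assert s == pytest.approx(action(left, dw, 0.7) + action(right, dw, 0.7),
                                  rel=1e-12)

    def test_reversal_symmetry(self, rng):
        dw = analytic_surface("double_well")
        grids = np.column_stack([np.linspace(-1, 1, 15),
                                 0.2 * rng.standard_normal(15)])
        p = DiscretePath(grids)
        assert action(p, dw, 0.5) == pytest.approx(
            action(p.reversed(), dw, 0.5), rel=1e-12
        )

    def test_positive_gamma_required(self):
        with pytest.raises(ValueError):
            action(arc_path(), analytic_surface("double_well"), 0.0)


class TestTarget:
    def test_uniform_path_has_zero_spacing_penalty(self):
        dw = analytic_surface("double_well")
        p = init_path_linear(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), 20)
        spec = PathSpec(n_grids=20, gamma=0.7, rho=50.0, c_repulsion=0.0)
        t, _ = target(p, dw, spec)
        assert t == pytest.approx(action(p, dw, 0.7), rel=1e-12)

    def test_breaking_spacing_raises_penalty(self):
        dw = analytic_surface("double_well")
        spec = PathSpec(n_grids=20, gamma=0.7, rho=50.0, c_repulsion=0.0)
        p = init_path_linear(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), 20)
        t0, _ = target(p, dw, spec)
        bent = p.grids.copy()
        bent[10] += 0.8 * (bent[11] - bent[10])  # slide grid along the path
        t1, _ = target(DiscretePath(bent), dw, spec)
        assert t1 > t0

    def test_gradient_matches_finite_differences(self, rng):
        dw = analytic_surface("double_well")
        spec = PathSpec(n_grids=12, gamma=0.6, rho=10.0, c_repulsion=0.05)
        grids = np.column_stack([np.linspace(-1, 1, 12),
                                 0.3 * rng.standard_normal(12)])
        path = DiscretePath(grids)
        _, g = target(path, dw, spec)
        h = 1e-6
        num = np.zeros_like(grids)
        for i in range(1, 11):
            for d in range(2):
                up, dn = grids.copy(), grids.copy()
                up[i, d] += h
                dn[i, d] -= h
                num[i, d] = (target(DiscretePath(up), dw, spec)[0]
                             - target(DiscretePath(dn), dw, spec)[0]) / (2 * h)
        assert np.abs(num - g).max() / max(np.abs(num).max(), 1.0) < 1e-5

    def test_endpoint_gradient_zero(self, rng):
        dw = analytic_surface("double_well")
        spec = PathSpec(n_grids=10, gamma=0.6)
        _, g = target(arc_path(10), dw, spec)
        assert np.all(g[0] == 0) and np.all(g[-1] == 0)


class TestOptimizeSdp:
    def test_flat_potential_converges_to_chord(self):
        flat = FlatPotential()
        spec = PathSpec(n_grids=20, gamma=1.0, rho=100.0, c_repulsion=0.0)
        out = optimize_sdp(arc_path(20, height=0.7), flat, spec)
        assert np.abs(out.grids[:, 1]).max() < 1e-4
        np.testing.assert_array_equal(out.grids[0], arc_path(20, 0.7).grids[0])

    def test_double_well_passes_near_saddle(self):
        dw = analytic_surface("double_well")
        saddle = dw.saddles[0]
        spec = PathSpec(n_grids=40, gamma=0.3, rho=50.0)
        out = optimize_sdp(arc_path(40, height=1.0), dw, spec)
        dist = np.linalg.norm(out.grids - saddle, axis=1).min()
        assert dist < 0.05
        u = np.array([dw.energy(g) for g in out.grids])
        i_max = int(np.argmax(u))
        i_saddle = int(np.argmin(np.linalg.norm(out.grids - saddle, axis=1)))
        assert abs(i_max - i_saddle) <= 2

    def test_large_gamma_approaches_chord(self):
        dw = analytic_surface("double_well")
        umax = max(abs(dw.energy(g)) for g in arc_path(30, 1.0).grids)
        spec = PathSpec(n_grids=30, gamma=1e6 * max(umax, 1.0), rho=100.0)
        out = optimize_sdp(arc_path(30, height=1.0), dw, spec)
        assert np.abs(out.grids[:, 1]).max() < 0.02

    def test_dynamic_programming_oracle(self):
        import networkx as nx

        dw = analytic_surface("double_well")
        gamma = 0.5
        lin = np.linspace(-1.3, 1.3, 21)
        xs, ys = np.meshgrid(lin, lin, indexing="ij")
        g = nx.Graph()
        for i in range(21):
            for j in range(21):
                g.add_node((i, j))
        for i in range(21):
            for j in range(21):
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if not (0 <= a < 21 and 0 <= b < 21):
                            continue
                        p = np.array([xs[i, j], ys[i, j]])
                        q = np.array([xs[a, b], ys[a, b]])
                        w = np.exp((dw.energy(p) + dw.energy(q)) / (2 * gamma)) \
                            * np.linalg.norm(q - p)
                        g.add_edge((i, j), (a, b), weight=w)
        start = (np.argmin(np.abs(lin + 1)), np.argmin(np.abs(lin)))
        end = (np.argmin(np.abs(lin - 1)), np.argmin(np.abs(lin)))
        s_lattice = nx.dijkstra_path_length(g, start, end)

        spec = PathSpec(n_grids=40, gamma=gamma, rho=50.0)
        out = optimize_sdp(arc_path(40, height=1.0), dw, spec)
        s_opt = action(out, dw, gamma)
        assert s_opt <= 1.05 * s_lattice

    def test_spacing_uniform_after_optimization(self):
        dw = analytic_surface("double_well")
        spec = PathSpec(n_grids=30, gamma=0.5, rho=50.0)
        out = optimize_sdp(arc_path(30, 1.0), dw, spec)
        assert out.spacing_deviation <= spec.spacing_tol

    def test_rho_monotonically_tightens_spacing(self):
        dw = analytic_surface("double_well")
        devs = []
        for rho in (1.0, 30.0, 300.0):
            spec = PathSpec(n_grids=25, gamma=0.5, rho=rho, spacing_tol=10.0)
            out = optimize_sdp(arc_path(25, 1.0), dw, spec)
            devs.append(out.spacing_deviation)
        assert devs[0] >= devs[-1]


class TestBacktracking:
    def test_engineered_form_break_reform(self):
        series = {"contact_a": np.array([0, 0, 1, 1, 0, 1], dtype=bool)}
        report = detect_backtracking(series)
        assert len(report) == 1
        row = report.iloc[0]
        assert (row.formed_at, row.broken_after, row.reformed_at) == (2, 3, 5)

    def test_monotone_formation_no_events(self):
        series = {"contact_a": np.array([0, 0, 1, 1, 1], dtype=bool),
                  "contact_b": np.array([0, 0, 0, 0, 0], dtype=bool)}
        assert len(detect_backtracking(series)) == 0

    def test_two_gaps_two_events(self):
        series = {"c": np.array([1, 0, 1, 0, 1], dtype=bool)}
        report = detect_backtracking(series)
        assert len(report) == 2


class TestProfilePath:
    def test_degenerate_native_path(self, toy_topology, toy_native_map_fixture,
                                    toy_system):
        grids = np.repeat(toy_topology.native_coords.ravel()[None], 5, axis=0)
        path = DiscretePath(grids)
        prof, backtrack = profile_path(path, toy_topology,
                                       toy_native_map_fixture,
                                       potential=toy_system)
        assert len(prof) == 5
        assert prof["Q_f"].nunique() == 1 and prof["Q_f"].iloc[0] == 1.0
        assert prof["Q_interface"].iloc[0] == 1.0
        assert len(backtrack) == 0

    def test_validate_potential_accepts_surfaces(self):
        validate_potential(analytic_surface("double_well"), np.array([0.3, 0.2]))
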