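"""Mutual-repression switch: balance maps, equilibria, scans, dynamics."""
from dataclasses import replace

import numpy as np
import pytest

from yeastcons.bistability import (
    MetabolicLoadParams,
    Model3Params,
    default_switch_params,
    find_equilibria,
    model3_balance,
    scan_gains,
    select_operating_point,
    simulate_switch,
)
from yeastcons.composition import DilutionSchedule, Spike
from yeastcons.species import Signal

OPERATING = {"K1": 10.0, "K2": 10.0 ** 0.5}  # bistable cell of the default scan


def brute_force_equilibria(params, n=2000):
    """Independent oracle: dense log-grid intersection scan of the nullclines."""
    f, g = model3_balance(params)
    a_max = float(g(0.0)) * 1.1
    grid = np.geomspace(a_max * 1e-9, a_max, n)
    h = g(f(grid)) - grid
    sign = np.sign(h)
    roots = []
    for i in range(n - 1):
        if sign[i] * sign[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(80):  # bisection
                mid = np.sqrt(lo * hi)
                if np.sign(g(f(mid)) - mid) == sign[i]:
                    lo = mid
                else:
                    hi = mid
            roots.append(np.sqrt(lo * hi))
    return roots


def random_params(rng, n1_range=(0.3, 4.0), n2_range=(0.3, 2.0)):
    lu = lambda a, b: float(np.exp(rng.uniform(np.log(a), np.log(b))))
    return Model3Params(
        V_A=lu(30, 500), V_I=lu(100, 2000), c_A=rng.uniform(0, 2),
        c_I=rng.uniform(0, 5), th1=lu(5, 500), n1=rng.uniform(*n1_range),
        th2=lu(5, 500), n2=rng.uniform(*n2_range),
        delta_A=lu(0.5, 3), delta_I=lu(0.5, 3),
        gamma_B=lu(1, 10), th_B=lu(5, 500), gamma_G=lu(1, 10), th_G=lu(5, 500),
        K1=lu(0.2, 5), K2=lu(0.2, 5), K3=lu(0.2, 5), K4=lu(0.2, 5),
    )


class TestBalanceMaps:
    def test_asymptotes(self):
        p = default_switch_params()
        f, g = model3_balance(p)
        assert f(0.0) == pytest.approx(p.K1 * (p.c_I + p.V_I) / p.delta_I)
        assert f(1e12) == pytest.approx(
            p.K1 * p.c_I / (p.delta_I + p.K3 * p.gamma_G), rel=1e-3)
        assert g(0.0) == pytest.approx(p.K2 * (p.c_A + p.V_A) / p.delta_A)

    def test_strictly_decreasing(self, rng):
        for _ in range(5):
            p = random_params(rng)
            f, g = model3_balance(p)
            grid = np.geomspace(1e-3, 1e5, 200)
            assert np.all(np.diff(f(grid)) < 0)
            assert np.all(np.diff(g(grid)) < 0)


class TestFindEquilibria:
    def test_unit_hill_coefficients_single_equilibrium_any_gains(self):
        """With n1 = n2 = 1 the circuit is monostable at every stoichiometry."""
        base = replace(default_switch_params(), n1=1.0, n2=1.0)
        gains = np.geomspace(0.1, 10, 5)
        for K1 in gains:
            for K2 in gains:
                for K3 in gains[::2]:
                    for K4 in gains[::2]:
                        p = base.with_gains(K1=float(K1), K2=float(K2),
                                            K3=float(K3), K4=float(K4))
                        assert find_equilibria(p, n_grid=150).n == 1

    def test_symmetric_toggle_three_equilibria(self):
        p = Model3Params(
            V_A=300.0, V_I=300.0, c_A=0.5, c_I=0.5, th1=50.0, n1=3.0,
            th2=50.0, n2=3.0, delta_A=1.0, delta_I=1.0,
            gamma_B=0.0, th_B=100.0, gamma_G=0.0, th_G=100.0,
        )
        eq = find_equilibria(p)
        assert eq.n == 3
        assert eq.stability == ["stable", "unstable", "stable"]

    def test_operating_point_two_stable_one_unstable(self):
        p = default_switch_params().with_gains(**OPERATING)
        eq = find_equilibria(p)
        assert eq.n == 3
        assert sorted(eq.stability) == ["stable", "stable", "unstable"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            p = random_params(rng)
            eq = find_equilibria(p)
            oracle = brute_force_equilibria(p)
            assert eq.n == len(oracle)
            for (a, _), a_ref in zip(eq.points, oracle):
                assert a == pytest.approx(a_ref, rel=1e-2)

    def test_stability_agrees_with_forward_simulation(self):
        p = default_switch_params().with_gains(**OPERATING)
        eq = find_equilibria(p)
        for (a, i), lab in zip(eq.points, eq.stability):
            tc = simulate_switch(p, y0=(a * 1.05, i * 0.95), t_end=40.0,
                                 n_points=41)
            a_end = tc.state("alpha_factor")[-1]
            if lab == "stable":
                assert a_end == pytest.approx(a, rel=0.02)
            else:
                assert abs(a_end / a - 1) > 0.5  # repelled to another state


@pytest.fixture(scope="module")
def default_map():
    grid = np.geomspace(0.1, 10, 9)
    return scan_gains(default_switch_params(), ("K1", "K2"), grid, grid,
                      n_grid=200)


@pytest.fixture(scope="module")
def op_params():
    return default_switch_params().with_gains(**OPERATING)


class TestScanAndSelection:
    def test_default_circuit_has_contiguous_bistable_region(self, default_map):
        mask = default_map.bistable_mask
        assert mask.sum() >= 3
        # flood fill from one bistable cell reaches every bistable cell
        cells = {tuple(c) for c in np.argwhere(mask)}
        stack = [next(iter(cells))]
        seen = set()
        while stack:
            c = stack.pop()
            if c in seen:
                continue
            seen.add(c)
            i, j = c
            for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (i + d[0], j + d[1])
                if nb in cells and nb not in seen:
                    stack.append(nb)
        assert seen == cells

    def test_fold_change_defined_only_in_bistable_cells(self, default_map):
        assert np.all(np.isfinite(default_map.fold_change[default_map.bistable_mask]))
        assert np.all(np.isnan(default_map.fold_change[~default_map.bistable_mask]))
        assert np.all(default_map.n_equilibria >= 1)

    def test_operating_point_maximizes_stable_separation(self, default_map):
        op = select_operating_point(default_map)
        # exhaustive check over bistable cells
        def separation(gains):
            eq = find_equilibria(default_switch_params().with_gains(**gains))
            (a1, i1), (a2, i2) = eq.stable_points
            return np.hypot(np.log(a1) - np.log(a2), np.log(i1) - np.log(i2))
        best = max(
            ({"K1": float(default_map.grid_x[i]), "K2": float(default_map.grid_y[j])}
             for i, j in np.argwhere(default_map.bistable_mask)),
            key=separation)
        assert separation(op) == pytest.approx(separation(best), rel=1e-9)

    def test_broken_arm_degenerates_to_monostable(self):
        p = replace(default_switch_params(), gamma_G=0.0, K1=1e-3)
        grid = np.geomspace(0.1, 10, 4)
        m = scan_gains(p, ("K2", "K4"), grid, grid, n_grid=150)
        assert not m.bistable_mask.any()

    def test_monostable_map_selection_fails(self):
        base = replace(default_switch_params(), n1=1.0, n2=1.0)
        grid = np.geomspace(0.5, 2, 3)
        m = scan_gains(base, ("K1", "K2"), grid, grid, n_grid=150)
        with pytest.raises(ValueError, match="no bistable cell"):
            select_operating_point(m)


class TestSimulateSwitch:
    def test_stays_at_each_stable_equilibrium(self, op_params, iaa_sensor):
        eq = find_equilibria(op_params)
        for a, i in eq.stable_points:
            tc = simulate_switch(op_params, y0=(a, i), sensor=iaa_sensor,
                                 t_end=30.0, n_points=31)
            assert tc.state("alpha_factor")[-1] == pytest.approx(a, rel=1e-3)
            assert tc.state("auxin")[-1] == pytest.approx(i, rel=1e-3)

    def test_dynamic_equilibria_match_steady_state_model(self, op_params):
        """With no load and no dilution, relaxation endpoints coincide with
        the nullcline fixed points (within 1%)."""
        eq = find_equilibria(op_params)
        hi = max(eq.stable_points, key=lambda q: q[0])
        tc = simulate_switch(op_params, y0=(hi[0] * 1.3, hi[1]), t_end=50.0,
                             n_points=26)
        assert tc.state("alpha_factor")[-1] == pytest.approx(hi[0], rel=0.01)
        assert tc.state("auxin")[-1] == pytest.approx(hi[1], rel=0.01)

    def test_stimulus_protocol_toggles_twice(self, op_params, iaa_sensor):
        """Auxin spike at 3 h then alpha-factor spike at 15 h: two persistent
        state switches, each outlasting the decaying stimulus."""
        eq = find_equilibria(op_params)
        mid_a = [a for (a, _), s in zip(eq.points, eq.stability)
                 if s == "unstable"][0]
        dil = DilutionSchedule(period=2 / 3, retention=1 / 3)
        stim = [Spike(3.0, Signal.AUXIN, 5000.0),
                Spike(15.0, Signal.ALPHA_FACTOR, 1000.0)]
        tc = simulate_switch(op_params, stimuli=stim, dilution=dil,
                             sensor=iaa_sensor, t_end=30.0, n_points=301)
        a = tc.state("alpha_factor")
        lo_a, hi_a = min(p[0] for p in eq.stable_points), max(p[0] for p in eq.stable_points)
        # state at key times: high-A initially, low-A after auxin, high-A after alpha
        for t, want_high in [(2.5, True), (12.0, False), (14.5, False), (29.0, True)]:
            j = np.argmin(np.abs(tc.t - t))
            if want_high:
                assert a[j] > mid_a
            else:
                assert a[j] < mid_a
        # stimuli have decayed below sensor-relevant levels before each check
        assert tc.state("auxin_exo")[np.argmin(np.abs(tc.t - 12.0))] < 1.0
        assert tc.state("alpha_factor_exo")[-1] < 1.0

    def test_metabolic_load_destabilizes_high_state(self, op_params, iaa_sensor):
        eq = find_equilibria(op_params)
        hi = max(eq.stable_points, key=lambda q: q[0])
        mid_i = [i for (_, i), s in zip(eq.points, eq.stability)
                 if s == "unstable"][0]
        for rho, lost in [(0.0, False), (0.5, True)]:
            load = MetabolicLoadParams(rho=rho) if rho else None
            tc = simulate_switch(op_params, load=load, sensor=iaa_sensor,
                                 y0=hi, t_end=40.0, n_points=81)
            crossed = np.any(tc.state("auxin") > mid_i)
            assert crossed == lost, f"rho={rho}"

    def test_rho_bounds_validated(self):
        with pytest.raises(ValueError):
            MetabolicLoadParams(rho=1.5)
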