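"""Pricing, weight optimization, pruning, annealing and the DAO loop."""

from dataclasses import dataclass

import numpy as np
import pytest
from scipy import optimize

from mbrtplan.beams import Field, make_scenario_set, nominal_only
from mbrtplan.dao import (
    Aperture,
    AperturePool,
    DAOConfig,
    _Evaluator,
    aperture_unit_dose,
    beamlet_prices,
    best_aperture_for_field,
    kkt_residuals,
    optimize_weights,
    prune_zero,
    run_hybrid_dao,
    simulated_annealing,
)
from mbrtplan.objective import ObjectiveFunction, ObjectiveSpec, ObjectiveTerm

from conftest import sphere_structure, tiny_influence, water_grid


@dataclass
class _FakeInfluence:
    fields: list


def brute_force_best_aperture(jaw_rect, prices):
    """Exhaustive enumeration of all per-row contiguous intervals."""
    r0, r1, c0, c1 = jaw_rect
    ncols = c1 - c0
    grid = prices.reshape(r1 - r0, ncols)
    rows, total = [], 0.0
    for k in range(r1 - r0):
        best, best_iv = 0.0, None
        for left in range(ncols):
            for right in range(left + 1, ncols + 1):
                s = grid[k, left:right].sum()
                if s < best:
                    best, best_iv = s, (c0 + left, c0 + right)
        rows.append(best_iv)
        total += best
    return rows, total


class TestPricing:
    def test_hand_row_interval(self):
        f = Field("f", "photon", 6.0, 0.0, n_rows=1, n_cols=5)
        prices = np.array([-1.0, 2.0, -3.0, -1.0, 4.0])
        ap, total = best_aperture_for_field(0, _FakeInfluence([f]), prices)
        assert ap.rows == [(2, 4)]
        assert total == pytest.approx(-4.0)

    def test_all_positive_prices_close_all_rows(self):
        f = Field("f", "photon", 6.0, 0.0, n_rows=3, n_cols=4)
        ap, total = best_aperture_for_field(0, _FakeInfluence([f]), np.abs(np.arange(12)) + 1.0)
        assert ap.is_closed and total == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_4x6(self, seed):
        rng = np.random.default_rng(seed)
        f = Field("f", "photon", 6.0, 0.0, n_rows=4, n_cols=6)
        prices = rng.normal(0, 1, 24)
        ap, total = best_aperture_for_field(0, _FakeInfluence([f]), prices)
        rows, expected = brute_force_best_aperture(f.jaw_rect, prices)
        assert ap.rows == rows
        assert total == pytest.approx(expected, abs=1e-12)

    def test_aperture_price_equals_weight_derivative_at_zero(self, tiny_case):
        grid, structures = tiny_case
        ss = make_scenario_set(5.0, ("LR",))
        infl = tiny_influence(grid, structures, scenarios=ss)
        spec = ObjectiveSpec(
            [ObjectiveTerm("ctv", "min_dose", 60.0, 10.0), ObjectiveTerm("oar", "max_dose", 5.0, 5.0)],
            60.0,
            "ctv",
        )
        objfn = ObjectiveFunction(spec, infl.voxels.structure_index)
        ev = _Evaluator(objfn, ss)
        pool = AperturePool(len(ss), infl.voxels.n)
        # seed the pool so gradients are informative
        ap0 = Aperture(0, "ph0", [(1, 5)] * 6, 10.0)
        pool.add(ap0, aperture_unit_dose(infl, ap0))
        prices = beamlet_prices(pool, infl, ev)

        cand = Aperture(1, "el0", [(2, 4), None, (0, 6), None, None, (3, 5)], 0.0)
        price = prices[1][cand.open_beamlets(infl.fields[1].jaw_rect)].sum()
        ud = aperture_unit_dose(infl, cand)
        eps = 1e-4
        f_p = ev.value(pool.dose + eps * ud)
        f_m = ev.value(pool.dose - eps * ud)
        fd = (f_p - f_m) / (2 * eps)
        assert price == pytest.approx(fd, rel=1e-6)

    def test_zero_gradient_zero_prices(self, tiny_case):
        grid, structures = tiny_case
        infl = tiny_influence(grid, structures)
        spec = ObjectiveSpec([ObjectiveTerm("oar", "max_dose", 50.0, 1.0)], 60.0, "ctv")
        objfn = ObjectiveFunction(spec, infl.voxels.structure_index)
        ev = _Evaluator(objfn, None)
        pool = AperturePool(1, infl.voxels.n)  # zero dose, below every cap
        prices = beamlet_prices(pool, infl, ev)
        assert all(np.all(p == 0.0) for p in prices)


def _random_convex_pool(rng, n_ap, n_vox):
    """Pool with random unit doses + a convex min/max/mean objective."""
    pool = AperturePool(1, n_vox)
    for a in range(n_ap):
        ud = rng.uniform(0, 1, (1, n_vox)) * rng.uniform(0.3, 1.0)
        pool.add(Aperture(0, "f", [(0, 1)], float(rng.uniform(0, 2))), ud)
    pool.recompute_dose()
    half = n_vox // 2
    spec = ObjectiveSpec(
        [
            ObjectiveTerm("t", "min_dose", 1.0, 10.0),
            ObjectiveTerm("t", "max_dose", 1.1, 5.0),
            ObjectiveTerm("o", "mean_dose_upper", 0.15, 3.0),
            ObjectiveTerm("o", "max_dose", 0.5, 2.0),
        ],
        1.0,
        "t",
    )
    idx = {"t": np.arange(half), "o": np.arange(half, n_vox)}
    ev = _Evaluator(ObjectiveFunction(spec, idx), None)
    return pool, ev


class TestOptimizeWeights:
    def test_single_aperture_matches_golden_section(self):
        rng = np.random.default_rng(0)
        pool, ev = _random_convex_pool(rng, 1, 50)
        ud = pool.unit_dose[0]
        oracle = optimize.minimize_scalar(
            lambda w: ev.value(w * ud), bounds=(0.0, 50.0), method="bounded",
            options={"xatol": 1e-10},
        )
        cfg = DAOConfig(weight_tol=1e-8, weight_maxiter=500)
        optimize_weights(pool, ev, cfg)
        assert ev.value(pool.dose) == pytest.approx(oracle.fun, rel=1e-4, abs=1e-12)
        assert pool.weights[0] == pytest.approx(max(oracle.x, 0.0), rel=1e-3, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_convex_solver(self, seed):
        rng = np.random.default_rng(seed)
        pool, ev = _random_convex_pool(rng, 5, 200)
        cfg = DAOConfig(weight_tol=1e-8, weight_maxiter=1000)
        optimize_weights(pool, ev, cfg)
        ours = ev.value(pool.dose)
        arr = np.stack(pool.unit_dose)

        def fun(w):
            return ev.value(np.tensordot(w, arr, axes=(0, 0)))

        best = np.inf
        for x0 in (np.zeros(5), np.ones(5), rng.uniform(0, 2, 5)):
            res = optimize.minimize(
                fun, x0, method="SLSQP", bounds=[(0.0, None)] * 5,
                options={"maxiter": 500, "ftol": 1e-14},
            )
            best = min(best, res.fun)
        assert ours == pytest.approx(best, rel=1e-6, abs=1e-10)
        # KKT: gradient ~0 on active weights, >= 0 on zero weights
        g = kkt_residuals(pool, ev)
        w = pool.weights
        scale = max(1.0, np.abs(g).max())
        assert np.all(np.abs(g[w > 1e-10]) <= 1e-6 * scale)
        assert np.all(g[w <= 1e-10] >= -1e-6 * scale)

    def test_no_dose_in_term_structures_keeps_zero_weights(self):
        pool = AperturePool(1, 30)
        ud = np.zeros((1, 30))
        ud[0, 25:] = 1.0  # dose only outside the term structures
        pool.add(Aperture(0, "f", [(0, 1)], 0.0), ud)
        spec = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 0.0, 1.0)], 1.0, "t")
        ev = _Evaluator(ObjectiveFunction(spec, {"t": np.arange(10)}), None)
        f0 = ev.value(pool.dose)
        optimize_weights(pool, ev, DAOConfig())
        assert np.all(pool.weights == 0.0)
        assert ev.value(pool.dose) == f0


class TestPruneZero:
    def _pool(self, weights):
        pool = AperturePool(1, 4)
        rng = np.random.default_rng(1)
        for i, w in enumerate(weights):
            pool.add(Aperture(0, "f", [(0, 1)], w), rng.uniform(0, 1, (1, 4)))
        pool.recompute_dose()
        return pool

    def test_all_positive_unchanged(self):
        pool = self._pool([1.0, 0.5])
        prune_zero(pool)
        assert len(pool) == 2

    def test_exact_zero_removed_objective_preserved(self):
        pool = self._pool([1.0, 0.0])
        d_before = pool.dose.copy()
        prune_zero(pool)
        assert len(pool) == 1
        assert np.allclose(pool.dose, d_before, atol=1e-12)

    def test_relative_eps_rule(self):
        pool = self._pool([1.0, 1e-12])
        prune_zero(pool)
        assert len(pool) == 1


def _toy_single_row_setup():
    """One field, one MLC row, three beamlets; best shape is known."""
    grid = water_grid(n=10, spacing=5.0)
    target = sphere_structure(grid, (0, 0, 0), 11.0, "ctv", "target")
    from mbrtplan.geometry import Structure

    body = Structure("body", np.ones(grid.shape, bool), "body")
    f = Field("f", "photon", 6.0, 0.0, n_rows=1, n_cols=3)
    infl = tiny_influence(grid, [body, target], fields=[f])
    spec = ObjectiveSpec([ObjectiveTerm("ctv", "min_dose", 1.0, 10.0)], 1.0, "ctv")
    ev = _Evaluator(ObjectiveFunction(spec, infl.voxels.structure_index), None)
    return infl, ev


class TestSimulatedAnnealing:
    def test_greedy_never_worsens(self):
        infl, ev = _toy_single_row_setup()
        pool = AperturePool(1, infl.voxels.n)
        ap = Aperture(0, "f", [(0, 1)], 1.0)
        pool.add(ap, aperture_unit_dose(infl, ap))
        f_in = ev.value(pool.dose)
        cfg = DAOConfig(sa_t0=0.0, sa_moves_per_temp=30, sa_n_temps=5, seed=3)
        simulated_annealing(pool, infl, ev, cfg, np.random.default_rng(3))
        assert ev.value(pool.dose) <= f_in

    def test_fixed_seed_bit_identical(self, tiny_case):
        grid, structures = tiny_case
        infl = tiny_influence(grid, structures)
        spec = ObjectiveSpec([ObjectiveTerm("ctv", "min_dose", 30.0, 10.0)], 60.0, "ctv")
        ev = _Evaluator(ObjectiveFunction(spec, infl.voxels.structure_index), None)
        results = []
        for _ in range(2):
            pool = AperturePool(1, infl.voxels.n)
            ap = Aperture(0, "ph0", [(1, 4)] * 6, 5.0)
            pool.add(ap, aperture_unit_dose(infl, ap))
            cfg = DAOConfig(sa_moves_per_temp=15, sa_n_temps=5, seed=11)
            simulated_annealing(pool, infl, ev, cfg, np.random.default_rng(11))
            results.append((pool.apertures[0].rows, pool.apertures[0].weight, pool.dose.copy()))
        assert results[0][0] == results[1][0]
        assert results[0][1] == results[1][1]
        assert np.array_equal(results[0][2], results[1][2])

    def test_finds_exhaustive_neighborhood_optimum(self):
        infl, ev = _toy_single_row_setup()
        # enumerate all single-interval shapes at fixed weight
        best_f, best_rows = np.inf, None
        w = 1.0
        for left in range(3):
            for right in range(left + 1, 4):
                ap = Aperture(0, "f", [(left, right)], w)
                f_val = ev.value(w * aperture_unit_dose(infl, ap))
                if f_val < best_f:
                    best_f, best_rows = f_val, [(left, right)]
        pool = AperturePool(1, infl.voxels.n)
        ap = Aperture(0, "f", [(0, 1)], w)
        pool.add(ap, aperture_unit_dose(infl, ap))
        cfg = DAOConfig(sa_t0=0.05 * best_f, sa_moves_per_temp=40, sa_n_temps=10,
                        sa_p_shape=1.0, seed=5)
        simulated_annealing(pool, infl, ev, cfg, np.random.default_rng(5))
        assert ev.value(pool.dose) == pytest.approx(best_f, rel=1e-9)
        assert pool.apertures[0].rows == best_rows


def _two_field_case():
    grid = water_grid(n=14, spacing=5.0)
    from mbrtplan.geometry import Structure

    target = sphere_structure(grid, (0, 0, 0), 12.0, "ctv", "target")
    body = Structure("body", np.ones(grid.shape, bool), "body")
    fields = [
        Field("good", "photon", 6.0, 0.0, n_rows=4, n_cols=4),
        Field("el", "electron", 6.0, 180.0, n_rows=4, n_cols=4, ssd_mm=723.0),
    ]
    infl = tiny_influence(grid, [body, target], fields=fields)
    spec = ObjectiveSpec([ObjectiveTerm("ctv", "min_dose", 1.0, 10.0)], 1.0, "ctv")
    return infl, spec


class TestDaoLoop:
    def test_budget_zero_returns_empty_plan(self):
        infl, spec = _two_field_case()
        pool, log = run_hybrid_dao(infl, spec, None, DAOConfig(n_apertures_target=0))
        assert len(pool) == 0
        assert log[0]["objective"] == pytest.approx(
            ObjectiveFunction(spec, infl.voxels.structure_index).value(
                np.zeros(infl.voxels.n)
            )
        )

    def test_single_aperture_equals_enumeration_oracle(self):
        infl, spec = _two_field_case()
        cfg = DAOConfig(n_apertures_target=1, sa_n_temps=0, weight_tol=1e-8, seed=2)
        pool, log = run_hybrid_dao(infl, spec, None, cfg)
        assert len(pool) == 1

        # oracle: for each field's priced aperture, optimize its single weight
        objfn = ObjectiveFunction(spec, infl.voxels.structure_index)
        ev = _Evaluator(objfn, None)
        empty = AperturePool(1, infl.voxels.n)
        prices = beamlet_prices(empty, infl, ev)
        best = np.inf
        for f in range(2):
            ap, total = best_aperture_for_field(f, infl, prices[f])
            if total >= 0:
                continue
            ud = aperture_unit_dose(infl, ap)
            res = optimize.minimize_scalar(
                lambda w: ev.value(w * ud), bounds=(0, 1e4), method="bounded",
                options={"xatol": 1e-12},
            )
            best = min(best, res.fun)
        assert ev.value(pool.dose) == pytest.approx(best, rel=1e-4)

    def test_log_objective_non_increasing(self):
        infl, spec = _two_field_case()
        cfg = DAOConfig(n_apertures_target=4, sa_moves_per_temp=8, sa_n_temps=4, seed=0)
        pool, log = run_hybrid_dao(infl, spec, None, cfg)
        f_seq = [r["objective"] for r in log]
        assert all(f_seq[i + 1] <= f_seq[i] + 1e-9 for i in range(len(f_seq) - 1))

    def test_modality_blind_decision_prefers_better_field(self):
        # the anterior photon field covers the central target far better
        # than a 6 MeV posterior electron field (range 30 mm < depth)
        infl, spec = _two_field_case()
        cfg = DAOConfig(n_apertures_target=1, sa_n_temps=0, seed=0)
        pool, log = run_hybrid_dao(infl, spec, None, cfg)
        assert pool.apertures[0].field_id == "good"

    def test_nominal_only_robust_path_bit_identical_to_plain(self):
        infl, spec = _two_field_case()
        cfg = DAOConfig(n_apertures_target=3, sa_moves_per_temp=10, sa_n_temps=3, seed=7)
        pool_plain, log_plain = run_hybrid_dao(infl, spec, None, cfg)
        pool_rob, log_rob = run_hybrid_dao(infl, spec, nominal_only(), cfg)
        assert [a.rows for a in pool_plain.apertures] == [a.rows for a in pool_rob.apertures]
        assert np.array_equal(pool_plain.weights, pool_rob.weights)
        assert np.array_equal(pool_plain.dose, pool_rob.dose)
        assert [r["objective"] for r in log_plain] == [r["objective"] for r in log_rob]
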