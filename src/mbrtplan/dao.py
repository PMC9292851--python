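"""Hybrid direct aperture optimization: column generation + simulated annealing.

Starting from an empty aperture pool, each outer iteration

1. prices every beamlet of every field at the current pool dose (price =
   gradient of the robust objective with respect to an aperture weight at
   weight zero),
2. builds the most promising deliverable aperture for every field (per MLC
   row, the contiguous open interval of most negative summed price),
3. adds each candidate to a copy of the pool and runs deterministic
   non-negative weight optimization, zero-weight pruning, simulated
   annealing over aperture shapes and weights, and a second weight
   optimization on that copy,
4. keeps the candidate pool with the lowest robust objective (decision) and
   discards the rest,

until the aperture budget is reached or no field offers a negative-price
aperture.  Photon and electron fields pass through the identical code path;
the optimizer sees only dose-influence columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .beams import DoseInfluence, ScenarioSet
from .objective import ObjectiveFunction, ObjectiveSpec


@dataclass
class Aperture:
    """Per-row contiguous MLC openings over one field's beamlet grid.

    ``rows[k]`` is ``None`` (row closed) or a half-open column interval
    ``(left, right)`` in absolute jaw column indices; row ``k`` is jaw row
    ``r0 + k``.  ``weight`` is the relative MU.
    """

    field_index: int
    field_id: str
    rows: list[tuple[int, int] | None]
    weight: float = 0.0

    def open_beamlets(self, jaw_rect: tuple[int, int, int, int]) -> np.ndarray:
        """Beamlet indices (row-major within the jaws) open in this aperture."""
        r0, r1, c0, c1 = jaw_rect
        ncols = c1 - c0
        out = []
        for k, interval in enumerate(self.rows):
            if interval is None:
                continue
            left, right = interval
            if not (c0 <= left < right <= c1):
                raise ValueError("open interval outside jaws")
            out.extend(range(k * ncols + (left - c0), k * ncols + (right - c0)))
        return np.asarray(out, dtype=np.int64)

    @property
    def is_closed(self) -> bool:
        return all(r is None for r in self.rows)


@dataclass
class DAOConfig:
    """Aperture budget, annealing schedule and weight-optimization knobs."""

    n_apertures_target: int = 20
    sa_t0: float | None = None  # None: calibrated from a random move
    sa_alpha: float = 0.95
    sa_moves_per_temp: int = 20
    sa_n_temps: int = 30
    sa_sigma: float = 0.1
    sa_p_shape: float = 0.5
    weight_tol: float = 1e-6
    weight_maxiter: int = 300
    dv_refresh_passes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sa_alpha < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.n_apertures_target < 0:
            raise ValueError("aperture budget must be >= 0")


class _Evaluator:
    """Robust or plain objective over stacked per-scenario doses.

    With ``scenarios=None`` this is the non-robust path (plain objective on
    the single nominal dose).  With a nominal-only ScenarioSet the robust
    path reduces to the same numbers bit-for-bit, which is what ties the
    two modes together.
    """

    def __init__(self, objfn: ObjectiveFunction, scenarios: ScenarioSet | None):
        self.objfn = objfn
        self.scenarios = scenarios
        self.n_scen = 1 if scenarios is None else len(scenarios)

    def value(self, doses: np.ndarray, frozen=None) -> float:
        if self.scenarios is None:
            return self.objfn.value(doses[0], frozen)
        vals = self.objfn.value_many(doses, frozen)
        return float(self.scenarios.importance @ vals)

    def gradients(self, doses: np.ndarray, frozen=None) -> list[np.ndarray]:
        """Per-scenario voxel gradients, scaled by scenario importance."""
        return list(self.gradient_stack(doses, frozen))

    def gradient_stack(self, doses: np.ndarray, frozen=None) -> np.ndarray:
        """(n_scen, n_vox) importance-scaled gradient array in one pass."""
        g = self.objfn.gradient_many(doses[: self.n_scen], frozen)
        if self.scenarios is not None:
            g *= self.scenarios.importance[:, None]
        return g


class AperturePool:
    """Ordered apertures with cached per-scenario unit and total dose."""

    def __init__(self, n_scen: int, n_vox: int):
        self.apertures: list[Aperture] = []
        self.unit_dose: list[np.ndarray] = []  # (n_scen, n_vox) per aperture
        self.dose = np.zeros((n_scen, n_vox))

    def __len__(self) -> int:
        return len(self.apertures)

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.weight for a in self.apertures])

    def copy(self) -> "AperturePool":
        new = AperturePool(*self.dose.shape)
        new.apertures = [replace(a, rows=list(a.rows)) for a in self.apertures]
        new.unit_dose = list(self.unit_dose)  # unit doses replaced, not mutated
        new.dose = self.dose.copy()
        return new

    def add(self, aperture: Aperture, unit_dose: np.ndarray) -> None:
        self.apertures.append(aperture)
        self.unit_dose.append(unit_dose)
        if aperture.weight != 0.0:
            self.dose += aperture.weight * unit_dose

    def set_weights(self, w: np.ndarray) -> None:
        for a, wi in zip(self.apertures, w):
            a.weight = float(wi)
        self.recompute_dose()

    def recompute_dose(self) -> None:
        self.dose = np.zeros_like(self.dose)
        for a, ud in zip(self.apertures, self.unit_dose):
            if a.weight != 0.0:
                self.dose += a.weight * ud


def aperture_unit_dose(
    influence: DoseInfluence, aperture: Aperture, n_scen: int | None = None
) -> np.ndarray:
    """Per-scenario dose (n_scen, n_vox) of one aperture at unit weight.

    ``n_scen`` limits the computation to the first scenarios of the
    influence (1 for the non-robust path); default: all scenarios.
    """
    f = aperture.field_index
    jaw = influence.fields[f].jaw_rect
    open_b = aperture.open_beamlets(jaw)
    if n_scen is None:
        n_scen = len(influence.scenarios)
    out = np.zeros((n_scen, influence.voxels.n))
    if open_b.size == 0:
        return out
    for s in range(n_scen):
        out[s] = np.asarray(
            influence.matrix(f, s)[:, open_b].sum(axis=1)
        ).ravel()
    return out


# ---------------------------------------------------------------------------
# pricing
# ---------------------------------------------------------------------------

def beamlet_prices(
    pool: AperturePool, influence: DoseInfluence, ev: _Evaluator
) -> list[np.ndarray]:
    """Per-field beamlet prices at the current pool dose.

    The price of beamlet b in field f is the derivative of the robust
    objective with respect to the weight of an aperture opening only b,
    evaluated at weight zero: sum_s importance_s * (g_s . d_{f,b,s}).
    """
    grads = ev.gradients(pool.dose)
    prices = []
    for f in range(len(influence.fields)):
        p = np.zeros(influence.fields[f].n_beamlets)
        for s, g in enumerate(grads):
            p += influence.matrix(f, s).T @ g
        prices.append(p)
    return prices


def _best_interval_min_sum(row: np.ndarray) -> tuple[float, int, int]:
    """Minimum-sum contiguous subarray (Kadane); returns (sum, left, right))."""
    best = np.inf
    best_l = best_r = 0
    cur = 0.0
    cur_l = 0
    for j, x in enumerate(row):
        if cur > 0.0:
            cur = x
            cur_l = j
        else:
            cur += x
        if cur < best:
            best = cur
            best_l, best_r = cur_l, j + 1
    return best, best_l, best_r


def best_aperture_for_field(
    field_index: int, influence: DoseInfluence, prices: np.ndarray
) -> tuple[Aperture, float]:
    """Most promising deliverable aperture of one field, and its price.

    Rows are independent: each opens the contiguous interval minimizing its
    summed price, or stays closed when no interval is negative.  The
    returned aperture therefore attains the minimum total price over all
    single-interval-per-row apertures of the field.
    """
    fld = influence.fields[field_index]
    r0, r1, c0, c1 = fld.jaw_rect
    ncols = c1 - c0
    grid = prices.reshape(r1 - r0, ncols)
    rows: list[tuple[int, int] | None] = []
    total = 0.0
    for k in range(r1 - r0):
        s, left, right = _best_interval_min_sum(grid[k])
        if s < 0.0:
            rows.append((c0 + left, c0 + right))
            total += s
        else:
            rows.append(None)
    return Aperture(field_index, fld.id, rows, 0.0), total


# ---------------------------------------------------------------------------
# deterministic weight optimization
# ---------------------------------------------------------------------------

def optimize_weights(
    pool: AperturePool, ev: _Evaluator, cfg: DAOConfig
) -> AperturePool:
    """Non-negative weights minimizing the robust objective (in place).

    Bounded L-BFGS-B on the cone w >= 0 with the analytic gradient.  Active
    sets of dose-volume terms are frozen during each pass and refreshed
    between passes, so each inner problem is smooth and convex and the
    whole step is deterministic.  The pool's objective never increases: the
    incumbent weights are kept if the solver fails to improve.
    """
    if len(pool) == 0:
        return pool
    arr = np.stack(pool.unit_dose)  # (n_ap, n_scen, n_vox)
    w0 = np.maximum(pool.weights, 0.0)
    f_in = ev.value(pool.dose)

    has_dv = any(t.kind == "dose_volume_upper" for t, _ in ev.objfn._terms)
    passes = cfg.dv_refresh_passes if has_dv else 1
    w_cur = w0
    for _ in range(passes):
        doses_cur = np.tensordot(w_cur, arr, axes=(0, 0))
        frozen = ev.objfn.freeze_dv(doses_cur) if has_dv else None

        def fun(w):
            doses = np.tensordot(w, arr, axes=(0, 0))
            val = ev.value(doses, frozen)
            g_stack = ev.gradient_stack(doses, frozen)  # importance included
            gw = np.einsum("asv,sv->a", arr, g_stack)
            return val, gw

        res = optimize.minimize(
            fun,
            w_cur,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * len(w_cur),
            options={
                "maxiter": cfg.weight_maxiter,
                "ftol": 1e-16,
                "gtol": cfg.weight_tol * 1e-2,
            },
        )
        w_new = np.maximum(res.x, 0.0)
        if not has_dv:
            w_cur = w_new
            break
        if np.allclose(w_new, w_cur, rtol=1e-10, atol=1e-12):
            w_cur = w_new
            break
        w_cur = w_new

    doses = np.tensordot(w_cur, arr, axes=(0, 0))
    f_out = ev.value(doses)
    if f_out <= f_in + 1e-12:
        pool.set_weights(w_cur)
    # else: keep incumbent weights (monotonicity guarantee)
    return pool


def kkt_residuals(pool: AperturePool, ev: _Evaluator) -> np.ndarray:
    """Weight-space gradient at the current weights (for KKT checks)."""
    arr = np.stack(pool.unit_dose)
    return np.einsum("asv,sv->a", arr, ev.gradient_stack(pool.dose))


def prune_zero(pool: AperturePool, eps: float | None = None) -> AperturePool:
    """Drop apertures with (near-)zero weight; refresh the cached dose."""
    if len(pool) == 0:
        return pool
    w = pool.weights
    if eps is None:
        eps = 1e-8 * (w.max() if w.max() > 0 else 1.0)
    keep = [i for i, wi in enumerate(w) if wi > eps]
    if len(keep) < len(pool):
        pool.apertures = [pool.apertures[i] for i in keep]
        pool.unit_dose = [pool.unit_dose[i] for i in keep]
        pool.recompute_dose()
    return pool


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

def _random_move(pool: AperturePool, influence: DoseInfluence, cfg: DAOConfig, rng):
    """Propose a move; returns (kind, payload) or None if nothing to move.

    Shape move: shift one leaf edge by one column (which may open a closed
    row by one beamlet or close a one-beamlet row).  Weight move: multiply
    one aperture weight by exp(N(0, sigma)).
    """
    if len(pool) == 0:
        return None
    ai = int(rng.integers(len(pool)))
    ap = pool.apertures[ai]
    fld = influence.fields[ap.field_index]
    r0, r1, c0, c1 = fld.jaw_rect
    if c1 - c0 < 1 or r1 - r0 < 1:
        raise ValueError("field has empty jaws")
    if rng.random() < cfg.sa_p_shape:
        k = int(rng.integers(len(ap.rows)))
        interval = ap.rows[k]
        ncols = c1 - c0
        if interval is None:
            j = c0 + int(rng.integers(ncols))
            return ("shape", ai, k, (j, j + 1), +1, k * ncols + (j - c0))
        left, right = interval
        # candidate edge moves: (new_interval, +1/-1 beamlet, changed column)
        moves = []
        if left - 1 >= c0:
            moves.append(((left - 1, right), +1, left - 1))
        if left + 1 <= right:  # shrink from the left; may close the row
            moves.append((None if left + 1 == right else (left + 1, right), -1, left))
        if right + 1 <= c1:
            moves.append(((left, right + 1), +1, right))
        if right - 1 >= left:  # shrink from the right; may close the row
            moves.append((None if right - 1 == left else (left, right - 1), -1, right - 1))
        new_interval, delta, col = moves[int(rng.integers(len(moves)))]
        return ("shape", ai, k, new_interval, delta, k * ncols + (col - c0))
    factor = float(np.exp(rng.normal(0.0, cfg.sa_sigma)))
    return ("weight", ai, factor)


def _calibrate_t0(pool, influence, ev, cfg, rng) -> float:
    """T0 = 0.5 * |dF| of a calibration random move from the initial state."""
    f0 = ev.value(pool.dose)
    for _ in range(10):
        mv = _random_move(pool, influence, cfg, rng)
        if mv is None:
            break
        df = abs(_move_delta_value(pool, influence, ev, mv)[0] - f0)
        if df > 0:
            return 0.5 * df
    return max(1e-6 * max(f0, 1.0), 1e-12)


def _move_delta_value(pool, influence, ev, mv):
    """Trial objective and dose delta of a proposed move (state unchanged)."""
    if mv[0] == "weight":
        _, ai, factor = mv
        w_old = pool.apertures[ai].weight
        delta = (factor - 1.0) * w_old
        trial_dose = pool.dose + delta * pool.unit_dose[ai]
        return ev.value(trial_dose), ("weight", ai, w_old * factor)
    _, ai, k, new_interval, sign, beamlet = mv
    ap = pool.apertures[ai]
    col_dose = _beamlet_column(influence, ap.field_index, beamlet, ev.n_scen)
    trial_dose = pool.dose + sign * ap.weight * col_dose
    return ev.value(trial_dose), ("shape", ai, k, new_interval, sign, col_dose)


def _beamlet_column(
    influence: DoseInfluence, field_index: int, beamlet: int, n_scen: int | None = None
) -> np.ndarray:
    col = influence.beamlet_column(field_index, beamlet)
    return col if n_scen is None else col[:n_scen]


def simulated_annealing(
    pool: AperturePool,
    influence: DoseInfluence,
    ev: _Evaluator,
    cfg: DAOConfig,
    rng: np.random.Generator,
) -> AperturePool:
    """Metropolis refinement of aperture shapes and weights (in place).

    Accepts improving moves always, worsening moves with probability
    exp(-dF/T); geometric cooling T <- alpha*T.  Returns the best-visited
    state, so the objective never increases over the input pool.
    """
    if len(pool) == 0:
        return pool
    f_cur = ev.value(pool.dose)
    t = cfg.sa_t0 if cfg.sa_t0 is not None else _calibrate_t0(pool, influence, ev, cfg, rng)
    best_f = f_cur
    best_state = _snapshot(pool)
    accepted = 0
    proposed = 0
    for _ in range(cfg.sa_n_temps):
        for _ in range(cfg.sa_moves_per_temp):
            mv = _random_move(pool, influence, cfg, rng)
            if mv is None:
                continue
            proposed += 1
            f_trial, apply = _move_delta_value(pool, influence, ev, mv)
            df = f_trial - f_cur
            accept = df <= 0.0 or (t > 0.0 and rng.random() < np.exp(-df / t))
            if not accept:
                continue
            accepted += 1
            if apply[0] == "weight":
                _, ai, w_new = apply
                ap = pool.apertures[ai]
                pool.dose += (w_new - ap.weight) * pool.unit_dose[ai]
                ap.weight = w_new
            else:
                _, ai, k, new_interval, sign, col_dose = apply
                ap = pool.apertures[ai]
                ap.rows[k] = new_interval
                pool.unit_dose[ai] = pool.unit_dose[ai] + sign * col_dose
                pool.dose += sign * ap.weight * col_dose
            f_cur = f_trial
            if f_cur < best_f:
                best_f = f_cur
                best_state = _snapshot(pool)
        t *= cfg.sa_alpha
    _restore(pool, best_state)
    pool.sa_acceptance_rate = accepted / proposed if proposed else 0.0
    return pool


def _snapshot(pool: AperturePool):
    return (
        [replace(a, rows=list(a.rows)) for a in pool.apertures],
        [ud.copy() for ud in pool.unit_dose],
        pool.dose.copy(),
    )


def _restore(pool: AperturePool, state) -> None:
    pool.apertures, pool.unit_dose, pool.dose = (
        [replace(a, rows=list(a.rows)) for a in state[0]],
        list(state[1]),
        state[2].copy(),
    )


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def dao_iteration(
    pool: AperturePool,
    influence: DoseInfluence,
    ev: _Evaluator,
    cfg: DAOConfig,
    iteration: int,
) -> tuple[AperturePool, bool, dict]:
    """One pricing / multi-pool / decision step.

    Returns (selected pool, converged flag, log record).  Ties between
    candidate pools break toward the earlier field in configuration order.
    """
    prices = beamlet_prices(pool, influence, ev)
    candidates = []
    for f in range(len(influence.fields)):
        ap, total_price = best_aperture_for_field(f, influence, prices[f])
        if total_price < 0.0 and not ap.is_closed:
            candidates.append((f, ap))
    if not candidates:
        return pool, True, {"iteration": iteration, "converged": True}

    best_pool = None
    best_f = np.inf
    best_field = None
    best_rate = 0.0
    for f, ap in candidates:
        trial = pool.copy()
        trial.add(ap, aperture_unit_dose(influence, ap, ev.n_scen))
        optimize_weights(trial, ev, cfg)
        prune_zero(trial)
        rng = np.random.default_rng([cfg.seed, iteration, f])
        simulated_annealing(trial, influence, ev, cfg, rng)
        optimize_weights(trial, ev, cfg)
        f_trial = ev.value(trial.dose)
        if f_trial < best_f:
            best_f = f_trial
            best_pool = trial
            best_field = influence.fields[f].id
            best_rate = getattr(trial, "sa_acceptance_rate", 0.0)
    record = {
        "iteration": iteration,
        "objective": best_f,
        "n_apertures": len(best_pool),
        "chosen_field": best_field,
        "sa_acceptance_rate": best_rate,
        "converged": False,
    }
    return best_pool, False, record


def run_hybrid_dao(
    influence: DoseInfluence,
    spec: ObjectiveSpec,
    scenarios: ScenarioSet | None,
    cfg: DAOConfig,
) -> tuple[AperturePool, list[dict]]:
    """Full hybrid DAO loop from the empty pool to the aperture budget.

    ``scenarios=None`` runs the plain (non-robust) objective on the nominal
    scenario; a ScenarioSet runs the scenario-expectation robust objective.
    Returns the final pool and the per-iteration objective log (the logged
    objective sequence is non-increasing).
    """
    if scenarios is not None and len(scenarios) != len(influence.scenarios):
        raise ValueError("scenario set does not match the dose influence")
    objfn = ObjectiveFunction(spec, influence.voxels.structure_index)
    ev = _Evaluator(objfn, scenarios)
    pool = AperturePool(ev.n_scen, influence.voxels.n)
    log: list[dict] = [
        {
            "iteration": 0,
            "objective": ev.value(pool.dose),
            "n_apertures": 0,
            "chosen_field": None,
            "sa_acceptance_rate": 0.0,
            "converged": False,
        }
    ]
    it = 0
    while len(pool) < cfg.n_apertures_target:
        it += 1
        pool, converged, record = dao_iteration(pool, influence, ev, cfg, it)
        if converged:
            log.append({**record, "objective": ev.value(pool.dose), "n_apertures": len(pool)})
            break
        log.append(record)
    return pool, log
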