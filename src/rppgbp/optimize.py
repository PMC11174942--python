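"""Hybrid Nelder-Mead / particle-swarm optimizer and the calibration
driver that fits the empirical pressure parameters per BMI stratum.

The hybrid maintains 3N+1 particles for an N-dimensional problem. Each
iteration the particles are sorted by objective value and split into the
N best, the (N+1)th, and the 2N worst. The N best are preserved
untouched; one Nelder-Mead iteration on the simplex formed by the best
N+1 positions produces an updated (N+1)th particle; the particle-swarm
velocity/position update is then applied, but written back only to the
2N worst particles. Keeping the simplex's local refinement coupled to
the swarm's global exploration makes the hybrid markedly faster than
plain PSO on smooth low-dimensional calibration problems while retaining
its robustness to local minima.

Everything minimises; fitness for the calibration task is the RMSE of
the pressure formula's predictions against the reference readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .bp import (
    BMIInterval,
    BPParams,
    Kind,
    ParamTable,
    SubjectRecord,
    estimate_bp,
)
from .errors import DegenerateInputError, InvalidArgumentError, UnderdeterminedError

__all__ = ["NMPSOConfig", "Simplex", "nm_step", "pso_update", "SwarmState",
           "nmpso_optimize", "pso_optimize", "OptimizeResult",
           "fit_bp_params", "build_param_table"]


@dataclass(frozen=True)
class NMPSOConfig:
    """Hybrid optimizer settings.

    Defaults follow the standard configuration for this hybrid:
    reflection alpha=1, expansion gamma=2, contraction beta=0.5,
    acceleration c1=c2=1.5, inertia w=0.5, 100 iterations, and a search
    box of [0, 120] per dimension. ``v_max`` clamps the velocity
    magnitude per dimension (``v_min`` is a minimum speed, 0 = none):
    a one-sided velocity clamp would forbid downhill moves inside the
    box. The particle count is 3N+1 by construction (10 for N=3).
    """

    alpha: float = 1.0
    gamma: float = 2.0
    beta: float = 0.5
    delta: float = 0.5          # shrink coefficient (classical value)
    c1: float = 1.5
    c2: float = 1.5
    w: float = 0.5
    n_iter: int = 100
    v_max: float = 120.0
    v_min: float = 0.0
    x_min: float = 0.0
    x_max: float = 120.0
    nm_steps_per_iter: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.alpha > 0):
            raise InvalidArgumentError("alpha must be positive")
        if not (self.gamma > 1):
            raise InvalidArgumentError("gamma must exceed 1")
        if not (0 < self.beta < 1):
            raise InvalidArgumentError("beta must be in (0, 1)")
        if not (0 < self.delta < 1):
            raise InvalidArgumentError("delta must be in (0, 1)")
        if self.n_iter < 1:
            raise InvalidArgumentError("n_iter must be >= 1")
        if not (self.x_min < self.x_max):
            raise InvalidArgumentError("x_min must be below x_max")
        if self.v_min < 0 or self.v_max <= 0 or self.v_min > self.v_max:
            raise InvalidArgumentError("need 0 <= v_min <= v_max, v_max > 0")
        if self.nm_steps_per_iter < 1:
            raise InvalidArgumentError("nm_steps_per_iter must be >= 1")


# ---------------------------------------------------------------- Nelder-Mead


@dataclass
class Simplex:
    """N+1 points ordered by objective value (best first).

    Exposes the classical roles: P_low = points[0], P_sec_hi =
    points[-2], P_high = points[-1], and the centroid of all points
    except P_high.
    """

    points: np.ndarray   # (N+1, N)
    values: np.ndarray   # (N+1,)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.points.shape
        if m != n + 1:
            raise InvalidArgumentError(f"simplex in R^{n} needs {n + 1} points, got {m}")
        if self.values.shape != (m,):
            raise InvalidArgumentError("one value per point required")
        self.sort()

    def sort(self) -> None:
        order = np.argsort(self.values, kind="stable")
        self.points = self.points[order]
        self.values = self.values[order]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        """Centroid of all points except the worst."""
        return self.points[:-1].mean(axis=0)

    def is_degenerate(self, rtol: float = 1e-12) -> bool:
        span = self.points[1:] - self.points[0]
        scale = max(np.abs(span).max(), 1.0)
        return np.linalg.matrix_rank(span, tol=rtol * scale) < self.dim

    @classmethod
    def from_points(cls, points: np.ndarray, f: Callable[[np.ndarray], float]) -> "Simplex":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return cls(points, np.array([f(p) for p in points], dtype=float))


def nm_step(simplex: Simplex, f: Callable[[np.ndarray], float],
            config: NMPSOConfig = NMPSOConfig(),
            bounds: tuple[float, float] | None = None) -> Simplex:
    """One Nelder-Mead iteration: reflect, then expand / accept /
    contract / shrink by the classical decision tree.

    With ``bounds`` given, every trial point is projected onto the box
    before evaluation, so the decision tree operates on the constrained
    landscape (a post-hoc clip of an infeasible winner would discard the
    move that justified accepting it). The best point only moves during
    a shrink (toward itself, i.e. not at all), so the best value never
    worsens.
    """
    if simplex.is_degenerate():
        raise DegenerateInputError("simplex points are affinely dependent")
    alpha, gamma, beta, delta = config.alpha, config.gamma, config.beta, config.delta
    prj = (lambda p: np.clip(p, bounds[0], bounds[1])) if bounds else (lambda p: p)
    pts = simplex.points.copy()
    vals = simplex.values.copy()
    p_cent = pts[:-1].mean(axis=0)
    p_high = pts[-1]
    f_low, f_sec_hi, f_high = vals[0], vals[-2], vals[-1]

    p_ref = prj(p_cent + alpha * (p_cent - p_high))
    f_ref = f(p_ref)

    if f_ref < f_low:
        p_exp = prj(p_cent + gamma * (p_ref - p_cent))
        f_exp = f(p_exp)
        if f_exp < f_ref:
            pts[-1], vals[-1] = p_exp, f_exp
        else:
            pts[-1], vals[-1] = p_ref, f_ref
    elif f_ref < f_sec_hi:
        pts[-1], vals[-1] = p_ref, f_ref
    else:
        if f_ref < f_high:  # outside contraction
            p_con = prj(p_cent + beta * (p_ref - p_cent))
        else:               # inside contraction
            p_con = prj(p_cent + beta * (p_high - p_cent))
        f_con = f(p_con)
        if f_con < min(f_ref, f_high):
            pts[-1], vals[-1] = p_con, f_con
        else:  # shrink toward the best point
            for i in range(1, pts.shape[0]):
                pts[i] = prj(pts[0] + delta * (pts[i] - pts[0]))
                vals[i] = f(pts[i])
    return Simplex(pts, vals)


# ----------------------------------------------------------------------- PSO


@dataclass
class SwarmState:
    """Particle positions/velocities with personal and global bests."""

    x: np.ndarray        # (n_particles, N)
    v: np.ndarray        # (n_particles, N)
    values: np.ndarray   # (n_particles,)
    pbest_x: np.ndarray
    pbest_val: np.ndarray
    gbest_x: np.ndarray
    gbest_val: float
    iteration: int = 0

    @classmethod
    def initialize(cls, f: Callable[[np.ndarray], float], n_particles: int, dim: int,
                   config: NMPSOConfig, rng: np.random.Generator) -> "SwarmState":
        x = rng.uniform(config.x_min, config.x_max, size=(n_particles, dim))
        v = np.zeros((n_particles, dim))
        values = np.array([f(p) for p in x], dtype=float)
        g = int(np.argmin(values))
        return cls(x=x, v=v, values=values, pbest_x=x.copy(), pbest_val=values.copy(),
                   gbest_x=x[g].copy(), gbest_val=float(values[g]))

    def refresh_best(self, idx: np.ndarray | None = None) -> None:
        """Fold current positions into pbest/gbest (for indices idx)."""
        idx = np.arange(self.x.shape[0]) if idx is None else np.asarray(idx)
        improved = self.values[idx] < self.pbest_val[idx]
        upd = idx[improved]
        self.pbest_x[upd] = self.x[upd]
        self.pbest_val[upd] = self.values[upd]
        g = int(np.argmin(self.pbest_val))
        if self.pbest_val[g] < self.gbest_val:
            self.gbest_val = float(self.pbest_val[g])
            self.gbest_x = self.pbest_x[g].copy()


def _clamp_velocity(v: np.ndarray, config: NMPSOConfig) -> np.ndarray:
    v = np.clip(v, -config.v_max, config.v_max)
    if config.v_min > 0:
        small = np.abs(v) < config.v_min
        v = np.where(small, np.sign(v) * config.v_min, v)
    return v


def pso_update(state: SwarmState, config: NMPSOConfig, rng: np.random.Generator,
               f: Callable[[np.ndarray], float],
               mask: np.ndarray | None = None) -> SwarmState:
    """One particle-swarm velocity/position update (in place).

    ``rand1``/``rand2`` are drawn per particle per dimension. When
    ``mask`` is given, randoms are drawn for the whole population (so a
    masked and an unmasked run consume the same stream) but positions,
    velocities and bests are written back only at the masked indices.
    """
    n, dim = state.x.shape
    rand1 = rng.uniform(size=(n, dim))
    rand2 = rng.uniform(size=(n, dim))
    v_new = (config.w * state.v
             + rand1 * config.c1 * (state.pbest_x - state.x)
             + rand2 * config.c2 * (state.gbest_x - state.x))
    v_new = _clamp_velocity(v_new, config)
    x_new = np.clip(state.x + v_new, config.x_min, config.x_max)

    idx = np.arange(n) if mask is None else np.asarray(mask)
    state.v[idx] = v_new[idx]
    state.x[idx] = x_new[idx]
    state.values[idx] = [f(p) for p in state.x[idx]]
    state.refresh_best(idx)
    state.iteration += 1
    return state


# -------------------------------------------------------------------- hybrid


@dataclass(frozen=True)
class OptimizeResult:
    x: np.ndarray
    fun: float
    history: np.ndarray  # gbest value per iteration
    n_iter: int


def _axis_simplex(p0: np.ndarray, f: Callable[[np.ndarray], float],
                  config: NMPSOConfig) -> Simplex:
    """Fresh simplex around ``p0``: one vertex per axis at a 2% box
    step, stepping inward where ``p0`` touches a bound."""
    h = 0.02 * (config.x_max - config.x_min)
    pts = [p0.copy()]
    for d in range(p0.size):
        q = p0.copy()
        q[d] = q[d] + h if q[d] + h <= config.x_max else q[d] - h
        pts.append(q)
    return Simplex.from_points(np.array(pts), f)


def _match_replacement(new_simplex: Simplex, preserved: np.ndarray) -> tuple[np.ndarray, float]:
    """Best point of the NM-updated simplex that is not one of the
    preserved particles (after a shrink several points change; after any
    other move exactly one does)."""
    for p, v in zip(new_simplex.points, new_simplex.values):
        if not any(np.array_equal(p, q) for q in preserved):
            return p.copy(), float(v)
    # Degenerate: simplex collapsed onto preserved points.
    return new_simplex.points[-1].copy(), float(new_simplex.values[-1])


def nmpso_optimize(f: Callable[[np.ndarray], float], N: int,
                   config: NMPSOConfig = NMPSOConfig(),
                   *, use_nm: bool = True) -> OptimizeResult:
    """Minimise ``f`` over the configured box with 3N+1 particles.

    ``use_nm=False`` degrades to plain PSO with the same population and
    random stream, for paired comparisons. Fully deterministic under
    ``config.seed``; the returned history holds the global best value
    after each iteration and is non-increasing.
    """
    if N < 1:
        raise InvalidArgumentError("dimension N must be >= 1")
    n_particles = 3 * N + 1
    rng = np.random.default_rng(config.seed)
    state = SwarmState.initialize(f, n_particles, N, config, rng)
    history = np.empty(config.n_iter)

    for it in range(config.n_iter):
        order = np.argsort(state.values, kind="stable")
        best_idx = order[:N]          # preserved
        mid_idx = int(order[N])       # refined by NM
        worst_idx = order[N + 1:]     # moved by PSO

        if use_nm:
            simplex_pts = state.x[order[:N + 1]]
            simplex = Simplex(simplex_pts, state.values[order[:N + 1]])
            if simplex.is_degenerate():
                # Swarm collapse: restart the simplex around the best
                # point with small axis steps (classical NM restart).
                simplex = _axis_simplex(simplex.points[0], f, config)
            for _ in range(config.nm_steps_per_iter):
                simplex = nm_step(simplex, f, config,
                                  bounds=(config.x_min, config.x_max))
            new_pt, new_val = _match_replacement(simplex, state.x[best_idx])
            state.x[mid_idx] = new_pt
            state.values[mid_idx] = new_val
            state.refresh_best(np.array([mid_idx]))

        pso_update(state, config, rng, f, mask=worst_idx)
        history[it] = state.gbest_val

    return OptimizeResult(x=state.gbest_x.copy(), fun=state.gbest_val,
                          history=history, n_iter=config.n_iter)


def pso_optimize(f: Callable[[np.ndarray], float], N: int,
                 config: NMPSOConfig = NMPSOConfig()) -> OptimizeResult:
    """Plain PSO baseline with the same 3N+1 population."""
    return nmpso_optimize(f, N, config, use_nm=False)


# -------------------------------------------------------------- calibration


def _fitness(records: Sequence[SubjectRecord], kind: Kind) -> Callable[[np.ndarray], float]:
    x = np.array([r.feature(kind) for r in records])
    bmi = np.array([r.bmi for r in records])
    y = np.array([r.reference(kind) for r in records])

    def f(p: np.ndarray) -> float:
        pred = p[0] + p[1] * x + bmi * (1.0 + p[2] * x)
        return float(np.sqrt(np.mean((pred - y) ** 2)))

    return f


#: Iteration budget for calibration fits; raised above the generic
#: default because the RMSE bowl for this model is narrow along the
#: correlated (a1, a2) directions.
FIT_N_ITER = 300


def fit_bp_params(records: Sequence[SubjectRecord], kind: Kind,
                  config: NMPSOConfig | None = None) -> tuple[BPParams, float]:
    """Fit (a0, a1, a2) for one pressure kind by minimising prediction RMSE.

    Returns the fitted parameters and the achieved RMSE (mmHg). The
    search runs inside the configured box (default [0, 120]^3).
    """
    if len(records) < 3:
        raise UnderdeterminedError(
            f"need at least 3 records to fit 3 parameters, got {len(records)}")
    feats = {(r.feature(kind), r.bmi) for r in records}
    if len(feats) < 3:
        raise UnderdeterminedError(
            "records are degenerate: fewer than 3 distinct (feature, BMI) pairs")
    if config is None:
        config = NMPSOConfig(n_iter=FIT_N_ITER)
    f = _fitness(records, kind)
    res = nmpso_optimize(f, 3, config)
    a0, a1, a2 = res.x
    return BPParams(float(a0), float(a1), float(a2), kind), float(res.fun)


def _expand_records(records: Sequence[SubjectRecord], n_groups: int,
                    jitter_frac: float, rng: np.random.Generator
                    ) -> list[list[SubjectRecord]]:
    """Data expansion: bootstrap-resample the stratum's records into
    ``n_groups`` groups, jittering features by Gaussian noise of scale
    ``jitter_frac`` times each feature's range."""
    recs = list(records)
    if jitter_frac == 0:
        # Degenerate expansion: identical copies, so averaging the fits
        # is equivalent to a single fit.
        return [list(recs) for _ in range(n_groups)]
    n = len(recs)
    ranges = {}
    for attr in ("e_peak", "e_valley"):
        vals = np.array([getattr(r, attr) for r in recs])
        ranges[attr] = float(vals.max() - vals.min())
    groups = []
    for _ in range(n_groups):
        idx = rng.integers(0, n, size=n)
        group = []
        for i in idx:
            r = recs[int(i)]
            jp = rng.normal(0.0, jitter_frac * ranges["e_peak"]) if ranges["e_peak"] > 0 else 0.0
            jv = rng.normal(0.0, jitter_frac * ranges["e_valley"]) if ranges["e_valley"] > 0 else 0.0
            group.append(replace(r, e_peak=r.e_peak + jp, e_valley=r.e_valley + jv))
        groups.append(group)
    return groups


def build_param_table(
    cohort: Sequence[SubjectRecord],
    intervals: Sequence[tuple[float, float]],
    expansion_target: int = 20,
    config: NMPSOConfig | None = None,
    *,
    jitter_frac: float = 0.01,
    seed: int = 0,
) -> ParamTable:
    """Fit one (SBP, DBP) parameter pair per BMI stratum.

    Each stratum's records are expanded to ``expansion_target`` groups
    (bootstrap + feature jitter), each group is fitted independently,
    and the fitted triples are averaged component-wise.
    ``expansion_target=1`` uses the stratum's records once, unjittered.
    """
    if expansion_target < 1:
        raise InvalidArgumentError("expansion_target must be >= 1")
    by_interval: dict[tuple[float, float], list[SubjectRecord]] = {
        (lo, hi): [] for (lo, hi) in intervals}
    for r in cohort:
        for (lo, hi) in intervals:
            if lo <= r.bmi < hi:
                by_interval[(lo, hi)].append(r)
                break
    empty = [iv for iv, recs in by_interval.items() if not recs]
    if empty:
        raise InvalidArgumentError(
            f"no cohort records in interval(s) {sorted(empty)}; every stratum needs data")

    rng = np.random.default_rng(seed)
    out = []
    for (lo, hi), recs in sorted(by_interval.items()):
        if expansion_target == 1:
            groups = [list(recs)]
        else:
            groups = _expand_records(recs, expansion_target, jitter_frac, rng)
        fitted = {}
        for kind in ("sbp", "dbp"):
            triples = []
            for group in groups:
                params, _ = fit_bp_params(group, kind, config)
                triples.append(params.as_array())
            mean = np.mean(triples, axis=0)
            fitted[kind] = BPParams(float(mean[0]), float(mean[1]), float(mean[2]), kind)
        out.append(BMIInterval(lo, hi, fitted["sbp"], fitted["dbp"]))
    return ParamTable(out)
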