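"""Multi-stage collocation NLP for maximum batch productivity.

The fermentation time is divided into ``N_K`` finite elements allocated as
evenly as possible over ``N_F`` stages.  Within a stage the fractional
distribution of elementary flux modes ``y_l`` is constant while the total
activity ``a_jk`` (mmol glucose gDCW^-1 h^-1 through all modes) varies per
collocation point.  States are piecewise Lagrange polynomials on a Radau
grid; collocating the dynamics

    dx/dtau = h_l * a_jk * x0_jk * (R^T y_l)

at the interior-plus-right-endpoint nodes, with continuity between elements,
turns the optimal-control problem into a sparse nonlinear program over the
variables ``X`` (state nodes), ``Y`` (mode fractions per stage), ``A``
(activity) and ``h`` (element step length per stage).  The objective is the
volumetric productivity (product formed over total time); path constraints
keep the glucose uptake within its Han-Levenspiel bound and the ATP (and
oxygen) boundary fluxes within maintenance/supply limits, the step lengths
within a factor of ``step_ratio_max`` of each other, and force at least
80% of the initial glucose to be consumed.

The NLP is solved with SLSQP from a deterministic multistart (perturbed mode
fractions), each start seeded by a forward simulation of its policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from batchprod.collocation import CollocationScheme, lagrange_eval, radau_scheme
from batchprod.efm import EFMSet
from batchprod.kinetics import KineticSpec
from batchprod.models import BoundaryMap, ConfigurationError
from batchprod import oracle

logger = logging.getLogger(__name__)

_FEAS_TOL = 1e-6
_MARGIN = 1e-9          # interior margin replacing strict inequalities
_ACTIVITY_CAP = 1e3     # finite stand-in for the open upper bound on A


@dataclass
class VarBounds:
    x_max: float = 1000.0
    y_max: float = 1.0
    a_max: float = _ACTIVITY_CAP
    h_min: float = 0.1
    h_max: float = 30.0


@dataclass
class ProblemSpec:
    """Specification of one batch optimal-control problem."""

    efms: EFMSet
    kinetics: KineticSpec
    x0: Mapping[str, float]
    n_stages: int = 1
    n_elements: int = 20
    degree: int = 5
    var_bounds: VarBounds = field(default_factory=VarBounds)
    step_ratio_max: float = 10.0
    residual_glucose_fraction_max: float = 0.2

    def __post_init__(self) -> None:
        if self.efms.boundary is None:
            raise ConfigurationError("EFMSet must carry a boundary map")
        if len(self.efms) == 0:
            raise ConfigurationError("EFM set is empty")
        if self.n_stages < 1:
            raise ConfigurationError("need at least one fermentation stage")
        if self.n_elements < self.n_stages:
            raise ConfigurationError("need at least one element per stage")

    @property
    def boundary(self) -> BoundaryMap:
        return self.efms.boundary

    @property
    def tracked(self) -> list[str]:
        return self.boundary.tracked

    @property
    def stage_of(self) -> np.ndarray:
        """Element -> stage map; elements divided as evenly as possible."""
        base, rem = divmod(self.n_elements, self.n_stages)
        counts = [base + (1 if l < rem else 0) for l in range(self.n_stages)]
        return np.repeat(np.arange(self.n_stages), counts)


@dataclass
class DecisionVariables:
    X: np.ndarray      # (n_x, N_K, N_D+1) state nodal values
    Y: np.ndarray      # (N_F, N_R) fractional mode expression
    A: np.ndarray      # (N_K, N_D+1) total activity, mmol glc/gDCW/h
    h: np.ndarray      # (N_F,) element step length, h


@dataclass
class BatchSolution:
    variables: DecisionVariables
    t_f: float
    productivity: float           # mM h^-1
    yield_mol: float              # mol product / mol glucose consumed
    titer: float                  # mM
    trajectories: "object"        # pandas DataFrame: t plus tracked species
    solver_status: str            # optimal | infeasible | max_iter
    objective: float
    n_iter: int = 0
    constraint_violation: float = np.nan

    def summary(self) -> dict:
        return {
            "status": self.solver_status,
            "t_f_h": self.t_f,
            "productivity_mM_h": self.productivity,
            "yield_mol_mol": self.yield_mol,
            "titer_mM": self.titer,
        }


def variable_count(n_x: int, n_k: int, n_d: int, n_f: int, n_r: int) -> int:
    """Number of NLP decision variables for the given problem dimensions."""
    return n_x * n_k * (n_d + 1) + n_f * n_r + n_k * (n_d + 1) + n_f


# ---------------------------------------------------------------------------
# NLP assembly
# ---------------------------------------------------------------------------

class CollocationNLP:
    """Flattened variable vector, objective, and constraint callables."""

    def __init__(self, problem: ProblemSpec,
                 objective: str = "productivity",
                 productivity_target: float | None = None):
        self.problem = problem
        p = problem
        self.scheme: CollocationScheme = radau_scheme(p.degree)
        self.tracked = p.tracked
        self.n_x = len(self.tracked)
        self.n_k = p.n_elements
        self.n_d = p.degree
        self.n_f = p.n_stages
        self.n_r = len(p.efms)
        self.stage_of = p.stage_of
        self.objective_kind = objective
        self.productivity_target = productivity_target

        b = p.boundary
        self.i_bio = 0
        self.i_glc = self.tracked.index(b.substrate_species)
        self.i_prod = self.tracked.index(b.product_species)
        self.x0 = np.array([float(p.x0.get(sp, 0.0)) for sp in self.tracked])

        # mode yields for the tracked states; glucose is -1 by normalization
        cols = p.efms.columns
        self.R_track = np.zeros((self.n_r, self.n_x))
        for i, sp in enumerate(self.tracked):
            if sp == b.substrate_species:
                self.R_track[:, i] = -1.0
            elif sp in cols:
                self.R_track[:, i] = p.efms.modes[:, cols.index(sp)]
        self.q_atp = p.efms.col("atp") if "atp" in cols else None
        self.q_o2 = p.efms.col("o2") if "o2" in cols else None

        # species no retained mode can move are constants, not NLP states;
        # keeping them would add degenerate equalities pinned against bounds
        keep = {self.i_bio, self.i_glc, self.i_prod}
        self.act = np.array(sorted(
            keep | {i for i in range(self.n_x)
                    if np.abs(self.R_track[:, i]).max() > 1e-12}))
        self.n_xa = len(self.act)
        self._pos = {int(i): k for k, i in enumerate(self.act)}
        self.ia_bio = self._pos[self.i_bio]
        self.ia_glc = self._pos[self.i_glc]
        self.ia_prod = self._pos[self.i_prod]
        self.R_act = self.R_track[:, self.act]

        # variable scales: mM states by 100, biomass by 1, activity by 10,
        # step length by 10 -- conditioning for the interior-point/SQP solver
        state_scale = np.array(
            [1.0 if b.units_of.get(sp) == "gDCW/L" else 100.0
             for sp in self.tracked])
        self.state_scale = state_scale
        self.state_scale_act = state_scale[self.act]
        nxk = self.n_xa * self.n_k * (self.n_d + 1)
        nak = self.n_k * (self.n_d + 1)
        self.scale = np.concatenate([
            np.repeat(self.state_scale_act, self.n_k * (self.n_d + 1)),
            np.ones(self.n_f * self.n_r),
            np.full(nak, 10.0),
            np.full(self.n_f, 10.0),
        ])
        self._nxk, self._nyr, self._nak = nxk, self.n_f * self.n_r, nak
        vb = p.var_bounds
        lo = np.concatenate([
            np.full(nxk, 0.0),
            np.full(self._nyr, 0.0),
            np.full(nak, _MARGIN),
            np.full(self.n_f, vb.h_min),
        ])
        hi = np.concatenate([
            np.full(nxk, vb.x_max - _MARGIN),
            np.full(self._nyr, vb.y_max),
            np.full(nak, vb.a_max),
            np.full(self.n_f, vb.h_max),
        ])
        # pin the element-0 initial node to x0
        for k in range(self.n_xa):
            j = k * self.n_k * (self.n_d + 1)
            lo[j] = hi[j] = self.x0[self.act[k]]
        self.lo, self.hi = lo, hi
        self.n_vars = len(self.scale)

    # -- packing ---------------------------------------------------------
    def pack(self, dv: DecisionVariables) -> np.ndarray:
        raw = np.concatenate([dv.X[self.act].ravel(), dv.Y.ravel(),
                              dv.A.ravel(), dv.h])
        return raw / self.scale

    def unpack(self, z: np.ndarray) -> DecisionVariables:
        raw = z * self.scale
        nd1 = self.n_d + 1
        X_act = raw[:self._nxk].reshape(self.n_xa, self.n_k, nd1)
        # static species stay at their initial concentration
        X = np.broadcast_to(self.x0[:, None, None],
                            (self.n_x, self.n_k, nd1)).copy()
        X[self.act] = X_act
        Y = raw[self._nxk:self._nxk + self._nyr].reshape(self.n_f, self.n_r)
        A = raw[self._nxk + self._nyr:self._nxk + self._nyr + self._nak
                ].reshape(self.n_k, nd1)
        h = raw[self._nxk + self._nyr + self._nak:]
        return DecisionVariables(X=X, Y=Y, A=A, h=h)

    def bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lo / self.scale, self.hi / self.scale))

    # -- smooth glucose-uptake bound magnitude ---------------------------
    def _uptake_mag(self, X_nodes: np.ndarray) -> np.ndarray:
        """|Han-Levenspiel bound| at every (element, node); smooth clip of
        the inhibition base keeps the NLP differentiable near C*."""
        k = self.problem.kinetics
        b = self.problem.boundary
        x_glc = np.clip(X_nodes[self.i_glc], 0.0, None)
        mag = -k.v_max * x_glc / (x_glc + k.K_s)
        for inh in k.inhibitors:
            if inh.species not in self.tracked:
                continue
            conc = np.clip(X_nodes[self.tracked.index(inh.species)], 0.0, None)
            base = np.clip(1.0 - conc / inh.c_star, 1e-9, None)
            mag = mag * base ** inh.exponent
        return mag

    # -- constraints -----------------------------------------------------
    def eq_constraints(self, z: np.ndarray) -> np.ndarray:
        dv = self.unpack(z)
        Y, A, h = dv.Y, dv.A, dv.h
        X = dv.X[self.act]                             # active states only
        D = self.scheme.diff_matrix
        h_elem = h[self.stage_of]                      # (N_K,)
        Q = Y @ self.R_act                             # (N_F, n_xa)
        Q_elem = Q[self.stage_of]                      # (N_K, n_xa)
        # dynamics residual at k = 1..N_D
        dX = np.einsum("kn,ijn->ijk", D, X)            # (n_xa, N_K, N_D+1)
        rhs = (h_elem[None, :, None] * A[None, :, :]
               * X[self.ia_bio][None, :, :]
               * Q_elem.T[:, :, None])                 # (n_xa, N_K, N_D+1)
        dyn = (rhs - dX)[:, :, 1:] / self.state_scale_act[:, None, None]
        # continuity between elements
        cont = (X[:, :-1, -1] - X[:, 1:, 0]) / self.state_scale_act[:, None]
        # mode fractions sum to one per stage
        ysum = Y.sum(axis=1) - 1.0
        # pin the interpolation-only activity node
        apin = (A[:, 0] - A[:, 1]) / 10.0
        parts = [dyn.ravel(), cont.ravel(), ysum, apin]
        if self.productivity_target is not None:
            T = h_elem.sum()
            gain = X[self.ia_prod, -1, -1] - self.x0[self.i_prod]
            parts.append(np.array([
                (gain - self.productivity_target * T)
                / max(1.0, 10.0 * abs(self.productivity_target))]))
        return np.concatenate(parts)

    def ineq_constraints(self, z: np.ndarray) -> np.ndarray:
        dv = self.unpack(z)
        X, Y, A, h = dv.X, dv.Y, dv.A, dv.h
        p = self.problem
        mag = self._uptake_mag(X)[:, 1:]               # (N_K, N_D)
        uptake = (mag - A[:, 1:]) / 10.0
        parts = [uptake.ravel()]
        Q_elem_atp = None
        if self.q_atp is not None and p.kinetics.atp_maintenance > 0:
            Q_elem_atp = (Y @ self.q_atp)[self.stage_of]     # (N_K,)
            atp = (A[:, 1:] * Q_elem_atp[:, None]
                   - p.kinetics.atp_maintenance) / 5.0
            parts.append(atp.ravel())
        if self.q_o2 is not None:
            o2_min = p.kinetics.oxygen_uptake_max or 0.0
            Q_elem_o2 = (Y @ self.q_o2)[self.stage_of]
            o2 = (A[:, 1:] * Q_elem_o2[:, None] - o2_min) / 10.0
            parts.append(o2.ravel())
        if self.n_f > 1:
            ratio = []
            for l in range(self.n_f):
                for m in range(self.n_f):
                    if l != m:
                        ratio.append(p.step_ratio_max * h[m] - h[l])
            parts.append(np.array(ratio) / 30.0)
        glc_end = X[self.i_glc, -1, -1]
        resid = (p.residual_glucose_fraction_max * self.x0[self.i_glc]
                 - glc_end) / 100.0
        parts.append(np.array([resid]))
        return np.concatenate(parts)

    # -- objectives ------------------------------------------------------
    def total_time(self, z: np.ndarray) -> float:
        dv = self.unpack(z)
        return float(dv.h[self.stage_of].sum())

    def objective(self, z: np.ndarray) -> float:
        dv = self.unpack(z)
        T = dv.h[self.stage_of].sum()
        gain = dv.X[self.i_prod, -1, -1] - self.x0[self.i_prod]
        if self.objective_kind == "productivity":
            return -(gain / T) / 10.0
        if self.objective_kind == "yield":
            consumed = self.x0[self.i_glc] - dv.X[self.i_glc, -1, -1]
            return -gain / max(consumed, 1e-9)
        raise ConfigurationError(f"unknown objective {self.objective_kind!r}")

    def violation(self, z: np.ndarray) -> float:
        eq = np.abs(self.eq_constraints(z)).max(initial=0.0)
        ineq = np.abs(np.minimum(self.ineq_constraints(z), 0.0)).max(initial=0.0)
        return float(max(eq, ineq))


def assemble(problem: ProblemSpec, objective: str = "productivity",
             productivity_target: float | None = None) -> CollocationNLP:
    """Build the collocation NLP for a problem specification."""
    return CollocationNLP(problem, objective=objective,
                          productivity_target=productivity_target)


# ---------------------------------------------------------------------------
# Initial guesses
# ---------------------------------------------------------------------------

def _policy_guess(problem: ProblemSpec, Y: np.ndarray) -> DecisionVariables:
    """Forward-simulate the per-stage policy ``Y`` and sample it onto the
    collocation grid; deterministic for a given problem and policy."""
    p = problem
    nd1 = p.degree + 1
    scheme = radau_scheme(p.degree)
    tracked = p.tracked
    i_glc = tracked.index(p.boundary.substrate_species)
    x0_vec = np.array([float(p.x0.get(sp, 0.0)) for sp in tracked])

    horizon = 200.0
    # equal stage durations over the horizon; trim at 80% consumption
    try:
        strat = oracle.Strategy([
            oracle.StagePolicy(horizon / p.n_stages, Y[l])
            for l in range(p.n_stages)])
        sim = oracle.simulate(strat, p.efms, p.kinetics, p.x0,
                              rtol=1e-6, n_eval_per_stage=300)
        glc = sim.states[:, i_glc]
        target = p.residual_glucose_fraction_max * x0_vec[i_glc]
        hit = np.flatnonzero(glc <= target + 1e-9)
        t_end = float(sim.t[hit[0]]) if len(hit) else horizon / 4.0
        t_end = max(t_end, p.n_elements * p.var_bounds.h_min * 1.01)
        interp = lambda tq: np.array(
            [np.interp(tq, sim.t, sim.states[:, i]) for i in range(len(tracked))])
    except Exception as exc:  # diverging guess simulation: constant fallback
        logger.warning("guess simulation failed (%s); constant-state fallback", exc)
        t_end = p.n_elements * 1.0
        interp = lambda tq: x0_vec.copy()

    h_val = float(np.clip(t_end / p.n_elements, p.var_bounds.h_min,
                          p.var_bounds.h_max))
    h = np.full(p.n_stages, h_val)
    stage_of = p.stage_of
    X = np.zeros((len(tracked), p.n_elements, nd1))
    A = np.zeros((p.n_elements, nd1))
    t_start = 0.0
    for j in range(p.n_elements):
        for k, tau in enumerate(scheme.nodes):
            t_node = t_start + tau * h[stage_of[j]]
            xk = np.clip(interp(t_node), _MARGIN, p.var_bounds.x_max - _MARGIN)
            X[:, j, k] = xk
            xd = dict(zip(tracked, np.clip(xk, 0.0, None)))
            q = dict(zip(p.efms.columns, Y[stage_of[j]] @ p.efms.modes))
            a_min, a_max = oracle._activity_limits(q, xd, p.kinetics,
                                                   p.boundary.substrate_species)
            A[j, k] = np.clip(a_max, _MARGIN, p.var_bounds.a_max)
        t_start += h[stage_of[j]]
    X[:, 0, 0] = x0_vec
    return DecisionVariables(X=X, Y=Y.copy(), A=A, h=h)


def initial_guess(problem: ProblemSpec) -> DecisionVariables:
    """Deterministic default start: uniform mode mix, forward-simulated states."""
    Y = np.full((problem.n_stages, len(problem.efms)),
                1.0 / len(problem.efms))
    return _policy_guess(problem, Y)


def _multistart_policies(problem: ProblemSpec, seeds: Sequence[int]
                         ) -> list[np.ndarray]:
    """Deterministic family of per-stage mode-fraction matrices."""
    n_f, n_r = problem.n_stages, len(problem.efms)
    out = [np.full((n_f, n_r), 1.0 / n_r)]
    # growth-early / product-late heuristic using the mode yield columns
    b = problem.boundary
    cols = problem.efms.columns
    bio = problem.efms.col(b.biomass_species) if b.biomass_species in cols \
        else np.zeros(n_r)
    prod = problem.efms.col(b.product_species)
    Y = np.full((n_f, n_r), 0.05 / max(n_r - 1, 1))
    for l in range(n_f):
        w = 1.0 - l / max(n_f - 1, 1) if n_f > 1 else 0.5
        score = w * bio / max(bio.max(), 1e-12) + (1 - w) * prod / max(prod.max(), 1e-12)
        Y[l, int(np.argmax(score))] = 0.95
        Y[l] /= Y[l].sum()
    out.append(Y)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        out.append(rng.dirichlet(np.ones(n_r), size=n_f))
    return out


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

def _solve_nlp(nlp: CollocationNLP, dv0: DecisionVariables,
               maxiter: int = 250) -> tuple[np.ndarray, bool, int]:
    z0 = np.clip(nlp.pack(dv0), nlp.lo / nlp.scale, nlp.hi / nlp.scale)
    cons = [{"type": "eq", "fun": nlp.eq_constraints},
            {"type": "ineq", "fun": nlp.ineq_constraints}]
    res = minimize(nlp.objective, z0, method="SLSQP", bounds=nlp.bounds(),
                   constraints=cons,
                   options={"maxiter": maxiter, "ftol": 1e-9})
    return res.x, bool(res.success), int(res.nit)


def _solution_from_z(nlp: CollocationNLP, z: np.ndarray, success: bool,
                     n_iter: int) -> BatchSolution:
    import pandas as pd

    p = nlp.problem
    dv = nlp.unpack(z)
    viol = nlp.violation(z)
    feasible = viol <= 1e-5
    status = "optimal" if (success and feasible) else (
        "max_iter" if feasible else "infeasible")
    scheme = nlp.scheme
    h_elem = dv.h[nlp.stage_of]
    rows_t, rows_x = [], []
    t_start = 0.0
    taus = np.linspace(0.0, 1.0, 21)
    for j in range(nlp.n_k):
        vals = lagrange_eval(scheme, dv.X[:, j, :].T, taus)  # (21, n_x)
        rows_t.append(t_start + taus * h_elem[j])
        rows_x.append(vals)
        t_start += h_elem[j]
    t = np.concatenate(rows_t)
    states = np.vstack(rows_x)
    traj = pd.DataFrame({"t_h": t})
    for i, sp in enumerate(nlp.tracked):
        unit = p.boundary.units_of.get(sp, "mM")
        traj[f"{sp}_{unit.replace('/', '_')}"] = states[:, i]
    t_f = float(h_elem.sum())
    gain = float(dv.X[nlp.i_prod, -1, -1] - nlp.x0[nlp.i_prod])
    consumed = float(nlp.x0[nlp.i_glc] - dv.X[nlp.i_glc, -1, -1])
    productivity = gain / t_f if t_f > 0 else 0.0
    return BatchSolution(
        variables=dv, t_f=t_f, productivity=productivity,
        yield_mol=gain / consumed if consumed > 1e-9 else 0.0,
        titer=float(dv.X[nlp.i_prod, -1, -1]),
        trajectories=traj, solver_status=status,
        objective=float(nlp.objective(z)), n_iter=n_iter,
        constraint_violation=viol)


#: deterministic multistart seeds perturbing the mode fractions
MULTISTART_SEEDS = (11, 17, 23)


def solve_max_productivity(problem: ProblemSpec,
                           guess: DecisionVariables | None = None,
                           maxiter: int = 250,
                           seeds: Sequence[int] = MULTISTART_SEEDS
                           ) -> BatchSolution:
    """Maximize batch productivity over the collocation NLP.

    Runs a small deterministic multistart (uniform, growth-early heuristic,
    and Dirichlet-perturbed mode fractions) and returns the best feasible
    local optimum; when every start fails, the least-infeasible iterate is
    returned with its status, never an exception.
    """
    if float(problem.x0.get(problem.boundary.substrate_species, 0.0)) <= 0.0:
        nlp = assemble(problem)
        dv = initial_guess(problem)
        return replace(_solution_from_z(nlp, nlp.pack(dv), False, 0),
                       solver_status="infeasible")
    nlp = assemble(problem)
    starts: list[DecisionVariables] = []
    if guess is not None:
        starts.append(guess)
    else:
        starts.extend(_policy_guess(problem, Y)
                      for Y in _multistart_policies(problem, seeds))
    best: BatchSolution | None = None
    fallback: BatchSolution | None = None
    for dv0 in starts:
        try:
            z, ok, nit = _solve_nlp(nlp, dv0, maxiter=maxiter)
        except Exception as exc:
            logger.warning("solver raised on one start: %s", exc)
            continue
        sol = _solution_from_z(nlp, z, ok, nit)
        if sol.solver_status != "infeasible":
            if best is None or sol.productivity > best.productivity:
                best = sol
        else:
            if fallback is None or sol.constraint_violation < fallback.constraint_violation:
                fallback = sol
    if best is not None:
        return best
    if fallback is not None:
        return fallback
    dv = guess if guess is not None else initial_guess(problem)
    return replace(_solution_from_z(nlp, nlp.pack(dv), False, 0),
                   solver_status="infeasible")


def _embed_solution(problem: ProblemSpec, prev: BatchSolution,
                    prev_problem: ProblemSpec) -> DecisionVariables:
    """Map a solved policy onto a problem with a different stage count."""
    Y_prev = prev.variables.Y
    h_prev = prev.variables.h
    stage_prev = prev_problem.stage_of
    # cumulative time fraction of each previous stage
    t_elem = h_prev[stage_prev]
    t_total = t_elem.sum()
    t_frac = np.cumsum(t_elem) / t_total
    Y = np.zeros((problem.n_stages, Y_prev.shape[1]))
    h = np.zeros(problem.n_stages)
    stage_new = problem.stage_of
    for l in range(problem.n_stages):
        elems = np.flatnonzero(stage_new == l)
        mid = (elems.mean() + 0.5) / problem.n_elements
        prev_elem = int(np.searchsorted(t_frac, mid))
        prev_elem = min(prev_elem, len(stage_prev) - 1)
        Y[l] = Y_prev[stage_prev[prev_elem]]
        h[l] = np.clip(t_total / problem.n_elements,
                       problem.var_bounds.h_min, problem.var_bounds.h_max)
    dv = _policy_guess(problem, Y)
    dv.h[:] = h
    return dv


def stage_sweep(problem: ProblemSpec, stages: Sequence[int],
                maxiter: int = 250) -> list[BatchSolution]:
    """Solve the max-productivity problem for each stage count.

    Each count is warm-started from the previous solution (embedded into the
    refined stage structure) in addition to the default multistart, so the
    reported productivities inherit the feasible-set nesting of stage counts.
    """
    if not stages:
        raise ConfigurationError("stage list is empty")
    out: list[BatchSolution] = []
    prev: tuple[ProblemSpec, BatchSolution] | None = None
    for n_f in stages:
        prob_l = replace(problem, n_stages=n_f)
        sol = solve_max_productivity(prob_l, maxiter=maxiter)
        if prev is not None and prev[1].solver_status != "infeasible":
            try:
                dv0 = _embed_solution(prob_l, prev[1], prev[0])
                warm = solve_max_productivity(prob_l, guess=dv0, maxiter=maxiter)
                if warm.solver_status != "infeasible" and \
                        warm.productivity > sol.productivity:
                    sol = warm
            except Exception as exc:
                logger.warning("warm start across stage counts failed: %s", exc)
        out.append(sol)
        prev = (prob_l, sol)
    return out
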