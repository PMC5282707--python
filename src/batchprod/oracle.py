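"""Independent validation tools: forward ODE simulation and brute force.

The collocation NLP is checked against machinery that shares none of its
discretization: a multi-stage strategy (piecewise-constant mode fractions
with an activity policy) is integrated with an adaptive stiff-capable ODE
solver, and on desk-scale problems the best strategy is located by an
exhaustive grid search with a derivative-free polish.  The module also
builds the toy problems used throughout the test-suite.

Batch dynamics: for boundary concentration x with biomass x_0 (gDCW/L),
``dx_i/dt = v_i(t) x_0(t)`` where the specific exchange rates ``v`` are the
mode-fraction-weighted boundary yields times the total activity ``a``
(mmol glucose gDCW^-1 h^-1).  Glucose is consumed at exactly ``-a x_0``
because modes are normalized per mol of glucose.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from batchprod.efm import EFMSet
from batchprod.kinetics import KineticSpec, glucose_uptake_bound
from batchprod.models import BoundaryMap, ConfigurationError, MetabolicNetwork

logger = logging.getLogger(__name__)

_ATP_TOL = 1e-6


@dataclass
class StagePolicy:
    """One fermentation stage: duration, mode mix, and activity policy.

    ``activity`` is either ``"track_uptake_bound"`` (total flux rides the
    state-dependent maximum glucose uptake), a constant value capped by the
    uptake bound at every instant, or a callable of stage-local time (used to
    replay interpolated activity profiles from the collocation solver).
    """

    duration: float
    mode_fractions: np.ndarray
    activity: Literal["track_uptake_bound"] | float | Callable[[float], float] \
        = "track_uptake_bound"

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"stage duration must be >= 0, got {self.duration}")
        y = np.asarray(self.mode_fractions, dtype=float)
        if y.min() < -1e-12 or abs(y.sum() - 1.0) > 1e-9:
            raise ValueError("mode fractions must be in [0,1] and sum to 1")
        self.mode_fractions = np.clip(y, 0.0, None)


@dataclass
class Strategy:
    stages: list[StagePolicy]

    @property
    def total_time(self) -> float:
        return sum(s.duration for s in self.stages)


@dataclass
class SimResult:
    t: np.ndarray                    # h
    states: np.ndarray               # (n_t, n_tracked)
    tracked: list[str]
    productivity: float              # mM h^-1
    yield_mol: float                 # mol product per mol glucose consumed
    titer: float                     # mM
    feasible: bool
    atp_margin_min: float            # min over time of a*q_atp - maintenance
    atp_margin_t: np.ndarray         # the margin aligned with ``t``
    glucose_consumed_per_stage: np.ndarray

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.tracked, self.states[-1]))


def _mode_rates(efms: EFMSet, y: np.ndarray) -> dict[str, float]:
    """Mode-fraction-weighted boundary yields, one entry per projected column."""
    q = y @ efms.modes
    return dict(zip(efms.columns, q))


def _activity_limits(q: Mapping[str, float], x: Mapping[str, float],
                     kinetics: KineticSpec, substrate: str
                     ) -> tuple[float, float]:
    """Admissible total-activity interval [a_min, a_max] at state ``x``."""
    a_max = abs(glucose_uptake_bound(x, kinetics, substrate=substrate))
    q_o2 = q.get("o2", 0.0)
    if q_o2 < -1e-12:
        if kinetics.oxygen_uptake_max is None:
            a_max = 0.0
        else:
            a_max = min(a_max, kinetics.oxygen_uptake_max / q_o2)
    q_atp = q.get("atp", 0.0)
    if kinetics.atp_maintenance > 0:
        a_min = np.inf if q_atp <= 0 else kinetics.atp_maintenance / q_atp
    else:
        a_min = 0.0
    return a_min, a_max


def simulate(strategy: Strategy, efms: EFMSet, kinetics: KineticSpec,
             x0: Mapping[str, float], rtol: float = 1e-8,
             n_eval_per_stage: int = 200) -> SimResult:
    """Integrate a multi-stage strategy and score it.

    A strategy is infeasible when, at any evaluated instant, the realized
    activity cannot meet the ATP-maintenance (or oxygen) requirement; species
    are floored at zero inside the right-hand side so glucose exhaustion
    flattens the trajectory instead of going negative.
    """
    if efms.boundary is None:
        raise ConfigurationError("EFMSet has no boundary map")
    boundary = efms.boundary
    tracked = boundary.tracked
    substrate = boundary.substrate_species
    product = boundary.product_species
    idx = {sp: i for i, sp in enumerate(tracked)}
    z = np.array([float(x0.get(sp, 0.0)) for sp in tracked])
    i_bio = 0
    i_glc = idx[substrate]

    t_all = [np.array([0.0])]
    states_all = [z[None, :].copy()]
    margin_all = [np.array([np.inf])]
    atp_margin = np.inf
    feasible = True
    glc_per_stage = []
    t_offset = 0.0

    for stage in strategy.stages:
        if stage.duration == 0.0:
            glc_per_stage.append(0.0)
            continue
        y = stage.mode_fractions
        if len(y) != len(efms):
            raise ConfigurationError(
                f"stage has {len(y)} fractions for {len(efms)} modes")
        q = _mode_rates(efms, y)
        rate = np.zeros(len(tracked))
        for sp in tracked:
            rate[idx[sp]] = -1.0 if sp == substrate else q.get(sp, 0.0)

        def activity(x_vec: np.ndarray, t_local: float = 0.0) -> tuple[float, float]:
            xd = {sp: max(x_vec[idx[sp]], 0.0) for sp in tracked}
            a_min, a_max = _activity_limits(q, xd, kinetics, substrate)
            if stage.activity == "track_uptake_bound":
                a = a_max
            elif callable(stage.activity):
                a = max(float(stage.activity(t_local)), 0.0)
            else:
                a = min(float(stage.activity), a_max)
            return a, a * q.get("atp", 0.0) - kinetics.atp_maintenance

        def rhs(t: float, x_vec: np.ndarray) -> np.ndarray:
            a, _ = activity(x_vec, t)
            x_bio = max(x_vec[i_bio], 0.0)
            dx = a * x_bio * rate
            # freeze depletion at zero
            dx[np.asarray(x_vec) <= 0.0] = np.maximum(dx[np.asarray(x_vec) <= 0.0], 0.0)
            return dx

        t_eval = np.linspace(0.0, stage.duration, n_eval_per_stage)
        sol = solve_ivp(rhs, (0.0, stage.duration), z, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        glc_start = z[i_glc]
        z = sol.y[:, -1].copy()
        glc_per_stage.append(glc_start - z[i_glc])
        margins = np.array([activity(col, tk)[1]
                            for tk, col in zip(sol.t, sol.y.T)])
        atp_margin = min(atp_margin, float(margins.min()))
        if atp_margin < -_ATP_TOL:
            feasible = False
        t_all.append(sol.t[1:] + t_offset)
        states_all.append(np.clip(sol.y[:, 1:].T, -0.0, None))
        margin_all.append(margins[1:])
        t_offset += stage.duration

    t = np.concatenate(t_all)
    states = np.vstack(states_all)
    i_prod = idx[product]
    dp = states[-1, i_prod] - states[0, i_prod]
    dg = states[0, i_glc] - states[-1, i_glc]
    tf = t[-1]
    productivity = dp / tf if tf > 0 else 0.0
    yield_mol = dp / dg if dg > 1e-12 else 0.0
    if np.min(states) < -1e-9:
        feasible = False
    return SimResult(t=t, states=states, tracked=tracked,
                     productivity=productivity, yield_mol=yield_mol,
                     titer=float(states[-1, i_prod]), feasible=feasible,
                     atp_margin_min=float(atp_margin) if np.isfinite(atp_margin) else 0.0,
                     atp_margin_t=np.concatenate(margin_all),
                     glucose_consumed_per_stage=np.array(glc_per_stage))


def simulate_solution(problem, solution, rtol: float = 1e-8) -> SimResult:
    """Replay a collocation solution through the adaptive ODE integrator.

    The solved policy (per-stage mode fractions, with the optimized activity
    profile interpolated over each stage) is integrated independently of the
    collocation discretization; agreement of the final states validates the
    transcription.
    """
    from batchprod.collocation import lagrange_eval, radau_scheme

    dv = solution.variables
    scheme = radau_scheme(problem.degree)
    stage_of = problem.stage_of
    stages = []
    t_elem = dv.h[stage_of]
    for l in range(problem.n_stages):
        elems = np.flatnonzero(stage_of == l)
        duration = float(t_elem[elems].sum())
        # piecewise-polynomial activity profile over the stage's elements
        starts = np.concatenate([[0.0], np.cumsum(t_elem[elems])])
        A_stage = dv.A[elems]
        h_l = float(dv.h[l])

        def a_of_t(t_local: float, starts=starts, A_stage=A_stage, h_l=h_l):
            j = int(np.clip(np.searchsorted(starts, t_local, side="right") - 1,
                            0, len(A_stage) - 1))
            tau = np.clip((t_local - starts[j]) / h_l, 0.0, 1.0)
            return float(lagrange_eval(scheme, A_stage[j], tau))

        stages.append(StagePolicy(duration, dv.Y[l], a_of_t))
    strat = Strategy(stages)
    return simulate(strat, problem.efms, problem.kinetics, problem.x0, rtol=rtol)


# ---------------------------------------------------------------------------
# Brute-force strategy search (desk-scale oracle)
# ---------------------------------------------------------------------------

def _simplex_grid(n: int, resolution: int) -> np.ndarray:
    """All fraction vectors of length n on a grid with ``resolution`` steps."""
    pts = []
    for combo in itertools.combinations_with_replacement(range(n), resolution):
        v = np.zeros(n)
        for c in combo:
            v[c] += 1.0 / resolution
        pts.append(v)
    return np.unique(np.round(np.array(pts), 12), axis=0)


def _best_endpoint(sim: SimResult, efms: EFMSet, kinetics: KineticSpec,
                   residual_max: float = 0.2) -> tuple[float, float]:
    """Best (productivity, t_f) along a trajectory honoring the residual-
    glucose constraint and ATP feasibility of the whole prefix."""
    boundary = efms.boundary
    i_glc = sim.tracked.index(boundary.substrate_species)
    i_prod = sim.tracked.index(boundary.product_species)
    glc0 = sim.states[0, i_glc]
    ok = sim.states[:, i_glc] <= residual_max * glc0 + 1e-9
    # feasibility is prefix-wise: the strategy is truncated at t_f
    prefix_ok = np.minimum.accumulate(sim.atp_margin_t) >= -_ATP_TOL
    ok &= prefix_ok
    if not ok.any():
        return -np.inf, np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        prod = (sim.states[:, i_prod] - sim.states[0, i_prod]) / sim.t
    prod[~ok] = -np.inf
    prod[sim.t <= 0] = -np.inf
    k = int(np.argmax(prod))
    return float(prod[k]), float(sim.t[k])


def brute_force_best(efms: EFMSet, kinetics: KineticSpec,
                     x0: Mapping[str, float], n_stages: int = 1,
                     grid: int = 8, horizon: float = 80.0,
                     n_switch: int = 12, polish: bool = True
                     ) -> tuple[float, Strategy | None]:
    """Exhaustive grid search over stage mode-fractions and switch time.

    Deterministic; strategies use the track-uptake-bound activity policy.
    The final time is chosen along each simulated trajectory as the
    productivity-optimal instant among those consuming >= 80% of the initial
    glucose with ATP maintenance satisfied throughout.  A Nelder-Mead polish
    refines the best grid point.  Returns ``(-inf, None)`` when every grid
    point is infeasible.
    """
    if n_stages not in (1, 2):
        raise ValueError("brute_force_best supports 1 or 2 stages")
    if len(efms) > 4:
        raise ValueError("oracle search is limited to <= 4 modes")
    fracs = _simplex_grid(len(efms), grid)
    # adapt the horizon to the batch timescale: pilot run with a uniform mix
    try:
        pilot = simulate(Strategy([StagePolicy(
            horizon, np.full(len(efms), 1.0 / len(efms)))]),
            efms, kinetics, x0, rtol=1e-6, n_eval_per_stage=400)
        boundary = efms.boundary
        i_glc = pilot.tracked.index(boundary.substrate_species)
        glc0 = pilot.states[0, i_glc]
        hit = np.flatnonzero(pilot.states[:, i_glc] <= 0.2 * glc0)
        if len(hit):
            horizon = min(horizon, 2.5 * float(pilot.t[hit[0]]))
    except Exception:
        pass
    best = (-np.inf, None)

    def run(params: np.ndarray) -> tuple[float, Strategy | None]:
        # params: concat of per-stage fraction logits-free weights + switch frac
        if n_stages == 1:
            y1 = _project_simplex(params[:len(efms)])
            strat = Strategy([StagePolicy(horizon, y1)])
        else:
            y1 = _project_simplex(params[:len(efms)])
            y2 = _project_simplex(params[len(efms):2 * len(efms)])
            ts = float(np.clip(params[-1], 0.0, 1.0)) * horizon * 0.8
            strat = Strategy([StagePolicy(ts, y1),
                              StagePolicy(horizon - ts, y2)])
        sim = simulate(strat, efms, kinetics, x0, rtol=1e-8)
        p, tf = _best_endpoint(sim, efms, kinetics)
        if not np.isfinite(p):
            return -np.inf, None
        # truncate the strategy at the optimal endpoint
        stages = []
        remaining = tf
        for s in strat.stages:
            d = min(s.duration, remaining)
            if d > 0:
                stages.append(StagePolicy(d, s.mode_fractions, s.activity))
            remaining -= d
            if remaining <= 0:
                break
        return p, Strategy(stages)

    candidates: list[tuple[float, np.ndarray]] = []
    if n_stages == 1:
        for y in fracs:
            p, s = run(y)
            candidates.append((p, y))
            if p > best[0]:
                best = (p, s)
    else:
        switches = np.linspace(0.0, 1.0, n_switch)
        for y1 in fracs:
            for y2 in fracs:
                for sw in switches:
                    params = np.concatenate([y1, y2, [sw]])
                    p, s = run(params)
                    candidates.append((p, params))
                    if p > best[0]:
                        best = (p, s)
    if best[1] is None:
        return best
    if polish:
        # derivative-free refinement from the best few grid candidates
        candidates.sort(key=lambda c: -c[0])
        for p0, z0 in candidates[:3]:
            if not np.isfinite(p0):
                continue
            res = minimize(lambda z: -run(z)[0], z0, method="Nelder-Mead",
                           options={"maxiter": 200, "xatol": 1e-4,
                                    "fatol": 1e-7})
            p, s = run(res.x)
            if p > best[0]:
                best = (p, s)
    logger.info("oracle best productivity (%d stage): %.6g", n_stages, best[0])
    return best


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, n + 1) > (css - 1))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


# ---------------------------------------------------------------------------
# Toy problems
# ---------------------------------------------------------------------------

def make_toy_problem(name: str) -> tuple[MetabolicNetwork, EFMSet,
                                         KineticSpec, dict[str, float]]:
    """Fully specified desk-scale problems for validation.

    - ``diamond``: two parallel routes from substrate A to product P; used
      for enumeration checks (exactly two modes, both at yield 1).
    - ``growth_vs_product``: two boundary modes, a high-growth/low-product
      mode (biomass 0.04 gDCW/mmol, product 0.2, ATP 1.0 per glucose) and a
      zero-growth/high-product mode (product 1.5, ATP 0.5).
    - ``aerobic_shift``: adds an oxygen-consuming high-growth mode (biomass
      0.08, ATP 2.0, O2 -1.5) to emulate an aerobic-growth-then-anaerobic-
      production switch.
    """
    from batchprod import efm as efm_mod
    from batchprod.models import BoundaryMap, MetabolicNetwork

    if name == "diamond":
        mets = ["A", "B", "C", "P"]
        rxn_ids = ["EX_A", "AB", "AC", "BP", "CP", "EX_P"]
        S = np.array([
            # EX_A  AB  AC  BP  CP  EX_P
            [-1, -1, -1,  0,  0,  0],   # A
            [0,   1,  0, -1,  0,  0],   # B
            [0,   0,  1,  0, -1,  0],   # C
            [0,   0,  0,  1,  1, -1],   # P
        ], dtype=float)
        net = MetabolicNetwork(rxn_ids, mets, S,
                               reversible=np.array([True] + [False] * 5),
                               biomass_id=None, atp_demand_id=None)
        boundary = BoundaryMap(
            species=["P", "A"],
            exchange_of={"P": "EX_P", "A": "EX_A"},
            units_of={"P": "mM", "A": "mM"},
            product_species="P", substrate_species="A")
        full = efm_mod.enumerate_efms(net)
        efms = efm_mod.project_and_normalize(full, boundary)
        kinetics = KineticSpec(v_max=-10.0, K_s=1.0)
        x0 = {"A": 100.0, "P": 0.0}
        return net, efms, kinetics, x0

    if name in ("growth_vs_product", "aerobic_shift"):
        aerobic = name == "aerobic_shift"
        mets = ["glc", "X", "P", "atp", "adp"] + (["o2"] if aerobic else [])
        rxns: list[tuple[str, dict[str, float], bool]] = [
            ("EX_glc", {"glc": -1}, True),
            ("PATH_G", {"glc": -1, "adp": -1.0, "X": 0.04, "P": 0.2, "atp": 1.0}, False),
            ("PATH_P", {"glc": -1, "adp": -0.5, "P": 1.5, "atp": 0.5}, False),
            ("ATPM", {"atp": -1, "adp": 1}, False),
            ("EX_X", {"X": -1}, False),
            ("EX_P", {"P": -1}, False),
        ]
        if aerobic:
            rxns.insert(3, ("PATH_A", {"glc": -1, "o2": -1.5, "adp": -2.0,
                                       "X": 0.08, "atp": 2.0}, False))
            rxns.append(("EX_o2", {"o2": -1}, True))
        mi = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        rxn_ids, rev = [], []
        for j, (rid, st, r) in enumerate(rxns):
            rxn_ids.append(rid)
            rev.append(r)
            for m, c in st.items():
                S[mi[m], j] = c
        net = MetabolicNetwork(rxn_ids, mets, S, reversible=np.array(rev),
                               biomass_id="PATH_G", atp_demand_id="ATPM")
        species = ["X", "atp", "glc", "P"] + (["o2"] if aerobic else [])
        exchange_of = {"X": "EX_X", "atp": "ATPM", "glc": "EX_glc", "P": "EX_P"}
        units_of = {"X": "gDCW/L", "atp": "mmol/gDCW/h", "glc": "mM", "P": "mM"}
        flux_only = {"atp"}
        if aerobic:
            exchange_of["o2"] = "EX_o2"
            units_of["o2"] = "mmol/gDCW/h"
            flux_only.add("o2")
        boundary = BoundaryMap(species=species, exchange_of=exchange_of,
                               units_of=units_of, product_species="P",
                               substrate_species="glc", flux_only=flux_only)
        full = efm_mod.enumerate_efms(net)
        efms = efm_mod.project_and_normalize(full, boundary)
        # deterministic mode order: by descending biomass yield
        order = np.argsort(-efms.col("X"))
        efms = efms.subset([int(i) for i in order])
        kinetics = KineticSpec(
            v_max=-10.0, K_s=1.0, inhibitors=(("P", 800.0, 1.0),),
            atp_maintenance=2.0,
            oxygen_uptake_max=-10.0 if aerobic else None)
        x0 = {"X": 0.05, "glc": 100.0, "P": 0.0}
        return net, efms, kinetics, x0

    raise ValueError(f"unknown toy problem {name!r}")
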