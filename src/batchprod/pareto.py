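"""Productivity-yield Pareto surface by warm-started continuation.

The maximum productivity ``P_max`` is computed once; the NLP is then
re-solved with the product yield (product formed per glucose consumed) as
the objective while the productivity is pinned to ``alpha * P_max`` through
an equality constraint, sweeping ``alpha`` from 1 towards 0 and warm-
starting every solve from its neighbour.  The resulting frontier is the
envelope on which productivity cannot rise without sacrificing yield.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from batchprod.models import ConfigurationError
from batchprod.optimal_control import (
    BatchSolution,
    DecisionVariables,
    ProblemSpec,
    assemble,
    solve_max_productivity,
    _solution_from_z,
    _solve_nlp,
)

logger = logging.getLogger(__name__)

#: molar masses, g/mol, for mass-unit conversion of the surface
MOLAR_MASS = {"glucose": 180.16, "succinate": 118.09}


@dataclass
class ParetoSurface:
    points: pd.DataFrame      # alpha, productivity_mM_h, yield_mol_mol, titer_mM, t_f_h, status
    p_max: float              # mM h^-1, stage-specific maximum productivity

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df["productivity_g_L_h"] = (df["productivity_mM_h"]
                                    * MOLAR_MASS["succinate"] / 1000.0)
        df["yield_g_g"] = (df["yield_mol_mol"]
                           * MOLAR_MASS["succinate"] / MOLAR_MASS["glucose"])
        df.to_csv(path, index=False)


def max_yield_at_productivity(problem: ProblemSpec, alpha: float,
                              p_max: float,
                              guess: DecisionVariables | None = None,
                              maxiter: int = 250) -> BatchSolution:
    """Maximize yield subject to productivity == alpha * p_max.

    All collocation, kinetic-bound, step-ratio and residual-glucose
    constraints of the productivity problem are retained.
    """
    if not 0.0 <= alpha <= 1.0 + 1e-9:
        raise ConfigurationError(f"alpha must be in [0, 1], got {alpha}")
    if p_max <= 0:
        raise ConfigurationError("p_max must be positive")
    nlp = assemble(problem, objective="yield",
                   productivity_target=alpha * p_max)
    if guess is None:
        base = solve_max_productivity(problem, maxiter=maxiter)
        guess = base.variables
    z, ok, nit = _solve_nlp(nlp, guess, maxiter=maxiter)
    return _solution_from_z(nlp, z, ok, nit)


def pareto_surface(problem: ProblemSpec, n_alpha: int = 50,
                   maxiter: int = 250,
                   max_failure_fraction: float = 0.2) -> ParetoSurface:
    """Trace the full yield-productivity frontier over ``n_alpha`` values.

    Sweeps alpha from 1 downward with warm starts (the continuation
    direction that degrades gracefully from the productivity optimum);
    points that fail to converge are flagged by status.  Aborts when more
    than ``max_failure_fraction`` of the points fail.
    """
    if n_alpha < 2:
        raise ConfigurationError("need at least 2 alpha values")
    base = solve_max_productivity(problem, maxiter=maxiter)
    if base.solver_status == "infeasible":
        raise ConfigurationError("maximum-productivity problem is infeasible")
    p_max = base.productivity
    alphas = np.linspace(1.0, 0.0, n_alpha)
    rows = []
    guess = base.variables
    n_failed = 0
    for alpha in alphas:
        if alpha >= 1.0 - 1e-12:
            sol = base  # the constraint pins the productivity optimum
        else:
            sol = max_yield_at_productivity(problem, float(alpha), p_max,
                                            guess=guess, maxiter=maxiter)
        if sol.solver_status == "infeasible":
            # alpha = 0 pins net product formation to zero, which is
            # structurally infeasible whenever every mode makes product;
            # report it but do not count it as a continuation failure
            if alpha > 1e-12:
                n_failed += 1
        else:
            guess = sol.variables
        rows.append({
            "alpha": float(alpha),
            "productivity_mM_h": sol.productivity,
            "yield_mol_mol": sol.yield_mol,
            "titer_mM": sol.titer,
            "t_f_h": sol.t_f,
            "status": sol.solver_status,
            "n_iter": sol.n_iter,
        })
        if n_failed > max_failure_fraction * n_alpha:
            raise RuntimeError(
                f"{n_failed} of {len(rows)} Pareto points failed to converge; "
                "diagnostic bundle: " + repr(rows))
    df = pd.DataFrame(rows).sort_values("alpha").reset_index(drop=True)
    return ParetoSurface(points=df, p_max=p_max)


def compare_to_literature(surface: ParetoSurface, points_csv,
                          tol: float = 0.02) -> pd.DataFrame:
    """Classify experimental productivity/yield points against the surface.

    The CSV needs columns ``productivity_g_L_h``, ``yield_g_g`` and
    ``reference``.  Each point is 'inside' when the frontier (converted to
    mass units) attains at least its yield at its productivity,
    'outside' when it beats the computed envelope, and
    'outside-any-envelope' when its yield exceeds the stoichiometric
    maximum of the surface altogether.
    """
    lit = pd.read_csv(points_csv)
    required = {"productivity_g_L_h", "yield_g_g"}
    missing = required - set(lit.columns)
    if missing:
        raise ConfigurationError(f"literature CSV missing columns {missing}")
    conv_p = MOLAR_MASS["succinate"] / 1000.0
    conv_y = MOLAR_MASS["succinate"] / MOLAR_MASS["glucose"]
    surf = surface.points[surface.points["status"] != "infeasible"]
    sp = (surf["productivity_mM_h"] * conv_p).to_numpy()
    sy = (surf["yield_mol_mol"] * conv_y).to_numpy()
    order = np.argsort(sp)
    sp, sy = sp[order], sy[order]
    y_stoich_max = sy.max()
    labels = []
    for _, row in lit.iterrows():
        p, y = float(row["productivity_g_L_h"]), float(row["yield_g_g"])
        if y > y_stoich_max + tol:
            labels.append("outside-any-envelope")
            continue
        if p > sp.max() + tol:
            labels.append("outside")
            continue
        y_front = float(np.interp(p, sp, sy))
        labels.append("inside" if y <= y_front + tol else "outside")
    out = lit.copy()
    out["classification"] = labels
    return out
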