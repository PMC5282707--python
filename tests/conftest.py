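"""Shared fixtures: packaged networks, toy problems, and cached NLP solves.

Solving the collocation NLP is the expensive step, so solutions used by
several tests (solver-vs-oracle, re-simulation, monotonicity, stage-effect)
are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import batchprod as bp
from batchprod.optimal_control import ProblemSpec, solve_max_productivity, stage_sweep

# desk-scale discretization used throughout the suite
N_ELEMENTS = 6
DEGREE = 3


@pytest.fixture(scope="session")
def a_succ():
    net, boundary = bp.load_fixture("a_succinogenes_core")
    return net, boundary


@pytest.fixture(scope="session")
def a_succ_reduced(a_succ):
    net, boundary = a_succ
    full = bp.enumerate_efms(net)
    reduced, counts = bp.efm.reduce_modes(full, boundary)
    return full, reduced, counts


@pytest.fixture(scope="session")
def a_succ_formulas():
    """Carbon bookkeeping for the core fixture; cofactor pairs carry zero
    carbon so that conserved moieties cancel."""
    f = {m: {"C": c} for m, c in {
        "glc": 6, "pep": 3, "pyr": 3, "accoa": 2, "oaa": 4, "mal": 4,
        "fum": 4, "succ": 4, "cit": 6, "icit": 6, "akg": 5, "for": 1,
        "ac": 2, "co2": 1, "atp": 0, "adp": 0, "nad": 0, "nadh": 0,
        "biomass": 34}.items()}
    return f


@pytest.fixture(scope="session")
def toy_gv():
    net, efms, kinetics, x0 = bp.make_toy_problem("growth_vs_product")
    return net, efms, kinetics, x0


@pytest.fixture(scope="session")
def toy_aerobic():
    net, efms, kinetics, x0 = bp.make_toy_problem("aerobic_shift")
    return net, efms, kinetics, x0


def _problem(efms, kinetics, x0, n_stages):
    return ProblemSpec(efms=efms, kinetics=kinetics, x0=x0,
                       n_stages=n_stages, n_elements=N_ELEMENTS, degree=DEGREE)


@pytest.fixture(scope="session")
def gv_problems(toy_gv):
    _, efms, kinetics, x0 = toy_gv
    return {nf: _problem(efms, kinetics, x0, nf) for nf in (1, 2)}


@pytest.fixture(scope="session")
def gv_solutions(gv_problems):
    return {nf: solve_max_productivity(p) for nf, p in gv_problems.items()}


@pytest.fixture(scope="session")
def aerobic_problems(toy_aerobic):
    _, efms, kinetics, x0 = toy_aerobic
    return {nf: _problem(efms, kinetics, x0, nf) for nf in (1, 2, 3)}


@pytest.fixture(scope="session")
def aerobic_sweep(aerobic_problems):
    base = aerobic_problems[1]
    sols = stage_sweep(base, [1, 2, 3])
    return dict(zip([1, 2, 3], sols))


@pytest.fixture(scope="session")
def gv_oracle(toy_gv):
    _, efms, kinetics, x0 = toy_gv
    return {
        1: bp.brute_force_best(efms, kinetics, x0, n_stages=1),
        2: bp.brute_force_best(efms, kinetics, x0, n_stages=2,
                               grid=6, n_switch=10),
    }


@pytest.fixture(scope="session")
def aerobic_oracle(toy_aerobic):
    _, efms, kinetics, x0 = toy_aerobic
    return {
        1: bp.brute_force_best(efms, kinetics, x0, n_stages=1, grid=6),
        2: bp.brute_force_best(efms, kinetics, x0, n_stages=2,
                               grid=4, n_switch=8),
    }


@pytest.fixture(scope="session")
def a_succ_problem(a_succ_reduced):
    _, reduced, _ = a_succ_reduced
    kinetics = bp.preset("a_succinogenes")
    x0 = {"biomass": 0.05, "glc": 100.0}
    return _problem(reduced, kinetics, x0, 3)


@pytest.fixture(scope="session")
def a_succ_solution(a_succ_problem):
    return solve_max_productivity(a_succ_problem, maxiter=400)
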