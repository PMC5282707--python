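"""Stoichiometric model container, I/O, balance checking, and growth calibration.

A metabolic network is stored as a metabolites x reactions stoichiometric
matrix ``S`` so that the steady-state condition reads ``S v = 0`` for a flux
vector ``v`` indexed by reactions.  Exchange reactions cross the system
boundary and touch exactly one metabolite; by convention their flux is
negative for uptake and positive for secretion.

Two file formats are supported: SBML Level 3 (read through cobra) and a small
explicit JSON dialect used for the packaged fixtures.  The JSON dialect spells
out reversibility and the boundary map instead of relying on SBML
annotations, and round-trips the stoichiometric matrix exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

_LARGE_BOUND = 1000.0


class FormatError(ValueError):
    """Raised when a model file cannot be parsed into a network."""


class ConfigurationError(ValueError):
    """Raised when a network is structurally unusable for the method."""


class CalibrationError(ValueError):
    """Raised when the requested biomass yield cannot be reached."""

    def __init__(self, message: str, max_achievable: float | None = None):
        super().__init__(message)
        self.max_achievable = max_achievable


@dataclass
class MetabolicNetwork:
    """A stoichiometric model with exchange and biomass bookkeeping.

    ``stoich`` has one row per metabolite and one column per reaction, so the
    pseudo-steady-state condition is literally ``stoich @ v == 0``.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    stoich: np.ndarray
    reversible: np.ndarray
    biomass_id: str | None = None
    atp_demand_id: str | None = None

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        n_met, n_rxn = self.stoich.shape
        if n_met != len(self.metabolite_ids) or n_rxn != len(self.reaction_ids):
            raise ConfigurationError(
                f"stoichiometry shape {self.stoich.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x "
                f"{len(self.reaction_ids)} reactions"
            )
        if self.biomass_id is not None and self.biomass_id not in self.reaction_ids:
            raise ConfigurationError(f"biomass reaction {self.biomass_id!r} not in model")
        if self.atp_demand_id is not None and self.atp_demand_id not in self.reaction_ids:
            raise ConfigurationError(f"ATP demand reaction {self.atp_demand_id!r} not in model")

    # -- indexing helpers -------------------------------------------------
    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise ConfigurationError(f"reaction {rxn_id!r} not in model") from None

    def met_index(self, met_id: str) -> int:
        try:
            return self.metabolite_ids.index(met_id)
        except ValueError:
            raise ConfigurationError(f"metabolite {met_id!r} not in model") from None

    @property
    def exchange_ids(self) -> list[str]:
        """Reactions that touch exactly one metabolite (boundary crossings)."""
        out = []
        for j, rid in enumerate(self.reaction_ids):
            col = self.stoich[:, j]
            if np.count_nonzero(col) == 1:
                out.append(rid)
        return out

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            stoich=self.stoich.copy(),
            reversible=self.reversible.copy(),
            biomass_id=self.biomass_id,
            atp_demand_id=self.atp_demand_id,
        )


@dataclass
class BoundaryMap:
    """Names, units, and exchange wiring of the boundary species.

    ``species[0]`` is always biomass (gDCW/L); other tracked species are in
    mM.  ``flux_only`` species (ATP demand, oxygen supply) constrain exchange
    fluxes but have no tracked extracellular concentration.
    """

    species: list[str]
    exchange_of: dict[str, str]
    units_of: dict[str, str]
    product_species: str
    substrate_species: str
    flux_only: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigurationError("boundary species list is empty")
        # convention: biomass (gDCW/L) is species[0] whenever present
        for sp, unit in self.units_of.items():
            if unit == "gDCW/L" and sp != self.species[0]:
                raise ConfigurationError(
                    f"biomass species {sp!r} (gDCW/L) must be species[0]")
        self.flux_only = set(self.flux_only)
        if self.product_species == self.substrate_species:
            raise ConfigurationError("product and substrate must be distinct")
        for sp in (self.product_species, self.substrate_species):
            if sp not in self.species:
                raise ConfigurationError(f"{sp!r} not among boundary species")

    @property
    def biomass_species(self) -> str:
        return self.species[0]

    @property
    def tracked(self) -> list[str]:
        """Species with a dynamic concentration (states of the batch ODE)."""
        return [s for s in self.species if s not in self.flux_only]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _network_from_dict(doc: Mapping) -> MetabolicNetwork:
    try:
        mets = list(doc["metabolites"])
        rxns = doc["reactions"]
    except KeyError as exc:
        raise FormatError(f"JSON model missing required key {exc}") from None
    if not rxns:
        raise FormatError("model contains zero reactions")
    rxn_ids, reversible = [], []
    S = np.zeros((len(mets), len(rxns)))
    mi = {m: i for i, m in enumerate(mets)}
    for j, rxn in enumerate(rxns):
        try:
            rxn_ids.append(rxn["id"])
            reversible.append(bool(rxn.get("reversible", False)))
            for met, coeff in rxn["stoichiometry"].items():
                S[mi[met], j] = float(coeff)
        except KeyError as exc:
            raise FormatError(f"reaction #{j} missing field {exc}") from None
        except (ValueError, TypeError) as exc:
            raise FormatError(f"reaction {rxn.get('id', j)!r}: {exc}") from None
    biomass_id = doc.get("biomass_id")
    if biomass_id is None:
        raise ConfigurationError(
            "no biomass reaction identifiable; set 'biomass_id' explicitly"
        )
    return MetabolicNetwork(
        reaction_ids=rxn_ids,
        metabolite_ids=mets,
        stoich=S,
        reversible=np.array(reversible),
        biomass_id=biomass_id,
        atp_demand_id=doc.get("atp_demand_id"),
    )


def _boundary_from_dict(doc: Mapping) -> BoundaryMap:
    return BoundaryMap(
        species=list(doc["species"]),
        exchange_of=dict(doc["exchange_of"]),
        units_of=dict(doc["units_of"]),
        product_species=doc["product"],
        substrate_species=doc["substrate"],
        flux_only=set(doc.get("flux_only", [])),
    )


def read_network(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Read a metabolic model from SBML L3 or the repo JSON dialect.

    ``format`` is auto-detected from the suffix when not given.  Exchange
    reactions are detected structurally (single-metabolite columns).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from None
        return _network_from_dict(doc)
    if format == "sbml":
        return _read_sbml(path)
    raise FormatError(f"unknown model format {format!r}")


def _read_sbml(path: Path) -> MetabolicNetwork:
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several exception types
        raise FormatError(f"{path}: SBML parse failed ({exc})") from None
    if len(model.reactions) == 0:
        raise FormatError(f"{path}: SBML model contains zero reactions")
    mets = [m.id for m in model.metabolites]
    mi = {m: i for i, m in enumerate(mets)}
    rxn_ids, reversible = [], []
    S = np.zeros((len(mets), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        rxn_ids.append(rxn.id)
        reversible.append(rxn.lower_bound < 0 < rxn.upper_bound)
        for met, coeff in rxn.metabolites.items():
            S[mi[met.id], j] = coeff
    biomass_id = None
    objective_rxns = [r.id for r in model.reactions if r.objective_coefficient]
    if objective_rxns:
        biomass_id = objective_rxns[0]
    else:
        candidates = [r for r in rxn_ids if "biomass" in r.lower()]
        if candidates:
            biomass_id = candidates[0]
    if biomass_id is None:
        raise ConfigurationError(
            f"{path}: no biomass reaction identifiable; set biomass_id explicitly "
            "after reading, or mark one as the SBML objective"
        )
    atp_candidates = [r for r in rxn_ids if r.upper() in ("ATPM", "ATP_MAINTENANCE")]
    return MetabolicNetwork(
        reaction_ids=rxn_ids,
        metabolite_ids=mets,
        stoich=S,
        reversible=np.array(reversible),
        biomass_id=biomass_id,
        atp_demand_id=atp_candidates[0] if atp_candidates else None,
    )


def write_network(net: MetabolicNetwork, path: str | Path,
                  boundary: BoundaryMap | None = None) -> None:
    """Write the JSON dialect; exact round-trip of the stoichiometric matrix."""
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        col = net.stoich[:, j]
        stoich = {net.metabolite_ids[i]: col[i] for i in np.flatnonzero(col)}
        rxns.append({"id": rid, "stoichiometry": stoich,
                     "reversible": bool(net.reversible[j])})
    doc = {
        "metabolites": net.metabolite_ids,
        "reactions": rxns,
        "biomass_id": net.biomass_id,
        "atp_demand_id": net.atp_demand_id,
    }
    if boundary is not None:
        doc["boundary"] = {
            "species": boundary.species,
            "exchange_of": boundary.exchange_of,
            "units_of": boundary.units_of,
            "product": boundary.product_species,
            "substrate": boundary.substrate_species,
            "flux_only": sorted(boundary.flux_only),
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False))


def read_boundary(path: str | Path) -> BoundaryMap:
    """Read the boundary map embedded in a JSON-dialect model file."""
    doc = json.loads(Path(path).read_text())
    if "boundary" not in doc:
        raise ConfigurationError(f"{path} has no 'boundary' block")
    return _boundary_from_dict(doc["boundary"])


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file (model JSON, formulas, literature CSV)."""
    ref = resources.files("batchprod").joinpath("data").joinpath(name)
    with resources.as_file(ref) as p:
        return Path(p)


def load_fixture(name: str) -> tuple[MetabolicNetwork, BoundaryMap]:
    """Load a packaged model fixture together with its boundary map."""
    path = fixture_path(name if name.endswith(".json") else name + ".json")
    if not path.exists():
        raise ConfigurationError(f"unknown fixture {name!r}")
    net = read_network(path, format="json")
    boundary = read_boundary(path)
    return net, boundary


# ---------------------------------------------------------------------------
# Balance checking
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    unbalanced: list[tuple[str, str, float]]   # (reaction_id, element, residual)
    uncheckable: list[str]                     # reactions with missing formulas

    @property
    def ok(self) -> bool:
        return not self.unbalanced

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(self.unbalanced,
                     columns=["reaction_id", "element", "residual"]).to_csv(
            path, index=False)


def check_balances(net: MetabolicNetwork,
                   formulas: Mapping[str, Mapping[str, float]],
                   atol: float = 1e-9) -> BalanceReport:
    """Check elemental balance of every non-exchange reaction.

    ``formulas`` maps metabolite id to an elemental composition such as
    ``{"C": 6}``.  Only elements that appear in the provided formulas are
    checked; reactions touching a metabolite with no formula are reported as
    uncheckable rather than raising.
    """
    exchange = set(net.exchange_ids)
    elements = sorted({el for f in formulas.values() for el in f})
    unbalanced: list[tuple[str, str, float]] = []
    uncheckable: list[str] = []
    for j, rid in enumerate(net.reaction_ids):
        if rid in exchange:
            continue
        col = net.stoich[:, j]
        involved = [net.metabolite_ids[i] for i in np.flatnonzero(col)]
        if any(m not in formulas for m in involved):
            uncheckable.append(rid)
            continue
        for el in elements:
            residual = sum(col[net.met_index(m)] * formulas[m].get(el, 0.0)
                           for m in involved)
            if abs(residual) > atol:
                unbalanced.append((rid, el, float(residual)))
    return BalanceReport(unbalanced=unbalanced, uncheckable=uncheckable)


# ---------------------------------------------------------------------------
# Steady-state LP helpers
# ---------------------------------------------------------------------------

def fba(net: MetabolicNetwork, objective: str, *, maximize: bool = True,
        fixed: Mapping[str, float] | None = None,
        lower: Mapping[str, float] | None = None,
        upper: Mapping[str, float] | None = None) -> float:
    """Optimize one reaction flux subject to ``S v = 0`` and reversibilities.

    Returns the optimal flux through ``objective``.  ``fixed``/``lower``/
    ``upper`` override the default bounds (irreversible: [0, 1000];
    reversible: [-1000, 1000]).
    """
    n = len(net.reaction_ids)
    lb = np.where(net.reversible, -_LARGE_BOUND, 0.0)
    ub = np.full(n, _LARGE_BOUND)
    for name, val in (lower or {}).items():
        lb[net.rxn_index(name)] = val
    for name, val in (upper or {}).items():
        ub[net.rxn_index(name)] = val
    for name, val in (fixed or {}).items():
        j = net.rxn_index(name)
        lb[j] = ub[j] = val
    c = np.zeros(n)
    c[net.rxn_index(objective)] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=net.stoich, b_eq=np.zeros(len(net.metabolite_ids)),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        raise ConfigurationError(f"steady-state LP failed: {res.message}")
    return float(res.x[net.rxn_index(objective)])


def max_product_yield(net: MetabolicNetwork, boundary: BoundaryMap,
                      maintenance: float = 0.0) -> float:
    """Maximum theoretical product yield (mol product per mol glucose).

    Yield-maximizing steady-state LP at unit glucose uptake, CO2 exchange
    free, ATP demand bounded below by ``maintenance`` (0 disables it).
    """
    product_ex = boundary.exchange_of[boundary.product_species]
    glc_ex = boundary.exchange_of[boundary.substrate_species]
    lower = {}
    if net.atp_demand_id is not None:
        lower[net.atp_demand_id] = maintenance
    return fba(net, product_ex, fixed={glc_ex: -1.0}, lower=lower)


def growth_yield(net: MetabolicNetwork, boundary: BoundaryMap,
                 uptake_rate: float, maintenance: float = 0.0) -> float:
    """Growth-maximizing LP yield (gDCW per mmol glucose) at a fixed uptake."""
    glc_ex = boundary.exchange_of[boundary.substrate_species]
    biomass_ex = boundary.exchange_of[boundary.biomass_species]
    lower = {}
    if net.atp_demand_id is not None:
        lower[net.atp_demand_id] = maintenance
    mu = fba(net, biomass_ex, fixed={glc_ex: -abs(uptake_rate)}, lower=lower)
    return mu / abs(uptake_rate)


# ---------------------------------------------------------------------------
# Growth-energetics calibration
# ---------------------------------------------------------------------------

def calibrate_growth_energetics(net: MetabolicNetwork, boundary: BoundaryMap,
                                target_biomass_yield: float,
                                uptake_rate: float,
                                maintenance: float = 0.0,
                                atp_met: str = "atp", adp_met: str = "adp",
                                rel_tol: float = 1e-3,
                                coeff_max: float = 500.0) -> MetabolicNetwork:
    """Rescale growth-associated ATP demand to match a target biomass yield.

    The ATP (and paired ADP) coefficients of the biomass reaction are scaled
    by bisection until the growth-maximizing LP at ``uptake_rate`` mmol
    gDCW^-1 h^-1 glucose reproduces ``target_biomass_yield`` gDCW per mmol
    glucose.  The input network is left unmodified.
    """
    if target_biomass_yield < 0:
        raise CalibrationError("target biomass yield must be >= 0")
    if net.biomass_id is None:
        raise ConfigurationError("network has no biomass reaction")
    j_bio = net.rxn_index(net.biomass_id)
    i_atp = net.met_index(atp_met)
    if net.stoich[i_atp, j_bio] >= 0:
        raise ConfigurationError("biomass reaction does not consume ATP")
    i_adp = net.met_index(adp_met) if adp_met in net.metabolite_ids else None

    def with_coeff(g: float) -> MetabolicNetwork:
        out = net.copy()
        out.stoich[i_atp, j_bio] = -g
        if i_adp is not None:
            out.stoich[i_adp, j_bio] = g
        return out

    def yield_at(g: float) -> float:
        return growth_yield(with_coeff(g), boundary, uptake_rate, maintenance)

    y_min_gam = yield_at(0.0)
    if target_biomass_yield == 0.0:
        return with_coeff(coeff_max)
    if target_biomass_yield > y_min_gam * (1 + rel_tol):
        raise CalibrationError(
            f"target yield {target_biomass_yield} exceeds the maximum "
            f"achievable {y_min_gam:.4g} (at zero growth-ATP demand)",
            max_achievable=y_min_gam)
    lo, hi = 0.0, coeff_max
    if yield_at(hi) > target_biomass_yield:
        raise CalibrationError(
            f"target yield not reachable with growth-ATP coefficient "
            f"<= {coeff_max}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if yield_at(mid) > target_biomass_yield:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    g = 0.5 * (lo + hi)
    achieved = yield_at(g)
    if abs(achieved - target_biomass_yield) > rel_tol * target_biomass_yield:
        raise CalibrationError(
            f"calibration stalled: achieved {achieved:.5g} vs target "
            f"{target_biomass_yield}")
    logger.info("calibrated growth-ATP coefficient to %.4f (yield %.5f)", g, achieved)
    return with_coeff(g)
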