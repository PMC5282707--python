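"""State-dependent exchange-flux bounds from uptake and maintenance kinetics.

Glucose uptake follows a Han-Levenspiel law: a Monod term in glucose
multiplied by inhibition terms ``(1 - x_n/C*_n)^a_n`` that vanish when an
inhibitor (a fermentation product, or glucose itself) reaches its critical
concentration ``C*_n``.  Uptake fluxes are negative by convention, so the
law provides the lower (most negative) admissible glucose exchange flux.
Above a critical concentration the base of the power law turns negative and
fractional powers are undefined; the bound is clamped to zero there, since
the law is only valid below the critical concentration.

Maintenance enters as a state-independent lower bound on the ATP demand
flux, and (for aerobic organisms) a lower bound on oxygen exchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from batchprod.models import BoundaryMap, ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Inhibitor:
    species: str
    c_star: float    # critical concentration, mM
    exponent: float  # dimensionless

    def __post_init__(self) -> None:
        if self.c_star <= 0:
            raise ConfigurationError(f"C* for {self.species!r} must be > 0")
        if self.exponent < 0:
            raise ConfigurationError(f"exponent for {self.species!r} must be >= 0")


@dataclass(frozen=True)
class KineticSpec:
    """Uptake and maintenance parameters generating flux bounds.

    v_max: maximum specific glucose uptake, mmol gDCW^-1 h^-1 (negative).
    K_s: Monod half-saturation constant, mM.
    inhibitors: Han-Levenspiel inhibition terms.
    atp_maintenance: non-growth ATP demand lower bound, mmol gDCW^-1 h^-1.
    oxygen_uptake_max: most negative oxygen exchange flux, or None (anaerobic).
    """

    v_max: float
    K_s: float
    inhibitors: tuple[Inhibitor, ...] = ()
    atp_maintenance: float = 0.0
    oxygen_uptake_max: float | None = None

    def __post_init__(self) -> None:
        if self.K_s <= 0:
            raise ConfigurationError("K_s must be > 0")
        if self.atp_maintenance < 0:
            raise ConfigurationError("atp_maintenance must be >= 0")
        if self.oxygen_uptake_max is not None and self.oxygen_uptake_max > 0:
            raise ConfigurationError("oxygen_uptake_max must be <= 0 (uptake)")
        object.__setattr__(self, "inhibitors", tuple(
            i if isinstance(i, Inhibitor) else Inhibitor(*i) for i in self.inhibitors))


#: Named parameter presets.  The succinate producer's values come from a
#: Han-Levenspiel fit of batch growth data; the E. coli preset reuses the
#: same uptake law (no suitable substrate-inhibition model of its own
#: exists) with aerobic maintenance and oxygen-supply bounds.
_PRESETS: dict[str, KineticSpec] = {
    "a_succinogenes": KineticSpec(
        v_max=-11.47, K_s=11.27,
        inhibitors=(
            Inhibitor("glc", 860.4, 0.603),
            Inhibitor("succ", 385.7, 1.0),
            Inhibitor("for", 235.3, 1.0),
            Inhibitor("ac", 538.8, 1.0),
        ),
        atp_maintenance=4.7,
        oxygen_uptake_max=None,
    ),
    "e_coli": KineticSpec(
        v_max=-11.47, K_s=11.27,
        inhibitors=(
            Inhibitor("glc", 860.4, 0.603),
            Inhibitor("succ", 385.7, 1.0),
            Inhibitor("for", 235.3, 1.0),
            Inhibitor("ac", 538.8, 1.0),
        ),
        atp_maintenance=8.39,
        oxygen_uptake_max=-18.2,
    ),
}


def preset(name: str) -> KineticSpec:
    """Return a named kinetic preset ('a_succinogenes' or 'e_coli')."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown kinetic preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


def glucose_uptake_bound(x: Mapping[str, float], spec: KineticSpec,
                         substrate: str = "glc") -> float:
    """Most negative admissible glucose exchange flux at concentrations ``x``.

    ``x`` maps boundary species names to concentrations (mM; biomass g/L).
    Any inhibitor at or above its critical concentration clamps the bound to
    zero.  The result lies in ``[v_max, 0]``.
    """
    for sp, conc in x.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {sp!r}: {conc}")
    x_glc = x.get(substrate, 0.0)
    bound = spec.v_max * x_glc / (x_glc + spec.K_s)
    for inh in spec.inhibitors:
        conc = x.get(inh.species, 0.0)
        base = 1.0 - conc / inh.c_star
        if base <= 0.0:
            logger.warning(
                "inhibitor %s at %.4g mM >= C* %.4g mM: uptake clamped to 0",
                inh.species, conc, inh.c_star)
            return 0.0
        bound *= base ** inh.exponent
    return float(np.clip(bound, spec.v_max, 0.0))


def flux_bounds(x: Mapping[str, float], spec: KineticSpec,
                boundary: BoundaryMap) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper bound vectors over the boundary exchange fluxes.

    Glucose: [Han-Levenspiel bound, 0].  ATP demand: [maintenance, inf).
    Oxygen: [oxygen_uptake_max, 0] when aerobic, (0, 0) otherwise.
    Biomass and products: [0, inf).
    """
    n = len(boundary.species)
    lb = np.zeros(n)
    ub = np.full(n, np.inf)
    for sp in ("atp",):
        if spec.atp_maintenance and sp not in boundary.species:
            raise ConfigurationError("spec sets ATP maintenance but boundary has no 'atp'")
    for k, sp in enumerate(boundary.species):
        if sp == boundary.substrate_species:
            lb[k] = glucose_uptake_bound(x, spec, substrate=sp)
            ub[k] = 0.0
        elif sp == "atp":
            lb[k] = spec.atp_maintenance
        elif sp in ("o2", "oxygen"):
            lb[k] = spec.oxygen_uptake_max if spec.oxygen_uptake_max is not None else 0.0
            ub[k] = 0.0
    return lb, ub
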