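"""Elementary flux modes: enumeration, normalization, projection, reduction.

An elementary flux mode (EFM) is a support-minimal flux vector in the flux
cone ``{v : S v = 0, v_irrev >= 0}``; every feasible steady-state flux is a
nonnegative combination of EFMs.  For the batch optimal-control problem only
the effect of a mode on the boundary species matters, so modes are normalized
per mol of glucose consumed and projected onto boundary-species yield
coordinates; the projected set is then condensed to the vertices of its
convex hull and finally to the Pareto-optimal subset under the production
senses that an optimal-productivity solution can exploit.

Enumeration uses the double-description method on the split (all
irreversible) network with bit-set support tests, which is adequate for the
desk-scale networks packaged here; larger mode sets computed externally
(e.g. by efmtool) enter through :func:`import_efms`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from batchprod.models import BoundaryMap, ConfigurationError, MetabolicNetwork

logger = logging.getLogger(__name__)

#: residual tolerance for the nullspace condition S r = 0
NULLSPACE_TOL = 1e-9
#: tolerance for merging duplicate modes after scale-normalization
DUPLICATE_TOL = 1e-9
#: tolerance for convex-hull membership of dropped modes
HULL_TOL = 1e-8

Sense = Literal["maximize", "minimize", "ignore"]


class ResourceError(RuntimeError):
    """Enumeration would exceed the configured mode-count cap."""


class EmptyModeSetError(ValueError):
    """No mode consumes glucose; the optimization is impossible."""


@dataclass
class EFMSet:
    """A set of flux modes, either in reaction space or in yield space.

    In reaction space ``columns`` are reaction ids and rows are unnormalized
    flux vectors.  After :func:`project_and_normalize` the columns are
    boundary species (glucose dropped, implicitly -1 mol per mol), metabolite
    entries are mol per mol glucose, and the biomass entry is gDCW per mmol
    glucose.
    """

    modes: np.ndarray                      # (n_modes, n_columns)
    columns: list[str]
    boundary: BoundaryMap | None = None
    provenance: list[list[str]] | None = None   # active reactions per mode
    normalized: bool = False

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        if self.modes.size == 0:
            self.modes = self.modes.reshape(0, len(self.columns))
        if self.modes.shape[1] != len(self.columns):
            raise ConfigurationError(
                f"mode matrix has {self.modes.shape[1]} columns, "
                f"{len(self.columns)} labels")

    def __len__(self) -> int:
        return self.modes.shape[0]

    def col(self, name: str) -> np.ndarray:
        return self.modes[:, self.columns.index(name)]

    def subset(self, row_idx: Sequence[int]) -> "EFMSet":
        idx = list(row_idx)
        return EFMSet(
            modes=self.modes[idx],
            columns=list(self.columns),
            boundary=self.boundary,
            provenance=[self.provenance[i] for i in idx] if self.provenance else None,
            normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# Enumeration (double description with bit-set supports)
# ---------------------------------------------------------------------------

def _split_reversible(net: MetabolicNetwork) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Split reversible reactions into forward/backward irreversible pairs.

    Returns the augmented stoichiometric matrix and a map
    ``column -> (original_reaction, sign)``.
    """
    cols = []
    colmap = []
    for j in range(len(net.reaction_ids)):
        cols.append(net.stoich[:, j])
        colmap.append((j, +1))
        if net.reversible[j]:
            cols.append(-net.stoich[:, j])
            colmap.append((j, -1))
    return np.column_stack(cols), colmap


def _extreme_rays(S: np.ndarray, cap: int) -> np.ndarray:
    """Extreme rays of ``{v >= 0 : S v = 0}`` by double description.

    Processes one equality constraint at a time, combining adjacent positive
    and negative rays; support-minimality is enforced with a subset test over
    bit-set supports after each step.
    """
    m, n = S.shape
    rays = np.eye(n)
    # order constraints by increasing nonzero count keeps intermediate sets small
    order = np.argsort((S != 0).sum(axis=1))
    for row_i in order:
        a = S[row_i]
        vals = rays @ a
        zero = np.abs(vals) <= NULLSPACE_TOL * max(1.0, np.abs(rays).max())
        pos = (vals > 0) & ~zero
        neg = (vals < 0) & ~zero
        keep = rays[zero]
        rp, rn = rays[pos], rays[neg]
        vp, vn = vals[pos], vals[neg]
        # candidate combinations, deduped by support
        candidates: dict[int, np.ndarray] = {}
        for i in range(len(rp)):
            for j in range(len(rn)):
                r = vp[i] * rn[j] - vn[j] * rp[i]
                r /= np.abs(r).max()
                s = _support_bits(r)
                if s not in candidates:
                    candidates[s] = r
        # support-minimality within the new tableau (kept + candidate rays)
        pool = [(_support_bits(r), r) for r in keep] + list(candidates.items())
        supports = [s for s, _ in pool]
        new_rays = []
        for s, r in pool:
            minimal = True
            for other in supports:
                if other != s and (other & s) == other:
                    minimal = False
                    break
            if minimal:
                new_rays.append(r)
        rays = np.vstack(new_rays) if new_rays else np.zeros((0, n))
        if len(rays) > cap:
            raise ResourceError(
                f"intermediate ray count {len(rays)} exceeds cap {cap}; "
                "enumerate externally and use import_efms")
    return rays


def _support_bits(r: np.ndarray, tol: float = 1e-10) -> int:
    bits = 0
    for k in np.flatnonzero(np.abs(r) > tol * max(1.0, np.abs(r).max())):
        bits |= 1 << int(k)
    return bits


def enumerate_efms(net: MetabolicNetwork, cap: int = 10**6) -> EFMSet:
    """Enumerate all elementary flux modes of a network (up to scaling).

    Reversible reactions are split internally; two-cycle artifacts of the
    splitting are removed and the modes are mapped back to signed fluxes over
    the original reactions.
    """
    if len(net.reaction_ids) == 0:
        raise ConfigurationError("network has no reactions")
    S_split, colmap = _split_reversible(net)
    rays = _extreme_rays(S_split, cap)
    n = len(net.reaction_ids)
    modes = []
    for ray in rays:
        v = np.zeros(n)
        for c, (j, sign) in enumerate(colmap):
            v[j] += sign * ray[c]
        if np.abs(v).max() <= 1e-12:
            continue  # two-cycle artifact: forward and backward cancel
        v /= np.abs(v).max()
        modes.append(v)
    if not modes:
        return EFMSet(modes=np.zeros((0, n)), columns=list(net.reaction_ids))
    modes = _dedupe(np.array(modes))
    # final validation: nullspace residual and support-minimality
    resid = np.abs(net.stoich @ modes.T).max() if len(modes) else 0.0
    if resid > NULLSPACE_TOL * 10:
        raise RuntimeError(f"enumeration produced residual {resid:.2e}")
    modes = _minimal_support_filter(modes)
    logger.info("enumerated %d elementary modes", len(modes))
    return EFMSet(modes=modes, columns=list(net.reaction_ids))


def _dedupe(modes: np.ndarray, tol: float = DUPLICATE_TOL) -> np.ndarray:
    if len(modes) == 0:
        return modes
    scaled = modes / np.abs(modes).max(axis=1, keepdims=True)
    keep: list[int] = []
    for i in range(len(scaled)):
        if not any(np.abs(scaled[i] - scaled[k]).max() <= tol for k in keep):
            keep.append(i)
    return modes[keep]


def _minimal_support_filter(modes: np.ndarray) -> np.ndarray:
    supports = [_support_bits(m) for m in modes]
    keep = []
    for i, s in enumerate(supports):
        minimal = True
        for j, o in enumerate(supports):
            if i != j and o != s and (o & s) == o:
                minimal = False
                break
        if minimal:
            keep.append(i)
    return modes[keep]


# ---------------------------------------------------------------------------
# Import / export
# ---------------------------------------------------------------------------

def export_efms(efms: EFMSet, path: str | Path) -> None:
    """Write modes as CSV with column headers (reaction or species ids)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(efms.columns)
        if efms.provenance is not None:
            header.append("provenance")
        writer.writerow(header)
        for i, row in enumerate(efms.modes):
            out = [f"{x:.12g}" for x in row]
            if efms.provenance is not None:
                out.append(";".join(efms.provenance[i]))
            writer.writerow(out)


def import_efms(path: str | Path, net: MetabolicNetwork) -> EFMSet:
    """Read externally enumerated modes (CSV, reactions as columns) and
    validate each against the network before acceptance.

    Rows failing the nullspace condition or an irreversibility sign
    constraint are rejected with their row index.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            logger.warning("%s: empty EFM file; returning empty set", path)
            return EFMSet(modes=np.zeros((0, len(net.reaction_ids))),
                          columns=list(net.reaction_ids))
        rows = [r for r in reader if r]
    col_of = {}
    for k, name in enumerate(header):
        if name == "provenance":
            continue
        col_of[name] = k
    missing = [r for r in net.reaction_ids if r not in col_of]
    if missing:
        raise ConfigurationError(f"{path}: columns missing for reactions {missing}")
    modes = []
    errors = []
    for i, row in enumerate(rows):
        v = np.array([float(row[col_of[r]]) for r in net.reaction_ids])
        resid = np.abs(net.stoich @ v).max()
        if resid > NULLSPACE_TOL * max(1.0, np.abs(v).max()):
            errors.append(f"row {i}: nullspace residual {resid:.2e}")
            continue
        bad = [net.reaction_ids[j] for j in range(len(v))
               if not net.reversible[j] and v[j] < -1e-10]
        if bad:
            errors.append(f"row {i}: negative flux through irreversible {bad[0]}")
            continue
        modes.append(v)
    if errors:
        raise ConfigurationError(f"{path}: invalid modes rejected: " + "; ".join(errors))
    modes = np.array(modes) if modes else np.zeros((0, len(net.reaction_ids)))
    return EFMSet(modes=modes, columns=list(net.reaction_ids))


# ---------------------------------------------------------------------------
# Projection / normalization
# ---------------------------------------------------------------------------

def project_and_normalize(efms: EFMSet, boundary: BoundaryMap) -> EFMSet:
    """Normalize modes per mol glucose and project to boundary-species yields.

    The glucose column is fixed at -1 by the normalization and dropped (it is
    implicit in every yield coordinate); modes that consume no glucose are
    excluded and logged; duplicates after projection are merged.
    """
    glc_rxn = boundary.exchange_of[boundary.substrate_species]
    if glc_rxn not in efms.columns:
        raise ConfigurationError(f"glucose exchange {glc_rxn!r} not among mode columns")
    glc = efms.col(glc_rxn)
    consuming = glc < -1e-10
    n_dropped = int(len(efms) - consuming.sum())
    if n_dropped:
        logger.info("dropped %d modes with zero glucose uptake", n_dropped)
    if not consuming.any():
        raise EmptyModeSetError("no mode consumes glucose")
    species = [s for s in boundary.species if s != boundary.substrate_species]
    cols = []
    for sp in species:
        rxn = boundary.exchange_of[sp]
        if rxn not in efms.columns:
            raise ConfigurationError(f"exchange {rxn!r} for species {sp!r} missing")
        cols.append(efms.columns.index(rxn))
    sub = efms.modes[consuming][:, cols] / np.abs(glc[consuming])[:, None]
    provenance = None
    if efms.provenance is not None:
        provenance = [efms.provenance[i] for i in np.flatnonzero(consuming)]
    else:
        provenance = [
            [efms.columns[j] for j in np.flatnonzero(np.abs(efms.modes[i]) > 1e-10)]
            for i in np.flatnonzero(consuming)
        ]
    # merge duplicates after projection
    keep: list[int] = []
    for i in range(len(sub)):
        if not any(np.abs(sub[i] - sub[k]).max() <= DUPLICATE_TOL for k in keep):
            keep.append(i)
    if len(keep) < len(sub):
        logger.info("merged %d duplicate projected modes", len(sub) - len(keep))
    return EFMSet(modes=sub[keep], columns=species, boundary=boundary,
                  provenance=[provenance[i] for i in keep], normalized=True)


# ---------------------------------------------------------------------------
# Convex hull and Pareto reduction
# ---------------------------------------------------------------------------

def hull_vertices(efms: EFMSet) -> EFMSet:
    """Keep only modes at vertices of the convex hull of the yield points.

    Degenerate (affinely dependent) point sets are handled by working in the
    affine subspace spanned by the points.
    """
    pts = efms.modes
    if len(pts) <= 1:
        return efms.subset(range(len(pts)))
    center = pts.mean(axis=0)
    centered = pts - center
    # affine rank via SVD; project to the spanned subspace
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(1.0, np.abs(pts).max())
    rank = int((s > 1e-9 * scale * max(pts.shape)).sum())
    if rank == 0:
        return efms.subset([0])
    proj = centered @ vt[:rank].T
    if rank == 1:
        x = proj[:, 0]
        idx = sorted({int(np.argmin(x)), int(np.argmax(x))})
        return efms.subset(idx)
    from scipy.spatial import ConvexHull, QhullError
    try:
        hull = ConvexHull(proj)
        idx = sorted(set(int(i) for i in hull.vertices))
    except QhullError:
        hull = ConvexHull(proj, qhull_options="QJ")
        idx = sorted(set(int(i) for i in hull.vertices))
    return efms.subset(idx)


def default_senses(efms: EFMSet) -> dict[str, Sense]:
    """Production senses an optimal-productivity solution can exploit.

    Biomass, excess ATP, and the product are worth maximizing; oxygen uptake
    magnitude (a negative yield coordinate) is worth minimizing, i.e. its
    signed value is maximized; all other byproducts are ignored.
    """
    if efms.boundary is None:
        raise ConfigurationError("EFMSet has no boundary map")
    b = efms.boundary
    senses: dict[str, Sense] = {}
    for sp in efms.columns:
        if sp in (b.biomass_species, b.product_species, "atp"):
            senses[sp] = "maximize"
        elif sp in ("o2", "oxygen"):
            senses[sp] = "minimize"
        else:
            senses[sp] = "ignore"
    return senses


def pareto_filter(efms: EFMSet, senses: Mapping[str, Sense] | None = None) -> EFMSet:
    """Keep exactly the modes not dominated under the sense vector.

    A mode dominates another if it is at least as good in every considered
    coordinate and strictly better in one ("minimize" coordinates compare
    with the opposite sign; "ignore" coordinates do not participate).
    """
    if senses is None:
        senses = default_senses(efms)
    missing = [c for c in efms.columns if c not in senses]
    if missing:
        raise ConfigurationError(f"senses missing for species {missing}")
    sign = []
    cols = []
    for k, sp in enumerate(efms.columns):
        if senses[sp] == "maximize":
            sign.append(1.0)
            cols.append(k)
        elif senses[sp] == "minimize":
            sign.append(-1.0)
            cols.append(k)
    if not cols:
        raise ConfigurationError("all species ignored; Pareto filter undefined")
    pts = efms.modes[:, cols] * np.array(sign)
    # vectorized nondominance: i dominated iff some j has pts[j] >= pts[i]
    # everywhere and > somewhere (beyond tolerance)
    tol = 1e-9 * max(1.0, np.abs(pts).max())
    ge = (pts[:, None, :] >= pts[None, :, :] - tol).all(axis=2)
    gt = (pts[:, None, :] > pts[None, :, :] + tol).any(axis=2)
    dominated = (ge & gt).any(axis=0)
    keep = [int(i) for i in np.flatnonzero(~dominated)]
    return efms.subset(keep)


def reduce_modes(efms: EFMSet, boundary: BoundaryMap,
                 senses: Mapping[str, Sense] | None = None
                 ) -> tuple[EFMSet, dict[str, int]]:
    """Full reduction chain: project/normalize -> hull vertices -> Pareto.

    Returns the reduced set and the mode counts after each step.
    """
    counts = {"enumerated": len(efms)}
    projected = project_and_normalize(efms, boundary)
    counts["projected"] = len(projected)
    hull = hull_vertices(projected)
    counts["hull_vertices"] = len(hull)
    pareto = pareto_filter(hull, senses)
    counts["pareto"] = len(pareto)
    logger.info("mode reduction: %s", " -> ".join(f"{k}={v}" for k, v in counts.items()))
    return pareto, counts
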