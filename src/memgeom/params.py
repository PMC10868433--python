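"""Geometry-parameter estimation and sanity checks.

Two helpers mirror the workflow of setting up a membrane geometry:

* :func:`default_bicelle_radius` — when no ellipsoid inner radius is given,
  estimate one from the transmembrane cross-section: 1.5x the largest
  CA–CA distance among alpha-carbons within 3 Å of the membrane centre
  (half the diameter, times three), so the mimetic always surrounds the
  protein.
* :func:`check_bicelle_size` — warn when the chosen inner radius is
  smaller than half the widest atom-pair distance near the membrane
  centre, i.e. the protein would stick out of the bicelle/micelle.

:func:`optimize_geometry_params` grid-searches the kind-specific geometry
parameters to best match the residues the field scores as hydrophobic
(f_hyd at CA below 0.5) against the residues a spanfile declares to span
the membrane.  The match is scored with the Jaccard index by default
(balanced accuracy is available); ties break toward the smallest
parameter values so reports are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometrySpec, TransitionParams, hydration
from .structure import SpanFile, Structure

__all__ = ["OptimizationReport", "default_bicelle_radius", "check_bicelle_size",
           "optimize_geometry_params", "default_grid"]

MEMBRANE_CENTER_SLICE = 3.0     # Å; |z| window defining "at the membrane centre"
HYDROPHOBIC_FHYD_CUTOFF = 0.5   # CA below this counts as scored-in-membrane


@dataclass(frozen=True)
class OptimizationReport:
    """Result of the geometry-parameter grid search."""

    kind: str
    best: GeometrySpec
    best_objective: float
    objective_name: str
    candidates: tuple = field(repr=False)  # (GeometrySpec, objective) pairs

    def to_text(self) -> str:
        lines = [f"geometry: {self.kind}",
                 f"objective: {self.objective_name}",
                 f"best_objective: {self.best_objective:.4f}"]
        if self.kind == "ellipsoid":
            lines.append(f"recommended inner_radius: {self.best.inner_radius:g}")
        elif self.kind == "vesicle":
            lines.append(f"recommended radius: {self.best.vesicle_radius:g}")
            lines.append(f"recommended curvature: {self.best.curvature}")
        elif self.kind == "double_vesicle":
            lines.append(f"recommended inner_radius: {self.best.dv_inner_radius:g}")
            lines.append(f"recommended distance: {self.best.dv_distance:g}")
        lines.append("")
        lines.append("candidates (params -> objective):")
        for spec, obj in self.candidates:
            lines.append(f"  {_spec_params(spec)} -> {obj:.4f}")
        return "\n".join(lines) + "\n"


def _spec_params(spec: GeometrySpec) -> str:
    if spec.kind == "ellipsoid":
        return f"inner_radius={spec.inner_radius:g}"
    if spec.kind == "vesicle":
        return f"radius={spec.vesicle_radius:g} curvature={spec.curvature}"
    if spec.kind == "double_vesicle":
        return f"inner_radius={spec.dv_inner_radius:g} distance={spec.dv_distance:g}"
    return "(none)"


def _central_ca_coords(structure: Structure) -> np.ndarray:
    ca_idx = np.array(sorted(structure.ca_atom_indices().values()), dtype=int)
    coords = structure.xyz[ca_idx]
    return coords[np.abs(coords[:, 2]) <= MEMBRANE_CENTER_SLICE]


def _max_pairwise_distance(coords: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def default_bicelle_radius(structure: Structure,
                           params: TransitionParams = TransitionParams()) -> float:
    """Estimate the ellipsoid inner radius from the TM cross-section.

    Largest CA–CA distance among alpha-carbons with |z| <= 3 Å, halved and
    multiplied by three.
    """
    coords = _central_ca_coords(structure)
    if len(coords) < 2:
        raise ValueError(
            "need at least two CA atoms within 3 Å of the membrane centre to "
            "estimate a bicelle radius; pass an explicit inner radius instead")
    return 1.5 * _max_pairwise_distance(coords)


def check_bicelle_size(structure: Structure, geom: GeometrySpec,
                       params: TransitionParams = TransitionParams()) -> bool:
    """Warn if the bicelle/micelle may be smaller than the protein.

    Considers *all* atoms within 3 Å of the membrane mid-plane; returns
    True (and warns) when inner_radius < half the largest pairwise
    distance among them.
    """
    if geom.kind != "ellipsoid":
        raise ValueError("size check applies to the ellipsoid geometry")
    near = structure.xyz[np.abs(structure.xyz[:, 2]) <= MEMBRANE_CENTER_SLICE]
    if len(near) < 2:
        return False
    largest = _max_pairwise_distance(near)
    if geom.inner_radius < 0.5 * largest:
        warnings.warn(
            f"protein may be larger than the bicelle/micelle: inner radius "
            f"{geom.inner_radius:g} Å < half the widest cross-section "
            f"{0.5 * largest:.1f} Å")
        return True
    return False


def default_grid(kind: str) -> list[GeometrySpec]:
    """Default candidate grids per geometry kind.

    Vesicle radii span the experimentally reported curvature range
    (80–600 Å) plus near-flat sentinels (1000 Å and 1e6 Å) in both
    curvature directions.
    """
    if kind == "ellipsoid":
        return [GeometrySpec.ellipsoid(r) for r in np.arange(10.0, 101.0, 5.0)]
    if kind == "vesicle":
        radii = [*np.arange(80.0, 601.0, 20.0), 1000.0, 1e6]
        return [GeometrySpec.vesicle(r, curv)
                for r in radii for curv in ("down", "up")]
    if kind == "double_vesicle":
        return [GeometrySpec.double_vesicle(1000.0, d)
                for d in np.arange(10.0, 301.0, 10.0)]
    raise ValueError(f"no parameter grid for geometry kind {kind!r}")


def _objective(pred: set, truth: set, all_residues: set, name: str) -> float:
    if name == "jaccard":
        union = pred | truth
        return len(pred & truth) / len(union) if union else 0.0
    if name == "balanced_accuracy":
        pos = truth
        neg = all_residues - truth
        tpr = len(pred & pos) / len(pos) if pos else 0.0
        tnr = len(neg - pred) / len(neg) if neg else 0.0
        return 0.5 * (tpr + tnr)
    raise ValueError(f"unknown objective {name!r}")


def optimize_geometry_params(structure: Structure, spanfile: SpanFile, kind: str,
                             grid: list[GeometrySpec] | None = None,
                             params: TransitionParams = TransitionParams(),
                             objective: str = "jaccard") -> OptimizationReport:
    """Exhaustive grid search for geometry parameters matching a spanfile.

    For each candidate geometry, residues whose CA has f_hyd < 0.5 form
    the predicted membrane-embedded set; the objective compares it with the
    spanfile residue set.  The grid-order-first maximum is returned, and
    grids are ordered smallest-parameters-first, so ties resolve to the
    smallest values.
    """
    if grid is None:
        grid = default_grid(kind)
    if not grid:
        raise ValueError("candidate grid is empty")
    if any(g.kind != kind for g in grid):
        raise ValueError(f"grid contains geometries of a different kind than {kind!r}")
    span_residues = spanfile.residues()
    if max(span_residues, default=0) > structure.n_residues:
        raise ValueError("spanfile residue range exceeds structure size")

    ca_map = structure.ca_atom_indices()
    poses = np.array(sorted(ca_map))
    ca_xyz = structure.xyz[[ca_map[p] for p in poses]]
    all_residues = set(int(p) for p in poses)

    scored = []
    for spec in grid:
        f = hydration(ca_xyz, spec, params=params).f_hyd
        pred = {int(p) for p, v in zip(poses, f) if v < HYDROPHOBIC_FHYD_CUTOFF}
        scored.append((spec, _objective(pred, span_residues, all_residues, objective)))
    best_spec, best_obj = max(scored, key=lambda t: t[1])
    # max() keeps the first maximum; grids are ordered smallest-first
    return OptimizationReport(kind=kind, best=best_spec, best_objective=best_obj,
                              objective_name=objective, candidates=tuple(scored))
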