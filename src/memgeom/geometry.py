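"""Implicit-membrane hydration fields for four membrane geometries.

The membrane is represented implicitly by a scalar *transition function*
``f_hyd`` in [0, 1]: 0 means an atom sits in the hydrophobic core of the
bilayer (or membrane mimetic), 1 means it is fully solvated in water.
Membrane-dependent energy terms weight their per-atom contributions by
``1 - f_hyd``, so the field *is* the membrane.

All geometries share one rational-sigmoid transition family

    sigma(u) = u^n / (1 + u^n),    u = depth / t

with hydrophobic half-thickness ``t`` (default 15 Å) and steepness ``n``
(default 10).  The four geometries differ only in how the depth coordinate
is measured:

* **slab** — depth is ``|z|``, the distance from the membrane mid-plane.
* **ellipsoid** (micelle/bicelle) — a planar disc of radius ``inner_radius``
  capped by a hemispherical rim; the micelle is the special case
  ``inner_radius = 0``.  The radial factor ``h = r'^n/(1+r'^n)`` composes
  with the slab factor via the same union rule as the pore.
* **vesicle** — a sphere of radius ``R`` centred at ``(0, 0, -R)`` (or
  ``+R``), so the protein origin lies on the membrane mid-surface; depth is
  the signed radial distance from that surface.
* **double_vesicle** — two concentric spheres representing two membranes
  (gap junctions, double envelopes); the fields multiply, so a point is
  hydrophobic inside either membrane.

An aqueous pore ``f_cavity`` (a radial sigmoid around an axis parallel to
z) composes with any geometry field through the probabilistic union

    f_hyd = f_thk + f_cavity - f_thk * f_cavity.

Structures are assumed to be in membrane coordinates already: membrane
normal along z, membrane centre at the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "TransitionParams",
    "GeometrySpec",
    "PoreSpec",
    "HydrationResult",
    "f_thk_slab",
    "f_ellipsoid",
    "f_vesicle",
    "f_double_vesicle",
    "f_cavity",
    "compose_pore",
    "geometry_field",
    "hydration",
    "gradient_f_hyd",
]

GeometryKind = Literal["slab", "ellipsoid", "vesicle", "double_vesicle"]


@dataclass(frozen=True)
class TransitionParams:
    """Shared parameters of the hydrophobicity transition.

    Parameters
    ----------
    half_thickness : float
        Hydrophobic half-thickness t of the membrane in Å.  The transition
        passes through 0.5 at depth t.  Default 15 Å (a typical phospholipid
        bilayer hydrophobic half-width).
    steepness : float
        Dimensionless exponent n of the rational sigmoid.  Larger values
        sharpen the water/core interface.  Default 10.
    """

    half_thickness: float = 15.0
    steepness: float = 10.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.half_thickness) and self.half_thickness > 0):
            raise ValueError(f"half_thickness must be positive, got {self.half_thickness}")
        if not (np.isfinite(self.steepness) and self.steepness > 0):
            raise ValueError(f"steepness must be positive, got {self.steepness}")


@dataclass(frozen=True)
class GeometrySpec:
    """Tagged union of the four membrane geometries.

    Use the constructors :meth:`slab`, :meth:`ellipsoid`, :meth:`vesicle`
    and :meth:`double_vesicle` rather than filling fields by hand.

    ``curvature`` selects whether a (double) vesicle curves down (sphere
    centre below the protein, at negative z) or up.
    """

    kind: GeometryKind = "slab"
    inner_radius: float = 0.0          # ellipsoid: planar-disc radius; 0 = micelle
    outer_radius: Optional[float] = None  # ellipsoid; None -> inner_radius + t
    vesicle_radius: float = 0.0        # vesicle: curvature radius R
    curvature: Literal["down", "up"] = "down"
    dv_inner_radius: float = 0.0       # double_vesicle: inner mid-surface radius
    dv_distance: float = 0.0           # double_vesicle: edge-to-edge membrane gap

    @classmethod
    def slab(cls) -> "GeometrySpec":
        return cls(kind="slab")

    @classmethod
    def ellipsoid(cls, inner_radius: float, outer_radius: float | None = None) -> "GeometrySpec":
        if inner_radius < 0 or not np.isfinite(inner_radius):
            raise ValueError(f"inner_radius must be >= 0, got {inner_radius}")
        if outer_radius is not None and outer_radius <= 0:
            raise ValueError(f"outer_radius must be > 0, got {outer_radius}")
        return cls(kind="ellipsoid", inner_radius=float(inner_radius),
                   outer_radius=None if outer_radius is None else float(outer_radius))

    @classmethod
    def micelle(cls) -> "GeometrySpec":
        """Micelle = ellipsoid with no planar section (inner_radius 0)."""
        return cls.ellipsoid(0.0)

    @classmethod
    def vesicle(cls, radius: float, curvature: Literal["down", "up"] = "down") -> "GeometrySpec":
        if not (np.isfinite(radius) and radius > 0):
            raise ValueError(f"vesicle radius must be > 0, got {radius}")
        if curvature not in ("down", "up"):
            raise ValueError(f"curvature must be 'down' or 'up', got {curvature!r}")
        return cls(kind="vesicle", vesicle_radius=float(radius), curvature=curvature)

    @classmethod
    def double_vesicle(cls, inner_radius: float, distance: float,
                       curvature: Literal["down", "up"] = "down") -> "GeometrySpec":
        if not (np.isfinite(inner_radius) and inner_radius > 0):
            raise ValueError(f"double-vesicle inner radius must be > 0, got {inner_radius}")
        if not (np.isfinite(distance) and distance >= 0):
            raise ValueError(f"double-vesicle distance must be >= 0, got {distance}")
        return cls(kind="double_vesicle", dv_inner_radius=float(inner_radius),
                   dv_distance=float(distance), curvature=curvature)

    # -- derived quantities -------------------------------------------------

    def ellipsoid_outer_radius(self, params: TransitionParams) -> float:
        """Outer radius of the ellipsoid: inner_radius + membrane half-thickness
        unless set explicitly."""
        if self.outer_radius is not None:
            return self.outer_radius
        return self.inner_radius + params.half_thickness

    def dv_outer_surface_radius(self, params: TransitionParams) -> float:
        """Mid-surface radius of the outer sphere of a double vesicle.

        The user-facing distance is measured between membrane *edges*
        (outer edge of the inner membrane to inner edge of the outer
        membrane), which guarantees the two membranes never overlap:
        outer = inner + 2t + d.
        """
        return self.dv_inner_radius + 2.0 * params.half_thickness + self.dv_distance

    def sphere_center(self, params: TransitionParams) -> np.ndarray:
        """Centre of the defining sphere(s), on the z axis."""
        sign = -1.0 if self.curvature == "down" else 1.0
        if self.kind == "vesicle":
            return np.array([0.0, 0.0, sign * self.vesicle_radius])
        if self.kind == "double_vesicle":
            # Place the centre so the aqueous gap between the membranes is
            # centred on the origin, where the protein sits.
            t, d = params.half_thickness, self.dv_distance
            return np.array([0.0, 0.0, sign * (self.dv_inner_radius + t + d / 2.0)])
        raise ValueError(f"geometry kind {self.kind!r} has no sphere centre")


@dataclass(frozen=True)
class PoreSpec:
    """Aqueous pore: a water-filled channel along an axis parallel to z.

    ``f_cavity = 1 / (1 + (rho/radius)^m)`` where rho is the lateral
    distance to the axis through ``(center_x, center_y)``: 1 on the axis,
    0.5 at ``radius``, 0 far away.
    """

    radius: float
    center_x: float = 0.0
    center_y: float = 0.0
    steepness: float = 10.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"pore radius must be > 0, got {self.radius}")
        if not (np.isfinite(self.steepness) and self.steepness > 0):
            raise ValueError(f"pore steepness must be > 0, got {self.steepness}")


@dataclass(frozen=True)
class HydrationResult:
    """Per-atom hydration values for a structure in a given geometry.

    ``f_thk`` is the geometry transition (before pore composition),
    ``f_cavity`` the pore transition (zeros when no pore), and ``f_hyd``
    their union.  ``h_radial`` holds the ellipsoid radial factor h when the
    geometry is an ellipsoid, else None.
    """

    f_thk: np.ndarray
    f_cavity: np.ndarray
    f_hyd: np.ndarray
    geometry: GeometrySpec
    params: TransitionParams
    pore: Optional[PoreSpec] = None
    h_radial: Optional[np.ndarray] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.f_hyd)


# ---------------------------------------------------------------------------
# scalar transition machinery
# ---------------------------------------------------------------------------

def _sigmoid(u: np.ndarray, n: float) -> np.ndarray:
    """u^n / (1 + u^n) for u >= 0, overflow-safe for large u and n."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u <= 1.0
    us = u[small] ** n
    out[small] = us / (1.0 + us)
    # for u > 1 use the reciprocal form 1 / (1 + u^-n)
    ul = u[~small] ** (-n)
    out[~small] = 1.0 / (1.0 + ul)
    return out


def _dsigmoid(u: np.ndarray, n: float) -> np.ndarray:
    """d/du of ``_sigmoid`` = n u^(n-1) / (1 + u^n)^2, overflow-safe."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u <= 1.0
    us = u[small] ** n
    out[small] = n * u[small] ** (n - 1.0) / (1.0 + us) ** 2
    ul = u[~small] ** (-n)
    out[~small] = n * u[~small] ** (-n - 1.0) / (1.0 + ul) ** 2
    return out


def _check_positions(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, dtype=float)
    if pos.shape[-1] != 3:
        raise ValueError(f"positions must have shape (..., 3), got {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    return pos


# ---------------------------------------------------------------------------
# transition functions
# ---------------------------------------------------------------------------

def f_thk_slab(z, params: TransitionParams = TransitionParams()):
    """Slab (flat-bilayer) transition: depends only on depth ``|z|``.

    0 at the membrane centre, 0.5 at depth t, -> 1 in bulk water.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    return _sigmoid(np.abs(z) / params.half_thickness, params.steepness)


def _ellipsoid_radial(pos: np.ndarray, geom: GeometrySpec, params: TransitionParams):
    """Effective radial coordinate r' and the factor h for the ellipsoid.

    The hydrophobic region is a disc of radius ``inner_radius`` in the
    membrane plane with a rounded rim: the distance that enters the sigmoid
    is measured from the edge of the disc, so

        r_eff = inner_radius + sqrt(max(0, rho - inner_radius)^2 + z^2)

    and r' = r_eff / outer_radius.  With inner_radius = 0 (micelle) this is
    the plain spherical distance from the origin.
    """
    outer = geom.ellipsoid_outer_radius(params)
    if outer <= 0:
        raise ValueError(f"ellipsoid outer radius must be > 0, got {outer}")
    x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
    rho = np.hypot(x, y)
    q = np.maximum(0.0, rho - geom.inner_radius)
    s = np.hypot(q, z)
    r_prime = (geom.inner_radius + s) / outer
    return r_prime, _sigmoid(r_prime, params.steepness)


def f_ellipsoid(pos, geom: GeometrySpec, params: TransitionParams = TransitionParams()):
    """Ellipsoid (micelle/bicelle) transition field.

    Union composition of the slab factor along z and the radial factor h:
    ``f = f_z + h - f_z * h``; equals 1 wherever either factor is 1.
    """
    if geom.kind != "ellipsoid":
        raise ValueError(f"expected ellipsoid geometry, got {geom.kind!r}")
    pos = _check_positions(pos)
    _, h = _ellipsoid_radial(pos, geom, params)
    fz = f_thk_slab(pos[..., 2], params)
    return fz + h - fz * h


def f_vesicle(pos, geom: GeometrySpec, params: TransitionParams = TransitionParams()):
    """Vesicle (curved membrane) transition field.

    The membrane mid-surface is a sphere of radius R centred at
    ``(0, 0, -R)`` (curvature 'down') or ``(0, 0, +R)``; the signed radial
    depth ``|pos - centre| - R`` plays the role of z, so the origin — where
    the protein is embedded — lies exactly on the mid-surface.
    """
    if geom.kind != "vesicle":
        raise ValueError(f"expected vesicle geometry, got {geom.kind!r}")
    pos = _check_positions(pos)
    center = geom.sphere_center(params)
    depth = np.linalg.norm(pos - center, axis=-1) - geom.vesicle_radius
    return f_thk_slab(depth, params)


def f_double_vesicle(pos, geom: GeometrySpec, params: TransitionParams = TransitionParams()):
    """Double-membrane transition field: product of two concentric vesicles.

    The inner sphere has mid-surface radius ``dv_inner_radius``; the outer
    sphere sits at ``dv_inner_radius + 2t + dv_distance`` so the aqueous gap
    between the membrane edges is exactly ``dv_distance`` wide.  The common
    centre is placed so the gap is centred on the origin.  The product rule
    makes a point hydrophobic (0) inside either membrane and aqueous (1)
    only when far from both.
    """
    if geom.kind != "double_vesicle":
        raise ValueError(f"expected double_vesicle geometry, got {geom.kind!r}")
    pos = _check_positions(pos)
    center = geom.sphere_center(params)
    r = np.linalg.norm(pos - center, axis=-1)
    f1 = f_thk_slab(r - geom.dv_inner_radius, params)
    f2 = f_thk_slab(r - geom.dv_outer_surface_radius(params), params)
    return f1 * f2


def f_cavity(pos, pore: PoreSpec):
    """Pore transition: 1 on the pore axis, 0.5 at the pore radius, -> 0 away."""
    if not pore.enabled:
        raise ValueError("pore is disabled")
    pos = _check_positions(pos)
    rho = np.hypot(pos[..., 0] - pore.center_x, pos[..., 1] - pore.center_y)
    return 1.0 - _sigmoid(rho / pore.radius, pore.steepness)


def compose_pore(f_thk, f_cav):
    """Union composition ``f_hyd = f_thk + f_cavity - f_thk * f_cavity``.

    Probabilistic-union algebra: commutative, identity 0, absorbing 1, and
    the result is never below either input.
    """
    f_thk = np.asarray(f_thk, dtype=float)
    f_cav = np.asarray(f_cav, dtype=float)
    if np.any((f_thk < 0) | (f_thk > 1)) or np.any((f_cav < 0) | (f_cav > 1)):
        raise ValueError("compose_pore inputs must lie in [0, 1]")
    out = f_thk + f_cav - f_thk * f_cav
    # enforce the algebra exactly at the boundary: 1 absorbs, and rounding
    # must not push the union outside [0, 1]
    out = np.where((f_thk == 1.0) | (f_cav == 1.0), 1.0, out)
    return np.clip(out, 0.0, 1.0)


def geometry_field(pos, geom: GeometrySpec, params: TransitionParams = TransitionParams()):
    """Evaluate the geometry transition (no pore) for any geometry kind."""
    if geom.kind == "slab":
        pos = _check_positions(pos)
        return f_thk_slab(pos[..., 2], params)
    if geom.kind == "ellipsoid":
        return f_ellipsoid(pos, geom, params)
    if geom.kind == "vesicle":
        return f_vesicle(pos, geom, params)
    if geom.kind == "double_vesicle":
        return f_double_vesicle(pos, geom, params)
    raise ValueError(f"unknown geometry kind {geom.kind!r}")


def hydration(structure, geom: GeometrySpec, pore: Optional[PoreSpec] = None,
              params: TransitionParams = TransitionParams()) -> HydrationResult:
    """Per-atom hydration of a structure: geometry field, optionally pore-composed.

    ``structure`` is anything with an ``xyz`` attribute of shape (N, 3)
    (e.g. :class:`memgeom.structure.Structure`) or a bare (N, 3) array.
    """
    xyz = getattr(structure, "xyz", structure)
    xyz = _check_positions(xyz)
    if xyz.ndim != 2 or xyz.shape[0] == 0:
        raise ValueError("structure must contain at least one atom")
    f_geo = geometry_field(xyz, geom, params)
    h_rad = None
    if geom.kind == "ellipsoid":
        _, h_rad = _ellipsoid_radial(xyz, geom, params)
    if pore is not None and pore.enabled:
        f_cav = f_cavity(xyz, pore)
        f_hyd = compose_pore(f_geo, f_cav)
    else:
        f_cav = np.zeros_like(f_geo)
        f_hyd = f_geo
    return HydrationResult(f_thk=f_geo, f_cavity=f_cav, f_hyd=f_hyd,
                           geometry=geom, params=params, pore=pore, h_radial=h_rad)


# ---------------------------------------------------------------------------
# analytic gradients
# ---------------------------------------------------------------------------

_EPS_RADIAL = 1e-9


def _grad_slab(pos: np.ndarray, params: TransitionParams) -> np.ndarray:
    z = pos[..., 2]
    t, n = params.half_thickness, params.steepness
    dfdz = _dsigmoid(np.abs(z) / t, n) * np.sign(z) / t
    grad = np.zeros_like(pos)
    grad[..., 2] = dfdz
    return grad


def _grad_vesicle_like(pos: np.ndarray, center: np.ndarray, surface_radius: float,
                       params: TransitionParams):
    """Gradient of f_thk(|pos-center| - R) plus the field value itself."""
    t, n = params.half_thickness, params.steepness
    rel = pos - center
    r = np.linalg.norm(rel, axis=-1)
    depth = r - surface_radius
    f = _sigmoid(np.abs(depth) / t, n)
    dfdr = _dsigmoid(np.abs(depth) / t, n) * np.sign(depth) / t
    at_center = r < _EPS_RADIAL
    if np.any(at_center):
        warnings.warn("gradient evaluated at a sphere centre; defined as zero there")
    safe_r = np.where(at_center, 1.0, r)
    unit = rel / safe_r[..., None]
    grad = dfdr[..., None] * unit
    grad[at_center] = 0.0
    return f, grad


def _grad_ellipsoid(pos: np.ndarray, geom: GeometrySpec, params: TransitionParams) -> np.ndarray:
    t, n = params.half_thickness, params.steepness
    outer = geom.ellipsoid_outer_radius(params)
    x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
    rho = np.hypot(x, y)
    q = np.maximum(0.0, rho - geom.inner_radius)
    s = np.hypot(q, z)
    r_prime = (geom.inner_radius + s) / outer
    h = _sigmoid(r_prime, n)
    dh = _dsigmoid(r_prime, n) / outer
    fz = _sigmoid(np.abs(z) / t, n)
    dfz = _dsigmoid(np.abs(z) / t, n) * np.sign(z) / t

    on_rim = s < _EPS_RADIAL  # the disc z=0, rho <= inner_radius: kink of s
    if np.any(on_rim):
        warnings.warn("ellipsoid gradient on the mid-plane disc; radial part defined zero")
    safe_s = np.where(on_rim, 1.0, s)
    safe_rho = np.where(rho < _EPS_RADIAL, 1.0, rho)
    # grad s: lateral (q/s) * rho_hat, vertical z/s
    gs_lat = q / safe_s
    gs = np.empty_like(pos)
    gs[..., 0] = gs_lat * x / safe_rho
    gs[..., 1] = gs_lat * y / safe_rho
    gs[..., 2] = z / safe_s
    gs[on_rim] = 0.0
    # f = fz + h - fz*h  ->  grad = (1-h) fz' e_z + (1-fz) h'(r') grad s / outer... dh already /outer
    grad = (1.0 - fz)[..., None] * dh[..., None] * gs
    grad[..., 2] += (1.0 - h) * dfz
    return grad


def _grad_geometry(pos: np.ndarray, geom: GeometrySpec, params: TransitionParams) -> np.ndarray:
    if geom.kind == "slab":
        return _grad_slab(pos, params)
    if geom.kind == "ellipsoid":
        return _grad_ellipsoid(pos, geom, params)
    if geom.kind == "vesicle":
        _, g = _grad_vesicle_like(pos, geom.sphere_center(params), geom.vesicle_radius, params)
        return g
    if geom.kind == "double_vesicle":
        center = geom.sphere_center(params)
        f1, g1 = _grad_vesicle_like(pos, center, geom.dv_inner_radius, params)
        f2, g2 = _grad_vesicle_like(pos, center, geom.dv_outer_surface_radius(params), params)
        return f1[..., None] * g2 + f2[..., None] * g1
    raise ValueError(f"unknown geometry kind {geom.kind!r}")


def _grad_cavity(pos: np.ndarray, pore: PoreSpec):
    dx = pos[..., 0] - pore.center_x
    dy = pos[..., 1] - pore.center_y
    rho = np.hypot(dx, dy)
    fc = 1.0 - _sigmoid(rho / pore.radius, pore.steepness)
    dfc = -_dsigmoid(rho / pore.radius, pore.steepness) / pore.radius
    safe_rho = np.where(rho < _EPS_RADIAL, 1.0, rho)
    grad = np.zeros_like(pos)
    grad[..., 0] = dfc * dx / safe_rho
    grad[..., 1] = dfc * dy / safe_rho
    grad[rho < _EPS_RADIAL] = 0.0  # smooth axis for m > 1: derivative vanishes
    return fc, grad


def gradient_f_hyd(pos, geom: GeometrySpec, pore: Optional[PoreSpec] = None,
                   params: TransitionParams = TransitionParams()) -> np.ndarray:
    """Analytic spatial gradient of ``f_hyd`` (units 1/Å).

    Matches the product/union rules of the field evaluation; at removable
    singular points (sphere centres, the ellipsoid mid-plane disc) the
    undefined directional part is defined as zero with a warning.
    """
    pos = _check_positions(pos)
    g_geo = _grad_geometry(pos, geom, params)
    if pore is None or not pore.enabled:
        return g_geo
    f_geo = geometry_field(pos, geom, params)
    fc, g_cav = _grad_cavity(pos, pore)
    return (1.0 - fc)[..., None] * g_geo + (1.0 - f_geo)[..., None] * g_cav
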