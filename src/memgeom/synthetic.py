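"""Synthetic structures and ensembles with known ground truth.

Everything the rest of the package consumes — membrane-coordinate PDB
structures, spanfiles, pore specifications, score/RMSD ensembles — can be
generated here, so geometry recovery, pore classification and the
discrimination metrics are all testable closed-loop without downloading
any real structure.

The structural generators produce idealised alpha-helical CA traces
(rise 1.5 Å per residue, 100 deg twist, helix radius 2.3 Å) in membrane
coordinates: membrane normal along z, membrane centre at the origin.
They are simplified in ways that matter for interpretation: no side
chains (except the poly-alanine mode), no loops connecting helices, no
deviation from ideal helical geometry, and noise (where any) is
isotropic Gaussian on coordinates.
"""

from __future__ import annotations

import numpy as np

from .geometry import PoreSpec, TransitionParams
from .metrics import EnsembleTable
from .structure import SpanFile, Structure

__all__ = ["make_tm_helix", "make_pore_bundle", "make_curved_bundle",
           "make_funnel_ensemble"]

HELIX_RISE = 1.5       # Å per residue along the helix axis
HELIX_RADIUS = 2.3     # Å, CA distance from the helix axis
HELIX_TWIST = 100.0    # degrees per residue
COORD_NOISE_SD = 0.0   # Å, default positional jitter (generators accept their own)


def _assemble(ca_xyz: np.ndarray, resname: str = "ALA",
              chain_per_atom=None, mode: str = "ca") -> Structure:
    """Build a Structure from per-residue CA coordinates.

    ``mode="ca"`` emits a CA-only trace; ``mode="polyala"`` adds idealised
    N, C, O and CB positions around each CA (geometry only approximate —
    sufficient to exercise per-atom energetics, not stereochemistry).
    """
    n = len(ca_xyz)
    chains = chain_per_atom if chain_per_atom is not None else ["A"] * n
    serial, names, elements, resnames, chain_ids, resnums, pose, xyz = \
        [], [], [], [], [], [], [], []
    # local frame per residue from the chain direction
    for i, ca in enumerate(ca_xyz):
        d = ca_xyz[min(i + 1, n - 1)] - ca_xyz[max(i - 1, 0)]
        d = d / np.linalg.norm(d)
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        if mode == "ca":
            atoms = [("CA", "C", ca)]
        else:
            atoms = [
                ("N", "N", ca - 1.46 * d + 0.3 * perp),
                ("CA", "C", ca),
                ("C", "C", ca + 1.52 * d + 0.3 * perp),
                ("O", "O", ca + 1.52 * d + 1.5 * perp),
                ("CB", "C", ca + 1.53 * np.cross(d, perp)),
            ]
        for name, element, p in atoms:
            serial.append(len(serial) + 1)
            names.append(name)
            elements.append(element)
            resnames.append(resname)
            chain_ids.append(chains[i])
            resnums.append(i + 1)
            pose.append(i + 1)
            xyz.append(p)
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(names, dtype=object),
        element=np.asarray(elements, dtype=object),
        resname=np.asarray(resnames, dtype=object),
        chain=np.asarray(chain_ids, dtype=object),
        resnum=np.asarray(resnums, dtype=int),
        pose_index=np.asarray(pose, dtype=int),
        xyz=np.asarray(xyz, dtype=float),
        b_factor=np.zeros(len(serial)),
        is_hetatm=np.zeros(len(serial), dtype=bool),
    )


def _helix_trace(n_res: int, rise: float, radius: float,
                 axis_point: np.ndarray, axis_dir: np.ndarray,
                 phase_deg: float = 0.0) -> np.ndarray:
    """CA coordinates of an ideal helix around an arbitrary axis."""
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    perp = np.cross(axis_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    perp2 = np.cross(axis_dir, perp)
    offsets = (np.arange(n_res) - (n_res - 1) / 2.0) * rise
    angles = np.deg2rad(HELIX_TWIST * np.arange(n_res) + phase_deg)
    return (axis_point[None, :]
            + offsets[:, None] * axis_dir[None, :]
            + radius * np.cos(angles)[:, None] * perp[None, :]
            + radius * np.sin(angles)[:, None] * perp2[None, :])


def _spans_from_depth(depth: np.ndarray, n_res: int,
                      half_thickness: float) -> SpanFile:
    """Contiguous runs of residues with |depth| < half_thickness."""
    inside = np.abs(depth) < half_thickness
    spans = []
    start = None
    for i, flag in enumerate(inside, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, n_res))
    if not spans:
        raise ValueError("no residues inside the membrane; nothing to span")
    return SpanFile.from_ranges(spans, n_res)


def make_tm_helix(n_res: int = 31, rise: float = HELIX_RISE,
                  radius: float = HELIX_RADIUS, seed: int = 0,
                  noise_sd: float = COORD_NOISE_SD,
                  mode: str = "ca") -> tuple[Structure, SpanFile]:
    """Single transmembrane helix along z, centred at the origin.

    Returns the structure and the spanfile of residues within the default
    15 Å hydrophobic half-thickness.  Deterministic for a fixed seed.
    """
    if n_res < 5:
        raise ValueError(f"need at least 5 residues, got {n_res}")
    rng = np.random.default_rng(seed)
    ca = _helix_trace(n_res, rise, radius, np.zeros(3), np.array([0.0, 0.0, 1.0]))
    if noise_sd > 0:
        ca = ca + rng.normal(0.0, noise_sd, ca.shape)
    ca = ca - ca.mean(axis=0)  # centre of mass at the origin
    st = _assemble(ca, mode=mode)
    span = _spans_from_depth(ca[:, 2], n_res, TransitionParams().half_thickness)
    return st, span


def make_pore_bundle(n_helices: int = 4, pore_radius: float = 5.0,
                     seed: int = 0, n_res: int = 21,
                     noise_sd: float = COORD_NOISE_SD
                     ) -> tuple[Structure, PoreSpec, SpanFile]:
    """Helix bundle around a central aqueous pore on the z axis.

    Helix axes stand on a circle of radius ``pore_radius + 3`` Å; the CA
    wobble makes some face the pore (lateral distance < axis circle) and
    some face the lipid.  The returned PoreSpec has radius ``pore_radius``.
    """
    if n_helices < 3:
        raise ValueError(f"need at least 3 helices around a pore, got {n_helices}")
    if n_res < 5:
        raise ValueError(f"need at least 5 residues per helix, got {n_res}")
    rng = np.random.default_rng(seed)
    ring = pore_radius + 3.0
    traces, chains = [], []
    for k in range(n_helices):
        theta = 2.0 * np.pi * k / n_helices
        axis_point = np.array([ring * np.cos(theta), ring * np.sin(theta), 0.0])
        # phase so the first CA points at the pore axis
        phase = np.degrees(theta) + 180.0
        tr = _helix_trace(n_res, HELIX_RISE, HELIX_RADIUS, axis_point,
                          np.array([0.0, 0.0, 1.0]), phase_deg=phase)
        if noise_sd > 0:
            tr = tr + rng.normal(0.0, noise_sd, tr.shape)
        traces.append(tr)
        chains.extend(chr(ord("A") + k) * n_res)
    ca = np.vstack(traces)
    st = _assemble(ca, chain_per_atom=chains)
    span = _spans_from_depth(ca[:, 2], n_helices * n_res,
                             TransitionParams().half_thickness)
    pore = PoreSpec(radius=pore_radius)
    return st, pore, span


def make_curved_bundle(R_true: float = 120.0, n_helices: int = 7,
                       seed: int = 0, n_res: int = 31,
                       lateral_extent: float = 200.0,
                       noise_sd: float = COORD_NOISE_SD
                       ) -> tuple[Structure, SpanFile]:
    """Helix bundle embedded in a curved membrane of known radius.

    Helix midpoints lie on the sphere of radius ``R_true`` centred at
    ``(0, 0, -R_true)`` (curvature down) with lateral offsets spread up to
    ``lateral_extent / 2``; each helix runs along the local sphere normal.
    The spanfile marks residues within the 15 Å hydrophobic half-thickness
    of the true curved membrane — the ground truth a geometry optimiser
    should recover.
    """
    if R_true < 50.0:
        raise ValueError(f"curvature radius below 50 Å not supported, got {R_true}")
    if lateral_extent / 2.0 >= R_true:
        raise ValueError("lateral extent exceeds the curvature radius")
    rng = np.random.default_rng(seed)
    center = np.array([0.0, 0.0, -R_true])
    # one central helix, the rest on rings of increasing lateral offset
    laterals = np.linspace(0.0, lateral_extent / 2.0, n_helices)
    azimuths = rng.uniform(0.0, 2.0 * np.pi, n_helices)
    traces, chains, depths = [], [], []
    for k, (lat, az) in enumerate(zip(laterals, azimuths)):
        z_mid = -R_true + np.sqrt(R_true ** 2 - lat ** 2)
        midpoint = np.array([lat * np.cos(az), lat * np.sin(az), z_mid])
        normal = (midpoint - center) / R_true
        tr = _helix_trace(n_res, HELIX_RISE, HELIX_RADIUS, midpoint, normal)
        if noise_sd > 0:
            tr = tr + rng.normal(0.0, noise_sd, tr.shape)
        traces.append(tr)
        chains.extend(chr(ord("A") + k % 26) * n_res)
        depths.append(np.linalg.norm(tr - center, axis=1) - R_true)
    ca = np.vstack(traces)
    st = _assemble(ca, chain_per_atom=chains)
    span = _spans_from_depth(np.concatenate(depths), n_helices * n_res,
                             TransitionParams().half_thickness)
    return st, span


def make_funnel_ensemble(n_models: int = 1000, funnel_quality: float = 1.0,
                         seed: int = 0, rmsd_sd: float = 5.0,
                         score_slope: float = 1.0,
                         score_noise_sd: float = 5.0) -> EnsembleTable:
    """Score/RMSD ensemble with tunable funnel quality q in [0, 1].

    rmsd ~ |Normal(0, rmsd_sd)|;
    score = q * slope * rmsd + (1 - q) * Normal(0, score_noise_sd).

    q = 1 gives a perfect funnel (score rank == RMSD rank, enrichment 10);
    q = 0 gives a score independent of RMSD (enrichment ~1 on average).
    """
    if n_models < 20:
        raise ValueError(f"need at least 20 models, got {n_models}")
    if not 0.0 <= funnel_quality <= 1.0:
        raise ValueError(f"funnel_quality must be in [0, 1], got {funnel_quality}")
    rng = np.random.default_rng(seed)
    rmsd = np.abs(rng.normal(0.0, rmsd_sd, n_models))
    score = (funnel_quality * score_slope * rmsd
             + (1.0 - funnel_quality) * rng.normal(0.0, score_noise_sd, n_models))
    return EnsembleTable.from_arrays(score, rmsd)
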