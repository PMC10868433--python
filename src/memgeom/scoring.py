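"""Geometry-dependent burial free energy and residue environment classes.

The burial term sums, over all atoms, the water-to-bilayer transfer free
energy weighted by how deeply the atom sits in the hydrophobic phase:

    dG_memb = sum_r sum_a (1 - f_hyd(a)) * dG_wl(a)

so an atom fully in water (f_hyd = 1) contributes nothing and an atom in
the membrane core (f_hyd = 0) contributes its full transfer energy.  The
per-atom-class transfer energies are supplied by an :class:`EnergyTable`;
the bundled default spreads residue-level side-chain transfer values (on
the scale of the Moon–Fleming hydrophobicity measurements, kcal/mol,
negative = prefers the bilayer) evenly over side-chain heavy atoms, with
backbone atoms at zero.  It is a demonstration parameterisation — any
table can be loaded from a two-column text file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import HydrationResult
from .structure import Structure

__all__ = ["EnergyTable", "BurialScore", "burial_energy", "classify_residues",
           "RESIDUE_LABELS"]

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}

# Side-chain water->bilayer transfer free energies, kcal/mol
# (demonstration defaults on the Moon–Fleming scale; negative favours the
# hydrophobic phase).  Loadable replacements: EnergyTable.from_file.
_DEFAULT_SIDECHAIN_DG = {
    "ALA": -0.50, "ARG": +2.60, "ASN": +1.30, "ASP": +2.20, "CYS": -0.60,
    "GLN": +1.20, "GLU": +2.00, "GLY": 0.00, "HIS": +1.60, "ILE": -1.60,
    "LEU": -1.80, "LYS": +2.30, "MET": -1.40, "PHE": -2.00, "PRO": +0.40,
    "SER": +0.60, "THR": +0.50, "TRP": -2.10, "TYR": -1.00, "VAL": -1.00,
}

# heavy side-chain atom counts of the standard residues
_SIDECHAIN_HEAVY = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}


@dataclass(frozen=True)
class EnergyTable:
    """Water->bilayer transfer energies per atom class.

    ``entries`` maps ``"RES:ATOM"`` keys (e.g. ``"LEU:CD1"``) to kcal/mol;
    ``element_fallback`` maps bare element symbols.  Unknown atoms fall back
    to their element entry, else 0 with a warning.
    """

    entries: dict
    element_fallback: dict

    def __post_init__(self) -> None:
        values = list(self.entries.values()) + list(self.element_fallback.values())
        if not values:
            raise ValueError("energy table is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("energy table contains non-finite values")

    @classmethod
    def default_demo(cls) -> "EnergyTable":
        """Residue-level defaults spread evenly over side-chain heavy atoms."""
        entries = {}
        for res, dg in _DEFAULT_SIDECHAIN_DG.items():
            n_heavy = _SIDECHAIN_HEAVY[res]
            entries[f"{res}:*sidechain*"] = dg / n_heavy if n_heavy else 0.0
        return cls(entries=entries, element_fallback={"C": 0.0, "N": 0.0,
                                                      "O": 0.0, "S": 0.0})

    @classmethod
    def from_file(cls, path) -> "EnergyTable":
        """Load 'RES:ATOM value' or 'ELEMENT value' lines ('#' comments)."""
        entries, fallback = {}, {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            key, value = ln.split()[:2]
            if ":" in key:
                entries[key.upper()] = float(value)
            else:
                fallback[key.upper()] = float(value)
        return cls(entries=entries, element_fallback=fallback)

    def lookup(self, resname: str, atom_name: str, element: str) -> float:
        key = f"{resname.upper()}:{atom_name.upper()}"
        if key in self.entries:
            return self.entries[key]
        if atom_name.upper() in _BACKBONE:
            return 0.0
        if not atom_name.upper().startswith("H"):
            wild = f"{resname.upper()}:*sidechain*"
            if wild in self.entries:
                return self.entries[wild]
        if element.upper() in self.element_fallback:
            return self.element_fallback[element.upper()]
        warnings.warn(f"no transfer energy for {resname}:{atom_name}; using 0")
        return 0.0


@dataclass(frozen=True)
class BurialScore:
    """Total burial free energy and its per-residue decomposition (kcal/mol)."""

    total: float
    per_residue: dict  # pose residue number -> kcal/mol


def burial_energy(structure: Structure, hydration: HydrationResult,
                  table: EnergyTable | None = None) -> BurialScore:
    """Evaluate dG_memb = sum_atoms (1 - f_hyd) * dG_wl over the structure."""
    if table is None:
        table = EnergyTable.default_demo()
    f_hyd = np.asarray(hydration.f_hyd, dtype=float)
    if f_hyd.shape != (structure.n_atoms,):
        raise ValueError("hydration does not match structure")
    dg = np.array([table.lookup(str(r), str(a), str(e))
                   for r, a, e in zip(structure.resname, structure.name,
                                      structure.element)])
    contrib = (1.0 - f_hyd) * dg
    per_residue: dict[int, float] = {}
    for pose, c in zip(structure.pose_index, contrib):
        per_residue[int(pose)] = per_residue.get(int(pose), 0.0) + float(c)
    return BurialScore(total=float(contrib.sum()), per_residue=per_residue)


RESIDUE_LABELS = ("pore_facing", "lipid_facing", "aqueous", "interface")

# pore-facing rule thresholds (transition-function units)
PORE_FACING_MIN_FCAVITY = 0.1
PORE_FACING_MAX_FTHK = 0.75
# environment cut-offs on f_hyd, symmetric about 0.5
LIPID_FACING_MAX_FHYD = 0.25
AQUEOUS_MIN_FHYD = 0.75


def classify_residues(structure: Structure, hydration: HydrationResult,
                      representative: str = "CA") -> dict[int, str]:
    """Label each residue pore_facing / lipid_facing / aqueous / interface.

    A residue is *pore-facing* when, at its representative atom,
    ``f_cavity > 0.1`` and ``f_thk < 0.75`` — i.e. the pore contributes
    measurable hydration and the residue is not already out of the bilayer.
    Remaining residues are lipid_facing (f_hyd < 0.25), aqueous
    (f_hyd > 0.75) or interface.

    ``representative`` is ``"CA"`` (default) or ``"sidechain_centroid"``,
    which averages the transition values over side-chain heavy atoms and
    falls back to CA for glycine/CA-only residues.
    """
    if hydration.pore is None or not hydration.pore.enabled:
        raise ValueError("classification requires pore-enabled hydration")
    if representative not in ("CA", "sidechain_centroid"):
        raise ValueError(f"unknown representative atom rule {representative!r}")

    ca_idx = structure.ca_atom_indices()
    labels: dict[int, str] = {}
    for pose in range(1, structure.n_residues + 1):
        if representative == "sidechain_centroid":
            mask = (structure.pose_index == pose) & \
                   ~np.isin(structure.name.astype(str), list(_BACKBONE))
            idx = np.flatnonzero(mask)
            if idx.size:
                f_thk = float(hydration.f_thk[idx].mean())
                f_cav = float(hydration.f_cavity[idx].mean())
                f_hyd = float(hydration.f_hyd[idx].mean())
            elif pose in ca_idx:
                i = ca_idx[pose]
                f_thk, f_cav, f_hyd = (float(hydration.f_thk[i]),
                                       float(hydration.f_cavity[i]),
                                       float(hydration.f_hyd[i]))
            else:
                continue
        else:
            if pose not in ca_idx:
                continue
            i = ca_idx[pose]
            f_thk, f_cav, f_hyd = (float(hydration.f_thk[i]),
                                   float(hydration.f_cavity[i]),
                                   float(hydration.f_hyd[i]))
        if f_cav > PORE_FACING_MIN_FCAVITY and f_thk < PORE_FACING_MAX_FTHK:
            labels[pose] = "pore_facing"
        elif f_hyd < LIPID_FACING_MAX_FHYD:
            labels[pose] = "lipid_facing"
        elif f_hyd > AQUEOUS_MIN_FHYD:
            labels[pose] = "aqueous"
        else:
            labels[pose] = "interface"
    return labels
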