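"""PDB structures, spanfiles, and B-factor annotation.

Structures are held as flat, atom-ordered arrays — enough identity to
round-trip a coordinate file and address residues, nothing more.  Parsing
is delegated to gemmi; writing uses the fixed-column PDB v3.3 layout
(coordinates in columns 31–54, B-factor in 61–66) so that annotated files
open in PyMOL/ChimeraX for colouring by the transition value.

A spanfile lists the residue ranges expected to cross the membrane, in the
widely used Rosetta dialect::

    <free-text header>
    <n_spans> <n_res>
    antiparallel
    n2c
    <start> <end>      # one line per span, 1-based inclusive, pose numbering
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = ["Structure", "SpanFile", "read_pdb", "write_pdb",
           "read_spanfile", "write_spanfile", "map_transition_to_bfactor"]


@dataclass(frozen=True)
class Structure:
    """Ordered atoms with coordinates and a writable B-factor slot.

    ``pose_index`` numbers residues 1..N in order of first appearance
    (spanfile semantics); the original PDB ``resnum``/``chain`` are kept
    for output.
    """

    serial: np.ndarray      # (N,) int
    name: np.ndarray        # (N,) atom names, e.g. "CA"
    element: np.ndarray     # (N,) element symbols
    resname: np.ndarray     # (N,)
    chain: np.ndarray       # (N,)
    resnum: np.ndarray      # (N,) int, PDB numbering
    pose_index: np.ndarray  # (N,) int, 1-based residue order of appearance
    xyz: np.ndarray         # (N, 3) float, Å
    b_factor: np.ndarray    # (N,) float
    is_hetatm: np.ndarray   # (N,) bool

    def __post_init__(self) -> None:
        n = len(self.serial)
        if n == 0:
            raise ValueError("structure must contain at least one atom")
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz shape {self.xyz.shape} does not match {n} atoms")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def n_residues(self) -> int:
        return int(self.pose_index.max())

    def ca_atom_indices(self) -> dict[int, int]:
        """Map pose residue number -> index of its CA atom.

        Residues without a CA are excluded with a warning; CA-based
        operations silently skip them.
        """
        out: dict[int, int] = {}
        for i in np.flatnonzero(self.name == "CA"):
            out.setdefault(int(self.pose_index[i]), int(i))
        missing = set(range(1, self.n_residues + 1)) - out.keys()
        if missing:
            warnings.warn(f"{len(missing)} residue(s) lack a CA atom and are "
                          "excluded from CA-based operations")
        return out

    def with_b_factors(self, b: np.ndarray) -> "Structure":
        b = np.asarray(b, dtype=float)
        if b.shape != (self.n_atoms,):
            raise ValueError(f"expected {self.n_atoms} B-factors, got shape {b.shape}")
        return replace(self, b_factor=b)


def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    HETATM records are retained but flagged; for alternate locations only
    the first conformer is kept, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if any(atom.altloc not in ("", "\0", "A")
           for chain in st[0] for res in chain for atom in res):
        warnings.warn(f"{path}: alternate locations present; keeping first conformer")
    st.remove_alternative_conformations()

    serial, name, element, resname, chain_ids, resnum, pose, het = \
        [], [], [], [], [], [], [], []
    xyz, b = [], []
    seen_residues: dict[tuple, int] = {}
    for chain in st[0]:
        for res in chain:
            key = (chain.name, res.seqid.num, res.seqid.icode)
            if key not in seen_residues:
                seen_residues[key] = len(seen_residues) + 1
            for atom in res:
                serial.append(atom.serial)
                name.append(atom.name)
                element.append(atom.element.name.upper())
                resname.append(res.name)
                chain_ids.append(chain.name)
                resnum.append(res.seqid.num)
                pose.append(seen_residues[key])
                het.append(res.het_flag == "H")
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                b.append(atom.b_iso)
    if not serial:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(name, dtype=object),
        element=np.asarray(element, dtype=object),
        resname=np.asarray(resname, dtype=object),
        chain=np.asarray(chain_ids, dtype=object),
        resnum=np.asarray(resnum, dtype=int),
        pose_index=np.asarray(pose, dtype=int),
        xyz=np.asarray(xyz, dtype=float),
        b_factor=np.asarray(b, dtype=float),
        is_hetatm=np.asarray(het, dtype=bool),
    )


def _format_atom_name(name: str, element: str) -> str:
    # PDB v3.3: element symbol right-justified in columns 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column PDB v3.3 ATOM/HETATM records (occupancy 1.00)."""
    lines = []
    for i in range(structure.n_atoms):
        record = "HETATM" if structure.is_hetatm[i] else "ATOM  "
        x, y, z = structure.xyz[i]
        lines.append(
            f"{record}{structure.serial[i] % 100000:5d} "
            f"{_format_atom_name(str(structure.name[i]), str(structure.element[i]))}"
            f" {str(structure.resname[i]):>3s} {str(structure.chain[i])[:1]:1s}"
            f"{structure.resnum[i] % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{structure.b_factor[i]:6.2f}"
            f"          {str(structure.element[i]):>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def map_transition_to_bfactor(structure: Structure, hydration) -> Structure:
    """Copy the per-atom ``f_hyd`` into the B-factor slot (rounded to 2 dp).

    Coordinates and every other field are untouched; writing the result
    with :func:`write_pdb` quantises to the %6.2f B-factor column, so a
    value of 0 prints as ``0.00`` and 1 as ``1.00``.
    """
    f_hyd = np.asarray(getattr(hydration, "f_hyd", hydration), dtype=float)
    if f_hyd.shape != (structure.n_atoms,):
        raise ValueError(
            f"hydration has {f_hyd.shape} values for {structure.n_atoms} atoms")
    return structure.with_b_factors(np.round(f_hyd, 2))


# ---------------------------------------------------------------------------
# spanfiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpanFile:
    """Membrane-spanning residue ranges (1-based inclusive, pose numbering)."""

    n_res: int
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("spanfile must contain at least one span")
        for start, end in self.spans:
            if not (1 <= start <= end <= self.n_res):
                raise ValueError(
                    f"span ({start}, {end}) outside 1..{self.n_res}")

    @classmethod
    def from_ranges(cls, spans: Iterable[tuple[int, int]], n_res: int) -> "SpanFile":
        return cls(n_res=n_res, spans=_normalize_spans(spans))

    def residues(self) -> set[int]:
        """Set of residue pose numbers covered by any span."""
        out: set[int] = set()
        for start, end in self.spans:
            out.update(range(start, end + 1))
        return out


def _normalize_spans(spans: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    spans = sorted((int(s), int(e)) for s, e in spans)
    merged: list[list[int]] = []
    overlapped = False
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            overlapped = True
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    if overlapped:
        warnings.warn("overlapping spans merged")
    return tuple((s, e) for s, e in merged)


def read_spanfile(path) -> SpanFile:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if len(lines) < 5:
        raise ValueError(f"{path}: truncated spanfile (need header, counts, "
                         "topology lines and at least one span)")
    try:
        n_spans, n_res = (int(tok) for tok in lines[1].split()[:2])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line 2 must be '<n_spans> <n_res>'") from exc
    raw = []
    for ln in lines[4:4 + n_spans]:
        toks = ln.split()
        if len(toks) < 2:
            raise ValueError(f"{path}: bad span line {ln!r}")
        raw.append((int(toks[0]), int(toks[1])))
    if len(raw) != n_spans:
        raise ValueError(f"{path}: declared {n_spans} spans, found {len(raw)}")
    return SpanFile(n_res=n_res, spans=_normalize_spans(raw))


def write_spanfile(spanfile: SpanFile, path) -> None:
    lines = [
        "TM region prediction",
        f"{len(spanfile.spans)} {spanfile.n_res}",
        "antiparallel",
        "n2c",
    ]
    lines += [f"\t{start}\t{end}" for start, end in spanfile.spans]
    Path(path).write_text("\n".join(lines) + "\n")
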