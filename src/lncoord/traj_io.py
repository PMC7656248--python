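"""Topology/trajectory containers, standard-format I/O, and atom selections.

Internal units are nm for coordinates and box edges and ps for time; PDB
files (angstrom by convention) are converted on read and write.  Boxes are
orthorhombic only and all distances elsewhere in the package use the
minimum-image convention.

Formats: single- and multi-model PDB (MODEL/ENDMDL blocks, CRYST1 box) via
biotite, and XYZ with a plain-text sidecar box file holding one edge triple
per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import LN_SERIES, WATER_RESNAMES

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "TrajectoryFormatError",
    "SelectionError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
]

_LN_UPPER = {s.upper() for s in LN_SERIES}


class TrajectoryFormatError(ValueError):
    """Malformed or inconsistent topology/trajectory input."""


class SelectionError(ValueError):
    """Invalid atom-selection expression."""


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    resname: str
    resid: int
    element: str
    molclass: str  # peptide | ion | water


@dataclass
class Topology:
    """Ordered atom list with per-atom molecule classification."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        idx = [a.index for a in self.atoms]
        if idx != list(range(len(self.atoms))):
            raise TrajectoryFormatError("atom indices must be contiguous from 0")
        self._check_water_oxygens()

    def _check_water_oxygens(self) -> None:
        counts: dict[tuple[str, int], int] = {}
        for a in self.atoms:
            if a.molclass == "water":
                key = (a.resname, a.resid)
                counts[key] = counts.get(key, 0) + (1 if a.element == "O" else 0)
        bad = [k for k, n in counts.items() if n != 1]
        if bad:
            raise TrajectoryFormatError(f"waters without exactly one oxygen: {bad[:5]}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def class_counts(self) -> dict[str, int]:
        out = {"peptide": 0, "ion": 0, "water": 0}
        for a in self.atoms:
            out[a.molclass] += 1
        return out

    def water_oxygen_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.molclass == "water" and a.element == "O"],
            dtype=int,
        )


@dataclass
class Trajectory:
    """Frames of coordinates (nm) with per-frame orthorhombic box edges (nm)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray          # (n_frames, 3)
    times: np.ndarray        # (n_frames,) ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryFormatError("coordinates must have shape (frames, atoms, 3)")
        n = self.n_frames
        if self.box.shape != (n, 3) or self.times.shape != (n,):
            raise TrajectoryFormatError("box/times length must equal n_frames")
        if np.any(self.box <= 0):
            raise TrajectoryFormatError("box edges must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AtomSelection:
    expression: str
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# classification

def _classify(name: str, resname: str, element: str) -> str:
    if resname.upper() in WATER_RESNAMES:
        return "water"
    if element.capitalize() in LN_SERIES or resname.upper() in _LN_UPPER:
        return "ion"
    return "peptide"


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].capitalize() in LN_SERIES:
        return stripped[:2].capitalize()
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# PDB / XYZ readers

def read_topology(path: str | Path) -> Topology:
    """Read a PDB topology (first model) and classify each atom.

    Waters are detected by residue name (HOH/WAT/SOL), the ion by element or
    residue name in the lanthanide symbol set; anything else is peptide.
    Atoms without a recognisable element are classified peptide with a
    warning.  Duplicate atom serial numbers are a format error.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    serials = arr.atom_id
    if len(np.unique(serials)) != len(serials):
        raise TrajectoryFormatError(f"duplicate atom serial numbers in {path}")
    atoms = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        resname = str(arr.res_name[i])
        element = str(arr.element[i]).capitalize()
        if not element:
            element = _guess_element(name)
        if not element:
            warnings.warn(f"atom {i} ({name}) has no element; classified peptide")
        atoms.append(
            Atom(
                index=i,
                name=name,
                resname=resname,
                resid=int(arr.res_id[i]),
                element=element,
                molclass=_classify(name, resname, element),
            )
        )
    return Topology(atoms)


def _box_from_biotite(box: np.ndarray | None, n_frames: int, path) -> np.ndarray:
    if box is None:
        raise TrajectoryFormatError(
            f"{path}: no CRYST1 record; a box is required (no silent infinite box)"
        )
    box = np.asarray(box, dtype=float)
    if box.ndim == 2:  # single (3,3) cell
        box = np.broadcast_to(box, (n_frames, 3, 3))
    return np.ascontiguousarray(np.diagonal(box, axis1=1, axis2=2))


def read_trajectory(
    path: str | Path,
    topology: Topology,
    unit: str = "A",
    dt: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or concatenated-XYZ trajectory.

    Parameters
    ----------
    unit:
        Declared coordinate unit of the file, ``"A"`` or ``"nm"``; always
        normalised to nm in the returned trajectory.  PDB files are
        angstrom by convention.
    dt:
        Frame spacing in ps used to synthesise frame times.

    XYZ files require a sidecar box file at ``<path>.box`` (one whitespace
    separated edge triple in nm per frame, or a single line reused for all
    frames) because the format itself carries no cell.
    """
    path = Path(path)
    scale = {"A": 0.1, "nm": 1.0}.get(unit)
    if scale is None:
        raise ValueError(f"unit must be 'A' or 'nm', got {unit!r}")
    if path.suffix.lower() == ".xyz":
        coords = _read_xyz_frames(path, topology)
        coords = coords * scale
        box = _read_box_sidecar(path, coords.shape[0])
    else:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        coords = np.asarray(stack.coord, dtype=float) * 0.1  # PDB is angstrom
        if stack.array_length() != topology.n_atoms:
            raise TrajectoryFormatError(
                f"{path}: atom count {stack.array_length()} != topology {topology.n_atoms}"
            )
        box = _box_from_biotite(stack.box, coords.shape[0], path) * 0.1  # A -> nm
    if coords.shape[1] != topology.n_atoms:
        raise TrajectoryFormatError(
            f"{path}: atom count {coords.shape[1]} != topology {topology.n_atoms}"
        )
    times = np.arange(coords.shape[0], dtype=float) * dt
    return Trajectory(coords, box, times)


def _read_xyz_frames(path: Path, topology: Topology) -> np.ndarray:
    frames = []
    lines = path.read_text().splitlines()
    k = 0
    frame_no = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].split()[0])
        except ValueError:
            raise TrajectoryFormatError(f"{path}: bad atom-count line at {k}") from None
        if n != topology.n_atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_no} has {n} atoms, topology has {topology.n_atoms}"
            )
        block = lines[k + 2 : k + 2 + n]
        if len(block) < n:
            raise TrajectoryFormatError(f"{path}: truncated frame {frame_no}")
        frames.append([[float(x) for x in ln.split()[1:4]] for ln in block])
        k += 2 + n
        frame_no += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    return np.asarray(frames, dtype=float)


def _read_box_sidecar(path: Path, n_frames: int) -> np.ndarray:
    sidecar = path.with_suffix(path.suffix + ".box")
    if not sidecar.exists():
        raise TrajectoryFormatError(
            f"{path}: XYZ carries no cell and sidecar {sidecar} is missing"
        )
    rows = [
        [float(x) for x in ln.split()]
        for ln in sidecar.read_text().splitlines()
        if ln.strip()
    ]
    box = np.asarray(rows, dtype=float)
    if box.shape == (1, 3):
        box = np.broadcast_to(box, (n_frames, 3)).copy()
    if box.shape != (n_frames, 3):
        raise TrajectoryFormatError(f"{sidecar}: expected {n_frames} edge triples")
    return box


# ---------------------------------------------------------------------------
# writers

def write_trajectory(
    traj: Trajectory,
    topology: Topology,
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write a trajectory as multi-model PDB (with CRYST1) or XYZ + box sidecar."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "pdb":
        _write_pdb(traj, topology, path)
    elif fmt == "xyz":
        _write_xyz(traj, topology, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _biotite_template(topology: Topology) -> struc.AtomArray:
    arr = struc.AtomArray(topology.n_atoms)
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.res_name = np.array([a.resname for a in topology.atoms])
    arr.res_id = np.array([a.resid for a in topology.atoms])
    arr.element = np.array([a.element.upper() for a in topology.atoms])
    arr.chain_id = np.array(["A"] * topology.n_atoms)
    arr.hetero = np.array([a.molclass != "peptide" for a in topology.atoms])
    return arr


def _write_pdb(traj: Trajectory, topology: Topology, path: Path) -> None:
    template = _biotite_template(topology)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = np.asarray(traj.coordinates, dtype=np.float32) * 10.0  # nm -> A
    cell = np.zeros((traj.n_frames, 3, 3))
    for ax in range(3):
        cell[:, ax, ax] = traj.box[:, ax] * 10.0
    stack.box = cell
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _write_xyz(traj: Trajectory, topology: Topology, path: Path) -> None:
    names = [a.name for a in topology.atoms]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {f} t={traj.times[f]:.3f} ps (nm)\n")
            for name, (x, y, z) in zip(names, traj.coordinates[f]):
                fh.write(f"{name:<4s} {x:.6f} {y:.6f} {z:.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".box")
    np.savetxt(sidecar, traj.box, fmt="%.6f")


# ---------------------------------------------------------------------------
# selection grammar:  expr := term ('or' term)* ; term := factor ('and' factor)*
#                     factor := 'not' factor | '(' expr ')' | key value

_KEYWORDS = {"resid", "resname", "name"}


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.toks = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing input at token {self.pos}: {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("expected ')'")
            return mask
        if tok in _KEYWORDS:
            key = self.take()
            value = self.take()
            return self.leaf(key, value)
        raise SelectionError(f"unknown keyword at token {self.pos}: {tok!r}")

    def leaf(self, key: str, value: str) -> np.ndarray:
        atoms = self.top.atoms
        if key == "resid":
            try:
                rid = int(value)
            except ValueError:
                raise SelectionError(f"resid takes an integer, got {value!r}") from None
            return np.array([a.resid == rid for a in atoms])
        if key == "resname":
            return np.array([a.resname.upper() == value.upper() for a in atoms])
        return np.array([a.name.upper() == value.upper() for a in atoms])


def select_atoms(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a boolean selection expression to sorted atom indices.

    Grammar: ``resid N``, ``resname X``, ``name Y`` combined with ``and``,
    ``or``, ``not`` and parentheses.  Resolution is deterministic; an empty
    result is valid.
    """
    tokens = expression.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return AtomSelection(expression, np.flatnonzero(mask))


def single_atom_index(topology: Topology, selection: AtomSelection | str) -> int:
    """Resolve a selection that must match exactly one atom."""
    sel = (
        select_atoms(topology, selection) if isinstance(selection, str) else selection
    )
    if len(sel) != 1:
        raise SelectionError(
            f"selection {sel.expression!r} matched {len(sel)} atoms; expected 1"
        )
    return int(sel.indices[0])
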