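"""Structures, trajectories and sequences.

The package analyses multi-frame protein/chromophore coordinates.  The
mandatory on-disk trajectory dialect is multi-model PDB (MODEL/ENDMDL
blocks), chosen because it is plain text and inspectable down to the last
coordinate; binary formats can be adapted externally and converted to this
dialect.  Author residue numbering from the file is authoritative
throughout (sites such as 113, 122, 181, 296 are always author numbers);
internal atom indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "SequenceRecord",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_fasta",
    "select_atoms",
    "invert_selection",
    "pairwise_identity",
    "series_to_csv",
    "table_to_csv",
    "table_to_json",
]

# Average atomic masses (Da) for the elements that occur in protein /
# retinal / water systems; anything unexpected falls back to carbon.
_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845, "SE": 78.971,
}

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "H2O"}

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


class SelectionError(ValueError):
    """Raised for malformed atom-selection expressions."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology; fields mirror the PDB ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    mass: float
    hetero: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES


class Topology:
    """Ordered atom list plus the derived residue grouping.

    Residues are keyed by ``(chain_id, residue_id, residue_name)`` in first
    appearance order; the grouping is a partition of the atom list.
    """

    def __init__(self, atoms: Sequence[Atom], resolution: float | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.resolution = resolution
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")
        self._residues: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._residues.setdefault((a.chain_id, a.residue_id, a.residue_name), []).append(i)
        # cached column arrays for fast selection
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.hetero_mask = np.array([a.hetero for a in self.atoms], dtype=bool)
        self.water_mask = np.array([a.is_water for a in self.atoms], dtype=bool)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        return list(self._residues)

    def residue_atoms(self, chain_id: str, residue_id: int) -> list[int]:
        """Atom indices of one residue (any residue_name on that key)."""
        out = [i for (c, r, _), idx in self._residues.items() if c == chain_id and r == residue_id
               for i in idx]
        return out


@dataclass
class Frame:
    """Per-frame coordinates in Å for every topology atom."""

    index: int
    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """A topology plus an ordered list of frames sharing it."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        if len(frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        for f in frames:
            if f.coordinates.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"frame {f.index} has {f.coordinates.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        self.topology = topology
        self.frames: list[Frame] = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


class AtomSelection:
    """Ordered, duplicate-free 0-based atom indices into one topology."""

    def __init__(self, topology: Topology, indices: Iterable[int]):
        idx = np.asarray(list(indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= topology.n_atoms):
            raise ValueError("selection index out of range")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        self.topology = topology
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def coordinates(self, frame: Frame) -> np.ndarray:
        return frame.coordinates[self.indices]

    def masses(self) -> np.ndarray:
        return self.topology.masses[self.indices]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if len(stripped) >= 2 and stripped[:2].upper() in _MASSES and stripped[:2].upper() not in (
        "CA", "CD", "CE", "NA", "ND", "NE", "NZ", "OD", "OE", "OG", "OH", "SD", "SG",
    ):
        return stripped[:2].upper()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        residue_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed {line[:6].strip()} record at line {lineno}: {exc}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    mass = _MASSES.get(element, 12.011)
    atom = Atom(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_id=residue_id, chain_id=chain_id, mass=mass,
        hetero=line.startswith("HETATM"),
    )
    return atom, np.array([x, y, z])


def _parse_resolution(lines: list[str]) -> float | None:
    for line in lines:
        if line.startswith("REMARK   2 RESOLUTION"):
            tail = line.split("RESOLUTION.", 1)[-1]
            for tok in tail.split():
                try:
                    return float(tok)
                except ValueError:
                    continue
    return None


def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a (single-model) PDB file into a topology and one frame.

    Atoms come back in file order with author numbering preserved; hetero
    residues (retinal, waters, ...) are retained and flagged.  If the file
    has MODEL blocks only the first model is read.  The crystallographic
    resolution is parsed from the ``REMARK 2`` header when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    in_model = False
    seen_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if seen_model:
                break
            in_model = seen_model = True
        elif rec == "ENDMDL" and in_model:
            break
        elif rec in ("ATOM", "HETATM"):
            atom, xyz = _parse_atom_line(line, lineno)
            atoms.append(atom)
            coords.append(xyz)
    if not atoms:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    topology = Topology(atoms, resolution=_parse_resolution(lines))
    return topology, Frame(index=0, coordinates=np.array(coords))


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-model PDB file as a trajectory over an existing topology.

    One frame per MODEL block, ordered by MODEL number.  Every block must
    contain exactly the topology's atom count; a mismatch is reported with
    the offending model number.
    """
    path = Path(path)
    frames: list[Frame] = []
    current: list[np.ndarray] | None = None
    model_number = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                try:
                    model_number = int(line.split()[1])
                except (IndexError, ValueError):
                    model_number = len(frames) + 1
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # tolerate headerless single block
                    model_number = 1
                    current = []
                _, xyz = _parse_atom_line(line, lineno)
                current.append(xyz)
            elif rec == "ENDMDL":
                if current is None:
                    raise PDBParseError(f"ENDMDL without MODEL at line {lineno}")
                if len(current) != topology.n_atoms:
                    raise PDBParseError(
                        f"model {model_number} has {len(current)} atoms, "
                        f"expected {topology.n_atoms}"
                    )
                frames.append(Frame(index=len(frames), coordinates=np.array(current)))
                current = None
    if current:
        if len(current) != topology.n_atoms:
            raise PDBParseError(
                f"model {model_number} has {len(current)} atoms, expected {topology.n_atoms}"
            )
        frames.append(Frame(index=len(frames), coordinates=np.array(current)))
    if not frames:
        raise PDBParseError(f"no models found in {path}")
    return Trajectory(topology, frames)


def _format_atom_line(atom: Atom, xyz: np.ndarray) -> str:
    record = "HETATM" if atom.hetero else "ATOM  "
    name = atom.name
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    return (
        f"{record}{atom.serial:>5d} {name}{'':1s}{atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write one frame as a single-model PDB file (1e-3 Å precision)."""
    with open(path, "w") as fh:
        for atom, xyz in zip(topology.atoms, frame.coordinates):
            fh.write(_format_atom_line(atom, xyz) + "\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:>4d}\n")
            for atom, xyz in zip(traj.topology.atoms, frame.coordinates):
                fh.write(_format_atom_line(atom, xyz) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Sequences


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records (Biopython backend); errors on empty/headerless input."""
    from Bio import SeqIO

    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper().strip())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity from a global alignment of two protein sequences.

    Alignment uses BLOSUM62 with affine gaps (open 10, extend 0.5); identity
    is matches / alignment length × 100.  Round the result to one decimal or
    to the nearest integer for reporting.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(a.residues, b.residues)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


# ---------------------------------------------------------------------------
# Atom selection

_FIELD_ALIASES = {
    "name": "name",
    "resname": "residue_name",
    "residue_name": "residue_name",
    "resid": "residue_id",
    "residue_id": "residue_id",
    "chain": "chain_id",
    "chain_id": "chain_id",
    "element": "element",
}

_BARE_KEYWORDS = {"heavy", "water", "protein", "hetero", "all"}


def _clause_mask(topology: Topology, clause: str) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    head = tokens[0].lower()
    if head in _BARE_KEYWORDS:
        if len(tokens) > 1:
            raise SelectionError(f"keyword '{head}' takes no arguments")
        if head == "heavy":
            return topology.heavy_mask.copy()
        if head == "water":
            return topology.water_mask.copy()
        if head == "hetero":
            return topology.hetero_mask.copy()
        if head == "protein":
            return ~topology.hetero_mask & ~topology.water_mask
        return np.ones(topology.n_atoms, dtype=bool)
    if head not in _FIELD_ALIASES:
        raise SelectionError(f"unknown selection field '{tokens[0]}'")
    field_name = _FIELD_ALIASES[head]
    values = tokens[1:]
    if not values:
        raise SelectionError(f"field '{head}' needs at least one value")
    if field_name == "residue_id":
        mask = np.zeros(topology.n_atoms, dtype=bool)
        for v in values:
            if ":" in v:
                lo, hi = v.split(":")
                mask |= (topology.residue_ids >= int(lo)) & (topology.residue_ids <= int(hi))
            else:
                mask |= topology.residue_ids == int(v)
        return mask
    column = getattr(topology, {"name": "names", "residue_name": "residue_names",
                                "chain_id": "chain_ids", "element": "elements"}[field_name])
    return np.isin(column, values)


def select_atoms(
    topology: Topology, expression: str | Callable[[Atom], bool]
) -> AtomSelection:
    """Select atoms by a small expression language or a per-atom predicate.

    Expression clauses are conjunctions joined by ``and``; each clause is a
    field (``name``, ``resname``, ``resid``, ``chain``, ``element``) followed
    by one or more accepted values (``resid`` also takes ``lo:hi`` ranges),
    or a bare keyword (``heavy``, ``water``, ``protein``, ``hetero``,
    ``all``).  Empty selections are returned, not raised.
    """
    if callable(expression):
        idx = [i for i, a in enumerate(topology.atoms) if expression(a)]
        return AtomSelection(topology, idx)
    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        mask &= _clause_mask(topology, clause.strip())
    return AtomSelection(topology, np.nonzero(mask)[0])


def invert_selection(selection: AtomSelection) -> AtomSelection:
    """Complement of a selection over the same topology."""
    mask = np.ones(selection.topology.n_atoms, dtype=bool)
    mask[selection.indices] = False
    return AtomSelection(selection.topology, np.nonzero(mask)[0])


# ---------------------------------------------------------------------------
# Result writers


def series_to_csv(series, path: str | Path) -> None:
    """Write a SeriesResult as CSV with columns frame,value."""
    df = pd.DataFrame({"frame": series.frame_indices, series.name: series.values})
    df.to_csv(path, index=False)


def table_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def table_to_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
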