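"""Reading, writing and selecting PDB-format coordinates.

Parses the fixed-column ATOM/HETATM records of a PDB file into a
chain -> residue -> atom hierarchy, resolving alternate locations and
keeping ligand (HETATM) residues.  Only the first MODEL of a multi-model
file is read: the crystal structures this package compares are
single-model.  Selections are expressed as residue ranges with an atom
filter (CA-only, backbone, all heavy atoms) and materialise into ordered,
labelled coordinate sets suitable for superposition and RMSD work.

Missing residues are a fact of life in crystallographic models (flexible
loops are often not resolved); selections skip them silently but report a
coverage count so callers can decide whether a comparison is meaningful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ResidueRange",
    "CoordinateSet",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "pair_common_atoms",
]

# Standard water residue names excluded from selections by default.
_WATER_NAMES = {"HOH", "WAT", "DOD"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AtomFilter = Literal["CA", "backbone", "heavy"]


class PDBParseError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty or a range cannot be resolved."""


@dataclass(frozen=True)
class AtomRecord:
    """One crystallographic atom (ATOM or HETATM record)."""

    serial: int
    name: str
    altloc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float
    b_factor: float
    element: str
    is_hetero: bool

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() in ("H", "D")
        # Fall back to the atom-name convention (e.g. "HB2", "1HG1").
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")


@dataclass
class Residue:
    res_name: str
    res_seq: int
    i_code: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)  # name -> atom

    @property
    def is_hetero(self) -> bool:
        return any(a.is_hetero for a in self.atoms.values())

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms.values() if not a.is_hydrogen]


@dataclass
class Structure:
    """A parsed model: ordered chains of ordered residues of atoms."""

    pdb_id: str
    chains: dict[str, dict[tuple[int, str], Residue]]
    model_index: int = 1

    def residue(self, chain_id: str, res_seq: int, i_code: str = "") -> Residue:
        try:
            return self.chains[chain_id][(res_seq, i_code)]
        except KeyError:
            raise SelectionError(
                f"residue {chain_id}:{res_seq}{i_code or ''} not in model"
            ) from None

    def has_residue(self, chain_id: str, res_seq: int, i_code: str = "") -> bool:
        return chain_id in self.chains and (res_seq, i_code) in self.chains[chain_id]

    def iter_atoms(self) -> Iterable[AtomRecord]:
        for residues in self.chains.values():
            for res in residues.values():
                yield from res.atoms.values()

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on one chain, with atom filter."""

    chain_id: str
    start: int
    end: int
    atom_filter: AtomFilter = "heavy"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")
        if self.atom_filter not in ("CA", "backbone", "heavy"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoordinateSet:
    """Ordered labelled points; the order IS the pairing order."""

    labels: list[tuple[str, int, str]]  # (chain_id, res_seq, atom name)
    points: np.ndarray  # shape (n, 3), Å

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have the same length")

    def __len__(self) -> int:
        return len(self.labels)


def _parse_atom_line(line: str, lineno: int, hetero: bool) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record too short for coordinates")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        i_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_field = line[60:66].strip()
        b_factor = float(b_field) if b_field else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-column record ({exc})") from None
    pos = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(pos)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    return AtomRecord(
        serial=serial, name=name, altloc=altloc, res_name=res_name,
        chain_id=chain_id, res_seq=res_seq, i_code=i_code, position=pos,
        occupancy=occupancy, b_factor=b_factor, element=element, is_hetero=hetero,
    )


def read_pdb(source, pdb_id: str = "") -> Structure:
    """Parse a PDB text stream or path into a :class:`Structure`.

    Only MODEL 1 is read.  Alternate locations are resolved by keeping the
    highest-occupancy conformer (ties broken alphabetically by altloc id).
    HETATM residues (ligands, waters) are retained with ``is_hetero=True``.

    Raises
    ------
    PDBParseError
        On a malformed record (the message names the line number) or if the
        file contains no ATOM/HETATM records.
    """
    if isinstance(source, (str,)) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError("source must be a path, a PDB text string, or a stream")

    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    # Candidate atoms keyed on full identity, used for altloc resolution.
    candidates: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str, str]] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM  ", "HETATM"):
            continue
        atom = _parse_atom_line(line, lineno, hetero=(rec == "HETATM"))
        key = (atom.chain_id, atom.res_seq, atom.i_code, atom.name)
        if key not in candidates:
            candidates[key] = []
            order.append(key)
        candidates[key].append(atom)

    if not candidates:
        raise PDBParseError("no ATOM or HETATM records found")

    for key in order:
        # Highest occupancy wins; ties go to the alphabetically first altloc.
        atom = min(candidates[key], key=lambda a: (-a.occupancy, a.altloc))
        chain = chains.setdefault(atom.chain_id, {})
        rkey = (atom.res_seq, atom.i_code)
        res = chain.get(rkey)
        if res is None:
            res = Residue(atom.res_name, atom.res_seq, atom.i_code)
            chain[rkey] = res
        if atom.name in res.atoms:
            raise PDBParseError(
                f"duplicate atom {atom.chain_id}:{atom.res_seq}:{atom.name} "
                f"(serial {atom.serial}) with identical altloc"
            )
        res.atoms[atom.name] = atom

    return Structure(pdb_id=pdb_id, chains=chains, model_index=1)


def write_pdb(s: Structure) -> str:
    """Serialize a structure back to PDB fixed-column text (3-decimal Å)."""
    lines = []
    serial = 0
    for chain_id, residues in s.chains.items():
        last_hetero = None
        for res in residues.values():
            for atom in res.atoms.values():
                serial += 1
                rec = "HETATM" if atom.is_hetero else "ATOM  "
                name = atom.name
                # Columns 13-16: element-justified atom name.
                if len(name) < 4 and len(atom.element) < 2:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                x, y, z = atom.position
                lines.append(
                    f"{rec}{serial:5d} {name_field}{atom.altloc or ' ':1s}"
                    f"{atom.res_name:>3s} {chain_id:1s}{atom.res_seq:4d}"
                    f"{atom.i_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          {atom.element:>2s}"
                )
                last_hetero = atom.is_hetero
        if last_hetero is False:
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _residue_atom_names(res: Residue, atom_filter: AtomFilter) -> list[str]:
    if atom_filter == "CA":
        return ["CA"] if "CA" in res.atoms else []
    if atom_filter == "backbone":
        return [n for n in BACKBONE_ATOMS if n in res.atoms]
    # All heavy atoms, backbone first then side chain in file order.
    names = [n for n in BACKBONE_ATOMS if n in res.atoms]
    names += [a.name for a in res.heavy_atoms() if a.name not in BACKBONE_ATOMS]
    return names


def select_atoms(
    s: Structure,
    r: ResidueRange,
    include_waters: bool = False,
    with_coverage: bool = False,
):
    """Materialise a residue range into an ordered :class:`CoordinateSet`.

    Atoms come out in residue order, with backbone atoms in canonical
    N, CA, C, O order.  Residues of the range missing from the model are
    skipped; with ``with_coverage=True`` the number of residues actually
    found is returned alongside the coordinates.  Hydrogens and waters are
    excluded (ranges address the polypeptide).

    Raises
    ------
    SelectionError
        If the chain is absent or the selection is empty (an empty
        selection would make any downstream RMSD vacuous).
    """
    if r.chain_id not in s.chains:
        raise SelectionError(f"chain {r.chain_id!r} not present in structure")
    labels: list[tuple[str, int, str]] = []
    points: list[np.ndarray] = []
    covered = 0
    chain = s.chains[r.chain_id]
    for res_seq in range(r.start, r.end + 1):
        res = chain.get((res_seq, ""))
        if res is None or (res.is_water and not include_waters):
            continue
        names = _residue_atom_names(res, r.atom_filter)
        if names:
            covered += 1
        for name in names:
            labels.append((r.chain_id, res_seq, name))
            points.append(res.atoms[name].position)
    if not labels:
        raise SelectionError(
            f"selection {r.chain_id}:{r.start}-{r.end} ({r.atom_filter}) is empty"
        )
    cset = CoordinateSet(labels, np.vstack(points))
    if with_coverage:
        return cset, covered
    return cset


def pair_common_atoms(
    a: CoordinateSet, b: CoordinateSet
) -> tuple[CoordinateSet, CoordinateSet]:
    """Restrict two coordinate sets to their common (res_seq, atom) labels.

    Pairing is chain-agnostic — comparisons across crystal forms use
    different chain letters for the same polypeptide — and preserves the
    order of ``a``.  Needed because crystallographic models of the same
    protein resolve different residue subsets.

    Raises
    ------
    SelectionError
        If either set is empty or the label intersection is empty.
    """
    if len(a) == 0 or len(b) == 0:
        raise SelectionError("cannot pair empty coordinate sets")
    b_index = {(res, name): i for i, (_, res, name) in enumerate(b.labels)}
    ia: list[int] = []
    ib: list[int] = []
    for i, (_, res, name) in enumerate(a.labels):
        j = b_index.get((res, name))
        if j is not None:
            ia.append(i)
            ib.append(j)
    if not ia:
        raise SelectionError("no common (residue, atom) labels between sets")
    sub_a = CoordinateSet([a.labels[i] for i in ia], a.points[ia])
    sub_b = CoordinateSet([b.labels[j] for j in ib], b.points[ib])
    return sub_a, sub_b
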