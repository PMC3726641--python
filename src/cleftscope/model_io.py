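"""Domain types and readers/writers for structures, trajectories and hills.

Units are fixed project-wide: coordinates in Angstrom, times in ps,
energies in kcal/mol. Atom indexing is 0-based internally; PDB serial
numbers are preserved only as labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import AnnotationError, EmptyInputError, ParseError
from .templates import RESIDUE_TEMPLATES

ResidueKey = tuple[str, int]  # (chain_id, residue_index)


@dataclass
class AtomRecord:
    """One atom: identity, residue membership and a position in Angstrom."""

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    serial: int | None = None  # PDB serial, label only

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index)


@dataclass
class Structure:
    """A bag of atoms with base coordinates (no annotation)."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique within a structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_id(self, name: str, residue_name: str | None = None,
                residue_index: int | None = None, chain_id: str | None = None) -> int:
        """Return the id of the first atom matching all given fields."""
        for a in self.atoms:
            if a.name != name:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if residue_index is not None and a.residue_index != residue_index:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            return a.atom_id
        raise KeyError(f"no atom {name!r} matching the given residue filters")


@dataclass
class Topology:
    """Static annotation consumed by every detector.

    donors are (heavy atom id, attached H id) pairs; acceptors map atom id
    to acceptor class ("ON" or "S"); rings are ordered atom-id lists of
    length >= 5 treated as planar aromatic; charge_class and molecule_class
    are keyed per residue.
    """

    atoms: list[AtomRecord]
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: dict[int, str] = field(default_factory=dict)
    rings: list[list[int]] = field(default_factory=list)
    charge_class: dict[ResidueKey, str] = field(default_factory=dict)
    equivalence_groups: dict[str, list[int]] = field(default_factory=dict)
    molecule_class: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ring in self.rings:
            if len(ring) < 5:
                raise ValueError("every ring must have >= 5 member atoms")
        seen: set[int] = set()
        for name, members in self.equivalence_groups.items():
            if seen & set(members):
                raise ValueError(f"equivalence group {name!r} overlaps another group")
            seen |= set(members)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom(self, atom_id: int) -> AtomRecord:
        return self.atoms[atom_id]

    def residue_of(self, atom_id: int) -> ResidueKey:
        return self.atoms[atom_id].residue_key

    def atom_id(self, name: str, **kw) -> int:
        return Structure.atom_id(self, name, **kw)  # type: ignore[arg-type]

    def residues_of_class(self, molecule_class: str) -> set[ResidueKey]:
        return {k for k, v in self.molecule_class.items() if v == molecule_class}


@dataclass
class Frame:
    """One trajectory frame: a timestamp and index-aligned positions."""

    time: float
    positions: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")


@dataclass
class Trajectory:
    """Ordered frames over a (possibly annotated) set of atoms."""

    topology: Structure | Topology
    frames: list[Frame]
    timestep: float = 1.0

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.positions.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.positions.shape[0]} positions, expected {n}")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window(self, start: float | None = None, end: float | None = None) -> "Trajectory":
        """Frames with start < time <= end (either bound may be None)."""
        kept = [f for f in self.frames
                if (start is None or f.time > start) and (end is None or f.time <= end)]
        return Trajectory(self.topology, kept, self.timestep)


@dataclass
class HillRecord:
    """One deposited Gaussian of a metadynamics bias."""

    time: float
    center: np.ndarray
    sigma: np.ndarray
    height: float
    bias_factor: float

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.center.shape != self.sigma.shape:
            raise ValueError("center and sigma must have the same dimensionality")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse_atom_line(line: str, lineno: int, atom_id: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    return AtomRecord(atom_id=atom_id, name=name,
                      element=element or _guess_element(name),
                      residue_name=resname, residue_index=resseq,
                      chain_id=chain, position=np.array([x, y, z]),
                      serial=serial)


def read_pdb(path: str | Path, timestep: float = 1.0) -> Structure | Trajectory:
    """Read a PDB file (ATOM/HETATM/MODEL/ENDMDL subset).

    A single-model file yields a :class:`Structure`; multi-model files
    yield a :class:`Trajectory` whose frames follow file order, with
    frame times ``model_index * timestep``.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno, len(current)))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    counts = {len(m) for m in models}
    if len(counts) > 1:
        raise ParseError(f"{path}: MODEL blocks have differing atom counts {sorted(counts)}")
    structure = Structure(atoms=models[0])
    if len(models) == 1:
        return structure
    frames = [Frame(time=i * timestep,
                    positions=np.array([a.position for a in m]))
              for i, m in enumerate(models)]
    return Trajectory(topology=structure, frames=frames, timestep=timestep)


def _format_atom_line(a: AtomRecord, serial: int, pos: np.ndarray) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
    return (f"ATOM  {serial:>5} {name:<4} {a.residue_name:>3} {a.chain_id:1}"
            f"{a.residue_index:>4}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}")


def write_pdb(obj: Structure | Topology | Trajectory, path: str | Path) -> None:
    """Write a structure or trajectory as (multi-model) PDB."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, Trajectory):
        atoms = obj.topology.atoms
        for i, frame in enumerate(obj.frames, start=1):
            lines.append(f"MODEL     {i:>4}")
            for a in atoms:
                lines.append(_format_atom_line(a, a.atom_id + 1, frame.positions[a.atom_id]))
            lines.append("ENDMDL")
    else:
        for a in obj.atoms:
            lines.append(_format_atom_line(a, a.atom_id + 1, a.position))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path: str | Path, topology: Structure | Topology | None = None,
                        timestep: float = 1.0) -> Trajectory:
    """Read an XYZ trajectory; the comment line may carry ``time=<ps>``.

    Missing time stamps are filled as ``frame_index * timestep``. The atom
    count must be constant across frames.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ParseError(f"{path}: atom count changed from {n_expected} to {n} "
                             f"at line {i + 1}")
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ParseError(f"{path}: truncated frame starting at line {i + 1}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = None
        for token in comment.split():
            if token.startswith("time="):
                try:
                    time = float(token[5:])
                except ValueError as exc:
                    raise ParseError(f"{path}: bad time stamp at line {i + 2}") from exc
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise ParseError(f"{path}: truncated frame starting at line {i + 1}")
        pos = np.empty((n, 3))
        for j, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed XYZ row at line {i + 3 + j}")
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"{path}: malformed XYZ row at line {i + 3 + j}") from exc
        if time is None:
            time = len(frames) * timestep
        frames.append(Frame(time=time, positions=pos))
        i += 2 + n
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    if topology is None:
        topology = Structure(atoms=[
            AtomRecord(atom_id=k, name=f"X{k}", element="X", residue_name="UNK",
                       residue_index=1, chain_id="A", position=frames[0].positions[k])
            for k in range(n_expected or 0)])
    return Trajectory(topology=topology, frames=frames, timestep=timestep)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    atoms = traj.topology.atoms
    out: list[str] = []
    for frame in traj.frames:
        out.append(str(len(atoms)))
        out.append(f"time={frame.time:g}")
        for a in atoms:
            p = frame.positions[a.atom_id]
            out.append(f"{a.element:<2} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PLUMED-style HILLS
# ---------------------------------------------------------------------------

def read_hills(path: str | Path) -> list[HillRecord]:
    """Read a whitespace-separated HILLS file with a ``#! FIELDS`` header.

    The header declares ``time cv... sigma_cv... height biasf``; the CV
    dimensionality is inferred from it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    fields: list[str] | None = None
    records: list[HillRecord] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#!"):
            parts = stripped.split()
            if len(parts) >= 3 and parts[1] == "FIELDS":
                fields = parts[2:]
            continue
        if stripped.startswith("#"):
            continue
        if fields is None:
            raise ParseError(f"{path}: data before '#! FIELDS' header at line {lineno}")
        cv_names = [f for f in fields
                    if f not in ("time", "height", "biasf") and not f.startswith("sigma_")]
        n_cv = len(cv_names)
        expected = 3 + 2 * n_cv
        tokens = stripped.split()
        if len(tokens) != expected:
            raise ParseError(f"{path}: line {lineno} has {len(tokens)} columns, "
                             f"header declares {expected}")
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value at line {lineno}") from exc
        row = dict(zip(fields, values))
        center = np.array([row[n] for n in cv_names])
        sigma = np.array([row[f"sigma_{n}"] for n in cv_names])
        records.append(HillRecord(time=row["time"], center=center, sigma=sigma,
                                  height=row["height"], bias_factor=row["biasf"]))
    if fields is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    return records


def write_hills(hills: Iterable[HillRecord], path: str | Path,
                cv_names: Sequence[str] | None = None) -> None:
    """Write hills in the dialect read back by :func:`read_hills`."""
    hills = list(hills)
    path = Path(path)
    dim = len(hills[0].center) if hills else 1
    if cv_names is None:
        cv_names = [f"cv{i + 1}" for i in range(dim)]
    header = ("#! FIELDS time " + " ".join(cv_names) + " "
              + " ".join(f"sigma_{n}" for n in cv_names) + " height biasf")
    rows = [header]
    for h in hills:
        vals = ([h.time] + list(h.center) + list(h.sigma) + [h.height, h.bias_factor])
        rows.append(" ".join(f"{v:.6g}" for v in vals))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_topology(structure: Structure,
                      rules: dict[str, dict] | None = None) -> Topology:
    """Annotate a structure with donors/acceptors/rings/classes per template.

    Deterministic: the same structure and templates always yield an
    identical topology. Unknown residue names raise
    :class:`AnnotationError` listing the offending residues.
    """
    rules = rules if rules is not None else RESIDUE_TEMPLATES

    residues: dict[ResidueKey, list[AtomRecord]] = {}
    for a in structure.atoms:
        residues.setdefault(a.residue_key, []).append(a)

    unknown = sorted({atoms[0].residue_name for atoms in residues.values()
                      if atoms[0].residue_name not in rules})
    if unknown:
        raise AnnotationError(f"unknown residue name(s): {', '.join(unknown)}")

    donors: list[tuple[int, int]] = []
    acceptors: dict[int, str] = {}
    rings: list[list[int]] = []
    charge: dict[ResidueKey, str] = {}
    molecule: dict[ResidueKey, str] = {}
    groups: dict[str, list[int]] = {}

    for key, atoms in residues.items():
        resname = atoms[0].residue_name
        tmpl = rules[resname]
        by_name = {a.name: a.atom_id for a in atoms}
        charge[key] = tmpl["charge"]
        molecule[key] = tmpl["molecule"]
        for heavy, hydrogen in tmpl["donors"]:
            if heavy in by_name and hydrogen in by_name:
                donors.append((by_name[heavy], by_name[hydrogen]))
        for name, klass in tmpl["acceptors"].items():
            if name in by_name:
                acceptors[by_name[name]] = klass
        for ring in tmpl["rings"]:
            missing = [n for n in ring if n not in by_name]
            if missing:
                raise AnnotationError(
                    f"residue {resname} {key}: ring atoms missing: {missing}")
            rings.append([by_name[n] for n in ring])
        for gname, members in tmpl["equivalence"].items():
            present = [by_name[n] for n in members if n in by_name]
            if not present:
                continue
            unique = gname
            while unique in groups:
                unique = f"{gname}@{key[0]}{key[1]}"
                if unique in groups:
                    unique = f"{unique}+"
            groups[unique] = present

    return Topology(atoms=list(structure.atoms), donors=donors, acceptors=acceptors,
                    rings=rings, charge_class=charge, equivalence_groups=groups,
                    molecule_class=molecule)
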