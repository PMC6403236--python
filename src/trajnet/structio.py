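"""Structures, trajectories, atom selections and nonbonded parameter tables.

All coordinates are stored in nm (PDB files are read and written in Å),
masses in amu, charges in e, Lennard-Jones sigma in nm and epsilon in
kJ/mol.  Every downstream module consumes the types defined here.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    ATOMIC_MASSES,
    NUCLEIC_BACKBONE_NAMES,
    NUCLEIC_RESNAMES,
    PROTEIN_BACKBONE_NAMES,
    PROTEIN_RESNAMES,
)


class TrajnetError(Exception):
    """Base class for package errors."""


class PDBParseError(TrajnetError):
    """Raised for malformed or inconsistent PDB input."""


class SelectionError(TrajnetError):
    """Raised for ill-formed selection expressions or empty required selections."""


class ParameterError(TrajnetError):
    """Raised for invalid or incomplete nonbonded parameter tables."""


# --------------------------------------------------------------------------- #
# Atoms and topologies
# --------------------------------------------------------------------------- #

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "FE", "ZN", "SE"}


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    The first alphabetic character of the stripped name is taken as the
    element; names that exactly match a common two-letter element (CL, BR,
    NA, MG, FE, ZN, SE) are taken whole.  Explicit element columns in a PDB
    file always take precedence over this heuristic.
    """
    stripped = atom_name.strip().upper()
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")


def mass_of(element: str) -> float:
    """Standard atomic mass (amu) for an element symbol; unknown → error."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise TrajnetError(f"no atomic mass tabulated for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.  Identity fields follow PDB conventions."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    mass: float

    def __post_init__(self) -> None:
        if not self.element:
            raise TrajnetError("atom element must be non-empty")
        if self.mass <= 0:
            raise TrajnetError(f"atom mass must be positive, got {self.mass}")


class Topology:
    """Ordered atom table shared by all frames of a trajectory."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.resid, a.name)
            if key in seen:
                raise TrajnetError(f"duplicate atom (chain,resid,name)={key}")
            seen.add(key)
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element.upper() for a in self.atoms], dtype=object)
        self.resnames = np.array([a.resname for a in self.atoms], dtype=object)
        self.resids = np.array([a.resid for a in self.atoms], dtype=int)
        self.chains = np.array([a.chain for a in self.atoms], dtype=object)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def copy(self) -> "Topology":
        return Topology(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) keys."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if (a.chain, a.resid) not in seen:
                seen.add((a.chain, a.resid))
                out.append((a.chain, a.resid, a.resname))
        return out

    def residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys` order."""
        keys = {(c, r): i for i, (c, r, _) in enumerate(self.residue_keys())}
        return np.array([keys[(a.chain, a.resid)] for a in self.atoms], dtype=int)

    def renumber_chain(self, chain: str, offset: int) -> "Topology":
        """Return a copy with ``offset`` added to every resid of ``chain``.

        Utility for mapping a second protomer onto a continuous numbering
        scheme (e.g. chain B 28–696 → 697–1365); disabled unless called.
        """
        atoms = [
            dataclasses.replace(a, resid=a.resid + offset) if a.chain == chain else a
            for a in self.atoms
        ]
        return Topology(atoms)


@dataclass
class Structure:
    """A topology with one set of coordinates (nm)."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.topology), 3):
            raise TrajnetError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.topology)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajnetError("non-finite coordinates")


@dataclass
class Trajectory:
    """Ordered frames (nm) over a shared topology with uniform time spacing."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    timestep_ps: float = 1.0
    time_origin_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.topology), 3):
            raise TrajnetError(
                f"coords shape {self.coords.shape} does not match topology of "
                f"{len(self.topology)} atoms"
            )
        if self.timestep_ps <= 0:
            raise TrajnetError("timestep_ps must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise TrajnetError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return self.time_origin_ps + self.timestep_ps * np.arange(self.n_frames)

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.coords[i])

    def __len__(self) -> int:
        return self.n_frames

    def last_window(self, window_ps: float) -> np.ndarray:
        """Frame indices with time > t_end − window, inclusive of the final frame."""
        t = self.times_ps
        return np.nonzero(t > t[-1] - window_ps)[0]


def concatenate(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Pool frames from several runs over one common topology."""
    if not trajectories:
        raise TrajnetError("no trajectories to concatenate")
    first = trajectories[0]
    for t in trajectories[1:]:
        if t.n_atoms != first.n_atoms:
            raise TrajnetError("trajectories have differing atom counts")
    coords = np.concatenate([t.coords for t in trajectories], axis=0)
    return Trajectory(first.topology, coords, first.timestep_ps, first.time_origin_ps)


# --------------------------------------------------------------------------- #
# PDB reading / writing
# --------------------------------------------------------------------------- #


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name)
    element = element.upper()
    atom = Atom(serial, name, element, resname, resid, chain, mass_of(element))
    return atom, np.array([x, y, z]) / 10.0  # Å → nm


def read_pdb(
    path: str | Path, timestep_ps: float = 1.0, time_origin_ps: float = 0.0
) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory, converting Å → nm.

    Files without MODEL/ENDMDL blocks yield a single frame.  The atom table
    is taken from the first model; later models must contain the same number
    of atoms.  PDB files carry no time axis, so frame spacing is supplied by
    ``timestep_ps``.
    """
    path = Path(path)
    frames: list[list[np.ndarray]] = []
    atoms: list[Atom] = []
    current: list[np.ndarray] | None = None
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                current = None
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno)
                if not saw_model:
                    if current is None:
                        current = []
                    atoms.append(atom)
                    current.append(xyz)
                else:
                    if not in_model:
                        raise PDBParseError(
                            f"ATOM record outside MODEL block at line {lineno}"
                        )
                    if len(frames) == 0:
                        atoms.append(atom)
                    current.append(xyz)
    if current is not None:
        frames.append(current)
    if not frames or not atoms:
        raise PDBParseError(f"no atoms found in {path}")
    n = len(atoms)
    for i, fr in enumerate(frames):
        if len(fr) != n:
            raise PDBParseError(
                f"model {i + 1} has {len(fr)} atoms, expected {n} (mismatched models)"
            )
    coords = np.array(frames, dtype=float)
    topology = Topology(atoms)
    return Trajectory(topology, coords, timestep_ps, time_origin_ps)


def _format_atom_name(name: str) -> str:
    # Names of <4 chars start in column 14 (PDB convention).
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(
    trajectory: Trajectory,
    path: str | Path,
    bfactors: np.ndarray | None = None,
    remarks: Iterable[str] | None = None,
    force_model_records: bool = False,
) -> None:
    """Write a Trajectory as a fixed-column multi-model PDB file (nm → Å).

    ``bfactors`` may be per-atom (n,) or per-frame-per-atom (F, n); the
    B-factor column is the standard vehicle for mapping per-atom scalars
    (e.g. betweenness centrality) onto a structure.  A single-frame
    trajectory is written without MODEL records unless
    ``force_model_records`` is set.
    """
    top = trajectory.topology
    for a in top.atoms:
        if len(a.chain.strip()) > 1:
            raise TrajnetError(f"chain id {a.chain!r} longer than 1 character")
    n_frames = trajectory.n_frames
    bf = None
    if bfactors is not None:
        bf = np.asarray(bfactors, dtype=float)
        if bf.ndim == 1:
            bf = np.broadcast_to(bf, (n_frames, len(top)))
        if bf.shape != (n_frames, len(top)):
            raise TrajnetError("bfactors shape does not match trajectory")
    use_models = force_model_records or n_frames > 1
    with open(path, "w") as fh:
        if remarks:
            for r in remarks:
                fh.write(f"REMARK   1 {r}\n")
        for f in range(n_frames):
            if use_models:
                fh.write(f"MODEL     {f + 1:4d}\n")
            xyz = trajectory.coords[f] * 10.0  # nm → Å
            for i, a in enumerate(top.atoms):
                b = bf[f, i] if bf is not None else 0.0
                b = min(max(b, -99.99), 999.99)
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {resname:<4s}{chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                        serial=a.serial % 100000,
                        name=_format_atom_name(a.name),
                        resname=a.resname[:4],
                        chain=a.chain[:1] if a.chain.strip() else " ",
                        resid=a.resid % 10000,
                        x=xyz[i, 0],
                        y=xyz[i, 1],
                        z=xyz[i, 2],
                        occ=1.00,
                        b=b,
                        elem=a.element[:2],
                    )
                )
            if use_models:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------- #
# Selections
# --------------------------------------------------------------------------- #


@dataclass
class Selection:
    """A resolved atom selection: the expression and strictly increasing indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise SelectionError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


_KEYWORDS = ("backbone", "heavy", "all", "protein", "nucleic")
_FIELDS = ("chain", "resid", "name", "element", "resname")
_OPERATORS = ("and", "or", "not", "(", ")")


def _tokenize(expression: str) -> list[str]:
    return re.findall(r"\(|\)|[^\s()]+", expression)


class _SelectionParser:
    """Recursive-descent parser for the selection mini-language.

    Grammar: or_expr := and_expr ('or' and_expr)* ; and_expr := unary ('and'
    unary)* ; unary := 'not' unary | '(' or_expr ')' | keyword | field values.
    ``resid`` accepts single ids and colon ranges (``resid 3:10``).
    """

    def __init__(self, topology: Topology, expression: str):
        self.top = topology
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.expression = expression
        self._is_protein = np.array(
            [r in PROTEIN_RESNAMES for r in topology.resnames], dtype=bool
        )
        self._is_nucleic = np.array(
            [r in NUCLEIC_RESNAMES for r in topology.resnames], dtype=bool
        )

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._or_expr()
        if self.pos != len(self.tokens):
            raise SelectionError(
                f"unexpected token {self.tokens[self.pos]!r} in {self.expression!r}"
            )
        return mask

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self.pos += 1
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek() == "and":
            self.pos += 1
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"truncated expression {self.expression!r}")
        if tok == "not":
            self.pos += 1
            return ~self._unary()
        if tok == "(":
            self.pos += 1
            mask = self._or_expr()
            if self._peek() != ")":
                raise SelectionError("unbalanced parentheses")
            self.pos += 1
            return mask
        return self._primary()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while True:
            tok = self._peek()
            if tok is None or tok in _OPERATORS or tok in _FIELDS or tok in _KEYWORDS:
                break
            vals.append(tok)
            self.pos += 1
        if not vals:
            raise SelectionError(f"field without values in {self.expression!r}")
        return vals

    def _primary(self) -> np.ndarray:
        tok = self.tokens[self.pos]
        top = self.top
        if tok == "all":
            self.pos += 1
            return np.ones(len(top), dtype=bool)
        if tok == "heavy":
            self.pos += 1
            return top.elements != "H"
        if tok == "protein":
            self.pos += 1
            return self._is_protein.copy()
        if tok == "nucleic":
            self.pos += 1
            return self._is_nucleic.copy()
        if tok == "backbone":
            self.pos += 1
            prot_bb = self._is_protein & np.isin(
                top.names.astype(str), list(PROTEIN_BACKBONE_NAMES)
            )
            nuc_bb = self._is_nucleic & np.isin(
                top.names.astype(str), list(NUCLEIC_BACKBONE_NAMES)
            )
            return prot_bb | nuc_bb
        if tok == "chain":
            self.pos += 1
            return np.isin(top.chains.astype(str), self._values())
        if tok == "name":
            self.pos += 1
            return np.isin(top.names.astype(str), self._values())
        if tok == "resname":
            self.pos += 1
            return np.isin(top.resnames.astype(str), self._values())
        if tok == "element":
            self.pos += 1
            vals = [v.upper() for v in self._values()]
            return np.isin(top.elements.astype(str), vals)
        if tok == "resid":
            self.pos += 1
            mask = np.zeros(len(top), dtype=bool)
            for v in self._values():
                if ":" in v:
                    lo_s, hi_s = v.split(":", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad resid range {v!r}") from None
                    mask |= (top.resids >= lo) & (top.resids <= hi)
                else:
                    try:
                        mask |= top.resids == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resid {v!r}") from None
            return mask
        raise SelectionError(
            f"unknown token {tok!r}; accepted keywords: "
            f"{', '.join(_KEYWORDS + _FIELDS + _OPERATORS)}"
        )


def resolve_selection(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression against a topology.

    The mini-language supports ``chain``, ``resid`` (ids and ``lo:hi``
    ranges), ``name``, ``resname``, ``element``, the keywords ``backbone``,
    ``heavy``, ``protein``, ``nucleic``, ``all``, and ``and/or/not`` with
    parentheses.
    """
    mask = _SelectionParser(topology, expression).parse()
    return Selection(expression, np.nonzero(mask)[0])


# --------------------------------------------------------------------------- #
# Nonbonded parameter tables
# --------------------------------------------------------------------------- #


@dataclass
class NonbondedParams:
    """Per-atom charge (e) and Lennard-Jones sigma (nm) / epsilon (kJ/mol)."""

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    combination_rule: str = "lorentz_berthelot"

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if not (self.charge.shape == self.sigma.shape == self.epsilon.shape):
            raise ParameterError("charge/sigma/epsilon must have equal lengths")
        if np.any(self.sigma < 0):
            raise ParameterError("sigma must be non-negative")
        if np.any(self.epsilon < 0):
            raise ParameterError("epsilon must be non-negative")
        if self.combination_rule not in ("lorentz_berthelot", "geometric"):
            raise ParameterError(
                f"unknown combination rule {self.combination_rule!r}"
            )

    @property
    def n_atoms(self) -> int:
        return int(self.charge.size)


def load_params(
    path: str | Path,
    topology: Topology,
    combination_rule: str = "lorentz_berthelot",
) -> NonbondedParams:
    """Load a whitespace-separated nonbonded parameter table.

    Two layouts are accepted, detected from the header line:

    * ``resname name charge sigma epsilon`` — keyed by (resname, atom name);
    * ``serial charge sigma epsilon`` — keyed by atom serial.

    Every topology atom must be covered; duplicates are an error (no silent
    override).
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise ParameterError(f"empty parameter table {path}")
    header = [h.lower() for h in rows[0]]
    body = rows[1:]
    if header[:2] == ["resname", "name"]:
        keyed: dict[tuple[str, str], tuple[float, float, float]] = {}
        for r in body:
            if len(r) != 5:
                raise ParameterError(f"bad row in {path}: {' '.join(r)!r}")
            key = (r[0], r[1])
            vals = (float(r[2]), float(r[3]), float(r[4]))
            if key in keyed:
                raise ParameterError(f"duplicate parameter entry for {key}")
            keyed[key] = vals
        missing = sorted(
            {(a.resname, a.name) for a in topology.atoms} - set(keyed)
        )
        if missing:
            raise ParameterError(f"parameter table missing atoms: {missing}")
        triples = [keyed[(a.resname, a.name)] for a in topology.atoms]
    elif header[0] == "serial":
        by_serial: dict[int, tuple[float, float, float]] = {}
        for r in body:
            if len(r) != 4:
                raise ParameterError(f"bad row in {path}: {' '.join(r)!r}")
            s = int(r[0])
            if s in by_serial:
                raise ParameterError(f"duplicate parameter entry for serial {s}")
            by_serial[s] = (float(r[1]), float(r[2]), float(r[3]))
        missing_serials = [a.serial for a in topology.atoms if a.serial not in by_serial]
        if missing_serials:
            raise ParameterError(
                f"parameter table missing serials: {missing_serials}"
            )
        triples = [by_serial[a.serial] for a in topology.atoms]
    else:
        raise ParameterError(
            "unrecognised header; expected 'resname name charge sigma epsilon' "
            "or 'serial charge sigma epsilon'"
        )
    arr = np.array(triples, dtype=float)
    return NonbondedParams(arr[:, 0], arr[:, 1], arr[:, 2], combination_rule)


def write_params(
    params: NonbondedParams, topology: Topology, path: str | Path
) -> None:
    """Write a serial-keyed parameter table readable by :func:`load_params`."""
    if params.n_atoms != len(topology):
        raise ParameterError("params do not match topology")
    with open(path, "w") as fh:
        fh.write("serial charge sigma epsilon\n")
        for a, q, s, e in zip(
            topology.atoms, params.charge, params.sigma, params.epsilon
        ):
            fh.write(f"{a.serial} {q:.10g} {s:.10g} {e:.10g}\n")
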