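"""PDB coordinate model with full alternate-location fidelity.

The parser keeps every altloc indicator, occupancy and B factor exactly as
deposited; conformer grouping treats blank-altloc atoms as shared between
all states of a residue, so residues whose states are labelled e.g. only
'C' and 'D' are never silently dropped.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# common modified residues mapped to a standard parent for sequence/typing
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "KCX": "LYS", "CME": "CYS", "LLP": "LYS",
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records; message names the line."""


@dataclass
class Atom:
    """One atom record; altloc '' means no alternate-location indicator."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_NAMES and not self.is_hydrogen


@dataclass
class ConformerState:
    """One rigid coordinate set of a residue (a single altloc state).

    Blank-altloc atoms are shared into every state, so ``atoms`` is always a
    complete picture of the residue in that state.
    """

    state_id: str
    atoms: list[Atom]
    occupancy: float = 1.0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord


@dataclass
class Residue:
    res_name: str
    seq_id: tuple[int, str]  # (author number, insertion code)
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def standard_parent(self) -> str | None:
        """Standard residue type, mapping e.g. MSE->MET; None for ligands."""
        if self.res_name in THREE_TO_ONE:
            return self.res_name
        return NONSTANDARD_PARENT.get(self.res_name)

    @property
    def is_amino_acid(self) -> bool:
        return self.standard_parent is not None

    @property
    def one_letter(self) -> str:
        parent = self.standard_parent
        return THREE_TO_ONE[parent] if parent else "X"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, *self.seq_id)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        num, icode = self.seq_id
        return f"{self.chain_id}/{self.res_name}{num}{icode}"


@dataclass
class StructureModel:
    pdb_id: str = ""
    resolution: float | None = None
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    het: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    def all_atoms(self, include_het: bool = False) -> list[Atom]:
        atoms = [a for r in self.residues() for a in r.atoms]
        if include_het:
            atoms += [a for r in self.het for a in r.atoms]
        return atoms


def _parse_float(text: str, what: str, lineno: int, default: float | None = None) -> float:
    text = text.strip()
    if not text:
        if default is not None:
            return default
        raise PDBParseError(f"line {lineno}: missing {what}")
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad {what} field {text!r}") from exc


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HD" and (len(name.strip()) == 4 or any(c.isdigit() for c in name)):
        return "H"
    return stripped[0].upper()


def read_pdb(source: str | Path | io.TextIOBase) -> StructureModel:
    """Parse fixed-column PDB text into a :class:`StructureModel`.

    ``source`` may be a path, raw PDB text, or an open text handle.  All
    altloc indicators, occupancies and B factors are preserved; hydrogens
    are retained (flagged through :attr:`Atom.is_hydrogen`).  Only the
    first MODEL of a multi-model file is read (with a warning).
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip()[:6] in ("ATOM  ", "HETATM", "HEADER", "REMARK"):
            text = s
        else:
            text = Path(source).read_text()
    if not text.strip():
        raise PDBParseError("empty PDB input")

    model = StructureModel()
    index: dict[tuple[str, int, str, str, bool], Residue] = {}
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), 1):
        rec = line[:6]
        if rec == "HEADER":
            model.pdb_id = line[62:66].strip().lower() or model.pdb_id
        elif rec == "REMARK" and line[6:10].strip() == "2" and "RESOLUTION." in line:
            token = line.split("RESOLUTION.", 1)[1].split()
            if token:
                try:
                    model.resolution = float(token[0])
                except ValueError:
                    pass  # e.g. "NOT APPLICABLE"
        elif rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                warnings.warn("multi-MODEL file: only the first MODEL is read", stacklevel=2)
                break
        elif rec == "ENDMDL":
            continue  # keep scanning so a second MODEL record triggers the warning
        elif rec in ("ATOM  ", "HETATM"):
            if in_model > 1:
                continue
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            name = line[12:16].strip()
            if not name:
                raise PDBParseError(f"line {lineno}: blank atom name")
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or " "
            try:
                res_seq = int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
            icode = line[26].strip()
            coord = np.array([
                _parse_float(line[30:38], "x", lineno),
                _parse_float(line[38:46], "y", lineno),
                _parse_float(line[46:54], "z", lineno),
            ])
            occupancy = _parse_float(line[54:60], "occupancy", lineno, default=1.0)
            b_factor = _parse_float(line[60:66], "B factor", lineno, default=0.0)
            element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(line[12:16])
            occupancy = min(max(occupancy, 0.0), 1.0)
            atom = Atom(name=name, element=element, coord=coord, altloc=altloc,
                        occupancy=occupancy, b_factor=b_factor, serial=lineno)
            is_het = rec == "HETATM" and res_name not in THREE_TO_ONE
            rkey = (chain_id, res_seq, icode, res_name, is_het)
            residue = index.get(rkey)
            if residue is None:
                residue = Residue(res_name=res_name, seq_id=(res_seq, icode),
                                  chain_id=chain_id, is_hetero=is_het)
                index[rkey] = residue
                if is_het and residue.standard_parent is None:
                    model.het.append(residue)
                else:
                    model.chains.setdefault(chain_id, []).append(residue)
            residue.atoms.append(atom)

    if not index:
        raise PDBParseError("no ATOM/HETATM records found")
    for chain in model.chains.values():
        chain.sort(key=lambda r: r.seq_id)
    _check_occupancy_sums(model)
    return model


def _check_occupancy_sums(model: StructureModel) -> None:
    """Log (never raise) occupancy sums > 1 per atom name within a residue."""
    for residue in model.residues():
        sums: dict[str, float] = {}
        for atom in residue.atoms:
            if atom.altloc:
                sums[atom.name] = sums.get(atom.name, 0.0) + atom.occupancy
        for name, total in sums.items():
            if total > 1.0 + 1e-6:
                log.warning("%s atom %s: altloc occupancies sum to %.3f > 1",
                            residue, name, total)


def group_conformers(residue: Residue) -> list[ConformerState]:
    """Partition a residue's atoms into alternate-location states.

    One state per distinct altloc indicator, ordered by indicator;
    blank-altloc atoms are shared into every state.  A residue with only
    blank altlocs yields a single state of occupancy 1.
    """
    if not residue.atoms:
        raise ValueError("cannot group conformers of an empty residue")
    indicators = sorted({a.altloc for a in residue.atoms if a.altloc})
    shared = [a for a in residue.atoms if not a.altloc]
    if not indicators:
        return [ConformerState(state_id="", atoms=list(residue.atoms), occupancy=1.0)]
    states = []
    for ind in indicators:
        own = [a for a in residue.atoms if a.altloc == ind]
        states.append(ConformerState(state_id=ind, atoms=shared + own,
                                     occupancy=_state_occupancy(own, residue)))
    return states


def _state_occupancy(own_atoms: list[Atom], residue: Residue) -> float:
    """Representative occupancy: mode over the state's side-chain atoms."""
    pool = [a for a in own_atoms if a.is_sidechain] or own_atoms
    values = [round(a.occupancy, 3) for a in pool]
    if not values:
        return 1.0
    counts: dict[float, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    mode = max(counts, key=lambda v: (counts[v], -values.index(v)))
    if len(counts) > 1:
        log.info("%s: inconsistent occupancies within one altloc state %s; using mode %.3f",
                 residue, sorted(counts), mode)
    return mode


def first_conformer(residue: Residue) -> ConformerState:
    """The state with the lexicographically smallest indicator.

    When the residue has labelled states, 'A' (or the smallest present
    label, e.g. 'B' for a {'B','C'} residue) wins; an all-blank residue
    returns its single state.
    """
    return group_conformers(residue)[0]


def sidechain_b_average(residue: Residue) -> float | None:
    """Mean B factor of heavy atoms other than N, CA, C, O; None for Gly."""
    values = [a.b_factor for a in residue.atoms if a.is_sidechain]
    if not values:
        return None
    return float(np.mean(values))


def chain_sequence(chain: list[Residue]) -> str:
    """One-letter sequence in seq_id order; altloc multiplicity collapses.

    One letter per chain residue ('X' for unmapped types), so sequence
    positions index directly into the chain's residue list.
    """
    return "".join(r.one_letter for r in chain)


_MAX_COORD = 9999.999
_MIN_COORD = -999.999


def _format_atom_name(atom: Atom) -> str:
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize to fixed-column PDB text, re-readable by :func:`read_pdb`."""
    lines = []
    if model.pdb_id or model.resolution is not None:
        lines.append(f"HEADER    {'':52s}{model.pdb_id.upper():>4s}")  # idCode cols 63-66
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    serial = 0
    for chain_id in model.chains:
        for residue in model.chains[chain_id]:
            for atom in residue.atoms:
                serial += 1
                lines.append(_atom_line("ATOM", serial, atom, residue))
        lines.append(f"TER   {serial + 1:>5d}")
        serial += 1
    for residue in model.het:
        for atom in residue.atoms:
            serial += 1
            lines.append(_atom_line("HETATM", serial, atom, residue))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _atom_line(rec: str, serial: int, atom: Atom, residue: Residue) -> str:
    x, y, z = atom.coord
    for v in (x, y, z):
        if not _MIN_COORD <= v <= _MAX_COORD:
            raise ValueError(f"coordinate {v:.3f} exceeds PDB field width")
    num, icode = residue.seq_id
    return (
        f"{rec:<6s}{serial:>5d} {_format_atom_name(atom)}{atom.altloc or ' '}"
        f"{residue.res_name:>3s} {residue.chain_id:1s}{num:>4d}{icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"{'':10s}{atom.element:>2s}"
    )
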