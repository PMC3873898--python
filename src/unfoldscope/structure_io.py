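"""Multi-model PDB trajectory I/O and the internal structural data model.

Length unit is Å throughout the data model (PDB-native); observables that
the rest of the package reports in nm are converted at those API
boundaries, never per record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom", "Residue", "Frame", "Trajectory",
    "read_pdb_models", "write_pdb_models", "validate_backbone",
    "add_amide_hydrogens", "BackboneReport",
]

# Masses (Da) for elements that occur in globin backbones plus heme iron.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "FE": 55.845, "P": 30.974, "SE": 78.971,
}
DEFAULT_MASS = 12.0

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Time tag emitted/parsed on a REMARK 250 line per MODEL.
_TIME_TAG = "REMARK 250  TIME_PS"


def element_mass(element: str) -> float:
    """Mass of *element* in Da; unknown elements fall back to 12.0 with a warning."""
    m = ATOMIC_MASSES.get(element.strip().upper())
    if m is None:
        warnings.warn(f"unknown element {element!r}; assuming mass {DEFAULT_MASS} Da")
        return DEFAULT_MASS
    return m


@dataclass
class Atom:
    """A single atom: PDB name, element, Cartesian coordinates in Å, mass in Da."""

    name: str
    element: str
    coords: np.ndarray
    mass: float | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.mass is None:
            self.mass = element_mass(self.element)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.mass, self.is_hetero)


@dataclass
class Residue:
    """One amino-acid residue with named backbone access (N, CA, C, O, H)."""

    index: int
    name: str
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("residue index must be ≥ 1")
        for role in BACKBONE_NAMES:
            if sum(1 for a in self.atoms if a.name == role) > 1:
                raise ValueError(f"residue {self.index}: duplicate backbone atom {role}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def n(self) -> Atom | None:
        return self.atom("N")

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def c(self) -> Atom | None:
        return self.atom("C")

    @property
    def o(self) -> Atom | None:
        return self.atom("O")

    @property
    def h(self) -> Atom | None:
        return self.atom("H")

    def missing_backbone(self) -> list[str]:
        return [r for r in BACKBONE_NAMES if self.atom(r) is None]

    def copy(self) -> "Residue":
        return Residue(self.index, self.name, self.chain, [a.copy() for a in self.atoms])


@dataclass
class Frame:
    """One trajectory frame: ordered residues, optional heme group, time in ps."""

    time: float
    residues: list[Residue]
    heme: list[Atom] | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("frame time must be ≥ 0")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        if self.heme is not None and not any(a.name == "FE" for a in self.heme):
            raise ValueError("heme group present but contains no FE atom")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_index(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def coords(self, atom_name: str) -> np.ndarray:
        """(n_residues, 3) array of one named atom per residue; NaN where absent."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            a = r.atom(atom_name)
            if a is not None:
                out[i] = a.coords
        return out

    def copy(self) -> "Frame":
        heme = [a.copy() for a in self.heme] if self.heme is not None else None
        return Frame(self.time, [r.copy() for r in self.residues], heme)


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one residue list."""

    frames: list[Frame]
    temperature: float = 300.0
    source: str = ""

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        if self.frames:
            ref = [(r.index, r.name) for r in self.frames[0].residues]
            for k, f in enumerate(self.frames[1:], start=1):
                if [(r.index, r.name) for r in f.residues] != ref:
                    raise ValueError(f"frame {k} has an inconsistent residue list")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class BackboneReport:
    """Per-residue missing-backbone report from :func:`validate_backbone`."""

    missing: dict[int, list[str]]
    assignable: bool

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.missing


def validate_backbone(frame: Frame) -> BackboneReport:
    """List residues lacking any of N, CA, C, O.

    A frame is *assignable* iff no interior residue (any but the chain
    termini) is incomplete — terminal residues commonly lack OXT/H and a
    missing terminal O still blocks only its own H-bond, not assignment.
    """
    missing = {r.index: m for r in frame.residues if (m := r.missing_backbone())}
    interior = {r.index for r in frame.residues[1:-1]}
    assignable = not (set(missing) & interior) if len(frame.residues) > 2 else not missing
    return BackboneReport(missing, assignable)


def add_amide_hydrogens(frame: Frame) -> Frame:
    """Return a copy of *frame* with backbone amide hydrogens placed.

    For each residue i ≥ 2 that is not a proline, H sits at
    ``N_i + u`` where u is the unit vector from O_{i-1} to C_{i-1}
    scaled to 1.00 Å (the carbonyl direction, the standard DSSP
    placement). The first residue and prolines get no H. Re-running
    replaces existing H atoms, so the operation is idempotent.
    Residues whose predecessor lacks C or O are skipped.
    """
    out = frame.copy()
    for prev, res in zip(out.residues, out.residues[1:]):
        res.atoms = [a for a in res.atoms if a.name != "H"]
        if res.name == "PRO":
            continue
        if prev.c is None or prev.o is None or res.n is None:
            continue
        u = prev.c.coords - prev.o.coords
        norm = np.linalg.norm(u)
        if norm == 0:
            continue
        h = res.n.coords + u / norm
        res.atoms.append(Atom("H", "H", h))
    if out.residues:
        first = out.residues[0]
        first.atoms = [a for a in first.atoms if a.name != "H"]
    return out


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _scan_model_times(path: Path) -> dict[int, float]:
    """Light text pass collecting per-MODEL time tags (ps) if present."""
    times: dict[int, float] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = int(line[10:14])
            elif line.startswith(_TIME_TAG) and current is not None:
                times[current] = float(line[len(_TIME_TAG):].strip())
    return times


def _biopython_atom(atom) -> Atom:
    name = atom.get_name().strip()
    element = (atom.element or name[:1]).strip()
    return Atom(name, element, np.asarray(atom.get_coord(), dtype=float))


def read_pdb_models(path: str | Path, dt_ps: float = 1.0,
                    temperature: float = 300.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One :class:`Frame` per MODEL (a single un-modelled structure yields one
    frame). ATOM records become residues; a HETATM residue named HEM becomes
    the frame's heme group. Altlocs other than ''/'A' are dropped; insertion
    codes are rejected; multi-chain protein input is rejected (the study
    system is monomeric). Frame time is the per-model REMARK time tag when
    present, else (model serial − first serial) × *dt_ps*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    times = _scan_model_times(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))

    frames: list[Frame] = []
    serials = sorted(m.serial_num if m.serial_num else m.id + 1 for m in structure)
    first_serial = serials[0] if serials else 1
    for model in structure:
        serial = model.serial_num if model.serial_num else model.id + 1
        residues: list[Residue] = []
        heme: list[Atom] = []
        chains_seen = set()
        for chain in model:
            for res in chain:
                hetflag, seq, icode = res.get_id()
                if icode.strip():
                    raise ValueError(
                        f"insertion code {icode!r} at residue {seq}: not supported")
                atoms = []
                for atom in res.get_unpacked_list():
                    if atom.get_altloc() not in (" ", "", "A"):
                        continue
                    atoms.append(_biopython_atom(atom))
                if hetflag.strip():
                    if res.get_resname().strip() == "HEM":
                        for a in atoms:
                            a.is_hetero = True
                        heme.extend(atoms)
                    continue  # waters / other ligands ignored
                chains_seen.add(chain.id)
                residues.append(Residue(seq, res.get_resname().strip(), chain.id, atoms))
        if len(chains_seen) > 1:
            raise ValueError(f"multi-chain protein input (chains {sorted(chains_seen)}); "
                             "only single-chain globins are supported")
        t = times.get(serial, (serial - first_serial) * dt_ps)
        frames.append(Frame(t, residues, heme or None))
    if not frames:
        raise ValueError(f"{path}: no models found")
    return Trajectory(frames, temperature=temperature, source=str(path))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(record: str, serial: int, name: str, resname: str,
                      chain: str, resseq: int, coords: np.ndarray,
                      element: str) -> str:
    if np.any(np.abs(coords) >= 10000.0):
        raise ValueError(f"coordinate {coords} exceeds the PDB fixed-width field (±9999.999)")
    # Atom-name column convention: names of <4 chars start in column 14.
    pdb_name = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {pdb_name}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:>4d}    {coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element.upper():>2s}")


def write_pdb_models(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB file.

    MODEL/ENDMDL per frame, a REMARK 250 time tag per model, HETATM records
    for the heme group, TER after the protein chain.
    """
    if not traj.frames:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    lines: list[str] = ["REMARK 250 UNFOLDSCOPE TRAJECTORY"]
    for k, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {k:>4d}")
        lines.append(f"{_TIME_TAG} {frame.time:.4f}")
        serial = 1
        last = None
        for res in frame.residues:
            for atom in res.atoms:
                lines.append(_format_atom_line(
                    "ATOM", serial, atom.name, res.name, res.chain or "A",
                    res.index, atom.coords, atom.element))
                serial += 1
            last = res
        if last is not None:
            lines.append(f"TER   {serial:>5d}      {last.name:>3s} "
                         f"{last.chain or 'A':1s}{last.index:>4d}")
            serial += 1
        if frame.heme:
            for atom in frame.heme:
                lines.append(_format_atom_line(
                    "HETATM", serial, atom.name, "HEM", "A", 201,
                    atom.coords, atom.element))
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
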