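"""Structures, ensembles and chemical-shift tables: types and file I/O.

Multi-model PDB files are the canonical ensemble format (what MD
post-processing tools emit); parsing and writing go through :mod:`gemmi`.
Chemical shifts come in two dialects: SPARTA+-style whitespace tables
(``VARS``/``FORMAT`` headers, columns RESID RESNAME ATOMNAME ... SHIFT) and a
plain TSV with columns ``chain  seq  atom_class  shift`` (optional ``icode``
and ``resname``).  Only the six backbone-reporter atom classes are kept:
CA, CB, C, N, HA, HN.

Residue identity is always the author numbering (chain, seq, icode) so that
structures and experimental shift tables cross-reference without renumbering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: The six chemical-shift atom classes scored by the benchmark.
ATOM_CLASSES: tuple[str, ...] = ("CA", "CB", "C", "N", "HA", "HN")

#: Phosphorylated residue names recognised throughout, mapped to site type.
PHOSPHO_RESIDUES: dict[str, str] = {"SEP": "pSer", "TPO": "pThr", "PTR": "pTyr"}

#: Parent (unmodified) residue of each phospho residue.
PARENT_RESIDUE: dict[str, str] = {"SEP": "SER", "TPO": "THR", "PTR": "TYR"}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # phospho residues report their parent letter
    "SEP": "S", "TPO": "T", "PTR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items() if k not in PHOSPHO_RESIDUES}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class TopologyError(ValueError):
    """Raised when ensemble frames disagree on residues or atom names."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue: (chain, seq, icode)."""

    chain: str
    seq: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42A"
        return f"{self.chain}:{self.seq}{self.icode}"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    key: ResidueKey
    name: str  # 3-letter code, e.g. "ALA", "SEP"
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has(self, *names: str) -> bool:
        return all(self.atom(n) is not None for n in names)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def is_phospho(self) -> bool:
        return self.name in PHOSPHO_RESIDUES


class Conformation:
    """A single structure: an ordered list of residues with atoms.

    Residue order follows file order.  Phospho residues (SEP/TPO/PTR) are
    first-class residues; ``sequence`` maps them to their parent letter.
    """

    def __init__(self, residues: Sequence[Residue]):
        self.residues: list[Residue] = list(residues)
        self._index: dict[ResidueKey, Residue] = {}
        for r in self.residues:
            if r.key in self._index:
                raise ValueError(f"duplicate residue key {r.key}")
            self._index[r.key] = r

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def get(self, key: ResidueKey) -> Residue | None:
        return self._index.get(key)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.key.chain, []).append(r)
        return out

    def coords(self, atom_names: Iterable[str] | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to given atom names."""
        names = set(atom_names) if atom_names is not None else None
        rows = [
            a.coord
            for r in self.residues
            for a in r.atoms
            if names is None or a.name in names
        ]
        if not rows:
            raise ValueError("empty atom selection")
        return np.array(rows, dtype=float)

    def topology_signature(self) -> list[tuple[ResidueKey, str, tuple[str, ...]]]:
        return [(r.key, r.name, tuple(a.name for a in r.atoms)) for r in self.residues]


class Ensemble:
    """Frames sharing one topology (same residues, same atom names)."""

    def __init__(self, frames: Sequence[Conformation], frame_times: Sequence[float] | None = None):
        if not frames:
            raise ValueError("an Ensemble needs at least one frame")
        sig0 = frames[0].topology_signature()
        for i, f in enumerate(frames[1:], start=2):
            sig = f.topology_signature()
            if sig != sig0:
                for a, b in zip(sig0, sig):
                    if a != b:
                        raise TopologyError(
                            f"frame {i} differs from frame 1 at residue {a[0]}: "
                            f"{a[1]}/{list(a[2])} vs {b[1]}/{list(b[2])}"
                        )
                raise TopologyError(f"frame {i} has {len(sig)} residues, frame 1 has {len(sig0)}")
        self.frames: list[Conformation] = list(frames)
        self.frame_times = list(frame_times) if frame_times is not None else None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> Conformation:
        return self.frames[0]


class ShiftTable:
    """(ResidueKey, atom class) -> chemical shift in ppm.

    Optionally carries residue names so that random-coil references can be
    resolved when forming secondary shifts.
    """

    def __init__(
        self,
        records: Iterable[tuple[ResidueKey, str, float]] = (),
        resnames: Mapping[ResidueKey, str] | None = None,
    ):
        self._shifts: dict[tuple[ResidueKey, str], float] = {}
        self.resnames: dict[ResidueKey, str] = dict(resnames or {})
        for key, cls, shift in records:
            self.add(key, cls, shift)

    def add(self, key: ResidueKey, atom_class: str, shift: float) -> None:
        if atom_class not in ATOM_CLASSES:
            raise ValueError(f"unknown atom class {atom_class!r}")
        if not math.isfinite(shift):
            raise ValueError(f"non-finite shift for {key}/{atom_class}")
        k = (key, atom_class)
        if k in self._shifts:
            raise ParseError(f"duplicate record for {key}/{atom_class}")
        self._shifts[k] = float(shift)

    def get(self, key: ResidueKey, atom_class: str) -> float | None:
        return self._shifts.get((key, atom_class))

    def __len__(self) -> int:
        return len(self._shifts)

    def __iter__(self) -> Iterator[tuple[ResidueKey, str, float]]:
        for (key, cls), shift in self._shifts.items():
            yield key, cls, shift

    def __contains__(self, item: tuple[ResidueKey, str]) -> bool:
        return item in self._shifts

    def residue_keys(self) -> list[ResidueKey]:
        return sorted({k for k, _ in self._shifts})

    def records(self) -> dict[tuple[ResidueKey, str], float]:
        return dict(self._shifts)

    def sorted_records(self) -> list[tuple[ResidueKey, str, float]]:
        return sorted(
            ((k, c, s) for (k, c), s in self._shifts.items()),
            key=lambda t: (t[0], ATOM_CLASSES.index(t[1])),
        )

    def restrict(self, keys: Iterable[ResidueKey]) -> "ShiftTable":
        keep = set(keys)
        out = ShiftTable(resnames={k: v for k, v in self.resnames.items() if k in keep})
        for key, cls, shift in self:
            if key in keep:
                out.add(key, cls, shift)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return self._shifts == other._shifts


# ---------------------------------------------------------------------------
# PDB ensembles


def _keep_residue(res: gemmi.Residue) -> bool:
    name = res.name.strip().upper()
    if name in PHOSPHO_RESIDUES:
        return True
    if name in _WATER_NAMES:
        return False
    if res.het_flag == "H":
        # other heteroatoms (ions, ligands) are outside the benchmark
        return name in THREE_TO_ONE
    return True


def _validate_pdb_text(path: Path) -> None:
    """Check coordinate fields of ATOM/HETATM lines parse as numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated ATOM/HETATM line")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None


def read_pdb_models(path: str | Path) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL; a bare ATOM-only file yields one frame.  HETATM
    records for SEP/TPO/PTR are kept as residues; waters, ions and other
    heteroatoms are dropped.  Alternate locations: altloc blank or "A" kept,
    others dropped (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line numbers itself
        raise ParseError(f"{path}: {exc}") from exc

    dropped_altloc = 0
    frames: list[Conformation] = []
    for model in st:
        residues: list[Residue] = []
        for chain in model:
            for res in chain:
                if not _keep_residue(res):
                    continue
                key = ResidueKey(chain.name or "A", res.seqid.num, (res.seqid.icode or " ").strip())
                atoms: list[AtomRecord] = []
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        dropped_altloc += 1
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            element=atom.element.name,
                            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy=atom.occ,
                            bfactor=atom.b_iso,
                        )
                    )
                if atoms:
                    residues.append(Residue(key=key, name=res.name.strip().upper(), atoms=atoms))
        if residues:
            frames.append(Conformation(residues))
    if dropped_altloc:
        logger.info("%s: dropped %d alternate-location atoms", path, dropped_altloc)
    if not frames:
        raise ParseError(f"{path}: no protein residues found")
    return Ensemble(frames)


def write_pdb_models(ens: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB file (coordinates to 3 dp)."""
    st = gemmi.Structure()
    st.name = "phosbench"
    for i, frame in enumerate(ens.frames, start=1):
        model = gemmi.Model(i)
        for chain_name, residues in frame.chains().items():
            chain = gemmi.Chain(chain_name)
            for r in residues:
                res = gemmi.Residue()
                res.name = r.name
                res.seqid = gemmi.SeqId(r.key.seq, r.key.icode or " ")
                res.het_flag = "H" if r.name in PHOSPHO_RESIDUES else "A"
                for a in r.atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element or a.name[0])
                    atom.pos = gemmi.Position(*a.coord)
                    atom.occ = a.occupancy
                    atom.b_iso = a.bfactor
                    atom.serial = a.serial
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def detect_modifications(conf: Conformation) -> set[tuple[ResidueKey, str]]:
    """Phosphosites in a structure: {(ResidueKey, 'pSer'|'pThr'|'pTyr')}."""
    return {(r.key, PHOSPHO_RESIDUES[r.name]) for r in conf if r.is_phospho}


# ---------------------------------------------------------------------------
# Shift tables

_SPARTA_HEADER_KEYWORDS = ("VARS", "FORMAT", "REMARK", "DATA")


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0].upper()
            if first in _SPARTA_HEADER_KEYWORDS:
                return "sparta"
            if "chain" in stripped.lower().split("\t") or stripped.lower().startswith("chain"):
                return "tsv"
            return "sparta"
    raise ParseError(f"{path}: empty shift table")


def _normalise_atom_name(name: str) -> str | None:
    """Map a predictor atom name onto one of the six classes (None = drop)."""
    name = name.upper()
    if name == "H":
        return "HN"
    if name in ATOM_CLASSES:
        return name
    return None


def _read_sparta(path: Path) -> ShiftTable:
    columns: list[str] | None = None
    raw: list[tuple[int, str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if fields[0].upper() in _SPARTA_HEADER_KEYWORDS:
                if fields[0].upper() == "VARS":
                    columns = [f.upper() for f in fields[1:]]
                continue
            cols = columns or ["RESID", "RESNAME", "ATOMNAME", "SHIFT"]
            for need in ("RESID", "RESNAME", "ATOMNAME", "SHIFT"):
                if need not in cols:
                    raise ParseError(f"{path}: VARS line lacks column {need}")
            if len(fields) < len(cols):
                raise ParseError(f"{path}:{lineno}: expected {len(cols)} fields")
            try:
                resid = int(fields[cols.index("RESID")])
                shift = float(fields[cols.index("SHIFT")])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            resname = fields[cols.index("RESNAME")].upper()
            atomname = fields[cols.index("ATOMNAME")].upper()
            raw.append((resid, resname, atomname, shift))

    table = ShiftTable()
    dropped = 0
    # glycine HA2/HA3 pairs collapse onto HA by averaging
    pending_ha: dict[int, list[float]] = {}
    for resid, resname, atomname, shift in raw:
        key = ResidueKey("A", resid)
        if len(resname) == 1:
            resname = ONE_TO_THREE.get(resname, resname)
        table.resnames.setdefault(key, resname)
        if atomname in ("HA2", "HA3"):
            pending_ha.setdefault(resid, []).append(shift)
            continue
        cls = _normalise_atom_name(atomname)
        if cls is None:
            dropped += 1
            continue
        table.add(key, cls, shift)
    for resid, values in pending_ha.items():
        table.add(ResidueKey("A", resid), "HA", float(np.mean(values)))
    if dropped:
        logger.info("%s: dropped %d records outside the six atom classes", path, dropped)
    return table


def _read_tsv(path: Path) -> ShiftTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for need in ("chain", "seq", "atom_class", "shift"):
        if need not in df.columns:
            raise ParseError(f"{path}: missing column {need!r}")
    def _cell(d: dict, name: str) -> str:
        v = d.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
            return ""
        return str(v).strip()

    table = ShiftTable()
    dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            seq = int(d["seq"])
            shift = float(d["shift"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric seq/shift in row {d}") from None
        key = ResidueKey(_cell(d, "chain"), seq, _cell(d, "icode"))
        cls = _normalise_atom_name(_cell(d, "atom_class"))
        if cls is None:
            dropped += 1
            continue
        table.add(key, cls, shift)
        resname = _cell(d, "resname")
        if resname:
            table.resnames.setdefault(key, resname.upper())
    if dropped:
        logger.info("%s: dropped %d records outside the six atom classes", path, dropped)
    return table


def read_shift_table(path: str | Path, dialect: str | None = None) -> ShiftTable:
    """Read a chemical-shift table (``sparta`` or ``tsv`` dialect).

    With ``dialect=None`` the dialect is auto-detected; the TSV writer's
    output always re-reads to an equal table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect == "sparta":
        return _read_sparta(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write a ShiftTable in the plain-TSV dialect."""
    lines = ["chain\tseq\ticode\tresname\tatom_class\tshift"]
    for key, cls, shift in table.sorted_records():
        resname = table.resnames.get(key, "")
        lines.append(f"{key.chain}\t{key.seq}\t{key.icode}\t{resname}\t{cls}\t{shift:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
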