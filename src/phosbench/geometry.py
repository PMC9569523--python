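"""Structural mathematics: superposition, RMSD/RMSF, Rg, end-to-end, dihedrals.

All distances in Angstrom, all angles in degrees in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .structure_io import AtomRecord, Conformation, Ensemble, Residue

# Average atomic masses for the elements that occur in protein backbones and
# the phosphate group; fall back to carbon for unknowns.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    """Optimal rigid-body fit: x_fit = rotation @ x_mobile + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Weighted least-squares rigid superposition (Kabsch, via SVD).

    The reflection branch is removed by flipping the sign of the smallest
    singular vector when det < 0, so the rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be N x 3")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0) / wsum
    mu_r = (w[:, None] * reference).sum(axis=0) / wsum
    X = mobile - mu_m
    Y = reference - mu_r
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) reference coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    diff = (X @ R.T) - Y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _atom_mass(atom: AtomRecord) -> float:
    element = (atom.element or atom.name[:1]).upper()
    return _MASSES.get(element, 12.011)


def rg(
    conf: Conformation,
    selection: Callable[[Residue, AtomRecord], bool] | None = None,
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration: sqrt( sum m_i |r_i - r_cm|^2 / sum m_i )."""
    coords, masses = [], []
    for r in conf:
        for a in r.atoms:
            if selection is None or selection(r, a):
                coords.append(a.coord)
                masses.append(_atom_mass(a) if mass_weighted else 1.0)
    if not coords:
        raise ValueError("empty atom selection")
    x = np.array(coords)
    m = np.array(masses)
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    d2 = np.einsum("ij,ij->i", x - com, x - com)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def end_to_end(conf: Conformation) -> float:
    """Distance between the first and last CA atoms."""
    cas = [r.atom("CA") for r in conf]
    cas = [a for a in cas if a is not None]
    if len(cas) < 2:
        raise ValueError("need CA atoms in at least two residues")
    first, last = None, None
    for r in conf.residues:
        a = r.atom("CA")
        if a is not None:
            if first is None:
                first = a
            last = a
    if conf.residues[0].atom("CA") is None or conf.residues[-1].atom("CA") is None:
        raise ValueError("terminal residue lacks a CA atom")
    assert first is not None and last is not None
    return float(np.linalg.norm(last.coord - first.coord))


def _selected_coords(
    conf: Conformation, selection: Callable[[Residue, AtomRecord], bool] | None
) -> tuple[np.ndarray, list[int]]:
    """Coordinates of selected atoms plus the residue index of each atom."""
    coords, res_idx = [], []
    for i, r in enumerate(conf.residues):
        for a in r.atoms:
            if selection is None or selection(r, a):
                coords.append(a.coord)
                res_idx.append(i)
    if not coords:
        raise ValueError("empty atom selection")
    return np.array(coords), res_idx


def _default_backbone(residue: Residue, atom: AtomRecord) -> bool:
    return atom.name in BACKBONE_HEAVY


def rmsd_series(
    ens: Ensemble,
    reference: Conformation | None = None,
    selection: Callable[[Residue, AtomRecord], bool] | None = None,
) -> np.ndarray:
    """Per-frame best-fit RMSD to a reference (default: first frame).

    Selection defaults to backbone heavy atoms (N, CA, C, O).
    """
    sel = selection or _default_backbone
    ref = reference if reference is not None else ens.frames[0]
    ref_xyz, _ = _selected_coords(ref, sel)
    out = np.empty(ens.n_frames)
    for i, frame in enumerate(ens):
        xyz, _ = _selected_coords(frame, sel)
        out[i] = kabsch_superpose(xyz, ref_xyz).rmsd
    return out


def rmsf(
    ens: Ensemble,
    selection: Callable[[Residue, AtomRecord], bool] | None = None,
) -> np.ndarray:
    """Per-residue RMSF about the iteratively superposed mean structure.

    Frames are superposed onto the first frame, a mean structure is formed,
    frames are re-superposed onto that mean (one refinement pass), and
    RMSF_i = sqrt(mean_frames |r_i - <r_i>|^2), averaged over selected atoms
    within each residue.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    sel = selection or _default_backbone
    ref_xyz, res_idx = _selected_coords(ens.frames[0], sel)
    stack = np.empty((ens.n_frames, len(ref_xyz), 3))
    for i, frame in enumerate(ens):
        xyz, _ = _selected_coords(frame, sel)
        stack[i] = kabsch_superpose(xyz, ref_xyz).apply(xyz)
    mean = stack.mean(axis=0)
    for i in range(ens.n_frames):
        stack[i] = kabsch_superpose(stack[i], mean).apply(stack[i])
    mean = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    n_res = len(ens.topology)
    out = np.full(n_res, np.nan)
    idx = np.array(res_idx)
    for i in range(n_res):
        mask = idx == i
        if mask.any():
            out[i] = per_atom[mask].mean()
    return out


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees, IUPAC sign convention, in (-180, 180].

    Returns NaN when any three consecutive atoms are collinear.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1)
    norm2 = np.linalg.norm(n2)
    if norm1 < 1e-9 or norm2 < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def backbone_dihedrals(ens: Ensemble | Conformation) -> np.ndarray:
    """(phi, psi) per frame and residue, degrees; NaN where undefined.

    phi = C(i-1)-N(i)-CA(i)-C(i); psi = N(i)-CA(i)-C(i)-N(i+1).
    phi is undefined for the first residue of a chain, psi for the last;
    missing backbone atoms leave the angle NaN.  Returns an array of shape
    (n_frames, n_residues, 2); a bare Conformation is treated as one frame.
    """
    if isinstance(ens, Conformation):
        ens = Ensemble([ens])
    n_res = len(ens.topology)
    out = np.full((ens.n_frames, n_res, 2), np.nan)
    for f, frame in enumerate(ens):
        residues = frame.residues
        for i, r in enumerate(residues):
            prev_r = residues[i - 1] if i > 0 and residues[i - 1].key.chain == r.key.chain else None
            next_r = (
                residues[i + 1]
                if i + 1 < len(residues) and residues[i + 1].key.chain == r.key.chain
                else None
            )
            n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
            if n is None or ca is None or c is None:
                continue
            if prev_r is not None:
                c_prev = prev_r.atom("C")
                if c_prev is not None:
                    out[f, i, 0] = dihedral(c_prev.coord, n.coord, ca.coord, c.coord)
            if next_r is not None:
                n_next = next_r.atom("N")
                if n_next is not None:
                    out[f, i, 1] = dihedral(n.coord, ca.coord, c.coord, n_next.coord)
    return out
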