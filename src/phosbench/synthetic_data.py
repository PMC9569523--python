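"""Ground-truth synthetic fixtures: backbones, ensembles and shift tables.

The generator stands in for MD ensembles and chemical-shift predictions so
every metric in the package can be checked against a known truth:

- :func:`build_backbone` constructs N/CA/C/O (+CB, amide H, and a pseudo
  phosphate for SEP/TPO/PTR) from per-residue (phi, psi) by sequential
  internal-to-Cartesian (NeRF) placement with standard peptide geometry.
  Backbone dihedrals measured on the output recover the inputs.
- :func:`make_ensemble` samples frames whose per-residue secondary-structure
  states follow stated targets, with tight Gaussian dihedral noise and
  optional Cartesian jitter.
- :func:`make_shift_experiment` builds an experimental shift table as
  random-coil + secondary-structure offsets and per-"force-field" predicted
  tables as experiment + Gaussian error with controlled per-class sigma, so
  score recovery is checkable.

Everything is driven by one integer seed; identical seeds give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .secstruct import place_amide_hydrogens
from .structure_io import (
    ATOM_CLASSES,
    Conformation,
    Ensemble,
    ONE_TO_THREE,
    Residue,
    ResidueKey,
    AtomRecord,
    ShiftTable,
)
from .shift_eval import RandomCoilTable

# Standard peptide-bond geometry (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: Canonical (phi, psi) of the generator's secondary-structure states.
STATE_ANGLES = {
    "H": (-57.0, -47.0),  # alpha helix
    "E": (-120.0, 120.0),  # extended strand
    "P": (-75.0, 145.0),  # polyproline II
}
#: Dihedral jitter around the canonical state values (degrees).
ANGLE_SIGMA = 5.0
#: Coil state: phi, psi drawn uniformly from this broad upper-left basin.
COIL_PHI = (-160.0, -60.0)
COIL_PSI = (60.0, 180.0)

_PHOSPHO_LOWER = {"s": "SEP", "t": "TPO", "y": "PTR"}
_HYDROXYL_NAME = {"SEP": "OG", "TPO": "OG1", "PTR": "OH"}

#: Secondary-structure offsets added to random-coil shifts (ppm) when
#: synthesising an "experimental" table, per generator state and class.
DEFAULT_SS_OFFSETS: dict[str, dict[str, float]] = {
    "H": {"CA": 2.6, "CB": -0.4, "C": 1.8, "N": -1.5, "HA": -0.35, "HN": -0.2},
    "E": {"CA": -1.4, "CB": 2.2, "C": -1.3, "N": 2.5, "HA": 0.4, "HN": 0.3},
    "P": {"CA": -0.8, "CB": 0.0, "C": -0.5, "N": 0.0, "HA": 0.1, "HN": 0.0},
    "C": {c: 0.0 for c in ATOM_CLASSES},
}


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """NeRF atom placement: d with |cd|=bond, angle(bcd)=angle, torsion(abcd)=torsion."""
    theta = math.radians(angle)
    chi = -math.radians(torsion)  # sign fixed so measured IUPAC torsions equal the input
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _residue_name(letter: str) -> str:
    if letter in _PHOSPHO_LOWER:
        return _PHOSPHO_LOWER[letter]
    if letter.upper() in ONE_TO_THREE:
        return ONE_TO_THREE[letter.upper()]
    raise ValueError(f"unknown sequence letter {letter!r}")


def _idealized_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca + (-0.58273431 * a + 0.56802827 * b - 0.54067466 * cc)


def _phosphate_atoms(ca: np.ndarray, cb: np.ndarray, resname: str, serial0: int) -> list[AtomRecord]:
    """Idealised hydroxyl-O + P + 3 phosphate O along the CA->CB direction."""
    u = cb - ca
    u /= np.linalg.norm(u)
    og = cb + 1.42 * u
    p = og + 1.61 * u
    # orthonormal frame perpendicular to u
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    atoms = [AtomRecord(serial0, _HYDROXYL_NAME[resname], "O", og)]
    atoms.append(AtomRecord(serial0 + 1, "P", "P", p))
    tilt = math.radians(180.0 - 109.5)  # O-P-OG angle 109.5
    for k, name in enumerate(("O1P", "O2P", "O3P")):
        phi = math.radians(120.0 * k)
        d = math.cos(tilt) * u + math.sin(tilt) * (math.cos(phi) * v + math.sin(phi) * w)
        atoms.append(AtomRecord(serial0 + 2 + k, name, "O", p + 1.48 * d))
    return atoms


def build_backbone(
    sequence: str,
    phi_psi: Sequence[tuple[float, float]] | np.ndarray,
    chain: str = "A",
    start_seq: int = 1,
    add_hydrogens: bool = True,
) -> Conformation:
    """Build a peptide backbone from per-residue (phi, psi), omega = 180.

    ``sequence`` is one-letter; lowercase s/t/y mark SEP/TPO/PTR (built with
    an idealised pseudo-phosphate on CB).  phi of the first residue and psi
    of the last only orient terminal atoms.  Measured dihedrals round-trip
    to the inputs within numerical accuracy.
    """
    angles = np.asarray(phi_psi, dtype=float)
    if angles.shape != (len(sequence), 2) or not np.all(np.isfinite(angles)):
        raise ValueError("phi_psi must be a finite (n_residues, 2) array")
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    dummy = np.array([0.0, 1.0, 0.0])
    C[0] = _place(dummy, N[0], CA[0], BOND_CA_C, ANGLE_N_CA_C, angles[0, 0] + 180.0)
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, angles[i - 1, 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, angles[i, 0])
    for i in range(n_res):
        O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, angles[i, 1] + 180.0)

    residues = []
    serial = 1
    for i, letter in enumerate(sequence):
        resname = _residue_name(letter)
        atoms = [
            AtomRecord(serial, "N", "N", N[i]),
            AtomRecord(serial + 1, "CA", "C", CA[i]),
            AtomRecord(serial + 2, "C", "C", C[i]),
            AtomRecord(serial + 3, "O", "O", O[i]),
        ]
        serial += 4
        if resname != "GLY":
            cb = _idealized_cb(N[i], CA[i], C[i])
            atoms.append(AtomRecord(serial, "CB", "C", cb))
            serial += 1
            if resname in _HYDROXYL_NAME:
                phos = _phosphate_atoms(CA[i], cb, resname, serial)
                atoms.extend(phos)
                serial += len(phos)
        residues.append(Residue(ResidueKey(chain, start_seq + i), resname, atoms))
    conf = Conformation(residues)
    if add_hydrogens:
        conf = place_amide_hydrogens(conf)
    return conf


def make_helix(n_res: int = 12, sequence: str | None = None) -> Conformation:
    """Ideal alpha helix at (phi, psi) = (-57, -47)."""
    seq = sequence or "A" * n_res
    return build_backbone(seq, [STATE_ANGLES["H"]] * len(seq))


def _pair_energy_count(
    nA: np.ndarray, hA: np.ndarray, cA: np.ndarray, oA: np.ndarray,
    nB: np.ndarray, hB: np.ndarray, cB: np.ndarray, oB: np.ndarray,
) -> tuple[int, float]:
    """Count and sum Kabsch-Sander inter-strand bonds (both directions)."""

    def _dir(nd, hd, ca_, oa_):
        r_on = np.linalg.norm(oa_[None, :, :] - nd[:, None, :], axis=2)
        r_ch = np.linalg.norm(ca_[None, :, :] - hd[:, None, :], axis=2)
        r_oh = np.linalg.norm(oa_[None, :, :] - hd[:, None, :], axis=2)
        r_cn = np.linalg.norm(ca_[None, :, :] - nd[:, None, :], axis=2)
        with np.errstate(divide="ignore"):
            e = 27.888 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        e = np.where(np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) < 0.5, -9.9, e)
        return e

    e1 = _dir(nB, hB, cA, oA)  # B donates to A
    e2 = _dir(nA, hA, cB, oB)  # A donates to B
    bonds = (e1 < -0.5).sum() + (e2 < -0.5).sum()
    energy = float(e1[e1 < -0.5].sum() + e2[e2 < -0.5].sum())
    return int(bonds), energy


def make_strand_pair(
    n_res: int = 8, antiparallel: bool = True, sequence: str | None = None
) -> Conformation:
    """Two ideal strands placed to hydrogen-bond as a two-stranded sheet.

    The partner strand is a rigid copy of the first (flipped for the
    antiparallel case) positioned by a deterministic grid search, in the
    strand's own frame, that maximises the number of Kabsch-Sander
    inter-strand hydrogen bonds.
    """
    seq = sequence or "V" * n_res
    strand = build_backbone(seq, [STATE_ANGLES["E"]] * len(seq), chain="A")

    # strand frame: e1 along the chain axis, e2 along the mean carbonyl
    # direction (the H-bond direction, alternating sign removed), e3 normal
    ca = np.array([r.atom("CA").coord for r in strand.residues])
    e1 = ca[-1] - ca[0]
    e1 /= np.linalg.norm(e1)
    co = np.array(
        [
            (r.atom("O").coord - r.atom("C").coord) * (-1.0) ** i
            for i, r in enumerate(strand.residues)
        ]
    ).mean(axis=0)
    co -= (co @ e1) * e1
    e2 = co / np.linalg.norm(co)
    e3 = np.cross(e1, e2)

    names = ["N", "H", "C", "O"]
    base = {
        nm: np.array([r.atom(nm).coord if r.atom(nm) else np.full(3, 1e6) for r in strand.residues])
        for nm in names
    }
    centroid = ca.mean(axis=0)

    def rot180(axis: np.ndarray) -> np.ndarray:
        a = axis / np.linalg.norm(axis)
        return 2.0 * np.outer(a, a) - np.eye(3)

    rotations = [rot180(e2), rot180(e3)] if antiparallel else [np.eye(3)]
    best = None  # (bonds, -energy, R, shift)
    for R in rotations:
        rotated = {nm: (base[nm] - centroid) @ R.T + centroid for nm in names}
        for d1 in np.arange(-4.0, 4.01, 0.25):
            for d2 in np.arange(3.8, 5.81, 0.1):
                for sign in (1.0, -1.0):
                    shift = d1 * e1 + sign * d2 * e2
                    cand = {nm: rotated[nm] + shift for nm in names}
                    bonds, energy = _pair_energy_count(
                        base["N"], base["H"], base["C"], base["O"],
                        cand["N"], cand["H"], cand["C"], cand["O"],
                    )
                    key = (bonds, -energy)
                    if best is None or key > best[0]:
                        best = (key, R, shift)
    assert best is not None
    _, R, shift = best
    residues = []
    serial = 1000
    for i, r in enumerate(strand.residues):
        atoms = []
        for a in r.atoms:
            coord = (a.coord - centroid) @ R.T + centroid + shift
            atoms.append(AtomRecord(serial, a.name, a.element, coord))
            serial += 1
        residues.append(Residue(ResidueKey("B", 101 + i), r.name, atoms))
    return Conformation(list(strand.residues) + residues)


@dataclass
class GeneratorSpec:
    """Conditions for a synthetic ensemble / shift experiment.

    ``sequence``: one-letter, lowercase s/t/y for phospho residues.
    ``ss_target``: per-residue state string over {H, E, P, C}, or a list of
    (weight, string) mixed at frame level.  ``shift_noise``: per force
    field, either one sigma (ppm, all classes) or a per-class mapping.
    """

    sequence: str
    ss_target: str | list[tuple[float, str]] = ""
    noise_sigma: float = 0.0
    n_frames: int = 100
    shift_noise: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if not self.ss_target:
            self.ss_target = "C" * len(self.sequence)
        targets = (
            [self.ss_target] if isinstance(self.ss_target, str)
            else [t for _, t in self.ss_target]
        )
        for t in targets:
            if len(t) != len(self.sequence):
                raise ValueError("ss_target length differs from sequence length")
            if set(t) - set("HEPC"):
                raise ValueError(f"unknown state letters in {t!r}")
        if self.noise_sigma < 0 or self.n_frames < 1:
            raise ValueError("noise_sigma must be >= 0 and n_frames >= 1")

    def weighted_targets(self) -> list[tuple[float, str]]:
        if isinstance(self.ss_target, str):
            return [(1.0, self.ss_target)]
        total = sum(w for w, _ in self.ss_target)
        return [(w / total, t) for w, t in self.ss_target]

    def dominant_target(self) -> str:
        return max(self.weighted_targets(), key=lambda wt: wt[0])[1]


def _sample_angles(target: str, rng: np.random.Generator) -> np.ndarray:
    out = np.empty((len(target), 2))
    for i, state in enumerate(target):
        if state == "C":
            out[i, 0] = rng.uniform(*COIL_PHI)
            out[i, 1] = rng.uniform(*COIL_PSI)
        else:
            out[i] = np.array(STATE_ANGLES[state]) + rng.normal(0.0, ANGLE_SIGMA, 2)
    return out


def make_ensemble(spec: GeneratorSpec) -> tuple[Ensemble, dict]:
    """Sample an ensemble realising the spec's secondary-structure targets.

    Returns (ensemble, truth) where truth holds the per-frame state strings
    and the intended per-residue state fractions.
    """
    rng = np.random.default_rng(spec.seed)
    weights, targets = zip(*spec.weighted_targets())
    frames = []
    frame_states = []
    for _ in range(spec.n_frames):
        t_idx = rng.choice(len(targets), p=np.asarray(weights))
        target = targets[t_idx]
        frame_states.append(target)
        conf = build_backbone(spec.sequence, _sample_angles(target, rng))
        if spec.noise_sigma > 0:
            for r in conf:
                for a in r.atoms:
                    a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)
        frames.append(conf)
    n_res = len(spec.sequence)
    fractions = {
        state: np.array(
            [sum(1 for t in frame_states if t[i] == state) / spec.n_frames for i in range(n_res)]
        )
        for state in "HEPC"
    }
    truth = {"frame_states": frame_states, "state_fractions": fractions}
    return Ensemble(frames), truth


def _sigma_for(noise: float | Mapping[str, float], atom_class: str) -> float:
    if isinstance(noise, Mapping):
        return float(noise.get(atom_class, 0.0))
    return float(noise)


def make_shift_experiment(
    spec: GeneratorSpec,
    rc: RandomCoilTable | None = None,
    ss_offsets: Mapping[str, Mapping[str, float]] | None = None,
    site_noise: Mapping[str, float | Mapping[str, float]] | None = None,
) -> tuple[ShiftTable, dict[str, ShiftTable], dict[str, dict[str, float]]]:
    """Synthesise an experimental shift table and noisy per-force-field predictions.

    exp = random-coil + state offset per residue/class (state from the
    spec's dominant target); pred(ff) = exp + N(0, sigma_{ff,class}).
    ``site_noise`` optionally overrides sigma at phospho residues only, so a
    candidate can be best at modification sites without being best overall.
    Returns (exp, {ff: pred}, {ff: {class: sigma}} truth).
    """
    rc = rc or RandomCoilTable()
    offsets = ss_offsets or DEFAULT_SS_OFFSETS
    rng = np.random.default_rng(spec.seed)
    target = spec.dominant_target()

    exp = ShiftTable()
    for i, letter in enumerate(spec.sequence):
        resname = _residue_name(letter)
        key = ResidueKey("A", i + 1)
        exp.resnames[key] = resname
        state = target[i]
        for cls in ATOM_CLASSES:
            base = rc.get(resname, cls)
            if base is None:
                continue
            exp.add(key, cls, base + float(offsets[state].get(cls, 0.0)))

    phospho_keys = {
        ResidueKey("A", i + 1)
        for i, letter in enumerate(spec.sequence)
        if letter in _PHOSPHO_LOWER
    }
    preds: dict[str, ShiftTable] = {}
    truth: dict[str, dict[str, float]] = {}
    for ff, noise in spec.shift_noise.items():
        pred = ShiftTable(resnames=dict(exp.resnames))
        truth[ff] = {}
        for key, cls, shift in exp.sorted_records():
            sigma = _sigma_for(noise, cls)
            if site_noise and ff in site_noise and key in phospho_keys:
                sigma = _sigma_for(site_noise[ff], cls)
            truth[ff][cls] = _sigma_for(noise, cls)
            err = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            pred.add(key, cls, shift + err)
        preds[ff] = pred
    return exp, preds, truth


def make_frame_predictions(
    exp: ShiftTable, sigma: float, n_frames: int, seed: int = 0
) -> list[ShiftTable]:
    """Per-frame predicted tables: exp + i.i.d. N(0, sigma) each frame.

    The cumulative average converges to ``exp`` at the 1/sqrt(t) rate,
    which is what a converging simulation's shift predictions look like.
    """
    rng = np.random.default_rng(seed)
    out = []
    records = exp.sorted_records()
    for _ in range(n_frames):
        t = ShiftTable(resnames=dict(exp.resnames))
        for key, cls, shift in records:
            t.add(key, cls, shift + rng.normal(0.0, sigma))
        out.append(t)
    return out
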