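"""Distributional ensemble analyses.

RMSD-Rg free-energy landscapes (Boltzmann inversion of a 2-D histogram),
Ramachandran densities with named-region occupancies, a Jensen-Shannon
divergence between densities, and geometric hydrogen-bond counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Conformation, Ensemble, Residue, ResidueKey

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL = 0.0019872041

#: Default rectangular (phi, psi) region masks in degrees.  PPII overlaps
#: are resolved in favour of sheet (sheet is tested first).
DEFAULT_REGIONS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "helix": ((-100.0, -30.0), (-67.0, -7.0)),
    "sheet": ((-180.0, -90.0), (90.0, 180.0)),
    "ppii": ((-90.0, -20.0), (50.0, 180.0)),
}


@dataclass
class Landscape2D:
    """Binned free-energy surface over (RMSD, Rg); kcal/mol."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # NaN = unoccupied bin
    counts: np.ndarray
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        x_mid = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        y_mid = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return pd.DataFrame(self.free_energy, index=x_mid, columns=y_mid)


@dataclass
class RamaDensity:
    """Normalised (phi, psi) histogram on a periodic square grid."""

    bin_width: float
    density: np.ndarray  # shape (n_bins, n_bins), phi rows, psi columns
    edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.density.shape[0]
        if self.density.shape != (n, n) or not np.isclose(n * self.bin_width, 360.0):
            raise ValueError("density grid must be square and span 360 degrees")
        self.edges = -180.0 + self.bin_width * np.arange(n + 1)

    def region_occupancy(
        self,
        regions: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    ) -> dict[str, float]:
        """Probability mass of each named region plus the remainder.

        Rectangles are applied in order sheet -> ppii -> helix so the PPII
        mask excludes its sheet overlap; a bin belongs to the first region
        that contains its centre.
        """
        regions = dict(regions or DEFAULT_REGIONS)
        n = self.density.shape[0]
        mids = self.edges[:-1] + self.bin_width / 2.0
        order = [r for r in ("sheet", "ppii", "helix") if r in regions]
        order += [r for r in regions if r not in order]
        out = {name: 0.0 for name in regions}
        out["other"] = 0.0
        for i in range(n):
            for j in range(n):
                phi, psi = mids[i], mids[j]
                for name in order:
                    (plo, phi_hi), (slo, shi) = regions[name]
                    if plo <= phi <= phi_hi and slo <= psi <= shi:
                        out[name] += self.density[i, j]
                        break
                else:
                    out["other"] += self.density[i, j]
        return out


def free_energy_landscape(
    rmsd_series: np.ndarray,
    rg_series: np.ndarray,
    bins: int | tuple[int, int] = 50,
    temperature: float = 298.15,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> Landscape2D:
    """Boltzmann-invert a 2-D (RMSD, Rg) histogram: F = -kT ln(P / P_max).

    The most occupied bin sits at F = 0; unoccupied bins are NaN.
    """
    x = np.asarray(rmsd_series, dtype=float)
    y = np.asarray(rg_series, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need equal-length, non-empty RMSD and Rg series")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = None
    if x_range is not None or y_range is not None:
        rng = (x_range or (x.min(), x.max()), y_range or (y.min(), y.max()))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=rng)
    p = counts / counts.sum()
    f = np.full_like(p, np.nan)
    occupied = p > 0
    f[occupied] = -KB_KCAL * temperature * np.log(p[occupied] / p.max())
    return Landscape2D(
        x_edges=x_edges, y_edges=y_edges, free_energy=f, counts=counts,
        temperature=temperature,
    )


def ramachandran_density(
    dihedrals: np.ndarray,
    residue_indices: Sequence[int] | None = None,
    bin_width: float = 10.0,
) -> RamaDensity:
    """Normalised (phi, psi) density from a DihedralSeries array.

    ``dihedrals``: shape (n_frames, n_residues, 2) in degrees with NaN for
    undefined angles; ``residue_indices`` optionally restricts to a subset
    (e.g. modification sites).  Angles are wrapped into (-180, 180].
    """
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError("bin width must divide 360")
    d = np.asarray(dihedrals, dtype=float)
    if d.ndim == 2:
        d = d[None, :, :]
    if residue_indices is not None:
        idx = list(residue_indices)
        if not idx:
            raise ValueError("empty residue subset")
        d = d[:, idx, :]
    pairs = d.reshape(-1, 2)
    pairs = pairs[~np.isnan(pairs).any(axis=1)]
    if pairs.size == 0:
        raise ValueError("no defined (phi, psi) pairs in the selection")
    # wrap into (-180, 180]
    wrapped = ((pairs + 180.0) % 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    n = int(round(360.0 / bin_width))
    # bin index: (-180, 180] maps to 0..n-1 with right-closed bins
    ij = np.ceil((wrapped + 180.0) / bin_width).astype(int) - 1
    ij = np.clip(ij, 0, n - 1)
    hist = np.zeros((n, n))
    np.add.at(hist, (ij[:, 0], ij[:, 1]), 1.0)
    return RamaDensity(bin_width=bin_width, density=hist / hist.sum())


def density_divergence(p: RamaDensity, q: RamaDensity) -> float:
    """Jensen-Shannon divergence (natural log) between two densities.

    0 iff the densities coincide; ln 2 for disjoint supports.
    """
    if p.density.shape != q.density.shape or p.bin_width != q.bin_width:
        raise ValueError("densities live on different grids")
    a = p.density.ravel()
    b = q.density.ravel()
    m = 0.5 * (a + b)

    def _kl(x: np.ndarray, y: np.ndarray) -> float:
        mask = x > 0
        return float(np.sum(x[mask] * np.log(x[mask] / y[mask])))

    return 0.5 * _kl(a, m) + 0.5 * _kl(b, m)


# ---------------------------------------------------------------------------
# Hydrogen bonds

#: Donor heavy atoms: backbone amide N plus side-chain O/N bearing an H.
#: Acceptors: any oxygen, including phosphate O1P/O2P/O3P (or OP1..OP3).
HBOND_DISTANCE = 3.5  # donor-acceptor heavy-atom cutoff, Angstrom
HBOND_ANGLE = 135.0  # minimum donor-H-acceptor angle, degrees

_H_COVALENT = 1.25  # H belongs to the nearest heavy atom within this radius


def _frame_hbonds(
    conf: Conformation, subset: set[ResidueKey] | None
) -> dict[ResidueKey, int]:
    donors = []  # (residue index, heavy coord, H coord)
    acceptors = []  # (residue index, coord)
    for ri, res in enumerate(conf.residues):
        heavies = [a for a in res.atoms if a.element != "H" and not a.name.startswith("H")]
        hydrogens = [a for a in res.atoms if a.element == "H" or a.name.startswith("H")]
        for a in heavies:
            if a.name.startswith("O"):
                acceptors.append((ri, a.coord))
            if not a.name.startswith(("N", "O")):
                continue
            for h in hydrogens:
                if np.linalg.norm(h.coord - a.coord) <= _H_COVALENT:
                    donors.append((ri, a.coord, h.coord))
    if not donors or not acceptors:
        raise ValueError("no identifiable donors or acceptors")
    counts: dict[ResidueKey, int] = {}
    keys = [r.key for r in conf.residues]
    for di, d_xyz, h_xyz in donors:
        for ai, a_xyz in acceptors:
            if ai == di:
                continue
            if np.linalg.norm(d_xyz - a_xyz) > HBOND_DISTANCE:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom < 1e-9:
                continue
            ang = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0)))
            if ang < HBOND_ANGLE:
                continue
            for ri in (di, ai):
                key = keys[ri]
                if subset is None or key in subset:
                    counts[key] = counts.get(key, 0) + 1
    return counts


def hbond_counts(
    ens: Ensemble, subset: Iterable[ResidueKey] | None = None
) -> pd.Series:
    """Mean number of hydrogen bonds each residue participates in per frame.

    Geometric criterion: donor-acceptor heavy-atom distance <= 3.5 A and
    donor-H-acceptor angle >= 135 degrees.  A bond is credited to both the
    donor and the acceptor residue.  ``subset`` restricts the report (and
    the credit) to given residues, e.g. the phosphosites.
    """
    subset_set = set(subset) if subset is not None else None
    keys = [r.key for r in ens.topology]
    if subset_set is not None:
        keys = [k for k in keys if k in subset_set]
    totals = {k: 0.0 for k in keys}
    for frame in ens:
        for key, n in _frame_hbonds(frame, subset_set).items():
            if key in totals:
                totals[key] += n
    return pd.Series(
        {str(k): v / ens.n_frames for k, v in totals.items()}, dtype=float
    )
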