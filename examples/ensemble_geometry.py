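"""Geometry and distributional analyses of a synthetic ensemble.

Samples a 60-frame ensemble of an 18-residue peptide that is helical in
the middle and coil at the ends, then computes per-frame Rg and
end-to-end distance, an RMSD-Rg free-energy landscape, Ramachandran
region occupancies, and mean hydrogen-bond counts.
"""

import numpy as np

from phosbench import (
    backbone_dihedrals,
    end_to_end,
    free_energy_landscape,
    hbond_counts,
    ramachandran_density,
    rg,
    rmsd_series,
    ss_fractions,
)
from phosbench.synthetic_data import GeneratorSpec, make_ensemble

spec = GeneratorSpec(
    sequence="A" * 18, ss_target="CCC" + "H" * 12 + "CCC", n_frames=60, seed=4
)
ens, _ = make_ensemble(spec)

rgs = np.array([rg(f) for f in ens])
e2e = np.array([end_to_end(f) for f in ens])
print(f"Rg  mean {rgs.mean():.2f} A   end-to-end mean {e2e.mean():.2f} A")

fr = ss_fractions(ens)
print(f"helix fraction, middle residues: {fr.iloc[6:12]['helix'].mean():.2f}")

scape = free_energy_landscape(rmsd_series(ens), rgs, bins=20)
print(f"free-energy range: 0 .. {np.nanmax(scape.free_energy):.2f} kcal/mol")

density = ramachandran_density(backbone_dihedrals(ens))
occ = density.region_occupancy()
print("Ramachandran occupancy:", {k: round(float(v), 2) for k, v in occ.items()})

counts = hbond_counts(ens)
print(f"mean H-bonds per residue (helix core): {counts.iloc[6:12].mean():.2f}")
print(
    "\nThe landscape zero is the most occupied (RMSD, Rg) bin; occupancies"
    "\nuse the default helix/sheet/PPII rectangles on a 10-degree grid."
)
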