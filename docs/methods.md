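# Methods

## Problem and scope

Molecular-dynamics force fields are trained mostly on folded proteins, yet
phosphorylation sites (phosphoserine SEP, phosphothreonine TPO,
phosphotyrosine PTR) sit predominantly in disordered regions.  Whether a
given force field samples realistic conformations for a phosphorylated
protein is therefore an empirical question, and the natural referee is NMR:
chemical shifts computed from a simulated ensemble can be compared with the
measured ones.  phosbench implements that referee as a reusable pipeline.
It does not run MD and does not predict chemical shifts; ensembles
(multi-model PDB) and predicted shift tables (SPARTA+-style or TSV) are
inputs.

## The force-field score

For candidate ensemble (force field) *f* and atom class
*i* ∈ {CA, CB, C, N, HA, HN}, let RMSD(f, i) be the root-mean-square
deviation between predicted and experimental shifts over all residues
paired on (chain, author number, class).  With
rmsd_norm(i) = min over candidates of RMSD(·, i),

    FFscore(f) = (1/N) Σ_i RMSD(f, i) / rmsd_norm(i)

over the N classes measured for *every* candidate.  Each ratio is ≥ 1, so
FFscore ≥ 1 and the candidate that dominates every class scores exactly 1.
The modification score is the same statistic computed after restricting the
pairing to the phosphorylated residues; it isolates local accuracy at the
modification site, which the global score dilutes.  Classes missing for any
candidate are excluded from N (pairwise-complete): a per-class minimum over
a partial column would bias the normaliser.  If a class minimum is 0 while
a competitor is nonzero the ratio is undefined and an error is raised; a
class where every candidate is exactly 0 contributes ratio 1.

Score pairs are summarised on a traffic-light scale: the general axis is
green below 1.2, yellow in [1.2, 1.3], red above 1.3; the modification axis
is green below 2, light-green in [2, 5], yellow in (5, 10], red above 10;
the overall category is the worse axis.  Boundary values fall to the
category whose closed edge they touch, as listed.

## Secondary structure

`secstruct` implements the classic Kabsch–Sander algorithm: the
electrostatic hydrogen-bond proxy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

with a bond called at E < −0.5 and a clamp at −9.9 for pathological
contacts (< 0.5 Å); n-turns (n = 3, 4, 5) from i → i+n bonds; H/G/I from
two consecutive turns; antiparallel and parallel bridges, extended to E
ladders, isolated bridges B; hydrogen-bonded turns T; bends S where the
CA(i−2)–CA(i)–CA(i+2) angle exceeds 70°.  Priority follows the classic
ordering (H over strands over G/I over T over S).  Three conventions are
mirrored from the reference DSSP lineage so assignments agree with it:
the amide hydrogen is always recomputed as N + (C_prev − O_prev)/|…| (the
assignment is a pure function of the heavy-atom backbone), each donor keeps
only its two lowest-energy acceptor candidates, and residue i+1 never
donates back to residue i (its H sits on that carbonyl).  Chain breaks
(C–N > 2.5 Å) interrupt all patterns.  No π-helix refinements from modern
DSSP versions are applied.

The coarse 3-class mapping used by the disorder statistic is, deliberately,
{H, G, I} → helix, {B, E, T, S} → sheet, blank → disordered.  Folding T and
S into "sheet" is unconventional, but it is the mapping this benchmark's
disorder fraction is defined on; a `conventional` mapping
({B, E} → sheet, rest disordered) is available, and the 8-letter string is
always retained for re-mapping.  Phospho residues are treated as their
parent amino acid (backbone-only algorithm).

## Geometry and distributional analyses

Superposition is weighted Kabsch via SVD with the reflection branch
corrected by the determinant sign.  RMSF superposes frames on the first
frame, forms the mean structure, re-superposes on that mean (one refinement
pass — deterministic, standard practice) and averages per-residue.  The
default fitting selection is backbone heavy atoms (N, CA, C, O),
configurable.  Rg is mass-weighted by default with a flag to disable (the
convention is not fixed by the problem; both are offered).  Dihedrals
follow the IUPAC sign convention, degrees in (−180, 180], undefined values
carried as NaN rather than errors.

Free-energy landscapes Boltzmann-invert a 2-D (RMSD, Rg) histogram:
F = −k_B T ln(P/P_max), T = 298.15 K by default, 50×50 bins spanning the
observed range; unoccupied bins are missing (NaN), not 0 or +∞, so TSV
exports stay honest.  Ramachandran densities use a 10° periodic grid with
right-closed bins; named-region occupancies use rectangular masks —
helix φ ∈ [−100, −30], ψ ∈ [−67, −7]; sheet φ ∈ [−180, −90],
ψ ∈ [90, 180]; PPII φ ∈ [−90, −20], ψ ∈ [50, 180] with the sheet overlap
resolved in favour of sheet — configurable, since region boundaries are a
convention.  Densities are compared by Jensen–Shannon divergence (natural
log, range [0, ln 2]).  Hydrogen bonds use the common geometric criterion:
donor–acceptor heavy-atom distance ≤ 3.5 Å and donor–H–acceptor angle
≥ 135°, both configurable; phosphate oxygens (O1P/O2P/O3P, OP1–OP3) are
acceptors; a bond is credited to both participating residues.

## Convergence

The convergence diagnostic cumulatively averages per-frame predicted
tables, converts to secondary shifts (observed minus random-coil), and
reports the RMSE against experimental secondary shifts pooled over all six
classes — one curve per force field.  Its final point equals, identically,
the pooled RMSD of the full-ensemble-average prediction, which the tests
assert to 1e−9.  The series is emitted at every frame; downsampling is a
plotting concern.

The built-in random-coil reference is a Wishart-style peptide table
(values in `shift_eval._RC_DATA`; Gly has no CB, Pro no N/HN), overridable
from a TSV.  SEP/TPO/PTR default to their parent residue's values.  The
reference only moves the zero of the Δδ scale; all RMSD-based scores use
raw shifts and are reference-free.

## PDB survey

Each structure (first model of multi-model entries) yields its disorder
fraction (disordered residues / all residues), its phosphosites with the
coarse class at each site, and a disordered-protein flag at fraction
> 0.5.  Chains are surveyed together within an entry; duplicate chains all
count (no deduplication rule is imposed).  Aggregation reports overall
residue-level class percentages, per-phospho-type site percentages, and
protein/site counts, all exact on a corpus by construction.

## Synthetic data: what it emulates and what it does not

`build_backbone` places N/CA/C/O (plus CB, amide H, and an idealised
pseudo-phosphate on SEP/TPO/PTR) by sequential NeRF construction with
standard peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, ω = 180°).  Measured dihedrals round-trip the inputs to well
under 0.5°.  Canonical state angles are H (−57, −47), E (−120, 120),
PPII (−75, 145), matching the Ramachandran region masks so generator truth
labels align with measured occupancies; the coil state draws uniformly
from φ ∈ (−160, −60), ψ ∈ (60, 180), a basin that forms no persistent
hydrogen-bond pattern.  Ensembles sample per-residue states with 5°
Gaussian dihedral jitter and optional Cartesian noise; strand pairs are
positioned by a deterministic grid search (in the strand's own frame) that
maximises Kabsch–Sander inter-strand bonds.  Shift experiments are built
as random-coil + state offsets (helix/sheet offsets of literature-typical
sign and magnitude, e.g. CA +2.6 ppm in helix), with per-force-field
Gaussian prediction error of controlled per-class sigma — so the expected
RMSD table is known and score recovery is checkable.  All randomness flows
from one integer seed.

What passing tests therefore show: the metrics recover planted truth on
geometrically ideal, noise-controlled inputs.  What they do not show:
side-chain packing, solvent effects, realistic shift-prediction error
correlations (SPARTA+ errors are not i.i.d. Gaussian across residues), or
PDB pathologies beyond altlocs and waters.  Real-data conclusions inherit
those caveats.

## Numerical choices and degenerate inputs

- Collinear atoms make a dihedral NaN (flagged, not an error); collinear
  reference coordinates make superposition an error.
- Duplicate shift records and non-numeric shifts are errors; atom classes
  outside the six are dropped with a logged count; glycine HA2/HA3 pairs
  average onto HA.
- Altloc "A" or blank kept, others dropped and counted; waters and
  non-phospho heteroatoms dropped.
- Ensemble frames must be topology-identical; the first differing residue
  is named in the error.
- TSVs serialise floats at 6 significant digits; reruns with the same
  config and seed are byte-identical.

## Problem sizes used in tests

Score-recovery checks use 500-residue synthetic proteins with 20
replicates; DSSP fidelity uses 20 generated fixtures (helices, single and
paired strands, coils) compared residue-by-residue against an independent
reference implementation; RMSF calibration uses 500 frames.  These sizes
make the statistical tolerances (7–10%) comfortably tight while the whole
suite stays fast.

## Known limitations

- Beta-bulge linkage between ladders is not implemented (classic ladders
  only); on bulged sheets E runs may fragment where reference DSSP merges
  them.
- The survey counts entries as files; biological-assembly or asymmetric
  unit distinctions are the user's responsibility.
- mmCIF input is not supported; convert to multi-model PDB first.
- Trajectory binary formats (DCD/XTC/NetCDF) are out of scope; export
  ensembles to multi-model PDB with your MD post-processing tool
  (e.g. cpptraj `trajout ensemble.pdb multi` or mdtraj's `save_pdb`).
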