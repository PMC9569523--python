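"""Survey of phosphorylation-site disorder propensity over a PDB corpus.

For each structure: fraction of residues assigned "disordered" by the
3-class secondary-structure mapping, the phosphosites present
(SEP/TPO/PTR) with the coarse class each one sits in, and a
disordered-protein flag (more than half the residues disordered).
Aggregation over a corpus yields the three panels of the survey: overall
secondary-structure composition, per-phospho-type site composition, and
protein/site counts.

For NMR-style multi-model entries only the first model is surveyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .secstruct import COARSE_CLASSES, assign_dssp
from .structure_io import Conformation, ResidueKey, detect_modifications, read_pdb_models

logger = logging.getLogger(__name__)

DISORDER_THRESHOLD = 0.5  # disordered protein when fraction > 0.5


@dataclass
class SurveyRecord:
    structure_id: str
    length: int
    disorder_fraction: float
    sites: list[tuple[ResidueKey, str, str]]  # (key, phospho type, coarse class)
    class_counts: dict[str, int]  # residues per coarse class

    @property
    def is_disordered_protein(self) -> bool:
        return self.disorder_fraction > DISORDER_THRESHOLD


def survey_structure(
    conf: Conformation, structure_id: str = "", coarse_mapping: str = "default"
) -> SurveyRecord:
    """Disorder fraction and per-site coarse classes for one structure."""
    if len(conf) == 0:
        raise ValueError("structure has no residues")
    assignment = assign_dssp(conf, coarse_mapping=coarse_mapping)
    coarse_by_key = dict(zip(assignment.keys, assignment.coarse))
    n_dis = sum(1 for c in assignment.coarse if c == "disordered")
    sites = sorted(
        (key, ptype, coarse_by_key[key])
        for key, ptype in detect_modifications(conf)
    )
    return SurveyRecord(
        structure_id=structure_id,
        length=len(conf),
        disorder_fraction=n_dis / len(conf),
        sites=list(sites),
        class_counts=assignment.coarse_counts(),
    )


def survey_directory(
    directory: str | Path, coarse_mapping: str = "default"
) -> list[SurveyRecord]:
    """Survey every ``*.pdb`` file in a directory (first model only)."""
    directory = Path(directory)
    records = []
    for path in sorted(directory.glob("*.pdb")):
        try:
            ens = read_pdb_models(path)
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        records.append(
            survey_structure(ens.frames[0], structure_id=path.stem, coarse_mapping=coarse_mapping)
        )
    if not records:
        raise ValueError(f"no readable PDB files in {directory}")
    return records


def aggregate(records: Sequence[SurveyRecord]) -> dict[str, pd.DataFrame]:
    """Corpus-level propensity tables.

    - ``overall``: residue-level percentage of each coarse class pooled over
      all structures (one row, sums to 100).
    - ``sites``: per phospho type, percentage of sites in each coarse class
      (rows sum to 100; empty if the corpus has no sites).
    - ``counts``: number of proteins containing each phospho type, number of
      sites, and number of disordered proteins.
    """
    if not records:
        raise ValueError("no survey records")
    total = sum(r.length for r in records)
    pooled = {c: sum(r.class_counts.get(c, 0) for r in records) for c in COARSE_CLASSES}
    overall = pd.DataFrame(
        {c: [100.0 * pooled[c] / total] for c in COARSE_CLASSES},
        index=["all_residues"],
    )

    site_rows: dict[str, dict[str, int]] = {}
    for r in records:
        for _, ptype, coarse in r.sites:
            site_rows.setdefault(ptype, {c: 0 for c in COARSE_CLASSES})
            site_rows[ptype][coarse] += 1
    if site_rows:
        sites = pd.DataFrame(site_rows).T.reindex(columns=list(COARSE_CLASSES)).fillna(0)
        sites = 100.0 * sites.div(sites.sum(axis=1), axis=0)
        sites = sites.sort_index()
    else:
        sites = pd.DataFrame(columns=list(COARSE_CLASSES))

    count_rows = {}
    for ptype in sorted({p for r in records for _, p, _ in r.sites}):
        n_proteins = sum(1 for r in records if any(p == ptype for _, p, _ in r.sites))
        n_sites = sum(sum(1 for _, p, _ in r.sites if p == ptype) for r in records)
        count_rows[ptype] = {"proteins": n_proteins, "sites": n_sites}
    counts = pd.DataFrame(count_rows).T if count_rows else pd.DataFrame(
        columns=["proteins", "sites"]
    )
    counts.loc["disordered_proteins"] = {
        "proteins": sum(1 for r in records if r.is_disordered_protein),
        "sites": sum(len(r.sites) for r in records if r.is_disordered_protein),
    }
    return {"overall": overall, "sites": sites, "counts": counts}
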