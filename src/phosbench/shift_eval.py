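"""Chemical-shift agreement metrics.

Secondary chemical shifts (observed minus random-coil), per-atom-class RMSD
between predicted and experimental tables, and the cumulative-average
convergence curve used to judge whether an ensemble's shift predictions have
equilibrated.

The built-in random-coil reference ships Wishart-style peptide values for
the 20 canonical residues; SEP/TPO/PTR default to their parent residue.  The
choice of reference only moves the zero of the secondary-shift scale — all
RMSD-based score comparisons use raw shifts and are reference-free.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    ATOM_CLASSES,
    PARENT_RESIDUE,
    ResidueKey,
    ShiftTable,
)

logger = logging.getLogger(__name__)

# Random-coil chemical shifts (ppm) per residue type and atom class,
# Wishart-style peptide reference values.  Gly has no CB; Pro has no HN
# (and its amide N is unusual enough that we leave it out too).
_RC_DATA: dict[str, dict[str, float]] = {
    "ALA": {"CA": 52.5, "CB": 19.1, "C": 177.8, "N": 123.8, "HA": 4.32, "HN": 8.24},
    "ARG": {"CA": 56.0, "CB": 30.9, "C": 176.3, "N": 120.5, "HA": 4.34, "HN": 8.23},
    "ASN": {"CA": 53.1, "CB": 38.9, "C": 175.2, "N": 118.7, "HA": 4.74, "HN": 8.40},
    "ASP": {"CA": 54.2, "CB": 41.1, "C": 176.3, "N": 120.4, "HA": 4.64, "HN": 8.34},
    "CYS": {"CA": 58.2, "CB": 28.0, "C": 174.6, "N": 118.8, "HA": 4.55, "HN": 8.32},
    "GLN": {"CA": 55.7, "CB": 29.4, "C": 176.0, "N": 119.8, "HA": 4.34, "HN": 8.32},
    "GLU": {"CA": 56.6, "CB": 29.9, "C": 176.6, "N": 120.2, "HA": 4.35, "HN": 8.42},
    "GLY": {"CA": 45.1, "C": 174.9, "N": 108.8, "HA": 3.96, "HN": 8.33},
    "HIS": {"CA": 55.0, "CB": 29.0, "C": 174.1, "N": 118.2, "HA": 4.73, "HN": 8.42},
    "ILE": {"CA": 61.1, "CB": 38.8, "C": 176.4, "N": 119.9, "HA": 4.17, "HN": 8.00},
    "LEU": {"CA": 55.1, "CB": 42.4, "C": 177.6, "N": 121.8, "HA": 4.32, "HN": 8.16},
    "LYS": {"CA": 56.2, "CB": 33.1, "C": 176.6, "N": 120.4, "HA": 4.32, "HN": 8.29},
    "MET": {"CA": 55.4, "CB": 32.9, "C": 176.3, "N": 119.6, "HA": 4.48, "HN": 8.28},
    "PHE": {"CA": 57.7, "CB": 39.6, "C": 175.8, "N": 120.3, "HA": 4.62, "HN": 8.30},
    "PRO": {"CA": 63.3, "CB": 32.1, "C": 177.3, "HA": 4.42},
    "SER": {"CA": 58.3, "CB": 63.8, "C": 174.6, "N": 115.7, "HA": 4.47, "HN": 8.31},
    "THR": {"CA": 61.8, "CB": 69.8, "C": 174.7, "N": 113.6, "HA": 4.35, "HN": 8.15},
    "TRP": {"CA": 57.5, "CB": 29.6, "C": 176.1, "N": 121.3, "HA": 4.66, "HN": 8.25},
    "TYR": {"CA": 57.9, "CB": 38.8, "C": 175.9, "N": 120.3, "HA": 4.55, "HN": 8.12},
    "VAL": {"CA": 62.2, "CB": 32.9, "C": 176.3, "N": 119.2, "HA": 4.12, "HN": 8.03},
}


class RandomCoilTable:
    """(residue 3-letter code, atom class) -> random-coil shift in ppm."""

    def __init__(self, values: dict[str, dict[str, float]] | None = None):
        data = {k: dict(v) for k, v in (values or _RC_DATA).items()}
        # phospho residues default to parent values
        for phospho, parent in PARENT_RESIDUE.items():
            data.setdefault(phospho, dict(data[parent]))
        self._values = data

    def get(self, resname: str, atom_class: str) -> float | None:
        return self._values.get(resname.upper(), {}).get(atom_class)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RandomCoilTable":
        """Load an override table: columns resname, atom_class, shift."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        values: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            d = row._asdict()
            values.setdefault(str(d["resname"]).upper(), {})[
                str(d["atom_class"]).upper()
            ] = float(d["shift"])
        return cls(values)


def secondary_shifts(obs: ShiftTable, rc: RandomCoilTable) -> ShiftTable:
    """Observed minus random-coil shift per record (Delta-delta).

    Records whose residue name is unknown, or whose (residue type, class)
    has no random-coil value, are dropped with a logged count.
    """
    out = ShiftTable(resnames=dict(obs.resnames))
    dropped = 0
    for key, cls, shift in obs:
        resname = obs.resnames.get(key)
        ref = rc.get(resname, cls) if resname else None
        if ref is None:
            dropped += 1
            continue
        out.add(key, cls, shift - ref)
    if dropped:
        logger.info("secondary_shifts: dropped %d unresolvable records", dropped)
    return out


def _paired_errors(
    pred: ShiftTable, exp: ShiftTable, subset: set[ResidueKey] | None
) -> dict[str, np.ndarray]:
    errors: dict[str, list[float]] = {}
    exp_records = exp.records()
    for (key, cls), p in pred.records().items():
        if subset is not None and key not in subset:
            continue
        e = exp_records.get((key, cls))
        if e is None:
            continue
        errors.setdefault(cls, []).append(p - e)
    return {cls: np.array(v) for cls, v in errors.items()}


def rmsd_by_class(
    pred: ShiftTable,
    exp: ShiftTable,
    subset: Iterable[ResidueKey] | None = None,
) -> pd.Series:
    """Shift RMSD per atom class over records paired on (residue, class).

    Classes with no paired record are NaN (missing, not zero).  ``subset``
    optionally restricts pairing to given residues (e.g. phosphosites).
    """
    subset_set = set(subset) if subset is not None else None
    errors = _paired_errors(pred, exp, subset_set)
    if not errors:
        raise ValueError("no paired records between predicted and experimental tables")
    out = pd.Series(np.nan, index=list(ATOM_CLASSES), dtype=float)
    for cls, errs in errors.items():
        out[cls] = float(np.sqrt(np.mean(errs**2)))
    return out


def build_rmsd_table(
    preds: dict[str, ShiftTable],
    exp: ShiftTable,
    subset: Iterable[ResidueKey] | None = None,
) -> pd.DataFrame:
    """RMSD-by-class rows for several force fields against one experiment."""
    subset_list = list(subset) if subset is not None else None
    rows = {
        label: rmsd_by_class(pred, exp, subset=subset_list)
        for label, pred in preds.items()
    }
    return pd.DataFrame(rows).T.reindex(columns=list(ATOM_CLASSES))


def average_shift_tables(tables: Sequence[ShiftTable]) -> ShiftTable:
    """Record-wise mean of topology-consistent shift tables."""
    if not tables:
        raise ValueError("no tables to average")
    keys0 = set(tables[0].records())
    for i, t in enumerate(tables[1:], start=2):
        if set(t.records()) != keys0:
            raise ValueError(f"table {i} has a different record set than table 1")
    out = ShiftTable(resnames=dict(tables[0].resnames))
    for key, cls in sorted(keys0, key=lambda kc: (kc[0], ATOM_CLASSES.index(kc[1]))):
        out.add(key, cls, float(np.mean([t.get(key, cls) for t in tables])))
    return out


def convergence_curve(
    per_frame_preds: Sequence[ShiftTable],
    exp_secondary: ShiftTable,
    rc: RandomCoilTable,
) -> pd.DataFrame:
    """Cumulative-average convergence of predicted secondary shifts.

    At frame t the predictions are averaged over frames 1..t, converted to
    secondary shifts against ``rc``, and the RMSE against the experimental
    secondary shifts is pooled over all six atom classes.  Returns a
    DataFrame with columns ``frame`` (1-based) and ``rmse``.
    """
    if len(per_frame_preds) < 2:
        raise ValueError("convergence needs at least two frames of predictions")
    keys0 = set(per_frame_preds[0].records())
    resnames = dict(per_frame_preds[0].resnames)
    for i, t in enumerate(per_frame_preds[1:], start=2):
        if set(t.records()) != keys0:
            raise ValueError(f"frame {i} has a different record set than frame 1")

    exp_records = exp_secondary.records()
    rmse = []
    running: dict[tuple[ResidueKey, str], float] = {k: 0.0 for k in keys0}
    for t, table in enumerate(per_frame_preds, start=1):
        recs = table.records()
        for k in keys0:
            running[k] += recs[k]
        sq, count = 0.0, 0
        for (key, cls), total in running.items():
            e = exp_records.get((key, cls))
            if e is None:
                continue
            resname = resnames.get(key)
            ref = rc.get(resname, cls) if resname else None
            if ref is None:
                continue
            delta_pred = total / t - ref
            sq += (delta_pred - e) ** 2
            count += 1
        if count == 0:
            raise ValueError("no records pair with the experimental table")
        rmse.append(np.sqrt(sq / count))
    return pd.DataFrame({"frame": np.arange(1, len(per_frame_preds) + 1), "rmse": rmse})
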