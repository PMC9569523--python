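"""Force-field scores from per-class chemical-shift RMSD tables.

The general score of a candidate (force field) is the mean, over atom
classes, of its shift RMSD divided by the lowest RMSD any candidate attains
in that class:

    score(ff) = (1/N) * sum_i  rmsd(ff, i) / min_ff' rmsd(ff', i)

Every ratio is >= 1, so scores are >= 1 and the candidate that dominates
every class scores exactly 1.  The modification score is the same statistic
computed on an RMSD table restricted to records at phosphorylated residues.
Classes missing for any candidate are excluded from N (pairwise-complete):
the per-class minimum is only meaningful when every candidate is measured.

Categories summarise a (general, modification) pair on a traffic-light
scale: the general axis turns at 1.2 and 1.3, the modification axis at 2, 5
and 10, and the overall category is the worse of the two axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("green", "light_green", "yellow", "red")

#: General-score axis: green < 1.2 <= yellow <= 1.3 < red.
GENERAL_THRESHOLDS = (1.2, 1.3)
#: Modification-score axis: green < 2 <= light_green <= 5 < yellow <= 10 < red.
MODIFICATION_THRESHOLDS = (2.0, 5.0, 10.0)


@dataclass
class ScoreCard:
    """Per force field: general score, modification score, category."""

    general: dict[str, float]
    modification: dict[str, float] = field(default_factory=dict)
    normalization: dict[str, float] = field(default_factory=dict)
    n_classes: int = 0

    @property
    def categories(self) -> dict[str, str]:
        return {
            ff: categorize(self.general[ff], self.modification.get(ff, 1.0))
            for ff in self.general
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ff in self.general:
            rows.append(
                {
                    "force_field": ff,
                    "general_score": self.general[ff],
                    "modification_score": self.modification.get(ff, np.nan),
                    "category": self.categories[ff],
                }
            )
        return pd.DataFrame(rows).set_index("force_field")


def _scores(table: pd.DataFrame) -> tuple[dict[str, float], dict[str, float], int]:
    if table.shape[0] < 2:
        raise ValueError("scoring needs at least two force fields")
    complete = table.columns[table.notna().all(axis=0)]
    skipped = [c for c in table.columns if c not in complete]
    if skipped:
        logger.info("classes excluded (missing for some force field): %s", skipped)
    if len(complete) == 0:
        raise ValueError("no atom class has values for all force fields")
    sub = table[complete]
    if (sub < 0).any().any():
        raise ValueError("RMSD cells must be non-negative")
    norms = sub.min(axis=0)
    ratios = pd.DataFrame(index=sub.index, columns=complete, dtype=float)
    for cls in complete:
        nrm = norms[cls]
        col = sub[cls]
        if nrm == 0.0:
            if (col == 0.0).all():
                ratios[cls] = 1.0  # all candidates perfect: ratio defined as 1
            else:
                raise ValueError(
                    f"class {cls}: zero minimum RMSD with a nonzero competitor "
                    "(undefined ratio)"
                )
        else:
            ratios[cls] = col / nrm
    scores = ratios.mean(axis=1)
    return dict(scores), dict(norms), len(complete)


def ffscore(table: pd.DataFrame) -> ScoreCard:
    """General force-field scores from an RMSD-by-class table.

    ``table``: rows = force-field labels, columns = atom classes, cells =
    shift RMSD in ppm (NaN = missing).  Returns a :class:`ScoreCard` with
    the per-class normalising minima and the number of classes scored.
    """
    scores, norms, n = _scores(table)
    return ScoreCard(general=scores, normalization=norms, n_classes=n)


def modification_ffscore(table_mod: pd.DataFrame) -> dict[str, float]:
    """Modification-site scores: same statistic on a site-restricted table."""
    scores, _, _ = _scores(table_mod)
    return scores


def score_ensembles(
    table: pd.DataFrame, table_mod: pd.DataFrame | None = None
) -> ScoreCard:
    """General + modification scores in one ScoreCard."""
    card = ffscore(table)
    if table_mod is not None:
        card.modification = modification_ffscore(table_mod)
    return card


def categorize(general: float, modification: float) -> str:
    """Traffic-light category for a (general, modification) score pair."""
    if general < 1.0 or modification < 1.0:
        raise ValueError("scores are >= 1 by construction")
    g_lo, g_hi = GENERAL_THRESHOLDS
    if general < g_lo:
        g_cat = "green"
    elif general <= g_hi:
        g_cat = "yellow"
    else:
        g_cat = "red"
    m_lo, m_mid, m_hi = MODIFICATION_THRESHOLDS
    if modification < m_lo:
        m_cat = "green"
    elif modification <= m_mid:
        m_cat = "light_green"
    elif modification <= m_hi:
        m_cat = "yellow"
    else:
        m_cat = "red"
    return max(g_cat, m_cat, key=CATEGORIES.index)
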