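"""BrdU/EdU fate-mapping demographics for thymidine-analog pulse-chase
experiments on IBA1+ microglia.

Cells labeled with BrdU (injected before microglial depletion) and/or EdU
(injected during repopulation) partition the labeled IBA1+ population into
three demographic classes: BrdU+EdU- (originally dividing, not repopulated),
BrdU+EdU+ (repopulated from originally dividing cells) and BrdU-EdU+
(repopulated from originally non-dividing cells).  Fractions are normalized
to the thymidine-analog-labeled IBA1+ cells; double-negative IBA1+ cells are
excluded from the demographic denominator but enter labeling efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Demographics",
    "DEMOGRAPHIC_CLASSES",
    "demographics",
    "labeling_efficiency",
    "group_summary",
]

DEMOGRAPHIC_CLASSES = ("BrdU+EdU-", "BrdU+EdU+", "BrdU-EdU+")


@dataclass
class Demographics:
    """Three-population fractions among labeled IBA1+ cells."""

    fractions: dict[str, float]  # class -> fraction (NaN when undefined)
    n_labeled: int  # denominator: BrdU or EdU positive IBA1+ cells
    n_iba1: int
    defined: bool

    @property
    def brdu_positive_fraction(self) -> float:
        """Combined fraction repopulating from originally dividing (BrdU+) cells."""
        return self.fractions["BrdU+EdU-"] + self.fractions["BrdU+EdU+"]

    @property
    def brdu_negative_fraction(self) -> float:
        return self.fractions["BrdU-EdU+"]


def _iba1_positive(cells: pd.DataFrame) -> pd.DataFrame:
    for col in ("iba1", "brdu", "edu"):
        if col not in cells.columns:
            raise ValueError(f"cell table missing column {col!r}")
    return cells[cells["iba1"].astype(bool)]


def demographics(cells: pd.DataFrame, include_unlabeled: bool = False) -> Demographics:
    """Three-population demographics of a labeled-cell table.

    The denominator is the number of IBA1+ cells positive for BrdU or EdU;
    with ``include_unlabeled`` every IBA1+ cell counts instead (sensitivity
    variant).  A zero denominator yields NaN fractions flagged as undefined.
    """
    iba1 = _iba1_positive(cells)
    brdu = iba1["brdu"].astype(bool)
    edu = iba1["edu"].astype(bool)
    counts = {
        "BrdU+EdU-": int((brdu & ~edu).sum()),
        "BrdU+EdU+": int((brdu & edu).sum()),
        "BrdU-EdU+": int((~brdu & edu).sum()),
    }
    n_labeled = sum(counts.values())
    denom = len(iba1) if include_unlabeled else n_labeled
    if denom == 0:
        fractions = {c: float("nan") for c in DEMOGRAPHIC_CLASSES}
        return Demographics(fractions, n_labeled, len(iba1), defined=False)
    fractions = {c: counts[c] / denom for c in DEMOGRAPHIC_CLASSES}
    return Demographics(fractions, n_labeled, len(iba1), defined=True)


def labeling_efficiency(cells: pd.DataFrame) -> float:
    """BrdU+IBA1+ cells as a fraction of all IBA1+ cells (NaN when no IBA1+)."""
    iba1 = _iba1_positive(cells)
    if len(iba1) == 0:
        return float("nan")
    return float(iba1["brdu"].astype(bool).sum() / len(iba1))


def group_summary(
    cells: pd.DataFrame,
    grouping: str = "group",
    section: str = "section_id",
    include_unlabeled: bool = False,
) -> pd.DataFrame:
    """Per-group demographics with section-level dispersion.

    Fractions are computed per section first, then averaged within each
    group (mean +/- s.e.m. across sections), which avoids pseudo-replication
    from pooling sections of unequal size.  Group-level pooled fractions are
    reported alongside.
    """
    if grouping not in cells.columns:
        raise ValueError(f"missing grouping column {grouping!r}")
    rows = []
    for group, group_cells in cells.groupby(grouping):
        pooled = demographics(group_cells, include_unlabeled)
        per_section = []
        if section in group_cells.columns:
            for _, sec_cells in group_cells.groupby(section):
                d = demographics(sec_cells, include_unlabeled)
                if d.defined:
                    per_section.append([d.fractions[c] for c in DEMOGRAPHIC_CLASSES])
        sec = np.array(per_section) if per_section else np.empty((0, 3))
        for i, cls in enumerate(DEMOGRAPHIC_CLASSES):
            rows.append(
                {
                    grouping: group,
                    "class": cls,
                    "fraction": pooled.fractions[cls],
                    "n_labeled": pooled.n_labeled,
                    "n_sections": len(sec),
                    "section_mean": sec[:, i].mean() if len(sec) else float("nan"),
                    "section_sem": (
                        sec[:, i].std(ddof=1) / np.sqrt(len(sec))
                        if len(sec) > 1
                        else 0.0 if len(sec) == 1 else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
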