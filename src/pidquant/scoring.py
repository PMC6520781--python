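"""Per-cell tallies and the four sample-level statistics.

* total PIDs score         — mean detected particles per cell,
* nuclear PIDs score       — mean particles inside the nucleus per cell,
* extranuclear PIDs score  — total minus nuclear (exact identity),
* ENR                      — extranuclear score / nuclear score.

ENR is a ratio of sample-level means, not a mean of per-cell ratios
(per-cell ratios blow up for cells with empty nuclei); it is undefined
(``None``) exactly when the nuclear score is zero.

Cells whose nucleus touches the field border have truncated extranuclear
territory and are excluded from scores by default (``border_flag``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imgio import LabelMask

__all__ = [
    "SampleScores",
    "cell_counts",
    "sample_scores",
    "aggregate_fields",
    "PAPER_CUTOFFS",
    "ScoringError",
]

#: Published cut-off preset used to dichotomize cohort score columns.
PAPER_CUTOFFS: dict[str, float] = {
    "er_allred": 6,
    "pr_allred": 6,
    "pr_hscore": 100,
    "er_hscore": 110,
    "total_score": 72.5,
    "extranuclear_score": 28,
    "nuclear_score": 48,
    "enr": 0.5,
    "ki67_li": 14,
}

#: Advisory sampling target: fields per sample and cells per sample.
DEFAULT_N_FIELDS = 5
DEFAULT_N_CELLS = 1000


class ScoringError(ValueError):
    pass


@dataclass
class SampleScores:
    n_cells: int
    total_score: float
    nuclear_score: float
    extranuclear_score: float
    enr: float | None

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "total_score": self.total_score,
            "nuclear_score": self.nuclear_score,
            "extranuclear_score": self.extranuclear_score,
            "enr": self.enr,
        }


def cell_counts(assignments: pd.DataFrame, nuclei: LabelMask) -> pd.DataFrame:
    """Tally nuclear/extranuclear spots per cell.

    Every label present in the mask gets a row (zero counts included);
    unassigned spots contribute to no row.  ``border_flag`` marks cells
    whose nucleus touches the field border.

    Returns a DataFrame with columns
    ``cell_id, n_nuclear, n_extranuclear, n_total, border_flag``.
    """
    ids = nuclei.label_ids
    out = pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "n_nuclear": 0,
            "n_extranuclear": 0,
        }
    )
    assigned = assignments[assignments["compartment"] != "unassigned"]
    if len(assigned):
        tallies = (
            assigned.groupby(["cell_id", "compartment"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for comp, col in (("nuclear", "n_nuclear"), ("extranuclear", "n_extranuclear")):
            if comp in tallies.columns:
                m = out["cell_id"].map(tallies[comp])
                out[col] = m.fillna(0).astype(int)
    out["n_total"] = out["n_nuclear"] + out["n_extranuclear"]
    border = set(int(b) for b in nuclei.border_labels())
    out["border_flag"] = out["cell_id"].isin(border)
    return out


def sample_scores(cells: pd.DataFrame, include_border: bool = False) -> SampleScores:
    """Roll per-cell counts up to the four sample-level statistics.

    Raises :class:`ScoringError` when no (non-border) cells remain.  When
    the nuclear score is zero but extranuclear particles exist, ENR is
    undefined: ``enr=None`` and a warning is emitted.
    """
    if len(cells) == 0:
        raise ScoringError("no cells to score")
    use = cells if include_border else cells[~cells["border_flag"]]
    if len(use) == 0:
        raise ScoringError("all cells touch the field border; nothing to score")
    nuclear = float(use["n_nuclear"].mean())
    extranuclear = float(use["n_extranuclear"].mean())
    total = nuclear + extranuclear
    if nuclear == 0:
        enr = None
        if extranuclear > 0:
            warnings.warn(
                "nuclear score is 0 with extranuclear particles present: "
                "ENR is undefined",
                stacklevel=2,
            )
    else:
        enr = extranuclear / nuclear
    return SampleScores(
        n_cells=int(len(use)),
        total_score=total,
        nuclear_score=nuclear,
        extranuclear_score=extranuclear,
        enr=enr,
    )


def aggregate_fields(
    cell_counts_per_field: Sequence[pd.DataFrame], include_border: bool = False
) -> SampleScores:
    """Pool per-cell counts across fields before averaging.

    This is cell-weighted pooling — identical to scoring the concatenated
    cell list — not a mean of per-field means, so fields with different
    cell numbers contribute proportionally.
    """
    if len(cell_counts_per_field) == 0:
        raise ScoringError("no fields to aggregate")
    pooled = pd.concat(cell_counts_per_field, ignore_index=True)
    return sample_scores(pooled, include_border=include_border)
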