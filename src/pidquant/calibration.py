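"""Calibration of the acceptance distance against whole-cell membrane truth.

A pathologist-style whole-cell mask defines the *true* extranuclear score of
a cell: spots inside the whole-cell label minus spots inside its nucleus.
Sweeping candidate distances through the nearest-neighbor pipeline and
correlating the estimated extranuclear score with this truth (squared
Pearson correlation across samples) selects the optimal distance; ties go
to the smaller, more conservative distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .assignment import assign_spots, distance_field
from .imgio import LabelMask
from .scoring import cell_counts, sample_scores
from .spot_detection import SpotSet, count_spots_in_mask

__all__ = [
    "CalibrationResult",
    "DistanceHistogram",
    "DEFAULT_CANDIDATE_D_UM",
    "pearson_r2",
    "true_extranuclear",
    "sweep_distance",
    "membrane_distance_histogram",
    "run_calibration_experiment",
]

DEFAULT_CANDIDATE_D_UM = (2.0, 4.0, 6.0, 8.0)
DEFAULT_HISTOGRAM_EDGES_UM = (1.0, 3.0, 5.0, 7.0, 9.0)


@dataclass
class CalibrationResult:
    candidate_d_um: tuple[float, ...]
    r2_per_d: dict[float, float]
    optimal_d_um: float
    n_units: int


@dataclass
class DistanceHistogram:
    bin_edges_um: np.ndarray
    counts: np.ndarray
    per_cell_um: pd.Series  # mean nucleus-to-membrane distance per cell


def pearson_r2(x, y) -> float:
    """Square of the sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r² is undefined for a constant input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def _check_containment(nuclei: LabelMask, cells: LabelMask) -> None:
    if cells.kind != "whole_cell":
        raise ValueError(f"expected a whole_cell mask, got kind={cells.kind!r}")
    if cells.shape != nuclei.shape:
        raise ValueError("nucleus and whole-cell masks differ in geometry")
    inside = nuclei.labels > 0
    if not np.array_equal(nuclei.labels[inside], cells.labels[inside]):
        bad = np.unique(nuclei.labels[inside & (nuclei.labels != cells.labels)])
        raise ValueError(
            f"nuclei {bad[:5].tolist()} are not contained in their same-numbered "
            "whole-cell labels"
        )


def true_extranuclear(
    spots: SpotSet,
    nuclei: LabelMask,
    cells: LabelMask,
    include_border: bool = False,
) -> pd.DataFrame:
    """Membrane-truth extranuclear count per cell.

    For each cell: spots whose centroid pixel lies in the whole-cell label
    minus spots in the same-numbered nucleus label.  Spots outside every
    whole-cell label are excluded.  Returns a DataFrame with columns
    ``cell_id, n_cell, n_nucleus, truth, border_flag``.
    """
    _check_containment(nuclei, cells)
    in_cell = count_spots_in_mask(spots, cells)
    in_nuc = count_spots_in_mask(spots, nuclei)
    # border convention matches scoring: a cell is a border cell iff its
    # *nucleus* touches the field edge, so truth and estimate drop the
    # same cells when compared
    border = set(int(b) for b in nuclei.border_labels())
    rows = []
    for cid in cells.label_ids:
        cid = int(cid)
        n_cell = in_cell.get(cid, 0)
        n_nuc = in_nuc.get(cid, 0)
        rows.append(
            {
                "cell_id": cid,
                "n_cell": n_cell,
                "n_nucleus": n_nuc,
                "truth": n_cell - n_nuc,
                "border_flag": cid in border,
            }
        )
    out = pd.DataFrame(rows)
    if not include_border:
        out = out[~out["border_flag"]].reset_index(drop=True)
    return out


def sweep_distance(
    samples: Sequence[tuple[SpotSet, LabelMask, LabelMask]],
    candidate_d_um: Sequence[float] = DEFAULT_CANDIDATE_D_UM,
    unit: str = "sample",
    include_border: bool = False,
) -> CalibrationResult:
    """Sweep candidate distances and select the one whose extranuclear
    estimate correlates best with the membrane truth.

    Parameters
    ----------
    samples
        Sequence of ``(spots, nuclei, cells)`` triples, one per sample
        (``unit="sample"``) or a single field whose cells are the
        correlation units (``unit="cell"``).
    candidate_d_um
        Distances to try; default ``(2, 4, 6, 8)`` μm.
    unit
        ``"sample"`` correlates per-sample mean scores across samples;
        ``"cell"`` correlates per-cell counts within the given fields.

    Returns
    -------
    CalibrationResult
        r² per candidate distance and the arg-max distance
        (ties broken toward the smaller distance).
    """
    if unit not in ("sample", "cell"):
        raise ValueError("unit must be 'sample' or 'cell'")
    candidate_d_um = tuple(float(d) for d in candidate_d_um)
    est: dict[float, list[float]] = {d: [] for d in candidate_d_um}
    truth_vals: list[float] = []
    for spots, nuclei, cells in samples:
        truth_df = true_extranuclear(spots, nuclei, cells, include_border=include_border)
        dfield = distance_field(nuclei)
        per_d_counts = {}
        for d in candidate_d_um:
            a = assign_spots(spots, nuclei, d_max_um=d, dfield=dfield)
            cc = cell_counts(a, nuclei)
            per_d_counts[d] = cc
        if unit == "sample":
            truth_vals.append(float(truth_df["truth"].mean()))
            for d in candidate_d_um:
                est[d].append(
                    sample_scores(per_d_counts[d], include_border=include_border).extranuclear_score
                )
        else:
            keep = truth_df.set_index("cell_id")["truth"]
            truth_vals.extend(keep.to_list())
            for d in candidate_d_um:
                cc = per_d_counts[d].set_index("cell_id")
                est[d].extend(cc.loc[keep.index, "n_extranuclear"].to_list())
    n_units = len(truth_vals)
    if n_units < 3:
        raise ValueError(f"need >= 3 correlation units, got {n_units}")
    r2 = {d: pearson_r2(est[d], truth_vals) for d in candidate_d_um}
    best = max(sorted(candidate_d_um), key=lambda d: (r2[d], -d))
    return CalibrationResult(
        candidate_d_um=candidate_d_um,
        r2_per_d=r2,
        optimal_d_um=float(best),
        n_units=n_units,
    )


def membrane_distance_histogram(
    nuclei: LabelMask,
    cells: LabelMask,
    bin_edges_um: Sequence[float] = DEFAULT_HISTOGRAM_EDGES_UM,
    include_border: bool = False,
) -> DistanceHistogram:
    """Histogram of per-cell nucleus-to-membrane distances.

    A cell's distance is the mean, over its membrane-boundary pixels (cell
    pixels with a 4-neighbor outside the cell or on the field edge), of the
    Euclidean distance to its nucleus.
    """
    _check_containment(nuclei, cells)
    dfield = distance_field(nuclei)
    lab = cells.labels
    # outer boundary: cell pixels whose 4-neighborhood leaves the label
    pad = np.pad(lab, 1, mode="constant", constant_values=-1)
    boundary = (
        (pad[:-2, 1:-1] != lab)
        | (pad[2:, 1:-1] != lab)
        | (pad[1:-1, :-2] != lab)
        | (pad[1:-1, 2:] != lab)
    ) & (lab > 0)
    border = set(int(b) for b in nuclei.border_labels())
    dists = {}
    for cid in cells.label_ids:
        cid = int(cid)
        if not include_border and cid in border:
            continue
        sel = boundary & (lab == cid)
        if not sel.any():
            raise ValueError(f"cell {cid} has no membrane boundary pixels")
        dists[cid] = float(dfield.dist_um[sel].mean())
    per_cell = pd.Series(dists, name="distance_um")
    counts, edges = np.histogram(per_cell.to_numpy(), bins=np.asarray(bin_edges_um, float))
    return DistanceHistogram(bin_edges_um=edges, counts=counts, per_cell_um=per_cell)


def run_calibration_experiment(
    seed: int = 0,
    n_samples: int = 30,
    n_cells: int = 200,
    expression_range: float = 10.0,
    base_nuclear_mean: float = 10.0,
    base_extranuclear_mean: float = 3.0,
    field_shape: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 0.25,
    candidate_d_um: Sequence[float] = DEFAULT_CANDIDATE_D_UM,
) -> CalibrationResult:
    """Full in-silico replica of the membrane-truth validation experiment.

    Simulates ``n_samples`` stained fields whose per-cell particle means
    span a geometric ``expression_range`` (samples representing a range of
    expression levels, as in the bench validation), runs single-particle
    detection on each rendered image, and sweeps the candidate distances
    against the whole-cell-mask truth with per-sample correlation units.

    Membranes sit ~4 μm beyond the nuclear boundary (generator default),
    so the sweep should select 4 μm and achieve a high r² there.
    """
    from .spot_detection import detect_spots
    from .synthetic_data import TissueSimParams, simulate_field

    rng = np.random.default_rng(seed)
    half = np.sqrt(expression_range)
    scales = np.geomspace(1 / half, half, n_samples)
    samples = []
    for s in scales:
        p = TissueSimParams(
            n_cells=n_cells,
            field_shape=field_shape,
            pixel_size_um=pixel_size_um,
            seed=int(rng.integers(2**31)),
            nuclear_counts=(base_nuclear_mean * s, 5.0),
            extranuclear_counts=(base_extranuclear_mean * s, 5.0),
        )
        img, nuclei, cells, _ = simulate_field(p)
        spots = detect_spots(img)
        samples.append((spots, nuclei, cells))
    return sweep_distance(samples, candidate_d_um=candidate_d_um, unit="sample")
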