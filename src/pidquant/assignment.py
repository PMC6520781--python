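"""The nearest-neighbor method: compartment assignment of detected spots.

Each spot is classified by the pixel containing its centroid:

* inside a nucleus label          -> ``nuclear`` for that nucleus,
* within ``d_max_um`` of a nucleus -> ``extranuclear`` for the nearest one,
* farther than ``d_max_um``        -> ``unassigned``.

Distance is the Euclidean distance to the nearest nucleus *pixel* (i.e. to
the nuclear boundary/area, not the centroid), measured in μm.  Ties between
equidistant nuclei are broken toward the smaller label id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import LabelMask

__all__ = ["DistanceField", "distance_field", "assign_spots", "DEFAULT_D_MAX_UM"]

#: Calibrated acceptance distance for extranuclear particles (μm).
DEFAULT_D_MAX_UM = 4.0

COMPARTMENTS = ("nuclear", "extranuclear", "unassigned")


@dataclass
class DistanceField:
    """Distance (μm) from each pixel to the nearest nucleus, plus that
    nucleus' label.  ``dist_um`` is exactly 0 on nucleus pixels, where
    ``nearest_label`` equals the pixel's own label."""

    dist_um: np.ndarray
    nearest_label: np.ndarray
    pixel_size_um: float


def distance_field(nuclei: LabelMask) -> DistanceField:
    """Exact Euclidean distance transform of the background, with arg-min labels.

    The distance grid comes from a single EDT of the background.  The
    nearest-nucleus label is resolved per label over a padded bounding box
    (pad = max background distance), processing labels in increasing order
    with strict improvement so equidistant ties go to the smaller label.
    """
    if nuclei.kind != "nucleus":
        raise ValueError(f"expected a nucleus mask, got kind={nuclei.kind!r}")
    labels = nuclei.labels
    if nuclei.n_objects == 0:
        raise ValueError("empty mask: no nuclei to measure distances from")

    bg = labels == 0
    dist_px = ndimage.distance_transform_edt(bg)
    pad = int(np.ceil(dist_px.max())) + 1

    best = np.where(bg, np.inf, 0.0)
    nearest = labels.copy()

    objects = ndimage.find_objects(labels)
    h, w = labels.shape
    for lab in nuclei.label_ids:
        sl = objects[lab - 1]
        if sl is None:  # pragma: no cover - find_objects gap
            continue
        ys = slice(max(0, sl[0].start - pad), min(h, sl[0].stop + pad))
        xs = slice(max(0, sl[1].start - pad), min(w, sl[1].stop + pad))
        crop = (ys, xs)
        d_k = ndimage.distance_transform_edt(labels[crop] != lab)
        best_c = best[crop]
        nearest_c = nearest[crop]
        improve = d_k < best_c - 1e-9
        best_c[improve] = d_k[improve]
        nearest_c[improve] = lab

    # every background pixel lies within `pad` of its arg-min nucleus' bbox,
    # so the per-label pass reproduces the global EDT exactly
    assert np.allclose(best, dist_px), "per-label distance pass disagrees with EDT"
    return DistanceField(
        dist_um=best * nuclei.pixel_size_um,
        nearest_label=nearest,
        pixel_size_um=nuclei.pixel_size_um,
    )


def assign_spots(
    spots,
    nuclei: LabelMask,
    d_max_um: float = DEFAULT_D_MAX_UM,
    dfield: DistanceField | None = None,
) -> pd.DataFrame:
    """Assign every spot to a compartment and (where applicable) a cell.

    Parameters
    ----------
    spots
        :class:`~pidquant.spot_detection.SpotSet` for the same field.
    nuclei
        Nucleus label mask sharing the field geometry.
    d_max_um
        Acceptance distance for extranuclear particles (default 4 μm).
    dfield
        Optional precomputed :func:`distance_field` (reused when sweeping
        several distances over the same mask).

    Returns
    -------
    pandas.DataFrame
        One row per spot: ``field_id, spot_idx, cell_id, compartment,
        distance_um``.  ``cell_id`` is ``pd.NA`` for unassigned spots.
    """
    if not (d_max_um > 0):
        raise ValueError("d_max_um must be > 0")
    if dfield is None:
        dfield = distance_field(nuclei)
    if dfield.dist_um.shape != nuclei.shape:
        raise ValueError("distance field does not match the mask geometry")

    h, w = nuclei.shape
    n = len(spots)
    if n == 0:
        return pd.DataFrame(
            {
                "field_id": pd.Series([], dtype=object),
                "spot_idx": pd.Series([], dtype=int),
                "cell_id": pd.Series([], dtype="Int64"),
                "compartment": pd.Series([], dtype=object),
                "distance_um": pd.Series([], dtype=float),
            }
        )
    ix = np.clip(np.rint(spots.x_px).astype(int), 0, w - 1)
    iy = np.clip(np.rint(spots.y_px).astype(int), 0, h - 1)

    own_label = nuclei.labels[iy, ix]
    dist = dfield.dist_um[iy, ix]
    near = dfield.nearest_label[iy, ix]

    cell_id = np.where(own_label > 0, own_label, np.where(dist <= d_max_um, near, 0))
    compartment = np.where(
        own_label > 0,
        "nuclear",
        np.where(dist <= d_max_um, "extranuclear", "unassigned"),
    )
    out = pd.DataFrame(
        {
            "field_id": spots.field_id,
            "spot_idx": np.arange(n),
            "cell_id": pd.array(cell_id, dtype="Int64"),
            "compartment": compartment,
            "distance_um": np.where(own_label > 0, 0.0, dist),
        }
    )
    out.loc[out["compartment"] == "unassigned", "cell_id"] = pd.NA
    return out
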