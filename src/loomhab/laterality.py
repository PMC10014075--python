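"""Hemispheric indices, binocularity classes, GABA calls and region summaries.

The hemispheric index (HI) measures lateralization of a cell population with
respect to the stimulated eye:

    HI = (n_ipsilateral - n_contralateral) / n_total

so -1 means exclusive presence in the hemisphere contralateral to the
stimulus and 0 a balanced split.  Variants cover monocular populations (per
selective eye) and binocular populations (referenced to the right eye).
GABAergic identity is called from the fraction of an ROI's pixels covered by
the binarized red (gad1b) channel, threshold 70%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

GABA_OVERLAP_THRESH = 0.7
MIDLINE_TOL_UM = 2.0


def assign_hemisphere(x_um, midline_x_um: float, tol_um: float = MIDLINE_TOL_UM) -> np.ndarray:
    """Hemisphere label from atlas x-coordinate relative to the midsagittal plane.

    Cells within ``tol_um`` of the midline are flagged ``ambiguous`` and are
    excluded from HI counts.
    """
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    out = np.where(x < midline_x_um - tol_um, "left",
                   np.where(x > midline_x_um + tol_um, "right", "ambiguous"))
    return out


def _counts(hemispheres: np.ndarray) -> tuple[int, int]:
    h = np.asarray(hemispheres)
    return int(np.sum(h == "left")), int(np.sum(h == "right"))


def hi_single_eye(cells: pd.DataFrame, stimulated_eye: str) -> float:
    """HI of a population under single-eye stimulation.

    ``cells`` needs a ``hemisphere`` column (left/right; ambiguous rows are
    dropped).  Ipsilateral means the hemisphere on the same side as the
    stimulated eye.  Empty populations are undefined (NaN, with a warning).
    """
    if stimulated_eye not in ("left", "right"):
        raise ValueError("stimulated_eye must be 'left' or 'right'")
    hemi = cells["hemisphere"].to_numpy()
    hemi = hemi[hemi != "ambiguous"]
    n_left, n_right = _counts(hemi)
    total = n_left + n_right
    if total == 0:
        warnings.warn("empty cell set: HI undefined")
        return float("nan")
    n_ipsi = n_left if stimulated_eye == "left" else n_right
    return (n_ipsi - (total - n_ipsi)) / total


def hi_monocular(cells: pd.DataFrame) -> dict:
    """Per-eye HI for monocular populations.

    ``cells`` needs ``hemisphere`` and ``eye`` (the eye the cell is selective
    to).  HI_R = (right-eye cells in the right hemisphere - in the left) /
    n right-eye cells, and symmetrically for HI_L; empty classes give NaN.
    """
    out = {}
    for eye in ("right", "left"):
        sub = cells[(cells["eye"] == eye) & (cells["hemisphere"] != "ambiguous")]
        n_left, n_right = _counts(sub["hemisphere"].to_numpy())
        total = n_left + n_right
        if total == 0:
            warnings.warn(f"no monocular cells selective to the {eye} eye")
            out[eye] = float("nan")
            continue
        same = n_right if eye == "right" else n_left
        out[eye] = (same - (total - same)) / total
    return out


def hi_binocular_right(cells: pd.DataFrame) -> float:
    """HI of a binocular population referenced to the right eye.

    (cells in the hemisphere ipsilateral to the right eye - contralateral) /
    total; the right hemisphere is ipsilateral to the right eye.
    """
    hemi = cells["hemisphere"].to_numpy()
    hemi = hemi[hemi != "ambiguous"]
    n_left, n_right = _counts(hemi)
    total = n_left + n_right
    if total == 0:
        warnings.warn("empty cell set: HI undefined")
        return float("nan")
    return (n_right - n_left) / total


def classify_binocularity(resp_left_eye, resp_right_eye) -> np.ndarray:
    """Binocularity class per cell from its per-eye responsiveness.

    ``resp_left_eye`` / ``resp_right_eye`` are boolean flags (the relevant
    stimulus-type bit under each eye's protocol).  Responsive to exactly one
    eye -> monocular_that_eye; both -> binocular; neither -> none.  A dataset
    with only one eye's protocol is an error: the single-eye HI path applies.
    """
    if resp_left_eye is None or resp_right_eye is None:
        raise ValueError("both eyes' protocols are required to classify binocularity")
    L = np.atleast_1d(np.asarray(resp_left_eye, dtype=bool))
    R = np.atleast_1d(np.asarray(resp_right_eye, dtype=bool))
    if L.shape != R.shape:
        raise ValueError("per-eye flags must have the same length")
    out = np.full(L.shape, "none", dtype=object)
    out[L & R] = "binocular"
    out[L & ~R] = "monocular_left"
    out[R & ~L] = "monocular_right"
    return out


@dataclass
class GabaCall:
    """GABAergic call for one ROI."""

    roi_id: int
    overlap_fraction: float
    is_gaba: bool


def gaba_assign(roi_label_mask: np.ndarray, red_image: np.ndarray,
                binarize: str | float = "otsu",
                overlap_thresh: float = GABA_OVERLAP_THRESH) -> pd.DataFrame:
    """Call GABAergic identity from red-channel coverage of each ROI.

    The red image is binarized (Otsu by default, or a fixed threshold) and
    overlaid on the label mask; a cell is GABAergic iff the red label covers
    strictly more than ``overlap_thresh`` (70%) of its ROI pixels.  The mask
    and image must share the pixel grid.
    """
    mask = np.asarray(roi_label_mask)
    red = np.asarray(red_image, dtype=float)
    if mask.shape != red.shape:
        raise ValueError("label mask and red image must share the pixel grid")
    if binarize == "otsu":
        thr = threshold_otsu(red)
    else:
        thr = float(binarize)
    binary = red > thr
    rows = []
    for roi_id in np.unique(mask):
        if roi_id == 0:
            continue
        sel = mask == roi_id
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"empty ROI {roi_id}")
        frac = float(binary[sel].sum()) / n
        rows.append({"roi_id": int(roi_id), "overlap_fraction": frac,
                     "is_gaba": frac > overlap_thresh})
    if not rows:
        raise ValueError("label mask contains no ROIs")
    return pd.DataFrame(rows)


def region_summary(cells: pd.DataFrame, label_col: str = "dyn_class",
                   min_cells: int = 10, min_fish: int = 3) -> pd.DataFrame:
    """Per-region class counts, filtered by representation.

    A region is kept only if it contains at least ``min_cells`` cells drawn
    from at least ``min_fish`` distinct fish.  Returns one row per retained
    region with total cells, fish count, and one count column per class
    label (e.g. dynamics class or GABA flag).
    """
    for col in ("region", "fish_id", label_col):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for region, sub in cells.groupby("region"):
        n_cells = len(sub)
        n_fish = sub["fish_id"].nunique()
        if n_cells < min_cells or n_fish < min_fish:
            continue
        row = {"region": region, "n_cells": n_cells, "n_fish": n_fish}
        for label, cnt in sub[label_col].value_counts().items():
            row[f"n_{label}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0) if rows else pd.DataFrame(
        columns=["region", "n_cells", "n_fish"])
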