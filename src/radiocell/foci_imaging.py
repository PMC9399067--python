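"""DNA double-strand-break foci counting from fluorescence z-stacks.

Reimplements the image-analysis macro used for 53BP1 scoring: z-stacks
are maximum-projected; nuclei are segmented from the nuclear stain
(global Otsu threshold, hole filling, minimum-size filter, watershed
splitting of touching nuclei on the distance transform); within each
nucleus the damage-marker mean and standard deviation set a per-nucleus
threshold (mean + k·SD), and thresholded connected components above a
minimum area are counted as foci.  Because the threshold is ROI-relative,
counts are invariant to affine rescaling of the damage channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "NucleusROI",
    "read_stack",
    "write_stack",
    "max_project",
    "segment_nuclei",
    "count_foci",
    "count_foci_image",
    "focus_timecourse",
]


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF into a (z, y, x) float array."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    return arr[None, ...] if arr.ndim == 2 else arr


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (z, y, x) array as a multi-page 32-bit TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


@dataclass(frozen=True)
class NucleusROI:
    """A segmented nucleus: label id, boolean mask (full image frame), area."""

    label: int
    mask: np.ndarray
    area_px: int

    def signal_stats(self, image: np.ndarray) -> tuple[float, float]:
        vals = image[self.mask]
        return float(vals.mean()), float(vals.std())


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the first (z) axis; 2-D input is returned
    unchanged."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("stack must be (z, y, x) with >= 1 plane")
    return arr.max(axis=0)


def segment_nuclei(
    nuclear_image: np.ndarray,
    min_area_px: int = 500,
    split_touching: bool = True,
    peak_min_distance_px: int = 15,
) -> list[NucleusROI]:
    """Segment nucleus-sized objects from the nuclear-stain channel.

    Global Otsu threshold, hole filling, minimum-area filter; touching
    nuclei are split by watershed on the distance transform with markers
    at its local maxima.  A blank/constant image yields an empty list with
    a warning.
    """
    img = np.asarray(nuclear_image, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("constant nuclear image: no nuclei found", stacklevel=2)
        return []
    binary = img > threshold_otsu(img)
    binary = ndi.binary_fill_holes(binary)
    lab = sk_label(binary)
    sizes = np.bincount(lab.ravel())
    binary = sizes[lab] >= min_area_px
    binary &= lab > 0
    if not binary.any():
        warnings.warn("no nucleus-sized objects found", stacklevel=2)
        return []

    if split_touching:
        distance = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(
            distance,
            labels=binary,
            min_distance=peak_min_distance_px,
            exclude_border=False,
        )
        markers = np.zeros_like(binary, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = sk_label(binary)

    rois = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        rois.append(
            NucleusROI(
                label=int(prop.label),
                mask=labels == prop.label,
                area_px=int(prop.area),
            )
        )
    return rois


def count_foci(
    roi: NucleusROI,
    damage_image: np.ndarray,
    k: float = 2.0,
    min_focus_area_px: int = 4,
) -> int:
    """Count damage foci inside one nucleus.

    Threshold = mean + k·SD of the damage signal within the ROI; connected
    components above threshold and at least ``min_focus_area_px`` large are
    counted.
    """
    if roi.area_px == 0:
        raise ValueError("empty ROI")
    img = np.asarray(damage_image, dtype=float)
    mean, sd = roi.signal_stats(img)
    if sd == 0:
        return 0
    above = (img > mean + k * sd) & roi.mask
    labels = sk_label(above)
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_focus_area_px))


def count_foci_image(
    nuclear_image: np.ndarray,
    damage_image: np.ndarray,
    k: float = 2.0,
    min_focus_area_px: int = 4,
    min_nucleus_area_px: int = 500,
) -> pd.DataFrame:
    """Segment nuclei and count foci per nucleus in one field of view."""
    rois = segment_nuclei(nuclear_image, min_area_px=min_nucleus_area_px)
    rows = [
        {
            "roi_id": roi.label,
            "area_px": roi.area_px,
            "foci_count": count_foci(
                roi, damage_image, k=k, min_focus_area_px=min_focus_area_px
            ),
        }
        for roi in rois
    ]
    return pd.DataFrame(rows, columns=["roi_id", "area_px", "foci_count"])


def focus_timecourse(
    per_nucleus: pd.DataFrame,
    untreated_label: str = "untreated",
) -> pd.DataFrame:
    """Per-condition/timepoint summary of foci counts.

    ``per_nucleus`` needs columns ``condition``, ``timepoint_h`` and
    ``foci_count``.  Returns mean, SEM (= SD/sqrt(n)) and n per group, plus
    fold change versus the untreated condition at the same timepoint when
    an untreated group is present.
    """
    required = {"condition", "timepoint_h", "foci_count"}
    if not required <= set(per_nucleus.columns):
        raise ValueError(f"per-nucleus table needs columns {sorted(required)}")
    g = per_nucleus.groupby(["condition", "timepoint_h"])["foci_count"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])

    if untreated_label in set(out["condition"]):
        ref = out[out["condition"] == untreated_label].set_index("timepoint_h")[
            "mean"
        ]
        out["fold_change_vs_untreated"] = [
            m / ref[tp] if tp in ref.index and ref[tp] > 0 else np.nan
            for m, tp in zip(out["mean"], out["timepoint_h"])
        ]
    return out
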