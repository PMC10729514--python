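"""Histology quantification: optical density, neuron counts, vacuolization.

All measures share one thresholding convention.  A cutoff is calibrated as
the mean intensity of a region of interest on the contralesional side of the
section; "optical density" is then the mean intensity of the pixels strictly
above that cutoff, reported together with the above-threshold pixel count.

Neurons (NeuN channel) are connected components above threshold, sized in
um^2 and stratified into putative interneurons (small, 23-115 um^2) and
putative motor neurons (large, 116-345 um^2).  Components overlapping a
damage/autofluorescence exclusion mask are flagged and never counted.
Vacuolization is scored on the myelin channel as enclosed holes (fill-holes
minus mask) inside myelin-positive tissue.

The damage detector here is a classical morphological reconstruction of the
trainable segmenter used interactively in the original workflow: damage is
taken to be regions simultaneously bright in at least two channels and much
larger than any soma.  An externally supplied exclusion mask can be used
instead wherever an ``exclusion`` argument is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .image_prep import Quadrant, flat_field, quadrant_of_point

logger = logging.getLogger(__name__)

# Size stratification bounds (um^2), contiguous on the continuous area scale.
SMALL_MIN_UM2 = 23.0
SMALL_MAX_UM2 = 116.0  # exclusive; also the inclusive lower edge of "large"
LARGE_MAX_UM2 = 345.0

SIZE_SMALL = "small"
SIZE_LARGE = "large"
SIZE_EXCLUDED = "excluded-by-size"

#: Default rostrocaudal count windows (um, inclusive bounds). Windows may
#: overlap; the perilesional window deliberately contains the other two.
DEFAULT_COUNT_WINDOWS: dict[str, tuple[float, float]] = {
    "caudal": (0.0, 2000.0),
    "rostral": (-2000.0, -500.0),
    "perilesional": (-2000.0, 2000.0),
}

#: Flat-field element used inside the damage detector. Deliberately larger
#: than the soma-scale element: a 25 px top-hat removes lesion-scale blobs
#: along with the illumination field, so damage must be isolated with an
#: element larger than the damage regions themselves.
DAMAGE_FLAT_FIELD_RADIUS_PX = 80


def classify_area(area_um2: float) -> str:
    """Size class of a detection: small [23, 116), large [116, 345], else excluded."""
    if SMALL_MIN_UM2 <= area_um2 < SMALL_MAX_UM2:
        return SIZE_SMALL
    if SMALL_MAX_UM2 <= area_um2 <= LARGE_MAX_UM2:
        return SIZE_LARGE
    return SIZE_EXCLUDED


@dataclass
class DensityResult:
    """Above-threshold staining intensity for one section side."""

    animal: str
    channel: str
    position_um: float
    side: str
    threshold: float
    mean_above: float  # NaN when no pixel exceeds the threshold
    n_above: int


@dataclass
class CellDetection:
    """One detected NeuN+ object."""

    centroid_px: tuple[float, float]
    n_pixels: int
    area_um2: float
    mean_intensity: float
    quadrant: Quadrant
    size_class: str
    excluded_by_damage: bool


@dataclass
class VacuoleResult:
    """Vacuolization score for one section side."""

    animal: str
    position_um: float
    side: str
    n_vacuoles: int
    area_fraction: float  # vacuole px / myelin-positive px on this side
    myelin_px: int
    vacuole_px: int


def contralesional_threshold(
    image: np.ndarray,
    roi_mask: np.ndarray,
    *,
    canal_col: float | None = None,
    side_of_lesion: str | None = None,
) -> float:
    """Cutoff threshold: the arithmetic mean intensity within the ROI.

    When ``canal_col`` and ``side_of_lesion`` are given, the ROI is verified
    to lie entirely on the contralesional half of the section.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("ROI mask shape mismatch")
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    if canal_col is not None and side_of_lesion is not None:
        cols = np.nonzero(roi_mask)[1]
        col0 = int(round(canal_col))
        if side_of_lesion == "right" and cols.max() >= col0:
            raise ValueError("ROI extends onto the ipsilateral (right) half")
        if side_of_lesion == "left" and cols.min() <= col0:
            raise ValueError("ROI extends onto the ipsilateral (left) half")
    return float(image[roi_mask].mean())


def mirrored_roi(
    shape: tuple[int, int],
    canal_px: tuple[float, float],
    side_of_lesion: str,
    *,
    half_size_px: int = 20,
    offset_px: tuple[int, int] = (0, 60),
) -> np.ndarray:
    """Default contralesional ROI: a square reflected across the canal line.

    Placed ``offset_px`` (rows, cols) away from the canal into the
    contralesional half; configurable because the original placement was a
    rater's choice.
    """
    row0, col0 = int(round(canal_px[0])), int(round(canal_px[1]))
    direction = -1 if side_of_lesion == "right" else 1
    cr = row0 + offset_px[0]
    cc = col0 + direction * abs(offset_px[1])
    mask = np.zeros(shape, dtype=bool)
    r_lo, r_hi = max(cr - half_size_px, 0), min(cr + half_size_px, shape[0])
    c_lo, c_hi = max(cc - half_size_px, 0), min(cc + half_size_px, shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        raise ValueError("mirrored ROI falls outside the image")
    mask[r_lo:r_hi, c_lo:c_hi] = True
    return mask


def optical_density(
    image: np.ndarray,
    region_mask: np.ndarray,
    threshold: float,
) -> tuple[float, int]:
    """Mean intensity and count of region pixels strictly above ``threshold``.

    Returns ``(nan, 0)`` when no pixel exceeds the cutoff.
    """
    image = np.asarray(image, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != image.shape:
        raise ValueError("region mask shape mismatch")
    if not region_mask.any():
        raise ValueError("region is empty")
    vals = image[region_mask]
    above = vals[vals > threshold]
    if above.size == 0:
        return float("nan"), 0
    return float(above.mean()), int(above.size)


def detect_damage(
    channels: dict[str, np.ndarray],
    pixel_size_um: float = 1.0,
    *,
    rel_threshold: float = 0.1,
    n_channels_required: int = 2,
    closing_radius_px: int = 5,
    min_area_um2: float = 4.0 * LARGE_MAX_UM2,
    flat_field_radius_px: int | None = DAMAGE_FLAT_FIELD_RADIUS_PX,
) -> np.ndarray:
    """Binary mask of overt tissue-damage / autofluorescence regions.

    A pixel is a damage candidate when it is bright (above ``rel_threshold``
    times the robust cross-channel maximum) in at least
    ``n_channels_required`` channels simultaneously — genuine stains light up
    a single channel, lesion autofluorescence bleeds into all of them.
    Candidates are closed morphologically and components smaller than
    ``min_area_um2`` (default 4x the largest neuron, so no soma can qualify)
    are dropped.

    ``flat_field_radius_px`` is the top-hat element applied to each channel
    first; it is larger than the quantification element because lesion-scale
    blobs must survive it.  Pass ``None`` for channels that are already
    illumination-corrected at a suitable scale.
    """
    if not channels:
        raise ValueError("no channels supplied")
    imgs = {}
    for ch, img in channels.items():
        img = np.asarray(img, dtype=float)
        if flat_field_radius_px is not None:
            img = flat_field(img, flat_field_radius_px)
        imgs[ch] = img
    shape = next(iter(imgs.values())).shape
    vmax = max(float(np.percentile(img, 99.9)) for img in imgs.values())
    if vmax <= 0:
        return np.zeros(shape, dtype=bool)
    thr = rel_threshold * vmax
    bright_count = np.zeros(shape, dtype=int)
    for img in imgs.values():
        bright_count += img > thr
    mask = bright_count >= n_channels_required
    if closing_radius_px > 0:
        mask = closing(mask, footprint=disk(closing_radius_px)).astype(bool)
    min_px = max(int(np.ceil(min_area_um2 / pixel_size_um**2)), 1)
    lbl = label(mask, connectivity=1)
    sizes = np.bincount(lbl.ravel())
    keep = np.zeros_like(sizes, dtype=bool)
    keep[1:] = sizes[1:] >= min_px
    return keep[lbl]


def detect_neurons(
    neun_image: np.ndarray,
    threshold: float,
    exclusion: np.ndarray | None,
    quadrants: np.ndarray,
    pixel_size_um: float,
    *,
    side_of_lesion: str | None = None,
    canal_px: tuple[float, float] | None = None,
) -> list[CellDetection]:
    """Detect NeuN+ somata as above-threshold connected components.

    Components are 4-connected pixel sets strictly above ``threshold``.  Each
    yields a centroid, an area in um^2 (pixel count x pixel_size_um^2), the
    quadrant under its centroid, and a size class; any overlap with the
    exclusion mask sets ``excluded_by_damage``.  Components outside the
    23-345 um^2 band are retained in the output but classed
    ``excluded-by-size`` (sub-23 um^2 objects are treated as debris).
    """
    neun_image = np.asarray(neun_image, dtype=float)
    mask = neun_image > threshold
    if exclusion is not None:
        exclusion = np.asarray(exclusion, dtype=bool)
        if exclusion.shape != mask.shape:
            raise ValueError("exclusion mask shape mismatch")
    lbl = label(mask, connectivity=1)
    detections: list[CellDetection] = []
    for region in regionprops(lbl, intensity_image=neun_image):
        area_um2 = region.area * pixel_size_um**2
        centroid = (float(region.centroid[0]), float(region.centroid[1]))
        if canal_px is not None and side_of_lesion is not None:
            quad = quadrant_of_point(centroid, canal_px, side_of_lesion)
        else:
            qr = min(max(int(round(centroid[0])), 0), quadrants.shape[0] - 1)
            qc = min(max(int(round(centroid[1])), 0), quadrants.shape[1] - 1)
            quad = Quadrant(int(quadrants[qr, qc]))
        excluded = False
        if exclusion is not None:
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            excluded = bool(exclusion[rr, cc].any())
        detections.append(
            CellDetection(
                centroid_px=centroid,
                n_pixels=int(region.area),
                area_um2=float(area_um2),
                mean_intensity=float(region.intensity_mean),
                quadrant=quad,
                size_class=classify_area(area_um2),
                excluded_by_damage=excluded,
            )
        )
    return detections


def detections_to_frame(
    detections: list[CellDetection],
    *,
    animal: str = "",
    section: int = 0,
    channel: str = "neun",
    position_um: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-detection table (one row per detected object)."""
    rows = [
        {
            "animal": animal,
            "section": section,
            "channel": channel,
            "position_um": position_um,
            "y": d.centroid_px[0],
            "x": d.centroid_px[1],
            "area_um2": d.area_um2,
            "mean_intensity": d.mean_intensity,
            "quadrant": d.quadrant.name.lower().replace("_", "-"),
            "size_class": d.size_class,
            "excluded": d.excluded_by_damage,
        }
        for d in detections
    ]
    columns = [
        "animal", "section", "channel", "position_um", "y", "x",
        "area_um2", "mean_intensity", "quadrant", "size_class", "excluded",
    ]
    return pd.DataFrame(rows, columns=columns)


_QUADRANT_NAMES = [q.name.lower().replace("_", "-") for q in Quadrant if q != Quadrant.OUTSIDE]


def neuron_count_table(
    detections: pd.DataFrame,
    windows: dict[str, tuple[float, float]] | None = None,
    *,
    animals: list[str] | None = None,
) -> pd.DataFrame:
    """Counts per animal x quadrant x size class x rostrocaudal window.

    Only countable detections enter the table: size class small or large and
    not excluded by damage.  Windows are inclusive position intervals and may
    overlap (the default perilesional window contains the other two).  The
    output is a dense tidy table: every combination appears, zero-filled.
    """
    if windows is None:
        windows = DEFAULT_COUNT_WINDOWS
    if animals is None:
        animals = sorted(detections["animal"].unique()) if len(detections) else []
    counted = detections[
        detections["size_class"].isin([SIZE_SMALL, SIZE_LARGE])
        & ~detections["excluded"].astype(bool)
    ] if len(detections) else detections
    rows = []
    for animal in animals:
        sub_a = counted[counted["animal"] == animal] if len(counted) else counted
        for win_name, (lo, hi) in windows.items():
            sub_w = (
                sub_a[(sub_a["position_um"] >= lo) & (sub_a["position_um"] <= hi)]
                if len(sub_a)
                else sub_a
            )
            for quad in _QUADRANT_NAMES:
                for size in (SIZE_SMALL, SIZE_LARGE):
                    n = (
                        int(((sub_w["quadrant"] == quad) & (sub_w["size_class"] == size)).sum())
                        if len(sub_w)
                        else 0
                    )
                    rows.append(
                        {
                            "animal": animal,
                            "window": win_name,
                            "quadrant": quad,
                            "size_class": size,
                            "count": n,
                        }
                    )
    return pd.DataFrame(rows, columns=["animal", "window", "quadrant", "size_class", "count"])


def vacuole_quant(
    myelin_image: np.ndarray,
    side_masks: dict[str, np.ndarray],
    *,
    threshold: float | None = None,
    min_area_px: int = 10,
    animal: str = "",
    position_um: float = 0.0,
) -> list[VacuoleResult]:
    """Count enclosed holes in myelin-positive tissue, per section side.

    Myelin-positive pixels are those above ``threshold``; when ``None`` the
    cutoff is half the median intensity — the median sits at the myelin
    tissue level (holes and lesion hyperintensity are minorities), so the
    rule is robust to damage regions and, being a fixed fraction of a
    quantile, invariant to uniform intensity scaling.  Vacuoles are the
    connected components of
    ``fill_holes(myelin) & ~myelin`` of at least ``min_area_px`` pixels; each
    is assigned to the side containing its centroid.  A side with no
    myelin-positive pixels yields no result (logged).
    """
    myelin_image = np.asarray(myelin_image, dtype=float)
    if threshold is None:
        med = float(np.median(myelin_image))
        if med <= 0:
            logger.warning("myelin channel median <= 0: no positive pixels, no vacuole result")
            return []
        threshold = 0.5 * med
    myelin = myelin_image > threshold
    holes = ndimage.binary_fill_holes(myelin) & ~myelin
    lbl = label(holes, connectivity=1)
    results = []
    for side, smask in side_masks.items():
        smask = np.asarray(smask, dtype=bool)
        myelin_px = int((myelin & smask).sum())
        if myelin_px == 0:
            logger.warning("no myelin-positive pixels on side %r of %s", side, animal or "?")
            continue
        n_vac = 0
        vac_px = 0
        for region in regionprops(lbl):
            if region.area < min_area_px:
                continue
            cr, cc = (int(round(c)) for c in region.centroid)
            if smask[cr, cc]:
                n_vac += 1
                vac_px += int(region.area)
        results.append(
            VacuoleResult(
                animal=animal,
                position_um=position_um,
                side=side,
                n_vacuoles=n_vac,
                area_fraction=vac_px / myelin_px,
                myelin_px=myelin_px,
                vacuole_px=vac_px,
            )
        )
    return results


def density_profile(
    results: pd.DataFrame,
    range_um: float = 10_000.0,
    bin_um: float = 140.0,
) -> pd.DataFrame:
    """Rostrocaudal profile of optical density, binned by position.

    ``results`` is a tidy table with columns ``side``, ``position_um`` and
    ``mean_above`` (one row per section x side, e.g. built from
    :class:`DensityResult` rows).  Sections within ``+/- range_um`` are
    assigned to bins of width ``bin_um`` centred on multiples of ``bin_um``
    (bin 0 is the epicenter); the profile reports mean, standard deviation
    and n per side x bin, pooling animals when present.
    """
    if range_um <= 0 or bin_um <= 0:
        raise ValueError("range_um and bin_um must be positive")
    if len(results) == 0:
        raise ValueError("no density results supplied")
    df = results.copy()
    df = df[np.abs(df["position_um"]) <= range_um]
    if len(df) == 0:
        raise ValueError(f"no sections within +/-{range_um} um")
    df["bin_um"] = (np.round(df["position_um"] / bin_um) * bin_um).astype(float)
    grouped = (
        df.groupby(["side", "bin_um"])["mean_above"]
        .agg(od_mean="mean", od_sd="std", n="count")
        .reset_index()
        .sort_values(["side", "bin_um"])
        .reset_index(drop=True)
    )
    return grouped
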