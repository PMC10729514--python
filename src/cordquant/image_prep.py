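"""Section-image preprocessing: flat-fielding, orientation, quadrants, positions.

Transverse spinal-cord sections are imaged as single-plane multi-channel
fluorescence micrographs.  Before quantification each section is

1. flat-fielded with a white top-hat transform (image minus its morphological
   opening) to remove slowly varying illumination artifacts,
2. rotated so the dorsal surface points up, using a user-supplied angle and
   the central-canal landmark identified by a blinded rater, and
3. partitioned into four quadrants (ipsi/contra x dorsal/ventral) by straight
   vertical and horizontal lines through the central canal.

Rostrocaudal position along the cord is assigned from the serial-sectioning
layout: sections cut at ``section_thickness_um`` and distributed over
``n_series`` staining series, so consecutive same-stain sections are
``thickness * n_series`` apart (140 um for the 20 um / 7-series default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, white_tophat

logger = logging.getLogger(__name__)

DEFAULT_STRUCTURING_RADIUS_PX = 25
DEFAULT_SECTION_THICKNESS_UM = 20.0
DEFAULT_N_SERIES = 7


class SectionExcludedError(RuntimeError):
    """Raised when a section cannot be oriented (e.g. missing canal landmark)."""


class Quadrant(IntEnum):
    """Quadrant labels; 0 is reserved for pixels outside the tissue mask."""

    OUTSIDE = 0
    IPSI_DORSAL = 1
    IPSI_VENTRAL = 2
    CONTRA_DORSAL = 3
    CONTRA_VENTRAL = 4


@dataclass
class SectionRecord:
    """One oriented multi-channel section with landmarks and position.

    Attributes
    ----------
    channels : dict[str, numpy.ndarray]
        Per-channel image grids (float), all the same shape, dorsal up.
    pixel_size_um : float
        Pixel edge length in micrometres.
    canal_px : tuple[float, float]
        Central-canal landmark as (row, col) in the oriented frame.
    rotation_deg : float
        Rotation that was applied to reach the oriented frame.
    side_of_lesion : str
        ``"left"`` or ``"right"``: which image half is ipsilesional.
    position_um : float
        Signed rostrocaudal offset from the lesion epicenter (rostral < 0).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    canal_px: tuple[float, float]
    rotation_deg: float
    side_of_lesion: str
    animal: str = ""
    series: str = ""
    slot: int = 1
    section_index: int = 0
    position_um: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def flat_field(
    image: np.ndarray,
    structuring_radius_px: int = DEFAULT_STRUCTURING_RADIUS_PX,
) -> np.ndarray:
    """White top-hat flat-field correction.

    Subtracts the morphological opening (erosion then dilation with a disk of
    ``structuring_radius_px``) from the image, removing any structure larger
    than the disk — in particular smooth illumination fields — while
    preserving compact bright objects such as stained somata.

    The output is pointwise non-negative and never exceeds the input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if np.any(image < 0):
        raise ValueError("flat_field expects a non-negative image")
    r = int(structuring_radius_px)
    if r < 1:
        raise ValueError(f"structuring radius must be >= 1, got {structuring_radius_px}")
    if 2 * r + 1 > min(image.shape):
        raise ValueError(
            f"structuring disk (diameter {2 * r + 1}) larger than image {image.shape}"
        )
    # 'crosses' is an exact decomposition of the disk (identical support and
    # result), but runs the separable passes far faster than the full kernel
    return white_tophat(image, footprint=disk(r, decomposition="crosses"))


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    """Rotation in (row, col) coordinates; positive = counterclockwise on screen."""
    t = np.deg2rad(angle_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def rotate_image(image: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate about the image center, preserving shape (constant 0 fill).

    ``order=0`` gives nearest-neighbour resampling (use for label masks).
    """
    image = np.asarray(image, dtype=float)
    # exact right angles on square grids: use the lossless grid rotation
    # (the general affine path drops border pixels to FP jitter)
    if angle_deg % 90.0 == 0.0:
        k = int(angle_deg // 90) % 4
        if k == 0:
            return image.copy()
        if k == 2 or image.shape[0] == image.shape[1]:
            return np.rot90(image, k).copy()
    center = (np.asarray(image.shape) - 1) / 2.0
    rinv = _rotation_matrix(-angle_deg)
    offset = center - rinv @ center
    return ndimage.affine_transform(
        image, rinv, offset=offset, order=order, mode="constant", cval=0.0
    )


def rotate_point(
    point: tuple[float, float], angle_deg: float, shape: tuple[int, int]
) -> tuple[float, float]:
    """Map a (row, col) point under the same rotation as :func:`rotate_image`."""
    center = (np.asarray(shape) - 1) / 2.0
    out = _rotation_matrix(angle_deg) @ (np.asarray(point, dtype=float) - center) + center
    return float(out[0]), float(out[1])


def orient_section(
    channels: dict[str, np.ndarray],
    canal_px: tuple[float, float] | None,
    rotation_deg: float,
    side_of_lesion: str,
    pixel_size_um: float = 1.0,
    *,
    animal: str = "",
    series: str = "",
    slot: int = 1,
    section_index: int = 0,
    position_um: float = 0.0,
    interp_order: int = 1,
) -> SectionRecord:
    """Rotate all channels to the dorsal-up frame and carry the canal along.

    The rotation angle and canal location come from a blinded human rater
    (there is no automatic landmark detection).  A section without a canal
    landmark cannot be partitioned and raises :class:`SectionExcludedError`.
    """
    if side_of_lesion not in ("left", "right"):
        raise ValueError(f"side_of_lesion must be 'left' or 'right', got {side_of_lesion!r}")
    if not channels:
        raise ValueError("no channels supplied")
    if canal_px is None:
        logger.warning("section %s/%s/%s excluded: missing canal landmark",
                       animal, series, section_index)
        raise SectionExcludedError("missing central-canal landmark")
    if abs(rotation_deg) > 180.0:
        raise ValueError(f"|rotation| must be <= 180 degrees, got {rotation_deg}")
    shapes = {ch: np.asarray(img).shape for ch, img in channels.items()}
    shape = next(iter(shapes.values()))
    if any(s != shape for s in shapes.values()):
        raise ValueError(f"channel shapes differ: {shapes}")
    r, c = canal_px
    if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
        raise ValueError(f"canal {canal_px} outside image of shape {shape}")

    if rotation_deg == 0.0:
        rotated = {ch: np.asarray(img, dtype=float).copy() for ch, img in channels.items()}
        new_canal = (float(r), float(c))
    else:
        rotated = {
            ch: rotate_image(img, rotation_deg, order=interp_order)
            for ch, img in channels.items()
        }
        new_canal = rotate_point(canal_px, rotation_deg, shape)

    return SectionRecord(
        channels=rotated,
        pixel_size_um=float(pixel_size_um),
        canal_px=new_canal,
        rotation_deg=float(rotation_deg),
        side_of_lesion=side_of_lesion,
        animal=animal,
        series=series,
        slot=slot,
        section_index=section_index,
        position_um=float(position_um),
    )


def quadrant_of_point(
    point: tuple[float, float],
    canal_px: tuple[float, float],
    side_of_lesion: str,
) -> Quadrant:
    """Quadrant of a single (row, col) point; ties go to dorsal/ipsilateral.

    Uses the same integer dividing lines as :func:`quadrant_masks`, so a
    detection centroid and the mask pixel under it always agree.
    """
    row0 = int(round(canal_px[0]))
    col0 = int(round(canal_px[1]))
    pr = int(round(point[0]))
    pc = int(round(point[1]))
    dorsal = pr <= row0
    if side_of_lesion == "right":
        ipsi = pc >= col0
    elif side_of_lesion == "left":
        ipsi = pc <= col0
    else:
        raise ValueError(f"side_of_lesion must be 'left' or 'right', got {side_of_lesion!r}")
    if ipsi:
        return Quadrant.IPSI_DORSAL if dorsal else Quadrant.IPSI_VENTRAL
    return Quadrant.CONTRA_DORSAL if dorsal else Quadrant.CONTRA_VENTRAL


def quadrant_masks(
    record: SectionRecord, tissue_mask: np.ndarray | None = None
) -> np.ndarray:
    """Label grid partitioning the tissue into the four canal-centred quadrants.

    The ipsi/contra split is the vertical line through the central canal and
    the dorsal/ventral split the horizontal line through it; pixels exactly on
    a dividing line are assigned to the dorsal and ipsilateral sides.  Pixels
    outside ``tissue_mask`` (whole image if ``None``) get ``Quadrant.OUTSIDE``.
    """
    shape = record.shape
    row0 = int(round(record.canal_px[0]))
    col0 = int(round(record.canal_px[1]))
    if row0 <= 0 or row0 >= shape[0] - 1 or col0 <= 0 or col0 >= shape[1] - 1:
        raise ValueError(f"canal {record.canal_px} on or outside the image border")
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    dorsal = rows <= row0
    if record.side_of_lesion == "right":
        ipsi = cols >= col0
    else:
        ipsi = cols <= col0
    labels = np.where(
        ipsi,
        np.where(dorsal, Quadrant.IPSI_DORSAL, Quadrant.IPSI_VENTRAL),
        np.where(dorsal, Quadrant.CONTRA_DORSAL, Quadrant.CONTRA_VENTRAL),
    ).astype(np.uint8)
    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if tissue_mask.shape != shape:
            raise ValueError("tissue mask shape mismatch")
        labels[~tissue_mask] = Quadrant.OUTSIDE
    return labels


def side_masks(record: SectionRecord) -> dict[str, np.ndarray]:
    """Boolean ipsi/contra half masks using the quadrant dividing line."""
    q = quadrant_masks(record)
    return {
        "ipsi": (q == Quadrant.IPSI_DORSAL) | (q == Quadrant.IPSI_VENTRAL),
        "contra": (q == Quadrant.CONTRA_DORSAL) | (q == Quadrant.CONTRA_VENTRAL),
    }


def assign_position(
    series_slot: int,
    section_index: int,
    epicenter_index: int,
    section_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM,
    n_series: int = DEFAULT_N_SERIES,
) -> float:
    """Signed rostrocaudal position (um) of a section within its stain series.

    Consecutive sections of the same series are ``section_thickness_um *
    n_series`` apart (140 um by default); the epicenter section is 0 and
    rostral positions are negative.
    """
    if not 1 <= series_slot <= n_series:
        raise ValueError(f"series_slot must be in [1, {n_series}], got {series_slot}")
    if section_thickness_um <= 0 or n_series < 1:
        raise ValueError("section_thickness_um must be > 0 and n_series >= 1")
    return (section_index - epicenter_index) * section_thickness_um * n_series


def suggest_epicenter(damage_areas: dict[int, float]) -> int:
    """Section index with the largest damage-mask area (epicenter heuristic).

    The epicenter is normally identified anatomically; this helper merely
    proposes the section whose detected damage area is maximal.
    """
    if not damage_areas:
        raise ValueError("no damage areas supplied")
    return max(sorted(damage_areas), key=lambda k: damage_areas[k])


# ---------------------------------------------------------------------------
# Landmark-file IO

LANDMARK_COLUMNS = ["animal", "series", "slot", "index", "canal_x", "canal_y", "rotation_deg"]


def read_landmarks(path: str | Path) -> pd.DataFrame:
    """Read a rater landmark table (canal_x = column, canal_y = row)."""
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark file {path} missing columns {sorted(missing)}")
    return df


def write_landmarks(df: pd.DataFrame, path: str | Path) -> None:
    df[LANDMARK_COLUMNS].to_csv(path, index=False)
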