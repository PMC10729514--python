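"""Synthetic fluorescence section images with exhaustive ground truth.

The generator emulates the features the quantification pipeline must cope
with — and nothing more: blob-like stained somata rendered as hard intensity
disks (so the true rasterized area is unambiguous), a smooth low-frequency
illumination field that a soma-scale top-hat should remove, bright diffuse
damage regions bleeding into every channel, and dark vacuole holes punched
into an otherwise bright myelin channel.  Additive Gaussian noise is
optional.  Every rendered structure is reported back as ground truth.

Scale conventions (configurable): 16-bit-like intensity range, 1 um/px.
Cells peak well above the illumination amplitude and damage regions are
brighter and at least 4x larger in radius than any soma, which keeps the
classical damage detector well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..image_prep import Quadrant, quadrant_of_point
from ..section_quant import classify_area

CHANNELS = ("iba1", "gfap", "neun", "myelin")


@dataclass(frozen=True)
class CellSpec:
    """One stained soma: a hard disk of added intensity in one channel."""

    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    peak_intensity: float
    channel: str = "neun"


@dataclass(frozen=True)
class DamageSpec:
    """A large diffuse bright patch rendered into all channels."""

    center_px: tuple[float, float]
    radius_px: float
    intensity: float


@dataclass(frozen=True)
class VacuoleSpec:
    """A disk-shaped zero-intensity hole in the myelin channel."""

    center_px: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic section.

    The illumination background is ``offset + amplitude * cos(...) * cos(...)``
    with spatial period ``background_scale_px`` and random phases; the scale
    defaults to >= 5x the flat-field structuring element so the top-hat is
    expected to remove it.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    background_offset: float = 2000.0
    background_amplitude: float = 400.0
    background_scale_px: float = 160.0
    cells: tuple[CellSpec, ...] = ()
    damage_regions: tuple[DamageSpec, ...] = ()
    vacuoles: tuple[VacuoleSpec, ...] = ()
    myelin_intensity: float = 8000.0
    noise_sd: float = 0.0
    seed: int = 0
    canal_px: tuple[float, float] | None = None  # defaults to image center
    side_of_lesion: str = "right"

    def canal(self) -> tuple[float, float]:
        if self.canal_px is not None:
            return self.canal_px
        return ((self.image_size_px[0] - 1) / 2.0, (self.image_size_px[1] - 1) / 2.0)

    def validate(self) -> None:
        h, w = self.image_size_px
        if h < 2 or w < 2:
            raise ValueError(f"image size too small: {self.image_size_px}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.background_amplitude < 0 or self.background_offset < 0:
            raise ValueError("background parameters must be non-negative")
        if self.background_scale_px <= 0:
            raise ValueError("background_scale_px must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.myelin_intensity < 0:
            raise ValueError("myelin_intensity must be >= 0")
        if self.side_of_lesion not in ("left", "right"):
            raise ValueError(f"bad side_of_lesion {self.side_of_lesion!r}")
        for c in self.cells:
            if c.radius_px <= 0:
                raise ValueError(f"cell radius must be > 0: {c}")
            if c.peak_intensity < 0:
                raise ValueError(f"cell intensity must be >= 0: {c}")
            if c.channel not in CHANNELS:
                raise ValueError(f"unknown channel {c.channel!r}")
            self._check_inside(c.center_px)
        for d in self.damage_regions:
            if d.radius_px <= 0 or d.intensity < 0:
                raise ValueError(f"bad damage region: {d}")
            self._check_inside(d.center_px)
        for v in self.vacuoles:
            if v.radius_px <= 0:
                raise ValueError(f"bad vacuole: {v}")
            self._check_inside(v.center_px)
        cr, cc = self.canal()
        if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
            raise ValueError(f"canal {self.canal()} outside image")

    def _check_inside(self, center: tuple[float, float]) -> None:
        h, w = self.image_size_px
        if not (0 <= center[0] <= h - 1 and 0 <= center[1] <= w - 1):
            raise ValueError(f"center {center} outside image of size {self.image_size_px}")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    channel: str
    centroid_px: tuple[float, float]  # centroid of the rasterized disk
    n_pixels: int
    area_um2: float
    quadrant: Quadrant
    size_class: str
    peak_intensity: float
    overlaps: bool  # shares pixels with another cell in the same channel


@dataclass
class GroundTruth:
    """Everything the generator knows about a section."""

    cells: list[CellTruth]
    damage_mask: np.ndarray  # bool
    vacuole_masks: list[np.ndarray]  # one bool mask per vacuole
    illumination: np.ndarray
    canal_px: tuple[float, float]
    side_of_lesion: str

    def count_table(self) -> dict[tuple[Quadrant, str], int]:
        """True countable-cell counts by (quadrant, size class).

        Mirrors the counting rules: only small/large cells count, and cells
        overlapping the damage mask are excluded.
        """
        out: dict[tuple[Quadrant, str], int] = {}
        for c in self.cells:
            if c.size_class not in ("small", "large"):
                continue
            cr, cc = (int(round(x)) for x in c.centroid_px)
            if self.damage_mask[cr, cc]:
                continue
            key = (c.quadrant, c.size_class)
            out[key] = out.get(key, 0) + 1
        return out


def disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Pixels whose centers lie within ``radius`` of ``center`` (inclusive)."""
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr * rr + cc * cc <= radius * radius


def _background(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size_px
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    field = np.cos(2 * np.pi * rows / spec.background_scale_px + phase_r) * np.cos(
        2 * np.pi * cols / spec.background_scale_px + phase_c
    )
    return spec.background_offset + spec.background_amplitude * field


def _damage_profile(
    shape: tuple[int, int], d: DamageSpec, taper_frac: float = 0.15
) -> np.ndarray:
    """Flat-topped disk with a cosine rim taper: diffuse but mostly full-intensity."""
    rr = np.arange(shape[0])[:, None] - d.center_px[0]
    cc = np.arange(shape[1])[None, :] - d.center_px[1]
    r = np.sqrt(rr * rr + cc * cc)
    w = taper_frac * d.radius_px
    core = d.radius_px - w
    out = np.zeros(shape)
    out[r <= core] = 1.0
    rim = (r > core) & (r <= d.radius_px)
    out[rim] = 0.5 * (1.0 + np.cos(np.pi * (r[rim] - core) / w))
    return d.intensity * out


def make_section(spec: SectionSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render a section: per-channel float images plus full ground truth.

    Deterministic for a fixed spec (including seed).  With no cells, no
    damage, zero myelin intensity and zero noise the images equal the
    illumination field exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size_px
    illumination = _background(spec, rng)
    channels = {ch: illumination.copy() for ch in CHANNELS}
    canal = spec.canal()

    # myelin base staining (before vacuole holes are punched)
    channels["myelin"] += spec.myelin_intensity

    # cells: hard disks, one channel each
    per_channel_counts = {ch: np.zeros(shape, dtype=np.int16) for ch in CHANNELS}
    cell_masks = []
    for cell in spec.cells:
        m = disk_mask(shape, cell.center_px, cell.radius_px)
        channels[cell.channel][m] += cell.peak_intensity
        per_channel_counts[cell.channel] += m
        cell_masks.append(m)

    # damage: diffuse bright patches in every channel
    damage_mask = np.zeros(shape, dtype=bool)
    for d in spec.damage_regions:
        profile = _damage_profile(shape, d)
        for ch in CHANNELS:
            channels[ch] += profile
        damage_mask |= disk_mask(shape, d.center_px, d.radius_px)

    # vacuoles: zero-intensity holes in the myelin channel
    vacuole_masks = []
    for v in spec.vacuoles:
        m = disk_mask(shape, v.center_px, v.radius_px)
        channels["myelin"][m] = 0.0
        vacuole_masks.append(m)

    if spec.noise_sd > 0:
        for ch in CHANNELS:
            channels[ch] = np.clip(
                channels[ch] + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None
            )

    cells_truth = []
    for cell, m in zip(spec.cells, cell_masks):
        coords = np.argwhere(m)
        n_px = int(coords.shape[0])
        centroid = tuple(coords.mean(axis=0)) if n_px else cell.center_px
        area = n_px * spec.pixel_size_um**2
        overlaps = bool((per_channel_counts[cell.channel][m] > 1).any()) if n_px else False
        cells_truth.append(
            CellTruth(
                channel=cell.channel,
                centroid_px=(float(centroid[0]), float(centroid[1])),
                n_pixels=n_px,
                area_um2=float(area),
                quadrant=quadrant_of_point(centroid, canal, spec.side_of_lesion),
                size_class=classify_area(area),
                peak_intensity=cell.peak_intensity,
                overlaps=overlaps,
            )
        )

    truth = GroundTruth(
        cells=cells_truth,
        damage_mask=damage_mask,
        vacuole_masks=vacuole_masks,
        illumination=illumination,
        canal_px=canal,
        side_of_lesion=spec.side_of_lesion,
    )
    return channels, truth


# Radii whose rasterized areas (at 1 um/px) sit safely inside the size bins:
# r=3..5 -> 29..81 px (small, 23-115); r=7..9 -> 149..253 px (large, 116-345).
SAFE_SMALL_RADII = (3.0, 4.0, 5.0)
SAFE_LARGE_RADII = (7.0, 8.0, 9.0)


def random_cells(
    n_small: int,
    n_large: int,
    *,
    shape: tuple[int, int] = (256, 256),
    channel: str = "neun",
    peak_intensity: float = 8000.0,
    rng: np.random.Generator | None = None,
    margin_px: float = 12.0,
    min_separation_px: float = 24.0,
    side: str | None = None,
    canal_col: float | None = None,
    avoid: list[tuple[tuple[float, float], float]] | None = None,
    max_tries: int = 20_000,
) -> list[CellSpec]:
    """Place non-overlapping cells at bin-safe radii by rejection sampling.

    ``side`` restricts placement to the left/right half relative to
    ``canal_col`` (a guard band keeps cells off the dividing line so their
    quadrant is unambiguous); ``avoid`` is a list of (center, radius) keep-out
    disks, e.g. planted damage regions.
    """
    rng = np.random.default_rng() if rng is None else rng
    radii = [float(rng.choice(SAFE_SMALL_RADII)) for _ in range(n_small)] + [
        float(rng.choice(SAFE_LARGE_RADII)) for _ in range(n_large)
    ]
    placed: list[CellSpec] = []
    h, w = shape
    col_lo, col_hi = margin_px, w - 1 - margin_px
    if side is not None:
        if canal_col is None:
            canal_col = (w - 1) / 2.0
        guard = min_separation_px / 2.0
        if side == "right":
            col_lo = max(col_lo, canal_col + guard)
        elif side == "left":
            col_hi = min(col_hi, canal_col - guard)
        else:
            raise ValueError(f"bad side {side!r}")
    for radius in radii:
        for _ in range(max_tries):
            r = rng.uniform(margin_px, h - 1 - margin_px)
            c = rng.uniform(col_lo, col_hi)
            ok = all(
                np.hypot(r - p.center_px[0], c - p.center_px[1]) >= min_separation_px
                for p in placed
            )
            if ok and avoid:
                ok = all(
                    np.hypot(r - ac[0], c - ac[1]) >= ar + radius + 4.0
                    for ac, ar in avoid
                )
            if ok:
                placed.append(
                    CellSpec(
                        center_px=(r, c),
                        radius_px=radius,
                        peak_intensity=peak_intensity,
                        channel=channel,
                    )
                )
                break
        else:
            raise RuntimeError("could not place all cells; relax density or size")
    return placed


def with_cells(spec: SectionSpec, cells: list[CellSpec]) -> SectionSpec:
    """Spec copy with ``cells`` appended."""
    return replace(spec, cells=tuple(spec.cells) + tuple(cells))
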