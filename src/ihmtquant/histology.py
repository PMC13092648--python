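"""Collagen quantification in Picrosirius-red histology images.

Under polarized light, Picrosirius-red-stained collagen is birefringent:
thick Type I fibers appear red/orange/yellow while thin Type III fibers
appear green, on a near-black background.  Classification therefore works in
HLS (hue-lightness-saturation) space: a lightness/saturation gate decides
which pixels are collagen at all, and fixed hue bands assign each collagen
pixel to a color class.  Per-class pixel fractions, normalised to total
collagen, give the Type I (red+orange+yellow) and Type III (green)
percentages.

Under brightfield illumination the same stain shows collagen as saturated
red, myocytes yellow and adipocytes as near-white aggregates; area fractions
of collagen and adipocytes are obtained by HSL box thresholding.

Hue is in degrees on the 0-360 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EmptyRegionError, NoCollagenError

__all__ = [
    "PixelClass",
    "HLSImage",
    "HueBandConfig",
    "CollagenFractions",
    "HSLBand",
    "BrightfieldBandConfig",
    "BrightfieldSegmentation",
    "rgb_to_hls",
    "hls_to_rgb",
    "classify_collagen_pixels",
    "collagen_type_fractions",
    "segment_brightfield",
]


class PixelClass(IntEnum):
    """Per-pixel classes of the polarized-light collagen classifier."""

    NON_COLLAGEN = 0
    RED = 1
    ORANGE = 2
    YELLOW = 3
    GREEN = 4
    OTHER = 5       # collagen by the gate, hue outside every band


#: Band classes in hue order of the default configuration.
BAND_CLASSES = (PixelClass.RED, PixelClass.ORANGE, PixelClass.YELLOW,
                PixelClass.GREEN)


@dataclass
class HLSImage:
    """Per-pixel hue (degrees, [0, 360)), lightness and saturation ([0, 1]).

    Achromatic pixels (saturation exactly 0) have no defined hue; it is
    reported as 0 and flagged via :attr:`achromatic`.
    """

    hue: np.ndarray
    lightness: np.ndarray
    saturation: np.ndarray

    @property
    def achromatic(self) -> np.ndarray:
        return self.saturation == 0


def rgb_to_hls(image: np.ndarray) -> HLSImage:
    """Standard RGB -> HLS transform of an 8-bit (or float [0,1]) RGB image.

    Follows the classic HLS hexcone formulas (identical to ``colorsys``),
    vectorised; hue is returned in degrees.
    """
    image = np.asarray(image)
    if image.ndim < 1 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image with 3 channels on the last axis")
    if np.issubdtype(image.dtype, np.integer):
        rgb = image.astype(float) / 255.0
    else:
        rgb = image.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.max(rgb, axis=-1)
    minc = np.min(rgb, axis=-1)
    light = (maxc + minc) / 2.0
    rangec = maxc - minc
    chromatic = rangec > 0

    sat = np.zeros_like(light)
    lo = chromatic & (light <= 0.5)
    hi = chromatic & (light > 0.5)
    sat[lo] = rangec[lo] / (maxc + minc)[lo]
    sat[hi] = rangec[hi] / (2.0 - maxc - minc)[hi]

    with np.errstate(divide="ignore", invalid="ignore"):
        rc = (maxc - r) / rangec
        gc = (maxc - g) / rangec
        bc = (maxc - b) / rangec
    h = np.zeros_like(light)
    is_r = chromatic & (r == maxc)
    is_g = chromatic & ~is_r & (g == maxc)
    is_b = chromatic & ~is_r & ~is_g
    h[is_r] = (bc - gc)[is_r]
    h[is_g] = 2.0 + (rc - bc)[is_g]
    h[is_b] = 4.0 + (gc - rc)[is_b]
    hue = ((h / 6.0) % 1.0) * 360.0
    hue[~chromatic] = 0.0
    return HLSImage(hue=hue, lightness=light, saturation=sat)


def hls_to_rgb(hue: np.ndarray, lightness: np.ndarray,
               saturation: np.ndarray) -> np.ndarray:
    """Inverse HLS -> RGB transform (hue in degrees); returns floats in [0,1]."""
    h = (np.asarray(hue, dtype=float) / 360.0) % 1.0
    l = np.asarray(lightness, dtype=float)
    s = np.asarray(saturation, dtype=float)
    m2 = np.where(l <= 0.5, l * (1.0 + s), l + s - l * s)
    m1 = 2.0 * l - m2

    def channel(hue_shifted):
        hh = hue_shifted % 1.0
        out = np.where(hh < 1.0 / 6.0, m1 + (m2 - m1) * hh * 6.0,
               np.where(hh < 0.5, m2,
               np.where(hh < 2.0 / 3.0, m1 + (m2 - m1) * (2.0 / 3.0 - hh) * 6.0,
                        m1)))
        return out

    r = channel(h + 1.0 / 3.0)
    g = channel(h)
    b = channel(h - 1.0 / 3.0)
    rgb = np.stack([r, g, b], axis=-1)
    return np.where((s == 0)[..., None], l[..., None], rgb)


def _intervals_disjoint(intervals: Sequence[tuple[float, float]]) -> bool:
    ordered = sorted(intervals)
    return all(a[1] <= b[0] for a, b in zip(ordered, ordered[1:]))


def _in_intervals(hue: np.ndarray, intervals) -> np.ndarray:
    out = np.zeros(hue.shape, dtype=bool)
    for lo, hi in intervals:
        out |= (hue >= lo) & (hue < hi)
    return out


@dataclass
class HueBandConfig:
    """Hue bands (degrees, half-open ``[lo, hi)``) and the collagen gate.

    The printed integer band limits share endpoints; adopting half-open
    intervals makes the bands a partition, with a boundary hue assigned to
    the higher band (hue 20 is orange, not red).  A pixel counts as collagen
    only if it passes the lightness window and minimum saturation —
    birefringent collagen is bright and colorful against the dark polarized
    background, and achromatic pixels are never collagen.
    """

    red: tuple[tuple[float, float], ...] = ((330.0, 360.0), (0.0, 20.0))
    orange: tuple[tuple[float, float], ...] = ((20.0, 39.0),)
    yellow: tuple[tuple[float, float], ...] = ((39.0, 62.0),)
    green: tuple[tuple[float, float], ...] = ((62.0, 129.0),)
    lightness_gate: tuple[float, float] = (0.08, 0.97)
    saturation_min: float = 0.10

    def __post_init__(self) -> None:
        allint = [iv for band in self.bands.values() for iv in band]
        for lo, hi in allint:
            if not (0 <= lo < hi <= 360):
                raise ConfigurationError(f"hue interval [{lo}, {hi}) out of range")
        if not _intervals_disjoint(allint):
            raise ConfigurationError("hue bands must be pairwise disjoint")
        if not 0 <= self.lightness_gate[0] < self.lightness_gate[1] <= 1:
            raise ConfigurationError("invalid lightness gate")

    @property
    def bands(self) -> dict[PixelClass, tuple[tuple[float, float], ...]]:
        return {PixelClass.RED: self.red, PixelClass.ORANGE: self.orange,
                PixelClass.YELLOW: self.yellow, PixelClass.GREEN: self.green}


def classify_collagen_pixels(hls: HLSImage,
                             roi_mask: np.ndarray | None = None,
                             config: HueBandConfig | None = None) -> np.ndarray:
    """Assign every pixel a :class:`PixelClass`.

    A pixel is collagen iff it lies in the ROI, is chromatic, passes the
    saturation minimum and falls inside the lightness window; collagen pixels
    are then binned by hue band, with :attr:`PixelClass.OTHER` for gated
    pixels whose hue lies outside every band.
    """
    config = config or HueBandConfig()
    if roi_mask is None:
        roi_mask = np.ones(hls.hue.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise EmptyRegionError("ROI mask selects no pixels")

    l_min, l_max = config.lightness_gate
    gate = (roi_mask
            & (hls.saturation >= config.saturation_min)
            & ~hls.achromatic
            & (hls.lightness >= l_min) & (hls.lightness <= l_max))

    classes = np.full(hls.hue.shape, int(PixelClass.NON_COLLAGEN), dtype=np.uint8)
    classes[gate] = int(PixelClass.OTHER)
    for cls, intervals in config.bands.items():
        classes[gate & _in_intervals(hls.hue, intervals)] = int(cls)
    return classes


@dataclass
class CollagenFractions:
    """Per-band collagen percentages, normalised to total collagen pixels.

    Type I aggregates red+orange+yellow; Type III is the green fraction;
    ``other_pct`` collects gated pixels outside every band, so the three
    aggregates always sum to 100.
    """

    n_collagen_px: int
    frac_red: float
    frac_orange: float
    frac_yellow: float
    frac_green: float
    type1_pct: float
    type3_pct: float
    other_pct: float

    def to_dict(self) -> dict:
        return {"n_collagen_px": self.n_collagen_px,
                "frac_red": self.frac_red, "frac_orange": self.frac_orange,
                "frac_yellow": self.frac_yellow, "frac_green": self.frac_green,
                "type1_pct": self.type1_pct, "type3_pct": self.type3_pct,
                "other_pct": self.other_pct}


def collagen_type_fractions(classes: np.ndarray,
                            roi_mask: np.ndarray | None = None) -> CollagenFractions:
    """Band percentages over collagen pixels from a classified image."""
    classes = np.asarray(classes)
    if roi_mask is not None:
        classes = classes[np.asarray(roi_mask, dtype=bool)]
    collagen = classes[classes != int(PixelClass.NON_COLLAGEN)]
    n = int(collagen.size)
    if n == 0:
        raise NoCollagenError("no collagen pixels; type fractions are undefined")
    counts = {cls: int(np.count_nonzero(collagen == int(cls)))
              for cls in (*BAND_CLASSES, PixelClass.OTHER)}
    pct = {cls: 100.0 * c / n for cls, c in counts.items()}
    # aggregate from pixel counts, not from the rounded per-band fractions,
    # so Type I is exact when the counts are
    n_type1 = (counts[PixelClass.RED] + counts[PixelClass.ORANGE]
               + counts[PixelClass.YELLOW])
    return CollagenFractions(
        n_collagen_px=n,
        frac_red=pct[PixelClass.RED], frac_orange=pct[PixelClass.ORANGE],
        frac_yellow=pct[PixelClass.YELLOW], frac_green=pct[PixelClass.GREEN],
        type1_pct=100.0 * n_type1 / n, type3_pct=pct[PixelClass.GREEN],
        other_pct=pct[PixelClass.OTHER])


# ---------------------------------------------------------------------------
# Brightfield segmentation


@dataclass(frozen=True)
class HSLBand:
    """A box in HSL space: hue intervals (or None = any hue) and closed
    saturation/lightness ranges."""

    hue: tuple[tuple[float, float], ...] | None
    saturation: tuple[float, float] = (0.0, 1.0)
    lightness: tuple[float, float] = (0.0, 1.0)

    def membership(self, hls: HLSImage) -> np.ndarray:
        ok = ((hls.saturation >= self.saturation[0])
              & (hls.saturation <= self.saturation[1])
              & (hls.lightness >= self.lightness[0])
              & (hls.lightness <= self.lightness[1]))
        if self.hue is not None:
            ok &= _in_intervals(hls.hue, self.hue) & ~hls.achromatic
        return ok

    def overlaps(self, other: "HSLBand") -> bool:
        def ranges_meet(a, b):
            return a[0] <= b[1] and b[0] <= a[1]
        if not ranges_meet(self.saturation, other.saturation):
            return False
        if not ranges_meet(self.lightness, other.lightness):
            return False
        if self.hue is None or other.hue is None:
            return True
        return any(a[0] < b[1] and b[0] < a[1]
                   for a in self.hue for b in other.hue)


@dataclass
class BrightfieldBandConfig:
    """HSL boxes for collagen and adipocytes in brightfield images.

    Defaults follow the stain's brightfield appearance: collagen as saturated
    red, adipocytes as bright, unsaturated (near-white) aggregates.  The
    alternative reading — collagen isolated as blue after filter inversion
    and adipocytes as dark pixels — is available via
    :meth:`inverted_thresholds`.
    """

    collagen: HSLBand = field(default_factory=lambda: HSLBand(
        hue=((330.0, 360.0), (0.0, 20.0)),
        saturation=(0.30, 1.0), lightness=(0.10, 0.80)))
    adipocyte: HSLBand = field(default_factory=lambda: HSLBand(
        hue=None, saturation=(0.0, 0.15), lightness=(0.85, 1.0)))

    def __post_init__(self) -> None:
        if self.collagen.overlaps(self.adipocyte):
            raise ConfigurationError(
                "collagen and adipocyte bands overlap; masks would not be disjoint")

    @classmethod
    def inverted_thresholds(cls) -> "BrightfieldBandConfig":
        return cls(collagen=HSLBand(hue=((200.0, 260.0),),
                                    saturation=(0.30, 1.0), lightness=(0.10, 0.90)),
                   adipocyte=HSLBand(hue=None, saturation=(0.0, 1.0),
                                     lightness=(0.0, 0.08)))


@dataclass
class BrightfieldSegmentation:
    """Disjoint collagen/adipocyte masks and their ROI-area percentages."""

    collagen_mask: np.ndarray
    adipocyte_mask: np.ndarray
    frac_total_collagen: float
    frac_adipocyte: float
    n_roi_px: int


def segment_brightfield(image: np.ndarray,
                        roi_mask: np.ndarray | None = None,
                        config: BrightfieldBandConfig | None = None
                        ) -> BrightfieldSegmentation:
    """Threshold collagen and adipocytes in a brightfield image.

    Fractions are areas relative to the ROI pixel count.  An ROI that
    contains no pixels of either class yields zero fractions with a warning.
    """
    import warnings

    config = config or BrightfieldBandConfig()
    hls = rgb_to_hls(image)
    if roi_mask is None:
        roi_mask = np.ones(hls.hue.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise EmptyRegionError("ROI mask selects no pixels")

    collagen = config.collagen.membership(hls) & roi_mask
    adipocyte = config.adipocyte.membership(hls) & roi_mask
    n_roi = int(roi_mask.sum())
    frac_col = 100.0 * collagen.sum() / n_roi
    frac_adp = 100.0 * adipocyte.sum() / n_roi
    if frac_col == 0.0 and frac_adp == 0.0:
        warnings.warn("ROI contains no collagen or adipocyte pixels", stacklevel=2)
    return BrightfieldSegmentation(collagen_mask=collagen, adipocyte_mask=adipocyte,
                                   frac_total_collagen=float(frac_col),
                                   frac_adipocyte=float(frac_adp), n_roi_px=n_roi)
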