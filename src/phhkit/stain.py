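"""Perls Prussian-blue "blue/pink" stain quantification.

A Perls-stained section contains three color populations: Prussian-blue
pigment (ferric iron), eosin-pink counterstained tissue, and background
(slide glass, white matter voids).  Pixels are classified with one
axis-aligned box per stain class in RGB space — an inclusive (low, high)
interval per channel — and iron deposition is summarized as the fraction

    ratio = blue / (blue + pink)

i.e. iron-positive area over recognized tissue area.  Background pixels never
enter the ratio.  A pixel that falls inside both boxes is assigned BLUE: the
assay's analyte is iron, so the iron class takes precedence.

The threshold values themselves are an empirical choice per staining batch.
:data:`DEFAULT_THRESHOLDS` ships a documented stand-in suitable for the
synthetic image generator; real batches should calibrate against annotated
patches (:func:`calibrate_thresholds`) and record the set used alongside
every ratio (:class:`StainRatioResult` carries it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    CalibrationError,
    ConfigurationError,
    DimensionError,
    FormatError,
    UndefinedRatioError,
)

# class codes used in class maps (uint8)
OTHER = 0
PINK = 1
BLUE = 2
MASKED = 255

Interval = tuple[int, int]
Box = tuple[Interval, Interval, Interval]

_CHANNELS = ("R", "G", "B")


def _validate_box(box: Box, what: str) -> None:
    if len(box) != 3:
        raise ConfigurationError(f"{what} must have one (low, high) interval per RGB channel")
    for ch, (lo, hi) in zip(_CHANNELS, box):
        if not (0 <= lo <= 255 and 0 <= hi <= 255):
            raise ConfigurationError(f"{what} {ch} bounds ({lo}, {hi}) outside [0, 255]")
        if lo > hi:
            raise ConfigurationError(f"{what} {ch} interval has low {lo} > high {hi}")


@dataclass(frozen=True)
class RGBThresholdSet:
    """Axis-aligned RGB boxes defining the blue and pink stain classes.

    Bounds are inclusive on both ends, in 8-bit units.  ``provenance`` records
    whether the set is the shipped default or was calibrated from patches.
    """

    blue_box: Box
    pink_box: Box
    name: str = "unnamed"
    provenance: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "blue_box", tuple((int(a), int(b)) for a, b in self.blue_box))
        object.__setattr__(self, "pink_box", tuple((int(a), int(b)) for a, b in self.pink_box))
        _validate_box(self.blue_box, "blue_box")
        _validate_box(self.pink_box, "pink_box")
        if self.provenance not in ("default", "calibrated"):
            raise ConfigurationError(f"provenance must be 'default' or 'calibrated', got {self.provenance!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "provenance": self.provenance,
            "blue_box": {ch: list(iv) for ch, iv in zip(_CHANNELS, self.blue_box)},
            "pink_box": {ch: list(iv) for ch, iv in zip(_CHANNELS, self.pink_box)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RGBThresholdSet":
        try:
            blue = tuple(tuple(d["blue_box"][ch]) for ch in _CHANNELS)
            pink = tuple(tuple(d["pink_box"][ch]) for ch in _CHANNELS)
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed threshold-set mapping: {exc}") from exc
        return cls(blue_box=blue, pink_box=pink,
                   name=d.get("name", "unnamed"), provenance=d.get("provenance", "default"))


#: Shipped stand-in threshold set.  The blue box keeps red low and blue high
#: (Prussian-blue pigment); the pink box keeps red high with moderate green
#: and blue (eosin).  Near-white background falls outside both boxes.  These
#: values were chosen for the synthetic color model, not fitted to any real
#: staining batch — calibrate per batch for real slides.
DEFAULT_THRESHOLDS = RGBThresholdSet(
    blue_box=((0, 140), (0, 160), (110, 255)),
    pink_box=((170, 255), (90, 200), (120, 220)),
    name="synthetic-default",
    provenance="default",
)


@dataclass(frozen=True)
class PixelClassCounts:
    """Pixel tallies for one classified image (masked pixels excluded)."""

    blue: int
    pink: int
    other: int

    def __post_init__(self) -> None:
        for name in ("blue", "pink", "other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count is negative")

    @property
    def total(self) -> int:
        return self.blue + self.pink + self.other


@dataclass(frozen=True)
class StainRatioResult:
    """Iron-deposition ratio for one image, with full provenance."""

    counts: PixelClassCounts
    ratio: float
    image_id: str
    thresholds_used: RGBThresholdSet = field(repr=False, default=DEFAULT_THRESHOLDS)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an RGB image of shape (H, W, 3), got shape {image.shape}")
    if image.dtype != np.uint8:
        raise FormatError(
            f"expected 8-bit/channel image (uint8), got {image.dtype}; "
            "convert or rescale before classification"
        )
    return image


def _in_box(image: np.ndarray, box: Box) -> np.ndarray:
    inside = np.ones(image.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate(box):
        ch = image[:, :, c]
        inside &= (ch >= lo) & (ch <= hi)
    return inside


def classify_pixels(
    image: np.ndarray,
    thresholds: RGBThresholdSet = DEFAULT_THRESHOLDS,
    tissue_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, PixelClassCounts]:
    """Classify every pixel as BLUE, PINK or OTHER.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 RGB raster.
    thresholds
        The stain class boxes.  BLUE takes precedence where boxes overlap.
    tissue_mask
        Optional ``(H, W)`` boolean raster; ``False`` pixels are excluded from
        the counts and coded :data:`MASKED` in the class map.

    Returns
    -------
    (class_map, counts)
        ``class_map`` is ``(H, W)`` uint8 with codes OTHER=0, PINK=1, BLUE=2,
        MASKED=255; ``counts`` tallies the unmasked pixels.
    """
    image = _check_image(image)
    class_map = np.zeros(image.shape[:2], dtype=np.uint8)
    class_map[_in_box(image, thresholds.pink_box)] = PINK
    class_map[_in_box(image, thresholds.blue_box)] = BLUE  # precedence: iron wins
    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if tissue_mask.shape != image.shape[:2]:
            raise DimensionError(
                f"tissue mask shape {tissue_mask.shape} does not match image {image.shape[:2]}"
            )
        class_map[~tissue_mask] = MASKED
    counts = PixelClassCounts(
        blue=int(np.count_nonzero(class_map == BLUE)),
        pink=int(np.count_nonzero(class_map == PINK)),
        other=int(np.count_nonzero(class_map == OTHER)),
    )
    return class_map, counts


def blue_pink_ratio(
    counts: PixelClassCounts,
    image_id: str = "",
    thresholds_used: RGBThresholdSet = DEFAULT_THRESHOLDS,
) -> StainRatioResult:
    """Iron-deposition ratio blue / (blue + pink) for one image.

    Background/OTHER pixels never enter numerator or denominator.  An image
    with no blue and no pink pixels has no recognized tissue and raises
    :class:`UndefinedRatioError` rather than returning a silent 0.
    """
    denom = counts.blue + counts.pink
    if denom == 0:
        raise UndefinedRatioError(
            f"image {image_id or '<unnamed>'}: no blue or pink pixels recognized; "
            "ratio undefined (check thresholds or tissue mask)"
        )
    return StainRatioResult(
        counts=counts,
        ratio=counts.blue / denom,
        image_id=image_id,
        thresholds_used=thresholds_used,
    )


def quantify_image(
    image: np.ndarray,
    thresholds: RGBThresholdSet = DEFAULT_THRESHOLDS,
    tissue_mask: np.ndarray | None = None,
    image_id: str = "",
) -> tuple[np.ndarray, StainRatioResult]:
    """Classify and compute the ratio in one call (the per-image pipeline)."""
    class_map, counts = classify_pixels(image, thresholds, tissue_mask)
    return class_map, blue_pink_ratio(counts, image_id, thresholds)


# ---------------------------------------------------------------------------
# calibration

def _class_accuracy(pixels: np.ndarray, box: Box) -> float:
    """Fraction of the given pixels (N, 3) falling inside the box."""
    if len(pixels) == 0:
        return 0.0
    inside = np.ones(len(pixels), dtype=bool)
    for c, (lo, hi) in enumerate(box):
        inside &= (pixels[:, c] >= lo) & (pixels[:, c] <= hi)
    return float(np.count_nonzero(inside)) / len(pixels)


def _flatten_patches(annotated_patches: Sequence[tuple[np.ndarray, str]]) -> dict[str, np.ndarray]:
    pools: dict[str, list[np.ndarray]] = {"blue": [], "pink": [], "other": []}
    for patch, label in annotated_patches:
        label = label.lower()
        if label not in pools:
            raise CalibrationError(f"unknown patch label {label!r}; expected blue/pink/other")
        patch = _check_image(np.asarray(patch))
        pools[label].append(patch.reshape(-1, 3))
    return {k: (np.concatenate(v) if v else np.empty((0, 3), dtype=np.uint8)) for k, v in pools.items()}


def calibrate_thresholds(
    annotated_patches: Sequence[tuple[np.ndarray, str]],
    search_grid: Mapping[str, Mapping[str, Sequence[Interval]]],
    name: str = "calibrated",
) -> RGBThresholdSet:
    """Grid-search the stain boxes against pure-class annotated patches.

    Parameters
    ----------
    annotated_patches
        ``(image region, label)`` pairs with label in {"blue", "pink",
        "other"}.  Regions are pure-class by annotation.  At least one blue
        and one pink patch are required; "other" patches improve specificity.
    search_grid
        ``{"blue": {"R": [(lo, hi), ...], "G": ..., "B": ...}, "pink": ...}``
        — candidate inclusive intervals per channel per class.  The search is
        exhaustive over the per-class Cartesian product of the channel
        candidates.

    Each class box is chosen to maximize balanced accuracy: the mean of
    sensitivity on its own class pixels and specificity against all other
    pixels (the remaining classes pooled).  Ties break toward the earliest
    point in grid ordering, so a fixed grid always yields the same set.
    """
    pools = _flatten_patches(annotated_patches)
    for cls in ("blue", "pink"):
        if len(pools[cls]) == 0:
            raise CalibrationError(f"no annotated patches for required class {cls!r}")

    boxes: dict[str, Box] = {}
    for cls in ("blue", "pink"):
        try:
            cands = [list(search_grid[cls][ch]) for ch in _CHANNELS]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"search grid missing candidates for {cls}/{exc}") from exc
        if any(len(c) == 0 for c in cands):
            raise ConfigurationError(f"degenerate search grid: empty candidate list for class {cls!r}")
        own = pools[cls]
        rest = np.concatenate([pools[k] for k in ("blue", "pink", "other") if k != cls])
        best_score, best_box = -1.0, None
        for box in itertools.product(*cands):
            box = tuple(box)
            _validate_box(box, f"{cls} candidate box")
            sens = _class_accuracy(own, box)
            spec = 1.0 - _class_accuracy(rest, box) if len(rest) else 1.0
            score = 0.5 * (sens + spec)
            if score > best_score:  # strict: first max in grid order wins
                best_score, best_box = score, box
        boxes[cls] = best_box
    return RGBThresholdSet(
        blue_box=boxes["blue"], pink_box=boxes["pink"], name=name, provenance="calibrated"
    )
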