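"""Synthetic fixtures: stained sections, ventricle phantoms, cohorts.

The study's slides and scans are not redistributable, so every analysis
stage is exercised against generated data with known ground truth:

* :func:`make_stain_image` — an RGB image mixing three color populations
  (Prussian-blue-like, eosin-pink-like, near-white background) at exact,
  largest-remainder-allocated pixel counts, with optional Gaussian color
  jitter.  The default class centers sit inside the default threshold boxes
  of :mod:`phhkit.stain`, so at zero jitter classification recovers the
  generated counts exactly.
* :func:`make_ventricle_stack` — serial label masks of an axis-aligned
  ellipsoid "ventricle" whose volume is known in closed form
  (4/3 pi a b c), for validating Cavalieri slice-area integration.
* :func:`make_cohort` — a seeded four-group longitudinal cohort whose
  generating group-day means default to the study's printed mean ventricular
  CSF trajectories (saline control, hemoglobin, ferric iron, lysed RBC at
  postnatal days 5/12/19/26).  Between-subject spread is lognormal around
  each group-day mean; the default coefficient of variation of 1.0 is scaled
  from the one printed SEM (iron day 26: 0.9695 +/- 0.1386, n = 49, hence
  SD ~= mean).  Optional dropout emulates death from severe hydrocephalus:
  once a subject's volume exceeds a threshold it may die and contribute no
  later scans (rows are simply absent, never imputed).

Every generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .stain import PixelClassCounts
from .volumetry import Compartment, SliceAreaRecord

# ---------------------------------------------------------------------------
# stained-section images


class SpatialLayout(str, Enum):
    RANDOM_PIXELS = "random_pixels"
    BLOBS = "blobs"


#: Class color centers, chosen inside the default threshold boxes.
BLUE_CENTER = (60, 80, 190)
PINK_CENTER = (230, 150, 170)
BACKGROUND_COLOR = (245, 245, 245)


@dataclass(frozen=True)
class StainImageSpec:
    """Recipe for one synthetic Perls/eosin section image."""

    width: int = 100
    height: int = 100
    true_blue_fraction: float = 0.003
    true_pink_fraction: float = 0.90
    blue_color_center: tuple[int, int, int] = BLUE_CENTER
    pink_color_center: tuple[int, int, int] = PINK_CENTER
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    jitter_sd: float = 6.0
    spatial_layout: SpatialLayout = SpatialLayout.RANDOM_PIXELS
    seed: int = 0

    def __post_init__(self) -> None:
        b, p = self.true_blue_fraction, self.true_pink_fraction
        if not (0 <= b <= 1 and 0 <= p <= 1 and b + p <= 1):
            raise ConfigurationError(
                f"stain fractions must lie in [0, 1] with sum <= 1, got blue={b}, pink={p}"
            )
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("image dimensions must be >= 1 pixel")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer class counts summing to n, by largest-remainder allocation.

    Ties in the fractional remainders break toward the earlier class.
    """
    ideal = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in ideal]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _blob_assignment(rng: np.random.Generator, h: int, w: int,
                     n_blue: int, n_pink: int) -> np.ndarray:
    """Class index per pixel (0=blue, 1=pink, 2=bg) in blob-like clusters,
    preserving exact class counts: the n_blue pixels nearest a few random
    blue seeds become blue, then the n_pink nearest pink seeds become pink."""
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    n = h * w
    assignment = np.full(n, 2, dtype=np.uint8)

    def nearest_score(n_seeds: int) -> np.ndarray:
        seeds = np.column_stack([rng.uniform(0, h, n_seeds), rng.uniform(0, w, n_seeds)])
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        return d.min(axis=1)

    blue_score = nearest_score(max(1, n_blue // 400 + 1))
    blue_idx = np.argsort(blue_score, kind="stable")[:n_blue]
    assignment[blue_idx] = 0
    remaining = np.flatnonzero(assignment == 2)
    pink_score = nearest_score(max(1, 4))[remaining]
    pink_idx = remaining[np.argsort(pink_score, kind="stable")[:n_pink]]
    assignment[pink_idx] = 1
    return assignment


def make_stain_image(spec: StainImageSpec) -> tuple[np.ndarray, PixelClassCounts]:
    """Generate an RGB section image plus its ground-truth class counts.

    Pixel counts per class are fixed by largest-remainder allocation of the
    spec fractions over width*height pixels; colors are sampled around the
    class centers with per-channel Gaussian jitter, rounded and clipped to
    [0, 255].  Identical spec (including seed) gives a bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.width * spec.height
    bg_fraction = 1.0 - spec.true_blue_fraction - spec.true_pink_fraction
    n_blue, n_pink, _ = _largest_remainder_counts(
        n, [spec.true_blue_fraction, spec.true_pink_fraction, bg_fraction]
    )
    if spec.spatial_layout is SpatialLayout.BLOBS:
        assignment = _blob_assignment(rng, spec.height, spec.width, n_blue, n_pink)
    else:
        assignment = np.full(n, 2, dtype=np.uint8)
        perm = rng.permutation(n)
        assignment[perm[:n_blue]] = 0
        assignment[perm[n_blue:n_blue + n_pink]] = 1

    centers = np.array(
        [spec.blue_color_center, spec.pink_color_center, spec.background_color], dtype=float
    )
    pixels = centers[assignment]
    if spec.jitter_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.jitter_sd, size=pixels.shape)
    image = np.clip(np.rint(pixels), 0, 255).astype(np.uint8).reshape(spec.height, spec.width, 3)
    counts = PixelClassCounts(blue=n_blue, pink=n_pink, other=n - n_blue - n_pink)
    return image, counts


# ---------------------------------------------------------------------------
# ventricle phantom


def make_ventricle_stack(
    semi_axes: tuple[float, float, float],
    pixel_spacing: float = 0.02,
    thickness: float = 0.1,
    seed: int = 0,
) -> tuple[list[np.ndarray], float]:
    """Serial label masks of an ellipsoid ventricle phantom.

    The ellipsoid (semi-axes ``a, b, c`` in mm, axis-aligned, sliced along
    the ``c`` axis) is rasterized into per-slice masks labeled
    ``Compartment.LATERAL_L`` at the given in-plane pixel spacing; slices are
    placed at the centers of consecutive thickness-``t`` slabs covering
    ``[-c, c]``.  Returns the masks and the analytic volume 4/3 pi a b c in
    mL.  ``seed`` is accepted for interface uniformity; the phantom is
    deterministic.
    """
    a, b, c = (float(x) for x in semi_axes)
    if a < 0 or b < 0 or c < 0 or pixel_spacing <= 0 or thickness <= 0:
        raise ConfigurationError("semi-axes must be >= 0; spacing and thickness > 0")
    analytic_ml = (4.0 / 3.0) * np.pi * a * b * c / 1000.0
    if a == 0 or b == 0 or c == 0:
        return [], analytic_ml
    if thickness > min(a, b, c):
        warnings.warn(
            f"slice thickness {thickness} mm exceeds the smallest semi-axis "
            f"{min(a, b, c)} mm; the phantom is under-resolved", stacklevel=2,
        )
    n_slices = int(np.ceil(2 * c / thickness))
    nx = int(np.ceil(2 * a / pixel_spacing)) + 3
    ny = int(np.ceil(2 * b / pixel_spacing)) + 3
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing
    xx2 = (x[None, :] / a) ** 2
    yy2 = (y[:, None] / b) ** 2
    masks = []
    for k in range(n_slices):
        z = -c + (k + 0.5) * thickness
        r2 = 1.0 - (z / c) ** 2
        mask = np.where(xx2 + yy2 <= r2, np.uint8(Compartment.LATERAL_L), np.uint8(0))
        masks.append(mask)
    return masks, analytic_ml


def stack_to_records(
    masks: Sequence[np.ndarray],
    pixel_spacing: float,
    thickness: float,
    subject_id: str = "phantom",
    day: int = 0,
) -> list[SliceAreaRecord]:
    """Convert a phantom stack into slice-area records (one per slice per
    compartment present), ready for :func:`phhkit.volumetry.volume_from_areas`."""
    from .volumetry import area_from_mask

    records = []
    for k, mask in enumerate(masks):
        areas = area_from_mask(mask, (pixel_spacing, pixel_spacing))
        for comp, area in areas.items():
            if area > 0:
                records.append(SliceAreaRecord(
                    subject_id=subject_id, day=day, slice_index=k,
                    compartment=comp, area=area, thickness=thickness,
                ))
    return records


# ---------------------------------------------------------------------------
# longitudinal cohort

#: Printed group-mean ventricular CSF volume trajectories (mL) at postnatal
#: days 5, 12, 19, 26 for the four injection groups.
DEFAULT_GROUP_MEANS: dict[str, tuple[float, ...]] = {
    "control": (0.01208, 0.005668, 0.0105, 0.0115),
    "Hb": (0.007613, 0.03797, 0.03839, 0.02312),
    "iron": (0.04906, 0.2462, 0.5019, 0.9695),
    "L-RBC": (0.04934, 0.1970, 0.2635, 0.3760),
}

DEFAULT_DAYS: tuple[int, ...] = (5, 12, 19, 26)

#: Study group sizes (animals per injection group).
DEFAULT_N_PER_GROUP: dict[str, int] = {"control": 20, "Hb": 25, "iron": 49, "L-RBC": 41}

#: Default between-subject lognormal coefficient of variation (see module
#: docstring for its provenance).
DEFAULT_CV = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a seeded longitudinal four-group cohort."""

    group_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    days: Sequence[int] = DEFAULT_DAYS
    n_per_group: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    cv: float = DEFAULT_CV
    dropout_threshold: float | None = None  # mL; None disables dropout
    dropout_prob: float = 0.5  # P(death | volume above threshold), per scan
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError(f"between-subject spread (cv) must be >= 0, got {self.cv}")
        for g, means in self.group_means.items():
            if len(means) != len(self.days):
                raise ConfigurationError(
                    f"group {g!r} has {len(means)} means for {len(self.days)} days")
            if any(m <= 0 for m in means):
                raise ConfigurationError(f"group {g!r} has non-positive mean volumes")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob must be in [0, 1]")

    def n_for(self, group: str) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        return int(self.n_per_group.get(group, 10))


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a longitudinal cohort as a long (group, subject, day, volume)
    table.

    Volumes are lognormal around each group-day mean with coefficient of
    variation ``spec.cv`` (cv = 0 reproduces the means exactly).  With
    dropout enabled, a subject whose drawn volume exceeds the threshold dies
    with probability ``dropout_prob`` after that scan and contributes no
    later rows.
    """
    rng = np.random.default_rng(spec.seed)
    sigma2 = np.log1p(spec.cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for group, means in spec.group_means.items():
        for i in range(spec.n_for(group)):
            subject = f"{group}-{i + 1:03d}"
            for day, m in zip(spec.days, means):
                if spec.cv == 0:
                    vol = float(m)
                else:
                    mu = np.log(m) - sigma2 / 2.0  # E[lognormal(mu, sigma)] = m
                    vol = float(rng.lognormal(mean=mu, sigma=sigma))
                rows.append((group, subject, int(day), vol))
                if (spec.dropout_threshold is not None
                        and vol > spec.dropout_threshold
                        and rng.random() < spec.dropout_prob):
                    break  # death: no further scans for this subject
    return pd.DataFrame(rows, columns=["group", "subject", "day", "volume"])
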