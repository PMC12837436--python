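"""Readers and writers for the pipeline's on-disk formats.

Images are PNG/TIFF, 8-bit RGB; tables are comma-separated UTF-8 CSV with a
required header and '.' decimal; threshold sets and reports are JSON.  All
readers validate schemas eagerly and raise :class:`~phhkit.errors.SchemaError`
subclasses naming the offending column or property.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, SchemaError
from .stain import RGBThresholdSet
from .volumetry import Compartment, SliceAreaRecord, VolumeMeasurement

LONG_TABLE_COLUMNS = ("group", "subject", "day", "volume")
SLICE_AREA_COLUMNS = ("subject_id", "day", "slice_index", "compartment", "area_mm2", "thickness_mm")


# ---------------------------------------------------------------------------
# images

def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 RGB array."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: expected 8-bit/channel image, got {arr.dtype}; "
            "rescale to uint8 (e.g. skimage.util.img_as_ubyte) before analysis"
        )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3-channel RGB, got shape {arr.shape}; "
            "convert (drop alpha / expand grayscale) before analysis"
        )
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image))


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a 2-D indexed label mask (compartment codes, 0 = background)."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label masks must be single-channel, got shape {arr.shape}")
    return arr


def read_mask_sidecar(mask_path: str | Path) -> dict:
    """Read the JSON sidecar (``<mask>.json``) describing one mask slice:
    subject_id, day, slice_index, pixel_spacing [row, col] mm, thickness mm."""
    sidecar = Path(str(mask_path) + ".json")
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar} for mask {mask_path}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "day", "slice_index", "pixel_spacing", "thickness"):
        if key not in meta:
            raise SchemaError(f"{sidecar}: sidecar missing required property {key!r}")
    return meta


# ---------------------------------------------------------------------------
# threshold sets

def read_thresholds(path: str | Path) -> RGBThresholdSet:
    return RGBThresholdSet.from_dict(json.loads(Path(path).read_text()))


def write_thresholds(path: str | Path, thresholds: RGBThresholdSet) -> None:
    Path(path).write_text(json.dumps(thresholds.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# tables

def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format cohort table (group, subject, day, volume).

    Group labels are data-driven and pass through untouched; absent visits
    are simply absent rows.
    """
    df = pd.read_csv(path)
    _require_columns(df, LONG_TABLE_COLUMNS, path)
    df = df.loc[:, list(LONG_TABLE_COLUMNS)]
    try:
        df["day"] = df["day"].astype(int)
        df["volume"] = df["volume"].astype(float)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: non-numeric day/volume values: {exc}") from exc
    df["group"] = df["group"].astype(str)
    df["subject"] = df["subject"].astype(str)
    return df


def write_long_table(path: str | Path, df: pd.DataFrame) -> None:
    df.loc[:, list(LONG_TABLE_COLUMNS)].to_csv(path, index=False)


def read_slice_area_table(path: str | Path) -> list[SliceAreaRecord]:
    """Read slice-area records: subject_id, day, slice_index, compartment
    (enum name), area_mm2, thickness_mm."""
    df = pd.read_csv(path)
    _require_columns(df, SLICE_AREA_COLUMNS, path)
    records = []
    for row in df.itertuples(index=False):
        try:
            comp = Compartment[str(row.compartment)]
        except KeyError as exc:
            raise SchemaError(
                f"{path}: unknown compartment {row.compartment!r}; "
                f"valid: {[c.name for c in Compartment]}"
            ) from exc
        records.append(SliceAreaRecord(
            subject_id=str(row.subject_id), day=int(row.day),
            slice_index=int(row.slice_index), compartment=comp,
            area=float(row.area_mm2), thickness=float(row.thickness_mm),
        ))
    return records


def write_volume_table(path: str | Path, measurements: list[VolumeMeasurement]) -> None:
    pd.DataFrame(
        [(m.subject_id, m.day, m.volume, m.n_slices_included) for m in measurements],
        columns=["subject_id", "day", "volume_mL", "n_slices_included"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and manifests

@dataclasses.dataclass
class RunConfig:
    """Validated run-level configuration shared by the CLI subcommands."""

    threshold_set_path: Path | None = None
    alpha: float = 0.05
    inclusion: frozenset[Compartment] = frozenset(
        {Compartment.LATERAL_L, Compartment.LATERAL_R, Compartment.THIRD})
    slice_thickness: float | None = None  # mm; no default, scanner-specific
    seed: int = 0
    output_dir: Path = Path(".")
    verbosity: int = 0

    def validate(self) -> "RunConfig":
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.threshold_set_path is not None and not Path(self.threshold_set_path).exists():
            raise ConfigurationError(f"threshold set file not found: {self.threshold_set_path}")
        if self.slice_thickness is not None and self.slice_thickness <= 0:
            raise ConfigurationError(f"slice thickness must be > 0 mm, got {self.slice_thickness}")
        return self


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path: str | Path, command: str, config: dict,
                   inputs: list[str | Path], outputs: list[str | Path]) -> Path:
    """Write a reproducibility manifest next to a command's primary output."""
    from . import __version__

    manifest = {
        "command": command,
        "phhkit_version": __version__,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
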