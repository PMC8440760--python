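"""Core data types and file I/O.

Images are 2-D grayscale arrays: 8-bit integer straight off disk, float in
[0, 1] after normalisation.  Coordinates are 0-based ``(row=y, col=x)`` with
the origin at the top-left; annotation files store ``x`` (column) before
``y`` (row).  Point annotations carry a benign/suspicious label; a manifest
binds the recent/prior image pair of each (patient, view) to its annotation
file.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class View(str, enum.Enum):
    CC = "CC"
    MLO = "MLO"


class Round(str, enum.Enum):
    PRIOR = "prior"
    RECENT = "recent"


class Label(str, enum.Enum):
    BENIGN = "benign"
    SUSPICIOUS = "suspicious"


class FormatError(ValueError):
    """Raised when a file decodes but violates the expected image format."""


@dataclass
class MammoImage:
    """One grayscale mammographic view plus acquisition metadata.

    ``pixels`` holds either raw 8-bit values in [0, 255] or, after
    normalisation, floats in [0, 1].
    """

    pixels: np.ndarray
    patient_id: str = ""
    view: Optional[View] = None
    round: Optional[Round] = None
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise FormatError(
                f"image must be 2-D with positive extent, got shape {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "MammoImage":
        """Copy of this image with replaced pixel data, metadata preserved."""
        return MammoImage(
            pixels=pixels,
            patient_id=self.patient_id,
            view=self.view,
            round=self.round,
            pixel_spacing=self.pixel_spacing,
        )


@dataclass
class Annotation:
    """Point marking of a single microcalcification."""

    patient_id: str
    view: View
    round: Round
    x: int  # column
    y: int  # row
    label: Label


@dataclass
class ManifestRecord:
    patient_id: str
    view: View
    recent_path: Path
    prior_path: Path
    annotation_path: Path
    population: str  # "normal" | "suspicious"


@dataclass
class Manifest:
    records: list[ManifestRecord] = field(default_factory=list)


def read_image(path: str | Path, format: Optional[str] = None) -> MammoImage:
    """Read a single-frame grayscale image (DICOM, PNG or TIFF).

    Pixel values are returned untouched.  Colour or multi-frame inputs raise
    :class:`FormatError` naming the offending property.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3:
            raise FormatError(f"multi-frame or colour DICOM not supported: shape {arr.shape}")
        spacing = None
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = float(ps[0])
        return MammoImage(pixels=np.asarray(arr), pixel_spacing=spacing)
    if fmt in ("png", "tif", "tiff"):
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        if arr.ndim == 3:
            raise FormatError(f"colour image not supported: {arr.shape[2]} channels")
        return MammoImage(pixels=np.asarray(arr))
    raise FormatError(f"unknown image format {fmt!r}")


def write_image(img: MammoImage | np.ndarray, path: str | Path) -> None:
    """Write to PNG/TIFF.  Float images in [0, 1] are scaled to 8-bit;
    integer images are written as-is (must fit uint8)."""
    import imageio.v3 as iio

    arr = img.pixels if isinstance(img, MammoImage) else np.asarray(img)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    iio.imwrite(str(Path(path)), arr)


_ANNOTATION_COLUMNS = ["patient_id", "view", "round", "x", "y", "label"]


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read per-microcalcification point annotations from CSV.

    Expects header columns patient_id, view, round, x, y, label; labels
    restricted to benign/suspicious.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing columns {missing}")
    anns: list[Annotation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            label = Label(str(row.label))
        except ValueError:
            raise ValueError(
                f"unknown label {row.label!r} at row {i + 1} of {path}; "
                f"expected one of {[l.value for l in Label]}"
            ) from None
        anns.append(
            Annotation(
                patient_id=str(row.patient_id),
                view=View(str(row.view)),
                round=Round(str(row.round)),
                x=int(row.x),
                y=int(row.y),
                label=label,
            )
        )
    return anns


def write_annotations(anns: Sequence[Annotation], path: str | Path, extra: Optional[dict] = None) -> None:
    rows = [
        {
            "patient_id": a.patient_id,
            "view": a.view.value,
            "round": a.round.value,
            "x": a.x,
            "y": a.y,
            "label": a.label.value,
        }
        for a in anns
    ]
    df = pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)
    if extra:
        for k, v in extra.items():
            df[k] = v
    df.to_csv(path, index=False)


def load_manifest(path: str | Path) -> Manifest:
    """Load a YAML manifest listing image pairs and annotation files.

    Paths are resolved relative to the manifest's directory; every referenced
    file must exist, and each (patient, view) may appear only once.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    records = []
    seen: set[tuple[str, str]] = set()
    for rec in raw.get("records", []):
        key = (str(rec["patient_id"]), str(rec["view"]))
        if key in seen:
            raise ValueError(f"duplicate manifest entry for patient/view {key}")
        seen.add(key)
        paths = {
            k: (base / rec[k]) for k in ("recent_path", "prior_path", "annotation_path")
        }
        for k, p in paths.items():
            if not p.exists():
                raise IOError(f"manifest references missing file {p} ({k})")
        records.append(
            ManifestRecord(
                patient_id=str(rec["patient_id"]),
                view=View(str(rec["view"])),
                population=str(rec.get("population", "normal")),
                **paths,
            )
        )
    return Manifest(records=records)
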