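"""Reading and writing the pipeline's on-disk formats.

Images travel as 8-bit grayscale PNG, class maps as indexed PNG with the
palette BG/NM/M = 0/1/2, raw two-view scans optionally as DICOM secondary
capture, and cohorts as a JSON manifest.  Polygon annotations in the JSON
layout produced by common labelling tools (a list of ``shapes`` with
polygon ``points``) can be rasterised to binary masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "save_png",
    "load_png",
    "save_label_png",
    "load_label_png",
    "polygons_to_mask",
    "load_annotation_json",
    "write_manifest",
    "read_manifest",
    "write_dicom",
]

_LABEL_PALETTE = [0, 0, 0, 90, 200, 90, 220, 60, 60]  # BG black, NM green, M red


def save_png(path, image: np.ndarray) -> None:
    """Write an image as 8-bit grayscale PNG (values clipped to [0, 255])."""
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_png(path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("L"))


def save_label_png(path, classes: np.ndarray) -> None:
    """Write a BG/NM/M class map as an indexed-palette PNG."""
    img = Image.fromarray(np.asarray(classes, dtype=np.uint8), mode="P")
    img.putpalette(_LABEL_PALETTE + [0] * (768 - len(_LABEL_PALETTE)))
    img.save(Path(path))


def load_label_png(path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)), dtype=np.uint8)


def polygons_to_mask(shape: tuple[int, int], polygons) -> np.ndarray:
    """Rasterise polygons (lists of (x, y) vertices) to a boolean mask."""
    from PIL import ImageDraw

    img = Image.new("1", (shape[1], shape[0]), 0)
    draw = ImageDraw.Draw(img)
    for poly in polygons:
        pts = [(float(x), float(y)) for x, y in poly]
        if len(pts) >= 3:
            draw.polygon(pts, fill=1)
    return np.asarray(img, dtype=bool)


def load_annotation_json(path, shape: tuple[int, int]) -> np.ndarray:
    """Read a polygon-annotation JSON file (``shapes`` -> ``points``) and
    return the union of its polygons as a boolean metastasis mask."""
    with open(Path(path)) as fh:
        blob = json.load(fh)
    polys = [s["points"] for s in blob.get("shapes", []) if s.get("points")]
    return polygons_to_mask(shape, polys)


def write_manifest(path, entries: list[dict]) -> None:
    with open(Path(path), "w") as fh:
        json.dump({"samples": entries}, fh, indent=2)


def read_manifest(path) -> list[dict]:
    with open(Path(path)) as fh:
        return json.load(fh)["samples"]


def write_dicom(path, image: np.ndarray, source_id: str = "phantom") -> None:
    """Write a single grayscale view as a DICOM secondary-capture object."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = source_id
    ds.PatientName = source_id
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(Path(path), enforce_file_format=True)


def read_dicom(path) -> np.ndarray:
    import pydicom

    return pydicom.dcmread(Path(path)).pixel_array
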