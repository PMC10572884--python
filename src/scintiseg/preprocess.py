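"""Raw-scan preprocessing: body-range detection, cut-and-center to 950x256,
linear brightness normalization into the mean-intensity band (7, 14),
above-knee cropping to 640 rows, and horizontal AP/PA merging to 640x512.

All steps are deterministic and scale-free (no resampling): the body is
located by projection profiles, recentred by integer shifts, and intensity
is adjusted by a single multiplicative gain per image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawScan",
    "NormalizationConfig",
    "ProcessedImage",
    "detect_body_range",
    "cut_and_center",
    "apply_geometry",
    "normalize_brightness",
    "crop_above_knees",
    "merge_views",
    "preprocess_scan",
]

logger = logging.getLogger(__name__)

VIEW_ROWS = 950       # cut-and-center output height per view
ABOVE_KNEE_ROWS = 640  # rows kept above the knees
VIEW_COLS = 256


class EmptyBodyError(ValueError):
    """No body found: projection profile never exceeds the noise floor."""


class DimensionError(ValueError):
    """Input image dimensions violate a stage's contract."""


class NormalizationError(RuntimeError):
    """Brightness normalization could not reach the target band."""


@dataclass(frozen=True)
class RawScan:
    """A raw two-view acquisition (AP and PA count images, same shape)."""

    ap_view: np.ndarray
    pa_view: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        if self.ap_view.shape != self.pa_view.shape:
            raise DimensionError(
                f"AP and PA shapes differ: {self.ap_view.shape} vs {self.pa_view.shape}"
            )


@dataclass(frozen=True)
class NormalizationConfig:
    """Target mean-intensity band and iteration cap for brightness gain."""

    target_mean_low: float = 7.0
    target_mean_high: float = 14.0
    max_iterations: int = 20
    output_range: tuple[float, float] = (0.0, 255.0)
    body_only: bool = False  # mean over body pixels instead of whole image

    def __post_init__(self):
        if not (0 < self.target_mean_low < self.target_mean_high):
            raise ValueError("need 0 < low < high for the target band")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ProcessedImage:
    """Merged, normalized 640x512 image ready for network input."""

    pixels: np.ndarray
    source_id: str = ""
    provenance: dict = field(default_factory=dict)


def detect_body_range(
    view: np.ndarray, noise_floor_frac: float = 0.01
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the body by projection profiles.

    Returns ``((row_lo, row_hi), (col_lo, col_hi))`` — inclusive bounds of
    the span of rows (columns) whose profile sum exceeds ``noise_floor_frac``
    times the maximum row (column) sum.
    """
    view = np.asarray(view, dtype=np.float64)
    if view.size == 0:
        raise DimensionError("empty image")
    bounds = []
    for axis in (1, 0):
        profile = view.sum(axis=axis)
        floor = noise_floor_frac * profile.max()
        above = np.flatnonzero(profile > floor)
        if above.size == 0 or profile.max() <= 0:
            raise EmptyBodyError("projection profile never exceeds the noise floor")
        bounds.append((int(above[0]), int(above[-1])))
    return bounds[0], bounds[1]


def cut_and_center(
    view: np.ndarray,
    bounds: tuple[tuple[int, int], tuple[int, int]],
    out_rows: int = VIEW_ROWS,
    return_geometry: bool = False,
) -> np.ndarray:
    """Cut the detected body span and place it on a ``out_rows`` x W canvas,
    vertically centred, with the body's horizontal centre of mass shifted to
    the canvas midline.  Values are copied, never rescaled.

    A body taller than ``out_rows`` is truncated at the bottom (a warning is
    logged); above-knee anatomy is always in the upper rows.
    """
    view = np.asarray(view)
    (r0, r1), (c0, c1) = bounds
    h, w = view.shape
    body = view[r0 : r1 + 1]
    if body.shape[0] > out_rows:
        logger.warning(
            "body spans %d rows > %d; truncating bottom", body.shape[0], out_rows
        )
        body = body[:out_rows]
    out = np.zeros((out_rows, w), dtype=view.dtype)
    top = (out_rows - body.shape[0]) // 2
    out[top : top + body.shape[0]] = body

    # horizontal centre of mass, intensity-weighted: body counts dominate the
    # sparse air noise, so the estimate tracks the anatomy
    cols = np.arange(w, dtype=np.float64)
    weight = float(out.sum())
    if weight == 0:
        shift = 0
    else:
        com = float((out.astype(np.float64) * cols[None, :]).sum()) / weight
        shift = int(round((w / 2.0 - 0.5) - com))
    out = _hshift(out, shift)
    if return_geometry:
        return out, {
            "row_lo": r0,
            "rows": body.shape[0],
            "top": top,
            "shift": shift,
            "out_rows": out_rows,
        }
    return out


def _hshift(img: np.ndarray, shift: int) -> np.ndarray:
    """Horizontal integer shift with zero fill."""
    if shift == 0:
        return img
    w = img.shape[1]
    out = np.zeros_like(img)
    if shift > 0:
        out[:, shift:] = img[:, : w - shift]
    else:
        out[:, :shift] = img[:, -shift:]
    return out


def apply_geometry(view: np.ndarray, geometry: dict) -> np.ndarray:
    """Re-apply a cut_and_center geometry (row crop, vertical placement,
    horizontal shift) to a parallel image such as an annotation mask."""
    view = np.asarray(view)
    out_rows = geometry["out_rows"]
    body = view[geometry["row_lo"] : geometry["row_lo"] + geometry["rows"]]
    out = np.zeros((out_rows, view.shape[1]), dtype=view.dtype)
    out[geometry["top"] : geometry["top"] + body.shape[0]] = body
    return _hshift(out, geometry["shift"])


def normalize_brightness(
    image: np.ndarray,
    config: NormalizationConfig = NormalizationConfig(),
) -> tuple[np.ndarray, float]:
    """Linearly scale ``image`` until its mean intensity lies inside the open
    band ``(target_mean_low, target_mean_high)``.

    Each pass multiplies by ``midpoint / current_mean`` and clips to the
    output range; clipping can shift the mean, hence the re-check loop.
    Returns ``(normalized float32 image, total applied gain)``.
    """
    img = np.asarray(image, dtype=np.float64)
    if config.body_only:
        body = img > 0
        if not body.any():
            raise NormalizationError("no body pixels to normalize over")
    lo, hi = config.target_mean_low, config.target_mean_high
    mid = 0.5 * (lo + hi)
    out = img.copy()
    total_gain = 1.0
    for _ in range(config.max_iterations):
        mean = out[out > 0].mean() if config.body_only else out.mean()
        if lo < mean < hi:
            return out.astype(np.float32), total_gain
        if mean <= 0:
            raise NormalizationError("image mean is zero; cannot normalize")
        gain = mid / mean
        total_gain *= gain
        out = np.clip(out * gain, *config.output_range)
    raise NormalizationError(
        f"mean not in ({lo}, {hi}) after {config.max_iterations} iterations"
    )


def crop_above_knees(image: np.ndarray, keep_rows: int = ABOVE_KNEE_ROWS) -> np.ndarray:
    """Keep rows [0, keep_rows) — the anatomy above the knees."""
    image = np.asarray(image)
    if image.shape[0] < keep_rows:
        raise DimensionError(
            f"image has {image.shape[0]} rows; need at least {keep_rows}"
        )
    return image[:keep_rows].copy()


def merge_views(ap: np.ndarray, pa: np.ndarray) -> np.ndarray:
    """Horizontally merge AP (left half) and PA (right half)."""
    ap = np.asarray(ap)
    pa = np.asarray(pa)
    if ap.shape != pa.shape:
        raise DimensionError(f"view shapes differ: {ap.shape} vs {pa.shape}")
    return np.hstack([ap, pa])


def preprocess_scan(
    scan: RawScan,
    config: NormalizationConfig = NormalizationConfig(),
    noise_floor_frac: float = 0.01,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> ProcessedImage | tuple[ProcessedImage, np.ndarray]:
    """Full preprocessing chain: detect body, cut/center each view, normalize
    brightness, crop above the knees, merge.

    If per-view annotation ``masks`` (AP, PA) are given they are carried
    through the same geometric transforms (without intensity changes) and the
    merged mask is returned alongside the image.  A final gain pass keeps the
    merged image's mean inside the target band even when cropping shifted it.
    """
    views = []
    mask_views = []
    provenance: dict = {"gains": [], "bounds": []}
    for idx, view in enumerate((scan.ap_view, scan.pa_view)):
        bounds = detect_body_range(view, noise_floor_frac)
        cut, geometry = cut_and_center(view, bounds, return_geometry=True)
        norm, gain = normalize_brightness(cut, config)
        views.append(crop_above_knees(norm))
        provenance["gains"].append(gain)
        provenance["bounds"].append(bounds)
        if masks is not None:
            mcut = apply_geometry(masks[idx].astype(np.uint8), geometry)
            mask_views.append(crop_above_knees(mcut) > 0)
    merged = merge_views(views[0], views[1])
    mean = merged.mean()
    if not (config.target_mean_low < mean < config.target_mean_high):
        merged, gain = normalize_brightness(merged, config)
        provenance["gains"].append(gain)
    processed = ProcessedImage(
        pixels=merged.astype(np.float32),
        source_id=scan.source_id,
        provenance=provenance,
    )
    if masks is not None:
        return processed, merge_views(mask_views[0], mask_views[1])
    return processed
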