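"""Synthetic whole-body bone-scan phantoms.

Planar bone scintigraphy acquires paired anterior (AP) and posterior (PA)
count images of a patient after injection of a bone-seeking tracer.  The
phantoms generated here emulate the statistical structure of such scans —
a connected, horizontally centred body silhouette over a near-zero air
background, skeleton-like high-uptake structures (spine, ribs, pelvis,
joints), and optionally bright focal "hotspot" lesions — so that every
downstream stage (preprocessing, mask generation, training, evaluation)
can be exercised without clinical data.

Lesions are Gaussian-profile blobs with random eccentricity; they model the
appearance of metastatic hotspots, not scanner physics.  Air noise is
Poisson, because the raw scans are count images.  The generator is fully
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "silhouette_mask",
]

_ARTIFACT_KINDS = frozenset({"bladder", "injection_site", "motion"})


class PhantomConfigError(ValueError):
    """Raised for an invalid phantom configuration."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic two-view bone scan.

    ``view_shape`` defaults to the clinical acquisition matrix (1024 rows x
    256 columns per view); smaller shapes produce geometrically similar
    phantoms for fast tests.  Intensities are 8-bit count levels; the lower
    bound of ``lesion_intensity_range`` must exceed the upper bound of
    ``body_intensity_range`` so lesions are strictly brighter than the
    median body pixel.
    """

    seed: int = 0
    view_shape: tuple[int, int] = (1024, 256)
    n_lesions: int = 3
    lesion_intensity_range: tuple[float, float] = (150.0, 230.0)
    body_intensity_range: tuple[float, float] = (80.0, 130.0)
    air_noise_level: float = 0.05
    artifact_flags: frozenset[str] = field(default_factory=frozenset)
    lesion_sigma_frac: tuple[float, float] = (0.010, 0.025)
    cohort_tag: str = "breast_like"

    def validate(self) -> None:
        h, w = self.view_shape
        if h < 16 or w < 16:
            raise PhantomConfigError(f"view_shape too small: {self.view_shape}")
        if self.n_lesions < 0:
            raise PhantomConfigError("n_lesions must be non-negative")
        lo, hi = self.lesion_intensity_range
        blo, bhi = self.body_intensity_range
        if not (lo < hi) or not (blo < bhi):
            raise PhantomConfigError("intensity ranges must be non-empty intervals")
        # lesion amplitudes are additive on the body base, so detectability
        # requires clearing the Poisson count noise, not the body level
        if lo <= 3.0 * np.sqrt(bhi):
            raise PhantomConfigError(
                "lesion amplitude must exceed the body count-noise scale"
            )
        if self.air_noise_level < 0:
            raise PhantomConfigError("air_noise_level must be non-negative")
        unknown = set(self.artifact_flags) - _ARTIFACT_KINDS
        if unknown:
            raise PhantomConfigError(f"unknown artifact flags: {sorted(unknown)}")


@dataclass(frozen=True)
class PhantomSample:
    """One synthetic patient scan: AP/PA views plus ground-truth lesion masks."""

    ap_view: np.ndarray
    pa_view: np.ndarray
    lesion_mask_ap: np.ndarray
    lesion_mask_pa: np.ndarray
    polarity: str  # "positive" | "negative"
    cohort_tag: str
    seed: int

    @property
    def silhouette_ap(self) -> np.ndarray:
        return silhouette_mask(self.ap_view.shape)

    @property
    def silhouette_pa(self) -> np.ndarray:
        return silhouette_mask(self.pa_view.shape)


def clinical_like_config(
    view_shape: tuple[int, int] = (64, 64), n_lesions: int = 2
) -> PhantomConfig:
    """Phantom settings that land the segmentation task in a clinical-like
    difficulty regime: moderate additive lesion amplitudes that overlap the
    bright skeletal structures, plus bladder and injection-site confounders.
    Used for protocol-comparison experiments, where background interference
    (not raw lesion contrast) is the phenomenon of interest."""
    return PhantomConfig(
        view_shape=view_shape,
        n_lesions=n_lesions,
        lesion_intensity_range=(50.0, 140.0),
        lesion_sigma_frac=(0.03, 0.05),
        artifact_flags=frozenset({"bladder", "injection_site"}),
    )


def silhouette_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean body silhouette for a view of the given shape.

    The silhouette is built from head/neck/torso/arms/pelvis/legs primitives
    in coordinates normalised to the view, spans rows ~[0.05, 0.95]*H, is
    connected, and is symmetric about the vertical midline.
    """
    h, w = shape
    rr = (np.arange(h, dtype=np.float64) / h)[:, None]
    cc = ((np.arange(w, dtype=np.float64) - (w - 1) / 2.0) / w)[None, :]
    ac = np.abs(cc)

    head = ((rr - 0.09) / 0.045) ** 2 + (cc / 0.11) ** 2 <= 1.0
    neck = (rr >= 0.12) & (rr <= 0.17) & (ac <= 0.05)
    shoulder_w = np.where(rr < 0.22, 0.21, 0.16)
    torso = (rr >= 0.16) & (rr <= 0.52) & (ac <= shoulder_w)
    arms = (rr >= 0.18) & (rr <= 0.46) & (ac >= 0.19) & (ac <= 0.26)
    pelvis = (rr >= 0.50) & (rr <= 0.60) & (ac <= 0.19)
    legs = (rr >= 0.58) & (rr <= 0.95) & (ac >= 0.035) & (ac <= 0.16)
    return head | neck | torso | arms | pelvis | legs


def _uptake_map(shape: tuple[int, int], cfg: PhantomConfig) -> np.ndarray:
    """Mean count level per pixel: body base plus skeleton-like structures."""
    h, w = shape
    rr = (np.arange(h, dtype=np.float64) / h)[:, None]
    cc = ((np.arange(w, dtype=np.float64) - (w - 1) / 2.0) / w)[None, :]
    ac = np.abs(cc)
    blo, bhi = cfg.body_intensity_range
    base = np.full(shape, blo + 0.3 * (bhi - blo))

    spine = (ac <= 0.02) & (rr >= 0.14) & (rr <= 0.58)
    skull = ((rr - 0.09) / 0.045) ** 2 + (cc / 0.11) ** 2 <= 1.0
    skull &= ((rr - 0.09) / 0.034) ** 2 + (cc / 0.085) ** 2 >= 1.0
    ribs = np.zeros(shape, dtype=bool)
    for r0 in np.arange(0.20, 0.40, 0.035):
        ribs |= (rr >= r0) & (rr <= r0 + 0.012) & (ac <= 0.14)
    pelvis_rim = (
        (rr >= 0.50)
        & (rr <= 0.60)
        & (ac <= 0.19)
        & (((rr - 0.55) / 0.04) ** 2 + (cc / 0.13) ** 2 >= 1.0)
    )
    shoulders = ((rr - 0.20) / 0.02) ** 2 + ((ac - 0.185) / 0.03) ** 2 <= 1.0
    knees = ((rr - 0.78) / 0.02) ** 2 + ((ac - 0.095) / 0.035) ** 2 <= 1.0

    boost = 0.55 * (bhi - blo)
    for m in (spine, skull, pelvis_rim, shoulders, knees):
        base[m] += boost
    base[ribs] += 0.35 * (bhi - blo)
    return base


def _place_lesions(
    rng: np.random.Generator, cfg: PhantomConfig, body: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (additive lesion image, boolean lesion mask) with exactly
    ``n_lesions`` well-separated connected components inside the torso/pelvis
    region of the silhouette."""
    h, w = body.shape
    img = np.zeros((h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    if cfg.n_lesions == 0:
        return img, mask
    from scipy import ndimage

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    smin, smax = cfg.lesion_sigma_frac
    diag = float(np.hypot(h, w))
    placed = 0
    attempts = 0
    while placed < cfg.n_lesions:
        attempts += 1
        if attempts > 1000:
            raise PhantomConfigError(
                f"could not place {cfg.n_lesions} disjoint lesions in view {body.shape}"
            )
        sig_a = rng.uniform(smin, smax) * diag
        sig_b = sig_a * rng.uniform(0.5, 1.0)  # eccentricity
        theta = rng.uniform(0.0, np.pi)
        r0 = rng.uniform(0.17 * h, 0.58 * h)
        c0 = rng.uniform(0.5 * w - 0.18 * w, 0.5 * w + 0.18 * w)
        ct, st = np.cos(theta), np.sin(theta)
        dr = rows - r0
        dc = cols - c0
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        g = np.exp(-0.5 * ((u / sig_a) ** 2 + (v / sig_b) ** 2))
        supp = g >= 0.45
        if not supp.any():
            continue
        # the whole support must sit inside the silhouette, and stay clear of
        # previously placed lesions so components remain countable
        if (supp & ~body).any():
            continue
        if (ndimage.binary_dilation(supp, iterations=2) & mask).any():
            continue
        amp = rng.uniform(*cfg.lesion_intensity_range)
        img += amp * g
        mask |= supp
        placed += 1
    return img, mask


def _artifact_image(
    rng: np.random.Generator, cfg: PhantomConfig, shape: tuple[int, int]
) -> np.ndarray:
    """Confounding hotspots at anatomically plausible fixed regions."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float64)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    def blob(r0, c0, sig, amp):
        g = np.exp(-0.5 * (((rows - r0) / sig) ** 2 + ((cols - c0) / sig) ** 2))
        return amp * g

    # confounders can be as hot as true lesions (bladder activity, tracer
    # pooled at the injection site)
    if "bladder" in cfg.artifact_flags:
        amp = rng.uniform(*cfg.lesion_intensity_range)
        img += blob(0.585 * h, 0.5 * w, 0.012 * np.hypot(h, w), amp)
    if "injection_site" in cfg.artifact_flags:
        amp = rng.uniform(*cfg.lesion_intensity_range)
        side = rng.choice([-1.0, 1.0])
        img += blob(0.44 * h, 0.5 * w + side * 0.22 * w, 0.008 * np.hypot(h, w), amp)
    return img


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one deterministic two-view phantom.

    The PA view mirrors the AP geometry (the posterior camera sees the body
    flipped left-right) with independent count noise; the two lesion masks
    are mirror images, so each view's mask has exactly ``n_lesions``
    connected components.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # one lesion-geometry stream shared by both views, separate noise streams
    geom_rng = np.random.default_rng(rng.integers(0, 2**31))
    ap_noise_seed = int(rng.integers(0, 2**31))
    pa_noise_seed = int(rng.integers(0, 2**31))

    body = silhouette_mask(config.view_shape)
    uptake = _uptake_map(config.view_shape, config)
    lesion_img, lesion_mask = _place_lesions(geom_rng, config, body)
    artifacts = _artifact_image(geom_rng, config, config.view_shape)
    lam = np.where(body, uptake, config.air_noise_level)

    views = []
    masks = []
    for noise_seed, mirror in ((ap_noise_seed, False), (pa_noise_seed, True)):
        nrng = np.random.default_rng(noise_seed)
        li = lesion_img[:, ::-1] if mirror else lesion_img
        lm = lesion_mask[:, ::-1] if mirror else lesion_mask
        ar = artifacts[:, ::-1] if mirror else artifacts
        view = nrng.poisson(lam).astype(np.float64) + li + np.where(body, ar, 0.0)
        if "motion" in config.artifact_flags:
            h, w = config.view_shape
            r0 = int(0.25 * h)
            band = max(h // 64, 1)
            view[r0 : r0 + band] = np.roll(view[r0 : r0 + band], w // 32, axis=1)
        views.append(np.clip(view, 0, 255).astype(np.uint8))
        masks.append(lm.copy())

    return PhantomSample(
        ap_view=views[0],
        pa_view=views[1],
        lesion_mask_ap=masks[0],
        lesion_mask_pa=masks[1],
        polarity="positive" if config.n_lesions > 0 else "negative",
        cohort_tag=config.cohort_tag,
        seed=config.seed,
    )


def derive_seed(base_seed: int, index: int) -> int:
    """Fixed arithmetic mapping a master seed and sample index to a per-sample
    seed below 2**31."""
    return (base_seed * 1_000_003 + 7919 * index + 17) % (2**31)


def generate_cohort(
    n_positive: int,
    n_negative: int,
    base_seed: int,
    config: PhantomConfig | None = None,
) -> list[PhantomSample]:
    """Generate a deterministic cohort of ``n_positive`` lesion-bearing and
    ``n_negative`` lesion-free phantoms (positives first).

    Each sample gets a distinct seed derived from ``base_seed``; ``config``
    supplies all other settings (its own seed and n_lesions are overridden).
    """
    if n_positive < 0 or n_negative < 0:
        raise PhantomConfigError("cohort sizes must be non-negative")
    base = config if config is not None else PhantomConfig()
    samples: list[PhantomSample] = []
    for i in range(n_positive + n_negative):
        seed = derive_seed(base_seed, i)
        if i < n_positive:
            n_lesions = base.n_lesions if base.n_lesions > 0 else 3
        else:
            n_lesions = 0
        samples.append(
            generate_phantom(replace(base, seed=seed, n_lesions=n_lesions))
        )
    return samples
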