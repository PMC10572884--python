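"""Three-class label construction: air background (BG), non-metastatic body
(NM) and metastasis (M).

Binary lesion annotations only mark M; everything else is lumped into one
background class that mixes air with informative body tissue.  The two NM
extraction routes implemented here split that background:

* Otsu thresholding — the intensity threshold maximizing between-class
  variance separates air from body; body pixels minus the (manually
  annotated) M regions become NM.
* negative mining — a model trained on positive samples only is run over
  lesion-free scans; since no true lesions exist there, every predicted
  metastasis pixel is a false positive and is harvested as NM.  On positive
  samples the annotated M regions are subtracted from the prediction first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BG, NM, M = 0, 1, 2

__all__ = [
    "BG",
    "NM",
    "M",
    "LabelMap",
    "NMMask",
    "otsu_threshold",
    "make_nm_mask_otsu",
    "mine_negative_masks",
    "mine_positive_masks",
    "encode_three_class",
]


class DegenerateHistogramError(ValueError):
    """Otsu threshold undefined: the image has fewer than two intensity levels."""


class LabelConsistencyError(ValueError):
    """NM and M masks overlap or shapes disagree."""


@dataclass(frozen=True)
class NMMask:
    """Binary non-metastatic-tissue mask plus how it was produced."""

    mask: np.ndarray
    method: str  # "otsu" | "negative_mining"
    source_polarity: str = "positive"  # "positive" | "negative"


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class map over {BG, NM, M}."""

    classes: np.ndarray

    def one_hot(self, n_classes: int = 3) -> np.ndarray:
        """(C, H, W) one-hot encoding; channels sum to 1 everywhere."""
        return np.eye(n_classes, dtype=np.float32)[self.classes].transpose(2, 0, 1)

    @staticmethod
    def from_one_hot(one_hot: np.ndarray) -> "LabelMap":
        return LabelMap(classes=np.argmax(one_hot, axis=0).astype(np.uint8))


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin integer histogram.

    Returns the smallest integer ``t`` in [0, 255) maximizing the
    between-class variance of the split ``{x <= t}`` vs ``{x > t}``.
    Computed with cumulative moments (exact, not iterative).
    """
    img = np.clip(np.asarray(image), 0, 255).astype(np.int64)
    if np.unique(img).size < 2:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)              # P(x <= t)
    mu = np.cumsum(p * np.arange(256))  # first moment up to t
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    return int(np.argmax(sigma_b))  # argmax takes the smallest maximizer


def make_nm_mask_otsu(image: np.ndarray, m_mask: np.ndarray) -> NMMask:
    """NM = body pixels (above the Otsu threshold) minus annotated M pixels."""
    image = np.asarray(image)
    m_mask = np.asarray(m_mask, dtype=bool)
    if image.shape != m_mask.shape:
        raise LabelConsistencyError(
            f"shape mismatch: image {image.shape}, M mask {m_mask.shape}"
        )
    t = otsu_threshold(image)
    body = image > t
    return NMMask(
        mask=body & ~m_mask,
        method="otsu",
        source_polarity="positive" if m_mask.any() else "negative",
    )


def _predicted_m(model, image: np.ndarray, m_class: int | None) -> np.ndarray:
    from .network import predict  # local import to avoid a cycle

    pred = predict(model, image)
    cls = m_class if m_class is not None else pred.probabilities.shape[0] - 1
    return pred.argmax_classes == cls


def mine_negative_masks(
    model, negatives: list[np.ndarray], m_class: int | None = None
) -> list[NMMask]:
    """Harvest a positives-only model's false positives on lesion-free images.

    ``model`` must expose the network ``forward`` contract (see
    :mod:`scintiseg.network`); the predicted-metastasis class defaults to the
    model's last channel.  Every predicted-M pixel on a negative sample is a
    false positive by construction and becomes NM.
    """
    return [
        NMMask(
            mask=_predicted_m(model, img, m_class),
            method="negative_mining",
            source_polarity="negative",
        )
        for img in negatives
    ]


def mine_positive_masks(
    model,
    positives: list[np.ndarray],
    m_masks: list[np.ndarray],
    m_class: int | None = None,
) -> list[NMMask]:
    """As :func:`mine_negative_masks` but on positive samples: the annotated
    M regions are excluded from the harvested prediction."""
    out = []
    for img, m in zip(positives, m_masks):
        pred = _predicted_m(model, img, m_class)
        out.append(
            NMMask(
                mask=pred & ~np.asarray(m, dtype=bool),
                method="negative_mining",
                source_polarity="positive",
            )
        )
    return out


def encode_three_class(nm: NMMask | np.ndarray, m_mask: np.ndarray) -> LabelMap:
    """Combine disjoint NM and M masks into a single BG/NM/M class map."""
    nm_arr = np.asarray(nm.mask if isinstance(nm, NMMask) else nm, dtype=bool)
    m_arr = np.asarray(m_mask, dtype=bool)
    if nm_arr.shape != m_arr.shape:
        raise LabelConsistencyError(
            f"shape mismatch: NM {nm_arr.shape}, M {m_arr.shape}"
        )
    if (nm_arr & m_arr).any():
        raise LabelConsistencyError("NM and M masks overlap")
    classes = np.zeros(nm_arr.shape, dtype=np.uint8)
    classes[nm_arr] = NM
    classes[m_arr] = M
    return LabelMap(classes=classes)
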