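"""Scratch-assay (wound-healing) quantification from grayscale micrographs.

The confluent cell monolayer is highly textured while the cell-free
scratch is smooth, so local Shannon entropy separates the two: entropy is
computed per pixel over a disk neighborhood, an Otsu threshold on the
entropy map splits textured from smooth, and the pixel count A below the
threshold is the open-wound proxy. The open-wound percentage of timepoint
t is 100 * A_t / A_0 with A_0 from the first (t0) image; it is 100 at t0
by construction and is not clamped (a widening wound exceeds 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk


@dataclass
class WoundMeasurement:
    timepoint: str
    entropy_map: np.ndarray  # bits per pixel
    threshold_bits: float
    area_px: int
    open_wound_pct: float


def entropy_map(img: np.ndarray, radius: int = 5) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the intensity histogram in a
    disk of the given radius, mirror-padded at the borders.

    The image must be 2-D with intensities on the 8-bit scale [0, 255];
    RGB input should be converted to luma first (:func:`to_grayscale`).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("entropy_map expects a 2-D grayscale image")
    if min(img.shape) < 2 * (2 * radius + 1):
        raise ValueError(f"image {img.shape} smaller than 2x the entropy footprint")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    padded = np.pad(np.ascontiguousarray(img, dtype=np.uint8), radius, mode="reflect")
    ent = _rank_entropy(padded, disk(radius))
    return ent[radius:-radius, radius:-radius].astype(float)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma conversion for RGB(A) input; pass-through for 2-D arrays."""
    if img.ndim == 2:
        return img
    rgb = img[..., :3].astype(float)
    return np.clip(rgb @ np.array([0.2126, 0.7152, 0.0722]), 0, 255)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold on a value map: 256-bin histogram over [min, max],
    returning the bin edge that maximizes the between-class variance
    (lowest qualifying edge on ties)."""
    v = np.asarray(values, float).ravel()
    if np.unique(v).size < 2:
        raise ValueError("constant map: Otsu threshold undefined")
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_tot = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_tot * w0 - mu) ** 2 / (w0 * w1)
    between = np.nan_to_num(between[:-1], nan=-np.inf)
    best = int(np.argmax(between))  # argmax takes the first (lowest) maximizer
    return float(edges[best + 1])


def quantify_series(
    images: list[np.ndarray],
    radius: int = 5,
    threshold_mode: str = "per_image",
    timepoints: list[str] | None = None,
) -> list[WoundMeasurement]:
    """Quantify an ordered scratch-assay image series (first image = t0).

    ``threshold_mode='per_image'`` recomputes the Otsu threshold on each
    timepoint's entropy map; ``'t0_fixed'`` reuses the t0 threshold for
    the whole series. A is the count of pixels with entropy strictly below
    the threshold.
    """
    if not images:
        raise ValueError("empty image series")
    if threshold_mode not in {"per_image", "t0_fixed"}:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    shape0 = np.asarray(images[0]).shape
    if any(np.asarray(im).shape != shape0 for im in images):
        raise ValueError("images in a series must share dimensions")
    if timepoints is None:
        timepoints = [f"t{i}" for i in range(len(images))]

    out: list[WoundMeasurement] = []
    thr0: float | None = None
    a0: int | None = None
    for label, img in zip(timepoints, images):
        ent = entropy_map(to_grayscale(np.asarray(img)), radius)
        if threshold_mode == "per_image" or thr0 is None:
            thr = otsu_threshold(ent)
            if thr0 is None:
                thr0 = thr
        if threshold_mode == "t0_fixed":
            thr = thr0
        area = int(np.sum(ent < thr))
        if a0 is None:
            if area == 0:
                raise ValueError("no open wound detectable at t0 (A_0 = 0)")
            a0 = area
        out.append(WoundMeasurement(label, ent, thr, area, 100.0 * area / a0))
    return out
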