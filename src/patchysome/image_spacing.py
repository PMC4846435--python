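"""Domain-spacing measurement on projection images.

Reproduces the micrograph analysis procedure: segment the domains,
store each domain's center of mass, compute all pairwise Euclidean
distances, keep only each point's shortest distance, convert pixels to
nm, and report the mean and (sample) SD of those minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .domain_analysis import InsufficientPointsError
from .synthetic_tem import ProjectionImage

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), int)


@dataclass
class DomainCenters:
    points: np.ndarray   # (n, 2) pixel coordinates as (row, col)
    px_to_nm: float

    def __post_init__(self):
        if self.px_to_nm <= 0:
            raise ValueError("px_to_nm must be positive")

    @property
    def n_domains(self) -> int:
        return len(self.points)


def segment_domains(image: ProjectionImage, threshold: float | None = None,
                    polarity: str = "light", min_area: int = 1):
    """Label connected domain regions (8-connectivity).

    ``polarity='light'`` selects pixels above the threshold (unstained
    domains on a dark matrix), ``'dark'`` selects below.  Without a
    threshold, Otsu's method on the image histogram is used.  Regions
    smaller than ``min_area`` pixels are dropped.  Returns ``(labels,
    n_regions)`` with labels relabelled 1..n.
    """
    pix = image.pixels.astype(float)
    if threshold is None:
        threshold = float(threshold_otsu(image.pixels))
    if polarity == "light":
        mask = pix > threshold
    elif polarity == "dark":
        mask = pix < threshold
    else:
        raise ValueError("polarity must be 'light' or 'dark'")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if min_area > 1 and n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area) + 1
        remap = np.zeros(n + 1, labels.dtype)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
        n = len(keep)
    if n == 0:
        logger.warning("no domain regions found (threshold %.1f)", threshold)
    return labels, n


def region_centers(image: ProjectionImage, labels: np.ndarray, n_regions: int,
                   polarity: str = "light") -> DomainCenters:
    """Intensity-weighted centroid of each labeled region (pixel coords).

    Weights are the deviation from the background gray on the domain
    side, so brighter (or darker) pixels pull the center harder, which
    is the image analog of a center of mass.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    pix = image.pixels.astype(float)
    weights = pix if polarity == "light" else (255.0 - pix)
    centers = ndimage.center_of_mass(weights, labels,
                                     index=np.arange(1, n_regions + 1))
    return DomainCenters(points=np.asarray(centers, float),
                         px_to_nm=image.px_size)


def spacing_from_centers(centers: DomainCenters) -> tuple[float, float]:
    """Per-point shortest-distance statistic in nm: (mean, sample SD)."""
    pts = centers.points
    if len(pts) < 2:
        raise InsufficientPointsError("need at least 2 domain centers")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    np.fill_diagonal(dist, np.inf)
    minima = dist.min(axis=1) * centers.px_to_nm
    return float(minima.mean()), float(minima.std(ddof=1))


def measure_image_spacing(image: ProjectionImage, threshold: float | None = None,
                          polarity: str = "light", min_area: int = 2) -> dict:
    """Full pipeline: segment -> centers -> spacing; returns a summary dict."""
    labels, n = segment_domains(image, threshold, polarity, min_area)
    if n < 2:
        raise InsufficientPointsError(
            f"only {n} domain(s) segmented; cannot measure spacing")
    centers = region_centers(image, labels, n, polarity)
    mean_nm, sd_nm = spacing_from_centers(centers)
    return {"n_domains": n, "mean_nm": mean_nm, "sd_nm": sd_nm,
            "px_size": image.px_size}
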