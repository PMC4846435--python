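"""Synthetic projection images emulating negatively stained micrographs.

In PTA-stained transmission images of these polymersomes the PMPC-rich
matrix takes up stain and appears dark while PEO-rich domains stay
light.  Because the vesicle is imaged in transmission, features from
the top and bottom hemispheres superimpose; the renderer therefore
projects *all* beads orthographically along one axis, exactly as the
"see-through" rendering of the simulated polymersomes.

The generator side produces planar point patterns with analytically
known nearest-neighbor spacing (hexagonal lattices, jittered lattices,
Poisson-disk samples) that serve as ground truth for the image-analysis
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .params import KIND_PMPC
from .sphere_init import SurfaceConfiguration

BACKGROUND_GRAY = 128.0
STAIN_AMPLITUDE = 80.0


@dataclass
class ProjectionImage:
    """8-bit grayscale raster with pixel calibration and stain polarity."""

    pixels: np.ndarray              # (H, W) uint8; origin top-left, y down
    px_size: float                  # nm / pixel
    stain_polarity: str = "PMPC_dark"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.px_size <= 0:
            raise ValueError("px_size must be positive")
        if min(self.pixels.shape) < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if self.stain_polarity not in ("PMPC_dark", "PMPC_light"):
            raise ValueError("unknown stain polarity")

    @property
    def shape(self):
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        iio.imwrite(str(path), self.pixels)

    @classmethod
    def load(cls, path: str | Path, px_size: float,
             stain_polarity: str = "PMPC_dark") -> "ProjectionImage":
        arr = np.asarray(iio.imread(str(path)))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return cls(pixels=arr.astype(np.uint8), px_size=px_size,
                   stain_polarity=stain_polarity)


def generate_point_pattern(kind: str, spacing: float, jitter: float,
                           extent: tuple[float, float], seed: int = 0
                           ) -> np.ndarray:
    """2D point patterns with known nearest-neighbor statistics.

    ``hexagonal``: triangular lattice with lattice constant ``spacing``
    (nearest-neighbor distance exactly ``spacing`` at zero jitter);
    ``jittered_hex``: the same lattice plus isotropic Gaussian
    displacements with standard deviation ``jitter``;
    ``poisson_disk``: dart-throwing sample whose per-point nearest
    neighbor distance is at least ``spacing``.

    Coordinates are in nm within ``[0, extent[0]] x [0, extent[1]]``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    w, h = extent
    rng = np.random.default_rng(seed)
    if kind in ("hexagonal", "jittered_hex"):
        dy = spacing * np.sqrt(3.0) / 2.0
        rows = int(h // dy) + 1
        cols = int(w // spacing) + 1
        pts = []
        for r in range(rows):
            x0 = 0.5 * spacing if r % 2 else 0.0
            for c in range(cols):
                x = x0 + c * spacing
                y = r * dy
                if x <= w and y <= h:
                    pts.append((x, y))
        pts = np.array(pts)
        if kind == "jittered_hex" and jitter > 0:
            pts = pts + rng.normal(0.0, jitter, pts.shape)
    elif kind == "poisson_disk":
        # dart throwing; spacing acts as the exclusion radius
        target = int(0.6 * (w * h) / (np.pi * (spacing / 2) ** 2))
        pts = []
        tree_pts = np.empty((0, 2))
        for _ in range(200 * max(target, 1)):
            cand = rng.uniform((0, 0), (w, h))
            if len(pts) == 0:
                pts.append(cand)
            else:
                tree = cKDTree(np.array(pts))
                if tree.query(cand, k=1)[0] >= spacing:
                    pts.append(cand)
            if len(pts) >= target:
                break
        pts = np.array(pts)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if len(pts) < 2:
        raise ValueError("extent too small to hold at least 2 points")
    return pts


def write_fixture_set(out_dir, specs, px_size: float = 0.5,
                      noise_sd: float = 8.0, extent=(80.0, 80.0)):
    """Render a batch of point-pattern fixtures and a manifest CSV.

    ``specs`` is an iterable of ``(kind, spacing, jitter, seed)`` tuples;
    each becomes ``fixture_<i>.png`` plus a row in ``manifest.csv``
    recording seed, kind, spacing, jitter and pixel size.
    """
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (kind, spacing, jitter, seed) in enumerate(specs):
        pts = generate_point_pattern(kind, spacing, jitter, extent, seed)
        img = render_projection(pts, px_size=px_size, noise_sd=noise_sd,
                                seed=seed, extent=extent)
        name = f"fixture_{i:03d}.png"
        img.save(out / name)
        rows.append({"file": name, "seed": seed, "kind": kind,
                     "spacing_nm": spacing, "jitter_nm": jitter,
                     "px_size_nm": px_size, "n_points": len(pts)})
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return rows


def render_projection(source, px_size: float, blur_sigma: float = 0.15,
                      noise_sd: float = 8.0, polarity: str = "PMPC_dark",
                      seed: int = 0, extent: tuple[float, float] | None = None,
                      length_scale: float = 1.0) -> ProjectionImage:
    """Render beads or 2D points into a synthetic stained projection.

    ``source`` is either a SurfaceConfiguration (orthographic projection
    of all beads along z, both hemispheres superimposed; PMPC beads get
    the stain-side amplitude, PEO beads the opposite) or an (m, 2) array
    of planar points rendered as light domains on the stained matrix.

    Each point contributes a Gaussian footprint of width ``blur_sigma``
    (nm).  Pixel noise is additive Gaussian, deterministic per ``seed``.
    ``length_scale`` multiplies input coordinates first (use 10 to
    render simulation output at physical scale).
    """
    dark = -STAIN_AMPLITUDE if polarity == "PMPC_dark" else STAIN_AMPLITUDE
    light = -dark
    if isinstance(source, SurfaceConfiguration):
        xy = source.positions[:, :2] * length_scale
        amp = np.where(source.kinds() == KIND_PMPC, dark, light)
        r = source.radius * length_scale
        xy = xy + r  # shift to positive quadrant
        if extent is None:
            extent = (2 * r, 2 * r)
    else:
        xy = np.asarray(source, float) * length_scale
        amp = np.full(len(xy), light)
        if extent is None:
            if len(xy) == 0:
                raise ValueError("empty point input needs an explicit extent")
            extent = (xy[:, 0].max() + 2, xy[:, 1].max() + 2)
    w_px = max(16, int(np.ceil(extent[0] / px_size)))
    h_px = max(16, int(np.ceil(extent[1] / px_size)))
    canvas = np.zeros((h_px, w_px))
    sigma_px = max(blur_sigma / px_size, 1e-6)
    if len(xy):
        # bilinear splat then Gaussian blur; weight chosen so an isolated
        # point's peak equals its amplitude after the blur
        weight = amp * 2.0 * np.pi * sigma_px**2
        col = xy[:, 0] / px_size
        row = xy[:, 1] / px_size
        c0 = np.floor(col).astype(int)
        r0 = np.floor(row).astype(int)
        fc = col - c0
        fr = row - r0
        for dr_, dc_, wgt in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                              (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            rr = r0 + dr_
            cc = c0 + dc_
            ok = (rr >= 0) & (rr < h_px) & (cc >= 0) & (cc < w_px)
            np.add.at(canvas, (rr[ok], cc[ok]), weight[ok] * wgt[ok])
        canvas = ndimage.gaussian_filter(canvas, sigma_px)
    img = BACKGROUND_GRAY + canvas
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if len(xy) >= 2:
        tree = cKDTree(xy)
        min_nn = tree.query(xy, k=2)[0][:, 1].min()
        if px_size > min_nn:
            import logging
            logging.getLogger(__name__).warning(
                "pixel size %.3g nm does not resolve the pattern spacing %.3g nm",
                px_size, min_nn)
    return ProjectionImage(
        pixels=pixels, px_size=px_size, stain_polarity=polarity,
        provenance={"seed": seed, "blur_sigma": blur_sigma,
                    "noise_sd": noise_sd, "n_points": int(len(xy))})
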