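"""Cisternal substructure metrics: radial lumen profiles and per-cisterna
grey-level co-occurrence (GLCM) texture properties.

The GLCM here is a masked, disc-pooled accumulator: for every ordered pixel
pair (p, q) with both pixels inside one cisterna mask and
0 < ||p - q|| <= neighbourhood radius, the pair of quantised grey levels is
counted.  All offsets within the disc are pooled into a single matrix; the
radius is set to the apparent width of a single tubule so the texture probes
structure at the tubule scale (nanoholes, matrix pitch) rather than shot
noise or large-scale shading.  Per-cisterna properties are pooled across an
image weighted by pixel count, so many small cisternae cannot dominate, and
any per-image average requires at least five cisternae.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .er_segment import ERNetworkSegmentation

#: minimum cisternae per image before any averaged/pooled result is issued
MIN_CISTERNAE = 5


class InsufficientCisternaeError(ValueError):
    """Fewer cisternae in the image than the per-image minimum."""

    def __init__(self, count: int, minimum: int = MIN_CISTERNAE):
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"only {count} cisternae in image; {minimum} required")


# ---------------------------------------------------------------------------
# Radial binning
# ---------------------------------------------------------------------------

def radial_bin_map(cisterna_mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each cisterna pixel a radial bin: 0 at the edge rising to
    n_bins-1 at the centre.

    bin = floor(n_bins * d / d_max) clipped to n_bins-1, where d is the
    Euclidean distance to the nearest background pixel and d_max the
    maximum distance inside this cisterna.  Pixels outside the mask get -1.
    """
    mask = np.asarray(cisterna_mask, dtype=bool)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not mask.any():
        raise ValueError("empty cisterna mask")
    if mask.sum() == 1:
        warnings.warn("single-pixel cisterna: degenerate radial binning",
                      stacklevel=2)
    d = ndi.distance_transform_edt(mask)
    d_max = d.max()
    bins = np.full(mask.shape, -1, dtype=np.int32)
    bins[mask] = np.minimum((n_bins * d[mask] / d_max).astype(np.int32),
                            n_bins - 1)
    return bins


@dataclass
class RadialProfile:
    """Mean radial intensity profile averaged over cisternae.

    bin 0 is the cisterna edge, the last bin the centre; ``sd`` is the
    spread across cisternae per bin.
    """

    n_bins: int
    mean_intensity: np.ndarray
    sd: np.ndarray
    n_cisternae: int
    edge_marker_bin: int = 0

    @property
    def bin_axis(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


def radial_intensity_profile(image: np.ndarray,
                             segmentation: ERNetworkSegmentation,
                             n_bins: int = 10) -> RadialProfile:
    """Per-cisterna radial bin means, averaged unweighted across cisternae.

    Raises InsufficientCisternaeError when the image holds fewer than
    MIN_CISTERNAE cisternae, so that no unrepresentative profile is ever
    averaged into a group result.
    """
    image = np.asarray(image, dtype=float)
    ids = segmentation.cisterna_ids
    if len(ids) < MIN_CISTERNAE:
        raise InsufficientCisternaeError(len(ids))
    per = np.full((len(ids), n_bins), np.nan)
    for row, cid in enumerate(ids):
        mask = segmentation.cisterna_mask(int(cid))
        bins = radial_bin_map(mask, n_bins)
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                per[row, b] = image[sel].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per, axis=0)
        sd = np.nanstd(per, axis=0, ddof=1)
    return RadialProfile(n_bins=n_bins, mean_intensity=mean, sd=sd,
                         n_cisternae=len(ids))


# ---------------------------------------------------------------------------
# GLCM accumulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMSpec:
    """Neighbourhood and quantisation of the co-occurrence accumulator."""

    neighbourhood_radius_px: float = 3.0
    n_levels: int = 8
    symmetric: bool = True

    def __post_init__(self):
        if self.neighbourhood_radius_px < 1:
            raise ValueError("neighbourhood_radius_px must be >= 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def disc_offsets(radius: float) -> list:
    """All half-plane integer offsets with 0 < ||(dr, dc)|| <= radius.

    The half-plane (dr > 0, or dr == 0 and dc > 0) enumerates every
    unordered pixel pair exactly once; the symmetric accumulator adds the
    transpose, which is equivalent to counting both orderings.
    """
    r = int(np.floor(radius))
    out = []
    for dr in range(0, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc <= 0:
                continue
            if dr * dr + dc * dc <= radius * radius:
                out.append((dr, dc))
    return out


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantise intensities over the mask's own min-max range into
    n_levels grey levels (constant regions map to level 0)."""
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.int32)
    if hi > lo:
        q[mask] = np.minimum(((image[mask] - lo) / (hi - lo)
                              * n_levels).astype(np.int32), n_levels - 1)
    return q


def glcm_of_cisterna(image: np.ndarray, cisterna_mask: np.ndarray,
                     spec: GLCMSpec = GLCMSpec()) -> np.ndarray:
    """Normalised co-occurrence matrix of one cisterna.

    Counts quantised grey-level pairs over all pixel pairs with both pixels
    in the mask and separation within the neighbourhood disc, pooling every
    offset into one matrix; normalised so the entries sum to 1.
    """
    mask = np.asarray(cisterna_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("cisterna mask must contain at least 2 pixels")
    q = quantize(image, mask, spec.n_levels)
    glcm = np.zeros((spec.n_levels, spec.n_levels), dtype=float)
    for dr, dc in disc_offsets(spec.neighbourhood_radius_px):
        a = mask[max(dr, 0):mask.shape[0] - max(-dr, 0),
                 max(dc, 0):mask.shape[1] - max(-dc, 0)]
        b = mask[max(-dr, 0):mask.shape[0] - max(dr, 0),
                 max(-dc, 0):mask.shape[1] - max(dc, 0)]
        both = a & b
        qa = q[max(dr, 0):q.shape[0] - max(-dr, 0),
               max(dc, 0):q.shape[1] - max(-dc, 0)][both]
        qb = q[max(-dr, 0):q.shape[0] - max(dr, 0),
               max(-dc, 0):q.shape[1] - max(dc, 0)][both]
        np.add.at(glcm, (qa, qb), 1.0)
    if spec.symmetric:
        glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        raise ValueError("no pixel pairs within the neighbourhood radius")
    return glcm / total


@dataclass(frozen=True)
class GLCMProperties:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    correlation_degenerate: bool = False

    def as_dict(self) -> dict:
        return {"contrast": self.contrast, "correlation": self.correlation,
                "energy": self.energy, "homogeneity": self.homogeneity}


def glcm_properties(glcm: np.ndarray) -> GLCMProperties:
    """The four scalar texture properties of a normalised GLCM.

    contrast    = sum (i-j)^2 p(i,j)          (0 for a constant image)
    correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j)
                  (0, flagged, when either marginal is degenerate)
    energy      = sum p^2                      (1 for a constant image)
    homogeneity = sum p / (1 + |i-j|)          (1 for a diagonal GLCM)
    """
    glcm = np.asarray(glcm, dtype=float)
    if glcm.ndim != 2 or glcm.shape[0] != glcm.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(glcm.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalised to sum 1")
    n = glcm.shape[0]
    i = np.arange(n)[:, None] * np.ones((1, n))
    j = np.ones((n, 1)) * np.arange(n)[None, :]
    contrast = float(((i - j) ** 2 * glcm).sum())
    energy = float((glcm ** 2).sum())
    homogeneity = float((glcm / (1.0 + np.abs(i - j))).sum())
    pi = glcm.sum(axis=1)
    pj = glcm.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        return GLCMProperties(contrast, 0.0, energy, homogeneity,
                              correlation_degenerate=True)
    corr = float((((i - mu_i) * (j - mu_j) * glcm).sum())
                 / np.sqrt(var_i * var_j))
    return GLCMProperties(contrast, corr, energy, homogeneity)


PROPERTY_NAMES = ("contrast", "correlation", "energy", "homogeneity")


def per_cisterna_properties(image: np.ndarray,
                            segmentation: ERNetworkSegmentation,
                            spec: GLCMSpec = GLCMSpec()) -> pd.DataFrame:
    """Tidy table of the four GLCM properties for every cisterna."""
    rows = []
    for cid in segmentation.cisterna_ids:
        mask = segmentation.cisterna_mask(int(cid))
        props = glcm_properties(glcm_of_cisterna(image, mask, spec))
        rows.append({"cisterna_id": int(cid), "area_px": int(mask.sum()),
                     **props.as_dict(),
                     "correlation_degenerate": props.correlation_degenerate})
    return pd.DataFrame(rows)


def pool_properties(per_cisterna: pd.DataFrame) -> dict:
    """Pixel-weighted pooled properties over all cisternae of one image.

    pooled = sum(area_i * prop_i) / sum(area_i) for each property, so the
    network total is weighted by cisternae pixels rather than dominated by
    many small cisternae.  Requires at least MIN_CISTERNAE rows.
    """
    n = len(per_cisterna)
    if n < MIN_CISTERNAE:
        raise InsufficientCisternaeError(n)
    w = per_cisterna["area_px"].to_numpy(dtype=float)
    pooled = {}
    for prop in PROPERTY_NAMES:
        v = per_cisterna[prop].to_numpy(dtype=float)
        pooled[prop] = float((w * v).sum() / w.sum())
    pooled["n_cisternae"] = n
    pooled["total_area_px"] = float(w.sum())
    return pooled


@dataclass
class GLCMSummary:
    """Per-image texture summary: per-cisterna table + pooled values."""

    per_cisterna: pd.DataFrame
    pooled: dict
    image_id: str | None = None
    condition: str | None = None
    spec: GLCMSpec = field(default_factory=GLCMSpec)


def summarize_image(image: np.ndarray, segmentation: ERNetworkSegmentation,
                    spec: GLCMSpec = GLCMSpec(), image_id: str | None = None,
                    condition: str | None = None) -> GLCMSummary:
    per = per_cisterna_properties(image, segmentation, spec)
    return GLCMSummary(per_cisterna=per, pooled=pool_properties(per),
                       image_id=image_id, condition=condition, spec=spec)
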