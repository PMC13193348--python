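"""Synthetic fluorescence-microscopy phantoms with exact ground truth.

Generates the four scene families used to validate the analysis stages:

* cortical ER networks — tubules (~40 nm diameter) meeting at three-way
  junctions, decorated with cisternae whose lumen is either a uniform sac,
  a sac punctured by nanoholes, or a dense tubular matrix whose compressed
  centre excludes lumenal marker;
* Golgi-stack edge traces with known curvature and width profiles;
* 405/488 excitation-ratio image pairs with a known true ratio;
* whole-cell scenes with a known Golgi intensity fraction and a known
  apoplast/interior secretion ratio.

Geometry is continuous, in nanometres, with the origin at the centre of the
top-left pixel; rasterisation samples pixel (or sub-pixel) centres.  The
imaging model is: emission map -> isotropic Gaussian PSF (parameterised by
FWHM) -> photon scaling -> Poisson shot noise -> additive Gaussian read
noise + constant background.  Identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default lateral pixel pitch (nm); the acquisition this emulates reports a
#: pixel scaling of 0.046 um (configurable, see :func:`pixel_size_from_scaling`)
DEFAULT_PIXEL_SIZE_NM = 46.0
#: confocal PSF FWHM (nm) assumed throughout
DEFAULT_PSF_FWHM_NM = 140.0
#: ER tubule diameter (nm)
DEFAULT_TUBULE_DIAMETER_NM = 40.0


class PlacementError(RuntimeError):
    """Raised when requested geometry cannot be placed inside the region."""


def pixel_size_from_scaling(value_um: float, interpret: str = "lateral") -> float:
    """Convert a reported pixel scaling to a lateral pixel size in nm.

    Microscope metadata sometimes reports pixel scaling with ambiguous units
    (lateral pitch in um vs pixel area in um^2).  ``interpret="lateral"``
    treats the value as the pitch; ``interpret="area"`` as the pixel area.
    """
    if value_um <= 0:
        raise ValueError("pixel scaling must be positive")
    if interpret == "lateral":
        return value_um * 1000.0
    if interpret == "area":
        return math.sqrt(value_um) * 1000.0
    raise ValueError(f"unknown interpretation {interpret!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Imaging parameters shared by all phantom renderers.

    photon_scale is the expected photon count at unit emission; it may be
    ``inf`` for a noiseless render.  read_noise_sd and background_level are
    in detector counts.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    psf_fwhm_nm: float = DEFAULT_PSF_FWHM_NM
    photon_scale: float = 200.0
    read_noise_sd: float = 2.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_fwhm_nm < 0:
            raise ValueError("psf_fwhm_nm must be >= 0")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape entries must be > 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm * FWHM_TO_SIGMA / self.pixel_size_nm

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(height, width) of the field of view in nm."""
        r, c = self.image_shape
        return (r * self.pixel_size_nm, c * self.pixel_size_nm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass
class Cisterna:
    """One cisterna region with its lumen substructure."""

    polygon: Polygon
    substructure: str  # sac | sac_nanoholes | tubular_matrix
    params: dict = field(default_factory=dict)


@dataclass
class ERPhantomLayout:
    """Continuous-geometry description of an ER scene (nm coordinates)."""

    segments: list  # list of ((x0, y0), (x1, y1)) tubule segments
    tubule_diameter_nm: float = DEFAULT_TUBULE_DIAMETER_NM
    cisternae: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def node_degrees(self) -> dict:
        """Census of node degrees in the skeleton graph (exact coordinates)."""
        deg: dict = {}
        for a, b in self.segments:
            for p in (tuple(a), tuple(b)):
                deg[p] = deg.get(p, 0) + 1
        return deg

    def n_junctions(self) -> int:
        return sum(1 for d in self.node_degrees().values() if d == 3)


@dataclass
class GroundTruth:
    """Per-pixel truth accompanying a rendered phantom."""

    label_map: np.ndarray | None = None  # 0 bg, 1 tubule, >=2 cisterna ids
    lumen_occupancy: np.ndarray | None = None  # in [0, 1]
    true_params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass
class MultiChannelImage:
    """2D multi-channel image with physical pixel size and channel names."""

    data: np.ndarray  # (C, H, W)
    channels: list
    pixel_size_nm: float
    meta: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def write_tiff(self, path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with the metadata."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32))
        sidecar = {
            "channels": list(self.channels),
            "pixel_size_nm": self.pixel_size_nm,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tiff(cls, path) -> "MultiChannelImage":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            return cls(data, info["channels"], info["pixel_size_nm"],
                       info.get("meta", {}))
        return cls(data, [f"ch{i}" for i in range(len(data))], float("nan"))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# ER network skeleton
# ---------------------------------------------------------------------------

def _random_point_in(polygon: Polygon, rng, max_tries: int = 2000):
    minx, miny, maxx, maxy = polygon.bounds
    for _ in range(max_tries):
        p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if polygon.covers(Point(p)):
            return p
    raise PlacementError("could not place a point inside the region")


def full_frame_region(spec: PhantomSpec, margin_nm: float | None = None) -> Polygon:
    """Rectangle covering the field of view, inset by ``margin_nm``."""
    h, w = spec.extent_nm
    m = 2 * spec.pixel_size_nm if margin_nm is None else margin_nm
    return Polygon([(m, m), (w - m, m), (w - m, h - m), (m, h - m)])


def make_tubule_network(spec: PhantomSpec, n_junctions: int,
                        region: Polygon | None = None,
                        tubule_diameter_nm: float = DEFAULT_TUBULE_DIAMETER_NM,
                        rng=None) -> ERPhantomLayout:
    """Grow a connected tubule skeleton with exactly ``n_junctions``
    three-way junctions inside ``region``.

    The skeleton starts as a single open segment; each junction is created by
    branching from an interior point of an existing segment to a fresh
    endpoint, so every internal node has degree 3 by construction.
    """
    if n_junctions < 0:
        raise ValueError("n_junctions must be >= 0")
    region = full_frame_region(spec) if region is None else region
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    span = math.hypot(*(np.subtract(region.bounds[2:], region.bounds[:2])))
    min_sep = min(0.25 * span, 8 * tubule_diameter_nm)
    if span < 4 * tubule_diameter_nm:
        raise PlacementError("region too small for a tubule network")

    for _ in range(200):
        a = _random_point_in(region, rng)
        b = _random_point_in(region, rng)
        if math.dist(a, b) >= min_sep:
            break
    else:
        raise PlacementError("region too small to place the seed tubule")
    segments = [(a, b)]

    for _ in range(n_junctions):
        for _attempt in range(500):
            lengths = np.array([math.dist(p, q) for p, q in segments])
            i = int(rng.choice(len(segments), p=lengths / lengths.sum()))
            p, q = segments[i]
            t = rng.uniform(0.25, 0.75)
            branch_pt = (p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1]))
            tip = _random_point_in(region, rng)
            if math.dist(branch_pt, tip) < 0.15 * min_sep:
                continue
            segments[i] = (p, branch_pt)
            segments.append((branch_pt, q))
            segments.append((branch_pt, tip))
            break
        else:
            raise PlacementError(
                f"could not place junction inside region (placed "
                f"{ERPhantomLayout(segments).n_junctions()} of {n_junctions})")

    return ERPhantomLayout(segments=segments,
                           tubule_diameter_nm=tubule_diameter_nm)


# ---------------------------------------------------------------------------
# Cisternae and their lumen substructure
# ---------------------------------------------------------------------------

_SUBSTRUCTURES = ("sac", "sac_nanoholes", "tubular_matrix")


def add_cisterna(layout: ERPhantomLayout, substructure: str,
                 params: dict) -> ERPhantomLayout:
    """Return a copy of ``layout`` with one more cisterna.

    ``params`` must contain ``polygon`` (shapely Polygon or vertex list, nm).
    Substructure-specific keys:

    * ``sac`` — none; lumen occupancy 1 across the region.
    * ``sac_nanoholes`` — ``hole_radius_nm``, plus either explicit
      ``hole_centers`` or ``hole_density_per_um2`` and ``seed``; occupancy 0
      inside each circular hole.  If merged holes cover more than half the
      region a warning is recorded on the layout (it is not an error).
    * ``tubular_matrix`` — packed parallel internal tubule stripes
      (``spacing_nm`` default 2x tubule diameter, stripe width = tubule
      diameter) and a continuous ``edge_band_nm`` of full occupancy along
      the region boundary; elsewhere occupancy is capped at ``floor``.
    """
    if substructure not in _SUBSTRUCTURES:
        raise ValueError(f"unknown substructure {substructure!r}")
    params = dict(params)
    poly = params.pop("polygon")
    if not isinstance(poly, Polygon):
        poly = Polygon(poly)
    if not poly.is_valid or poly.is_empty:
        raise ValueError("cisterna polygon must be simple and non-empty")

    new = ERPhantomLayout(
        segments=list(layout.segments),
        tubule_diameter_nm=layout.tubule_diameter_nm,
        cisternae=list(layout.cisternae),
        warnings=list(layout.warnings),
    )

    if substructure == "sac_nanoholes":
        r = float(params["hole_radius_nm"])
        if r <= 0:
            raise ValueError("hole_radius_nm must be > 0")
        if "hole_centers" not in params:
            density = float(params["hole_density_per_um2"])
            rng = np.random.default_rng(params.get("seed", 0))
            area_um2 = poly.area / 1e6
            n_holes = int(round(density * area_um2))
            centers = [_random_point_in(poly, rng) for _ in range(n_holes)]
            params["hole_centers"] = centers
        centers = params["hole_centers"]
        if centers:
            holes = shapely.unary_union(
                [Point(c).buffer(r, quad_segs=8) for c in centers])
            frac = holes.intersection(poly).area / poly.area
            if frac > 0.5:
                new.warnings.append(
                    f"nanoholes merge to {frac:.0%} of cisterna area")
    elif substructure == "tubular_matrix":
        params.setdefault("spacing_nm", 2.0 * layout.tubule_diameter_nm)
        params.setdefault("stripe_width_nm", layout.tubule_diameter_nm)
        params.setdefault("edge_band_nm", 3.0 * layout.tubule_diameter_nm)
        params.setdefault("floor", 0.1)
        params.setdefault("orientation_deg", 0.0)

    new.cisternae.append(Cisterna(polygon=poly, substructure=substructure,
                                  params=params))
    return new


def cisterna_occupancy(cist: Cisterna, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lumen occupancy of ``cist`` at points (x, y) in nm (points assumed
    inside the polygon)."""
    occ = np.ones(x.shape, dtype=float)
    if cist.substructure == "sac":
        return occ
    if cist.substructure == "sac_nanoholes":
        r2 = float(cist.params["hole_radius_nm"]) ** 2
        for cx, cy in cist.params["hole_centers"]:
            occ[(x - cx) ** 2 + (y - cy) ** 2 <= r2] = 0.0
        return occ
    # tubular_matrix: stripes of full occupancy at the tubule pitch, a solid
    # edge band, and a low floor in the compressed inter-tubule space
    p = cist.params
    theta = math.radians(p["orientation_deg"])
    u = x * math.cos(theta) + y * math.sin(theta)
    stripes = np.mod(u, p["spacing_nm"]) < p["stripe_width_nm"]
    occ = np.where(stripes, 1.0, p["floor"])
    pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
    d_edge = shapely.distance(pts, cist.polygon.exterior).reshape(x.shape)
    occ[d_edge <= p["edge_band_nm"]] = 1.0
    return occ


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _seg_distance(x, y, a, b):
    """Distance from points (x, y) to segment a-b, vectorised."""
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return np.hypot(x - ax, y - ay)
    t = np.clip(((x - ax) * dx + (y - ay) * dy) / L2, 0.0, 1.0)
    return np.hypot(x - (ax + t * dx), y - (ay + t * dy))


def _subpixel_grid(spec: PhantomSpec, ss: int):
    rows, cols = spec.image_shape
    idx = (np.arange(rows * ss) + 0.5) / ss - 0.5
    jdx = (np.arange(cols * ss) + 0.5) / ss - 0.5
    y = idx[:, None] * spec.pixel_size_nm * np.ones((1, cols * ss))
    x = np.ones((rows * ss, 1)) * (jdx[None, :] * spec.pixel_size_nm)
    return x, y


def _block_mean(arr: np.ndarray, ss: int) -> np.ndarray:
    h, w = arr.shape
    return arr.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def _polygon_mask_points(poly: Polygon, x, y):
    return shapely.intersects_xy(poly, x, y)


def render_er_image(layout: ERPhantomLayout, spec: PhantomSpec,
                    channels=("lumen",), morphogen_mode: str = "whole",
                    supersample: int = 2, noise: bool = True):
    """Render an ER phantom to a multi-channel image plus its ground truth.

    Channels: ``lumen`` (marker filling the ER lumen, weighted by the
    cisternal lumen occupancy), ``membrane`` (uniform over the ER membrane
    footprint), ``morphogen`` (membrane-bound morphogen; ``morphogen_mode``
    ``"whole"`` distributes it over the whole ER, ``"edges"`` confines it to
    cisterna edge bands and tubules).  Rendering never modifies the layout
    or the returned ground truth maps.
    """
    bad = set(channels) - {"lumen", "membrane", "morphogen"}
    if bad:
        raise ValueError(f"unknown channels {sorted(bad)}")
    if 0 < spec.psf_fwhm_nm < spec.pixel_size_nm:
        warnings.warn("PSF FWHM below pixel size: PSF is undersampled",
                      stacklevel=2)
    ss = int(supersample)
    rows, cols = spec.image_shape
    x, y = _subpixel_grid(spec, ss)
    rng = np.random.default_rng([spec.seed, 2654435761 % (2**31)])

    # tubule band occupancy on the subpixel grid
    r_tub = layout.tubule_diameter_nm / 2.0
    d_min = np.full(x.shape, np.inf)
    for a, b in layout.segments:
        np.minimum(d_min, _seg_distance(x, y, a, b), out=d_min)
    tubule_ss = (d_min <= r_tub).astype(float)

    # cisterna occupancy, id map on the subpixel grid
    lumen_ss = tubule_ss.copy()
    cist_edge_ss = np.zeros_like(tubule_ss)
    cist_any_ss = np.zeros(x.shape, dtype=bool)
    label_map = np.zeros((rows, cols), dtype=np.int32)
    xc = (np.arange(cols) * spec.pixel_size_nm)[None, :] * np.ones((rows, 1))
    yc = (np.arange(rows) * spec.pixel_size_nm)[:, None] * np.ones((1, cols))
    edge_w = layout.tubule_diameter_nm
    for k, cist in enumerate(layout.cisternae):
        inside = _polygon_mask_points(cist.polygon, x, y)
        if not inside.any():
            continue
        occ = np.zeros_like(tubule_ss)
        occ[inside] = cisterna_occupancy(cist, x[inside], y[inside])
        np.maximum(lumen_ss, occ, out=lumen_ss)
        cist_any_ss |= inside
        # membrane of the cisterna: band along the polygon boundary
        pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
        d_b = shapely.distance(pts, cist.polygon.exterior).reshape(x.shape)
        cist_edge_ss[np.abs(d_b) <= edge_w] = 1.0
        label_map[_polygon_mask_points(cist.polygon, xc, yc)] = k + 2

    tub_px_cover = _block_mean(tubule_ss, ss)
    label_map[(label_map == 0) & (tub_px_cover > 0.2)] = 1

    emission_maps = {}
    er_ss = np.maximum(tubule_ss, cist_any_ss.astype(float))
    for ch in channels:
        if ch == "lumen":
            em = lumen_ss
        elif ch == "membrane":
            em = np.maximum(tubule_ss, cist_edge_ss)
            em = np.maximum(em, 0.35 * cist_any_ss)  # faint sheet membrane
        else:  # morphogen
            if morphogen_mode == "edges":
                em = np.maximum(tubule_ss, cist_edge_ss)
            elif morphogen_mode == "whole":
                em = er_ss
            else:
                raise ValueError(f"unknown morphogen_mode {morphogen_mode!r}")
        emission_maps[ch] = _block_mean(em, ss)

    sigma = spec.psf_sigma_px
    data = np.empty((len(channels), rows, cols), dtype=float)
    for i, ch in enumerate(channels):
        em = emission_maps[ch]
        if sigma > 0:
            em = gaussian_filter(em, sigma, mode="constant")
        if np.isinf(spec.photon_scale) or not noise:
            img = (spec.photon_scale if np.isfinite(spec.photon_scale) else 1.0) \
                * em + spec.background_level
            if noise and np.isinf(spec.photon_scale):
                img = img + rng.normal(0.0, spec.read_noise_sd, em.shape) \
                    if spec.read_noise_sd > 0 else img
        else:
            img = rng.poisson(spec.photon_scale * em
                              + spec.background_level).astype(float)
            if spec.read_noise_sd > 0:
                img += rng.normal(0.0, spec.read_noise_sd, em.shape)
        data[i] = img

    gt = GroundTruth(
        label_map=label_map,
        lumen_occupancy=_block_mean(lumen_ss, ss),
        true_params={
            "tubule_diameter_nm": layout.tubule_diameter_nm,
            "n_junctions": layout.n_junctions(),
            "substructures": [c.substructure for c in layout.cisternae],
            "spec": spec.to_dict(),
        },
        warnings=list(layout.warnings),
    )
    img = MultiChannelImage(data, list(channels), spec.pixel_size_nm,
                            meta={"seed": spec.seed, "spec": spec.to_dict()})
    return img, gt


# ---------------------------------------------------------------------------
# Convenience scene builder (network + cisternae in one call)
# ---------------------------------------------------------------------------

def _blob_polygon(center, radius_nm, rng, n_vertices: int = 24,
                  roughness: float = 0.12) -> Polygon:
    """Star-shaped polygon with smooth low-order radial modulation."""
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    mod = np.zeros_like(theta)
    for k in (2, 3):
        mod += rng.normal(0, roughness) * np.cos(k * theta)
        mod += rng.normal(0, roughness) * np.sin(k * theta)
    r = radius_nm * np.clip(1.0 + mod, 0.55, 1.45)
    pts = np.column_stack([center[0] + r * np.cos(theta),
                           center[1] + r * np.sin(theta)])
    return Polygon(pts)


def make_er_scene(spec: PhantomSpec, n_junctions: int = 6,
                  n_cisternae: int = 6, substructure: str = "sac",
                  cisterna_radius_nm: float = 700.0,
                  substructure_params: dict | None = None) -> ERPhantomLayout:
    """Build a full ER layout: tubule network plus ``n_cisternae`` randomly
    placed, non-overlapping cisternae of one substructure type."""
    rng = np.random.default_rng(spec.seed)
    region = full_frame_region(spec, margin_nm=cisterna_radius_nm
                               + 2 * spec.pixel_size_nm)
    layout = make_tubule_network(spec, n_junctions, rng=rng,
                                 region=full_frame_region(spec))
    centers: list = []
    min_sep = 2.6 * cisterna_radius_nm
    for _ in range(n_cisternae):
        for _try in range(3000):
            c = _random_point_in(region, rng)
            if all(math.dist(c, o) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"placed only {len(centers)} of {n_cisternae} cisternae")
    for c in centers:
        poly = _blob_polygon(c, cisterna_radius_nm, rng)
        params = dict(substructure_params or {})
        params["polygon"] = poly
        if substructure == "sac_nanoholes":
            params.setdefault("hole_radius_nm", 60.0)
            params.setdefault("hole_density_per_um2", 8.0)
            params.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
        if substructure == "tubular_matrix":
            params.setdefault("orientation_deg",
                              float(rng.uniform(0.0, 180.0)))
        layout = add_cisterna(layout, substructure, params)
    return layout


# ---------------------------------------------------------------------------
# Golgi-stack phantom (EM-trace scale)
# ---------------------------------------------------------------------------

@dataclass
class GolgiPhantom:
    """Traced Golgi stack with known curvature and width profiles."""

    edge_pairs: list        # [(edge_a (N,2), edge_b (N,2)), ...] in nm
    centerlines: list       # [(N,2) arrays]
    true_curvature_nm: float
    true_width_profiles: list  # [w(s) arrays, nm]
    base_width_nm: float


def make_golgi_phantom(arc_radius_nm: float, n_cisternae: int = 3,
                       base_width_nm: float = 27.0,
                       swelling_amplitude_nm: float = 0.0,
                       seed: int = 0, cisterna_length_nm: float = 1200.0,
                       n_points: int = 60,
                       stack_spacing_nm: float = 80.0) -> GolgiPhantom:
    """Generate paired edge traces of Golgi cisternae along a circular arc.

    ``arc_radius_nm`` may be ``inf`` for straight cisternae.  Local width is
    ``base_width_nm`` plus smooth random swelling bumps bounded by
    ``swelling_amplitude_nm``; the true mean curvature of each centerline is
    ``1/arc_radius_nm``.
    """
    if n_cisternae < 1:
        raise ValueError("n_cisternae must be >= 1")
    if not (arc_radius_nm > 0):
        raise ValueError("arc_radius_nm must be > 0 (or inf for straight)")
    if swelling_amplitude_nm >= base_width_nm:
        raise ValueError("swelling amplitude >= base width gives a "
                         "self-intersecting cisterna")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, cisterna_length_nm, n_points)
    edge_pairs, centerlines, widths = [], [], []
    for k in range(n_cisternae):
        w = np.full_like(s, base_width_nm)
        if swelling_amplitude_nm > 0:
            for _ in range(rng.poisson(3) + 1):
                pos = rng.uniform(0.1, 0.9) * cisterna_length_nm
                amp = rng.uniform(0.3, 1.0) * swelling_amplitude_nm
                sig = cisterna_length_nm / rng.uniform(10.0, 20.0)
                w = w + amp * np.exp(-0.5 * ((s - pos) / sig) ** 2)
            w = np.clip(w, 0.2 * base_width_nm,
                        base_width_nm + swelling_amplitude_nm)
        if math.isinf(arc_radius_nm):
            center = np.column_stack([s, np.full_like(s, k * stack_spacing_nm)])
            normal = np.tile([0.0, 1.0], (len(s), 1))
        else:
            rk = arc_radius_nm + k * stack_spacing_nm
            phi = s / rk
            center = np.column_stack([rk * np.sin(phi),
                                      rk * (1.0 - np.cos(phi))])
            # inward normal (towards arc centre at (0, rk))
            normal = np.column_stack([-np.sin(phi), np.cos(phi)])
        edge_a = center + 0.5 * w[:, None] * normal
        edge_b = center - 0.5 * w[:, None] * normal
        edge_pairs.append((edge_a, edge_b))
        centerlines.append(center)
        widths.append(w)
    kappa = 0.0 if math.isinf(arc_radius_nm) else 1.0 / arc_radius_nm
    return GolgiPhantom(edge_pairs, centerlines, kappa, widths, base_width_nm)


# ---------------------------------------------------------------------------
# Ratio-pair phantom (roGFP2-style 405/488 imaging)
# ---------------------------------------------------------------------------

def _smooth_field(shape, rng, lo=0.6, hi=1.4, sigma_px=8.0):
    f = gaussian_filter(rng.uniform(0, 1, shape), sigma_px, mode="reflect")
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def make_ratio_pair(true_ratio, spec: PhantomSpec, bleed_coeff: float = 0.0,
                    background: float = 0.0, autofluor_level: float | None = None,
                    noise: bool = True):
    """Render a 405/488/autofluorescence triple with a known true ratio.

    I405 = true_ratio * S + bleed_coeff * A + background (+ noise);
    I488 = S + background (+ noise); the autofluorescence channel records
    A + background.  S is a smooth latent signal field at the spec's photon
    scale; A a smooth autofluorescence field.
    """
    ratio = np.asarray(true_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("true_ratio must be > 0")
    if not (0 <= bleed_coeff < 1):
        raise ValueError("bleed_coeff must be in [0, 1)")
    rng = np.random.default_rng([spec.seed, 97])
    shape = spec.image_shape
    if ratio.ndim == 0:
        ratio = np.full(shape, float(ratio))
    S = spec.photon_scale * _smooth_field(shape, rng)
    A = (0.2 * spec.photon_scale if autofluor_level is None
         else autofluor_level) * _smooth_field(shape, rng)
    mean405 = ratio * S + bleed_coeff * A + background
    mean488 = S + background
    meanauto = A + background

    def _detect(mean):
        if not noise:
            return mean.copy()
        img = rng.poisson(mean).astype(float)
        if spec.read_noise_sd > 0:
            img += rng.normal(0, spec.read_noise_sd, shape)
        return img

    data = np.stack([_detect(mean405), _detect(mean488), _detect(meanauto)])
    img = MultiChannelImage(data, ["405", "488", "auto"], spec.pixel_size_nm,
                            meta={"seed": spec.seed})
    gt = GroundTruth(true_params={"true_ratio": ratio,
                                  "bleed_coeff": bleed_coeff,
                                  "background": background,
                                  "latent_S": S, "latent_A": A})
    return img, gt


#: control excitation-ratio presets: cytosolic (reducing) and ER-lumenal
#: (oxidising) roGFP2 environments
RATIO_PRESETS = {"cytosol": 0.45, "er_lumen": 1.34}


# ---------------------------------------------------------------------------
# Whole-cell scene (transport + secretion)
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Named polygon ROIs in pixel coordinates (x=col, y=row, 0-based)."""

    golgi: list = field(default_factory=list)
    er: list = field(default_factory=list)
    background: list = field(default_factory=list)
    cell_boundary: Polygon | None = None

    def to_json(self) -> str:
        def coords(p):
            return list(map(list, np.asarray(p.exterior.coords)))
        d = {"golgi": [coords(p) for p in self.golgi],
             "er": [coords(p) for p in self.er],
             "background": [coords(p) for p in self.background]}
        if self.cell_boundary is not None:
            d["cell_boundary"] = coords(self.cell_boundary)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ROISet":
        d = json.loads(text)
        return cls(golgi=[Polygon(p) for p in d.get("golgi", [])],
                   er=[Polygon(p) for p in d.get("er", [])],
                   background=[Polygon(p) for p in d.get("background", [])],
                   cell_boundary=(Polygon(d["cell_boundary"])
                                  if "cell_boundary" in d else None))


def _disc_polygon(cx, cy, r, n=24):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(th),
                                    cy + r * np.sin(th)]))


def make_cell_scene(golgi_fraction: float, n_golgi: int,
                    secretion_ratio: float, spec: PhantomSpec,
                    noise: bool = True):
    """Render a cell with Golgi puncta carrying a known share of the
    background-corrected marker intensity, plus an apoplast band whose mean
    is ``secretion_ratio`` times the cell-interior mean.

    Returns (image, rois, ground_truth).  The emitted ROI set mirrors the
    manual measurement protocol: 3 Golgi ROIs, 3 ER ROIs, one background
    ROI outside the cell, and the cell-boundary polygon.
    """
    if not (0 <= golgi_fraction < 100):
        raise ValueError("golgi_fraction must be in [0, 100)")
    if secretion_ratio < 0:
        raise ValueError("secretion_ratio must be >= 0")
    if n_golgi == 0 and golgi_fraction > 0:
        raise ValueError("golgi_fraction > 0 requires n_golgi > 0")
    rows, cols = spec.image_shape
    rng = np.random.default_rng([spec.seed, 31])

    ring_px = int(round(1500.0 / spec.pixel_size_nm))  # 1.5 um ring + margin
    inset = ring_px + 6
    cell = Polygon([(inset, inset), (cols - inset, inset),
                    (cols - inset, rows - inset), (inset, rows - inset)])

    yy, xx = np.mgrid[0:rows, 0:cols]
    interior = _polygon_mask_points(cell, xx.astype(float), yy.astype(float))

    er_level = 1.0
    g_level = (er_level * golgi_fraction / (100.0 - golgi_fraction)
               if golgi_fraction > 0 else 0.0)
    emission = np.where(interior, er_level, 0.0)

    golgi_r = 5.0
    roi_r = 2.5
    centers = []
    minx, miny, maxx, maxy = cell.bounds
    pad = 3 * golgi_r
    while len(centers) < n_golgi:
        c = (rng.uniform(minx + pad, maxx - pad),
             rng.uniform(miny + pad, maxy - pad))
        if all(math.dist(c, o) > 4 * golgi_r for o in centers):
            centers.append(c)
    for cx, cy in centers:
        emission[(xx - cx) ** 2 + (yy - cy) ** 2 <= golgi_r ** 2] = g_level

    interior_mean = emission[interior].mean()
    ring_poly = cell.buffer(ring_px).difference(cell)
    ring = _polygon_mask_points(ring_poly, xx.astype(float), yy.astype(float))

    # calibrate the ring level so the *detected* apoplast/interior mean
    # ratio — including PSF blur and the constant detector background —
    # equals secretion_ratio (fixed point in the ring emission)
    sigma = spec.psf_sigma_px
    scale = spec.photon_scale if np.isfinite(spec.photon_scale) else 1.0
    bg = spec.background_level

    def _blur(a):
        return gaussian_filter(a, sigma, mode="constant") if sigma > 0 else a

    level = secretion_ratio * interior_mean
    if secretion_ratio > 0:
        for _ in range(4):
            emission[ring] = level
            emb = _blur(emission)
            i_mean = scale * emb[interior].mean() + bg
            a_mean = scale * emb[ring].mean() + bg
            achieved = a_mean / i_mean
            if achieved > 0:
                level *= secretion_ratio / achieved
    emission[ring] = level
    em = _blur(emission)
    if noise:
        img_arr = rng.poisson(spec.photon_scale * em
                              + spec.background_level).astype(float)
        if spec.read_noise_sd > 0:
            img_arr += rng.normal(0, spec.read_noise_sd, em.shape)
    else:
        img_arr = spec.photon_scale * em + spec.background_level

    golgi_rois = [_disc_polygon(cx, cy, roi_r) for cx, cy in centers[:3]]
    # ER ROIs: squares away from every punctum
    er_rois = []
    side = 6.0
    while len(er_rois) < 3:
        c = (rng.uniform(minx + pad, maxx - pad),
             rng.uniform(miny + pad, maxy - pad))
        if all(math.dist(c, o) > golgi_r + side * 1.5 for o in centers):
            er_rois.append(Polygon([(c[0] - side, c[1] - side),
                                    (c[0] + side, c[1] - side),
                                    (c[0] + side, c[1] + side),
                                    (c[0] - side, c[1] + side)]))
    bg_roi = Polygon([(1, 1), (inset - ring_px - 3, 1),
                      (inset - ring_px - 3, inset - ring_px - 3),
                      (1, inset - ring_px - 3)])
    rois = ROISet(golgi=golgi_rois, er=er_rois, background=[bg_roi],
                  cell_boundary=cell)
    gt = GroundTruth(true_params={
        "golgi_fraction": golgi_fraction,
        "secretion_ratio": secretion_ratio,
        "n_golgi": n_golgi,
        "golgi_centers": centers,
        "interior_mean_emission": interior_mean,
    })
    img = MultiChannelImage(img_arr[None], ["marker"], spec.pixel_size_nm,
                            meta={"seed": spec.seed})
    return img, rois, gt
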