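"""Rate maps and spatial statistics.

A :class:`RateMap` is the mean activity of one unit over spatial bins (graph
nodes rendered onto a raster for lattice worlds), with per-bin occupancy and a
validity mask.  On top of it: spatial autocorrelograms, the rotational
("gridness") score with grid scale/orientation, and masked Pearson spatial
correlations between maps.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .worlds import World, SQUARE, HEX


@dataclasses.dataclass
class RateMap:
    values: np.ndarray          # (H, W), nan at invalid bins
    occupancy: np.ndarray       # (H, W) visit counts (>= 0)
    bin_size: float = 1.0

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.occupancy > 0)

    def smoothed(self, sigma: float = 1.0) -> "RateMap":
        """Gaussian smoothing with normalized (mask-aware) convolution."""
        m = self.mask.astype(float)
        v = np.where(self.mask, self.values, 0.0)
        num = ndimage.gaussian_filter(v, sigma)
        den = ndimage.gaussian_filter(m, sigma)
        out = np.where(den > 1e-6, num / np.maximum(den, 1e-12), np.nan)
        out[~(den > 1e-6)] = np.nan
        return RateMap(out, self.occupancy.copy(), self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        ys, xs = np.indices(self.values.shape)
        return pd.DataFrame({
            "bin_x": xs.ravel(), "bin_y": ys.ravel(),
            "value": self.values.ravel(),
            "occupancy": self.occupancy.ravel()})


@dataclasses.dataclass
class GridStats:
    gridness: float
    scale: float
    orientation: float
    peak_locations: np.ndarray  # (k, 2) (x, y) in bins, relative to center
    valid: bool = True


class DimensionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# building rate maps
# ---------------------------------------------------------------------------

def node_means(activity: np.ndarray, nodes: np.ndarray, n_nodes: int):
    """Mean activity and visit count per graph node."""
    activity = np.asarray(activity, dtype=float)
    nodes = np.asarray(nodes)
    if len(activity) != len(nodes):
        raise DimensionError("activity and trajectory lengths differ")
    count = np.bincount(nodes, minlength=n_nodes).astype(float)
    total = np.bincount(nodes, weights=activity, minlength=n_nodes)
    means = np.full(n_nodes, np.nan)
    np.divide(total, count, out=means, where=count > 0)
    return means, count


def render_on_lattice(values: np.ndarray, count: np.ndarray, world: World,
                      hex_pitch: float = 0.5) -> RateMap:
    """Render per-node values onto a 2D raster using the world layout.

    Square worlds map directly to a width x width grid.  Hex worlds are
    rendered by nearest-node resampling of the axial layout onto a raster of
    pitch ``hex_pitch`` lattice spacings (bins further than one spacing from
    any node are invalid)."""
    coords = world.coords
    if world.kind == SQUARE:
        w = world.size_params["width"]
        grid = np.full((w, w), np.nan)
        occ = np.zeros((w, w))
        xs = coords[:, 0].astype(int)
        ys = coords[:, 1].astype(int)
        grid[ys, xs] = values
        occ[ys, xs] = count
        return RateMap(grid, occ)
    if world.kind == HEX:
        lo = coords.min(axis=0) - 0.5
        hi = coords.max(axis=0) + 0.5
        nx = int(np.ceil((hi[0] - lo[0]) / hex_pitch)) + 1
        ny = int(np.ceil((hi[1] - lo[1]) / hex_pitch)) + 1
        gx, gy = np.meshgrid(lo[0] + hex_pitch * np.arange(nx),
                             lo[1] + hex_pitch * np.arange(ny))
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        nearest = d2.argmin(axis=1)
        near_enough = d2[np.arange(len(pts)), nearest] <= 0.75 ** 2
        vals = np.where(near_enough, values[nearest], np.nan)
        occs = np.where(near_enough, count[nearest], 0.0)
        return RateMap(vals.reshape(ny, nx), occs.reshape(ny, nx),
                       bin_size=hex_pitch)
    raise DimensionError(f"no lattice rendering for kind {world.kind!r}")


def compute_ratemap(activity: np.ndarray, nodes: np.ndarray,
                    world: World) -> RateMap:
    """Mean activity of one unit at each node of a lattice world."""
    means, count = node_means(activity, nodes, world.n_nodes)
    return render_on_lattice(means, count, world)


def ratemap_from_array(values: np.ndarray, occupancy=None) -> RateMap:
    """Wrap an already-binned arena map (full occupancy by default)."""
    values = np.asarray(values, dtype=float)
    occ = np.ones_like(values) if occupancy is None else np.asarray(occupancy)
    return RateMap(values.copy(), occ.astype(float))


# ---------------------------------------------------------------------------
# autocorrelograms and gridness
# ---------------------------------------------------------------------------

def spatial_autocorrelogram(rmap: RateMap, min_overlap: int = 20):
    """Pearson correlation of the map with itself at every 2D offset.

    Output has shape (2H-1, 2W-1) with the zero offset at the center; offsets
    whose valid-bin overlap is below ``min_overlap`` are nan."""
    if rmap.mask.sum() < 2:
        raise DimensionError("need at least 2 valid bins")
    m = rmap.mask.astype(float)
    v = np.where(rmap.mask, rmap.values, 0.0)
    # masked Pearson at every offset via FFT cross-correlations of
    # (values, values^2, mask)
    from scipy.signal import correlate
    n = correlate(m, m, mode="full", method="fft")
    sa = correlate(v, m, mode="full", method="fft")
    sb = correlate(m, v, mode="full", method="fft")
    sab = correlate(v, v, mode="full", method="fft")
    saa = correlate(v * v, m, mode="full", method="fft")
    sbb = correlate(m, v * v, mode="full", method="fft")
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / n
        var_a = saa - sa ** 2 / n
        var_b = sbb - sb ** 2 / n
        out = cov / np.sqrt(var_a * var_b)
    bad = (n < min_overlap) | (var_a < 1e-9) | (var_b < 1e-9)
    out[bad] = np.nan
    return np.clip(out, -1.0, 1.0)


def _rotate_about_center(img: np.ndarray, angle_deg: float) -> np.ndarray:
    filled = np.where(np.isfinite(img), img, 0.0)
    valid = np.isfinite(img).astype(float)
    r = ndimage.rotate(filled, angle_deg, reshape=False, order=1, cval=0.0)
    m = ndimage.rotate(valid, angle_deg, reshape=False, order=1, cval=0.0)
    out = np.where(m > 0.99, r / np.maximum(m, 1e-9), np.nan)
    return out


def _autocorr_peaks(ac: np.ndarray):
    """Local maxima of the autocorrelogram, sorted by distance from center."""
    filled = np.where(np.isfinite(ac), ac, -1.0)
    coords = peak_local_max(filled, min_distance=2, threshold_abs=0.0,
                            exclude_border=False)
    cy, cx = (np.asarray(ac.shape) - 1) / 2.0
    rel = coords[:, ::-1] - np.array([cx, cy])     # -> (x, y)
    d = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(d)
    return rel[order], d[order]


def grid_score_scale(rmap: RateMap, smooth_sigma: Optional[float] = 1.0,
                     annulus=(0.5, 1.5)) -> GridStats:
    """Rotational gridness plus grid scale and orientation.

    gridness = min(corr at 60, 120 deg) - max(corr at 30, 90, 150 deg),
    computed over an annulus around the central peak of the (optionally
    smoothed) autocorrelogram; scale = median distance of the six nearest
    peaks (in bins times bin_size); orientation = angle of the nearest peak
    folded into [0, 60) degrees.  A map with no detectable off-center peaks
    returns ``valid=False`` instead of raising."""
    m = rmap.smoothed(smooth_sigma) if smooth_sigma else rmap
    ac = spatial_autocorrelogram(m)
    rel, d = _autocorr_peaks(ac)
    off = d > 1.5
    if off.sum() < 1:
        return GridStats(np.nan, np.nan, np.nan, np.empty((0, 2)),
                         valid=False)
    ring = rel[off][:6]
    ring_d = d[off][:6]
    scale_bins = float(np.median(ring_d))
    orientation = float(np.degrees(np.arctan2(ring[0][1], ring[0][0]))
                        % 60.0)
    cy, cx = (np.asarray(ac.shape) - 1) / 2.0
    ys, xs = np.indices(ac.shape)
    r = np.hypot(xs - cx, ys - cy)
    ann = (r >= annulus[0] * scale_bins) & (r <= annulus[1] * scale_bins)

    def ann_corr(angle):
        rot = _rotate_about_center(ac, angle)
        a, b = ac[ann], rot[ann]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 10:
            return np.nan
        return float(np.corrcoef(a[ok], b[ok])[0, 1])

    same = [ann_corr(60), ann_corr(120)]
    diff = [ann_corr(30), ann_corr(90), ann_corr(150)]
    gridness = float(np.nanmin(same) - np.nanmax(diff))
    return GridStats(gridness=gridness,
                     scale=scale_bins * rmap.bin_size,
                     orientation=orientation,
                     peak_locations=ring, valid=True)


def spatial_correlation(a: RateMap, b: RateMap) -> float:
    """Pearson correlation over jointly valid bins; nan if degenerate."""
    if a.values.shape != b.values.shape:
        raise DimensionError("maps have different geometries")
    ok = a.mask & b.mask
    if ok.sum() < 2:
        return np.nan
    x, y = a.values[ok], b.values[ok]
    if x.std() < 1e-12 or y.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
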