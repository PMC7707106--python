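"""Place-grid remapping statistics.

Tests whether place cells, despite global remapping between two environments,
keep their relationship to grid cells.  Two pair measures are computed for
each (place cell, grid cell) pair from the same animal:

* **gridAtPlace** -- the grid cell's firing rate at the place cell's peak.
* **minDist** -- the distance from the place peak to the nearest grid firing
  peak, normalized by the grid scale (ideal-grid fits only, so peaks beyond
  the arena are available).

The X (environment 1) and Y (environment 2) values are correlated over pairs
and compared against permutation nulls built by re-drawing place-cell peaks,
either at random valid locations or from other recorded cells.  Grid-cell /
place-cell correlation-structure preservation and a remapping sanity check
complete the suite.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ratemaps import GridStats, RateMap, grid_score_scale, \
    spatial_correlation

GRID, PLACE = "grid", "place"
RANDOM_LOCATION, OTHER_CELL_PEAK = "random_location", "other_cell_peak"


@dataclasses.dataclass
class CellRecord:
    cell_id: str
    animal_id: str
    cell_type: str                     # "grid" or "place"
    maps: dict                         # env_id -> RateMap
    grid_stats: dict = dataclasses.field(default_factory=dict)
    fits: dict = dataclasses.field(default_factory=dict)

    def peak(self, env) -> tuple:
        """(x, y) argmax bin of the map; ties broken by lowest bin index."""
        m = self.maps[env]
        v = np.where(m.mask, m.values, -np.inf)
        flat = int(np.argmax(v))
        y, x = np.unravel_index(flat, v.shape)
        return (int(x), int(y))


@dataclasses.dataclass
class IdealGridFit:
    scale: float
    orientation: float                 # degrees in [0, 60)
    phase: np.ndarray                  # (2,) offset of a peak, bins
    amplitude: float
    offset: float
    fit_error: float
    valid: bool = True


@dataclasses.dataclass
class PermutationResult:
    r_obs: float
    null: np.ndarray
    p_value: float
    n_perms: int
    scheme: str
    n_pairs: int = 0


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ideal grid model
# ---------------------------------------------------------------------------

def _wavevectors(scale: float, orientation_deg: float) -> np.ndarray:
    """Three wavevectors at 60-degree separation for a hexagonal lattice of
    spacing `scale` (peak-to-peak distance between neighboring fields)."""
    k = 4.0 * np.pi / (np.sqrt(3.0) * scale)
    angles = np.radians(orientation_deg) + np.radians([0.0, 60.0, 120.0]) \
        + np.pi / 6.0  # wavevectors bisect the lattice directions
    return k * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def ideal_grid_map(shape: tuple, scale: float, orientation_deg: float,
                   phase: Sequence[float], amplitude: float = 1.0,
                   offset: float = 0.0) -> np.ndarray:
    """Sum of three plane-wave cosines; peaks form a hexagonal lattice of
    spacing `scale` with one peak at `phase` (x, y).  Normalized so the peak
    value is offset + amplitude."""
    H, W = shape
    ys, xs = np.indices((H, W)).astype(float)
    r = np.stack([xs - phase[0], ys - phase[1]], axis=-1)
    ks = _wavevectors(scale, orientation_deg)
    s = sum(np.cos(r @ ks[i]) for i in range(3))
    return offset + amplitude * (s + 1.5) / 4.5


def grid_peak_lattice(scale: float, orientation_deg: float,
                      phase: Sequence[float], shape: tuple,
                      margin_scales: float = 1.5) -> np.ndarray:
    """All lattice peak positions covering the arena plus a margin (peaks
    outside the box are deliberately included)."""
    th = np.radians(orientation_deg)
    v1 = scale * np.array([np.cos(th), np.sin(th)])
    v2 = scale * np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
    H, W = shape
    margin = margin_scales * scale
    nmax = int(np.ceil((max(H, W) + 2 * margin) / scale)) + 2
    pts = []
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            p = np.asarray(phase) + i * v1 + j * v2
            if -margin <= p[0] <= W - 1 + margin and \
                    -margin <= p[1] <= H - 1 + margin:
                pts.append(p)
    return np.asarray(pts)


def fit_ideal_grid(rmap: RateMap, init: Optional[GridStats] = None,
                   n_phase: int = 6) -> IdealGridFit:
    """Least-squares fit of the three-cosine ideal grid to a rate map.

    Coarse grid search over (scale, orientation, phase) seeded from the
    autocorrelogram statistics, then local refinement of all six parameters.
    A map without detectable grid structure returns a flagged fit with
    infinite error."""
    if init is None:
        init = grid_score_scale(rmap)
    if not init.valid or not np.isfinite(init.scale) or init.scale <= 0:
        return IdealGridFit(np.nan, np.nan, np.zeros(2), np.nan, np.nan,
                            np.inf, valid=False)
    mask = rmap.mask
    v = rmap.values
    target = v[mask]
    if target.std() < 1e-12:
        return IdealGridFit(np.nan, np.nan, np.zeros(2), np.nan, np.nan,
                            np.inf, valid=False)

    def sse(scale, orient, phase):
        model = ideal_grid_map(v.shape, scale, orient, phase)[mask]
        A = np.stack([model, np.ones_like(model)], axis=1)
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        resid = target - A @ coef
        return float((resid ** 2).sum()), coef

    best = None
    scale0 = init.scale / rmap.bin_size if rmap.bin_size != 1.0 else init.scale
    for scale in scale0 * np.array([0.85, 1.0, 1.15]):
        th = np.radians(init.orientation)
        v1 = scale * np.array([np.cos(th), np.sin(th)])
        v2 = scale * np.array([np.cos(th + np.pi / 3),
                               np.sin(th + np.pi / 3)])
        for orient in init.orientation + np.array([-5.0, 0.0, 5.0]):
            for a in np.linspace(0, 1, n_phase, endpoint=False):
                for b in np.linspace(0, 1, n_phase, endpoint=False):
                    phase = a * v1 + b * v2
                    err, coef = sse(scale, orient, phase)
                    if best is None or err < best[0]:
                        best = (err, scale, orient, phase, coef)

    _, scale, orient, phase, coef = best

    def residual(theta):
        s, o, px, py, amp, off = theta
        if s <= 1e-3:
            return np.full(mask.sum(), 1e6)
        model = off + amp * ideal_grid_map(v.shape, s, o, (px, py))[mask]
        return model - target

    x0 = np.array([scale, orient, phase[0], phase[1], coef[0], coef[1]])
    try:
        res = optimize.least_squares(residual, x0, method="lm",
                                     max_nfev=400)
        s, o, px, py, amp, off = res.x
        err = float((res.fun ** 2).sum())
    except Exception:
        s, o, px, py = scale, orient, phase[0], phase[1]
        amp, off = coef
        err = best[0]
    # fold the phase into the cell around the origin and the orientation
    # into [0, 60)
    o = o % 60.0
    return IdealGridFit(scale=float(s) * rmap.bin_size, orientation=float(o),
                        phase=np.array([px, py], dtype=float),
                        amplitude=float(amp), offset=float(off),
                        fit_error=err, valid=np.isfinite(err))


def ideal_map_from_fit(fit: IdealGridFit, shape: tuple) -> RateMap:
    vals = fit.offset + fit.amplitude * ideal_grid_map(
        shape, fit.scale, fit.orientation, fit.phase)
    return RateMap(vals, np.ones(shape))


# ---------------------------------------------------------------------------
# preprocessing and pair measures
# ---------------------------------------------------------------------------

def _near_border(peak, shape, border_frac) -> bool:
    x, y = peak
    H, W = shape
    bx, by = border_frac * W, border_frac * H
    return (x <= bx or x >= W - 1 - bx or y <= by or y >= H - 1 - by)


def preprocess_cells(records: Sequence[CellRecord], grid_cutoff: float = 0.8,
                     border_frac: float = 0.10, use_ideal: bool = True,
                     envs: Optional[Sequence] = None):
    """Filter cells and (optionally) replace grid maps by ideal-grid fits.

    Grid cells whose gridness in any analysis environment falls below
    ``grid_cutoff`` are removed; place cells whose peak lies within
    ``border_frac`` of the environment width from any wall are removed (in
    any environment).  Returns the surviving records (new list)."""
    out = []
    for rec in records:
        use_envs = envs if envs is not None else sorted(rec.maps)
        if rec.cell_type == GRID:
            ok = True
            need_stats = grid_cutoff > 0 or use_ideal
            for e in use_envs:
                if not need_stats:
                    break
                gs = rec.grid_stats.get(e)
                if gs is None:
                    gs = grid_score_scale(rec.maps[e])
                    rec.grid_stats[e] = gs
                if not gs.valid or not (gs.gridness >= grid_cutoff):
                    ok = False
                    break
            if not ok:
                continue
            if use_ideal:
                bad = False
                for e in use_envs:
                    fit = fit_ideal_grid(rec.maps[e], rec.grid_stats[e])
                    if not fit.valid:
                        bad = True
                        break
                    rec.fits[e] = fit
                if bad:
                    continue
            out.append(rec)
        else:
            shape = rec.maps[use_envs[0]].values.shape
            if any(_near_border(rec.peak(e), shape, border_frac)
                   for e in use_envs):
                continue
            out.append(rec)
    return out


def grid_value_at(grid: CellRecord, env, pos, use_ideal: bool) -> float:
    """Grid-cell firing rate at an (x, y) bin, from the ideal fit if
    requested (analytic, defined everywhere) else the raw map."""
    x, y = pos
    if use_ideal and env in grid.fits:
        f = grid.fits[env]
        val = f.offset + f.amplitude * ideal_grid_map(
            (1, 1), f.scale, f.orientation,
            (f.phase[0] - x, f.phase[1] - y))[0, 0]
        return float(val)
    m = grid.maps[env]
    if not m.mask[y, x]:
        return np.nan
    return float(m.values[y, x])


def grid_at_place(place: CellRecord, grid: CellRecord, env,
                  use_ideal: bool = True) -> float:
    """Grid firing rate at the place cell's peak location."""
    if place.animal_id != grid.animal_id:
        raise DegenerateDataError("pairs must come from the same animal")
    return grid_value_at(grid, env, place.peak(env), use_ideal)


def min_dist(place: CellRecord, grid: CellRecord, env) -> float:
    """Scale-normalized distance from the place peak to the nearest grid
    peak of the ideal-grid fit (extended peaks included)."""
    if env not in grid.fits:
        raise DegenerateDataError("min_dist requires an ideal-grid fit")
    f = grid.fits[env]
    shape = grid.maps[env].values.shape
    peaks = grid_peak_lattice(f.scale, f.orientation, f.phase, shape)
    if len(peaks) == 0:
        return np.nan
    p = np.asarray(place.peak(env), dtype=float)
    d = np.min(np.hypot(*(peaks - p).T))
    return float(d / f.scale)


def pair_measures(records: Sequence[CellRecord], env_pair: tuple,
                  measure: str = "gridAtPlace",
                  use_ideal: bool = True) -> pd.DataFrame:
    """All same-animal (place, grid) pair values in the two environments."""
    e1, e2 = env_pair
    places = [r for r in records if r.cell_type == PLACE]
    grids = [r for r in records if r.cell_type == GRID]
    rows = []
    for p in places:
        for g in grids:
            if p.animal_id != g.animal_id:
                continue
            if measure == "gridAtPlace":
                X = grid_at_place(p, g, e1, use_ideal)
                Y = grid_at_place(p, g, e2, use_ideal)
            elif measure == "minDist":
                X = min_dist(p, g, e1)
                Y = min_dist(p, g, e2)
            else:
                raise ValueError(f"unknown measure {measure!r}")
            rows.append({"place_id": p.cell_id, "grid_id": g.cell_id,
                         "animal_id": p.animal_id, "X": X, "Y": Y,
                         "measure": measure})
    return pd.DataFrame(rows)


def _pearson(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() < 1e-12 or y.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def pair_correlation_test(records: Sequence[CellRecord], env_pair: tuple,
                          measure: str = "gridAtPlace",
                          n_perms: int = 5000,
                          scheme: str = RANDOM_LOCATION,
                          use_ideal: bool = True, border_frac: float = 0.10,
                          seed: int = 0) -> PermutationResult:
    """Correlation of (X, Y) over place-grid pairs against a permutation
    null built by re-drawing each place cell's peak and recomputing both
    measures.  One-sided p with the +1 correction."""
    e1, e2 = env_pair
    rng = np.random.default_rng(seed)
    df = pair_measures(records, env_pair, measure, use_ideal)
    if len(df) < 3:
        raise DegenerateDataError("need at least 3 place-grid pairs")
    r_obs = _pearson(df["X"].to_numpy(), df["Y"].to_numpy())
    if not np.isfinite(r_obs):
        raise DegenerateDataError("degenerate pair-measure variance")

    places = [r for r in records if r.cell_type == PLACE]
    grids = [r for r in records if r.cell_type == GRID]
    shape = places[0].maps[e1].values.shape
    H, Wd = shape

    # candidate peak positions passing the border rule
    ys, xs = np.indices(shape)
    keep = ~np.array([[_near_border((x, y), shape, border_frac)
                       for x in range(Wd)] for y in range(H)])
    cand = np.stack([xs[keep], ys[keep]], axis=1)   # (C, 2) as (x, y)

    if scheme == OTHER_CELL_PEAK:
        pool = {e: np.asarray([p.peak(e) for p in places])
                for e in env_pair}

    # per grid cell and env: measure value at every candidate position
    def value_table(g, env):
        if measure == "gridAtPlace":
            if use_ideal and env in g.fits:
                f = g.fits[env]
                vals = f.offset + f.amplitude * ideal_grid_map(
                    shape, f.scale, f.orientation, f.phase)
            else:
                vals = np.where(g.maps[env].mask, g.maps[env].values,
                                np.nan)
            return vals[cand[:, 1], cand[:, 0]]
        f = g.fits[env]
        peaks = grid_peak_lattice(f.scale, f.orientation, f.phase, shape)
        d = np.hypot(cand[:, 0, None] - peaks[None, :, 0],
                     cand[:, 1, None] - peaks[None, :, 1]).min(axis=1)
        return d / f.scale

    pair_index = []
    g_by_id = {g.cell_id: i for i, g in enumerate(grids)}
    p_by_id = {p.cell_id: i for i, p in enumerate(places)}
    for _, row in df.iterrows():
        pair_index.append((p_by_id[row["place_id"]],
                           g_by_id[row["grid_id"]]))
    pair_index = np.asarray(pair_index)
    tables = {e: np.stack([value_table(g, e) for g in grids])
              for e in env_pair}   # (G, C)
    cand_lookup = {tuple(c): i for i, c in enumerate(map(tuple, cand))}

    null = np.empty(n_perms)
    nP = len(places)
    for k in range(n_perms):
        if scheme == RANDOM_LOCATION:
            idx1 = rng.integers(len(cand), size=nP)
            idx2 = rng.integers(len(cand), size=nP)
        else:
            # independent draws per environment: borrowing the same cell's
            # peak in both would merely relabel pairs, leaving r unchanged
            perm1 = rng.permutation(nP)
            perm2 = rng.permutation(nP)
            idx1 = np.array([cand_lookup.get(tuple(pool[e1][j]), -1)
                             for j in perm1])
            idx2 = np.array([cand_lookup.get(tuple(pool[e2][j]), -1)
                             for j in perm2])
        X = tables[e1][pair_index[:, 1], idx1[pair_index[:, 0]]]
        Y = tables[e2][pair_index[:, 1], idx2[pair_index[:, 0]]]
        null[k] = _pearson(X, Y)
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= r_obs)) / (len(null) + 1.0)
    return PermutationResult(r_obs=r_obs, null=null, p_value=float(p),
                             n_perms=n_perms, scheme=scheme,
                             n_pairs=len(df))


# ---------------------------------------------------------------------------
# correlation-structure preservation and remapping checks
# ---------------------------------------------------------------------------

def structure_preservation_test(records: Sequence[CellRecord],
                                cell_type: str, env_pair: tuple,
                                n_perms: int = 5000,
                                seed: int = 0) -> PermutationResult:
    """Is the cell-by-cell spatial-correlation matrix preserved across
    environments?  Correlates upper triangles; null permutes cell identity
    in the second environment."""
    e1, e2 = env_pair
    cells = [r for r in records if r.cell_type == cell_type
             and e1 in r.maps and e2 in r.maps]
    n = len(cells)
    if n < 3:
        raise DegenerateDataError("need at least 3 cells")

    def corr_matrix(env):
        C = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = spatial_correlation(
                    cells[i].maps[env], cells[j].maps[env])
        return C

    C1, C2 = corr_matrix(e1), corr_matrix(e2)
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(C1[iu], C2[iu])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    for k in range(n_perms):
        perm = rng.permutation(n)
        null[k] = _pearson(C1[iu], C2[perm][:, perm][iu])
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= r_obs)) / (len(null) + 1.0)
    return PermutationResult(r_obs=r_obs, null=null, p_value=float(p),
                             n_perms=n_perms, scheme="cell_identity",
                             n_pairs=len(iu[0]))


def remapping_check(records: Sequence[CellRecord], env_pair: tuple):
    """Across-environment spatial correlations per cell (mean near 0 under
    global remapping); returns (DataFrame, summary dict)."""
    e1, e2 = env_pair
    rows = []
    for r in records:
        if e1 in r.maps and e2 in r.maps:
            rows.append({
                "cell_id": r.cell_id, "cell_type": r.cell_type,
                "correlation": spatial_correlation(r.maps[e1], r.maps[e2])})
    df = pd.DataFrame(rows)
    cc = df["correlation"].dropna()
    summary = {
        "mean": float(cc.mean()),
        "sem": float(cc.std(ddof=1) / np.sqrt(max(len(cc), 1))),
        "n": int(len(cc)),
        "remapped": bool(abs(cc.mean()) < 0.5),
        "hist": np.histogram(cc, bins=np.linspace(-1, 1, 21))[0].tolist(),
    }
    return df, summary
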