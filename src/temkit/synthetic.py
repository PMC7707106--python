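"""Synthetic grid/place/lap-cell populations with known ground truth.

Emulates the structure of paired grid- and place-cell recordings across two
environments (the kind of data the remapping statistics consume) when no real
recordings are available:

* grid cells are ideal three-cosine grids organized in modules (shared scale
  and orientation, uniform phases); between environments each module realigns
  coherently (common phase shift plus a small rotation);
* place cells are isotropic Gaussian bumps; with probability ``rho`` a place
  cell's environment-2 peak lands on the lattice of its anchor grid cell at
  the same phase residual it had in environment 1 (phase preservation),
  otherwise it relocates uniformly;
* truncated Gaussian noise is added to every map.

``rho = 1`` with zero noise makes the place-grid relationship exactly
preserved; ``rho = 0`` destroys it, giving calibration data for the
permutation tests.  A second generator produces lap-activity populations
(spatial / lap-specific / lap-counting archetypes) for the ESR analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .esr import LapActivity
from .ratemaps import ratemap_from_array
from .remap import CellRecord, GRID, PLACE, grid_peak_lattice, \
    ideal_grid_map


@dataclasses.dataclass
class SynthPopSpec:
    """Population parameters; defaults give a modest two-module population
    in a 40 x 40-bin arena."""

    n_modules: int = 2
    scales: Sequence[float] = (8.0, 12.0)
    orientations: Sequence[float] = (5.0, 20.0)
    n_grid_per_module: int = 8
    n_place: int = 20
    arena: tuple = (40, 40)
    rho: float = 1.0
    noise_sd: float = 0.0
    place_width_range: tuple = (1.5, 3.0)
    realign_rotation_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if min(self.arena) < 10:
            raise ValueError("arena must be at least 10 x 10 bins")
        if len(self.scales) != self.n_modules or \
                len(self.orientations) != self.n_modules:
            raise ValueError("need one scale/orientation per module")


def _noisy(vals, sd, rng):
    if sd <= 0:
        return vals
    return np.clip(vals + rng.normal(0, sd, vals.shape), 0.0, None)


def _gauss_bump(shape, center, width):
    H, W = shape
    ys, xs = np.indices((H, W)).astype(float)
    return np.exp(-(((xs - center[0]) ** 2 + (ys - center[1]) ** 2)
                    / (2 * width ** 2)))


def gen_population(spec: SynthPopSpec):
    """Generate CellRecords for two environments ("env1", "env2").

    Grid cells carry their generating parameters in ``rec.truth``-style
    entries of grid_stats-compatible dict form is avoided; ground truth is
    returned separately as a dict for tests."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.arena
    shape = (H, W)
    records, truth = [], {"grid": [], "place": []}

    # module realignment between environments
    shifts = [rng.uniform(0, s, size=2) for s in spec.scales]
    rots = rng.normal(0, spec.realign_rotation_sd, size=spec.n_modules)

    grid_params = []   # (module, scale, orient1, orient2, phase1, phase2)
    for m in range(spec.n_modules):
        for _ in range(spec.n_grid_per_module):
            phase1 = rng.uniform(0, spec.scales[m], size=2)
            phase2 = phase1 + shifts[m]
            grid_params.append((m, spec.scales[m],
                                spec.orientations[m],
                                spec.orientations[m] + rots[m],
                                phase1, phase2))

    for i, (m, s, o1, o2, ph1, ph2) in enumerate(grid_params):
        maps = {
            "env1": ratemap_from_array(_noisy(
                ideal_grid_map(shape, s, o1, ph1), spec.noise_sd, rng)),
            "env2": ratemap_from_array(_noisy(
                ideal_grid_map(shape, s, o2, ph2), spec.noise_sd, rng)),
        }
        records.append(CellRecord(cell_id=f"g{i}", animal_id="synth",
                                  cell_type=GRID, maps=maps))
        truth["grid"].append({"module": m, "scale": s,
                              "orientation": (o1, o2),
                              "phase": (ph1, ph2)})

    for j in range(spec.n_place):
        width = rng.uniform(*spec.place_width_range)
        peak1 = rng.uniform([0, 0], [W - 1, H - 1])
        # anchor grid cell: a per-cell latent module/cell choice
        anchor = int(rng.integers(len(grid_params)))
        m, s, o1, o2, ph1, ph2 = grid_params[anchor]
        if rng.uniform() < spec.rho:
            # residual of the env-1 peak w.r.t. the anchor lattice,
            # re-applied on the anchor's env-2 lattice
            lat1 = grid_peak_lattice(s, o1, ph1, shape)
            k = np.argmin(np.hypot(*(lat1 - peak1).T))
            resid = peak1 - lat1[k]
            lat2 = grid_peak_lattice(s, o2, ph2, shape)
            inside = (lat2[:, 0] > 0) & (lat2[:, 0] < W - 1) & \
                     (lat2[:, 1] > 0) & (lat2[:, 1] < H - 1)
            lat2 = lat2[inside] if inside.any() else lat2
            peak2 = lat2[rng.integers(len(lat2))] + resid
            peak2 = np.clip(peak2, [0, 0], [W - 1, H - 1])
        else:
            peak2 = rng.uniform([0, 0], [W - 1, H - 1])
        maps = {
            "env1": ratemap_from_array(_noisy(
                _gauss_bump(shape, peak1, width), spec.noise_sd, rng)),
            "env2": ratemap_from_array(_noisy(
                _gauss_bump(shape, peak2, width), spec.noise_sd, rng)),
        }
        records.append(CellRecord(cell_id=f"p{j}", animal_id="synth",
                                  cell_type=PLACE, maps=maps))
        truth["place"].append({"peak": (peak1, peak2), "width": width,
                               "anchor": anchor})
    return records, truth


SPATIAL, LAP_SPECIFIC, COUNTING = "spatial", "lap_specific", "counting"


def gen_lap_population(n_cells: int, mix=(1 / 3, 1 / 3, 1 / 3),
                       n_trials: int = 15, n_laps: int = 4,
                       lap_length: int = 8, noise_sd: float = 0.0,
                       seed: int = 0):
    """Lap-activity pairs (two environments) for three cell archetypes.

    * spatial: same profile every lap;
    * lap_specific: fires on one preferred lap only;
    * counting: amplitude ramps linearly with lap number.

    Environment 2 redraws each cell's spatial peak but preserves its lap
    preference.  Returns (pop_env1, pop_env2, labels)."""
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels, pop1, pop2 = [], [], []
    kinds = rng.choice([SPATIAL, LAP_SPECIFIC, COUNTING], size=n_cells,
                       p=list(mix))
    for kind in kinds:
        pref = int(rng.integers(n_laps))
        ramp = np.linspace(0.25, 1.0, n_laps)
        if rng.uniform() < 0.5:
            ramp = ramp[::-1].copy()
        cells = []
        for env in range(2):
            peak = int(rng.integers(lap_length))
            profile = np.exp(-0.5 * ((np.arange(lap_length) - peak)
                                     / 1.0) ** 2)
            act = np.zeros((n_trials, n_laps, lap_length))
            if kind == SPATIAL:
                act[:] = profile[None, None, :]
            elif kind == LAP_SPECIFIC:
                act[:, pref, :] = profile[None, :]
            else:
                act[:] = ramp[None, :, None] * profile[None, None, :]
            act = np.clip(act + rng.normal(0, noise_sd, act.shape), 0,
                          None) if noise_sd > 0 else act
            cells.append(LapActivity(act))
        pop1.append(cells[0])
        pop2.append(cells[1])
        labels.append(kind)
    return pop1, pop2, labels
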