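"""Experiment orchestration: configs, run directories, rate-map export, and
the model-side remapping experiment (train on 2D worlds, export grid/place
maps in two unseen environments, run the place-grid pair statistics)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Optional, Sequence

import numpy as np
import yaml

from . import remap as remap_mod
from . import training as tr
from . import worlds as W
from .model import TEM, StreamSpec
from .ratemaps import compute_ratemap
from .remap import CellRecord, GRID, PLACE
from .training import TrainConfig, TrainResult, run_model_on_trajectory


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Flat experiment configuration (task + model + training + analysis)."""

    world_kind: str = "line"
    world_sizes: Sequence[int] = (4, 5, 6)
    ns: int = 45
    ns_c: int = 10
    n_g: Sequence[int] = (12, 9)
    n_f: Sequence[int] = (4, 3)
    n_env_rounds: int = 10
    batch_size: int = 16
    env_steps_range: Sequence[int] = (200, 300)
    bptt_len: int = 25
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    straight_bias: float = 1.0
    analyses: Sequence[str] = ()
    eval_steps: int = 400
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in d.items()}
        return json.dumps(d, sort_keys=True, indent=1)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            world_kind=self.world_kind, world_sizes=tuple(self.world_sizes),
            ns=self.ns, n_env_rounds=self.n_env_rounds,
            batch_size=self.batch_size,
            env_steps_range=tuple(self.env_steps_range),
            bptt_len=self.bptt_len, lr_start=self.lr_start,
            lr_end=self.lr_end, straight_bias=self.straight_bias,
            seed=self.seed)

    def stream_spec(self) -> StreamSpec:
        return StreamSpec(n_g=tuple(self.n_g), n_f=tuple(self.n_f),
                          ns=self.ns, ns_c=self.ns_c)


# ---------------------------------------------------------------------------
# rate-map export from trained models
# ---------------------------------------------------------------------------

def record_unit_activity(model: TEM, world: W.World,
                         policy: Optional[W.WalkPolicy] = None,
                         n_steps: int = 2000, seed: int = 0,
                         layer: str = "g"):
    """(activity (T, n_units), trajectory) for a fresh run of the model on
    one environment; `layer` is 'g' (structural) or 'p' (conjunctive)."""
    policy = policy or W.WalkPolicy()
    traj = W.walk(world, policy, n_steps, seed=seed)
    key = {"g": "g_inf", "p": "p_inf"}[layer]
    _, rec = run_model_on_trajectory(model, world, traj, record=(key,))
    return rec[key], traj


def export_ratemaps(model: TEM, world: W.World, layer: str = "g",
                    n_steps: int = 2000, seed: int = 0,
                    policy: Optional[W.WalkPolicy] = None):
    """One RateMap per unit of the chosen layer over a lattice world."""
    act, traj = record_unit_activity(model, world, policy, n_steps, seed,
                                     layer)
    maps = []
    for u in range(act.shape[1]):
        maps.append(compute_ratemap(act[:, u], traj.nodes, world))
    return maps


def export_lap_activity(model: TEM, world: W.World, n_trials: int = 15,
                        seed: int = 0, layer: str = "p") -> np.ndarray:
    """Lap-activity tensor (trials, n_laps, lap_length, n_units) from runs
    on a loop world (trials are consecutive full loops of one run, the
    canonical segmentation for a periodic track)."""
    if world.kind != W.LOOP:
        raise ConfigError("lap activity requires a loop world")
    lap = world.size_params["lap_length"]
    n_laps = world.size_params["n_laps"]
    n = world.n_nodes
    act, traj = record_unit_activity(
        model, world, W.WalkPolicy(), n_steps=n_trials * n + 1, seed=seed,
        layer=layer)
    # align to the next visit of node 0 so laps are phase-locked
    start = int(np.argmax(traj.nodes == 0))
    act = act[start:start + n_trials * n]
    if len(act) < n_trials * n:  # wrap-around short runs
        reps = int(np.ceil(n_trials * n / max(len(act), 1)))
        act = np.tile(act, (reps, 1))[: n_trials * n]
    return np.abs(act).reshape(n_trials, n_laps, lap, -1)


def tem_cell_records(model: TEM, worlds: Sequence[W.World],
                     env_ids: Sequence[str] = ("env1", "env2"),
                     n_steps: int = 2000, seed: int = 0,
                     min_rate: float = 0.05, standardize: bool = True):
    """CellRecords of model units across environments: structural units as
    grid-cell candidates, conjunctive units as place-cell candidates.
    Units whose peak activity is below `min_rate` in any environment are
    dropped as silent.

    Model activations carry arbitrary per-unit scales (unlike firing
    rates), so by default each unit's map is z-scored within each
    environment; without this the pair measures are dominated by unit
    amplitude rather than spatial structure."""
    layers = {"g": GRID, "p": PLACE}
    per_layer_maps = {lay: [] for lay in layers}
    for k, world in enumerate(worlds):
        for lay in layers:
            maps = export_ratemaps(model, world, layer=lay,
                                   n_steps=n_steps, seed=seed + k)
            per_layer_maps[lay].append(maps)
    records = []
    for lay, ctype in layers.items():
        n_units = len(per_layer_maps[lay][0])
        for u in range(n_units):
            maps = {env_ids[k]: per_layer_maps[lay][k][u]
                    for k in range(len(worlds))}
            peak = min(np.nanmax(np.abs(m.values))
                       if np.isfinite(m.values).any() else 0.0
                       for m in maps.values())
            if not np.isfinite(peak) or peak < min_rate:
                continue
            for m in maps.values():
                m.values = np.abs(m.values)
                if standardize:
                    v = m.values[m.mask]
                    if v.std() > 1e-9:
                        m.values = (m.values - v.mean()) / v.std()
            records.append(CellRecord(cell_id=f"{lay}{u}",
                                      animal_id="tem", cell_type=ctype,
                                      maps=maps))
    return records


def tem_grid_at_place_experiment(model: TEM, width: int, ns: int,
                                 n_steps: int = 2000, n_perms: int = 5000,
                                 grid_cutoff: float = 0.0,
                                 max_grid: int = 40, max_place: int = 60,
                                 seed: int = 0):
    """The model-side place-grid preservation analysis on two unseen square
    environments: export maps, filter, correlate gridAtPlace across the
    environment pair, and test against the place-peak permutation null."""
    rng = np.random.default_rng(seed)
    worlds = [W.assign_sensory(W.make_lattice_world(W.SQUARE, width, s),
                               ns, int(rng.integers(2 ** 31)))
              for s in range(2)]
    records = tem_cell_records(model, worlds, n_steps=n_steps, seed=seed)
    grids = [r for r in records if r.cell_type == GRID]
    places = [r for r in records if r.cell_type == PLACE]
    if grid_cutoff > 0:
        grids = remap_mod.preprocess_cells(
            grids, grid_cutoff=grid_cutoff, use_ideal=False)
    # keep spatially informative units (non-flat maps), bounded counts
    def spread(rec):
        v = np.concatenate([m.values[m.mask] for m in rec.maps.values()])
        return float(np.std(v))
    grids = sorted(grids, key=spread, reverse=True)[:max_grid]
    places = sorted(places, key=spread, reverse=True)[:max_place]
    records = grids + places
    result = remap_mod.pair_correlation_test(
        records, ("env1", "env2"), measure="gridAtPlace",
        n_perms=n_perms, scheme=remap_mod.RANDOM_LOCATION,
        use_ideal=False, border_frac=0.0, seed=seed)
    return result, records


# ---------------------------------------------------------------------------
# run directories
# ---------------------------------------------------------------------------

def run_experiment(config: RunConfig, out_dir) -> pathlib.Path:
    """simulate -> train -> export -> analyze, into a run directory.

    Re-running with the same config and seed reproduces the outputs."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    result: TrainResult = tr.train(config.train_config(),
                                   spec=config.stream_spec())
    meta = {"config_hash": config.config_hash, "package": "temkit"}
    result.metrics.assign(**meta).to_csv(out / "metrics.csv", index=False)
    result.model.save(out / "model.npz")
    # zero-shot evaluation on a fresh environment
    rng = np.random.default_rng(config.seed + 1)
    world = tr.make_world(config.world_kind,
                          int(rng.choice(list(config.world_sizes))),
                          config.ns, int(rng.integers(2 ** 31)))
    df = tr.evaluate_zero_shot(result.model, world, W.WalkPolicy(),
                               config.eval_steps,
                               seed=int(rng.integers(2 ** 31)))
    df.assign(**meta).to_csv(out / "zero_shot.csv", index=False)
    (out / "STAGES").write_text("simulate\ntrain\nevaluate\n")
    return out
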