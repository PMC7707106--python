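"""Training loop: truncated BPTT over sequences of environments.

The objective is the deterministic surrogate of the sequence ELBO:
``L_total = sum_t Lx_t + Lp_t + Lg_t`` where the sensory term ``Lx`` is a
cross-entropy evaluated for three generative routes (from the inferred p; from
the inferred g through the attractor; and ancestrally from the previous g
through path integration and the attractor), ``Lp`` and ``Lg`` are squared
errors between inferred and generated latents, and an optional memory term
ties the inferred p to the sensory-cued retrieval.  Losses are masked at
never-visited nodes, since their observations are unpredictable in principle.

Environments are run in parallel as a batch; Hebbian matrices are reset at
every environment switch.  BPTT windows are consecutive and non-overlapping.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import worlds as W
from .autodiff import Adam, Tensor
from .model import TEM, StreamSpec


@dataclasses.dataclass
class LossBreakdown:
    Lx_routes: tuple       # three cross-entropy terms (floats)
    Lp: float
    Lg: float
    total: object = None   # Tensor during training, float otherwise

    @property
    def Lx(self):
        return float(sum(self.Lx_routes))


@dataclasses.dataclass
class TrainConfig:
    """Hyper-parameters and schedules for a training run.

    The defaults mirror the open-field study conditions (BPTT window 25,
    learning rate annealed 1e-3 -> 1e-4, 2000-5000 steps per environment,
    forgetting/remembering rates ramped to 0.9999/0.5).  Desk-scale presets
    for the smaller tasks shrink the environment count and step budget, not
    the schedules."""

    world_kind: str = "square"
    world_sizes: Sequence[int] = (8, 9, 10, 11)
    ns: int = 45
    n_env_rounds: int = 60          # rounds of `batch_size` parallel envs
    batch_size: int = 16
    env_steps_range: tuple = (2000, 5000)
    bptt_len: int = 25
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    lambda_range: tuple = (0.5, 0.9999)
    eta_range: tuple = (0.1, 0.5)
    schedule_frac: float = 0.1      # fraction of rounds for lambda/eta ramp
    curriculum_frac: float = 0.2    # ramp of Lg/Lp weights and sensory_weight
    curriculum_start: float = 0.1
    memory_loss_weight: float = 1.0
    grad_clip: float = 2.0
    straight_bias: float = 1.0      # slight bias for straight paths (2D)
    loop_n_laps: int = 4
    loop_lap_length: int = 8
    dtype: str = "float32"          # training precision
    seed: int = 0

    def lr_at(self, frac: float) -> float:
        return float(self.lr_start * (self.lr_end / self.lr_start) ** frac)

    def ramp(self, frac: float, lo: float, hi: float, horizon: float):
        if horizon <= 0:
            return hi
        return float(lo + (hi - lo) * min(frac / horizon, 1.0))


def make_world(kind: str, size: int, ns: int, seed: int,
               loop_lap_length: int = 8, loop_n_laps: int = 4) -> W.World:
    if kind == W.LINE:
        w = W.make_line_world(size, seed)
    elif kind == W.TREE:
        w = W.make_tree_world(size, seed)
    elif kind in (W.SQUARE, W.HEX):
        w = W.make_lattice_world(kind, size, seed)
    elif kind == W.LOOP:
        w = W.make_loop_world(loop_lap_length, loop_n_laps, seed)
    else:
        raise W.WorldError(f"unknown world kind {kind!r}")
    return W.assign_sensory(w, ns, seed)


def n_actions_for(kind: str, max_size: int) -> int:
    """Size of the action vocabulary shared across environments of a task."""
    if kind == W.LINE:
        return 2 * (max_size - 1)
    if kind == W.TREE:
        return len(W.TREE_RELATIONS)
    if kind == W.SQUARE:
        return 4
    if kind == W.HEX:
        return 6
    if kind == W.LOOP:
        return 1
    raise W.WorldError(f"unknown world kind {kind!r}")


def visit_status(traj: W.Trajectory) -> np.ndarray:
    """Per-step codes: 0 first visit, 1 revisit via a previously used
    incoming edge, 2 revisit via a new edge (the zero-shot inference case).

    Step t is the arrival at traj.nodes[t]; its incoming edge is
    (nodes[t-1], actions[t-1]).  Step 0 is a first visit by convention."""
    seen_nodes, seen_edges = set(), set()
    codes = np.zeros(len(traj), dtype=np.int64)
    for t in range(len(traj)):
        node = int(traj.nodes[t])
        edge = None if t == 0 else (int(traj.nodes[t - 1]),
                                    int(traj.actions[t - 1]), node)
        if node not in seen_nodes:
            codes[t] = 0
        elif edge in seen_edges:
            codes[t] = 1
        else:
            codes[t] = 2
        seen_nodes.add(node)
        if edge is not None:
            seen_edges.add(edge)
    return codes


def node_agent_correct(traj: W.Trajectory) -> np.ndarray:
    """Oracle with perfect structural knowledge and per-node memory: correct
    exactly at previously visited nodes."""
    return visit_status(traj) > 0


def edge_agent_correct(traj: W.Trajectory) -> np.ndarray:
    """Oracle that memorizes directed edges: correct only when the incoming
    (node, action) transition has been taken before."""
    seen = set()
    out = np.zeros(len(traj), dtype=bool)
    for t in range(1, len(traj)):
        key = (int(traj.nodes[t - 1]), int(traj.actions[t - 1]))
        out[t] = key in seen
        seen.add(key)
    return out


def compute_loss(outputs, x_true, visited, weights):
    """Per-window loss terms; all terms are zeroed where visited is False.

    weights: dict with 'gp' (curriculum weight on Lg/Lp) and 'mem' (memory
    retrieval term weight)."""
    mask = np.asarray(visited, dtype=float)
    B = len(x_true)
    routes = []
    for key in ("logits_i", "logits_ii", "logits_iii"):
        routes.append(ad.sum_(ad.cross_entropy_logits(
            outputs[key], x_true, weight=mask)))
    lx = routes[0] + routes[1] + routes[2]
    mt = Tensor(mask[:, None])
    dp = outputs["p_inf"] - outputs["p_gen"]
    lp = ad.sum_(ad.mul(ad.square(dp), mt))
    if weights.get("mem", 0.0) > 0:
        dpx = outputs["p_inf"] - outputs["p_x"]
        lp = lp + ad.mul(ad.sum_(ad.mul(ad.square(dpx), mt)),
                         weights["mem"])
    lg = None
    for gi, gg in zip(outputs["g_inf"], outputs["g_gen"]):
        term = ad.sum_(ad.mul(ad.square(gi - gg), mt))
        lg = term if lg is None else lg + term
    wgp = weights.get("gp", 1.0)
    total = ad.mul(lx, 1.0 / max(B, 1)) + \
        ad.mul(lp + lg, wgp / max(B, 1))
    return LossBreakdown(
        Lx_routes=tuple(float(r.data) / max(B, 1) for r in routes),
        Lp=float(lp.data) / max(B, 1), Lg=float(lg.data) / max(B, 1),
        total=total)


@dataclasses.dataclass
class TrainResult:
    model: TEM
    metrics: pd.DataFrame
    config: TrainConfig


def _batch_envs(cfg: TrainConfig, rng, round_idx: int):
    """Worlds + trajectories + visit codes for one batch round."""
    sizes = rng.choice(list(cfg.world_sizes), size=cfg.batch_size)
    steps = int(rng.integers(cfg.env_steps_range[0],
                             cfg.env_steps_range[1] + 1))
    policy = W.WalkPolicy(straight_bias=(
        cfg.straight_bias if cfg.world_kind in (W.SQUARE, W.HEX) else 0.0))
    worlds, trajs, codes = [], [], []
    for b in range(cfg.batch_size):
        seed = int(rng.integers(2 ** 31))
        world = make_world(cfg.world_kind, int(sizes[b]), cfg.ns, seed,
                           cfg.loop_lap_length, cfg.loop_n_laps)
        traj = W.walk(world, policy, steps, seed=seed + 1,
                      env_id=round_idx * cfg.batch_size + b)
        worlds.append(world)
        trajs.append(traj)
        codes.append(visit_status(traj))
    return worlds, trajs, np.stack(codes)


def train(cfg: TrainConfig, model: Optional[TEM] = None,
          spec: Optional[StreamSpec] = None,
          progress: bool = False) -> TrainResult:
    """Train a TEM with Adam over truncated-BPTT windows.

    Raises RuntimeError on divergence (non-finite loss)."""
    with ad.default_dtype(cfg.dtype):
        return _train_inner(cfg, model, spec, progress)


def _train_inner(cfg, model, spec, progress):
    rng = np.random.default_rng(cfg.seed)
    n_actions = n_actions_for(cfg.world_kind, max(cfg.world_sizes))
    if model is None:
        model = TEM(spec or StreamSpec(ns=cfg.ns), n_actions,
                    seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=cfg.lr_start, clip_norm=cfg.grad_clip)
    rows = []
    t0 = time.time()
    for rnd in range(cfg.n_env_rounds):
        frac = rnd / max(cfg.n_env_rounds - 1, 1)
        lam = cfg.ramp(frac, *cfg.lambda_range, cfg.schedule_frac)
        eta = cfg.ramp(frac, *cfg.eta_range, cfg.schedule_frac)
        wgp = cfg.ramp(frac, cfg.curriculum_start, 1.0, cfg.curriculum_frac)
        sw = cfg.ramp(frac, 0.0, 1.0, cfg.curriculum_frac)
        opt.lr = cfg.lr_at(frac)
        worlds, trajs, codes = _batch_envs(cfg, rng, rnd)
        T = len(trajs[0])
        xs = np.stack([t.objects for t in trajs])        # (B, T)
        acts = np.stack([t.actions for t in trajs])      # (B, T)
        state = model.init_state(cfg.batch_size)
        correct = np.zeros((cfg.batch_size, T), dtype=bool)
        for w0 in range(0, T, cfg.bptt_len):
            w1 = min(w0 + cfg.bptt_len, T)
            total = None
            parts = []
            for t in range(w0, w1):
                out, state = model.step(
                    xs[:, t], acts[:, t - 1] if t > 0 else
                    np.zeros(cfg.batch_size, dtype=np.int64),
                    state, lam, eta, sensory_weight=sw, first=(t == 0))
                lb = compute_loss(out, xs[:, t], codes[:, t] > 0,
                                  {"gp": wgp, "mem": cfg.memory_loss_weight})
                parts.append(lb)
                total = lb.total if total is None else total + lb.total
                correct[:, t] = (
                    out["logits_iii"].data.argmax(-1) == xs[:, t])
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at round {rnd}")
            opt.zero_grad()
            total.backward()
            opt.step()
            state = state.detached()
        for st, name in ((0, "first"), (1, "same_edge"), (2, "new_edge")):
            sel = codes == st
            rows.append({
                "round": rnd, "status": name,
                "n": int(sel.sum()),
                "accuracy": float(correct[sel].mean()) if sel.any() else
                np.nan,
                "Lx": np.mean([p.Lx for p in parts]),
                "Lp": np.mean([p.Lp for p in parts]),
                "Lg": np.mean([p.Lg for p in parts]),
                "lambda": lam, "eta": eta, "lr": opt.lr,
                "sensory_weight": sw,
                "frac_nodes_visited": float(np.mean(
                    [len(set(t.nodes[:k].tolist())) / w.n_nodes
                     for t, w, k in zip(trajs, worlds, [T] * len(trajs))])),
                "elapsed_s": time.time() - t0,
            })
        if progress:
            acc = rows[-1]["accuracy"]
            print(f"round {rnd}: revisit-new-edge acc={acc:.3f} "
                  f"Lx={rows[-1]['Lx']:.2f}")
    return TrainResult(model=model, metrics=pd.DataFrame(rows), config=cfg)


def run_model_on_trajectory(model: TEM, world: W.World, traj: W.Trajectory,
                            sensory_weight: float = 1.0,
                            lambda_: float = 0.9999, eta: float = 0.5,
                            record=()):
    """Run a (trained) model over one trajectory with fresh memories.

    Returns (correct (T,) bool from the ancestral route-iii prediction,
    recorded dict of per-step arrays for keys in `record`)."""
    T = len(traj)
    state = model.init_state(1)
    correct = np.zeros(T, dtype=bool)
    rec = {k: [] for k in record}
    with ad.no_grad():
        for t in range(T):
            a = traj.actions[t - 1:t] if t > 0 else np.zeros(1, np.int64)
            out, state = model.step(traj.objects[t:t + 1], a, state,
                                    lambda_, eta,
                                    sensory_weight=sensory_weight,
                                    first=(t == 0))
            correct[t] = int(out["logits_iii"].data.argmax(-1)[0]) == \
                int(traj.objects[t])
            for k in record:
                v = out[k]
                if isinstance(v, list):
                    rec[k].append(np.concatenate(
                        [x.data[0] for x in v]))
                else:
                    rec[k].append(v.data[0])
    return correct, {k: np.asarray(v) for k, v in rec.items()}


def evaluate_zero_shot(model: TEM, world: W.World, policy: W.WalkPolicy,
                       n_steps: int, seed: int = 0) -> pd.DataFrame:
    """Per-step prediction correctness on an unseen environment, labeled by
    visit status; memories start empty."""
    traj = W.walk(world, policy, n_steps, seed=seed)
    codes = visit_status(traj)
    correct, _ = run_model_on_trajectory(model, world, traj)
    return pd.DataFrame({
        "t": np.arange(n_steps), "node": traj.nodes,
        "status": np.array(["first", "same_edge", "new_edge"])[codes],
        "correct": correct,
        "node_agent": node_agent_correct(traj),
        "edge_agent": edge_agent_correct(traj),
    })


def zero_shot_summary(df: pd.DataFrame) -> pd.Series:
    return df.groupby("status")["correct"].mean()
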