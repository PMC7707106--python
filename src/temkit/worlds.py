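"""Relational graph worlds and action-labeled walks.

Four families of environments are provided, each a deterministic labeled
transition system with a random sensory-token assignment per node:

* **line** -- fully connected ordered line (transitive-inference task); the
  action for edge i -> j encodes (sign(j - i), |j - i|).
* **tree** -- full binary family tree with 10 relation types (social
  hierarchy task).
* **square / hex** -- 4-connected square lattices and 6-connected hexagonal
  patches of a triangular lattice (open-field spatial tasks).
* **loop** -- directed cycle of ``n_laps`` laps of length ``lap_length``
  whose sensory tokens repeat every lap except a unique per-environment
  reward token at the start of the full loop.

Walks over a world are produced by :func:`walk` under a configurable
:class:`WalkPolicy` (softmax over per-edge scores: straight-path persistence,
approach-to-shiny-object, and boundary dwell biases).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional

import numpy as np

LINE, TREE, SQUARE, HEX, LOOP = "line", "tree", "square", "hex", "loop"

#: relation vocabulary of the family-tree task (gender collapsed; children,
#: niblings and cousins disambiguated by birth order).
TREE_RELATIONS = (
    "sibling", "parent", "grandparent", "child1", "child2",
    "auntuncle", "niecenephew1", "niecenephew2", "cousin1", "cousin2",
)


class WorldError(ValueError):
    pass


@dataclasses.dataclass
class World:
    """Action-labeled relational graph with a per-node sensory assignment."""

    kind: str
    n_nodes: int
    edges: list  # list of (src, action_id, dst)
    action_vocab: list
    sensory: Optional[np.ndarray] = None  # node -> object id
    ns: Optional[int] = None
    size_params: dict = dataclasses.field(default_factory=dict)
    shiny_nodes: frozenset = frozenset()
    coords: Optional[np.ndarray] = None  # (n_nodes, 2) spatial layout if any

    def __post_init__(self):
        self._trans = {}
        self._out = [[] for _ in range(self.n_nodes)]
        for s, a, d in self.edges:
            key = (s, a)
            if key in self._trans and self._trans[key] != d:
                raise WorldError(f"non-deterministic transition at {key}")
            self._trans[key] = d
            self._out[s].append((a, d))

    @property
    def nodes(self):
        return range(self.n_nodes)

    @property
    def n_actions(self):
        return len(self.action_vocab)

    def step(self, node: int, action: int) -> Optional[int]:
        return self._trans.get((node, action))

    def out_edges(self, node: int):
        return self._out[node]

    def undirected_edge_count(self) -> int:
        return len({(min(s, d), max(s, d)) for s, _, d in self.edges})

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "n_nodes": self.n_nodes,
            "edges": [list(map(int, e)) for e in self.edges],
            "action_vocab": [str(a) for a in self.action_vocab],
            "sensory": None if self.sensory is None else
                       [int(v) for v in self.sensory],
            "ns": self.ns,
            "size_params": self.size_params,
            "shiny_nodes": sorted(int(v) for v in self.shiny_nodes),
            "coords": None if self.coords is None else self.coords.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "World":
        d = json.loads(s)
        return cls(
            kind=d["kind"], n_nodes=d["n_nodes"],
            edges=[tuple(e) for e in d["edges"]],
            action_vocab=d["action_vocab"],
            sensory=None if d["sensory"] is None else np.asarray(d["sensory"]),
            ns=d["ns"], size_params=d["size_params"],
            shiny_nodes=frozenset(d["shiny_nodes"]),
            coords=None if d["coords"] is None else np.asarray(d["coords"]),
        )


@dataclasses.dataclass
class Trajectory:
    """Sequence of (node, action, object) steps through one environment."""

    nodes: np.ndarray
    actions: np.ndarray
    objects: np.ndarray
    env_id: int = 0

    def __len__(self):
        return len(self.nodes)

    def validate(self, world: World) -> bool:
        for t in range(len(self.nodes) - 1):
            if world.step(int(self.nodes[t]), int(self.actions[t])) != \
                    int(self.nodes[t + 1]):
                return False
        return bool(np.all(world.sensory[self.nodes] == self.objects))

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps({"node": int(n), "action": int(a), "object": int(o)})
            for n, a, o in zip(self.nodes, self.actions, self.objects))


@dataclasses.dataclass
class WalkPolicy:
    """Softmax walk policy; all-zero biases give a uniform random walk."""

    straight_bias: float = 0.0
    object_bias: float = 0.0
    border_bias: float = 0.0
    temperature: float = 1.0

    def __post_init__(self):
        if min(self.straight_bias, self.object_bias, self.border_bias) < 0:
            raise WorldError("walk biases must be nonnegative")


# ---------------------------------------------------------------------------
# world constructors
# ---------------------------------------------------------------------------

def make_line_world(n_states: int, seed: int = 0) -> World:
    """Fully connected ordered line; action for i -> j is (sign, distance)."""
    if n_states < 2:
        raise WorldError("line world needs at least 2 states")
    vocab = []
    for dist in range(1, n_states):
        vocab.append(("+", dist))
        vocab.append(("-", dist))
    index = {a: i for i, a in enumerate(vocab)}
    edges = []
    for i in range(n_states):
        for j in range(n_states):
            if i == j:
                continue
            a = ("+" if j > i else "-", abs(j - i))
            edges.append((i, index[a], j))
    coords = np.stack([np.arange(n_states), np.zeros(n_states)], axis=1)
    return World(LINE, n_states, edges, vocab,
                 size_params={"n_states": n_states}, coords=coords.astype(float))


def _tree_children(n_nodes):
    """Heap-indexed full binary tree: children of i are 2i+1, 2i+2."""
    ch = {}
    for i in range(n_nodes):
        c1, c2 = 2 * i + 1, 2 * i + 2
        if c2 < n_nodes:
            ch[i] = (c1, c2)
    return ch


def make_tree_world(levels: int, seed: int = 0) -> World:
    """Full binary family tree; `levels` calibrated so 3 levels -> 15 nodes.

    Relation edges are generated for the 10 relation types wherever defined.
    """
    if levels < 1:
        raise WorldError("tree world needs at least 1 level")
    n_nodes = 2 ** (levels + 1) - 1
    ch = _tree_children(n_nodes)
    parent = {}
    for i, (c1, c2) in ch.items():
        parent[c1] = i
        parent[c2] = i
    vocab = list(TREE_RELATIONS)
    idx = {r: i for i, r in enumerate(vocab)}
    edges = []

    def sib(i):
        if i not in parent:
            return None
        c1, c2 = ch[parent[i]]
        return c2 if i == c1 else c1

    for i in range(n_nodes):
        s = sib(i)
        if s is not None:
            edges.append((i, idx["sibling"], s))
        if i in parent:
            edges.append((i, idx["parent"], parent[i]))
            gp = parent.get(parent[i])
            if gp is not None:
                edges.append((i, idx["grandparent"], gp))
            ps = sib(parent[i])
            if ps is not None:
                edges.append((i, idx["auntuncle"], ps))
                if ps in ch:
                    edges.append((i, idx["cousin1"], ch[ps][0]))
                    edges.append((i, idx["cousin2"], ch[ps][1]))
        if i in ch:
            edges.append((i, idx["child1"], ch[i][0]))
            edges.append((i, idx["child2"], ch[i][1]))
        if s is not None and s in ch:
            edges.append((i, idx["niecenephew1"], ch[s][0]))
            edges.append((i, idx["niecenephew2"], ch[s][1]))
    coords = np.zeros((n_nodes, 2))
    for i in range(n_nodes):
        depth = int(math.floor(math.log2(i + 1)))
        pos = i - (2 ** depth - 1)
        coords[i] = (pos - (2 ** depth - 1) / 2.0, -depth)
    return World(TREE, n_nodes, edges, vocab,
                 size_params={"levels": levels}, coords=coords)


_SQUARE_DIRS = (("N", (0, 1)), ("E", (1, 0)), ("S", (0, -1)), ("W", (-1, 0)))
# axial-coordinate directions of a 6-connected triangular lattice
_HEX_DIRS = (("E", (1, 0)), ("NE", (1, -1)), ("NW", (0, -1)),
             ("W", (-1, 0)), ("SW", (-1, 1)), ("SE", (0, 1)))


def make_lattice_world(kind: str, width: int, seed: int = 0) -> World:
    """Square (4-connected) or hexagonal (6-connected) lattice world.

    For ``hex``, `width` is the number of nodes on each outer side of a
    hexagonal patch of the triangular lattice (axial coordinates), giving
    3*width**2 - 3*width + 1 nodes.
    """
    if width < 1:
        raise WorldError("lattice width must be >= 1")
    if kind == SQUARE:
        dirs = _SQUARE_DIRS
        cells = [(x, y) for y in range(width) for x in range(width)]
        coords = np.asarray(cells, dtype=float)
    elif kind == HEX:
        dirs = _HEX_DIRS
        n = width - 1
        cells = [(q, r) for q in range(-n, n + 1) for r in range(-n, n + 1)
                 if -n <= -q - r <= n]
        # axial -> cartesian layout (unit lattice spacing)
        coords = np.asarray([(q + r / 2.0, r * math.sqrt(3) / 2.0)
                             for q, r in cells])
    else:
        raise WorldError(f"unknown lattice kind: {kind!r}")
    index = {c: i for i, c in enumerate(cells)}
    vocab = [name for name, _ in dirs]
    edges = []
    for c, i in index.items():
        for a, (name, (dx, dy)) in enumerate(dirs):
            nb = (c[0] + dx, c[1] + dy)
            if nb in index:
                edges.append((i, a, index[nb]))
    return World(kind, len(cells), edges, vocab,
                 size_params={"width": width}, coords=coords)


def inverse_action(world: World, action: int) -> int:
    """Opposite action on a spatial world (N <-> S, E <-> W, etc.)."""
    if world.kind == SQUARE:
        return (action + 2) % 4
    if world.kind == HEX:
        return (action + 3) % 6
    if world.kind == LINE:
        sign, dist = world.action_vocab[action]
        return world.action_vocab.index(("-" if sign == "+" else "+", dist))
    raise WorldError(f"no inverse action for kind {world.kind!r}")


def make_loop_world(lap_length: int, n_laps: int, seed: int = 0) -> World:
    """Directed cycle of n_laps laps; token pattern repeats per lap except a
    unique reward token at node 0 (start of each full loop)."""
    if lap_length < 1 or n_laps < 1:
        raise WorldError("lap_length and n_laps must be >= 1")
    n = lap_length * n_laps
    edges = [(i, 0, (i + 1) % n) for i in range(n)]
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return World(LOOP, n, edges, ["forward"],
                 size_params={"lap_length": lap_length, "n_laps": n_laps},
                 coords=coords)


def assign_sensory(world: World, ns: int, seed: int) -> World:
    """Assign object tokens uniformly with replacement (fresh copy).

    Loop worlds get a per-lap repeating pattern with the reserved reward
    token ``ns - 1`` at node 0."""
    if ns < 1:
        raise WorldError("ns must be >= 1")
    rng = np.random.default_rng(seed)
    w = dataclasses.replace(world)
    if world.kind == LOOP:
        lap = world.size_params["lap_length"]
        pattern = rng.integers(0, max(ns - 1, 1), size=lap)
        sensory = np.tile(pattern, world.n_nodes // lap)
        sensory[0] = ns - 1  # unique per-environment reward observation
    else:
        sensory = rng.integers(0, ns, size=world.n_nodes)
    w.sensory = sensory.astype(np.int64)
    w.ns = ns
    return w


# ---------------------------------------------------------------------------
# walks
# ---------------------------------------------------------------------------

def _border_score(world: World) -> np.ndarray:
    """1 for boundary nodes of a lattice (fewer than max degree), else 0."""
    deg = np.asarray([len(world.out_edges(i)) for i in world.nodes])
    return (deg < deg.max()).astype(float)


def _dist_to_shiny(world: World) -> np.ndarray:
    """Graph distance of each node to the nearest shiny node (BFS)."""
    INF = np.inf
    dist = np.full(world.n_nodes, INF)
    frontier = list(world.shiny_nodes)
    for s in frontier:
        dist[s] = 0
    # BFS over reversed edges (distance *to* shiny nodes)
    rev = [[] for _ in range(world.n_nodes)]
    for s, _, d in world.edges:
        rev[d].append(s)
    while frontier:
        nxt = []
        for v in frontier:
            for u in rev[v]:
                if dist[u] > dist[v] + 1:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def walk(world: World, policy: WalkPolicy, n_steps: int, seed: int = 0,
         start: Optional[int] = None, env_id: int = 0) -> Trajectory:
    """Sample an action-labeled trajectory of ``n_steps`` transitions."""
    if world.sensory is None:
        raise WorldError("world has no sensory assignment; call assign_sensory")
    if n_steps < 1:
        raise WorldError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    border = _border_score(world) if policy.border_bias > 0 else None
    shiny_dist = (_dist_to_shiny(world)
                  if policy.object_bias > 0 and world.shiny_nodes else None)
    node = int(rng.integers(world.n_nodes)) if start is None else start
    nodes, actions = [node], []
    prev_action = None
    for _ in range(n_steps):
        out = world.out_edges(node)
        if not out:
            raise WorldError(f"walk stuck: node {node} has no outgoing edges")
        scores = np.zeros(len(out))
        for k, (a, d) in enumerate(out):
            if prev_action is not None and a == prev_action:
                scores[k] += policy.straight_bias
            if shiny_dist is not None:
                scores[k] += policy.object_bias * (
                    shiny_dist[node] - shiny_dist[d])
            if border is not None:
                scores[k] += policy.border_bias * border[d]
        p = np.exp((scores - scores.max()) / policy.temperature)
        p /= p.sum()
        k = rng.choice(len(out), p=p)
        a, node = out[k]
        actions.append(a)
        nodes.append(node)
        prev_action = a
    nodes = np.asarray(nodes[:-1], dtype=np.int64)
    actions = np.asarray(actions, dtype=np.int64)
    return Trajectory(nodes=nodes, actions=actions,
                      objects=world.sensory[nodes], env_id=env_id)


def covering_path_length(world: World, max_len: Optional[int] = None):
    """Length (edge count) of a shortest node-covering path, by DFS search
    for a Hamiltonian path first; falls back to None if none exists."""
    n = world.n_nodes
    adj = [[d for _, d in world.out_edges(i)] for i in range(n)]

    def extend(node, visited, depth):
        if depth == n:
            return True
        for d in adj[node]:
            if d not in visited:
                visited.add(d)
                if extend(d, visited, depth + 1):
                    return True
                visited.remove(d)
        return False

    for s in range(n):
        if extend(s, {s}, 1):
            return n - 1
    return None
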