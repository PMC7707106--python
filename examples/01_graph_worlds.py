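"""Build the task graphs and take a biased walk.

Constructs one world of each family, prints its size against the closed
form, and shows how a straight-path bias changes walk statistics on a 2D
lattice.
"""

import numpy as np

from temkit import worlds as W

line = W.make_line_world(5)
tree = W.make_tree_world(3)
hexw = W.make_lattice_world(W.HEX, 5)
square = W.make_lattice_world(W.SQUARE, 8)
loop = W.make_loop_world(8, 4)

print("line of 5 states:", line.n_nodes, "nodes,", len(line.edges),
      "labeled edges (complete digraph: n(n-1) = 20)")
print("3-level family tree:", tree.n_nodes, "nodes (full binary tree)")
print("hex patch, edge width 5:", hexw.n_nodes,
      "nodes (3w^2 - 3w + 1 = 61)")
print("square of width 8:", square.n_nodes, "nodes")
print("loop of 4 laps x 8 bins:", loop.n_nodes, "nodes")

# ordinal query on a 6-state line: which node is 3 above node 2?
line6 = W.make_line_world(6)
a = line6.action_vocab.index(("+", 3))
print("line query '3 above node 2' ->", line6.step(2, a))

# a walk with a straight-path bias has longer runs of repeated actions
world = W.assign_sensory(square, ns=45, seed=0)


def mean_run_length(traj):
    runs, cur = [], 1
    for a, b in zip(traj.actions[:-1], traj.actions[1:]):
        cur = cur + 1 if a == b else (runs.append(cur), 1)[1]
    return np.mean(runs)


plain = W.walk(world, W.WalkPolicy(), 5000, seed=1)
biased = W.walk(world, W.WalkPolicy(straight_bias=2.0), 5000, seed=1)
print(f"mean straight-run length: unbiased {mean_run_length(plain):.2f}, "
      f"biased {mean_run_length(biased):.2f}")
print("(the biased agent keeps heading direction longer, the behavioral "
      "statistic under which grid-like codes emerge)")
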