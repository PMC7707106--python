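"""Train a small model on the transitive-inference (line) task.

A two-stream network is trained on fully connected line graphs of 4-6
states with random token assignments, then evaluated zero-shot in unseen
environments.  Prediction accuracy is split by visit status: first visits
are unpredictable in principle (chance = 1/45), while revisits -- including
revisits via a never-taken edge -- become predictable once the structure
and the memory machinery are learned.

This desk demo uses a reduced round budget (minutes); push n_env_rounds to
several hundred for the full effect.
"""

import numpy as np
import pandas as pd

from temkit import worlds as W
from temkit.model import StreamSpec
from temkit.training import (TrainConfig, evaluate_zero_shot, make_world,
                             train)

cfg = TrainConfig(world_kind="line", world_sizes=(4, 5, 6), ns=45,
                  n_env_rounds=60, batch_size=16,
                  env_steps_range=(250, 300), straight_bias=0.0, seed=0)
spec = StreamSpec(n_g=(12, 9), n_f=(4, 3), ns=45, ns_c=10)
print("training on", cfg.n_env_rounds, "rounds of", cfg.batch_size,
      "parallel line-graph environments ...")
res = train(cfg, spec=spec, progress=True)

rng = np.random.default_rng(99)
frames = []
for k in range(5):
    world = make_world("line", int(rng.integers(4, 7)), 45,
                       int(rng.integers(2 ** 31)))
    frames.append(evaluate_zero_shot(res.model, world, W.WalkPolicy(),
                                     300, seed=int(rng.integers(2 ** 31))))
df = pd.concat(frames)
print("\nzero-shot accuracy in unseen environments, by visit status:")
print(df.groupby("status")["correct"].mean().round(3))
print("node-agent oracle (perfect structure + per-node memory):")
print(df.groupby("status")["node_agent"].mean().round(3))
print("\nfirst visits sit at chance (1/45 = 0.022); at this short demo "
      "budget the model is early on its learning curve -- around 300 "
      "rounds zero-shot revisit accuracy clears 0.7 and by ~700 rounds "
      "0.9, approaching the node-agent oracle (see tests/ and "
      "scripts/acceptance.py)")
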