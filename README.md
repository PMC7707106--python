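# temkit

A scientific Python implementation of the **Tolman–Eichenbaum Machine
(TEM)** — a factorized structural/sensory memory network for the
hippocampal–entorhinal system — together with the relational graph worlds
it is trained on and the neural-representation statistics (gridness,
gridAtPlace, minDist, event-specific rate) used to compare model and
recorded grid/place-cell populations.

## The problem

An agent walks on a graph (an open arena, an ordered line, a family tree,
a multi-lap loop) whose nodes carry arbitrary sensory tokens, and must
predict the next observation.  Solving this across many environments that
share structure but differ in tokens requires *factorizing* knowledge: an
abstract structural code **g** that path-integrates under relational
actions (`g_t = f_g(g_{t-1} + W_a g_{t-1})`, medial-entorhinal analogue), a
sensory code **x** (lateral-entorhinal analogue), and a conjunctive code
**p = f_p(x̃ ⊙ g̃)** (hippocampal analogue) bound one-shot into a fast
Hebbian memory `M_t = λM_{t-1} + η(p_t − p̂_t)(p_t + p̂_t)ᵀ` and retrieved
by attractor dynamics `h ← f_p(κh + Mh)`.  Trained end-to-end by
backpropagation through time — *through* the memory writes and attractor
iterations — the network performs zero-shot inference: on returning to a
node via a never-taken edge it predicts the token seen there before.  Its
units develop grid-, place-, border- and lap-coding responses, and its
remapping behavior across environments preserves place–grid relationships,
a quantitative prediction the analysis suite measures with permutation
statistics.

The package is a library first (`import temkit`), with narrative scripts
under `examples/` and a thin `temkit` CLI (`simulate`, `train`, `synth`,
`analyze`, `run`) for shell use.  Since the datasets the remapping
analysis was designed for have no public accession, a synthetic generator
(`temkit.synthetic`) produces grid/place/lap-cell populations with known
ground truth (module realignment, a phase-preservation parameter ρ, noise)
so every statistic is testable.

## Worked example

`python examples/02_memory_retrieval.py` — one-shot Hebbian storage and
attractor pattern completion:

```
stored 5 patterns in a 20x20 Hebbian matrix
cue 0 (40% strength) -> best match 0, cosine 0.976
cue 1 (40% strength) -> best match 1, cosine 0.988
cue 2 (40% strength) -> best match 2, cosine 0.994
cue 3 (40% strength) -> best match 3, cosine 0.988
cue 4 (40% strength) -> best match 4, cosine 0.982
```

Each degraded cue settles onto its own stored conjunction — the mechanism
by which a revisited location recalls what was seen there.

`python examples/04_synthetic_remapping.py` — the place–grid preservation
statistic on synthetic populations:

```
rho=1: gridAtPlace correlation r=+0.878 over 30 pairs, permutation p=0.0005
rho=0: gridAtPlace correlation r=-0.351 over 24 pairs, permutation p=0.9075
```

`r` correlates, across place–grid cell pairs, the grid cell's firing rate
at the place cell's peak in environment 1 (X) against environment 2 (Y);
the null re-draws place peaks and recomputes both.  With phase
preservation (ρ=1) the relationship survives remapping; with ρ=0 it does
not.

`python examples/03_train_line_task.py` trains a small model on the
transitive-inference task and prints zero-shot accuracy by visit status
(first visits sit at chance 1/45; revisit accuracy rises toward the
node-agent oracle as training lengthens).  `examples/05_esr_lap_cells.py`
shows the hand-computable ESR example — a lap-2-only cell has ESR
`(-0.25, +0.75, -0.25, -0.25)` and classification ratio `3 > 1.25` — and
a population that spatially remaps while keeping its lap code.

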