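# Methods

`temkit` implements a factorized structural/sensory memory network — the
Tolman–Eichenbaum Machine (TEM) — together with the graph-world tasks it is
trained on and the neural-representation statistics used to interrogate its
(and real) grid/place-cell populations.  This note records the model as
implemented, the choices made where the design was genuinely open, and what
the synthetic data can and cannot establish.

## The model

The agent sees a stream of sensory tokens `x_t` and relational actions
`a_t` generated by walks on a graph whose nodes carry randomly assigned
tokens.  The objective is next-observation prediction.  Knowledge is
factorized into:

* **Structural code `g`** (medial-entorhinal analogue): per-stream vectors
  that *path-integrate* — `g_t = f_g(g_{t-1} + W_a g_{t-1})` with one
  learnable matrix per action per stream, `f_g` clipping to [−1, 1].  The
  same transition weights serve the generative and inference passes.
* **Sensory code**: one-hot tokens are compressed to a two-hot code over
  `ns_c = 10` positions (token *i* ↦ the *i*-th 2-subset in lexicographic
  order; capacity C(10,2) = 45 = `ns`), exponentially filtered per stream
  (`x^f_t = (1−α_f) x^f_{t-1} + α_f x^c_t`, learnable `α_f`), then
  normalized (demean → rectify → unit norm), scaled by `w_p`, and tiled.
* **Conjunctive code `p`** (hippocampal analogue): elementwise product of
  the tiled sensory vector and the repeated structural projection (the
  first `n_f` components of `g`, each repeated `ns_c` times), passed
  through a leaky-rectified unit thresholded at ±1.  By construction this
  equals a flattened outer product: unit `(j, i)` binds structural
  component `j` to sensory component `i`.
* **Fast Hebbian memory**: `M_t = λ M_{t-1} + η (p_t − p̂_t)(p_t + p̂_t)ᵀ`,
  reset at every environment switch.  A second, sensory-cued matrix `M^x`
  (same rule with the sensory retrieval `p^x`) accelerates learning; the
  generative matrix is restricted to an upper-triangular stream-block
  structure (stream f′ → f only when f′ ≥ f).  Retrieval iterates
  `h ← f_p(κ h + M h)` (κ = 0.8, 5 iterations; in the generative pass
  stream *k* of *n* stops after `max(5−k+1, 1)` iterations, its frozen
  value still feeding lower streams).
* **Decoder**: logits = `f_d(w_x · W_tileᵀ p¹) + b_x`, where `W_tileᵀ`
  pools the tiled copies of the stream-1 block back to `ns_c` values and
  `f_d` is a bias-free 2-layer MLP.  Stream 1 predicts the raw token,
  which presses it toward the fastest spatial scale.

Inference order per step: compress → filter → sensory-cued retrieval
(`p^x` from `M^x`) → infer `g` → infer `p` → Hebbian writes → generative
predictions of `x` by three routes (from inferred `p_t`; from `g_t`
through the attractor; ancestrally from `g_{t-1}` through path integration
and the attractor).  The ancestral route is the model's genuine
"prediction before seeing", and is what all accuracy metrics use.

`g` inference fuses the path-integrated mean with a memory-cued estimate
(2-layer MLPs mapping the pooled sensory retrieval to a mean and a
softplus precision; a second MLP gives the path precision from
`g_{t-1}`): a precision-weighted average, multiplied by a curriculum
weight `w ∈ [0,1]` on the memory precision, so `w = 0` reduces exactly to
path integration.

**Deterministic build.**  The probabilistic formulation is trained as its
means-only surrogate: `L_total = Σ_t Lx_t + Lp_t + Lg_t`, with `Lx` a
cross-entropy summed over the three generative routes, `Lp`/`Lg` squared
errors between inferred and generated latents (plus a memory term tying
`p_t` to `p^x_t`), and all terms zeroed at never-visited nodes, whose
observations are unpredictable in principle.  No sampling anywhere.

## Training

Truncated BPTT with consecutive, non-overlapping 25-step windows (100 for
the loop task), Adam with learning rate annealed exponentially 1e-3 →
1e-4 over the environment budget, gradient clipping at global norm 2.0.
Gradients flow through the Hebbian writes and attractor iterations, which
is why the package carries its own reverse-mode tape (`temkit.autodiff`)
with fused primitives for the memory update and the attractor loop;
gradients of every primitive and of the full three-step rollout are
checked against central finite differences in the test-suite.  Training
runs in float32 (the Hebbian matrices dominate memory bandwidth);
analysis code is float64.

Schedules (ramp shapes were not prescribed; these are the package's
choices): λ and η ramp linearly from (0.5, 0.1) to (0.9999, 0.5) over the
first 10 % of environments; the `Lg`/`Lp` curriculum weight ramps 0.1 → 1
and the memory-fusion weight 0 → 1 over the first 20 %.  Environments run
in parallel batches of 16; each batch round draws fresh worlds with fresh
token assignments, and memories are reset at the switch.

### Problem sizes

The open-field configuration is 5 streams, `n_g = [30,30,24,18,18]`,
`n_f = [10,10,8,6,6]` (hippocampal blocks [100,100,80,60,60]), `ns = 45`;
the loop task uses `n_g = [18,18,15,15,15]`, `n_f = [6,6,5,4,4]` and BPTT
100.  Full 2D runs need on the order of 50 000 gradient updates and are
documented long-running (hours on one CPU).  The test-suite and the
acceptance script therefore run *scaled-down twins*: 2 streams
(`n_g = [12, 9]`, `n_f = [4, 3]`), line graphs of 4–6 states or squares
of width 4–5, a few hundred batch rounds.  These sizes were chosen as the
smallest at which the qualitative phenomena (zero-shot revisit inference,
positive grid-at-place coupling) are stable; thresholds in the tests are
the relaxed desk-scale ones stated alongside them.

## Analysis suite

* **Rate maps**: mean unit activity per graph node, rendered onto rasters
  (hex patches via nearest-node resampling at half the lattice pitch).
  Autocorrelograms are masked Pearson correlations at every 2D offset
  (FFT cross-correlation identities; offsets with < 20 overlapping valid
  bins are undefined).  Gridness is the standard annulus-rotation score
  `min(corr 60°, 120°) − max(corr 30°, 90°, 150°)`, the annulus spanning
  0.5–1.5 grid scales, with scale the median distance of the six nearest
  autocorrelogram peaks; the cited original gridness procedure is not
  reproduced in the source text, so this de-facto definition stands in
  for it, consistent with the 0 / 0.3 / 0.8 cutoffs used downstream.
* **Ideal grid fits**: three plane-wave cosines with 60°-separated
  wavevectors (`|k| = 4π/(√3·scale)`), amplitude and offset, fitted by a
  coarse (scale × orientation × phase) search seeded from the
  autocorrelogram followed by Levenberg–Marquardt refinement.  The fitted
  lattice supplies grid peaks beyond the arena, which `minDist` needs.
* **Pair measures**: `gridAtPlace` (grid rate at the place peak;
  ideal-fit or raw maps) and `minDist` (scale-normalized distance from
  the place peak to the nearest grid peak; ideal fits only).  The X/Y
  values from two environments are correlated over same-animal pairs and
  tested against nulls that re-draw place peaks 5000 times — uniformly
  over positions passing preprocessing, or borrowed from other recorded
  cells — recomputing both X and Y each time; one-sided
  `p = (1 + #{null ≥ obs}) / (n + 1)`.
* **Preprocessing**: grid-score cutoffs {0, 0.3, 0.8}; place cells peaking
  within 10 % of the environment width of a wall are dropped (border-cell
  control); the conservative pipeline is cutoff 0.8 + ideal fits +
  border filter, the liberal one cutoff 0 + raw maps + border filter.
* **Model-unit records**: when the pair statistics are run on the
  network's own units, each unit's map is z-scored within each
  environment first — model activations carry arbitrary per-unit scales
  (unlike firing rates), and without standardization the X/Y correlation
  and its permutation null are both driven to ≈1 by unit amplitude alone.
* **Structure preservation / remapping checks**: cell × cell
  spatial-correlation matrices correlated across environments (upper
  triangles, identity-permutation null); per-cell across-environment
  spatial correlations should straddle 0 under global remapping.
* **ESR**: trial-average → lap-average spatial profile → peak bin →
  model-corrected (spatial-profile-subtracted) activity at the peak →
  length-4 ESR vector.  Non-spatial cells: max |ESR| / max spatial
  activity > 1.25 (strict; the absolute value fixes the sign convention
  the source leaves open).  Across-environment ESR and spatial
  correlations against a cell-identity shuffle quantify preserved lap
  coding under spatial remapping.

## Synthetic populations

The rodent datasets this analysis suite was built for have no public
accession, so the generator produces their structural twin: grid cells as
ideal cosine grids in modules (shared scale/orientation, uniform phases)
that realign coherently between environments (per-module phase shift +
small rotation, 2° s.d.); place cells as Gaussian bumps (width 1.5–3
bins) whose environment-2 peak preserves, with probability ρ, its phase
residual on the lattice of a per-cell anchor grid cell, else relocates
uniformly over the full arena (so that after the border filter the
observed-peak support coincides with the permutation null's candidate
set — this alignment is what makes the type-I calibration exact);
truncated Gaussian noise on all maps.  With one module and ρ = 1 the pair
correlation approaches 1; with several modules the per-cell anchor is
unknown to the analyst, which caps the attainable correlation — the same
module-uncertainty argument the biological analysis makes for observing
r ≈ 0.3 rather than 1.  The lap-activity generator emits spatial,
lap-specific and lap-counting archetypes with preserved lap preference
and redrawn spatial peaks across environments.

What passing tests show: the statistics recover known ground truth and
their nulls are calibrated.  What they do not show: anything about
tetrode noise, theta dynamics, inhomogeneous sampling or non-ideal grid
geometry in real recordings.

## Numerical choices and degenerate inputs

Leaky slope 0.01 throughout; activations clip hard in the forward pass
with a straight-through leak in the backward pass.  `f_n` of an all-equal
vector (zero after demeaning) falls back to an ε-floored norm rather than
dividing by zero.  Place-cell peaks break ties by lowest bin index.
Flat or structureless maps yield flagged (`valid=False`) grid statistics
and fits instead of exceptions; degenerate pair variance raises a typed
error.  All randomness flows through seeded `numpy` generators; batch
parallelism is deterministic given the config seed.

## Known limitations

* The deterministic surrogate cannot express uncertainty over `g`; the
  sampled ELBO variant is documented but not trained.
* Desk-scale twins use 2 streams and small worlds; grid-cell geometry in
  such models is rudimentary, so model-side pair correlations are
  demonstrated as positive and significant rather than matched to the
  full-scale figure.
* The exact functional forms of the precision maps and the decompression
  MLP are not printed in the source; 2-layer ELU networks of hidden width
  2× input are used, exposed in `ModelParams` for substitution.
* Walk-policy bias strengths for object/border behaviors are exposed as
  configuration; the source states only their existence.
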