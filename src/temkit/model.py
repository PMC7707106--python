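"""The Tolman-Eichenbaum Machine: forward computations.

The network factorizes knowledge into *structural* codes ``g`` (medial
entorhinal analogue; per-stream vectors that path-integrate under
action-conditioned recurrent weights) and *conjunctive* codes ``p``
(hippocampal analogue; the elementwise binding of the structural code with a
filtered sensory code).  Conjunctions are stored in fast Hebbian weight
matrices ``M`` and retrieved by attractor dynamics, so that on returning to a
known abstract location the network recalls what it saw there.

The build is deterministic ("means only"): every latent is represented by the
mean of its distribution; uncertainties appear only as precision weights when
combining the path-integrated and memory-cued estimates of ``g``.

Shapes use a leading batch axis B (parallel environments).  Per stream ``f``:
``n_g[f]`` structural units, of which the first ``n_f[f]`` project to
hippocampus; the hippocampal block has ``ns_c * n_f[f]`` units with index
``j * ns_c + i`` binding structural component ``j`` to sensory component
``i`` (flattened outer product).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, parameter


class CapacityError(ValueError):
    pass


@dataclasses.dataclass
class StreamSpec:
    """Dimensions of the multi-stream hierarchy.

    Defaults follow the open-field configuration: 5 streams with structural
    sizes [30, 30, 24, 18, 18], hippocampal projections of the first third of
    each, 45 sensory tokens compressed to a 10-dimensional two-hot code, and
    generative attractor iteration counts decreasing from 5 (stream 1) to 1
    (stream 5)."""

    n_g: Sequence[int] = (30, 30, 24, 18, 18)
    n_f: Sequence[int] = (10, 10, 8, 6, 6)
    ns: int = 45
    ns_c: int = 10
    iters_gen: Optional[Sequence[int]] = None
    attractor_iters: int = 5

    def __post_init__(self):
        self.n_g = tuple(self.n_g)
        self.n_f = tuple(self.n_f)
        if len(self.n_f) != len(self.n_g):
            raise ValueError("n_g and n_f must have equal length")
        if any(f > g for f, g in zip(self.n_f, self.n_g)):
            raise ValueError("n_f must not exceed n_g per stream")
        if self.iters_gen is None:
            k = len(self.n_g)
            self.iters_gen = tuple(max(self.attractor_iters - i, 1)
                                   for i in range(k))
        else:
            self.iters_gen = tuple(self.iters_gen)
        if self.ns > self.ns_c * (self.ns_c - 1) // 2:
            raise CapacityError(
                f"two-hot code over {self.ns_c} positions holds "
                f"{self.ns_c * (self.ns_c - 1) // 2} tokens < ns={self.ns}")

    @property
    def n_streams(self):
        return len(self.n_g)

    @property
    def n_p(self):
        return tuple(self.ns_c * f for f in self.n_f)

    @property
    def p_total(self):
        return sum(self.n_p)

    def p_slices(self):
        out, start = [], 0
        for d in self.n_p:
            out.append(slice(start, start + d))
            start += d
        return out


def two_hot_codebook(ns: int, ns_c: int) -> np.ndarray:
    """Injective one-hot -> two-hot map: token i gets the i-th 2-subset of
    the ns_c positions in lexicographic order."""
    if ns > ns_c * (ns_c - 1) // 2:
        raise CapacityError("ns exceeds two-hot capacity C(ns_c, 2)")
    book = np.zeros((ns, ns_c))
    for i, (a, b) in enumerate(itertools.islice(
            itertools.combinations(range(ns_c), 2), ns)):
        book[i, a] = book[i, b] = 1.0
    return book


def compress_sensory(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Map one-hot rows (B, ns) to two-hot rows (B, ns_c)."""
    return np.asarray(x) @ codebook


def temporal_filter(x_c, prev_xf, alpha):
    """Exponential smoothing: xf_t = (1 - alpha) xf_{t-1} + alpha x_c."""
    a = alpha.data if isinstance(alpha, Tensor) else alpha
    if np.any(a <= 0) or np.any(a > 1):
        raise ValueError("alpha must lie in (0, 1]")
    return ad.add(ad.mul(prev_xf, ad.add(1.0, ad.mul(alpha, -1.0))),
                  ad.mul(x_c, alpha))


def normalize_sensory(xf, eps=1e-8):
    """f_n: demean, rectify, then scale to unit Euclidean norm.

    A degenerate all-equal input (zero after demeaning) falls back to the
    rectified vector with an epsilon floor on the norm, avoiding a 0/0 at
    cold start."""
    centered = xf - ad.mean_(xf, axis=-1, keepdims=True)
    r = ad.relu(centered)
    norm = ad.sqrt(ad.sum_(ad.square(r), axis=-1, keepdims=True) + eps ** 2)
    return ad.div(r, norm)


def hebbian_write(M, p, p_hat, lambda_, eta, mask=None):
    """M <- lambda * M + eta * (p - p_hat)(p + p_hat)^T, optionally masked.

    p, p_hat: (B, P); M: (B, P, P).  The mask (P, P) restricts the generative
    memory to its upper-triangular stream-block structure."""
    return ad.hebbian_update(M, p, p_hat, lambda_, eta, mask=mask)


@dataclasses.dataclass
class TEMState:
    """Mutable per-environment-batch state carried across time steps."""

    g: list          # per stream (B, n_g) tensors
    xf: list         # per stream (B, ns_c) tensors
    M: Tensor        # (B, P, P) generative Hebbian memory
    Mx: Tensor       # (B, P, P) inference Hebbian memory

    def detached(self):
        return TEMState(g=[gi.detach() for gi in self.g],
                        xf=[x.detach() for x in self.xf],
                        M=self.M.detach(), Mx=self.Mx.detach())


class TEM:
    """Network parameters plus the generative/inference forward pass."""

    def __init__(self, spec: StreamSpec, n_actions: int, seed: int = 0,
                 kappa: float = 0.8, leak: float = 0.01,
                 shiny_stream: Optional[int] = None):
        self.spec = spec
        self.n_actions = n_actions
        self.kappa = kappa
        self.leak = leak
        self.shiny_stream = shiny_stream
        self.codebook = two_hot_codebook(spec.ns, spec.ns_c)
        self.block_mask = self._build_block_mask()
        rng = np.random.default_rng(seed)
        self.params = {}
        k = spec.n_streams

        def par(name, shape, scale=None):
            if scale is None:
                scale = 1.0 / np.sqrt(max(shape[-1], 1))
            p = parameter(rng.normal(0.0, scale, size=shape), name=name)
            self.params[name] = p
            return p

        for s in range(k):
            ng, nf = spec.n_g[s], spec.n_f[s]
            self.params[f"Wa{s}"] = parameter(
                np.zeros((n_actions, ng, ng)), name=f"Wa{s}")
            # spread of smoothing constants: stream 1 fast, later streams slow
            a0 = np.log(0.9 / 0.1) - s * 1.2
            self.params[f"alpha{s}"] = parameter(np.array(a0),
                                                 name=f"alpha{s}")
            self.params[f"g0{s}"] = parameter(
                rng.normal(0, 0.3, size=ng), name=f"g0{s}")
            self.params[f"wp{s}"] = parameter(np.array(1.0), name=f"wp{s}")
            h = 2 * nf
            par(f"memW1{s}", (nf, h))
            self.params[f"memb1{s}"] = parameter(np.zeros(h))
            par(f"memW2{s}", (h, ng))
            self.params[f"memb2{s}"] = parameter(np.zeros(ng))
            par(f"mtauW1{s}", (nf, h))
            self.params[f"mtaub1{s}"] = parameter(np.zeros(h))
            par(f"mtauW2{s}", (h, ng))
            self.params[f"mtaub2{s}"] = parameter(np.zeros(ng))
            par(f"ptauW1{s}", (ng, 2 * ng))
            self.params[f"ptaub1{s}"] = parameter(np.zeros(2 * ng))
            par(f"ptauW2{s}", (2 * ng, ng))
            self.params[f"ptaub2{s}"] = parameter(np.zeros(ng))
            if shiny_stream == s:
                self.params[f"shiny{s}"] = parameter(
                    rng.normal(0, 0.1, size=ng), name=f"shiny{s}")
        # sensory decoder (stream 1 predicts the raw sensory token)
        self.params["wx"] = parameter(np.array(1.0), name="wx")
        self.params["bx"] = parameter(np.zeros(spec.ns), name="bx")
        par("decW1", (spec.ns_c, 2 * spec.ns_c))
        par("decW2", (2 * spec.ns_c, spec.ns))

    # -- plumbing ---------------------------------------------------------
    def _build_block_mask(self) -> np.ndarray:
        """Upper-triangular stream-block mask for the generative memory:
        connections from stream f' to f allowed only when f' >= f."""
        P = self.spec.p_total
        mask = np.zeros((P, P))
        sl = self.spec.p_slices()
        for f in range(self.spec.n_streams):
            for fp in range(f, self.spec.n_streams):
                mask[sl[f], sl[fp]] = 1.0
        return mask

    def parameters(self):
        return list(self.params.values())

    def alphas(self):
        return [ad.sigmoid(self.params[f"alpha{s}"])
                for s in range(self.spec.n_streams)]

    def init_state(self, batch: int) -> TEMState:
        """Fresh state for a batch of new environments (memories zeroed)."""
        P = self.spec.p_total
        g = [ad.tile_last(ad.reshape(self.params[f"g0{s}"],
                                     (1, self.spec.n_g[s])), 1)
             for s in range(self.spec.n_streams)]
        # broadcast learnable g0 across the batch
        g = [ad.mul(gi, np.ones((batch, 1))) for gi in g]
        xf = [Tensor(np.zeros((batch, self.spec.ns_c)))
              for _ in range(self.spec.n_streams)]
        return TEMState(g=g, xf=xf,
                        M=Tensor(np.zeros((batch, P, P))),
                        Mx=Tensor(np.zeros((batch, P, P))))

    # -- per-operation forward pieces -------------------------------------
    def sensory_to_hippocampus(self, xn, stream: int):
        """x_tilde = W_tile (w_p * f_n(x_f)): scale then tile n_f times."""
        scaled = ad.mul(xn, self.params[f"wp{stream}"])
        return ad.tile_last(scaled, self.spec.n_f[stream])

    def g_to_hippocampus(self, g, stream: int):
        """g_tilde = W_repeat f_down(g): first n_f comps, each repeated
        ns_c times."""
        nf = self.spec.n_f[stream]
        gf = g[:, :nf]
        return ad.repeat_last(gf, self.spec.ns_c)

    def path_integrate(self, g_prev, actions, stream: int,
                       no_action: bool = False):
        """g = f_g(g_prev + W_a[action] g_prev), components clipped to
        [-1, 1].  With ``no_action`` the reserved action id 0 is used."""
        actions = np.asarray(actions)
        if np.any(actions < 0) or np.any(actions >= self.n_actions):
            raise ValueError("action id outside the vocabulary")
        if no_action:
            actions = np.zeros_like(actions)
        A = ad.take0(self.params[f"Wa{stream}"], actions)
        B, ng = g_prev.shape
        delta = ad.reshape(ad.matmul(A, ad.reshape(g_prev, (B, ng, 1))),
                           (B, ng))
        return ad.leaky_clamp(g_prev + delta, leak=self.leak)

    def attractor(self, cue, M, iters_per_stream):
        """h_tau = f_p(kappa h_{tau-1} + M h_{tau-1}); stream f's output is
        frozen after iters_per_stream[f] iterations (it keeps feeding the
        other streams at its frozen value)."""
        if cue.shape[-1] != self.spec.p_total:
            raise ValueError("cue length does not match hippocampal dim")
        slices = [(sl.start, sl.stop) for sl in self.spec.p_slices()]
        return ad.attractor_sequence(cue, M, list(iters_per_stream),
                                     self.kappa, self.leak, slices)

    def infer_g(self, g_path, p_x, g_prev, sensory_weight: float,
                shiny=None):
        """Precision-weighted fusion of the path-integrated estimate with the
        memory-cued estimate read out of the sensory-cued retrieval p_x.

        sensory_weight in [0, 1] is the training curriculum knob; at 0 the
        result is exactly the path-integrated g."""
        sl = self.spec.p_slices()
        out = []
        for s in range(self.spec.n_streams):
            mu_p = g_path[s]
            if sensory_weight == 0.0:
                g_new = mu_p
            else:
                nf, ng = self.spec.n_f[s], self.spec.n_g[s]
                seg = p_x[:, sl[s]]
                B = seg.shape[0]
                pooled = ad.sum_(ad.reshape(seg, (B, nf, self.spec.ns_c)),
                                 axis=-1)
                hmid = ad.elu(ad.linear(pooled, self.params[f"memW1{s}"],
                                        self.params[f"memb1{s}"]))
                mu_m = ad.linear(hmid, self.params[f"memW2{s}"],
                                 self.params[f"memb2{s}"])
                tmid = ad.elu(ad.linear(pooled, self.params[f"mtauW1{s}"],
                                        self.params[f"mtaub1{s}"]))
                tau_m = ad.softplus(ad.linear(tmid, self.params[f"mtauW2{s}"],
                                              self.params[f"mtaub2{s}"]))
                pmid = ad.elu(ad.linear(g_prev[s], self.params[f"ptauW1{s}"],
                                        self.params[f"ptaub1{s}"]))
                tau_p = ad.softplus(ad.linear(pmid, self.params[f"ptauW2{s}"],
                                              self.params[f"ptaub2{s}"]))
                w_tau_m = ad.mul(tau_m, sensory_weight)
                num = ad.mul(tau_p, mu_p) + ad.mul(w_tau_m, mu_m)
                den = tau_p + w_tau_m + 1e-9
                g_new = ad.leaky_clamp(ad.div(num, den), leak=self.leak)
            if shiny is not None and self.shiny_stream == s:
                ind = np.asarray(shiny, dtype=float)[:, None]
                g_new = ad.leaky_clamp(
                    g_new + ad.mul(self.params[f"shiny{s}"], ind),
                    leak=self.leak)
            out.append(g_new)
        return out

    def infer_p(self, x_tilde, g_tilde):
        """p = f_p(x_tilde * g_tilde): leaky-rectified, thresholded at 1."""
        if x_tilde.shape != g_tilde.shape:
            raise ValueError("x_tilde and g_tilde shapes differ")
        return ad.leaky_relu_clamp(ad.mul(x_tilde, g_tilde), leak=self.leak)

    def decode_sensory(self, p):
        """Categorical logits over the ns tokens from the stream-1 block of p
        (pool tiled copies with W_tile^T, decompress with f_d, add b_x)."""
        sl = self.spec.p_slices()[0]
        nf = self.spec.n_f[0]
        seg = p[:, sl]
        B = seg.shape[0]
        pooled = ad.sum_(ad.reshape(seg, (B, nf, self.spec.ns_c)), axis=-2)
        z = ad.mul(pooled, self.params["wx"])
        hid = ad.elu(ad.matmul(z, self.params["decW1"]))
        logits = ad.matmul(hid, self.params["decW2"]) + self.params["bx"]
        return logits

    # -- full step ---------------------------------------------------------
    def step(self, x_ids, actions, state: TEMState, lambda_: float,
             eta: float, sensory_weight: float = 0.0,
             shiny=None, no_action_generative: bool = False,
             first: bool = False):
        """One inference + generative step for a batch of environments.

        Order of computation: compress -> filter -> sensory-cued retrieval
        (p_x from M_x) -> infer g (path o memory fusion) -> infer p ->
        Hebbian writes (both matrices) -> generative predictions of x by
        three routes: (i) from the inferred p_t, (ii) g_t -> attractor(M) ->
        p_hat -> x, (iii) g_{t-1} -> path integration -> attractor(M) -> x.

        Returns (outputs dict, new TEMState)."""
        spec = self.spec
        x_ids = np.asarray(x_ids)
        onehot = np.zeros((len(x_ids), spec.ns))
        onehot[np.arange(len(x_ids)), x_ids] = 1.0
        x_c = Tensor(compress_sensory(onehot, self.codebook))

        alphas = self.alphas()
        xf_new, x_tildes, xns = [], [], []
        for s in range(spec.n_streams):
            xf = temporal_filter(x_c, state.xf[s], alphas[s])
            xf_new.append(xf)
            xn = normalize_sensory(xf)
            xns.append(xn)
            x_tildes.append(self.sensory_to_hippocampus(xn, s))
        x_tilde_cat = ad.concat(x_tildes, axis=-1)

        # inference memory: retrieval cued purely by the sensorium
        iters_inf = [spec.attractor_iters] * spec.n_streams
        p_x = self.attractor(x_tilde_cat, state.Mx, iters_inf)

        # path integration (also the generative mean for g); the very first
        # step of an environment has no incoming action, so the prior is the
        # initial g itself
        if first:
            g_path = [ad.leaky_clamp(state.g[s], leak=self.leak)
                      for s in range(spec.n_streams)]
        else:
            g_path = [self.path_integrate(state.g[s], actions, s)
                      for s in range(spec.n_streams)]
        g_inf = self.infer_g(g_path, p_x, state.g, sensory_weight,
                             shiny=shiny)

        # conjunctive inference
        g_tildes = [self.g_to_hippocampus(g_inf[s], s)
                    for s in range(spec.n_streams)]
        g_tilde_cat = ad.concat(g_tildes, axis=-1)
        p_inf = self.infer_p(x_tilde_cat, g_tilde_cat)

        # generative retrieval from the inferred g (route ii)
        p_gen = self.attractor(g_tilde_cat, state.M, spec.iters_gen)

        # route iii: purely generative prediction from the previous state
        if first:
            g_prior = g_path
        else:
            g_prior = [self.path_integrate(state.g[s], actions, s,
                                           no_action=no_action_generative)
                       for s in range(spec.n_streams)]
        g_prior_tilde = ad.concat(
            [self.g_to_hippocampus(g_prior[s], s)
             for s in range(spec.n_streams)], axis=-1)
        p_prior = self.attractor(g_prior_tilde, state.M, spec.iters_gen)

        logits_i = self.decode_sensory(p_inf)
        logits_ii = self.decode_sensory(p_gen)
        logits_iii = self.decode_sensory(p_prior)

        # Hebbian writes (after inference, before the next step)
        M_new = hebbian_write(state.M, p_inf, p_gen, lambda_, eta,
                              mask=self.block_mask)
        Mx_new = hebbian_write(state.Mx, p_inf, p_x, lambda_, eta)

        new_state = TEMState(g=g_inf, xf=xf_new, M=M_new, Mx=Mx_new)
        outputs = {
            "logits_i": logits_i, "logits_ii": logits_ii,
            "logits_iii": logits_iii,
            "g_inf": g_inf, "g_gen": g_path,
            "p_inf": p_inf, "p_gen": p_gen, "p_x": p_x,
            "x_tilde": x_tilde_cat, "g_tilde": g_tilde_cat,
        }
        return outputs, new_state

    # -- checkpointing -----------------------------------------------------
    def save(self, path):
        header = {
            "n_g": list(self.spec.n_g), "n_f": list(self.spec.n_f),
            "ns": self.spec.ns, "ns_c": self.spec.ns_c,
            "iters_gen": list(self.spec.iters_gen),
            "n_actions": self.n_actions, "kappa": self.kappa,
            "leak": self.leak, "shiny_stream": self.shiny_stream,
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8),
            **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "TEM":
        with np.load(path) as f:
            header = json.loads(bytes(f["__header__"]).decode())
            spec = StreamSpec(n_g=header["n_g"], n_f=header["n_f"],
                              ns=header["ns"], ns_c=header["ns_c"],
                              iters_gen=header["iters_gen"])
            model = cls(spec, header["n_actions"], kappa=header["kappa"],
                        leak=header["leak"],
                        shiny_stream=header["shiny_stream"])
            for k in model.params:
                model.params[k].data = f[k].copy()
        return model
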