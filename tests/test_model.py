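"""TEM forward computations: coding, filtering, binding, memory."""

import numpy as np
import pytest

from temkit import autodiff as ad
from temkit.autodiff import Tensor
from temkit.model import (CapacityError, StreamSpec, TEM, compress_sensory,
                          hebbian_write, normalize_sensory,
                          temporal_filter, two_hot_codebook)


class TestTwoHotCode:
    def test_exhaustive_and_injective_over_45_tokens(self):
        book = two_hot_codebook(45, 10)
        rows = {tuple(r) for r in book}
        assert len(rows) == 45                       # injective
        assert all(r.sum() == 2 for r in book)       # two-hot
        # exactly all 2-subsets of 10 positions
        from itertools import combinations
        expect = set()
        for a, b in combinations(range(10), 2):
            v = np.zeros(10)
            v[a] = v[b] = 1
            expect.add(tuple(v))
        assert rows == expect

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            two_hot_codebook(46, 10)
        with pytest.raises(CapacityError):
            StreamSpec(n_g=(6,), n_f=(2,), ns=11, ns_c=5)

    def test_compress_one_hot_batch(self):
        book = two_hot_codebook(45, 10)
        x = np.zeros((3, 45))
        x[[0, 1, 2], [0, 7, 44]] = 1
        out = compress_sensory(x, book)
        assert np.all(out.sum(axis=1) == 2)
        assert np.array_equal(out[0], book[0])


class TestTemporalFilter:
    def test_alpha_one_is_identity(self):
        x = Tensor(np.random.default_rng(0).uniform(size=(2, 5)))
        prev = Tensor(np.random.default_rng(1).uniform(size=(2, 5)))
        out = temporal_filter(x, prev, 1.0)
        assert np.allclose(out.data, x.data)

    def test_constant_input_fixed_point(self):
        c = np.full((1, 5), 0.37)
        xf = Tensor(np.zeros((1, 5)))
        for _ in range(200):
            xf = temporal_filter(Tensor(c), xf, 0.3)
        assert np.allclose(xf.data, c, atol=1e-10)

    def test_impulse_response_geometric(self):
        # unit impulse at t=0, alpha=0.5: value at step k is 0.5 * 0.5^k
        xf = Tensor(np.zeros((1, 1)))
        xf = temporal_filter(Tensor(np.ones((1, 1))), xf, 0.5)
        for k in range(6):
            assert xf.data[0, 0] == pytest.approx(0.5 * 0.5 ** k)
            xf = temporal_filter(Tensor(np.zeros((1, 1))), xf, 0.5)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            temporal_filter(Tensor(np.zeros((1, 2))),
                            Tensor(np.zeros((1, 2))), 1.5)


class TestSensoryNormalization:
    def test_unit_norm(self):
        x = Tensor(np.random.default_rng(0).uniform(0.1, 1, (4, 10)))
        out = normalize_sensory(x)
        assert np.allclose(np.linalg.norm(out.data, axis=-1), 1, atol=1e-4)

    def test_two_hot_survives_demean_rectify(self):
        # cold start with alpha=1: only the 2 positive entries survive
        v = np.zeros((1, 10))
        v[0, [2, 7]] = 1.0
        out = normalize_sensory(Tensor(v)).data[0]
        assert (out[[2, 7]] > 0).all()
        assert np.allclose(out[[0, 1, 3, 4, 5, 6, 8, 9]], 0)

    def test_degenerate_all_equal_input_no_nan(self):
        out = normalize_sensory(Tensor(np.full((1, 10), 0.3)))
        assert np.isfinite(out.data).all()


class TestBinding:
    def test_tiling_identity(self, small_model):
        m = small_model
        xn = Tensor(np.random.default_rng(0).uniform(size=(1, 5)))
        xt = m.sensory_to_hippocampus(xn, 0).data[0]
        nf, nsc = m.spec.n_f[0], m.spec.ns_c
        for j in range(nf):
            assert np.allclose(xt[j * nsc:(j + 1) * nsc], xt[:nsc])

    def test_g_tilde_repeat_and_all_ones(self, small_model):
        m = small_model
        g = Tensor(np.ones((1, m.spec.n_g[0])))
        gt = m.g_to_hippocampus(g, 0)
        assert np.allclose(gt.data, 1.0)
        assert gt.shape == (1, m.spec.ns_c * m.spec.n_f[0])

    def test_outer_product_identity(self, small_model):
        """infer_p equals the clamped leaky-rectified flattened outer
        product of the sensory ns_c-vector and the structural projection."""
        m = small_model
        rng = np.random.default_rng(5)
        xn = rng.uniform(-1, 1, (1, m.spec.ns_c))
        g = rng.uniform(-1, 1, (1, m.spec.n_g[0]))
        xt = m.sensory_to_hippocampus(Tensor(xn), 0)
        gt = m.g_to_hippocampus(Tensor(g), 0)
        p = m.infer_p(xt, gt).data[0]
        wp = float(m.params["wp0"].data)
        outer = np.outer(g[0, :m.spec.n_f[0]], wp * xn[0]).ravel()
        oracle = np.clip(np.where(outer < 0, 0.01 * outer, outer), -1, 1)
        assert np.allclose(p, oracle)

    def test_hippocampal_sizes_default_spec(self, default_spec):
        assert list(default_spec.n_p) == [100, 100, 80, 60, 60]

    def test_infer_p_sign_and_ones(self, small_model):
        m = small_model
        ones = Tensor(np.ones((1, 10)))
        assert np.allclose(m.infer_p(ones, ones).data, 1.0)
        rng = np.random.default_rng(0)
        a = Tensor(rng.choice([-1.0, 1.0], size=(1, 10)))
        b = Tensor(rng.choice([-1.0, 1.0], size=(1, 10)))
        p = m.infer_p(a, b).data
        assert np.all(np.sign(p) == np.sign(a.data * b.data))

    def test_infer_p_shape_mismatch(self, small_model):
        with pytest.raises(ValueError):
            small_model.infer_p(Tensor(np.ones((1, 10))),
                                Tensor(np.ones((1, 8))))


class TestPathIntegration:
    def test_zero_weights_identity_inside_threshold(self, small_spec):
        m = TEM(small_spec, n_actions=3, seed=0)  # Wa zero-initialized
        g = Tensor(np.random.default_rng(0).uniform(-0.9, 0.9, (2, 6)))
        out = m.path_integrate(g, np.array([1, 2]), 0)
        assert np.allclose(out.data, g.data)

    def test_output_bounded(self, small_model):
        g = Tensor(np.random.default_rng(0).uniform(-5, 5, (4, 6)))
        out = small_model.path_integrate(g, np.array([0, 1, 2, 0]), 0)
        assert np.all(np.abs(out.data) <= 1.0)

    def test_unknown_action(self, small_model):
        with pytest.raises(ValueError):
            small_model.path_integrate(Tensor(np.zeros((1, 6))),
                                       np.array([7]), 0)


class TestAttractor:
    def test_zero_memory_zero_kappa(self, small_spec):
        m = TEM(small_spec, n_actions=3, seed=0, kappa=0.0)
        P = small_spec.p_total
        cue = Tensor(np.random.default_rng(0).uniform(-1, 1, (1, P)))
        out = m.attractor(cue, Tensor(np.zeros((1, P, P))), [1, 1])
        assert np.allclose(out.data, 0.0)

    def test_zero_memory_kappa_one_fixed_point(self, small_spec):
        m = TEM(small_spec, n_actions=3, seed=0, kappa=1.0)
        P = small_spec.p_total
        cue = Tensor(np.random.default_rng(0).uniform(0, 0.9, (1, P)))
        out = m.attractor(cue, Tensor(np.zeros((1, P, P))),
                          list(small_spec.iters_gen))
        assert np.allclose(out.data, cue.data)

    def test_single_pattern_completion(self, small_spec):
        """A stored unit-norm pattern is completed from a corrupted cue:
        retrieval raises the cosine similarity above the cue's."""
        m = TEM(small_spec, n_actions=3, seed=0)
        P = small_spec.p_total
        rng = np.random.default_rng(1)
        p_star = rng.uniform(0, 1, (1, P))
        p_star /= np.linalg.norm(p_star)
        M = Tensor(0.8 * p_star[0][:, None] * p_star[0][None, :][None])
        cue_v = p_star.copy()
        cue_v[0, : P // 2] = 0.0          # half the pattern missing
        out = m.attractor(Tensor(0.5 * cue_v), M, [5, 5]).data[0]

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

        assert cos(out, p_star[0]) > cos(cue_v[0], p_star[0])

    def test_dimension_error(self, small_model):
        with pytest.raises(ValueError):
            small_model.attractor(Tensor(np.zeros((1, 7))),
                                  Tensor(np.zeros((1, 7, 7))), [1, 1])


class TestHebbianMemory:
    def test_identity_when_eta_zero(self):
        M = Tensor(np.random.default_rng(0).normal(size=(1, 6, 6)))
        p = Tensor(np.random.default_rng(1).uniform(size=(1, 6)))
        out = hebbian_write(M, p, p, 1.0, 0.0)
        assert np.allclose(out.data, M.data)

    def test_perfect_prediction_writes_nothing(self):
        M = Tensor(np.zeros((1, 6, 6)))
        p = Tensor(np.random.default_rng(0).uniform(size=(1, 6)))
        out = hebbian_write(M, p, p, 0.5, 1.0)
        assert np.allclose(out.data, 0.5 * M.data)

    def test_outer_product_oracle(self):
        p = np.random.default_rng(0).uniform(size=(1, 6))
        out = hebbian_write(Tensor(np.zeros((1, 6, 6))), Tensor(p),
                            Tensor(np.zeros((1, 6))), 0.0, 1.0)
        assert np.allclose(out.data[0], np.outer(p[0], p[0]))

    def test_block_mask_conserved_under_writes(self, small_model):
        m = small_model
        P = m.spec.p_total
        rng = np.random.default_rng(0)
        M = Tensor(np.zeros((1, P, P)))
        for _ in range(7):
            p = Tensor(rng.uniform(-1, 1, (1, P)))
            ph = Tensor(rng.uniform(-1, 1, (1, P)))
            M = hebbian_write(M, p, ph, 0.9, 0.5, mask=m.block_mask)
        assert np.all(M.data[0][m.block_mask == 0] == 0)
        # mask itself: stream-2 -> stream-1 rows allowed, reverse not
        sl = m.spec.p_slices()
        assert m.block_mask[sl[0], sl[1]].all()
        assert not m.block_mask[sl[1], sl[0]].any()

    def test_write_read_round_trip_five_patterns(self, small_spec):
        """Up to 5 near-orthogonal patterns, written with lambda=1, are each
        retrieved with top cosine similarity by their own structural cue."""
        m = TEM(small_spec, n_actions=3, seed=0)
        P = small_spec.p_total
        rng = np.random.default_rng(4)
        k = 5
        patterns = np.zeros((k, P))
        blocks = np.array_split(np.arange(P), k)
        for i in range(k):  # disjoint support -> near-orthogonal
            patterns[i, blocks[i]] = rng.uniform(0.5, 1.0,
                                                 size=len(blocks[i]))
        M = Tensor(np.zeros((1, P, P)))
        for i in range(k):
            M = hebbian_write(M, Tensor(patterns[i:i + 1]),
                              Tensor(np.zeros((1, P))), 1.0, 0.5)
        for i in range(k):
            out = m.attractor(Tensor(0.4 * patterns[i:i + 1]), M,
                              [5, 5]).data[0]
            sims = [out @ patterns[j] /
                    (np.linalg.norm(out) * np.linalg.norm(patterns[j]))
                    for j in range(k)]
            assert int(np.argmax(sims)) == i


class TestDecodingAndStep:
    def test_softmax_properties(self, small_model):
        p = Tensor(np.random.default_rng(0).uniform(-1, 1, (3, 20)))
        logits = small_model.decode_sensory(p).data
        probs = np.exp(logits - logits.max(-1, keepdims=True))
        probs /= probs.sum(-1, keepdims=True)
        assert np.all(probs > 0)
        assert np.allclose(probs.sum(-1), 1)

    def test_zero_p_uniform_when_bias_zero(self, small_model):
        logits = small_model.decode_sensory(
            Tensor(np.zeros((1, 20)))).data[0]
        assert np.allclose(logits, logits[0])

    def test_first_step_empty_memory_routes_uninformative(self, small_model):
        m = small_model
        st = m.init_state(2)
        out, _ = m.step(np.array([1, 2]), np.zeros(2, np.int64), st,
                        0.9, 0.5, first=True)
        lg = out["logits_iii"].data
        # empty memory: the ancestral prediction cannot depend on which
        # token was actually observed (both batch rows saw different tokens)
        assert np.allclose(lg[0], lg[1], atol=1e-9)

    def test_boundedness_over_random_sequences(self, small_model):
        m = small_model
        rng = np.random.default_rng(0)
        st = m.init_state(3)
        for t in range(30):
            out, st = m.step(rng.integers(0, 10, 3),
                             rng.integers(0, 3, 3), st, 0.9, 0.5,
                             sensory_weight=0.8, first=(t == 0))
        for s in range(m.spec.n_streams):
            assert np.all(np.abs(st.g[s].data) <= 1.0)
        assert np.all(np.abs(out["p_inf"].data) <= 1.0)

    def test_sensory_weight_zero_returns_path_g(self, small_model):
        m = small_model
        st = m.init_state(1)
        out, _ = m.step(np.array([3]), np.array([1]), st, 0.9, 0.5,
                        sensory_weight=0.0)
        for s in range(m.spec.n_streams):
            assert np.allclose(out["g_inf"][s].data, out["g_gen"][s].data)

    def test_checkpoint_roundtrip(self, small_model, tmp_path):
        m = small_model
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = TEM.load(path)
        st1, st2 = m.init_state(1), m2.init_state(1)
        o1, _ = m.step(np.array([2]), np.array([0]), st1, 0.9, 0.5)
        o2, _ = m2.step(np.array([2]), np.array([0]), st2, 0.9, 0.5)
        assert np.allclose(o1["logits_i"].data, o2["logits_i"].data)


class TestShinyStateMode:
    def test_shiny_indicator_conditions_designated_stream(self, small_spec):
        """With a designated shiny stream, the indicator shifts that
        stream's inferred g; the generative pass can run without the
        action label (reserved action 0)."""
        m = TEM(small_spec, n_actions=3, seed=0, shiny_stream=0)
        st1, st2 = m.init_state(1), m.init_state(1)
        out_off, _ = m.step(np.array([1]), np.array([1]), st1, 0.9, 0.5,
                            shiny=np.array([0.0]),
                            no_action_generative=True)
        out_on, _ = m.step(np.array([1]), np.array([1]), st2, 0.9, 0.5,
                           shiny=np.array([1.0]),
                           no_action_generative=True)
        assert not np.allclose(out_on["g_inf"][0].data,
                               out_off["g_inf"][0].data)
        # undesignated stream unaffected by the indicator
        assert np.allclose(out_on["g_inf"][1].data,
                           out_off["g_inf"][1].data)
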