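"""Place-grid pair measures, ideal-grid fitting, and permutation tests."""

import numpy as np
import pytest

from temkit.ratemaps import grid_score_scale, ratemap_from_array
from temkit.remap import (CellRecord, DegenerateDataError, GRID, PLACE,
                          fit_ideal_grid, grid_at_place, grid_peak_lattice,
                          ideal_grid_map, ideal_map_from_fit, min_dist,
                          pair_correlation_test, pair_measures,
                          preprocess_cells, remapping_check,
                          structure_preservation_test)
from temkit.synthetic import SynthPopSpec, gen_population


def make_grid_record(cell_id="g0", scale=9.0, orient=12.0, phase=(4.0, 6.0),
                     shape=(40, 40), envs=("env1",)):
    maps = {e: ratemap_from_array(ideal_grid_map(shape, scale, orient,
                                                 phase)) for e in envs}
    return CellRecord(cell_id, "a0", GRID, maps)


def make_place_record(cell_id="p0", peak=(20, 20), width=2.0,
                      shape=(40, 40), envs=("env1",)):
    ys, xs = np.indices(shape).astype(float)
    bump = np.exp(-((xs - peak[0]) ** 2 + (ys - peak[1]) ** 2)
                  / (2 * width ** 2))
    return CellRecord(cell_id, "a0", PLACE,
                      {e: ratemap_from_array(bump.copy()) for e in envs})


class TestIdealGridFit:
    def test_parameter_recovery_noiseless(self):
        true_scale, true_orient, true_phase = 10.0, 15.0, (5.0, 5.0)
        rec = make_grid_record(scale=true_scale, orient=true_orient,
                               phase=true_phase, shape=(48, 48))
        fit = fit_ideal_grid(rec.maps["env1"])
        assert fit.valid
        assert fit.scale == pytest.approx(true_scale, rel=0.02)
        assert min(abs(fit.orientation - true_orient),
                   60 - abs(fit.orientation - true_orient)) < 1.0
        # recovered phase must coincide with the true peak lattice
        lat = grid_peak_lattice(true_scale, true_orient, true_phase,
                                (48, 48))
        d = np.min(np.hypot(*(lat - fit.phase).T))
        assert d < 0.5

    def test_flat_map_flagged(self):
        fit = fit_ideal_grid(ratemap_from_array(np.ones((30, 30))))
        assert not fit.valid and np.isinf(fit.fit_error)

    def test_lattice_closure_under_generators(self):
        fit_scale, fit_orient, phase = 8.0, 20.0, (3.0, 2.0)
        lat = grid_peak_lattice(fit_scale, fit_orient, phase, (40, 40),
                                margin_scales=2.0)
        th = np.radians(fit_orient)
        v1 = fit_scale * np.array([np.cos(th), np.sin(th)])
        pts = {tuple(np.round(p, 6)) for p in lat}
        interior = [p for p in lat
                    if 5 < p[0] < 35 and 5 < p[1] < 35]
        for p in interior:
            assert tuple(np.round(p + v1, 6)) in pts
            assert tuple(np.round(p - v1, 6)) in pts

    def test_fitted_map_reproduces_input(self):
        rec = make_grid_record(scale=8.0, orient=30.0, phase=(2.0, 7.0))
        fit = fit_ideal_grid(rec.maps["env1"])
        recon = ideal_map_from_fit(fit, (40, 40))
        resid = np.abs(recon.values - rec.maps["env1"].values)
        assert resid.max() < 0.05


class TestPreprocessing:
    def test_border_rule(self):
        near = make_place_record("near", peak=(1, 1), shape=(20, 20))
        far = make_place_record("far", peak=(10, 10), shape=(20, 20))
        out = preprocess_cells([near, far], grid_cutoff=0.0,
                               border_frac=0.10, use_ideal=False)
        assert [r.cell_id for r in out] == ["far"]
        # border_frac=0 removes nothing
        out0 = preprocess_cells([near, far], grid_cutoff=0.0,
                                border_frac=0.0, use_ideal=False)
        assert len(out0) == 2

    def test_grid_cutoff_monotone(self):
        rng = np.random.default_rng(0)
        recs = [make_grid_record(f"g{i}", scale=8 + i)
                for i in range(3)]
        noise = [CellRecord(f"n{i}", "a0", GRID, {"env1": ratemap_from_array(
            rng.uniform(size=(40, 40)))}) for i in range(3)]
        loose = preprocess_cells(recs + noise, grid_cutoff=0.3,
                                 use_ideal=False)
        strict = preprocess_cells(recs + noise, grid_cutoff=0.8,
                                  use_ideal=False)
        assert len(strict) <= len(loose)
        assert len(strict) >= 3  # ideal grids always survive


class TestPairMeasures:
    def test_grid_at_place_constant_map(self):
        g = CellRecord("g0", "a0", GRID,
                       {"env1": ratemap_from_array(np.full((20, 20), 3.3))})
        p = make_place_record(peak=(7, 12), shape=(20, 20))
        assert grid_at_place(p, g, "env1", use_ideal=False) == \
            pytest.approx(3.3)

    def test_place_peak_on_grid_node_and_trough(self):
        scale, orient, phase = 10.0, 0.0, (20.0, 20.0)
        g = make_grid_record(scale=scale, orient=orient, phase=phase)
        fit = fit_ideal_grid(g.maps["env1"])
        g.fits["env1"] = fit
        on_peak = make_place_record(peak=(20, 20))
        v_peak = grid_at_place(on_peak, g, "env1", use_ideal=True)
        assert v_peak == pytest.approx(np.nanmax(g.maps["env1"].values),
                                       abs=0.05)
        # centroid of three neighboring peaks is the deepest trough
        trough = (20 + scale / 2, 20 + scale / (2 * np.sqrt(3)))
        at_trough = make_place_record(
            peak=(round(trough[0]), round(trough[1])))
        v_trough = grid_at_place(at_trough, g, "env1", use_ideal=True)
        assert v_trough < np.nanmin(g.maps["env1"].values) + 0.1

    def test_min_dist_zero_at_peak_and_hex_centroid(self):
        scale = 12.0
        g = make_grid_record(scale=scale, orient=0.0, phase=(18.0, 18.0),
                             shape=(44, 44))
        g.fits["env1"] = fit_ideal_grid(g.maps["env1"])
        at_peak = make_place_record(peak=(18, 18), shape=(44, 44))
        assert min_dist(at_peak, g, "env1") < 0.06
        # centroid of a lattice triangle: distance s/sqrt(3), normalized
        cx = 18 + scale / 2
        cy = 18 + scale / (2 * np.sqrt(3))
        at_centroid = make_place_record(peak=(round(cx), round(cy)),
                                        shape=(44, 44))
        assert min_dist(at_centroid, g, "env1") == pytest.approx(
            1 / np.sqrt(3), abs=0.07)

    def test_min_dist_scale_invariance(self):
        for k, shape in ((1.0, (36, 36)), (1.5, (54, 54))):
            g = make_grid_record(scale=8.0 * k, orient=5.0,
                                 phase=(10 * k, 10 * k), shape=shape)
            g.fits["env1"] = fit_ideal_grid(g.maps["env1"])
            p = make_place_record(peak=(int(14 * k), int(14 * k)),
                                  shape=shape)
            d = min_dist(p, g, "env1")
            if k == 1.0:
                d_ref = d
        assert d == pytest.approx(d_ref, abs=0.1)

    def test_same_animal_required(self):
        g = make_grid_record()
        p = make_place_record()
        p.animal_id = "other"
        with pytest.raises(DegenerateDataError):
            grid_at_place(p, g, "env1")


class TestPermutationTests:
    def test_single_module_perfect_preservation(self):
        # with one module every pair keeps its relation: r near 1
        records, _ = gen_population(SynthPopSpec(
            n_modules=1, scales=(9.0,), orientations=(12.0,),
            rho=1.0, noise_sd=0.0, n_place=10, n_grid_per_module=6,
            seed=0))
        records = preprocess_cells(records, grid_cutoff=0.0,
                                   border_frac=0.10, use_ideal=False)
        res = pair_correlation_test(records, ("env1", "env2"),
                                    n_perms=200, use_ideal=False, seed=1)
        assert res.r_obs > 0.8
        assert res.p_value <= 0.02

    def test_two_module_preservation_positive_significant(self):
        # anchor-module uncertainty dilutes but does not destroy the effect
        records, _ = gen_population(SynthPopSpec(
            rho=1.0, noise_sd=0.0, n_place=8, n_grid_per_module=4,
            seed=0))
        records = preprocess_cells(records, grid_cutoff=0.0,
                                   border_frac=0.10, use_ideal=False)
        res = pair_correlation_test(records, ("env1", "env2"),
                                    n_perms=200, use_ideal=False, seed=1)
        assert res.r_obs > 0.2
        assert res.p_value <= 0.05

    def test_trivial_x_equals_y(self):
        # X == Y exactly: observed correlation is 1, p at its floor
        records, _ = gen_population(SynthPopSpec(
            rho=1.0, noise_sd=0.0, n_place=6, n_grid_per_module=3, seed=3))
        for r in records:   # duplicate env1 into env2: X == Y for all pairs
            r.maps["env2"] = r.maps["env1"]
        records = preprocess_cells(records, grid_cutoff=0.0,
                                   border_frac=0.10, use_ideal=False)
        res = pair_correlation_test(records, ("env1", "env2"),
                                    n_perms=99, use_ideal=False, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value <= 1 / 50

    def test_null_population_nonsignificant_mostly(self):
        # quick sanity (full calibration is exercised at acceptance level)
        hits = 0
        for s in range(10):
            records, _ = gen_population(SynthPopSpec(
                rho=0.0, noise_sd=0.0, n_place=8, n_grid_per_module=4,
                arena=(24, 24), scales=(6.0, 9.0), seed=100 + s))
            records = preprocess_cells(records, grid_cutoff=0.0,
                                       border_frac=0.10, use_ideal=False)
            res = pair_correlation_test(records, ("env1", "env2"),
                                        n_perms=99, use_ideal=False,
                                        seed=s)
            hits += res.p_value <= 0.05
        assert hits <= 3

    def test_too_few_pairs(self):
        g = make_grid_record(envs=("env1", "env2"))
        p = make_place_record(envs=("env1", "env2"))
        with pytest.raises(DegenerateDataError):
            pair_correlation_test([g, p], ("env1", "env2"), n_perms=10,
                                  use_ideal=False)


class TestStructureAndRemapping:
    def test_identical_maps_full_preservation(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(5):
            m = ratemap_from_array(rng.uniform(size=(20, 20)))
            recs.append(CellRecord(f"c{i}", "a0", GRID,
                                   {"env1": m, "env2": m}))
        res = structure_preservation_test(recs, GRID, ("env1", "env2"),
                                          n_perms=200, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_realigned_module_preserves_structure(self):
        records, _ = gen_population(SynthPopSpec(
            n_modules=1, scales=(9.0,), orientations=(10.0,),
            n_grid_per_module=8, n_place=3, rho=1.0, noise_sd=0.0,
            seed=2))
        grids = [r for r in records if r.cell_type == GRID]
        res = structure_preservation_test(grids, GRID, ("env1", "env2"),
                                          n_perms=500, seed=0)
        assert res.r_obs > 0.5
        assert res.p_value < 0.01

    def test_independent_place_maps_no_structure(self):
        rng = np.random.default_rng(1)
        recs = [CellRecord(f"c{i}", "a0", PLACE,
                           {"env1": ratemap_from_array(
                               rng.uniform(size=(20, 20))),
                            "env2": ratemap_from_array(
                                rng.uniform(size=(20, 20)))})
                for i in range(8)]
        res = structure_preservation_test(recs, PLACE, ("env1", "env2"),
                                          n_perms=200, seed=0)
        assert abs(res.r_obs) < 0.5

    def test_remapping_check_distinguishes(self):
        rng = np.random.default_rng(2)
        same = [CellRecord(f"s{i}", "a0", PLACE, {
            "env1": ratemap_from_array(m := rng.uniform(size=(15, 15))),
            "env2": ratemap_from_array(m)}) for i in range(6)]
        indep = [CellRecord(f"i{i}", "a0", PLACE, {
            "env1": ratemap_from_array(rng.uniform(size=(15, 15))),
            "env2": ratemap_from_array(rng.uniform(size=(15, 15)))})
            for i in range(6)]
        _, s_same = remapping_check(same, ("env1", "env2"))
        _, s_indep = remapping_check(indep, ("env1", "env2"))
        assert s_same["mean"] > 0.99 and not s_same["remapped"]
        assert abs(s_indep["mean"]) < 0.3 and s_indep["remapped"]

    def test_statistics_invariant_to_order_and_scaling(self):
        records, _ = gen_population(SynthPopSpec(
            rho=1.0, noise_sd=0.0, n_place=6, n_grid_per_module=3,
            seed=5))
        records = preprocess_cells(records, grid_cutoff=0.0,
                                   border_frac=0.10, use_ideal=False)
        df1 = pair_measures(records, ("env1", "env2"), use_ideal=False)
        for r in records:
            for m in r.maps.values():
                m.values = m.values * 4.2   # positive rescale
        df2 = pair_measures(records[::-1], ("env1", "env2"),
                            use_ideal=False)
        m1 = df1.sort_values(["place_id", "grid_id"])
        m2 = df2.sort_values(["place_id", "grid_id"])
        r1 = np.corrcoef(m1["X"], m1["Y"])[0, 1]
        r2 = np.corrcoef(m2["X"], m2["Y"])[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestOtherCellPeakScheme:
    def test_borrowed_peak_null_behaves(self):
        from temkit.remap import OTHER_CELL_PEAK
        records, _ = gen_population(SynthPopSpec(
            n_modules=1, scales=(9.0,), orientations=(12.0,),
            rho=1.0, noise_sd=0.0, n_place=10, n_grid_per_module=5,
            seed=4))
        records = preprocess_cells(records, grid_cutoff=0.0,
                                   border_frac=0.10, use_ideal=False)
        res = pair_correlation_test(records, ("env1", "env2"),
                                    n_perms=200, use_ideal=False,
                                    scheme=OTHER_CELL_PEAK, seed=0)
        assert res.scheme == OTHER_CELL_PEAK
        assert res.r_obs > 0.5
        assert res.p_value <= 0.05
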