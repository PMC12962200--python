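import numpy as np
import pytest
from sklearn.base import clone

import ptxshim as px
from ptxshim import CostSpec, ShimConstraints, SubjectShim, UniversalShim
from ptxshim.shim import _normalize


def brute_force_phase_only(B_list, cost_kind, n_levels=64):
    """Exhaustive phase-grid oracle for <=3 channel phase-only shimming.

    Channel 1 phase is fixed at 0 (global-phase invariance); every other
    channel sweeps n_levels phases.  Returns (best cost, one-grid-step
    cost bound near the optimum).
    """
    C = B_list[0].shape[1]
    phases = [np.zeros(1)] + [
        np.linspace(0, 2 * np.pi, n_levels, endpoint=False) for _ in range(C - 1)
    ]
    grids = np.meshgrid(*phases, indexing="ij")
    phi = np.stack([g.ravel() for g in grids], axis=-1)  # (n_points, C)
    W = np.exp(1j * phi) / np.sqrt(C)  # all unit-norm

    def costs_for(B):
        m = np.abs(W @ B.T)  # (n_points, M)
        e = m.mean(axis=1)
        if cost_kind == "efficiency":
            return 1.0 / e
        return m.std(axis=1) / e

    total = np.sqrt(sum(costs_for(B) ** 2 for B in B_list))
    best = np.argmin(total)
    # local cost scale: worst jump to a one-step neighbour along any axis
    step_bound = 0.0
    idx = np.array(np.unravel_index(best, [len(p) for p in phases]))
    for ax in range(1, C):
        for delta in (-1, 1):
            nb = idx.copy()
            nb[ax] = (nb[ax] + delta) % n_levels
            flat = np.ravel_multi_index(nb, [len(p) for p in phases])
            step_bound = max(step_bound, abs(total[flat] - total[best]))
    return float(total[best]), float(step_bound)


class TestSubjectOptimizer:
    def test_single_channel_reduces_to_identity(self, toy_map_factory):
        fmap, roi = toy_map_factory(1, seed=0)
        res = px.optimize_subject(
            fmap, roi, ShimConstraints(alpha_min=0.001, alpha_max=1000.0, w_max=1.0),
            n_restarts=2, seed=0,
        )
        assert abs(res.shim.weights[0]) == pytest.approx(1.0, abs=1e-9)
        assert res.cost_value == pytest.approx(
            px.efficiency_cost(fmap, [1.0], roi), rel=1e-8
        )

    def test_two_identical_channels_split_in_phase(self, wide_constraints):
        grid = px.VoxelGrid((6, 1, 1), (5.0, 5.0, 5.0))
        vals = np.tile(np.linspace(1, 2, 6), (2, 1)).reshape(2, 6, 1, 1).astype(complex)
        fmap = px.ChannelFieldMap(grid, vals)
        roi = np.ones((6, 1, 1), bool)
        res = px.optimize_subject(fmap, roi, wide_constraints, n_restarts=4, seed=0)
        expected = np.array([1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert np.allclose(np.abs(res.shim.weights), expected, atol=1e-6)
        # in-phase: relative phase ~ 0
        rel = np.angle(res.shim.weights[1] / res.shim.weights[0])
        assert abs(rel) < 1e-6
        single = px.efficiency_cost(fmap, [1.0, 0.0], roi)
        assert res.cost_value == pytest.approx(single / np.sqrt(2), rel=1e-8)

    @pytest.mark.parametrize("n_channels", [2, 3])
    @pytest.mark.parametrize("cost_kind", ["efficiency", "coefficient_of_variation"])
    def test_phase_only_matches_brute_force(self, toy_map_factory, n_channels, cost_kind):
        fmap, roi = toy_map_factory(n_channels, seed=10 + n_channels)
        B = fmap.values[:, roi].T
        oracle, step = brute_force_phase_only([B], cost_kind)
        res = px.optimize_subject(
            fmap, roi,
            ShimConstraints(alpha_min=0.001, alpha_max=1000.0, w_max=1.0,
                            mode="phase_only"),
            CostSpec(kind=cost_kind), n_restarts=6, seed=0,
        )
        assert res.cost_value <= oracle + 1e-9
        assert oracle - res.cost_value <= step + 1e-9

    def test_returns_unit_norm_and_fixed_global_phase(self, small_subject, geometry):
        res = px.optimize_subject(
            small_subject.field_map, small_subject.phantom.roi_mask,
            n_restarts=2, seed=0, geometry=geometry,
        )
        w = res.shim.weights
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-9)
        assert np.angle(w[0]) == pytest.approx(0.0, abs=1e-9)

    def test_converged_solution_is_feasible(self, small_subject, geometry):
        res = px.optimize_subject(
            small_subject.field_map, small_subject.phantom.roi_mask,
            n_restarts=2, seed=1, geometry=geometry,
        )
        assert res.converged
        rep = res.constraint_report
        assert rep["max_weight_mag"] <= 0.35 + 1e-6
        assert rep["min_alpha"] >= 0.8 - 1e-6
        assert rep["max_alpha"] <= 1.3 + 1e-6

    def test_constraint_report_consistent_with_weights(self, small_subject, geometry):
        res = px.optimize_subject(
            small_subject.field_map, small_subject.phantom.roi_mask,
            n_restarts=2, seed=0, geometry=geometry,
        )
        rep = px.constraint_violations(
            small_subject.field_map, res.shim.weights, ShimConstraints(),
            small_subject.phantom.roi_mask,
        )
        assert rep["max_alpha"] == pytest.approx(res.constraint_report["max_alpha"], abs=1e-6)
        assert rep["max_weight_mag"] == pytest.approx(
            res.constraint_report["max_weight_mag"], abs=1e-6
        )

    def test_phase_magnitude_beats_phase_only(self, small_subject, geometry):
        common = dict(n_restarts=2, seed=0, geometry=geometry)
        pm = px.optimize_subject(
            small_subject.field_map, small_subject.phantom.roi_mask,
            ShimConstraints(mode="phase_magnitude"), **common,
        )
        po = px.optimize_subject(
            small_subject.field_map, small_subject.phantom.roi_mask,
            ShimConstraints(mode="phase_only"), **common,
        )
        assert pm.cost_value <= po.cost_value + 1e-6

    def test_weight_cap_below_equal_split_rejected(self, toy_map_factory):
        fmap, roi = toy_map_factory(4)
        with pytest.raises(ValueError, match="w_max"):
            px.optimize_subject(fmap, roi, ShimConstraints(w_max=0.3), n_restarts=1)


class TestUniversalOptimizer:
    def test_single_subject_reduces_to_subject_optimum(self, toy_map_factory,
                                                       wide_constraints):
        fmap, roi = toy_map_factory(3, seed=20)
        subj = px.optimize_subject(fmap, roi, wide_constraints, n_restarts=4, seed=0)
        grid = fmap.grid
        phantom = px.HeadPhantom(grid, roi, roi, roi)
        db = px.TrainingDatabase([px.SubjectDataset("s1", fmap, phantom)])
        uni = px.optimize_universal(db, wide_constraints, n_restarts=4, seed=0)
        assert uni.cost_value == pytest.approx(subj.cost_value, rel=1e-6)

    def test_duplicated_subjects_share_the_argmin(self, toy_map_factory,
                                                  wide_constraints):
        fmap, roi = toy_map_factory(3, seed=21)
        phantom = px.HeadPhantom(fmap.grid, roi, roi, roi)
        one = px.TrainingDatabase([px.SubjectDataset("s1", fmap, phantom)])
        three = px.TrainingDatabase(
            [px.SubjectDataset(f"s{i}", fmap, phantom) for i in range(3)]
        )
        res1 = px.optimize_universal(one, wide_constraints, n_restarts=4, seed=0)
        res3 = px.optimize_universal(three, wide_constraints, n_restarts=4, seed=0)
        # F scales by sqrt(3); the argmin is unchanged
        assert res3.cost_value == pytest.approx(np.sqrt(3) * res1.cost_value, rel=1e-6)
        overlap = abs(np.vdot(res1.shim.weights, res3.shim.weights))
        assert overlap == pytest.approx(1.0, abs=1e-4)

    def test_three_subject_phase_only_matches_brute_force(self, wide_constraints):
        rng = np.random.default_rng(5)
        grid = px.VoxelGrid((12, 1, 1), (5.0, 5.0, 5.0))
        roi = np.ones((12, 1, 1), bool)
        datasets, B_list = [], []
        for i in range(3):
            vals = rng.standard_normal((2, 12, 1, 1)) + 1j * rng.standard_normal((2, 12, 1, 1))
            fmap = px.ChannelFieldMap(grid, vals)
            phantom = px.HeadPhantom(grid, roi, roi, roi)
            datasets.append(px.SubjectDataset(f"s{i}", fmap, phantom))
            B_list.append(vals[:, roi].T)
        oracle, step = brute_force_phase_only(B_list, "efficiency")
        cons = px.ShimConstraints(alpha_min=0.001, alpha_max=1000.0, w_max=1.0,
                                  mode="phase_only")
        res = px.optimize_universal(
            px.TrainingDatabase(datasets), cons, n_restarts=6, seed=0
        )
        assert res.cost_value <= oracle + 1e-9
        assert oracle - res.cost_value <= step + 1e-9

    def test_empty_database_rejected(self, wide_constraints):
        with pytest.raises(ValueError):
            px.optimize_universal(px.TrainingDatabase([]), wide_constraints)


class TestDominance:
    def test_subject_universal_cp_ordering(self, small_population):
        """Nested optimisation scopes order the strategies.

        The universal shim beats CP mode in efficiency cost on every
        subject; in homogeneity (median ROI NRMSE) the subject-specific
        solutions beat the universal shim, which beats CP mode.  (The raw
        efficiency cost of the universal shim can undercut the
        subject-specific one on single subjects because its flip-angle
        bounds are soft penalties, not hard constraints.)
        """
        geom = small_population.geometry
        uni = px.optimize_universal(small_population, n_restarts=2, seed=0,
                                    geometry=geom)
        cp_w = px.cp_mode(geom).weights
        nrmse_subj, nrmse_uni, nrmse_cp = [], [], []
        for i, ds in enumerate(small_population):
            roi = ds.phantom.roi_mask
            subj = px.optimize_subject(ds.field_map, roi, n_restarts=2, seed=i,
                                       geometry=geom)
            assert subj.converged
            c_uni = px.efficiency_cost(ds.field_map, uni.shim.weights, roi)
            c_cp = px.efficiency_cost(ds.field_map, cp_w, roi)
            assert c_uni <= c_cp + 1e-6
            for w, acc in ((subj.shim.weights, nrmse_subj),
                           (uni.shim.weights, nrmse_uni), (cp_w, nrmse_cp)):
                alpha, _ = px.apply_shim(ds.field_map, w, roi)
                acc.append(px.nrmse(alpha, roi))
        assert np.median(nrmse_subj) <= np.median(nrmse_uni) + 1e-6
        assert np.median(nrmse_uni) <= np.median(nrmse_cp) + 1e-6


class TestEstimatorProtocol:
    def test_params_roundtrip_and_clone(self):
        est = SubjectShim(cost="coefficient_of_variation", n_restarts=3, seed=5)
        params = est.get_params()
        assert params["cost"] == "coefficient_of_variation"
        twin = clone(est)
        assert twin.get_params() == params
        est.set_params(n_restarts=7)
        assert est.n_restarts == 7

    def test_predict_requires_fit(self, toy_map_factory):
        fmap, roi = toy_map_factory(2)
        with pytest.raises(AttributeError, match="not fitted"):
            SubjectShim().predict(fmap, roi)

    def test_fitted_attributes_present(self, toy_map_factory, wide_constraints):
        fmap, roi = toy_map_factory(2, seed=30)
        est = SubjectShim(alpha_min=0.001, alpha_max=1000.0, w_max=1.0,
                          n_restarts=2).fit(fmap, roi)
        assert est.weights_.shape == (2,)
        assert isinstance(est.cost_, float)
        assert est.converged_
        alpha = est.predict(fmap, roi)
        assert alpha[roi].mean() == pytest.approx(1.0)

    def test_universal_estimator_fits_database(self, small_population):
        est = UniversalShim(n_restarts=2, seed=0).fit(small_population)
        assert est.weights_.shape == (16,)
        assert np.linalg.norm(est.weights_) == pytest.approx(1.0, abs=1e-9)


class TestApplyShim:
    def test_composition_identity(self, small_subject):
        w = _normalize(np.ones(16, complex))
        roi = small_subject.phantom.roi_mask
        alpha, rep = px.apply_shim(small_subject.field_map, w, roi)
        direct = px.flip_angle_map(small_subject.field_map, w, roi)
        assert np.array_equal(alpha, direct)
        assert "feasible" in rep

    def test_cp_shim_yields_finite_nrmse(self, small_subject, geometry):
        alpha, _ = px.apply_shim(
            small_subject.field_map, px.cp_mode(geometry).weights,
            small_subject.phantom.roi_mask,
        )
        val = px.nrmse(alpha, small_subject.phantom.roi_mask)
        assert np.isfinite(val) and val > 0

    def test_universal_shim_transfers_to_held_out_subject(self, small_population,
                                                          geometry, small_grid):
        uni = px.optimize_universal(small_population, n_restarts=2, seed=0,
                                    geometry=geometry)
        held_out = px.generate_population(1, geometry, grid=small_grid, seed=99)[0]
        alpha, _ = px.apply_shim(
            held_out.field_map, uni.shim.weights, held_out.phantom.roi_mask
        )
        assert np.isfinite(px.nrmse(alpha, held_out.phantom.roi_mask))
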