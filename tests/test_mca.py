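"""Control-coefficient algebra, theorems, Monte Carlo propagation."""

import numpy as np
import pandas as pd
import pytest

from cysmca.mca import (
    SingularJacobianError,
    control_coefficients,
    control_from_state,
    control_pattern_report,
    link_decomposition,
    monte_carlo_mca,
)
from cysmca.mca import _mca_once
from cysmca.model import stoichiometric_matrix
from cysmca.synthetic import (
    FEED_REACTIONS,
    NEAR_EQUILIBRIUM,
    solve_steady_state,
    true_control_coefficients,
)


def _eq_class(model):
    return {r: ("near" if r in NEAR_EQUILIBRIUM else "far")
            for r in model.reaction_ids}


@pytest.fixture(scope="module")
def full_model_result(kmodel):
    """Control coefficients of the default model with true elasticities."""
    ref = solve_steady_state(kmodel, {}, label="ref")
    N, mets, cols = stoichiometric_matrix(kmodel.model, internal_only=True)
    rxns = [r for r in cols if r not in FEED_REACTIONS]
    keep = [cols.index(r) for r in rxns]
    E = kmodel.scaled_elasticity_matrix(mets)[keep, :]
    return control_coefficients(
        N[:, keep], E,
        J=np.array([ref.rates[r] for r in rxns]),
        c=np.array([ref.concentrations[m] for m in mets]),
        reaction_ids=rxns, metabolite_ids=mets), ref


class TestLinkDecomposition:
    def test_full_rank_gives_identity_link(self):
        N = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        N_R, L, dep = link_decomposition(N)
        np.testing.assert_allclose(L, np.eye(2))
        np.testing.assert_allclose(N_R, N)
        assert dep == []

    def test_conserved_pair_yields_minus_one_link_row(self):
        N = np.array([[-1.0], [1.0]])        # A + B conserved
        N_R, L, dep = link_decomposition(N)
        assert dep == [1]
        np.testing.assert_allclose(L, [[1.0], [-1.0]])
        np.testing.assert_allclose(L @ N_R, N)

    def test_rank_preserved(self, kmodel):
        N, _, _ = stoichiometric_matrix(kmodel.model, internal_only=True)
        N_R, L, dep = link_decomposition(N)
        assert np.linalg.matrix_rank(N_R) == np.linalg.matrix_rank(N)
        np.testing.assert_allclose(L @ N_R, N, atol=1e-9)


class TestControlCoefficients:
    def test_two_step_chain_closed_form(self):
        N = np.array([[1.0, -1.0]])
        E = np.array([[-1.0], [1.0]])
        res = control_coefficients(N, E, np.ones(2), np.ones(1),
                                   ["supply", "demand"], ["S"])
        np.testing.assert_allclose(res.C_J.to_numpy(), 0.5, atol=1e-12)
        np.testing.assert_allclose(res.C_S.to_numpy(), [[0.5, -0.5]],
                                   atol=1e-12)

    def test_summation_theorems(self, full_model_result):
        res, _ = full_model_result
        assert np.abs(res.C_J.sum(axis=1) - 1).max() < 1e-6
        assert np.abs(res.C_S.sum(axis=1)).max() < 1e-6

    def test_connectivity_theorems_on_conservation_free_chain(self):
        # 3-step chain, no conserved moieties
        N = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        E = np.array([[-0.8, 0.0], [0.6, -1.2], [0.0, 0.9]])
        res = control_coefficients(N, E, np.ones(3), np.ones(2))
        CJ, CS = res.C_J.to_numpy(), res.C_S.to_numpy()
        np.testing.assert_allclose(CJ @ E, 0.0, atol=1e-10)
        np.testing.assert_allclose(CS @ E, -np.eye(2), atol=1e-10)

    def test_matches_finite_difference_oracle(self, kmodel,
                                              full_model_result):
        res, _ = full_model_result
        CJ_fd, CS_fd, flux_ids, enz, mets = true_control_coefficients(
            kmodel, 1e-3)
        np.testing.assert_allclose(
            res.C_J.loc[flux_ids, enz].to_numpy(), CJ_fd, atol=1e-3)
        np.testing.assert_allclose(
            res.C_S.loc[mets, enz].to_numpy(), CS_fd, atol=1e-3)

    def test_singular_jacobian_reports_condition_number(self):
        N = np.array([[1.0, -1.0]])
        E = np.zeros((2, 1))                 # no feedback at all
        with pytest.raises(SingularJacobianError, match="condition"):
            control_coefficients(N, E, np.ones(2), np.ones(1))

    def test_nonpositive_concentration_rejected(self):
        N = np.array([[1.0, -1.0]])
        E = np.array([[-1.0], [1.0]])
        with pytest.raises(ValueError):
            control_coefficients(N, E, np.ones(2), np.zeros(1))


@pytest.fixture(scope="module")
def mc_inputs(kmodel, dataset):
    return dataset, kmodel.model, _eq_class(kmodel.model), \
        dataset.ground_truth["dG_ref"]


class TestMonteCarlo:

    def test_zero_noise_degenerates_to_point_estimate(self, mc_inputs):
        ds, model, eq, dgr = mc_inputs
        mc = monte_carlo_mca(ds, model, eq, dgr, n_iter=10, noise_cv=0.0,
                             seed=3)
        width = (mc.hi_C_J - mc.lo_C_J).abs().to_numpy().max()
        assert width < 1e-12
        point = _mca_once(ds, model, eq, dgr, 1e-3)
        pd.testing.assert_frame_equal(mc.median_C_J, point.C_J)

    def test_interval_width_shrinks_with_noise(self, mc_inputs):
        ds, model, eq, dgr = mc_inputs
        widths = []
        for cv in (0.1, 0.01, 0.001):
            mc = monte_carlo_mca(ds, model, eq, dgr, n_iter=40,
                                 noise_cv=cv, seed=5)
            w = np.abs((mc.hi_C_J - mc.lo_C_J).to_numpy())
            widths.append(float(np.median(w)))
        assert widths[2] < widths[1] < widths[0]

    def test_fixed_seed_reproducible(self, mc_inputs):
        ds, model, eq, dgr = mc_inputs
        a = monte_carlo_mca(ds, model, eq, dgr, n_iter=15, noise_cv=0.05,
                            seed=9)
        b = monte_carlo_mca(ds, model, eq, dgr, n_iter=15, noise_cv=0.05,
                            seed=9)
        pd.testing.assert_frame_equal(a.median_C_J, b.median_C_J)
        pd.testing.assert_frame_equal(a.hi_C_J, b.hi_C_J)

    def test_summation_theorems_hold_per_resampled_iterate(self, mc_inputs):
        """Reconciling the resampled reference fluxes onto N v = 0 keeps
        the theorems exact for every Monte Carlo iterate."""
        from cysmca.mca import _resample_state
        from cysmca.synthetic import SyntheticDataset

        ds, model, eq, dgr = mc_inputs
        rng = np.random.default_rng(4)
        for _ in range(5):
            noisy = SyntheticDataset(
                reference=_resample_state(ds.reference, 0.1, rng),
                perturbations=[_resample_state(s, 0.1, rng)
                               for s in ds.perturbations],
                noise_cv=0.1, seed=-1, ground_truth=ds.ground_truth)
            res = _mca_once(noisy, model, eq, dgr, 1e-3)
            assert np.abs(res.C_J.sum(axis=1) - 1).max() < 1e-6
            assert np.abs(res.C_S.sum(axis=1)).max() < 1e-6

    def test_sign_stability_of_decoupled_steps_is_perfect(self, mc_inputs):
        ds, model, eq, dgr = mc_inputs
        mc = monte_carlo_mca(ds, model, eq, dgr, n_iter=60, noise_cv=0.10,
                             seed=11)
        med = mc.median_C_J
        stab = mc.sign_stability_C_J
        # the lumped respiratory steps balance only clamped pools, so
        # they fully control their own flux (C = 1) with certain sign
        for r in ("NADH5", "ATPS"):
            assert med.at[r, r] == pytest.approx(1.0, abs=1e-9)
            assert stab.at[r, r] >= 0.9
        assert (stab.to_numpy() >= 0.5 - 1e-9).all()


class TestControlPatternReport:
    def test_competing_cysteine_branch_enzymes_repress_each_other(
            self, full_model_result):
        res, _ = full_model_result
        assert res.C_J.at["CYSS", "SLCYSS"] < 0
        assert res.C_J.at["SLCYSS", "CYSS"] < 0
        assert res.C_J.at["CYSS", "CYSS"] > 0
        assert res.C_J.at["SLCYSS", "SLCYSS"] > 0

    def test_chain_supply_and_demand_control_positively(self):
        N = np.array([[1.0, -1.0]])
        E = np.array([[-1.0], [1.0]])
        res = control_coefficients(N, E, np.ones(2), np.ones(1),
                                   ["supply", "demand"], ["S"])
        rep = control_pattern_report(res, "demand",
                                     pseudo_reactions=())
        assert (rep["C_J"] > 0).all()

    def test_report_sorted_and_deterministic(self, full_model_result):
        res, _ = full_model_result
        rep = control_pattern_report(res, "YdeD")
        assert list(rep["C_J"]) == sorted(rep["C_J"], reverse=True)
        rep2 = control_pattern_report(res, "YdeD")
        pd.testing.assert_frame_equal(rep, rep2)

    def test_unknown_target_flux_raises(self, full_model_result):
        res, _ = full_model_result
        with pytest.raises(KeyError):
            control_pattern_report(res, "NOT_A_FLUX")
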