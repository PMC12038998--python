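"""Thermokinetic closed form and lin-log regression."""

import numpy as np
import pytest

from cysmca.constants import R_KJ
from cysmca.elasticity import (
    CONDITION_LIMIT,
    assemble_elasticity_matrix,
    default_effectors,
    linlog_elasticities,
    scale_elasticities,
    thermokinetic_elasticity,
    unscale_elasticities,
)
from cysmca.synthetic import (
    FAR_FROM_EQUILIBRIUM,
    NEAR_EQUILIBRIUM,
    SteadyState,
    SyntheticDataset,
    generate_perturbation_dataset,
)

T = 305.15


class TestThermokinetic:
    def test_half_disequilibrium_substrate(self):
        dg = R_KJ * T * np.log(0.5)        # Gamma = 1/2
        assert thermokinetic_elasticity(-1, dg, T) == pytest.approx(1.0)

    def test_sign_symmetry_for_product(self):
        dg = R_KJ * T * np.log(0.5)
        assert thermokinetic_elasticity(+1, dg, T) == pytest.approx(-1.0)

    def test_vanishes_in_saturated_forward_limit(self):
        assert abs(thermokinetic_elasticity(-1, -500.0, T)) < 1e-12

    def test_diverges_approaching_equilibrium(self):
        near = thermokinetic_elasticity(-1, -0.01, T)
        nearer = thermokinetic_elasticity(-1, -0.001, T)
        assert nearer > near > 1.0

    def test_monotone_in_gibbs_energy_for_substrate(self):
        values = [thermokinetic_elasticity(-1, dg, T)
                  for dg in (-8.0, -4.0, -2.0, -1.0, -0.5)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_forward_infeasible_rejected(self):
        with pytest.raises(ValueError):
            thermokinetic_elasticity(-1, +1.0, T)


def _two_state_dataset(x_values, y_values):
    ref = SteadyState("ref", {"S": 1.0}, {"r": 1.0}, is_reference=True)
    perts = [
        SteadyState(f"p{k}", {"S": float(np.exp(x))}, {"r": 1.0 + y})
        for k, (x, y) in enumerate(zip(x_values, y_values))
    ]
    return SyntheticDataset(reference=ref, perturbations=perts,
                            noise_cv=0.0, seed=0, ground_truth={})


class TestLinLogRegression:
    def test_two_point_exact_solve(self):
        ds = _two_state_dataset([0.1, -0.1], [0.1, -0.1])
        row, diag = linlog_elasticities(ds, "r", ["S"])
        assert row["S"] == pytest.approx(1.0)
        assert diag["residual_variance"] < 1e-24

    def test_zero_design_matrix_rejected(self):
        ds = _two_state_dataset([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero design"):
            linlog_elasticities(ds, "r", ["S"])

    def test_more_effectors_than_states_rejected(self):
        ds = _two_state_dataset([0.1], [0.1])
        ds.reference.concentrations["P"] = 1.0
        ds.perturbations[0].concentrations["P"] = 1.1
        with pytest.raises(ValueError, match="cannot identify"):
            linlog_elasticities(ds, "r", ["S", "P"])

    def test_zero_reference_flux_rejected(self):
        ds = _two_state_dataset([0.1, -0.1], [0.1, -0.1])
        ds.reference.rates["r"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            linlog_elasticities(ds, "r", ["S"])

    def test_noise_free_recovery_exact_on_full_rank_designs(
            self, kmodel, dataset):
        checked = 0
        for rid, row_true in kmodel.elasticities.items():
            effectors = default_effectors(kmodel.model, rid)
            if not effectors:
                continue
            row, diag = linlog_elasticities(dataset, rid, effectors)
            if diag["condition_number"] >= CONDITION_LIMIT:
                continue
            for met in effectors:
                true = row_true.get(met, 0.0)
                assert row[met] == pytest.approx(true, abs=1e-7,
                                                 rel=1e-7)
            checked += 1
        assert checked >= 15     # most far-from-equilibrium rows qualify

    def test_identifiability_improves_with_lower_noise(self, kmodel):
        """Regression-identifiability smoke test.

        The 7-min feed stages excite fluxes only weakly (a few percent),
        so elasticity recovery demands correspondingly small flux
        measurement error; the median relative error must shrink with
        the noise level and reach 30% once the noise is well below the
        flux excitation.
        """
        probe = ["PDH", "ICDH", "SUCDH", "GND", "PPC", "CS", "PFK", "AKGDH"]
        medians = []
        for cv in (0.01, 0.001):
            errs = []
            for rep in range(10):
                ds = generate_perturbation_dataset(
                    kmodel, noise_cv=cv, seed=200 + rep)
                for rid in probe:
                    eff = default_effectors(kmodel.model, rid)
                    row, _ = linlog_elasticities(ds, rid, eff)
                    for met in eff:
                        true = kmodel.elasticities[rid].get(met, 0.0)
                        if abs(true) > 0.05:
                            errs.append(abs(row[met] - true) / abs(true))
            medians.append(float(np.median(errs)))
        assert medians[1] < medians[0]
        assert medians[1] <= 0.30


class TestAssembly:
    def test_seventeen_thermokinetic_twenty_linlog_rows(self, kmodel,
                                                        dataset):
        eq = {r: ("near" if r in NEAR_EQUILIBRIUM else "far")
              for r in kmodel.model.reaction_ids}
        E = assemble_elasticity_matrix(kmodel.model, eq, dataset,
                                       dGr=dataset.ground_truth["dG_ref"])
        core = set(NEAR_EQUILIBRIUM) | set(FAR_FROM_EQUILIBRIUM)
        tk = [r for r in core if E.method[r] == "thermokinetic"]
        ll = [r for r in core if E.method[r] == "linlog"]
        assert len(tk) == 17 and len(ll) == 20

    def test_matrix_matches_generator_truth_on_identified_rows(
            self, kmodel, dataset):
        eq = {r: ("near" if r in NEAR_EQUILIBRIUM else "far")
              for r in kmodel.model.reaction_ids}
        E = assemble_elasticity_matrix(kmodel.model, eq, dataset,
                                       dGr=dataset.ground_truth["dG_ref"])
        species = list(E.values.columns)
        E_true = kmodel.scaled_elasticity_matrix(species)
        E_est = E.matrix(species)
        for i, rid in enumerate(kmodel.model.reaction_ids):
            diag = E.diagnostics.get(rid, {})
            if diag.get("condition_number", 0) >= CONDITION_LIMIT:
                continue     # rank-deficient design, ridge fallback
            np.testing.assert_allclose(E_est[i], E_true[i], atol=1e-6,
                                       err_msg=rid)

    def test_sparsity_pattern(self, kmodel, dataset):
        eq = {r: ("near" if r in NEAR_EQUILIBRIUM else "far")
              for r in kmodel.model.reaction_ids}
        E = assemble_elasticity_matrix(kmodel.model, eq, dataset,
                                       dGr=dataset.ground_truth["dG_ref"])
        assert E.values.at["PGI", "Pyr"] == 0.0
        assert E.values.at["TPI", "OAS"] == 0.0

    def test_unclassified_reaction_raises(self, kmodel, dataset):
        eq = {r: ("near" if r in NEAR_EQUILIBRIUM else "far")
              for r in kmodel.model.reaction_ids}
        del eq["PGI"]
        with pytest.raises(ValueError, match="PGI"):
            assemble_elasticity_matrix(kmodel.model, eq, dataset,
                                       dGr=dataset.ground_truth["dG_ref"])


def test_scaled_unscaled_roundtrip():
    rng = np.random.default_rng(0)
    E = rng.normal(size=(4, 3))
    J = rng.uniform(0.5, 2.0, 4)
    c = rng.uniform(0.1, 5.0, 3)
    back = scale_elasticities(unscale_elasticities(E, J, c), J, c)
    np.testing.assert_allclose(back, E, rtol=1e-12)
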