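"""Synthetic steady-state perturbation data with known kinetic ground truth.

Emulates the short-term perturbation experiment design: cells at a
production reference state are fed four alternative carbon-source regimes
(glucose; pyruvate; glucose+pyruvate; glucose+succinate) at three feed
levels each, giving 12 perturbed metabolic steady states plus the
reference.  The cell model is built on the reduced stoichiometric network
with lin-log rate laws for reactions far from thermodynamic equilibrium
and thermokinetic-affinity rate laws for near-equilibrium reactions, so
every downstream estimator (flux reconciliation, elasticity regression,
control-coefficient algebra) can be validated against exact ground truth.

Enzyme levels are held at their reference values across all states: the
perturbations last minutes, far below the time scale of expression
changes, which is the identifying assumption of the lin-log regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .constants import DEFAULT_TEMPERATURE, R_KJ
from .model import (
    MetabolicModel,
    ReactionSpec,
    augment_model,
    build_reduced_model,
    stoichiometric_matrix,
)

__all__ = [
    "NEAR_EQUILIBRIUM",
    "FAR_FROM_EQUILIBRIUM",
    "REFERENCE_CONCENTRATIONS_MM",
    "KineticModel",
    "PerturbationDesign",
    "SteadyState",
    "SyntheticDataset",
    "SteadyStateError",
    "GenerationError",
    "default_augmented_model",
    "make_default_kinetic_model",
    "solve_steady_state",
    "generate_perturbation_dataset",
    "true_control_coefficients",
    "write_dataset",
    "read_dataset",
]

#: Enzymes found near thermodynamic equilibrium in the production state.
NEAR_EQUILIBRIUM = (
    "PGI", "FBA", "TPI", "GAPD", "PGK", "PGM", "ENO", "ACONT", "SUCOAS",
    "FUM", "MDH", "RPE", "RPI", "TKT1", "TALA", "PGCD", "PSERT",
)

#: Enzymes far from thermodynamic equilibrium in the production state.
FAR_FROM_EQUILIBRIUM = (
    "PTS", "PFK", "PDH", "PPC", "ACS", "CS", "ICDH", "AKGDH", "SUCDH",
    "G6PDH", "GND", "TKT2", "PSPL", "SERAT", "CYSS", "SLCYSS", "SCYSSL",
    "YdeD", "NADH5", "ATPS",
)

#: Reference-state metabolite concentrations, mM.  Intracellular pools are
#: typical glucose-fed E. coli values; the low O-acetylserine pool reflects
#: the exporter-driven intracellular OAS scarcity of the producer strain.
REFERENCE_CONCENTRATIONS_MM: dict[str, float] = {
    "Glucose_ext": 11.0,
    "G6P": 1.9, "F6P": 0.45, "FDP": 1.5, "DHAP": 0.37, "GAP": 0.22,
    "13DPG": 0.06, "3PG": 1.5, "2PG": 0.4, "PEP": 0.18, "Pyr": 0.39,
    "AcCoA": 0.6, "CoA": 0.5, "Citrate": 1.1, "Isocitrate": 0.11,
    "AKG": 0.44, "SucCoA": 0.23, "Succinate": 0.57, "Fumarate": 0.12,
    "Malate": 1.7, "OAA": 0.05, "6PGC": 0.8, "Ru5P": 0.11, "Xu5P": 0.14,
    "R5P": 0.08, "S7P": 0.88, "E4P": 0.05, "3PHP": 0.01, "Pser": 0.05,
    "Lser": 0.1, "OAS": 0.04, "lcys": 0.2, "slcys": 0.05, "Acetate": 3.0,
    # clamped pools (constant across states, still enter Gibbs energies)
    "ATP": 9.6, "ADP": 0.56, "AMP": 0.28, "Pi": 10.0, "PPi": 0.5,
    "NAD": 2.6, "NADH": 0.083, "NADP": 0.002, "NADPH": 0.12,
    "Q8": 0.2, "Q8H2": 0.05, "CO2": 1.3, "H2S": 0.01, "SO3": 0.05,
    "S2O3": 5.0, "Lglu": 96.0, "OAS_ext": 10.0, "lcys_ext": 10.0,
}

#: Reference glucose uptake rate, mmol g^-1 h^-1 (production-state value).
REFERENCE_GLUCOSE_UPTAKE = 2.2
#: Reference coupled OAS/L-cysteine export, mmol g^-1 h^-1
#: (24.6 mg g^-1 h^-1 of L-cysteine).
REFERENCE_CYS_EXPORT = 0.203

#: Classic E. coli biomass precursor demands, mmol per g cell dry weight;
#: the drain flux unit is then the specific growth rate (h^-1).
BIOMASS_PRECURSORS = {
    "G6P": 0.205, "F6P": 0.071, "R5P": 0.898, "E4P": 0.361, "GAP": 0.129,
    "3PG": 1.496, "PEP": 0.519, "Pyr": 2.833, "AcCoA": 3.748,
    "OAA": 1.787, "AKG": 1.079,
}


class SteadyStateError(RuntimeError):
    """Steady-state solver failed to converge."""


class GenerationError(RuntimeError):
    """Synthetic dataset generation rejected the parameter set."""


def default_augmented_model(model: MetabolicModel | None = None) -> MetabolicModel:
    """Reduced model plus boundary feeds and lumped drains.

    Adds the perturbation feed reactions (glucose, pyruvate, succinate
    uptake), a lumped biomass-precursor drain (flux unit: specific growth
    rate) and a glutamate-dehydrogenase step that recycles the
    2-oxoglutarate released by transamination back into the clamped
    glutamate pool.  Without the latter two sinks the network, taken with
    all printed reaction directions, cannot carry a positive serine/
    cysteine flux at steady state.
    """
    base = model if model is not None else build_reduced_model()
    biomass_stoich = {m: -c for m, c in BIOMASS_PRECURSORS.items()}
    biomass_stoich["CoA"] = BIOMASS_PRECURSORS["AcCoA"]  # acetyl carrier returns
    extra = [
        ReactionSpec("GLCfeed", "glucose supply to the medium",
                     {"Glucose_ext": 1.0}),
        ReactionSpec("PYRup", "pyruvate uptake (perturbation feed)",
                     {"Pyr": 1.0}),
        ReactionSpec("SUCCup", "succinate uptake (perturbation feed)",
                     {"Succinate": 1.0}),
        ReactionSpec("GDH", "glutamate dehydrogenase (nitrogen assimilation)",
                     {"AKG": -1.0, "NADPH": -1.0, "NADP": 1.0, "Lglu": 1.0}),
        ReactionSpec("ACEex", "acetate overflow export",
                     {"Acetate": -1.0}),
        ReactionSpec("BIOMASS", "lumped biomass precursor drain",
                     biomass_stoich),
    ]
    return augment_model(base, extra)


#: Reactions whose activity is a boundary feed, not an enzyme of the cell.
FEED_REACTIONS = ("GLCfeed", "PYRup", "SUCCup")


# ---------------------------------------------------------------------------
# kinetic model
# ---------------------------------------------------------------------------

@dataclass
class KineticModel:
    """Reduced network equipped with reference state and rate laws.

    Rate-law kinds per reaction: ``linlog`` (far from equilibrium),
    ``thermokinetic`` (near equilibrium, affinity-driven) and ``feed``
    (constant boundary flux).  All laws return the reference flux exactly
    at the reference state.
    """

    model: MetabolicModel
    dynamic_species: list[str]
    c_ref: dict[str, float]          # mM, all species
    J_ref: dict[str, float]          # mmol g^-1 h^-1
    kinds: dict[str, str]
    elasticities: dict[str, dict[str, float]]   # lin-log rows, scaled
    dG_ref: dict[str, float]         # kJ mol^-1, reference Gibbs energies
    dG0: dict[str, float]            # kJ mol^-1, standard transformed
    temperature: float = DEFAULT_TEMPERATURE
    #: dynamic species treated as clamped exogenous effectors (the medium
    #: glucose pool: feeding sets its level, uptake responds kinetically)
    exogenous: tuple[str, ...] = ("Glucose_ext",)

    @property
    def free_species(self) -> list[str]:
        """Dynamic species solved for at steady state."""
        return [s for s in self.dynamic_species if s not in self.exogenous]

    # dense caches, built lazily
    _cache: dict = field(default_factory=dict, repr=False)

    def _dense(self) -> dict:
        if self._cache:
            return self._cache
        rxns = self.model.reaction_ids
        dyn = self.dynamic_species
        n, m = len(rxns), len(dyn)
        dyn_ix = {s: j for j, s in enumerate(dyn)}
        J = np.array([self.J_ref[r] for r in rxns])
        kind = np.array([self.kinds[r] for r in rxns])
        E = np.zeros((n, m))
        for i, r in enumerate(rxns):
            for met, eps in self.elasticities.get(r, {}).items():
                j = dyn_ix.get(met)
                if j is not None:
                    E[i, j] = eps
        S = np.zeros((n, m))
        for i, rxn in enumerate(self.model.reactions):
            for met, coef in rxn.stoichiometry.items():
                j = dyn_ix.get(met)
                if j is not None:
                    S[i, j] = coef
        dG = np.array([self.dG_ref.get(r, np.nan) for r in rxns])
        rt = R_KJ * self.temperature
        gamma_ref = np.where(np.isfinite(dG), np.exp(dG / rt), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            Vf = np.where(kind == "thermokinetic", J / (1.0 - gamma_ref), np.nan)
        self._cache = {
            "rxns": rxns, "dyn_ix": dyn_ix, "J": J, "kind": kind, "E": E,
            "S": S, "dG": dG, "Vf": Vf, "rt": rt,
        }
        return self._cache

    def flux_vector(self, x: np.ndarray, activity: np.ndarray | None = None,
                    feed_flux: Mapping[str, float] | None = None) -> np.ndarray:
        """Reaction rates at log-deviation state ``x`` (= ln c/c_ref).

        ``activity`` holds relative enzyme levels e/e_ref; ``feed_flux``
        overrides the flux of constant boundary feeds.
        """
        d = self._dense()
        J, kind, E, S, dG, Vf, rt = (
            d["J"], d["kind"], d["E"], d["S"], d["dG"], d["Vf"], d["rt"])
        a = np.ones(len(J)) if activity is None else activity
        v = np.empty(len(J))
        ll = kind == "linlog"
        v[ll] = a[ll] * J[ll] * (1.0 + E[ll] @ x)
        tk = kind == "thermokinetic"
        dg_x = dG[tk] + rt * (S[tk] @ x)
        v[tk] = a[tk] * Vf[tk] * (1.0 - np.exp(dg_x / rt))
        fd = kind == "feed"
        v[fd] = a[fd] * J[fd]
        if feed_flux:
            for rid, val in feed_flux.items():
                v[d["rxns"].index(rid)] = val
        return v

    def flux_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d v / d x (reactions x dynamic species) at unit activity."""
        d = self._dense()
        J, kind, E, S, dG, Vf, rt = (
            d["J"], d["kind"], d["E"], d["S"], d["dG"], d["Vf"], d["rt"])
        out = np.zeros_like(E)
        ll = kind == "linlog"
        out[ll] = J[ll, None] * E[ll]
        tk = kind == "thermokinetic"
        gamma = np.exp(np.clip(dG[tk] + rt * (S[tk] @ x), -500, 500) / rt)
        out[tk] = -(Vf[tk] * gamma)[:, None] * S[tk]
        return out

    def scaled_elasticity_matrix(self, species: Sequence[str]) -> np.ndarray:
        """True scaled elasticities d ln v / d ln c over ``species`` columns.

        Thermokinetic rows use the affinity closed form at the reference
        Gibbs energy; lin-log rows return their coefficients; feed rows
        are zero.
        """
        d = self._dense()
        cols = {s: j for j, s in enumerate(species)}
        n = len(d["rxns"])
        out = np.zeros((n, len(species)))
        rt = d["rt"]
        for i, rid in enumerate(d["rxns"]):
            kind = self.kinds[rid]
            if kind == "linlog":
                for met, eps in self.elasticities.get(rid, {}).items():
                    if met in cols:
                        out[i, cols[met]] = eps
            elif kind == "thermokinetic":
                gamma = np.exp(self.dG_ref[rid] / rt)
                factor = gamma / (1.0 - gamma)
                for met, coef in self.model.reaction(rid).stoichiometry.items():
                    if met in cols and met != "H2O":
                        out[i, cols[met]] = -coef * factor
        return out


# ---------------------------------------------------------------------------
# reference flux distribution
# ---------------------------------------------------------------------------

_TARGET_FLUXES = {
    # rough pathway-level guesses; reconciled exactly onto N v = 0 below
    "PGI": 1.55, "PFK": 1.95, "FBA": 1.95, "TPI": 1.95, "GAPD": 4.1,
    "PGK": 4.1, "PGM": 3.6, "ENO": 3.6, "PDH": 1.7, "PPC": 0.45,
    "CS": 1.6, "ACONT": 1.6, "ICDH": 1.6, "AKGDH": 1.7,
    "SUCOAS": 1.7, "SUCDH": 1.7, "FUM": 1.7, "MDH": 1.7, "G6PDH": 0.6,
    "GND": 0.6, "RPE": 0.25, "RPI": 0.35, "TKT1": 0.15, "TKT2": 0.1,
    "TALA": 0.15, "PGCD": 0.41, "PSERT": 0.41, "PSPL": 0.41, "SERAT": 0.41,
    "CYSS": 0.11, "SLCYSS": 0.093, "SCYSSL": 0.093, "GDH": 0.3,
    "BIOMASS": 0.08, "ACS": 0.15, "ACEex": 0.05,
}


def _reference_fluxes(model: MetabolicModel, dynamic: Sequence[str]) -> dict[str, float]:
    """Reference flux distribution: closest point to the pathway-level
    targets satisfying the dynamic-species balances exactly, with the
    measured glucose uptake and product export pinned."""
    N, rows, cols = stoichiometric_matrix(model, internal_only=False)
    keep = [rows.index(s) for s in dynamic]
    N = N[keep, :]
    n = len(cols)
    fixed = {
        "PTS": REFERENCE_GLUCOSE_UPTAKE,
        "GLCfeed": REFERENCE_GLUCOSE_UPTAKE,
        "YdeD": REFERENCE_CYS_EXPORT,
        "PYRup": 0.0,
        "SUCCup": 0.0,
    }
    target = np.array([
        fixed.get(r, _TARGET_FLUXES.get(r, 0.5)) for r in cols])
    w = 1.0 / np.maximum(np.abs(target), 0.05)
    rows_eq = [N]
    rhs = [np.zeros(N.shape[0])]
    for rid, val in fixed.items():
        e = np.zeros(n)
        e[cols.index(rid)] = 1.0
        rows_eq.append(e[None, :])
        rhs.append([val])
    A = np.vstack(rows_eq)
    b = np.concatenate(rhs)
    # KKT system of min ||w (v - target)||^2 s.t. A v = b
    W2 = np.diag(w**2)
    K = np.block([[W2, A.T], [A, np.zeros((A.shape[0], A.shape[0]))]])
    r = np.concatenate([W2 @ target, b])
    sol = np.linalg.lstsq(K, r, rcond=None)[0]
    v = sol[:n]
    J = dict(zip(cols, v))
    # the respiratory chain and ATP synthase balance clamped pools only;
    # assign them their electron/energy bookkeeping values
    nadh_producers = ["GAPD", "PDH", "AKGDH", "MDH", "G6PDH", "PGCD"]
    J["NADH5"] = float(sum(J[r] for r in nadh_producers))
    J["ATPS"] = float(1.5 * J["NADH5"])
    return J


# ---------------------------------------------------------------------------
# default kinetic model
# ---------------------------------------------------------------------------

def make_default_kinetic_model(
    model: MetabolicModel | None = None,
    seed: int = 1,
    temperature: float = DEFAULT_TEMPERATURE,
) -> KineticModel:
    """Parameterize the default ground-truth cell model.

    Near-equilibrium enzymes get thermokinetic-affinity laws with
    reference Gibbs energies drawn uniformly in (-2.5, -0.5) kJ mol^-1; far
    ones get lin-log laws with Gibbs energies in (-35, -12) and scaled
    elasticities drawn from a stated prior (substrates +U(0.8, 2.0),
    products -U(0.1, 0.5)); boundary feeds carry constant fluxes.
    Deterministic for a fixed seed.
    """
    full = default_augmented_model(model)
    rng = np.random.default_rng(seed)
    dynamic = [m.id for m in full.metabolites if m.internal] + ["Glucose_ext"]
    c_ref = dict(REFERENCE_CONCENTRATIONS_MM)
    J_ref = _reference_fluxes(full, dynamic)

    rt = R_KJ * temperature
    kinds: dict[str, str] = {}
    elasticities: dict[str, dict[str, float]] = {}
    dG_ref: dict[str, float] = {}
    dG0: dict[str, float] = {}
    near, far = set(NEAR_EQUILIBRIUM), set(FAR_FROM_EQUILIBRIUM)
    for rxn in full.reactions:
        rid = rxn.id
        if rid in FEED_REACTIONS:
            kinds[rid] = "feed"
            continue
        if rid in near:
            kinds[rid] = "thermokinetic"
            # keep the mass-action ratio close to equilibrium so the
            # affinity elasticities stay O(1) (at -9 kJ/mol they would be
            # ~0.03 and the network could barely re-balance)
            dg = float(rng.uniform(-2.5, -0.5))
        else:
            kinds[rid] = "linlog"
            dg = float(rng.uniform(-35.0, -12.0))
            # generalized-mass-action prior: sign from stoichiometry,
            # one positive reaction gain with per-metabolite asymmetry.
            # The sign-symmetric backbone keeps the steady-state Jacobian
            # close to -N W N^T, i.e. the network is dynamically stable.
            gain = float(rng.uniform(0.5, 1.4))
            if rid == "BIOMASS":
                gain = float(rng.uniform(0.1, 0.25))
            row: dict[str, float] = {}
            for met, coef in rxn.stoichiometry.items():
                if met not in dynamic or met == "H2O":
                    continue
                row[met] = float(-coef * gain
                                 * (1.0 + rng.uniform(-0.3, 0.3)))
            elasticities[rid] = row
        dG_ref[rid] = dg
        # back out the standard transformed Gibbs energy from c_ref (in M)
        q = sum(
            coef * np.log(c_ref[met] * 1e-3)
            for met, coef in rxn.stoichiometry.items()
            if met != "H2O"
        )
        dG0[rid] = float(dg - rt * q)

    return KineticModel(
        model=full, dynamic_species=dynamic, c_ref=c_ref, J_ref=J_ref,
        kinds=kinds, elasticities=elasticities, dG_ref=dG_ref, dG0=dG0,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    """One metabolic equilibrium state: concentrations (mM) and rates."""

    label: str
    concentrations: dict[str, float]
    rates: dict[str, float]
    is_reference: bool = False


def _balance_operators(kmodel: KineticModel, clamp: Sequence[str] = ()):
    """Independent balance rows and conservation relations over the
    dynamic species (minus exogenous effectors and extra clamps)."""
    dyn = [s for s in kmodel.free_species if s not in clamp]
    N, rows, cols = stoichiometric_matrix(kmodel.model, internal_only=False)
    keep = [rows.index(s) for s in dyn]
    Nd = N[keep, :]
    # independent rows via pivoted QR of Nd^T
    q, r, piv = scipy.linalg.qr(Nd.T, pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-9 * max(1.0, abs(r[0, 0]))))
    indep = sorted(piv[:rank])
    T = scipy.linalg.null_space(Nd.T).T       # conserved pools, rows
    return dyn, Nd, indep, T


def solve_steady_state(
    kmodel: KineticModel,
    boundary: Mapping[str, float] | None = None,
    label: str = "state",
    x0: np.ndarray | None = None,
    clamp: Sequence[str] = (),
    tol: float = 1e-10,
    activity: Mapping[str, float] | None = None,
) -> SteadyState:
    """Solve for a metabolic steady state under a boundary setting.

    ``boundary`` maps reaction ids to an absolute flux (boundary feeds)
    or a relative activity e/e_ref (enzymatic steps), and exogenous
    species ids to a relative concentration c/c_ref (e.g. the medium
    glucose level set by the feeding stage).  Conserved pools (the CoA
    moiety) are held at their reference totals.  Raises
    :class:`SteadyStateError` with the residual norm on non-convergence.
    """
    boundary = dict(boundary or {})
    rxns = kmodel.model.reaction_ids
    dyn_full = kmodel.dynamic_species
    rxn_boundary: dict[str, float] = {}
    exo_boundary: dict[str, float] = {}
    for key, val in boundary.items():
        if key in rxns:
            rxn_boundary[key] = float(val)
        elif key in kmodel.exogenous:
            exo_boundary[key] = float(val)
        else:
            raise KeyError(f"unknown reaction or exogenous species {key!r}")

    def assemble(theta: float):
        """Boundary interpolated a fraction ``theta`` of the way from the
        reference setting to the requested one."""
        a = np.ones(len(rxns))
        feeds: dict[str, float] = {}
        for rid, val in rxn_boundary.items():
            if kmodel.kinds[rid] == "feed":
                ref = kmodel.J_ref[rid]
                feeds[rid] = ref + theta * (val - ref)
            else:
                a[rxns.index(rid)] = 1.0 + theta * (val - 1.0)
        if activity:
            for rid, val in activity.items():
                a[rxns.index(rid)] = 1.0 + theta * (float(val) - 1.0)
        x_base = np.zeros(len(dyn_full))
        for sp, scale in exo_boundary.items():
            x_base[dyn_full.index(sp)] = theta * np.log(scale)
        return a, feeds, x_base

    dyn, Nd, indep, T = _balance_operators(kmodel, clamp)
    sel = np.array([dyn_full.index(s) for s in dyn])
    c_ref = np.array([kmodel.c_ref[s] for s in dyn])

    def solve_at(theta: float, x_start: np.ndarray | None):
        """One Newton solve at an interpolated boundary; returns (x, v)
        or None on failure."""
        act, feed_over, x_base = assemble(theta)

        def residual(xs: np.ndarray) -> np.ndarray:
            xs = np.clip(xs, -40.0, 40.0)
            x_full = x_base.copy()
            x_full[sel] = xs
            v = kmodel.flux_vector(x_full, act, feed_over)
            bal = (Nd @ v)[indep]
            cons = T @ (c_ref * np.exp(xs) - c_ref) if T.size else np.empty(0)
            return np.concatenate([bal, cons])

        if x_start is None:
            # linearized first-order response as the starting point
            dvdx = (act[:, None] * kmodel.flux_jacobian(x_base))[:, sel]
            M = np.vstack([(Nd @ dvdx)[indep],
                           T @ np.diag(c_ref) if T.size else
                           np.empty((0, len(dyn)))])
            v_at_base = kmodel.flux_vector(x_base, act, feed_over)
            b = np.concatenate([(Nd @ v_at_base)[indep], np.zeros(T.shape[0])])
            x_start = np.clip(
                np.linalg.lstsq(M, -b, rcond=None)[0], -1.0, 1.0)
        sol = scipy.optimize.root(residual, x_start, method="hybr",
                                  options={"xtol": 1e-12, "maxfev": 20000})
        x_full = x_base.copy()
        x_full[sel] = sol.x
        v = kmodel.flux_vector(x_full, act, feed_over)
        scale = max(np.max(np.abs(v)), 1.0)
        if np.max(np.abs((Nd @ v))) > 1e-8 * scale:
            return None
        return sol.x, v

    # continuation in the boundary setting: bisect toward the target when
    # a direct solve fails (the perturbed root can be far from the guess)
    theta_done, x_cur = 0.0, (None if x0 is None else np.asarray(x0, float))
    result = None
    theta_try = 1.0
    for _ in range(60):
        res = solve_at(theta_try, x_cur)
        if res is not None:
            theta_done, x_cur = theta_try, res[0]
            if theta_try >= 1.0:
                result = res
                break
            theta_try = 1.0
        else:
            theta_try = theta_done + (theta_try - theta_done) / 2.0
            if theta_try - theta_done < 1e-3:
                break
    if result is None:
        act, feed_over, x_base = assemble(1.0)
        x_full = x_base.copy()
        if x_cur is not None:
            x_full[sel] = x_cur
        v = kmodel.flux_vector(x_full, act, feed_over)
        resid = float(np.max(np.abs(Nd @ v)))
        raise SteadyStateError(
            f"steady state {label!r} did not converge; "
            f"max |N v| = {resid:.3e} after continuation to "
            f"theta = {theta_done:.3f}"
        )
    x_sol, v = result
    conc = dict(kmodel.c_ref)
    for j, s in enumerate(dyn):
        conc[s] = kmodel.c_ref[s] * float(np.exp(x_sol[j]))
    for sp, scale in exo_boundary.items():
        conc[sp] = kmodel.c_ref[sp] * scale
    rates = dict(zip(rxns, map(float, v)))
    if "GLCfeed" in rates and "PTS" in rates:
        # the glucose supply matches uptake at steady state (bookkeeping)
        rates["GLCfeed"] = rates["PTS"]
    return SteadyState(label=label, concentrations=conc, rates=rates)


# ---------------------------------------------------------------------------
# perturbation design and dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationDesign:
    """4 carbon-source regimes x 3 feed levels (30/60/90 mL h^-1 stages).

    Feed settings are boundary fluxes in mmol g^-1 h^-1 (glucose feeds
    are expressed relative to the reference uptake).
    """

    #: relative medium-glucose level per feeding stage (feeding raises the
    #: extracellular glucose pool; uptake responds through the PTS kinetics)
    glucose_scales: tuple[float, ...] = (1.25, 1.50, 1.75)
    pyruvate_fluxes: tuple[float, ...] = (0.06, 0.12, 0.18)
    mixed_glucose_scales: tuple[float, ...] = (1.15, 1.30, 1.45)
    mixed_pyruvate_fluxes: tuple[float, ...] = (0.04, 0.08, 0.12)
    succinate_fluxes: tuple[float, ...] = (0.04, 0.08, 0.12)
    stage_duration_min: float = 7.0
    feed_rates_ml_h: tuple[float, ...] = (30.0, 60.0, 90.0)

    def boundaries(self) -> list[tuple[str, dict[str, float]]]:
        out = []
        for k in range(3):
            out.append((f"glc_{int(self.feed_rates_ml_h[k])}",
                        {"Glucose_ext": self.glucose_scales[k]}))
        for k in range(3):
            out.append((f"pyr_{int(self.feed_rates_ml_h[k])}",
                        {"PYRup": self.pyruvate_fluxes[k]}))
        for k in range(3):
            out.append((f"glcpyr_{int(self.feed_rates_ml_h[k])}",
                        {"Glucose_ext": self.mixed_glucose_scales[k],
                         "PYRup": self.mixed_pyruvate_fluxes[k]}))
        for k in range(3):
            out.append((f"glcsucc_{int(self.feed_rates_ml_h[k])}",
                        {"Glucose_ext": self.mixed_glucose_scales[k],
                         "SUCCup": self.succinate_fluxes[k]}))
        return out


@dataclass
class SyntheticDataset:
    """Reference + 12 perturbation states with ground-truth sidecar."""

    reference: SteadyState
    perturbations: list[SteadyState]
    noise_cv: float
    seed: int
    ground_truth: dict

    @property
    def states(self) -> list[SteadyState]:
        return [self.reference] + self.perturbations

    def concentrations_frame(self):
        import pandas as pd
        return pd.DataFrame(
            {s.label: s.concentrations for s in self.states}
        ).T

    def rates_frame(self):
        import pandas as pd
        return pd.DataFrame({s.label: s.rates for s in self.states}).T


def generate_perturbation_dataset(
    kmodel: KineticModel,
    design: PerturbationDesign | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate the 13-state dataset (reference + 4 regimes x 3 levels).

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied independently to every concentration and
    rate; ``noise_cv=0`` returns the exact model outputs.  Any state
    without strictly positive L-cysteine export rejects the parameter
    set with :class:`GenerationError`.
    """
    design = design or PerturbationDesign()
    reference = solve_steady_state(kmodel, {}, label="reference")
    reference.is_reference = True
    states = []
    prev_regime, x_prev = None, None
    for label, bnd in design.boundaries():
        regime = label.rsplit("_", 1)[0]
        x0 = x_prev if regime == prev_regime else None
        st = solve_steady_state(kmodel, bnd, label=label, x0=x0)
        # consecutive feeding stages of one reactor: warm-start the next
        # stage from the current steady state, like the experiment does
        x_prev = np.array([
            np.log(st.concentrations[s] / kmodel.c_ref[s])
            for s in kmodel.free_species])
        prev_regime = regime
        states.append(st)
    for st in [reference] + states:
        if st.rates["YdeD"] <= 0:
            raise GenerationError(
                f"state {st.label!r} lost positive L-cysteine export "
                f"(YdeD = {st.rates['YdeD']:.4g}); parameter set rejected"
            )

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))

        def jitter(d: dict[str, float]) -> dict[str, float]:
            keys = list(d)
            f = np.exp(rng.normal(-sigma**2 / 2.0, sigma, len(keys)))
            return {k: d[k] * float(fk) for k, fk in zip(keys, f)}

        reference = SteadyState(reference.label,
                                jitter(reference.concentrations),
                                jitter(reference.rates), True)
        states = [SteadyState(s.label, jitter(s.concentrations),
                              jitter(s.rates)) for s in states]

    truth = {
        "elasticities": {r: dict(kmodel.elasticities.get(r, {}))
                         for r in kmodel.model.reaction_ids},
        "kinds": dict(kmodel.kinds),
        "dG_ref": dict(kmodel.dG_ref),
        "dG0": dict(kmodel.dG0),
        "J_ref": dict(kmodel.J_ref),
        "c_ref": dict(kmodel.c_ref),
    }
    return SyntheticDataset(reference=reference, perturbations=states,
                            noise_cv=noise_cv, seed=seed, ground_truth=truth)


# ---------------------------------------------------------------------------
# finite-difference control-coefficient oracle
# ---------------------------------------------------------------------------

def true_control_coefficients(
    kmodel: KineticModel,
    relative_step: float = 1e-3,
    enzymes: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Finite-difference flux/concentration control coefficients.

    Perturbs each enzyme level by ``exp(+-relative_step)`` around the
    reference, re-solves the steady state with the external glucose pool
    clamped (the control-analysis boundary condition), and returns
    central differences of ln J and ln c.  Rows of C_J sum to 1 and rows
    of C_S sum to 0 up to O(step^2).
    """
    rxns = kmodel.model.reaction_ids
    flux_ids = [r for r in rxns if r not in FEED_REACTIONS]
    enzymes = list(enzymes) if enzymes is not None else list(flux_ids)
    mets = kmodel.free_species
    base = solve_steady_state(kmodel, {}, label="fd_reference")
    m = len(mets)
    CJ = np.zeros((len(flux_ids), len(enzymes)))
    CS = np.zeros((m, len(enzymes)))
    h = relative_step
    for k, enz in enumerate(enzymes):
        sols = []
        for sgn in (+1.0, -1.0):
            try:
                sols.append(solve_steady_state(
                    kmodel, {enz: float(np.exp(sgn * h))},
                    label=f"fd_{enz}_{sgn:+.0f}"))
            except SteadyStateError as err:
                raise SteadyStateError(
                    f"finite-difference perturbation of {enz!r} failed: {err}"
                ) from err
        hi, lo = sols
        for i, r in enumerate(flux_ids):
            num = np.log(abs(hi.rates[r])) - np.log(abs(lo.rates[r]))
            CJ[i, k] = num / (2 * h)
        for j, s in enumerate(mets):
            num = np.log(hi.concentrations[s]) - np.log(lo.concentrations[s])
            CS[j, k] = num / (2 * h)
    return CJ, CS, flux_ids, enzymes, mets


# ---------------------------------------------------------------------------
# dataset serialization (two CSV tables + a JSON ground-truth sidecar)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write metabolome/rates CSVs and the ground-truth JSON sidecar."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.concentrations_frame().rename_axis("state").to_csv(
        directory / "metabolome_mM.csv")
    dataset.rates_frame().rename_axis("state").to_csv(
        directory / "rates_mmol_g_h.csv")
    sidecar = {
        "reference_label": dataset.reference.label,
        "noise_cv": dataset.noise_cv,
        "seed": dataset.seed,
        "ground_truth": dataset.ground_truth,
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    conc = pd.read_csv(directory / "metabolome_mM.csv", index_col="state")
    rates = pd.read_csv(directory / "rates_mmol_g_h.csv", index_col="state")
    sidecar = json.loads((directory / "ground_truth.json").read_text())
    ref_label = sidecar["reference_label"]
    states = []
    reference = None
    for label in conc.index:
        st = SteadyState(
            label=str(label),
            concentrations=conc.loc[label].dropna().to_dict(),
            rates=rates.loc[label].dropna().to_dict(),
            is_reference=(label == ref_label),
        )
        if st.is_reference:
            reference = st
        else:
            states.append(st)
    if reference is None:
        raise ValueError(f"no state labelled {ref_label!r} in {directory}")
    return SyntheticDataset(
        reference=reference, perturbations=states,
        noise_cv=float(sidecar.get("noise_cv", 0.0)),
        seed=int(sidecar.get("seed", 0)),
        ground_truth=sidecar.get("ground_truth", {}),
    )
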