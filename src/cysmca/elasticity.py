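"""Scaled elasticities: thermokinetic closed form and lin-log regression.

Near thermodynamic equilibrium the elasticity of a reaction with respect
to a participant is dominated by the driving force: with the mass-action
disequilibrium ratio Gamma = exp(dG_r / RT),

    eps_ij = -s_ij * Gamma / (1 - Gamma),

which diverges as dG_r -> 0- and vanishes in the saturated forward limit.
Far from equilibrium the thermodynamic term is negligible and the
elasticities are estimated by regressing the lin-log rate law

    v_k / J_ref - 1 = sum_j eps_j ln(c_jk / c_j,ref)

over the perturbation states k, with enzyme levels held at the reference
(short-term perturbations, no expression change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_KJ
from .model import MetabolicModel
from .synthetic import FEED_REACTIONS, SyntheticDataset

__all__ = [
    "ElasticityMatrix",
    "thermokinetic_elasticity",
    "linlog_elasticities",
    "assemble_elasticity_matrix",
    "scale_elasticities",
    "unscale_elasticities",
    "default_effectors",
]

#: Measured extracellular effectors included in regressions by default.
DEFAULT_EXOGENOUS_EFFECTORS = ("Glucose_ext",)

#: Condition number above which ridge regularization is switched on.
CONDITION_LIMIT = 1e6
RIDGE_FALLBACK = 1e-3


@dataclass
class ElasticityMatrix:
    """Scaled elasticities (reactions x effector species) with provenance."""

    values: pd.DataFrame                 # rows: reactions, cols: species
    method: dict[str, str]               # thermokinetic | linlog | none
    diagnostics: dict[str, dict] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.values.index)

    def matrix(self, species: Sequence[str],
               reactions: Sequence[str] | None = None) -> np.ndarray:
        rxns = list(reactions) if reactions is not None else self.reaction_ids
        out = np.zeros((len(rxns), len(species)))
        for i, r in enumerate(rxns):
            for j, s in enumerate(species):
                if s in self.values.columns:
                    out[i, j] = self.values.at[r, s]
        return out


def thermokinetic_elasticity(
    s_ij: float, dGr: float, T: float = DEFAULT_TEMPERATURE
) -> float:
    """Closed-form near-equilibrium elasticity -s * Gamma / (1 - Gamma)."""
    if dGr >= 0:
        raise ValueError(
            f"thermokinetic elasticity requires a forward-operating "
            f"reaction (dG_r < 0), got {dGr}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    gamma = np.exp(dGr / (R_KJ * T))
    return float(-s_ij * gamma / (1.0 - gamma))


def linlog_elasticities(
    dataset: SyntheticDataset,
    reaction: str,
    effector_set: Sequence[str],
    regularization: float = 0.0,
    fluxes: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], dict]:
    """Least-squares lin-log elasticities for one reaction.

    ``fluxes`` optionally maps state labels to the reaction's flux (e.g. a
    per-state constraint-based point estimate); by default the dataset's
    recorded rates are used.  Ridge shrinkage with ``regularization`` > 0;
    a rank-deficient design with zero regularization raises.
    """
    ref = dataset.reference
    if ref is None or not ref.is_reference:
        raise ValueError("dataset has no reference state")
    effectors = list(effector_set)
    if not effectors:
        return {}, {"n_states": 0, "residual_variance": 0.0,
                    "condition_number": np.nan}
    states = dataset.perturbations
    rows, y = [], []
    j_ref = (fluxes[ref.label] if fluxes is not None
             else ref.rates[reaction])
    if j_ref == 0:
        raise ValueError(f"reference flux of {reaction!r} is zero; "
                         "scaled elasticities undefined")
    for st in states:
        v = fluxes[st.label] if fluxes is not None else st.rates[reaction]
        rows.append([np.log(st.concentrations[m] / ref.concentrations[m])
                     for m in effectors])
        y.append(v / j_ref - 1.0)
    X = np.array(rows)
    y = np.array(y)
    if len(states) < len(effectors):
        raise ValueError(
            f"{reaction}: {len(states)} perturbation states cannot "
            f"identify {len(effectors)} elasticities")
    if np.allclose(X, 0.0):
        raise ValueError(
            f"{reaction}: zero design matrix (all states at the "
            "reference concentrations)")
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    lam = regularization
    if lam == 0.0 and cond > CONDITION_LIMIT:
        if sv[-1] == 0.0:
            raise ValueError(
                f"{reaction}: rank-deficient design; pass regularization "
                "> 0 (ridge) to stabilize the fit")
        lam = RIDGE_FALLBACK
    if lam > 0:
        A = X.T @ X + lam * np.eye(len(effectors))
        eps = np.linalg.solve(A, X.T @ y)
    else:
        eps, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ eps
    dof = max(len(states) - len(effectors), 1)
    diag = {
        "n_states": len(states),
        "residual_variance": float(resid @ resid / dof),
        "condition_number": cond,
        "ridge": lam,
    }
    return dict(zip(effectors, map(float, eps))), diag


def default_effectors(
    model: MetabolicModel, reaction: str,
    exogenous: Sequence[str] = DEFAULT_EXOGENOUS_EFFECTORS,
) -> list[str]:
    """Reactants/products that are internal (or measured exogenous)."""
    internal = set(model.internal_metabolite_ids) | set(exogenous)
    rxn = model.reaction(reaction)
    return [m for m in rxn.stoichiometry if m in internal and m != "H2O"]


def assemble_elasticity_matrix(
    model: MetabolicModel,
    eq_class: Mapping[str, str],
    dataset: SyntheticDataset,
    dGr: Mapping[str, float] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    regularization: float = 0.0,
    fluxes_by_state: Mapping[str, Mapping[str, float]] | None = None,
    extra_effectors: Mapping[str, Sequence[str]] | None = None,
) -> ElasticityMatrix:
    """Full scaled-elasticity matrix for the model.

    ``eq_class`` assigns near/far per reaction (from the thermodynamic
    classification); near rows use the closed form at the representative
    Gibbs energy ``dGr``, far rows are regressed from the dataset.  Feed
    reactions get zero rows.  Unclassified reactions raise.
    """
    dGr = dict(dGr or {})
    species = list(dict.fromkeys(
        model.internal_metabolite_ids + list(DEFAULT_EXOGENOUS_EFFECTORS)))
    rxns = model.reaction_ids
    values = pd.DataFrame(0.0, index=rxns, columns=species)
    method: dict[str, str] = {}
    diagnostics: dict[str, dict] = {}
    flux_table = None
    if fluxes_by_state is not None:
        flux_table = fluxes_by_state
    for rid in rxns:
        if rid in FEED_REACTIONS:
            method[rid] = "none"
            continue
        cls = eq_class.get(rid)
        if cls == "near":
            if rid not in dGr:
                raise KeyError(
                    f"near-equilibrium reaction {rid!r} has no dG_r value")
            for met, coef in model.reaction(rid).stoichiometry.items():
                if met in values.columns and met != "H2O":
                    values.at[rid, met] = thermokinetic_elasticity(
                        coef, dGr[rid], temperature)
            method[rid] = "thermokinetic"
        elif cls == "far":
            effectors = default_effectors(model, rid)
            if extra_effectors and rid in extra_effectors:
                effectors = list(dict.fromkeys(
                    effectors + list(extra_effectors[rid])))
            per_state = None
            if flux_table is not None:
                per_state = {lab: fl[rid] for lab, fl in flux_table.items()}
            row, diag = linlog_elasticities(
                dataset, rid, effectors, regularization, fluxes=per_state)
            for met, eps in row.items():
                values.at[rid, met] = eps
            method[rid] = "linlog"
            diagnostics[rid] = diag
        else:
            raise ValueError(
                f"reaction {rid!r} is not classified (near/far); "
                "run the thermodynamic classification first")
    return ElasticityMatrix(values=values, method=method,
                            diagnostics=diagnostics)


def unscale_elasticities(E: np.ndarray, J: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Convert scaled elasticities to dv/dc: diag(J) E diag(c)^-1."""
    return (J[:, None] * E) / c[None, :]


def scale_elasticities(dvdc: np.ndarray, J: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Convert dv/dc back to scaled elasticities."""
    return (dvdc * c[None, :]) / J[:, None]
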