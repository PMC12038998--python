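"""Metabolic control analysis: control coefficients and their uncertainty.

Flux and concentration control coefficients follow the steady-state
sensitivity algebra for (possibly conservation-constrained) networks.
With N = L N_R the link decomposition of the internal stoichiometric
matrix, dv/dc the unscaled elasticities and M = N_R (dv/dc) L the reduced
Jacobian:

    C_S^u = -L M^-1 N_R
    C_J^u = I + (dv/dc) C_S^u
    C_J   = dg(J)^-1 C_J^u dg(J),    C_S = dg(c)^-1 C_S^u dg(J)

The summation theorems (C_J rows sum to 1, C_S rows to 0) hold whenever
the reference fluxes satisfy N J = 0, and are verified on output.
Measurement uncertainty is propagated by Monte Carlo: concentrations and
rates are resampled, fluxes re-reconciled, elasticities re-assembled and
the control coefficients recomputed per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .elasticity import ElasticityMatrix, assemble_elasticity_matrix
from .fluxes import fit_fluxes
from .model import MetabolicModel, stoichiometric_matrix
from .synthetic import FEED_REACTIONS, SteadyState, SyntheticDataset

__all__ = [
    "ControlAnalysisResult",
    "MonteCarloSummary",
    "SingularJacobianError",
    "link_decomposition",
    "control_coefficients",
    "monte_carlo_mca",
    "control_pattern_report",
]

#: Reference fluxes below this magnitude are excluded from scaling.
FLUX_SCALE_FLOOR = 1e-9


class SingularJacobianError(np.linalg.LinAlgError):
    """The reduced Jacobian M = N_R dvdc L is numerically singular."""


@dataclass
class ControlAnalysisResult:
    """Scaled control coefficients at one reference state."""

    C_J: pd.DataFrame          # fluxes x enzymes
    C_S: pd.DataFrame          # internal metabolites x enzymes
    reference_fluxes: dict[str, float]
    reference_concentrations: dict[str, float]
    excluded_fluxes: list[str] = field(default_factory=list)


@dataclass
class MonteCarloSummary:
    """Percentile summary of Monte Carlo control-coefficient samples."""

    median_C_J: pd.DataFrame
    lo_C_J: pd.DataFrame
    hi_C_J: pd.DataFrame
    sign_stability_C_J: pd.DataFrame
    median_C_S: pd.DataFrame
    lo_C_S: pd.DataFrame
    hi_C_S: pd.DataFrame
    n_iterations: int
    n_dropped: int
    seed: int
    point_estimate: ControlAnalysisResult | None = None


def link_decomposition(
    N: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Split N into independent rows: N = L N_R.

    Returns ``(N_R, L, dependent_rows)`` with N_R of full row rank and L
    carrying an identity block on the independent rows.  Dependent rows
    arise from conserved moieties (e.g. the CoA pool).
    """
    if N.size == 0:
        raise ValueError("empty stoichiometric matrix")
    _, r, piv = scipy.linalg.qr(N.T, pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(1.0, diag[0])))
    indep = sorted(piv[:rank])
    dependent = [i for i in range(N.shape[0]) if i not in indep]
    N_R = N[indep, :]
    # L solves N = L N_R exactly (rows of N lie in the span of N_R)
    L = N @ np.linalg.pinv(N_R)
    L[np.abs(L) < 1e-10] = 0.0
    for k, i in enumerate(indep):
        L[i, :] = 0.0
        L[i, k] = 1.0
    return N_R, L, dependent


def control_coefficients(
    N: np.ndarray,
    E_scaled: np.ndarray,
    J: np.ndarray,
    c: np.ndarray,
    reaction_ids: Sequence[str] | None = None,
    metabolite_ids: Sequence[str] | None = None,
) -> ControlAnalysisResult:
    """Scaled flux and concentration control coefficients.

    ``N``: internal stoichiometric matrix (metabolites x reactions);
    ``E_scaled``: scaled elasticities (reactions x metabolites);
    ``J``, ``c``: reference fluxes and concentrations used for scaling.
    Reactions with |J| below the scale floor are excluded from the
    scaled output (their scaled coefficients are undefined).
    """
    m, n = N.shape
    if E_scaled.shape != (n, m):
        raise ValueError(f"elasticity matrix must be {n}x{m}")
    rxns = list(reaction_ids) if reaction_ids else [f"R{i}" for i in range(n)]
    mets = (list(metabolite_ids) if metabolite_ids
            else [f"M{j}" for j in range(m)])
    if np.any(c <= 0):
        raise ValueError("reference concentrations must be positive")
    J_safe = np.where(np.abs(J) < FLUX_SCALE_FLOOR, 1.0, J)
    dvdc = (J_safe[:, None] * E_scaled) / c[None, :]
    N_R, L, _ = link_decomposition(N)
    M = N_R @ dvdc @ L
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularJacobianError(
            f"reduced Jacobian is singular (condition number {cond:.3g}); "
            "the steady state is structurally unstable")
    CSu = -L @ np.linalg.solve(M, N_R)
    CJu = np.eye(n) + dvdc @ CSu
    keep = np.abs(J) >= FLUX_SCALE_FLOOR
    excluded = [rxns[i] for i in range(n) if not keep[i]]
    CJ = np.diag(1.0 / J_safe) @ CJu @ np.diag(J_safe)
    CS = np.diag(1.0 / c) @ CSu @ np.diag(J_safe)
    CJ_df = pd.DataFrame(CJ, index=rxns, columns=rxns)
    CS_df = pd.DataFrame(CS, index=mets, columns=rxns)
    if excluded:
        CJ_df = CJ_df.drop(index=excluded, columns=excluded)
        CS_df = CS_df.drop(columns=excluded)
    return ControlAnalysisResult(
        C_J=CJ_df, C_S=CS_df,
        reference_fluxes=dict(zip(rxns, map(float, J))),
        reference_concentrations=dict(zip(mets, map(float, c))),
        excluded_fluxes=excluded,
    )


def control_from_state(
    model: MetabolicModel,
    elasticities: ElasticityMatrix | np.ndarray,
    state: SteadyState,
    enzymes: Sequence[str] | None = None,
) -> ControlAnalysisResult:
    """Convenience wrapper: control coefficients at a steady state.

    Uses the model's internal metabolites and excludes boundary feed
    reactions (their fluxes are imposed, not enzyme-catalysed).
    """
    N, mets, cols = stoichiometric_matrix(model, internal_only=True)
    rxns = [r for r in cols if r not in FEED_REACTIONS]
    keep = [cols.index(r) for r in rxns]
    N_sub = N[:, keep]
    if isinstance(elasticities, ElasticityMatrix):
        E = elasticities.matrix(mets, reactions=rxns)
    else:
        E = np.asarray(elasticities)
    J = np.array([state.rates[r] for r in rxns])
    c = np.array([state.concentrations[m] for m in mets])
    return control_coefficients(N_sub, E, J, c,
                                reaction_ids=rxns, metabolite_ids=mets)


# ---------------------------------------------------------------------------
# Monte Carlo propagation
# ---------------------------------------------------------------------------

def _resample_state(state: SteadyState, cv: float,
                    rng: np.random.Generator) -> SteadyState:
    """Truncated-normal (at zero) resampling of a state's observables."""

    def draw(value: float) -> float:
        if value == 0.0:
            return 0.0
        sd = abs(value) * cv
        for _ in range(100):
            x = rng.normal(value, sd)
            if x * np.sign(value) > 0:
                return float(x)
        return float(value)

    return SteadyState(
        label=state.label,
        concentrations={k: draw(v) for k, v in state.concentrations.items()},
        rates={k: draw(v) for k, v in state.rates.items()},
        is_reference=state.is_reference,
    )


def monte_carlo_mca(
    dataset: SyntheticDataset,
    model: MetabolicModel,
    eq_class: Mapping[str, str],
    dGr: Mapping[str, float],
    n_iter: int = 10_000,
    noise_cv: float = 0.10,
    seed: int = 0,
    regularization: float = 1e-3,
    percentiles: tuple[float, float] = (2.5, 97.5),
    max_drop_fraction: float = 0.5,
) -> MonteCarloSummary:
    """Monte Carlo uncertainty of the control coefficients.

    Each iteration resamples every measured concentration and rate from a
    normal distribution truncated at zero (CV ``noise_cv``), reconciles
    the resampled reference fluxes onto N v = 0, re-assembles the
    elasticity matrix and recomputes the control coefficients.
    Iterations with singular Jacobians or failed regressions are dropped
    and counted; more than ``max_drop_fraction`` dropped raises.  A small
    ridge penalty (default 1e-3) keeps the per-iterate lin-log estimator
    well-posed: without it, rank-deficient effector designs acquire
    noise-dominated null-space components that swamp the summaries.
    """
    rng = np.random.default_rng(seed)
    point = _mca_once(dataset, model, eq_class, dGr, regularization)
    rxns = list(point.C_J.index)
    mets = list(point.C_S.index)
    cj_samples, cs_samples = [], []
    dropped = 0
    for _ in range(n_iter):
        try:
            noisy = SyntheticDataset(
                reference=_resample_state(dataset.reference, noise_cv, rng),
                perturbations=[_resample_state(s, noise_cv, rng)
                               for s in dataset.perturbations],
                noise_cv=noise_cv, seed=-1, ground_truth=dataset.ground_truth)
            res = _mca_once(noisy, model, eq_class, dGr, regularization)
            cj_samples.append(res.C_J.reindex(index=rxns, columns=rxns)
                              .to_numpy())
            cs_samples.append(res.C_S.reindex(index=mets, columns=rxns)
                              .to_numpy())
        except (SingularJacobianError, ValueError, KeyError,
                np.linalg.LinAlgError):
            dropped += 1
    if n_iter > 0 and dropped > max_drop_fraction * n_iter:
        raise RuntimeError(
            f"Monte Carlo unstable: {dropped}/{n_iter} iterations dropped")
    cj = np.array(cj_samples)
    cs = np.array(cs_samples)
    lo_p, hi_p = percentiles
    med_cj = np.median(cj, axis=0)
    sign_stab = np.mean(np.sign(cj) == np.sign(med_cj)[None, :, :], axis=0)
    # entries whose median is exactly zero count as fully sign-stable
    sign_stab[med_cj == 0] = 1.0

    def df(a, index, cols):
        return pd.DataFrame(a, index=index, columns=cols)

    return MonteCarloSummary(
        median_C_J=df(med_cj, rxns, rxns),
        lo_C_J=df(np.percentile(cj, lo_p, axis=0), rxns, rxns),
        hi_C_J=df(np.percentile(cj, hi_p, axis=0), rxns, rxns),
        sign_stability_C_J=df(sign_stab, rxns, rxns),
        median_C_S=df(np.median(cs, axis=0), mets, rxns),
        lo_C_S=df(np.percentile(cs, lo_p, axis=0), mets, rxns),
        hi_C_S=df(np.percentile(cs, hi_p, axis=0), mets, rxns),
        n_iterations=n_iter,
        n_dropped=dropped,
        seed=seed,
        point_estimate=point,
    )


def _mca_once(
    dataset: SyntheticDataset,
    model: MetabolicModel,
    eq_class: Mapping[str, str],
    dGr: Mapping[str, float],
    regularization: float,
) -> ControlAnalysisResult:
    """One elasticity assembly + control-coefficient computation."""
    E = assemble_elasticity_matrix(
        model, eq_class, dataset, dGr=dGr, regularization=regularization)
    ref = dataset.reference
    # reconcile the (resampled) reference rates onto the steady-state
    # manifold of the enzymatic (feed-free) network, so the summation
    # theorems hold exactly per iterate; the perturbation feeds are off
    # at the reference state and must not absorb measurement noise
    sub = MetabolicModel(
        list(model.metabolites),
        [r for r in model.reactions if r.id not in FEED_REACTIONS],
        name=model.name)
    recon = fit_fluxes(sub, {k: v for k, v in ref.rates.items()
                             if k not in FEED_REACTIONS},
                       state_label=ref.label)
    rates = dict(ref.rates)
    rates.update(recon.fluxes)
    for rid in FEED_REACTIONS:
        if rid in rates and rid != "GLCfeed":
            rates[rid] = 0.0
    state = SteadyState(label=ref.label,
                        concentrations=ref.concentrations,
                        rates=rates,
                        is_reference=True)
    return control_from_state(model, E, state)


def control_pattern_report(
    result: ControlAnalysisResult | MonteCarloSummary,
    target_flux: str = "YdeD",
    pseudo_reactions: Sequence[str] = ("NADH5", "ATPS", "BIOMASS", "GDH",
                                       "ACEex"),
) -> pd.DataFrame:
    """Enzymes ranked by signed control over a target flux.

    Default target is the cysteine export step.  Ties are broken by
    enzyme id; lumped pseudo-reactions are flagged.
    """
    if isinstance(result, MonteCarloSummary):
        cj = result.median_C_J
    else:
        cj = result.C_J
    if target_flux not in cj.index:
        raise KeyError(f"unknown target flux {target_flux!r}")
    row = cj.loc[target_flux]
    tbl = pd.DataFrame({
        "enzyme": row.index,
        "C_J": row.to_numpy(),
        "pseudo": [e in pseudo_reactions for e in row.index],
    })
    tbl = tbl.sort_values(["C_J", "enzyme"],
                          ascending=[False, True]).reset_index(drop=True)
    return tbl
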