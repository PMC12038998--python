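"""Constraint-based flux estimation on the reduced model.

Flux balance analysis (FBA) and flux variability analysis (FVA) are linear
programs over N v = 0 with flux bounds; the loopless variant excludes
thermodynamically infeasible internal cycles with the standard
binary/potential formulation.  Thermodynamics-based flux analysis (TFA)
couples each reaction's direction to the sign of its Gibbs reaction
energy

    dG_r = dG0' + R T sum_j s_j ln c_j

through binary use-variables, and reports ranges for fluxes, Gibbs
energies and log-concentrations.  All programs are solved with the HiGHS
LP/MILP solvers.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import LinearConstraint, linprog
from scipy.optimize import milp as _scipy_milp
from scipy.optimize import Bounds as OptBounds


@contextlib.contextmanager
def _quiet_native_output():
    """Mute the C-level stdout/stderr chatter of the bundled MILP solver."""
    try:
        saved = [os.dup(fd) for fd in (1, 2)]
    except OSError:
        yield
        return
    try:
        with open(os.devnull, "wb") as devnull:
            for fd in (1, 2):
                os.dup2(devnull.fileno(), fd)
        yield
    finally:
        try:
            import ctypes
            ctypes.CDLL(None).fflush(None)   # drain C stdio buffers
        except OSError:
            pass
        for fd, s in zip((1, 2), saved):
            os.dup2(s, fd)
            os.close(s)


def milp(*args, **kwargs):
    with _quiet_native_output():
        return _scipy_milp(*args, **kwargs)

from .constants import DEFAULT_TEMPERATURE, EQ_THRESHOLD, R_KJ
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FluxDistribution",
    "ThermoAnnotation",
    "ConcentrationBounds",
    "InfeasibleError",
    "fba",
    "fva",
    "fit_fluxes",
    "delta_g_reaction",
    "tfa",
    "classify_equilibrium",
]

#: Strictness margin for the direction-energy coupling, kJ mol^-1.
DG_EPSILON = 1e-3
#: Big-M constant for the TFA indicator constraints, kJ mol^-1.
DG_BIG_M = 1000.0


class InfeasibleError(RuntimeError):
    """The (MI)LP has no feasible point under the given constraints."""


@dataclass
class FluxDistribution:
    """Point flux estimate (and optional ranges) for one metabolic state."""

    state_label: str
    fluxes: dict[str, float]
    objective_value: float | None = None
    ranges: dict[str, tuple[float, float]] | None = None

    def as_array(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


@dataclass
class ThermoAnnotation:
    """Gibbs-energy annotation and equilibrium class per reaction."""

    dG0: dict[str, float]
    dGr_range: dict[str, tuple[float, float]]
    eq_class: dict[str, str] = field(default_factory=dict)

    def representative(self, rxn_id: str) -> float:
        lo, hi = self.dGr_range[rxn_id]
        return 0.5 * (lo + hi)


@dataclass
class ConcentrationBounds:
    """Metabolite concentration bounds in mM (water excluded from TFA)."""

    bounds: dict[str, tuple[float, float]]
    temperature: float = DEFAULT_TEMPERATURE
    #: default range for unmeasured metabolites, mM (10 nM .. 50 mM)
    default: tuple[float, float] = (1e-2, 50.0)

    def __post_init__(self) -> None:
        for met, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid bounds for {met!r}: ({lo}, {hi})")

    def ln_molar(self, met: str) -> tuple[float, float]:
        lo, hi = self.bounds.get(met, self.default)
        return float(np.log(lo * 1e-3)), float(np.log(hi * 1e-3))

    @classmethod
    def from_measurement(
        cls, concentrations: Mapping[str, float], rel_sd: float = 0.2, **kw
    ) -> "ConcentrationBounds":
        """Measured metabolome narrows the bounds to +- 1 SD."""
        return cls({m: (c * (1 - rel_sd), c * (1 + rel_sd))
                    for m, c in concentrations.items() if c > 0}, **kw)


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------

def _bounds_vector(
    model: MetabolicModel,
    rate_constraints: Mapping[str, tuple[float, float] | float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    ids = model.reaction_ids
    for rid, bnd in (rate_constraints or {}).items():
        i = ids.index(rid)
        if np.isscalar(bnd):
            lb[i] = ub[i] = float(bnd)
        else:
            lo, hi = bnd
            lb[i], ub[i] = float(lo), float(hi)
    if np.any(lb > ub):
        bad = [ids[i] for i in np.where(lb > ub)[0]]
        raise InfeasibleError(f"conflicting bounds (lb > ub) for {bad}")
    return lb, ub


def fba(
    model: MetabolicModel,
    objective_reaction: str,
    rate_constraints: Mapping[str, tuple[float, float] | float] | None = None,
    maximize: bool = True,
    state_label: str = "state",
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction's flux.

    Solves max (or min) v_obj subject to N v = 0 over internal
    metabolites, the model's flux bounds, and any measured-rate
    constraints (scalar = equality, pair = band).
    """
    N, _, cols = stoichiometric_matrix(model, internal_only=True)
    i_obj = cols.index(objective_reaction)
    lb, ub = _bounds_vector(model, rate_constraints)
    c = np.zeros(len(cols))
    c[i_obj] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=N, b_eq=np.zeros(N.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        raise InfeasibleError(
            f"FBA infeasible for state {state_label!r}: the steady-state "
            "balances cannot be met within the given rate constraints")
    if res.status == 3:
        raise InfeasibleError(
            f"FBA unbounded for objective {objective_reaction!r}")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(cols, map(float, res.x)))
    return FluxDistribution(state_label=state_label, fluxes=fluxes,
                            objective_value=float(fluxes[objective_reaction]))


def _internal_cycle_basis(model: MetabolicModel) -> tuple[list[int], np.ndarray]:
    """Columns of purely internal reactions and a basis of their cycles."""
    N, rows, cols = stoichiometric_matrix(model, internal_only=True)
    internal_mets = set(rows)
    # boundary/exchange steps (one-sided or touching external species)
    # cannot be part of a thermodynamically infeasible internal cycle
    cand = [i for i, rxn in enumerate(model.reactions)
            if set(rxn.stoichiometry) <= internal_mets
            and rxn.reactants and rxn.products]
    if not cand:
        return [], np.empty((0, 0))
    K = scipy.linalg.null_space(N[:, cand])
    return cand, K.T      # rows of K span the internal cycles


def fva(
    model: MetabolicModel,
    objective_reaction: str,
    fraction: float = 0.999,
    rate_constraints: Mapping[str, tuple[float, float] | float] | None = None,
    loopless: bool = False,
    reactions: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability at a fraction of the FBA optimum.

    Per reaction, the minimum and maximum flux subject to the objective
    reaching ``fraction`` x the FBA optimum.  With ``loopless`` the
    solutions are additionally required to carry no internal
    thermodynamically infeasible cycle (binary/potential MILP).
    """
    opt = fba(model, objective_reaction, rate_constraints).objective_value
    N, _, cols = stoichiometric_matrix(model, internal_only=True)
    lb, ub = _bounds_vector(model, rate_constraints)
    i_obj = cols.index(objective_reaction)
    lb = lb.copy()
    lb[i_obj] = max(lb[i_obj], fraction * opt)
    targets = list(reactions) if reactions else list(cols)

    cand, K = ([], np.empty((0, 0)))
    if loopless:
        cand, K = _internal_cycle_basis(model)
        loopless = len(cand) > 0 and K.shape[0] > 0

    out: dict[str, tuple[float, float]] = {}
    n = len(cols)
    for rid in targets:
        i = cols.index(rid)
        vals = []
        for sense in (+1.0, -1.0):
            if not loopless:
                c = np.zeros(n)
                c[i] = sense
                res = linprog(c, A_eq=N, b_eq=np.zeros(N.shape[0]),
                              bounds=list(zip(lb, ub)), method="highs")
                if res.status == 2:
                    raise InfeasibleError(
                        f"FVA infeasible at fraction {fraction}")
                vals.append(float(res.x[i]))
            else:
                vals.append(_loopless_extreme(N, lb, ub, i, sense, cand, K))
        out[rid] = (min(vals), max(vals))
    return out


def _loopless_extreme(N, lb, ub, i_target, sense, cand, K) -> float:
    """MILP extreme of one flux under the loopless condition."""
    n = N.shape[1]
    k = len(cand)
    big_m = float(max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0))
    kg = 1000.0
    # variables: v (n), a (k, binary), G (k)
    nv = n + 2 * k
    c = np.zeros(nv)
    c[i_target] = sense
    A, lo, hi = [], [], []

    def row(vals: dict[int, float]):
        r = np.zeros(nv)
        for j, val in vals.items():
            r[j] = val
        return r

    for r_ix in range(N.shape[0]):
        A.append(row({j: N[r_ix, j] for j in range(n) if N[r_ix, j] != 0}))
        lo.append(0.0)
        hi.append(0.0)
    for kk, j in enumerate(cand):
        a_ix, g_ix = n + kk, n + k + kk
        # -M (1 - a) <= v_j <= M a   (direction indicator)
        A.append(row({j: 1.0, a_ix: -big_m}))
        lo.append(-big_m)
        hi.append(0.0)
        # a = 1 -> G <= -1 ; a = 0 -> G >= 1   (combined two-sided row)
        A.append(row({g_ix: 1.0, a_ix: kg + 1.0}))
        lo.append(1.0)
        hi.append(kg)
    # cycle-orthogonality: K G = 0
    for krow in K:
        A.append(row({n + k + kk: krow[kk] for kk in range(k)
                      if abs(krow[kk]) > 1e-12}))
        lo.append(0.0)
        hi.append(0.0)

    lower = np.concatenate([lb, np.zeros(k), -kg * np.ones(k)])
    upper = np.concatenate([ub, np.ones(k), kg * np.ones(k)])
    integrality = np.concatenate(
        [np.zeros(n), np.ones(k), np.zeros(k)])
    res = milp(c, constraints=LinearConstraint(np.array(A), lo, hi),
               bounds=OptBounds(lower, upper), integrality=integrality)
    if res.status != 0 or res.x is None:
        raise InfeasibleError("loopless FVA MILP infeasible")
    return float(res.x[i_target])


def fit_fluxes(
    model: MetabolicModel,
    measured: Mapping[str, float],
    sd: Mapping[str, float] | float = 1.0,
    state_label: str = "state",
) -> FluxDistribution:
    """Reconcile measured rates onto the steady-state manifold.

    Weighted least squares projection of the measured flux vector onto
    N v = 0 (null-space parameterization).  Noise-free consistent input
    is returned unchanged; noisy measurements are minimally adjusted.
    """
    N, _, cols = stoichiometric_matrix(model, internal_only=True)
    Z = scipy.linalg.null_space(N)
    m = np.array([measured.get(r, 0.0) for r in cols])
    observed = np.array([r in measured for r in cols])
    if np.isscalar(sd):
        w = np.where(observed, 1.0 / float(sd), 1e-3)
    else:
        w = np.array([1.0 / sd.get(r, 1e3) for r in cols])
    y, *_ = np.linalg.lstsq(w[:, None] * Z, w * m, rcond=None)
    v = Z @ y
    return FluxDistribution(state_label=state_label,
                            fluxes=dict(zip(cols, map(float, v))))


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def delta_g_reaction(
    dG0: float,
    stoichiometry: Mapping[str, float],
    ln_concentrations: Mapping[str, float],
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Gibbs reaction energy dG_r = dG0' + R T sum s_j ln c_j (kJ mol^-1).

    ``ln_concentrations`` are natural logs of molar concentrations; water
    is omitted (activity 1).
    """
    q = 0.0
    for met, coef in stoichiometry.items():
        if met == "H2O":
            continue
        if met not in ln_concentrations:
            raise KeyError(f"no concentration for metabolite {met!r}")
        q += coef * ln_concentrations[met]
    return float(dG0 + R_KJ * T * q)


def classify_equilibrium(
    dGr: float | None, threshold: float = EQ_THRESHOLD
) -> str:
    """near / far / unclassified by distance from equilibrium.

    Gibbs energies in [threshold, 0] are near equilibrium (the boundary
    value itself counts as near); below the threshold is far; positive or
    missing values are unclassified.
    """
    if dGr is None or not np.isfinite(dGr) or dGr > 0:
        return "unclassified"
    return "near" if dGr >= threshold else "far"


def annotate_equilibrium(annotation: ThermoAnnotation,
                         threshold: float = EQ_THRESHOLD) -> ThermoAnnotation:
    """Fill ``eq_class`` from the representative Gibbs energy per reaction."""
    for rid in annotation.dGr_range:
        annotation.eq_class[rid] = classify_equilibrium(
            annotation.representative(rid), threshold)
    return annotation


def tfa(
    model: MetabolicModel,
    bounds: ConcentrationBounds,
    dG0: Mapping[str, float],
    rate_constraints: Mapping[str, tuple[float, float] | float] | None = None,
    compute_flux_ranges: bool = True,
    compute_lnc_ranges: bool = False,
) -> tuple[dict[str, tuple[float, float]], ThermoAnnotation,
           dict[str, tuple[float, float]]]:
    """Thermodynamics-based flux analysis.

    Mixed-integer program coupling flux directions to Gibbs-energy signs:
    any feasible solution satisfies v_i > 0 => dG_r,i < 0 and
    v_i < 0 => dG_r,i > 0 for every reaction with a known dG0'.  Returns
    (flux ranges, ThermoAnnotation with dG_r ranges and classes, ln-
    concentration ranges).
    """
    N, _, cols = stoichiometric_matrix(model, internal_only=True)
    lb, ub = _bounds_vector(model, rate_constraints)
    n = len(cols)
    thermo = [r.id for r in model.reactions if r.id in dG0]
    mets = sorted({m for rid in thermo
                   for m in model.reaction(rid).stoichiometry
                   if m != "H2O"})
    met_ix = {m: j for j, m in enumerate(mets)}
    nm, nt = len(mets), len(thermo)
    T = bounds.temperature
    rt = R_KJ * T

    # variables: v (n) | lnc (nm) | dG (nt) | b+ (nt) | b- (nt)
    nv = n + nm + 3 * nt
    A_rows, lo, hi = [], [], []

    def row(vals: dict[int, float]):
        r = np.zeros(nv)
        for j, val in vals.items():
            r[j] = val
        return r

    for r_ix in range(N.shape[0]):
        A_rows.append(row({j: N[r_ix, j] for j in range(n)
                           if N[r_ix, j] != 0}))
        lo.append(0.0); hi.append(0.0)
    for k, rid in enumerate(thermo):
        g_ix = n + nm + k
        bp_ix = n + nm + nt + k
        bm_ix = n + nm + 2 * nt + k
        i_v = cols.index(rid)
        # dG definition: dG - RT sum s_j lnc_j = dG0
        vals = {g_ix: 1.0}
        for met, coef in model.reaction(rid).stoichiometry.items():
            if met == "H2O":
                continue
            vals[n + met_ix[met]] = vals.get(n + met_ix[met], 0.0) - rt * coef
        A_rows.append(row(vals)); lo.append(dG0[rid]); hi.append(dG0[rid])
        # direction coupling
        A_rows.append(row({i_v: 1.0, bp_ix: -max(ub[i_v], 0.0)}))
        lo.append(-np.inf); hi.append(0.0)          # v <= ub b+
        A_rows.append(row({i_v: 1.0, bm_ix: -min(lb[i_v], 0.0)}))
        lo.append(0.0); hi.append(np.inf)           # v >= lb b-
        A_rows.append(row({bp_ix: 1.0, bm_ix: 1.0}))
        lo.append(0.0); hi.append(1.0)
        # b+ = 1 -> dG <= -eps ; b- = 1 -> dG >= +eps
        A_rows.append(row({g_ix: 1.0, bp_ix: DG_BIG_M}))
        lo.append(-np.inf); hi.append(DG_BIG_M - DG_EPSILON)
        A_rows.append(row({g_ix: 1.0, bm_ix: -DG_BIG_M}))
        lo.append(-DG_BIG_M + DG_EPSILON); hi.append(np.inf)

    lnc_lo = np.array([bounds.ln_molar(m)[0] for m in mets])
    lnc_hi = np.array([bounds.ln_molar(m)[1] for m in mets])
    lower = np.concatenate([lb, lnc_lo, -DG_BIG_M * np.ones(nt),
                            np.zeros(2 * nt)])
    upper = np.concatenate([ub, lnc_hi, DG_BIG_M * np.ones(nt),
                            np.ones(2 * nt)])
    integrality = np.concatenate([np.zeros(n + nm + nt), np.ones(2 * nt)])
    constraints = LinearConstraint(np.array(A_rows), lo, hi)

    def extreme(ix: int, sense: float, what: str) -> float:
        c = np.zeros(nv)
        c[ix] = sense
        res = milp(c, constraints=constraints,
                   bounds=OptBounds(lower, upper), integrality=integrality)
        if res.status != 0 or res.x is None:
            raise InfeasibleError(
                f"TFA infeasible while bounding {what}: thermodynamic "
                "constraints conflict with the rate constraints")
        return float(res.x[ix])

    flux_ranges: dict[str, tuple[float, float]] = {}
    if compute_flux_ranges:
        for i, rid in enumerate(cols):
            flux_ranges[rid] = (extreme(i, +1.0, f"flux {rid}"),
                                extreme(i, -1.0, f"flux {rid}"))
    dgr_range = {}
    for k, rid in enumerate(thermo):
        g_ix = n + nm + k
        dgr_range[rid] = (extreme(g_ix, +1.0, f"dG {rid}"),
                          extreme(g_ix, -1.0, f"dG {rid}"))
    lnc_ranges: dict[str, tuple[float, float]] = {}
    if compute_lnc_ranges:
        for m in mets:
            j = n + met_ix[m]
            lnc_ranges[m] = (extreme(j, +1.0, f"lnc {m}"),
                             extreme(j, -1.0, f"lnc {m}"))
    ann = annotate_equilibrium(
        ThermoAnnotation(dG0=dict(dG0), dGr_range=dgr_range))
    return flux_ranges, ann, lnc_ranges
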