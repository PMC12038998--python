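"""Synthetic fed-batch L-cysteine production runs with exact mass balances.

Emulates the 15-L-scale process layout: a glucose batch phase with
exponential growth, automatic feed start on glucose depletion, dual
glucose/thiosulfate feeding, cysteine and N-acetylserine accumulation, and
off-gas trajectories.  Every time step books glucose carbon into biomass,
products and CO2 explicitly, so the generated series closes its carbon
balance by construction — the CO2 evolution rate is the carbon not fixed
in biomass or products.  This makes the series an exact oracle for the
rate and carbon-balance estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    AIR_CO2_FRACTION,
    AIR_O2_FRACTION,
    BIOMASS_CARBON_FRACTION,
    BROTH_CARBON,
    CARBON_ATOMIC_MASS,
    MOLAR_MASS,
    MOLAR_VOLUME_NORM,
)
from .rates import FedBatchTimeSeries

__all__ = ["FedBatchParams", "generate_fedbatch_series"]


@dataclass(frozen=True)
class FedBatchParams:
    """Process and strain parameters of the simulated fed-batch run.

    Defaults follow the reference process: 10 L initial volume, 10 g/L
    batch glucose, growth at 0.21 h^-1 until depletion, then feeding with
    670 g/L glucose and 320 g/L ammonium thiosulfate stocks at 32 degC.
    """

    volume0_L: float = 10.0
    biomass0_gL: float = 1.8
    batch_glucose_gL: float = 10.0
    mu_max: float = 0.21                 # 1/h, batch growth
    mu_fedbatch: float = 0.08            # 1/h, early fed-batch growth
    biomass_max_gL: float = 35.0         # stationary-phase ceiling
    yield_x_glc: float = 0.42            # g CDW per g glucose consumed
    product_carbon_efficiency: float = 0.55   # product C / glucose C in that route
    q_cys_mg: float = 24.6               # mg g^-1 h^-1 cysteine export
    q_nas_mg: float = 30.1               # mg g^-1 h^-1 OAS export (as NAS)
    q_ace_mg: float = 3.0                # mg g^-1 h^-1 acetate overflow
    maintenance_glc: float = 0.04        # g glucose per g CDW per h
    feed_glucose_gL: float = 670.0
    feed_thiosulfate_gL: float = 320.0
    thiosulfate_feed_start_h: float = 2.0    # h after inoculation
    q_tso_mg: float = 45.0               # mg g^-1 h^-1 thiosulfate uptake
    duration_h: float = 50.0
    dt_h: float = 0.02
    respiratory_quotient: float = 1.0    # CER / OUR
    gas_flow_NLmin: float = 20.0
    feed_excess: float = 1.02            # feed rate vs consumption rate


def generate_fedbatch_series(
    params: FedBatchParams | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> FedBatchTimeSeries:
    """Simulate one fed-batch run.

    With ``noise_cv = 0`` the trajectories are exact: at every sample the
    carbon fed as glucose equals the carbon in biomass, products, CO2 and
    residual glucose.  Multiplicative log-normal noise (coefficient of
    variation ``noise_cv``) can be applied to the measured concentration
    and off-gas columns; the underlying balances stay intact.
    """
    p = params or FedBatchParams()
    rng = np.random.default_rng(seed)
    n_steps = int(round(p.duration_h / p.dt_h)) + 1
    t = np.arange(n_steps) * p.dt_h

    V = p.volume0_L
    X = p.biomass0_gL * V            # g
    S = p.batch_glucose_gL * V       # g glucose
    TSO = 0.0                        # g thiosulfate
    cys = np.float64(0.0)            # g
    nas = np.float64(0.0)
    ace = np.float64(0.0)
    co2_mol = 0.0                    # cumulative mol CO2 (bookkeeping)
    feed_started = False
    feed_start_time = np.nan

    mC = {k: BROTH_CARBON[k] / MOLAR_MASS[k] for k in ("glucose", "cysteine",
                                                       "NAS", "acetate")}
    cols = {k: np.zeros(n_steps) for k in (
        "volume_L", "biomass_gL", "glucose_gL", "thiosulfate_gL",
        "cysteine_gL", "NAS_gL", "acetate_gL",
        "feed_glucose_Lh", "feed_thiosulfate_Lh",
        "offgas_O2", "offgas_CO2", "gas_flow_NLmin",
        "cer_mmol_L_h", "our_mmol_L_h")}

    for k in range(n_steps):
        # feed rates for the step ahead
        if feed_started:
            mu = p.mu_fedbatch if X / V < p.biomass_max_gL else 0.0
            q_cys, q_nas, q_ace = p.q_cys_mg, p.q_nas_mg, p.q_ace_mg
        else:
            mu = p.mu_max
            q_cys, q_ace = 0.0, 0.0
            q_nas = p.q_nas_mg * 0.3      # constitutive OAS export
        dX = mu * X                                 # g/h
        dcys = q_cys * 1e-3 * X                     # g/h
        dnas = q_nas * 1e-3 * X
        dace = q_ace * 1e-3 * X
        # glucose demand: growth + maintenance + the product routes (the
        # latter at a fixed carbon efficiency, the rest respired)
        prod_c = dcys * mC["cysteine"] + dnas * mC["NAS"] + dace * mC["acetate"]
        glc_cons_rate = ((mu / p.yield_x_glc + p.maintenance_glc) * X
                         + prod_c / mC["glucose"]
                         / p.product_carbon_efficiency)          # g/h
        if feed_started:
            f_glc = glc_cons_rate * p.feed_excess / p.feed_glucose_gL  # L/h
        else:
            f_glc = 0.0
        if t[k] >= p.thiosulfate_feed_start_h:
            f_tso = p.q_tso_mg * 1e-3 * X * 1.05 / p.feed_thiosulfate_gL
        else:
            f_tso = 0.0

        # gas rates from the explicit carbon bookkeeping of this step
        c_in = glc_cons_rate * mC["glucose"]        # mol C / h consumed
        c_fix = (dX * BIOMASS_CARBON_FRACTION / CARBON_ATOMIC_MASS
                 + prod_c)
        cer_mol_h = max(c_in - c_fix, 0.0)          # mol CO2 / h
        our_mol_h = cer_mol_h / p.respiratory_quotient
        cer = cer_mol_h * 1000.0 / V                # mmol L^-1 h^-1
        our = our_mol_h * 1000.0 / V

        # off-gas fractions via the inverse inert balance
        n_in = p.gas_flow_NLmin * 60.0 / MOLAR_VOLUME_NORM  # mol/h
        o2_out = n_in * AIR_O2_FRACTION - our_mol_h
        co2_out = n_in * AIR_CO2_FRACTION + cer_mol_h
        n2 = n_in * (1.0 - AIR_O2_FRACTION - AIR_CO2_FRACTION)
        n_out = n2 + o2_out + co2_out
        y_o2, y_co2 = o2_out / n_out, co2_out / n_out

        cols["volume_L"][k] = V
        cols["biomass_gL"][k] = X / V
        cols["glucose_gL"][k] = max(S, 0.0) / V
        cols["thiosulfate_gL"][k] = max(TSO, 0.0) / V
        cols["cysteine_gL"][k] = cys / V
        cols["NAS_gL"][k] = nas / V
        cols["acetate_gL"][k] = ace / V
        cols["feed_glucose_Lh"][k] = f_glc
        cols["feed_thiosulfate_Lh"][k] = f_tso
        cols["offgas_O2"][k] = y_o2
        cols["offgas_CO2"][k] = y_co2
        cols["gas_flow_NLmin"][k] = p.gas_flow_NLmin
        cols["cer_mmol_L_h"][k] = cer
        cols["our_mmol_L_h"][k] = our

        if k == n_steps - 1:
            break
        dt = p.dt_h
        S += (f_glc * p.feed_glucose_gL - glc_cons_rate) * dt
        TSO += (f_tso * p.feed_thiosulfate_gL
                - p.q_tso_mg * 1e-3 * X) * dt
        TSO = max(TSO, 0.0)
        X += dX * dt
        cys += dcys * dt
        nas += dnas * dt
        ace += dace * dt
        co2_mol += cer_mol_h * dt
        V += (f_glc + f_tso) * dt
        if not feed_started and S <= 0.0:
            # batch glucose wholly consumed: feeding starts automatically
            S = 0.0
            feed_started = True
            feed_start_time = t[k + 1]

    df = pd.DataFrame({"time_h": t, **cols})
    truth = {
        "feed_start_h": float(feed_start_time),
        "q_cys_mg": p.q_cys_mg,
        "q_nas_mg": p.q_nas_mg,
        "q_ace_mg": p.q_ace_mg,
        "cumulative_co2_mol": co2_mol,
        "mu_fedbatch": p.mu_fedbatch,
        "respiratory_quotient": p.respiratory_quotient,
    }
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noisy = ["biomass_gL", "glucose_gL", "thiosulfate_gL", "cysteine_gL",
                 "NAS_gL", "acetate_gL", "offgas_O2", "offgas_CO2"]
        for col in noisy:
            f = np.exp(rng.normal(-sigma**2 / 2.0, sigma, n_steps))
            df[col] = df[col] * f
    return FedBatchTimeSeries(
        data=df,
        feed_concentrations={"glucose": p.feed_glucose_gL,
                             "thiosulfate": p.feed_thiosulfate_gL},
        ground_truth=truth,
    )
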