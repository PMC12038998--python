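"""Bioprocess rate estimation for fed-batch time series.

Cell-specific rates are computed from total-amount (volume x concentration)
differences with explicit feed correction rather than from concentration
derivatives, because the broth volume changes during fed-batch operation:

    q = [V(t2) C(t2) - V(t1) C(t1) - fed(t1, t2)] / int_t1^t2 X V dt

with the biomass integral by the trapezoid rule over the sampled points.
Gas exchange rates come from the inert (N2) balance of the off-gas.

Exported O-acetylserine is quantified through its extracellular isomer
N-acetylserine; both have the same molar mass, so mass-based export rates
are interchangeable between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

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

__all__ = [
    "FedBatchTimeSeries",
    "SpecificRates",
    "CarbonBalance",
    "specific_rate",
    "volumetric_productivity",
    "selectivity",
    "gas_exchange_rates",
    "carbon_balance",
]


@dataclass
class FedBatchTimeSeries:
    """Tidy fed-batch trajectory.

    ``data`` columns: ``time_h``, ``volume_L``, ``biomass_gL``, one
    ``<species>_gL`` column per dissolved species, one ``feed_<species>_Lh``
    column per feed, and optionally ``offgas_O2``, ``offgas_CO2``
    (volume fractions) plus ``gas_flow_NLmin``.  ``feed_concentrations``
    maps fed species to their stock concentration in g L^-1.
    """

    data: pd.DataFrame
    feed_concentrations: Mapping[str, float] = field(default_factory=dict)
    inlet_o2: float = AIR_O2_FRACTION
    inlet_co2: float = AIR_CO2_FRACTION
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if (self.data["volume_L"] < 0).any() or (self.data["biomass_gL"] < 0).any():
            raise ValueError("volume and biomass must be non-negative")

    @property
    def species(self) -> list[str]:
        return [c[:-3] for c in self.data.columns
                if c.endswith("_gL") and c != "biomass_gL"]

    def window(self, t1: float, t2: float) -> pd.DataFrame:
        df = self.data
        return df[(df["time_h"] >= t1 - 1e-12) & (df["time_h"] <= t2 + 1e-12)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SpecificRates:
    """Cell-specific rates over an interval, mg g^-1 h^-1 (uptake < 0)."""

    interval: tuple[float, float]
    q: dict[str, float]


@dataclass
class CarbonBalance:
    """Shares of fed glucose carbon recovered per sink, in percent."""

    shares: dict[str, float]       # biomass, CO2, cysteine, NAS, ...
    unaccounted: float

    @property
    def accounted(self) -> float:
        return 100.0 - self.unaccounted


def _interval_frame(series: FedBatchTimeSeries, t1: float, t2: float) -> pd.DataFrame:
    if not t1 < t2:
        raise ValueError(f"need t1 < t2, got {t1} >= {t2}")
    df = series.window(t1, t2)
    if len(df) < 2:
        raise ValueError(
            f"fewer than 2 samples in [{t1}, {t2}] h; cannot form a rate")
    return df


def _amount_fed(series: FedBatchTimeSeries, species: str, df: pd.DataFrame) -> float:
    """Mass of a species added by its feed over the frame, in g."""
    col = f"feed_{species}_Lh"
    if col not in df.columns or species not in series.feed_concentrations:
        return 0.0
    t = df["time_h"].to_numpy()
    rate = df[col].to_numpy() * series.feed_concentrations[species]
    return float(np.trapezoid(rate, t))


def specific_rate(
    series: FedBatchTimeSeries, species: str, t1: float, t2: float
) -> float:
    """Cell-specific net production rate of a species, mg g^-1 h^-1.

    Positive values are export/production, negative uptake.  The feed
    correction is zero for species that are not fed.
    """
    df = _interval_frame(series, t1, t2)
    col = f"{species}_gL"
    if col not in df.columns:
        raise KeyError(f"no concentration column for species {species!r}")
    t = df["time_h"].to_numpy()
    amount = df["volume_L"].to_numpy() * df[col].to_numpy()
    fed = _amount_fed(series, species, df)
    xv = df["volume_L"].to_numpy() * df["biomass_gL"].to_numpy()
    biomass_hours = float(np.trapezoid(xv, t))     # g h
    return (amount[-1] - amount[0] - fed) / biomass_hours * 1000.0


def volumetric_productivity(
    series: FedBatchTimeSeries, species: str, t1: float, t2: float
) -> float:
    """Concentration change per time, g L^-1 h^-1."""
    df = _interval_frame(series, t1, t2)
    col = f"{species}_gL"
    if col not in df.columns:
        raise KeyError(f"no concentration column for species {species!r}")
    c = df[col].to_numpy()
    t = df["time_h"].to_numpy()
    return float((c[-1] - c[0]) / (t[-1] - t[0]))


def selectivity(q_product: float, q_byproduct: float) -> float:
    """Ratio of product to by-product export rate (dimensionless).

    For the cysteine process this is q_cys / q_OAS, with medium NAS
    accepted as the measured proxy for exported OAS.
    """
    if q_byproduct <= 0:
        raise ValueError(
            f"selectivity undefined for non-positive by-product rate "
            f"({q_byproduct})")
    return q_product / q_byproduct


def gas_exchange_rates(
    series: FedBatchTimeSeries, t: float
) -> tuple[float, float]:
    """(OUR, CER) in mmol L^-1 h^-1 at the sample nearest to ``t``.

    Inert-balance method: the molar air inflow follows from the norm-
    condition gas flow; the outflow from the nitrogen balance; OUR and
    CER from the O2/CO2 fraction differences.
    """
    df = series.data
    for col in ("offgas_O2", "offgas_CO2", "gas_flow_NLmin"):
        if col not in df.columns:
            raise KeyError(f"off-gas data missing: no column {col!r}")
    i = int((df["time_h"] - t).abs().idxmin())
    row = df.loc[i]
    n_in = row["gas_flow_NLmin"] * 60.0 / MOLAR_VOLUME_NORM * 1000.0  # mmol/h
    y_o2_in, y_co2_in = series.inlet_o2, series.inlet_co2
    y_n2_in = 1.0 - y_o2_in - y_co2_in
    y_o2, y_co2 = row["offgas_O2"], row["offgas_CO2"]
    y_n2 = 1.0 - y_o2 - y_co2
    n_out = n_in * y_n2_in / y_n2
    V = row["volume_L"]
    our = (n_in * y_o2_in - n_out * y_o2) / V
    cer = (n_out * y_co2 - n_in * y_co2_in) / V
    return float(our), float(cer)


def _cumulative_co2_mol(series: FedBatchTimeSeries) -> float:
    """Total CO2 evolved over the series, mol, by trapezoid of CER * V."""
    df = series.data
    t = df["time_h"].to_numpy()
    n_in = df["gas_flow_NLmin"].to_numpy() * 60.0 / MOLAR_VOLUME_NORM * 1e3
    y_n2_in = 1.0 - series.inlet_o2 - series.inlet_co2
    y_o2 = df["offgas_O2"].to_numpy()
    y_co2 = df["offgas_CO2"].to_numpy()
    n_out = n_in * y_n2_in / (1.0 - y_o2 - y_co2)
    cer_v = n_out * y_co2 - n_in * series.inlet_co2     # mmol/h, whole broth
    return float(np.trapezoid(cer_v, t)) / 1000.0


def carbon_balance(
    series: FedBatchTimeSeries,
    carbon_map: Mapping[str, int] | None = None,
    biomass_carbon_fraction: float = BIOMASS_CARBON_FRACTION,
) -> CarbonBalance:
    """Carbon molar balance over the whole series, as percent of the
    carbon fed as glucose (initial batch charge plus feed).

    Sinks: biomass, CO2 (from off-gas), each carbon-bearing dissolved
    species (net of its initial amount), and residual glucose left in the
    broth.  The unaccounted share closes the balance to 100%.
    """
    cmap = dict(BROTH_CARBON)
    if carbon_map:
        cmap.update(carbon_map)
    df = series.data
    first, last = df.iloc[0], df.iloc[-1]

    fed_glucose_g = _amount_fed(series, "glucose", df)
    initial_glucose_g = first["volume_L"] * first.get("glucose_gL", 0.0)
    total_in_molC = (fed_glucose_g + initial_glucose_g) / MOLAR_MASS["glucose"] * 6
    if total_in_molC <= 0:
        raise ValueError("no glucose carbon supplied; balance undefined")

    shares: dict[str, float] = {}
    d_biomass_g = last["volume_L"] * last["biomass_gL"] - \
        first["volume_L"] * first["biomass_gL"]
    shares["biomass"] = (d_biomass_g * biomass_carbon_fraction
                         / CARBON_ATOMIC_MASS) / total_in_molC * 100.0
    if "offgas_CO2" in df.columns:
        shares["CO2"] = _cumulative_co2_mol(series) / total_in_molC * 100.0
    for sp in series.species:
        if sp == "glucose":
            continue
        n_c = cmap.get(sp)
        if n_c is None:
            raise KeyError(f"no carbon annotation for species {sp!r}")
        if n_c == 0:
            continue
        if sp not in MOLAR_MASS:
            raise KeyError(f"no molar mass for species {sp!r}")
        delta_g = (last["volume_L"] * last[f"{sp}_gL"]
                   - first["volume_L"] * first[f"{sp}_gL"])
        delta_g -= _amount_fed(series, sp, df)
        shares[sp] = delta_g / MOLAR_MASS[sp] * n_c / total_in_molC * 100.0
    residual_glc = (last["volume_L"] * last.get("glucose_gL", 0.0)
                    - 0.0) / MOLAR_MASS["glucose"] * 6
    shares["residual_glucose"] = residual_glc / total_in_molC * 100.0
    unaccounted = 100.0 - sum(shares.values())
    return CarbonBalance(shares=shares, unaccounted=float(unaccounted))
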