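"""Physical constants and shared defaults."""

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Default cultivation temperature (32 degC), K.
DEFAULT_TEMPERATURE = 305.15

#: Equilibrium classification threshold, kJ mol^-1.  Reactions with a Gibbs
#: reaction energy in [EQ_THRESHOLD, 0] are "near" equilibrium, below it "far".
EQ_THRESHOLD = -10.0

#: Fraction of the FBA optimum retained during FVA range computation.
DEFAULT_FVA_FRACTION = 0.999

#: Default Monte Carlo iteration count for control-coefficient uncertainty.
DEFAULT_MC_ITERATIONS = 10_000

#: Molar volume of an ideal gas at norm conditions (0 degC, 1 atm), L mol^-1.
MOLAR_VOLUME_NORM = 22.414

#: Biomass carbon content, g carbon per g cell dry weight (CH1.77O0.49N0.24).
BIOMASS_CARBON_FRACTION = 0.474

#: Carbon moles per gram biomass use this atomic mass, g mol^-1.
CARBON_ATOMIC_MASS = 12.011

#: Molar masses of broth species tracked by the bioprocess calculators, g mol^-1.
MOLAR_MASS = {
    "glucose": 180.156,
    "cysteine": 121.158,
    "NAS": 147.129,
    "OAS": 147.129,
    "acetate": 60.052,
    "thiosulfate": 112.13,
    "CO2": 44.009,
}

#: Carbon atoms per molecule for the broth species above.
BROTH_CARBON = {
    "glucose": 6,
    "cysteine": 3,
    "NAS": 5,
    "OAS": 5,
    "acetate": 2,
    "thiosulfate": 0,
    "CO2": 1,
}

#: Composition of dry pressurised air used in off-gas balancing.
AIR_O2_FRACTION = 0.2095
AIR_CO2_FRACTION = 0.0004
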