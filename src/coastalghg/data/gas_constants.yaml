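# Gas-specific physical constants used by coastalghg.
#
# Solubility coefficient sets follow the Bunsen/volumetric fits of
# Wiesenburg & Guinasso (1979, J. Chem. Eng. Data 24) for CH4 and
# Weiss (1974, Mar. Chem. 2) for CO2.  Each set parameterises
#   ln(sol) = A1 + A2*(100/T) + A3*ln(T/100) + S*[B1 + B2*(T/100) + B3*(T/100)^2]
# with T in kelvin and S in PSU.  `solubility_form` records what the fit
# returns natively: the dimensionless Bunsen coefficient (CH4) or the
# volumetric solubility K0 in mol L^-1 atm^-1 (CO2); the library converts
# both to the common {beta, K0 [mol m^-3 atm^-1]} contract.
#
# Schmidt-number polynomials Sc(t) = a + b*t + c*t^2 + d*t^3 + e*t^4
# (t in deg C) are the fresh-water (S = 0) and sea-water (S = 35) fits of
# Wanninkhof (2014, Limnol. Oceanogr. Methods 12), valid -2..40 deg C.
#
# sgwp_100 is the sustained-flux global warming potential over a 100-year
# horizon on a mass basis (Neubauer & Megonigal 2015): a continuously
# emitted gram of CH4 exerts 45 times the radiative forcing of a gram of
# CO2 over that horizon.
schema_version: 1
gases:
  CO2:
    molar_mass: 44.01            # g mol^-1
    sgwp_100: 1.0
    solubility_form: k0_mol_per_l_atm
    solubility_constants:
      A1: -58.0931
      A2: 90.5069
      A3: 22.2940
      B1: 0.027766
      B2: -0.025888
      B3: 0.0050578
    solubility_valid_celsius: [-1.0, 40.0]
    sc_coefficients_fresh: [1923.6, -125.06, 4.3773, -0.085681, 0.00070284]
    sc_coefficients_sea: [2116.8, -136.25, 4.7353, -0.092307, 0.0007555]
    sc_valid_celsius: [-2.0, 40.0]
  CH4:
    molar_mass: 16.04            # g mol^-1
    sgwp_100: 45.0
    solubility_form: bunsen
    solubility_constants:
      A1: -68.8862
      A2: 101.4956
      A3: 28.7314
      B1: -0.076146
      B2: 0.043970
      B3: -0.0068672
    solubility_valid_celsius: [-2.0, 30.0]
    sc_coefficients_fresh: [1909.4, -120.78, 4.1555, -0.080578, 0.00065777]
    sc_coefficients_sea: [2101.2, -131.54, 4.4931, -0.08676, 0.00070663]
    sc_valid_celsius: [-2.0, 40.0]
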