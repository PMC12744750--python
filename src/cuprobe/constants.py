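"""Reference constants.

Probe constants are *conditional* equilibrium constants (pH 7, ~0.1 M ionic
strength); they are defaults, intended to be overridden from configuration
when a different literature calibration is preferred.
"""

#: Cumulative formation constant of Cu(BCA)2, M^-2 (log10 = 17.2; Xiao et al.
#: 2011, J. Biol. Chem. 286:11047). BCA binds Cu(I) as a 2:1 BCA:Cu complex.
BCA_BETA2: float = 10.0**17.2

#: Molar extinction coefficient of the Cu(BCA)2 complex at 358 nm, M^-1 cm^-1.
BCA_EPSILON_358: float = 42_900.0

#: Wavelength (nm) at which Cu(BCA)2 formation is followed.
BCA_WAVELENGTH_NM: float = 358.0

#: Cumulative formation constant of the Cu(I):PLS2 complex, M^-2
#: (competition against excess BCA; POLARIS peptide of Arabidopsis).
PLS_BETA2: float = 3.79e19

#: Cu(I) dissociation constant of the Arabidopsis copper chaperone ATX1, M.
#: ATX1 binds Cu(I) 1:1; its K_D calibrates cytosolic Cu(I) availability.
ATX1_KD: float = 5.47e-18

#: Residue contributions to the 280 nm extinction coefficient, M^-1 cm^-1
#: (Pace et al. 1995 convention: Tyr 1490, Trp 5500, cystine 125).
EPSILON_280_TYR: float = 1490.0
EPSILON_280_TRP: float = 5500.0
EPSILON_280_CYSTINE: float = 125.0

#: A280-to-concentration calibration factor determined for synthetic PLS by
#: quantitative amino-acid analysis.
PLS_A280_CALIBRATION: float = 2.27
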