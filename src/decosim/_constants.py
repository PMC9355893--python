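"""Physical constants (CODATA, 6 significant figures)."""

PLANCK_JS = 6.62607e-34
ELECTRON_MASS_KG = 9.10938e-31
ELEMENTARY_CHARGE_C = 1.60218e-19
SPEED_OF_LIGHT_MS = 2.99792e8

# electron rest energy in eV, m c^2 / e
ELECTRON_REST_ENERGY_EV = (
    ELECTRON_MASS_KG * SPEED_OF_LIGHT_MS**2 / ELEMENTARY_CHARGE_C
)
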