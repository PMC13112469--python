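"""Physical constants and unit conversions (internal units: Å, e, kJ/mol)."""

import scipy.constants as _sc

#: Coulomb constant e^2 N_A / (4 pi eps_0), in kJ mol^-1 Å e^-2.
#: Energy of two unit charges 1 Å apart in vacuum: 1389.35 kJ/mol.
COULOMB_KJ_MOL_ANG = (
    _sc.e**2 * _sc.Avogadro / (4.0 * _sc.pi * _sc.epsilon_0 * 1e-10) / 1000.0
)

#: thermochemical calorie -> kJ
CAL_TO_KJ = _sc.calorie / 1000.0

#: Default temperature, K
TEMPERATURE_K = 298.15

#: Water probe radius for solvent-accessible surface, Å
DEFAULT_PROBE_RADIUS = 1.4

#: Interfacial tension coefficient for the non-polar binding term,
#: cal mol^-1 Å^-2 (converted to kJ internally).
DEFAULT_GAMMA_CAL = 5.0

#: Solvent / solute relative permittivities for the two-dielectric model
#: (water 78; the polyphenolic solute 3.0, in the polyimide/polypropylene range).
DEFAULT_EPS_SOLVENT = 78.0
DEFAULT_EPS_SOLUTE = 3.0
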