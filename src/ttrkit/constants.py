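"""Physical constants and shared defaults.

All energies in kcal/mol, concentrations in molar, temperatures in kelvin,
volumes in liters, distances in angstroms unless a name says otherwise.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Default temperature (25 degC), the temperature of the titrations.
T_STANDARD: float = 298.15

#: Heavy-atom donor-acceptor distance cutoff for hydrogen bonds (angstrom).
HBOND_CUTOFF: float = 3.0

#: Relaxed cutoff for halogen (Cl...X) contacts (angstrom).
CL_CONTACT_CUTOFF: float = 3.5
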