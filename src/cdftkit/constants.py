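"""Physical constants and package-wide defaults."""

#: Conversion factor between hartree and electron-volt.
HARTREE_TO_EV = 27.2114

#: HOMO energy of tetracyanoethylene (hartree), the reference zero of the
#: empirical nucleophilicity scale N = E_HOMO - E_HOMO(TCE).
TCE_HOMO_HARTREE = -0.34586

#: Standard temperature (K) for thermochemistry.
DEFAULT_TEMPERATURE_K = 298.15

#: Electrophilicity difference below which a dipole/dipolarophile pair is
#: treated as reacting through a polar one-step mechanism (eV).
DEFAULT_POLARITY_THRESHOLD_EV = 4.5

#: (low, high) cutoffs on the electrophilicity index omega (eV) separating
#: marginal / moderate / strong electrophiles on the standard scale.
DEFAULT_ELECTROPHILE_CUTOFFS = (0.80, 1.50)

#: Default tolerance on the Fukui sum rules sum(f+) = sum(f-) = 1.
FUKUI_SUM_TOL = 0.02

#: Tolerance (e) on supersystem neutrality when evaluating GEDT.
GEDT_NEUTRALITY_TOL = 0.01
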