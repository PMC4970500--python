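"""Physical constants used throughout the simulator (SI units, CODATA)."""

import scipy.constants as _sc

#: Planck constant times speed of light, J m
HC = _sc.h * _sc.c

#: elementary charge, C (converts eV to J)
EV = _sc.e

#: Thomson scattering length (classical electron radius), m
R_ELECTRON = _sc.physical_constants["classical electron radius"][0]

#: Avogadro constant, mol^-1
N_AVOGADRO = _sc.N_A
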