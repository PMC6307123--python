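"""Physical constants (CODATA-ish values, units noted per name)."""

import numpy as np

#: electron rest energy, MeV
MEC2 = 0.51099895
#: two electron rest masses — pair-production threshold, MeV
PAIR_THRESHOLD = 2.0 * MEC2
#: classical electron radius, cm
RE = 2.8179403262e-13
#: Thomson cross section, cm^2
SIGMA_THOMSON = 8.0 * np.pi / 3.0 * RE**2
#: Avogadro constant, 1/mol
NA = 6.02214076e23
#: MeV per gray-gram (1 MeV/g = 1.602e-10 Gy)
MEV_PER_G_TO_GY = 1.602176634e-10
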