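"""Regenerate the synthetic per-element physics tables shipped with mcdose.

The package needs, per element, photoelectric and pair-production cross
sections and electron collision/radiative mass stopping powers on a common
energy grid.  These tables are *synthetic*: they are computed from standard
analytic approximations rather than taken from an evaluated data library,
which is adequate for a megavoltage engine whose dominant photon channel
(Compton) is treated analytically:

* collision stopping power: Bethe formula for electrons with ICRU mean
  excitation energies, no density-effect correction;
* radiative stopping power: (T + m_e c^2) / X0 with the PDG radiation length;
* photoelectric: Born-approximation Z^5 scaling, non-relativistic
  epsilon^-7/2 branch crossing over to the high-energy 1/epsilon tail;
* pair production: Bethe-Heitler complete-screening asymptote
  (7/9) * A / (X0 * N_A) with a cubic threshold turn-on at 1.022 MeV.

Run from the repository root:  python scripts/make_element_tables.py
"""

from pathlib import Path

import numpy as np

MEC2 = 0.51099895          # electron rest energy, MeV
RE = 2.8179403262e-13      # classical electron radius, cm
SIGMA_T = 8.0 * np.pi / 3.0 * RE**2   # Thomson cross section, cm^2
ALPHA = 1.0 / 137.035999
NA = 6.02214076e23

# Z: (symbol, A [g/mol], I [eV])
ELEMENTS = {
    1: ("H", 1.008, 19.2),
    6: ("C", 12.011, 78.0),
    7: ("N", 14.007, 82.0),
    8: ("O", 15.999, 95.0),
    18: ("Ar", 39.948, 188.0),
    20: ("Ca", 40.078, 191.0),
    74: ("W", 183.84, 727.0),
}


def radiation_length(Z: int, A: float) -> float:
    """PDG approximate radiation length in g/cm^2."""
    return 716.4 * A / (Z * (Z + 1) * np.log(287.0 / np.sqrt(Z)))


def bethe_collision_sp(T, Z, A, I_ev):
    """Electron collision mass stopping power (MeV cm^2/g), Bethe formula."""
    tau = T / MEC2
    beta2 = tau * (tau + 2.0) / (tau + 1.0) ** 2
    i_ratio = I_ev * 1e-6 / MEC2
    f_minus = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (tau + 1.0) ** 2
    arg = tau**2 * (tau + 2.0) / (2.0 * i_ratio**2)
    val = 0.153536 * (Z / A) / beta2 * (np.log(arg) + f_minus)
    return np.maximum(val, 1e-3)


def radiative_sp(T, Z, A):
    return (T + MEC2) / radiation_length(Z, A)


def photoelectric_xs(E, Z):
    """Per-atom photoelectric cross section (cm^2), Born-approximation scaling."""
    eps = E / MEC2
    low = 4.0 * np.sqrt(2.0) * eps**-3.5 / (1.0 + eps) ** 2.5
    high = 1.5 / eps
    return SIGMA_T * ALPHA**4 * Z**5 * (low + high)


def pair_xs(E, Z, A):
    """Per-atom pair-production cross section (cm^2)."""
    sigma_inf = (7.0 / 9.0) * A / (radiation_length(Z, A) * NA)
    f = np.clip((E - 2.0 * MEC2) / E, 0.0, 1.0) ** 3
    return sigma_inf * f


def main() -> None:
    grid = np.geomspace(1e-3, 30.0, 90)
    out = Path(__file__).resolve().parents[1] / "src" / "mcdose" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "element_tables_synthetic.tsv"
    with path.open("w") as fh:
        fh.write("# synthetic per-element physics tables (see scripts/make_element_tables.py)\n")
        fh.write("# Z\tsymbol\tA_g_mol\tI_eV\tE_MeV\tsigma_photo_cm2\tsigma_pair_cm2"
                 "\tscol_MeVcm2_g\tsrad_MeVcm2_g\n")
        for Z, (sym, A, I_ev) in sorted(ELEMENTS.items()):
            for E in grid:
                fh.write(
                    f"{Z}\t{sym}\t{A}\t{I_ev}\t{E:.8e}\t{photoelectric_xs(E, Z):.8e}\t"
                    f"{pair_xs(E, Z, A):.8e}\t{bethe_collision_sp(E, Z, A, I_ev):.8e}\t"
                    f"{radiative_sp(E, Z, A):.8e}\n"
                )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
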